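"""End-to-end orchestration: fragments -> islands -> differential sites ->
annotation -> expression -> integration -> switch report.

Each stage logs its in/out counts so a run narrates the filtering funnel on
any dataset.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import annotate as ann
from . import diffbind, expression, integrate, islands
from .annotate import GeneAnnotation
from .config import RunConfig
from .io import (read_bed, read_chrom_sizes, read_counts, read_sample_sheet,
                 write_json, write_tsv)
from .islands import FragmentSet, PeakSet

logger = logging.getLogger(__name__)


def load_fragments(data_dir: Path, state: str, mark: str, replicate: int) -> FragmentSet:
    path = Path(data_dir) / f"{state}_{mark}_rep{replicate}.bed"
    records = read_bed(path)
    return FragmentSet.from_intervals(path.stem, state, mark, replicate,
                                      [(c, s, e) for c, s, e, *_ in
                                       ((r if len(r) == 3 else r[:3]) for r in records)])


def consensus_for_state(data_dir: Path, state: str, mark: str,
                        chrom_sizes: dict[str, int], cfg: RunConfig,
                        n_replicates: int) -> PeakSet:
    """Call islands per replicate and merge into the state consensus."""
    params = cfg.islands_ezh2 if mark == "EZH2" else cfg.islands_k27
    peaksets = []
    for rep in range(1, n_replicates + 1):
        frags = load_fragments(data_dir, state, mark, rep)
        ps = islands.call_islands_from_fragments(frags, chrom_sizes, params)
        logger.info("%s %s rep%d: %d islands", state, mark, rep, len(ps))
        peaksets.append(ps)
    consensus = islands.merge_replicates(peaksets, cfg.merge_gap_bp)
    logger.info("%s %s consensus: %d islands", state, mark, len(consensus))
    return consensus


def run_pipeline(data_dir, outdir, cfg: RunConfig,
                 n_replicates: int = 2) -> dict:
    """Run the full cascade on a dataset directory; returns the switch report.

    Expects the writer layout of ``simulate.write_dataset``: per-sample
    fragment BEDs, ``chrom.sizes``, ``annotation.bed``, ``counts.tsv``,
    ``samples.tsv``.
    """
    data_dir, outdir = Path(data_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom_sizes = read_chrom_sizes(data_dir / "chrom.sizes")
    genes = GeneAnnotation.from_bed6(read_bed(data_dir / "annotation.bed"))
    state_a, state_b = cfg.state_a, cfg.state_b

    filtered: dict[str, PeakSet] = {}
    for state in (state_a, state_b):
        ez = consensus_for_state(data_dir, state, "EZH2", chrom_sizes, cfg, n_replicates)
        k27 = consensus_for_state(data_dir, state, "H3K27me3", chrom_sizes, cfg, n_replicates)
        filtered[state] = islands.filter_cooccupancy(ez, k27, cfg.cooccupancy_min_fraction)

    sites = diffbind.site_union(filtered[state_a], filtered[state_b])
    logger.info("site union: %d sites (%d A-only, %d B-only, %d common)",
                len(sites), sum(s.origin == "A-only" for s in sites),
                sum(s.origin == "B-only" for s in sites),
                sum(s.origin == "common" for s in sites))
    frags_a = [load_fragments(data_dir, state_a, "EZH2", r) for r in range(1, n_replicates + 1)]
    frags_b = [load_fragments(data_dir, state_b, "EZH2", r) for r in range(1, n_replicates + 1)]
    sites = diffbind.classify_sites(sites, frags_a, frags_b, cfg.diff)
    write_tsv(diffbind.sites_table(sites), outdir / "differential_sites.tsv")
    write_tsv(diffbind.volcano_table(sites, cfg.diff), outdir / "volcano.tsv")

    gene_map = ann.site_gene_map(sites, genes, cfg.tss_max_dist_bp)
    write_tsv(gene_map, outdir / "site_gene_map.tsv")

    counts = read_counts(data_dir / "counts.tsv")
    sheet = read_sample_sheet(data_dir / "samples.tsv")
    tpm = expression.compute_tpm(counts, genes)

    sensitive_up: dict[str, set[str]] = {}
    for state in (state_a, state_b):
        de = expression.within_state_de(counts, sheet, state).with_tpm(tpm)
        up, _down = expression.flag_sensitive(de, cfg.de)
        sensitive_up[state] = up
        write_tsv(de.table.reset_index().rename(columns={"index": "gene"}),
                  outdir / f"de_ezh2i_{state}.tsv")

    between = expression.between_state_de(counts, sheet, state_a, state_b).with_tpm(tpm)
    write_tsv(between.table.reset_index().rename(columns={"index": "gene"}),
              outdir / "de_between_states.tsv")

    silenced = integrate.run_cascade(gene_map, "B-enriched", state_b,
                                     sensitive_up[state_b], between, cfg.de)
    derepressed = integrate.run_cascade(gene_map, "A-enriched", state_a,
                                        sensitive_up[state_a], between, cfg.de)
    for res in (silenced, derepressed):
        write_tsv(res.table.reset_index(), outdir / f"cascade_{res.state}.tsv")
    report = integrate.switch_report(silenced, derepressed, tpm, sheet)
    write_json(report, outdir / "switch_report.json")
    return report
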