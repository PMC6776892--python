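"""Synthetic study-design generator with planted, machine-readable ground truth.

Emulates the statistical structure of the study's sequencing design without
any real reads: two to three cellular states (untransformed-like ``UT``,
optional pre-neoplastic ``PN``, transformed-like ``TR``), two ChIP
replicates per state and mark, uniform background fragment coverage plus
broad enriched domains — shared and state-specific, with every EZH2 domain
nested inside a wider H3K27me3 domain — RNA counts with EZH2i-responsive
genes, state-concordant "switch" genes whose promoter domain gain/loss
matches a planted between-state expression shift, and promoter methylation
anti-correlated with inhibitor sensitivity.

All randomness flows from one root seed; child streams are derived per
(purpose, state, mark, replicate) through CRC32-keyed ``SeedSequence``
spawns, so adding a sample never perturbs existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneAnnotation
from .config import SimConfig
from .io import write_bed, write_chrom_sizes, write_counts, write_json, write_tsv
from .islands import FragmentSet

_MIN_UNIT_GAP_BP = 12_000   # keeps unrelated genes outside the 5 kb promoter window


class SizingError(ValueError):
    """The requested genes/domains do not fit in the configured genome."""


def _rng(seed: int, *tokens) -> np.random.Generator:
    """Deterministic child stream keyed by the root seed and string tokens."""
    key = [zlib.crc32(str(t).encode()) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key]))


@dataclass
class GroundTruthManifest:
    """Planted domains and genes of a synthetic run; JSON round-trippable."""

    chrom_sizes: dict[str, int]
    states: list[str]
    planted_domains: list[dict]          # chrom,start,end,mark,states,enrichment,kind,domain_id
    planted_sensitive_genes: dict[str, dict[str, float]]   # state -> {gene: log2fc}
    planted_switch_genes: dict[str, dict[str, list[dict]]] # state -> silenced/derepressed lists
    gene_annotation: list[dict]
    gene_base_mean: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "chrom_sizes": self.chrom_sizes,
            "states": self.states,
            "planted_domains": self.planted_domains,
            "planted_sensitive_genes": self.planted_sensitive_genes,
            "planted_switch_genes": self.planted_switch_genes,
            "gene_annotation": self.gene_annotation,
            "gene_base_mean": self.gene_base_mean,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthManifest":
        return cls(
            chrom_sizes={k: int(v) for k, v in d["chrom_sizes"].items()},
            states=list(d["states"]),
            planted_domains=list(d["planted_domains"]),
            planted_sensitive_genes={s: dict(g) for s, g in d["planted_sensitive_genes"].items()},
            planted_switch_genes={s: {k: list(v) for k, v in grp.items()}
                                  for s, grp in d["planted_switch_genes"].items()},
            gene_annotation=list(d["gene_annotation"]),
            gene_base_mean=dict(d["gene_base_mean"]),
        )

    def annotation(self) -> GeneAnnotation:
        return GeneAnnotation(pd.DataFrame(self.gene_annotation))

    def domains_for(self, state: str, mark: str) -> list[dict]:
        return [d for d in self.planted_domains
                if d["mark"] == mark and state in d["states"]]

    def sensitive_union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.planted_sensitive_genes.values():
            out |= set(genes)
        return out


# ---------------------------------------------------------------------------
# genome / annotation / manifest


def simulate_genome(config: SimConfig):
    """Lay out genes and planted domains; returns (chrom_sizes, annotation, manifest).

    Genes are placed non-overlapping on both strands with inter-unit gaps of
    at least 12 kb so that no unrelated gene falls inside another unit's 5 kb
    promoter window.  Every switch gene's EZH2 domain is centred on its TSS
    (distance 0) in exactly the declared states.
    """
    rng = _rng(config.seed, "genome")
    states = config.states
    state_b = states[-1]
    chrom_sizes = {f"chr{i + 1}": config.chrom_length_bp for i in range(config.n_chroms)}

    n_gained, n_lost = config.n_switch_genes
    n_switch = n_gained + n_lost
    if n_switch + config.n_sensitive_genes > config.n_genes:
        raise SizingError("n_genes too small for the planted switch and sensitive genes")

    ezh2_w = config.domain_width_bp
    unit_w_domain = ezh2_w + 2 * config.k27_margin_bp

    # unit kinds: ("common", None), ("specific", state), ("switch_gained",),
    # ("switch_lost",), ("gene", None)
    units: list[tuple[str, str | None, int]] = []
    units += [("common", None, unit_w_domain)] * config.n_common_domains
    for s in states:
        units += [("specific", s, unit_w_domain)] * config.n_state_specific_domains
    units += [("switch_gained", state_b, unit_w_domain)] * n_gained
    units += [("switch_lost", state_b, unit_w_domain)] * n_lost
    units += [("gene", None, config.gene_length_bp)] * (config.n_genes - n_switch)

    order = rng.permutation(len(units))
    units = [units[i] for i in order]
    chrom_of = rng.integers(0, config.n_chroms, size=len(units))

    placements: list[tuple[str, int, str, str | None, int]] = []  # chrom,start,kind,state,width
    for ci, chrom in enumerate(chrom_sizes):
        idx = [i for i in range(len(units)) if chrom_of[i] == ci]
        widths = [units[i][2] for i in idx]
        total = sum(widths) + (len(idx) + 1) * _MIN_UNIT_GAP_BP
        L = chrom_sizes[chrom]
        if total > L:
            raise SizingError(
                f"{chrom}: {len(idx)} units need {total} bp but chromosome is {L} bp; "
                "reduce n_genes/n_*_domains or enlarge the genome")
        slack = L - total
        extra = rng.dirichlet(np.ones(len(idx) + 1)) * slack if idx else []
        pos = _MIN_UNIT_GAP_BP
        for j, i in enumerate(idx):
            pos += int(extra[j])
            kind, st, w = units[i]
            placements.append((chrom, pos, kind, st, w))
            pos += w + _MIN_UNIT_GAP_BP

    domains: list[dict] = []
    genes: list[dict] = []
    switch_records: dict[str, list[dict]] = {"silenced": [], "derepressed": []}
    gene_counter = 0
    domain_counter = 0

    def add_domain(chrom: str, unit_start: int, domain_states: list[str], kind: str) -> int:
        nonlocal domain_counter
        ez_start = unit_start + config.k27_margin_bp
        ez_end = ez_start + ezh2_w
        domain_counter += 1
        did = domain_counter
        domains.append({"domain_id": f"dom_{did}", "chrom": chrom,
                        "start": int(ez_start), "end": int(ez_end), "mark": "EZH2",
                        "states": list(domain_states),
                        "enrichment": config.enrichment_factor, "kind": kind})
        domains.append({"domain_id": f"dom_{did}_k27", "chrom": chrom,
                        "start": int(unit_start), "end": int(unit_start + unit_w_domain),
                        "mark": "H3K27me3", "states": list(domain_states),
                        "enrichment": config.enrichment_factor, "kind": kind})
        return did

    def add_gene(chrom: str, start: int, *, tss_at: int | None = None) -> dict:
        nonlocal gene_counter
        gene_counter += 1
        name = f"gene_{gene_counter:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        gl = config.gene_length_bp
        if tss_at is None:
            g_start = start
        elif strand == "+":
            g_start = tss_at
        else:
            g_start = tss_at - gl + 1
        g_end = g_start + gl
        g_start = max(0, g_start)
        tss = g_start if strand == "+" else g_end - 1
        rec = {"gene": name, "chrom": chrom, "start": int(g_start), "end": int(g_end),
               "strand": strand, "tss": int(tss), "length_bp": int(g_end - g_start)}
        genes.append(rec)
        return rec

    for chrom, start, kind, st, w in placements:
        if kind == "gene":
            add_gene(chrom, start)
        elif kind == "common":
            add_domain(chrom, start, states, "common")
        elif kind == "specific":
            add_domain(chrom, start, [st], "specific")
        elif kind == "switch_gained":
            did = add_domain(chrom, start, [state_b], "switch_gained")
            center = start + config.k27_margin_bp + ezh2_w // 2
            rec = add_gene(chrom, start, tss_at=center)
            switch_records["silenced"].append(
                {"gene": rec["gene"], "domain_id": f"dom_{did}",
                 "bound_states": [state_b], "expression_direction": "down"})
        elif kind == "switch_lost":
            other = [s for s in states if s != state_b]
            did = add_domain(chrom, start, other, "switch_lost")
            center = start + config.k27_margin_bp + ezh2_w // 2
            rec = add_gene(chrom, start, tss_at=center)
            switch_records["derepressed"].append(
                {"gene": rec["gene"], "domain_id": f"dom_{did}",
                 "bound_states": other, "expression_direction": "up"})

    annotation = GeneAnnotation(pd.DataFrame(genes))

    # base means span ~4 orders of magnitude; planted genes forced detectable
    base = 10.0 ** rng.uniform(-1.0, 3.0, size=len(genes))
    gene_ids = [g["gene"] for g in genes]
    base_mean = dict(zip(gene_ids, base.round(4).tolist()))

    switch_gene_ids = {r["gene"] for grp in switch_records.values() for r in grp}
    regular = [g for g in gene_ids if g not in switch_gene_ids]
    rng.shuffle(regular)
    plain_sensitive = regular[: config.n_sensitive_genes]

    sensitive: dict[str, dict[str, float]] = {s: {} for s in states}
    for i, g in enumerate(plain_sensitive):
        st = states[i % len(states)]
        sensitive[st][g] = config.de_log2fc
        base_mean[g] = float(np.round(rng.uniform(50, 500), 4))
    for rec in switch_records["silenced"]:
        sensitive[state_b][rec["gene"]] = config.de_log2fc
        base_mean[rec["gene"]] = float(np.round(rng.uniform(100, 500), 4))
    for rec in switch_records["derepressed"]:
        for st in rec["bound_states"]:
            sensitive[st][rec["gene"]] = config.de_log2fc
        base_mean[rec["gene"]] = float(np.round(rng.uniform(100, 500), 4))

    manifest = GroundTruthManifest(
        chrom_sizes=chrom_sizes,
        states=states,
        planted_domains=domains,
        planted_sensitive_genes=sensitive,
        planted_switch_genes={state_b: switch_records},
        gene_annotation=genes,
        gene_base_mean=base_mean,
    )
    return chrom_sizes, annotation, manifest


# ---------------------------------------------------------------------------
# ChIP fragments


def simulate_chip_fragments(manifest: GroundTruthManifest, state: str, mark: str,
                            replicate: int, config: SimConfig) -> FragmentSet:
    """One sample's fragments from a piecewise-constant midpoint intensity.

    Background intensity is uniform; inside each planted (mark, state) domain
    it is multiplied by the domain's enrichment.  Fragment length is fixed;
    intervals are clipped to chromosome bounds.  The replicate index keys the
    random stream and jitters the library size, so replicates differ but share
    domain positions.
    """
    if state not in manifest.states:
        raise KeyError(f"unknown state {state!r}; manifest has {manifest.states}")
    if mark not in {"EZH2", "H3K27me3"}:
        raise KeyError(f"unknown mark {mark!r}")
    rng = _rng(config.seed, "chip", state, mark, replicate)
    chroms = list(manifest.chrom_sizes)
    lengths = np.array([manifest.chrom_sizes[c] for c in chroms], dtype=float)
    domains = manifest.domains_for(state, mark)

    lib_target = config.resolved_library_size()
    jitter = 1.0 + rng.uniform(-config.library_jitter, config.library_jitter)
    n_frags = int(round(lib_target * jitter))
    sample_id = f"{state}_{mark}_rep{replicate}"
    if n_frags == 0:
        return FragmentSet.from_intervals(sample_id, state, mark, replicate, [])

    # weight components: per-chromosome background + per-domain excess
    comp_weights = list(lengths)
    comp_info: list[tuple[str, float, float]] = [(c, 0.0, float(l))
                                                 for c, l in zip(chroms, lengths)]
    for d in domains:
        comp_weights.append((d["end"] - d["start"]) * (d["enrichment"] - 1.0))
        comp_info.append((d["chrom"], float(d["start"]), float(d["end"])))
    w = np.asarray(comp_weights, dtype=float)
    comp = rng.choice(len(w), size=n_frags, p=w / w.sum())
    u = rng.random(n_frags)
    flen = config.fragment_length_bp
    half = flen // 2
    intervals = []
    for ci, ui in zip(comp, u):
        chrom, lo, hi = comp_info[ci]
        mid = int(lo + ui * (hi - lo))
        start = max(0, mid - half)
        end = min(manifest.chrom_sizes[chrom], start + flen)
        start = max(0, min(start, end - 1))
        intervals.append((chrom, start, end))
    return FragmentSet.from_intervals(sample_id, state, mark, replicate, intervals)


# ---------------------------------------------------------------------------
# RNA-seq counts


def default_sample_sheet(config: SimConfig) -> pd.DataFrame:
    """states x {vehicle, EZH2i} x rna_replicates sample sheet."""
    rows = []
    for state in config.states:
        for treatment in ("vehicle", "EZH2i"):
            for rep in range(1, config.rna_replicates + 1):
                rows.append({"sample": f"{state}_{treatment}_rep{rep}",
                             "state": state, "treatment": treatment, "replicate": rep})
    return pd.DataFrame(rows)


def simulate_rnaseq_counts(manifest: GroundTruthManifest, design: pd.DataFrame,
                           config: SimConfig) -> pd.DataFrame:
    """Genes x samples NB counts implementing the planted effects.

    Planted EZH2i-sensitive genes are multiplied by ``2**de_log2fc`` in
    inhibitor-treated samples of their state; switch genes carry a
    ``2**-switch_log2fc`` repression in every state where their promoter
    domain is present; per-sample library-size factors jitter by
    ``rna_size_factor_jitter``.
    """
    bad = set(design["treatment"]) - {"vehicle", "EZH2i"}
    if bad:
        raise ValueError(f"unknown treatment labels {sorted(bad)}")
    bad_states = set(design["state"]) - set(manifest.states)
    if bad_states:
        raise ValueError(f"states not in manifest: {sorted(bad_states)}")
    genes = [g["gene"] for g in manifest.gene_annotation]
    base = np.array([manifest.gene_base_mean[g] for g in genes])

    # per-state repression factor for switch genes (bound => repressed)
    repression = {s: np.ones(len(genes)) for s in manifest.states}
    gene_index = {g: i for i, g in enumerate(genes)}
    for grp in manifest.planted_switch_genes.values():
        for rec in grp["silenced"] + grp["derepressed"]:
            for st in rec["bound_states"]:
                repression[st][gene_index[rec["gene"]]] = 2.0 ** (-config.switch_log2fc)
    ezh2i_boost = {s: np.ones(len(genes)) for s in manifest.states}
    for st, gmap in manifest.planted_sensitive_genes.items():
        for g, lfc in gmap.items():
            ezh2i_boost[st][gene_index[g]] = 2.0 ** lfc

    alpha = config.nb_dispersion
    cols = {}
    for row in design.itertuples():
        rng = _rng(config.seed, "rna", row.state, row.treatment, row.replicate)
        sf = 1.0 + rng.uniform(-config.rna_size_factor_jitter,
                               config.rna_size_factor_jitter)
        mu = base * repression[row.state] * sf
        if row.treatment == "EZH2i":
            mu = mu * ezh2i_boost[row.state]
        if alpha > 0:
            r = 1.0 / alpha
            p = r / (r + mu)
            cols[row.sample] = rng.negative_binomial(r, p)
        else:
            cols[row.sample] = rng.poisson(mu)
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))


# ---------------------------------------------------------------------------
# methylation


def simulate_methylation(manifest: GroundTruthManifest, config: SimConfig,
                         clone_genes: list[str] | None = None,
                         n_clones: int = 10, n_cpgs: int = 20):
    """Promoter methylation fractions plus clone matrices for selected genes.

    Sensitive genes draw from the low-methylation Beta, insensitive genes from
    the high one; clone-matrix entries are Bernoulli draws at the gene's
    planted fraction.  Returns (methylation DataFrame, {gene: clones x CpGs
    int array}).
    """
    rng = _rng(config.seed, "methylation")
    (a_lo, b_lo), (a_hi, b_hi) = config.methylation_beta_params
    sensitive = manifest.sensitive_union()
    genes = [g["gene"] for g in manifest.gene_annotation]
    rows = []
    fractions: dict[str, float] = {}
    for g in genes:
        if g in sensitive:
            f = rng.beta(a_lo, b_lo)
            label = "sensitive"
        else:
            f = rng.beta(a_hi, b_hi)
            label = "insensitive"
        fractions[g] = float(f)
        rows.append({"gene": g, "promoter_methylation": float(f), "set": label})
    meth = pd.DataFrame(rows)

    clone_matrices: dict[str, np.ndarray] = {}
    if clone_genes:
        for g in clone_genes:
            if g not in fractions:
                raise KeyError(f"unknown gene {g!r}")
            crng = _rng(config.seed, "clones", g)
            clone_matrices[g] = (crng.random((n_clones, n_cpgs)) < fractions[g]).astype(int)
    return meth, clone_matrices


# ---------------------------------------------------------------------------
# dataset writer


def write_dataset(config: SimConfig, outdir,
                  extra_ezh2_replicates: int = 0) -> GroundTruthManifest:
    """Emit a full synthetic dataset under ``outdir``.

    Files: ``chrom.sizes``, ``annotation.bed`` (BED6),
    ``{state}_{mark}_rep{i}.bed`` (BED3), ``counts.tsv`` + ``samples.tsv``,
    ``methylation.tsv`` and ``manifest.json``; coordinates 0-based half-open.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom_sizes, annotation, manifest = simulate_genome(config)
    write_chrom_sizes(chrom_sizes, outdir / "chrom.sizes")
    write_bed(annotation.to_bed6(), outdir / "annotation.bed")
    for state in config.states:
        for mark in ("EZH2", "H3K27me3"):
            n_reps = config.replicates_per_mark
            if mark == "EZH2":
                n_reps += extra_ezh2_replicates
            for rep in range(1, n_reps + 1):
                fs = simulate_chip_fragments(manifest, state, mark, rep, config)
                write_bed(fs.intervals(), outdir / f"{state}_{mark}_rep{rep}.bed")
    design = default_sample_sheet(config)
    counts = simulate_rnaseq_counts(manifest, design, config)
    write_counts(counts, outdir / "counts.tsv")
    write_tsv(design, outdir / "samples.tsv")
    meth, _ = simulate_methylation(manifest, config)
    write_tsv(meth, outdir / "methylation.tsv")
    write_json(manifest.to_dict(), outdir / "manifest.json")
    return manifest
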