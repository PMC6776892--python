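"""Peak-to-gene annotation and genomic feature enrichment.

Differential binding sites are assigned to genes by proximity to the
transcription start site: all TSSs falling inside a site are recorded; if
none do, every gene at the minimal distance is recorded (exact-bp
equidistance keeps all tied genes); assignments beyond 5 kb are dropped.
Feature-class enrichment (CpG islands, lamina-associated domains) of
differential vs common sites is tested with a two-tailed Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffbind import DifferentialSite
from .stats import fisher_exact_two_tailed, hypergeom_upper_tail

logger = logging.getLogger(__name__)


@dataclass
class GeneAnnotation:
    """One TSS per gene id; strand-aware (TSS = start on '+', end-1 on '-')."""

    table: pd.DataFrame   # columns: gene, chrom, start, end, strand, tss, length_bp

    def __post_init__(self) -> None:
        required = {"gene", "chrom", "start", "end", "strand", "tss", "length_bp"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns {sorted(missing)}")
        if self.table["gene"].duplicated().any():
            raise ValueError("gene ids must be unique")

    @classmethod
    def from_bed6(cls, records, gene_length_override=None) -> "GeneAnnotation":
        """Build from BED6 tuples (chrom, start, end, name, score, strand)."""
        rows = []
        for chrom, start, end, name, _score, strand in records:
            if strand not in "+-":
                raise ValueError(f"gene {name}: strand must be + or -")
            tss = start if strand == "+" else end - 1
            rows.append({"gene": name, "chrom": chrom, "start": start, "end": end,
                         "strand": strand, "tss": tss, "length_bp": end - start})
        return cls(pd.DataFrame(rows))

    def to_bed6(self):
        for row in self.table.itertuples():
            yield (row.chrom, row.start, row.end, row.gene, 0, row.strand)

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    def lengths(self) -> pd.Series:
        return self.table.set_index("gene")["length_bp"]


@dataclass
class FeatureTrack:
    """A named set of genomic intervals (BED3), internally merged."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        merged: list[tuple[str, int, int]] = []
        for chrom, s, e in sorted(self.intervals):
            if merged and merged[-1][0] == chrom and s <= merged[-1][2]:
                merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], e))
            else:
                merged.append((chrom, s, e))
        self.intervals = merged


def annotate_site(site, genes: GeneAnnotation, max_dist_bp: int = 5_000) -> list[str]:
    """Gene ids assigned to a site by TSS proximity.

    Distance is 0 for a TSS inside ``[start, end)``; otherwise
    ``min(|tss - start|, |tss - (end - 1)|)`` from the site edges.  All
    inside-TSS genes are returned; else all genes at the minimum positive
    distance (exact-bp ties kept).  Genes farther than ``max_dist_bp`` never
    qualify.
    """
    if isinstance(site, DifferentialSite):
        chrom, start, end = site.chrom, site.start, site.end
    else:
        chrom, start, end = site
    tab = genes.table
    if len(tab) == 0:
        logger.warning("empty gene annotation: no assignment possible")
        return []
    on_chrom = tab[tab["chrom"] == chrom]
    if len(on_chrom) == 0:
        return []
    tss = on_chrom["tss"].to_numpy()
    inside = (tss >= start) & (tss < end)
    if inside.any():
        return on_chrom["gene"].to_numpy()[inside].tolist()
    dist = np.minimum(np.abs(tss - start), np.abs(tss - (end - 1)))
    dmin = dist.min()
    if dmin > max_dist_bp:
        return []
    return on_chrom["gene"].to_numpy()[dist == dmin].tolist()


def site_gene_map(sites: list[DifferentialSite], genes: GeneAnnotation,
                  max_dist_bp: int = 5_000) -> pd.DataFrame:
    """Long-format site-to-gene map with distances, for classified sites."""
    rows = []
    tab = genes.table.set_index("gene")
    for i, s in enumerate(sites):
        for g in annotate_site(s, genes, max_dist_bp):
            tss = int(tab.loc[g, "tss"])
            if s.start <= tss < s.end:
                d = 0
            else:
                d = int(min(abs(tss - s.start), abs(tss - (s.end - 1))))
            rows.append({"site_id": f"site_{i + 1}", "chrom": s.chrom,
                         "start": s.start, "end": s.end, "class": s.site_class,
                         "origin": s.origin, "gene": g, "distance_bp": d})
    return pd.DataFrame(rows, columns=["site_id", "chrom", "start", "end",
                                       "class", "origin", "gene", "distance_bp"])


def feature_overlap_table(sites_by_class: dict[str, list], track: FeatureTrack) -> pd.DataFrame:
    """Per-class (overlapping, non-overlapping) counts against a feature track.

    A site overlaps iff it shares >= 1 bp with any track interval; the two
    counts partition each class.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in track.intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    rows = []
    for cls, sites in sites_by_class.items():
        n_over = 0
        for site in sites:
            chrom, start, end = (site.chrom, site.start, site.end) \
                if isinstance(site, DifferentialSite) else site
            for a, b in by_chrom.get(chrom, ()):
                if min(b, end) > max(a, start):
                    n_over += 1
                    break
        rows.append({"class": cls, "feature": track.name,
                     "overlapping": n_over, "non_overlapping": len(sites) - n_over})
    return pd.DataFrame(rows)


def feature_enrichment_report(sites_by_class: dict[str, list],
                              track: FeatureTrack,
                              reference_class: str = "common") -> pd.DataFrame:
    """Fisher two-tailed enrichment of each differential class vs the common
    class for one feature track (the CpG-island / LAD comparisons)."""
    tab = feature_overlap_table(sites_by_class, track).set_index("class")
    ref = tab.loc[reference_class]
    rows = []
    for cls in tab.index:
        if cls == reference_class:
            continue
        t = [[int(tab.loc[cls, "overlapping"]), int(tab.loc[cls, "non_overlapping"])],
             [int(ref["overlapping"]), int(ref["non_overlapping"])]]
        odds, p = fisher_exact_two_tailed(t)
        rows.append({"class": cls, "feature": track.name,
                     "overlapping": t[0][0], "non_overlapping": t[0][1],
                     "ref_overlapping": t[1][0], "ref_non_overlapping": t[1][1],
                     "odds_ratio": odds, "p_value": p})
    return pd.DataFrame(rows)


def geneset_overlap_test(hits: set, gene_set: set, universe: set) -> tuple[int, float]:
    """Upper-tail hypergeometric overlap test between a hit list and a gene set."""
    hits, gene_set, universe = set(hits), set(gene_set), set(universe)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    overlap = len(hits & gene_set)
    p = hypergeom_upper_tail(overlap, len(hits), len(gene_set), len(universe))
    return overlap, p
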