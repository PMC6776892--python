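"""Differential EZH2 binding between cellular states.

Consensus peak sets of two states are fused into a union of binding sites
(state-unique and common), per-site tag counts are normalised to a common
sequencing depth (tags per ten million by default, replicates pooled), and
each site is tested in both directions with a Poisson enrichment test.
Sites with fold change >= 1.5 and Poisson p <= 1e-20 are called
"large-magnitude" differential sites; everything else is unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DiffParams
from .islands import FragmentSet, PeakSet
from .stats import log_poisson_sf

logger = logging.getLogger(__name__)

_LN10 = math.log(10.0)


@dataclass
class DifferentialSite:
    """A union binding site with per-state normalised counts and its class."""

    chrom: str
    start: int
    end: int
    origin: str                    # 'A-only' | 'B-only' | 'common'
    norm_count_a: float = 0.0
    norm_count_b: float = 0.0
    fold_change: float = 1.0       # pseudocounted A-over-B ratio
    log_p_a_over_b: float = 0.0    # natural log Poisson p, A as target
    log_p_b_over_a: float = 0.0
    site_class: str = "unchanged"  # 'A-enriched' | 'B-enriched' | 'unchanged'

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def site_union(peaks_a: PeakSet, peaks_b: PeakSet) -> list[DifferentialSite]:
    """Fuse two consensus PeakSets into a sorted union of binding sites.

    Islands overlapping by >= 1 bp across (or within) states are fused into a
    single spanning interval; a fused interval containing islands from both
    states is ``common``, otherwise it keeps its single-state origin.
    """
    tagged = [(isl.chrom, isl.start, isl.end, "A") for isl in peaks_a.islands]
    tagged += [(isl.chrom, isl.start, isl.end, "B") for isl in peaks_b.islands]
    tagged.sort(key=lambda t: (t[0], t[1]))
    sites: list[DifferentialSite] = []
    cur = None  # [chrom, start, end, set_of_sides]
    for chrom, start, end, side in tagged:
        if cur is not None and cur[0] == chrom and start < cur[2]:
            cur[2] = max(cur[2], end)
            cur[3].add(side)
        else:
            if cur is not None:
                sites.append(_close_site(cur))
            cur = [chrom, start, end, {side}]
    if cur is not None:
        sites.append(_close_site(cur))
    return sites


def _close_site(cur) -> DifferentialSite:
    chrom, start, end, sides = cur
    origin = "common" if len(sides) == 2 else ("A-only" if "A" in sides else "B-only")
    return DifferentialSite(chrom, start, end, origin)


def pooled_midpoints(fragment_sets: list[FragmentSet]) -> tuple[dict[str, np.ndarray], int]:
    """Sorted fragment midpoints per chromosome, pooled over replicates,
    plus the pooled library size."""
    mids: dict[str, list[np.ndarray]] = {}
    total = 0
    for fs in fragment_sets:
        total += fs.library_size
        frag = fs.fragments
        for ci, chrom in enumerate(fs.chroms):
            sel = frag["chrom"] == ci
            if sel.any():
                m = (frag["start"][sel] + frag["end"][sel]) // 2
                mids.setdefault(chrom, []).append(m)
    return {c: np.sort(np.concatenate(v)) for c, v in mids.items()}, total


def normalized_count(midpoints: dict[str, np.ndarray], library_size: int,
                     interval: tuple[str, int, int], norm_depth: float = 1e7) -> float:
    """Tags-per-``norm_depth`` count of pooled fragment midpoints in an interval."""
    if library_size <= 0:
        raise ValueError("pooled library size must be positive")
    chrom, start, end = interval
    m = midpoints.get(chrom)
    if m is None or m.size == 0:
        return 0.0
    n = int(np.searchsorted(m, end, side="left") - np.searchsorted(m, start, side="left"))
    return n * norm_depth / library_size


def poisson_diff_test(target: float, background: float,
                      params: DiffParams = DiffParams()) -> tuple[float, float]:
    """Directional Poisson enrichment test on normalised tag counts.

    fold = (target + pseudocount) / (background + pseudocount);
    p = P(X >= round(target)) under Poisson(max(background, pseudocount)).
    Returns (fold_change, natural-log p).
    """
    if target < 0 or background < 0:
        raise ValueError("normalised counts must be non-negative")
    fold = (target + params.pseudocount) / (background + params.pseudocount)
    lam = max(background, params.pseudocount)
    log_p = log_poisson_sf(int(round(target)), lam)
    return fold, float(log_p)


def classify_sites(sites: list[DifferentialSite],
                   frags_a: list[FragmentSet], frags_b: list[FragmentSet],
                   params: DiffParams = DiffParams()) -> list[DifferentialSite]:
    """Attach normalised counts, run both directional tests, classify.

    A-enriched iff fold(A over B) >= fc_min and p(A over B) <= p_max
    (inclusive thresholds); symmetric for B; ties (possible only at
    fc_min == 1) resolve to unchanged.  Classification uses the unfloored p.
    """
    mids_a, lib_a = pooled_midpoints(frags_a)
    mids_b, lib_b = pooled_midpoints(frags_b)
    log_p_max = math.log(params.p_max)
    for site in sites:
        na = normalized_count(mids_a, lib_a, site.interval, params.norm_depth)
        nb = normalized_count(mids_b, lib_b, site.interval, params.norm_depth)
        site.norm_count_a, site.norm_count_b = na, nb
        fold_ab, log_p_ab = poisson_diff_test(na, nb, params)
        fold_ba, log_p_ba = poisson_diff_test(nb, na, params)
        site.fold_change = fold_ab
        site.log_p_a_over_b = log_p_ab
        site.log_p_b_over_a = log_p_ba
        a_hit = fold_ab >= params.fc_min and log_p_ab <= log_p_max
        b_hit = fold_ba >= params.fc_min and log_p_ba <= log_p_max
        if a_hit and b_hit:          # only possible at fc_min == 1 ties
            site.site_class = "unchanged"
        elif a_hit:
            site.site_class = "A-enriched"
        elif b_hit:
            site.site_class = "B-enriched"
        else:
            site.site_class = "unchanged"
    n_a = sum(s.site_class == "A-enriched" for s in sites)
    n_b = sum(s.site_class == "B-enriched" for s in sites)
    logger.info("differential classification: %d A-enriched, %d B-enriched, %d unchanged",
                n_a, n_b, len(sites) - n_a - n_b)
    return sites


def volcano_table(sites: list[DifferentialSite],
                  params: DiffParams = DiffParams()) -> pd.DataFrame:
    """Signed volcano table: log2 fold (A over B) and -log10 p of the
    direction with the stronger signal, with p floored at
    ``display_p_floor`` for display only."""
    log_floor = math.log(params.display_p_floor)
    rows = []
    for s in sites:
        if s.norm_count_a >= s.norm_count_b:
            log_p, sign = s.log_p_a_over_b, +1.0
        else:
            log_p, sign = s.log_p_b_over_a, -1.0
        capped = max(log_p, log_floor)
        rows.append({
            "chrom": s.chrom, "start": s.start, "end": s.end, "origin": s.origin,
            "norm_count_A": s.norm_count_a, "norm_count_B": s.norm_count_b,
            "log2_fold_A_over_B": math.log2(s.fold_change),
            "neg_log10_p": -capped / _LN10,
            "signed_neg_log10_p": -sign * capped / _LN10,
            "class": s.site_class,
        })
    return pd.DataFrame(rows)


def sites_table(sites: list[DifferentialSite]) -> pd.DataFrame:
    """Classified sites as a BED6+ style DataFrame for TSV export."""
    rows = []
    for i, s in enumerate(sites):
        rows.append({
            "chrom": s.chrom, "start": s.start, "end": s.end,
            "name": f"site_{i + 1}", "score": 0, "strand": ".",
            "origin": s.origin,
            "norm_count_A": round(s.norm_count_a, 4),
            "norm_count_B": round(s.norm_count_b, 4),
            "log2_fold_A_over_B": round(math.log2(s.fold_change), 4),
            "neg_log10_p_A_over_B": round(-s.log_p_a_over_b / _LN10, 4),
            "neg_log10_p_B_over_A": round(-s.log_p_b_over_a / _LN10, 4),
            "class": s.site_class,
        })
    return pd.DataFrame(rows)


def replicate_validation(sites: list[DifferentialSite],
                         extra_replicate: PeakSet) -> dict[str, dict[str, float]]:
    """Fraction of A-/B-enriched sites overlapping (>= 1 bp) an independent
    replicate's islands; returns counts and fractions per class."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for isl in extra_replicate.islands:
        by_chrom.setdefault(isl.chrom, []).append((isl.start, isl.end))
    out = {}
    for cls in ("A-enriched", "B-enriched"):
        subset = [s for s in sites if s.site_class == cls]
        n_hit = 0
        for s in subset:
            for a, b in by_chrom.get(s.chrom, ()):
                if min(b, s.end) > max(a, s.start):
                    n_hit += 1
                    break
        out[cls] = {
            "n_sites": len(subset),
            "n_validated": n_hit,
            "fraction": (n_hit / len(subset)) if subset else 0.0,
        }
    return out
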