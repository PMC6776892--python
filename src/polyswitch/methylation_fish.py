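"""Bisulphite clone-matrix summaries, gene-set methylation comparisons, and
RNA-FISH foci scoring.

Clone matrices are per-molecule bisulphite results (clones x CpGs, 0/1 with
missing values); summaries report methylated fractions per CpG, per clone
and overall.  Promoter methylation of EZH2i-sensitive vs insensitive gene
sets is compared per cell line with a pooled-variance two-sample t-test,
Holm-corrected across the family of comparisons.  FISH foci counts are
averaged per image and banded -, +, ++, +++ at mean foci-per-nuclei cuts of
0.50 / 0.75 / 1.0; a field is positive above 0.8 foci/nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import holm_adjust


@dataclass
class CloneMatrix:
    """Binary methylation calls, clones x CpGs; NaN marks missing."""

    gene: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] < 1:
            raise ValueError("clone matrix must be 2-D with >= 1 clone")
        valid = np.isnan(m) | (m == 0) | (m == 1)
        if not valid.all():
            raise ValueError("entries must be 0, 1 or missing (NaN)")
        self.matrix = m


def clone_summary(cm: CloneMatrix) -> dict:
    """Methylated fractions per CpG, per clone, and overall.

    Fractions are methylated / non-missing; an all-missing CpG is reported as
    NaN and excluded from the overall fraction.
    """
    m = cm.matrix
    with np.errstate(invalid="ignore"):
        per_cpg = np.nanmean(m, axis=0)
        per_clone = np.nanmean(m, axis=1)
    n_valid = np.sum(~np.isnan(m))
    overall = float(np.nansum(m) / n_valid) if n_valid else float("nan")
    return {
        "gene": cm.gene,
        "per_cpg_fraction": per_cpg,
        "per_clone_fraction": per_clone,
        "overall_fraction": overall,
        "n_clones": m.shape[0],
        "n_cpgs": m.shape[1],
    }


def compare_gene_sets(meth: pd.DataFrame, sensitive: set[str], insensitive: set[str],
                      value_columns: list[str] | None = None) -> pd.DataFrame:
    """Sensitive-vs-insensitive methylation t-tests, Holm-corrected.

    ``meth`` is gene-keyed with one methylation column per comparison (cell
    line / sample); with a single ``promoter_methylation`` column one
    comparison is made.  Unpaired two-sample t with pooled variance; Holm
    step-down across the family of comparisons.
    """
    if not sensitive or not insensitive:
        raise ValueError("both gene sets must be non-empty")
    tab = meth.set_index("gene") if "gene" in meth.columns else meth
    if value_columns is None:
        value_columns = [c for c in tab.columns
                         if pd.api.types.is_numeric_dtype(tab[c])]
    if not value_columns:
        raise ValueError("no numeric methylation columns found")
    rows = []
    for col in value_columns:
        a = tab.loc[tab.index.intersection(list(sensitive)), col].dropna().to_numpy()
        b = tab.loc[tab.index.intersection(list(insensitive)), col].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"comparison {col!r}: each set needs >= 2 genes with data")
        t, p = _pooled_t(a, b)
        rows.append({"comparison": col, "n_sensitive": len(a), "n_insensitive": len(b),
                     "mean_sensitive": float(a.mean()), "mean_insensitive": float(b.mean()),
                     "t": float(t), "p_value": float(p)})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_value"].to_numpy())
    return out


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Unpaired two-sample t with pooled variance; identical degenerate
    samples (zero pooled variance, equal means) give t = 0, p = 1."""
    na, nb = len(a), len(b)
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0, 1.0
        return float(np.sign(diff)) * float("inf"), 0.0
    t = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p)


_BANDS = ((0.50, "-"), (0.75, "+"), (1.0, "++"))
_POSITIVE_FIELD_CUT = 0.8


@dataclass
class FociRecord:
    """Scored RNA-FISH record for one sample."""

    sample_id: str
    image_ratios: list[float]
    mean_ratio: float
    band: str
    positive_field_fraction: float


def band_for_mean(mean_ratio: float) -> str:
    """Total, monotone banding of the mean foci-per-nuclei ratio.

    <= 0.50 -> '-';  (0.50, 0.75] -> '+';  (0.75, 1.0] -> '++';  > 1.0 ->
    '+++'.  The printed bands ("0–0.5", "0.51–0.75", ...) leave (0.50, 0.51)
    undefined for continuous means; half-open boundaries at 0.50/0.75/1.0
    make the function total.
    """
    if mean_ratio < 0:
        raise ValueError("mean ratio cannot be negative")
    for cut, label in _BANDS:
        if mean_ratio <= cut:
            return label
    return "+++"


def score_foci(sample_id: str, images: list[tuple[float, float]]) -> FociRecord:
    """Score a sample from per-image (foci, nuclei) counts.

    The mean ratio is the mean of per-image foci/nuclei (not pooled counts);
    an image is a positive field when its ratio exceeds 0.8.
    """
    if not images:
        raise ValueError("need at least one image")
    ratios = []
    for i, (foci, nuclei) in enumerate(images, 1):
        if nuclei <= 0:
            raise ValueError(f"image {i}: nuclei count must be positive")
        if foci < 0:
            raise ValueError(f"image {i}: negative foci count")
        ratios.append(foci / nuclei)
    mean_ratio = float(np.mean(ratios))
    positive = sum(r > _POSITIVE_FIELD_CUT for r in ratios) / len(ratios)
    return FociRecord(sample_id, ratios, mean_ratio, band_for_mean(mean_ratio), positive)


def score_foci_table(df: pd.DataFrame) -> pd.DataFrame:
    """Score a foci TSV (columns sample, foci, nuclei) into a band table."""
    required = {"sample", "foci", "nuclei"}
    if missing := required - set(df.columns):
        raise ValueError(f"foci table missing columns {sorted(missing)}")
    rows = []
    for sample, grp in df.groupby("sample", sort=False):
        rec = score_foci(str(sample), list(zip(grp["foci"], grp["nuclei"])))
        rows.append({"sample": sample, "n_images": len(rec.image_ratios),
                     "mean_foci_per_nuclei": rec.mean_ratio, "band": rec.band,
                     "positive_field_fraction": rec.positive_field_fraction})
    return pd.DataFrame(rows)


def clone_matrix_from_tsv(df: pd.DataFrame, gene: str) -> CloneMatrix:
    """Build a CloneMatrix from a TSV slice (rows clones, columns CpGs)."""
    return CloneMatrix(gene, df.to_numpy(dtype=float))
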