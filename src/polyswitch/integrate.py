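"""The three-filter ChIP/RNA integration cascade and the switch report.

For the state in which EZH2 binding is enriched, candidate genes are those
annotated to a large-magnitude differential site at their promoter (within
5 kb of the TSS); the second filter keeps genes upregulated by EZH2
inhibition in that state; the third keeps genes whose between-state
expression change is concordant with the binding change — down where a
binding site is gained in the transformed-like state, up where one is lost.
Genes passing all three filters form the state-specific target list; the
switch report pairs the silenced and de-repressed panels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .config import DEThresholds
from .expression import DEResult

logger = logging.getLogger(__name__)


@dataclass
class CascadeResult:
    """Per-candidate filter flags and provenance for one enriched state.

    ``enriched_class`` is the differential-site class whose genes are the
    candidates ('A-enriched' or 'B-enriched'); the final target set is the
    genes with all three flags.
    """

    state: str
    enriched_class: str
    table: pd.DataFrame   # gene-indexed: peak ids, distance, flags, DE stats
    ambiguous_genes: list[str]

    @property
    def final_genes(self) -> list[str]:
        if len(self.table) == 0:
            return []
        mask = (self.table["has_differential_promoter_peak"]
                & self.table["ezh2i_sensitive"]
                & self.table["concordant_between_states"])
        return sorted(self.table.index[mask])


def run_cascade(site_gene_map: pd.DataFrame, enriched_class: str, state: str,
                sensitive_up: set[str], between_state: DEResult,
                thresholds: DEThresholds = DEThresholds()) -> CascadeResult:
    """Run the three filters for one direction.

    ``enriched_class`` names the differential class where binding is present
    in ``state`` ('B-enriched' for the transformed-like state, 'A-enriched'
    for the reference).  Concordance uses the between-state DE result
    (B over A): genes at B-enriched sites must be significantly down in B,
    genes at A-enriched sites significantly up in B.  Genes annotated to
    sites of both enriched classes are ambiguous and excluded.
    """
    if enriched_class not in {"A-enriched", "B-enriched"}:
        raise ValueError("enriched_class must be 'A-enriched' or 'B-enriched'")
    de = between_state.table
    if len(site_gene_map):
        unknown = set(site_gene_map["gene"]) - set(de.index)
        if unknown:
            raise ValueError(f"site-gene map names genes absent from DE result: "
                             f"{sorted(unknown)[:5]} ...")
    hits = site_gene_map[site_gene_map["class"] == enriched_class]
    other_class = "A-enriched" if enriched_class == "B-enriched" else "B-enriched"
    other_genes = set(site_gene_map.loc[site_gene_map["class"] == other_class, "gene"])
    ambiguous = sorted(set(hits["gene"]) & other_genes)
    if ambiguous:
        logger.info("cascade %s: excluding %d ambiguous genes bound in both "
                    "directions: %s", state, len(ambiguous), ambiguous)
    hits = hits[~hits["gene"].isin(ambiguous)]

    want_down = enriched_class == "B-enriched"
    rows = []
    for gene, grp in hits.groupby("gene"):
        stats = de.loc[gene]
        lfc, fdr = float(stats["log2_fc"]), float(stats["fdr"])
        max_tpm = float(stats["max_tpm"]) if "max_tpm" in stats else float("inf")
        if want_down:
            concordant = (lfc <= -thresholds.abs_log2fc_min
                          and fdr <= thresholds.fdr_max
                          and max_tpm >= thresholds.max_tpm_min)
        else:
            concordant = (lfc >= thresholds.abs_log2fc_min
                          and fdr <= thresholds.fdr_max
                          and max_tpm >= thresholds.max_tpm_min)
        rows.append({
            "gene": gene,
            "peak_ids": ",".join(grp["site_id"]),
            "min_distance_bp": int(grp["distance_bp"].min()),
            "has_differential_promoter_peak": True,
            "ezh2i_sensitive": gene in sensitive_up,
            "concordant_between_states": bool(concordant),
            "between_state_log2_fc": lfc,
            "between_state_fdr": fdr,
        })
    table = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["peak_ids", "min_distance_bp", "has_differential_promoter_peak",
                 "ezh2i_sensitive", "concordant_between_states",
                 "between_state_log2_fc", "between_state_fdr"])
    result = CascadeResult(state, enriched_class, table, ambiguous)
    logger.info("cascade %s (%s): %d candidates -> %d sensitive -> %d final",
                state, enriched_class, len(table),
                int((table["has_differential_promoter_peak"]
                     & table["ezh2i_sensitive"]).sum()) if len(table) else 0,
                len(result.final_genes))
    return result


def switch_report(result_silenced: CascadeResult, result_derepressed: CascadeResult,
                  tpm: pd.DataFrame | None = None,
                  sample_sheet: pd.DataFrame | None = None) -> dict:
    """Two-panel switch report: genes silenced in the transformed-like state
    (binding gained there) and genes de-repressed (binding lost).

    When TPM and a sample sheet are given, each panel carries row-centred
    per-state vehicle mean TPMs ready for heatmap rendering.
    """
    def panel(result: CascadeResult) -> list[dict]:
        out = []
        for gene in result.final_genes:
            row = result.table.loc[gene]
            rec = {"gene": gene, "peak_ids": row["peak_ids"],
                   "min_distance_bp": int(row["min_distance_bp"]),
                   "between_state_log2_fc": float(row["between_state_log2_fc"]),
                   "between_state_fdr": float(row["between_state_fdr"])}
            if tpm is not None and sample_sheet is not None:
                veh = sample_sheet[sample_sheet["treatment"] == "vehicle"]
                means = {st: float(tpm.loc[gene, grp["sample"]].mean())
                         for st, grp in veh.groupby("state")}
                center = sum(means.values()) / len(means)
                rec["centred_vehicle_tpm"] = {st: m - center for st, m in means.items()}
            out.append(rec)
        return out

    return {
        "silenced_in_transformed": panel(result_silenced),
        "derepressed_in_transformed": panel(result_derepressed),
        "silenced_state": result_silenced.state,
        "derepressed_reference_state": result_derepressed.state,
        "ambiguous_genes": sorted(set(result_silenced.ambiguous_genes)
                                  | set(result_derepressed.ambiguous_genes)),
    }


def plot_switch_heatmap(report: dict, path) -> None:
    """Render the report's row-centred TPM panels as a heatmap (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    rows, labels = [], []
    for panel in ("silenced_in_transformed", "derepressed_in_transformed"):
        for rec in report[panel]:
            if "centred_vehicle_tpm" in rec:
                rows.append(list(rec["centred_vehicle_tpm"].values()))
                labels.append(rec["gene"])
    if not rows:
        return
    states = list(report["silenced_in_transformed"][0]["centred_vehicle_tpm"]) \
        if report["silenced_in_transformed"] else \
        list(report["derepressed_in_transformed"][0]["centred_vehicle_tpm"])
    fig, ax = plt.subplots(figsize=(1 + len(states), 0.5 + 0.3 * len(rows)))
    im = ax.imshow(np.asarray(rows), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(len(states)), states)
    ax.set_yticks(range(len(labels)), labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="centred mean vehicle TPM")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
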