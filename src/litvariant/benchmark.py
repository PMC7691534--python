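"""Recompute database-comparison summary statistics from bundled tables.

Four fixture tables ship as package data under ``data/paper_tables/``:

* ``variant_resources.tsv`` — per-variant reference counts (total and true
  positive) for 108 clinically encountered variants across a full-text
  literature index, Google Scholar, PubMed and ClinVar;
* ``interpretation_counts.tsv`` — per-gene variant counts by clinical
  interpretation category (index vs ClinVar) for 27 genes;
* ``cnv_comparison.tsv`` — reference counts for 10 clinically relevant
  cytobands (index total/exact vs PubMed exact);
* ``fusion_comparison.tsv`` — per-pair reference counts for fusions common
  to the index and the COSMIC curated database.

All derived statistics (column totals, per-row percentages and folds,
unweighted means) are recomputed here, never read from the fixture.
Percentages and folds round half-up to one decimal uniformly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from litvariant._util import round_half_up

RESOURCES = ("mastermind", "google_scholar", "pubmed", "clinvar")

_TABLES = "litvariant.data.paper_tables"


def _read_tsv(name: str) -> pd.DataFrame:
    with resources.files(_TABLES).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_variant_resource_table() -> tuple[pd.DataFrame, int]:
    """(rows, aggregate count of references missing from the first resource)."""
    df = _read_tsv("variant_resources.tsv")
    meta = json.loads(
        resources.files(_TABLES).joinpath("variant_resources_meta.json").read_text()
    )
    return df, int(meta["references_missing_from_first_resource"])


def load_interpretation_table() -> pd.DataFrame:
    return _read_tsv("interpretation_counts.tsv")


def load_cnv_comparison_table() -> pd.DataFrame:
    return _read_tsv("cnv_comparison.tsv")


def load_fusion_comparison_table() -> tuple[pd.DataFrame, int, int]:
    """(common-pair rows, tool unique-pair count, reference unique-pair count)."""
    df = _read_tsv("fusion_comparison.tsv")
    meta = json.loads(resources.files(_TABLES).joinpath("fusion_meta.json").read_text())
    return df, int(meta["tool_unique_pairs"]), int(meta["reference_unique_pairs"])


# ---------------------------------------------------------------------------
# Variant resource metrics
# ---------------------------------------------------------------------------

@dataclass
class ResourceMetrics:
    resource: str
    total_papers: int
    total_tp: int
    mean_tp_pct: float | None       # unweighted over rows with >= 1 paper
    variant_sensitivity_pct: float  # % of rows with >= 1 TP
    reference_sensitivity_pct: float  # TPs / (first-resource TPs + missing)
    fold_vs: dict[str, float | None]  # first-resource TP / this-resource TP


def variant_resource_metrics(
    rows: pd.DataFrame, union_extra: int
) -> dict[str, ResourceMetrics]:
    """Per-resource summary metrics of the variant comparison table.

    The mean true-positive percentage averages per-row TP% over rows where
    the resource returned at least one paper (rows with zero papers have
    no defined percentage).  Reference-level sensitivity divides each
    resource's TPs by the union estimate: the first resource's TPs plus
    the aggregate count of references it missed (``union_extra``).  The
    fold column reports the first resource's TP yield against each other
    resource.  Raises on an empty table.
    """
    if rows.empty:
        raise ValueError("empty comparison table")
    if union_extra < 0:
        raise ValueError("union_extra must be >= 0")
    first_tp = int(rows[f"{RESOURCES[0]}_tp"].sum())
    union = first_tp + union_extra
    out: dict[str, ResourceMetrics] = {}
    for res in RESOURCES:
        totals = rows[f"{res}_total"]
        tps = rows[f"{res}_tp"]
        answered = totals > 0
        if answered.any():
            mean_tp = round_half_up(
                float((100.0 * tps[answered] / totals[answered]).mean())
            )
        else:
            mean_tp = None
        out[res] = ResourceMetrics(
            resource=res,
            total_papers=int(totals.sum()),
            total_tp=int(tps.sum()),
            mean_tp_pct=mean_tp,
            variant_sensitivity_pct=round_half_up(100.0 * float((tps >= 1).mean())),
            reference_sensitivity_pct=round_half_up(100.0 * tps.sum() / union),
            fold_vs={
                other: (round_half_up(first_tp / rows[f"{other}_tp"].sum())
                        if rows[f"{other}_tp"].sum() > 0 else None)
                for other in RESOURCES
                if other != res
            } if res == RESOURCES[0] else {},
        )
    return out


def resource_flags(rows: pd.DataFrame) -> dict[str, int]:
    """Per-row advantage flag counts.

    ONLY recomputes from the raw counts (the first resource alone returned
    true positives).  MORE and MISSING depend on reference *identity* —
    a resource can tie on counts yet hold different references — so they
    are read from the fixture's flag column; ``more_by_counts`` reports
    the strictly-greater-count approximation as a diagnostic.
    """
    others = [r for r in RESOURCES[1:]]
    first = rows[f"{RESOURCES[0]}_tp"]
    only = (first > 0) & (sum(rows[f"{r}_tp"] for r in others) == 0)
    more_by_counts = first > 0
    for r in others:
        more_by_counts &= first > rows[f"{r}_tp"]
    flags = rows["flags"].fillna("")
    return {
        "only": int(only.sum()),
        "more": int(flags.str.contains("MORE").sum()),
        "more_by_counts": int(more_by_counts.sum()),
        "missing": int(flags.str.contains("MISSING").sum()),
    }


# ---------------------------------------------------------------------------
# Interpretation (clinical significance) summary
# ---------------------------------------------------------------------------

def interpretation_summary(rows: pd.DataFrame) -> dict:
    """Totals, disease-causing counts and fold ratios of the 27-gene table.

    Disease-causing = pathogenic + likely pathogenic.  Overall folds use
    column totals; per-gene folds are rounded to one decimal first and then
    averaged over genes with a defined ratio (genes dividing by zero are
    excluded).
    """
    mm_total = int(rows["mm_total"].sum())
    cv_total = int(rows["cv_total"].sum())
    mm_dc = rows["mm_pathogenic"] + rows["mm_likely_pathogenic"]
    cv_dc = rows["cv_pathogenic"] + rows["cv_likely_pathogenic"]

    def _per_gene_mean(numer: pd.Series, denom: pd.Series) -> float | None:
        defined = denom > 0
        if not defined.any():
            return None
        folds = (numer[defined] / denom[defined]).map(lambda v: round_half_up(v))
        return round_half_up(float(folds.mean()))

    return {
        "mm_total": mm_total,
        "cv_total": cv_total,
        "mm_disease_causing": int(mm_dc.sum()),
        "cv_disease_causing": int(cv_dc.sum()),
        "fold_total": round_half_up(mm_total / cv_total),
        "fold_disease_causing": round_half_up(mm_dc.sum() / cv_dc.sum()),
        "mean_per_gene_fold_total": _per_gene_mean(rows["mm_total"], rows["cv_total"]),
        "mean_per_gene_fold_disease_causing": _per_gene_mean(mm_dc, cv_dc),
        "genes": len(rows),
    }


# ---------------------------------------------------------------------------
# CNV comparison summary
# ---------------------------------------------------------------------------

def cnv_comparison_summary(rows: pd.DataFrame) -> dict:
    """Min / unweighted mean / max of reference counts and fold columns.

    Per-row folds (total-vs-external and exact-vs-external) are rounded to
    one decimal before summarizing; rows with a zero external count are
    excluded from the fold summaries and flagged.
    """
    defined = rows["pubmed_refs"] > 0
    fold_total = (rows.loc[defined, "mm_total_refs"] / rows.loc[defined, "pubmed_refs"]).map(round_half_up)
    fold_exact = (rows.loc[defined, "mm_exact_refs"] / rows.loc[defined, "pubmed_refs"]).map(round_half_up)

    def mmm(series: pd.Series, as_int: bool = False) -> dict:
        mean = float(series.mean())
        return {
            "min": (int(series.min()) if as_int else float(series.min())),
            "mean": (int(round_half_up(mean, 0)) if as_int else round_half_up(mean)),
            "max": (int(series.max()) if as_int else float(series.max())),
        }

    return {
        "total_refs": mmm(rows["mm_total_refs"], as_int=True),
        "exact_refs": mmm(rows["mm_exact_refs"], as_int=True),
        "external_refs": mmm(rows["pubmed_refs"], as_int=True),
        "fold_total": mmm(fold_total),
        "fold_exact": mmm(fold_exact),
        "rows_excluded_from_folds": int((~defined).sum()),
        "rows": len(rows),
    }


# ---------------------------------------------------------------------------
# Fusion comparison summary
# ---------------------------------------------------------------------------

def fusion_comparison_summary(
    tool_pairs: int, reference_pairs: int, rows: pd.DataFrame
) -> dict:
    """Unique-pair yield increase and per-common-pair reference ratios."""
    if tool_pairs <= 0 or reference_pairs < 0:
        raise ValueError("pair counts must be positive")
    if reference_pairs == 0:
        increase = None
    else:
        increase = int(round_half_up(100.0 * (tool_pairs - reference_pairs) / reference_pairs, 0))
    ratios = (rows["mm_refs"] / rows["cosmic_refs"]).map(round_half_up)
    return {
        "yield_increase_pct": increase,
        "tool_pairs": tool_pairs,
        "reference_pairs": reference_pairs,
        "per_pair_ratios": dict(zip(rows["fusion"], ratios)),
        "mean_common_pair_ratio": round_half_up(float(ratios.mean())),
        "common_pairs": len(rows),
    }


def all_table_metrics() -> dict:
    """Every bundled-table summary in one JSON-serializable dict."""
    t2, missing = load_variant_resource_table()
    t3 = load_interpretation_table()
    t4 = load_cnv_comparison_table()
    t5, tool_pairs, ref_pairs = load_fusion_comparison_table()
    metrics = variant_resource_metrics(t2, missing)
    return {
        "variant_resources": {
            res: {
                "total_papers": m.total_papers,
                "total_tp": m.total_tp,
                "mean_tp_pct": m.mean_tp_pct,
                "variant_sensitivity_pct": m.variant_sensitivity_pct,
                "reference_sensitivity_pct": m.reference_sensitivity_pct,
                "fold_vs": m.fold_vs,
            }
            for res, m in metrics.items()
        },
        "variant_resource_flags": resource_flags(t2),
        "interpretation": interpretation_summary(t3),
        "cnv_comparison": cnv_comparison_summary(t4),
        "fusion_comparison": fusion_comparison_summary(tool_pairs, ref_pairs, t5),
    }
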