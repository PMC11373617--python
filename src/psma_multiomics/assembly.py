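"""Design-matrix assembly: join the category-tagged feature blocks and apply
the whole-dataset missingness exclusion.

The canonical schema is 203 columns: 13 clinical + 113 radiomics-wide
(107 texture/shape/histogram + 6 conventional SUV metrics) + 53 genomics
(51 pathway disruptions + TMB + CNV burden) + 23 pathomics + 1 biopsy ISUP.
Note the per-fold pipeline re-applies the missingness filter on each
training partition; the assembly-level filter exists for whole-dataset
reporting only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["OmicsFeatureTable", "assemble", "missingness_filter"]

CATEGORIES = ("clinical", "radiomics", "genomics", "pathomics", "bxISUP")


@dataclass
class OmicsFeatureTable:
    """Patients x features with per-column category tags and a label vector."""

    data: pd.DataFrame
    categories: dict[str, str]  # column name -> category
    labels: pd.Series  # binary, 1 = high risk

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("duplicate feature names in design matrix")
        unknown = set(self.categories.values()) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown feature categories: {sorted(unknown)}")
        untagged = set(self.data.columns) - set(self.categories)
        if untagged:
            raise ValueError(f"untagged features: {sorted(untagged)[:5]} ...")

    def category_columns(self, category: str) -> list[str]:
        return [c for c in self.data.columns if self.categories[c] == category]

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        out = self.data.copy()
        out["label"] = self.labels
        out.to_csv(path)
        sidecar = {"categories": self.categories}
        path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def assemble(
    clinical: pd.DataFrame,
    radiomics: pd.DataFrame,
    genomics: pd.DataFrame,
    pathomics: pd.DataFrame,
    bx_isup: pd.Series,
    labels: pd.Series,
) -> OmicsFeatureTable:
    """Join all blocks on patient id into one category-tagged table.

    Patients are those present in `labels`; a patient absent from a block
    gets missing values for that block's columns.  Duplicate patient ids or
    an empty patient set are errors.
    """
    for name, blk in [
        ("clinical", clinical),
        ("radiomics", radiomics),
        ("genomics", genomics),
        ("pathomics", pathomics),
    ]:
        if blk.index.duplicated().any():
            raise ValueError(f"duplicate patient ids in {name} block")
    if labels.index.duplicated().any():
        raise ValueError("duplicate patient ids in labels")
    index = labels.index
    if len(index) == 0:
        raise ValueError("no patients in labels")

    parts = []
    categories: dict[str, str] = {}
    for cat, blk in [
        ("clinical", clinical),
        ("radiomics", radiomics),
        ("genomics", genomics),
        ("pathomics", pathomics),
    ]:
        aligned = blk.reindex(index)
        parts.append(aligned)
        categories.update({c: cat for c in blk.columns})
    bx = bx_isup.reindex(index).astype(float).rename("bxISUP")
    parts.append(bx.to_frame())
    categories["bxISUP"] = "bxISUP"
    data = pd.concat(parts, axis=1)
    if data.dropna(how="all").empty:
        raise ValueError("empty intersection: no patient has any feature data")
    return OmicsFeatureTable(data=data, categories=categories, labels=labels.astype(int))


def missingness_filter(
    table: OmicsFeatureTable, threshold: float = 0.30
) -> tuple[OmicsFeatureTable, pd.DataFrame]:
    """Drop columns whose missing fraction strictly exceeds `threshold`.

    Returns the filtered table and an exclusion report (feature, category,
    missing_fraction, dropped).
    """
    frac = table.data.isna().mean(axis=0)
    dropped = frac[frac > threshold].index.tolist()
    report = pd.DataFrame(
        {
            "feature": frac.index,
            "category": [table.categories[c] for c in frac.index],
            "missing_fraction": frac.values,
            "dropped": [c in dropped for c in frac.index],
        }
    ).set_index("feature")
    kept = [c for c in table.data.columns if c not in dropped]
    filtered = OmicsFeatureTable(
        data=table.data[kept],
        categories={c: table.categories[c] for c in kept},
        labels=table.labels,
    )
    return filtered, report


def subset_categories(table: OmicsFeatureTable, categories: list[str]) -> OmicsFeatureTable:
    """Restrict the design matrix to the given feature categories (for
    feature-type ablation experiments)."""
    unknown = set(categories) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    cols = [c for c in table.data.columns if table.categories[c] in categories]
    if not cols:
        raise ValueError("no features left after category subsetting")
    return OmicsFeatureTable(
        data=table.data[cols],
        categories={c: table.categories[c] for c in cols},
        labels=table.labels,
    )


def cohort_design_matrix(cohort, include_tma_gleason: bool = True) -> OmicsFeatureTable:
    """Convenience: assemble the full design matrix of a synthetic cohort."""
    return assemble(
        clinical=cohort.clinical_table,
        radiomics=cohort.radiomics_table,
        genomics=cohort.genomics_features(),
        pathomics=cohort.pathomics_features(include_tma_gleason=include_tma_gleason),
        bx_isup=cohort.bx_isup,
        labels=cohort.labels,
    )
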