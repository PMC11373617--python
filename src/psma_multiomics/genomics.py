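"""Variant-to-pathway genomics features.

The chain: per-variant pathogenicity *metascore* (mean of the available
EVE / PolyPhen / cohort-normalized CADD scores), summed per gene into a
gene disruption score, summed per KEGG-style pathway into a pathway
disruption score.  Cohort-level burdens: TMB (somatic variants per Mb of
sequenced territory) and CNV burden (fraction of the sequenced territory
covered by copy-number segments).

Intervals are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "GeneSetCatalog",
    "normalize_cadd",
    "variant_metascore",
    "gene_disruption",
    "pathway_disruption",
    "compute_tmb",
    "compute_cnv_burden",
    "mutated_gene_frequency",
    "genomics_block",
]


@dataclass(frozen=True)
class VariantRecord:
    """One annotated somatic variant with up to three pathogenicity scores."""

    patient_id: str
    gene: str
    eve: float | None = None  # in [0, 1]
    cadd: float | None = None  # nonnegative, scale-free until normalized
    polyphen: float | None = None  # in [0, 1]

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")

    @property
    def scorable(self) -> bool:
        return any(s is not None and not np.isnan(s) for s in (self.eve, self.cadd, self.polyphen))


@dataclass
class GeneSetCatalog:
    """pathway_id -> set of gene symbols, with optional display names."""

    sets: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(not pid for pid in self.sets):
            raise ValueError("empty pathway id in catalog")

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCatalog":
        sets: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                pid, desc, *genes = line.split("\t")
                sets[pid] = {g for g in genes if g}
                names[pid] = desc
        return cls(sets, names)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for pid in sorted(self.sets):
                genes = "\t".join(sorted(self.sets[pid]))
                fh.write(f"{pid}\t{self.names.get(pid, pid)}\t{genes}\n")


def normalize_cadd(values: np.ndarray | list) -> np.ndarray:
    """Cohort-level min-max normalization of CADD to [0, 1].

    Missing values (NaN) pass through; a degenerate range (all values
    identical) maps everything to 0.
    """
    arr = np.asarray(values, dtype=float)
    observed = arr[~np.isnan(arr)]
    if observed.size == 0:
        raise ValueError("all CADD values missing; nothing to normalize")
    lo, hi = observed.min(), observed.max()
    if hi == lo:
        out = np.where(np.isnan(arr), np.nan, 0.0)
    else:
        out = (arr - lo) / (hi - lo)
    return out


def variant_metascore(
    eve: float | None, cadd_norm: float | None, polyphen: float | None
) -> float:
    """Unweighted mean of the available scores; CADD must be pre-normalized."""
    scores = [
        s for s in (eve, cadd_norm, polyphen) if s is not None and not np.isnan(s)
    ]
    if not scores:
        raise ValueError("variant has no pathogenicity scores; exclude it")
    return float(np.mean(scores))


def _metascore_table(variants: pd.DataFrame) -> pd.DataFrame:
    """Add a `metascore` column; unscorable variants get NaN with a warning."""
    tbl = variants.copy()
    cadd = tbl["cadd"].to_numpy(dtype=float)
    tbl["cadd_norm"] = np.nan if np.all(np.isnan(cadd)) else normalize_cadd(cadd)
    stacked = tbl[["eve", "cadd_norm", "polyphen"]].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        tbl["metascore"] = np.nanmean(stacked, axis=1)
    n_unscorable = int(tbl["metascore"].isna().sum())
    if n_unscorable:
        log.warning(
            "%d variants have no pathogenicity score and are excluded from "
            "disruption scores (still counted for TMB)",
            n_unscorable,
        )
    return tbl


def gene_disruption(variants: pd.DataFrame) -> pd.Series:
    """Per-gene disruption for ONE patient: sum of variant metascores.

    `variants` needs columns gene/eve/cadd/polyphen; CADD should already be
    cohort-normalized to [0, 1] by the caller (pass ``cadd_normalized=True``
    semantics: this helper normalizes over whatever it is given, so for
    cohort-consistent scores use :func:`genomics_block`).
    """
    if variants.empty:
        return pd.Series(dtype=float)
    tbl = _metascore_table(variants)
    return tbl.groupby("gene")["metascore"].sum(min_count=1).fillna(0.0)


def pathway_disruption(gene_scores: pd.Series, catalog: GeneSetCatalog) -> pd.Series:
    """Per-pathway disruption: sum of gene disruption over the pathway's genes.

    Genes without variants contribute 0; a gene in k pathways contributes to
    all k.
    """
    out = {}
    for pid, genes in catalog.sets.items():
        present = [g for g in genes if g in gene_scores.index]
        out[pid] = float(gene_scores.loc[present].sum()) if present else 0.0
    return pd.Series(out).sort_index()


def compute_tmb(n_variants: int, sequenced_size_bp: int) -> float:
    """Somatic variants per megabase of sequenced territory."""
    if sequenced_size_bp <= 0:
        raise ValueError("sequenced region size must be positive")
    if n_variants < 0:
        raise ValueError("variant count must be nonnegative")
    return n_variants / (sequenced_size_bp / 1e6)


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Union of 0-based half-open intervals as a sorted (m, 2) array."""
    if iv.size == 0:
        return iv.reshape(0, 2)
    iv = iv[np.argsort(iv[:, 0])]
    merged = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged)


def _intersect_unions(a: np.ndarray, b: np.ndarray) -> int:
    """Total overlap length between two merged interval sets."""
    total, i, j = 0, 0, 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            total += hi - lo
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return int(total)


def compute_cnv_burden(
    segments: np.ndarray | list, regions: np.ndarray | list
) -> float:
    """Fraction of the sequenced territory covered by CNV segments.

    Overlapping segments are merged and intersected with the union of
    sequenced regions before summing, so the ratio is guaranteed <= 1.
    Intervals are (start, end) pairs, 0-based half-open, one chromosome's
    worth or pre-offset to a common coordinate space.
    """
    regions = np.asarray(regions, dtype=np.int64).reshape(-1, 2)
    if regions.size == 0:
        raise ValueError("sequenced regions must be non-empty")
    segments = np.asarray(segments, dtype=np.int64).reshape(-1, 2)
    reg_u = _merge_intervals(regions)
    reg_len = int((reg_u[:, 1] - reg_u[:, 0]).sum())
    if reg_len == 0:
        raise ValueError("sequenced regions have zero total length")
    if segments.size == 0:
        return 0.0
    seg_u = _merge_intervals(segments)
    return _intersect_unions(seg_u, reg_u) / reg_len


def mutated_gene_frequency(variant_tables: dict[str, pd.DataFrame]) -> pd.Series:
    """Per-gene fraction of patients carrying >= 1 variant in that gene."""
    if not variant_tables:
        raise ValueError("need at least one patient")
    n = len(variant_tables)
    counts: dict[str, int] = {}
    for tbl in variant_tables.values():
        for g in set(tbl["gene"]) if len(tbl) else set():
            counts[g] = counts.get(g, 0) + 1
    return (pd.Series(counts, dtype=float) / n).sort_index()


def genomics_block(
    variant_tables: dict[str, pd.DataFrame],
    catalog: GeneSetCatalog,
    cnv_segments: dict[str, np.ndarray],
    sequenced_regions: np.ndarray,
) -> pd.DataFrame:
    """Full genomics feature block: one pathway-disruption column per pathway
    plus TMB and CNV_burden.  CADD is min-max normalized over the whole
    cohort's variants (cohort-level normalization), then metascores, gene and
    pathway sums are computed per patient.
    """
    regions = np.asarray(sequenced_regions, dtype=np.int64).reshape(-1, 2)
    reg_u = _merge_intervals(regions)
    reg_len = int((reg_u[:, 1] - reg_u[:, 0]).sum())

    # cohort-level CADD normalization: pool all variants
    pooled = pd.concat(
        [t.assign(_pid=pid) for pid, t in variant_tables.items()],
        ignore_index=True,
    ) if any(len(t) for t in variant_tables.values()) else pd.DataFrame(
        columns=["_pid", "gene", "eve", "cadd", "polyphen"]
    )
    if len(pooled):
        cadd = pooled["cadd"].to_numpy(dtype=float)
        if np.all(np.isnan(cadd)):
            pooled["cadd_norm"] = np.nan
        else:
            pooled["cadd_norm"] = normalize_cadd(cadd)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            pooled["metascore"] = np.nanmean(
                pooled[["eve", "cadd_norm", "polyphen"]].to_numpy(dtype=float), axis=1
            )

    rows = {}
    for pid in sorted(variant_tables):
        tbl = pooled[pooled["_pid"] == pid] if len(pooled) else pooled
        gene_scores = (
            tbl.dropna(subset=["metascore"]).groupby("gene")["metascore"].sum()
            if len(tbl)
            else pd.Series(dtype=float)
        )
        pw = pathway_disruption(gene_scores, catalog)
        row = {f"pathway::{pid_}": v for pid_, v in pw.items()}
        row["TMB"] = compute_tmb(len(variant_tables[pid]), reg_len)
        segs = cnv_segments.get(pid, np.empty((0, 2)))
        row["CNV_burden"] = compute_cnv_burden(segs, regions)
        rows[pid] = row
    block = pd.DataFrame.from_dict(rows, orient="index")
    cols = sorted(c for c in block.columns if c.startswith("pathway::")) + ["TMB", "CNV_burden"]
    block = block[cols]
    block.index.name = "patient"
    return block
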