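"""Synthetic multiomics prostate-cancer cohort generator.

Emulates the data structure the downstream analysis assumes: per-patient
somatic variant tables with EVE/CADD/PolyPhen annotations, CNV segments over
a fixed exome-like sequenced territory, a KEGG-style gene-set catalog, SUV
phantom volumes with spherical lesion masks, tissue-microarray IHC cores
(3 tumor + 3 normal per marker), clinical covariates with realistic
missingness, and whole-mount Gleason labels with a biopsy-grade column
derived through a configurable confusion kernel.

Labels are drawn first; features are generated conditional on the binary
high/low-risk label so that planted effects (``effect_map``, in SD units of
the feature) are interpretable and recoverable.  Directly simulated columns
(clinical, the delegated radiomics set) realize the requested effect
exactly in expectation; columns computed from raw blocks (pathway
disruption, CNV burden, H-scores, SUV metrics) plant the effect on the
underlying raw quantities, calibrated against the cohort's empirical SD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomics import GeneSetCatalog, genomics_block
from .pathomics import pathomics_block
from .radiomics import SuvVolume, VoiMask, suv_metrics

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_suv_phantom",
    "write_cohort",
]

# ---------------------------------------------------------------- schema

#: the 13 clinical covariates; (name, kind, loc, scale | n_levels, image_read)
_CLINICAL_SCHEMA: list[tuple] = [
    ("clin::age", "cont", 64.0, 7.6, False),
    ("clin::psa_serum", "cont", 11.0, 6.0, False),
    ("clin::prostate_volume", "cont", 45.0, 15.0, False),
    ("clin::psa_density", "cont", 0.25, 0.12, False),
    ("clin::bmi", "cont", 26.0, 3.5, False),
    ("clin::ct_stage", "cat", 3, None, False),
    ("clin::dre_suspicious", "cat", 2, None, False),
    ("clin::family_history", "cat", 2, None, False),
    ("clin::prior_biopsy", "cat", 2, None, False),
    ("clin::pirads", "cat", 3, None, True),
    ("clin::mri_lesion_diameter_mm", "cont", 14.0, 6.0, True),
    ("clin::adc_min", "cont", 750.0, 150.0, True),
    ("clin::mri_epe", "cat", 2, None, True),
]

_IHC_MARKERS = [
    "PSA", "PSMA", "AR", "ERG", "Ki67", "PTEN", "p53", "AMACR", "CK5", "SYP", "CHGA",
]

# delegated IBSI radiomics catalog: 107 feature names across seven families
_RAD_FAMILIES: dict[str, list[str]] = {
    "firstorder": [
        "Energy", "TotalEnergy", "Entropy", "Minimum", "Percentile10", "Percentile90",
        "Maximum", "Mean", "Median", "InterquartileRange", "Range",
        "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation", "RootMeanSquared",
        "Skewness", "Kurtosis", "Variance", "Uniformity",
    ],
    "glcm": [
        "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
        "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
        "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
        "Imc1", "Imc2", "InverseVariance", "JointEnergy", "JointEntropy", "MCC",
        "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
    ],
    "glrlm": [
        "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
        "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
        "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
        "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
        "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
        "ShortRunLowGrayLevelEmphasis",
    ],
    "glszm": [
        "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
        "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
        "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
        "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
        "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
        "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
        "ZoneEntropy", "ZonePercentage", "ZoneVariance",
    ],
    "gldm": [
        "DependenceEntropy", "DependenceNonUniformity",
        "DependenceNonUniformityNormalized", "DependenceVariance",
        "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
        "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
        "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
        "SmallDependenceLowGrayLevelEmphasis",
    ],
    "ngtdm": ["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"],
    "shape": [
        "Elongation", "Flatness", "LeastAxisLength", "MajorAxisLength",
        "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "Maximum2DDiameterSlice",
        "Maximum3DDiameter", "MeshVolume", "MinorAxisLength", "Sphericity",
        "SurfaceArea", "SurfaceVolumeRatio", "VoxelVolume",
    ],
}

DELEGATED_RADIOMICS_COLUMNS = [
    f"rad::{fam}::{name}" for fam, names in _RAD_FAMILIES.items() for name in names
]
assert len(DELEGATED_RADIOMICS_COLUMNS) == 107


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    ``effect_map`` maps a feature-table column name to a standardized effect
    size: the difference in class means (high minus low risk) in units of
    the feature's SD.  Zero / absent means the feature is label-independent.
    """

    n_patients: int = 65
    prevalence_high: float = 0.57
    n_pathways: int = 51
    n_genes: int = 300
    genes_per_pathway: int = 15
    n_markers: int = 11
    n_clinical: int = 13
    missing_rate_map: dict[str, float] = field(
        default_factory=lambda: {
            "clinical": 0.02,
            "clinical_image_read": 0.35,
            "radiomics": 0.0,
            "genomics": 0.0,
            "pathomics": 0.05,
        }
    )
    effect_map: dict[str, float] = field(default_factory=dict)
    bx_concordance: float = 0.70
    #: when False, biopsy-style grades (bxISUP, TMA Gleason) are permuted
    #: across patients, decoupling them from the label: required for a
    #: label-null cohort, since a concordance-linked biopsy grade is
    #: informative by construction.
    bx_informative: bool = True
    mean_variants_per_patient: float = 30.0
    sequenced_mb: float = 30.0
    phantom_shape: tuple[int, int, int] = (24, 24, 24)
    phantom_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_patients": self.n_patients,
            "n_pathways": self.n_pathways,
            "n_genes": self.n_genes,
            "genes_per_pathway": self.genes_per_pathway,
            "n_markers": self.n_markers,
            "n_clinical": self.n_clinical,
        }
        for name, v in counts.items():
            if int(v) < 1:
                raise ValueError(f"configuration error: {name} must be >= 1, got {v}")
        fracs = {"prevalence_high": self.prevalence_high, "bx_concordance": self.bx_concordance}
        fracs.update({f"missing_rate_map[{k}]": v for k, v in self.missing_rate_map.items()})
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"configuration error: {name}={v} outside [0, 1]")
        if self.n_markers > len(_IHC_MARKERS):
            raise ValueError(
                f"configuration error: at most {len(_IHC_MARKERS)} IHC markers supported"
            )


@dataclass
class SyntheticCohort:
    """All raw blocks plus pre-derived feature blocks for one cohort draw."""

    config: CohortConfig
    patients: list[str]
    labels: pd.Series  # binary: 1 = high risk (whole-mount ISUP >= 3)
    gs_labels: pd.DataFrame  # primary, secondary, isup, risk
    bx_isup: pd.Series
    clinical_table: pd.DataFrame
    variant_tables: dict[str, pd.DataFrame]
    cnv_segments: dict[str, np.ndarray]
    sequenced_regions: np.ndarray
    gene_set_catalog: GeneSetCatalog
    suv_volumes: dict[str, SuvVolume]
    voi_masks: dict[str, VoiMask]
    ihc_cores: pd.DataFrame
    radiomics_table: pd.DataFrame  # 6 computed SUV metrics + delegated set

    def genomics_features(self) -> pd.DataFrame:
        return genomics_block(
            self.variant_tables,
            self.gene_set_catalog,
            self.cnv_segments,
            self.sequenced_regions,
        )

    def pathomics_features(self, include_tma_gleason: bool = True) -> pd.DataFrame:
        block = pathomics_block(self.ihc_cores)
        if include_tma_gleason:
            # TMA-core Gleason grade: the biopsy-like grade read on the cores
            block["ihc::tma_gleason"] = self.gs_labels.loc[block.index, "tma_gleason"]
        return block


def generate_suv_phantom(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    lesion_center_mm: tuple[float, float, float],
    lesion_radius_mm: float,
    lesion_suv: float,
    background_suv: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[SuvVolume, VoiMask]:
    """Spherical-lesion SUV phantom: background + lesion + Gaussian noise.

    The mask marks voxels whose centers lie within `lesion_radius_mm` of the
    lesion center (mm coordinates, voxel center i at (i + 0.5) * spacing).
    """
    shape = tuple(int(s) for s in shape)
    extent = [sh * sp for sh, sp in zip(shape, spacing)]
    for c, r, e in zip(lesion_center_mm, [lesion_radius_mm] * 3, extent):
        if c - r < 0 or c + r > e:
            raise ValueError(
                f"geometry error: lesion (center {lesion_center_mm}, "
                f"radius {lesion_radius_mm} mm) does not fit inside the grid"
            )
    coords = np.meshgrid(
        *[(np.arange(n) + 0.5) * sp for n, sp in zip(shape, spacing)], indexing="ij"
    )
    dist2 = sum((c - cc) ** 2 for c, cc in zip(coords, lesion_center_mm))
    mask = dist2 <= lesion_radius_mm**2
    rng = np.random.default_rng(seed)
    data = np.full(shape, float(background_suv))
    data[mask] = lesion_suv
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=shape)
    return SuvVolume(data, tuple(spacing)), VoiMask(mask)


# ---------------------------------------------------------------- helpers


def _isup_from_binary(rng: np.random.Generator, high: np.ndarray) -> np.ndarray:
    """Whole-mount ISUP grade consistent with the binary risk label."""
    grades = np.empty(high.shape, dtype=int)
    n_hi = int(high.sum())
    grades[high] = rng.choice([3, 4, 5], size=n_hi, p=[0.5, 0.3, 0.2])
    grades[~high] = rng.choice([1, 2], size=len(high) - n_hi, p=[0.4, 0.6])
    return grades


_ISUP_TO_GS = {1: (3, 3), 2: (3, 4), 3: (4, 3), 4: (4, 4), 5: (4, 5)}


def _confuse_grade(rng: np.random.Generator, grades: np.ndarray, concordance: float) -> np.ndarray:
    """Biopsy-style grade: keep with prob `concordance`, else move one grade
    (down-grading twice as likely as up-grading, the documented biopsy bias)."""
    out = grades.copy()
    flip = rng.random(len(grades)) >= concordance
    step = np.where(rng.random(len(grades)) < 2 / 3, -1, +1)
    out[flip] = np.clip(grades[flip] + step[flip], 1, 5)
    # a "discordant" draw that clips back onto the same grade is left as-is
    return out


def _apply_missing(rng: np.random.Generator, block: pd.DataFrame, rate: float) -> pd.DataFrame:
    if rate <= 0:
        return block
    mask = rng.random(block.shape) < rate
    out = block.copy().astype(float)
    out.values[mask] = np.nan
    return out


def _clinical_schema(n_clinical: int) -> list[tuple]:
    schema = list(_CLINICAL_SCHEMA[:n_clinical])
    for i in range(len(schema), n_clinical):
        schema.append((f"clin::extra_{i:02d}", "cont", 0.0, 1.0, False))
    return schema


# ---------------------------------------------------------------- generator


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one synthetic cohort.  Deterministic for a fixed config seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    patients = [f"P{i + 1:03d}" for i in range(n)]
    effect = dict(config.effect_map)

    # ---- labels first -------------------------------------------------
    high = rng.random(n) < config.prevalence_high
    if high.all() or not high.any():
        # force both classes so stratified analyses remain defined
        high[0], high[-1] = False, True
    isup = _isup_from_binary(rng, high)
    bx = _confuse_grade(rng, isup, config.bx_concordance)
    tma = _confuse_grade(rng, isup, config.bx_concordance)
    if not config.bx_informative:
        bx = rng.permutation(bx)
        tma = rng.permutation(tma)
    gs = pd.DataFrame(
        {
            "primary": [_ISUP_TO_GS[g][0] for g in isup],
            "secondary": [_ISUP_TO_GS[g][1] for g in isup],
            "isup": isup,
            "risk": np.where(high, "high", "low"),
            "tma_gleason": tma,
        },
        index=patients,
    )
    gs.index.name = "patient"
    labels = pd.Series(high.astype(int), index=patients, name="label")
    y = high.astype(float)

    # ---- clinical ------------------------------------------------------
    schema = _clinical_schema(config.n_clinical)
    clin = {}
    image_read_cols = []
    for name, kind, a, b, img in schema:
        e = effect.get(name, 0.0)
        z = rng.normal(size=n) + e * y
        if kind == "cont":
            clin[name] = a + b * z
        else:  # integer-coded categorical with `a` levels via normal quantiles
            edges = np.quantile(np.sort(rng.normal(size=4000)), np.linspace(0, 1, a + 1)[1:-1])
            clin[name] = np.digitize(z, edges).astype(float)
        if img:
            image_read_cols.append(name)
    clinical = pd.DataFrame(clin, index=patients)
    clinical.index.name = "patient"
    rate_plain = config.missing_rate_map.get("clinical", 0.0)
    rate_img = config.missing_rate_map.get("clinical_image_read", rate_plain)
    plain_cols = [c for c in clinical.columns if c not in image_read_cols]
    clinical[plain_cols] = _apply_missing(rng, clinical[plain_cols], rate_plain)
    if image_read_cols:
        clinical[image_read_cols] = _apply_missing(rng, clinical[image_read_cols], rate_img)

    # ---- gene pool / pathway catalog ----------------------------------
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    sets = {}
    names = {}
    for p in range(config.n_pathways):
        pid = f"PW{p + 1:02d}"
        sets[pid] = set(rng.choice(genes, size=min(config.genes_per_pathway, config.n_genes), replace=False))
        names[pid] = f"synthetic pathway {p + 1}"
    catalog = GeneSetCatalog(sets, names)

    # ---- sequenced regions + variants ---------------------------------
    region_size = int(config.sequenced_mb * 1e6 / 60)
    starts = np.arange(60, dtype=np.int64) * 2 * region_size
    regions = np.stack([starts, starts + region_size], axis=1)

    gene_w = 1.0 / np.arange(1, config.n_genes + 1) ** 0.9  # recurrently mutated head
    gene_w /= gene_w.sum()
    lam = config.mean_variants_per_patient
    tmb_effect = effect.get("TMB", 0.0)
    variant_tables: dict[str, pd.DataFrame] = {}
    for pid, yy in zip(patients, y):
        lam_i = max(0.5, lam + tmb_effect * np.sqrt(lam) * yy)
        m = rng.poisson(lam_i)
        gsyms = rng.choice(genes, size=m, p=gene_w)
        eve = rng.beta(2.0, 2.0, size=m)
        polyphen = rng.beta(0.5, 0.5, size=m)
        cadd = rng.gamma(2.0, 8.0, size=m)
        for arr in (eve, polyphen, cadd):  # each score missing for ~15% of variants
            arr[rng.random(m) < 0.15] = np.nan
        variant_tables[pid] = pd.DataFrame(
            {"gene": gsyms, "eve": eve, "cadd": cadd, "polyphen": polyphen}
        )

    # ---- CNV segments --------------------------------------------------
    cnv_effect = effect.get("CNV_burden", 0.0)
    base_frac = rng.beta(2.0, 10.0, size=n) * 0.5
    frac = np.clip(base_frac + cnv_effect * base_frac.std() * y, 0.0, 0.95)
    cnv_segments: dict[str, np.ndarray] = {}
    for pid, f in zip(patients, frac):
        segs = []
        # cover a fraction f of each of a random subset of regions
        k = max(1, int(round(f * 60)))
        chosen = rng.choice(60, size=k, replace=False)
        for ridx in chosen:
            s, e = regions[ridx]
            seg_len = int((e - s) * min(1.0, f * 60 / k))
            off = rng.integers(0, max(1, (e - s) - seg_len + 1))
            segs.append((s + off, s + off + seg_len))
        cnv_segments[pid] = np.asarray(segs, dtype=np.int64)

    # ---- planted pathway-disruption effects ---------------------------
    pathway_effects = {
        k: v for k, v in effect.items() if k.startswith("pathway::") and v != 0.0
    }
    if pathway_effects:
        base = genomics_block(variant_tables, catalog, cnv_segments, regions)
        for col, e in pathway_effects.items():
            pw_id = col.split("::", 1)[1]
            if pw_id not in catalog.sets:
                raise ValueError(f"configuration error: unknown pathway {pw_id}")
            sd = float(base[col].std(ddof=0))
            sd = sd if sd > 0 else 1.0
            target = abs(e) * sd
            onto_high = e > 0  # negative effect: load the LOW class instead
            pw_genes = sorted(catalog.sets[pw_id])
            for pid, yy in zip(patients, y):
                if bool(yy) != onto_high:
                    continue
                m = max(1, int(np.ceil(target)))
                score = min(1.0, target / m)
                add = pd.DataFrame(
                    {
                        "gene": rng.choice(pw_genes, size=m),
                        "eve": np.full(m, score),
                        "cadd": np.full(m, np.nan),
                        "polyphen": np.full(m, score),
                    }
                )
                variant_tables[pid] = pd.concat(
                    [variant_tables[pid], add], ignore_index=True
                )

    # ---- SUV phantoms + computed SUV metrics ---------------------------
    suv_effect = effect.get("rad::suv::SUVmax", 0.0)
    lesion_suv = rng.lognormal(np.log(8.0), 0.35, size=n)
    lesion_suv = lesion_suv + suv_effect * lesion_suv.std() * y
    radius = rng.uniform(6.0, 10.0, size=n)
    center = tuple(
        sh * sp / 2.0 for sh, sp in zip(config.phantom_shape, config.phantom_spacing)
    )
    suv_volumes: dict[str, SuvVolume] = {}
    voi_masks: dict[str, VoiMask] = {}
    suv_rows = {}
    for i, pid in enumerate(patients):
        vol, msk = generate_suv_phantom(
            config.phantom_shape,
            config.phantom_spacing,
            center,
            float(radius[i]),
            float(max(1.5, lesion_suv[i])),
            background_suv=1.0,
            noise_sd=0.3,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        suv_volumes[pid] = vol
        voi_masks[pid] = msk
        suv_rows[pid] = {f"rad::suv::{k}": v for k, v in suv_metrics(vol, msk).items()}
    suv_block = pd.DataFrame.from_dict(suv_rows, orient="index")

    # ---- delegated radiomics columns (simulated) -----------------------
    rad_sim = {}
    for col in DELEGATED_RADIOMICS_COLUMNS:
        e = effect.get(col, 0.0)
        rad_sim[col] = rng.normal(size=n) + e * y
    rad_block = pd.concat(
        [suv_block, pd.DataFrame(rad_sim, index=patients)], axis=1
    )
    rad_block.index.name = "patient"
    rad_block = _apply_missing(rng, rad_block, config.missing_rate_map.get("radiomics", 0.0))

    # ---- IHC cores ------------------------------------------------------
    markers = _IHC_MARKERS[: config.n_markers]
    rows = []
    for marker in markers:
        e = max(
            effect.get(f"ihc::{marker}::max", 0.0),
            effect.get(f"ihc::{marker}::avg", 0.0),
            key=abs,
        )
        u = rng.normal(size=n) + e * y  # patient-level latent expression
        for pid, ui in zip(patients, u):
            for core_type, n_cores in (("tumor", 3), ("normal", 3)):
                shift = 0.0 if core_type == "tumor" else -1.0
                for c in range(n_cores):
                    v = ui + shift + rng.normal(0.0, 0.5)
                    strong = float(np.clip(30.0 + 14.0 * v, 0.0, 85.0))
                    moderate = float(np.clip(25.0 + 4.0 * v, 0.0, 100.0 - strong))
                    weak = float(
                        np.clip(20.0 + rng.normal(0, 3), 0.0, 100.0 - strong - moderate)
                    )
                    rows.append(
                        (pid, marker, f"{core_type}_{c + 1}", core_type, weak, moderate, strong)
                    )
    ihc = pd.DataFrame(
        rows,
        columns=["patient", "marker", "core_id", "core_type", "pct_weak", "pct_moderate", "pct_strong"],
    )
    # pathomics missingness: drop whole cores at the configured rate
    p_rate = config.missing_rate_map.get("pathomics", 0.0)
    if p_rate > 0:
        keep = rng.random(len(ihc)) >= p_rate
        ihc = ihc[keep].reset_index(drop=True)

    return SyntheticCohort(
        config=config,
        patients=patients,
        labels=labels,
        gs_labels=gs,
        bx_isup=pd.Series(bx, index=patients, name="bx_isup"),
        clinical_table=clinical,
        variant_tables=variant_tables,
        cnv_segments=cnv_segments,
        sequenced_regions=regions,
        gene_set_catalog=catalog,
        suv_volumes=suv_volumes,
        voi_masks=voi_masks,
        ihc_cores=ihc,
        radiomics_table=rad_block,
    )


# ---------------------------------------------------------------- disk IO


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path, write_volumes: bool = False) -> None:
    """Write the cohort as plain-text files (CSV/TSV/BED/GMT + JSON config);
    SUV volumes/masks optionally as NRRD."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.clinical_table.to_csv(out / "clinical.csv")
    cohort.radiomics_table.to_csv(out / "radiomics.csv")
    cohort.ihc_cores.to_csv(out / "ihc_cores.csv", index=False)
    lab = cohort.gs_labels.copy()
    lab["bx_isup"] = cohort.bx_isup
    lab.to_csv(out / "labels.csv")
    vdir = out / "variants"
    vdir.mkdir(exist_ok=True)
    for pid, tbl in cohort.variant_tables.items():
        tbl.assign(patient=pid)[["patient", "gene", "eve", "cadd", "polyphen"]].to_csv(
            vdir / f"{pid}.tsv", sep="\t", index=False
        )
    cdir = out / "cnv"
    cdir.mkdir(exist_ok=True)
    for pid, segs in cohort.cnv_segments.items():
        pd.DataFrame(segs, columns=["start", "end"]).assign(chrom="chrS")[
            ["chrom", "start", "end"]
        ].to_csv(cdir / f"{pid}.bed", sep="\t", index=False, header=False)
    pd.DataFrame(cohort.sequenced_regions, columns=["start", "end"]).assign(chrom="chrS")[
        ["chrom", "start", "end"]
    ].to_csv(out / "sequenced_regions.bed", sep="\t", index=False, header=False)
    cohort.gene_set_catalog.to_gmt(out / "gene_sets.gmt")
    cfg = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(cohort.config).items()
    }
    (out / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))
    if write_volumes:
        import SimpleITK as sitk

        voldir = out / "volumes"
        voldir.mkdir(exist_ok=True)
        for pid in cohort.patients:
            img = sitk.GetImageFromArray(cohort.suv_volumes[pid].data)
            img.SetSpacing(tuple(reversed(cohort.suv_volumes[pid].spacing)))
            sitk.WriteImage(img, str(voldir / f"{pid}_suv.nrrd"))
            msk = sitk.GetImageFromArray(cohort.voi_masks[pid].data.astype(np.uint8))
            msk.SetSpacing(img.GetSpacing())
            sitk.WriteImage(msk, str(voldir / f"{pid}_mask.nrrd"))
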