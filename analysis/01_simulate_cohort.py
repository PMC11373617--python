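"""Simulate the study-structured multiomics cohort and write it to disk.

Generates 65 patients at 57% high-risk prevalence with the full raw-data
complement (variant tables, CNV segments, SUV phantoms, IHC cores,
clinical covariates, Gleason labels + biopsy grades) and reports the basic
cohort descriptives.
"""

import sys
from pathlib import Path

import psma_multiomics as pm
from psma_multiomics.genomics import mutated_gene_frequency

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    cfg = pm.CohortConfig(seed=SEED)
    cohort = pm.generate_cohort(cfg)
    pm.cohort.write_cohort(cohort, OUT)

    n_high = int(cohort.labels.sum())
    print(f"cohort: {cfg.n_patients} patients, seed {SEED}")
    print(f"high risk (ISUP >= 3): {n_high} ({100 * n_high / cfg.n_patients:.0f}%)")
    freq = mutated_gene_frequency(cohort.variant_tables)
    print(f"genes mutated in >= 10% of patients: {(freq >= 0.10).sum()}")
    concord = (cohort.bx_isup.to_numpy() == cohort.gs_labels["isup"].to_numpy()).mean()
    print(f"biopsy/whole-mount ISUP concordance: {concord:.2f}")
    img = cohort.clinical_table[
        ["clin::pirads", "clin::mri_lesion_diameter_mm", "clin::adc_min", "clin::mri_epe"]
    ]
    print(f"image-read clinical missingness: {img.isna().mean().mean():.2f}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
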