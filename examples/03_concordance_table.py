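"""Tumor-plasma concordance, stratified by stage, tissue, and platform.

A plasma sample is concordant with its tumor when at least one of the
mutations found in the solid tumor is also detected in plasma. Because
shed ctDNA scales with tumor burden, concordance climbs steeply from
early-stage to advanced disease.
"""

from ctdna_concord import (
    CohortParams,
    CtDNAQuant,
    evaluate_sample,
    simulate_cohort,
    summarize,
    tumor_profile_summary,
)
from ctdna_concord.ddpcr import DETECTION_THRESHOLD_MAF_PCT

cohort = simulate_cohort(CohortParams(n_patients=180, seed=42))

variants_by_sample = {}
for v in cohort.variants_as_objects():
    variants_by_sample.setdefault(v.sample_id, []).append(v)

maf_by_variant = {
    (row.sample_id, f"{row.chrom}:{row.pos}:{row.ref}>{row.alt}"): row.true_maf_pct
    for row in cohort.true_plasma_maf.itertuples(index=False)
}

records = []
for row in cohort.sample_sheet.itertuples(index=False):
    variants = variants_by_sample[row.sample_id]
    plasma = [
        CtDNAQuant(
            sample_id=row.sample_id,
            locus=str(v.locus),
            maf_pct=maf_by_variant[(row.sample_id, str(v.locus))],
            detected=maf_by_variant[(row.sample_id, str(v.locus))]
            >= DETECTION_THRESHOLD_MAF_PCT,
        )
        for v in variants
    ]
    records.append(
        evaluate_sample(variants, plasma, stage=row.stage,
                        tissue=row.tissue, platform=row.platform)
    )

table = summarize(records)
print(table.to_string(index=False))

profile = tumor_profile_summary(cohort.variants_as_objects())
print()
print("mutations per tumor sample (%):", profile["mutations_per_sample_pct"])
print("most frequently mutated genes  :",
      dict(list(profile["per_gene_mutated_samples"].items())[:5]))
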