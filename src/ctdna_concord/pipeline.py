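"""End-to-end driver: simulate -> call -> quantify -> concord -> survive.

The driver chains every stage on a synthetic cohort (or user-supplied
tables via the individual stage functions), writes every intermediate
table, and records a manifest with the seed, a config hash, and the
record counts entering and leaving each filter — attrition through the
detection gates is the analysis's central narrative.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calling import (
    PlasmaCall,
    call_amplicon,
    call_dnaseq_positional,
    call_generead,
    call_tagseq_ckv,
    collapse_consensus,
    group_positional_families,
    group_umi_families,
)
from .cohort import CohortParams, SyntheticCohort, simulate_cohort, survival_records
from .concordance import (
    ConcordanceRecord,
    cross_platform_agreement,
    evaluate_sample,
    summarize,
    tumor_profile_summary,
)
from .ddpcr import (
    CtDNAQuant,
    copies_per_ml_from_yield,
    quantify_sample,
    representative_mutation,
    simulate_partition,
)
from .errors import SaturationError
from .io import PipelineConfig, write_variant_table
from .reads import ReadSimParams, simulate_read_families
from .survival import SurvivalReport, maxstat_cutpoint, survival_report
from .variants import Locus, TumorVariant

log = logging.getLogger("ctdna_concord")

_NGS_CHEMISTRIES = ("positional", "tagged_umi", "amplicon")


@dataclass
class PipelineResult:
    cohort: SyntheticCohort
    calls: pd.DataFrame
    quants: pd.DataFrame
    concordance_records: list[ConcordanceRecord]
    concordance_summary: pd.DataFrame
    cross_platform: object | None
    tumor_profile: dict
    cutpoint: float
    report: SurvivalReport | None
    manifest: dict


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _ngs_call(
    variant_row, true_maf: float, chemistry: str, config: PipelineConfig, seed: int
) -> PlasmaCall:
    locus = Locus(variant_row.chrom, int(variant_row.pos), variant_row.ref, variant_row.alt)
    params = ReadSimParams(
        locus=locus,
        variant_type=variant_row.variant_type,
        n_molecules=config.n_molecules_ngs,
        maf_molecular=true_maf,
        error_rate=0.001,
        chemistry=chemistry,
        sample_id=variant_row.sample_id,
        seed=seed,
    )
    reads, _ = simulate_read_families(params)
    thr = config.thresholds
    kwargs = dict(sample_id=variant_row.sample_id, locus=str(locus))
    if chemistry == "positional":
        fams = group_positional_families(reads)
        return call_dnaseq_positional(fams, alt="alt", thresholds=thr, **kwargs)
    if chemistry == "tagged_umi":
        fams = group_umi_families(reads)
        consensus = collapse_consensus(fams, min_size=1)
        return call_tagseq_ckv(
            consensus, alt="alt", variant_type=variant_row.variant_type,
            thresholds=thr, **kwargs,
        )
    return call_amplicon(
        reads, alt="alt", variant_type=variant_row.variant_type,
        thresholds=thr, **kwargs,
    )


def _ddpcr_quant(
    variant_row, true_maf: float, yield_ng: float, config: PipelineConfig,
    rng: np.random.Generator,
) -> CtDNAQuant:
    total_copies_per_ml = yield_ng * 1000.0 / config.pg_per_genome
    loaded = (
        total_copies_per_ml
        * config.plasma_ml_extracted
        * config.reaction_fraction_of_elution
    )
    n_mut = int(round(loaded * true_maf / 100.0))
    n_wt = int(round(loaded * (1 - true_maf / 100.0)))
    d = simulate_partition(
        n_mut,
        n_wt,
        config.n_droplets,
        rng,
        sample_id=variant_row.sample_id,
        assay=f"{variant_row.gene}_{variant_row.protein_change}",
        droplet_volume_nl=config.droplet_volume_nl,
        reaction_fraction_of_elution=config.reaction_fraction_of_elution,
        plasma_ml_extracted=config.plasma_ml_extracted,
    )
    try:
        q = quantify_sample(d, threshold_maf_pct=config.ddpcr_threshold_maf_pct)
    except SaturationError:
        # saturated wells are re-expressed through the yield-based conversion
        q = CtDNAQuant(
            sample_id=variant_row.sample_id,
            assay=d.assay,
            mut_copies_per_ml_plasma=copies_per_ml_from_yield(
                yield_ng, true_maf, config.pg_per_genome
            ),
            maf_pct=true_maf,
            detected=true_maf >= config.ddpcr_threshold_maf_pct,
        )
    q.locus = str(
        Locus(variant_row.chrom, int(variant_row.pos), variant_row.ref, variant_row.alt)
    )
    return q


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage in order and write all intermediate tables."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    master = np.random.SeedSequence(config.seed)
    cohort_seed, ddpcr_seed, ngs_seed = (
        int(s.generate_state(1)[0] % (2**31 - 1)) for s in master.spawn(3)
    )

    cohort = simulate_cohort(CohortParams(n_patients=config.n_patients, seed=cohort_seed))
    sheet = cohort.sample_sheet
    log.info("simulated cohort: %d patients, %d tumor variants", len(sheet), len(cohort.tumor_variants))

    true_maf = cohort.true_plasma_maf.set_index(["sample_id", "chrom", "pos"])["true_maf_pct"]
    ddpcr_rng = np.random.default_rng(ddpcr_seed)
    ngs_rng = np.random.default_rng(ngs_seed)

    calls_rows: list[dict] = []
    quants_by_sample: dict[str, list[CtDNAQuant]] = {}
    ngs_status: dict[str, bool] = {}
    ddpcr_status: dict[str, bool] = {}

    for i, srow in enumerate(sheet.itertuples(index=False)):
        variants = cohort.tumor_variants[cohort.tumor_variants["sample_id"] == srow.sample_id]
        if variants.empty:
            continue
        chem = _NGS_CHEMISTRIES[i % len(_NGS_CHEMISTRIES)]
        sample_quants: list[CtDNAQuant] = []
        for vrow in variants.itertuples(index=False):
            maf = true_maf.loc[(vrow.sample_id, vrow.chrom, vrow.pos)]
            if isinstance(maf, pd.Series):  # duplicate loci: take the first
                maf = maf.iloc[0]
            maf = float(maf)
            if srow.platform in ("ddPCR", "both"):
                q = _ddpcr_quant(vrow, maf, srow.cfdna_yield_ng_per_ml, config, ddpcr_rng)
                sample_quants.append(q)
                ddpcr_status[srow.sample_id] = ddpcr_status.get(srow.sample_id, False) or q.detected
                calls_rows.append(
                    {
                        "sample_id": srow.sample_id, "locus": q.locus, "procedure": "ddpcr",
                        "depth": np.nan, "supporting": np.nan, "sr_pct": q.maf_pct,
                        "supporting_families": np.nan, "confidence": np.nan,
                        "detected": q.detected, "reason": "" if q.detected else "maf_below_threshold",
                    }
                )
            if srow.platform in ("NGS", "both"):
                call = _ngs_call(vrow, maf, chem, config, int(ngs_rng.integers(0, 2**31 - 1)))
                ngs_status[srow.sample_id] = ngs_status.get(srow.sample_id, False) or call.detected
                calls_rows.append(
                    {
                        "sample_id": call.sample_id, "locus": call.locus,
                        "procedure": call.procedure, "depth": call.depth,
                        "supporting": call.supporting, "sr_pct": call.sr_pct,
                        "supporting_families": call.supporting_families,
                        "confidence": call.confidence, "detected": call.detected,
                        "reason": call.reason,
                    }
                )
                if srow.platform == "NGS":
                    # NGS-only samples: express the level through yield x %SR
                    maf_est = call.sr_pct if call.detected else 0.0
                    q = CtDNAQuant(
                        sample_id=srow.sample_id,
                        assay=f"NGS_{chem}",
                        mut_copies_per_ml_plasma=copies_per_ml_from_yield(
                            srow.cfdna_yield_ng_per_ml, maf_est, config.pg_per_genome
                        ),
                        maf_pct=maf_est,
                        detected=call.detected,
                        locus=call.locus,
                    )
                    sample_quants.append(q)
        if sample_quants:
            quants_by_sample[srow.sample_id] = sample_quants

    calls = pd.DataFrame(calls_rows)

    # representative mutation per sample
    reps: dict[str, CtDNAQuant] = {}
    quant_rows = []
    for sid, qs in quants_by_sample.items():
        rep = representative_mutation(qs)
        reps[sid] = rep
        for q in qs:
            quant_rows.append(
                {
                    "sample_id": q.sample_id, "assay": q.assay, "locus": q.locus,
                    "maf_pct": q.maf_pct,
                    "mut_copies_per_ml_plasma": q.mut_copies_per_ml_plasma,
                    "wt_copies_per_ml_plasma": q.wt_copies_per_ml_plasma,
                    "detected": q.detected, "representative": q.representative,
                }
            )
    quants = pd.DataFrame(quant_rows)

    # per-sample concordance
    conc_records = []
    variants_obj = cohort.variants_as_objects()
    by_sample: dict[str, list[TumorVariant]] = {}
    for v in variants_obj:
        by_sample.setdefault(v.sample_id, []).append(v)
    call_objs: dict[str, list] = {}
    for sid, qs in quants_by_sample.items():
        call_objs[sid] = list(qs)
    for srow in sheet.itertuples(index=False):
        sid = srow.sample_id
        if sid not in by_sample or sid not in call_objs:
            continue
        conc_records.append(
            evaluate_sample(
                by_sample[sid],
                call_objs[sid],
                stage=srow.stage,
                tissue=srow.tissue,
                platform=srow.platform,
            )
        )
    conc_summary = summarize(conc_records) if conc_records else pd.DataFrame()
    log.info("concordance: %d samples evaluated", len(conc_records))

    both_ids = set(sheet.loc[sheet["platform"] == "both", "sample_id"])
    xplat = None
    shared = sorted(both_ids & set(ddpcr_status) & set(ngs_status))
    if shared:
        xplat = cross_platform_agreement(
            {s: ddpcr_status[s] for s in shared}, {s: ngs_status[s] for s in shared}
        )

    profile = tumor_profile_summary(variants_obj) if variants_obj else {}

    # survival
    report = None
    cutpoint = config.default_cutpoint
    surv_recs = survival_records(cohort.survival)
    if reps and len(surv_recs) >= 2:
        if config.cutpoint == "auto":
            detected = [
                r for r in surv_recs
                if r.sample_id in reps and reps[r.sample_id].detected
            ]
            for r in detected:
                r.ctdna_copies_per_ml = reps[r.sample_id].mut_copies_per_ml_plasma
            if len(detected) >= 10 and len({r.ctdna_copies_per_ml for r in detected}) > 1:
                cutpoint = maxstat_cutpoint(
                    detected, min_group_fraction=config.min_group_fraction
                ).cutpoint
        else:
            cutpoint = float(config.cutpoint)
        try:
            report = survival_report(surv_recs, reps, cutpoint=cutpoint)
        except Exception as exc:  # degenerate small cohorts
            log.warning("survival report skipped: %s", exc)

    # write outputs
    sheet.to_csv(outdir / "sample_sheet.csv", index=False)
    cohort.tumor_variants.to_csv(outdir / "tumor_variants.csv", index=False)
    write_variant_table(variants_obj, outdir / "tumor_variants.vcf", dialect="vcf_minimal")
    cohort.true_plasma_maf.to_csv(outdir / "true_plasma_maf.csv", index=False)
    cohort.survival.to_csv(outdir / "survival.csv", index=False)
    calls.to_csv(outdir / "plasma_calls.csv", index=False)
    quants.to_csv(outdir / "ctdna_quants.csv", index=False)
    if len(conc_summary):
        conc_summary.to_csv(outdir / "concordance_summary.csv", index=False)
    if report is not None:
        (outdir / "survival_report.txt").write_text(report.to_text() + "\n")
        pd.DataFrame(
            [(sid, g) for sid, g in report.groups.items()],
            columns=["sample_id", "group"],
        ).to_csv(outdir / "survival_groups.csv", index=False)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "n_patients": int(len(sheet)),
        "n_tumor_variants": int(len(cohort.tumor_variants)),
        "n_samples_evaluated": len(conc_records),
        "n_calls": int(len(calls)),
        "cutpoint_copies_per_ml": float(cutpoint),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        cohort=cohort,
        calls=calls,
        quants=quants,
        concordance_records=conc_records,
        concordance_summary=conc_summary,
        cross_platform=xplat,
        tumor_profile=profile,
        cutpoint=float(cutpoint),
        report=report,
        manifest=manifest,
    )
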