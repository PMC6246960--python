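"""Tumor-plasma concordance tabulation.

A sample is *concordant* when at least one of the somatic mutations
identified in its solid tumor is also detected in the matched plasma by
the applicable procedure's gates (ddPCR MAF >= 0.03%, or an NGS caller's
detected flag). Summaries are stratified by clinical stage (early =
up to Stage IIA, advanced = Stage IIB and above), by tissue of origin,
and by detection platform; samples run on both platforms contribute to
both platform rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .calling import PlasmaCall
from .ddpcr import CtDNAQuant
from .errors import InputError
from .variants import TumorVariant

EARLY, ADVANCED, UNKNOWN = "early", "advanced", "unknown"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching printed contingency tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConcordanceRecord:
    """Per-sample concordance decision with its stratification labels."""

    sample_id: str
    stage: str = UNKNOWN
    tissue: str = ""
    platform: str = ""  # ddPCR | NGS | both
    n_tumor_variants: int = 0
    n_detected_in_plasma: int = 0
    concordant: bool = False


def evaluate_sample(
    tumor_variants: list[TumorVariant],
    plasma_results: list[PlasmaCall | CtDNAQuant],
    stage: str = UNKNOWN,
    tissue: str = "",
    platform: str = "",
    require_all_variants: bool = False,
) -> ConcordanceRecord:
    """Decide concordance for one sample.

    Each plasma result is matched to a tumor variant by locus; results
    at loci absent from the tumor profile trigger a consistency warning
    and are ignored. With the default ``require_all_variants=False`` a
    single detected variant makes the sample concordant.
    """
    if not tumor_variants:
        raise InputError("evaluate_sample requires at least one tumor variant")
    sample_id = tumor_variants[0].sample_id
    tumor_loci = {str(v.locus) for v in tumor_variants}

    detected_loci: set[str] = set()
    for res in plasma_results:
        locus = res.locus if isinstance(res, (PlasmaCall, CtDNAQuant)) else ""
        if locus and locus not in tumor_loci:
            warnings.warn(
                f"{sample_id}: plasma result at {locus} has no matching tumor variant; ignored",
                stacklevel=2,
            )
            continue
        if res.detected:
            detected_loci.add(locus or "unmatched")
    n_det = len(detected_loci)
    if require_all_variants:
        concordant = n_det >= len(tumor_loci)
    else:
        concordant = n_det >= 1
    return ConcordanceRecord(
        sample_id=sample_id,
        stage=stage,
        tissue=tissue,
        platform=platform,
        n_tumor_variants=len(tumor_variants),
        n_detected_in_plasma=n_det,
        concordant=concordant,
    )


_BLOCKS = ("stage", "tissue", "platform")


def _summary_row(label: str, block: str, n: int, n_conc: int) -> dict:
    n_disc = n - n_conc
    return {
        "block": block,
        "stratum": label,
        "n": n,
        "n_concordant": n_conc,
        "pct_concordant": round_half_up(100.0 * n_conc / n) if n else 0.0,
        "n_discordant": n_disc,
        "pct_discordant": round_half_up(100.0 * n_disc / n) if n else 0.0,
    }


def summarize(
    records: list[ConcordanceRecord], strata: tuple[str, ...] = _BLOCKS
) -> pd.DataFrame:
    """Stratified concordance summary in the layout of a printed table.

    Stage block: unknown-stage samples are excluded. Platform block:
    samples run on both platforms are counted in each platform row.
    Percentages are rounded half-up to two decimals.
    """
    if not records:
        raise InputError("summarize requires at least one record")
    bad = [s for s in strata if s not in _BLOCKS]
    if bad:
        raise InputError(f"unknown strata {bad}; valid: {_BLOCKS}")
    df = pd.DataFrame([vars(r) for r in records])
    rows = [_summary_row("All samples", "all", len(df), int(df["concordant"].sum()))]
    if "stage" in strata:
        staged = df[df["stage"] != UNKNOWN]
        for stage in (EARLY, ADVANCED):
            sub = staged[staged["stage"] == stage]
            if len(sub):
                rows.append(_summary_row(stage, "stage", len(sub), int(sub["concordant"].sum())))
    if "tissue" in strata:
        for tissue, sub in df.groupby("tissue", sort=True):
            if tissue:
                rows.append(_summary_row(tissue, "tissue", len(sub), int(sub["concordant"].sum())))
    if "platform" in strata:
        for platform in ("ddPCR", "NGS"):
            sub = df[df["platform"].isin([platform, "both"])]
            if len(sub):
                rows.append(_summary_row(platform, "platform", len(sub), int(sub["concordant"].sum())))
    return pd.DataFrame(rows)


@dataclass
class AgreementSummary:
    n_shared: int
    n_agree: int
    pct_agree: float


def cross_platform_agreement(
    calls_a: dict[str, bool], calls_b: dict[str, bool]
) -> AgreementSummary:
    """Fraction of shared samples with identical detected status."""
    shared = sorted(set(calls_a) & set(calls_b))
    if not shared:
        raise InputError("no samples shared between the two platforms")
    n_agree = sum(1 for s in shared if bool(calls_a[s]) == bool(calls_b[s]))
    return AgreementSummary(
        n_shared=len(shared),
        n_agree=n_agree,
        pct_agree=round_half_up(100.0 * n_agree / len(shared)),
    )


def tumor_profile_summary(tumor_variants: list[TumorVariant]) -> dict:
    """Mutations-per-sample distribution and per-gene frequencies.

    Bins follow the conventional landscape summary: samples with exactly
    one trackable mutation, with 2-3, and with more than 3.
    """
    if not tumor_variants:
        raise InputError("no tumor variants to summarize")
    per_sample = pd.Series([v.sample_id for v in tumor_variants]).value_counts()
    n = len(per_sample)
    bins = {
        "1": int((per_sample == 1).sum()),
        "2-3": int(per_sample.between(2, 3).sum()),
        ">3": int((per_sample > 3).sum()),
    }
    pcts = {k: round_half_up(100.0 * v / n) for k, v in bins.items()}
    gene_counts = (
        pd.DataFrame({"gene": [v.gene for v in tumor_variants], "sample": [v.sample_id for v in tumor_variants]})
        .drop_duplicates()
        .groupby("gene")
        .size()
        .sort_values(ascending=False)
    )
    return {
        "n_samples": n,
        "mutations_per_sample_counts": bins,
        "mutations_per_sample_pct": pcts,
        "per_gene_mutated_samples": gene_counts.to_dict(),
    }
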