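"""Synthetic matched tumor-plasma cohorts.

Generates the full object set the downstream analysis consumes: a
sample sheet (tissue, clinical stage, platform, cfDNA yield), tumor
variant profiles (1-3+ somatic mutations per sample, mostly SNVs), true
plasma mutant allele fractions (log-uniform over several orders of
magnitude for detectable samples, all-zero for the undetectable ones,
with stage-dependent detection probability), and survival outcomes with
group-dependent exponential hazards under administrative censoring.

The defaults mirror a pan-cancer liquid-biopsy cohort: lung-dominated
tissue mix, ~20% early-stage (up to Stage IIA), cfDNA yields spanning
7.13-405 ng/mL and rising with stage, plasma MAFs between 0.28% and
94.7%, and a 27-month study window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .concordance import ADVANCED, EARLY, UNKNOWN
from .ddpcr import PG_PER_GENOME, copies_per_ml_from_yield
from .errors import ConfigurationError
from .survival import DAYS_PER_MONTH, HIGH, LOW, NOT_DETECTED, SurvivalRecord
from .variants import MULTI_BASE_INDEL, SINGLE_BASE_INDEL, SNV, Locus, TumorVariant

# Tissue mix of a 180-patient pan-cancer cohort (lung 93, breast 42,
# colorectal 22, bladder 12, ovarian 9, esophageal 1, sarcoma 1).
DEFAULT_TISSUE_MIX = {
    "lung": 93 / 180,
    "breast": 42 / 180,
    "colorectal": 22 / 180,
    "bladder": 12 / 180,
    "ovarian": 9 / 180,
    "esophageal": 1 / 180,
    "sarcoma": 1 / 180,
}

DEFAULT_STAGE_MIX = {EARLY: 36 / 180, ADVANCED: 133 / 180, UNKNOWN: 11 / 180}

# 59.18% of mutation-positive samples carry a single trackable mutation,
# 35.71% carry 2-3 (58, 18+17 and 5 of 98).
DEFAULT_MUTATIONS_PER_SAMPLE = {1: 58 / 98, 2: 18 / 98, 3: 17 / 98, 4: 5 / 98}

DEFAULT_YIELD_RANGE = {
    EARLY: (7.13, 80.0),
    ADVANCED: (15.0, 405.0),
    UNKNOWN: (7.13, 405.0),
}

DEFAULT_DETECT_PROB = {EARLY: 0.32, ADVANCED: 0.82, UNKNOWN: 0.72}

_GENE_POOL = [
    ("TP53", "chr17", 7_577_000, 0.30),
    ("EGFR", "chr7", 55_242_000, 0.22),
    ("KRAS", "chr12", 25_398_000, 0.14),
    ("PIK3CA", "chr3", 178_936_000, 0.12),
    ("BRAF", "chr7", 140_453_000, 0.08),
    ("APC", "chr5", 112_175_000, 0.06),
    ("CTNNB1", "chr3", 41_266_000, 0.04),
    ("FBXW7", "chr4", 153_245_000, 0.04),
]
_BASES = np.array(list("ACGT"))
_VARIANT_TYPE_PROBS = {SNV: 0.85, MULTI_BASE_INDEL: 0.10, SINGLE_BASE_INDEL: 0.05}
_PLATFORM_PROBS = {"ddPCR": 74 / 138, "NGS": 39 / 138, "both": 25 / 138}


@dataclass
class CohortParams:
    """Cohort-level generator configuration."""

    n_patients: int = 180
    tissue_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TISSUE_MIX))
    stage_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STAGE_MIX))
    mutations_per_sample_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MUTATIONS_PER_SAMPLE)
    )
    yield_range_ng_per_ml: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_YIELD_RANGE)
    )
    maf_log_range: tuple[float, float] = (0.28, 94.7)
    detect_prob_by_stage: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DETECT_PROB)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be non-negative")
        for name, m in (
            ("tissue_mix", self.tissue_mix),
            ("stage_mix", self.stage_mix),
            ("mutations_per_sample_dist", self.mutations_per_sample_dist),
        ):
            if not m:
                raise ConfigurationError(f"{name} is empty")
            if any(v < 0 for v in m.values()):
                raise ConfigurationError(f"{name} has a negative proportion")
            if abs(sum(m.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} proportions do not sum to 1")
        for stage, (lo, hi) in self.yield_range_ng_per_ml.items():
            if not 0 < lo <= hi:
                raise ConfigurationError(f"yield range for stage {stage!r} invalid")
        em = self.yield_range_ng_per_ml.get(EARLY)
        am = self.yield_range_ng_per_ml.get(ADVANCED)
        if em and am and (em[0] + em[1]) / 2 > (am[0] + am[1]) / 2:
            raise ConfigurationError("early-stage mean yield must not exceed advanced")
        lo, hi = self.maf_log_range
        if not 0 < lo <= hi <= 100:
            raise ConfigurationError("maf_log_range must lie in (0, 100]")
        for stage, p in self.detect_prob_by_stage.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(f"detect probability for {stage!r} outside [0, 1]")


@dataclass
class SurvivalSimParams:
    """Group-wise exponential survival with administrative censoring.

    Default hazards place the group medians near 150 / 348 / 430 days
    (high / low / not_detected), i.e. survival advantages of roughly
    200 and 280 days for the low and undetectable groups.
    """

    group_hazards: dict[str, float] = field(
        default_factory=lambda: {HIGH: 0.00462, LOW: 0.00199, NOT_DETECTED: 0.00161}
    )
    study_days: float = 27 * DAYS_PER_MONTH  # ~822 days
    accrual_days: float = 0.0
    seed: int = 0

    def validate(self, groups_present: set[str] | None = None) -> None:
        if any(h <= 0 for h in self.group_hazards.values()):
            raise ConfigurationError("hazards must be strictly positive")
        if self.study_days < 0 or self.accrual_days < 0:
            raise ConfigurationError("study and accrual windows must be non-negative")
        if groups_present:
            missing = groups_present - set(self.group_hazards)
            if missing:
                raise ConfigurationError(f"no hazard configured for group(s) {sorted(missing)}")


@dataclass
class SyntheticCohort:
    """All tables of one simulated study."""

    sample_sheet: pd.DataFrame
    tumor_variants: pd.DataFrame
    true_plasma_maf: pd.DataFrame
    survival: pd.DataFrame

    def variants_as_objects(self) -> list[TumorVariant]:
        out = []
        for row in self.tumor_variants.itertuples(index=False):
            out.append(
                TumorVariant(
                    sample_id=row.sample_id,
                    locus=Locus(row.chrom, int(row.pos), row.ref, row.alt),
                    gene=row.gene,
                    protein_change=row.protein_change,
                    variant_type=row.variant_type,
                    tumor_maf_pct=row.tumor_maf_pct,
                )
            )
        return out


_SHEET_COLS = [
    "sample_id", "tissue", "stage", "platform", "cfdna_yield_ng_per_ml",
    "detectable", "representative_maf_pct", "ctdna_copies_per_ml",
]
_VAR_COLS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "protein_change",
    "variant_type", "tumor_maf_pct",
]
_MAF_COLS = ["sample_id", "chrom", "pos", "ref", "alt", "true_maf_pct"]
_SURV_COLS = ["sample_id", "time_days", "event", "group"]


def _choice(rng: np.random.Generator, dist: dict, size: int) -> np.ndarray:
    keys = list(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(keys), size=size, p=probs)
    return np.array(keys, dtype=object)[idx]


def simulate_cohort(params: CohortParams) -> SyntheticCohort:
    """Draw a full synthetic cohort; deterministic for a fixed seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    if n == 0:
        return SyntheticCohort(
            sample_sheet=pd.DataFrame(columns=_SHEET_COLS),
            tumor_variants=pd.DataFrame(columns=_VAR_COLS),
            true_plasma_maf=pd.DataFrame(columns=_MAF_COLS),
            survival=pd.DataFrame(columns=_SURV_COLS),
        )

    sample_ids = [f"P{i:04d}" for i in range(n)]
    tissues = _choice(rng, params.tissue_mix, n)
    stages = _choice(rng, params.stage_mix, n)
    platforms = _choice(rng, _PLATFORM_PROBS, n)

    yields = np.empty(n)
    for stage, (lo, hi) in params.yield_range_ng_per_ml.items():
        mask = stages == stage
        yields[mask] = np.exp(rng.uniform(np.log(lo), np.log(hi), size=int(mask.sum())))

    detect_p = np.array([params.detect_prob_by_stage[s] for s in stages])
    detectable = rng.random(n) < detect_p

    # tumor variants per sample
    n_muts = _choice(rng, params.mutations_per_sample_dist, n).astype(int)
    var_rows, maf_rows = [], []
    gene_probs = np.array([g[3] for g in _GENE_POOL])
    gene_probs = gene_probs / gene_probs.sum()
    lo, hi = params.maf_log_range
    rep_maf = np.zeros(n)
    for i, sid in enumerate(sample_ids):
        for k in range(n_muts[i]):
            gi = rng.choice(len(_GENE_POOL), p=gene_probs)
            gene, chrom, base_pos, _ = _GENE_POOL[gi]
            pos = int(base_pos + rng.integers(0, 5000))
            vt = str(_choice(rng, _VARIANT_TYPE_PROBS, 1)[0])
            if vt == SNV:
                ref, alt = rng.choice(4, size=2, replace=False)
                ref, alt = _BASES[ref], _BASES[alt]
            elif vt == SINGLE_BASE_INDEL:
                ref, alt = str(_BASES[rng.integers(4)]) * 2, str(_BASES[rng.integers(4)])
            else:
                ref = "".join(_BASES[rng.integers(0, 4, size=rng.integers(3, 8))])
                alt = ref[0]
            pch = f"p.{chr(65 + int(rng.integers(0, 26)))}{int(rng.integers(10, 900))}{chr(65 + int(rng.integers(0, 26)))}"
            tumor_maf = float(rng.uniform(5, 60))
            var_rows.append((sid, chrom, pos, str(ref), str(alt), gene, pch, vt, tumor_maf))
            if detectable[i]:
                maf = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                maf = 0.0
            maf_rows.append((sid, chrom, pos, str(ref), str(alt), maf))
            rep_maf[i] = max(rep_maf[i], maf)

    tumor_variants = pd.DataFrame(var_rows, columns=_VAR_COLS)
    true_maf = pd.DataFrame(maf_rows, columns=_MAF_COLS)

    copies = np.array(
        [copies_per_ml_from_yield(y, m, PG_PER_GENOME) for y, m in zip(yields, rep_maf)]
    )
    sheet = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue": tissues,
            "stage": stages,
            "platform": platforms,
            "cfdna_yield_ng_per_ml": yields,
            "detectable": detectable,
            "representative_maf_pct": rep_maf,
            "ctdna_copies_per_ml": copies,
        }
    )

    # survival linked to the ctDNA level through the standard three groups
    from .survival import DEFAULT_CUTPOINT_COPIES_PER_ML

    groups = {
        sid: (
            NOT_DETECTED
            if not det
            else (HIGH if c > DEFAULT_CUTPOINT_COPIES_PER_ML else LOW)
        )
        for sid, det, c in zip(sample_ids, detectable, copies)
    }
    surv_params = SurvivalSimParams(seed=int(rng.integers(0, 2**31 - 1)))
    survival = simulate_survival(groups, surv_params)

    return SyntheticCohort(
        sample_sheet=sheet,
        tumor_variants=tumor_variants,
        true_plasma_maf=true_maf,
        survival=survival,
    )


def simulate_survival(
    groups: dict[str, str], params: SurvivalSimParams
) -> pd.DataFrame:
    """Exponential event times per group with administrative censoring.

    Each subject enters uniformly within the accrual window and is
    followed until death or the end of the study, whichever comes
    first; censored subjects carry event = 0.
    """
    params.validate(groups_present=set(groups.values()))
    rng = np.random.default_rng(params.seed)
    rows = []
    for sid in groups:
        g = groups[sid]
        lam = params.group_hazards[g]
        entry = rng.uniform(0, params.accrual_days) if params.accrual_days > 0 else 0.0
        follow_up = max(params.study_days - entry, 0.0)
        t_event = rng.exponential(1.0 / lam)
        if t_event <= follow_up:
            rows.append((sid, t_event, 1, g))
        else:
            rows.append((sid, follow_up, 0, g))
    return pd.DataFrame(rows, columns=_SURV_COLS)


def survival_records(table: pd.DataFrame) -> list[SurvivalRecord]:
    """Convert a survival table to record objects."""
    return [
        SurvivalRecord(
            sample_id=row.sample_id,
            time_days=float(row.time_days),
            event=int(row.event),
            group=getattr(row, "group", None),
        )
        for row in table.itertuples(index=False)
    ]
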