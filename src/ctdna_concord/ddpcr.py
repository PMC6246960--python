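"""Droplet digital PCR quantification of mutant and wild-type targets.

A ddPCR reaction partitions the cfDNA input into ~20,000 nanoliter
droplets; after endpoint PCR each droplet is classified positive or
negative for the mutant and wild-type probes. Because molecules
distribute over droplets approximately as a Poisson process, the mean
number of target copies per droplet is recovered from the fraction of
negative droplets: lambda = -ln(1 - p), with p the positive fraction.
Concentrations are converted to copies per mL of plasma via the loaded
fraction of the cfDNA elution and the plasma volume extracted, and a
sample is called ctDNA-positive when its mutant allele frequency (MAF)
reaches a stringent 0.03% threshold (about 2 copies/mL plasma at the
median cfDNA yield of ~22 ng/mL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError, SaturationError

#: Mass of one haploid human genome equivalent, in picograms. Under this
#: constant, 22 ng/mL plasma at 0.03% MAF converts to 2.0 copies/mL.
PG_PER_GENOME = 3.3

#: QX200 droplet volume in nanoliters.
DROPLET_VOLUME_NL = 0.85

#: Detection threshold on mutant allele frequency, in percent (inclusive).
DETECTION_THRESHOLD_MAF_PCT = 0.03


@dataclass
class DropletData:
    """Classified droplet counts for one sample/assay well."""

    sample_id: str
    assay: str
    n_total: int
    n_mut_pos: int
    n_wt_pos: int
    droplet_volume_nl: float = DROPLET_VOLUME_NL
    reaction_fraction_of_elution: float = 1.0
    plasma_ml_extracted: float = 1.0

    def __post_init__(self) -> None:
        if self.n_total < 0 or not (0 <= self.n_mut_pos <= self.n_total):
            raise InputError(
                f"{self.sample_id}: mutant-positive droplets {self.n_mut_pos} "
                f"outside [0, {self.n_total}]"
            )
        if not 0 <= self.n_wt_pos <= self.n_total:
            raise InputError(
                f"{self.sample_id}: wild-type-positive droplets {self.n_wt_pos} "
                f"outside [0, {self.n_total}]"
            )
        if self.droplet_volume_nl <= 0:
            raise ConfigurationError("droplet volume must be positive")
        if self.reaction_fraction_of_elution <= 0 or self.plasma_ml_extracted <= 0:
            raise ConfigurationError("elution fraction and plasma volume must be positive")


@dataclass
class CtDNAQuant:
    """Per-sample, per-assay ctDNA level."""

    sample_id: str
    assay: str = ""
    mut_copies_per_ml_plasma: float = 0.0
    wt_copies_per_ml_plasma: float = 0.0
    maf_pct: float = 0.0
    detected: bool = False
    representative: bool = False
    locus: str = ""


def poisson_copies(n_pos: int, n_total: int, droplet_volume_nl: float = DROPLET_VOLUME_NL) -> float:
    """Estimate target concentration in copies per microliter of reaction.

    Applies the Poisson correction ``lambda = -ln(1 - n_pos/n_total)``
    (mean copies per droplet) and divides by the droplet volume.

    Raises
    ------
    SaturationError
        If every droplet is positive (the estimate diverges).
    InputError
        If there are no droplets.
    """
    if n_total <= 0:
        raise InputError("no droplets in well")
    if n_pos >= n_total:
        raise SaturationError(
            f"all {n_total} droplets positive: concentration not estimable"
        )
    lam = -math.log1p(-n_pos / n_total)
    return lam / (droplet_volume_nl * 1e-3)  # nL -> µL


def _copies_in_reaction(n_pos: int, n_total: int) -> float:
    """Total copies in the analyzed droplet volume: lambda * n_droplets."""
    if n_total <= 0:
        raise InputError("no droplets in well")
    if n_pos >= n_total:
        raise SaturationError(
            f"all {n_total} droplets positive: concentration not estimable"
        )
    return -math.log1p(-n_pos / n_total) * n_total


def quantify_sample(
    d: DropletData, threshold_maf_pct: float = DETECTION_THRESHOLD_MAF_PCT
) -> CtDNAQuant:
    """Convert droplet counts to MAF% and copies/mL plasma.

    Mutant and wild-type copy numbers in the reaction are scaled to the
    full cfDNA elution (dividing by the fraction loaded) and then to one
    milliliter of the plasma it came from. The MAF is the mutant fraction
    of total copies; it is independent of all volume constants because
    they cancel in the ratio.
    """
    mut = _copies_in_reaction(d.n_mut_pos, d.n_total)
    wt = _copies_in_reaction(d.n_wt_pos, d.n_total)
    scale = 1.0 / (d.reaction_fraction_of_elution * d.plasma_ml_extracted)
    total = mut + wt
    maf = 100.0 * mut / total if total > 0 else 0.0
    return CtDNAQuant(
        sample_id=d.sample_id,
        assay=d.assay,
        mut_copies_per_ml_plasma=mut * scale,
        wt_copies_per_ml_plasma=wt * scale,
        maf_pct=maf,
        detected=maf >= threshold_maf_pct,
    )


def copies_per_ml_from_yield(
    yield_ng_per_ml: float, maf_pct: float, pg_per_genome: float = PG_PER_GENOME
) -> float:
    """Mutant copies per mL plasma from a cfDNA yield and a MAF.

    ``copies/mL = (yield_ng_per_ml * 1000 / pg_per_genome) * maf_pct / 100``:
    the yield in pg/mL divided by the haploid genome mass gives total
    genome equivalents per mL, of which the MAF fraction is mutant.
    """
    if pg_per_genome <= 0:
        raise ConfigurationError("pg_per_genome must be positive")
    if yield_ng_per_ml < 0 or maf_pct < 0:
        raise InputError("yield and MAF must be non-negative")
    return (yield_ng_per_ml * 1000.0 / pg_per_genome) * maf_pct / 100.0


def representative_mutation(quants: list[CtDNAQuant]) -> CtDNAQuant:
    """The sample's representative ctDNA level: its highest-MAF mutation.

    Ties are broken deterministically by lexicographic locus order. The
    returned object is flagged ``representative``.
    """
    if not quants:
        raise InputError("representative_mutation requires a non-empty list")
    samples = {q.sample_id for q in quants}
    if len(samples) > 1:
        raise InputError(f"quants span multiple samples: {sorted(samples)}")
    best = min(quants, key=lambda q: (-q.maf_pct, q.locus))
    best.representative = True
    return best


def simulate_partition(
    n_mut: int,
    n_wt: int,
    n_droplets: int,
    rng: np.random.Generator,
    **kwargs,
) -> DropletData:
    """Distribute molecules uniformly over droplets and count positives.

    Forward model matching the Poisson estimator: each molecule lands in
    a uniformly chosen droplet; a droplet is probe-positive when it holds
    at least one molecule of that species.
    """
    if n_droplets <= 0:
        raise InputError("need at least one droplet")
    n_mut_pos = int(np.count_nonzero(rng.multinomial(n_mut, np.full(n_droplets, 1.0 / n_droplets))))
    n_wt_pos = int(np.count_nonzero(rng.multinomial(n_wt, np.full(n_droplets, 1.0 / n_droplets))))
    kwargs.setdefault("sample_id", "sim")
    kwargs.setdefault("assay", "sim")
    return DropletData(n_total=n_droplets, n_mut_pos=n_mut_pos, n_wt_pos=n_wt_pos, **kwargs)
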