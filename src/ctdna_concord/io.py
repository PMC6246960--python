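"""Shared readers and writers for the pipeline's file formats.

Internal coordinates are 0-based half-open everywhere; VCF's 1-based
convention is converted exactly at this boundary. The minimal VCF
dialect carries the tumor-profile annotations as INFO keys: SAMPLE,
GENE, PCHANGE, VTYPE, TMAF.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .calling import CallerThresholds
from .ddpcr import (
    DETECTION_THRESHOLD_MAF_PCT,
    DROPLET_VOLUME_NL,
    PG_PER_GENOME,
)
from .errors import ConfigurationError, ParseError
from .survival import DEFAULT_CUTPOINT_COPIES_PER_ML
from .variants import Locus, TumorVariant

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Sample identifier">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change">
##INFO=<ID=VTYPE,Number=1,Type=String,Description="Variant type">
##INFO=<ID=TMAF,Number=1,Type=Float,Description="Tumor mutant allele frequency, percent">
"""

_CSV_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "protein_change",
    "variant_type", "tumor_maf_pct",
]


def write_variant_table(
    variants: list[TumorVariant], path: str | Path, dialect: str = "vcf_minimal"
) -> None:
    """Write tumor variants as minimal VCF (1-based) or CSV (0-based)."""
    path = Path(path)
    if dialect == "csv":
        rows = [
            {
                "sample_id": v.sample_id,
                "chrom": v.locus.chrom,
                "pos": v.locus.pos,
                "ref": v.locus.ref,
                "alt": v.locus.alt,
                "gene": v.gene,
                "protein_change": v.protein_change,
                "variant_type": v.variant_type,
                "tumor_maf_pct": v.tumor_maf_pct,
            }
            for v in variants
        ]
        pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
        return
    if dialect != "vcf_minimal":
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    chroms = sorted({v.locus.chrom for v in variants})
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = (
                f"SAMPLE={v.sample_id};GENE={v.gene or '.'};"
                f"PCHANGE={v.protein_change or '.'};VTYPE={v.variant_type};"
                f"TMAF={v.tumor_maf_pct:.6g}"
            )
            fh.write(
                f"{v.locus.chrom}\t{v.locus.pos + 1}\t.\t{v.locus.ref}\t"
                f"{v.locus.alt}\t.\tPASS\t{info}\n"
            )


def read_variant_table(path: str | Path, dialect: str = "vcf_minimal") -> list[TumorVariant]:
    """Read tumor variants; VCF positions are shifted to 0-based."""
    path = Path(path)
    if dialect == "csv":
        df = pd.read_csv(path)
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}", line=1)
        out = []
        for row in df.itertuples(index=False):
            out.append(
                TumorVariant(
                    sample_id=str(row.sample_id),
                    locus=Locus(str(row.chrom), int(row.pos), str(row.ref), str(row.alt)),
                    gene=str(row.gene),
                    protein_change=str(row.protein_change),
                    variant_type=str(row.variant_type),
                    tumor_maf_pct=float(row.tumor_maf_pct),
                )
            )
        return out
    if dialect != "vcf_minimal":
        raise ConfigurationError(f"unknown dialect {dialect!r}")

    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            try:
                info = rec.info
                out.append(
                    TumorVariant(
                        sample_id=str(info.get("SAMPLE", "NA")),
                        # pysam .start is already 0-based (VCF POS - 1)
                        locus=Locus(rec.chrom, rec.start, rec.ref, rec.alts[0]),
                        gene=str(info.get("GENE", "")),
                        protein_change=str(info.get("PCHANGE", "")),
                        variant_type=str(info.get("VTYPE", "SNV")),
                        tumor_maf_pct=float(info.get("TMAF", float("nan"))),
                    )
                )
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}: malformed VCF record at {rec.chrom}:{rec.pos}: {exc}")
    return out


@dataclass
class PipelineConfig:
    """Everything the end-to-end driver needs, with assay defaults."""

    n_patients: int = 180
    seed: int = 0
    thresholds: CallerThresholds = field(default_factory=CallerThresholds)
    ddpcr_threshold_maf_pct: float = DETECTION_THRESHOLD_MAF_PCT
    droplet_volume_nl: float = DROPLET_VOLUME_NL
    pg_per_genome: float = PG_PER_GENOME
    cutpoint: float | str = "auto"  # "auto" => maxstat search
    min_group_fraction: float = 0.1
    default_cutpoint: float = DEFAULT_CUTPOINT_COPIES_PER_ML
    n_molecules_ngs: int = 3000
    plasma_ml_extracted: float = 2.0
    reaction_fraction_of_elution: float = 0.25
    n_droplets: int = 20000
    outdir: str = "results"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        thr = d.pop("thresholds", {})
        cfg = cls(**d)
        if isinstance(thr, dict):
            cfg.thresholds = CallerThresholds(**thr)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        try:
            return cls.from_dict(data)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}")
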