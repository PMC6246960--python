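"""Simulation and I/O of aligned plasma cfDNA read records.

Reads are abstract alignment records at a single query locus: we track
only the coordinates (0-based, half-open, the BED/pysam convention),
an optional UMI tag, the allele the read reports at the
query position, and the strand. Each original cfDNA molecule gives rise
to one *read family*: all of its PCR/sequencing copies. With positional
(endogenous-UMI) chemistry the family is identified by the shared
alignment start/end; with tagged chemistry by an explicit UMI; amplicon
chemistry produces no family structure at all (every read shares the
amplicon's coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, ParseError
from .variants import Locus, SNV, VARIANT_TYPES

READ_COLUMNS = ["sample_id", "chrom", "start", "end", "umi", "allele", "strand"]
ALLELES = ("ref", "alt", "other")

#: Default family-size distribution: geometric-like with mean ~6 reads
#: per original molecule. A fixture choice, not a claim about any assay.
DEFAULT_FAMILY_SIZE_DIST = {
    1: 0.10, 2: 0.10, 3: 0.12, 4: 0.12, 5: 0.12, 6: 0.11,
    7: 0.09, 8: 0.07, 9: 0.05, 10: 0.04, 12: 0.04, 15: 0.04,
}


@dataclass
class ReadSimParams:
    """Configuration for one simulated locus."""

    locus: Locus
    variant_type: str = SNV
    n_molecules: int = 1000
    maf_molecular: float = 1.0  # percent of molecules carrying alt
    family_size_dist: dict[int, float] | None = None
    error_rate: float = 0.001
    chemistry: str = "positional"  # positional | tagged_umi | amplicon
    collision_rate: float = 0.0  # positional only: P(molecule reuses an earlier key)
    sample_id: str = "S1"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.maf_molecular <= 100.0:
            raise ConfigurationError("maf_molecular must be in [0, 100]")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ConfigurationError("error_rate must be in [0, 0.05]")
        if self.chemistry not in ("positional", "tagged_umi", "amplicon"):
            raise ConfigurationError(f"unknown chemistry {self.chemistry!r}")
        if self.variant_type not in VARIANT_TYPES:
            raise ConfigurationError(f"unknown variant type {self.variant_type!r}")
        dist = self.family_size_dist or DEFAULT_FAMILY_SIZE_DIST
        if abs(sum(dist.values()) - 1.0) > 1e-9:
            raise ConfigurationError("family_size_dist must sum to 1")
        if any(s < 1 for s in dist):
            raise ConfigurationError("family sizes must be >= 1")
        if self.n_molecules == 0 and self.maf_molecular > 0:
            raise ConfigurationError("n_molecules=0 with maf>0 has no molecules to mutate")
        if not 0.0 <= self.collision_rate < 1.0:
            raise ConfigurationError("collision_rate must be in [0, 1)")


def simulate_read_families(params: ReadSimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit reads with family structure plus a per-molecule truth table.

    Each molecule draws its family size from ``family_size_dist`` and its
    true allele (alt with probability ``maf_molecular``%). Every read
    reports the molecule's true allele, flipped ref<->alt independently
    with probability ``error_rate`` and replaced by a third ("other")
    allele with probability ``error_rate/3`` — so that at MAF 0 the
    expected alt-read fraction equals the configured error rate.

    Returns ``(reads, truth)``; ``truth`` has one row per molecule with
    its family key and true allele.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_molecules
    locus = params.locus

    dist = params.family_size_dist or DEFAULT_FAMILY_SIZE_DIST
    size_values = np.array(sorted(dist), dtype=int)
    size_probs = np.array([dist[s] for s in size_values], dtype=float)
    size_probs = size_probs / size_probs.sum()

    if n == 0:
        empty = pd.DataFrame(columns=READ_COLUMNS)
        truth = pd.DataFrame(columns=["molecule", "chrom", "start", "end", "umi", "true_allele"])
        return empty, truth

    is_alt = rng.random(n) < params.maf_molecular / 100.0
    sizes = rng.choice(size_values, size=n, p=size_probs)

    # Family keys per chemistry.
    pos = locus.pos
    if params.chemistry == "amplicon":
        starts = np.full(n, max(pos - 60, 0))
        ends = np.full(n, pos + 60)
        umis = np.full(n, ".", dtype=object)
    else:
        idx = np.arange(n)
        starts = np.maximum(pos - 1 - (idx % 150), 0)
        ends = pos + 1 + idx // 150
        if params.chemistry == "tagged_umi":
            umis = np.array([f"UMI{i:07d}" for i in idx], dtype=object)
            # tagged molecules share a modest set of fragment coordinates
            starts = np.maximum(pos - 1 - rng.integers(0, 60, size=n), 0)
            ends = pos + 1 + rng.integers(0, 60, size=n)
        else:
            umis = np.full(n, ".", dtype=object)
            if params.collision_rate > 0 and n > 1:
                collide = np.flatnonzero(rng.random(n) < params.collision_rate)
                collide = collide[collide > 0]
                for i in collide:
                    j = int(rng.integers(0, i))
                    starts[i], ends[i] = starts[j], ends[j]

    truth = pd.DataFrame(
        {
            "molecule": np.arange(n),
            "chrom": locus.chrom,
            "start": starts,
            "end": ends,
            "umi": umis,
            "true_allele": np.where(is_alt, "alt", "ref"),
            "family_size": sizes,
        }
    )

    # Expand molecules into reads and inject error.
    mol_idx = np.repeat(np.arange(n), sizes)
    n_reads = mol_idx.size
    true_allele = np.where(is_alt, "alt", "ref")[mol_idx].astype(object)
    u = rng.random(n_reads)
    e = params.error_rate
    flipped = np.where(true_allele == "alt", "ref", "alt").astype(object)
    allele = true_allele.copy()
    allele[u < e] = flipped[u < e]
    allele[(u >= e) & (u < e + e / 3.0)] = "other"

    reads = pd.DataFrame(
        {
            "sample_id": params.sample_id,
            "chrom": locus.chrom,
            "start": starts[mol_idx],
            "end": ends[mol_idx],
            "umi": umis[mol_idx],
            "allele": allele,
            "strand": np.where(rng.random(n_reads) < 0.5, "+", "-"),
        }
    )
    return reads, truth


def write_sam_lite(reads: pd.DataFrame, path: str | Path) -> None:
    """Write reads as tab-separated SAM-lite with a header row.

    Columns: sample_id, chrom, start, end, umi, allele, strand;
    absent UMIs are written as ".".
    """
    df = reads.loc[:, READ_COLUMNS].copy()
    df["umi"] = df["umi"].fillna(".")
    df.to_csv(path, sep="\t", index=False)


def read_sam_lite(path: str | Path) -> pd.DataFrame:
    """Read a SAM-lite TSV, validating coordinates per line."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"umi": str, "sample_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}", line=1)
    if df.empty:
        return df.astype({"start": int, "end": int}).loc[:, READ_COLUMNS]
    for col in ("start", "end"):
        if not pd.api.types.is_integer_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            line = int(bad[0]) + 2 if len(bad) else None
            raise ParseError(f"{path}: non-integer {col}", line=line)
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        # +2: one for the header row, one for 1-based line numbering
        raise ParseError(f"{path}: start >= end", line=int(bad[0]) + 2)
    df["umi"] = df["umi"].fillna(".")
    return df.loc[:, READ_COLUMNS]


def write_sam(reads: pd.DataFrame, path: str | Path, umi_tag: str = "RX") -> None:
    """Export reads as standard SAM with the UMI in a tag field."""
    import pysam

    chroms = sorted(reads["chrom"].unique()) if len(reads) else ["chr1"]
    max_end = int(reads["end"].max()) + 1000 if len(reads) else 1000
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": max_end} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, row in enumerate(reads.itertuples(index=False)):
            a = pysam.AlignedSegment()
            a.query_name = f"{row.sample_id}.read{i}"
            length = int(row.end) - int(row.start)
            a.query_sequence = "N" * length
            a.flag = 16 if row.strand == "-" else 0
            a.reference_id = tid[row.chrom]
            a.reference_start = int(row.start)
            a.mapping_quality = 60
            a.cigarstring = f"{length}M"
            tags = [("ZA", str(row.allele)), ("ZS", str(row.sample_id))]
            if row.umi and row.umi != ".":
                tags.append((umi_tag, str(row.umi)))
            a.tags = tags
            out.write(a)


def read_sam(path: str | Path, umi_tag: str = "RX") -> pd.DataFrame:
    """Import reads from a standard SAM written by :func:`write_sam`."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r") as f:
        for a in f:
            rows.append(
                {
                    "sample_id": a.get_tag("ZS") if a.has_tag("ZS") else "NA",
                    "chrom": a.reference_name,
                    "start": a.reference_start,
                    "end": a.reference_end,
                    "umi": a.get_tag(umi_tag) if a.has_tag(umi_tag) else ".",
                    "allele": a.get_tag("ZA") if a.has_tag("ZA") else "other",
                    "strand": "-" if a.is_reverse else "+",
                }
            )
    return pd.DataFrame(rows, columns=READ_COLUMNS)
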