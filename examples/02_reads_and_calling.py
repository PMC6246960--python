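"""Simulate sequencing read families at one locus and run the callers.

Each cfDNA molecule yields a small family of duplicate reads (PCR +
sequencing). Grouping reads back into families — by start/end position
or by a molecular barcode (UMI) — lets a caller demand that a variant be
seen in multiple independent molecules with internally consistent
families, which suppresses polymerase and sequencing errors.
"""

from ctdna_concord import ReadSimParams, simulate_read_families, Locus
from ctdna_concord.calling import (
    call_amplicon,
    call_dnaseq_positional,
    call_tagseq_ckv,
    collapse_consensus,
    group_positional_families,
    group_umi_families,
)

locus = Locus("chr7", 55_242_464, "A", "T")

# --- positional chemistry + family-consensus caller -----------------------
reads, truth = simulate_read_families(
    ReadSimParams(locus=locus, chemistry="positional", n_molecules=2000,
                  maf_molecular=0.5, error_rate=0.001, seed=11)
)
families = group_positional_families(reads)
call = call_dnaseq_positional(families, locus=str(locus))
n_true_alt = (truth["true_allele"] == "alt").sum()
print(f"positional: {len(truth)} molecules ({n_true_alt} truly mutant), "
      f"{len(families)} families")
print(f"  detected={call.detected}  supporting families={call.supporting_families}")

# --- tagged-UMI chemistry + consensus-key-value caller --------------------
reads, truth = simulate_read_families(
    ReadSimParams(locus=locus, chemistry="tagged_umi", n_molecules=2000,
                  maf_molecular=0.5, error_rate=0.001, seed=12)
)
consensus = collapse_consensus(group_umi_families(reads))
call = call_tagseq_ckv(consensus, locus=str(locus))
print(f"tagged UMI: consensus depth {len(consensus.reads)}, "
      f"detected={call.detected}, %SR={call.sr_pct:.2f}")

# --- amplicon chemistry + binomial caller ---------------------------------
reads, truth = simulate_read_families(
    ReadSimParams(locus=locus, chemistry="amplicon", n_molecules=2000,
                  maf_molecular=0.5, error_rate=0.001, seed=13)
)
call = call_amplicon(reads, locus=str(locus))
print(f"amplicon  : depth {len(reads)}, detected={call.detected}, "
      f"confidence={call.confidence:.1f} (Phred), %SR={call.sr_pct:.2f}")
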