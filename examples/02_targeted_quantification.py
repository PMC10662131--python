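"""Quantify megakaryocyte cfDNA from targeted bisulfite amplicon reads.

Simulates 2000 sequenced molecules of one 5-CpG MK marker in a sample whose
true MK-derived fraction is 20%, classifies each molecule (unmethylated with
up to one methylated-CpG exception for MK markers), audits bisulfite
conversion at non-CpG cytosines, and converts the unmethylated fraction to
genome equivalents per ml plasma: fraction x cfDNA ng/ml x 303.
"""

import cforigin as cf
from cforigin import synthetic as syn

reads, n_true = syn.simulate_amplicon_reads(
    "MK_marker_0", true_fraction=0.20, n_reads=2_000,
    conversion_failure_rate=0.005, sequencing_error_rate=0.001, seed=3,
)

rule = cf.ClassificationRule(max_methylated=1)  # MK one-exception rule
mf = cf.marker_fraction(reads, rule)
qc = cf.conversion_qc(reads, min_rate=0.98)

cfdna_ng_per_ml = 10.0
ge = cf.ge_per_ml(mf.fraction, cfdna_ng_per_ml)

print(f"molecules sequenced:        {mf.n_reads}")
print(f"unmethylated molecules:     {mf.n_unmethylated}")
print(f"unmethylated fraction:      {mf.fraction:.4f} (true spiked: {n_true / 2000:.4f})")
print(f"bisulfite conversion rate:  {qc.conversion_rate:.4f} (pass: {qc.passed})")
print(f"MK cfDNA concentration:     {ge:.0f} GE/ml at {cfdna_ng_per_ml} ng/ml total cfDNA")
# The GE/ml figure is the number of haploid megakaryocyte genome equivalents
# per ml plasma (1 ng of DNA = 303 haploid genomes of 3.3 pg each).
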