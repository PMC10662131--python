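"""Platelet WGBS composition: chromosome representation and per-platelet DNA.

Simulates low-coverage WGBS chromosome counts of platelet DNA (59%
mitochondrial, with chr4 over- and chr17 under-representation), then derives
the mitochondrial fraction, per-chromosome enrichment relative to reference
length, and the implied genomic DNA content per platelet.
"""

import cforigin as cf
from cforigin import synthetic as syn

counts, expected = syn.simulate_wgbs_counts(syn.WgbsConfig(n_reads=100_000), seed=9)

mito = cf.mito_fraction(counts)
rep = cf.chromosome_representation(counts, exclude=(counts.mt_name(),))
print(f"mitochondrial DNA fraction: {mito:.3f}")
print(f"chr4 enrichment (nuclear):  {rep.loc['chr4', 'enrichment']:.2f}")
print(f"chr17 enrichment (nuclear): {rep.loc['chr17', 'enrichment']:.2f}")

# consistency arithmetic: 5 mitochondria x 16.569 kb at the measured fraction
kb = cf.genomic_kb_per_platelet(5, 16.569, mito_dna_fraction=mito)
gpp = cf.genomes_per_platelet(total_dna_ng=3.3, platelet_count=int(5e8))
print(f"genomic DNA per platelet:   {kb:.1f} kb")
print(f"genomes per platelet:       {gpp:.1e}")
# ~57 kb of nuclear DNA per platelet and ~2e-6 haploid genomes/platelet mean
# each platelet traps only ~0.1% of its parent megakaryocyte's genome.
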