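# Toy annotation-guideline-style stop list: biological or ambiguous terms
# excluded from chemical annotation by convention.
dna
enzyme
hormone
insulin
lead
lipid
peptide
protein
rna
water
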