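# Toy Jochem-style stop list: chemistry-adjacent common nouns (may be
# multi-word) that are rarely annotated as chemical entities.
acid
base
buffer
compound
crystal
gas
metal
mineral
oil
salt
solution
solvent
water solution
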