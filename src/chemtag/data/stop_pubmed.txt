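# Toy PubMed-style stop list: frequent abstract vocabulary.
also
among
analysis
been
can
cells
compared
control
data
during
effect
found
group
has
have
however
increased
its
levels
method
observed
patients
results
showed
study
these
treatment
using
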