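# Toy basic-English stop list: short common words that dictionary taggers
# extract constantly but that are almost never chemical mentions.
a
about
after
all
and
as
at
be
between
both
by
do
for
from
in
is
it
make
may
most
no
not
of
on
or
so
the
this
to
was
we
were
which
with
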