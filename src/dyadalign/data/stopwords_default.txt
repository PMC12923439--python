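0
1
10
11
12
2
3
4
5
6
7
8
9
a
about
across
ah
along
alright
among
an
around
at
behind
beside
between
beyond
by
bye
can
could
down
during
eh
eight
eleven
er
erm
five
for
four
from
goodbye
gosh
he
hello
her
hers
herself
hey
hi
him
himself
his
hm
hmm
howdy
huh
i
in
inside
into
it
its
itself
may
me
mhm
might
mine
mm
must
my
myself
nine
no
nope
of
off
oh
ok
okay
on
one
onto
ought
our
ours
ourselves
out
outside
over
really
right
seven
shall
she
should
six
ten
that
the
their
theirs
them
themselves
these
they
this
those
three
through
to
toward
towards
twelve
two
uh
uhhuh
um
under
up
upon
us
we
welcome
what
which
who
whom
whose
will
with
within
without
would
wow
yeah
yep
yes
you
your
yours
yourself
yourselves
zero
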