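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
again
ah
along
alright
also
although
always
am
among
an
and
anyway
are
around
as
at
be
because
been
behind
being
beside
between
beyond
but
by
bye
can
could
did
do
does
doing
down
during
eh
eight
eleven
er
erm
even
five
for
four
from
goodbye
gosh
had
has
have
having
he
hello
her
here
hers
herself
hey
hi
him
himself
his
hm
hmm
how
howdy
huh
i
if
in
inside
into
is
it
its
itself
just
may
maybe
me
mhm
might
mine
mm
must
my
myself
never
nine
no
nope
nor
not
now
of
off
often
oh
ok
okay
on
one
only
onto
or
ought
our
ours
ourselves
out
outside
over
perhaps
quite
rather
really
right
seven
shall
she
should
six
so
sometimes
still
such
ten
than
that
the
their
theirs
them
themselves
then
there
these
they
this
those
though
three
through
to
too
toward
towards
twelve
two
uh
uhhuh
um
under
unless
until
up
upon
us
very
was
we
welcome
well
were
what
when
where
whether
which
while
who
whom
whose
why
will
with
within
without
would
wow
yeah
yep
yes
yet
you
your
yours
yourself
yourselves
zero
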