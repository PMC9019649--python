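# English function words: prepositions, conjunctions, pronouns,
# auxiliaries, determiners. One word per line; lines starting with #
# are comments. Articles (a, an, the) are listed here too but are
# additionally flagged as articles by the tokenizer.
a
an
the
and
or
but
nor
so
yet
for
if
then
than
because
although
though
while
whereas
unless
until
since
when
whenever
where
wherever
whether
that
which
who
whom
whose
what
whatever
this
these
those
i
me
my
mine
myself
we
us
our
ours
ourselves
you
your
yours
yourself
yourselves
he
him
his
himself
she
her
hers
herself
it
its
itself
they
them
their
theirs
themselves
one
ones
someone
somebody
something
anyone
anybody
anything
everyone
everybody
everything
noone
nobody
nothing
be
am
is
are
was
were
been
being
have
has
had
having
do
does
did
doing
will
would
shall
should
may
might
must
can
could
ought
in
on
at
by
to
of
from
with
without
within
into
onto
upon
about
above
below
under
over
between
among
through
throughout
during
before
after
against
along
across
around
behind
beside
besides
beyond
despite
down
up
off
out
near
per
toward
towards
via
as
not
no
nor
too
very
also
just
only
such
both
each
either
neither
few
more
most
other
some
any
all
own
same
s
t
don
now
here
there
how
why
again
further
once
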