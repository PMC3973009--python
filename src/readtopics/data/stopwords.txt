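# Default English stop-word list: function words (articles, prepositions,
# conjunctions, pronouns, auxiliaries) and a few high-frequency adverbs.
# One word per line; lines starting with '#' are comments.
a
about
above
across
after
again
against
all
almost
along
already
also
although
always
am
among
an
and
another
any
anyone
anything
are
around
as
at
be
because
been
before
being
below
between
both
but
by
can
cannot
could
did
do
does
doing
done
down
during
each
either
else
enough
etc
even
ever
every
few
for
from
further
had
has
have
having
he
her
here
hers
herself
him
himself
his
how
however
i
if
in
into
is
it
its
itself
just
least
less
many
may
me
might
more
most
much
must
my
myself
neither
no
nor
not
now
of
off
often
on
once
one
only
onto
or
other
our
ours
ourselves
out
over
own
per
rather
same
she
should
since
so
some
somewhat
still
such
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
through
throughout
thus
to
together
too
toward
towards
under
until
up
upon
us
very
was
we
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
yet
you
your
yours
yourself
yourselves
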