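about
above
after
again
against
all
and
any
are
because
been
before
being
below
between
both
but
can
cannot
could
did
does
doing
down
during
each
few
for
from
further
had
has
have
having
her
here
hers
herself
him
himself
his
how
into
its
itself
just
more
most
myself
nor
not
now
off
once
only
other
our
ours
ourselves
out
over
own
same
she
should
some
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
too
under
until
very
was
were
what
when
where
which
while
who
whom
why
will
with
would
you
your
yours
yourself
yourselves
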