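# Synthetic best-effort reconstruction of a compact "BIOSSES-style" English
# stop list (the original list is not published); replace this file to use
# the exact list from another toolkit.
a
about
after
again
against
all
also
although
among
an
and
any
are
as
at
be
because
been
before
being
between
both
but
by
can
could
did
do
does
during
each
either
for
from
further
had
has
have
having
here
how
however
if
in
into
is
it
its
itself
just
may
might
more
most
much
must
neither
no
nor
not
of
off
on
once
only
or
other
our
out
over
per
shall
should
since
so
some
such
than
that
the
their
them
then
there
therefore
these
they
this
those
through
thus
to
under
until
upon
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
would
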