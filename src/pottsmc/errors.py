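"""Exception types shared across the package."""


class PottsError(Exception):
    """Base class for package-specific errors."""


class LatticeBoundsError(PottsError, IndexError):
    """A site lies outside the lattice."""


class UnknownIndexError(PottsError, KeyError):
    """A cell index outside the index set Sigma = {0, ..., K} was requested."""


class MissingInteractionError(PottsError, KeyError):
    """The surface-energy matrix has no entry for a required type pair."""


class StateSpaceCapExceeded(PottsError, ValueError):
    """Enumerating the configuration space would exceed the configured cap."""


class PreconditionError(PottsError, ValueError):
    """An operation's precondition on its input is violated."""


class InternalConsistencyError(PottsError, RuntimeError):
    """Two independent computations of the same object disagree.

    Raised (never silently patched) when e.g. the present-index class
    decomposition does not match the graph-theoretic communication classes.
    """


class ConfigurationError(PottsError, ValueError):
    """A model or experiment configuration is invalid or incomplete."""
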