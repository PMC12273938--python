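"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`InputError` -> 2,
:class:`DegenerateStatisticsError` -> 3.
"""


class PleogradeError(Exception):
    """Base class for all package-specific errors."""


class InputError(PleogradeError):
    """Malformed, missing or contract-violating input data."""


class DegenerateStatisticsError(PleogradeError):
    """A statistic is undefined on this input (zero variance, empty group, ...)."""


class ResamplingError(PleogradeError):
    """Rejection-sampling budget exhausted; the requested distribution is infeasible."""


class PlacementError(PleogradeError):
    """Could not place the requested nuclei in the field within the attempt budget."""
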