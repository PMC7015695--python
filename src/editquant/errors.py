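"""Exception hierarchy for editquant.

All library errors derive from :class:`EditQuantError` so callers (and the
CLI) can catch one base class; subclasses distinguish bad user input from
model-construction failures and from statistics that are undefined on the
given data (which are reported, never silently returned as NaN).
"""


class EditQuantError(Exception):
    """Base class for all editquant errors."""


class InputError(EditQuantError, ValueError):
    """Malformed input (non-ACGT sequence, empty read, bad parameter)."""


class ModelError(EditQuantError, ValueError):
    """A reference/donor model violates its structural invariants."""


class ConstraintInfeasibleError(EditQuantError):
    """Rejection sampling could not satisfy the sequence constraints."""


class NoFragmentError(EditQuantError):
    """No restriction cut downstream of the primer: no ligation fragment."""


class UndefinedStatisticError(EditQuantError):
    """A frequency/percentage has an empty denominator."""


class ConfigError(EditQuantError, ValueError):
    """Invalid or unknown run-configuration keys/values."""
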