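"""Exception hierarchy for ibrkit."""


class IbrkitError(Exception):
    """Base class for all ibrkit errors."""


class ParameterError(IbrkitError, ValueError):
    """Invalid parameter values (negative sizes, out-of-range rates, ...)."""


class FormatError(IbrkitError, ValueError):
    """Malformed input file (GENEPOP, ASCII grid, matrix CSV)."""


class PlacementError(IbrkitError, RuntimeError):
    """Focal-group placement could not satisfy the separation constraint."""


class ConnectivityError(IbrkitError, RuntimeError):
    """Resistor network is disconnected between focal nodes."""


class UndefinedStatisticError(IbrkitError, ArithmeticError):
    """A statistic is undefined for this input (e.g. FIS with Hexp = 0)."""


class CombinationError(IbrkitError, ValueError):
    """Coefficient-weighted surface combination is undefined (mixed signs, ...)."""
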