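"""Exception hierarchy shared across mockforge modules."""


class MockforgeError(Exception):
    """Base class for all mockforge errors."""

    exit_code = 1


class RegistryLoadError(MockforgeError):
    """Malformed or inconsistent strain registry table."""

    exit_code = 2


class DegenerateCompositionError(MockforgeError):
    """GC fraction leaves no adenine to measure (gc >= 1) or is invalid."""

    exit_code = 3


class NoReferenceError(MockforgeError):
    """A counting reference (e.g. bead events) is missing."""

    exit_code = 4


class InsufficientDataError(MockforgeError):
    """Too few observations for the requested statistic."""

    exit_code = 5


class DomainError(MockforgeError):
    """Numeric input outside the operation's domain."""

    exit_code = 6


class InsufficientStockError(MockforgeError):
    """A mixing recipe needs more stock volume than is available."""

    exit_code = 7


class InfeasibleDesignError(MockforgeError):
    """Stocks are too dilute to reach the design concentration."""

    exit_code = 8


class SaturationError(MockforgeError):
    """All ddPCR droplets positive; Poisson estimate undefined."""

    exit_code = 9


class NoDataError(MockforgeError):
    """Empty measurement (zero droplets, all-zero counts, ...)."""

    exit_code = 10


class SchemaError(MockforgeError):
    """Input table does not match the expected column layout."""

    exit_code = 11


class ConsistencyError(MockforgeError):
    """Cross-referenced inputs disagree (strain sets, designs, ...)."""

    exit_code = 12


class ConfigError(MockforgeError):
    """Invalid simulation or design configuration."""

    exit_code = 13
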