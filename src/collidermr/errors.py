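"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration errors -> 2, data errors
-> 3, numerical failures -> 4.
"""


class ColliderMRError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ColliderMRError, ValueError):
    """Invalid simulation / estimator / SIMEX configuration."""


class DataError(ColliderMRError, ValueError):
    """Malformed or unusable input data (missing values, bad shapes...)."""


class SingularDesignError(DataError):
    """Rank-deficient regression design, e.g. duplicated SNP columns."""


class NumericalError(ColliderMRError, RuntimeError):
    """A solver failed to converge or produced an unusable result."""
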