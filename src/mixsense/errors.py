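"""Exception hierarchy shared across the package."""


class MixsenseError(Exception):
    """Base class for all package-specific errors."""


class VcfError(MixsenseError):
    """A VCF could not be read or lacks required fields."""


class MissingSampleError(VcfError):
    """The requested sample is not present in a multi-sample VCF."""


class DepthTableError(MixsenseError):
    """A per-base coverage table is malformed."""


class DesignError(MixsenseError):
    """A mixture design or run configuration is inconsistent."""


class FitError(MixsenseError):
    """A probit sensitivity fit failed or produced an invalid estimate."""


class ConfigError(MixsenseError):
    """A run configuration file is invalid."""
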