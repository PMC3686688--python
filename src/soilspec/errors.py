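"""Named exceptions raised across the pipeline."""


class SoilSpecError(ValueError):
    """Base class for domain validation failures."""


class UnknownSubsetError(SoilSpecError):
    """An unrecognised library subset name was requested."""


class UnknownRecipeError(SoilSpecError):
    """An unrecognised pre-treatment or predictor recipe was requested."""


class ConstantSpectrumError(SoilSpecError):
    """A per-spectrum scaling (SNV) met a zero-variance spectrum."""


class ConstantColumnError(SoilSpecError):
    """A predictor column had zero variance where scaling was required."""


class UndefinedStatisticError(SoilSpecError):
    """A validation statistic is undefined for the given inputs."""


class FormatError(SoilSpecError):
    """A file did not conform to the documented library format."""


class ConfigError(SoilSpecError):
    """A run configuration failed schema validation."""
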