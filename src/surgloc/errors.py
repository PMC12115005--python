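"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A config object or option combination is invalid."""


class DataError(ValueError):
    """Input data are malformed, misaligned, or empty where content is required."""


class ShapeError(ValueError):
    """Array arguments disagree in length or dimensionality."""


class DegenerateClassError(ValueError):
    """A class has zero training samples, so its balancing weight is undefined."""


class DegenerateImageError(ValueError):
    """An image is constant, so foreground/background separation is undefined."""


class UndefinedAPError(ValueError):
    """Average precision is undefined because the class has no positive labels."""
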