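"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration object violates its invariants."""


class DerivationError(RuntimeError):
    """A prompt cannot be derived from the given mask."""


class ShapeError(ValueError):
    """Array shapes are inconsistent with the architecture or each other."""


class TrainingError(RuntimeError):
    """Training diverged (non-finite loss)."""


class ValidationError(ValueError):
    """Loaded data violates the dataset contract (e.g. non-binary mask labels)."""
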