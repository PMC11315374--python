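"""Exception types for contract violations."""


class ShapeMismatchError(ValueError):
    """Two feature maps that must agree in shape do not."""


class ConfigurationError(ValueError):
    """A model/block configuration violates a structural invariant."""


class DataError(ValueError):
    """Labels, vocabularies or records violate a data contract."""
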