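"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Invalid configuration: bad parameter combination, unknown key, missing sidecar."""


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two modes above background; no valley to pick."""


class ThresholdSearchError(RuntimeError):
    """No threshold in the bracket satisfies the shape-area constraint."""


class ReferenceSegmentationError(RuntimeError):
    """A tooth could not be segmented on the user-chosen reference slice."""
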