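"""Package-wide exception types."""


class InvalidConfigError(ValueError):
    """A simulation or estimator configuration violates its invariants."""


class NoSignalError(RuntimeError):
    """An estimate is requested from data carrying no usable signal
    (e.g. zero retained depth segments, zero coverage-reference reads)."""
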