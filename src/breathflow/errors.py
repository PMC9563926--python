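"""Exception hierarchy for the breathflow pipeline."""


class BreathflowError(Exception):
    """Base class for all pipeline errors."""


class EmptySessionError(BreathflowError):
    """A scan stream contained no usable MS1 scans."""


class MzxmlParseError(BreathflowError):
    """Malformed mzXML; message names the offending scan where possible."""


class CalibrationError(BreathflowError):
    """Mass recalibration could not be fitted (too few calibrants matched)."""


class NoBreathDetectedError(BreathflowError):
    """No scan passed the exhalation gate — a failed measurement."""


class NormalizationError(BreathflowError):
    """Invalid normalization request (wrong state order, zero TIC, ...)."""


class StatsError(BreathflowError):
    """Degenerate statistical input (empty sample, group too small, ...)."""


class ClassificationError(BreathflowError):
    """Invalid classification setup (single class, fewer subjects than folds)."""


class ConfigError(BreathflowError):
    """Invalid or incomplete run configuration."""
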