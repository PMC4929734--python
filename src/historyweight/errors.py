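"""Exception hierarchy for the history weighting pipeline."""


class HistoryWeightError(Exception):
    """Base class for all package-specific errors."""


class EmptyCohortError(HistoryWeightError):
    """An operation that requires probands received none."""


class ConfigError(HistoryWeightError):
    """A configuration value is out of its legal range or inconsistent."""


class IneligibleProbandError(HistoryWeightError):
    """A proband that fails the eligibility rules reached a scoring step."""


class DegenerateTableError(HistoryWeightError):
    """Conditional probability table estimation needs both carriers and non-carriers."""


class InsufficientProbandsError(HistoryWeightError):
    """Fewer qualifying proband observations than the scoring policy minimum."""


class PoolExhaustedError(HistoryWeightError):
    """A composite-control pool is empty where a hard error is required."""


class StratumExhaustedError(HistoryWeightError):
    """Not enough probands (or source variants) in the requested truth stratum."""


class UndefinedPredictiveValueError(HistoryWeightError):
    """PPV or NPV is 0/0 because no calls were made on the relevant side."""


class CalibrationError(HistoryWeightError):
    """No grid pair satisfied the calibration admissibility criterion."""

    def __init__(self, message, best_near_miss=None):
        super().__init__(message)
        self.best_near_miss = best_near_miss


class ParseError(HistoryWeightError):
    """A delimited input file is malformed; carries file/line context."""

    def __init__(self, message, path=None, line=None):
        loc = f"{path or '<input>'}:{line}" if line is not None else str(path or "<input>")
        super().__init__(f"{loc}: {message}")
        self.path = path
        self.line = line
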