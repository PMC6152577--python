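"""Exception hierarchy for the two-sample MR pipeline."""


class TsmrError(Exception):
    """Base class for all package errors."""


class FormatError(TsmrError):
    """A summary-statistic table is structurally unusable (e.g. missing a mandatory column)."""


class ValidationError(TsmrError):
    """A value violates a domain invariant (allele symbol, SE <= 0, p outside (0,1], ...)."""


class EmptyInstrumentError(TsmrError):
    """No instruments survive selection/harmonization; downstream estimators cannot run."""


class InsufficientInstrumentsError(TsmrError):
    """Fewer instruments than the estimator's minimum (3 for MR-Egger and weighted median)."""


class ScaleError(TsmrError):
    """An estimate was used on the wrong analysis scale (e.g. exponentiating a continuous-outcome beta)."""
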