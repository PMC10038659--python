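"""Exception hierarchy for the eccquant pipeline."""


class EccQuantError(Exception):
    """Base class for all eccquant errors."""


class ConsistencyError(EccQuantError):
    """Cross-referenced inputs disagree (e.g. an accession missing from the database)."""


class DataError(EccQuantError):
    """Malformed or degenerate input data (zero channel totals, bad TSV cells, ...)."""


class DesignError(EccQuantError):
    """An experimental design that cannot support the requested computation."""


class QuantificationError(EccQuantError):
    """A peptide or protein could not be quantified (e.g. no heavy-reference signal)."""


class FitError(EccQuantError):
    """A model fit is impossible on the given inputs (degenerate regressors, ...)."""
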