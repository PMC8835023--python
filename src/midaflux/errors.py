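"""Exception hierarchy.

The CLI maps these onto distinct exit codes: input/validation problems
(:class:`ValidationError`) exit with 2, mathematically degenerate inputs
(:class:`DegenerateEnrichmentError`) with 3.
"""


class MidafluxError(Exception):
    """Base class for all package errors."""


class ValidationError(MidafluxError):
    """Invalid user input: bad sequence, missing column, malformed table."""


class DegenerateEnrichmentError(MidafluxError):
    """Precursor enrichment is degenerate (p = 0 or EMmax = 0): fractional
    synthesis is undefined."""
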