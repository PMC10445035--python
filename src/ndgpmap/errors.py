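"""Exception hierarchy for ndgpmap."""


class NDGPMapError(Exception):
    """Base class for all ndgpmap errors."""


class InvalidGenotypeError(NDGPMapError):
    """A genotype string does not belong to the declared genotype space."""


class MapFormatError(NDGPMapError):
    """A GP-map file violates the TSV dialect (bad header, duplicate rows, ...)."""


class MapValidationError(NDGPMapError):
    """A map violates a semantic invariant (e.g. non-normalized distributions).

    ``offenders`` lists the genotypes (or entities) that failed validation.
    """

    def __init__(self, message: str, offenders: list | None = None):
        super().__init__(message)
        self.offenders = list(offenders or [])


class UndefinedQuantityError(NDGPMapError):
    """A quantity is undefined for the given input (empty neutral set, zero variance, ...)."""


class SampledMapEstimationError(NDGPMapError):
    """The requested quantity cannot be estimated from a genotype sample.

    Phenotypic evolvability is the canonical case: it depends on the whole
    neutral set and cannot be inferred reliably from random sequence samples.
    """


class StateSpaceError(NDGPMapError):
    """A brute-force enumeration would exceed the configured state-space guard."""


class FoldingBackendError(NDGPMapError):
    """The thermodynamic folding engine failed for a sequence."""
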