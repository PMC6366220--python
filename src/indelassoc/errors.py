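"""Exception hierarchy for the indel-association toolkit."""


class IndelAssocError(Exception):
    """Base class for all package-specific errors."""


class CohortValidationError(IndelAssocError):
    """A cohort file or in-memory cohort violates the data contract.

    Carries ``row_errors``: a list of ``(row_number, message)`` pairs so a
    caller can report every offending line, not just the first.
    """

    def __init__(self, message: str, row_errors=None):
        super().__init__(message)
        self.row_errors = list(row_errors or [])


class UnknownLocusError(IndelAssocError, KeyError):
    """A locus name does not refer to any locus declared in the cohort."""


class EmptyLocusError(IndelAssocError):
    """No animals carry a non-missing genotype at the requested locus."""


class DegenerateLocusError(IndelAssocError):
    """A genotype configuration for which the requested statistic is undefined."""


class UndefinedLDError(IndelAssocError):
    """Linkage disequilibrium is undefined (a locus is monomorphic)."""


class EmptyTableError(IndelAssocError):
    """A contingency table with no complete observations."""


class EnumerationCapacityError(IndelAssocError):
    """Exact-test enumeration would exceed the configured table budget."""


class InsufficientGroupsError(IndelAssocError):
    """Fewer than two genotype groups meet the minimum size for testing."""


class SimulationSpecError(IndelAssocError):
    """A synthetic-cohort specification is internally inconsistent."""
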