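"""Exception hierarchy for the quicklama toolkit.

Every anticipated failure mode raises a subclass of :class:`QuickLamaError`
so callers (and the CLI) can distinguish design-time problems from
simulated-chemistry problems.
"""


class QuickLamaError(Exception):
    """Base class for all toolkit errors."""


class AlphabetError(QuickLamaError, ValueError):
    """A sequence contains characters outside the permitted alphabet."""


class CoordinateError(QuickLamaError, ValueError):
    """A coordinate, offset or length is outside its valid domain."""


class DesignError(QuickLamaError):
    """The target cannot be turned into a valid synthesis plan."""


class AmplificationError(QuickLamaError):
    """A simulated PCR cannot produce a product."""


class AmbiguousPrimingError(AmplificationError):
    """A primer binds the template at more than one site."""

    def __init__(self, primer_name: str, positions: list[int]):
        self.primer_name = primer_name
        self.positions = positions
        super().__init__(
            f"primer {primer_name} binds at multiple sites: {positions}"
        )


class NoProductError(AmplificationError):
    """Primers bind but face outward (or otherwise yield no amplicon)."""


class GeometryError(QuickLamaError):
    """Duplex end geometry is incompatible with the requested operation."""


class CohesionError(QuickLamaError):
    """Overhangs are absent, blunt, or not mutually complementary."""


class UnligatableNickError(QuickLamaError):
    """A nick lacks the 5'-phosphate required for ligase sealing."""


class IncompatibleFragmentsError(QuickLamaError):
    """Fragment E is not a circular permutation of fragment A."""


class GenerationError(QuickLamaError):
    """A synthetic fixture's constraints could not be satisfied."""


class ReadLengthError(QuickLamaError, ValueError):
    """A sequencing read is too short for the requested comparison."""


class InputError(QuickLamaError):
    """CLI-level input problem (missing file, unresolvable locus, ...)."""
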