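"""Exception types shared across the package."""


class NearHGTError(Exception):
    """Base class for package errors."""


class GeneNotInGenomeError(NearHGTError, KeyError):
    """A focal gene was requested from a genome that does not contain it."""


class NoSharedGenesError(NearHGTError, ValueError):
    """Two genomes have an empty core (shared) gene set."""


class NoComparableSitesError(NearHGTError, ValueError):
    """A sequence pair has no alignment column with two unambiguous bases."""


class SaturatedDistanceError(NearHGTError, ValueError):
    """Hamming fraction >= 3/4: the Jukes-Cantor correction diverges."""


class CRMTestSkipped(NearHGTError):
    """A single CRM test could not be carried out; carries the reason.

    Raised (and caught by the driver, which logs it) for saturated or
    uninformative distances and missing orthologs -- skips are reported,
    never silently dropped.
    """

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason
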