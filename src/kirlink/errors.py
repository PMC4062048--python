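"""Exception hierarchy shared across the toolkit."""


class KirlinkError(Exception):
    """Base class for all toolkit errors."""


class SaturationError(KirlinkError):
    """No negative droplets observed: the Poisson estimate of the mean
    occupancy is unbounded. Wells in this state must be diluted and rerun;
    the toolkit never converts them into +inf silently."""


class NoReferenceError(KirlinkError):
    """Reference channel concentration is zero; a copy-number ratio is
    undefined."""


class UndefinedLinkageError(KirlinkError):
    """The %L denominator is zero, so no normalized linkage score exists."""


class DegenerateFitError(KirlinkError):
    """Too few observations to fit the requested mixture."""


class InfeasibleGenotypeError(KirlinkError):
    """A copy-number total outside the diploid range implied by the
    per-haplotype maximum."""


class DropletTableError(KirlinkError):
    """Malformed droplet-count table; carries per-row messages."""

    def __init__(self, messages):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


class PedigreeTableError(KirlinkError):
    """Structurally invalid pedigree table."""
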