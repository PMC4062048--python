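"""Poisson statistics of droplet partitioning.

A droplet digital PCR reaction distributes target molecules at random into
~20,000 nanoliter droplets. Under Poisson loading, the fraction of droplets
that stay negative for a target is exp(-lambda), where lambda is the mean
number of target molecules per droplet, so

    lambda_hat = -ln(n_negative / n_total)

and the absolute concentration follows from the droplet volume without any
calibration curve. This module converts negative/total droplet counts into
lambda and copies-per-microliter estimates with confidence intervals, and
extracts per-channel marginal counts from duplex quadrant data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import SaturationError

#: Default droplet volume in nanoliters (one nanoliter reactors).
DEFAULT_DROPLET_VOLUME_NL = 1.0

#: Named instrument presets for droplet volume (nL).
DROPLET_VOLUME_PRESETS = {"nominal": 1.0, "qx100": 0.85}

#: Wells with fewer accepted droplets than this are flagged for review.
DEFAULT_MIN_DROPLETS = 8000


@dataclass(frozen=True)
class QuadrantCounts:
    """End-point classes of one duplex well.

    Channel A is the first fluorophore (conventionally FAM), channel B the
    second (conventionally HEX). ``n_pn`` counts A+B- droplets and ``n_np``
    counts A-B+ droplets.
    """

    n_nn: int
    n_pn: int
    n_np: int
    n_pp: int
    channel_a_name: str = "A"
    channel_b_name: str = "B"

    def __post_init__(self) -> None:
        counts = (self.n_nn, self.n_pn, self.n_np, self.n_pp)
        if any(int(c) != c or c < 0 for c in counts):
            raise ValueError(f"quadrant counts must be non-negative integers, got {counts}")
        if self.n_total <= 0:
            raise ValueError("well contains no droplets")

    @property
    def n_total(self) -> int:
        return self.n_nn + self.n_pn + self.n_np + self.n_pp

    @classmethod
    def from_total(cls, n_total: int, n_pp: int, n_pn: int, n_np: int, n_nn: int,
                   **kwargs) -> "QuadrantCounts":
        """Build from a table row carrying an explicit total, verifying it."""
        if n_pp + n_pn + n_np + n_nn != n_total:
            raise ValueError(
                f"quadrant counts sum to {n_pp + n_pn + n_np + n_nn}, expected {n_total}"
            )
        return cls(n_nn=n_nn, n_pn=n_pn, n_np=n_np, n_pp=n_pp, **kwargs)


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Absolute quantification of one channel of one well."""

    lambda_hat: float
    concentration: float  # copies per microliter
    ci_low: float
    ci_high: float
    n_droplets: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    saturated: bool = False
    qc_pass: bool = True


def lambda_from_counts(n_negative: int, n_total: int) -> float:
    """Mean target molecules per droplet from the negative-droplet fraction.

    Raises :class:`SaturationError` when no negative droplets were observed
    (the estimate is unbounded) and ``ValueError`` on invalid counts.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_negative <= n_total:
        raise ValueError(f"n_negative={n_negative} outside [0, {n_total}]")
    if n_negative == 0:
        raise SaturationError(
            f"all {n_total} droplets positive; mean occupancy is unbounded"
        )
    return -math.log(n_negative / n_total)


def lambda_std_error(n_negative: int, n_total: int) -> float:
    """Delta-method standard error of lambda_hat.

    lambda = -ln(p) with p the binomial negative fraction, so
    se = sqrt((1 - p) / (n * p)).
    """
    if n_negative == 0:
        raise SaturationError("standard error undefined for a saturated well")
    p = n_negative / n_total
    return math.sqrt((1.0 - p) / (n_total * p))


def lambda_ci(n_negative: int, n_total: int, level: float = 0.95) -> tuple[float, float]:
    """Symmetric normal-approximation interval on lambda, floored at zero."""
    lam = lambda_from_counts(n_negative, n_total)
    se = lambda_std_error(n_negative, n_total)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return max(0.0, lam - z * se), lam + z * se


def concentration_estimate(
    n_negative: int,
    n_total: int,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    level: float = 0.95,
    min_droplets: int = DEFAULT_MIN_DROPLETS,
) -> ConcentrationEstimate:
    """Copies-per-microliter estimate for one channel.

    One molecule per nanoliter droplet corresponds to 1000 copies/uL, so the
    conversion is ``1000 * lambda / droplet_volume_nl``. Saturated wells are
    returned flagged with NaN values rather than raising, so that plate-level
    processing can continue.
    """
    if droplet_volume_nl <= 0:
        raise ValueError("droplet volume must be positive")
    qc = n_total >= min_droplets
    scale = 1000.0 / droplet_volume_nl
    try:
        lam = lambda_from_counts(n_negative, n_total)
    except SaturationError:
        return ConcentrationEstimate(
            lambda_hat=math.nan, concentration=math.nan,
            ci_low=math.nan, ci_high=math.nan,
            n_droplets=n_total, droplet_volume_nl=droplet_volume_nl,
            saturated=True, qc_pass=qc,
        )
    lo, hi = lambda_ci(n_negative, n_total, level)
    return ConcentrationEstimate(
        lambda_hat=lam, concentration=lam * scale,
        ci_low=lo * scale, ci_high=hi * scale,
        n_droplets=n_total, droplet_volume_nl=droplet_volume_nl,
        saturated=False, qc_pass=qc,
    )


def channel_marginals(q: QuadrantCounts, channel: str) -> tuple[int, int]:
    """Collapse quadrant counts to (n_negative, n_total) for one channel.

    ``channel`` may be "A"/"B" or the stored channel target name.
    """
    if channel in ("A", q.channel_a_name):
        return q.n_nn + q.n_np, q.n_total
    if channel in ("B", q.channel_b_name):
        return q.n_nn + q.n_pn, q.n_total
    raise ValueError(
        f"unknown channel {channel!r}; expected A/{q.channel_a_name} or B/{q.channel_b_name}"
    )
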