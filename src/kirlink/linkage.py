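"""Chance-corrected two-target linkage from duplex droplet counts.

When two PCR targets sit on the same DNA fragment they enter the same
droplet together, so double-positive droplets occur more often than the
product of the two marginal positive rates predicts. Writing lambda_a and
lambda_b for the per-channel mean occupancies and lambda_union for
-ln(double-negative fraction), the mean number of *linked* molecules per
droplet is

    gamma = lambda_a + lambda_b - lambda_union
          = ln( p_nn / (p_a_neg * p_b_neg) )

which is exactly zero (in expectation) under independent loading. Dividing
the linked-molecule concentration by a channel's total concentration gives
the normalized linkage score %L, the percentage of that target's molecules
that are physically joined to the partner target. Restriction digestion at
a site between the two loci severs the molecules and must abrogate %L; the
undigested/digested contrast is the operational test for the presence of a
haplotype motif such as KIR2DL2~KIR2DL5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import SaturationError, UndefinedLinkageError
from .quant import DEFAULT_DROPLET_VOLUME_NL, QuadrantCounts, channel_marginals, lambda_from_counts

#: %L above which an undigested assay counts as evidence for the motif.
DEFAULT_PRESENCE_THRESHOLD = 1.0
#: Digested %L must fall to at most this fraction of the undigested %L.
DEFAULT_ABROGATION_FRACTION = 0.5
#: Undigested %L below this is flagged as weak / possibly long-range linkage.
DEFAULT_WEAK_THRESHOLD = 5.0

NORMALIZATION_MODES = ("max_channel", "channel_a", "channel_b")


@dataclass(frozen=True)
class LinkageResult:
    """Linked-molecule estimate for one duplex well."""

    lambda_a: float
    lambda_b: float
    lambda_union: float
    gamma: float
    linked_concentration: float  # copies/uL carrying both targets
    percent_linked: float
    normalization: str = "max_channel"
    ci_low: float | None = None
    ci_high: float | None = None
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL

    @property
    def gamma_floored(self) -> float:
        """Zero-floored gamma for reporting; raw values retain noise sign."""
        return max(0.0, self.gamma)


@dataclass(frozen=True)
class DigestionContrast:
    """Undigested vs digested %L for one sample/assay."""

    percent_linked_undigested: float
    percent_linked_digested: float
    delta: float
    abrogated: bool
    no_linkage: bool


@dataclass(frozen=True)
class MotifCall:
    """Presence/absence call for one haplotype motif in one sample."""

    assay: str
    present: bool
    percent_linked_undigested: float
    percent_linked_digested: float
    abrogated: bool
    weak: bool = False


def linked_concentration(
    q: QuadrantCounts,
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL,
    normalization: str = "max_channel",
) -> LinkageResult:
    """Estimate the concentration of doubly-marked molecules in one well.

    Requires at least one double-negative droplet; saturation of either
    channel is a subset of that condition and raises the same error.
    """
    if q.n_nn == 0:
        raise SaturationError("no double-negative droplets; linkage estimate unbounded")
    a_neg, n = channel_marginals(q, "A")
    b_neg, _ = channel_marginals(q, "B")
    lam_a = lambda_from_counts(a_neg, n)
    lam_b = lambda_from_counts(b_neg, n)
    lam_union = lambda_from_counts(q.n_nn, n)
    gamma = lam_a + lam_b - lam_union
    result = LinkageResult(
        lambda_a=lam_a, lambda_b=lam_b, lambda_union=lam_union,
        gamma=gamma, linked_concentration=gamma * 1000.0 / droplet_volume_nl,
        percent_linked=math.nan, normalization=normalization,
        droplet_volume_nl=droplet_volume_nl,
    )
    try:
        pl = percent_linked(result, normalization)
    except UndefinedLinkageError:
        pl = math.nan  # empty-channel well; explicit %L calls still raise
    return replace(result, percent_linked=pl)


def percent_linked(r: LinkageResult, normalization: str = "max_channel") -> float:
    """Normalize gamma to the %L score (0-100 scale; noise may push the point
    estimate slightly outside).

    ``max_channel`` divides by the larger of the two channel concentrations,
    which respects the copy-number ceiling (a sample with two copies of the
    common target and one of the partner can reach at most %L = 50).
    ``channel_a`` / ``channel_b`` divide by that channel explicitly.
    """
    if normalization == "max_channel":
        denom = max(r.lambda_a, r.lambda_b)
    elif normalization == "channel_a":
        denom = r.lambda_a
    elif normalization == "channel_b":
        denom = r.lambda_b
    else:
        raise ValueError(f"unknown normalization {normalization!r}; use one of {NORMALIZATION_MODES}")
    if denom <= 0:
        raise UndefinedLinkageError("denominator concentration is zero; %L undefined")
    return 100.0 * r.gamma / denom


def percent_linked_ci(
    q: QuadrantCounts,
    normalization: str = "max_channel",
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval on %L.

    Resamples the four quadrant counts from their multinomial distribution;
    degenerate resamples (no double negatives, or a zero denominator) are
    dropped, which only matters for extreme wells.
    """
    rng = np.random.default_rng(seed)
    n = q.n_total
    probs = np.array([q.n_nn, q.n_pn, q.n_np, q.n_pp], dtype=float) / n
    draws = rng.multinomial(n, probs, size=n_boot).astype(float)
    nn, pn, np_, _pp = draws.T
    a_neg = nn + np_
    b_neg = nn + pn
    ok = (nn > 0) & (a_neg < n) & (b_neg < n)
    if not ok.any():
        raise SaturationError("all bootstrap resamples degenerate")
    lam_a = -np.log(a_neg[ok] / n)
    lam_b = -np.log(b_neg[ok] / n)
    gamma = lam_a + lam_b + np.log(nn[ok] / n)
    if normalization == "max_channel":
        denom = np.maximum(lam_a, lam_b)
    elif normalization == "channel_a":
        denom = lam_a
    elif normalization == "channel_b":
        denom = lam_b
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    valid = denom > 0
    if not valid.any():
        raise UndefinedLinkageError("denominator zero in all bootstrap resamples")
    pl = 100.0 * gamma[valid] / denom[valid]
    alpha = 1.0 - level
    return (float(np.quantile(pl, alpha / 2)), float(np.quantile(pl, 1 - alpha / 2)))


def digestion_contrast(
    undigested: LinkageResult | float,
    digested: LinkageResult | float,
    abrogation_fraction: float = DEFAULT_ABROGATION_FRACTION,
) -> DigestionContrast:
    """Compare %L before and after restriction digestion.

    Linkage counts as abrogated when the digested score drops to at most
    ``abrogation_fraction`` of the undigested score. A well with nothing to
    abrogate (undigested %L <= 0) is flagged ``no_linkage``.
    """
    pl_u = undigested.percent_linked if isinstance(undigested, LinkageResult) else float(undigested)
    pl_d = digested.percent_linked if isinstance(digested, LinkageResult) else float(digested)
    no_linkage = pl_u <= 0
    abrogated = (not no_linkage) and pl_d <= abrogation_fraction * pl_u
    return DigestionContrast(
        percent_linked_undigested=pl_u, percent_linked_digested=pl_d,
        delta=pl_u - pl_d, abrogated=abrogated, no_linkage=no_linkage,
    )


def call_motif(
    assay: str,
    percent_linked_undigested: float,
    percent_linked_digested: float,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    abrogation_fraction: float = DEFAULT_ABROGATION_FRACTION,
    weak_threshold: float = DEFAULT_WEAK_THRESHOLD,
) -> MotifCall:
    """Call a haplotype motif present when undigested %L clears the presence
    threshold and digestion abrogates it.

    Low-but-real scores (above threshold, below ``weak_threshold``) are
    flagged weak: they can reflect long-range linkage on unusual extended
    haplotypes rather than the canonical adjacent arrangement.
    """
    contrast = digestion_contrast(
        percent_linked_undigested, percent_linked_digested, abrogation_fraction
    )
    present = percent_linked_undigested > presence_threshold and contrast.abrogated
    return MotifCall(
        assay=assay, present=present,
        percent_linked_undigested=percent_linked_undigested,
        percent_linked_digested=percent_linked_digested,
        abrogated=contrast.abrogated,
        weak=present and percent_linked_undigested < weak_threshold,
    )
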