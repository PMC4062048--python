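"""Copy-number estimation, mixture clustering and method concordance.

A duplex well carries the gene of interest on channel A and the invariant
reference RPP30 (one copy per haplotype, two per diploid genome) on channel
B. The raw copy number is the concentration ratio corrected for diploidy:

    raw_cn = 2 * lambda_target / lambda_reference

Raw estimates from a plate of samples rarely sit exactly on integers
(archival DNA in particular drifts low), so they are clustered with a
one-dimensional Gaussian mixture fitted by expectation-maximization, the
number of components chosen by BIC, and each component mapped to an integer
copy number. Calls with a weak posterior, or whose confidence interval
excludes the called integer, are flagged for human review. Agreement with
an orthogonal genotyping method is summarized by Cohen's kappa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa as _sm_cohens_kappa

from .errors import DegenerateFitError, NoReferenceError, SaturationError
from .quant import QuadrantCounts, channel_marginals, lambda_from_counts, lambda_std_error

DEFAULT_POSTERIOR_FLOOR = 0.95
#: Smallest credible cluster spread, in copy-number units. Distinct integer
#: copy-number states sit ~1 apart; structure finer than a few hundredths of
#: a copy is measurement noise, not a separate state.
SD_FLOOR_COPIES = 0.02


@dataclass(frozen=True)
class CNVEstimate:
    sample_id: str
    gene: str
    raw_cn: float
    ci_low: float
    ci_high: float
    lambda_target: float
    lambda_ref: float
    n_droplets: int


@dataclass(frozen=True)
class CopyNumberModel:
    """Fitted one-dimensional Gaussian mixture over raw copy-number values."""

    k: int
    means: np.ndarray  # sorted ascending
    sds: np.ndarray
    weights: np.ndarray
    bic: float
    loglik: float
    component_to_integer: np.ndarray  # strictly increasing ints
    variance_mode: str  # "equal" or "free"
    loglik_trace: np.ndarray  # per-iteration log-likelihood of the winning fit


@dataclass(frozen=True)
class CopyNumberCall:
    sample_id: str
    integer_cn: int
    posterior: float
    review_flag: bool


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    n_pairs: int
    contingency: pd.DataFrame
    degenerate: bool = False


def cnv_from_quadrants(
    q: QuadrantCounts,
    sample_id: str = "",
    gene: str = "",
    level: float = 0.95,
) -> CNVEstimate:
    """Diploidy-corrected copy number from one target-vs-reference well.

    The confidence interval is a delta-method interval on the log-ratio,
    treating the two channel estimates as independent (they share droplets,
    so this is an approximation on the conservative side for typical loads).
    """
    a_neg, n = channel_marginals(q, "A")
    b_neg, _ = channel_marginals(q, "B")
    lam_ref = lambda_from_counts(b_neg, n)  # raises SaturationError if b_neg == 0
    if lam_ref == 0:
        raise NoReferenceError("reference channel concentration is zero")
    if a_neg == 0:
        raise SaturationError("target channel saturated")
    lam_t = lambda_from_counts(a_neg, n)
    raw = 2.0 * lam_t / lam_ref
    if lam_t == 0:
        return CNVEstimate(sample_id, gene, 0.0, 0.0, 0.0, lam_t, lam_ref, n)
    # var(log lambda) = var(lambda) / lambda^2
    se_log = math.sqrt(
        (lambda_std_error(a_neg, n) / lam_t) ** 2
        + (lambda_std_error(b_neg, n) / lam_ref) ** 2
    )
    z = stats.norm.ppf(0.5 + level / 2.0)
    return CNVEstimate(
        sample_id=sample_id, gene=gene, raw_cn=raw,
        ci_low=raw * math.exp(-z * se_log), ci_high=raw * math.exp(z * se_log),
        lambda_target=lam_t, lambda_ref=lam_ref, n_droplets=n,
    )


def _em_fit_1d(x: np.ndarray, k: int, equal_variance: bool,
               tol: float = 1e-8, max_iter: int = 1000):
    """EM for a k-component 1-D Gaussian mixture with quantile initialization.

    Returns (means, sds, weights, loglik_trace). Deterministic given the data.

    Component standard deviations are floored at :data:`SD_FLOOR_COPIES`,
    which blocks the classic one-dimensional degeneracy where a component
    collapses onto tied or near-tied values (replicate wells of one sample,
    exact zeros) and drives the likelihood to a spike that BIC would
    otherwise reward with spurious extra components.
    """
    n = x.size
    means = np.quantile(x, (np.arange(k) + 0.5) / k)
    sd_floor = SD_FLOOR_COPIES
    sd0 = max(float(np.std(x)), sd_floor)
    sds = np.full(k, sd0)
    weights = np.full(k, 1.0 / k)
    trace = []
    ll_old = -np.inf
    for _ in range(max_iter):
        # E step: responsibilities via log-densities for stability
        logdens = (
            -0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
            - np.log(sds[None, :]) - 0.5 * math.log(2 * math.pi)
            + np.log(weights[None, :])
        )
        m = logdens.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logdens - m).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        resp = np.exp(logdens - lse[:, None])
        if ll - ll_old < tol and len(trace) > 1:
            break
        ll_old = ll
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        sq = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0)
        if equal_variance:
            sds = np.full(k, max(math.sqrt(sq.sum() / n), sd_floor))
        else:
            sds = np.maximum(np.sqrt(sq / nk), sd_floor)
    return means, sds, weights, np.array(trace)


def _map_components_to_integers(means: np.ndarray) -> np.ndarray:
    """Nearest integer per sorted component mean; collisions resolved by
    pushing later components up so the mapping stays strictly increasing.
    Tolerates plates whose clusters sit systematically below the integers."""
    ints = np.rint(means).astype(int)
    ints[0] = max(ints[0], 0)
    for i in range(1, ints.size):
        ints[i] = max(ints[i], ints[i - 1] + 1)
    return ints


def fit_copy_number_mixture(
    values,
    k_candidates=range(1, 6),
    seed: int | None = None,
) -> CopyNumberModel:
    """Fit 1-D Gaussian mixtures over a range of component counts and keep
    the best model by BIC.

    Both the equal-variance and free-variance parameterizations are fitted
    for every candidate k. Initialization is by quantiles, so the fit is
    deterministic; ``seed`` is accepted for interface symmetry with the
    stochastic operations.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise DegenerateFitError("need at least two values to fit a mixture")
    if not np.all(np.isfinite(x)):
        raise ValueError("raw copy-number values must be finite")
    feasible = [k for k in k_candidates if k <= x.size]
    if not feasible:
        raise DegenerateFitError(
            f"{x.size} values cannot support any of the requested component counts"
        )
    best = None
    for k in feasible:
        for equal_variance in (True, False):
            means, sds, weights, trace = _em_fit_1d(x, k, equal_variance)
            ll = trace[-1]
            # equal: k means + 1 sd + (k-1) weights; free: k + k + (k-1)
            n_params = (2 * k) if equal_variance else (3 * k - 1)
            bic = -2.0 * ll + n_params * math.log(x.size)
            if best is None or bic < best.bic - 1e-12:
                order = np.argsort(means)
                best = CopyNumberModel(
                    k=k, means=means[order], sds=sds[order], weights=weights[order],
                    bic=float(bic), loglik=float(ll),
                    component_to_integer=_map_components_to_integers(means[order]),
                    variance_mode="equal" if equal_variance else "free",
                    loglik_trace=trace,
                )
    return best


def component_posteriors(model: CopyNumberModel, values) -> np.ndarray:
    """Posterior membership matrix (n_values x k) under the fitted mixture."""
    x = np.asarray(list(values), dtype=float)
    dens = model.weights * stats.norm.pdf(
        x[:, None], loc=model.means[None, :], scale=model.sds[None, :]
    )
    total = dens.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    return dens / total


def assign_copy_numbers(
    model: CopyNumberModel,
    estimates,
    posterior_floor: float = DEFAULT_POSTERIOR_FLOOR,
) -> list[CopyNumberCall]:
    """Assign each estimate the integer of its maximum-posterior component.

    ``estimates`` may be CNVEstimate objects or bare floats. Ties break
    toward the lower integer. A call is flagged for review when its
    posterior is below ``posterior_floor`` or when the estimate's own
    confidence interval excludes the called integer — the situation where
    the clustering and the single-well statistics disagree and a human
    should look (e.g. a sample binned at zero copies whose interval sits
    strictly above zero, suggesting a true copy number of one).
    """
    ests = list(estimates)
    vals = [e.raw_cn if isinstance(e, CNVEstimate) else float(e) for e in ests]
    post = component_posteriors(model, vals)
    calls = []
    for i, (e, v) in enumerate(zip(ests, vals)):
        # lowest-mean component among (near-)ties wins
        j = int(np.argmax(post[i] >= post[i].max() - 1e-9))
        integer = int(model.component_to_integer[j])
        p = float(post[i, j])
        flag = p < posterior_floor
        if isinstance(e, CNVEstimate):
            if not e.ci_low <= integer <= e.ci_high:
                flag = True
            sample_id = e.sample_id
        else:
            sample_id = str(i)
        calls.append(CopyNumberCall(sample_id=sample_id, integer_cn=integer,
                                    posterior=p, review_flag=flag))
    return calls


def cohen_kappa(calls_method1, calls_method2, level: float = 0.95) -> KappaResult:
    """Cohen's kappa between two categorical call vectors.

    Categories are the union of those observed in either vector, treated as
    unordered. The interval is the asymptotic normal interval on kappa,
    clamped to [-1, 1]. When every pair falls in one identical category the
    expected agreement is 1 and kappa is undefined; the result is returned
    with ``degenerate=True`` and NaN values.
    """
    c1 = pd.Categorical(calls_method1)
    c2 = pd.Categorical(calls_method2)
    if len(c1) != len(c2):
        raise ValueError("call vectors must have equal length")
    if len(c1) < 2:
        raise ValueError("need at least two pairs")
    cats = sorted(set(c1.categories) | set(c2.categories))
    c1 = c1.set_categories(cats)
    c2 = c2.set_categories(cats)
    table = pd.crosstab(c1, c2, dropna=False)
    table = table.reindex(index=cats, columns=cats, fill_value=0)
    if len(cats) == 1:
        return KappaResult(kappa=math.nan, ci_low=math.nan, ci_high=math.nan,
                           n_pairs=len(c1), contingency=table, degenerate=True)
    alpha = 1.0 - level
    with np.errstate(invalid="ignore"):
        res = _sm_cohens_kappa(table.to_numpy(), return_results=True)
    z = stats.norm.ppf(1 - alpha / 2.0)
    if math.isfinite(res.std_kappa):
        lo = max(-1.0, float(res.kappa - z * res.std_kappa))
        hi = min(1.0, float(res.kappa + z * res.std_kappa))
    else:  # tiny tables can yield a negative variance estimate
        lo, hi = -1.0, 1.0
    return KappaResult(kappa=float(res.kappa), ci_low=lo, ci_high=hi,
                       n_pairs=len(c1), contingency=table)
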