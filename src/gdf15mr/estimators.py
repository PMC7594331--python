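"""Two-sample MR estimators and diagnostics.

Given harmonized per-SNP effects (beta_x_j, se_x_j) on the exposure and
(beta_y_j, se_y_j) on the outcome, the causal effect theta (log-odds of the
outcome per unit exposure) is estimated by:

* the per-SNP Wald ratio  theta_j = beta_y_j / beta_x_j  with a delta-method
  standard error (first order: se_y_j / |beta_x_j|; second order adds the
  exposure-noise term beta_y_j^2 se_x_j^2 / beta_x_j^4);
* inverse-variance weighting (IVW): theta_hat = sum(w_j theta_j) / sum(w_j)
  with w_j = 1 / se_j^2, fixed-effects SE (sum w_j)^(-1/2), Cochran's
  Q = sum w_j (theta_j - theta_hat)^2 on L - 1 df for heterogeneity;
* the weighted median: the weighted 50th percentile of the ratio estimates,
  consistent while valid instruments carry at least half the weight; SE by
  parametric bootstrap;
* MR-Egger: weighted regression of beta_y on beta_x with a free intercept;
  a nonzero intercept indicates directional horizontal pleiotropy, and under
  the InSIDE assumption the slope remains a consistent causal estimate.

All p-values are two-sided from the standard normal distribution (a
t-distribution switch is available for Egger).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

Z_975 = float(sps.norm.ppf(0.975))


class EstimationError(ValueError):
    pass


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald ratio with delta-method SE and inverse-variance weight."""

    rsid: str
    estimate: float
    se: float

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise EstimationError(f"{self.rsid}: ratio SE must be > 0")

    @property
    def weight(self) -> float:
        return self.se**-2


@dataclass(frozen=True)
class MRResult:
    """One method's pooled causal estimate on the log-odds scale."""

    method: str  # {IVW, weighted_median, MR_Egger}
    estimate: float
    se: float
    pval: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_snps: int
    # heterogeneity (IVW)
    q_stat: float | None = None
    q_pval: float | None = None
    # pleiotropy (MR-Egger)
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None


def two_sided_p(estimate: float, se: float) -> float:
    """Two-sided normal p-value, p = 2 (1 - Phi(|estimate/se|))."""
    if not se > 0:
        raise EstimationError(f"se must be > 0, got {se}")
    return float(2 * sps.norm.sf(abs(estimate / se)))


def to_odds_ratio(
    estimate: float, se: float, level: float = 0.95
) -> tuple[float, float, float]:
    """Convert a log-odds estimate to OR with a Wald confidence interval."""
    if not se > 0:
        raise EstimationError(f"se must be > 0, got {se}")
    if not 0 < level < 1:
        raise EstimationError(f"confidence level must be in (0, 1), got {level}")
    z = float(sps.norm.ppf((1 + level) / 2))
    return (
        math.exp(estimate),
        math.exp(estimate - z * se),
        math.exp(estimate + z * se),
    )


def _result(method: str, estimate: float, se: float, n_snps: int, **extra) -> MRResult:
    or_, lo, hi = to_odds_ratio(estimate, se)
    return MRResult(
        method=method,
        estimate=float(estimate),
        se=float(se),
        pval=two_sided_p(estimate, se),
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        n_snps=n_snps,
        **extra,
    )


def wald_ratio(h, order: str = "first") -> RatioEstimate:
    """Per-SNP Wald ratio beta_outcome / beta_exposure.

    ``order``: ``first`` uses only outcome noise (se_y / |beta_x|);
    ``second`` adds the exposure-noise delta term
    sqrt(se_y^2 / beta_x^2 + beta_y^2 se_x^2 / beta_x^4).
    """
    bx, by = h.beta_exposure, h.beta_outcome
    if bx == 0:
        raise EstimationError(f"{h.rsid}: exposure beta is zero, Wald ratio undefined")
    estimate = by / bx
    if order == "first":
        se = h.se_outcome / abs(bx)
    elif order == "second":
        se = math.sqrt(h.se_outcome**2 / bx**2 + by**2 * h.se_exposure**2 / bx**4)
    else:
        raise EstimationError(f"order must be first|second, got {order!r}")
    return RatioEstimate(rsid=h.rsid, estimate=estimate, se=se)


def ivw(ratios: list[RatioEstimate], model: str = "fixed") -> MRResult:
    """Inverse-variance-weighted meta-analysis of Wald ratios.

    ``model``: ``fixed`` or ``random_multiplicative`` (SE inflated by
    max(1, sqrt(Q / (L - 1)))).  Heterogeneity fields are present for L >= 2.
    """
    if not ratios:
        raise EstimationError("IVW requires at least one ratio")
    if model not in ("fixed", "random_multiplicative"):
        raise EstimationError(f"model must be fixed|random_multiplicative, got {model!r}")
    theta = np.array([r.estimate for r in ratios])
    w = np.array([r.weight for r in ratios])
    est = float(np.sum(w * theta) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    L = len(ratios)
    q = q_p = None
    if L >= 2:
        q = float(np.sum(w * (theta - est) ** 2))
        q_p = float(sps.chi2.sf(q, L - 1))
        if model == "random_multiplicative":
            se *= max(1.0, math.sqrt(q / (L - 1)))
    return _result("IVW", est, se, L, q_stat=q, q_pval=q_p)


def _weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    """Weighted 50th percentile by linear interpolation of cumulative
    weight midpoints p_j = cumsum(w_norm) - w_norm / 2 against sorted values."""
    order = np.argsort(theta, kind="stable")
    theta_s = theta[order]
    w_s = w[order] / np.sum(w)
    p = np.cumsum(w_s) - w_s / 2
    return float(np.interp(0.5, p, theta_s))


def weighted_median(
    ratios: list[RatioEstimate],
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> MRResult:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Each bootstrap replicate redraws theta_j* ~ Normal(theta_j, se_j) and
    recomputes the weighted median with the original inverse-variance
    weights; the SE is the SD across replicates.  Requires >= 3 ratios and
    n_boot >= 100.
    """
    if len(ratios) < 3:
        raise EstimationError(
            "weighted median requires at least 3 instruments; use IVW instead"
        )
    if n_boot < 100:
        raise EstimationError(f"n_boot must be >= 100, got {n_boot}")
    theta = np.array([r.estimate for r in ratios])
    se = np.array([r.se for r in ratios])
    w = np.array([r.weight for r in ratios])
    est = _weighted_median(theta, w)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = theta + se * rng.standard_normal((n_boot, len(ratios)))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        boot[b] = _weighted_median(draws[b], w)
    se_boot = float(np.std(boot, ddof=1))
    return _result("weighted_median", est, se_boot, len(ratios))


def _orient(bx: np.ndarray, by: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip (beta_x, beta_y) pairs so all exposure effects are positive."""
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, by * sign


def mr_egger(
    instruments,
    fit_intercept: bool = True,
    distribution: str = "normal",
) -> MRResult:
    """MR-Egger regression: weighted LS of beta_outcome on beta_exposure with
    a free intercept, weights 1 / se_outcome^2, after orienting all exposure
    effects positive.

    SEs carry a multiplicative overdispersion factor
    max(1, sqrt(RSS_w / (L - k))).  ``distribution``: ``normal`` (default) or
    ``t`` (L - k df) for the slope/intercept p-values.  ``fit_intercept=False``
    gives the zero-intercept fit, algebraically identical to fixed-effects IVW
    with first-order Wald SEs.
    """
    L = len(instruments)
    if L < 3 and fit_intercept:
        raise EstimationError("MR-Egger requires at least 3 instruments")
    if L < 1:
        raise EstimationError("no instruments")
    if distribution not in ("normal", "t"):
        raise EstimationError(f"distribution must be normal|t, got {distribution!r}")
    bx = np.array([h.beta_exposure for h in instruments])
    by = np.array([h.beta_outcome for h in instruments])
    sy = np.array([h.se_outcome for h in instruments])
    if np.any(bx == 0):
        raise EstimationError("zero exposure beta; cannot orient instrument")
    bx, by = _orient(bx, by)
    w = sy**-2.0

    X = np.column_stack([np.ones(L), bx]) if fit_intercept else bx[:, None]
    k = X.shape[1]
    if L <= k or np.linalg.matrix_rank(X * np.sqrt(w)[:, None]) < k:
        raise EstimationError("singular Egger fit: exposure effects are collinear")
    XtWX = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(XtWX, X.T @ (w * by))
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid**2))
    phi = max(1.0, rss_w / (L - k))  # multiplicative overdispersion
    cov = phi * np.linalg.inv(XtWX)
    ses = np.sqrt(np.diag(cov))

    if fit_intercept:
        intercept, slope = coef
        intercept_se, slope_se = ses
    else:
        intercept = intercept_se = None
        (slope,), (slope_se,) = coef, ses

    if distribution == "t":
        df = L - k
        pfun = lambda e, s: float(2 * sps.t.sf(abs(e / s), df))
    else:
        pfun = two_sided_p
    or_, lo, hi = to_odds_ratio(slope, slope_se)
    return MRResult(
        method="MR_Egger",
        estimate=float(slope),
        se=float(slope_se),
        pval=pfun(slope, slope_se),
        odds_ratio=or_,
        ci_low=lo,
        ci_high=hi,
        n_snps=L,
        egger_intercept=None if intercept is None else float(intercept),
        egger_intercept_se=None if intercept_se is None else float(intercept_se),
        egger_intercept_p=None
        if intercept is None
        else pfun(intercept, intercept_se),
    )
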