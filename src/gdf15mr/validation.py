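"""Monte-Carlo validation of the estimators against the synthetic generator.

Runs many independent simulated exposure/outcome pairs through the full
harmonize -> Wald ratio -> estimator path and collects the per-replicate
estimates, so calibration claims (unbiasedness under valid instruments,
Egger-intercept recovery of the mean pleiotropic effect, type-I error of
the pleiotropy test) can be checked empirically.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .estimators import _weighted_median, ivw, mr_egger, wald_ratio
from .harmonize import harmonize_sets
from .synthgwas import SimulationConfig, simulate_pair

MAX_SEED = 2**31 - 1


def run_replicates(
    config: SimulationConfig, n_reps: int, seed: int = 0
) -> pd.DataFrame:
    """Simulate ``n_reps`` studies under ``config`` and estimate each one.

    Returns one row per replicate with columns ``ivw``, ``wm`` (weighted
    median point estimate), ``egger_slope``, ``egger_intercept``,
    ``egger_intercept_p``, ``q_pval`` and ``mean_alpha`` (the replicate's
    realized mean pleiotropic effect).  Per-replicate seeds derive from
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_reps):
        cfg = replace(config, seed=int(rng.integers(MAX_SEED)))
        exposure, outcome, truth = simulate_pair(cfg)
        harmonized, _ = harmonize_sets(exposure, outcome)
        ratios = [wald_ratio(h, order="first") for h in harmonized]
        pooled = ivw(ratios)
        theta = np.array([r.estimate for r in ratios])
        weights = np.array([r.weight for r in ratios])
        egger = mr_egger(harmonized)
        rows.append(
            {
                "ivw": pooled.estimate,
                "wm": _weighted_median(theta, weights),
                "egger_slope": egger.estimate,
                "egger_intercept": egger.egger_intercept,
                "egger_intercept_p": egger.egger_intercept_p,
                "q_pval": pooled.q_pval,
                "mean_alpha": float(truth["alpha"].mean()),
            }
        )
    return pd.DataFrame(rows)


def summarize_recovery(reps: pd.DataFrame, truth: float) -> pd.DataFrame:
    """Mean, Monte-Carlo SE of the mean, and bias per estimator column."""
    out = []
    for col in ("ivw", "wm", "egger_slope"):
        mean = reps[col].mean()
        mc_se = reps[col].std(ddof=1) / np.sqrt(len(reps))
        out.append(
            {
                "estimator": col,
                "mean": mean,
                "mc_se": mc_se,
                "truth": truth,
                "bias": mean - truth,
                "abs_bias_in_mc_se": abs(mean - truth) / mc_se,
            }
        )
    return pd.DataFrame(out)


def intercept_type_i_error(reps: pd.DataFrame, level: float = 0.05) -> dict[str, float]:
    """Empirical rejection rate of the Egger intercept test with its
    binomial standard error."""
    rate = float((reps["egger_intercept_p"] < level).mean())
    n = len(reps)
    return {
        "rate": rate,
        "nominal": level,
        "binom_se": float(np.sqrt(level * (1 - level) / n)),
        "n_reps": n,
    }
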