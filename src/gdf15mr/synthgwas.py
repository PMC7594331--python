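"""Synthetic paired GWAS summary statistics with known ground truth.

The generator works directly at the summary level — the regime two-sample MR
operates in.  For SNP j with true instrument strength gamma_j and direct
(pleiotropic) outcome effect alpha_j:

    beta_x_j ~ Normal(gamma_j,            se_x_j^2)   (exposure study)
    beta_y_j ~ Normal(theta gamma_j + alpha_j, se_y_j^2)   (outcome study)

alpha_j is zero for valid instruments; invalid instruments draw
alpha_j ~ Normal(alpha_mean, alpha_sd) — ``balanced`` pleiotropy has
alpha_mean = 0, ``directional`` a nonzero mean.  Because alpha is drawn
independently of gamma, directional pleiotropy satisfies the InSIDE
assumption and the MR-Egger intercept estimates the mean pleiotropic effect.

Defaults mirror a cis-pQTL exposure GWAS of a few thousand individuals paired
with large disease consortia: per-SNP exposure SEs near 1/sqrt(5440) ~ 0.014,
outcome SEs 0.01-0.03, and instrument strengths of 0.1-0.5 SD per allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats_io import LDMatrix, SNPAssociation, SummaryStatsSet

#: allele pairs that are not strand-ambiguous
NON_PALINDROMIC_PAIRS = (
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
)
PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one paired exposure/outcome simulation."""

    n_snps: int = 50
    theta: float = 0.1
    gamma_range: tuple[float, float] = (0.1, 0.5)
    se_x_range: tuple[float, float] = (0.010, 0.018)
    se_y_range: tuple[float, float] = (0.010, 0.030)
    pleiotropy_mode: str = "none"  # {none, balanced, directional}
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    invalid_fraction: float = 0.0
    eaf_range: tuple[float, float] = (0.05, 0.95)
    allow_palindromic: bool = False
    n_exposure: int = 5440
    n_outcome: int = 400000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise SimulationError("n_snps must be >= 1")
        for name in ("gamma_range", "se_x_range", "se_y_range", "eaf_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise SimulationError(f"{name} is not well-ordered: ({lo}, {hi})")
        if self.se_x_range[0] <= 0 or self.se_y_range[0] <= 0:
            raise SimulationError("standard-error ranges must be positive")
        if not (0 < self.eaf_range[0] and self.eaf_range[1] < 1):
            raise SimulationError("eaf_range must lie inside (0, 1)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise SimulationError(
                f"pleiotropy_mode must be none|balanced|directional, got {self.pleiotropy_mode!r}"
            )
        if self.pleiotropy_mode == "balanced" and self.alpha_mean != 0:
            raise SimulationError("balanced pleiotropy requires alpha_mean = 0")
        if not 0 <= self.invalid_fraction <= 1:
            raise SimulationError("invalid_fraction must be in [0, 1]")

    @classmethod
    def balanced(cls, alpha_sd: float = 0.05, invalid_fraction: float = 0.3, **kw):
        return cls(pleiotropy_mode="balanced", alpha_mean=0.0, alpha_sd=alpha_sd,
                   invalid_fraction=invalid_fraction, **kw)

    @classmethod
    def directional(cls, alpha_mean: float = 0.05, alpha_sd: float = 0.02,
                    invalid_fraction: float = 1.0, **kw):
        return cls(pleiotropy_mode="directional", alpha_mean=alpha_mean,
                   alpha_sd=alpha_sd, invalid_fraction=invalid_fraction, **kw)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * sps.norm.sf(np.abs(beta / se))
    # keep p in (0, 1] so records validate even for extreme z-scores
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_pair(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[SummaryStatsSet, SummaryStatsSet, pd.DataFrame]:
    """Generate one exposure study, one outcome study, and the truth record.

    The truth record is a per-SNP table (rsid, gamma, alpha, is_invalid,
    theta) suitable for audit; write it alongside outputs with
    ``truth.to_csv(path, sep="\\t", index=False)``.
    Identical config (same seed) gives identical output.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = config.n_snps
    gamma = rng.uniform(*config.gamma_range, size=m)
    se_x = rng.uniform(*config.se_x_range, size=m)
    se_y = rng.uniform(*config.se_y_range, size=m)

    alpha = np.zeros(m)
    invalid = np.zeros(m, dtype=bool)
    if config.pleiotropy_mode != "none" and config.invalid_fraction > 0:
        n_invalid = int(round(config.invalid_fraction * m))
        idx = rng.choice(m, size=n_invalid, replace=False)
        invalid[idx] = True
        alpha[idx] = rng.normal(config.alpha_mean, config.alpha_sd, size=n_invalid)

    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(config.theta * gamma + alpha, se_y)
    eaf = rng.uniform(*config.eaf_range, size=m)
    pairs = NON_PALINDROMIC_PAIRS + (PALINDROMIC_PAIRS if config.allow_palindromic else ())
    allele_idx = rng.integers(0, len(pairs), size=m)

    rsids = [f"rs{100000 + j}" for j in range(m)]
    positions = 1_000_000 + 5000 * np.arange(m)

    def build(trait, betas, ses, n, trait_type) -> SummaryStatsSet:
        pv = _pvals(betas, ses)
        recs = [
            SNPAssociation(
                rsid=rsids[j],
                chromosome="19",
                position=int(positions[j]),
                effect_allele=pairs[allele_idx[j]][0],
                other_allele=pairs[allele_idx[j]][1],
                eaf=float(eaf[j]),
                beta=float(betas[j]),
                se=float(ses[j]),
                pval=float(pv[j]),
                n=n,
            )
            for j in range(m)
        ]
        return SummaryStatsSet(trait_name=trait, records=recs, trait_type=trait_type)

    exposure = build("exposure", beta_x, se_x, config.n_exposure, "continuous")
    outcome = build("outcome", beta_y, se_y, config.n_outcome, "binary")
    truth = pd.DataFrame(
        {
            "rsid": rsids,
            "gamma": gamma,
            "alpha": alpha,
            "is_invalid": invalid,
            "theta": config.theta,
        }
    )
    return exposure, outcome, truth


def simulate_ld_matrix(
    rsids: list[str],
    block_structure: list[tuple[list[str], float]] | None = None,
) -> LDMatrix:
    """Block LD matrix: within-group r² as given, zero across groups.

    ``block_structure`` is a list of (group rsids, target r²); groups must be
    disjoint subsets of ``rsids``.
    """
    idx = {r: i for i, r in enumerate(rsids)}
    k = len(rsids)
    r2 = np.zeros((k, k))
    np.fill_diagonal(r2, 1.0)
    seen: set[str] = set()
    for group, target in block_structure or []:
        if not 0 <= target <= 1:
            raise SimulationError(f"block r2 {target} outside [0, 1]")
        if seen & set(group):
            raise SimulationError("LD blocks must be disjoint")
        seen |= set(group)
        for a in group:
            for b in group:
                if a != b:
                    r2[idx[a], idx[b]] = target
    return LDMatrix(rsids=tuple(rsids), r2=r2)


#: the nine candidate GDF-15 cis-SNPs: five retained instruments, three in
#: high LD with a retained SNP, one below genome-wide significance
KEPT_RSIDS = ("rs1227731", "rs3195944", "rs17725099", "rs888663", "rs749451")
LD_DROPPED_RSIDS = ("rs1054564", "rs3746181", "rs1363120")
PVALUE_DROPPED_RSID = "rs16982345"


def gdf15_fixture() -> tuple[SummaryStatsSet, LDMatrix, dict[str, SummaryStatsSet]]:
    """Deterministic synthetic stand-in for the GDF-15 candidate-instrument data.

    The nine candidate rsIDs are real; every numeric value (p-values, betas,
    r²) is synthetic, constructed only so that default instrument selection
    (p < 5e-8, prune at r² >= 0.8) retains the five instrument SNPs, drops
    the three high-LD SNPs against a retained partner, and drops the one
    sub-threshold SNP.  Returns (exposure set of 9 SNPs, LD matrix, outcome
    sets keyed by the nine cardiovascular outcome labels).
    """
    config = SimulationConfig(n_snps=9, theta=0.05, seed=20191)
    rng = np.random.default_rng(config.seed)
    exposure, _, _ = simulate_pair(config, rng=rng)

    order = KEPT_RSIDS + LD_DROPPED_RSIDS + (PVALUE_DROPPED_RSID,)
    # strong instruments get tiny p; the LD-dropped trio significant but
    # weaker than their retained partners; the last SNP just misses 5e-8
    pvals = dict(zip(KEPT_RSIDS, (1e-30, 2e-25, 5e-22, 3e-18, 8e-15)))
    pvals.update(dict(zip(LD_DROPPED_RSIDS, (1e-12, 4e-12, 2e-11))))
    pvals[PVALUE_DROPPED_RSID] = 6e-8

    records = []
    for rsid, rec in zip(order, exposure.records):
        z = float(sps.norm.isf(pvals[rsid] / 2))
        records.append(
            SNPAssociation(
                rsid=rsid,
                chromosome="19",
                position=rec.position,
                effect_allele=rec.effect_allele,
                other_allele=rec.other_allele,
                eaf=rec.eaf,
                beta=abs(rec.beta) if rec.beta != 0 else 0.1,
                se=abs(rec.beta) / z,
                pval=pvals[rsid],
                n=5440,
            )
        )
    exposure = SummaryStatsSet("GDF15", records, trait_type="continuous")

    ld = simulate_ld_matrix(
        list(order),
        block_structure=[
            ([KEPT_RSIDS[0], LD_DROPPED_RSIDS[0]], 0.90),
            ([KEPT_RSIDS[1], LD_DROPPED_RSIDS[1]], 0.85),
            ([KEPT_RSIDS[2], LD_DROPPED_RSIDS[2]], 0.88),
        ],
    )

    outcome_labels = ("AIS", "CES", "LAS", "SVS", "AF", "HF", "NICM", "CAD", "MI")
    outcomes: dict[str, SummaryStatsSet] = {}
    for i, label in enumerate(outcome_labels):
        ocfg = SimulationConfig(n_snps=9, theta=0.05, seed=20191 + 7 * (i + 1))
        _, out, _ = simulate_pair(ocfg)
        recs = []
        for rsid, exp_rec, out_rec in zip(order, exposure.records, out.records):
            recs.append(
                SNPAssociation(
                    rsid=rsid,
                    chromosome="19",
                    position=exp_rec.position,
                    effect_allele=exp_rec.effect_allele,
                    other_allele=exp_rec.other_allele,
                    eaf=exp_rec.eaf,
                    beta=out_rec.beta,
                    se=out_rec.se,
                    pval=out_rec.pval,
                    n=400000,
                )
            )
        outcomes[label] = SummaryStatsSet(label, recs, trait_type="binary")
    return exposure, ld, outcomes
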