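"""Instrument selection: significance filter, LD pruning, pleiotropy exclusions.

The selection pipeline is the standard one for cis-instrument MR: keep SNPs
at genome-wide significance (p < 5e-8, strict), greedily prune correlated
pairs at r² >= 0.8 keeping the smaller-p member, then drop SNPs flagged for
known pleiotropic associations via an offline exclusion list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .sumstats_io import LDMatrix, SummaryStatsSet

GENOME_WIDE_P = 5e-8
DEFAULT_R2 = 0.8


class SelectionError(ValueError):
    pass


@dataclass
class SelectionReport:
    """Accounting of every input SNP: kept, or dropped with a reason.

    Invariant: kept and the three dropped lists partition the input rsids.
    """

    kept: list[str] = field(default_factory=list)
    dropped_pvalue: list[str] = field(default_factory=list)
    #: (dropped rsid, retained partner rsid, r2 that triggered removal)
    dropped_ld: list[tuple[str, str, float]] = field(default_factory=list)
    dropped_excluded: list[str] = field(default_factory=list)
    #: rsids on the exclusion list that were not present in the input
    unknown_exclusions: list[str] = field(default_factory=list)

    @property
    def dropped_ld_rsids(self) -> list[str]:
        return [r for r, _, _ in self.dropped_ld]

    @property
    def n_input(self) -> int:
        return (
            len(self.kept)
            + len(self.dropped_pvalue)
            + len(self.dropped_ld)
            + len(self.dropped_excluded)
        )

    def merge(self, other: "SelectionReport") -> "SelectionReport":
        """Compose with a later stage: its kept list supersedes ours."""
        return SelectionReport(
            kept=list(other.kept),
            dropped_pvalue=self.dropped_pvalue + other.dropped_pvalue,
            dropped_ld=self.dropped_ld + other.dropped_ld,
            dropped_excluded=self.dropped_excluded + other.dropped_excluded,
            unknown_exclusions=self.unknown_exclusions + other.unknown_exclusions,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rsid": r, "stage": "kept", "reason": "", "partner_rsid": "", "r2": ""}
                for r in self.kept]
        rows += [
            {"rsid": r, "stage": "pvalue", "reason": "above significance threshold",
             "partner_rsid": "", "r2": ""}
            for r in self.dropped_pvalue
        ]
        rows += [
            {"rsid": r, "stage": "ld", "reason": "high LD with retained SNP",
             "partner_rsid": p, "r2": f"{v:.3f}"}
            for r, p, v in self.dropped_ld
        ]
        rows += [
            {"rsid": r, "stage": "excluded", "reason": "exclusion list",
             "partner_rsid": "", "r2": ""}
            for r in self.dropped_excluded
        ]
        return pd.DataFrame(rows, columns=["rsid", "stage", "reason", "partner_rsid", "r2"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_genomewide(
    stats: SummaryStatsSet, threshold: float = GENOME_WIDE_P
) -> tuple[SummaryStatsSet, SelectionReport]:
    """Keep records with p strictly below ``threshold`` (default 5e-8)."""
    if not 0 < threshold < 1:
        raise SelectionError(f"threshold must be in (0, 1), got {threshold}")
    if len(stats) == 0:
        raise SelectionError("empty summary-statistics set")
    kept = [r for r in stats if r.pval < threshold]
    dropped = [r.rsid for r in stats if r.pval >= threshold]
    report = SelectionReport(kept=[r.rsid for r in kept], dropped_pvalue=dropped)
    return stats.subset(report.kept), report


def prune_ld(
    stats: SummaryStatsSet, ld: LDMatrix, r2_threshold: float = DEFAULT_R2
) -> tuple[SummaryStatsSet, SelectionReport]:
    """Greedy LD pruning (clumping): keep the smallest-p SNP, drop its r² >= threshold
    partners, repeat on the remainder.  Ties on p broken by rsid.

    The kept set never contains a pair at or above ``r2_threshold``.
    """
    missing = [r.rsid for r in stats if r.rsid not in ld]
    if missing:
        raise SelectionError(f"rsid(s) missing from LD matrix: {', '.join(missing)}")
    remaining = sorted(stats.records, key=lambda r: (r.pval, r.rsid))
    kept: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    while remaining:
        index_snp = remaining.pop(0)
        kept.append(index_snp.rsid)
        still: list = []
        for r in remaining:
            v = ld.value(index_snp.rsid, r.rsid)
            if v >= r2_threshold:
                dropped.append((r.rsid, index_snp.rsid, v))
            else:
                still.append(r)
        remaining = still
    report = SelectionReport(kept=kept, dropped_ld=dropped)
    return stats.subset(kept), report


def apply_exclusions(
    stats: SummaryStatsSet, exclude: list[str]
) -> tuple[SummaryStatsSet, SelectionReport]:
    """Remove listed rsids; unknown entries are recorded, not an error."""
    present = set(stats.rsids)
    dropped = [r for r in exclude if r in present]
    unknown = [r for r in exclude if r not in present]
    kept = [r for r in stats.rsids if r not in set(dropped)]
    report = SelectionReport(
        kept=kept, dropped_excluded=dropped, unknown_exclusions=unknown
    )
    return stats.subset(kept), report


def select_instruments(
    stats: SummaryStatsSet,
    ld: LDMatrix,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = DEFAULT_R2,
    exclude: list[str] | None = None,
) -> tuple[SummaryStatsSet, SelectionReport]:
    """Full selection: p-value filter, then LD pruning, then exclusions.

    The returned report aggregates all three stages; its lists partition the
    input rsids.  Raises :class:`SelectionError` if nothing survives.
    """
    kept_stats, report = filter_genomewide(stats, p_threshold)
    if len(kept_stats) > 0:
        kept_stats, ld_report = prune_ld(kept_stats, ld, r2_threshold)
        report = report.merge(ld_report)
    kept_stats, ex_report = apply_exclusions(kept_stats, exclude or [])
    report = report.merge(ex_report)
    if len(kept_stats) == 0:
        raise SelectionError(
            "no instruments remain after selection; review the p-value and r2 thresholds"
        )
    return kept_stats, report
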