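"""Read, validate and write GWAS summary statistics, LD matrices and results.

File dialect: tab-separated with a header is canonical; comma-separated files
are accepted on read.  Missing effect-allele frequency or sample size is an
empty field, never 0.  Positions are 1-based.  Only biallelic SNPs with
single-nucleotide A/C/G/T alleles are accepted; indels and multi-allelic
records are rejected at read time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")

#: canonical column order for summary-statistics TSVs
SUMSTATS_COLUMNS = (
    "rsid",
    "chr",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

REQUIRED_COLUMNS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pval")


class SumstatsFormatError(ValueError):
    """A file is structurally unusable (missing columns, non-square matrix)."""


class SumstatsValidationError(ValueError):
    """Rows or values violate a stated invariant (duplicate rsid, se <= 0)."""


@dataclass(frozen=True)
class SNPAssociation:
    """One SNP's association record in one GWAS.

    ``beta`` is the effect per copy of ``effect_allele``: per-SD of the
    exposure for continuous traits, log-odds for binary outcomes.
    ``eaf`` and ``n`` may be ``None`` (missing).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chromosome: str = ""
    position: int | None = None
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise SumstatsValidationError(
                f"{self.rsid}: effect allele {self.effect_allele!r} is not one of A/C/G/T"
            )
        if self.other_allele not in VALID_ALLELES:
            raise SumstatsValidationError(
                f"{self.rsid}: other allele {self.other_allele!r} is not one of A/C/G/T"
            )
        if self.effect_allele == self.other_allele:
            raise SumstatsValidationError(f"{self.rsid}: alleles are identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise SumstatsValidationError(f"{self.rsid}: se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise SumstatsValidationError(
                f"{self.rsid}: pval must be in (0, 1], got {self.pval}"
            )
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise SumstatsValidationError(
                f"{self.rsid}: eaf must be in [0, 1], got {self.eaf}"
            )
        if self.n is not None and not self.n > 0:
            raise SumstatsValidationError(f"{self.rsid}: n must be > 0, got {self.n}")
        if not math.isfinite(self.beta):
            raise SumstatsValidationError(f"{self.rsid}: beta is not finite")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.effect_allele, self.other_allele))

    def is_palindromic(self) -> bool:
        """True for A/T or G/C SNPs, whose strand is ambiguous."""
        return self.alleles in (frozenset("AT"), frozenset("GC"))


@dataclass
class SummaryStatsSet:
    """An ordered set of per-SNP associations from one GWAS, unique by rsid."""

    trait_name: str
    records: list[SNPAssociation] = field(default_factory=list)
    trait_type: str = "binary"  # {continuous, binary}

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        dups = _duplicates(r.rsid for r in self.records)
        if dups:
            raise SumstatsValidationError(f"duplicate rsid(s): {', '.join(sorted(dups))}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, rsid: str) -> bool:
        return any(r.rsid == rsid for r in self.records)

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    def get(self, rsid: str) -> SNPAssociation:
        for r in self.records:
            if r.rsid == rsid:
                return r
        raise KeyError(rsid)

    def subset(self, rsids: Iterable[str]) -> "SummaryStatsSet":
        """Records whose rsid is in ``rsids``, input order preserved."""
        keep = set(rsids)
        return replace(self, records=[r for r in self.records if r.rsid in keep])


@dataclass(frozen=True)
class LDMatrix:
    """Pairwise squared-correlation (r²) matrix over an ordered set of rsids."""

    rsids: tuple[str, ...]
    r2: np.ndarray

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        k = len(self.rsids)
        if r2.shape != (k, k):
            raise SumstatsFormatError(
                f"LD matrix shape {r2.shape} does not match {k} rsids"
            )
        if np.any(r2 < -1e-12) or np.any(r2 > 1 + 1e-12):
            raise SumstatsValidationError("LD r2 values must lie in [0, 1]")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-6):
            raise SumstatsValidationError("LD matrix diagonal must be 1")
        if not np.allclose(r2, r2.T, atol=1e-6):
            raise SumstatsValidationError("LD matrix must be symmetric (tolerance 1e-6)")
        object.__setattr__(self, "r2", r2)

    def value(self, a: str, b: str) -> float:
        i, j = self.rsids.index(a), self.rsids.index(b)
        return float(self.r2[i, j])

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.rsids


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in items:
        if x in seen:
            dups.add(x)
        seen.add(x)
    return dups


def _read_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited table, sniffing tab vs comma from the header line."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_type: str = "binary",
) -> tuple[SummaryStatsSet, int]:
    """Read a summary-statistics table into a validated :class:`SummaryStatsSet`.

    Parameters
    ----------
    path:
        Tab- or comma-separated file with a header.
    column_map:
        Optional mapping from file column names to the canonical names
        (``rsid, chr, pos, effect_allele, other_allele, eaf, beta, se,
        pval, n``).
    trait_name:
        Name of the trait; defaults to the file stem.
    trait_type:
        ``continuous`` or ``binary``.

    Returns
    -------
    (stats, n_rejected):
        the validated set (input order preserved) and the count of rows
        rejected for violating a per-record invariant.

    Raises
    ------
    SumstatsFormatError
        if a required column is missing after mapping.
    SumstatsValidationError
        if an rsid is duplicated or a kept row has non-positive SE.
    """
    df = _read_table(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"missing required column(s): {', '.join(missing)}")

    dups = _duplicates(df["rsid"])
    if dups:
        raise SumstatsValidationError(f"duplicate rsid(s): {', '.join(sorted(dups))}")

    records: list[SNPAssociation] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        se = float(d["se"]) if d["se"] != "" else float("nan")
        if not se > 0:
            raise SumstatsValidationError(
                f"{d['rsid']}: non-positive se {d['se']!r}"
            )
        try:
            records.append(
                SNPAssociation(
                    rsid=d["rsid"],
                    chromosome=str(d.get("chr", "") or ""),
                    position=int(d["pos"]) if d.get("pos", "") != "" else None,
                    effect_allele=d["effect_allele"].upper(),
                    other_allele=d["other_allele"].upper(),
                    eaf=float(d["eaf"]) if d.get("eaf", "") != "" else None,
                    beta=float(d["beta"]),
                    se=se,
                    pval=float(d["pval"]),
                    n=int(float(d["n"])) if d.get("n", "") != "" else None,
                )
            )
        except (SumstatsValidationError, ValueError):
            n_rejected += 1
    return (
        SummaryStatsSet(
            trait_name=trait_name or Path(path).stem,
            records=records,
            trait_type=trait_type,
        ),
        n_rejected,
    )


def write_sumstats(stats: SummaryStatsSet, path: str | Path) -> None:
    """Write a summary-statistics set as the canonical tab-separated table."""
    rows = []
    for r in stats:
        rows.append(
            {
                "rsid": r.rsid,
                "chr": r.chromosome,
                "pos": "" if r.position is None else r.position,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": "" if r.eaf is None else repr(r.eaf),
                "beta": repr(r.beta),
                "se": repr(r.se),
                "pval": repr(r.pval),
                "n": "" if r.n is None else r.n,
            }
        )
    pd.DataFrame(rows, columns=list(SUMSTATS_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_ld_matrix(path: str | Path) -> LDMatrix:
    """Read an LD r² matrix.

    Accepts either a labeled square matrix (first column = rsid labels,
    header = the same rsids) or the three-column long form
    ``rsid_a, rsid_b, r2`` (unlisted pairs default to r² = 0).
    """
    df = _read_table(path)
    cols = [c.lower() for c in df.columns]
    if cols[:3] == ["rsid_a", "rsid_b", "r2"] and len(df.columns) == 3:
        return _ld_from_long(df)
    labels = df.iloc[:, 0].tolist()
    header = list(df.columns[1:])
    if len(header) != len(labels):
        raise SumstatsFormatError(
            f"LD matrix is not square: {len(labels)} rows vs {len(header)} columns"
        )
    if header != labels:
        raise SumstatsFormatError("LD matrix row and column rsid labels differ")
    r2 = df.iloc[:, 1:].astype(float).to_numpy()
    return LDMatrix(rsids=tuple(labels), r2=r2)


def _ld_from_long(df: pd.DataFrame) -> LDMatrix:
    df = df.rename(columns={c: c.lower() for c in df.columns})
    rsids = list(dict.fromkeys(df["rsid_a"].tolist() + df["rsid_b"].tolist()))
    idx = {r: i for i, r in enumerate(rsids)}
    k = len(rsids)
    r2 = np.zeros((k, k))
    np.fill_diagonal(r2, 1.0)
    for row in df.itertuples(index=False):
        i, j = idx[row.rsid_a], idx[row.rsid_b]
        v = float(row.r2)
        if r2[j, i] not in (0.0, 1.0) and abs(r2[j, i] - v) > 1e-6:
            raise SumstatsValidationError(
                f"LD long form lists inconsistent r2 for {row.rsid_a}/{row.rsid_b}"
            )
        r2[i, j] = r2[j, i] = v
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(rsids=tuple(rsids), r2=r2)


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    """Write the labeled square TSV form."""
    df = pd.DataFrame(ld.r2, index=list(ld.rsids), columns=list(ld.rsids))
    df.to_csv(path, sep="\t", index_label="rsid")


def read_exclusion_list(path: str | Path) -> list[str]:
    """One rsid per line; '#' starts a comment; blank lines ignored."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            out.append(token)
    return out


RESULTS_COLUMNS = (
    "outcome",
    "n_snps",
    "ivw_estimate",
    "ivw_se",
    "ivw_pval",
    "ivw_q",
    "ivw_q_pval",
    "wm_estimate",
    "wm_se",
    "wm_pval",
    "egger_estimate",
    "egger_se",
    "egger_pval",
    "egger_intercept",
    "egger_intercept_p",
    "or",
    "or_ci_low",
    "or_ci_high",
)


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return ""
    return f"{x:.3f}"


def write_results_table(results: Mapping[str, Mapping[str, "object"]], path: str | Path) -> None:
    """Write a per-outcome results grid as a TSV, 3-decimal formatting.

    ``results`` maps outcome label -> mapping of method name
    (``IVW``, ``weighted_median``, ``MR_Egger``) to :class:`~gdf15mr.estimators.MRResult`.
    Methods absent for an outcome (e.g. too few instruments) leave blank cells.
    """
    if not results:
        raise ValueError("results table requires at least one outcome")
    rows = []
    for outcome, by_method in results.items():
        ivw_r = by_method.get("IVW")
        wm_r = by_method.get("weighted_median")
        eg_r = by_method.get("MR_Egger")
        row: dict[str, str] = {c: "" for c in RESULTS_COLUMNS}
        row["outcome"] = outcome
        if ivw_r is not None:
            row.update(
                n_snps=str(ivw_r.n_snps),
                ivw_estimate=_fmt(ivw_r.estimate),
                ivw_se=_fmt(ivw_r.se),
                ivw_pval=_fmt(ivw_r.pval),
                ivw_q=_fmt(ivw_r.q_stat),
                ivw_q_pval=_fmt(ivw_r.q_pval),
                **{
                    "or": _fmt(ivw_r.odds_ratio),
                    "or_ci_low": _fmt(ivw_r.ci_low),
                    "or_ci_high": _fmt(ivw_r.ci_high),
                },
            )
        if wm_r is not None:
            row.update(
                wm_estimate=_fmt(wm_r.estimate),
                wm_se=_fmt(wm_r.se),
                wm_pval=_fmt(wm_r.pval),
            )
        if eg_r is not None:
            row.update(
                egger_estimate=_fmt(eg_r.estimate),
                egger_se=_fmt(eg_r.se),
                egger_pval=_fmt(eg_r.pval),
                egger_intercept=_fmt(eg_r.egger_intercept),
                egger_intercept_p=_fmt(eg_r.egger_intercept_p),
            )
        rows.append(row)
    pd.DataFrame(rows, columns=list(RESULTS_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a results grid written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t", dtype={"outcome": str})
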