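"""Align exposure and outcome summary statistics to a shared effect allele.

Two-sample MR combines per-SNP effects from two independent GWAS, which may
report effects for opposite alleles or on opposite strands.  For each SNP the
outcome record is rewritten so its effect allele matches the exposure's:

* identical allele pair -> unchanged;
* swapped effect/other alleles -> outcome beta negated, eaf -> 1 - eaf;
* strand complements (e.g. A/G vs T/C) -> complemented, then the two rules
  above;
* palindromic SNPs (A/T, G/C) are strand-ambiguous: resolved by allele
  frequency when both eafs are available and both fall outside the ambiguity
  window [0.42, 0.58], otherwise dropped;
* anything else -> dropped as an allele mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .sumstats_io import SNPAssociation, SummaryStatsSet

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: eaf window within which a palindromic SNP's strand cannot be inferred
AMBIGUOUS_EAF_WINDOW = (0.42, 0.58)

ACTIONS = ("unchanged", "flipped", "dropped_palindromic", "dropped_mismatch")


class HarmonizationError(ValueError):
    pass


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP carrying exposure and outcome effects for the same effect allele."""

    rsid: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    action: str  # one of ACTIONS
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")
        if not self.dropped and (self.se_exposure <= 0 or self.se_outcome <= 0):
            raise ValueError(f"{self.rsid}: standard errors must be > 0")

    @property
    def dropped(self) -> bool:
        return self.action.startswith("dropped")


def _frequencies_resolve(exp_eaf: float | None, out_eaf: float | None) -> bool:
    """Can allele frequency disambiguate a palindromic SNP's strand?"""
    lo, hi = AMBIGUOUS_EAF_WINDOW
    return (
        exp_eaf is not None
        and out_eaf is not None
        and not lo <= exp_eaf <= hi
        and not lo <= out_eaf <= hi
    )


def harmonize_pair(
    exposure: SNPAssociation,
    outcome: SNPAssociation,
    palindrome_policy: str = "frequency",
) -> HarmonizedInstrument:
    """Harmonize one outcome record against its exposure record.

    ``palindrome_policy``: ``frequency`` (resolve by eaf when unambiguous,
    else drop) or ``drop`` (always drop palindromic SNPs).
    """
    if exposure.rsid != outcome.rsid:
        raise HarmonizationError(
            f"rsid mismatch: {exposure.rsid} vs {outcome.rsid}"
        )
    if palindrome_policy not in ("frequency", "drop"):
        raise HarmonizationError(f"unknown palindrome policy {palindrome_policy!r}")

    def make(beta_out: float, eaf_out: float | None, action: str) -> HarmonizedInstrument:
        return HarmonizedInstrument(
            rsid=exposure.rsid,
            beta_exposure=exposure.beta,
            se_exposure=exposure.se,
            beta_outcome=beta_out,
            se_outcome=outcome.se,
            action=action,
            eaf_exposure=exposure.eaf,
            eaf_outcome=eaf_out,
        )

    def drop(action: str) -> HarmonizedInstrument:
        return HarmonizedInstrument(
            rsid=exposure.rsid,
            beta_exposure=exposure.beta,
            se_exposure=exposure.se,
            beta_outcome=outcome.beta,
            se_outcome=outcome.se,
            action=action,
            eaf_exposure=exposure.eaf,
            eaf_outcome=outcome.eaf,
        )

    if exposure.is_palindromic():
        # Alleles always "match" (possibly via self-complement), but strand is
        # ambiguous; orientation must come from allele frequency.
        if outcome.alleles != exposure.alleles:
            return drop("dropped_mismatch")
        if palindrome_policy == "drop" or not _frequencies_resolve(
            exposure.eaf, outcome.eaf
        ):
            return drop("dropped_palindromic")
        # Strand is unknown, so the allele labels are uninformative; the two
        # effect alleles are the same physical allele iff their frequencies
        # fall on the same side of 0.5.
        same_side = (exposure.eaf > 0.5) == (outcome.eaf > 0.5)
        if same_side:
            return make(outcome.beta, outcome.eaf, "unchanged")
        return make(
            -outcome.beta,
            None if outcome.eaf is None else 1 - outcome.eaf,
            "flipped",
        )

    ea, oa = outcome.effect_allele, outcome.other_allele
    for _strand in ("as_is", "complement"):
        if _strand == "complement":
            ea, oa = COMPLEMENT[ea], COMPLEMENT[oa]
        if (ea, oa) == (exposure.effect_allele, exposure.other_allele):
            return make(outcome.beta, outcome.eaf, "unchanged")
        if (ea, oa) == (exposure.other_allele, exposure.effect_allele):
            return make(
                -outcome.beta,
                None if outcome.eaf is None else 1 - outcome.eaf,
                "flipped",
            )
    return drop("dropped_mismatch")


def harmonize_sets(
    exposure_set: SummaryStatsSet,
    outcome_set: SummaryStatsSet,
    palindrome_policy: str = "frequency",
) -> tuple[list[HarmonizedInstrument], pd.DataFrame]:
    """Harmonize the rsid intersection of two studies.

    Returns the retained instruments (exposure order) and a per-SNP report
    covering every exposure rsid exactly once: its action, or ``missing`` if
    absent from the outcome set.  Raises if the intersection is empty.
    """
    outcome_by_rsid = {r.rsid: r for r in outcome_set}
    harmonized: list[HarmonizedInstrument] = []
    rows: list[dict[str, str]] = []
    for exp in exposure_set:
        out = outcome_by_rsid.get(exp.rsid)
        if out is None:
            rows.append({"rsid": exp.rsid, "action": "missing",
                         "detail": "absent from outcome study"})
            continue
        h = harmonize_pair(exp, out, palindrome_policy)
        rows.append({"rsid": h.rsid, "action": h.action, "detail": ""})
        if not h.dropped:
            harmonized.append(h)
    if not any(r["action"] != "missing" for r in rows):
        raise HarmonizationError(
            f"no shared rsids between {exposure_set.trait_name!r} and "
            f"{outcome_set.trait_name!r}"
        )
    report = pd.DataFrame(rows, columns=["rsid", "action", "detail"])
    return harmonized, report


def write_harmonization_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)
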