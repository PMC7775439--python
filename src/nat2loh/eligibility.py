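"""Patient-level eligibility decisions and cohort summary statistics.

A patient is eligible for allele-selective NAT2 LOH therapy when four
conditions hold in order: the normal diplotype is an intermediate acetylator
(one rapid, one slow allele); the tumor shows LOH; the lost allele is the
rapid one; and the retained slow allele encodes an APA-sensitive enzyme
(groups *5, *6, *14 — not *7).  The cohort summary mirrors the published
per-genotype count layout (individuals, LOH events, rapid-allele losses) with
derived percentages recomputed from the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .defs import (
    AlleleTable,
    _data_path,
    genotype_label,
    phenotype_of_pair,
)
from .errors import ValidationError
from .loh import LohCall

REASONS = (
    "eligible",
    "not-intermediate",
    "no-LOH",
    "slow-allele-lost",
    "retained-allele-APA-resistant",
    "unresolved",
)


@dataclass
class PatientCall:
    """Joined normal haplotype + tumor LOH + eligibility decision."""

    patient: str
    normal_pair: Optional[Tuple[str, str]]
    phenotype: Optional[str]
    loh: Optional[bool]
    lost_allele: Optional[str]
    eligible: bool
    reason: str
    tumor_pair: Optional[Tuple[str, str]] = None


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def decide_eligibility(
    patient: str,
    normal_pair: Optional[Tuple[str, str]],
    loh_call: Optional[LohCall],
    table: AlleleTable,
    tumor_pair: Optional[Tuple[str, str]] = None,
) -> PatientCall:
    """Apply the eligibility rule; the reason records the first failing
    condition in rule order."""
    if normal_pair is None:
        return PatientCall(
            patient=patient, normal_pair=None, phenotype=None, loh=None,
            lost_allele=None, eligible=False, reason="unresolved",
        )
    phenotype = phenotype_of_pair(normal_pair[0], normal_pair[1], table)
    loh = loh_call.loh if loh_call is not None else None
    lost = loh_call.lost_allele if loh_call is not None else None
    base = dict(
        patient=patient, normal_pair=normal_pair, phenotype=phenotype,
        loh=loh, lost_allele=lost, tumor_pair=tumor_pair,
    )
    if phenotype != "intermediate":
        return PatientCall(eligible=False, reason="not-intermediate", **base)
    if not loh:
        return PatientCall(eligible=False, reason="no-LOH", **base)
    if lost is None or table[lost].phenotype != "rapid":
        return PatientCall(eligible=False, reason="slow-allele-lost", **base)
    retained = (
        normal_pair[1] if normal_pair[0] == lost else normal_pair[0]
    )
    if not table[retained].apa_sensitive:
        return PatientCall(
            eligible=False, reason="retained-allele-APA-resistant", **base
        )
    return PatientCall(eligible=True, reason="eligible", **base)


@dataclass
class CohortSummary:
    """Per-genotype counts and derived cohort percentages."""

    rows: pd.DataFrame  # genotype, phenotype, individuals, loh_events,
    #                     rapid_losses, eligible
    subtotals: Dict[str, Dict[str, int]] = field(default_factory=dict)
    totals: Dict[str, int] = field(default_factory=dict)
    derived: Dict[str, float] = field(default_factory=dict)
    group_freq_pct: Dict[str, float] = field(default_factory=dict)
    n_unresolved: int = 0


def _is_rapid_loss(genotype: str, lost: Optional[str], table: AlleleTable) -> bool:
    return lost is not None and table[lost].phenotype == "rapid"


def summarize_counts(
    counts: pd.DataFrame,
    table: AlleleTable,
    n_unresolved: int = 0,
) -> CohortSummary:
    """Build a cohort summary from a per-genotype count table.

    ``counts`` needs columns genotype (e.g. ``*4/*5B``), individuals,
    loh_events, rapid_losses.  Eligible events per genotype are the rapid
    losses of intermediate genotypes whose slow allele is APA-sensitive.
    Derived percentages are rounded half-up to one decimal.
    """
    rows = []
    for _, row in counts.iterrows():
        a1, a2 = str(row["genotype"]).split("/")
        phenotype = phenotype_of_pair(a1, a2, table)
        label = genotype_label(a1, a2, table)
        n = int(row["individuals"])
        loh = int(row["loh_events"])
        rapid_lost = int(row["rapid_losses"])
        if not 0 <= rapid_lost <= loh <= n:
            raise ValidationError(
                f"{label}: inconsistent counts {n}/{loh}/{rapid_lost}"
            )
        if phenotype == "intermediate":
            slow = a2 if table[a1].phenotype == "rapid" else a1
            eligible = rapid_lost if table[slow].apa_sensitive else 0
        else:
            eligible = 0
        rows.append(
            dict(genotype=label, phenotype=phenotype, individuals=n,
                 loh_events=loh, rapid_losses=rapid_lost, eligible=eligible)
        )
    df = pd.DataFrame(rows)

    subtotals: Dict[str, Dict[str, int]] = {}
    for phenotype in ("rapid", "intermediate", "slow"):
        sub = df[df["phenotype"] == phenotype]
        subtotals[phenotype] = {
            col: int(sub[col].sum())
            for col in ("individuals", "loh_events", "rapid_losses", "eligible")
        }
    totals = {
        col: int(df[col].sum())
        for col in ("individuals", "loh_events", "rapid_losses", "eligible")
    }

    n_total = totals["individuals"]
    inter = subtotals["intermediate"]

    def pct(num: int, den: int, ndigits: int = 1) -> float:
        return round_half_up(100.0 * num / den, ndigits) if den else 0.0

    derived = {
        "overall_loh_pct": pct(totals["loh_events"], n_total),
        "intermediate_pct": pct(inter["individuals"], n_total),
        "intermediate_loh_pct": pct(inter["loh_events"], inter["individuals"]),
        "rapid_loss_among_intermediate_loh_pct": pct(
            inter["rapid_losses"], inter["loh_events"]
        ),
        "eligible_pct": pct(totals["eligible"], n_total),
        "eligible_pct_int": pct(totals["eligible"], n_total, ndigits=0),
    }
    for _, row in df[df["phenotype"] == "intermediate"].iterrows():
        key = row["genotype"]
        derived[f"eligible_from_{key}_pct"] = pct(row["eligible"], n_total)
        derived[f"rapid_loss_rate_{key}_pct"] = pct(
            row["rapid_losses"], row["individuals"], ndigits=0
        )
        derived[f"loh_rate_{key}_pct"] = pct(
            row["loh_events"], row["individuals"], ndigits=0
        )

    # allele-group frequencies over the resolved individuals
    allele_counts: Dict[str, int] = {}
    for _, row in df.iterrows():
        for name in row["genotype"].split("/"):
            group = table[name].group
            allele_counts[group] = (
                allele_counts.get(group, 0) + int(row["individuals"])
            )
    group_freq_pct = {
        g: pct(c, 2 * n_total) for g, c in sorted(allele_counts.items())
    }

    return CohortSummary(
        rows=df, subtotals=subtotals, totals=totals, derived=derived,
        group_freq_pct=group_freq_pct, n_unresolved=n_unresolved,
    )


def summarize_cohort(
    patients: Iterable[PatientCall],
    table: AlleleTable,
) -> CohortSummary:
    """Aggregate per-patient calls into the per-genotype summary."""
    acc: Dict[str, Dict[str, int]] = {}
    n_unresolved = 0
    for p in patients:
        if p.normal_pair is None:
            n_unresolved += 1
            continue
        label = genotype_label(p.normal_pair[0], p.normal_pair[1], table)
        slot = acc.setdefault(
            label, {"individuals": 0, "loh_events": 0, "rapid_losses": 0}
        )
        slot["individuals"] += 1
        if p.loh:
            slot["loh_events"] += 1
            if _is_rapid_loss(label, p.lost_allele, table):
                slot["rapid_losses"] += 1
    counts = pd.DataFrame(
        [dict(genotype=g, **v) for g, v in sorted(acc.items())]
    )
    return summarize_counts(counts, table, n_unresolved=n_unresolved)


def load_table1(cohort: str = "finnish") -> pd.DataFrame:
    """Packaged per-genotype count fixtures transcribed from the published
    tumor/normal cohort table (``finnish``, ``swedish`` or ``combined``)."""
    from .io import read_tsv

    if cohort in ("finnish", "swedish"):
        return read_tsv(_data_path(f"table1_{cohort}.tsv"))
    if cohort == "combined":
        fi = read_tsv(_data_path("table1_finnish.tsv"))
        sw = read_tsv(_data_path("table1_swedish.tsv"))
        merged = (
            pd.concat([fi, sw])
            .groupby("genotype", as_index=False)
            .sum(numeric_only=True)
        )
        return merged
    raise ValidationError(f"unknown cohort {cohort!r}")


def load_population_reference() -> pd.DataFrame:
    """Published global per-group slow-allele statistics (percent units)."""
    from .io import read_tsv

    return read_tsv(_data_path("thousand_genomes_summary.tsv"))


def estimate_eligible_population(
    annual_incidence: float,
    f_intermediate: float,
    f_loh: float,
    f_rapid_lost: Optional[float] = None,
) -> Dict[str, float]:
    """Expected annual count of therapy-eligible patients.

    The estimate is the plain product of the supplied factors: annual case
    incidence x fraction with an APA-targetable intermediate diplotype x
    fraction of tumors with LOH at the locus, optionally x the fraction of
    LOH events losing the rapid allele (omitted factors default to 1).  Each
    factor is echoed in the output for provenance.
    """
    if annual_incidence < 0:
        raise ValidationError("annual incidence must be >= 0")
    factors = {"f_intermediate": f_intermediate, "f_loh": f_loh}
    if f_rapid_lost is not None:
        factors["f_rapid_lost"] = f_rapid_lost
    for name, value in factors.items():
        if not 0.0 <= value <= 1.0:
            raise ValidationError(f"{name}={value} outside [0, 1]")
    estimate = annual_incidence
    for value in factors.values():
        estimate *= value
    out = {"annual_incidence": annual_incidence, **factors,
           "expected_annual_eligible": estimate}
    return out
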