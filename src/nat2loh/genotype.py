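"""Diplotype imputation from unphased genotypes and population statistics.

SNP-array or WGS variant calls give unphased alternate-allele counts at the
seven classifying sites.  The star-allele pair is recovered by exhaustive
enumeration: an unordered pair of catalogued alleles is a candidate iff, site
by site, the combined alternate multiplicity of its two patterns (0/1/2)
matches the genotype.  The classic NAT2 phase ambiguity — e.g. heterozygosity
at 341, 481 and 803 fitting both *4/*5B and *5A/*12A — is resolved by a
diplotype prior (product of population allele frequencies) with all
candidates retained for audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .defs import (
    AlleleTable,
    RAPID_GROUPS,
    SLOW_GROUPS,
    SiteCatalog,
    allele_sort_key,
)
from .errors import ValidationError

Genotype = Mapping[str, Optional[int]]  # rsid -> alt-allele count (0/1/2/None)
Pair = Tuple[str, str]


@dataclass
class ImputedPair:
    """Result of imputing one sample's star-allele pair."""

    sample: str
    allele1: Optional[str]
    allele2: Optional[str]
    candidates: Tuple[Tuple[Pair, float], ...] = ()
    resolved: bool = False
    ambiguous_tie: bool = False
    uniform_prior: bool = False
    no_call_reason: Optional[str] = None

    @property
    def pair(self) -> Optional[Pair]:
        if self.allele1 is None:
            return None
        return (self.allele1, self.allele2)


def _pair_multiplicity(pair: Pair, table: AlleleTable, rsid: str) -> int:
    return sum(
        any(r == rsid for r, _ in table[name].alt_pattern) for name in pair
    )


def collapse_to_genotype(pair: Pair, table: AlleleTable,
                         catalog: SiteCatalog) -> Dict[str, int]:
    """Unphase a diplotype into per-classifying-site alt counts."""
    return {
        s.rsid: _pair_multiplicity(pair, table, s.rsid)
        for s in catalog.classifying
    }


def enumerate_pairs(
    genotype: Genotype,
    table: AlleleTable,
    catalog: SiteCatalog,
) -> List[Pair]:
    """All unordered allele pairs exactly reproducing the genotype.

    Requires non-missing genotypes at the seven classifying sites; missing
    auxiliary sites never block imputation.  An empty list means the genotype
    is unresolvable under the packaged allele table.
    """
    classifying = [s.rsid for s in catalog.classifying]
    missing = [r for r in classifying if genotype.get(r) is None]
    if missing:
        raise ValidationError(
            f"missing classifying-site genotype(s): {', '.join(missing)}"
        )
    for rsid in classifying:
        if genotype[rsid] not in (0, 1, 2):
            raise ValidationError(f"{rsid}: genotype must be 0, 1 or 2")
    names = sorted(table.names(), key=allele_sort_key)
    out: List[Pair] = []
    for pair in combinations_with_replacement(names, 2):
        if all(
            _pair_multiplicity(pair, table, rsid) == genotype[rsid]
            for rsid in classifying
        ):
            out.append(pair)
    return out


def resolve_pair(
    candidates: Sequence[Pair],
    frequencies: Mapping[str, float],
    sample: str = "sample",
) -> ImputedPair:
    """Choose among candidate pairs by the diplotype frequency-product prior.

    Ties are broken by natural allele-name order and flagged; a candidate
    allele missing from the frequency table triggers a flagged fallback to a
    uniform prior.  All candidates are retained in the output.
    """
    if not candidates:
        return ImputedPair(
            sample=sample, allele1=None, allele2=None,
            resolved=False, no_call_reason="no_consistent_pair",
        )
    uniform = any(
        name not in frequencies for pair in candidates for name in pair
    )
    def score(pair: Pair) -> float:
        if uniform:
            return 1.0
        return frequencies[pair[0]] * frequencies[pair[1]]

    scored = sorted(
        ((pair, score(pair)) for pair in candidates),
        key=lambda kv: (
            -kv[1],
            allele_sort_key(kv[0][0]),
            allele_sort_key(kv[0][1]),
        ),
    )
    best_pair, best_score = scored[0]
    tie = len(scored) > 1 and scored[1][1] == best_score
    return ImputedPair(
        sample=sample,
        allele1=best_pair[0],
        allele2=best_pair[1],
        candidates=tuple(scored),
        resolved=True,
        ambiguous_tie=tie,
        uniform_prior=uniform,
    )


def impute_sample(
    genotype: Genotype,
    table: AlleleTable,
    catalog: SiteCatalog,
    frequencies: Mapping[str, float],
    sample: str = "sample",
) -> ImputedPair:
    """Enumerate and resolve in one step; missing classifying sites no-call."""
    try:
        candidates = enumerate_pairs(genotype, table, catalog)
    except ValidationError:
        return ImputedPair(
            sample=sample, allele1=None, allele2=None,
            resolved=False, no_call_reason="missing_classifying_genotype",
        )
    return resolve_pair(candidates, frequencies, sample=sample)


@dataclass
class PopulationSummary:
    """Allele-group frequencies and heterozygosity categories."""

    n_individuals: int
    group_freq: Dict[str, float] = field(default_factory=dict)
    het_any: Dict[str, float] = field(default_factory=dict)
    het_with_rapid: Dict[str, float] = field(default_factory=dict)


def population_frequencies(
    pairs: pd.DataFrame,
    table: AlleleTable,
    rapid_groups: Sequence[str] = ("*4", "*12"),
) -> PopulationSummary:
    """Population statistics from a table of phased allele pairs.

    ``pairs`` needs columns ``allele1``/``allele2``.  Returns allele-group
    frequencies, the fraction of individuals heterozygous for each slow group
    (one allele in the group, the other outside it), and the fraction
    heterozygous with a rapid allele (*4 or *12) on the other haplotype —
    the APA-targetable configuration.
    """
    if len(pairs) == 0:
        raise ValidationError("cannot compute frequencies of an empty cohort")
    n = len(pairs)
    groups1 = pairs["allele1"].map(lambda a: table[a].group)
    groups2 = pairs["allele2"].map(lambda a: table[a].group)
    counts = groups1.value_counts().add(groups2.value_counts(), fill_value=0)
    group_freq = (counts / (2 * n)).to_dict()

    het_any: Dict[str, float] = {}
    het_with_rapid: Dict[str, float] = {}
    rapid = set(rapid_groups)
    for group in sorted(SLOW_GROUPS, key=allele_sort_key):
        in1, in2 = (groups1 == group), (groups2 == group)
        het = in1 ^ in2
        het_any[group] = float(het.sum()) / n
        with_rapid = (in1 & groups2.isin(rapid)) | (in2 & groups1.isin(rapid))
        het_with_rapid[group] = float(with_rapid.sum()) / n
    return PopulationSummary(
        n_individuals=n,
        group_freq=group_freq,
        het_any=het_any,
        het_with_rapid=het_with_rapid,
    )


def intermediate_targetable_fraction(
    het_with_rapid: Mapping[str, float]
) -> float:
    """Sum of per-slow-group heterozygous-with-rapid fractions: the fraction
    of a population with an APA-targetable intermediate diplotype."""
    return float(sum(het_with_rapid.values()))
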