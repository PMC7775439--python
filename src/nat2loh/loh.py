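"""Tumor-vs-normal loss-of-heterozygosity calling by allelic imbalance.

Only sites heterozygous in the matched normal are informative.  LOH is called
when the allelic balance of the tumor departs from the normal by at least a
threshold (default 0.10, matching both the SNP-array B-allele-frequency rule
and the WGS read-support rule) at one or more informative positions.  The
direction of the shift, combined with the phase of the normal diplotype,
identifies which star allele was lost.  Directional consistency across
informative sites is reported as a diagnostic, never enforced.

The B allele is the alternate (non-reference) base throughout.  No tumor
purity correction is applied to calls; under hemizygous one-copy loss at
purity p the expected tumor BAF of the lost allele is (1-p)/(2-p), so with a
threshold t the event is detectable iff p >= 2t/(0.5+t) (1/3 at t = 0.10).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .defs import AlleleTable
from .errors import ValidationError


@dataclass
class LohCall:
    """Allelic-imbalance verdict for one tumor/normal pair."""

    sample: str
    loh: Optional[bool]  # None = no-call
    n_informative: int = 0
    max_shift: float = 0.0
    # +1: B/alt fraction increased at the max-shift site; -1: decreased
    direction: int = 0
    consistent: bool = True
    lost_allele: Optional[str] = None
    mode: str = "baf"
    no_call_reason: Optional[str] = None
    # signed per-site shift (tumor minus normal alt fraction), informative only
    site_shifts: Dict[str, float] = field(default_factory=dict)

    @property
    def is_call(self) -> bool:
        return self.loh is not None


def _verdict(
    sample: str,
    shifts: Dict[str, float],
    threshold: float,
    mode: str,
) -> LohCall:
    if not 0 < threshold <= 0.5:
        raise ValidationError(f"threshold {threshold} outside (0, 0.5]")
    if not shifts:
        return LohCall(
            sample=sample, loh=None, mode=mode,
            no_call_reason="uninformative",
        )
    # inclusive threshold, guarded against binary-float representation noise
    # (0.50 - 0.40 must count as a 0.10 shift)
    eps = 1e-9
    rsid_max = max(shifts, key=lambda r: (abs(shifts[r]), r))
    max_shift = abs(shifts[rsid_max])
    loh = max_shift >= threshold - eps
    over = {r: s for r, s in shifts.items() if abs(s) >= threshold - eps}
    signs = {1 if s > 0 else -1 for s in over.values() if s != 0}
    consistent = len(signs) <= 1
    return LohCall(
        sample=sample,
        loh=loh,
        n_informative=len(shifts),
        max_shift=max_shift,
        direction=(1 if shifts[rsid_max] > 0 else -1) if loh else 0,
        consistent=consistent,
        mode=mode,
        site_shifts=shifts,
    )


def call_loh_baf(
    records: pd.DataFrame,
    threshold: float = 0.10,
    sample: str = "sample",
) -> LohCall:
    """Call LOH from a B-allele-frequency table.

    ``records`` needs columns rsid, normal_baf, tumor_baf, normal_gt (values
    ``het``/``hom-ref``/``hom-alt`` or 0/1/2 alt counts).  LOH iff
    |tumor_baf - normal_baf| >= threshold (inclusive) at >= 1 informative
    (normal-het) site; all sites hom in the normal yields a no-call, which is
    distinct from "no LOH".
    """
    shifts: Dict[str, float] = {}
    for _, row in records.iterrows():
        gt = str(row["normal_gt"]).strip()
        if gt not in ("het", "1", "0/1", "1/0"):
            continue
        shifts[str(row["rsid"])] = float(row["tumor_baf"]) - float(
            row["normal_baf"]
        )
    return _verdict(sample, shifts, threshold, mode="baf")


def call_loh_readcounts(
    records: pd.DataFrame,
    threshold: float = 0.10,
    sample: str = "sample",
    mode: str = "readcount",
) -> LohCall:
    """Call LOH from per-site (or per-allele-class) read counts.

    ``records`` needs columns marker, normal_ref, normal_alt, tumor_ref,
    tumor_alt.  Per informative position (both alleles seen in the normal)
    the alternate-support fraction is computed in normal and tumor; LOH iff
    the absolute fraction shift >= threshold at >= 1 position.  The same rule
    applies to long-read star-allele class counts (mode="longread").
    """
    shifts: Dict[str, float] = {}
    any_informative = False
    for _, row in records.iterrows():
        n_ref, n_alt = float(row["normal_ref"]), float(row["normal_alt"])
        t_ref, t_alt = float(row["tumor_ref"]), float(row["tumor_alt"])
        if n_ref <= 0 or n_alt <= 0:
            continue  # not heterozygous in the normal
        any_informative = True
        if t_ref + t_alt == 0:
            continue  # no tumor coverage at this site
        normal_frac = n_alt / (n_ref + n_alt)
        tumor_frac = t_alt / (t_ref + t_alt)
        shifts[str(row["marker"])] = tumor_frac - normal_frac
    if any_informative and not shifts:
        return LohCall(
            sample=sample, loh=None, mode=mode,
            no_call_reason="no_tumor_reads",
        )
    return _verdict(sample, shifts, threshold, mode=mode)


def phase_classifying_sites(
    pair: Tuple[str, str], table: AlleleTable
) -> Dict[str, str]:
    """Map each classifying site heterozygous within a diplotype to the allele
    carrying its alternate base."""
    p1, p2 = table[pair[0]].alt_pattern, table[pair[1]].alt_pattern
    phase = {}
    for rsid, _base in p1 ^ p2:  # sites where exactly one haplotype has alt
        phase[rsid] = pair[0] if any(r == rsid for r, _ in p1) else pair[1]
    return phase


def lost_allele(
    pair: Tuple[str, str],
    site_shifts: Mapping[str, float],
    table: AlleleTable,
    phase: Optional[Mapping[str, str]] = None,
) -> Tuple[Optional[str], bool]:
    """Identify the star allele on the decreased haplotype.

    ``site_shifts`` are signed tumor-minus-normal alternate-fraction shifts at
    informative markers; ``phase`` maps each marker to the allele carrying its
    alternate base (derived from the diplotype's classifying sites when not
    supplied).  Returns (allele or None, conflict flag): a homozygous normal
    is uninformative, and a tied vote between the two haplotypes yields
    (None, True).
    """
    if pair[0] == pair[1]:
        return None, False
    if phase is None:
        phase = phase_classifying_sites(pair, table)
    votes = {pair[0]: 0, pair[1]: 0}
    other = {pair[0]: pair[1], pair[1]: pair[0]}
    for rsid, shift in site_shifts.items():
        carrier = phase.get(rsid)
        if carrier is None or shift == 0:
            continue
        # alt fraction down means the alt-carrying haplotype was lost
        votes[carrier if shift < 0 else other[carrier]] += 1
    if votes[pair[0]] == votes[pair[1]]:
        conflict = votes[pair[0]] > 0
        return None, conflict
    return max(votes, key=lambda a: votes[a]), False
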