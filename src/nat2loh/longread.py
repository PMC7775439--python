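"""Long-read amplicon haplotyping: demultiplex, filter, align, call diplotypes.

The assay amplifies a 2096 bp product spanning the NAT2 coding exon with
primer pairs tagged by a sample-unique 15 bp barcode plus a 5 bp padding
sequence on both sides.  A star-allele diplotype is called per sample from
the reads that span all seven allele-classifying SNP positions: each spanning
read is classified into an allele by its pattern of alternate bases, classes
are ranked by read support, and a second allele is accepted only with
sufficient minor-class support.

Alignment is semi-global (the read is located as an infix of the amplicon
reference, free end-gaps on the reference) with unit edit costs via edlib;
reads are aligned in their better-scoring orientation, forward preferred on
ties.  An externally aligned SAM/BAM path is available through
:func:`observations_from_sam`.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import edlib

from .defs import AlleleTable, SiteCatalog, UnclassifiedPattern, classify_pattern
from .errors import AmbiguousBaseError, ValidationError

BARCODE_LEN = 15
PADDING_LEN = 5
TAG_LEN = BARCODE_LEN + PADDING_LEN

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class ReadRecord:
    """One sequencing read, possibly demultiplexed and trimmed."""

    read_id: str
    sequence: str
    qualities: Optional[str] = None
    sample: Optional[str] = None  # None = unassigned
    orientation: Optional[str] = None  # "forward" / "reverse"

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError(f"read {self.read_id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SiteObservation:
    """Per-read base call at one catalogued site ('-' = gap)."""

    read_id: str
    rsid: str
    observed_base: str
    in_alignment: bool


@dataclass
class DiploidCall:
    """Per-sample diploid star-allele call with read-support evidence."""

    sample: str
    allele1: Optional[str]
    allele2: Optional[str]
    support1: int = 0
    support2: int = 0
    spanning_total: int = 0
    unclassified_count: int = 0
    novel_flag: bool = False
    no_call_reason: Optional[str] = None
    notes: Tuple[str, ...] = ()

    @property
    def is_call(self) -> bool:
        return self.no_call_reason is None

    @property
    def homozygous(self) -> bool:
        return self.is_call and self.allele1 == self.allele2


def _check_barcode_table(table: Mapping[str, Tuple[str, str]]) -> None:
    seen: Dict[str, str] = {}
    for sample, (fwd, rev) in table.items():
        for bc in (fwd, rev):
            if len(bc) != BARCODE_LEN:
                raise ValidationError(
                    f"sample {sample}: barcode {bc} is not {BARCODE_LEN} bp"
                )
        for which, bc in (("fwd", fwd), ("rev", rev)):
            key = f"{which}:{bc}"
            if key in seen and seen[key] != sample:
                raise ValidationError(
                    f"duplicate {which} barcode {bc} shared by samples "
                    f"{seen[key]} and {sample}"
                )
            seen[key] = sample


def demultiplex(
    reads: Iterable[ReadRecord],
    barcode_table: Mapping[str, Tuple[str, str]],
    max_mismatch: int = 1,
    trim: bool = True,
) -> Tuple[List[ReadRecord], Dict[str, int]]:
    """Assign reads to samples by terminal barcodes.

    A read is assigned when a barcode matches within ``max_mismatch`` at a
    read end, searching both orientations.  Equal-distance matches to two
    samples leave the read unassigned, as does disagreement between the two
    ends when both carry a recognizable barcode.  Assigned reads are oriented
    forward and, if ``trim``, stripped of barcode+padding at both ends.
    Returns the reads plus an accounting dict.
    """
    _check_barcode_table(barcode_table)
    out: List[ReadRecord] = []
    acct = {"total": 0, "assigned": 0, "unassigned": 0}
    for read in reads:
        acct["total"] += 1
        assignment = _match_read(read.sequence, barcode_table, max_mismatch)
        if assignment is None:
            out.append(
                ReadRecord(read.read_id, read.sequence, read.qualities)
            )
            acct["unassigned"] += 1
            continue
        sample, orientation = assignment
        seq, qual = read.sequence, read.qualities
        if orientation == "reverse":
            seq = revcomp(seq)
            qual = qual[::-1] if qual else None
        if trim and len(seq) > 2 * TAG_LEN:
            seq = seq[TAG_LEN:-TAG_LEN]
            qual = qual[TAG_LEN:-TAG_LEN] if qual else None
        out.append(ReadRecord(read.read_id, seq, qual, sample, orientation))
        acct["assigned"] += 1
        acct[f"sample:{sample}"] = acct.get(f"sample:{sample}", 0) + 1
    return out, acct


def _match_read(
    seq: str,
    barcode_table: Mapping[str, Tuple[str, str]],
    max_mismatch: int,
) -> Optional[Tuple[str, str]]:
    if len(seq) < 2 * TAG_LEN:
        return None
    # In forward orientation the read starts with the forward barcode and ends
    # with the reverse complement of the reverse barcode.
    best: List[Tuple[int, str, str, str]] = []  # (dist, sample, orient, end)
    for orient in ("forward", "reverse"):
        o = seq if orient == "forward" else revcomp(seq)
        start, end = o[:BARCODE_LEN], o[-BARCODE_LEN:]
        for sample, (fwd, rev) in barcode_table.items():
            d1 = hamming(start, fwd)
            if d1 <= max_mismatch:
                best.append((d1, sample, orient, "start"))
            d2 = hamming(end, revcomp(rev))
            if d2 <= max_mismatch:
                best.append((d2, sample, orient, "end"))
    if not best:
        return None
    dmin = min(b[0] for b in best)
    winners = [b for b in best if b[0] == dmin]
    samples = {b[1] for b in winners}
    if len(samples) > 1:
        return None  # equal-distance tie between samples
    sample = samples.pop()
    orient = winners[0][2]
    # both-end agreement: if the other end also carries a recognizable barcode
    # it must point to the same sample
    other = {b[1] for b in best if b[2] == orient} | {sample}
    if len(other) > 1:
        return None
    return sample, orient


def filter_by_length(
    reads: Iterable[ReadRecord], lo: int = 1500, hi: int = 2300
) -> Tuple[List[ReadRecord], Dict[str, float]]:
    """Retain reads with lo <= length <= hi (inclusive); report accounting."""
    if lo > hi:
        raise ValidationError(f"invalid length window [{lo}, {hi}]")
    reads = list(reads)
    kept = [r for r in reads if lo <= len(r) <= hi]
    total = len(reads)
    acct = {
        "length_total": total,
        "length_pass": len(kept),
        "length_fail": total - len(kept),
        "length_pass_fraction": len(kept) / total if total else 0.0,
    }
    return kept, acct


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def align_and_genotype_read(
    read: ReadRecord,
    reference: str,
    catalog: SiteCatalog,
    min_identity: float = 0.8,
) -> Tuple[List[SiteObservation], bool, str]:
    """Align one (trimmed) read to the amplicon and call its base at each
    catalog site.

    Returns (observations, aligned, orientation).  Reads whose best alignment
    identity falls below ``min_identity`` are marked unaligned and yield no
    observations.
    """
    if not reference:
        raise ValidationError("empty reference")
    fwd = edlib.align(read.sequence, reference, mode="HW", task="path")
    rc = revcomp(read.sequence)
    rev = edlib.align(rc, reference, mode="HW", task="path")
    if rev["editDistance"] < fwd["editDistance"]:
        res, seq, orientation = rev, rc, "reverse"
    else:
        res, seq, orientation = fwd, read.sequence, "forward"

    ops = _CIGAR_RE.findall(res["cigar"] or "")
    columns = sum(int(n) for n, _ in ops)
    identity = 1.0 - res["editDistance"] / columns if columns else 0.0
    if identity < min_identity:
        return [], False, orientation

    start, _end = res["locations"][0]
    wanted = {s.amplicon_offset: s for s in catalog}
    calls: Dict[int, str] = {}
    tpos, qpos = start, 0
    for n, op in ops:
        n = int(n)
        if op in ("=", "X", "M"):
            for k in range(n):
                if tpos + k in wanted:
                    calls[tpos + k] = seq[qpos + k]
            tpos += n
            qpos += n
        elif op == "D":  # gap in read, consumes reference
            for k in range(n):
                if tpos + k in wanted:
                    calls[tpos + k] = "-"
            tpos += n
        elif op == "I":  # insertion in read
            qpos += n
    observations = [
        SiteObservation(
            read_id=read.read_id,
            rsid=site.rsid,
            observed_base=calls.get(offset, "-"),
            in_alignment=offset in calls,
        )
        for offset, site in sorted(wanted.items())
    ]
    return observations, True, orientation


ReadCall = Union[str, UnclassifiedPattern]


def classify_read(
    observations: Sequence[SiteObservation],
    catalog: SiteCatalog,
    table: AlleleTable,
) -> Optional[ReadCall]:
    """Turn one read's site observations into an allele call.

    Returns None when the read does not span all seven classifying sites with
    non-gap bases (such reads are excluded from the spanning set — deleted
    bases are never imputed); an :class:`UnclassifiedPattern` when the pattern
    matches no catalogued allele or carries a non-catalog base; otherwise the
    allele name.
    """
    by_rsid = {o.rsid: o for o in observations}
    observed = []
    for site in catalog.classifying:
        obs = by_rsid.get(site.rsid)
        if obs is None or not obs.in_alignment or obs.observed_base == "-":
            return None
        if obs.observed_base != site.ref:
            observed.append((site.rsid, obs.observed_base))
    try:
        return classify_pattern(observed, catalog, table)
    except AmbiguousBaseError:
        return UnclassifiedPattern(frozenset(observed))


def call_diploid(
    read_calls: Sequence[ReadCall],
    sample: str = "sample",
    min_spanning: int = 20,
    min_minor_fraction: float = 0.20,
    min_minor_reads: int = 5,
    novel_fraction: float = 0.20,
) -> DiploidCall:
    """Call a diploid star-allele pair from per-spanning-read allele calls.

    Allele classes are ranked by spanning-read support; the top class is
    allele 1 and the runner-up becomes allele 2 only if its fraction of
    spanning reads is >= ``min_minor_fraction`` and its count >=
    ``min_minor_reads``, otherwise the call is homozygous.  Fewer than
    ``min_spanning`` spanning reads, or zero classified reads, yield a
    no-call.  If the modal unclassified pattern exceeds ``novel_fraction`` of
    spanning reads the call is flagged as a novel-allele candidate.
    """
    spanning_total = len(read_calls)
    classified = Counter(c for c in read_calls if isinstance(c, str))
    unclassified = Counter(
        c.pattern for c in read_calls if isinstance(c, UnclassifiedPattern)
    )
    unclassified_count = sum(unclassified.values())
    novel = bool(
        unclassified
        and spanning_total
        and max(unclassified.values()) / spanning_total >= novel_fraction
    )

    base = dict(
        sample=sample,
        spanning_total=spanning_total,
        unclassified_count=unclassified_count,
        novel_flag=novel,
    )
    if spanning_total < min_spanning:
        return DiploidCall(
            allele1=None, allele2=None,
            no_call_reason="below_min_spanning", **base,
        )
    if not classified:
        return DiploidCall(
            allele1=None, allele2=None,
            no_call_reason="no_classifiable_reads", **base,
        )

    from .defs import allele_sort_key

    ranked = sorted(
        classified.items(), key=lambda kv: (-kv[1], allele_sort_key(kv[0]))
    )
    allele1, support1 = ranked[0]
    notes: List[str] = []
    if len(ranked) > 1:
        allele2, support2 = ranked[1]
        if (
            support2 / spanning_total >= min_minor_fraction
            and support2 >= min_minor_reads
        ):
            return DiploidCall(
                allele1=allele1, allele2=allele2,
                support1=support1, support2=support2, notes=tuple(notes),
                **base,
            )
    if spanning_total < 100:
        notes.append("second allele not excluded (low spanning coverage)")
    return DiploidCall(
        allele1=allele1, allele2=allele1,
        support1=support1, support2=0, notes=tuple(notes), **base,
    )


def run_longread_pipeline(
    reads: Iterable[ReadRecord],
    barcode_table: Mapping[str, Tuple[str, str]],
    reference: str,
    catalog: SiteCatalog,
    table: AlleleTable,
    *,
    max_mismatch: int = 1,
    lo: int = 1500,
    hi: int = 2300,
    min_identity: float = 0.8,
    min_spanning: int = 20,
    min_minor_fraction: float = 0.20,
    min_minor_reads: int = 5,
    novel_fraction: float = 0.20,
) -> Tuple[Dict[str, DiploidCall], Dict[str, float], Dict[str, List[ReadCall]]]:
    """Full pipeline: demultiplex -> length filter -> align -> diploid calls.

    Returns (per-sample calls, stage accounting, per-sample read calls).  The
    accounting conserves reads across stages: total = assigned + unassigned;
    assigned = length_pass + length_fail; length_pass = aligned + unaligned.
    """
    demuxed, acct = demultiplex(reads, barcode_table, max_mismatch=max_mismatch)
    assigned = [r for r in demuxed if r.sample is not None]
    kept, len_acct = filter_by_length(assigned, lo=lo, hi=hi)
    acct.update(len_acct)

    acct["aligned"] = 0
    acct["unaligned"] = 0
    per_sample: Dict[str, List[ReadCall]] = {s: [] for s in barcode_table}
    for read in kept:
        observations, aligned, _orient = align_and_genotype_read(
            read, reference, catalog, min_identity=min_identity
        )
        if not aligned:
            acct["unaligned"] += 1
            continue
        acct["aligned"] += 1
        call = classify_read(observations, catalog, table)
        if call is not None:
            per_sample[read.sample].append(call)

    calls = {
        sample: call_diploid(
            rc, sample=sample, min_spanning=min_spanning,
            min_minor_fraction=min_minor_fraction,
            min_minor_reads=min_minor_reads, novel_fraction=novel_fraction,
        )
        for sample, rc in per_sample.items()
    }
    return calls, acct, per_sample


def observations_from_sam(
    path: str,
    catalog: SiteCatalog,
    coords: str = "amplicon",
) -> Dict[str, List[SiteObservation]]:
    """Extract per-read site observations from externally aligned SAM/BAM.

    ``coords`` selects whether alignment reference positions are offsets in
    the packaged amplicon ("amplicon") or GRCh38 chr8 positions ("genomic").
    """
    import pysam

    if coords == "amplicon":
        wanted = {s.amplicon_offset: s for s in catalog}
    elif coords == "genomic":
        wanted = {s.pos - 1: s for s in catalog}
    else:
        raise ValidationError(f"unknown coords mode {coords!r}")

    out: Dict[str, List[SiteObservation]] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            calls: Dict[int, str] = {}
            for qpos, rpos in aln.get_aligned_pairs():
                if rpos in wanted:
                    calls[rpos] = (
                        aln.query_sequence[qpos] if qpos is not None else "-"
                    )
            out[aln.query_name] = [
                SiteObservation(
                    read_id=aln.query_name,
                    rsid=site.rsid,
                    observed_base=calls.get(rpos, "-"),
                    in_alignment=rpos in calls,
                )
                for rpos, site in sorted(wanted.items())
            ]
    return out
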