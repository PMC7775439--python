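"""Synthetic cohorts, long reads and BAF tables with known truth.

The generator emulates the statistical structure the pipeline assumes:
Hardy-Weinberg diplotype populations at stated allele frequencies; paired
tumor/normal cohorts with hemizygous one-copy loss at a stated LOH rate
(either haplotype lost with near-equal probability for heterozygotes) and a
single clonal tumor purity; CCS-like long reads drawn from the two haplotype
templates with uniform substitution and geometric-length indel errors,
barcode+padding tags and random orientation; and noisy B-allele-frequency
tables where the lost allele's tumor BAF follows the hemizygous-deletion
closed form (1-p)/(2-p) at purity p.

All randomness flows from a single integer seed through one
``numpy.random.default_rng`` stream per entry point, so outputs are
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .defs import (
    AlleleTable,
    SiteCatalog,
    load_allele_frequencies,
    load_definitions,
    packaged_amplicon_path,
)
from .errors import ValidationError
from .longread import PADDING_LEN, ReadRecord, revcomp

_BASES = np.array(list("ACGT"))


@dataclass
class SimParams:
    """Parameters of the synthetic study conditions.

    Defaults reproduce the published setting: allele frequencies from the
    packaged global table, LOH probability 0.243 (the overall locus LOH rate
    of the larger cohort), equal chance of losing either haplotype, tumor
    purity 0.6 (cohort samples required > 40% tumor cell content), 2096 bp
    amplicon reads with CCS-like 1% substitution / 0.5% indel errors and
    truncated-normal length jitter, and BAF noise sd 0.05 (half the 0.10
    imbalance threshold, which equals one normal-sample sd).
    """

    allele_freqs: Mapping[str, float] = field(
        default_factory=load_allele_frequencies
    )
    n: int = 100
    loh_prob: float = 0.243
    p_rapid_lost: float = 0.5
    purity: float = 0.6
    coverage: int = 100
    sub_rate: float = 0.01
    indel_rate: float = 0.005
    length_sd: float = 300.0
    length_bounds: Tuple[float, float] = (0.6, 1.1)
    baf_sd: float = 0.05
    aux_het_prob: float = 0.45
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.allele_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"allele frequencies sum to {total}, expected 1"
            )
        for name in ("loh_prob", "p_rapid_lost", "sub_rate", "indel_rate",
                     "aux_het_prob"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name}={value} outside [0, 1]")
        if not 0.0 < self.purity <= 1.0:
            raise ValidationError(f"purity={self.purity} outside (0, 1]")
        if self.n < 0 or self.coverage < 0:
            raise ValidationError("n and coverage must be >= 0")


def _rng(params: SimParams, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng((params.seed + salt) % (2**31))


def sim_population(params: SimParams) -> pd.DataFrame:
    """Hardy-Weinberg population: two independent allele draws per individual.

    Returns a phased diplotype table with columns sample, allele1, allele2.
    """
    params.validate()
    rng = _rng(params, salt=1)
    names = sorted(params.allele_freqs)
    probs = np.array([params.allele_freqs[a] for a in names], dtype=float)
    probs = probs / probs.sum()
    draws = rng.choice(len(names), size=(params.n, 2), p=probs)
    return pd.DataFrame(
        {
            "sample": [f"S{i:05d}" for i in range(params.n)],
            "allele1": [names[i] for i in draws[:, 0]],
            "allele2": [names[i] for i in draws[:, 1]],
        }
    )


def sim_tumor_normal(
    diplotypes: pd.DataFrame,
    params: SimParams,
    table: Optional[AlleleTable] = None,
) -> pd.DataFrame:
    """Assign LOH truth labels to a diplotype population.

    Each patient undergoes LOH with probability ``loh_prob``; for
    heterozygotes the rapid haplotype is the one lost with probability
    ``p_rapid_lost`` when the pair is rapid/slow (uniform otherwise and for
    homozygous-name pairs).  Adds columns loh (bool), lost_allele,
    retained_allele.
    """
    params.validate()
    if table is None:
        _, table = load_definitions()
    rng = _rng(params, salt=2)
    out = diplotypes.copy()
    n = len(out)
    loh = rng.random(n) < params.loh_prob
    lost: List[Optional[str]] = []
    retained: List[Optional[str]] = []
    for i, row in enumerate(out.itertuples(index=False)):
        if not loh[i]:
            lost.append(None)
            retained.append(None)
            continue
        a1, a2 = row.allele1, row.allele2
        p1, p2 = table[a1].phenotype, table[a2].phenotype
        if a1 == a2 or p1 == p2:
            which = a1 if rng.random() < 0.5 else a2
        else:
            rapid, slow = (a1, a2) if p1 == "rapid" else (a2, a1)
            which = rapid if rng.random() < params.p_rapid_lost else slow
        lost.append(which)
        retained.append(row.allele2 if which == row.allele1 else row.allele1)
    out["loh"] = loh
    out["lost_allele"] = lost
    out["retained_allele"] = retained
    return out


def haplotype_template(
    allele: str,
    reference: str,
    catalog: SiteCatalog,
    table: AlleleTable,
) -> str:
    """Amplicon sequence of one star allele (reference with its alternates)."""
    seq = list(reference)
    alt_sites = dict(table[allele].alt_pattern)
    for site in catalog:
        if site.rsid in alt_sites:
            seq[site.amplicon_offset] = alt_sites[site.rsid]
    return "".join(seq)


def _mutate(seq: str, rng: np.random.Generator, sub_rate: float,
            indel_rate: float) -> str:
    """Apply uniform substitutions and geometric-length indels."""
    out: List[str] = []
    i = 0
    n = len(seq)
    while i < n:
        r = rng.random()
        if r < indel_rate:
            length = int(rng.geometric(0.5))
            if rng.random() < 0.5:  # insertion before this base
                out.append("".join(rng.choice(_BASES, size=length)))
                out.append(seq[i])
                i += 1
            else:  # deletion
                i += length
        elif r < indel_rate + sub_rate:
            base = seq[i]
            choices = [b for b in "ACGT" if b != base]
            out.append(choices[int(rng.integers(3))])
            i += 1
        else:
            out.append(seq[i])
            i += 1
    return "".join(out)


def sim_long_reads(
    diplotype: Tuple[str, str],
    params: SimParams,
    barcode_pair: Tuple[str, str],
    sample: str = "sample",
    reference: Optional[str] = None,
    catalog: Optional[SiteCatalog] = None,
    table: Optional[AlleleTable] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[List[ReadRecord], List[str]]:
    """Simulate barcoded amplicon long reads for one diploid sample.

    Coverage is split binomially between the two haplotype templates; each
    read is a contiguous slice of its template with truncated-normal length
    jitter, substitution/indel errors, barcode+padding attached at both ends
    and random orientation.  Returns the reads plus the per-read truth
    haplotype names.
    """
    params.validate()
    if catalog is None or table is None:
        catalog, table = load_definitions()
    if reference is None:
        from .io import read_fasta

        reference = read_fasta(packaged_amplicon_path())
    if rng is None:
        rng = _rng(params, salt=3)
    fwd_bc, rev_bc = barcode_pair
    pad = "".join(rng.choice(_BASES, size=PADDING_LEN))
    templates = {
        name: haplotype_template(name, reference, catalog, table)
        for name in set(diplotype)
    }
    amp_len = len(reference)
    lo = int(params.length_bounds[0] * amp_len)
    hi = int(params.length_bounds[1] * amp_len)

    n_hap1 = int(rng.binomial(params.coverage, 0.5))
    origins = [diplotype[0]] * n_hap1 + [diplotype[1]] * (
        params.coverage - n_hap1
    )
    reads: List[ReadRecord] = []
    truth: List[str] = []
    for idx, origin in enumerate(origins):
        template = templates[origin]
        while True:  # truncated normal
            length = int(round(rng.normal(amp_len, params.length_sd)))
            if lo <= length <= hi:
                break
        insert_len = min(length, len(template))
        start = int(rng.integers(0, len(template) - insert_len + 1))
        insert = template[start:start + insert_len]
        insert = _mutate(insert, rng, params.sub_rate, params.indel_rate)
        seq = fwd_bc + pad + insert + revcomp(rev_bc + pad)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(
            ReadRecord(read_id=f"{sample}_r{idx:05d}", sequence=seq)
        )
        truth.append(origin)
    return reads, truth


def sim_baf_table(
    diplotype: Tuple[str, str],
    loh: bool,
    lost_allele: Optional[str],
    params: SimParams,
    catalog: Optional[SiteCatalog] = None,
    table: Optional[AlleleTable] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate a tumor/normal BAF table for one patient.

    Classifying sites heterozygous under the diplotype plus auxiliary markers
    (heterozygous with probability ``aux_het_prob``, alternate phased to a
    random haplotype) are informative.  Normal BAF is 0.5 + noise; under
    hemizygous loss at purity p the tumor BAF is (1-p)/(2-p) for alleles on
    the lost haplotype and the complement for the retained one, + noise,
    truncated to [0, 1].  The ``alt_on_lost`` column records phase truth.
    """
    params.validate()
    if catalog is None or table is None:
        catalog, table = load_definitions()
    if rng is None:
        rng = _rng(params, salt=4)
    if loh and lost_allele is None:
        raise ValidationError("loh=True requires a lost_allele")

    from .loh import phase_classifying_sites

    phase = (
        phase_classifying_sites(diplotype, table)
        if diplotype[0] != diplotype[1]
        else {}
    )
    hap_names = ("hap1", "hap2")
    lost_hap = None
    if loh:
        lost_hap = "hap1" if lost_allele == diplotype[0] else "hap2"

    p = params.purity
    lost_baf = (1.0 - p) / (2.0 - p)
    rows = []
    for site in catalog:
        if site.role == "classifying":
            carrier = phase.get(site.rsid)
            if carrier is None:
                continue  # homozygous within the diplotype: uninformative
            alt_hap = "hap1" if carrier == diplotype[0] else "hap2"
        else:
            if rng.random() >= params.aux_het_prob:
                continue
            alt_hap = hap_names[int(rng.integers(2))]
        normal = 0.5 + rng.normal(0.0, params.baf_sd)
        if loh:
            alt_lost = alt_hap == lost_hap
            tumor = (lost_baf if alt_lost else 1.0 - lost_baf) + rng.normal(
                0.0, params.baf_sd
            )
        else:
            alt_lost = False
            tumor = 0.5 + rng.normal(0.0, params.baf_sd)
        rows.append(
            dict(
                rsid=site.rsid,
                normal_baf=float(np.clip(normal, 0.0, 1.0)),
                tumor_baf=float(np.clip(tumor, 0.0, 1.0)),
                normal_gt="het",
                alt_on_lost=alt_lost,
            )
        )
    return pd.DataFrame(
        rows, columns=["rsid", "normal_baf", "tumor_baf", "normal_gt",
                       "alt_on_lost"]
    )


def default_barcodes(n: int, seed: int = 7) -> Dict[str, Tuple[str, str]]:
    """Deterministic sample->(fwd, rev) barcode table of 15-mers."""
    rng = np.random.default_rng(seed)
    table: Dict[str, Tuple[str, str]] = {}
    seen = set()
    i = 0
    while len(table) < n:
        fwd = "".join(rng.choice(_BASES, size=15))
        rev = "".join(rng.choice(_BASES, size=15))
        if fwd in seen or rev in seen or fwd == rev:
            continue
        seen.update((fwd, rev))
        table[f"S{i:03d}"] = (fwd, rev)
        i += 1
    return table
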