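"""NAT2 site catalog and star-allele definitions.

The NAT2 coding exon carries seven common allele-classifying SNPs
(CDS positions 191, 282, 341, 481, 590, 803, 857).  A star allele is a named
haplotype defined by the subset of those sites carrying the alternate base;
the reference haplotype *4 carries none.  Allele groups (*4, *5, ... *14)
collapse sub-alleles sharing the group-defining substitution and map onto the
acetylator phenotype: *4/*11/*12/*13 are rapid, *5/*6/*7/*14 are slow.  Among
the slow groups, *5, *6 and *14 encode enzymes that fail to detoxify the
cytotoxic NAT2 substrate APA (hence tumors retaining only such an allele are
drug-sensitive), while *7 retains near-wild-type activity against APA.

Definitions are data, not code: they ship as editable TSV files and are loaded
and validated by :func:`load_definitions`.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import FrozenSet, Iterable, Mapping, Optional, Tuple, Union

from .errors import (
    AmbiguousBaseError,
    DefinitionError,
    ParseError,
    UnknownAlleleError,
)

# 1-based inclusive GRCh38 interval of the packaged amplicon (2096 bp,
# containing the full protein-coding exon).  Genomic position of CDS base c is
# CDS_OFFSET + c.
AMPLICON_CHROM = "chr8"
AMPLICON_START = 18399625
AMPLICON_END = 18401720
CDS_OFFSET = 18400003

RAPID_GROUPS = frozenset({"*4", "*11", "*12", "*13"})
SLOW_GROUPS = frozenset({"*5", "*6", "*7", "*14"})
APA_SENSITIVE_GROUPS = frozenset({"*5", "*6", "*14"})

Pattern = FrozenSet[Tuple[str, str]]


@dataclass(frozen=True)
class SiteDef:
    """One catalogued NAT2 SNP site."""

    rsid: str
    chrom: str
    pos: int  # 1-based GRCh38
    cds_pos: int  # 1-based position in the coding sequence; 0 for non-coding
    ref: str
    alt: str
    role: str  # "classifying" or "auxiliary"

    @property
    def amplicon_offset(self) -> int:
        """0-based offset of this site within the packaged amplicon."""
        return self.pos - AMPLICON_START


@dataclass(frozen=True)
class AlleleDef:
    """One star allele: its defining alternate-base pattern and annotations."""

    name: str
    group: str
    phenotype: str  # "rapid" or "slow"
    apa_sensitive: bool
    alt_pattern: Pattern


@dataclass(frozen=True)
class UnclassifiedPattern:
    """A classifying-site pattern matching no catalogued allele (novel-allele
    candidate)."""

    pattern: Pattern

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        inner = ",".join(f"{r}:{b}" for r, b in sorted(self.pattern))
        return f"unclassified({inner})"


class SiteCatalog:
    """Validated, indexed collection of :class:`SiteDef`."""

    def __init__(self, sites: Iterable[SiteDef]):
        self.sites = tuple(sites)
        self.by_rsid = {s.rsid: s for s in self.sites}
        self.by_pos = {(s.chrom, s.pos): s for s in self.sites}
        self.classifying = tuple(
            sorted((s for s in self.sites if s.role == "classifying"),
                   key=lambda s: s.pos)
        )
        self._validate()

    def _validate(self) -> None:
        if len(self.by_rsid) != len(self.sites):
            raise DefinitionError("duplicate rsid in site table")
        if len(self.classifying) != 7:
            raise DefinitionError(
                f"expected 7 classifying sites, found {len(self.classifying)}"
            )
        for s in self.sites:
            if not (AMPLICON_START <= s.pos <= AMPLICON_END):
                raise DefinitionError(
                    f"{s.rsid}: position {s.pos} outside amplicon interval"
                )
            if s.cds_pos and s.pos != CDS_OFFSET + s.cds_pos:
                raise DefinitionError(
                    f"{s.rsid}: genomic pos {s.pos} and CDS pos {s.cds_pos} "
                    "are inconsistent"
                )
            if s.ref == s.alt or {s.ref, s.alt} - set("ACGT"):
                raise DefinitionError(f"{s.rsid}: invalid ref/alt {s.ref}/{s.alt}")

    def __iter__(self):
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)


class AlleleTable:
    """Validated, indexed collection of :class:`AlleleDef`."""

    def __init__(self, alleles: Iterable[AlleleDef], catalog: SiteCatalog):
        self.alleles = tuple(alleles)
        self.catalog = catalog
        self.by_name = {a.name: a for a in self.alleles}
        self.by_pattern = {}
        self._validate()

    def _validate(self) -> None:
        if len(self.by_name) != len(self.alleles):
            raise DefinitionError("duplicate allele name in allele table")
        classifying = {s.rsid for s in self.catalog.classifying}
        for a in self.alleles:
            for rsid, base in a.alt_pattern:
                site = self.catalog.by_rsid.get(rsid)
                if site is None:
                    raise DefinitionError(f"{a.name}: unknown site {rsid}")
                if rsid not in classifying:
                    raise DefinitionError(
                        f"{a.name}: {rsid} is not a classifying site"
                    )
                if base != site.alt:
                    raise DefinitionError(
                        f"{a.name}: {rsid} alternate base {base} does not match "
                        f"catalog ({site.alt})"
                    )
            if a.alt_pattern in self.by_pattern:
                other = self.by_pattern[a.alt_pattern].name
                raise DefinitionError(
                    f"alleles {other} and {a.name} share one pattern"
                )
            self.by_pattern[a.alt_pattern] = a
            if a.phenotype not in ("rapid", "slow"):
                raise DefinitionError(f"{a.name}: bad phenotype {a.phenotype}")

    def __iter__(self):
        return iter(self.alleles)

    def __len__(self) -> int:
        return len(self.alleles)

    def __getitem__(self, name: str) -> AlleleDef:
        try:
            return self.by_name[name]
        except KeyError:
            raise UnknownAlleleError(name) from None

    def names(self) -> Tuple[str, ...]:
        return tuple(a.name for a in self.alleles)


def _data_path(filename: str) -> Path:
    return Path(resources.files("nat2loh").joinpath("data", filename))


def packaged_amplicon_path() -> Path:
    """Path of the packaged (synthetic stand-in) amplicon reference FASTA."""
    return _data_path("nat2_amplicon.synthetic.fasta")


def _read_tsv(path: Path, columns) -> list:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(
            (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
        )
        header = next(reader, None)
        if header is None or [c.strip() for c in header] != list(columns):
            raise ParseError(f"{path}: expected columns {list(columns)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(columns):
                raise ParseError(
                    f"{path} line {lineno}: expected {len(columns)} fields, "
                    f"got {len(row)}"
                )
            rows.append((lineno, row))
    return rows


def parse_pattern(text: str, lineno: Optional[int] = None) -> Pattern:
    """Parse a semicolon-separated ``rsid:alt`` list into a pattern."""
    text = text.strip()
    if not text:
        return frozenset()
    pairs = []
    for item in text.split(";"):
        m = re.fullmatch(r"(rs\d+):([ACGT])", item.strip())
        if m is None:
            where = f" line {lineno}" if lineno else ""
            raise ParseError(f"bad pattern element {item!r}{where}")
        pairs.append((m.group(1), m.group(2)))
    return frozenset(pairs)


def load_definitions(
    sites_path: Union[str, Path, None] = None,
    alleles_path: Union[str, Path, None] = None,
) -> Tuple[SiteCatalog, AlleleTable]:
    """Load and validate the site catalog and allele table.

    With no arguments the packaged defaults are used.  Raises
    :class:`ParseError` for malformed rows (naming the line) and
    :class:`DefinitionError` for duplicate names/patterns or patterns
    referencing unknown sites.
    """
    sites_path = Path(sites_path) if sites_path else _data_path("nat2_sites.tsv")
    alleles_path = (
        Path(alleles_path) if alleles_path else _data_path("nat2_alleles.tsv")
    )

    sites = []
    cols = ("rsid", "chrom", "pos", "cds_pos", "ref", "alt", "role")
    for lineno, row in _read_tsv(sites_path, cols):
        try:
            sites.append(
                SiteDef(
                    rsid=row[0], chrom=row[1], pos=int(row[2]),
                    cds_pos=int(row[3]), ref=row[4].upper(), alt=row[5].upper(),
                    role=row[6],
                )
            )
        except ValueError as exc:
            raise ParseError(f"{sites_path} line {lineno}: {exc}") from None
    catalog = SiteCatalog(sites)

    alleles = []
    cols = ("name", "group", "phenotype", "apa_sensitive", "pattern")
    for lineno, row in _read_tsv(alleles_path, cols):
        flag = row[3].strip().lower()
        if flag not in ("true", "false"):
            raise ParseError(
                f"{alleles_path} line {lineno}: apa_sensitive must be "
                f"True/False, got {row[3]!r}"
            )
        alleles.append(
            AlleleDef(
                name=row[0], group=row[1], phenotype=row[2],
                apa_sensitive=(flag == "true"),
                alt_pattern=parse_pattern(row[4], lineno),
            )
        )
    return catalog, AlleleTable(alleles, catalog)


def load_allele_frequencies(
    path: Union[str, Path, None] = None
) -> Mapping[str, float]:
    """Per-allele population frequencies (default: packaged nominal table)."""
    path = Path(path) if path else _data_path("nat2_allele_freqs.tsv")
    freqs = {}
    for lineno, row in _read_tsv(path, ("allele", "frequency")):
        try:
            freqs[row[0]] = float(row[1])
        except ValueError:
            raise ParseError(f"{path} line {lineno}: bad frequency {row[1]!r}")
    return freqs


def classify_pattern(
    observed: Iterable[Tuple[str, str]],
    catalog: SiteCatalog,
    table: AlleleTable,
) -> Union[str, UnclassifiedPattern]:
    """Map an observed classifying-site alternate pattern to a star allele.

    ``observed`` lists the (rsid, base) pairs at which the haplotype departs
    from the reference; sites absent from it are taken as reference.  A
    pattern matching no catalogued allele is returned as
    :class:`UnclassifiedPattern` rather than raising, so novel-allele
    candidates stay visible downstream.
    """
    pattern = set()
    for rsid, base in observed:
        site = catalog.by_rsid.get(rsid)
        if site is None or site.role != "classifying":
            raise AmbiguousBaseError(f"{rsid} is not a classifying site")
        if base == site.ref:
            continue  # explicit reference observation
        if base != site.alt:
            raise AmbiguousBaseError(
                f"{rsid}: base {base} is neither ref ({site.ref}) nor alt "
                f"({site.alt})"
            )
        pattern.add((rsid, base))
    pattern = frozenset(pattern)
    allele = table.by_pattern.get(pattern)
    if allele is None:
        return UnclassifiedPattern(pattern)
    return allele.name


def phenotype_of_pair(a1: str, a2: str, table: AlleleTable) -> str:
    """Acetylator phenotype of a diplotype: rapid/intermediate/slow."""
    p1, p2 = table[a1].phenotype, table[a2].phenotype
    if p1 == p2:
        return p1
    return "intermediate"


_NAME_RE = re.compile(r"\*(\d+)([A-Z]*)")


def allele_sort_key(name: str) -> Tuple[int, str]:
    """Natural ordering of star-allele names (*4 < *5A < *5B < *12A)."""
    m = _NAME_RE.fullmatch(name)
    if m is None:
        return (10**6, name)
    return (int(m.group(1)), m.group(2))


def normalize_pair(a1: str, a2: str, table: AlleleTable) -> Tuple[str, str]:
    """Order a diplotype for display: rapid allele first, then natural order."""
    def key(name):
        return (0 if table[name].phenotype == "rapid" else 1,
                allele_sort_key(name))
    first, second = sorted((a1, a2), key=key)
    return first, second


def genotype_label(a1: str, a2: str, table: AlleleTable) -> str:
    first, second = normalize_pair(a1, a2, table)
    return f"{first}/{second}"
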