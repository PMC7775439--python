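"""Shared format readers and writers (FASTQ, FASTA, VCF, TSV).

All tabular outputs are TSV with a commented header block carrying the tool
version and the effective parameters of the run, so that any result file is
self-describing.  FASTQ quality encoding is Sanger/Phred+33 throughout.
"""

from __future__ import annotations

import gzip
import io as _io
import os
import tempfile
from pathlib import Path
from typing import Dict, Iterable, Iterator, Mapping, Optional, Tuple, Union

import pandas as pd
from Bio import SeqIO

from .errors import ParseError, ValidationError

PathLike = Union[str, Path]


def _open_text(path: PathLike, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: PathLike) -> Iterator[Tuple[str, str, Optional[str]]]:
    """Yield (read_id, sequence, quality-string) from FASTQ(.gz)."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            quals = rec.letter_annotations.get("phred_quality")
            qstr = (
                "".join(chr(min(q, 93) + 33) for q in quals) if quals else None
            )
            yield rec.id, str(rec.seq).upper(), qstr


def write_fastq(
    records: Iterable[Tuple[str, str, Optional[str]]], path: PathLike
) -> int:
    """Write (id, seq, qual) records as FASTQ(.gz); returns record count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for read_id, seq, qual in records:
            if qual is None:
                qual = "I" * len(seq)
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: PathLike) -> str:
    """Read the single sequence of a FASTA file (uppercased)."""
    with _open_text(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    if len(records) != 1:
        raise ParseError(f"{path}: expected exactly one FASTA record")
    return str(records[0].seq).upper()


def read_barcode_table(path: PathLike) -> Dict[str, Tuple[str, str]]:
    """Read a barcode TSV with columns sample, fwd_barcode, rev_barcode."""
    df = read_tsv(path)
    required = {"sample", "fwd_barcode", "rev_barcode"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    table = {}
    for _, row in df.iterrows():
        table[str(row["sample"])] = (
            str(row["fwd_barcode"]).upper(),
            str(row["rev_barcode"]).upper(),
        )
    return table


def read_tsv(path: PathLike) -> pd.DataFrame:
    """Read a TSV, skipping ``#`` comment lines."""
    return pd.read_csv(path, sep="\t", comment="#", dtype={"sample": str})


def write_tsv(
    df: pd.DataFrame,
    path: PathLike,
    params: Optional[Mapping[str, object]] = None,
) -> None:
    """Atomically write a TSV with a commented provenance header."""
    from . import __version__

    buf = _io.StringIO()
    buf.write(f"# nat2loh {__version__}\n")
    for key, value in (params or {}).items():
        buf.write(f"# {key}={value}\n")
    df.to_csv(buf, sep="\t", index=False)
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(buf.getvalue())
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


_GT_CODES = {"0/0": 0, "0|0": 0, "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
             "1/1": 2, "1|1": 2, "./.": None, ".|.": None, ".": None}


def read_genotype_table(path: PathLike) -> Dict[str, Dict[str, Optional[int]]]:
    """Read unphased genotypes from TSV: column ``sample`` plus one column per
    rsid with codes 0/0, 0/1, 1/1 or ./. — returns sample -> rsid -> alt count.
    """
    df = read_tsv(path)
    if "sample" not in df.columns:
        raise ParseError(f"{path}: missing column 'sample'")
    out: Dict[str, Dict[str, Optional[int]]] = {}
    for _, row in df.iterrows():
        calls = {}
        for col in df.columns:
            if col == "sample":
                continue
            raw = str(row[col]).strip()
            if raw == "nan":
                raw = "."
            if raw not in _GT_CODES:
                raise ParseError(
                    f"{path}: bad genotype {raw!r} in column {col}"
                )
            calls[col] = _GT_CODES[raw]
        out[str(row["sample"])] = calls
    return out


def read_genotype_vcf(path: PathLike, catalog) -> Dict[str, Dict[str, Optional[int]]]:
    """Read unphased genotypes at catalog sites from a VCF.

    Sites are matched by (chrom, pos, ref, alt) first, falling back to the ID
    column; multiallelic records at catalog positions are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    out = {s: {} for s in samples}
    positions = {(s.chrom, s.pos): s for s in catalog}
    chrom_alias = {s.chrom.lstrip("chr"): s.chrom for s in catalog}
    for variant in vcf:
        chrom = variant.CHROM if variant.CHROM.startswith("chr") else \
            chrom_alias.get(variant.CHROM, variant.CHROM)
        site = positions.get((chrom, variant.POS))
        if site is None:
            site = catalog.by_rsid.get(variant.ID)
        if site is None:
            continue
        if len(variant.ALT) > 1:
            raise ParseError(
                f"{path}: multiallelic record at {variant.CHROM}:{variant.POS}"
            )
        if variant.REF != site.ref or (variant.ALT and variant.ALT[0] != site.alt):
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        for sample, gt in zip(samples, variant.gt_types):
            out[sample][site.rsid] = {0: 0, 1: 1, 3: 2, 2: None}[int(gt)]
    return out


def read_baf_table(path: PathLike) -> pd.DataFrame:
    """Read a BAF TSV: rsid, normal_baf, tumor_baf, normal_gt."""
    df = read_tsv(path)
    required = {"rsid", "normal_baf", "tumor_baf", "normal_gt"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    for col in ("normal_baf", "tumor_baf"):
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise ValidationError(f"{path}: {col} outside [0, 1]")
    return df


def read_counts_table(path: PathLike) -> pd.DataFrame:
    """Read an allele-count TSV: marker, normal_ref, normal_alt, tumor_ref,
    tumor_alt (``marker`` is an rsid or a star-allele class label)."""
    df = read_tsv(path)
    required = {"marker", "normal_ref", "normal_alt", "tumor_ref", "tumor_alt"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    counts = df[sorted(required - {"marker"})]
    if (counts < 0).any().any():
        raise ValidationError(f"{path}: negative counts")
    return df
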