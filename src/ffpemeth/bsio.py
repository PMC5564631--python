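"""Readers/writers for the standard formats the pipeline touches, and the
shared coordinate/data model.

All internal coordinates are 0-based half-open (BED convention).  Conversion
to and from 1-based coordinates happens only at the SAM and VCF boundaries,
inside this module.

The SAM layer is backed by pysam; records are converted to the lightweight
:class:`AlignedRead` container so downstream code never handles pysam
objects directly.  Duplicate-flagged and secondary/supplementary reads are
*retained* by the reader and filtered by consumers, so each analysis states
its own filter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pysam
from pyfaidx import Fasta

__all__ = [
    "GenomicSite",
    "Region",
    "AlignedRead",
    "BsioError",
    "read_sam",
    "write_sam",
    "read_bed",
    "write_bed",
    "sort_regions",
    "merge_regions",
    "read_vcf_ct_candidates",
    "write_vcf_sites",
    "read_fasta",
    "write_fasta",
]

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER = 0x2
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_DUP = 0x400
FLAG_SUPPLEMENTARY = 0x800

#: optional SAM tag carrying the bisulfite strand ("OT" or "OB")
BS_STRAND_TAG = "XB"


class BsioError(ValueError):
    """Malformed input for one of the supported formats."""


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A strand-resolved single-base position (0-based, forward reference)."""

    chrom: str
    pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise BsioError(f"negative position: {self.pos}")
        if self.strand not in ("+", "-"):
            raise BsioError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True, order=True)
class Region:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise BsioError(
                f"invalid region {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and start < self.end and self.start < end


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = set("MIS=X")


@dataclass
class AlignedRead:
    """One SAM alignment record in internal (0-based) coordinates."""

    name: str
    flag: int
    chrom: str | None
    pos: int  # 0-based leftmost reference position
    mapq: int
    cigar: str | None
    seq: str
    qual: str  # Phred+33 string, same length as seq
    tags: dict = field(default_factory=dict)

    # -- flag helpers -----------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FLAG_UNMAPPED)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FLAG_SUPPLEMENTARY)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FLAG_DUP)

    @property
    def is_primary(self) -> bool:
        return not (self.is_secondary or self.is_supplementary)

    @property
    def mate(self) -> int | None:
        """Mate index (1 or 2) for paired reads, else None."""
        if not self.is_paired:
            return None
        if self.flag & FLAG_READ1 and not self.flag & FLAG_READ2:
            return 1
        if self.flag & FLAG_READ2 and not self.flag & FLAG_READ1:
            return 2
        return None

    @property
    def bs_strand_tag(self) -> str | None:
        v = self.tags.get(BS_STRAND_TAG)
        return v if v in ("OT", "OB") else None

    # -- alignment geometry ----------------------------------------------
    @property
    def query_length(self) -> int:
        return len(self.seq)

    def cigar_ops(self) -> list[tuple[int, str]]:
        if not self.cigar or self.cigar == "*":
            return []
        ops = _CIGAR_RE.findall(self.cigar)
        consumed = "".join(f"{n}{op}" for n, op in ops)
        if consumed != self.cigar:
            raise BsioError(f"unparseable CIGAR {self.cigar!r} for read {self.name}")
        return [(int(n), op) for n, op in ops]

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (query_pos, ref_pos) for every aligned (M/=/X) base."""
        q, r = 0, self.pos
        for n, op in self.cigar_ops():
            if op in ("M", "=", "X"):
                for i in range(n):
                    yield q + i, r + i
                q += n
                r += n
            elif op in ("I", "S"):
                q += n
            elif op in ("D", "N"):
                r += n
            # H and P consume nothing

    @property
    def reference_end(self) -> int:
        r = self.pos
        for n, op in self.cigar_ops():
            if op in ("M", "=", "X", "D", "N"):
                r += n
        return r

    def validate(self) -> None:
        ops = self.cigar_ops()
        if ops:
            qlen = sum(n for n, op in ops if op in _QUERY_OPS)
            if qlen != len(self.seq):
                raise BsioError(
                    f"read {self.name}: CIGAR consumes {qlen} query bases "
                    f"but SEQ has {len(self.seq)}"
                )
        if self.is_paired and self.mate is None:
            raise BsioError(f"read {self.name}: paired flags are contradictory")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def _from_pysam(rec: pysam.AlignedSegment) -> AlignedRead:
    qual = rec.query_qualities
    tags = dict(rec.get_tags())
    if rec.next_reference_name is not None:
        tags["__rnext"] = rec.next_reference_name
        tags["__pnext"] = rec.next_reference_start
        tags["__tlen"] = rec.template_length
    return AlignedRead(
        name=rec.query_name or "",
        flag=rec.flag,
        chrom=rec.reference_name,
        pos=rec.reference_start if rec.reference_start is not None else -1,
        mapq=rec.mapping_quality,
        cigar=rec.cigarstring,
        seq=rec.query_sequence or "",
        qual=pysam.qualities_to_qualitystring(qual) if qual is not None else "",
        tags=tags,
    )


def read_sam(path: str | Path) -> Iterator[AlignedRead]:
    """Stream AlignedRead records from a SAM file, in file order.

    SAM's 1-based POS arrives as pysam's 0-based ``reference_start``, which is
    kept as the internal convention.  A missing/empty header or a malformed
    record raises :class:`BsioError`; the record error names the approximate
    line number.
    """
    path = Path(path)
    try:
        af = pysam.AlignmentFile(str(path), "r", check_sq=False)
    except ValueError as e:
        raise BsioError(f"{path}: cannot parse SAM header: {e}") from e
    with af:
        header = af.header.to_dict()
        if not header.get("SQ"):
            raise BsioError(f"{path}: SAM header has no @SQ lines")
        n_header_lines = str(af.header).count("\n")
        i = 0
        it = af.fetch(until_eof=True)
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except Exception as e:  # pysam raises various parse errors
                raise BsioError(
                    f"{path}: malformed SAM record near line {n_header_lines + i + 1}: {e}"
                ) from e
            i += 1
            read = _from_pysam(rec)
            try:
                read.validate()
            except BsioError as e:
                raise BsioError(
                    f"{path}: line {n_header_lines + i}: {e}"
                ) from e
            yield read


def write_sam(
    path: str | Path,
    reads: Iterable[AlignedRead],
    references: Mapping[str, int],
) -> int:
    """Write reads as plain SAM with an @HD/@SQ header; returns record count."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": int(length)} for name, length in references.items()],
    }
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.name
            rec.flag = read.flag
            if read.chrom is not None:
                rec.reference_id = out.header.get_tid(read.chrom)
                rec.reference_start = read.pos
            rec.mapping_quality = read.mapq
            rec.cigarstring = read.cigar
            rec.query_sequence = read.seq
            if read.qual:
                rec.query_qualities = pysam.qualitystring_to_array(read.qual)
            # mate fields may be carried as "__"-prefixed metadata entries
            rnext = read.tags.get("__rnext")
            pnext = read.tags.get("__pnext")
            tlen = read.tags.get("__tlen")
            if rnext is not None:
                rec.next_reference_id = out.header.get_tid(rnext)
            if pnext is not None:
                rec.next_reference_start = pnext
            if tlen is not None:
                rec.template_length = tlen
            rec.set_tags(
                sorted((k, v) for k, v in read.tags.items() if not k.startswith("__"))
            )
            out.write(rec)
            n += 1
    return n


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[Region]:
    """Read a BED3+ file into Regions, preserving input order."""
    regions: list[Region] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BsioError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, s, e = parts[0], parts[1], parts[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise BsioError(
                    f"{path}:{lineno}: non-numeric coordinates {s!r}/{e!r}"
                ) from exc
            if start >= end:
                raise BsioError(f"{path}:{lineno}: start {start} >= end {end}")
            regions.append(Region(chrom, start, end))
    return regions


def write_bed(path: str | Path, regions: Iterable[Region]) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
            n += 1
    return n


def sort_regions(regions: Iterable[Region]) -> list[Region]:
    """Order regions by (chrom, start, end)."""
    return sorted(regions, key=lambda r: (r.chrom, r.start, r.end))


def merge_regions(regions: Iterable[Region], gap: int = 0) -> list[Region]:
    """Merge overlapping or book-ended (within ``gap`` bp) regions.

    Output is disjoint and sorted; with gap=0 only touching/overlapping
    intervals are joined.
    """
    out: list[Region] = []
    for r in sort_regions(regions):
        if out and r.chrom == out[-1].chrom and r.start <= out[-1].end + gap:
            if r.end > out[-1].end:
                out[-1] = Region(r.chrom, out[-1].start, r.end)
        else:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# VCF (sites only)
# ---------------------------------------------------------------------------

def read_vcf_ct_candidates(path: str | Path) -> list[GenomicSite]:
    """Read candidate C>T SNV sites (forward-strand convention) from a VCF.

    Only records with REF=C and an ALT allele of T are returned; the 1-based
    VCF POS is converted to the internal 0-based convention.  Sites are
    returned with '+' strand (the C is on the forward strand).
    """
    path = Path(path)
    sites: list[GenomicSite] = []
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as e:
        raise BsioError(f"{path}: cannot parse VCF: {e}") from e
    with vf:
        for rec in vf:
            if rec.ref is None or rec.alts is None:
                raise BsioError(
                    f"{path}: record at {rec.chrom}:{rec.pos} missing REF/ALT"
                )
            if rec.ref.upper() == "C" and any(a.upper() == "T" for a in rec.alts):
                sites.append(GenomicSite(rec.chrom, rec.pos - 1, "+"))
    return sites


def write_vcf_sites(
    path: str | Path,
    sites: Iterable[GenomicSite],
    references: Mapping[str, int],
    ref_allele: str = "C",
    alt_allele: str = "T",
) -> int:
    """Write a minimal sites-only VCF 4.2 (internal 0-based -> VCF 1-based)."""
    n = 0
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in references.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(sites):
            fh.write(f"{s.chrom}\t{s.pos + 1}\t.\t{ref_allele}\t{alt_allele}\t.\t.\t.\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into an in-memory dict of upper-case sequences."""
    with Fasta(str(path), rebuild=True) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
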