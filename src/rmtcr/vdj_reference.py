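"""Custom V(D)J segment reference construction, QC, and primer auditing.

Cellranger's IMGT-derived rhesus V(D)J reference lacks constant regions, so
a usable TCR reference has to be assembled by appending TRAC/TRBC alleles
(from IMGT and Ensembl CDS models) and then screened for premature stop
codons, frame-length problems, and other defects before alignment.  This
module parses and writes the pipe-delimited FASTA header dialect those
references use, runs the segment-level QC, and audits the nested enrichment
primers (which anneal to the constant regions) against the reference
sequences.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from importlib import resources
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import MeltingTemp, gc_fraction as _bio_gc_fraction

__all__ = [
    "Region",
    "Chain",
    "FlagCode",
    "SegmentRecord",
    "ReferenceSet",
    "QCFlag",
    "PrimerSite",
    "ENRICHMENT_PRIMERS",
    "parse_imgt_fasta",
    "load_bundled_cregions",
    "qc_segment",
    "filter_reference",
    "find_primer_sites",
    "nested_distance",
    "primer_properties",
    "write_reference_fasta",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DNA_ALPHABET = frozenset("ACGT")

#: Nested constant-region enrichment primers for the two 10x 5' chemistries.
#: Outer primers drive the first (target-enrichment) PCR, inner primers the
#: nested second round; all anneal antisense to the TRAC/TRBC sense strand.
ENRICHMENT_PRIMERS: dict[str, dict[str, str]] = {
    "v1": {
        "alpha_outer": "CCGGCCACTTTCAGGAGGAGG",
        "alpha_inner": "TGTTCTGTGATATGCACGTCAGAA",
        "beta_outer": "CCCCACTCACCTGCTCTACC",
        "beta_inner": "CTCAAACACAGCGACCTTGGGTGG",
    },
    "v2": {
        "alpha_outer": "CGGCCACTTTCAGGAGGAG",
        "alpha_inner": "TGTCTGTGATATGCACGTCAGA",
        "beta_outer": "CCCACTCACCTGCTCTACC",
        "beta_inner": "TCAAACACAGCGACCTTGGG",
    },
}


class Region(str, enum.Enum):
    V = "V-REGION"
    D = "D-REGION"
    J = "J-REGION"
    C = "C-REGION"
    L = "L-REGION"
    OTHER = "other"


class Chain(str, enum.Enum):
    TRA = "TRA"
    TRB = "TRB"
    OTHER = "other"


class FlagCode(str, enum.Enum):
    PREMATURE_STOP = "PREMATURE_STOP"
    FRAME_LENGTH = "FRAME_LENGTH"
    AMBIGUOUS_BASE = "AMBIGUOUS_BASE"
    TOO_SHORT = "TOO_SHORT"


@dataclass(frozen=True)
class QCFlag:
    code: FlagCode
    detail: str = ""
    position: int | None = None


@dataclass(frozen=True)
class SegmentRecord:
    """One V/D/J/C reference segment.

    ``region_raw``/``chain_raw`` keep the verbatim header strings so that
    writing the record back out is lossless even for region or chain values
    outside the known vocabulary.
    """

    record_id: int
    allele: str
    gene: str
    region: Region
    chain: Chain
    source_note: str = ""
    sequence: str = ""
    region_raw: str = ""
    chain_raw: str = ""
    extra_fields: tuple[str, ...] = ()
    partial: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.record_id}: empty sequence")
        if self.allele.count("*") != 1:
            raise ValueError(
                f"record {self.record_id}: allele {self.allele!r} must contain exactly one '*'"
            )
        bad = set(self.sequence) - (DNA_ALPHABET | {"N"})
        if bad:
            raise ValueError(
                f"record {self.record_id}: non-DNA characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReferenceSet:
    records: list[SegmentRecord] = field(default_factory=list)
    provenance: str = ""
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (header, reason)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate record_id in reference set")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, allele: str) -> SegmentRecord:
        for r in self.records:
            if r.allele == allele:
                return r
        raise KeyError(allele)


@dataclass(frozen=True)
class PrimerSite:
    """A primer/template match on a segment's sense strand.

    Coordinates are 0-based half-open on the sense strand.  ``strand`` is
    "sense" when the primer sequence itself matches the top strand and
    "antisense" when its reverse complement does (i.e. the primer acts as a
    reverse primer on this template).
    """

    segment_allele: str
    start: int
    end: int
    strand: str  # "sense" | "antisense"
    mismatches: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")
        if self.strand not in ("sense", "antisense"):
            raise ValueError(f"bad strand {self.strand!r}")


# ---------------------------------------------------------------------------
# FASTA dialect


def _parse_header(header: str) -> dict:
    """Split a pipe-delimited header like
    ``340|TRAC*01 IMGT|TRAC|C-REGION|TR|TRA|None|01``."""
    fields = header.split("|")
    if len(fields) < 8:
        raise ValueError(f"expected >= 8 '|'-separated fields, got {len(fields)}")
    allele_and_note = fields[1].split(" ", 1)
    allele = allele_and_note[0]
    note = allele_and_note[1] if len(allele_and_note) > 1 else ""
    region_raw = fields[3]
    chain_raw = fields[5]
    try:
        region = Region(region_raw)
    except ValueError:
        region = Region.OTHER
    try:
        chain = Chain(chain_raw)
    except ValueError:
        chain = Chain.OTHER
    return dict(
        record_id=int(fields[0]),
        allele=allele,
        source_note=note,
        gene=fields[2],
        region=region,
        region_raw=region_raw,
        chain=chain,
        chain_raw=chain_raw,
        extra_fields=tuple(fields[4:]),
    )


def parse_imgt_fasta(source: str | Path) -> ReferenceSet:
    """Parse a reference FASTA with pipe-delimited IMGT-dialect headers.

    ``source`` may be a path or the FASTA text itself.  Records with
    malformed headers or empty sequences are not fatal: they are collected
    in ``ReferenceSet.skipped`` with the reason.
    """
    if isinstance(source, Path) or (
        str(source)
        and "\n" not in str(source)
        and Path(str(source)).is_file()
    ):
        text = Path(source).read_text()
        provenance = str(source)
    else:
        text = str(source)
        provenance = "<string>"
    records: list[SegmentRecord] = []
    skipped: list[tuple[str, str]] = []
    for rec in SeqIO.parse(StringIO(text), "fasta"):
        header = rec.description
        seq = str(rec.seq).upper()
        try:
            fields = _parse_header(header)
            if not seq:
                raise ValueError("empty sequence")
            records.append(SegmentRecord(sequence=seq, **fields))
        except ValueError as exc:
            skipped.append((header, str(exc)))
    return ReferenceSet(records=records, provenance=provenance, skipped=skipped)


def load_bundled_cregions() -> ReferenceSet:
    """Load the bundled rhesus TRAC/TRBC constant-region alleles."""
    text = (
        resources.files("rmtcr.data").joinpath("rm_tcr_cregions.fasta").read_text()
    )
    ref = parse_imgt_fasta(text)
    ref.provenance = "bundled rm_tcr_cregions.fasta"
    return ref


def write_reference_fasta(ref: ReferenceSet, path: str | Path, width: int = 70) -> None:
    """Write ``ref`` so that ``parse_imgt_fasta`` round-trips losslessly."""
    out = []
    for r in ref.records:
        allele_field = f"{r.allele} {r.source_note}".rstrip()
        head = "|".join(
            [str(r.record_id), allele_field, r.gene, r.region_raw or r.region.value]
            + list(r.extra_fields)
        )
        out.append(SeqRecord(Seq(r.sequence), id=head, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(out)


# ---------------------------------------------------------------------------
# Segment QC


def qc_segment(
    record: SegmentRecord,
    frame_offset: int = 0,
    min_length: int = 30,
) -> list[QCFlag]:
    """Screen one segment for reference-breaking defects.

    Checks, reading codons from ``frame_offset``:

    * ``PREMATURE_STOP`` — an in-frame TAA/TAG/TGA anywhere except a
      terminal stop codon;
    * ``FRAME_LENGTH`` — a C-REGION whose length minus the frame offset is
      not a codon multiple (a frameshift symptom), unless the record is
      marked ``partial``;
    * ``AMBIGUOUS_BASE`` — any N (warning-class);
    * ``TOO_SHORT`` — sequence shorter than ``min_length``.

    Returns an empty list for a clean segment.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    seq = record.sequence
    flags: list[QCFlag] = []
    n = len(seq)

    codon_starts = range(frame_offset, n - 2, 3)
    in_frame_end = (n - frame_offset) % 3 == 0
    last_start = frame_offset + 3 * ((n - frame_offset) // 3 - 1) if in_frame_end else None
    for pos in codon_starts:
        codon = seq[pos : pos + 3]
        if codon in STOP_CODONS:
            if in_frame_end and pos == last_start:
                continue  # terminal stop is expected for a CDS-derived C region
            flags.append(
                QCFlag(
                    FlagCode.PREMATURE_STOP,
                    detail=f"stop codon {codon} at codon {(pos - frame_offset) // 3}",
                    position=pos,
                )
            )

    if (
        record.region is Region.C
        and not record.partial
        and (n - frame_offset) % 3 != 0
    ):
        flags.append(
            QCFlag(
                FlagCode.FRAME_LENGTH,
                detail=f"length {n} - frame {frame_offset} not divisible by 3",
            )
        )

    for pos, base in enumerate(seq):
        if base == "N":
            flags.append(QCFlag(FlagCode.AMBIGUOUS_BASE, detail="N", position=pos))

    if n < min_length:
        flags.append(QCFlag(FlagCode.TOO_SHORT, detail=f"length {n} < {min_length}"))

    return flags


DEFAULT_REMOVAL_CLASSES = frozenset({FlagCode.PREMATURE_STOP, FlagCode.FRAME_LENGTH})


def filter_reference(
    ref: ReferenceSet,
    frame_offsets: dict[str, int] | None = None,
    removal_classes: Iterable[FlagCode] = DEFAULT_REMOVAL_CLASSES,
    min_length: int = 30,
) -> tuple[ReferenceSet, list[tuple[SegmentRecord, list[QCFlag]]]]:
    """Partition a reference into clean records and removed ones.

    A record is removed iff it carries at least one flag from
    ``removal_classes`` (premature stops and frame-length defects by
    default; ambiguous bases only warn).  ``frame_offsets`` maps allele
    names to a reading-frame override; unlisted records are checked in
    frame 0.  Input order is preserved on both sides.
    """
    frame_offsets = frame_offsets or {}
    removal = frozenset(removal_classes)
    kept: list[SegmentRecord] = []
    removed: list[tuple[SegmentRecord, list[QCFlag]]] = []
    for rec in ref.records:
        flags = qc_segment(
            rec, frame_offset=frame_offsets.get(rec.allele, 0), min_length=min_length
        )
        if any(f.code in removal for f in flags):
            removed.append((rec, flags))
        else:
            kept.append(rec)
    return (
        ReferenceSet(records=kept, provenance=ref.provenance + " [filtered]"),
        removed,
    )


def qc_report_rows(
    ref: ReferenceSet, frame_offsets: dict[str, int] | None = None
) -> list[dict]:
    """Flat QC report (one row per flag) for TSV output."""
    frame_offsets = frame_offsets or {}
    rows = []
    for rec in ref.records:
        for f in qc_segment(rec, frame_offset=frame_offsets.get(rec.allele, 0)):
            rows.append(
                dict(
                    record_id=rec.record_id,
                    allele=rec.allele,
                    flag=f.code.value,
                    position="" if f.position is None else f.position,
                    detail=f.detail,
                )
            )
    return rows


# ---------------------------------------------------------------------------
# Primer audit


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _hamming_scan(template: str, probe: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All (start, mismatches) where probe aligns to template with at most
    max_mismatch substitutions. O(n*m); templates are short segments."""
    hits = []
    m = len(probe)
    for start in range(len(template) - m + 1):
        mm = 0
        window = template[start : start + m]
        for a, b in zip(window, probe):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            hits.append((start, mm))
    return hits


def find_primer_sites(
    primer: str, record: SegmentRecord, max_mismatch: int = 0
) -> list[PrimerSite]:
    """Locate every annealing site of ``primer`` on a segment.

    Both orientations are scanned: the primer matching the sense strand
    directly (strand="sense") and its reverse complement matching the sense
    strand (strand="antisense", i.e. the primer anneals as a reverse
    primer).  Mismatch model is Hamming distance only — no indels.  Sites
    are returned sorted by start.
    """
    primer = primer.upper()
    if len(primer) < 10:
        raise ValueError(f"primer length {len(primer)} < 10")
    bad = set(primer) - DNA_ALPHABET
    if bad:
        raise ValueError(f"primer contains non-ACGT characters: {sorted(bad)}")
    sites = [
        PrimerSite(record.allele, s, s + len(primer), "sense", mm)
        for s, mm in _hamming_scan(record.sequence, primer, max_mismatch)
    ] + [
        PrimerSite(record.allele, s, s + len(primer), "antisense", mm)
        for s, mm in _hamming_scan(record.sequence, _revcomp(primer), max_mismatch)
    ]
    return sorted(sites, key=lambda p: (p.start, p.strand))


def nested_distance(outer: PrimerSite, inner: PrimerSite) -> int:
    """Template distance between the 3' ends of a nested primer pair.

    For an antisense (reverse) primer the 3' end maps to the site's start
    coordinate on the sense strand; for a sense (forward) primer it maps to
    end - 1.  Positive when the outer primer's 3' end lies 3' of the
    inner's on the sense strand.
    """
    if outer.segment_allele != inner.segment_allele:
        raise ValueError(
            f"sites on different segments: {outer.segment_allele} vs {inner.segment_allele}"
        )
    if outer.strand != inner.strand:
        raise ValueError("sites on different strands")

    def three_prime(site: PrimerSite) -> int:
        return site.start if site.strand == "antisense" else site.end - 1

    return three_prime(outer) - three_prime(inner)


def primer_properties(primer: str) -> tuple[float, float]:
    """GC fraction and Wallace-rule melting temperature (2(A+T)+4(G+C) °C)."""
    primer = primer.upper()
    if not primer:
        raise ValueError("empty primer")
    bad = set(primer) - DNA_ALPHABET
    if bad:
        raise ValueError(f"primer contains non-ACGT characters: {sorted(bad)}")
    return _bio_gc_fraction(primer), float(MeltingTemp.Tm_Wallace(primer))
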