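"""Shared domain types, configuration, and coordinate conventions.

All internal coordinates are 0-based half-open (BAM convention); emitted
records are converted to 1-based (VCF convention) only at output time.

Variant representation follows the block-substitution style: an MNV or a
complex allele keeps non-empty ``ref`` and ``alt`` with no shared flanking
bases (``GG -> A``), while a pure insertion or deletion carries a single
left anchor base as VCF 4.2 requires (``TACA -> T``).
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

__all__ = [
    "Region",
    "ReadRecord",
    "Observation",
    "SiteEvidence",
    "ContingencyTable",
    "VariantCandidate",
    "CallerConfig",
    "TruthVariant",
    "ReferenceLookup",
    "RepresentationError",
    "MalformedReadError",
    "normalize_variant",
    "normalize_allele",
    "trim_allele",
]

#: CIGAR operations that consume query (read) bases.
QUERY_OPS = frozenset("MIS")
#: CIGAR operations that consume reference bases.
REF_OPS = frozenset("MDN")

_PYSAM_CIGAR = {0: "M", 1: "I", 2: "D", 3: "N", 4: "S", 5: "H", 7: "M", 8: "M"}


class RepresentationError(ValueError):
    """A variant's ref allele disagrees with the reference sequence."""


class MalformedReadError(ValueError):
    """A read's CIGAR is inconsistent with its sequence."""


@dataclass(frozen=True, order=True)
class Region:
    """Half-open genomic interval, 0-based."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"region start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"region end must exceed start: {self.contig}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        return self.contig == contig and start < self.end and end > self.start

    def contains(self, contig: str, pos: int) -> bool:
        return self.contig == contig and self.start <= pos < self.end


@dataclass
class ReadRecord:
    """One aligned read, decoupled from any BAM library record.

    ``cigar`` is a list of ``(op, length)`` with op in ``MIDNSH``; ``strand``
    is ``"+"`` or ``"-"``; ``sequence`` is stored in reference orientation as
    in SAM. ``mate_start`` is the mate's 0-based start or None for
    single-end data.
    """

    read_id: str
    contig: str
    start: int
    cigar: list[tuple[str, int]]
    sequence: str
    base_qualities: list[int]
    mapping_quality: int = 60
    strand: str = "+"
    is_duplicate: bool = False
    is_secondary: bool = False
    is_supplementary: bool = False
    is_unmapped: bool = False
    is_qcfail: bool = False
    mate_start: int | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.base_qualities):
            raise MalformedReadError(
                f"{self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.base_qualities)}"
            )
        qlen = sum(n for op, n in self.cigar if op in QUERY_OPS)
        if qlen != len(self.sequence):
            raise MalformedReadError(
                f"{self.read_id}: CIGAR consumes {qlen} query bases but "
                f"sequence has {len(self.sequence)}"
            )

    @property
    def reference_end(self) -> int:
        """One past the last reference base covered by this alignment."""
        return self.start + sum(n for op, n in self.cigar if op in REF_OPS)

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (query_index, reference_position) for every aligned (M) base."""
        q, r = 0, self.start
        for op, n in self.cigar:
            if op == "M":
                for i in range(n):
                    yield q + i, r + i
                q += n
                r += n
            elif op in "IS":
                q += n
            elif op in "DN":
                r += n
            # H consumes nothing

    @classmethod
    def from_pysam(cls, aln) -> "ReadRecord":
        """Build from a :class:`pysam.AlignedSegment`."""
        cigar = [(_PYSAM_CIGAR[op], n) for op, n in (aln.cigartuples or [])]
        quals = list(aln.query_qualities) if aln.query_qualities is not None else []
        return cls(
            read_id=aln.query_name,
            contig=aln.reference_name or "*",
            start=aln.reference_start,
            cigar=cigar,
            sequence=aln.query_sequence or "",
            base_qualities=quals,
            mapping_quality=aln.mapping_quality,
            strand="-" if aln.is_reverse else "+",
            is_duplicate=aln.is_duplicate,
            is_secondary=aln.is_secondary,
            is_supplementary=aln.is_supplementary,
            is_unmapped=aln.is_unmapped,
            is_qcfail=aln.is_qcfail,
            mate_start=aln.next_reference_start
            if aln.is_paired and aln.next_reference_start >= 0
            else None,
        )


#: One base (or gap/insertion token) seen by one read at one site.
#: ``allele`` is a single base for SNV evidence, or a token ``-<seq>`` /
#: ``+<seq>`` recorded at the anchor position of a deletion / insertion.
Observation = namedtuple(
    "Observation",
    ["read_id", "allele", "base_quality", "strand", "offset_in_read", "duplicate_group_id"],
)


@dataclass
class SiteEvidence:
    """Per-locus pileup column."""

    contig: str
    position: int
    observations: list[Observation] = field(default_factory=list)

    def depth(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 variant/reference counts: normal (n1, n0) vs tumor (c1, c0)."""

    n1: int
    n0: int
    c1: int
    c0: int

    def __post_init__(self) -> None:
        for name in ("n1", "n0", "c1", "c0"):
            if getattr(self, name) < 0:
                raise ValueError(f"contingency count {name} must be >= 0")

    @property
    def total(self) -> int:
        return self.n1 + self.n0 + self.c1 + self.c0


@dataclass
class VariantCandidate:
    """A candidate SNV/MNV/indel/complex event with its evidence summary.

    ``pos`` is 0-based internally; serialisation adds 1. Depth/support are
    duplicate-collapsed group counts. VAFs are percentages.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    vtype: str  # SNV | MNV | insertion | deletion | complex
    tumor_depth: int = 0
    tumor_support: int = 0
    normal_depth: int | None = None
    normal_support: int | None = None
    vaf_tumor: float | None = None
    vaf_normal: float | None = None
    lod_tumor: float | None = None
    lod_normal: float | None = None
    fet_p: float | None = None
    site_base_quality: int | None = None
    strand_support: tuple[int, int] = (0, 0)
    filters: set[str] = field(default_factory=set)
    origin: str = "unknown"
    supporting_reads: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.contig}:{self.pos}")

    @property
    def span_end(self) -> int:
        """End of the reference span (0-based, half-open)."""
        return self.pos + len(self.ref)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_pass(self) -> bool:
        return not self.filters


@dataclass(frozen=True)
class TruthVariant:
    """Ground-truth record emitted by the simulator for evaluation."""

    contig: str
    pos: int  # 0-based, same conventions as VariantCandidate
    ref: str
    alt: str
    vtype: str
    target_vaf: float  # percent

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass
class CallerConfig:
    """All tunable thresholds of the caller.

    Quality floors are Phred scores; ``min_vaf`` / VAFs are percentages;
    ``nf`` and ``germline_popaf_threshold`` are fractions, matching the
    conventions of the command-line flags they mirror.
    """

    min_base_quality: int = 13
    min_mapping_quality: int = 20
    min_support_reads: int = 2
    min_depth: int = 8
    min_vaf: float = 0.5  # percent; see docs/methods.md for the choice
    lod_threshold: float = 3.9
    fet_p_threshold: float = 0.05
    nf: float = 0.02  # max normal allele fraction
    normal_ratio: float = 0.2  # normal VAF must be < this x tumor VAF (or < nf)
    normal_lod_gate_ratio: float = 0.5
    snv_gap_merge_distance: int = 5
    gap_gap_merge_distance: int = 10
    max_mismatches_per_read: int = 3
    dup_support_fraction: float = 0.8
    germline_popaf_threshold: float = 0.01
    mnv_cooccurrence_fraction: float = 0.9
    count_overlapping_mates: bool = True
    drop_flagged_duplicates: bool = False
    strand_filter: bool = False
    end_distance_filter: int = 0  # 0 = off
    fet_mode: str = "one_sided"  # or "point"
    threads: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lod_threshold <= 0:
            raise ValueError("lod_threshold must be positive")
        if self.fet_mode not in ("one_sided", "point"):
            raise ValueError(f"unknown fet_mode {self.fet_mode!r}")
        for name in ("min_vaf", "fet_p_threshold", "nf", "normal_ratio",
                     "normal_lod_gate_ratio", "dup_support_fraction"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"{name} must be finite")


class ReferenceLookup:
    """Uniform sequence accessor over a dict of contig sequences or a FASTA.

    Accepts a ``Mapping[str, str]`` or any object with a pysam-style
    ``fetch(contig, start, end)`` (e.g. :class:`pysam.FastaFile`).
    """

    def __init__(self, source) -> None:
        self._source = source
        self._is_mapping = isinstance(source, Mapping)

    def fetch(self, contig: str, start: int, end: int) -> str:
        start = max(start, 0)
        if self._is_mapping:
            return self._source[contig][start:end].upper()
        return self._source.fetch(contig, start, end).upper()

    def base(self, contig: str, pos: int) -> str:
        return self.fetch(contig, pos, pos + 1)

    def length(self, contig: str) -> int:
        if self._is_mapping:
            return len(self._source[contig])
        return self._source.get_reference_length(contig)

    def contigs(self) -> list[str]:
        if self._is_mapping:
            return list(self._source)
        return list(self._source.references)


def trim_allele(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Strip bases shared by ref and alt (suffix first, then prefix).

    Returns the minimal ``(pos, ref, alt)``; one side may become empty, in
    which case the event is a pure insertion/deletion at ``pos``.
    """
    while ref and alt and ref[-1] == alt[-1] and not (len(ref) == 1 and len(alt) == 1):
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0] and not (len(ref) == 1 and len(alt) == 1):
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _left_align(reference: ReferenceLookup, contig: str, pos: int, seq: str) -> tuple[int, str]:
    # Shift a pure inserted/deleted sequence leftward while the preceding
    # reference base equals the event's last base (rotation invariance).
    while pos > 0:
        prev = reference.base(contig, pos - 1)
        if prev and prev == seq[-1]:
            seq = prev + seq[:-1]
            pos -= 1
        else:
            break
    return pos, seq


def normalize_allele(
    reference: ReferenceLookup, contig: str, pos: int, ref: str, alt: str
) -> tuple[int, str, str]:
    """Canonical representation of one allele (0-based ``pos``).

    SNVs and block substitutions are trimmed to their minimal non-empty
    form; pure insertions/deletions are left-aligned and returned with a
    single left anchor base.
    """
    pos, ref, alt = trim_allele(pos, ref, alt)
    if ref and alt:
        return pos, ref, alt
    if not ref and not alt:
        raise RepresentationError("empty allele after trimming")
    if not alt:  # deletion of `ref` at pos
        pos, seq = _left_align(reference, contig, pos, ref)
        if pos == 0:  # no base to anchor on the left; anchor on the right
            nxt = reference.base(contig, pos + len(seq))
            return pos, seq + nxt, nxt
        anchor = reference.base(contig, pos - 1)
        return pos - 1, anchor + seq, anchor
    # insertion of `alt` before pos
    pos, seq = _left_align(reference, contig, pos, alt)
    if pos == 0:
        nxt = reference.base(contig, 0)
        return pos, nxt, seq + nxt
    anchor = reference.base(contig, pos - 1)
    return pos - 1, anchor, anchor + seq


def normalize_variant(
    candidate: VariantCandidate, reference: ReferenceLookup
) -> VariantCandidate:
    """Return the candidate in canonical (left-aligned, minimal) form.

    Raises :class:`RepresentationError` when the stated ref allele does not
    match the reference sequence at ``pos``.
    """
    expected = reference.fetch(candidate.contig, candidate.pos, candidate.span_end)
    if candidate.ref and expected != candidate.ref.upper():
        raise RepresentationError(
            f"ref allele {candidate.ref!r} does not match reference "
            f"{expected!r} at {candidate.contig}:{candidate.pos + 1}"
        )
    pos, ref, alt = normalize_allele(
        reference, candidate.contig, candidate.pos, candidate.ref.upper(), candidate.alt.upper()
    )
    if (pos, ref, alt) == (candidate.pos, candidate.ref, candidate.alt):
        return candidate
    return replace(candidate, pos=pos, ref=ref, alt=alt)


def variant_type(ref: str, alt: str) -> str:
    """Classify a normalized allele by shape.

    Unequal-length alleles sharing a left anchor base are plain
    insertions/deletions; without a shared anchor the block mixes a gap
    with substituted bases and is complex (e.g. ``GG -> A``).
    """
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) == len(alt):
        return "MNV"
    if ref and alt and ref[0] == alt[0] and (len(ref) == 1 or len(alt) == 1):
        return "deletion" if len(ref) > len(alt) else "insertion"
    return "complex"
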