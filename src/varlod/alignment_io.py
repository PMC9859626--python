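"""BAM/BED input, read-level filtering, and pileup construction.

Read-level screens reject unmapped, QC-failed, secondary/supplementary
("multiple mapped") and low-mapping-quality reads, plus reads with no
overlap with the detection interval; flag-marked duplicates are dropped
only on request (by default they are kept and collapsed downstream by
signature). Base-quality screening happens per site while building the
pileup, not per read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from intervaltree import IntervalTree

from .datamodel import (
    CallerConfig,
    MalformedReadError,
    Observation,
    ReadRecord,
    Region,
    SiteEvidence,
)
from .quantify_filter import duplicate_group_map, group_duplicates

__all__ = [
    "ReadFilterResult",
    "RegionIndex",
    "load_regions",
    "passes_read_filters",
    "fetch_reads",
    "build_pileup",
]


@dataclass
class ReadFilterResult:
    read_id: str
    passed: bool
    reasons: list[str] = field(default_factory=list)


class RegionIndex:
    """Interval lookup over the merged target regions."""

    def __init__(self, regions: Iterable[Region]) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for r in regions:
            self._trees.setdefault(r.contig, IntervalTree()).addi(r.start, r.end)

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        tree = self._trees.get(contig)
        return bool(tree is not None and tree.overlaps(start, end))


def load_regions(bed_path: str) -> list[Region]:
    """Parse a 3+ column BED into merged, sorted, non-overlapping regions."""
    raw: list[Region] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{bed_path} line {lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as err:
                raise ValueError(
                    f"{bed_path} line {lineno}: non-integer coordinates"
                ) from err
            try:
                raw.append(Region(fields[0], start, end))
            except ValueError as err:
                raise ValueError(f"{bed_path} line {lineno}: {err}") from err
    if not raw:
        raise ValueError(f"{bed_path}: no regions found")
    raw.sort()
    merged = [raw[0]]
    for r in raw[1:]:
        last = merged[-1]
        if r.contig == last.contig and r.start <= last.end:
            merged[-1] = Region(last.contig, last.start, max(last.end, r.end))
        else:
            merged.append(r)
    return merged


def passes_read_filters(
    read: ReadRecord, region_index: RegionIndex, config: CallerConfig
) -> ReadFilterResult:
    """Pure predicate over one read; reasons name every failed screen."""
    reasons: list[str] = []
    if read.is_unmapped:
        reasons.append("unmapped")
    if read.is_qcfail:
        reasons.append("qcfail")
    if read.is_secondary or read.is_supplementary:
        reasons.append("secondary_or_supplementary")
    if read.mapping_quality < config.min_mapping_quality or read.mapping_quality == 0:
        reasons.append("low_mapq")
    if read.is_duplicate and config.drop_flagged_duplicates:
        reasons.append("flagged_duplicate")
    if not read.is_unmapped and not region_index.overlaps(
        read.contig, read.start, read.reference_end
    ):
        reasons.append("outside_interval")
    return ReadFilterResult(read_id=read.read_id, passed=not reasons, reasons=reasons)


def fetch_reads(
    bam, region: Region, region_index: RegionIndex, config: CallerConfig
) -> list[ReadRecord]:
    """Filter-passing ReadRecords overlapping ``region`` from an open BAM."""
    out = []
    for aln in bam.fetch(region.contig, region.start, region.end):
        read = ReadRecord.from_pysam(aln)
        if passes_read_filters(read, region_index, config).passed:
            out.append(read)
    return out


def build_pileup(
    reads: list[ReadRecord],
    region: Region,
    config: CallerConfig,
    dup_group_of: dict[str, int] | None = None,
) -> list[SiteEvidence]:
    """Per-site observation columns over ``region`` from passing reads.

    Observations below ``min_base_quality`` are excluded, as are bases
    within ``end_distance_filter`` positions of either read end when that
    optional screen is enabled (default off). Deletions and insertions
    additionally deposit a ``-<seq>`` / ``+<seq>`` token at their anchor
    position (the first deleted base / the base before the inserted
    sequence) so indel evidence is visible per column. Output is sorted
    by position and independent of input read order.
    """
    if dup_group_of is None:
        dup_group_of = duplicate_group_map(group_duplicates(reads))
    edge = config.end_distance_filter
    columns: dict[int, list[Observation]] = {}

    def add(pos: int, obs: Observation) -> None:
        if region.start <= pos < region.end:
            columns.setdefault(pos, []).append(obs)

    for read in sorted(reads, key=lambda r: (r.start, r.read_id)):
        gid = dup_group_of.get(read.read_id, -1)
        q, r = 0, read.start
        for op, n in read.cigar:
            if op == "M":
                for i in range(n):
                    if edge and not (edge <= q + i < len(read.sequence) - edge):
                        continue
                    bq = read.base_qualities[q + i]
                    if bq >= config.min_base_quality:
                        add(
                            r + i,
                            Observation(read.read_id, read.sequence[q + i], bq, read.strand, q + i, gid),
                        )
                q += n
                r += n
            elif op == "I":
                bq = max(read.base_qualities[q : q + n], default=0)
                add(
                    r,
                    Observation(read.read_id, "+" + read.sequence[q : q + n], bq, read.strand, q, gid),
                )
                q += n
            elif op == "D":
                flank = [read.base_qualities[q - 1]] if q > 0 else []
                if q < len(read.base_qualities):
                    flank.append(read.base_qualities[q])
                add(
                    r,
                    Observation(read.read_id, f"-{n}", max(flank, default=0), read.strand, q, gid),
                )
                r += n
            elif op == "S":
                q += n
            elif op == "N":
                r += n
            elif op == "H":
                pass
            else:
                raise MalformedReadError(f"{read.read_id}: unsupported CIGAR op {op!r}")
    return [
        SiteEvidence(contig=region.contig, position=pos, observations=obs)
        for pos, obs in sorted(columns.items())
    ]
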