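"""Insertion/deletion extraction from CIGARs and same-read event merging.

Events seen on one read are combined before any cross-read grouping:
a gap (deletion) or ins (insertion) pair on the same read merges when
fewer than ``gap_gap_merge_distance`` (10) reference bases separate their
inner edges, and an SNV on the same read is absorbed when its distance to
the nearest gap/ins edge is at most ``snv_gap_merge_distance`` (5). Events
on different reads are never merged. The merged allele's ref sequence is
read off the reference over the merged span, and its alt off the read's
component events, producing block records such as ``GG -> A``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .datamodel import (
    CallerConfig,
    ReadRecord,
    ReferenceLookup,
    VariantCandidate,
    variant_type,
)
from .quantify_filter import apply_variant_filters

log = logging.getLogger(__name__)

__all__ = [
    "IndelEvent",
    "ComplexEvent",
    "extract_indel_events",
    "read_snvs",
    "merge_same_read_events",
    "call_indel_candidates",
]

MAX_INDEL_EVENTS_PER_READ = 2  # reads with more gap/ins ops are alignment noise


@dataclass(frozen=True)
class IndelEvent:
    """One I/D CIGAR op on one read.

    For a deletion, ``anchor_pos`` is the first deleted reference base and
    ``sequence`` the deleted reference bases; for an insertion,
    ``anchor_pos`` is the reference base before which the insertion sits
    and ``sequence`` the inserted read bases.
    """

    read_id: str
    kind: str  # "gap" (deletion) | "ins" (insertion)
    anchor_pos: int
    length: int
    sequence: str

    @property
    def span(self) -> tuple[int, int]:
        """Reference span, half-open; zero-width for insertions."""
        if self.kind == "gap":
            return (self.anchor_pos, self.anchor_pos + self.length)
        return (self.anchor_pos, self.anchor_pos)


@dataclass
class ComplexEvent:
    """A merged per-read allele: one or more gaps/inss plus absorbed SNVs."""

    read_id: str
    span_start: int
    span_end: int
    ref_allele: str
    alt_allele: str
    component_events: list = field(default_factory=list)


def extract_indel_events(
    read: ReadRecord, reference: ReferenceLookup | None = None
) -> list[IndelEvent]:
    """Gap/ins events from the CIGAR; [] when the read has more than two.

    Reads carrying three or more separate indel ops are excluded from
    indel evidence entirely (returned list is empty), mirroring the
    retain-one-or-two rule.
    """
    events: list[IndelEvent] = []
    q, r = 0, read.start
    for op, n in read.cigar:
        if op == "M":
            q += n
            r += n
        elif op == "I":
            events.append(
                IndelEvent(read.read_id, "ins", r, n, read.sequence[q : q + n])
            )
            q += n
        elif op == "D":
            seq = (
                reference.fetch(read.contig, r, r + n) if reference is not None else "N" * n
            )
            events.append(IndelEvent(read.read_id, "gap", r, n, seq))
            r += n
        elif op in "SH":
            if op == "S":
                q += n
        elif op == "N":
            r += n
        else:
            raise ValueError(f"{read.read_id}: unsupported CIGAR op {op!r}")
    if len(events) > MAX_INDEL_EVENTS_PER_READ:
        return []
    return events


def read_snvs(
    read: ReadRecord, reference: ReferenceLookup, min_base_quality: int
) -> list[tuple[int, str, str, int]]:
    """Quality-passing mismatches on a read as (pos, ref, alt, qual)."""
    out = []
    ref_seq = reference.fetch(read.contig, read.start, read.reference_end)
    for q_idx, r_pos in read.aligned_pairs():
        if read.base_qualities[q_idx] < min_base_quality:
            continue
        rb = ref_seq[r_pos - read.start]
        ob = read.sequence[q_idx]
        if ob != rb and ob in "ACGT":
            out.append((r_pos, rb, ob, read.base_qualities[q_idx]))
    return out


def _gap_between(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Reference bases strictly between two half-open spans (0 if adjacent)."""
    if a[0] > b[0]:
        a, b = b, a
    return max(b[0] - a[1], 0)


def _snv_distance(pos: int, span: tuple[int, int]) -> int:
    """Coordinate gap from an SNV to the nearest span edge; adjacency = 1."""
    s, e = span
    if pos < s:
        return s - pos
    if pos >= e:
        return pos - e + 1
    return 0  # inside the span (between clustered gaps)


def merge_same_read_events(
    events: list[IndelEvent],
    snvs_on_read: list[tuple[int, str, str, int]],
    contig: str,
    reference: ReferenceLookup,
    config: CallerConfig,
) -> list[ComplexEvent]:
    """Combine one read's gaps/inss and nearby SNVs into allele records.

    Returns one :class:`ComplexEvent` per merged cluster (a lone clean
    indel yields a single-component record). Overlapping, contradictory
    events discard the whole read (empty result, warning logged).
    """
    if not events:
        return []
    read_id = events[0].read_id
    ordered = sorted(events, key=lambda e: e.span)
    for a, b in zip(ordered, ordered[1:]):
        if a.kind == "gap" and b.kind == "gap" and b.span[0] < a.span[1]:
            log.warning("%s: overlapping deletion events; read discarded", read_id)
            return []

    # 1) cluster gap/ins events: inner-edge separation < gap_gap_merge_distance
    clusters: list[list[IndelEvent]] = [[ordered[0]]]
    for ev in ordered[1:]:
        prev_span = (
            min(e.span[0] for e in clusters[-1]),
            max(e.span[1] for e in clusters[-1]),
        )
        if _gap_between(prev_span, ev.span) < config.gap_gap_merge_distance:
            clusters[-1].append(ev)
        else:
            clusters.append([ev])

    # 2) absorb SNVs within snv_gap_merge_distance of the nearest event edge
    attached: dict[int, list[tuple[int, str, str, int]]] = {i: [] for i in range(len(clusters))}
    for snv in snvs_on_read:
        pos = snv[0]
        best_i, best_d = None, None
        for i, cl in enumerate(clusters):
            d = min(_snv_distance(pos, ev.span) for ev in cl)
            if best_d is None or d < best_d:
                best_i, best_d = i, d
        if best_d is not None and best_d <= config.snv_gap_merge_distance:
            attached[best_i].append(snv)

    out: list[ComplexEvent] = []
    for i, cl in enumerate(clusters):
        snvs = sorted(attached[i])
        span_start = min(
            [e.span[0] for e in cl] + [s[0] for s in snvs]
        )
        span_end = max(
            [e.span[1] for e in cl] + [s[0] + 1 for s in snvs]
        )
        ref_allele = reference.fetch(contig, span_start, span_end)
        alt_allele = _build_alt(span_start, span_end, cl, snvs, ref_allele)
        out.append(
            ComplexEvent(
                read_id=read_id,
                span_start=span_start,
                span_end=span_end,
                ref_allele=ref_allele,
                alt_allele=alt_allele,
                component_events=list(cl) + snvs,
            )
        )
    return out


def _build_alt(
    span_start: int,
    span_end: int,
    events: list[IndelEvent],
    snvs: list[tuple[int, str, str, int]],
    ref_allele: str,
) -> str:
    deleted: set[int] = set()
    inserts: dict[int, str] = {}
    for ev in events:
        if ev.kind == "gap":
            deleted.update(range(ev.anchor_pos, ev.anchor_pos + ev.length))
        else:
            inserts[ev.anchor_pos] = inserts.get(ev.anchor_pos, "") + ev.sequence
    snv_alt = {pos: alt for pos, _ref, alt, _q in snvs}
    parts: list[str] = []
    for pos in range(span_start, span_end):
        if pos in inserts:
            parts.append(inserts[pos])
        if pos in deleted:
            continue
        parts.append(snv_alt.get(pos, ref_allele[pos - span_start]))
    if span_end in inserts:  # insertion flush with the right span edge
        parts.append(inserts[span_end])
    return "".join(parts)


def call_indel_candidates(
    allele_groups: dict[tuple, dict],
    config: CallerConfig,
) -> list[VariantCandidate]:
    """Turn per-allele evidence summaries into quantified candidates.

    ``allele_groups`` maps a normalized ``(contig, pos, ref, alt)`` key to
    a summary dict with duplicate-collapsed ``support`` and ``depth``
    (spanning reads only), ``strands``, ``quality`` and the supporting
    read-id set. Evidence floors are applied through the filter ledger;
    callers keep PASS records (tumor-only) or forward them to the paired
    cascade.
    """
    out: list[VariantCandidate] = []
    for (contig, pos, ref, alt), info in sorted(allele_groups.items()):
        if info["depth"] <= 0:
            continue
        cand = VariantCandidate(
            contig=contig,
            pos=pos,
            ref=ref,
            alt=alt,
            vtype=variant_type(ref, alt),
            tumor_support=info["support"],
            tumor_depth=info["depth"],
            vaf_tumor=100.0 * info["support"] / info["depth"],
            site_base_quality=info.get("quality"),
            strand_support=info.get("strands", (0, 0)),
            supporting_reads=frozenset(info.get("reads", ())),
        )
        out.append(apply_variant_filters(cand, config))
    return out
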