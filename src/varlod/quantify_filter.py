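"""Duplicate collapsing, VAF/site-quality computation, filter ledger, origin calls.

PCR amplification inflates raw read counts, so every depth and support
number the caller reports is a count of *duplicate groups*: reads sharing
an alignment signature (same fragment coordinates and strand) are presumed
copies of one molecule and contribute one unit. Within a group, the group
supports the variant only when more than ``dup_support_fraction`` (default
.8, strict) of its members carry the variant allele.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

from .datamodel import CallerConfig, ReadRecord, VariantCandidate

log = logging.getLogger(__name__)

__all__ = [
    "DuplicateGroup",
    "group_duplicates",
    "duplicate_group_map",
    "supporting_group_count",
    "collapse_counts",
    "compute_vaf",
    "site_base_quality",
    "apply_variant_filters",
    "classify_origin",
    "load_population_sites",
    "load_hotspot_sites",
]


@dataclass
class DuplicateGroup:
    group_id: int
    member_read_ids: list[str]
    signature: tuple
    strand: str

    def size(self) -> int:
        return len(self.member_read_ids)


def _signature(read: ReadRecord) -> tuple:
    # Both fragment ends when the mate's position is known (paired data),
    # otherwise the alignment's own span; strand always included so that
    # forward/reverse reads starting at one point stay distinct molecules.
    if read.mate_start is not None:
        return (read.contig, read.start, read.reference_end, read.strand, read.mate_start)
    return (read.contig, read.start, read.reference_end, read.strand, None)


def group_duplicates(reads: list[ReadRecord]) -> list[DuplicateGroup]:
    """Partition reads into presumed-PCR-duplicate groups by signature."""
    by_sig: dict[tuple, list[str]] = {}
    strands: dict[tuple, str] = {}
    for read in reads:
        sig = _signature(read)
        by_sig.setdefault(sig, []).append(read.read_id)
        strands[sig] = read.strand
    return [
        DuplicateGroup(group_id=i, member_read_ids=members, signature=sig, strand=strands[sig])
        for i, (sig, members) in enumerate(sorted(by_sig.items(), key=lambda kv: str(kv[0])))
    ]


def duplicate_group_map(groups: list[DuplicateGroup]) -> dict[str, int]:
    """read_id -> group_id lookup."""
    out: dict[str, int] = {}
    for g in groups:
        for rid in g.member_read_ids:
            out[rid] = g.group_id
    return out


def supporting_group_count(
    groups: list[DuplicateGroup],
    carrier_reads: set[str],
    informative_reads: set[str] | None = None,
    dup_support_fraction: float = 0.8,
) -> int:
    """Number of duplicate groups counting as variant-supporting reads.

    A group supports when the fraction of its informative members carrying
    the variant is strictly greater than ``dup_support_fraction``; an exact
    .8 does not support. ``informative_reads`` restricts the within-group
    denominator to reads that actually observed the site (defaults to all
    members).
    """
    n = 0
    for g in groups:
        members = [
            rid
            for rid in g.member_read_ids
            if informative_reads is None or rid in informative_reads
        ]
        if not members:
            continue
        frac = sum(rid in carrier_reads for rid in members) / len(members)
        if frac > dup_support_fraction:
            n += 1
    return n


def collapse_counts(
    groups: list[DuplicateGroup],
    carrier_reads: set[str],
    informative_reads: set[str],
    dup_support_fraction: float = 0.8,
) -> tuple[int, int, tuple[int, int]]:
    """Duplicate-collapsed (support, depth, supporting strand counts).

    Depth counts groups with at least one informative member; support as in
    :func:`supporting_group_count`; strand counts tally supporting groups
    by their signature strand.
    """
    depth = support = fwd = rev = 0
    for g in groups:
        members = [rid for rid in g.member_read_ids if rid in informative_reads]
        if not members:
            continue
        depth += 1
        frac = sum(rid in carrier_reads for rid in members) / len(members)
        if frac > dup_support_fraction:
            support += 1
            if g.strand == "+":
                fwd += 1
            else:
                rev += 1
    return support, depth, (fwd, rev)


def compute_vaf(support: int, depth: int) -> float:
    """VAF percent from duplicate-collapsed counts; errors on zero depth."""
    if depth <= 0:
        raise ValueError("VAF undefined: no eligible duplicate groups at site")
    return 100.0 * support / depth


def site_base_quality(supporting_qualities: list[int]) -> int:
    """Site quality = the maximum base quality among variant-supporting reads."""
    if not supporting_qualities:
        raise ValueError("no supporting observation at site")
    return max(supporting_qualities)


def apply_variant_filters(
    candidate: VariantCandidate, config: CallerConfig
) -> VariantCandidate:
    """Populate the candidate's filter-label set (empty set == PASS).

    Labels are a set: application order never matters. The strand screen is
    optional (off by default) and only fires when the variant is supported
    on a single strand.
    """
    f = candidate.filters
    if candidate.tumor_support < config.min_support_reads:
        f.add("low_support")
    if candidate.tumor_depth < config.min_depth:
        f.add("low_depth")
    if candidate.vaf_tumor is not None and candidate.vaf_tumor < config.min_vaf:
        f.add("low_vaf")
    if (
        candidate.site_base_quality is not None
        and candidate.site_base_quality < config.min_base_quality
    ):
        f.add("low_site_quality")
    if config.strand_filter:
        fwd, rev = candidate.strand_support
        if (fwd == 0 or rev == 0) and candidate.tumor_support > 0:
            f.add("strand_bias")
    return candidate


def classify_origin(
    candidate: VariantCandidate,
    population_sites: dict[tuple, float] | None,
    hotspot_sites: set[tuple] | None,
    config: CallerConfig,
) -> str:
    """Germline/somatic label for tumor-only calls.

    Germline when the population allele frequency at the normalized
    (contig, 1-based pos, ref, alt) is at or above the threshold (default
    1%); somatic when the site is in the hotspot set; ``both`` when both
    sources claim it; ``unknown`` otherwise.
    """
    key = (candidate.contig, candidate.pos + 1, candidate.ref, candidate.alt)
    germline = bool(
        population_sites
        and key in population_sites
        and population_sites[key] >= config.germline_popaf_threshold
    )
    somatic = bool(hotspot_sites and key in hotspot_sites)
    if germline and somatic:
        return "both"
    if germline:
        return "germline"
    if somatic:
        return "somatic"
    return "unknown"


def _iter_vcf_records(path: str):
    from cyvcf2 import VCF

    vcf = VCF(path)
    try:
        for rec in vcf:
            for alt in rec.ALT:
                yield rec.CHROM, rec.POS, rec.REF, alt, rec.INFO.get("AF")
    finally:
        vcf.close()


def load_population_sites(path: str) -> dict[tuple, float]:
    """Population allele frequencies from a VCF (AF INFO tag) or TSV.

    TSV columns: chrom, pos (1-based), ref, alt, af. Malformed rows are
    skipped with a warning.
    """
    sites: dict[tuple, float] = {}
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        for chrom, pos, ref, alt, af in _iter_vcf_records(path):
            if af is None:
                log.warning("population site %s:%s lacks AF tag; skipped", chrom, pos)
                continue
            sites[(chrom, pos, ref, alt)] = float(af)
        return sites
    with open(path) as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].startswith("#"):
                continue
            try:
                chrom, pos, ref, alt, af = row[0], int(row[1]), row[2], row[3], float(row[4])
            except (IndexError, ValueError):
                log.warning("%s line %d: malformed population record; skipped", path, i)
                continue
            sites[(chrom, pos, ref.upper(), alt.upper())] = af
    return sites


def load_hotspot_sites(path: str) -> set[tuple]:
    """Somatic hotspot sites from a VCF or a 4-column chrom/pos/ref/alt TSV."""
    sites: set[tuple] = set()
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        for chrom, pos, ref, alt, _ in _iter_vcf_records(path):
            sites.add((chrom, pos, ref, alt))
        return sites
    with open(path) as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].startswith("#"):
                continue
            try:
                sites.add((row[0], int(row[1]), row[2].upper(), row[3].upper()))
            except (IndexError, ValueError):
                log.warning("%s line %d: malformed hotspot record; skipped", path, i)
    return sites
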