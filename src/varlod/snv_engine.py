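"""Bayesian-classifier LOD scoring of SNVs and same-read MNV merging.

The mutation model compares, per site, the likelihood of the pileup under
a mutant allele present at fraction f against the reference-only model
(f = 0). With e_i = 10^(-q_i/10) the per-observation likelihoods are

    P(b_i | allele) = 1 - e_i        if b_i == allele
                      e_i / 3        otherwise

and the score is the log10 likelihood ratio

    LOD = sum_i log10[ f * P(b_i|alt) + (1 - f) * P(b_i|ref) ]
        - sum_i log10[ P(b_i|ref) ]

evaluated at f = f_hat, the duplicate-collapsed alt fraction. A candidate
survives when LOD >= lod_threshold (default 3.9).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .datamodel import CallerConfig, ReadRecord, ReferenceLookup, SiteEvidence, VariantCandidate
from .quantify_filter import supporting_group_count

__all__ = [
    "LodScore",
    "allele_likelihood",
    "tumor_lod",
    "discard_hypermutated_reads",
    "count_mismatches",
    "merge_adjacent_snvs",
]

_BASES = frozenset("ACGT")
_LOG10_FLOOR = 1e-300  # probabilities are clamped before taking logs


@dataclass(frozen=True)
class LodScore:
    allele: str
    f_hat: float
    lod: float

    @property
    def passes(self) -> bool:  # convenience; thresholding happens in callers
        return self.lod > 0


def allele_likelihood(observed_base: str, q: int, allele: str) -> float:
    """P(observed base | true allele) under the uniform-error model."""
    if observed_base not in _BASES or allele not in _BASES:
        raise ValueError(f"non-ACGT base in likelihood: {observed_base!r}/{allele!r}")
    if q < 0:
        raise ValueError("negative base quality")
    e = 10.0 ** (-q / 10.0)
    return 1.0 - e if observed_base == allele else e / 3.0


def tumor_lod(site: SiteEvidence, ref: str, alt: str, config: CallerConfig) -> LodScore:
    """Score one alternate allele at one site.

    f_hat comes from duplicate-collapsed counts (a group supports the alt
    when more than ``dup_support_fraction`` of its members show it); the
    likelihood product runs over all retained base observations at the
    site, in log space.
    """
    if ref == alt:
        raise ValueError("alt allele equals ref")
    obs = [o for o in site.observations if o.allele in _BASES]
    if not obs:
        raise ValueError(f"no base observations at {site.contig}:{site.position}")

    groups: dict[int, list[bool]] = {}
    for o in obs:
        groups.setdefault(o.duplicate_group_id, []).append(o.allele == alt)
    depth = len(groups)
    support = sum(
        1
        for flags in groups.values()
        if sum(flags) / len(flags) > config.dup_support_fraction
    )
    f_hat = support / depth

    if f_hat == 0.0:
        return LodScore(allele=alt, f_hat=0.0, lod=0.0)

    lod = 0.0
    for o in obs:
        p_ref = allele_likelihood(o.allele, o.base_quality, ref)
        p_alt = allele_likelihood(o.allele, o.base_quality, alt)
        num = f_hat * p_alt + (1.0 - f_hat) * p_ref
        lod += math.log10(max(num, _LOG10_FLOOR)) - math.log10(max(p_ref, _LOG10_FLOOR))
    return LodScore(allele=alt, f_hat=f_hat, lod=lod)


def count_mismatches(
    read: ReadRecord, reference: ReferenceLookup, min_base_quality: int
) -> int:
    """Mismatched aligned bases vs the reference, at quality-passing bases."""
    n = 0
    ref_seq = reference.fetch(read.contig, read.start, read.reference_end)
    seq, quals = read.sequence, read.base_qualities
    q = 0
    r = 0  # offset into ref_seq
    for op, ln in read.cigar:
        if op == "M":
            if seq[q : q + ln] != ref_seq[r : r + ln]:  # cheap block screen
                for i in range(ln):
                    if seq[q + i] != ref_seq[r + i] and quals[q + i] >= min_base_quality:
                        n += 1
            q += ln
            r += ln
        elif op in "IS":
            q += ln
        elif op in "DN":
            r += ln
    return n


def discard_hypermutated_reads(
    reads: list[ReadRecord], reference: ReferenceLookup, config: CallerConfig
) -> list[ReadRecord]:
    """Drop reads carrying >= max_mismatches_per_read mismatches (default 3).

    Dense mismatch clusters on one read are overwhelmingly alignment
    artifacts; such reads are removed from SNV evidence only (the indel
    path keeps them, since a genuine complex allele mismatches heavily).
    """
    return [
        r
        for r in reads
        if count_mismatches(r, reference, config.min_base_quality)
        < config.max_mismatches_per_read
    ]


def merge_adjacent_snvs(
    candidates: list[VariantCandidate],
    read_support_index: dict[tuple, frozenset],
    config: CallerConfig,
) -> list[VariantCandidate]:
    """Replace runs of adjacent, same-read SNVs with one MNV record.

    Two SNVs at consecutive positions co-occur when at least
    ``mnv_cooccurrence_fraction`` (default .9) of the reads supporting the
    lower-support member also support the other; co-occurring runs merge
    transitively into a block substitution (``CA -> AG``). Candidates that
    are not simple SNVs, or whose neighbors fail the co-occurrence test,
    pass through unchanged. Callers must pass only candidates that
    survived classification (a neighbor rejected in the normal sample is
    thereby never absorbed).
    """
    snvs = sorted(
        (c for c in candidates if c.vtype == "SNV"), key=lambda c: (c.contig, c.pos)
    )
    others = [c for c in candidates if c.vtype != "SNV"]

    def cooccur(a: VariantCandidate, b: VariantCandidate) -> bool:
        sa = read_support_index.get(a.key, a.supporting_reads)
        sb = read_support_index.get(b.key, b.supporting_reads)
        if not sa or not sb:
            return False
        smaller = min(len(sa), len(sb))
        return len(sa & sb) >= config.mnv_cooccurrence_fraction * smaller

    merged: list[VariantCandidate] = []
    run: list[VariantCandidate] = []

    def flush() -> None:
        if not run:
            return
        if len(run) == 1:
            merged.append(run[0])
        else:
            first = run[0]
            shared = frozenset.intersection(
                *[read_support_index.get(c.key, c.supporting_reads) for c in run]
            )
            merged.append(
                VariantCandidate(
                    contig=first.contig,
                    pos=first.pos,
                    ref="".join(c.ref for c in run),
                    alt="".join(c.alt for c in run),
                    vtype="MNV",
                    # conservative aggregation; quantification is redone by
                    # the pipeline against the merged haplotype
                    lod_tumor=min(
                        (c.lod_tumor for c in run if c.lod_tumor is not None),
                        default=None,
                    ),
                    fet_p=max(
                        (c.fet_p for c in run if c.fet_p is not None), default=None
                    ),
                    supporting_reads=shared,
                )
            )
        run.clear()

    for c in snvs:
        if run and c.contig == run[-1].contig and c.pos == run[-1].pos + 1 and cooccur(run[-1], c):
            run.append(c)
        else:
            flush()
            run.append(c)
    flush()
    return sorted(merged + others, key=lambda c: (c.contig, c.pos, c.alt))
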