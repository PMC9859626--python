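"""Synthetic aligned-read simulator with ground truth, plus evaluation metrics.

Reads are emitted pre-aligned with exact CIGARs (no aligner involved): a
variant haplotype is built by applying the truth variants to a random
reference contig, each fragment is drawn carrier/non-carrier with
probability equal to the variant's target VAF, and the fragment's CIGAR
is derived from the known reference/haplotype alignment chain. Base
errors are injected at a uniform rate, duplicates copy a fragment's
placement with independent errors, and everything is reproducible from
the seed.

The packaged external-quality-assessment truth list (94 variants, 2017
sample) ships as a plain TSV; its genomic coordinates are kept as contig
*labels* only — every variant is embedded in its own synthetic contig, so
no reference genome is needed to exercise the caller end to end.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pysam

from .datamodel import (
    ReadRecord,
    ReferenceLookup,
    TruthVariant,
    VariantCandidate,
    normalize_allele,
    trim_allele,
    variant_type,
)

__all__ = [
    "Haplotype",
    "SimSpec",
    "SimContig",
    "EvalResult",
    "simulate_contig",
    "simulate_reads",
    "write_outputs",
    "load_eqa_2017",
    "build_eqa_panel",
    "match_variants",
    "metrics",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass(frozen=True)
class Haplotype:
    """A set of truth variants carried together on one molecule."""

    variants: tuple[TruthVariant, ...]
    vaf: float  # percent of fragments drawn from this haplotype


@dataclass
class SimSpec:
    """Study conditions for one synthetic contig."""

    contig: str
    variants: list[TruthVariant]
    seed: int
    contig_length: int = 500
    depth: int = 2000
    read_length: int = 100
    base_quality: int = 30
    sequencing_error_rate: float = 1e-3
    duplicate_rate: float = 0.1
    strand_balance: float = 0.5
    #: fragment lengths are drawn uniformly in read_length * (1 +/- jitter);
    #: without this diversity, coordinate-signature duplicate collapsing
    #: would merge distinct molecules wholesale at high depth, which real
    #: libraries do not exhibit
    length_jitter: float = 0.2
    reference_seq: str | None = None
    haplotypes: list[Haplotype] | None = None  # default: one per variant

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        for v in self.variants:
            if not 0 <= v.target_vaf <= 100:
                raise ValueError(f"target VAF out of range: {v.target_vaf}")


@dataclass
class SimContig:
    contig: str
    reference_seq: str
    reads: list[ReadRecord]
    truth: list[TruthVariant]


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float | None = None
    sensitivity: float | None = None
    f1_harmonic: float | None = None
    f1_product: float | None = None


# ---------------------------------------------------------------------------
# haplotype alignment chain


def _trimmed(v: TruthVariant) -> tuple[int, str, str]:
    return trim_allele(v.pos, v.ref.upper(), v.alt.upper())


def _build_chain(ref_seq: str, variants: list[TruthVariant]):
    """Apply variants to the reference; return (alt_seq, segments).

    Segments tile the alignment between reference and haplotype:
    ``("M", ref_pos, alt_pos, length)`` for matches (also carrying the
    substituted bases of block substitutions), ``("D", ref_pos, alt_pos,
    length)`` and ``("I", ref_pos, alt_pos, length, seq)`` for gaps.
    """
    events = sorted(_trimmed(v) for v in variants)
    segs: list[tuple] = []
    parts: list[str] = []
    rc = ac = 0
    for pos, r, a in events:
        if pos < rc:
            raise ValueError("overlapping variants on one haplotype")
        if pos > rc:
            segs.append(("M", rc, ac, pos - rc))
            parts.append(ref_seq[rc:pos])
            ac += pos - rc
            rc = pos
        k = min(len(r), len(a))
        if k:
            segs.append(("M", rc, ac, k))
            parts.append(a[:k])
            rc += k
            ac += k
        if len(r) > k:
            segs.append(("D", rc, ac, len(r) - k))
            rc += len(r) - k
        elif len(a) > k:
            segs.append(("I", rc, ac, len(a) - k, a[k:]))
            parts.append(a[k:])
            ac += len(a) - k
    if rc < len(ref_seq):
        segs.append(("M", rc, ac, len(ref_seq) - rc))
        parts.append(ref_seq[rc:])
    return "".join(parts), segs


def _read_alignment(segs: list[tuple], s: int, e: int):
    """(reference_start, cigar) for a read covering haplotype bases [s, e)."""
    cigar: list[tuple[str, int]] = []
    ref_start = None
    for seg in segs:
        kind, rs, a0 = seg[0], seg[1], seg[2]
        if kind == "D":
            if cigar and a0 < e and a0 > s:
                cigar.append(("D", seg[3]))
            continue
        ln = seg[3]
        ov0, ov1 = max(s, a0), min(e, a0 + ln)
        if ov1 <= ov0:
            continue
        if kind == "M":
            if ref_start is None:
                ref_start = rs + (ov0 - a0)
            cigar.append(("M", ov1 - ov0))
        else:  # insertion
            cigar.append(("I", ov1 - ov0))
    # tidy: merge runs, clip edge gaps/insertions
    merged: list[tuple[str, int]] = []
    for op, n in cigar:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    while merged and merged[0][0] == "D":
        merged.pop(0)
    while merged and merged[-1][0] == "D":
        merged.pop()
    if merged and merged[0][0] == "I":
        merged[0] = ("S", merged[0][1])
    if merged and merged[-1][0] == "I":
        merged[-1] = ("S", merged[-1][1])
    if not any(op == "M" for op, _ in merged):
        return None
    return ref_start, merged


# ---------------------------------------------------------------------------
# simulation


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_contig(spec: SimSpec) -> SimContig:
    """Generate reference and aligned reads for one synthetic contig."""
    rng = np.random.default_rng(spec.seed)
    if spec.reference_seq is None:
        # self-generated contigs are forced to carry each ref allele
        seq = list(_random_sequence(rng, spec.contig_length))
        for v in spec.variants:
            if v.pos + len(v.ref) > len(seq):
                raise ValueError(f"variant at {v.pos} outside contig {spec.contig}")
            seq[v.pos : v.pos + len(v.ref)] = list(v.ref.upper())
        ref_seq = "".join(seq)
    else:
        ref_seq = spec.reference_seq
    for v in spec.variants:
        if v.pos + len(v.ref) > len(ref_seq):
            raise ValueError(f"variant at {v.pos} outside contig {spec.contig}")
        if v.ref and ref_seq[v.pos : v.pos + len(v.ref)] != v.ref.upper():
            raise ValueError(
                f"reference does not carry ref allele of {spec.contig}:{v.pos}"
            )

    haps = spec.haplotypes or [Haplotype((v,), v.target_vaf) for v in spec.variants]
    if sum(h.vaf for h in haps) > 100.0:
        raise ValueError("haplotype VAFs exceed 100%")
    chains = [_build_chain(ref_seq, list(h.variants)) for h in haps]

    rl = spec.read_length
    n_starts = len(ref_seq) - rl + 1
    n_frags = max(int(round(spec.depth * n_starts / rl)), 1)
    cum = np.cumsum([h.vaf / 100.0 for h in haps])
    len_lo = max(int(round(rl * (1 - spec.length_jitter))), 20)
    len_hi = max(int(round(rl * (1 + spec.length_jitter))), len_lo)

    reads: list[ReadRecord] = []
    u_hap = rng.random(n_frags)
    u_strand = rng.random(n_frags)
    u_dup = rng.random(n_frags)
    frag_lens = rng.integers(len_lo, len_hi + 1, size=n_frags)
    for i in range(n_frags):
        hap_idx = int(np.searchsorted(cum, u_hap[i], side="right"))
        if hap_idx >= len(haps):
            alt_seq, segs = ref_seq, [("M", 0, 0, len(ref_seq))]
        else:
            alt_seq, segs = chains[hap_idx]
        flen = int(frag_lens[i])
        max_start = len(alt_seq) - flen
        if max_start < 0:
            continue
        s = int(rng.integers(0, max_start + 1))
        aln = _read_alignment(segs, s, s + flen)
        if aln is None:
            continue
        ref_start, cigar = aln
        base_seq = alt_seq[s : s + flen]
        strand = "+" if u_strand[i] < spec.strand_balance else "-"
        n_copies = 2 if u_dup[i] < spec.duplicate_rate else 1
        for copy in range(n_copies):
            seq = _inject_errors(rng, base_seq, spec.sequencing_error_rate)
            rid = f"{spec.contig}.f{i}" + (".d" if copy else "")
            reads.append(
                ReadRecord(
                    read_id=rid,
                    contig=spec.contig,
                    start=ref_start,
                    cigar=list(cigar),
                    sequence=seq,
                    base_qualities=[spec.base_quality] * flen,
                    mapping_quality=60,
                    strand=strand,
                )
            )
    reads.sort(key=lambda r: (r.start, r.read_id))
    return SimContig(spec.contig, ref_seq, reads, list(spec.variants))


def _inject_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[int(rng.integers(0, 3))]
    return "".join(out)


# ---------------------------------------------------------------------------
# on-disk outputs

_CIGAR_NUM = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5}


@dataclass
class SimPaths:
    fasta: str
    bam: str
    bed: str
    truth: str


def write_outputs(contigs: list[SimContig], out_dir: str, prefix: str = "sim") -> SimPaths:
    """Write FASTA+fai, coordinate-sorted BAM+bai, BED and truth TSV."""
    os.makedirs(out_dir, exist_ok=True)
    fasta = os.path.join(out_dir, f"{prefix}.fa")
    bam = os.path.join(out_dir, f"{prefix}.bam")
    bed = os.path.join(out_dir, f"{prefix}.bed")
    truth = os.path.join(out_dir, f"{prefix}.truth.tsv")

    with open(fasta, "w") as fh:
        for c in contigs:
            fh.write(f">{c.contig}\n")
            for i in range(0, len(c.reference_seq), 60):
                fh.write(c.reference_seq[i : i + 60] + "\n")
    pysam.faidx(fasta)

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c.contig, "LN": len(c.reference_seq)} for c in contigs],
    }
    with pysam.AlignmentFile(bam, "wb", header=header) as out:
        for tid, c in enumerate(contigs):
            for r in c.reads:
                a = pysam.AlignedSegment()
                a.query_name = r.read_id
                a.query_sequence = r.sequence
                a.flag = 16 if r.strand == "-" else 0
                a.reference_id = tid
                a.reference_start = r.start
                a.mapping_quality = r.mapping_quality
                a.cigartuples = [(_CIGAR_NUM[op], n) for op, n in r.cigar]
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in r.base_qualities)
                )
                out.write(a)
    pysam.index(bam)

    with open(bed, "w") as fh:
        for c in contigs:
            fh.write(f"{c.contig}\t0\t{len(c.reference_seq)}\n")

    with open(truth, "w") as fh:
        fh.write("contig\tpos\tref\talt\tvtype\ttarget_vaf\n")
        for c in contigs:
            for v in c.truth:
                fh.write(
                    f"{v.contig}\t{v.pos + 1}\t{v.ref}\t{v.alt}\t{v.vtype}\t{v.target_vaf}\n"
                )
    return SimPaths(fasta=fasta, bam=bam, bed=bed, truth=truth)


def simulate_reads(spec: SimSpec, out_dir: str, prefix: str = "sim") -> SimPaths:
    """Single-contig convenience wrapper: simulate and write all outputs."""
    return write_outputs([simulate_contig(spec)], out_dir, prefix=prefix)


def read_truth_tsv(path: str) -> list[TruthVariant]:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                TruthVariant(
                    contig=row["contig"],
                    pos=int(row["pos"]) - 1,
                    ref=row["ref"],
                    alt=row["alt"],
                    vtype=row["vtype"],
                    target_vaf=float(row["target_vaf"]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# packaged EQA 2017 panel


def load_eqa_2017() -> list[dict]:
    """Rows of the packaged 2017 proficiency-panel variant list."""
    rows = []
    with resources.files("varlod.data").joinpath("eqa2017_variants.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(row)
    return rows


def build_eqa_panel(
    seed: int,
    depth: int = 2000,
    read_length: int = 100,
    base_quality: int = 30,
    contig_length: int = 500,
    offset: int = 240,
    duplicate_rate: float = 0.1,
    sequencing_error_rate: float = 1e-3,
) -> list[SimSpec]:
    """One SimSpec per panel variant, each on its own synthetic contig.

    The printed genomic coordinate becomes part of the contig label; the
    variant sits at a fixed offset inside a random contig whose sequence
    is forced to carry the ref allele there. Per-contig seeds derive
    deterministically from the master seed.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for row in load_eqa_2017():
        contig = f"{row['chrom']}_{row['start']}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        seq = list(_random_sequence(sub_rng, contig_length))
        vtype = row["vtype"].lower()
        ref_field = row["ref"].strip()
        alt_field = row["alt"].strip()
        if vtype == "insertion":
            # anchored form: anchor base + inserted sequence
            anchor = seq[offset - 1]
            variant = TruthVariant(
                contig, offset - 1, anchor, anchor + alt_field, "insertion",
                float(row["freq"]),
            )
        elif vtype == "deletion":
            seq[offset : offset + len(ref_field)] = list(ref_field)
            anchor = seq[offset - 1]
            variant = TruthVariant(
                contig, offset - 1, anchor + ref_field, anchor, "deletion",
                float(row["freq"]),
            )
        else:  # SNV / complex block
            seq[offset : offset + len(ref_field)] = list(ref_field)
            variant = TruthVariant(
                contig, offset, ref_field, alt_field,
                "SNV" if vtype == "snv" else "complex", float(row["freq"]),
            )
        specs.append(
            SimSpec(
                contig=contig,
                variants=[variant],
                seed=sub_seed,
                contig_length=contig_length,
                depth=depth,
                read_length=read_length,
                base_quality=base_quality,
                duplicate_rate=duplicate_rate,
                sequencing_error_rate=sequencing_error_rate,
                reference_seq="".join(seq),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# evaluation


def match_variants(
    calls: list[VariantCandidate],
    truth: list[TruthVariant],
    reference: ReferenceLookup,
) -> EvalResult:
    """Exact (contig, pos, ref, alt) matching after normalizing both sides."""

    def norm(contig, pos, ref, alt):
        return (contig,) + normalize_allele(reference, contig, pos, ref.upper(), alt.upper())

    call_keys = {norm(c.contig, c.pos, c.ref, c.alt) for c in calls}
    truth_keys = {norm(t.contig, t.pos, t.ref, t.alt) for t in truth}
    tp = len(call_keys & truth_keys)
    return metrics(tp=tp, fp=len(call_keys - truth_keys), fn=len(truth_keys - call_keys))


def metrics(tp: int, fp: int, fn: int) -> EvalResult:
    """Precision/sensitivity plus both F1 conventions.

    ``f1_harmonic`` is the usual 2PS/(P+S); ``f1_product`` is the plain
    product P*S. Both are reported side by side and labelled explicitly —
    comparisons in the literature use either, and they differ except at
    P = S = 1. Undefined metrics (empty call or truth set) stay None.
    """
    if tp < 0 or fp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    res = EvalResult(tp=tp, fp=fp, fn=fn)
    if tp + fp > 0:
        res.precision = tp / (tp + fp)
    if tp + fn > 0:
        res.sensitivity = tp / (tp + fn)
    if res.precision is not None and res.sensitivity is not None:
        p, s = res.precision, res.sensitivity
        res.f1_harmonic = 2 * p * s / (p + s) if (p + s) > 0 else 0.0
        res.f1_product = p * s
    return res
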