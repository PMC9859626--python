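"""Shared fixtures: synthetic reads, references, and end-to-end scenarios."""

from __future__ import annotations

import numpy as np
import pytest

from varlod.datamodel import (
    CallerConfig,
    ReadRecord,
    ReferenceLookup,
    TruthVariant,
)
from varlod.sim_eval import Haplotype, SimContig, SimSpec, simulate_contig, write_outputs


def make_read(
    contig="chr1",
    start=100,
    seq="ACGT",
    cigar=None,
    qual=30,
    read_id="r1",
    strand="+",
    mapq=60,
    mate_start=None,
    **flags,
):
    """Compact ReadRecord constructor for unit tests."""
    if cigar is None:
        cigar = [("M", len(seq))]
    quals = [qual] * len(seq) if isinstance(qual, int) else list(qual)
    return ReadRecord(
        read_id=read_id,
        contig=contig,
        start=start,
        cigar=cigar,
        sequence=seq,
        base_qualities=quals,
        mapping_quality=mapq,
        strand=strand,
        mate_start=mate_start,
        **flags,
    )


def random_reference(seed: int, length: int = 500, contig: str = "chr1") -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def embedded_reference(seed: int, offset: int, ref_allele: str, length: int = 500) -> str:
    """Random sequence forced to carry ``ref_allele`` at ``offset``."""
    seq = list(random_reference(seed, length))
    seq[offset : offset + len(ref_allele)] = list(ref_allele)
    return "".join(seq)


@pytest.fixture
def config():
    return CallerConfig()


@pytest.fixture
def refmap():
    seq = embedded_reference(11, 240, "G")
    return ReferenceLookup({"chr1": seq})


def run_sim_pipeline(
    tmp_path,
    tumor_contigs: list[SimContig],
    normal_contigs: list[SimContig] | None = None,
    config: CallerConfig | None = None,
    **pipeline_kw,
):
    """Write simulated contigs to disk and run the full caller on them."""
    from varlod.output_cli import run_pipeline

    config = config or CallerConfig()
    paths = write_outputs(tumor_contigs, str(tmp_path), prefix="tumor")
    normal_bam = None
    if normal_contigs is not None:
        npaths = write_outputs(normal_contigs, str(tmp_path), prefix="normal")
        normal_bam = npaths.bam
    out_vcf = str(tmp_path / "calls.vcf")
    vcf, manifest = run_pipeline(
        config, paths.bam, normal_bam, paths.bed, paths.fasta, out_vcf, **pipeline_kw
    )
    return paths, vcf, manifest


def read_vcf_calls(vcf_path):
    """Re-parse an emitted VCF through an independent parser."""
    from cyvcf2 import VCF

    from varlod.datamodel import VariantCandidate

    calls = []
    for rec in VCF(vcf_path):
        for alt in rec.ALT:
            calls.append(
                VariantCandidate(
                    contig=rec.CHROM, pos=rec.POS - 1, ref=rec.REF, alt=alt,
                    vtype=rec.INFO.get("TYPE", "SNV"),
                )
            )
    return calls


@pytest.fixture(scope="session")
def adjacent_snv_scenarios(tmp_path_factory):
    """Paired-mode fixtures for same-read adjacent-substitution behavior.

    Scenario "somatic_pair": two adjacent SNVs on one somatic haplotype,
    clean normal -> should merge into one block substitution.
    Scenario "germline_neighbor": the second SNV is a germline het (in the
    normal at ~50%) carried next to a somatic SNV -> only the somatic SNV
    may be emitted, unmerged.

    Sequencing errors are switched off: these fixtures probe read-phasing
    and representation behavior, not the error model.
    """
    from varlod.output_cli import run_pipeline

    out = {}
    base = tmp_path_factory.mktemp("mnv")

    # --- somatic pair: CA -> AG at offsets 240,241
    seq = embedded_reference(21, 240, "CA")
    hap = Haplotype(
        (
            TruthVariant("c1", 240, "C", "A", "SNV", 30.0),
            TruthVariant("c1", 241, "A", "G", "SNV", 30.0),
        ),
        vaf=30.0,
    )
    tumor = simulate_contig(
        SimSpec("c1", list(hap.variants), seed=101, depth=400, sequencing_error_rate=0.0,
                reference_seq=seq, haplotypes=[hap])
    )
    normal = simulate_contig(
        SimSpec("c1", [], seed=102, depth=400, sequencing_error_rate=0.0,
                reference_seq=seq)
    )
    tdir = base / "somatic_pair"
    tdir.mkdir()
    tp = write_outputs([tumor], str(tdir), prefix="tumor")
    np_ = write_outputs([normal], str(tdir), prefix="normal")
    vcf, _ = run_pipeline(
        CallerConfig(), tp.bam, np_.bam, tp.bed, tp.fasta, str(tdir / "out.vcf")
    )
    out["somatic_pair"] = read_vcf_calls(vcf)

    # --- germline neighbor: somatic C->T at 240 rides on the germline
    # A->G at 241 (het in both samples)
    seq = embedded_reference(31, 240, "CA")
    som = Haplotype(
        (
            TruthVariant("c2", 240, "C", "T", "SNV", 30.0),
            TruthVariant("c2", 241, "A", "G", "SNV", 30.0),
        ),
        vaf=30.0,
    )
    germ_extra = Haplotype((TruthVariant("c2", 241, "A", "G", "SNV", 20.0),), vaf=20.0)
    tumor = simulate_contig(
        SimSpec("c2", [v for h in (som, germ_extra) for v in h.variants], seed=103, depth=400,
                sequencing_error_rate=0.0, reference_seq=seq,
                haplotypes=[som, germ_extra])
    )
    germ = Haplotype((TruthVariant("c2", 241, "A", "G", "SNV", 50.0),), vaf=50.0)
    normal = simulate_contig(
        SimSpec("c2", list(germ.variants), seed=104, depth=400, sequencing_error_rate=0.0,
                reference_seq=seq, haplotypes=[germ])
    )
    ndir = base / "germline_neighbor"
    ndir.mkdir()
    tp = write_outputs([tumor], str(ndir), prefix="tumor")
    np_ = write_outputs([normal], str(ndir), prefix="normal")
    vcf, _ = run_pipeline(
        CallerConfig(), tp.bam, np_.bam, tp.bed, tp.fasta, str(ndir / "out.vcf")
    )
    out["germline_neighbor"] = read_vcf_calls(vcf)
    return out


@pytest.fixture(scope="session")
def complex_deletion_calls(tmp_path_factory):
    """Tumor-only calls for a deletion+SNV complex (GG -> A) at 20% VAF.

    Error-free reads: the fixture probes representation, not noise."""
    base = tmp_path_factory.mktemp("complex")
    seq = embedded_reference(41, 240, "GG")
    tumor = simulate_contig(
        SimSpec("c3", [TruthVariant("c3", 240, "GG", "A", "complex", 20.0)],
                seed=105, depth=400, sequencing_error_rate=0.0, reference_seq=seq)
    )
    from varlod.output_cli import run_pipeline

    tp = write_outputs([tumor], str(base), prefix="tumor")
    vcf, _ = run_pipeline(CallerConfig(), tp.bam, None, tp.bed, tp.fasta,
                          str(base / "out.vcf"))
    return read_vcf_calls(vcf)
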