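"""Tumor-normal somatic classification: frequency gates, normal LOD, FET.

The paired cascade, applied to each tumor candidate in order:

1. The normal allele fraction must be below ``nf`` OR below
   ``normal_ratio`` (.2) times the tumor fraction; otherwise reject.
2. A variant absent from the normal, or whose normal support sits
   entirely on one strand (an artifact signature), is emitted directly.
3. When the normal fraction is below ``normal_lod_gate_ratio`` (.5) times
   the tumor fraction, the LOD of the allele in the *normal* pileup is
   computed: a weak normal signal (LOD < 3.9) emits the variant; a strong
   one falls through to Fisher's exact test.
4. Fisher's exact test on the 2x2 table (normal n1/n0 vs tumor c1/c0)
   emits iff p <= ``fet_p_threshold``.

The exact-test point probability is the hypergeometric term

    p = (n1+n0)! (c1+c0)! (c1+n1)! (c0+n0)!
        / [ n1! n0! c1! c0! (n1+n0+c1+c0)! ]

computed in log-gamma space; the default p-value sums this over the
one-sided tail toward tumor enrichment (tables with fewer normal variant
reads at fixed margins), since the point term alone is not a valid test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .datamodel import CallerConfig, ContingencyTable, SiteEvidence
from . import snv_engine

__all__ = [
    "PairedDecision",
    "fisher_point_probability",
    "fisher_one_sided_p",
    "classify_paired",
]


@dataclass(frozen=True)
class PairedDecision:
    emit: bool
    path_taken: str
    fet_p: float | None = None
    lod_normal: float | None = None

    _EMIT_PATHS = frozenset(
        {"absent_in_normal", "same_direction_normal", "lod_gate_pass", "fet_pass"}
    )

    def __post_init__(self) -> None:
        if self.emit and self.path_taken not in self._EMIT_PATHS:
            raise ValueError(f"emitting decision on non-emitting path {self.path_taken}")


def _log_point(n1: int, n0: int, c1: int, c0: int) -> float:
    num = (
        gammaln(n1 + n0 + 1)
        + gammaln(c1 + c0 + 1)
        + gammaln(c1 + n1 + 1)
        + gammaln(c0 + n0 + 1)
    )
    den = (
        gammaln(n1 + 1)
        + gammaln(n0 + 1)
        + gammaln(c1 + 1)
        + gammaln(c0 + 1)
        + gammaln(n1 + n0 + c1 + c0 + 1)
    )
    return float(num - den)


def fisher_point_probability(t: ContingencyTable) -> float:
    """Exact hypergeometric probability of the observed table."""
    return float(min(np.exp(_log_point(t.n1, t.n0, t.c1, t.c0)), 1.0))


def fisher_one_sided_p(t: ContingencyTable) -> float:
    """One-sided p-value toward tumor enrichment.

    Sums the point probability over all tables with the same margins whose
    normal variant count is <= n1. Equals 1 when n1 is already maximal.
    """
    row_n = t.n1 + t.n0  # normal sample size
    col_v = t.n1 + t.c1  # total variant reads
    ks = np.arange(0, t.n1 + 1)
    # feasibility: k variant reads in normal requires c1' = col_v - k >= 0
    # and n0' = row_n - k >= 0 and c0' >= 0
    col_r = t.n0 + t.c0
    valid = (col_v - ks >= 0) & (row_n - ks >= 0) & (col_r - (row_n - ks) >= 0)
    ks = ks[valid]
    if ks.size == 0:
        return 1.0
    logs = np.array([_log_point(k, row_n - k, col_v - k, col_r - row_n + k) for k in ks])
    m = logs.max()
    return float(min(np.exp(m) * np.exp(logs - m).sum(), 1.0))


def _fet_p(t: ContingencyTable, config: CallerConfig) -> float:
    if config.fet_mode == "point":
        return fisher_point_probability(t)
    return fisher_one_sided_p(t)


def classify_paired(
    tumor_vaf: float,
    tumor_support: int,
    tumor_depth: int,
    normal_support: int,
    normal_depth: int,
    normal_strands: tuple[int, int],
    config: CallerConfig,
    normal_site: SiteEvidence | None = None,
    ref: str | None = None,
    alt: str | None = None,
) -> PairedDecision:
    """Run the somatic cascade for one candidate.

    VAFs are percentages; counts are duplicate-collapsed. ``normal_site``
    supplies base-level normal observations for the LOD gate; indel and
    complex alleles, which have no per-base error model, pass ``None`` and
    go straight from the frequency gates to Fisher's exact test.
    Zero normal coverage rejects the candidate outright (no evidence the
    site is somatic rather than unsequenced germline).
    """
    if normal_depth <= 0:
        return PairedDecision(emit=False, path_taken="no_normal_coverage")
    normal_vaf = 100.0 * normal_support / normal_depth

    # gate 1: normal frequency must be low absolutely or relative to tumor
    if not (normal_vaf < 100.0 * config.nf or normal_vaf < config.normal_ratio * tumor_vaf):
        return PairedDecision(emit=False, path_taken="nf_gate_fail")

    # gate 2: clean or single-stranded normal support emits directly
    if normal_support == 0:
        return PairedDecision(emit=True, path_taken="absent_in_normal")
    fwd, rev = normal_strands
    if fwd == 0 or rev == 0:
        return PairedDecision(emit=True, path_taken="same_direction_normal")

    table = ContingencyTable(
        n1=normal_support,
        n0=max(normal_depth - normal_support, 0),
        c1=tumor_support,
        c0=max(tumor_depth - tumor_support, 0),
    )

    # gate 3: weak normal signal measured by the LOD of the allele in the
    # normal pileup (base-level evidence only)
    if (
        normal_site is not None
        and ref is not None
        and alt is not None
        and normal_vaf < config.normal_lod_gate_ratio * tumor_vaf
    ):
        score = snv_engine.tumor_lod(normal_site, ref, alt, config)
        if score.lod < config.lod_threshold:
            return PairedDecision(emit=True, path_taken="lod_gate_pass", lod_normal=score.lod)
        p = _fet_p(table, config)
        return PairedDecision(
            emit=p <= config.fet_p_threshold,
            path_taken="fet_pass" if p <= config.fet_p_threshold else "fet_fail",
            fet_p=p,
            lod_normal=score.lod,
        )

    # gate 4: Fisher's exact test directly
    p = _fet_p(table, config)
    return PairedDecision(
        emit=p <= config.fet_p_threshold,
        path_taken="fet_pass" if p <= config.fet_p_threshold else "fet_fail",
        fet_p=p,
    )
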