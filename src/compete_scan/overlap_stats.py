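"""Co-occurrence counting and the shuffle permutation test.

This is the statistical core of the pipeline. For every (RBP, miRNA) pair,
the observed number ``O`` of overlapping or adjacent binding-site pairs on
the real transcript is compared with the same count ``C1..CN`` on ``N``
sequences obtained by shuffling the transcript's nucleotides (identical
base composition, random order). The empirical significance is

    p = K / N,   K = #{i : Ci >= O}

("equal to or larger" — ties count toward K). Multiple pairs are corrected
with the Benjamini-Hochberg step-up FDR. Pairs with ``O = 0`` are not
tested: their p-value is uninformative and would only dilute the FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .mirna_scan import MiRNA, ScanParams, SeedMatchSite, scan_mirna
from .rbp_scan import MotifModel, PWMScanner, RBPSite
from .sequence_io import NamedSequence, encode, shuffle_sequence

logger = logging.getLogger(__name__)


class PairKey(NamedTuple):
    rbp_name: str
    mirna_name: str


@dataclass(frozen=True)
class PairTestResult:
    """Permutation-test outcome for one (RBP, miRNA) pair on one transcript."""

    key: PairKey
    observed: int
    null_counts: tuple[int, ...]
    K: int
    pvalue: float
    qvalue: float | None = None

    @property
    def n_permutations(self) -> int:
        return len(self.null_counts)

    @property
    def p_floor(self) -> float:
        """Resolution of the permutation p-value: 1/N (p=0 means p < 1/N)."""
        return 1.0 / len(self.null_counts)


def _interval(site) -> tuple[int, int]:
    if isinstance(site, (SeedMatchSite, RBPSite)):
        return site.start, site.end
    start, end = site
    return int(start), int(end)


def within_distance(site_a, site_b, d: int) -> bool:
    """True if two half-open intervals overlap or lie within distance ``d``.

    With gap ``g = max(startA, startB) - min(endA, endB)``, the rule is
    ``g < d or g < 0``: at ``d = 0`` the sites must share at least one base
    (abutting sites are excluded); at ``d > 0`` gaps of up to ``d - 1``
    bases are additionally admitted ("distance < d").
    """
    if not 0 <= d <= 100:
        raise ValueError("distance must be in [0, 100]")
    sa, ea = _interval(site_a)
    sb, eb = _interval(site_b)
    g = max(sa, sb) - min(ea, eb)
    return g < d or g < 0


def _count_pairs(
    m_start: np.ndarray,
    m_end: np.ndarray,
    r_start_sorted: np.ndarray,
    r_end_sorted: np.ndarray,
    d: int,
) -> int:
    """Pairs (m, r) with max(starts) - min(ends) < max(d, overlap).

    Uses the identity: the pair qualifies iff r.start < m.end + d and
    r.end > m.start - d, counted with two sorted sweeps (searchsorted).
    """
    if len(m_start) == 0 or len(r_start_sorted) == 0:
        return 0
    upper = np.searchsorted(r_start_sorted, m_end + d, side="left")
    lower = np.searchsorted(r_end_sorted, m_start - d, side="right")
    return int((upper - lower).sum())


def count_cooccurrences(mirna_sites, rbp_sites, d: int) -> int:
    """Number of (miRNA site, RBP site) pairs overlapping/within distance d.

    Counts pair events: one miRNA site near two RBP sites contributes 2.
    Contract-equal to the all-pairs :func:`within_distance` check; computed
    by a sorted sweep.
    """
    if not 0 <= d <= 100:
        raise ValueError("distance must be in [0, 100]")
    m = np.array([_interval(s) for s in mirna_sites], dtype=np.int64).reshape(-1, 2)
    r = np.array([_interval(s) for s in rbp_sites], dtype=np.int64).reshape(-1, 2)
    return _count_pairs(
        m[:, 0], m[:, 1], np.sort(r[:, 0]), np.sort(r[:, 1]), d
    )


def permutation_pvalue(
    observed: int, null_counts: Sequence[int], correction: bool = False
) -> tuple[int, float]:
    """(K, p) for the permutation test: K = #{Ci >= O}, p = K/N.

    ``correction=True`` applies the small-sample form (K+1)/(N+1) instead;
    the default reports the plain ratio, including possible p = 0 (meaning
    p < 1/N at the achieved resolution).
    """
    counts = np.asarray(null_counts)
    n = len(counts)
    if n < 1:
        raise ValueError("need at least one permutation")
    k = int((counts >= observed).sum())
    p = (k + 1) / (n + 1) if correction else k / n
    return k, float(p)


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in input order."""
    ps = np.asarray(list(pvalues), dtype=float)
    if len(ps) == 0:
        return []
    if ((ps < 0) | (ps > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(ps, method="fdr_bh")[1])


def scan_stage(
    transcript: NamedSequence,
    mirnas: Sequence[MiRNA],
    motifs: Sequence[MotifModel],
    params: ScanParams,
    scanners: dict[str, PWMScanner] | None = None,
) -> tuple[dict[str, list[SeedMatchSite]], dict[str, list[RBPSite]]]:
    """Run the full scanning stage: miRNA sites and RBP sites per regulator."""
    if scanners is None:
        scanners = {m.rbp_name: PWMScanner(m) for m in motifs}
    mirna_sites = {m.name: scan_mirna(transcript, m, params) for m in mirnas}
    rbp_sites = {
        m.rbp_name: scanners[m.rbp_name].scan(
            transcript, params.rbp_pvalue_cutoff
        )
        for m in motifs
    }
    return mirna_sites, rbp_sites


def permutation_test(
    transcript: NamedSequence,
    mirnas: Sequence[MiRNA],
    motifs: Sequence[MotifModel],
    params: ScanParams,
) -> list[PairTestResult]:
    """Full evaluation stage for one transcript.

    Scans the real sequence, then ``params.n_permutations`` shuffles
    (replicate ``i`` is shuffled with seed ``base_seed + i``, so replicates
    are independently reproducible), counting co-occurrences at
    ``params.distance`` for every pair with observed count >= 1. Returns
    results with BH q-values, sorted by p-value then pair key.
    """
    if len({m.name for m in mirnas}) != len(mirnas):
        raise ValueError("duplicate miRNA names")
    if len({m.rbp_name for m in motifs}) != len(motifs):
        raise ValueError("duplicate RBP names")
    n = params.n_permutations
    scanners = {m.rbp_name: PWMScanner(m) for m in motifs}
    mirna_sites, rbp_sites = scan_stage(
        transcript, mirnas, motifs, params, scanners
    )

    observed = {}
    for motif in motifs:
        for mir in mirnas:
            o = count_cooccurrences(
                mirna_sites[mir.name], rbp_sites[motif.rbp_name],
                params.distance,
            )
            if o >= 1:
                observed[PairKey(motif.rbp_name, mir.name)] = o
    if not observed:
        logger.info(
            "%s: no co-occurring sites on the real sequence; nothing to test",
            transcript.name,
        )
        return []

    tested = sorted(observed)
    tested_mirnas = {k.mirna_name for k in tested}
    tested_rbps = {k.rbp_name for k in tested}
    mirna_objs = [m for m in mirnas if m.name in tested_mirnas]
    motif_objs = [m for m in motifs if m.rbp_name in tested_rbps]
    null = np.zeros((len(tested), n), dtype=np.int64)
    pair_index = {key: i for i, key in enumerate(tested)}

    for i in range(1, n + 1):
        shuffled = shuffle_sequence(
            transcript,
            params.base_seed + i,
            preserve_dinucleotides=params.preserve_dinucleotides,
        )
        codes = encode(shuffled.sequence)
        m_ivals = {}
        for mir in mirna_objs:
            sites = scan_mirna(shuffled, mir, params)
            arr = np.array([(s.start, s.end) for s in sites], dtype=np.int64)
            m_ivals[mir.name] = arr.reshape(-1, 2)
        for motif in motif_objs:
            k = motif.k
            starts = scanners[motif.rbp_name].hit_starts(
                codes, params.rbp_pvalue_cutoff
            )
            ends = starts + k
            for mir in mirna_objs:
                key = PairKey(motif.rbp_name, mir.name)
                if key not in pair_index:
                    continue
                mi = m_ivals[mir.name]
                null[pair_index[key], i - 1] = _count_pairs(
                    mi[:, 0], mi[:, 1], starts, ends, params.distance
                )

    results = []
    for key in tested:
        counts = null[pair_index[key]]
        k_stat, p = permutation_pvalue(
            observed[key], counts, correction=params.pvalue_correction
        )
        results.append(
            PairTestResult(
                key=key,
                observed=observed[key],
                null_counts=tuple(int(c) for c in counts),
                K=k_stat,
                pvalue=p,
            )
        )
    qvalues = bh_fdr([r.pvalue for r in results])
    results = [replace(r, qvalue=q) for r, q in zip(results, qvalues)]
    results.sort(key=lambda r: (r.pvalue, r.key))
    return results


def select_significant(
    results: Sequence[PairTestResult], fdr_cutoff: float
) -> list[PairTestResult]:
    """Results with q-value <= cutoff, ordered by (qvalue, pvalue, key)."""
    kept = [r for r in results if r.qvalue is not None and r.qvalue <= fdr_cutoff]
    kept.sort(key=lambda r: (r.qvalue, r.pvalue, r.key))
    return kept
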