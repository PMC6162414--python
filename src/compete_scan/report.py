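"""Pipeline orchestration, result tables and landscape summaries.

Runs the scanning and evaluation stages per transcript and writes the
three result artifacts: the tested-pair table (with O, K, N, p, q), the
per-site table of every co-occurring site pair, and the competition
network, plus a JSON run manifest for reproducibility. Multi-transcript
summaries (pair-count vs length correlation, shared-pair census) support
landscape-style analyses.

Output tables use 1-based inclusive coordinates (stated in their header
comments); internal coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.stats

from . import __version__
from .mirna_scan import MiRNA, ScanParams
from .network import CompetitionNetwork, build_network, export_network
from .overlap_stats import (
    PairKey,
    PairTestResult,
    bh_fdr,
    permutation_test,
    scan_stage,
    select_significant,
    within_distance,
)
from .rbp_scan import MotifModel
from .sequence_io import NamedSequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SitePairRecord:
    """One co-occurring (miRNA site, RBP site) event on the real sequence."""

    rbp_name: str
    mirna_name: str
    mirna_start: int
    mirna_end: int
    site_type: str
    ddg: float | None
    rbp_start: int
    rbp_end: int
    rbp_score: float
    rbp_pvalue: float
    gap: int  # max(starts) - min(ends); negative = overlapping bases


@dataclass
class TranscriptRunResult:
    """All per-transcript outputs of one pipeline run."""

    transcript_name: str
    transcript_length: int
    results: list[PairTestResult]
    significant: list[PairTestResult]
    site_pairs: list[SitePairRecord]
    network: CompetitionNetwork
    params: ScanParams


def _site_pair_records(
    transcript: NamedSequence,
    mirnas: Sequence[MiRNA],
    motifs: Sequence[MotifModel],
    params: ScanParams,
    tested: set[PairKey],
) -> list[SitePairRecord]:
    mirna_sites, rbp_sites = scan_stage(transcript, mirnas, motifs, params)
    records = []
    for key in sorted(tested):
        for ms in mirna_sites[key.mirna_name]:
            for rs in rbp_sites[key.rbp_name]:
                if within_distance(ms, rs, params.distance):
                    records.append(
                        SitePairRecord(
                            rbp_name=key.rbp_name,
                            mirna_name=key.mirna_name,
                            mirna_start=ms.start,
                            mirna_end=ms.end,
                            site_type=ms.site_type,
                            ddg=ms.ddg,
                            rbp_start=rs.start,
                            rbp_end=rs.end,
                            rbp_score=rs.score,
                            rbp_pvalue=rs.pvalue,
                            gap=max(ms.start, rs.start) - min(ms.end, rs.end),
                        )
                    )
    return records


def run_pipeline(
    transcripts: Sequence[NamedSequence],
    mirnas: Sequence[MiRNA],
    motifs: Sequence[MotifModel],
    params: ScanParams,
    global_fdr: bool = False,
) -> list[TranscriptRunResult]:
    """Scanning + evaluation stages for each transcript.

    By default the BH correction is applied per transcript across its
    tested pairs; ``global_fdr=True`` pools the p-values of all transcripts
    into one correction (for landscape-style runs over a collection).
    Deterministic given ``params.base_seed``.
    """
    out = []
    for transcript in transcripts:
        logger.info("scanning %s (%d nt)", transcript.name, len(transcript))
        results = permutation_test(transcript, mirnas, motifs, params)
        logger.info(
            "%s: %d pairs tested, %d permutations",
            transcript.name, len(results), params.n_permutations,
        )
        records = _site_pair_records(
            transcript, mirnas, motifs, params, {r.key for r in results}
        )
        significant = select_significant(results, params.fdr_cutoff)
        out.append(
            TranscriptRunResult(
                transcript_name=transcript.name,
                transcript_length=len(transcript),
                results=results,
                significant=significant,
                site_pairs=records,
                network=build_network(significant),
                params=params,
            )
        )
    if global_fdr and out:
        pooled = [(i, r) for i, run in enumerate(out) for r in run.results]
        qvalues = bh_fdr([r.pvalue for _, r in pooled])
        per_run: dict[int, list[PairTestResult]] = {i: [] for i in range(len(out))}
        for (i, r), q in zip(pooled, qvalues):
            per_run[i].append(dataclasses.replace(r, qvalue=q))
        for i, run in enumerate(out):
            run.results = sorted(
                per_run[i], key=lambda r: (r.pvalue, r.key)
            )
            run.significant = select_significant(run.results, params.fdr_cutoff)
            run.network = build_network(run.significant)
    return out


def pair_count_length_correlation(
    results: Sequence[TranscriptRunResult],
) -> dict:
    """Pearson correlation of significant-pair count with transcript length.

    Returns ``{"n", "r", "pvalue", "computable"}``; when either variable
    has zero variance the correlation is undefined and reported as
    not-computable rather than 0.
    """
    if len(results) < 3:
        raise ValueError("need at least 3 transcripts for a correlation")
    lengths = np.array([r.transcript_length for r in results], dtype=float)
    counts = np.array([len(r.significant) for r in results], dtype=float)
    if np.ptp(lengths) == 0 or np.ptp(counts) == 0:
        return {"n": len(results), "r": None, "pvalue": None,
                "computable": False}
    r, p = scipy.stats.pearsonr(lengths, counts)
    return {"n": len(results), "r": float(r), "pvalue": float(p),
            "computable": True}


def shared_pair_census(
    results: Sequence[TranscriptRunResult], k: int = 5
) -> dict:
    """How many transcripts share each significant (RBP, miRNA) pair.

    Returns the per-pair census (sorted by descending count then key) and
    the fraction of unique pairs significant in >= k transcripts.
    """
    counts: dict[PairKey, int] = {}
    for run in results:
        for res in run.significant:
            counts[res.key] = counts.get(res.key, 0) + 1
    census = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    n_unique = len(counts)
    n_shared = sum(1 for _, c in counts.items() if c >= k)
    return {
        "census": census,
        "n_unique_pairs": n_unique,
        "k": k,
        "n_shared_ge_k": n_shared,
        "fraction_shared_ge_k": (n_shared / n_unique) if n_unique else 0.0,
    }


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_outputs(result: TranscriptRunResult, outdir) -> dict[str, Path]:
    """Write the pair table, site table, network and manifest for one run.

    Re-running with the same inputs and seed reproduces the TSVs and the
    GraphML byte-for-byte; only the manifest timestamp differs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    name = result.transcript_name
    paths = {
        "pairs": outdir / f"{name}.pairs.tsv",
        "sites": outdir / f"{name}.sites.tsv",
        "network": outdir / f"{name}.network.graphml",
        "manifest": outdir / f"{name}.manifest.json",
    }

    with open(paths["pairs"], "w") as fh:
        fh.write("# permutation test of RBP/miRNA binding-site co-occurrence\n")
        fh.write("rbp\tmirna\tobserved\tK\tN\tpvalue\tp_floor\tqvalue\n")
        for r in result.results:
            fh.write(
                f"{r.key.rbp_name}\t{r.key.mirna_name}\t{r.observed}\t"
                f"{r.K}\t{r.n_permutations}\t{_fmt(r.pvalue)}\t"
                f"{_fmt(r.p_floor)}\t{_fmt(r.qvalue)}\n"
            )

    with open(paths["sites"], "w") as fh:
        fh.write("# coordinates are 1-based inclusive\n")
        fh.write(
            "rbp\tmirna\tmirna_start\tmirna_end\tsite_type\tddg\t"
            "rbp_start\trbp_end\trbp_score\trbp_pvalue\tgap\n"
        )
        for s in result.site_pairs:
            fh.write(
                f"{s.rbp_name}\t{s.mirna_name}\t{s.mirna_start + 1}\t"
                f"{s.mirna_end}\t{s.site_type}\t{_fmt(s.ddg)}\t"
                f"{s.rbp_start + 1}\t{s.rbp_end}\t{_fmt(s.rbp_score)}\t"
                f"{_fmt(s.rbp_pvalue)}\t{s.gap}\n"
            )

    export_network(result.network, paths["network"], "graphml")

    manifest = {
        "transcript": name,
        "transcript_length": result.transcript_length,
        "params": dataclasses.asdict(result.params),
        "n_pairs_tested": len(result.results),
        "n_pairs_significant": len(result.significant),
        "n_site_pairs": len(result.site_pairs),
        "version": __version__,
        "written_at": datetime.now(timezone.utc).isoformat(),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
        fh.write("\n")
    return paths
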