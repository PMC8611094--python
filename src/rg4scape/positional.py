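"""Metagene pileups around motif anchors and the 5'/3' read-skew statistic.

A pileup sums read 5' ends at each offset in [-w, +w] relative to anchor
midpoints (e.g. G4 motif midpoints), CPM-normalised by library size.  The
per-site skew

    S = (R3 - R5) / (R3 + R5)

contrasts the read mass 3' of the anchor (offsets > 0) with the mass 5' of
it (offsets < 0; offset 0 excluded).  S near +1 marks binding skewed
downstream of the motif, near -1 upstream, near 0 centred — the geometries
that distinguish helicases engaging a G4 from its 3' or 5' single-stranded
tail from proteins binding across the G-rich stretch itself.

Skew distributions of two proteins are compared with a two-sided
Mann-Whitney / Wilcoxon rank-sum test; because skew values tie heavily, the
small-sample branch is an exact tie-aware permutation distribution of the
rank sum (dynamic programming over midranks), and larger samples use the
tie-corrected normal approximation.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from rg4scape.transcriptome import Interval, ReadSet


@dataclass
class PileupProfile:
    """Summed read-5' counts per offset around anchor midpoints."""

    half_width: int
    offsets: np.ndarray  # -w .. +w
    counts: np.ndarray
    cpm: np.ndarray
    n_sites: int
    library_size: int


@dataclass
class SkewResult:
    """Per-site skew values and their median for one library."""

    skews: np.ndarray
    median: float
    n_sites: int
    min_reads: int


def _per_site_flanks(
    reads: ReadSet, anchors: Sequence[Interval], w: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(R5, R3, at-anchor) read-start counts per anchor, plus offset histogram."""
    starts = reads.starts_by_transcript()
    r5 = np.zeros(len(anchors), dtype=np.int64)
    r3 = np.zeros(len(anchors), dtype=np.int64)
    hist = np.zeros(2 * w + 1, dtype=np.int64)
    for i, a in enumerate(anchors):
        pos = starts.get(a.transcript_id)
        if pos is None:
            continue
        m = a.midpoint
        lo = np.searchsorted(pos, m - w, side="left")
        hi = np.searchsorted(pos, m + w, side="right")
        delta = pos[lo:hi] - m
        if delta.size:
            np.add.at(hist, delta + w, 1)
            r5[i] = int((delta < 0).sum())
            r3[i] = int((delta > 0).sum())
    return r5, r3, hist


def pileup_profile(
    reads: ReadSet, anchors: Sequence[Interval], w: int = 100
) -> PileupProfile:
    """Metagene pileup of read 5' ends in [-w, +w] around anchor midpoints."""
    if w < 1:
        raise ValueError("half-width w must be >= 1")
    if not anchors:
        raise ValueError("anchors must be nonempty")
    _, _, hist = _per_site_flanks(reads, anchors, w)
    cpm = hist * (1e6 / reads.size)
    return PileupProfile(
        half_width=w,
        offsets=np.arange(-w, w + 1),
        counts=hist,
        cpm=cpm,
        n_sites=len(anchors),
        library_size=reads.size,
    )


def skew_statistic(
    reads: ReadSet,
    anchors: Sequence[Interval],
    w: int = 100,
    min_reads: int = 5,
) -> SkewResult:
    """Per-site skew S = (R3 - R5)/(R3 + R5); sites with < min_reads dropped."""
    if not anchors:
        raise ValueError("anchors must be nonempty")
    r5, r3, _ = _per_site_flanks(reads, anchors, w)
    mass = r5 + r3
    keep = mass >= min_reads
    if not keep.any():
        raise ValueError(
            f"no site reaches min_reads={min_reads} within +/-{w} nt"
        )
    skews = (r3[keep] - r5[keep]) / mass[keep]
    return SkewResult(
        skews=skews.astype(float),
        median=float(np.median(skews)),
        n_sites=int(keep.sum()),
        min_reads=min_reads,
    )


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact permutation p for the rank-sum of ``a``, ties allowed.

    Midranks are doubled to stay integral; a subset-sum DP counts, for every
    achievable rank-sum, the number of size-|a| subsets of the pooled values
    attaining it.  p = P(RS as or more extreme than observed, either tail).
    """
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    order = np.argsort(pooled, kind="stable")
    ranks2 = np.empty(n, dtype=np.int64)  # 2 * midrank, integral under ties
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks2[order[i:j]] = (i + 1) + j  # 2 * (i+1+j)/2
        i = j
    obs = int(ranks2[:na].sum())
    max_sum = int(np.sort(ranks2)[-na:].sum())
    # dp[k][s] = #subsets of size k with doubled-rank-sum s
    dp = np.zeros((na + 1, max_sum + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in ranks2:
        for k in range(na, 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    dist = dp[na]
    total = dist.sum()
    lo = dist[: obs + 1].sum() / total
    hi = dist[obs:].sum() / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def compare_skew(
    a: SkewResult, b: SkewResult, exact_max_n: int = 20
) -> float:
    """Two-sided rank-sum p comparing two per-site skew distributions.

    Exact (tie-aware permutation DP) when both groups have <= exact_max_n
    sites; tie-corrected normal approximation otherwise.
    """
    xa, xb = np.asarray(a.skews, float), np.asarray(b.skews, float)
    if xa.size < 10 or xb.size < 10:
        raise ValueError("need >= 10 qualifying sites per group")
    if np.array_equal(xa, xb) and np.unique(xa).size == 1:
        return 1.0
    if xa.size <= exact_max_n and xb.size <= exact_max_n:
        return _exact_ranksum_p(xa, xb)
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def profile_frame(profile: PileupProfile) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "offset": profile.offsets,
            "count": profile.counts,
            "cpm": profile.cpm,
        }
    )
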