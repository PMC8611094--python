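"""CLIP-style peak calling with a zero-truncated negative binomial (ZTNB) null.

Read 5' ends are binned along each transcript; the background count
distribution is modelled as a negative binomial conditioned on counts >= 1
(zero truncation removes the uninformative unexpressed bins), fitted
jointly across all transcripts of a library.  Bins whose upper-tail
probability under the fit falls below a raw p-value cutoff (default 1e-4,
no multiplicity correction) are merged into peaks; consensus peaks are the
regions supported by peaks from at least ``min_replicates`` biological
replicates.

The NB is parameterised by mean ``mu`` and size ``r`` (variance
``mu + mu^2/r``); the ZTNB pmf is ``NB(k; r, mu) / (1 - NB(0; r, mu))``
for k >= 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from scipy import optimize, stats

from rg4scape.transcriptome import Interval, ReadSet

logger = logging.getLogger(__name__)

R_UPPER_BOUND = 1e6  # dispersion size above this is Poisson-like
R_LOWER_BOUND = 1e-2  # below this the ZTNB degenerates to a logarithmic series
MU_BOUNDS = (1e-8, 1e9)


@dataclass
class BinCounts:
    """Per-bin read-5'-end counts for one library replicate."""

    bin_size: int
    counts: Dict[Tuple[str, int], int]
    library_size: int

    def nonzero(self) -> np.ndarray:
        return np.asarray([c for c in self.counts.values() if c > 0], dtype=np.int64)


@dataclass
class ZTNBFit:
    """Maximum-likelihood ZTNB background fit."""

    mean: float
    dispersion: float  # NB size parameter r
    loglik: float
    n_bins_used: int
    converged: bool = True

    @property
    def _p(self) -> float:
        return self.dispersion / (self.dispersion + self.mean)


@dataclass
class Peak:
    """A called peak: a union of adjacent significant bins."""

    interval: Interval
    min_p: float
    total_count: int
    replicate_support: Set[int] = field(default_factory=set)


def bin_read_starts(reads: ReadSet, bin_size: int = 30) -> BinCounts:
    """Histogram read 5' ends into fixed-width bins per transcript.

    Each read contributes exactly once, at bin ``floor(start / bin_size)``.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if reads.size == 0:
        raise ValueError(f"empty ReadSet {reads.library_id!r}")
    counts: Dict[Tuple[str, int], int] = {}
    for t, starts in reads.starts_by_transcript().items():
        idx, n = np.unique(starts // bin_size, return_counts=True)
        for b, c in zip(idx, n):
            counts[(t, int(b))] = int(c)
    return BinCounts(bin_size=bin_size, counts=counts, library_size=reads.size)


def _clip_params(params: np.ndarray) -> Tuple[float, float]:
    log_mu = float(np.clip(params[0], math.log(MU_BOUNDS[0]), math.log(MU_BOUNDS[1])))
    log_r = float(np.clip(params[1], math.log(R_LOWER_BOUND), math.log(R_UPPER_BOUND)))
    return math.exp(log_mu), math.exp(log_r)


def _ztnb_nll(params: np.ndarray, k: np.ndarray, w: np.ndarray) -> float:
    mu, r = _clip_params(params)
    p = r / (r + mu)
    logp0 = stats.nbinom.logpmf(0, r, p)
    # log(1 - p0) via log1p for numerical safety when p0 ~ 1
    log_trunc = np.log1p(-math.exp(logp0)) if logp0 < -1e-12 else -np.inf
    ll = stats.nbinom.logpmf(k, r, p) - log_trunc
    return -float(np.dot(w, ll))


def fit_ztnb(counts: BinCounts, tol: float = 1e-8, max_iter: int = 500) -> ZTNBFit:
    """Fit (mean, dispersion) of the ZTNB by maximum likelihood.

    Only nonzero bins enter the fit.  Initialisation is method-of-moments
    on the truncated sample; optimisation runs in (log mu, log r) space
    with the dispersion boxed to [1e-2, 1e6]: a Poisson-like sample drives
    r to the upper bound, and a sample heavier-tailed than any NB (the
    ZTNB degenerates to a logarithmic series as mu, r -> 0) pins it at the
    lower bound; either boundary logs a warning.
    """
    k_all = counts.nonzero()
    if k_all.size < 50:
        raise ValueError(f"need >= 50 nonzero bins, got {k_all.size}")
    if np.all(k_all == k_all[0]):
        raise ValueError("no overdispersion signal: all nonzero counts equal")
    k, w = np.unique(k_all, return_counts=True)
    w = w.astype(float)

    m = float(np.mean(k_all))
    v = float(np.var(k_all))
    mu0 = max(m - 1.0, 0.1)  # truncation inflates the sample mean
    r0 = mu0 * mu0 / (v - mu0) if v > mu0 else 10.0
    r0 = min(max(r0, R_LOWER_BOUND), R_UPPER_BOUND)

    res = optimize.minimize(
        _ztnb_nll,
        x0=[math.log(mu0), math.log(r0)],
        args=(k, w),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": tol, "maxiter": max_iter * 10},
    )
    mu, r = _clip_params(res.x)
    at_upper = r >= R_UPPER_BOUND * (1 - 1e-9)
    at_lower = r <= R_LOWER_BOUND * (1 + 1e-9)
    if at_upper:
        logger.warning(
            "ZTNB dispersion hit upper bound r=%.0g (Poisson-like data)", r
        )
    elif at_lower:
        logger.warning(
            "ZTNB dispersion hit lower bound r=%.0g "
            "(heavier-tailed than any NB background)", r
        )
    if not res.success and not (at_upper or at_lower):
        raise RuntimeError(
            f"ZTNB fit did not converge: {res.message} "
            f"(mu={mu:.4g}, r={r:.4g}, nll={res.fun:.6g})"
        )
    return ZTNBFit(
        mean=mu,
        dispersion=r,
        loglik=-float(res.fun),
        n_bins_used=int(k_all.size),
        converged=bool(res.success),
    )


def fit_background(
    counts: BinCounts, p_exclude: float = 1e-3, rounds: int = 2
) -> ZTNBFit:
    """ZTNB background fit with iterative exclusion of signal bins.

    Bound-site bins inflate a single-pass fit's dispersion and push the
    calling threshold up; each round refits after dropping bins whose
    upper-tail probability under the current fit falls below ``p_exclude``
    (the same strategy peak callers use when estimating a local background
    outside candidate peaks).  ``rounds=1`` is the plain single-pass fit.
    """
    fit = fit_ztnb(counts)
    for _ in range(rounds - 1):
        keep = {
            key: c
            for key, c in counts.counts.items()
            if c < 1 or ztnb_upper_tail(fit, c) >= p_exclude
        }
        if len([c for c in keep.values() if c >= 1]) < 50:
            logger.warning("background refit would drop too many bins; stopping")
            break
        refit = fit_ztnb(
            BinCounts(
                bin_size=counts.bin_size,
                counts=keep,
                library_size=counts.library_size,
            )
        )
        if abs(refit.mean - fit.mean) < 1e-9 and abs(
            refit.dispersion - fit.dispersion
        ) < 1e-9:
            fit = refit
            break
        fit = refit
    return fit


def ztnb_upper_tail(fit: ZTNBFit, k: int) -> float:
    """P(X >= k | X >= 1) under the fitted ZTNB (k=1 gives exactly 1)."""
    if k < 1:
        raise ValueError("k must be >= 1 (truncated support)")
    p = fit._p
    sf0 = stats.nbinom.sf(0, fit.dispersion, p)
    return float(stats.nbinom.sf(k - 1, fit.dispersion, p) / sf0)


def call_peaks(
    counts: BinCounts,
    fit: ZTNBFit,
    p_cutoff: float = 1e-4,
    merge_gap_bins: int = 1,
) -> List[Peak]:
    """Call peaks as merged runs of bins with upper-tail p < p_cutoff.

    Significant bins separated by at most ``merge_gap_bins`` insignificant
    bins join one peak.  Peak intervals are in nucleotide coordinates.
    """
    bs = counts.bin_size
    # p-value depends on count only: memoise over distinct counts
    tail: Dict[int, float] = {}
    sig: Dict[str, List[Tuple[int, float, int]]] = {}
    for (t, b), c in counts.counts.items():
        if c < 1:
            continue
        pv = tail.get(c)
        if pv is None:
            pv = tail[c] = ztnb_upper_tail(fit, c)
        if pv < p_cutoff:
            sig.setdefault(t, []).append((b, pv, c))
    peaks: List[Peak] = []
    for t in sorted(sig):
        bins = sorted(sig[t])
        cur = [bins[0]]
        for item in bins[1:]:
            if item[0] - cur[-1][0] - 1 <= merge_gap_bins:
                cur.append(item)
            else:
                peaks.append(_assemble_peak(t, cur, bs))
                cur = [item]
        peaks.append(_assemble_peak(t, cur, bs))
    return peaks


def _assemble_peak(t: str, bins: List[Tuple[int, float, int]], bs: int) -> Peak:
    start = bins[0][0] * bs
    end = (bins[-1][0] + 1) * bs
    min_p = min(b[1] for b in bins)
    total = sum(b[2] for b in bins)
    score = -math.log10(min_p) if min_p > 0 else 350.0
    return Peak(
        interval=Interval(t, start, end, name="peak", score=round(score, 4)),
        min_p=min_p,
        total_count=total,
    )


def consensus_peaks(
    peak_sets: Sequence[Sequence[Peak]], min_replicates: int = 2
) -> List[Peak]:
    """Regions covered by peaks from >= min_replicates replicates.

    Each replicate contributes a merged footprint (depth 1 per replicate);
    the consensus is the per-base depth >= min_replicates footprint.  A
    peak present in a single replicate never reaches the consensus when
    min_replicates >= 2.
    """
    if min_replicates < 1:
        raise ValueError("min_replicates must be >= 1")
    if min_replicates > len(peak_sets):
        raise ValueError(
            f"min_replicates={min_replicates} exceeds replicate count {len(peak_sets)}"
        )
    # boundary-event sweep per transcript; each replicate counts once per base
    from rg4scape.transcriptome import merge_intervals

    events: Dict[str, List[Tuple[int, int]]] = {}
    rep_spans: List[List[Interval]] = []
    for peaks in peak_sets:
        merged = merge_intervals([p.interval for p in peaks]) if peaks else []
        rep_spans.append(merged)
        for iv in merged:
            events.setdefault(iv.transcript_id, []).append((iv.start, +1))
            events[iv.transcript_id].append((iv.end, -1))
    out: List[Peak] = []
    for t in sorted(events):
        # open before close at equal positions, so abutting regions coalesce
        ev = sorted(events[t], key=lambda x: (x[0], -x[1]))
        depth = 0
        region_start = None
        for pos, delta in ev:
            new_depth = depth + delta
            if depth < min_replicates <= new_depth:
                region_start = pos
            elif new_depth < min_replicates <= depth and region_start is not None:
                if pos > region_start:
                    out.append(_consensus_region(t, region_start, pos, peak_sets))
                region_start = None
            depth = new_depth
    return out


def _consensus_region(
    t: str, start: int, end: int, peak_sets: Sequence[Sequence[Peak]]
) -> Peak:
    region = Interval(t, start, end, name="consensus")
    support: Set[int] = set()
    min_p = 1.0
    total = 0
    for rep_id, peaks in enumerate(peak_sets):
        for p in peaks:
            if region.overlap(p.interval) > 0:
                support.add(rep_id)
                min_p = min(min_p, p.min_p)
                total += p.total_count
    score = -math.log10(min_p) if min_p > 0 else 350.0
    region = Interval(t, start, end, name="consensus", score=round(score, 4))
    return Peak(
        interval=region, min_p=min_p, total_count=total, replicate_support=support
    )
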