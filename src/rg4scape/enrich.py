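"""Interval-shuffling enrichment with empirical p-values and FDR.

The observed overlap of a query interval set (e.g. consensus peaks) with an
annotation (e.g. G4 motifs, or a transcript feature) is compared to a null
distribution built by relocating every query interval, length preserved, to
a uniformly random position within the transcriptome workspace: a target
transcript is drawn with probability proportional to its length among
transcripts long enough to hold the interval, and the start is uniform
within the transcript.  Fold enrichment = observed / mean(null); the
empirical p carries the +1 correction, so its floor is 1/(n_perm + 1) —
claiming FDR < 1e-4 therefore requires at least 10,000 permutations.

Two overlap statistics are offered: total nucleotides of overlap (``bp``,
the default) and the number of query intervals touching the annotation
(``count``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from rg4scape.transcriptome import (
    Interval,
    TranscriptAnnotation,
    merge_intervals,
)
from rg4scape.bg4diff import bh_fdr


@dataclass
class EnrichmentResult:
    query_name: str
    annotation_name: str
    observed: float
    expected_mean: float
    fold: float
    ci95: Tuple[float, float]
    empirical_p: float
    fdr: float
    n_permutations: int
    direction: str = "enrichment"


class _Workspace:
    """Transcript lengths prepared for length-respecting placement."""

    def __init__(self, annotations: Mapping[str, TranscriptAnnotation]):
        items = sorted(annotations.items())
        order = np.argsort([a.length for _, a in items], kind="stable")
        self.tids = [items[i][0] for i in order]
        self.lengths = np.asarray([items[i][1].length for i in order], dtype=np.int64)
        self.prefix = np.cumsum(self.lengths)

    def place(
        self, interval_lengths: np.ndarray, rng: np.random.Generator
    ) -> Tuple[np.ndarray, np.ndarray]:
        """Random (transcript index, start) per interval length."""
        i0 = np.searchsorted(self.lengths, interval_lengths, side="left")
        if np.any(i0 >= self.lengths.size):
            too_long = int(interval_lengths[i0 >= self.lengths.size].max())
            raise ValueError(
                f"interval of length {too_long} exceeds every transcript"
            )
        base = np.where(i0 > 0, self.prefix[np.maximum(i0 - 1, 0)], 0)
        total = self.prefix[-1] - base
        target = base + rng.random(interval_lengths.size) * total
        j = np.searchsorted(self.prefix, target, side="left")
        max_start = self.lengths[j] - interval_lengths
        starts = np.floor(rng.random(interval_lengths.size) * (max_start + 1)).astype(
            np.int64
        )
        return j, starts


def shuffle_intervals(
    query: Sequence[Interval],
    annotations: Mapping[str, TranscriptAnnotation],
    seed: int,
) -> List[Interval]:
    """One random relocation of every query interval (lengths preserved)."""
    ws = _Workspace(annotations)
    rng = np.random.default_rng(seed)
    lens = np.asarray([iv.length for iv in query], dtype=np.int64)
    j, starts = ws.place(lens, rng)
    return [
        Interval(ws.tids[int(tj)], int(s), int(s + L))
        for tj, s, L in zip(j, starts, lens)
    ]


class _AnnotationCoverage:
    """Per-transcript prefix-coverage of a merged annotation interval set."""

    def __init__(self, intervals: Sequence[Interval]):
        merged = merge_intervals(intervals)
        self.starts: Dict[str, np.ndarray] = {}
        self.ends: Dict[str, np.ndarray] = {}
        self.cum: Dict[str, np.ndarray] = {}
        by_t: Dict[str, List[Tuple[int, int]]] = {}
        for iv in merged:
            by_t.setdefault(iv.transcript_id, []).append((iv.start, iv.end))
        for t, spans in by_t.items():
            s = np.asarray([x[0] for x in spans], dtype=np.int64)
            e = np.asarray([x[1] for x in spans], dtype=np.int64)
            self.starts[t] = s
            self.ends[t] = e
            self.cum[t] = np.concatenate([[0], np.cumsum(e - s)])

    def covered_before(self, t: str, x: np.ndarray) -> np.ndarray:
        """Annotation bases in [0, x) on transcript t, vectorised over x."""
        s, e, cum = self.starts.get(t), self.ends.get(t), self.cum.get(t)
        if s is None:
            return np.zeros(x.shape, dtype=np.int64)
        k = np.searchsorted(s, x, side="right") - 1
        kk = np.maximum(k, 0)
        partial = np.clip(np.minimum(e[kk], x) - s[kk], 0, None)
        return np.where(k >= 0, cum[kk] + partial, 0)

    def overlaps(self, t: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        return self.covered_before(t, ends) - self.covered_before(t, starts)


def _statistic(
    cov: _AnnotationCoverage,
    tid_per_interval: Sequence[str],
    starts: np.ndarray,
    ends: np.ndarray,
    statistic: str,
) -> float:
    order: Dict[str, List[int]] = {}
    for i, t in enumerate(tid_per_interval):
        order.setdefault(t, []).append(i)
    total = 0.0
    for t, idx in order.items():
        ia = np.asarray(idx)
        ov = cov.overlaps(t, starts[ia], ends[ia])
        total += float(ov.sum()) if statistic == "bp" else float((ov > 0).sum())
    return total


def permutation_enrichment(
    query: Sequence[Interval],
    annotation_intervals: Sequence[Interval],
    annotations: Mapping[str, TranscriptAnnotation],
    n_perm: int = 10_000,
    statistic: str = "bp",
    seed: int = 0,
    query_name: str = "query",
    annotation_name: str = "annotation",
) -> EnrichmentResult:
    """Shuffle-based enrichment of a query set over one annotation."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if statistic not in ("bp", "count"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if not annotation_intervals:
        raise ValueError("empty annotation")
    if not query:
        raise ValueError("empty query")
    cov = _AnnotationCoverage(annotation_intervals)
    q_starts = np.asarray([iv.start for iv in query], dtype=np.int64)
    q_ends = np.asarray([iv.end for iv in query], dtype=np.int64)
    q_tids = [iv.transcript_id for iv in query]
    observed = _statistic(cov, q_tids, q_starts, q_ends, statistic)

    ws = _Workspace(annotations)
    rng = np.random.default_rng(seed)
    lens = q_ends - q_starts
    # all permutations in one shot, grouped by target transcript
    n = lens.size
    flat_lens = np.tile(lens, n_perm)
    j, starts = ws.place(flat_lens, rng)
    ends = starts + flat_lens
    perm_idx = np.repeat(np.arange(n_perm), n)
    null = np.zeros(n_perm, dtype=float)
    order = np.argsort(j, kind="stable")
    uniq, first = np.unique(j[order], return_index=True)
    bounds = np.append(first, j.size)
    for u, lo, hi in zip(uniq, bounds[:-1], bounds[1:]):
        idx = order[lo:hi]
        ov = cov.overlaps(ws.tids[int(u)], starts[idx], ends[idx])
        vals = ov.astype(float) if statistic == "bp" else (ov > 0).astype(float)
        np.add.at(null, perm_idx[idx], vals)

    expected = float(null.mean())
    fold = observed / expected if expected > 0 else math.inf
    if expected > 0:
        lo, hi = np.percentile(null / expected, [2.5, 97.5])
    else:
        lo = hi = math.nan
    p_enrich = (1 + int((null >= observed).sum())) / (1 + n_perm)
    p_deplete = (1 + int((null <= observed).sum())) / (1 + n_perm)
    if p_enrich <= p_deplete:
        emp_p, direction = p_enrich, "enrichment"
    else:
        emp_p, direction = p_deplete, "depletion"
    return EnrichmentResult(
        query_name=query_name,
        annotation_name=annotation_name,
        observed=observed,
        expected_mean=expected,
        fold=fold,
        ci95=(float(lo), float(hi)),
        empirical_p=emp_p,
        fdr=math.nan,
        n_permutations=n_perm,
        direction=direction,
    )


def enrichment_panel(
    query: Sequence[Interval],
    panel: Mapping[str, Sequence[Interval]],
    annotations: Mapping[str, TranscriptAnnotation],
    n_perm: int = 10_000,
    statistic: str = "bp",
    seed: int = 0,
    query_name: str = "query",
) -> List[EnrichmentResult]:
    """Enrichment against a named panel of annotations, with BH FDR across it."""
    results = []
    for i, (name, ann_ivs) in enumerate(sorted(panel.items())):
        results.append(
            permutation_enrichment(
                query,
                ann_ivs,
                annotations,
                n_perm=n_perm,
                statistic=statistic,
                seed=seed + i,
                query_name=query_name,
                annotation_name=name,
            )
        )
    q = bh_fdr([r.empirical_p for r in results])
    for r, qi in zip(results, q):
        r.fdr = float(qi)
    return results


def feature_panel(
    annotations: Mapping[str, TranscriptAnnotation]
) -> Dict[str, List[Interval]]:
    """The 5'UTR/CDS/3'UTR interval panel of a workspace."""
    panel: Dict[str, List[Interval]] = {"utr5": [], "cds": [], "utr3": []}
    for ann in annotations.values():
        for feat in panel:
            try:
                panel[feat].append(ann.feature_interval(feat))
            except ValueError:
                continue  # transcript lacks this feature
    return {k: v for k, v in panel.items() if v}


@dataclass
class MultiwayOverlap:
    """Support-depth integration of several peak sets with BG4 peaks."""

    support_at_least: Dict[int, List[Interval]]
    support_exactly: Dict[int, List[Interval]]
    confirmed_per_set: Dict[str, int]
    n_per_set: Dict[str, int]
    bg4_overlap_fraction: Dict[str, float]
    bg4_confirmed_any: int
    n_bg4: int


def multiway_overlap(
    peak_sets: Mapping[str, Sequence[Interval]],
    bg4_peaks: Sequence[Interval],
) -> MultiwayOverlap:
    """Depth-k footprints across peak sets plus BG4 confirmation flags.

    ``support_at_least[k]`` holds the merged regions covered by >= k of the
    peak sets.  A region of a peak set is "BG4-confirmed" when it overlaps
    any BG4 peak by >= 1 bp; ``bg4_overlap_fraction`` reports, per set, the
    fraction of BG4 peaks touching that set.
    """
    if len(peak_sets) < 2:
        raise ValueError("need at least two peak sets")
    from rg4scape.transcriptome import overlap_pairs

    events: Dict[str, List[Tuple[int, int]]] = {}
    for name, ivs in peak_sets.items():
        for iv in merge_intervals(ivs) if ivs else []:
            events.setdefault(iv.transcript_id, []).append((iv.start, +1))
            events[iv.transcript_id].append((iv.end, -1))
    n_sets = len(peak_sets)
    at_least: Dict[int, List[Interval]] = {k: [] for k in range(1, n_sets + 1)}
    for t in sorted(events):
        # depth is piecewise constant between sorted event positions
        ev = sorted(events[t])
        depth = 0
        prev = None
        for pos, delta in ev:
            if prev is not None and pos > prev and depth > 0:
                for k in range(1, min(depth, n_sets) + 1):
                    at_least[k].append(Interval(t, prev, pos))
            depth += delta
            prev = pos
    at_least = {k: merge_intervals(v) if v else [] for k, v in at_least.items()}
    exactly: Dict[int, List[Interval]] = {}
    for k in range(1, n_sets + 1):
        higher = at_least.get(k + 1, [])
        exactly[k] = _subtract(at_least[k], higher)

    confirmed: Dict[str, int] = {}
    n_per: Dict[str, int] = {}
    frac: Dict[str, float] = {}
    bg4_hit_any = np.zeros(len(bg4_peaks), dtype=bool)
    for name, ivs in peak_sets.items():
        ivs = list(ivs)
        n_per[name] = len(ivs)
        pairs = overlap_pairs(ivs, list(bg4_peaks)) if ivs and bg4_peaks else []
        confirmed[name] = len({i for i, _ in pairs})
        hit_bg4 = {j for _, j in pairs}
        for j in hit_bg4:
            bg4_hit_any[j] = True
        frac[name] = len(hit_bg4) / len(bg4_peaks) if bg4_peaks else math.nan
    return MultiwayOverlap(
        support_at_least=at_least,
        support_exactly=exactly,
        confirmed_per_set=confirmed,
        n_per_set=n_per,
        bg4_overlap_fraction=frac,
        bg4_confirmed_any=int(bg4_hit_any.sum()),
        n_bg4=len(bg4_peaks),
    )


def _subtract(a: List[Interval], b: List[Interval]) -> List[Interval]:
    """Set difference a \\ b on merged, sorted interval lists."""
    if not b:
        return list(a)
    b_by_t: Dict[str, List[Tuple[int, int]]] = {}
    for iv in b:
        b_by_t.setdefault(iv.transcript_id, []).append((iv.start, iv.end))
    out: List[Interval] = []
    for iv in a:
        cuts = sorted(b_by_t.get(iv.transcript_id, []))
        pos = iv.start
        for s, e in cuts:
            if e <= pos or s >= iv.end:
                continue
            if s > pos:
                out.append(Interval(iv.transcript_id, pos, s))
            pos = max(pos, e)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(Interval(iv.transcript_id, pos, iv.end))
    return out


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "query": [r.query_name for r in results],
            "annotation": [r.annotation_name for r in results],
            "observed": [r.observed for r in results],
            "expected": [r.expected_mean for r in results],
            "fold": [r.fold for r in results],
            "ci_low": [r.ci95[0] for r in results],
            "ci_high": [r.ci95[1] for r in results],
            "p": [r.empirical_p for r in results],
            "q": [r.fdr for r in results],
            "direction": [r.direction for r in results],
            "n_perm": [r.n_permutations for r in results],
        }
    )
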