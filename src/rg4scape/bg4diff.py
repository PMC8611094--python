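"""BG4 uvRIP differential-enrichment calling against input libraries.

Candidate regions are all bases whose coverage exceeds a CPM threshold in
ANY immunoprecipitation (IP) library, unioned and merged.  Reads are then
counted per region for every library, and each region is tested for
differential abundance (IP vs input) with a negative-binomial exact test
at a common method-of-moments dispersion on library-size-adjusted counts,
followed by Benjamini-Hochberg FDR.  Structure peaks are the regions that
pass the enrichment rule (log2FC > 0.8 and FDR < 0.05) for the G4-specific
antibody BG4 but NOT for the scaffold-matched negative-control antibody A9
— the negative-control filter removes "sticky" regions that any
single-chain antibody pulls down.

Normalisation is total-count scaling to the geometric-mean library size
with a common dispersion: a deliberate simplification of a TMM + tagwise
empirical-Bayes stack, keeping the NB exact test as the inferential core.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from rg4scape.transcriptome import (
    Interval,
    ReadSet,
    TranscriptAnnotation,
    cpm_coverage,
    merge_intervals,
    overlap_pairs,
)

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-6


@dataclass
class RegionCountMatrix:
    """Read counts per candidate region per library.

    ``counts`` is regions x libraries; ``roles`` maps each library column
    to a (role, replicate) pair with role in {"BG4", "A9", "input"}.
    """

    regions: List[Interval]
    counts: np.ndarray
    library_sizes: np.ndarray
    roles: List[Tuple[str, int]]

    def columns(self, role: str) -> List[int]:
        return [i for i, (r, _) in enumerate(self.roles) if r == role]


@dataclass
class DifferentialResult:
    region: Interval
    log2fc: float
    p: float
    fdr: float
    contrast: str
    flagged_zero: bool = False


def candidate_regions(
    ip_readsets: Sequence[ReadSet],
    annotations: Mapping[str, TranscriptAnnotation],
    cpm_threshold: float = 1.0,
) -> List[Interval]:
    """Bases above ``cpm_threshold`` CPM in any IP library, merged to regions."""
    if not ip_readsets:
        raise ValueError("need at least one IP library")
    pieces: List[Interval] = []
    for rs in ip_readsets:
        cov = cpm_coverage(rs, annotations)
        for t in sorted(cov):
            mask = cov[t] > cpm_threshold
            if not mask.any():
                continue
            padded = np.concatenate([[False], mask, [False]])
            edges = np.flatnonzero(padded[1:] != padded[:-1])
            for s, e in edges.reshape(-1, 2):
                pieces.append(Interval(t, int(s), int(e)))
    if not pieces:
        return []
    return merge_intervals(pieces)


def count_region_reads(
    regions: Sequence[Interval],
    readsets: Sequence[ReadSet],
    roles: Sequence[Tuple[str, int]],
) -> RegionCountMatrix:
    """Count reads overlapping (>=1 bp) each region in each library."""
    if len(readsets) != len(roles):
        raise ValueError("readsets and roles differ in length")
    counts = np.zeros((len(regions), len(readsets)), dtype=np.int64)
    for j, rs in enumerate(readsets):
        for i, _ in overlap_pairs(regions, rs.reads):
            counts[i, j] += 1
    return RegionCountMatrix(
        regions=list(regions),
        counts=counts,
        library_sizes=np.asarray([rs.size for rs in readsets], dtype=np.int64),
        roles=list(roles),
    )


def estimate_dispersion(
    matrix: RegionCountMatrix, role_pair: Tuple[str, str]
) -> float:
    """Common NB dispersion (phi, variance = mu + phi mu^2) by moments.

    Counts are scaled to the geometric-mean library size of the involved
    columns first.  Per-region phi estimates from both roles are pooled by
    a count-weighted mean and floored at 1e-6.
    """
    cols = [c for role in role_pair for c in matrix.columns(role)]
    for role in role_pair:
        if len(matrix.columns(role)) < 2:
            raise ValueError(
                f"role {role!r} has < 2 replicates; supply a dispersion explicitly"
            )
    libs = matrix.library_sizes[cols].astype(float)
    geo = math.exp(float(np.mean(np.log(libs))))
    num = 0.0
    den = 0.0
    for role in role_pair:
        rc = matrix.columns(role)
        scaled = matrix.counts[:, rc] * (geo / matrix.library_sizes[rc].astype(float))
        mu = scaled.mean(axis=1)
        var = scaled.var(axis=1, ddof=1)
        ok = mu > 0
        # weight each region's (var - mu)/mu^2 by mu^2 -> pooled ratio
        num += float(np.sum((var[ok] - mu[ok])))
        den += float(np.sum(mu[ok] ** 2))
    phi = num / den if den > 0 else DISPERSION_FLOOR
    if phi <= DISPERSION_FLOOR:
        logger.warning(
            "dispersion estimate %.3g at/below floor %.1g; using floor",
            phi,
            DISPERSION_FLOOR,
        )
        phi = DISPERSION_FLOOR
    return phi


def _conditional_logpmf(
    a: np.ndarray, t: int, n_a: int, n_b: int, phi: float
) -> np.ndarray:
    """log P(Y_A = a | Y_A + Y_B = t) for NB replicate sums at dispersion phi.

    The sum of n i.i.d. NB(r, p) is NB(n r, p); conditioning on the total
    cancels p, leaving a negative hypergeometric-type kernel.  phi -> 0
    recovers Binomial(t, n_a/(n_a+n_b)).
    """
    if phi < 1e-12:
        return stats.binom.logpmf(a, t, n_a / (n_a + n_b))
    r = 1.0 / phi
    la = (
        stats.nbinom.logpmf(a, n_a * r, 0.5)
        + stats.nbinom.logpmf(t - a, n_b * r, 0.5)
    )
    norm = logsumexp_stable(la)
    return la - norm


def logsumexp_stable(x: np.ndarray) -> float:
    m = float(np.max(x))
    return m + math.log(float(np.sum(np.exp(x - m))))


def nb_exact_test(
    matrix: RegionCountMatrix,
    region_index: int,
    contrast: Tuple[str, str],
    dispersion: float,
    pseudocount: float = 0.5,
) -> DifferentialResult:
    """Exact NB test of role A vs role B for one region.

    Counts are scaled to the geometric-mean library size and rounded; the
    two-sided p sums all conditional outcomes with probability <= that of
    the observed A-sum (the "minlike" rule, matching the exact binomial
    test in the zero-dispersion equal-library limit).  log2FC is computed
    on mean CPM with a pseudocount.
    """
    role_a, role_b = contrast
    ca, cb = matrix.columns(role_a), matrix.columns(role_b)
    if not ca or not cb:
        raise ValueError(f"contrast {contrast} has an empty side")
    raw = matrix.counts[region_index]
    libs = matrix.library_sizes.astype(float)

    cpm_a = float(np.mean(raw[ca] / libs[ca])) * 1e6
    cpm_b = float(np.mean(raw[cb] / libs[cb])) * 1e6
    log2fc = math.log2((cpm_a + pseudocount) / (cpm_b + pseudocount))

    cols = ca + cb
    geo = math.exp(float(np.mean(np.log(libs[cols]))))
    scaled = np.rint(raw[cols] * (geo / libs[cols])).astype(np.int64)
    ya = int(scaled[: len(ca)].sum())
    yb = int(scaled[len(ca) :].sum())
    total = ya + yb
    name = f"{role_a}-vs-{role_b}"
    if total == 0:
        return DifferentialResult(
            region=matrix.regions[region_index],
            log2fc=0.0,
            p=1.0,
            fdr=1.0,
            contrast=name,
            flagged_zero=True,
        )
    support = np.arange(total + 1)
    logp = _conditional_logpmf(support, total, len(ca), len(cb), dispersion)
    obs = logp[ya]
    # sum of all outcomes no more likely than observed (with fp slack)
    p = float(np.exp(logp[logp <= obs + 1e-10]).sum())
    return DifferentialResult(
        region=matrix.regions[region_index],
        log2fc=log2fc,
        p=min(p, 1.0),
        fdr=float("nan"),
        contrast=name,
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_exact_tests(
    matrix: RegionCountMatrix,
    contrast: Tuple[str, str],
    dispersion: Optional[float] = None,
) -> List[DifferentialResult]:
    """NB exact test for every region, with BH FDR across regions."""
    if dispersion is None:
        dispersion = estimate_dispersion(matrix, contrast)
    results = [
        nb_exact_test(matrix, i, contrast, dispersion)
        for i in range(len(matrix.regions))
    ]
    q = bh_fdr([r.p for r in results])
    for r, qi in zip(results, q):
        r.fdr = float(qi)
    return results


def call_structure_peaks(
    bg4_results: Sequence[DifferentialResult],
    a9_results: Sequence[DifferentialResult],
    lfc_min: float = 0.8,
    fdr_max: float = 0.05,
) -> List[Interval]:
    """Regions enriched by BG4 (log2FC > lfc_min, FDR < fdr_max) but not A9.

    Both thresholds are strict inequalities.  A region passing the same
    rule in the negative-control contrast is excluded.
    """
    if len(bg4_results) != len(a9_results) or any(
        b.region != a.region for b, a in zip(bg4_results, a9_results)
    ):
        raise ValueError("BG4 and A9 results must cover identical region sets")

    def passes(r: DifferentialResult) -> bool:
        return r.log2fc > lfc_min and r.fdr < fdr_max

    return [
        b.region
        for b, a in zip(bg4_results, a9_results)
        if passes(b) and not passes(a)
    ]


def results_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    """Tabular view of differential results (one row per region)."""
    return pd.DataFrame(
        {
            "transcript_id": [r.region.transcript_id for r in results],
            "start": [r.region.start for r in results],
            "end": [r.region.end for r in results],
            "log2fc": [r.log2fc for r in results],
            "p": [r.p for r in results],
            "fdr": [r.fdr for r in results],
            "contrast": [r.contrast for r in results],
        }
    )
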