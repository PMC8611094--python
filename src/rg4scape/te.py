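"""Translational efficiency (TE) from polysome/total RNA-seq counts.

TE of a transcript in one replicate of one condition is the ratio of its
CPM in the polysome fraction to its CPM in total lysate (pseudocount
guarded), so changes in transcript abundance cancel and only the ribosome
load moves the ratio.  Differential TE between conditions pairs replicates
by index, takes per-replicate Delta = log2(TE_treated / TE_control), and
tests the Deltas against zero with a one-sample t-test, BH-corrected
across transcripts; an unpaired Welch mode on log2 TE is available when
replicate structures differ.

Two gene-set views of the result are provided: a weighted running-sum
enrichment score (GSEA-style, gene-label permutation null, sign-matched
NES normalisation) over the logFC-TE ranking, and a hypergeometric
over-representation test of a label among the significant transcripts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from rg4scape.bg4diff import bh_fdr


@dataclass
class TECounts:
    """Raw counts per transcript for fraction x condition x replicate.

    ``counts[(fraction, condition, replicate)]`` is a pandas Series indexed
    by transcript_id; all series share one index.  Library sizes default to
    column sums.
    """

    counts: Dict[Tuple[str, str, int], pd.Series]
    library_sizes: Optional[Dict[Tuple[str, str, int], int]] = None

    def __post_init__(self) -> None:
        keys = list(self.counts)
        if not keys:
            raise ValueError("empty count set")
        idx = self.counts[keys[0]].index
        for k in keys:
            if not self.counts[k].index.equals(idx):
                raise ValueError("count columns must share one transcript index")
            if (self.counts[k] < 0).any():
                raise ValueError(f"negative counts in column {k}")
        if self.library_sizes is None:
            self.library_sizes = {k: int(v.sum()) for k, v in self.counts.items()}

    @property
    def transcripts(self) -> pd.Index:
        return self.counts[next(iter(self.counts))].index

    def replicates(self, condition: str) -> List[int]:
        reps = sorted(
            {r for (f, c, r) in self.counts if c == condition and f == "polysome"}
        )
        return reps

    def cpm(self, fraction: str, condition: str, replicate: int) -> pd.Series:
        key = (fraction, condition, replicate)
        n = self.library_sizes[key]
        if n <= 0:
            raise ValueError(f"library {key} has size {n}")
        return self.counts[key] * (1e6 / n)


@dataclass
class TEResult:
    transcript_id: str
    logfc_te: float
    p: float
    fdr: float
    te_control: float  # replicate-mean TE
    te_treated: float


@dataclass
class GeneSetResult:
    set_name: str
    es: float
    nes: float
    p: float
    fdr: float
    direction: int
    n_permutations: int


def translational_efficiency(
    counts: TECounts, condition: str, replicate: int, pseudocount: float = 0.5
) -> pd.Series:
    """TE = (CPM_polysome + c) / (CPM_total + c) per transcript."""
    cpm_p = counts.cpm("polysome", condition, replicate)
    cpm_t = counts.cpm("total", condition, replicate)
    return (cpm_p + pseudocount) / (cpm_t + pseudocount)


def differential_te(
    counts: TECounts,
    control: str = "control",
    treated: str = "treated",
    pseudocount: float = 0.5,
    min_cpm: float = 1.0,
    paired: bool = True,
) -> List[TEResult]:
    """Per-transcript log2 fold change in TE with t-test p and BH FDR.

    Transcripts whose total-fraction CPM stays below ``min_cpm`` in every
    library are excluded before testing.  Paired mode (default) matches
    replicates by index; unpaired mode runs Welch's t on log2 TE.
    """
    reps_c = counts.replicates(control)
    reps_t = counts.replicates(treated)
    if paired and reps_c != reps_t:
        raise ValueError(
            "paired mode needs matching replicate indices; use paired=False "
            "(Welch on log2 TE) for unpaired designs"
        )
    if min(len(reps_c), len(reps_t)) < 2:
        raise ValueError("need >= 2 replicates per condition")

    total_cpms = pd.concat(
        [
            counts.cpm("total", cond, r)
            for cond, reps in ((control, reps_c), (treated, reps_t))
            for r in reps
        ],
        axis=1,
    )
    expressed = (total_cpms >= min_cpm).any(axis=1)

    te_c = pd.concat(
        [translational_efficiency(counts, control, r, pseudocount) for r in reps_c],
        axis=1,
    )
    te_t = pd.concat(
        [translational_efficiency(counts, treated, r, pseudocount) for r in reps_t],
        axis=1,
    )
    te_c, te_t = te_c[expressed], te_t[expressed]

    results: List[TEResult] = []
    if paired:
        delta = np.log2(te_t.to_numpy() / te_c.to_numpy())
        logfc = delta.mean(axis=1)
        sd = delta.std(axis=1, ddof=1)
        n = delta.shape[1]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = logfc / (sd / math.sqrt(n))
        p = 2 * stats.t.sf(np.abs(tstat), df=n - 1)
        p = np.where(sd == 0, 1.0, p)  # zero-variance rule
    else:
        la, lb = np.log2(te_t.to_numpy()), np.log2(te_c.to_numpy())
        logfc = la.mean(axis=1) - lb.mean(axis=1)
        t_res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        p = np.where(np.isnan(t_res.pvalue), 1.0, t_res.pvalue)
    q = bh_fdr(np.clip(p, 0, 1))
    for i, tid in enumerate(te_c.index):
        results.append(
            TEResult(
                transcript_id=str(tid),
                logfc_te=float(logfc[i]),
                p=float(p[i]),
                fdr=float(q[i]),
                te_control=float(te_c.iloc[i].mean()),
                te_treated=float(te_t.iloc[i].mean()),
            )
        )
    return results


def running_enrichment_score(
    scores: pd.Series, members: Set[str], weight: float = 1.0
) -> float:
    """Signed maximum deviation of the weighted KS running sum.

    ``scores`` must be sorted descending.  Hits increment in proportion to
    |score|^weight (normalised over set hits); misses decrement 1/(N - m).
    """
    is_hit = scores.index.isin(members)
    m = int(is_hit.sum())
    n = scores.size
    if m == 0 or m == n:
        raise ValueError("gene set must be a proper nonempty subset of the ranking")
    w = np.abs(scores.to_numpy()) ** weight
    hit_w = np.where(is_hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = is_hit.astype(float)
        denom = float(m)
    running = np.cumsum(hit_w / denom - (~is_hit) / (n - m))
    return float(running[np.argmax(np.abs(running))])


def gene_set_running_score(
    logfc: Mapping[str, float],
    gene_set: Set[str],
    set_name: str = "set",
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GeneSetResult:
    """GSEA-style enrichment of a gene set over the logFC-TE ranking.

    The null permutes gene labels (|set| genes drawn at random) — a sample
    permutation null is not identifiable at 3 replicates.  NES = ES divided
    by the mean |null ES| of matching sign; the empirical p carries the +1
    correction against the same-sign null pool.
    """
    series = pd.Series(logfc, dtype=float)
    missing = sorted(set(gene_set) - set(series.index))
    if missing:
        raise ValueError(f"gene set members absent from ranking: {missing[:5]}...")
    if len(gene_set) < 5:
        raise ValueError("gene set must have >= 5 members")
    ranked = series.sort_values(ascending=False, kind="stable")
    es = running_enrichment_score(ranked, gene_set, weight)

    rng = np.random.default_rng(seed)
    ids = np.asarray(ranked.index)
    m = len(set(gene_set) & set(series.index))
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = set(rng.choice(ids, size=m, replace=False))
        null[i] = running_enrichment_score(ranked, perm, weight)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same_sign.size == 0:
        same_sign = np.asarray([es])
    nes = es / float(np.mean(np.abs(same_sign)))
    p = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (1 + same_sign.size)
    return GeneSetResult(
        set_name=set_name,
        es=es,
        nes=nes,
        p=p,
        fdr=p,  # single set: FDR = p; panels BH-correct externally
        direction=int(np.sign(es)) if es != 0 else 0,
        n_permutations=n_perm,
    )


def hypergeometric_test(
    significant: Set[str],
    labeled: Set[str],
    universe: Set[str],
    bonferroni_panels: int = 1,
) -> float:
    """Upper-tail hypergeometric p of label over-representation.

    P(overlap >= observed) drawing |significant| transcripts from the
    universe containing |labeled| labelled ones; optional Bonferroni
    factor for multi-label panels.
    """
    if not universe:
        raise ValueError("empty universe")
    if not significant <= universe or not labeled <= universe:
        raise ValueError("significant and labeled sets must be within the universe")
    n_univ = len(universe)
    n_lab = len(labeled)
    n_sig = len(significant)
    k = len(significant & labeled)
    if k == 0:
        p = 1.0 - stats.hypergeom.cdf(-1, n_univ, n_lab, n_sig)  # = 1
    else:
        p = float(stats.hypergeom.sf(k - 1, n_univ, n_lab, n_sig))
    return min(1.0, p * bonferroni_panels)


def results_frame(results: Sequence[TEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in results],
            "logfc_te": [r.logfc_te for r in results],
            "p": [r.p for r in results],
            "fdr": [r.fdr for r in results],
            "te_control": [r.te_control for r in results],
            "te_treated": [r.te_treated for r in results],
        }
    )
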