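"""ZTNB peak calling: fit oracles, tail probabilities, consensus rules."""

import logging
import math

import numpy as np
import pytest
from scipy import stats

from rg4scape.peakcall import (
    BinCounts,
    Peak,
    ZTNBFit,
    bin_read_starts,
    call_peaks,
    consensus_peaks,
    fit_background,
    fit_ztnb,
    ztnb_upper_tail,
)
from rg4scape.transcriptome import Interval, ReadSet


def make_counts(values, bin_size=30):
    counts = {("T1", i): int(v) for i, v in enumerate(values)}
    return BinCounts(bin_size=bin_size, counts=counts, library_size=int(sum(values)))


def ztnb_nll_direct(mu, r, sample):
    """Independent ZTNB negative log-likelihood (direct pmf arithmetic)."""
    k, w = np.unique(sample, return_counts=True)
    p = r / (r + mu)
    p0 = stats.nbinom.pmf(0, r, p)
    return -np.dot(w, stats.nbinom.logpmf(k, r, p) - math.log1p(-p0))


def grid_search(sample, mu_range, r_range, step):
    best = (None, None, np.inf)
    for mu in np.arange(*mu_range, step):
        for r in np.arange(*r_range, step):
            nll = ztnb_nll_direct(mu, r, sample)
            if nll < best[2]:
                best = (mu, r, nll)
    return best


class TestBinning:
    def test_all_starts_in_first_bin(self):
        rs = ReadSet("l", 1, "x", [Interval("T1", i, i + 30) for i in range(10)])
        counts = bin_read_starts(rs, bin_size=30)
        assert counts.counts == {("T1", 0): 10}

    def test_half_open_bin_boundary(self):
        rs = ReadSet("l", 1, "x", [Interval("T1", 30, 60)])
        assert bin_read_starts(rs, bin_size=30).counts == {("T1", 1): 1}

    def test_matches_brute_force_histogram(self, rng, toy_annotation):
        reads = []
        for _ in range(2000):
            t = ["T1", "T2"][rng.integers(2)]
            s = int(rng.integers(0, toy_annotation[t].length - 1))
            reads.append(Interval(t, s, s + 1))
        rs = ReadSet("l", 1, "x", reads)
        counts = bin_read_starts(rs, bin_size=25)
        brute = {}
        for r in reads:
            key = (r.transcript_id, r.start // 25)
            brute[key] = brute.get(key, 0) + 1
        assert counts.counts == brute
        assert sum(counts.counts.values()) == rs.size


class TestZTNBFit:
    def test_matches_grid_search_oracle(self):
        # heavy-tailed decaying histogram: constrained MLE pins the
        # dispersion at its lower box bound
        sample = np.repeat([1, 1, 1, 1, 2, 2, 3, 5, 9, 14], 20)
        fit = fit_ztnb(make_counts(sample))
        # coarse-to-fine grid search with an independent likelihood,
        # over the same dispersion box as the fit
        mu, r = 2.0, 2.0
        for step, half in ((0.1, 2.0), (0.01, 0.2), (1e-4, 0.02)):
            mu, r, _ = grid_search(
                sample,
                (max(mu - half, step), mu + half),
                (max(r - half, 0.01), r + half),
                step,
            )
        assert fit.mean == pytest.approx(mu, abs=1e-3)
        assert fit.dispersion == pytest.approx(r, abs=1e-3)

    def test_matches_grid_search_oracle_interior(self):
        # well-behaved overdispersed histogram with an interior optimum
        rng = np.random.default_rng(5)
        draws = rng.negative_binomial(2.0, 2.0 / (2.0 + 6.0), size=4000)
        sample = draws[draws >= 1]
        fit = fit_ztnb(make_counts(sample))
        mu, r = 6.0, 2.0
        for step, half in ((0.1, 3.0), (0.01, 0.2), (1e-4, 0.02)):
            mu, r, _ = grid_search(
                sample,
                (max(mu - half, step), mu + half),
                (max(r - half, 0.01), r + half),
                step,
            )
        assert fit.mean == pytest.approx(mu, abs=1e-3)
        assert fit.dispersion == pytest.approx(r, abs=1e-3)

    def test_parameter_recovery_from_ztnb_samples(self):
        rng = np.random.default_rng(0)
        mu, r = 2.0, 0.5
        p = r / (r + mu)
        draws = rng.negative_binomial(r, p, size=60_000)
        sample = draws[draws >= 1][:10_000]
        fit = fit_ztnb(make_counts(sample))
        assert 1.9 <= fit.mean <= 2.1
        assert 0.4 <= fit.dispersion <= 0.6

    def test_poisson_like_data_hits_dispersion_bound_with_warning(self, caplog):
        # under-dispersed (var < mean) counts: no finite NB dispersion fits,
        # so the estimate must pin the upper (Poisson-limit) bound
        rng = np.random.default_rng(1)
        sample = rng.binomial(50, 0.1, size=5000)
        sample = sample[sample >= 1]
        assert sample.var() < sample.mean()
        with caplog.at_level(logging.WARNING, logger="rg4scape.peakcall"):
            fit = fit_ztnb(make_counts(sample))
        assert fit.dispersion == pytest.approx(1e6)
        assert any("upper bound" in rec.message for rec in caplog.records)

    def test_degenerate_all_equal_rejected(self):
        with pytest.raises(ValueError, match="overdispersion"):
            fit_ztnb(make_counts([3] * 100))

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            fit_ztnb(make_counts([1, 2, 3]))


class TestUpperTail:
    def test_k_one_is_certain(self):
        fit = ZTNBFit(mean=3.0, dispersion=0.7, loglik=0.0, n_bins_used=100)
        assert ztnb_upper_tail(fit, 1) == pytest.approx(1.0)

    def test_matches_direct_pmf_summation(self):
        fit = ZTNBFit(mean=4.2, dispersion=1.3, loglik=0.0, n_bins_used=100)
        p = fit.dispersion / (fit.dispersion + fit.mean)
        p0 = stats.nbinom.pmf(0, fit.dispersion, p)
        for k in (1, 2, 3, 7, 15, 40):
            # direct summation of P(X >= k)/P(X >= 1) with a far tail bound
            upper = np.arange(k, 4000)
            direct = stats.nbinom.pmf(upper, fit.dispersion, p).sum() / (1 - p0)
            assert ztnb_upper_tail(fit, k) == pytest.approx(direct, rel=1e-10)

    def test_monotone_and_vanishing(self):
        fit = ZTNBFit(mean=4.2, dispersion=1.3, loglik=0.0, n_bins_used=100)
        vals = [ztnb_upper_tail(fit, k) for k in range(1, 200)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-12

    def test_k_below_support_rejected(self):
        fit = ZTNBFit(mean=4.2, dispersion=1.3, loglik=0.0, n_bins_used=100)
        with pytest.raises(ValueError):
            ztnb_upper_tail(fit, 0)


class TestCallPeaks:
    def background(self, rng, n_bins=2000, mean=5.0):
        vals = rng.poisson(mean, size=n_bins)
        return {("T1", i): int(v) for i, v in enumerate(vals) if v > 0}

    def test_planted_spike_yields_exactly_one_peak(self, rng):
        counts_map = self.background(rng)
        counts_map[("T1", 1000)] = 500  # 100x background
        counts = BinCounts(30, counts_map, sum(counts_map.values()))
        fit = fit_background(counts)
        peaks = call_peaks(counts, fit)
        assert len(peaks) == 1
        assert peaks[0].interval.start <= 1000 * 30 < peaks[0].interval.end

    def test_gap_merge_rule(self, rng):
        counts_map = self.background(rng)
        counts_map[("T1", 1000)] = 500
        counts_map[("T1", 1002)] = 500  # one insignificant bin between
        counts = BinCounts(30, counts_map, sum(counts_map.values()))
        fit = fit_background(counts)
        assert len(call_peaks(counts, fit, merge_gap_bins=1)) == 1
        assert len(call_peaks(counts, fit, merge_gap_bins=0)) == 2

    def test_calling_is_monotone_in_cutoff(self, rng):
        counts_map = self.background(rng, mean=8.0)
        for b in (100, 500, 900):
            counts_map[("T1", b)] = 120
        counts = BinCounts(30, counts_map, sum(counts_map.values()))
        fit = fit_background(counts)
        strict = call_peaks(counts, fit, p_cutoff=1e-6)
        loose = call_peaks(counts, fit, p_cutoff=1e-3)
        strict_cov = {
            (p.interval.start, p.interval.end) for p in strict
        }
        for s in strict_cov:
            assert any(
                q.interval.start <= s[0] and q.interval.end >= s[1] for q in loose
            )


class TestConsensus:
    def peak(self, t, s, e):
        return Peak(interval=Interval(t, s, e), min_p=1e-6, total_count=10)

    def test_identical_peak_in_all_replicates(self):
        sets = [[self.peak("T1", 100, 160)] for _ in range(3)]
        (c,) = consensus_peaks(sets, min_replicates=2)
        assert (c.interval.start, c.interval.end) == (100, 160)
        assert c.replicate_support == {0, 1, 2}

    def test_single_replicate_peak_never_in_consensus(self):
        sets = [[self.peak("T1", 100, 160)], [], []]
        assert consensus_peaks(sets, min_replicates=2) == []

    def test_staggered_peaks_match_depth_oracle(self, rng, toy_annotation):
        from conftest import random_intervals

        sets = []
        for _ in range(3):
            sets.append(
                [
                    Peak(interval=iv, min_p=1e-6, total_count=1)
                    for iv in random_intervals(rng, toy_annotation, 60)
                ]
            )
        for minrep in (1, 2, 3):
            cons = consensus_peaks(sets, min_replicates=minrep)
            # per-base depth oracle: count replicates covering each base
            got = set()
            for c in cons:
                got.update(
                    (c.interval.transcript_id, b)
                    for b in range(c.interval.start, c.interval.end)
                )
            expected = set()
            for t, ann in toy_annotation.items():
                for b in range(ann.length):
                    depth = sum(
                        1
                        for peaks in sets
                        if any(
                            p.interval.transcript_id == t
                            and p.interval.start <= b < p.interval.end
                            for p in peaks
                        )
                    )
                    if depth >= minrep:
                        expected.add((t, b))
            assert got == expected

    def test_union_and_intersection_limits(self):
        sets = [
            [self.peak("T1", 0, 50)],
            [self.peak("T1", 30, 80)],
            [self.peak("T1", 40, 60)],
        ]
        union = consensus_peaks(sets, min_replicates=1)
        assert [(c.interval.start, c.interval.end) for c in union] == [(0, 80)]
        inter = consensus_peaks(sets, min_replicates=3)
        assert [(c.interval.start, c.interval.end) for c in inter] == [(40, 50)]

    def test_min_replicates_exceeding_sets_rejected(self):
        with pytest.raises(ValueError):
            consensus_peaks([[self.peak("T1", 0, 10)]], min_replicates=2)
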