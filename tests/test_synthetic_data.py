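"""Generator: determinism, planted-signal structure, truth round trips."""

import numpy as np
import pytest

from rg4scape.g4scan import scan_sequences
from rg4scape.synthetic_data import (
    ProteinProfile,
    SimulationConfig,
    emit_truth,
    generate_transcriptome,
    load_truth,
    simulate_bg4_experiment,
    simulate_polysome_counts,
    simulate_protein_reads,
)
from rg4scape.transcriptome import overlap_pairs


class TestGenerateTranscriptome:
    def test_identical_seed_gives_identical_output(self):
        a = generate_transcriptome(SimulationConfig(seed=42, n_transcripts=40, rp_set_size=8))
        b = generate_transcriptome(SimulationConfig(seed=42, n_transcripts=40, rp_set_size=8))
        assert a[0] == b[0]  # sequences byte-identical
        assert [m.interval for m in a[2].motifs] == [m.interval for m in b[2].motifs]
        c = generate_transcriptome(SimulationConfig(seed=43, n_transcripts=40, rp_set_size=8))
        assert a[0] != c[0]

    def test_sequences_match_annotation_lengths(self, default_sim):
        _, sequences, annotations, _ = default_sim
        for t, seq in sequences.items():
            assert len(seq) == annotations[t].length

    def test_forced_utr5_planting_rate_one(self):
        cfg = SimulationConfig(
            seed=3,
            n_transcripts=30,
            rp_set_size=0,
            plant_rates={("utr5", "three"): 1.0},
        )
        _, _, truth = generate_transcriptome(cfg)
        with_motif = {m.interval.transcript_id for m in truth.motifs}
        assert len(with_motif) == 30
        assert all(m.feature == "utr5" for m in truth.motifs)

    def test_scanner_recovers_planted_spans_exactly(self, default_sim):
        _, sequences, _, truth = default_sim
        found = {
            (m.tetrad_class, m.interval.transcript_id, m.interval.start,
             m.interval.end)
            for m in scan_sequences(sequences)
        }
        for m in truth.motifs:
            key = (
                m.tetrad_class,
                m.interval.transcript_id,
                m.interval.start,
                m.interval.end,
            )
            assert key in found

    def test_rp_transcripts_start_with_pyrimidine_tract_then_utr5_motif(
        self, default_sim
    ):
        cfg, sequences, annotations, truth = default_sim
        rp = truth.gene_sets[cfg.rp_label]
        assert len(rp) == cfg.rp_set_size
        for t in rp:
            assert set(sequences[t][:8]) <= set("CU")
            has_utr5_three = any(
                m.interval.transcript_id == t
                and m.tetrad_class == "three"
                and m.feature == "utr5"
                for m in truth.motifs
            )
            assert has_utr5_three

    def test_truth_intervals_lie_within_transcripts(self, default_sim):
        _, _, annotations, truth = default_sim
        for m in truth.motifs:
            assert m.interval.end <= annotations[m.interval.transcript_id].length
        for d in truth.decoys:
            assert d.end <= annotations[d.transcript_id].length

    def test_infeasible_planting_is_an_error(self):
        with pytest.raises(ValueError, match="cannot hold"):
            SimulationConfig(seed=0, utr5_range=(10, 20))


class TestProteinReads:
    def test_library_size_exactly_as_configured(self, default_sim):
        cfg, _, annotations, truth = default_sim
        rs = simulate_protein_reads(cfg, truth, annotations, "centred", 1)
        assert rs.size == cfg.reads_per_library

    def test_unknown_protein_rejected(self, default_sim):
        cfg, _, annotations, truth = default_sim
        with pytest.raises(KeyError):
            simulate_protein_reads(cfg, truth, annotations, "nosuch", 1)

    def test_offset_mean_recovered_at_bound_sites(self, default_sim):
        cfg, _, annotations, truth = default_sim
        rs = simulate_protein_reads(cfg, truth, annotations, "helicase_3p", 1)
        starts = rs.starts_by_transcript()
        deltas = []
        for i in truth.protein_sites["helicase_3p"]:
            m = truth.motifs[i]
            pos = starts.get(m.interval.transcript_id)
            if pos is None:
                continue
            mid = m.interval.midpoint
            near = pos[(pos >= mid - 40) & (pos <= mid + 40)]
            deltas.extend(near - mid)
        assert 10 <= np.mean(deltas) <= 20

    def test_enrichment_one_is_indistinguishable_from_background(self):
        from scipy import stats

        cfg = SimulationConfig(
            seed=8,
            abundance_sigma=0.0,
            protein_profiles={"null": ProteinProfile(1.0, 0.0, 8.0)},
        )
        _, annotations, truth = generate_transcriptome(cfg)[1], None, None
        sequences, annotations, truth = generate_transcriptome(cfg)
        rs = simulate_protein_reads(cfg, truth, annotations, "null", 1)
        assert sum(rs.site_counts.values()) == 0
        starts = rs.starts_by_transcript()
        # chi-square of read counts at bound-site windows vs matched windows
        obs, exp = [], []
        for i in truth.protein_sites["null"]:
            m = truth.motifs[i]
            pos = starts.get(m.interval.transcript_id, np.array([]))
            mid = m.interval.midpoint
            obs.append(((pos >= mid - 15) & (pos < mid + 15)).sum())
            exp.append(((pos >= mid + 25) & (pos < mid + 55)).sum())
        total = sum(obs) + sum(exp)
        chi = stats.chisquare([sum(obs), sum(exp)], [total / 2, total / 2])
        assert chi.pvalue > 0.01

    def test_replicate_site_counts_highly_correlated(self, default_sim):
        cfg, _, annotations, truth = default_sim
        r1 = simulate_protein_reads(cfg, truth, annotations, "centred", 1)
        r2 = simulate_protein_reads(cfg, truth, annotations, "centred", 2)
        sites = truth.protein_sites["centred"]
        c1 = np.array([r1.site_counts[i] for i in sites])
        c2 = np.array([r2.site_counts[i] for i in sites])
        assert not np.array_equal(c1, c2)  # different draws
        assert np.corrcoef(c1, c2)[0, 1] > 0.9


class TestBG4Experiment:
    @staticmethod
    @pytest.fixture(scope="class")
    def experiment():
        cfg = SimulationConfig(seed=31)
        sequences, annotations, truth = generate_transcriptome(cfg)
        libs = simulate_bg4_experiment(cfg, truth, annotations)
        return cfg, annotations, truth, libs

    def test_library_sizes_exact_and_roles_complete(self, experiment):
        cfg, _, _, libs = experiment
        assert set(libs) == {"BG4", "A9", "input"}
        for role in libs:
            assert len(libs[role]) == cfg.replicates
            for rs in libs[role]:
                assert rs.size == cfg.reads_per_library

    def test_ip_input_ratio_near_enrichment_at_folded_motifs(self, experiment):
        cfg, annotations, truth, libs = experiment
        from rg4scape.bg4diff import count_region_reads

        roles = [(rs.condition, rs.replicate) for rs in libs["BG4"] + libs["input"]]
        m = count_region_reads(truth.bg4_regions, libs["BG4"] + libs["input"], roles)
        b = m.counts[:, m.columns("BG4")].sum(axis=1).astype(float)
        i = m.counts[:, m.columns("input")].sum(axis=1).astype(float)
        ratio = (b[i > 0] / i[i > 0]).mean()
        assert 3.0 <= ratio <= 5.0

    def test_unfolded_motifs_not_enriched(self, experiment):
        cfg, annotations, truth, libs = experiment
        from rg4scape.bg4diff import count_region_reads

        unfolded = [m.interval for m in truth.motifs if not m.folded]
        roles = [(rs.condition, rs.replicate) for rs in libs["BG4"] + libs["input"]]
        m = count_region_reads(unfolded, libs["BG4"] + libs["input"], roles)
        b = m.counts[:, m.columns("BG4")].sum()
        i = m.counts[:, m.columns("input")].sum()
        assert 0.7 <= b / i <= 1.3

    def test_decoys_enriched_in_both_antibodies(self, experiment):
        cfg, annotations, truth, libs = experiment
        from rg4scape.bg4diff import count_region_reads

        readsets = libs["BG4"] + libs["A9"] + libs["input"]
        roles = [(rs.condition, rs.replicate) for rs in readsets]
        m = count_region_reads(truth.decoys, readsets, roles)
        i = m.counts[:, m.columns("input")].sum()
        for role in ("BG4", "A9"):
            ratio = m.counts[:, m.columns(role)].sum() / i
            assert ratio > 2.0


class TestPolysomeCounts:
    def test_total_means_unchanged_between_conditions(self, default_sim):
        cfg, _, annotations, truth = default_sim
        tc = simulate_polysome_counts(cfg, truth, annotations)
        tot_c = sum(tc.counts[("total", "control", r)] for r in (1, 2, 3))
        tot_t = sum(tc.counts[("total", "treated", r)] for r in (1, 2, 3))
        # identical NB means: totals agree within sampling error
        assert abs(tot_c.sum() - tot_t.sum()) / tot_c.sum() < 0.01

    def test_planted_effect_only_in_treated_polysome_of_labeled_set(
        self, default_sim
    ):
        cfg, _, annotations, truth = default_sim
        tc = simulate_polysome_counts(cfg, truth, annotations)
        rp = truth.gene_sets[cfg.rp_label]
        pol_c = sum(tc.counts[("polysome", "control", r)] for r in (1, 2, 3))
        pol_t = sum(tc.counts[("polysome", "treated", r)] for r in (1, 2, 3))
        in_rp = pol_t[pol_t.index.isin(rp)].sum() / pol_c[pol_c.index.isin(rp)].sum()
        out_rp = (
            pol_t[~pol_t.index.isin(rp)].sum() / pol_c[~pol_c.index.isin(rp)].sum()
        )
        assert in_rp == pytest.approx(2 ** cfg.te_effect_log2, rel=0.05)
        assert out_rp == pytest.approx(1.0, rel=0.02)


class TestTruthSerialisation:
    def test_round_trip_is_lossless(self, default_sim, tmp_path):
        _, _, _, truth = default_sim
        emit_truth(truth, tmp_path)
        back = load_truth(tmp_path)
        assert [m.interval for m in back.motifs] == [
            m.interval for m in truth.motifs
        ]
        assert [m.folded for m in back.motifs] == [m.folded for m in truth.motifs]
        assert back.protein_sites == truth.protein_sites
        assert back.decoys == truth.decoys
        assert back.te_logfc == truth.te_logfc
        assert back.gene_sets == truth.gene_sets
        assert back.abundance == truth.abundance

    def test_emitted_files_byte_identical_across_runs(self, tmp_path):
        cfg = SimulationConfig(seed=77, n_transcripts=40, rp_set_size=8)
        for sub in ("a", "b"):
            _, _, truth = generate_transcriptome(cfg)
            emit_truth(truth, tmp_path / sub)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_truth_motifs_validate_against_annotation(self, default_sim, tmp_path):
        _, _, annotations, truth = default_sim
        emit_truth(truth, tmp_path)
        back = load_truth(tmp_path)
        for m in back.motifs:
            ann = annotations[m.interval.transcript_id]
            assert 0 <= m.interval.start < m.interval.end <= ann.length


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            ({"gc_content": 1.5}, "gc_content"),
            ({"folded_fraction": -0.1}, "folded_fraction"),
            ({"bg4_enrichment": 0.5}, "bg4_enrichment"),
            ({"reads_per_library": 10}, "reads_per_library"),
            ({"rp_set_size": 1000}, "rp_set_size"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            SimulationConfig(seed=0, **kwargs)
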