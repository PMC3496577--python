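import numpy as np
import pytest

from rhpanel.io import ABSENT, PRESENT, UNKNOWN
from rhpanel.simulate import (
    Chromosome,
    ParameterError,
    QPCRSimConfig,
    SimConfig,
    apply_retention,
    fragments_from_breakpoints,
    make_chimeric_scaffolds,
    markers_at,
    simulate_fragments,
    simulate_panel,
    simulate_qpcr,
)

MICRO = Chromosome("c1", 7.0, "micro")


class TestFragments:
    def test_poisson_mean(self):
        # expected breaks = rate * length = 0.2 * 50 = 10
        rng = np.random.default_rng(0)
        counts = [len(simulate_fragments(50.0, 0.2, rng)) for _ in range(10_000)]
        se = np.sqrt(10.0 / 10_000)
        assert abs(np.mean(counts) - 10.0) < 3 * se

    def test_vanishing_rate_gives_single_fragment(self):
        rng = np.random.default_rng(1)
        bps = simulate_fragments(50.0, 1e-9, rng)
        assert len(bps) == 0
        assert fragments_from_breakpoints(bps, 50.0) == [(0.0, 50.0)]

    def test_separation_frequency_matches_closed_form(self):
        # two loci x apart are separated with probability 1 - exp(-rate x)
        rate, x, length = 0.35, 2.0, 10.0
        rng = np.random.default_rng(2)
        n, sep = 20_000, 0
        for _ in range(n):
            bps = simulate_fragments(length, rate, rng)
            sep += int(np.any((bps > 4.0) & (bps < 4.0 + x)))
        p = 1.0 - np.exp(-rate * x)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(sep / n - p) < 3 * se

    def test_invalid_parameters(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ParameterError):
            simulate_fragments(-1.0, 0.2, rng)
        with pytest.raises(ParameterError):
            simulate_fragments(10.0, 0.0, rng)


class TestRetention:
    def test_boundary_rates(self):
        frags = [(0.0, 2.0), (2.0, 5.0), (5.0, 7.0)]
        rng = np.random.default_rng(0)
        cfg0 = SimConfig(chromosomes=[MICRO], retention={"micro": 1e-12, "macro": 0.2})
        assert apply_retention(frags, cfg0, MICRO, rng) == []
        cfg1 = SimConfig(chromosomes=[MICRO], retention={"micro": 1 - 1e-12, "macro": 0.2})
        assert apply_retention(frags, cfg1, MICRO, rng) == frags

    def test_empirical_marker_retention(self):
        # marginal marker retention converges to configured r (no boost)
        r = 0.281
        cfg = SimConfig(
            chromosomes=[MICRO],
            retention={"micro": r, "macro": 0.2},
            n_hybrids=5000,
            fp_rate=0.0,
            fn_rate=0.0,
            unknown_rate=0.0,
            seed=3,
        )
        truth, _ = simulate_panel(cfg, markers_at(MICRO, [3.5]))
        f = truth.presence.mean()
        se = np.sqrt(r * (1 - r) / cfg.n_hybrids)
        assert abs(f - r) < 3 * se

    def test_unknown_class_rejected(self):
        rng = np.random.default_rng(0)
        cfg = SimConfig(chromosomes=[MICRO], retention={"macro": 0.2, "micro": 0.3})
        bad = Chromosome("x", 5.0, "micro")
        cfg2 = SimConfig(chromosomes=[bad], retention={"macro": 0.2, "micro": 0.3})
        cfg2.retention = {"macro": 0.2}
        with pytest.raises(ParameterError, match="class"):
            apply_retention([(0.0, 5.0)], cfg2, bad, rng)


class TestPanel:
    def test_noiseless_observation_is_identity(self):
        cfg = SimConfig(
            chromosomes=[MICRO], fp_rate=0.0, fn_rate=0.0, unknown_rate=0.0, seed=4
        )
        truth, matrix = simulate_panel(cfg, markers_per_chrom=10)
        assert (matrix.calls == np.where(truth.presence, PRESENT, ABSENT)).all()

    def test_seed_determinism(self):
        cfg = SimConfig(seed=5)
        t1, m1 = simulate_panel(cfg, markers_per_chrom=8)
        t2, m2 = simulate_panel(cfg, markers_per_chrom=8)
        assert (m1.calls == m2.calls).all()
        assert (t1.presence == t2.presence).all()

    def test_presence_iff_covered_by_retained_fragment(self):
        cfg = SimConfig(chromosomes=[MICRO], seed=6, n_hybrids=20)
        markers = markers_at(MICRO, [1.0, 3.5, 6.0])
        truth, _ = simulate_panel(cfg, markers)
        for j in range(20):
            kept = truth.retained[j]["c1"]
            for i, m in enumerate(markers):
                pos = m.position_bp / 1e6
                covered = any(a <= pos <= b for a, b in kept)
                assert truth.presence[i, j] == covered

    def test_micro_retained_above_macro(self):
        # one-sided check of the configured 0.28 vs 0.20 class difference
        cfg = SimConfig(seed=7, n_hybrids=90)
        truth, matrix = simulate_panel(cfg, markers_per_chrom=30)
        classes = np.array(
            ["micro" if m.startswith("chrm") else "macro" for m in truth.marker_ids]
        )
        micro_f = truth.presence[classes == "micro"].mean()
        macro_f = truth.presence[classes == "macro"].mean()
        assert micro_f > macro_f

    def test_wga_dropout_is_marker_wise(self):
        cfg = SimConfig(
            seed=8,
            wga_dropout={"macro": 0.0, "micro": 1.0},
            fp_rate=0.0,
            fn_rate=0.0,
            unknown_rate=0.0,
        )
        truth, matrix = simulate_panel(cfg, markers_per_chrom=5)
        for mid in truth.dropped_markers:
            assert (matrix.row(mid) == ABSENT).all()
        micro_ids = [m for m in truth.marker_ids if m.startswith("chrm")]
        assert sorted(truth.dropped_markers) == sorted(micro_ids)

    def test_pairwise_discordance_matches_haploid_model(self):
        # discordance frequency for loci x apart: 2 theta r (1-r)
        rate, r, x = 0.35, 0.281, 1.5
        cfg = SimConfig(
            chromosomes=[MICRO],
            breakage_rate=rate,
            retention={"micro": r, "macro": 0.2},
            n_hybrids=8000,
            fp_rate=0.0,
            fn_rate=0.0,
            unknown_rate=0.0,
            seed=9,
        )
        truth, _ = simulate_panel(cfg, markers_at(MICRO, [2.0, 2.0 + x]))
        discord = (truth.presence[0] != truth.presence[1]).mean()
        theta = 1.0 - np.exp(-rate * x)
        p = 2.0 * theta * r * (1.0 - r)
        se = np.sqrt(p * (1 - p) / cfg.n_hybrids)
        assert abs(discord - p) < 3 * se


class TestQPCR:
    def test_noiseless_readouts_encode_truth(self):
        cfg = SimConfig(chromosomes=[MICRO], fp_rate=0, fn_rate=0, unknown_rate=0, seed=10)
        truth, _ = simulate_panel(cfg, markers_per_chrom=5)
        q = QPCRSimConfig(ct_sd=0.0, tm_sd=0.0, neg_no_amp_prob=0.0)
        tab = simulate_qpcr(
            truth.presence, truth.marker_ids, truth.hybrid_ids,
            np.random.default_rng(0), q,
        )
        hyb = tab[~tab.sample_id.isin(["DUCK_POS", "HAMSTER_NEG"])]
        for (mid, sid), grp in hyb.groupby(["marker_id", "sample_id"]):
            i = truth.marker_ids.index(mid)
            j = truth.hybrid_ids.index(sid)
            if truth.presence[i, j]:
                assert (grp.ct == q.ct_pos_mean).all()
                assert (grp.tm == q.tm_specific).all()
            else:
                assert (grp.ct == q.ct_neg_hybrid_mean).all()

    def test_positive_control_ct_in_recommended_window(self):
        # Ct ~ Normal(12, 1): P(10 <= Ct <= 16) = Phi(4) - Phi(-2) = 0.9772
        from scipy import stats

        q = QPCRSimConfig(ct_pos_mean=12.0, ct_sd=1.0)
        rows = []
        rng = np.random.default_rng(11)
        for _ in range(500):
            t = simulate_qpcr(np.ones((1, 1), dtype=bool), ["m"], ["H0"], rng, q)
            rows.append(t[t.sample_id == "DUCK_POS"].ct.to_numpy())
        cts = np.concatenate(rows)
        p = stats.norm.cdf(4.0) - stats.norm.cdf(-2.0)
        se = np.sqrt(p * (1 - p) / cts.size)
        assert abs(((cts >= 10) & (cts <= 16)).mean() - p) < 3 * se

    def test_wga_condition_yields_fewer_positives(self):
        cfg = SimConfig(chromosomes=[MICRO], fp_rate=0, fn_rate=0, unknown_rate=0, seed=12)
        truth, _ = simulate_panel(cfg, markers_per_chrom=10)
        from rhpanel.calling import CallingConfig, build_matrix

        rng = np.random.default_rng(1)
        pre = simulate_qpcr(truth.presence, truth.marker_ids, truth.hybrid_ids, rng,
                            condition="preamp")
        rng = np.random.default_rng(1)
        wga = simulate_qpcr(truth.presence, truth.marker_ids, truth.hybrid_ids, rng,
                            condition="wga")
        m_pre, _ = build_matrix(pre)
        # WGA positive controls amplify late (~22 cycles); widen the QC
        # window so the condition can be called and compared at all
        m_wga, _ = build_matrix(wga, CallingConfig(ct_pos_max=25.0))
        assert (m_wga.calls == PRESENT).sum() < (m_pre.calls == PRESENT).sum()


class TestChimericScaffolds:
    def test_no_chimeras_all_intact(self):
        cfg = SimConfig(seed=13)
        _, _, truth = make_chimeric_scaffolds(cfg, 5, 0, np.random.default_rng(0))
        assert all(v["status"] == "intact" for v in truth.values())

    def test_chimeric_alignments_span_two_chromosomes(self):
        cfg = SimConfig(seed=14)
        markers, segs, truth = make_chimeric_scaffolds(cfg, 0, 5, np.random.default_rng(1))
        for sca, info in truth.items():
            chroms = {s.ref_chrom for s in segs if s.scaffold_id == sca}
            assert len(chroms) == 2
            assert chroms == set(info["chromosomes"])

    def test_intact_flanking_pair_is_physically_close(self):
        cfg = SimConfig(seed=15)
        markers, _, truth = make_chimeric_scaffolds(
            cfg, 10, 0, np.random.default_rng(2), junction_gap_mb=0.1
        )
        by_sca = {}
        for m in markers:
            by_sca.setdefault(m.scaffold_id, []).append(m)
        for sca, (a, b) in by_sca.items():
            assert a.expected_chrom == b.expected_chrom
            assert abs(a.position_bp - b.position_bp) < 1_000_000

    def test_single_chromosome_cannot_be_chimeric(self):
        cfg = SimConfig(chromosomes=[MICRO])
        with pytest.raises(ParameterError):
            make_chimeric_scaffolds(cfg, 0, 1, np.random.default_rng(0))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"breakage_rate": 0.0},
            {"n_hybrids": 0},
            {"fp_rate": 1.5},
            {"retention": {"macro": 0.0, "micro": 0.3}},
            {"centromere_boost": 0.5},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            SimConfig(**kwargs)
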