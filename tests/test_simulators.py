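"""Generators: determinism, distributional sanity, truth consistency."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import saic
from saic import (
    NullSimConfig,
    PowerSimConfig,
    RocSimConfig,
    mix_with_normal,
    partial_auc,
    simulate_null_dataset,
    simulate_power_dataset,
    simulate_roc_dataset,
)
from saic.core_units import AMPLIFICATION, DELETION, ConfigurationError


class TestMixture:
    def test_neutral_and_pure_normal(self):
        assert mix_with_normal(2, 0.3) == 0.0
        assert mix_with_normal(7, 1.0) == 0.0

    def test_half_contaminated_tetraploid(self):
        assert mix_with_normal(4, 0.5) == pytest.approx(np.log2(1.5))

    def test_homozygous_deletion_floored(self):
        v = mix_with_normal(0, 0.0, floor=0.05)
        assert v == pytest.approx(np.log2(0.05 / 2))

    def test_domain_errors(self):
        with pytest.raises(ConfigurationError):
            mix_with_normal(2, 1.5)
        with pytest.raises(ConfigurationError):
            mix_with_normal(-1, 0.5)


class TestNullModel:
    def test_seed_determinism(self):
        cfg = NullSimConfig(clump_fraction=0.5)
        a = simulate_null_dataset(cfg, np.random.default_rng(5))
        b = simulate_null_dataset(cfg, np.random.default_rng(5))
        assert np.array_equal(a.values, b.values)

    def test_expected_altered_probe_mass(self):
        cfg = NullSimConfig(N=30, M=2000)
        counts = []
        for rep in range(20):
            X = simulate_null_dataset(cfg, np.random.default_rng(rep))
            counts.append((X.values != 0).sum() / (cfg.N))
        # mean units/sample = 6, mean length = 30 -> ~180 altered probes/sample
        assert np.mean(counts) == pytest.approx(180, rel=0.1)

    def test_unclumped_starts_uniform(self):
        """Run starts over many samples follow a uniform law (KS at 1%)."""
        cfg = NullSimConfig(N=40, M=2000, units_per_sample=(2, 3),
                            unit_length=(5, 10))
        starts = []
        for rep in range(30):
            X = simulate_null_dataset(cfg, np.random.default_rng([3, rep]))
            for row in X.values:
                nz = np.flatnonzero(np.diff(np.concatenate(
                    [[0], (row != 0).astype(int), [0]])) == 1)
                starts.extend(nz)
        p = stats.kstest(np.array(starts) / cfg.M, "uniform").pvalue
        assert p > 0.01

    def test_clumped_units_concentrate_within_sample(self):
        cfg = NullSimConfig(N=30, M=2000, clump_fraction=0.75)
        spans = []
        for rep in range(10):
            X = simulate_null_dataset(cfg, np.random.default_rng([4, rep]))
            for row in X.values:
                nz = np.flatnonzero(row != 0)
                if nz.size:
                    spans.append(np.ptp(nz) / cfg.M)
        cfg0 = dataclasses.replace(cfg, clump_fraction=0.0)
        spans0 = []
        for rep in range(10):
            X = simulate_null_dataset(cfg0, np.random.default_rng([4, rep]))
            for row in X.values:
                nz = np.flatnonzero(row != 0)
                if nz.size:
                    spans0.append(np.ptp(nz) / cfg.M)
        assert np.mean(spans) < np.mean(spans0)


class TestPowerModel:
    def test_truth_geometry_and_determinism(self):
        cfg = PowerSimConfig(N=20, M=2000)
        X, truth = simulate_power_dataset(cfg, np.random.default_rng(2))
        X2, truth2 = simulate_power_dataset(cfg, np.random.default_rng(2))
        assert np.array_equal(X.values, X2.values) and truth == truth2
        assert {t.tail for t in truth} == {AMPLIFICATION, DELETION}
        for t in truth:
            assert 150 <= t.length <= 250
        a, b = sorted((t.start, t.stop) for t in truth)
        assert a[1] <= b[0], "recurrent intervals overlap"

    def test_full_recurrence_hits_every_sample(self):
        cfg = PowerSimConfig(N=15, M=2000, omega=1.0)
        X, truth = simulate_power_dataset(cfg, np.random.default_rng(3))
        for t in truth:
            block = X.values[:, t.start:t.stop]
            assert (block != 0).all(axis=1).all()

    def test_carrier_rate_matches_omega(self):
        cfg = PowerSimConfig(N=40, M=2000, omega=0.3)
        rates = []
        for rep in range(25):
            X, truth = simulate_power_dataset(cfg, np.random.default_rng(rep))
            for t in truth:
                block = X.values[:, t.start:t.stop]
                rates.append((block != 0).any(axis=1).mean())
        assert np.mean(rates) == pytest.approx(0.3, abs=0.05)

    def test_values_are_mixture_ratios(self):
        cfg = PowerSimConfig(N=10, M=2000)
        X, _ = simulate_power_dataset(cfg, np.random.default_rng(4))
        assert np.isfinite(X.values).all()
        assert X.values.min() >= np.log2(cfg.copy_floor / 2) - 1e-12
        # amplification cannot exceed pure-tumor 8 copies
        assert X.values.max() <= np.log2(8 / 2) + 1e-12


class TestRocModel:
    def test_truth_labels_and_determinism(self):
        cfg = RocSimConfig()
        X, labels = simulate_roc_dataset(cfg, np.random.default_rng(6))
        X2, labels2 = simulate_roc_dataset(cfg, np.random.default_rng(6))
        assert np.array_equal(X.values, X2.values)
        assert all(np.array_equal(labels[t], labels2[t]) for t in labels)
        assert labels[AMPLIFICATION].sum() == 30 + 20 + 10
        assert labels[DELETION].sum() == 20
        assert not (labels[AMPLIFICATION] & labels[DELETION]).any()

    def test_beta_length_scales_truth(self):
        cfg = RocSimConfig(beta_length=2.0)
        _, labels = simulate_roc_dataset(cfg, np.random.default_rng(7))
        assert labels[AMPLIFICATION].sum() == 2 * 60

    def test_noise_only_probes_center_at_zero(self):
        cfg = RocSimConfig(background_count=(0, 0), omega=1e-9)
        X, labels = simulate_roc_dataset(cfg, np.random.default_rng(8))
        free = ~(labels[AMPLIFICATION] | labels[DELETION])
        assert abs(X.values[:, free].mean()) < 0.02


class TestMetrics:
    def test_fwer_replicate_edge_cases(self):
        cfg = NullSimConfig(N=4, M=200, units_per_sample=(2, 3))
        params = saic.simulation_params(permutations=30, alpha=0.2)
        v = saic.estimate_fwer(cfg, params, replicates=1, seed=0)
        assert v in (0.0, 1.0)
        tiny = dataclasses.replace(params, alpha=0.01)
        # alpha' below the attainable P floor: no calls possible
        assert saic.estimate_fwer(cfg, tiny, replicates=3, seed=1) == 0.0

    def test_power_detects_strong_recurrence(self):
        cfg = PowerSimConfig(N=30, M=1500, omega=0.6, mu_lambda=0.3,
                             sigma_lambda=0.1)
        params = saic.simulation_params(permutations=100)
        est = saic.estimate_power(cfg, params, replicates=4, seed=2)
        assert est.amplification == 1.0
        assert est.combined == pytest.approx(
            (est.amplification + est.deletion) / 2)
        assert np.isfinite(est.boundary_error_probes)

    def test_partial_auc_of_step_functions(self):
        perfect = [(0.0, 0.0), (0.0, 1.0), (1.0, 1.0)]
        assert partial_auc(perfect, 0.2) == pytest.approx(0.2)
        diagonal = [(0.0, 0.0), (1.0, 1.0)]
        assert partial_auc(diagonal, 0.2) == pytest.approx(0.02)

    def test_roc_curve_endpoints(self):
        cfg = RocSimConfig(N=10, M=600, background_count=(1, 3),
                           amp_truth=((25, 4),), del_truth_length=15,
                           omega=0.5)
        params = saic.simulation_params(permutations=50)
        pts = saic.roc_curve(cfg, params, [0.02, 0.5, 1.0], replicates=2,
                             seed=3)
        for tail in pts:
            fprs = [p[0] for p in pts[tail]]
            tprs = [p[1] for p in pts[tail]]
            assert fprs[0] == 0.0 and tprs[0] == 0.0
            assert fprs[-1] == 1.0 and tprs[-1] == 1.0
            assert all(x <= y for x, y in zip(fprs, fprs[1:]))


def test_roc_beats_frequency_baseline_when_units_survive_noise():
    """With mild probe noise the decomposition keeps informative units and
    the amplitude-aware, max-calibrated probe ranking beats the
    frequency-only statistic on partial AUC (FPR <= 0.2)."""
    cfg = RocSimConfig(noise_tiers=((0.1, 0.2),))
    params = saic.simulation_params(permutations=200)
    out = saic.compare_roc_with_frequency_baseline(cfg, params,
                                                   replicates=6, seed=5)
    assert (np.mean(out["saic_partial_auc"])
            > np.mean(out["baseline_partial_auc"]))
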