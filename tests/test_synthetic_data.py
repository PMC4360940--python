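import itertools

import numpy as np
import pytest
from scipy.special import expit

from tiestar import (
    CITestConfig,
    g2_test,
    is_dependent,
)
from tiestar.synthetic_data import (
    EquivalenceGroup,
    GeneratorConfig,
    bayes_auc_exact,
    calibrate_intercept,
    demo_config,
    enumerate_true_mbs,
    estimate_bayes_auc,
    generate,
    group,
    prevalence_interval,
)


def _groups(*sizes):
    out = []
    for i, s in enumerate(sizes):
        out.append(group(tuple(f"g{i}_{j}" for j in range(s)), f"src{i}"))
    return tuple(out)


class TestEnumerateTrueMBs:
    def test_cartesian_product_sizes_2_3(self):
        mbs = enumerate_true_mbs(_groups(2, 3), (1.0, 0.8))
        assert len(mbs) == 6
        assert all(len(s) == 2 for s in mbs)

    def test_two_by_two(self):
        assert len(enumerate_true_mbs(_groups(2, 2), (1.0, 1.0))) == 4

    def test_zero_weight_group_excluded(self):
        mbs = enumerate_true_mbs(_groups(2, 3), (1.0, 0.0))
        assert len(mbs) == 2
        assert all(s <= {"g0_0", "g0_1"} for s in mbs)

    def test_singletons(self):
        mbs = enumerate_true_mbs(_groups(3), (1.0,))
        assert mbs == [frozenset({"g0_0"}), frozenset({"g0_1"}), frozenset({"g0_2"})]

    def test_order_deterministic(self):
        a = enumerate_true_mbs(_groups(2, 2), (1.0, 1.0))
        b = enumerate_true_mbs(_groups(2, 2), (1.0, 1.0))
        assert a == b


class TestGenerate:
    def test_shapes_and_ground_truth(self):
        cfg = demo_config(n=500, seed=1)
        ds, truth = generate(cfg)
        assert ds.n == 500
        assert ds.p == 5 + cfg.n_noise
        assert len(truth.true_mbs) == 6
        assert truth.bayes_auc == pytest.approx(bayes_auc_exact(cfg))

    def test_single_group_no_equivalence(self):
        cfg = GeneratorConfig(n=300, groups=_groups(1), weights=(1.0,), n_noise=5, seed=2)
        _, truth = generate(cfg)
        assert truth.true_mbs == (frozenset({"g0_0"}),)

    def test_realized_prevalence_in_99pct_binomial_interval(self):
        cfg = demo_config(n=2000, seed=3)
        ds, _ = generate(cfg)
        lo, hi = prevalence_interval(2000, 0.17)
        assert lo <= ds.outcome.mean() <= hi

    def test_same_seed_byte_identical(self, tmp_path):
        from tiestar import write_dataset

        for run in ("a", "b"):
            ds, _ = generate(demo_config(n=400, seed=11))
            write_dataset(ds, tmp_path / f"{run}.csv", tmp_path / f"{run}.yaml")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
        assert (tmp_path / "a.yaml").read_bytes() == (tmp_path / "b.yaml").read_bytes()

    def test_group_members_equivalent_up_to_relabeling(self):
        # with zero corruption, any two members of a group have identical
        # (source level, outcome) contingency tables after inverting the maps
        cfg = demo_config(n=1500, seed=4)
        ds, _ = generate(cfg)
        for members in (("g1_a", "g1_b"), ("g2_a", "g2_b"), ("g2_a", "g2_c")):
            tables = []
            for m in members:
                codes = ds.column_codes(m)
                sch = ds.schema_of(m)
                # sign-flip maps source level 2 to the smallest (negative) value
                if sch.levels[0] < 0:
                    codes = codes.max() - codes
                table = np.zeros((3, 2), dtype=int)
                np.add.at(table, (codes, ds.outcome), 1)
                tables.append(table)
            for t in tables[1:]:
                np.testing.assert_array_equal(tables[0], t)

    def test_noise_features_independent_of_outcome(self):
        cfg = CITestConfig()
        rejections = 0
        replicates = 60
        for seed in range(replicates):
            ds, _ = generate(demo_config(n=500, seed=1000 + seed, n_noise=3))
            codes = ds.column_codes("noise_00")
            rejections += is_dependent(g2_test(codes, ds.outcome, (), cfg), cfg)
        mc_tol = np.sqrt(0.05 * 0.95 / replicates)
        assert rejections / replicates <= cfg.alpha + 3 * mc_tol

    def test_equivalence_noise_breaks_determinism(self):
        cfg = demo_config(n=800, seed=5, equivalence_noise=0.2)
        ds, _ = generate(cfg)
        a = ds.column_codes("g1_a")
        b = ds.column_codes("g1_b")
        assert np.any(a != b)  # corrupted members no longer perfect recodings


class TestBayesAUC:
    def test_no_signal_gives_half(self):
        cfg = GeneratorConfig(n=100, groups=_groups(1), weights=(0.0,), seed=0)
        assert bayes_auc_exact(cfg) == pytest.approx(0.5)

    def test_saturated_signal_approaches_one(self):
        cfg = GeneratorConfig(n=100, groups=_groups(1), weights=(25.0,),
                              prevalence=0.4, seed=0)
        assert bayes_auc_exact(cfg) > 0.95

    def test_exact_matches_independent_enumeration_for_single_source(self):
        # independent route: explicit loops over the 3 source levels
        w, prev = 1.5, 0.17
        cfg = GeneratorConfig(n=100, groups=_groups(1), weights=(w,), prevalence=prev, seed=0)
        b = calibrate_intercept((w,), prev)
        levels = [0, 1, 2]
        p = {s: expit(b + w * s) for s in levels}
        num = den_case = den_ctrl = 0.0
        for s_case, s_ctrl in itertools.product(levels, levels):
            wt = (1 / 9) * p[s_case] * (1 - p[s_ctrl])
            num += wt * ((p[s_case] > p[s_ctrl]) + 0.5 * (p[s_case] == p[s_ctrl]))
        den_case = sum(p[s] / 3 for s in levels)
        den_ctrl = sum((1 - p[s]) / 3 for s in levels)
        assert bayes_auc_exact(cfg) == pytest.approx(num / (den_case * den_ctrl), abs=1e-12)

    def test_monte_carlo_agrees_with_exact(self):
        cfg = demo_config(n=100, seed=6)
        est = estimate_bayes_auc(cfg, mc_samples=60_000)
        exact = bayes_auc_exact(cfg)
        assert abs(est.auc - exact) < 4 * est.se + 0.01

    def test_calibrated_intercept_hits_prevalence(self):
        b = calibrate_intercept((1.0, 0.8), 0.17)
        combos = np.array(list(itertools.product([0, 1, 2], repeat=2)))
        mean = expit(b + combos @ np.array([1.0, 0.8])).mean()
        assert mean == pytest.approx(0.17, abs=1e-9)

    def test_unbracketable_prevalence_raises(self):
        with pytest.raises(ValueError, match="bracket"):
            calibrate_intercept((200.0,), 1e-6)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"prevalence": 1.5},
            {"prevalence": 0.0},
            {"equivalence_noise": 1.0},
            {"n_noise": -1},
            {"weights": (1.0,)},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        base = dict(n=100, groups=_groups(2, 2), weights=(1.0, 1.0))
        base.update(kwargs)
        with pytest.raises(ValueError):
            GeneratorConfig(**base)

    def test_overlapping_groups_rejected(self):
        g1 = EquivalenceGroup(("a", "b"), "s1")
        g2 = EquivalenceGroup(("b", "c"), "s2")
        with pytest.raises(ValueError, match="disjoint"):
            GeneratorConfig(n=100, groups=(g1, g2), weights=(1.0, 1.0))
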