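import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from woundfield.explore import (
    ConstantInputError,
    FlatCurveError,
    SamplingConfig,
    classify_observed,
    classify_simple,
    compare_models,
    half_max_position,
    intersection_position,
    parameter_density,
    pearson,
    run_scan,
    sample_parameters,
)
from woundfield.model import HILL_NAMES, PARAM_NAMES, ModelConfiguration
from woundfield.synthetic_data import generate_reference_pair

GRID = (np.arange(100) + 0.5) / 100


class TestSampling:
    def test_ranges_respected(self):
        df = sample_parameters(SamplingConfig(n_sets=10_000, seed=0))
        assert df.shape == (10_000, len(PARAM_NAMES))
        assert df["k_deg_JNK"].between(0.01, 10_000).all()
        assert df["k_deg_JAK"].between(0.01, 10_000).all()
        assert df["k_act_EIG"].between(1e-5, 10).all()
        assert df["K_m_EIG"].between(1e-5, 10).all()
        assert df["d"].between(1.5, 4).all()
        for h in HILL_NAMES:
            assert df[h].between(1, 4).all()

    def test_determinism(self):
        a = sample_parameters(SamplingConfig(n_sets=500, seed=123))
        b = sample_parameters(SamplingConfig(n_sets=500, seed=123))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = sample_parameters(SamplingConfig(n_sets=10, seed=0))
        b = sample_parameters(SamplingConfig(n_sets=10, seed=1))
        assert not a.equals(b)

    def test_log_uniform_marginal(self):
        df = sample_parameters(SamplingConfig(n_sets=20_000, seed=7))
        logs = np.log10(df["gamma"])  # should be ~ U(-2, 4)
        d, p = stats.kstest(logs, stats.uniform(loc=-2, scale=6).cdf)
        assert p > 1e-3

    def test_integer_hill_scheme(self):
        df = sample_parameters(SamplingConfig(n_sets=1000, seed=0, hill_scheme="integer"))
        for h in HILL_NAMES:
            vals = df[h]
            assert np.array_equal(vals, vals.round())
            assert set(vals.unique()) <= {1.0, 2.0, 3.0, 4.0}

    def test_diffusion_regimes(self):
        slower = sample_parameters(SamplingConfig(n_sets=200, seed=0, diffusion="slower"))
        assert slower["d"].between(0.25, 0.67).all()
        equal = sample_parameters(SamplingConfig(n_sets=200, seed=0, diffusion="equal"))
        assert (equal["d"] == 1.0).all()

    def test_global_interval_mode(self):
        df = sample_parameters(SamplingConfig(n_sets=2000, seed=0, global_interval=True))
        assert df["k_act_EIG"].between(1e-3, 1e2).all()
        assert df["gamma"].between(1e-3, 1e2).all()
        assert df["d"].between(1.5, 4).all()  # regime range, not global

    def test_shared_inhibition_hill(self):
        df = sample_parameters(SamplingConfig(n_sets=50, seed=0, share_inhibition_hill=True))
        assert np.array_equal(df["ni1"], df["n2"])
        assert np.array_equal(df["ni2"], df["n3"])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SamplingConfig(n_sets=0)
        with pytest.raises(ValueError):
            SamplingConfig(ranges={"nope": (1, 2)})
        with pytest.raises(ValueError):
            SamplingConfig(ranges={"gamma": (5.0, 1.0)})


class TestClassifySimple:
    def test_maximal_separation(self):
        c = classify_simple((1.0 - GRID, GRID.copy()))
        assert c.simple
        assert c.rel_diff_jak == pytest.approx(1.0, abs=0.02)
        assert c.rel_diff_jnk == pytest.approx(1.0, abs=0.02)

    def test_flat_curves_fail_endpoints(self):
        c = classify_simple((np.full(100, 0.5), np.full(100, 0.5)))
        assert not c.simple
        assert not c.jak_rises and not c.jnk_falls

    def test_shallow_jak_below_threshold(self):
        jak = 0.95 + 0.05 * (GRID - GRID[0]) / (GRID[-1] - GRID[0])
        c = classify_simple((1.0 - GRID, jak))
        assert not c.simple
        assert c.rel_diff_jak == pytest.approx(0.05, abs=1e-12)
        assert c.jak_rises  # only the 10% criterion fails

    def test_zero_curve_flagged(self):
        c = classify_simple((np.zeros(100), GRID.copy()))
        assert not c.simple
        assert math.isnan(c.rel_diff_jnk)
        assert c.note

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(1e-6, 1e6))
    def test_scaling_invariance(self, scale):
        jnk, jak = 1.0 - GRID, GRID**2 + 0.01
        base = classify_simple((jnk, jak))
        scaled = classify_simple((jnk * scale, jak * scale))
        assert base.simple == scaled.simple


class TestClassifyObserved:
    def setup_method(self):
        self.refs = generate_reference_pair()

    def test_identical_curves(self):
        c = classify_observed((self.refs[0].values, self.refs[1].values), self.refs, GRID)
        assert c.observed
        assert c.r_jnk == pytest.approx(1.0)
        assert c.r_jak == pytest.approx(1.0)

    def test_reversed_jnk_anticorrelates(self):
        # the reference is monotone, so its x-reverse is strongly negatively
        # correlated (exactly -1 only for a point-symmetric curve)
        c = classify_observed((self.refs[0].values[::-1], self.refs[1].values), self.refs, GRID)
        assert not c.observed
        assert c.r_jnk < -0.9

    def test_constant_curve_flagged(self):
        c = classify_observed((np.full(100, 1.0), self.refs[1].values), self.refs, GRID)
        assert not c.observed
        assert math.isnan(c.r_jnk)
        assert c.note

    def test_threshold_is_strict(self):
        from woundfield.synthetic_data import generate_labeled_fixtures

        f = next(f for f in generate_labeled_fixtures(0) if f.name == "r-at-0.7")
        c = classify_observed((f.jnk, f.jak), self.refs, GRID)
        assert 0.7 - 1e-9 < c.r_jnk <= 0.7
        assert not c.observed

    def test_masked_reference_restricts_correlation(self):
        from woundfield.profiles import apply_mask

        jnk = self.refs[0].values.copy()
        jnk[:10] = 5.0  # corrupt the region that will be masked
        masked_ref = (apply_mask(self.refs[0], (0.0, 0.1)), self.refs[1])
        full = classify_observed((jnk, self.refs[1].values), self.refs, GRID)
        masked = classify_observed((jnk, self.refs[1].values), masked_ref, GRID)
        assert masked.r_jnk > full.r_jnk
        assert masked.r_jnk == pytest.approx(1.0, abs=1e-9)


class TestPearson:
    def test_affine_invariance(self):
        a = np.array([1.0, 2.0, 5.0, 7.0])
        assert pearson(a, 2 * a + 3) == pytest.approx(1.0)

    def test_anticorrelation(self):
        a = np.array([1.0, 2.0, 5.0, 7.0])
        assert pearson(a, -a) == pytest.approx(-1.0)

    def test_known_value(self):
        # direct evaluation of the product-moment formula
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_raises(self):
        with pytest.raises(ConstantInputError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            pearson([1.0, 2.0], [3.0, 4.0])

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 40))
    def test_matches_scipy(self, seed, n):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=n), rng.normal(size=n)
        assert pearson(a, b) == pytest.approx(stats.pearsonr(a, b).statistic, abs=1e-12)


class TestHalfMax:
    X = np.linspace(0.0, 1.0, 101)  # endpoint grid: analytic examples are exact

    def test_linear_decrease(self):
        hm = half_max_position(self.X, 1.0 - self.X)
        assert hm.crossed
        assert hm.position == pytest.approx(0.5, abs=1e-9)

    def test_exponential_closed_form(self):
        hm = half_max_position(self.X, np.exp(-10 * self.X))
        assert hm.position == pytest.approx(math.log(2) / 10, abs=2e-3)

    def test_flat_curve_raises(self):
        with pytest.raises(FlatCurveError):
            half_max_position(self.X, np.full(101, 2.0))

    def test_never_below_half(self):
        hm = half_max_position(self.X, 1.0 - 0.2 * self.X)
        assert not hm.crossed
        assert hm.position == self.X[-1]

    def test_increasing_curve_scans_left(self):
        hm = half_max_position(self.X, self.X.copy())
        assert hm.crossed
        assert hm.position == pytest.approx(0.5, abs=1e-9)


class TestIntersection:
    X = np.linspace(0.0, 1.0, 101)

    def test_symmetric_crossing(self):
        assert intersection_position(self.X, 1.0 - self.X, self.X) == pytest.approx(0.5, abs=1e-9)

    def test_no_crossing_is_absent(self):
        assert intersection_position(self.X, np.full(101, 1.0), np.full(101, 0.2)) is None

    def test_quadratic_crossing(self):
        # both curves already peak at 1 on [0, 1]; root of x^2 + x - 1
        gold = (math.sqrt(5) - 1) / 2
        pos = intersection_position(self.X, 1.0 - self.X, self.X**2)
        assert pos == pytest.approx(gold, abs=1e-3)

    def test_identical_flat_pair_is_absent(self):
        # rescaling maps both constants onto 1; no genuine crossing exists
        assert intersection_position(self.X, np.full(101, 0.7), np.full(101, 0.7)) is None

    def test_jak_strictly_above_at_left_edge(self):
        jnk = np.sin(np.pi * self.X) + 1e-3   # peaks mid-domain, low at x = 0
        jak = 1.0 - 0.5 * self.X              # rescaled to 1 at x = 0, above JNK
        pos = intersection_position(self.X, jnk, jak)
        assert pos == self.X[0]


ZERO_ACT_RANGES = {f"k_act_{s}": (1e-12, 1e-12) for s in ("EIG", "JNK", "JAK", "UPD")}


class TestRunScan:
    def test_zero_activation_not_bistable(self):
        rec = run_scan(SamplingConfig(n_sets=1, seed=0, ranges=ZERO_ACT_RANGES))
        assert len(rec) == 2
        assert not rec["simple"].any()
        assert not rec["observed"].any()

    def test_determinism(self):
        cfg = SamplingConfig(n_sets=3, seed=5)
        a = run_scan(cfg)
        b = run_scan(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_nonconverged_records_carry_false_flags(self):
        model_cfg = ModelConfiguration(horizon=1e-3, tolerance=1e-12)
        rec = run_scan(SamplingConfig(n_sets=2, seed=0), model_cfg)
        assert not rec["converged"].any()
        assert not rec["simple"].any()
        assert not rec["observed"].any()

    def test_parameters_joined_to_records(self):
        rec = run_scan(SamplingConfig(n_sets=2, seed=9))
        for name in PARAM_NAMES:
            assert name in rec.columns
        mut = rec[rec.topology == "mutual"].set_index("set_id")
        uni = rec[rec.topology == "unidirectional"].set_index("set_id")
        pd.testing.assert_frame_equal(mut[list(PARAM_NAMES)], uni[list(PARAM_NAMES)])

    def test_checkpointing(self, tmp_path):
        path = tmp_path / "records.partial.csv"
        rec = run_scan(SamplingConfig(n_sets=3, seed=1), checkpoint_path=path, checkpoint_every=1)
        on_disk = pd.read_csv(path)
        assert len(on_disk) == len(rec)


def _fake_records(simple_flags, topology="mutual", k_act_jnk=None):
    n = len(simple_flags)
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "set_id": np.arange(n),
        "topology": topology,
        "converged": True,
        "simple": simple_flags,
        "observed": simple_flags,
        "intersection": rng.uniform(0, 1, n),
        "k_act_JNK": k_act_jnk if k_act_jnk is not None else rng.uniform(0.01, 1e4, n),
    })
    return df


class TestCompareModels:
    @staticmethod
    def _records(n=10, mutual_hits=3, uni_hits=1):
        rows = []
        for topo, hits in (("mutual", mutual_hits), ("unidirectional", uni_hits)):
            for i in range(n):
                rows.append({"set_id": i, "topology": topo, "converged": True,
                             "simple": i < hits, "observed": i < hits})
        return pd.DataFrame(rows)

    def test_percentages(self):
        summary, paired = compare_models(self._records())
        assert summary.loc["mutual", "pct_simple"] == pytest.approx(30.0)
        assert summary.loc["unidirectional", "pct_simple"] == pytest.approx(10.0)
        assert paired.loc["simple", "both"] == 1
        assert paired.loc["simple", "mutual_only"] == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_models(pd.DataFrame(columns=["topology", "simple"]))

    def test_mismatched_ids_rejected(self):
        df = self._records()
        df = df[~((df.topology == "mutual") & (df.set_id == 0))]
        with pytest.raises(ValueError):
            compare_models(df)

    def test_all_false(self):
        summary, _ = compare_models(self._records(mutual_hits=0, uni_hits=0))
        assert (summary[["n_simple", "n_observed", "pct_simple"]].to_numpy() == 0).all()


class TestParameterDensity:
    def test_all_bistable(self):
        df = _fake_records([True] * 50)
        out = parameter_density(df, "k_act_JNK", bins=10)
        occupied = out[out.n_total > 0]
        assert (occupied.frequency == 1.0).all()
        assert out.n_total.sum() == 50

    def test_none_bistable(self):
        out = parameter_density(_fake_records([False] * 50), "k_act_JNK", bins=10)
        assert (out.frequency == 0.0).all()

    def test_median_split_fixture(self):
        rng = np.random.default_rng(1)
        vals = np.exp(rng.uniform(np.log(0.01), np.log(1e4), 400))
        flags = vals > np.median(vals)
        out = parameter_density(_fake_records(list(flags), k_act_jnk=vals), "k_act_JNK", bins=8)
        med = np.median(vals)
        for _, row in out[out.n_total > 0].iterrows():
            if row.bin_high <= med:
                assert row.frequency == 0.0
            elif row.bin_low >= med:
                assert row.frequency == 1.0

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            parameter_density(_fake_records([True]), "not_a_parameter")


def test_narrow_gradient_excluded():
    """tanh JNK curves: too-narrow gradients cannot match a broad reference."""
    refs = generate_reference_pair()
    jak = refs[1].values
    widths = [0.02, 0.05, 0.1, 0.2, 0.3, 0.45, 0.6]
    flags = []
    for w in widths:
        jnk = 0.5 * (1 - np.tanh((GRID - w) / 0.02))
        c = classify_observed((jnk, jak), refs, GRID)
        flags.append(c.observed)
    assert not flags[0]  # very narrow gradient never classifies as observed
    assert flags[-2] or flags[-1]  # broad gradients do
    # monotone in width: once wide enough to match, it keeps matching until
    # the gradient overshoots the reference's own width
    first_true = flags.index(True)
    assert all(flags[i] is False for i in range(first_true))
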