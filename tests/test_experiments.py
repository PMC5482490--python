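"""Experiment drivers: sweeps, perturbations, slow steps, steady state,
whole-translatome runs."""

import numpy as np
import pytest

from looptasep import TranscriptSpec
from looptasep.experiments import (
    length_sweep,
    loglog_slope,
    perturb,
    slow_step_scan,
    steady_state_diagnostics,
    translatome_run,
)
from looptasep.fixtures import make_transcriptome, synthetic_rate_table
from looptasep.rates import ReinitiationPolicy


class TestLoglogSlope:
    def test_exact_power_law(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        fit = loglog_slope(x, 3.0 / x)
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)
        assert fit.ci_high - fit.ci_low == pytest.approx(0.0, abs=1e-10)

    def test_constant_y(self):
        fit = loglog_slope([1, 10, 100], [5.0, 5.0, 5.0])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_noisy_power_law_coverage(self):
        rng = np.random.default_rng(8)
        x = np.logspace(0, 2, 20)
        covered = 0
        reps = 40
        for _ in range(reps):
            y = 2.0 * x**2.5 * rng.lognormal(0.0, 0.01, size=20)
            fit = loglog_slope(x, y)
            covered += fit.covers(2.5)
            assert abs(fit.slope - 2.5) < 0.05
        assert covered >= int(0.8 * reps)  # nominal 95% coverage

    def test_rejects_nonpositive_and_short(self):
        with pytest.raises(ValueError):
            loglog_slope([1, 2, 3], [1.0, -1.0, 2.0])
        with pytest.raises(ValueError):
            loglog_slope([1, 2], [1.0, 2.0])


class TestLengthSweep:
    def test_single_length_flags_slope_undefined(self):
        res = length_sweep(
            [40], ReinitiationPolicy(level=0.5), alpha=0.1, lifetime=20.0,
            n_runs=20, seed=0,
        )
        assert len(res.table) == 1
        assert all(s is None for s in res.slopes.values())

    def test_rows_sorted_one_per_length(self):
        res = length_sweep(
            [80, 40, 160], ReinitiationPolicy(level=0.9), alpha=0.05,
            lifetime=60.0, n_runs=30, seed=0,
        )
        assert list(res.table["length"]) == [40, 80, 160]
        assert res.table["level"].nunique() == 1

    def test_length_dependent_policy_sets_level_per_length(self):
        res = length_sweep(
            [400, 2000], ReinitiationPolicy(length_dependent=True), alpha=0.05,
            lifetime=30.0, n_runs=10, seed=0,
        )
        assert list(res.table["level"]) == pytest.approx([0.9, 0.5])


class TestPerturb:
    def spec(self, L=100, level=0.999, alpha=0.01, T=400.0):
        r = 10.0 * level
        return TranscriptSpec.uniform(
            L, 10.0, alpha=alpha, reinit_rate=r, release_rate=10.0 - r, lifetime=T
        )

    def test_factor_one_gives_exact_unity(self):
        res = perturb(self.spec(), "elong_all", 1.0, n_runs=50, seed=4)
        assert res.density_ratio == 1.0
        assert res.eff_init_ratio == 1.0
        assert res.yield_ratio == 1.0

    def test_reinit_scaling_at_level_zero_is_inert(self):
        spec = self.spec(level=0.0)
        res = perturb(spec, "reinit_rate", 2.0, n_runs=50, seed=4)
        assert res.density_ratio == 1.0 and res.yield_ratio == 1.0

    def test_alpha_doubling_without_reinitiation_doubles_throughput(self):
        # collision-free, no reinitiation: initiations scale linearly in alpha
        spec = self.spec(level=0.0, alpha=0.005, T=600.0)
        res = perturb(spec, "alpha", 2.0, n_runs=400, seed=4)
        assert res.eff_init_ratio == pytest.approx(2.0, abs=4 * res.se_eff_init_ratio)

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError, match="unknown perturbation"):
            perturb(self.spec(), "beta", 2.0, n_runs=10, seed=0)


class TestSlowStep:
    def test_no_change_gives_exact_unity(self):
        df = slow_step_scan(
            [60], ["middle"], [10.0], level=0.9, alpha=0.02, lifetime=100.0,
            n_runs=40, seed=1,
        )
        assert (df["yield_ratio"] == 1.0).all()
        assert (df["density_ratio"] == 1.0).all()

    def test_yield_ratio_monotone_in_slow_rate(self):
        df = slow_step_scan(
            [80], ["final"], [10.0, 1.0, 0.1], level=0.999, alpha=0.02,
            lifetime=300.0, n_runs=200, seed=2,
        )
        y = df.sort_values("slow_rate", ascending=False)["yield_ratio"].to_numpy()
        assert y[0] > y[1] > y[2]


class TestSteadyState:
    def test_alpha_zero_trivial(self):
        spec = TranscriptSpec.uniform(
            40, 10.0, alpha=0.0, reinit_rate=1.0, release_rate=1.0, lifetime=1.0
        )
        res = steady_state_diagnostics(spec, run_time=100.0, window=20.0,
                                       n_runs=50, grid_dt=1.0, seed=0)
        assert res.ss_density == 0.0 and res.first_passage == 0.0 and res.attained

    def test_no_reinitiation_reaches_steady_state_quickly(self):
        # pioneer round is ~6 s here; the mean density must attain its
        # steady-state value well before the end of the run
        spec = TranscriptSpec.uniform(
            60, 10.0, alpha=0.2, reinit_rate=0.0, release_rate=10.0, lifetime=1.0
        )
        res = steady_state_diagnostics(spec, run_time=400.0, window=100.0,
                                       n_runs=200, grid_dt=2.0, seed=3)
        assert res.attained
        assert res.first_passage is not None
        assert res.first_passage < 100.0

    def test_drifting_density_flagged_not_attained(self):
        # perfect reinitiation with ongoing initiation: the ribosome count
        # grows for the whole run, so the tail still drifts directionally
        spec = TranscriptSpec.uniform(
            400, 10.0, alpha=0.05, reinit_rate=10.0, release_rate=0.0, lifetime=1.0
        )
        res = steady_state_diagnostics(spec, run_time=600.0, window=300.0,
                                       n_runs=150, grid_dt=5.0, seed=5)
        assert not res.attained
        assert res.first_passage is None

    def test_window_validation(self):
        spec = TranscriptSpec.uniform(
            40, 10.0, alpha=0.1, reinit_rate=1.0, release_rate=1.0, lifetime=1.0
        )
        with pytest.raises(ValueError):
            steady_state_diagnostics(spec, run_time=10.0, window=10.0, n_runs=5)


@pytest.fixture(scope="module")
def records():
    return make_transcriptome(10, (15, 40), seed=3)


class TestTranslatome:
    def test_one_row_per_cds_and_deterministic(self, records):
        table = synthetic_rate_table()
        a = translatome_run(records, table, 50.0, alpha=0.05, n_runs=30, seed=9)
        b = translatome_run(records, table, 50.0, alpha=0.05, n_runs=30, seed=9)
        assert len(a.table) == 10
        assert a.table.equals(b.table)
        assert not a.failures and not a.excluded

    def test_determinism_is_per_transcript_id(self, records):
        table = synthetic_rate_table()
        a = translatome_run(records, table, 50.0, alpha=0.05, n_runs=30, seed=9)
        b = translatome_run(records[::-1], table, 50.0, alpha=0.05, n_runs=30, seed=9)
        merged = a.table.merge(b.table, on="transcript_id", suffixes=("_a", "_b"))
        assert (merged["density_a"] == merged["density_b"]).all()

    def test_short_lifetime_excluded(self, records):
        table = synthetic_rate_table()
        lifetimes = {rid: 1000.0 for rid, _ in records}
        lifetimes[records[0][0]] = 300.0  # below the 400 s cut
        res = translatome_run(records, table, lifetimes, alpha=0.05, n_runs=10, seed=1)
        assert res.excluded == [records[0][0]]
        assert len(res.table) == 9

    def test_bad_record_collected_not_fatal(self, records):
        table = synthetic_rate_table()
        bad = records + [("broken", "ATGNNNTAA")]
        res = translatome_run(bad, table, 50.0, alpha=0.05, n_runs=5, seed=1)
        assert len(res.table) == 10
        assert res.failures and res.failures[0][0] == "broken"
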