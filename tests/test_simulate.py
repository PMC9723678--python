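"""Simulator: design manifest arithmetic, logistic-washout dynamics against
an ODE oracle, bottleneck statistics, and seeded reproducibility."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import assemblage as A
from assemblage import ValidationError
from assemblage.simulate import pulse_dilute


# ---------------------------------------------------------------------------
# design manifest
# ---------------------------------------------------------------------------

class TestBuildDesign:
    def test_default_design_has_206_samples(self):
        manifest = A.build_design(A.DesignSpec())
        assert len(manifest) == 206  # 2 inoculum + 17 days x 4 regimes x 3 reps

    def test_degenerate_design_single_row(self):
        spec = A.DesignSpec(regimes=("UDH",), replicates_per_regime=1,
                            sampling_days=(10,), inoculum_samples=0)
        assert len(A.build_design(spec)) == 1

    @pytest.mark.parametrize("day,expected_mode,expected_period", [
        (2, "U", 1), (28, "U", 1), (30, "D", 2), (50, "D", 2),
    ])
    def test_crossover_relabels_disturbance(self, day, expected_mode, expected_period):
        spec = A.DesignSpec(regimes=("UDH",), replicates_per_regime=1,
                            sampling_days=(2, 28, 30, 50), inoculum_samples=0)
        manifest = A.build_design(spec)
        row = manifest[manifest["day"] == day].iloc[0]
        assert row["disturbance_at_sampling"] == expected_mode
        assert row["period"] == expected_period

    def test_validation_errors_name_the_field(self):
        with pytest.raises(ValidationError, match="regimes"):
            A.DesignSpec(regimes=())
        with pytest.raises(ValidationError, match="sampling_days"):
            A.DesignSpec(sampling_days=(5, 3, 8))


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

class TestDynamics:
    def test_chemostat_fixed_point(self):
        # dN/dt = 0 at N = K (1 - D/mu) = 0.6 K for mu=2.5, D=1
        taxa = [A.TaxonProfile("t", 2.5, 1000)]
        sch = A.RegimeSchedule(carrying_capacity=1e5, period_modes=("U", "U"))
        tr = A.simulate_microcosm(taxa, sch, drift=False)
        assert tr.total[-1] == pytest.approx(0.6e5, rel=1e-6)

    def test_skeleton_matches_ode_oracle(self):
        # independent oracle: adaptive integration of dN/dt = N(mu(1-N/K) - D)
        mu, K, D, N0, T = 2.5, 5e4, 1.0, 500.0, 10.0
        sol = solve_ivp(lambda t, y: y * (mu * (1 - y / K) - D), (0, T), [N0],
                        rtol=1e-10, atol=1e-8)
        taxa = [A.TaxonProfile("t", mu, int(N0))]
        sch = A.RegimeSchedule(carrying_capacity=K, period_modes=("U", "U"),
                               continuous_dilution_rate=D, crossover_day=5.0,
                               total_days=T)
        fine = A.simulate_microcosm(taxa, sch, step=0.01, drift=False)
        assert fine.total[-1] == pytest.approx(sol.y[0, -1], rel=0.01)
        # refinement shrinks the skeleton error
        coarse = A.simulate_microcosm(taxa, sch, step=0.1, drift=False)
        err = lambda tr: abs(tr.total[-1] - sol.y[0, -1])
        assert err(fine) < err(coarse)

    def test_pulse_reduces_biomass_fifty_fold(self, rng):
        # Monte Carlo: mean post-pulse biomass = N_before / 50 within 3 SE
        n_before = np.array([30_000, 20_000, 10_000])
        draws = np.array([pulse_dilute(n_before, 1 / 50, rng).sum()
                          for _ in range(10_000)])
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - n_before.sum() / 50) < 3 * se

    def test_neutral_bottleneck_is_a_martingale(self, rng):
        # E[relative abundance] is conserved by binomial subsampling
        n_before = np.array([6_000, 4_000])
        rel = []
        for _ in range(10_000):
            survivors = pulse_dilute(n_before, 1 / 50, rng)
            if survivors.sum() > 0:
                rel.append(survivors[0] / survivors.sum())
        rel = np.array(rel)
        se = rel.std(ddof=1) / np.sqrt(len(rel))
        assert abs(rel.mean() - 0.6) < 3 * se

    def test_growth_between_pulses_is_near_exponential(self):
        # N << K: per-taxon growth over one pulse interval ~ exp(mu dt)
        taxa = [A.TaxonProfile("t", 2.5, 2000)]
        sch = A.RegimeSchedule(carrying_capacity=1e7, period_modes=("D", "D"))
        tr = A.simulate_microcosm(taxa, sch, drift=False)
        n2, n4 = tr.state_at(2.0)[0], tr.state_at(4.0)[0]
        observed = n4 / (n2 / 50)  # growth from post-pulse state over 2 days
        assert observed == pytest.approx(np.exp(2.5 * 2.0), rel=0.05)

    def test_drift_trajectory_is_nonnegative_integer(self):
        taxa = A.neutral_community(n_taxa=30, total_abundance=5e3, seed=1)
        sch = A.RegimeSchedule(carrying_capacity=5e3)
        tr = A.simulate_microcosm(taxa, sch, seed=1)
        assert np.issubdtype(tr.states.dtype, np.integer)
        assert (tr.states >= 0).all()

    def test_extinct_community_stays_zero(self):
        taxa = [A.TaxonProfile("t", 2.5, 0)]
        sch = A.RegimeSchedule(carrying_capacity=1e4)
        tr = A.simulate_microcosm(taxa, sch, seed=0)
        assert tr.total.sum() == 0

    def test_step_must_divide_pulse_interval(self):
        taxa = [A.TaxonProfile("t", 2.5, 10)]
        sch = A.RegimeSchedule(carrying_capacity=1e4)
        with pytest.raises(ValidationError, match="pulse_interval"):
            A.simulate_microcosm(taxa, sch, step=0.3)

    def test_neutral_replicates_diverge_on_average(self):
        # the Bray-Curtis similarity between neutral replicates does not
        # increase with time (drift only)
        taxa = A.neutral_community(n_taxa=100, total_abundance=2e4, seed=8)
        sch = A.RegimeSchedule(carrying_capacity=2e4, period_modes=("U", "U"))
        reps = [A.simulate_microcosm(taxa, sch, seed=8, microcosm_id=f"r{i}")
                for i in range(3)]
        def mean_sim(day):
            states = [r.state_at(day) for r in reps]
            return np.mean([A.bray_curtis_similarity(states[i], states[j])
                            for i in range(3) for j in range(i + 1, 3)])
        assert mean_sim(50.0) < mean_sim(2.0)


# ---------------------------------------------------------------------------
# sequencing emulation
# ---------------------------------------------------------------------------

class TestSampleReads:
    def test_single_taxon_gets_all_reads(self):
        assert A.sample_reads(np.array([42]), 10_000)[0] == 10_000

    def test_read_sum_equals_depth(self, rng):
        counts = A.sample_reads(rng.integers(0, 500, size=50), 7_777, rng)
        assert counts.sum() == 7_777

    def test_multinomial_moments(self, rng):
        # 70/30 split at depth 10,000: binomial moments oracle
        draws = np.array([A.sample_reads(np.array([70.0, 30.0]), 10_000, rng)[0]
                          for _ in range(1_000)])
        se = np.sqrt(10_000 * 0.7 * 0.3)  # binomial SD of one draw
        assert abs(draws.mean() - 7_000) < 3 * se / np.sqrt(len(draws))

    def test_extinct_community_cannot_be_sequenced(self):
        with pytest.raises(ValidationError, match="extinct"):
            A.sample_reads(np.zeros(5), 100)


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

class TestSimulateExperiment:
    def test_columns_align_with_manifest(self, small_experiment):
        table, metadata = small_experiment
        assert table.shape[1] == len(metadata)
        assert table.samples == metadata["sample_id"].tolist()

    def test_same_seed_is_bit_identical(self):
        spec = A.DesignSpec(regimes=("UDH",), replicates_per_regime=2,
                            sampling_days=(2, 10), inoculum_samples=1)
        taxa = A.neutral_community(n_taxa=20, total_abundance=5e3, seed=3)
        sch = A.default_schedules(("UDH",), k_low=5e3)
        t1, m1 = A.simulate_experiment(spec, taxa, sch, seed=42)
        t2, m2 = A.simulate_experiment(spec, taxa, sch, seed=42)
        assert t1.data.equals(t2.data)
        assert m1.equals(m2)
        t3, _ = A.simulate_experiment(spec, taxa, sch, seed=43)
        assert not t1.data.equals(t3.data)

    def test_missing_schedule_is_rejected(self):
        spec = A.DesignSpec(regimes=("UDH", "DUH"))
        taxa = A.neutral_community(n_taxa=5, total_abundance=100, seed=0)
        with pytest.raises(ValidationError, match="DUH"):
            A.simulate_experiment(spec, taxa, A.default_schedules(("UDH",)), seed=0)
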