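"""Tests of the chromatin-mark / central-dogma simulator."""

import numpy as np
import pytest

from stochtune import (
    ChromatinState,
    FitnessReference,
    GeneKinetics,
    build_fitness_reference,
    compute_fitness,
    delta_F,
    half_life_to_step_prob,
    sample_gene_kinetics,
    score_last_quarter,
    simulate_physio,
    step_proteins,
    step_transcripts,
    sweep_parameters,
    transcription_rate,
    update_stabilizing_marks,
    update_tuning_marks,
)
from stochtune.config import PhysioConfig
from stochtune.physio import (
    sample_log2_translation_rates,
    sample_protein_half_lives_hours,
    sample_transcription_rates_per_hour,
)


class TestHalfLifeConversion:
    @pytest.mark.parametrize(
        "t_half,dt,expected",
        [
            (1.0, 1.0, 0.5),
            (2.0, 1.0, 1 - 2 ** (-0.5)),
            (1e12, 1.0, 0.0),
        ],
    )
    def test_closed_form(self, t_half, dt, expected):
        assert half_life_to_step_prob(t_half, dt) == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_half_life_rejected(self):
        with pytest.raises(ValueError):
            half_life_to_step_prob(0.0, 1.0)


class TestKineticPriors:
    def test_prior_means_match_stated_locations(self, priors, rng):
        """Sample means of 1e5 draws sit within 3 standard errors of the
        stated prior locations."""
        from scipy import stats as sps

        n = 100_000
        hl = sample_protein_half_lives_hours(n, priors, rng)
        se = hl.std() / np.sqrt(n)
        # rejection of non-positive draws truncates the t prior at 0, which
        # shifts its mean slightly above 1; compare against the analytic
        # truncated mean and check that shift is itself negligible
        alpha = (0.0 - 1.0) / 0.382
        tdist = sps.t(80)
        trunc_mean = 1.0 + 0.382 * tdist.expect(lambda z: z, lb=alpha) / (
            1 - tdist.cdf(alpha)
        )
        assert abs(trunc_mean - 1.0) < 0.01
        assert abs(hl.mean() - trunc_mean) < 3 * se

        lt = sample_log2_translation_rates(n, priors, rng)
        assert abs(lt.mean() - (-5.0)) < 3 * lt.std() / np.sqrt(n)

        tx = sample_transcription_rates_per_hour(n, priors, rng)
        # Gamma(shape=5, rate=2) has mean shape/rate = 2.5 transcripts/hour
        assert abs(tx.mean() - 2.5) < 3 * tx.std() / np.sqrt(n)

    def test_sampled_kinetics_are_valid_probabilities(self, priors, rng):
        kin = sample_gene_kinetics(500, priors, dt=1.0, rng=rng)
        for arr in (kin.r0, kin.d, kin.e, kin.l, kin.r_init):
            assert np.all((arr >= 0) & (arr <= 1))
        # unmarked promoters transcribe at the sampled physiological rate
        np.testing.assert_allclose(kin.r0 * 2, kin.r_init)

    def test_kinetics_roundtrip_through_tsv_frame(self, priors, rng):
        kin = sample_gene_kinetics(10, priors, dt=1.0, rng=rng)
        kin2 = GeneKinetics.from_frame(kin.to_frame())
        np.testing.assert_array_equal(kin.d, kin2.d)
        np.testing.assert_array_equal(kin.r0, kin2.r0)


class TestBirthDeathSteps:
    def test_empty_state_is_absorbing(self, rng):
        x = np.zeros(5, dtype=np.int64)
        out = step_transcripts(x, np.full(5, 0.3), np.zeros(5), rng)
        np.testing.assert_array_equal(out, 0)

    def test_certain_degradation(self, rng):
        x = np.full(5, 7, dtype=np.int64)
        out = step_transcripts(x, np.ones(5), np.zeros(5), rng)
        np.testing.assert_array_equal(out, 0)
        p = np.full(5, 9, dtype=np.int64)
        out = step_proteins(p, x, np.ones(5), np.zeros(5), rng)
        np.testing.assert_array_equal(out, 0)

    def test_invalid_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            step_transcripts(np.zeros(2, dtype=np.int64), np.full(2, 0.1), np.array([0.5, 1.2]), rng)

    def test_stationary_means_match_birth_death_theory(self, rng):
        """Long-run transcript mean -> r/d and protein mean -> (r/d)(l/e).

        Many identical independent genes give clean Monte-Carlo standard
        errors from the cross-gene spread at the final step.
        """
        n, r, d, l, e = 3000, 0.2, 0.05, 0.1, 0.02
        x = np.zeros(n, dtype=np.int64)
        p = np.zeros(n, dtype=np.int64)
        rv = np.full(n, r)
        for _ in range(600):  # ~30 transcript lifetimes, ~12 protein lifetimes
            x = step_transcripts(x, np.full(n, d), rv, rng)
            p = step_proteins(p, x, np.full(n, e), np.full(n, l), rng)
        assert abs(x.mean() - r / d) < 3 * x.std() / np.sqrt(n)
        assert abs(p.mean() - (r / d) * (l / e)) < 3 * p.std() / np.sqrt(n)

    def test_counts_never_negative(self, rng):
        x = rng.integers(0, 10, 50)
        p = rng.integers(0, 50, 50)
        for _ in range(200):
            x = step_transcripts(x, np.full(50, 0.5), np.full(50, 0.5), rng)
            p = step_proteins(p, x, np.full(50, 0.5), np.full(50, 0.5), rng)
            assert np.all(x >= 0) and np.all(p >= 0)


class TestFitness:
    def test_at_target(self):
        ref = FitnessReference(np.array([10.0, 20.0]))
        assert compute_fitness(np.array([10, 20]), ref) == 0.0

    def test_unit_offset(self):
        ref = FitnessReference(np.array([10.0, 20.0]))
        assert compute_fitness(np.array([11, 20]), ref) == -1.0

    def test_matches_loop_oracle(self, rng):
        ref = FitnessReference(rng.uniform(0, 100, 40))
        p = rng.integers(0, 200, 40)
        expected = -sum((a - b) ** 2 for a, b in zip(p, ref.target_protein_median)) ** 0.5
        assert compute_fitness(p, ref) == pytest.approx(expected, rel=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_fitness(np.zeros(3), FitnessReference(np.zeros(4)))


class TestDeltaF:
    def test_constant_history_is_zero(self):
        assert delta_F(np.full(100, -3.0), 10) == 0.0

    def test_block_arithmetic(self):
        assert delta_F([0.0, 0.0, 1.0, 1.0], 2) == 1.0

    def test_warmup_returns_zero(self):
        assert delta_F([1.0, 5.0, 9.0], 2) == 0.0

    def test_matches_block_mean_oracle(self, rng):
        h = rng.normal(size=57)
        w = 9
        expected = np.mean(h[-w:]) - np.mean(h[-2 * w : -w])
        assert delta_F(h, w) == pytest.approx(expected, rel=1e-12)


class TestMarkDynamics:
    def test_unmarked_promoter_only_drifts(self, small_physio, rng):
        cfg = small_physio.replace(p_tunestep=1.0, p_decay=1.0, p_random=0.0)
        chrom = ChromatinState.zeros(50)
        out = update_tuning_marks(chrom, dF=5.0, config=cfg, rng=rng)
        np.testing.assert_array_equal(out.mu, 0)

    def test_all_probabilities_zero_freezes_marks(self, small_physio, rng):
        cfg = small_physio.replace(p_tunestep=0.0, p_decay=0.0, p_random=0.0)
        chrom = ChromatinState(np.array([3, -5, 0]), np.array([1, 2, 3]))
        out = update_tuning_marks(chrom, dF=-2.0, config=cfg, rng=rng)
        np.testing.assert_array_equal(out.mu, chrom.mu)

    def test_directed_increment_support(self, rng):
        """dF>0, mu=+2, certain tunestep: mu rises by 1..tuning_step_max,
        capped at mu_max."""
        cfg = PhysioConfig(mu_max=4, p_tunestep=1.0, p_decay=0.0, p_random=0.0)
        increments = set()
        for _ in range(200):
            chrom = ChromatinState(np.array([2]), np.array([0]))
            out = update_tuning_marks(chrom, dF=1.0, config=cfg, rng=rng)
            increments.add(int(out.mu[0]) - 2)
        assert increments == {1, 2}  # 3 and 4 hit the mu_max=4 cap -> +2
        cfg2 = cfg.replace(mu_max=20)
        incr2 = set()
        for _ in range(300):
            out = update_tuning_marks(ChromatinState(np.array([2]), np.array([0])), 1.0, cfg2, rng)
            incr2.add(int(out.mu[0]) - 2)
        assert incr2 == {1, 2, 3, 4}

    def test_mu_bound_respected(self, rng):
        cfg = PhysioConfig(mu_max=5, p_tunestep=1.0, p_decay=0.2, p_random=1.0)
        chrom = ChromatinState(np.array([5, -5, 3]), np.zeros(3, dtype=int))
        for _ in range(100):
            chrom = update_tuning_marks(chrom, dF=1.0, config=cfg, rng=rng)
            assert np.all(np.abs(chrom.mu) <= 5)

    def test_stabilizing_marks_need_tuning_marks(self, small_physio, rng):
        chrom = ChromatinState.zeros(20)
        out = update_stabilizing_marks(chrom, small_physio.replace(p_s_mark=1.0), rng)
        np.testing.assert_array_equal(out.nu, 0)

    def test_stabilizing_certain_at_saturation(self, rng):
        cfg = PhysioConfig(mu_max=20, p_s_mark=1.0)
        chrom = ChromatinState(np.array([20, -20]), np.array([0, 0]))
        out = update_stabilizing_marks(chrom, cfg, rng)
        np.testing.assert_array_equal(out.nu, [1, -1])

    def test_stabilizing_empirical_rate(self, rng):
        """Increment frequency matches |mu| * p_s_mark / mu_max."""
        n = 100_000
        cfg = PhysioConfig(mu_max=20, p_s_mark=0.4)
        chrom = ChromatinState(np.full(n, 7), np.zeros(n, dtype=int))
        out = update_stabilizing_marks(chrom, cfg, rng)
        freq = np.mean(out.nu == 1)
        p = 7 * 0.4 / 20
        assert abs(freq - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestTranscriptionRate:
    def test_fully_repressed_promoter_silent(self):
        cfg = PhysioConfig(mu_max=10, m_s=0.05)
        chrom = ChromatinState(np.array([-10]), np.array([3]))
        assert transcription_rate(np.array([0.01]), chrom, cfg)[0] == 0.0

    def test_unmarked_promoter_doubles_r0(self):
        cfg = PhysioConfig(mu_max=10)
        chrom = ChromatinState.zeros(1)
        assert transcription_rate(np.array([0.01]), chrom, cfg)[0] == pytest.approx(0.02)

    def test_saturated_activation_quadruples_r0(self):
        cfg = PhysioConfig(mu_max=10)
        chrom = ChromatinState(np.array([10]), np.array([0]))
        assert transcription_rate(np.array([0.01]), chrom, cfg)[0] == pytest.approx(0.04)

    def test_clamped_to_valid_probability(self):
        cfg = PhysioConfig(mu_max=10, m_s=1.0)
        chrom = ChromatinState(np.array([10]), np.array([50]))
        assert transcription_rate(np.array([0.5]), chrom, cfg)[0] == 1.0


class TestFitnessReference:
    def test_zero_target_rates(self, priors, rng):
        cfg = PhysioConfig(n_genes=2, n_steps=200)
        kin = sample_gene_kinetics(2, priors, 1.0, rng)
        ref = build_fitness_reference(kin, np.zeros(2), cfg, rng, length_factor=2)
        np.testing.assert_array_equal(ref.target_protein_median, 0.0)

    def test_reference_median_matches_stationary_mean(self, rng):
        """Single gene r=0.01, d=0.01, l=0.05, e=0.001 has stationary
        protein mean (r/d)(l/e) = 50."""
        kin = GeneKinetics(
            r0=np.array([0.005]), d=np.array([0.01]), e=np.array([0.001]),
            l=np.array([0.05]), r_init=np.array([0.01]),
        )
        cfg = PhysioConfig(n_genes=1, n_steps=10_000)
        ref = build_fitness_reference(kin, np.array([0.01]), cfg, rng, length_factor=3)
        assert 40 <= ref.target_protein_median[0] <= 60

    def test_reproducible_under_seed(self, priors):
        cfg = PhysioConfig(n_genes=1, n_steps=300)
        kin = sample_gene_kinetics(1, priors, 1.0, np.random.default_rng(3))
        r1 = build_fitness_reference(kin, kin.r_init, cfg, np.random.default_rng(9), length_factor=2)
        r2 = build_fitness_reference(kin, kin.r_init, cfg, np.random.default_rng(9), length_factor=2)
        np.testing.assert_array_equal(r1.target_protein_median, r2.target_protein_median)


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(21)
    from stochtune.config import KineticsPriors

    cfg = PhysioConfig(n_genes=1, n_steps=4000, seed=3)
    kin = sample_gene_kinetics(1, KineticsPriors(), cfg.dt, rng)
    target = np.minimum(kin.r_init * 8, 1.0)
    ref = build_fitness_reference(kin, target, cfg, rng, length_factor=2)
    return cfg, kin, target, ref


@pytest.fixture(scope="module")
def sweep_inputs():
    rng = np.random.default_rng(5)
    from stochtune.config import KineticsPriors

    cfg = PhysioConfig(n_genes=1, n_steps=400, seed=11)
    kin = sample_gene_kinetics(1, KineticsPriors(), cfg.dt, rng)
    ref = build_fitness_reference(kin, kin.r_init, cfg, rng, length_factor=1)
    return cfg, kin, ref


class TestSimulatePhysio:
    def test_known_optimum_never_touches_marks(self, setup):
        cfg, kin, target, ref = setup
        traj = simulate_physio(cfg.replace(mode="known_optimum"), kin, ref, target_rates=target)
        np.testing.assert_array_equal(traj.mu, 0)
        np.testing.assert_array_equal(traj.nu, 0)

    @pytest.mark.parametrize("mode", ["tuning", "random_marks", "fixed_baseline", "known_optimum"])
    def test_determinism_per_mode(self, setup, mode):
        cfg, kin, target, ref = setup
        c = cfg.replace(mode=mode)
        t1 = simulate_physio(c, kin, ref, target_rates=target)
        t2 = simulate_physio(c, kin, ref, target_rates=target)
        np.testing.assert_array_equal(t1.fitness, t2.fitness)
        np.testing.assert_array_equal(t1.p, t2.p)

    def test_state_invariants(self, setup):
        cfg, kin, target, ref = setup
        traj = simulate_physio(cfg.replace(mode="tuning"), kin, ref, target_rates=target)
        assert np.all(traj.x >= 0) and np.all(traj.p >= 0)
        assert np.all(np.abs(traj.mu) <= cfg.mu_max)

    def test_known_optimum_outscores_fixed_baseline_for_shifted_target(self, setup):
        """With the target 8-fold above baseline, pinning r at the target
        must beat pinning it at the stale baseline."""
        cfg, kin, target, ref = setup
        cfg = cfg.replace(n_steps=20_000)
        s_opt = score_last_quarter(
            simulate_physio(cfg.replace(mode="known_optimum"), kin, ref, target_rates=target)
        )
        s_base = score_last_quarter(
            simulate_physio(cfg.replace(mode="fixed_baseline"), kin, ref, target_rates=target)
        )
        assert s_opt > s_base


class TestScoring:
    def test_constant_fitness(self):
        assert score_last_quarter(np.full(100, -3.0)) == -3.0

    def test_quarter_rounding(self):
        # n=8 -> last quarter is the final 2 entries, median of {6, 7}
        assert score_last_quarter(np.arange(8.0)) == 6.5

    def test_matches_sort_and_middle_oracle(self, rng):
        series = rng.normal(size=103)
        n_last = -(-103 // 4)
        tail = sorted(series[-n_last:])
        m = len(tail)
        expected = tail[m // 2] if m % 2 else (tail[m // 2 - 1] + tail[m // 2]) / 2
        assert score_last_quarter(series) == pytest.approx(expected, rel=1e-12)


class TestSweep:
    def test_empty_factor_set_gives_baseline_only(self, sweep_inputs):
        cfg, kin, ref = sweep_inputs
        table = sweep_parameters(cfg, kin, ref, factors=(), modes=("tuning",), n_seeds=1)
        assert set(table["parameter"]) == {"baseline"}

    def test_sweep_cell_count(self, sweep_inputs):
        cfg, kin, ref = sweep_inputs
        table = sweep_parameters(cfg, kin, ref, modes=("tuning",), n_seeds=1)
        # 1 baseline + 2 factors x 7 editable parameters
        assert len(table) == 1 + 2 * 7
        assert table["score"].notna().all()

    def test_invalid_probability_cells_clamped_and_flagged(self, sweep_inputs):
        cfg, kin, ref = sweep_inputs
        table = sweep_parameters(
            cfg.replace(p_tunestep=0.9), kin, ref, modes=("tuning",), n_seeds=1
        )
        cell = table[(table.parameter == "p_tunestep") & (table.factor == 2.0)]
        assert bool(cell["clamped"].iloc[0])
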