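"""Generator correctness: planted covariances, schedules, determinism."""

import numpy as np
import pytest

from musicnet import connectivity, graphmetrics, synthgen


@pytest.fixture(scope="module")
def pair():
    return synthgen.make_state_covariances(n_parcels=20, n_blocks=4)


class TestStateCovariances:
    def test_unit_diagonal_symmetric_psd(self, pair):
        for sc in pair:
            C = sc.matrix
            assert np.allclose(np.diag(C), 1.0, atol=1e-12)
            assert np.allclose(C, C.T, atol=1e-12)
            assert np.linalg.eigvalsh(C).min() >= -1e-10

    def test_block_structure_preserved(self, pair):
        modular, integrated = pair
        blocks = modular.block_assignment
        same = blocks[:, None] == blocks[None, :]
        off = ~np.eye(20, dtype=bool)
        within = modular.matrix[same & off]
        between = modular.matrix[~same]
        assert within.min() > between.max()  # block contrast survives repair
        assert np.allclose(
            integrated.matrix[off], integrated.matrix[off][0], atol=1e-10
        )

    def test_planted_metric_separation(self, pair):
        modular, integrated = pair

        def metrics(C):
            W = np.maximum(C.copy(), 0.0)
            np.fill_diagonal(W, 0.0)
            q = graphmetrics.louvain_partition(W, n_runs=20, seed=0).quality_q
            e, _ = graphmetrics.global_efficiency(W)
            return q, e

        q_m, e_m = metrics(modular.matrix)
        q_i, e_i = metrics(integrated.matrix)
        assert q_m - q_i >= 0.1
        assert e_i - e_m >= 0.05

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            synthgen.make_state_covariances(r_within=0.2, r_between_modular=0.5)
        with pytest.raises(ValueError):
            synthgen.StateCovariance(np.array([[1.0, 2.0], [2.0, 1.0]]), "modular")


class TestSchedules:
    def test_stationary_fraction(self):
        rng = np.random.default_rng(0)
        for p in (0.3, 0.62, 0.9):
            sched = synthgen.markov_schedule(200_000, p, 15.0, rng)
            frac = (sched == synthgen.MODULAR).mean()
            assert frac == pytest.approx(p, abs=0.02)

    def test_mean_dwell_length(self):
        rng = np.random.default_rng(1)
        sched = synthgen.markov_schedule(400_000, 0.5, 15.0, rng)
        # with p = 0.5 each regime's leave probability is 0.5/tau, so the
        # mean sojourn is 2*tau = 30 samples
        changes = np.flatnonzero(np.diff(sched)) + 1
        dwells = np.diff(np.concatenate([[0], changes]))
        assert dwells.mean() == pytest.approx(30.0, rel=0.05)

    def test_degenerate_probabilities(self):
        rng = np.random.default_rng(2)
        assert np.all(
            synthgen.markov_schedule(500, 1.0, 10.0, rng) == synthgen.MODULAR
        )
        assert np.all(
            synthgen.markov_schedule(500, 0.0, 10.0, rng) == synthgen.INTEGRATED
        )


class TestSimulateSubject:
    def test_single_regime_recovers_covariance(self):
        modular, _ = synthgen.make_state_covariances(
            n_parcels=10, n_blocks=2, check_separation=False
        )
        covs = {synthgen.MODULAR: modular.matrix}
        ts = synthgen.simulate_subject(
            covs, np.zeros(20_000, dtype=int), seed=3
        )
        emp = np.corrcoef(ts.values.T)
        assert np.abs(emp - modular.matrix).max() < 0.05

    def test_bit_identical_given_seed(self):
        modular, integrated = synthgen.make_state_covariances(
            10, 2, check_separation=False
        )
        covs = {0: modular.matrix, 1: integrated.matrix}
        sched = np.random.default_rng(5).integers(0, 2, 100)
        a = synthgen.simulate_subject(covs, sched, seed=7)
        b = synthgen.simulate_subject(covs, sched, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_mismatched_dimensions_rejected(self):
        with pytest.raises(ValueError):
            synthgen.simulate_subject(
                {0: np.eye(4), 1: np.eye(5)}, np.zeros(10, dtype=int), seed=0
            )


class TestCohort:
    def test_counts_and_groups(self, small_cohort):
        spec, runs, truth = small_cohort
        assert len(runs) == (spec.n_group_a + spec.n_group_b) * 2
        assert sum(g == "A" for g in truth.groups.values()) == spec.n_group_a
        assert sum(g == "B" for g in truth.groups.values()) == spec.n_group_b
        for run in runs:
            assert run.values.shape == (
                spec.n_timepoints_per_condition,
                spec.n_parcels,
            )

    def test_dwell_bias_direction(self, small_cohort):
        _, _, truth = small_cohort
        assert truth.modular_fraction("cond1") > truth.modular_fraction("cond2")

    def test_deterministic(self):
        spec = synthgen.small_profile(seed=21)
        runs_a, truth_a = synthgen.simulate_cohort(spec)
        runs_b, truth_b = synthgen.simulate_cohort(spec)
        for ra, rb in zip(runs_a, runs_b):
            assert np.array_equal(ra.values, rb.values)
        for key in truth_a.schedules:
            assert np.array_equal(truth_a.schedules[key], truth_b.schedules[key])

    def test_group_boost_raises_planted_efficiency(self):
        # the boosted covariance pair used for group A in condition 2 has
        # strictly higher planted static efficiency than the baseline
        modular, integrated = synthgen.make_state_covariances(20, 4)
        blocks = modular.block_assignment
        same = blocks[:, None] == blocks[None, :]

        def eff(C):
            W = np.maximum(C.copy(), 0.0)
            np.fill_diagonal(W, 0.0)
            return graphmetrics.global_efficiency(W)[0]

        delta = 0.075
        B = modular.matrix + np.where(same, 0.0, delta)
        np.fill_diagonal(B, 1.0)
        B = synthgen._psd_repair(B)
        assert eff(B) > eff(modular.matrix)

    def test_write_cohort_artifacts(self, tmp_path):
        spec = synthgen.small_profile(seed=3, n_group_a=2, n_group_b=2)
        runs, truth = synthgen.simulate_cohort(spec)
        design = synthgen.write_cohort(tmp_path, runs, truth, spec)
        assert len(design) == 8
        assert (tmp_path / "design.csv").exists()
        assert (tmp_path / "ground_truth.json").exists()
        for _, row in design.iterrows():
            assert (tmp_path / row["path"]).exists()
        rt = connectivity.read_roi_tsv(
            tmp_path / design.iloc[0]["path"], spec.tr_seconds
        )
        assert np.allclose(rt.values, runs[0].values, atol=1e-9)


class TestAudioAndCoupling:
    def test_validation(self):
        with pytest.raises(ValueError):
            synthgen.synth_audio(120.0, 4000.0, (0.0, 1.5), seed=0)
        with pytest.raises(ValueError):
            synthgen.synth_audio(90.0, 4000.0, (0.0,), seed=0)  # not a multiple
        with pytest.raises(ValueError):
            synthgen.synth_audio(60.0, 500.0, (0.0,), seed=0)  # below Nyquist
        with pytest.raises(ValueError):
            synthgen.synth_audio(120.0, 4000.0, (0.0,), seed=0)  # wrong count

    def test_pure_harmonic_segment_is_noiseless(self):
        a = synthgen.synth_audio(120.0, 4000.0, (0.0, 1.0), seed=4)
        b = synthgen.synth_audio(120.0, 4000.0, (0.0, 1.0), seed=99)
        seg = int(60 * 4000)
        assert np.array_equal(a.samples[:seg], b.samples[:seg])  # seed-free
        assert not np.array_equal(a.samples[seg:], b.samples[seg:])
        # harmonic is unit-RMS over the full signal, so a 60-s slice is close
        rms = np.sqrt(np.mean(a.samples[:seg] ** 2))
        assert rms == pytest.approx(1.0, abs=1e-3)

    def test_coupled_profile_probabilities(self):
        spec, alphas = synthgen.entropy_coupled_profile(seed=0)
        for cond, al in alphas.items():
            expected = [float(np.clip(0.9 - 0.7 * a, 0.0, 1.0)) for a in al]
            assert spec.segment_modular_prob[cond] == expected
        # planted direction: condition 1 more modular than condition 2
        m1 = np.mean(spec.segment_modular_prob["cond1"])
        m2 = np.mean(spec.segment_modular_prob["cond2"])
        assert m1 > m2
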