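import numpy as np
import pytest

from dnacyclize._quat import quat_multiply, quat_rotate, quat_to_matrix
from dnacyclize.elastic import MoleculeSpec, StiffnessSet, sample_steps
from dnacyclize.geometry import frames_from_steps
from dnacyclize.montecarlo import (
    NM_PER_INV_CUBIC_ANGSTROM,
    BinGrid,
    HalfEnsemble,
    brute_force_count,
    compute_J,
    convergence_check,
    cyclization_profile,
    default_split,
    estimate_J,
    generate_half_ensemble,
    pair_and_count,
)
from dnacyclize.so3 import ClosureTolerances, haar_ball_volume, haar_sample_quat

#: cheap, hit-rich configuration used by the stochastic invariance checks
FAT = ClosureTolerances(60.0, 0.6)


@pytest.fixture(scope="module")
def small_ensembles():
    spec = MoleculeSpec.single_bend(90.0, 147)
    m = default_split(147)
    first = generate_half_ensemble(spec, "first", m, 1500, 11)
    second = generate_half_ensemble(spec, "second", m, 1500, 12)
    return first, second


class TestHalfEnsembles:
    def test_zero_temperature_limit(self):
        # huge stiffness: every sample collapses to the intrinsic sub-chain
        spec = MoleculeSpec.single_bend(
            90.0, 147, stiffness=StiffnessSet.baseline(scale_beta=1e14)
        )
        m = default_split(147)
        second = generate_half_ensemble(spec, "second", m, 16, 0)
        theta, trans = spec.intrinsic_shape()
        origins, quats = frames_from_steps(theta[m - 1 :], trans[m - 1 :])
        assert np.allclose(second.end_pos, origins[-1], atol=1e-4)
        assert np.abs(second.end_pos - second.end_pos[0]).max() < 1e-4

    def test_pair_reconstructs_full_chain(self, baseline_spec, rng):
        # gluing a first and second half reproduces the directly composed
        # end state: r = r1 + T1 r2, T = T1 T2, and the stored first-half
        # transform makes |e - b| the lab-frame end-to-end distance
        N, m = baseline_spec.N, 70
        for _ in range(25):
            theta, trans = sample_steps(baseline_spec, 1, N, rng)
            o_full, q_full = frames_from_steps(theta, trans)
            o1, q1 = frames_from_steps(theta[: m - 1], trans[: m - 1])
            o2, q2 = frames_from_steps(theta[m - 1 :], trans[m - 1 :])
            r = o1[-1] + quat_rotate(q1[-1], o2[-1])
            assert np.allclose(r, o_full[-1], atol=1e-8)
            assert np.allclose(
                quat_to_matrix(quat_multiply(q1[-1], q2[-1])),
                quat_to_matrix(q_full[-1]),
                atol=1e-8,
            )
            conj = q1[-1] * np.array([1.0, -1, -1, -1])
            b = -quat_rotate(conj, o1[-1])
            assert np.isclose(
                np.linalg.norm(o2[-1] - b), np.linalg.norm(o_full[-1]), atol=1e-8
            )

    def test_invalid_split(self, baseline_spec):
        with pytest.raises(ValueError):
            generate_half_ensemble(baseline_spec, "first", 1, 10, 0)

    def test_deterministic_given_seed(self, baseline_spec):
        a = generate_half_ensemble(baseline_spec, "second", 74, 64, 123)
        b = generate_half_ensemble(baseline_spec, "second", 74, 64, 123)
        assert np.array_equal(a.end_pos, b.end_pos)
        assert np.array_equal(a.end_quat, b.end_quat)


class TestPairing:
    def test_binned_equals_brute_force(self, small_ensembles):
        first, second = small_ensembles
        for eps, delta in [(15, 0.15), (30, 0.3), (60, 0.6), (100, 1.0)]:
            tol = ClosureTolerances(eps, delta)
            assert pair_and_count(first, second, tol) == brute_force_count(
                first, second, tol
            )

    def test_tiny_eps_no_hits(self, small_ensembles):
        first, second = small_ensembles
        assert pair_and_count(first, second, ClosureTolerances(1e-9, 0.5)) == 0

    def test_delta_one_is_translation_only(self, small_ensembles):
        first, second = small_ensembles
        tol = ClosureTolerances(80.0, 1.0)
        n = pair_and_count(first, second, tol)
        d = first.end_pos[:, None, :] - second.end_pos[None, :, :]
        expected = int(np.sum(np.einsum("ijk,ijk->ij", d, d) <= tol.eps**2))
        assert n == expected

    def test_lab_rotation_invariance(self, small_ensembles, rng):
        # rotating every end state by a fixed lab rotation preserves counts
        first, second = small_ensembles
        q = haar_sample_quat(rng)
        Q = quat_to_matrix(q)
        rot_first = HalfEnsemble(
            "first",
            first.M,
            first.end_pos @ Q.T,
            quat_multiply(q, first.end_quat),
            first.split_m,
            first.N,
        )
        conj = q * np.array([1.0, -1, -1, -1])
        rot_second = HalfEnsemble(
            "second",
            second.M,
            second.end_pos @ Q.T,
            quat_multiply(second.end_quat, conj),
            second.split_m,
            second.N,
        )
        tol = ClosureTolerances(60.0, 0.6)
        assert pair_and_count(rot_first, rot_second, tol) == pair_and_count(
            first, second, tol
        )

    def test_too_fine_grid_rejected(self, small_ensembles):
        first, second = small_ensembles
        grid = BinGrid(n_z_bins=4096, xy_bin_width=30.0, z_range=(-500.0, 500.0))
        with pytest.raises(ValueError, match="bin width"):
            pair_and_count(first, second, ClosureTolerances(30.0, 0.3), grid)

    def test_mismatched_ensembles_rejected(self, baseline_spec, small_ensembles):
        first, _ = small_ensembles
        other = generate_half_ensemble(baseline_spec, "second", 80, 100, 1)
        with pytest.raises(ValueError, match="split"):
            pair_and_count(first, other, ClosureTolerances(30.0, 0.3))


class TestEstimateJ:
    def test_zero_hits_upper_bound(self):
        est = estimate_J(0, 1000, ClosureTolerances(30.0, 0.3))
        assert est.is_upper_bound
        assert est.J_nM > 0 and not np.isfinite(est.stderr_log10)

    def test_known_conversion(self):
        tol = ClosureTolerances(30.0, 0.3)
        est = estimate_J(100, 1 << 10, tol)
        manual = (
            100
            / (2.0**20 * tol.volume_trans * haar_ball_volume(0.3))
            * NM_PER_INV_CUBIC_ANGSTROM
        )
        assert np.isclose(est.J_nM, manual)
        assert np.isclose(est.stderr_log10, 0.1 / np.log(10))

    def test_planted_uniform_density(self, rng):
        # ends uniform in a box, orientations Haar: the recovered J is the
        # known analytic density 1/L^3 (in nM)
        L, margin, M = 220.0, 31.0, 4000
        tol = ClosureTolerances(30.0, 0.35)
        first = HalfEnsemble(
            "first",
            M,
            rng.uniform(0, L, (M, 3)),
            haar_sample_quat(rng, M),
            70,
            147,
        )
        second = HalfEnsemble(
            "second",
            M,
            rng.uniform(margin, L - margin, (M, 3)),
            haar_sample_quat(rng, M),
            70,
            147,
        )
        hits = pair_and_count(first, second, tol)
        est = estimate_J(hits, M, tol)
        expected = NM_PER_INV_CUBIC_ANGSTROM / L**3
        assert abs(np.log10(est.J_nM) - np.log10(expected)) < 3 * est.stderr_log10


class TestComputeJ:
    def test_seed_reproducibility(self, baseline_spec):
        a = compute_J(baseline_spec, 1 << 12, FAT, seed=3)
        b = compute_J(baseline_spec, 1 << 12, FAT, seed=3)
        assert a.hits == b.hits and a.J_nM == b.J_nM

    def test_split_invariance(self, baseline_spec):
        # J must not depend on where the molecule is cut (within counting
        # error, which is correlation-inflated at these tolerances);
        # balanced versus one-third split
        M = 1 << 15
        a = compute_J(baseline_spec, M, FAT, seed=21)
        b = compute_J(baseline_spec, M, FAT, seed=22, split_m=(147 + 1) // 3)
        sigma = np.hypot(a.stderr_log10, b.stderr_log10)
        assert abs(a.log10J - b.log10J) < 3.5 * sigma

    def test_corrected_stderr_tracks_seed_scatter(self, baseline_spec):
        # glued molecules share halves, so hits are a U-statistic: the
        # quoted error must reflect that, not bare Poisson counting
        vals, errs, hits = [], [], []
        for seed in range(6):
            e = compute_J(baseline_spec, 1 << 13, FAT, seed=40 + seed)
            vals.append(e.log10J)
            errs.append(e.stderr_log10)
            hits.append(e.hits)
        poisson = 1.0 / (np.log(10) * np.sqrt(np.mean(hits)))
        assert np.mean(errs) > 2 * poisson  # correlation inflation is real
        assert np.std(vals) < 4 * np.mean(errs)  # and roughly calibrated

    def test_tolerance_halving_stability(self, baseline_spec):
        # in the small-ball regime, halving (eps, delta) must leave log10 J
        # unchanged within the quoted (correlation-aware) errors
        ok, est, est_h = convergence_check(
            baseline_spec, 1 << 18, ClosureTolerances(30.0, 0.3), seed=31, n_sigma=3.5
        )
        assert not est.is_upper_bound and not est_h.is_upper_bound
        assert ok


class TestProfile:
    def test_profile_structure_and_period(self, baseline_spec):
        # coarse, fast profile: strong oscillation with period near the
        # helical repeat must survive even a low-M run
        # delta must stay moderate here: a wide orientation ball averages
        # over several bp of twist phase and damps the oscillation itself
        prof = cyclization_profile(
            baseline_spec,
            N_values=range(146, 171),
            M=1 << 14,
            tol=ClosureTolerances(60.0, 0.4),
            seed=9,
        )
        df = prof.data
        assert list(df["N"]) == list(range(146, 171))
        assert df["hits"].max() > 50
        good = prof.fit_points
        assert good.shape[0] >= 10
        res = prof.fit()
        assert 9.5 <= res.p <= 11.5
        assert abs(res.p - 10.5) < 0.7
        assert 145 < res.phi <= 145 + res.p

    def test_roundtrip_csv(self, baseline_spec, tmp_path):
        prof = cyclization_profile(
            baseline_spec,
            N_values=range(146, 150),
            M=1 << 10,
            tol=ClosureTolerances(80.0, 0.8),
            seed=9,
        )
        path = tmp_path / "prof.csv"
        prof.to_csv(path)
        back = type(prof).from_csv(path)
        assert np.allclose(
            back.data["log10J"], prof.data["log10J"], equal_nan=True
        )
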