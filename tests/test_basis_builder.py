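"""PCA of reaction paths, shifted-basis generation, pruning, orbit counting."""

import numpy as np
import pytest

from sbg.basis import make_basis
from sbg.basis_builder import (BuildConfig, BuildReport,
                               count_unique_evaluations,
                               generate_shifted_centers,
                               local_normal_mode_shifts, pca_of_path,
                               place_on_irc, prune_and_finalize,
                               select_components, shift_distance,
                               build_basis_set)
from sbg.fixtures import DOUBLE_WELL_V_CONST_CM, synthetic_irc
from sbg.geometry import path_from_points
from sbg.matrix_elements import assemble, overlap
from sbg.pes import DoubleWellProvider, HarmonicProvider, SymmetryOperation
from sbg.solver import solve


@pytest.fixture(scope="module")
def dw_cfg():
    return BuildConfig(n_irc_bases=9, v_const_wavenumber=DOUBLE_WELL_V_CONST_CM)


class TestPlaceOnIrc:
    def test_two_bases_sit_at_endpoints(self, dw1d, dw1d_path):
        cfg = BuildConfig(n_irc_bases=2, v_const_wavenumber=DOUBLE_WELL_V_CONST_CM)
        bases = place_on_irc(dw1d_path, dw1d, cfg)
        assert bases[0].center[0] == pytest.approx(-25.0, abs=1e-6)
        assert bases[1].center[0] == pytest.approx(25.0, abs=1e-6)

    def test_equal_arc_spacing(self, dw1d, dw1d_path, dw_cfg):
        bases = place_on_irc(dw1d_path, dw1d, dw_cfg)
        centers = np.array([b.center[0] for b in bases])
        assert np.allclose(np.diff(centers), np.diff(centers)[0], atol=1e-6)

    def test_uniform_widths_give_equal_adjacent_overlaps(self):
        prov = HarmonicProvider(np.array([[1e-4]]))
        path = path_from_points(np.linspace(-5, 5, 40)[:, None])
        cfg = BuildConfig(n_irc_bases=5)
        report = BuildReport()
        place_on_irc(path, prov, cfg, report)
        assert np.allclose(report.adjacent_overlaps,
                           report.adjacent_overlaps[0], atol=1e-10)

    def test_adjacent_overlap_near_target_regime(self, dw1d, dw1d_path):
        # spacing chosen so overlaps land in the practical 0.65-0.85 window
        cfg = BuildConfig(n_irc_bases=7, v_const_wavenumber=DOUBLE_WELL_V_CONST_CM)
        rep = BuildReport()
        place_on_irc(dw1d_path, dw1d, cfg, rep)
        assert all(0.65 <= s <= 0.85 for s in rep.adjacent_overlaps)


class TestPca:
    def test_collinear_path_rank_one(self):
        u = np.array([3.0, 4.0]) / 5.0
        t = np.linspace(0, 10, 25)
        path = path_from_points(np.outer(t, u))
        pca = pca_of_path(path)
        assert abs(pca.components[:, 0] @ u) == pytest.approx(1.0, abs=1e-12)
        assert pca.variances[0] == pytest.approx(np.sum((t - t.mean()) ** 2),
                                                 rel=1e-10)
        assert pca.variances[1] < 1e-12 * pca.variances[0]

    def test_planar_arc_rank_two(self):
        t = np.linspace(0, np.pi, 40)
        pts = np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
        pca = pca_of_path(path_from_points(pts))
        assert pca.ratios[1] > 1e-3
        assert pca.ratios[2] < 1e-12

    def test_variance_sum_equals_covariance_trace(self, dw1d_path):
        dense = dw1d_path.resample(200)
        pca = pca_of_path(dense)
        centered = dense.points - dense.points.mean(0)
        assert pca.variances.sum() == pytest.approx(
            np.trace(centered.T @ centered), rel=1e-8)
        gram = pca.components.T @ pca.components
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_coupled_well_has_second_component(self):
        prov = DoubleWellProvider(1.6e-2, 25.0, omegas=(4e-3,),
                                  couplings=(0.002,))
        path = synthetic_irc(prov, step=0.5)
        pca = pca_of_path(path.resample(300))
        assert pca.ratios[1] > 1e-6

    def test_separable_well_path_on_axis(self):
        prov = DoubleWellProvider(1.6e-2, 25.0, omegas=(4e-3,))
        path = synthetic_irc(prov, step=0.5)
        assert np.abs(path.points[:, 1]).max() < 1e-6


class TestSelectComponents:
    def test_threshold_selects_top_components(self):
        pca = pca_of_path(path_from_points(
            np.outer(np.linspace(0, 1, 10), [1.0, 0.0])))
        ratios = np.array([1.0, 1.3e-2, 1e-10])
        fake = type(pca)(mean=np.zeros(3), components=np.eye(3),
                         variances=ratios)
        assert select_components(fake, 1e-3) == [0, 1]
        assert select_components(fake, 1.0) == [0]
        assert select_components(fake, 1e-12) == [0, 1, 2]


class TestShiftDistance:
    def test_1d_closed_form(self):
        b = make_basis(np.zeros(1), np.array([[4.0]]), 700.0)
        # alpha = 1: d = sqrt(-2 ln 0.75)
        assert b.width[0, 0] == pytest.approx(1.0, rel=1e-12)
        d = shift_distance(b, np.array([1.0]), 0.75)
        assert d == pytest.approx(np.sqrt(-2.0 * np.log(0.75)), abs=1e-8)
        assert d == pytest.approx(0.75853, abs=1e-5)

    def test_limit_target_one(self):
        b = make_basis(np.zeros(1), np.array([[4.0]]), 700.0)
        assert shift_distance(b, np.array([1.0]), 0.999999) < 2e-3

    def test_anisotropic_closed_form_and_monotonicity(self):
        w = np.diag([4.0, 0.25])
        b = make_basis(np.zeros(2), (2 * w) @ (2 * w), 700.0)
        np.testing.assert_allclose(b.width, w, rtol=1e-10)
        d_stiff = shift_distance(b, np.array([1.0, 0.0]), 0.75)
        d_soft = shift_distance(b, np.array([0.0, 1.0]), 0.75)
        assert d_stiff < d_soft
        for u, aeff in ((np.array([1.0, 0.0]), 4.0), (np.array([0.0, 1.0]), 0.25)):
            closed = np.sqrt(-2.0 * np.log(0.75) / aeff)
            assert shift_distance(b, u, 0.75) == pytest.approx(closed, abs=1e-8)

    def test_non_unit_direction_rejected(self):
        b = make_basis(np.zeros(1), np.array([[4.0]]), 700.0)
        with pytest.raises(ValueError):
            shift_distance(b, np.array([2.0]), 0.75)


class TestShiftGeneration:
    def _fake_pca(self, dim):
        from sbg.basis_builder import PcaResult
        return PcaResult(mean=np.zeros(dim), components=np.eye(dim),
                         variances=np.arange(dim, 0, -1.0))

    def test_combinatorics_one_center_two_pcs(self):
        b = make_basis(np.zeros(3), np.diag([1e-4, 2e-4, 3e-4]), 700.0)
        cfg = BuildConfig()
        cands = generate_shifted_centers([b], self._fake_pca(3), [0, 1], cfg)
        assert len(cands) == 2 * 2 + 4 * 1  # 2k + 4*C(k,2), k=2

    def test_combinatorics_one_center_one_pc(self):
        b = make_basis(np.zeros(3), np.diag([1e-4, 2e-4, 3e-4]), 700.0)
        cands = generate_shifted_centers([b], self._fake_pca(3), [0],
                                         BuildConfig())
        assert len(cands) == 2

    def test_combinatorics_five_centers_two_pcs(self):
        bases = [make_basis(np.array([float(i), 0.0]), np.diag([1e-4, 2e-4]),
                            700.0) for i in range(5)]
        cands = generate_shifted_centers(bases, self._fake_pca(2), [0, 1],
                                         BuildConfig())
        assert len(cands) == 40

    def test_first_order_only(self):
        b = make_basis(np.zeros(2), np.diag([1e-4, 2e-4]), 700.0)
        cands = generate_shifted_centers([b], self._fake_pca(2), [0, 1],
                                         BuildConfig(second_order=False))
        assert len(cands) == 4


class TestPruning:
    def test_duplicate_candidate_removed(self, dw1d, dw_cfg, dw1d_path):
        irc = place_on_irc(dw1d_path, dw1d, dw_cfg)
        from sbg.basis_builder import _Candidate
        dup = _Candidate(irc[0].center.copy(), (0, 0, 0, 0))
        rep = BuildReport()
        final = prune_and_finalize([dup], irc, dw1d, dw_cfg, rep)
        assert len(final) == len(irc)
        assert rep.n_pruned_duplicates == 1

    def test_overlap_threshold_logic(self, dw1d, dw1d_path):
        irc = place_on_irc(dw1d_path, dw1d,
                           BuildConfig(n_irc_bases=5,
                                       v_const_wavenumber=DOUBLE_WELL_V_CONST_CM))
        from sbg.basis_builder import _Candidate
        near = _Candidate(irc[2].center + 0.5, (0,))
        tight = BuildConfig(n_irc_bases=5, prune_overlap_max=0.5,
                            target_overlap=0.4,
                            v_const_wavenumber=DOUBLE_WELL_V_CONST_CM)
        loose = BuildConfig(n_irc_bases=5, prune_overlap_max=0.9995,
                            v_const_wavenumber=DOUBLE_WELL_V_CONST_CM)
        kept_tight = prune_and_finalize([near], irc, dw1d, tight)
        kept_loose = prune_and_finalize([near], irc, dw1d, loose)
        assert len(kept_tight) == len(irc)
        assert len(kept_loose) == len(irc) + 1

    def test_final_set_respects_overlap_bound(self, dw1d_build):
        bases, _, cfg = dw1d_build
        n_irc = 9
        added = bases[n_irc:]
        for i, b in enumerate(added):
            others = bases[:n_irc] + added[:i]
            assert max(overlap(b, o) for o in others) <= cfg.prune_overlap_max + 1e-9


class TestEvaluationCounting:
    def _chain(self, n=5):
        prov = DoubleWellProvider(1.6e-2, 25.0)
        centers = np.linspace(-25, 25, n)
        return [make_basis(np.array([c]), prov.evaluate(np.array([c])).hessian,
                           2800.0) for c in centers]

    def test_identity_counts(self):
        bases = self._chain(5)
        assert count_unique_evaluations(bases) == 15
        assert count_unique_evaluations(bases, mode="centers") == 5
        assert count_unique_evaluations(self._chain(3)[:1]) == 1

    def test_reflection_reduces_pairs_to_nine(self):
        bases = self._chain(5)
        sym = SymmetryOperation(np.array([[-1.0]]))
        assert count_unique_evaluations(bases, sym, "pairs") == 9

    def test_reflection_center_orbits(self):
        bases = self._chain(5)
        sym = SymmetryOperation(np.array([[-1.0]]))
        assert count_unique_evaluations(bases, sym, "centers") == 3

    def test_non_permuting_symmetry_rejected(self):
        prov = DoubleWellProvider(1.6e-2, 25.0)
        bases = [make_basis(np.array([c]), prov.evaluate(np.array([c])).hessian,
                            2800.0) for c in (0.0, 10.0)]
        sym = SymmetryOperation(np.array([[-1.0]]))
        with pytest.raises(ValueError):
            count_unique_evaluations(bases, sym)


class TestLocalNormalModes:
    def test_axis_aligned_for_diagonal_hessian(self):
        prov = HarmonicProvider(np.diag([1e-4, 4e-4]))
        b = make_basis(np.zeros(2), prov.evaluate(np.zeros(2)).hessian, 700.0)
        cands = local_normal_mode_shifts([b], prov, BuildConfig())
        assert len(cands) == 2 * 2 + 4 * 1
        for c in cands[:4]:
            # first-order shifts move along exactly one axis
            assert np.sum(np.abs(c.center) > 1e-12) == 1

    def test_combinatorics(self):
        prov = HarmonicProvider(np.diag([1e-4, 2e-4, 4e-4]))
        b = make_basis(np.zeros(3), prov.evaluate(np.zeros(3)).hessian, 700.0)
        cands = local_normal_mode_shifts([b], prov, BuildConfig())
        m = 3
        assert len(cands) == 2 * m + 4 * (m * (m - 1) // 2)

    def test_matches_pca_build_on_separable_well(self, dw1d, dw1d_path, dw1d_dvr):
        from sbg.units import HARTREE_TO_CM

        cfg = BuildConfig(n_irc_bases=9, v_const_wavenumber=DOUBLE_WELL_V_CONST_CM)
        bases_pca, _ = build_basis_set(dw1d_path, dw1d, cfg, mode="pca")
        bases_lnm, _ = build_basis_set(dw1d_path, dw1d, cfg, mode="local_modes")
        s_pca = solve(assemble(bases_pca, dw1d)).levels_rel_cm1[1]
        s_lnm = solve(assemble(bases_lnm, dw1d)).levels_rel_cm1[1]
        ref = (dw1d_dvr[1] - dw1d_dvr[0]) * HARTREE_TO_CM
        assert s_pca == pytest.approx(ref, rel=0.05)
        assert s_lnm == pytest.approx(ref, rel=0.05)


class TestVariationalImprovement:
    def test_adding_bases_lowers_ground_state(self, dw1d, dw1d_path):
        # the local-harmonic potential is not strictly variational, so
        # monotone improvement is asserted to its accuracy (~1e-5 hartree)
        zpes = []
        for n in (5, 9, 13):
            cfg = BuildConfig(n_irc_bases=n,
                              v_const_wavenumber=DOUBLE_WELL_V_CONST_CM)
            bases, _ = build_basis_set(dw1d_path, dw1d, cfg)
            zpes.append(solve(assemble(bases, dw1d)).zpe)
        assert zpes[1] <= zpes[0] + 1e-5
        assert zpes[2] <= zpes[1] + 1e-5


class TestBuildConfigValidation:
    def test_invalid_overlap_ordering(self):
        with pytest.raises(ValueError):
            BuildConfig(target_overlap=0.95, prune_overlap_max=0.9)
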