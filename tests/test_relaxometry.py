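"""Fitter unit tests: round trips on noiseless data, optimality oracles,
and the map-level orchestration."""

import numpy as np
import pytest
import scipy.optimize

from qmyelin.cohort import (PhantomGeometry, build_label_volume,
                            default_tissues, sample_subject)
from qmyelin.forward import simulate_acquisitions
from qmyelin.relaxometry import (RegConfig, SrcConfig, T2Grid,
                                 TIGHT_SRC_BOUNDS, compute_mtr, epg_basis,
                                 fit_despot1_hifi, fit_despot2_fm,
                                 fit_mcdespot_src, fit_subject,
                                 fit_t2_spectrum, mwf_from_spectrum,
                                 _despot1_linear, _tikhonov_nnls)
from qmyelin.signals import (GraseProtocol, McDespotProtocol, TwoPoolParams,
                             bssfp_signal, irspgr_signal, multicomponent_decay,
                             spgr_signal, two_pool_signals)

RECOVERY_GRID = T2Grid(custom_points=(15.0, 20.0, 28.0, 40.0, 60.0, 80.0,
                                      120.0, 250.0, 600.0, 2000.0))


class TestT2Spectrum:
    def test_noiseless_two_component_recovery(self):
        prot = GraseProtocol()
        decay = multicomponent_decay([0.12, 0.88], [20.0, 80.0], 1000.0,
                                     prot, 180.0)
        spec = fit_t2_spectrum(decay, prot, RECOVERY_GRID,
                               RegConfig(mode="none"))
        assert spec.refocus_estimate == pytest.approx(180.0, abs=1.0)
        pts = RECOVERY_GRID.points
        assert spec.weights[pts == 20.0][0] == pytest.approx(0.12, abs=1e-3)
        assert spec.weights[pts == 80.0][0] == pytest.approx(0.88, abs=1e-3)

    def test_noiseless_low_flip_recovery(self):
        prot = GraseProtocol()
        decay = multicomponent_decay([0.12, 0.88], [20.0, 80.0], 1000.0,
                                     prot, 120.0)
        spec = fit_t2_spectrum(decay, prot, RECOVERY_GRID,
                               RegConfig(mode="none"))
        assert spec.refocus_estimate == pytest.approx(120.0, abs=1.0)
        assert mwf_from_spectrum(spec, RECOVERY_GRID) == pytest.approx(
            0.12, abs=1e-3)

    def test_single_long_component_gives_no_myelin(self):
        prot = GraseProtocol()
        decay = multicomponent_decay([1.0], [80.0], 1000.0, prot, 180.0)
        spec = fit_t2_spectrum(decay, prot, T2Grid(), RegConfig(mode="none"))
        assert mwf_from_spectrum(spec, T2Grid()) < 0.005

    def test_nnls_optimality_against_random_feasible(self, rng):
        prot = GraseProtocol()
        grid = T2Grid()
        decay = multicomponent_decay([0.2, 0.8], [25.0, 90.0], 1000.0, prot,
                                     160.0)
        noisy = decay + rng.normal(0, 0.005, decay.shape)
        noisy = np.abs(noisy)
        spec = fit_t2_spectrum(noisy, prot, grid, RegConfig(mode="none"))
        a = epg_basis(prot, grid, spec.refocus_estimate)
        res_opt = np.linalg.norm(a @ spec.weights - noisy)
        scale = spec.weights.sum()
        perturbed = np.abs(spec.weights[None, :]
                           + rng.normal(0, 0.02 * scale, (10_000, grid.count)))
        res_rand = np.linalg.norm(perturbed @ a.T - noisy, axis=1)
        assert np.all(res_opt <= res_rand + 1e-12)

    def test_nnls_optimality_against_lattice_oracle(self, rng):
        """Exhaustive grid oracle on a 3-point T2 grid: no lattice point
        beats the NNLS solution."""
        import itertools
        prot = GraseProtocol(etl=16)
        grid = T2Grid(custom_points=(20.0, 80.0, 400.0))
        decay = multicomponent_decay([0.15, 0.7, 0.15],
                                     [20.0, 80.0, 400.0], 1000.0, prot,
                                     180.0)
        noisy = np.abs(decay + rng.normal(0, 0.01, decay.shape))
        a = epg_basis(prot, grid, 180.0)
        x_opt, r_opt = scipy.optimize.nnls(a, noisy)
        axis = np.arange(0, 1.0001, 0.02)
        best_lattice = min(
            np.linalg.norm(a @ np.array(x) - noisy)
            for x in itertools.product(axis, repeat=3))
        assert r_opt <= best_lattice + 1e-12

    def test_tikhonov_chi2_inflation_criterion(self, rng):
        prot = GraseProtocol()
        grid = T2Grid()
        decay = multicomponent_decay([0.12, 0.88], [20.0, 80.0], 1000.0,
                                     prot, 180.0)
        noisy = np.abs(decay + rng.normal(0, 0.008, decay.shape))
        reg = RegConfig()
        a = epg_basis(prot, grid, 180.0)
        x0, r0 = scipy.optimize.nnls(a, noisy)
        x, rnorm, mu = _tikhonov_nnls(a, noisy, reg)
        assert mu > 0
        chi_ratio = rnorm ** 2 / r0 ** 2
        assert reg.chi2_min <= chi_ratio <= reg.chi2_max

    def test_all_zero_decay_rejected(self):
        with pytest.raises(ValueError):
            fit_t2_spectrum(np.zeros(32), GraseProtocol(), T2Grid(),
                            RegConfig())

    def test_bad_reg_mode(self):
        with pytest.raises(ValueError):
            RegConfig(mode="ridge")


class TestMwfFromSpectrum:
    grid = T2Grid(custom_points=(10.0, 20.0, 40.0, 80.0, 2000.0))

    def test_direct_ratio(self):
        w = np.array([0.0, 0.15, 0.0, 0.85, 0.0])
        assert mwf_from_spectrum(w, self.grid) == pytest.approx(0.15)

    def test_all_inside_window(self):
        w = np.array([0.2, 0.5, 0.3, 0.0, 0.0])
        assert mwf_from_spectrum(w, self.grid) == 1.0

    def test_all_at_long_t2(self):
        w = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        assert mwf_from_spectrum(w, self.grid) == 0.0

    def test_window_bounds_inclusive(self):
        w = np.array([0.5, 0.0, 0.5, 0.0, 0.0])  # mass at exactly 10 and 40
        assert mwf_from_spectrum(w, self.grid) == 1.0

    def test_zero_total_weight_masked(self):
        assert np.isnan(mwf_from_spectrum(np.zeros(5), self.grid))


class TestDespot1Hifi:
    def test_noiseless_recovery(self, mcdespot_protocol):
        prot = mcdespot_protocol
        spgr = spgr_signal(1.0, 900.0, np.array(prot.spgr_alphas),
                           prot.spgr_tr, 1.0)
        ir = irspgr_signal(1.0, 900.0, prot, 1.0)
        t1, m0, kappa = fit_despot1_hifi(spgr, ir, prot)
        assert t1 == pytest.approx(900.0, rel=1e-3)
        assert kappa == pytest.approx(1.0, abs=5e-3)
        assert m0 == pytest.approx(1.0, rel=1e-3)

    def test_miscalibrated_b1_recovery(self, mcdespot_protocol):
        prot = mcdespot_protocol
        spgr = spgr_signal(1.4, 900.0, np.array(prot.spgr_alphas),
                           prot.spgr_tr, 1.1)
        ir = irspgr_signal(1.4, 900.0, prot, 1.1)
        t1, m0, kappa = fit_despot1_hifi(spgr, ir, prot)
        assert kappa == pytest.approx(1.1, rel=5e-3)
        assert t1 == pytest.approx(900.0, rel=1e-3)

    def test_two_point_closed_form_slope(self):
        """Linearized DESPOT1 identity: slope = E1, t1 = -tr/ln(slope)."""
        tr, t1 = 6.5, 1100.0
        alphas = np.array([4.0, 18.0])
        s = spgr_signal(1.0, t1, alphas, tr)
        slope, _ = _despot1_linear(s, np.deg2rad(alphas), tr)
        assert -tr / np.log(slope) == pytest.approx(t1, rel=1e-12)

    def test_too_few_angles(self):
        with pytest.raises(ValueError):
            fit_despot1_hifi(np.array([0.1]), 0.05, McDespotProtocol())


class TestDespot2Fm:
    def test_noiseless_recovery_on_resonance(self, mcdespot_protocol):
        prot = mcdespot_protocol
        bs = np.stack([[bssfp_signal(1.0, 900.0, 80.0, a, prot.bssfp_tr,
                                     0.0, pc) for a in prot.bssfp_alphas]
                       for pc in prot.bssfp_phase_cycles])
        t2, df0, m0 = fit_despot2_fm(bs, 900.0, 1.0, prot)
        assert t2 == pytest.approx(80.0, rel=1e-3)
        assert abs(df0) < 0.5

    def test_off_resonance_principal_value(self, mcdespot_protocol):
        prot = mcdespot_protocol
        bs = np.stack([[bssfp_signal(1.0, 900.0, 80.0, a, prot.bssfp_tr,
                                     40.0, pc) for a in prot.bssfp_alphas]
                       for pc in prot.bssfp_phase_cycles])
        t2, df0, m0 = fit_despot2_fm(bs, 900.0, 1.0, prot)
        # magnitude data with +/- phase cycling cannot sign the offset
        assert abs(df0) == pytest.approx(40.0, abs=0.5)
        assert abs(df0) <= 1000.0 / (2 * prot.bssfp_tr)
        assert t2 == pytest.approx(80.0, rel=1e-3)

    def test_t2_bounded_by_t1(self, mcdespot_protocol, rng):
        prot = mcdespot_protocol
        bs = np.stack([[bssfp_signal(1.0, 200.0, 190.0, a, prot.bssfp_tr,
                                     0.0, pc) for a in prot.bssfp_alphas]
                       for pc in prot.bssfp_phase_cycles])
        noisy = np.abs(bs + rng.normal(0, 0.002, bs.shape))
        t2, df0, m0 = fit_despot2_fm(noisy, 200.0, 1.0, prot)
        assert t2 <= 200.0

    def test_invalid_t1_masked(self, mcdespot_protocol):
        bs = np.ones((2, 7))
        t2, df0, m0 = fit_despot2_fm(bs, np.nan, 1.0, mcdespot_protocol)
        assert np.isnan(t2) and np.isnan(df0)


class TestSrc:
    def test_noiseless_recovery_over_seeds(self, mcdespot_protocol):
        truth = TwoPoolParams(f_m=0.15, t1_m=400.0, t1_f=1000.0, t2_m=20.0,
                              t2_f=80.0, k_mf=9.0)
        y = two_pool_signals(truth, mcdespot_protocol)
        ests = [fit_mcdespot_src(y, 1.0, np.random.default_rng(s),
                                 protocol=mcdespot_protocol)[0].f_m
                for s in range(10)]
        assert np.median(ests) == pytest.approx(0.15, abs=0.02)

    def test_zero_myelin_truth(self, mcdespot_protocol):
        truth = TwoPoolParams(f_m=1e-9, t1_m=400.0, t1_f=1000.0, t2_m=20.0,
                              t2_f=80.0, k_mf=9.0)
        y = two_pool_signals(truth, mcdespot_protocol)
        est, _ = fit_mcdespot_src(y, 1.0, np.random.default_rng(0),
                                  protocol=mcdespot_protocol)
        assert est.f_m <= 0.02

    def test_box_volume_shrinks(self, mcdespot_protocol):
        truth = TwoPoolParams(f_m=0.12)
        y = two_pool_signals(truth, mcdespot_protocol)
        history = []
        fit_mcdespot_src(y, 1.0, np.random.default_rng(1),
                         SrcConfig(n_samples=500, n_retain=25,
                                   n_iterations=4),
                         protocol=mcdespot_protocol, polish=False,
                         box_history=history)
        vols = [np.prod(hi - lo) for lo, hi in history]
        assert len(vols) >= 2
        assert all(b < a for a, b in zip(vols, vols[1:]))

    def test_degenerate_box_returns_point(self, mcdespot_protocol):
        truth = TwoPoolParams(f_m=0.12)
        y = two_pool_signals(truth, mcdespot_protocol)
        point = {k: (v, v) for k, v in
                 {"f_m": 0.2, "t1_m": 400.0, "t1_f": 1000.0, "t2_m": 20.0,
                  "t2_f": 80.0, "k_mf": 9.0}.items()}
        est, score = fit_mcdespot_src(y, 1.0, np.random.default_rng(0),
                                      SrcConfig(bounds=point),
                                      protocol=mcdespot_protocol)
        assert est.f_m == 0.2

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            SrcConfig(n_samples=10, n_retain=10)
        with pytest.raises(ValueError):
            SrcConfig(estimator="mode")
        with pytest.raises(ValueError):
            SrcConfig(bounds={"f_m": (0.3, 0.1)})


class TestMtr:
    def test_formula_cases(self):
        out = compute_mtr(np.array([100.0, 50.0, 80.0]),
                          np.array([60.0, 50.0, 0.0]))
        np.testing.assert_allclose(out, [40.0, 0.0, 100.0], atol=0)

    def test_background_masked(self):
        out = compute_mtr(np.array([0.0, 10.0]), np.array([0.0, 5.0]))
        assert np.isnan(out[0]) and out[1] == 50.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            compute_mtr(np.ones(3), np.ones(4))


@pytest.fixture(scope="module")
def noiseless_subject():
    geom = PhantomGeometry(
        grid_shape=(16, 16, 16), voxel_size=(8.0, 8.0, 8.0),
        brain_radii=(50.0, 54.0, 46.0), wm_radii=(36.0, 40.0, 32.0),
        subcortical_radii=(8.0, 10.0, 8.0),
        subcortical_offsets=((-16.0, 0.0, 0.0), (16.0, 0.0, 0.0)),
        ventricle_radii=(5.0, 12.0, 6.0),
        ventricle_offsets=((-7.0, -3.0, 2.0), (7.0, -3.0, 2.0)))
    labels = build_label_volume(geom)
    tissues = default_tissues()
    subject = sample_subject(
        {k: v.__class__(**{**v.__dict__, "cv": 0.0}) for k, v in
         tissues.items()}, labels, "control", np.random.default_rng(0),
        "noiseless", geom)
    acq = simulate_acquisitions(subject, rng=np.random.default_rng(1))
    return geom, subject, acq


class TestFitSubject:
    src_cfg = SrcConfig(bounds=TIGHT_SRC_BOUNDS, n_samples=128, n_retain=16,
                        n_iterations=3, estimator="mean")

    def test_noiseless_mwf_recovery_in_wm(self, noiseless_subject):
        geom, subject, acq = noiseless_subject
        ms = fit_subject(acq, subject.brain_mask,
                         reg=RegConfig(mode="none"), src=self.src_cfg,
                         rng=np.random.default_rng(2), affine=geom.affine)
        wm = subject.tissue_mask("wm")
        err = np.abs(ms["mwf_g"][wm] - subject.mwf_map[wm])
        assert np.nanmedian(err) < 0.01
        # the single-pool "global T1" of exchanging two-pool tissue sits
        # near, but not at, the free-pool T1
        t1err = np.abs(ms["qt1"][wm] - subject.params["t1"][wm])
        assert np.nanmedian(t1err / subject.params["t1"][wm]) < 0.2
        mtr_err = np.abs(ms["mtr"][wm]
                         - 100 * subject.params["mt_delta"][wm])
        assert np.nanmedian(mtr_err) < 1e-6

    def test_missing_mt_flagged_absent(self, noiseless_subject):
        geom, subject, acq = noiseless_subject
        partial = {k: v for k, v in acq.items() if k != "mt"}
        ms = fit_subject(partial, subject.brain_mask,
                         reg=RegConfig(mode="none"), src=self.src_cfg,
                         rng=np.random.default_rng(2), affine=geom.affine)
        assert "mtr" in ms.absent
        assert "mtr" not in ms.maps
        assert "mwf_g" in ms.maps and "qt1" in ms.maps

    def test_maps_inherit_affine(self, noiseless_subject):
        geom, subject, acq = noiseless_subject
        ms = fit_subject({"mt": acq["mt"]}, subject.brain_mask,
                         affine=geom.affine)
        np.testing.assert_array_equal(ms.affine, geom.affine)
        assert set(ms.absent) >= {"mwf_g", "mwf_d", "qt1"}
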