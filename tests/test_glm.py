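"""First-level GLM: HRF, design, CSF PCs, AR(1) prewhitening, contrasts, PPI."""

import numpy as np
import pytest
from scipy.signal import lfilter

from conftest import toy_trials
from lcstress.errors import (
    DegenerateDesignError,
    InvalidArgumentError,
)
from lcstress.glm import (
    build_design,
    canonical_hrf,
    contrast_tmap,
    contrast_vector,
    csf_nuisance_pcs,
    fit_glm_ar1,
    ppi_design,
)


class TestHrf:
    def test_causal_zero_at_origin(self):
        h = canonical_hrf(2.0)
        assert h[0] == 0.0

    def test_peak_location(self):
        h = canonical_hrf(2.0, oversampling=32)
        dt = 2.0 / 32
        tpeak = np.argmax(h) * dt
        assert 4.0 <= tpeak <= 6.0
        assert h.max() == pytest.approx(1.0)

    def test_undershoot_present(self):
        h = canonical_hrf(2.0, oversampling=32)
        dt = 2.0 / 32
        late = h[int(12 / dt):int(20 / dt)]
        assert late.min() < 0

    def test_single_impulse_reproduces_kernel_shape(self):
        """One isolated brief event: the regressor is the (scaled) kernel
        shifted to the onset."""
        t = toy_trials("CI", duration=0.125)
        t.loc[1, "onset_seconds"] = 40.0
        d = build_design(t, 2.0, 60, hp_cutoff_s=None, oversampling=16)
        ci = d.X[:, d.index("CI")]
        assert np.argmax(ci) == pytest.approx(40 / 2 + 5 / 2, abs=1)
        assert np.all(ci[:int(40 / 2)] == 0)


class TestDesign:
    def test_missing_condition_column_zero_and_contrast_refused(self):
        t = toy_trials("CICICI")  # types: first, CI, IC, CI, IC, CI — no CC/II
        d = build_design(t, 2.0, 40, hp_cutoff_s=None)
        assert np.all(d.X[:, d.index("CC")] == 0)
        bold = np.ones((1, 1, 1, 40)) + np.arange(40) * 0.0
        bold += np.random.default_rng(0).standard_normal((1, 1, 1, 40))
        res = fit_glm_ar1(bold, d)
        with pytest.raises(InvalidArgumentError):
            contrast_tmap(res, contrast_vector(d, {"CC": 1.0, "CI": -1.0}))

    def test_separated_events_orthogonal(self):
        t = toy_trials("CI", soa=100.0)
        d = build_design(t, 2.0, 120, hp_cutoff_s=None)
        first = d.X[:, d.index("first")]
        ci = d.X[:, d.index("CI")]
        r = np.corrcoef(first, ci)[0, 1]
        assert abs(r) < 0.05

    def test_nuisance_length_mismatch(self):
        t = toy_trials("CI")
        with pytest.raises(InvalidArgumentError):
            build_design(t, 2.0, 40, nuisance={"m": np.zeros(10)})

    def test_design_stable_through_tsv_round_trip(self, tmp_path):
        from lcstress import io as cio
        from lcstress.synthetic import generate_trial_sequence
        t = generate_trial_sequence(30, 2)
        d1 = build_design(t, 2.0, 100)
        cio.write_events(tmp_path / "e.tsv", t)
        d2 = build_design(cio.read_events(tmp_path / "e.tsv"), 2.0, 100)
        assert d1.names == d2.names
        assert np.allclose(d1.X, d2.X, atol=1e-9)


class TestCsfPcs:
    def _bold_with_sinusoid(self, rng, n_scans=120):
        grid = (6, 6, 6)
        mask = np.zeros(grid)
        mask[2:5, 2:5, 2:5] = 0.9
        t = np.arange(n_scans)
        sine = np.sin(2 * np.pi * 0.07 * t)
        bold = 100 + 0.01 * rng.standard_normal(grid + (n_scans,))
        bold[mask > 0.5] += 3.0 * sine
        return bold, mask, sine

    def test_planted_component_recovered(self, rng):
        bold, mask, sine = self._bold_with_sinusoid(rng)
        pcs, ev = csf_nuisance_pcs(bold, mask, k=5)
        r = np.corrcoef(pcs[:, 0], sine)[0, 1]
        assert abs(r) > 0.99

    def test_components_orthonormal(self, rng):
        bold, mask, _ = self._bold_with_sinusoid(rng)
        pcs, _ = csf_nuisance_pcs(bold, mask, k=5)
        gram = pcs.T @ pcs
        assert np.allclose(gram, np.eye(5), atol=1e-8)

    def test_explained_variance_non_increasing(self, rng):
        bold, mask, _ = self._bold_with_sinusoid(rng)
        _, ev = csf_nuisance_pcs(bold, mask, k=5)
        assert np.all(np.diff(ev) <= 1e-12)

    def test_too_few_voxels_rejected(self, rng):
        bold = 100 + rng.standard_normal((3, 3, 3, 50))
        mask = np.zeros((3, 3, 3))
        mask[0, 0, 0] = 1.0
        with pytest.raises(InvalidArgumentError):
            csf_nuisance_pcs(bold, mask, k=5)


class TestFitGlm:
    def _toy_design(self, n_scans=80):
        t = toy_trials("CICIICCI" * 3, soa=6.0)
        return build_design(t, 2.0, n_scans, hp_cutoff_s=None)

    def test_noiseless_exact_recovery(self):
        d = self._toy_design()
        beta_true = np.linspace(0.5, 2.0, d.X.shape[1])
        y = d.X @ beta_true
        res = fit_glm_ar1(y.reshape(1, 1, 1, -1), d, ar1=0.0)
        assert np.allclose(res.betas.ravel(), beta_true, atol=1e-8)

    def test_phi_recovery_and_beta_bias(self):
        """Pooled AR(1) estimate near truth; contrast estimate unbiased.

        Uses a realistic scan count: the residual-based AR estimate carries
        an O(k/n) downward bias that only vanishes for long series.
        """
        from lcstress.synthetic import generate_trial_sequence
        t = generate_trial_sequence(160, 21)
        d = build_design(t, 2.0, 380, hp_cutoff_s=None)
        c = contrast_vector(d, {"CI": 1.0, "II": -1.0})
        phi = 0.3
        rng = np.random.default_rng(11)
        n_scans = d.n_scans
        n_vox = 4000
        e = rng.standard_normal((n_scans, n_vox)) * np.sqrt(1 - phi ** 2)
        e[0] = rng.standard_normal(n_vox)
        noise = lfilter([1.0], [1.0, -phi], e, axis=0)
        signal = 0.8 * (d.X[:, d.index("CI")] - d.X[:, d.index("II")]) / 2
        Y = 50 + noise + signal[:, None]
        res = fit_glm_ar1(Y.T.reshape(n_vox, 1, 1, n_scans), d)
        assert abs(res.phi - phi) < 0.05
        eff = contrast_tmap(res, c).effect.ravel()
        se = eff.std(ddof=1) / np.sqrt(n_vox)
        assert abs(eff.mean() - 0.8) < max(0.02 * 0.8, 4 * se)

    def test_equals_gls_oracle(self):
        """Prewhitened OLS equals explicit GLS with the AR(1) covariance."""
        t = toy_trials("CIIC", soa=6.0)
        d = build_design(t, 2.0, 28, hp_cutoff_s=None)
        rng = np.random.default_rng(5)
        y = d.X @ rng.standard_normal(d.X.shape[1]) + \
            lfilter([1], [1, -0.4], rng.standard_normal(28))
        phi = 0.4
        res = fit_glm_ar1(y.reshape(1, 1, 1, -1), d, ar1=phi)
        n = 28
        idx = np.arange(n)
        Sigma = phi ** np.abs(idx[:, None] - idx[None, :]) / (1 - phi ** 2)
        Si = np.linalg.inv(Sigma)
        keep = ~d.zero_columns()
        Xr = d.X[:, keep]
        beta_gls = np.linalg.solve(Xr.T @ Si @ Xr, Xr.T @ Si @ y)
        assert np.allclose(res.betas.ravel()[keep], beta_gls, atol=1e-8)

    def test_rank_deficient_design_rejected(self):
        d = self._toy_design()
        X = np.column_stack([d.X, d.X[:, 0]])
        from lcstress.glm import DesignMatrix
        d2 = DesignMatrix(d.names + ("dup",), X,
                          np.concatenate([d.is_condition, [True]]), 2.0)
        with pytest.raises(DegenerateDesignError):
            fit_glm_ar1(np.ones((1, 1, 1, d.n_scans)), d2)

    def test_csf_pcs_reduce_residual_variance(self):
        """Adding CSF PCs to the design lowers residual variance at
        physiology-contaminated voxels."""
        from lcstress.config import CohortConfig
        from lcstress.synthetic import generate_trial_sequence, simulate_bold
        cfg = CohortConfig(n_trials=60, n_scans=160, grid_shape=(16, 20, 13))
        reductions = []
        for s in range(5):
            t = generate_trial_sequence(cfg.n_trials, 40 + s)
            bold, masks, motion, blink = simulate_bold(
                t, cfg, {"lc_amplitude": 0.5}, 50 + s)
            pcs, _ = csf_nuisance_pcs(bold, masks["csf"], k=5)
            lc = masks["lc_1sd"] > 0
            sub = bold[lc][:, None, None, :]
            d0 = build_design(t, cfg.tr_seconds, cfg.n_scans, hp_cutoff_s=None)
            nuis = {f"pc{i}": pcs[:, i] for i in range(5)}
            d1 = build_design(t, cfg.tr_seconds, cfg.n_scans, nuisance=nuis,
                              hp_cutoff_s=None)
            v0 = fit_glm_ar1(sub, d0).sigma2.mean()
            v1 = fit_glm_ar1(sub, d1).sigma2.mean()
            reductions.append(v0 - v1)
        assert np.median(reductions) > 0


def test_null_contrast_t_is_student_t():
    """Null-voxel contrast t statistics follow Student-t with the
    effective df (KS agreement over 2000 voxel sims)."""
    from scipy import stats
    from scipy.signal import lfilter
    from lcstress.synthetic import generate_trial_sequence
    t_trials = generate_trial_sequence(160, 31)
    d = build_design(t_trials, 2.0, 380, hp_cutoff_s=None)
    rng = np.random.default_rng(13)
    phi = 0.3
    e = rng.standard_normal((380, 2000)) * np.sqrt(1 - phi ** 2)
    e[0] = rng.standard_normal(2000)
    Y = 100 + lfilter([1.0], [1.0, -phi], e, axis=0)
    res = fit_glm_ar1(Y.T.reshape(2000, 1, 1, 380), d)
    c = contrast_vector(d, {"CI": 1.0, "II": -1.0})
    tvals = contrast_tmap(res, c).t.ravel()
    assert stats.kstest(tvals, "t", args=(res.df,)).pvalue > 0.01


class TestContrast:
    def test_zero_contrast_rejected(self):
        t = toy_trials("CICIICCI", soa=6.0)
        d = build_design(t, 2.0, 40, hp_cutoff_s=None)
        res = fit_glm_ar1(
            np.random.default_rng(0).standard_normal((1, 1, 1, 40)) + 100, d)
        with pytest.raises(InvalidArgumentError):
            contrast_tmap(res, np.zeros(d.X.shape[1]))

    def test_equal_amplitudes_give_null_contrast(self):
        d = build_design(toy_trials("CICIICCI" * 2, soa=6.0), 2.0, 60,
                         hp_cutoff_s=None)
        amp = 1.3
        y = amp * (d.X[:, d.index("CI")] + d.X[:, d.index("II")])
        res = fit_glm_ar1((y + 100).reshape(1, 1, 1, -1), d, ar1=0.0)
        c = contrast_vector(d, {"CI": 1.0, "II": -1.0})
        assert abs(contrast_tmap(res, c).effect.ravel()[0]) < 1e-8


class TestPpi:
    def _design(self):
        t = toy_trials("CICIICCIICCI" * 2, soa=6.0)
        return build_design(t, 2.0, 90, hp_cutoff_s=None)

    def test_constant_seed_rejected(self):
        d = self._design()
        with pytest.raises(DegenerateDesignError):
            ppi_design(d, np.ones(d.n_scans))

    def test_zero_centred_seed_zero_interactions(self):
        d = self._design()
        seed = np.zeros(d.n_scans)
        seed[0] = 1e-9  # non-constant but negligible
        dp = ppi_design(d, seed)
        assert np.allclose(dp.X[:, dp.index("ppi_seed_x_CI")], 0, atol=1e-8)

    def test_planted_interaction_recovered(self):
        d = self._design()
        rng = np.random.default_rng(6)
        hits = 0
        amps = []
        for s in range(100):
            seed = rng.standard_normal(d.n_scans)
            ci = d.X[:, d.index("CI")]
            target = 0.6 * (seed - seed.mean()) * ci \
                + 0.3 * rng.standard_normal(d.n_scans)
            dp = ppi_design(d, seed)
            res = fit_glm_ar1((target + 100).reshape(1, 1, 1, -1), dp)
            c = contrast_vector(dp, {"ppi_seed_x_CI": 1.0,
                                     "ppi_seed_x_II": -1.0})
            eff = contrast_tmap(res, c).effect.ravel()[0]
            hits += eff > 0
            amps.append(eff)
        assert hits == 100
        assert abs(np.mean(amps) - 0.6) < 0.06

    def test_unrelated_seed_null_coupling(self):
        d = self._design()
        rng = np.random.default_rng(7)
        effs = []
        for s in range(100):
            seed = rng.standard_normal(d.n_scans)
            target = rng.standard_normal(d.n_scans)
            dp = ppi_design(d, seed)
            res = fit_glm_ar1((target + 100).reshape(1, 1, 1, -1), dp)
            c = contrast_vector(dp, {"ppi_seed_x_CI": 1.0,
                                     "ppi_seed_x_II": -1.0})
            effs.append(contrast_tmap(res, c).effect.ravel()[0])
        m = np.mean(effs)
        se = np.std(effs, ddof=1) / 10
        assert abs(m) < 4 * se
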