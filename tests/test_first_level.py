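"""GLM machinery: designs, DCT filter, AR(1) ReML, whitened fits, contrasts."""

import numpy as np
import pytest

import dyadsync as ds
from dyadsync.design import CONDITIONS
from dyadsync.first_level import (CONTRASTS, DesignMatrix, ar1_correlation,
                                  ar1_whiten, build_design, compute_contrast,
                                  dct_highpass_basis, estimate_ar1_reml,
                                  fit_glm, highpass_filter)


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def test_condition_design_has_six_interest_columns(mini_design):
    X = build_design(mini_design, participant="A", n_volumes=48)
    assert X.interest_names == list(CONDITIONS)
    assert len(X.interest_indices) == 6
    assert X.matrix.shape[0] == 6 * 48
    assert "verify" in X.names
    assert sum(n.startswith("intercept") for n in X.names) == 6


def test_trialwise_design_columns(mini_design):
    X = build_design(mini_design, participant="B", trialwise=True,
                     run_index=0, n_volumes=48)
    n_trials = mini_design.runs[0].n_trials
    # task-related columns: one per trial plus the verify no-interest column
    assert len(X.interest_names) == n_trials
    assert X.names[-2:] == ["verify", "intercept"]
    assert X.matrix.shape == (48, n_trials + 2)


def test_missing_condition_is_all_zero_error(mini_design):
    ja_run = next(r.run_index for r in mini_design.runs
                  if r.task_type == "fJA")
    with pytest.raises(ValueError, match="all-zero interest regressor"):
        build_design(mini_design, participant="A", runs=[ja_run],
                     n_volumes=48)


def test_events_beyond_run_end_rejected(mini_design):
    with pytest.raises(ValueError, match="beyond the run end"):
        build_design(mini_design, participant="A", trialwise=True,
                     run_index=0, n_volumes=30)


# ---------------------------------------------------------------------------
# DCT high-pass
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n,tr,cutoff", [(175, 2.5, 128.0), (96, 2.0, 100.0),
                                         (200, 1.0, 64.0), (48, 2.5, 128.0)])
def test_dct_column_count_matches_frequency_enumeration(n, tr, cutoff):
    """Columns = constant + cosines with period 2*N*TR/k >= cutoff."""
    B = dct_highpass_basis(n, tr, cutoff)
    admissible = sum(1 for k in range(1, n)
                     if 2.0 * n * tr / k >= cutoff)
    assert B.shape == (n, admissible + 1)
    # orthonormal
    assert np.allclose(B.T @ B, np.eye(B.shape[1]), atol=1e-10)


def test_dct_count_for_study_geometry():
    assert dct_highpass_basis(175, 2.5, 128.0).shape[1] == 7


def test_filter_removes_slow_cosine_keeps_fast():
    # grid where a 256 s cosine lies exactly in the drift span
    n, tr = 256, 1.0
    t_mid = (np.arange(n) + 0.5) * tr
    slow = np.cos(2 * np.pi * t_mid / 256.0)
    out = highpass_filter(slow, [slice(0, n)], tr, 128.0)
    assert np.sum(out ** 2) < 1e-10 * np.sum(slow ** 2)
    # study geometry: a 256 s cosine is off the cosine grid but still
    # almost entirely within the stop band
    n, tr = 175, 2.5
    t = np.arange(n) * tr
    slow = np.cos(2 * np.pi * t / 256.0)
    out = highpass_filter(slow, [slice(0, n)], tr, 128.0)
    assert np.sum(out ** 2) < 0.01 * np.sum(slow ** 2)
    fast = np.cos(2 * np.pi * t / 20.0)             # period 20 s: passes
    out = highpass_filter(fast, [slice(0, n)], tr, 128.0)
    assert np.sum(out ** 2) > 0.9 * np.sum(fast ** 2)


def test_filter_variance_reduction_matches_projector_rank():
    """White-noise variance loss equals the projector trace (oracle)."""
    n, tr, cutoff = 175, 2.5, 128.0
    B = dct_highpass_basis(n, tr, cutoff)
    P = np.eye(n) - B @ B.T                          # explicit projector
    rng = np.random.default_rng(0)
    Y = rng.standard_normal((4000, n))
    out = highpass_filter(Y, [slice(0, n)], tr, cutoff)
    assert np.allclose(out, Y @ P.T, atol=1e-10)
    ratio = np.sum(out ** 2) / np.sum(Y ** 2)
    assert ratio == pytest.approx((n - B.shape[1]) / n, abs=0.01)


def test_cutoff_too_small_rejected():
    with pytest.raises(ValueError):
        dct_highpass_basis(100, 2.5, 4.0)


# ---------------------------------------------------------------------------
# AR(1) whitening and ReML
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("phi", [0.0, 0.3, -0.4, 0.8])
def test_whitener_is_cholesky_of_inverse_correlation(phi):
    n = 12
    W = ar1_whiten(np.eye(n), phi).T                 # explicit transform matrix
    V = ar1_correlation(n, phi)
    assert np.allclose(W.T @ W, np.linalg.inv(V), atol=1e-10)


def _ar1_series(rng, n_vox, n_time, phi):
    x = rng.standard_normal((n_vox, n_time + 50))
    for t in range(1, x.shape[1]):
        x[:, t] = phi * x[:, t - 1] + np.sqrt(1 - phi ** 2) * x[:, t]
    return x[:, 50:]


def test_reml_recovers_white_noise():
    rng = np.random.default_rng(1)
    X = np.column_stack([np.ones(175), np.arange(175) / 175.0])
    phis = [estimate_ar1_reml(rng.standard_normal((300, 175)), X)
            for _ in range(3)]
    assert np.all(np.abs(phis) < 0.05)


def test_reml_recovers_generating_phi():
    rng = np.random.default_rng(2)
    X = np.column_stack([np.ones(175), np.arange(175) / 175.0])
    Y = _ar1_series(rng, 1000, 175, 0.4)
    phi = estimate_ar1_reml(Y, X)
    assert phi == pytest.approx(0.4, abs=0.05)


def test_reml_scale_invariance():
    rng = np.random.default_rng(3)
    X = np.ones((100, 1))
    Y = _ar1_series(rng, 200, 100, 0.3)
    assert estimate_ar1_reml(Y, X) == pytest.approx(
        estimate_ar1_reml(5.0 * Y, X), abs=1e-6)


def test_reml_rejects_constant_series():
    X = np.ones((50, 1))
    with pytest.raises(ValueError, match="constant"):
        estimate_ar1_reml(np.ones((10, 50)), X)


# ---------------------------------------------------------------------------
# GLM fitting
# ---------------------------------------------------------------------------

def _toy_design(n=60, tr=2.5, seed=0):
    rng = np.random.default_rng(seed)
    X = np.column_stack([ds.hrf_regressor([10 + 30 * k], [5.0],
                                          np.arange(n) * tr)
                         for k in range(3)] + [np.ones(n)])
    return DesignMatrix(matrix=X, names=["a", "b", "c", "intercept"],
                        frame_times=np.arange(n) * tr, tr_s=tr,
                        highpass_cutoff_s=128.0,
                        run_slices=[slice(0, n)], interest_names=["a", "b", "c"])


def test_noiseless_recovery_to_machine_precision():
    X = _toy_design()
    b_true = np.array([[2.0, -1.0, 0.5, 3.0], [0.0, 1.0, -2.0, 1.0]])
    Y = b_true @ X.matrix.T
    fit = fit_glm(Y, X, whiten="none")
    est = np.column_stack([fit.beta(n) for n in ["a", "b", "c"]])
    assert np.allclose(est, b_true[:, :3], atol=1e-8)
    # residuals orthogonal to the filtered design
    Xf = highpass_filter(X.matrix.T, X.run_slices, X.tr_s,
                         X.highpass_cutoff_s).T
    assert np.max(np.abs(fit.residuals @ Xf)) < 1e-6


def test_whitened_ols_equals_explicit_gls_oracle():
    """Whitened least squares == GLS with the explicit AR(1) covariance."""
    rng = np.random.default_rng(4)
    n, phi = 18, 0.45
    X = np.column_stack([np.ones(n), rng.standard_normal((n, 2))])
    Y = rng.standard_normal((5, n))
    Xw = ar1_whiten(X.T, phi).T
    Yw = ar1_whiten(Y, phi)
    beta_white = np.linalg.lstsq(Xw, Yw.T, rcond=None)[0]
    Vinv = np.linalg.inv(ar1_correlation(n, phi))
    beta_gls = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ Y.T)
    assert np.allclose(beta_white, beta_gls, atol=1e-10)


def test_filter_then_fit_equals_dct_nuisance_fit():
    """High-pass as projection == appending DCT columns as nuisance."""
    rng = np.random.default_rng(5)
    X = _toy_design(n=96)
    Y = rng.standard_normal((50, 96)) + 3.0 * X.matrix[:, 0]
    fit_proj = fit_glm(Y, X, whiten="none")
    B = dct_highpass_basis(96, X.tr_s, X.highpass_cutoff_s)
    X_aug = DesignMatrix(
        matrix=np.column_stack([X.matrix[:, :3], B]),
        names=["a", "b", "c"] + [f"dct{k}" for k in range(B.shape[1])],
        frame_times=X.frame_times, tr_s=X.tr_s,
        highpass_cutoff_s=X.highpass_cutoff_s, run_slices=X.run_slices,
        interest_names=["a", "b", "c"])
    Q, R = np.linalg.qr(X_aug.matrix)
    betas_aug = np.linalg.solve(R, Q.T @ Y.T).T[:, :3]
    est = np.column_stack([fit_proj.beta(n) for n in ["a", "b", "c"]])
    assert np.allclose(est, betas_aug, atol=1e-8)


def test_trialwise_betas_track_generating_amplitudes(mini_design):
    """At near-zero noise the trial betas recover the latent amplitudes."""
    truth = ds.SyncGroundTruth(
        grid_shape=(4, 4, 4),
        task_sync_mask=np.ones((4, 4, 4), bool),
        residual_sync_mask=np.zeros((4, 4, 4), bool),
        coupling_task=0.5, coupling_residual=0.0,
        noise_sd=0.01, drift_amp=0.1, amp_sd=0.5)
    sim = ds.simulate_pair(mini_design, truth, seed=8, n_volumes=48)
    run = sim.runs_a[0]
    X = build_design(mini_design, participant="A", trialwise=True,
                     run_index=run.run_index, n_volumes=48)
    fit = fit_glm(run.data.reshape(64, 48).astype(np.float64), X)
    betas = fit.interest_betas()
    amps = sim.latents[run.run_index]["amp_a"]
    cors = [np.corrcoef(betas[v], amps[v])[0, 1] for v in range(64)]
    assert np.mean(cors) > 0.95


def test_fit_rejects_nan_and_shape_mismatch(mini_design):
    X = build_design(mini_design, trialwise=True, run_index=0, n_volumes=48)
    with pytest.raises(ValueError, match="NaN"):
        fit_glm(np.full((4, 48), np.nan), X)
    with pytest.raises(ValueError, match="volumes"):
        fit_glm(np.zeros((4, 47)), X)


def test_glm_fit_ar1_phi_matches_noise_model(mini_design, mini_truth,
                                             mini_sim):
    """Pooled ReML phi on simulated data lands near the generating value."""
    run = mini_sim.runs_a[0]
    X = build_design(mini_design, trialwise=True, run_index=run.run_index,
                     n_volumes=48)
    fit = fit_glm(run, X, whiten="ar1")
    assert fit.whitened
    assert abs(fit.ar1_phi - mini_truth.ar1_phi) < 0.15


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

def _fake_condition_fit(betas_by_condition):
    n_vox = len(next(iter(betas_by_condition.values())))
    names = list(CONDITIONS)
    betas = np.column_stack([betas_by_condition[c] for c in names])
    X = DesignMatrix(matrix=np.zeros((10, 6)), names=names,
                     frame_times=np.arange(10) * 2.5, tr_s=2.5,
                     highpass_cutoff_s=128.0, run_slices=[slice(0, 10)],
                     interest_names=names)
    return ds.GLMFit(betas=betas, column_names=names,
                     residuals=np.zeros((n_vox, 10)), ar1_phi=None,
                     sigma2=np.ones(n_vox), design=X, whitened=False,
                     bad_voxels=np.zeros(n_vox, bool), dropped_columns=[])


def test_differential_contrast_weights_sum_to_zero():
    for name, w in CONTRASTS.items():
        assert sum(w) == 0, name


def test_contrast_null_when_conditions_equal():
    """sIJA vs its control: zero map when the two betas coincide."""
    rng = np.random.default_rng(6)
    common = rng.standard_normal(20)
    fit = _fake_condition_fit({
        "fIJA": rng.standard_normal(20), "fRJA": rng.standard_normal(20),
        "sIJA": common, "sRJA": rng.standard_normal(20),
        "fCTRL": rng.standard_normal(20), "sCTRL": common})
    img = compute_contrast(fit, CONTRASTS["sIJA"])
    assert np.allclose(img.values, 0.0, atol=1e-12)


def test_contrast_linearity_and_length_check():
    rng = np.random.default_rng(7)
    fit = _fake_condition_fit({c: rng.standard_normal(15) for c in CONDITIONS})
    w1 = np.array(CONTRASTS["IJA>RJA"], float)
    w2 = np.array(CONTRASTS["main_effect_JA"], float)
    c12 = compute_contrast(fit, w1 + w2).values
    assert np.allclose(c12, compute_contrast(fit, w1).values
                       + compute_contrast(fit, w2).values, atol=1e-12)
    with pytest.raises(ValueError, match="length"):
        compute_contrast(fit, [1, -1])
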