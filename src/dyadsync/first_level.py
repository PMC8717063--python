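"""Per-participant GLM estimation for the dyadic joint-attention study.

Two design-matrix flavors are supported:

* a **condition** design over the session with one interest regressor per
  condition (fIJA, fRJA, sIJA, sRJA, fCTRL, sCTRL), used for task
  activation contrasts, and
* a **trial-wise** design per run with one regressor per trial (32) plus
  one covariate of no interest for the verify phase, used to build
  beta series and residual time courses.

Interest events are 5 s boxcars starting at the role-assignment phase,
convolved with the canonical HRF.  Estimation follows the classical
massively univariate pipeline: discrete-cosine high-pass filtering
(cutoff period 128 s), a single pooled AR(1) noise coefficient estimated
by restricted maximum likelihood on voxels responding in a first-pass
OLS fit, exact AR(1) prewhitening of data and design, and least squares
on the whitened system.  No global scaling is applied.  Prewhitening can
be turned off (``whiten="none"``) to preserve the autocorrelation
structure of the residual time series for the inter-brain residual
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

from .design import (CONDITIONS, EVENT_DURATION_S, VERIFY_DURATION_S,
                     TaskDesign)
from .hrf import hrf_regressor
from .simulate import BOLDRun

DEFAULT_HIGHPASS_S = 128.0


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    matrix: np.ndarray              # time x regressors
    names: list
    frame_times: np.ndarray
    tr_s: float
    highpass_cutoff_s: float
    run_slices: list                # per-run time slices into the rows
    interest_names: list            # names of the regressors of interest

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def interest_indices(self) -> list:
        return [self.names.index(n) for n in self.interest_names]


def _events_of(run, participant):
    """(condition, event_onset, verify_onset) triples of one run."""
    return [(tr.condition(participant), tr.event_onset_s, tr.verify_onset_s)
            for tr in run.trials]


def build_design(design: TaskDesign, participant: str = "A",
                 trialwise: bool = False, run_index: int | None = None,
                 tr_s: float = 2.5, n_volumes: int = 175,
                 highpass_cutoff_s: float = DEFAULT_HIGHPASS_S,
                 conditions=None, runs=None) -> DesignMatrix:
    """Build a condition (session) or trial-wise (single-run) design matrix.

    The condition design concatenates the selected ``runs`` (default all
    six), with one HRF regressor per condition spanning the session, one
    verify-phase covariate of no interest, and one intercept per run.
    The trial-wise design covers the single ``run_index`` with one
    regressor per trial plus the verify covariate and an intercept.
    """
    frame = np.arange(n_volumes) * tr_s
    run_end = n_volumes * tr_s

    def check_events(evts):
        for _, on, von in evts:
            if on + EVENT_DURATION_S > run_end or von + VERIFY_DURATION_S > run_end:
                raise ValueError(
                    f"event at {on}s extends beyond the run end ({run_end}s)")

    if trialwise:
        if run_index is None:
            raise ValueError("trialwise designs are per run; pass run_index")
        run = design.runs[run_index]
        if run.run_index != run_index:
            run = next(r for r in design.runs if r.run_index == run_index)
        evts = _events_of(run, participant)
        check_events(evts)
        cols, names = [], []
        for i, (_, on, _) in enumerate(evts):
            cols.append(hrf_regressor([on], [EVENT_DURATION_S], frame))
            names.append(f"trial_{i:03d}")
        interest = list(names)
        cols.append(hrf_regressor([v for _, _, v in evts],
                                  [VERIFY_DURATION_S] * len(evts), frame))
        names.append("verify")
        cols.append(np.ones(n_volumes))
        names.append("intercept")
        X = np.column_stack(cols)
        return DesignMatrix(matrix=X, names=names, frame_times=frame,
                            tr_s=tr_s, highpass_cutoff_s=highpass_cutoff_s,
                            run_slices=[slice(0, n_volumes)],
                            interest_names=interest)

    # condition design across runs
    sel = [r for r in design.runs if runs is None or r.run_index in runs]
    if not sel:
        raise ValueError("no runs selected")
    conds = list(conditions) if conditions is not None else list(CONDITIONS)
    T = n_volumes * len(sel)
    names = conds + ["verify"] + [f"intercept_run{r.run_index}" for r in sel]
    X = np.zeros((T, len(names)))
    frame_all = np.concatenate([frame + k * run_end for k in range(len(sel))])
    run_slices = []
    for k, run in enumerate(sel):
        sl = slice(k * n_volumes, (k + 1) * n_volumes)
        run_slices.append(sl)
        evts = _events_of(run, participant)
        check_events(evts)
        for c in set(e[0] for e in evts):
            if c not in conds:
                raise ValueError(f"condition {c!r} in run {run.run_index} not "
                                 f"among modeled conditions {conds}")
        for ci, cond in enumerate(conds):
            ons = [on for (c, on, _) in evts if c == cond]
            if ons:
                X[sl, ci] = hrf_regressor(ons, [EVENT_DURATION_S] * len(ons), frame)
        X[sl, len(conds)] = hrf_regressor([v for (_, _, v) in evts],
                                          [VERIFY_DURATION_S] * len(evts), frame)
        X[sl, len(conds) + 1 + k] = 1.0
    zero = [conds[i] for i in range(len(conds))
            if not np.any(X[:, i])]
    if zero:
        raise ValueError(f"all-zero interest regressor(s) {zero}: no events of "
                         "these conditions in the selected runs")
    return DesignMatrix(matrix=X, names=names, frame_times=frame_all,
                        tr_s=tr_s, highpass_cutoff_s=highpass_cutoff_s,
                        run_slices=run_slices, interest_names=conds)


# ---------------------------------------------------------------------------
# High-pass filtering
# ---------------------------------------------------------------------------

def dct_highpass_basis(n_volumes: int, tr_s: float,
                       cutoff_s: float = DEFAULT_HIGHPASS_S) -> np.ndarray:
    """Orthonormal discrete-cosine drift basis (constant included).

    Columns are the DCT-II vectors whose periods ``2 N TR / k`` are at
    least ``cutoff_s``; the column count is ``floor(2 N TR / cutoff) + 1``
    including the constant.  Projecting data onto the complement of this
    basis implements the high-pass filter.
    """
    if cutoff_s <= 2 * tr_s:
        raise ValueError(f"cutoff {cutoff_s}s must exceed twice the TR")
    n_cos = int(2 * n_volumes * tr_s / cutoff_s)
    t = np.arange(n_volumes)
    cols = [np.full(n_volumes, 1.0 / np.sqrt(n_volumes))]
    for k in range(1, n_cos + 1):
        cols.append(np.sqrt(2.0 / n_volumes)
                    * np.cos(np.pi * k * (2 * t + 1) / (2 * n_volumes)))
    return np.column_stack(cols)


def highpass_filter(Y: np.ndarray, run_slices, tr_s: float,
                    cutoff_s: float = DEFAULT_HIGHPASS_S) -> np.ndarray:
    """Residualize the time axis (last) of ``Y`` against the DCT basis, per run.

    Computation stays in the input's float precision (float32 data are
    filtered in float32, which matters for large simulated cohorts).
    """
    Y = np.asarray(Y)
    dtype = Y.dtype if np.issubdtype(Y.dtype, np.floating) else np.float64
    out = Y.astype(dtype, copy=True)
    for sl in run_slices:
        n = sl.stop - sl.start
        B = _dct_cached(n, tr_s, cutoff_s, np.dtype(dtype).name)
        block = out[..., sl]
        out[..., sl] = block - (block @ B) @ B.T
    return out


_DCT_CACHE: dict = {}


def _dct_cached(n, tr_s, cutoff_s, dtype_name):
    key = (n, tr_s, cutoff_s, dtype_name)
    if key not in _DCT_CACHE:
        _DCT_CACHE[key] = dct_highpass_basis(n, tr_s, cutoff_s).astype(dtype_name)
    return _DCT_CACHE[key]


# ---------------------------------------------------------------------------
# AR(1) prewhitening
# ---------------------------------------------------------------------------

def ar1_whiten(x: np.ndarray, phi: float, run_slices=None) -> np.ndarray:
    """Apply the exact AR(1) whitening transform along the last axis.

    The transform is the Cholesky factor of the inverse AR(1) correlation
    matrix: the whitened series has identity covariance when the input
    has correlation ``phi**|i-j|``.  With ``run_slices`` the transform is
    applied independently per run (the process restarts at each run).
    """
    if not -1.0 < phi < 1.0:
        raise ValueError("phi must lie in (-1, 1)")
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float64)
    out = np.empty_like(x)
    slices = run_slices or [slice(0, x.shape[-1])]
    c = 1.0 / np.sqrt(1.0 - phi * phi)
    for sl in slices:
        blk = x[..., sl]
        out[..., sl.start] = blk[..., 0]
        out[..., sl.start + 1: sl.stop] = c * (blk[..., 1:] - phi * blk[..., :-1])
    return out


def ar1_correlation(n: int, phi: float) -> np.ndarray:
    """Explicit AR(1) correlation matrix ``phi**|i-j|`` (test oracle scale)."""
    idx = np.arange(n)
    return phi ** np.abs(idx[:, None] - idx[None, :])


def estimate_ar1_reml(series: np.ndarray, X: np.ndarray, run_slices=None,
                      bounds=(-0.95, 0.95), max_voxels: int = 1000,
                      xatol: float = 5e-3) -> float:
    """Pooled AR(1) coefficient by restricted maximum likelihood.

    ``series`` is (voxels, time); ``X`` the (time, p) design whose fixed
    effects are removed under the restricted likelihood.  A single ``phi``
    is fit to all pooled voxels with a common profiled noise variance,
    by scalar optimization of the restricted log-likelihood of an AR(1)
    noise model.
    """
    Y = np.atleast_2d(np.asarray(series, dtype=float))
    X = np.asarray(X, dtype=float)
    n = Y.shape[1]
    if n < 2:
        raise ValueError("need at least two time points")
    if X.shape[0] != n:
        raise ValueError("design rows must match series length")
    v = Y.var(axis=1)
    if np.all(v <= 0):
        raise ValueError("all pooled series are constant")
    Y = Y[v > 0]
    if Y.shape[0] > max_voxels:
        Y = Y[:: int(np.ceil(Y.shape[0] / max_voxels))][:max_voxels]
    slices = run_slices or [slice(0, n)]
    p = X.shape[1]
    n_runs = len(slices)

    def neg_restricted_ll(phi):
        Xw = ar1_whiten(X.T, phi, slices).T
        Yw = ar1_whiten(Y, phi, slices)
        Q, R = np.linalg.qr(Xw)
        diag = np.abs(np.diag(R))
        if np.any(diag < 1e-10):
            return np.inf
        resid = Yw - (Yw @ Q) @ Q.T
        rss = float(np.sum(resid * resid))
        if rss <= 0:
            return np.inf
        sigma2 = rss / (Y.shape[0] * (n - p))
        log_det_v = (n - n_runs) * np.log(1.0 - phi * phi)
        log_det_xvx = 2.0 * float(np.sum(np.log(diag)))
        return (n - p) * np.log(sigma2) + log_det_v + log_det_xvx

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=bounds,
                                   method="bounded",
                                   options={"xatol": xatol})
    return float(res.x)


# ---------------------------------------------------------------------------
# GLM fitting
# ---------------------------------------------------------------------------

@dataclass
class GLMFit:
    betas: np.ndarray               # voxel x kept regressors
    column_names: list              # names of kept (estimable) regressors
    residuals: np.ndarray           # voxel x time, filtered (+ whitened) space
    ar1_phi: float | None
    sigma2: np.ndarray              # voxel noise variance
    design: DesignMatrix
    whitened: bool
    bad_voxels: np.ndarray          # zero-variance voxels, betas forced to 0
    dropped_columns: list           # regressors annihilated by the filter
    grid_shape: tuple | None = None
    affine: np.ndarray | None = None

    def beta(self, name: str) -> np.ndarray:
        return self.betas[:, self.column_names.index(name)]

    def interest_betas(self) -> np.ndarray:
        """Voxel x interest-regressor betas in design order."""
        idx = [self.column_names.index(n) for n in self.design.interest_names]
        return self.betas[:, idx]


def _as_voxel_time(Y):
    grid_shape = affine = None
    if isinstance(Y, BOLDRun):
        grid_shape, affine = Y.grid_shape, Y.affine
        Y = Y.data.reshape(-1, Y.n_volumes)
    Y = np.asarray(Y)
    if not np.issubdtype(Y.dtype, np.floating):
        Y = Y.astype(np.float64)
    if Y.ndim == 4:
        grid_shape = Y.shape[:3]
        Y = Y.reshape(-1, Y.shape[-1])
    return np.atleast_2d(Y), grid_shape, affine


def fit_glm(Y, X: DesignMatrix, whiten: str = "ar1",
            pool_p: float = 1e-3, min_pool: int = 20,
            max_pool: int = 1000) -> GLMFit:
    """Fit the GLM voxelwise with high-pass filtering and optional AR(1)
    prewhitening.

    ``Y`` may be a :class:`~dyadsync.simulate.BOLDRun`, a 4D array or a
    (voxels, time) array.  With ``whiten="ar1"`` the pooled noise
    coefficient is estimated by ReML on voxels passing an omnibus F-test
    of the interest regressors (p < ``pool_p``) in a first-pass OLS fit,
    then data and design are exactly prewhitened before least squares.
    ``whiten="none"`` skips both steps, leaving residual autocorrelation
    intact.
    """
    if whiten not in ("ar1", "none"):
        raise ValueError("whiten must be 'ar1' or 'none'")
    Y, grid_shape, affine = _as_voxel_time(Y)
    if np.isnan(Y).any():
        raise ValueError("input data contain NaN")
    T = X.n_volumes
    if Y.shape[1] != T:
        raise ValueError(f"data have {Y.shape[1]} volumes, design has {T}")

    # high-pass filter data and design (per run)
    Yf = highpass_filter(Y, X.run_slices, X.tr_s, X.highpass_cutoff_s)
    Xf = highpass_filter(X.matrix.T, X.run_slices, X.tr_s,
                         X.highpass_cutoff_s).T

    # drop regressors annihilated by the filter (intercepts live in the
    # DCT span); they are not estimable in the filtered space
    norms = np.linalg.norm(Xf, axis=0)
    ref = np.linalg.norm(X.matrix, axis=0)
    keep = norms > 1e-8 * np.maximum(ref, 1.0)
    kept_names = [n for n, k in zip(X.names, keep) if k]
    dropped = [n for n, k in zip(X.names, keep) if not k]
    Xk = Xf[:, keep]
    rank = np.linalg.matrix_rank(Xk)
    if rank < Xk.shape[1]:
        raise ValueError("design matrix is rank deficient after filtering")

    n_filter = sum(dct_highpass_basis(sl.stop - sl.start, X.tr_s,
                                      X.highpass_cutoff_s).shape[1]
                   for sl in X.run_slices)
    dof = T - n_filter - Xk.shape[1]
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")

    bad = Yf.var(axis=1) <= 1e-12 * max(float(Yf.var()), 1e-30)

    phi = None
    if whiten == "ar1":
        phi = _pooled_phi(Y, Yf, Xk, X, kept_names, bad,
                          pool_p, min_pool, max_pool, dof)
        Yw = ar1_whiten(Yf, phi, X.run_slices)
        Xw = ar1_whiten(Xk.T, phi, X.run_slices).T
    else:
        Yw, Xw = Yf, Xk

    Q, R = np.linalg.qr(Xw)
    betas = np.linalg.solve(R, (Yw @ Q).T).T
    residuals = Yw - betas @ Xw.T
    betas[bad] = 0.0
    residuals[bad] = 0.0
    sigma2 = (residuals * residuals).sum(axis=1) / dof

    return GLMFit(betas=betas, column_names=kept_names, residuals=residuals,
                  ar1_phi=phi, sigma2=sigma2, design=X,
                  whitened=(whiten == "ar1"), bad_voxels=bad,
                  dropped_columns=dropped, grid_shape=grid_shape,
                  affine=affine)


def fit_glm_both(Y, X: DesignMatrix, pool_p: float = 1e-3,
                 min_pool: int = 20, max_pool: int = 500):
    """Fit the whitened and unwhitened GLM in one pass.

    The beta-series analysis needs AR(1)-prewhitened trial betas while
    the residual analysis needs residuals with serial correlation left
    intact; both share the filtering and first-pass OLS, so fitting them
    together roughly halves the cost on large cohorts.  Returns
    ``(fit_ar1, fit_none)``.
    """
    Y, grid_shape, affine = _as_voxel_time(Y)
    if np.isnan(Y).any():
        raise ValueError("input data contain NaN")
    T = X.n_volumes
    if Y.shape[1] != T:
        raise ValueError(f"data have {Y.shape[1]} volumes, design has {T}")
    Yf = highpass_filter(Y, X.run_slices, X.tr_s, X.highpass_cutoff_s)
    Xf = highpass_filter(X.matrix.T, X.run_slices, X.tr_s,
                         X.highpass_cutoff_s).T
    norms = np.linalg.norm(Xf, axis=0)
    ref = np.linalg.norm(X.matrix, axis=0)
    keep = norms > 1e-8 * np.maximum(ref, 1.0)
    kept_names = [n for n, k in zip(X.names, keep) if k]
    dropped = [n for n, k in zip(X.names, keep) if not k]
    Xk = Xf[:, keep]
    n_filter = sum(dct_highpass_basis(sl.stop - sl.start, X.tr_s,
                                      X.highpass_cutoff_s).shape[1]
                   for sl in X.run_slices)
    dof = T - n_filter - Xk.shape[1]
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    rowvar = Yf.var(axis=1)
    bad = rowvar <= 1e-12 * max(float(rowvar.mean()), 1e-30)

    # unwhitened OLS (also the first pass for AR pooling)
    Q, R = np.linalg.qr(Xk.astype(np.float64))
    Q = Q.astype(Yf.dtype, copy=False)
    proj = Yf @ Q
    betas0 = linalg.solve_triangular(
        R, proj.T.astype(np.float64)).T.astype(Yf.dtype)
    resid0 = Yf - proj @ Q.T
    betas0[bad] = 0.0
    resid0[bad] = 0.0
    sigma2_0 = (resid0 * resid0).sum(axis=1) / dof
    fit_none = GLMFit(betas=betas0, column_names=kept_names, residuals=resid0,
                      ar1_phi=None, sigma2=sigma2_0, design=X, whitened=False,
                      bad_voxels=bad, dropped_columns=dropped,
                      grid_shape=grid_shape, affine=affine)

    phi = _pooled_phi(Y, Yf, Xk, X, kept_names, bad, pool_p, min_pool,
                      max_pool, dof, first_pass_resid=resid0)
    Yw = ar1_whiten(Yf, phi, X.run_slices)
    Xw = ar1_whiten(Xk.T, phi, X.run_slices).T
    Qw, Rw = np.linalg.qr(Xw.astype(np.float64))
    Qw = Qw.astype(Yw.dtype, copy=False)
    projw = Yw @ Qw
    betas = linalg.solve_triangular(
        Rw, projw.T.astype(np.float64)).T.astype(Yw.dtype)
    residw = Yw - projw @ Qw.T
    betas[bad] = 0.0
    residw[bad] = 0.0
    sigma2 = (residw * residw).sum(axis=1) / dof
    fit_ar1 = GLMFit(betas=betas, column_names=kept_names, residuals=residw,
                     ar1_phi=phi, sigma2=sigma2, design=X, whitened=True,
                     bad_voxels=bad, dropped_columns=dropped,
                     grid_shape=grid_shape, affine=affine)
    return fit_ar1, fit_none


def _pooled_phi(Y, Yf, Xk, X, kept_names, bad, pool_p, min_pool, max_pool,
                dof, first_pass_resid=None):
    """First-pass OLS omnibus F over interest regressors -> pooling set -> ReML."""
    if first_pass_resid is None:
        Q, _ = np.linalg.qr(Xk)
        first_pass_resid = Yf - (Yf @ Q) @ Q.T
    rss1 = np.einsum("ij,ij->i", first_pass_resid, first_pass_resid)
    nuis_idx = [i for i, n in enumerate(kept_names)
                if n not in X.interest_names]
    q = len(kept_names) - len(nuis_idx)
    if q == 0:
        raise ValueError("no interest regressors survive filtering")
    # RSS of the nuisance-only model via the projection norm identity
    yy = np.einsum("ij,ij->i", Yf, Yf)
    if nuis_idx:
        Q0, _ = np.linalg.qr(Xk[:, nuis_idx].astype(np.float64))
        p0 = Yf @ Q0.astype(Yf.dtype)
        rss0 = yy - np.einsum("ij,ij->i", p0, p0)
    else:
        rss0 = yy
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / q) / (rss1 / dof)
    F[~np.isfinite(F)] = -np.inf
    F[bad] = -np.inf
    thresh = stats.f.isf(pool_p, q, dof)
    pool = np.flatnonzero(F > thresh)
    if pool.size < min_pool:
        pool = np.argsort(F)[::-1][:min_pool]
        pool = pool[np.isfinite(F[pool])]
    if pool.size == 0:
        raise ValueError("no usable voxels for AR(1) pooling")
    if pool.size > max_pool:
        pool = pool[:: int(np.ceil(pool.size / max_pool))][:max_pool]
    # augment the design with the per-run DCT blocks so the restricted
    # likelihood accounts for the filter's degrees of freedom exactly
    blocks = []
    for sl in X.run_slices:
        blocks.append(dct_highpass_basis(sl.stop - sl.start, X.tr_s,
                                         X.highpass_cutoff_s))
    Bfull = linalg.block_diag(*blocks)
    task_cols = [i for i, n in enumerate(X.names)
                 if n in kept_names]
    X_aug = np.column_stack([X.matrix[:, task_cols], Bfull])
    return estimate_ar1_reml(Y[pool], X_aug, run_slices=X.run_slices)


# ---------------------------------------------------------------------------
# Contrasts
# ---------------------------------------------------------------------------

@dataclass
class ContrastImage:
    values: np.ndarray              # per-voxel contrast of interest betas
    contrast_vector: np.ndarray
    participant_id: str = "unknown"
    name: str = ""
    grid_shape: tuple | None = None

    def volume(self) -> np.ndarray:
        if self.grid_shape is None:
            raise ValueError("no grid shape recorded")
        return self.values.reshape(self.grid_shape)


def compute_contrast(fit: GLMFit, weights, participant_id: str = "unknown",
                     name: str = "") -> ContrastImage:
    """Linear contrast of the interest-regressor betas, voxelwise."""
    w = np.asarray(weights, dtype=float)
    n_interest = len(fit.design.interest_names)
    if w.shape != (n_interest,):
        raise ValueError(f"contrast length {w.size} != {n_interest} interest "
                         "regressors")
    values = fit.interest_betas() @ w
    return ContrastImage(values=values, contrast_vector=w,
                         participant_id=participant_id, name=name,
                         grid_shape=fit.grid_shape)


#: Predefined second-level contrasts over the canonical condition order
#: (fIJA, fRJA, sIJA, sRJA, fCTRL, sCTRL).  Differential contrasts sum
#: to zero; the two conjunctions isolate spatial- and feature-specific
#: joint attention regardless of role.
CONTRASTS = {
    "sIJA":          (0, 0, 1, 0, 0, -1),
    "sRJA":          (0, 0, 0, 1, 0, -1),
    "fIJA":          (1, 0, 0, 0, -1, 0),
    "fRJA":          (0, 1, 0, 0, -1, 0),
    "sIJA>fIJA":     (-1, 0, 1, 0, 1, -1),
    "sRJA>fRJA":     (0, -1, 0, 1, 1, -1),
    "sIJA<fIJA":     (1, 0, -1, 0, -1, 1),
    "sRJA<fRJA":     (0, 1, 0, -1, -1, 1),
    "IJA>RJA":       (1, -1, 1, -1, 0, 0),
    "main_effect_JA": (1, 1, 1, 1, -2, -2),
}

CONJUNCTIONS = {
    "spatial_specific_JA": ("sIJA", "sRJA", "sIJA>fIJA", "sRJA>fRJA"),
    "feature_specific_JA": ("fIJA", "fRJA", "sIJA<fIJA", "sRJA<fRJA"),
}
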