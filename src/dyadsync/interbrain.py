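"""Inter-brain correlation: beta series, residual series, real and pseudo pairs.

The beta-series analysis orders each participant's trial-wise betas
across the four joint-attention runs — first fJA run, second fJA run,
first sJA run, second sJA run — giving 128 ordered amplitudes per voxel.
Because trial timing carries no jitter, this canonical reordering aligns
task order across participants, so members of *different* real pairs can
be recombined into pseudo pairs whose series are directly comparable:
each real pair contributes its role-sequence-A member and its B member,
and every A–B recombination across distinct real pairs is a pseudo pair
(P real pairs yield P·(P−1) pseudo pairs; 22 yield 462).

Synchronization is measured voxelwise: the Pearson correlation between
the two members' series at the same voxel coordinate, Fisher
z-transformed.  Residual time courses (from unwhitened trial-wise fits)
are correlated per run and their z values averaged within condition type
(JA vs control), so run boundaries never contribute spurious correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_JA_RUNS = 4


def fisher_z(r, eps: float = 1e-7):
    """Variance-stabilizing transform ``z = atanh(r)``.

    Correlations with ``|r| >= 1 - eps`` are clipped before the transform
    (a self-correlation maps to a large finite z rather than infinity);
    values outside [-1, 1] beyond float tolerance are rejected.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    return np.arctanh(np.clip(r, -1.0 + eps, 1.0 - eps))


@dataclass
class BetaSeries:
    """Ordered per-trial betas across the four reordered JA runs."""

    participant_id: str
    pair_id: str
    role_label: str                 # "A" or "B": which role sequence was followed
    values: np.ndarray              # voxel x (4 * trials-per-run) ordered betas
    grid_shape: tuple | None = None

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]


@dataclass
class ResidualSeries:
    """Per-run residual time courses of one condition type."""

    participant_id: str
    pair_id: str
    role_label: str
    condition_type: str             # "JA" or "control"
    runs: list                      # list of voxel x time arrays, session order
    grid_shape: tuple | None = None

    @property
    def values(self) -> np.ndarray:
        """Concatenation across runs (run boundaries in ``run_slices``)."""
        return np.concatenate(self.runs, axis=1)

    @property
    def run_slices(self) -> list:
        slices, start = [], 0
        for r in self.runs:
            slices.append(slice(start, start + r.shape[1]))
            start += r.shape[1]
        return slices


def assemble_beta_series(trialwise_fits: dict, task_types: dict,
                         participant_id: str = "unknown",
                         pair_id: str = "unknown",
                         role_label: str = "A") -> BetaSeries:
    """Build the canonical beta series from per-run trial-wise fits.

    Parameters
    ----------
    trialwise_fits
        Mapping run_index -> trial-wise :class:`~dyadsync.first_level.GLMFit`.
    task_types
        Mapping run_index -> task type; control runs are excluded and the
        JA runs reordered fJA1, fJA2, sJA1, sJA2 (session order within
        type).  Run indices may arrive in any order.

    Only the trial (interest) betas enter the series; the verify-phase
    no-interest beta is dropped.
    """
    f_runs = sorted(r for r, t in task_types.items() if t == "fJA")
    s_runs = sorted(r for r, t in task_types.items() if t == "sJA")
    if len(f_runs) != 2 or len(s_runs) != 2:
        raise ValueError(f"need two fJA and two sJA trial-wise fits, got "
                         f"{len(f_runs)} fJA / {len(s_runs)} sJA")
    blocks, n_trials = [], None
    grid_shape = None
    for r in f_runs + s_runs:
        if r not in trialwise_fits:
            raise ValueError(f"missing trial-wise fit for run {r}")
        fit = trialwise_fits[r]
        betas = fit.interest_betas()
        if n_trials is None:
            n_trials = betas.shape[1]
        elif betas.shape[1] != n_trials:
            raise ValueError("inconsistent trial counts across JA runs")
        grid_shape = fit.grid_shape or grid_shape
        blocks.append(betas)
    return BetaSeries(participant_id=participant_id, pair_id=pair_id,
                      role_label=role_label,
                      values=np.concatenate(blocks, axis=1),
                      grid_shape=grid_shape)


def assemble_residual_series(unwhitened_fits: dict, task_types: dict,
                             condition_type: str,
                             participant_id: str = "unknown",
                             pair_id: str = "unknown",
                             role_label: str = "A") -> ResidualSeries:
    """Collect residual time courses of one condition type (JA or control).

    JA residuals follow the same canonical fJA1, fJA2, sJA1, sJA2 order
    as the beta series; control residuals keep session order.  Fits must
    come from ``whiten="none"`` so the residual autocorrelation is
    preserved.
    """
    if condition_type == "JA":
        order = (sorted(r for r, t in task_types.items() if t == "fJA")
                 + sorted(r for r, t in task_types.items() if t == "sJA"))
    elif condition_type == "control":
        order = sorted(r for r, t in task_types.items() if t == "control")
    else:
        raise ValueError("condition_type must be 'JA' or 'control'")
    runs, grid_shape = [], None
    for r in order:
        fit = unwhitened_fits[r]
        if fit.whitened:
            raise ValueError("residual series require unwhitened fits "
                             "(whiten='none')")
        runs.append(fit.residuals)
        grid_shape = fit.grid_shape or grid_shape
    if not runs:
        raise ValueError(f"no {condition_type} runs among fits")
    return ResidualSeries(participant_id=participant_id, pair_id=pair_id,
                          role_label=role_label, condition_type=condition_type,
                          runs=runs, grid_shape=grid_shape)


# ---------------------------------------------------------------------------
# Pair enumeration
# ---------------------------------------------------------------------------

def enumerate_pseudo_pairs(real_pairs):
    """All cross-pair (A-member, B-member) recombinations.

    ``real_pairs`` is an ordered sequence of ``(a_id, b_id)`` tuples, one
    per real pair.  The result lists every ``(a_i, b_j)`` with ``i != j``
    in deterministic (i-major) order: ``P`` real pairs give ``P*(P-1)``
    pseudo pairs, none of which coincides with a real pair.
    """
    real_pairs = list(real_pairs)
    if len(real_pairs) < 2:
        raise ValueError("need at least two real pairs")
    ids = [m for p in real_pairs for m in p]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate participant ids across pairs")
    return [(a, b)
            for i, (a, _) in enumerate(real_pairs)
            for j, (_, b) in enumerate(real_pairs)
            if i != j]


# ---------------------------------------------------------------------------
# Voxelwise correlation
# ---------------------------------------------------------------------------

@dataclass
class PairCorrelationMap:
    member_ids: tuple
    pair_type: str                  # "real" | "pseudo"
    analysis: str                   # "beta_series" | "residual"
    r: np.ndarray                   # voxel map of correlations
    z: np.ndarray                   # Fisher z map
    valid: np.ndarray               # voxels where r is defined
    condition_type: str | None = None
    grid_shape: tuple | None = None


def _rowwise_pearson(x: np.ndarray, y: np.ndarray):
    xm = x - x.mean(axis=1, keepdims=True)
    ym = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xm * xm).sum(axis=1))
    sy = np.sqrt((ym * ym).sum(axis=1))
    valid = (sx > 0) & (sy > 0)
    denom = np.where(valid, sx * sy, 1.0)
    r = (xm * ym).sum(axis=1) / denom
    r = np.clip(np.where(valid, r, 0.0), -1.0, 1.0)
    return r, valid


def pair_correlation(x, y, clip_eps: float = 1e-7,
                     standardize_runs: bool = False) -> PairCorrelationMap:
    """Voxelwise synchronization map between two members' series.

    Both arguments must be the same series type on the same grid.  Beta
    series are correlated over their full 128-trial length (optionally
    z-scored per run first, off by default since betas are already
    per-trial amplitudes).  Residual series are demeaned and correlated
    per run, Fisher-transformed, and the z values averaged across the
    runs of the condition type; the reported r is the back-transform of
    that mean z.  Zero-variance voxels are flagged invalid with r = 0.
    """
    if type(x) is not type(y):
        raise TypeError("both series must be of the same analysis type")
    pair_type = "real" if x.pair_id == y.pair_id else "pseudo"
    if isinstance(x, BetaSeries):
        if x.values.shape != y.values.shape:
            raise ValueError("beta series shapes differ")
        if pair_type == "pseudo" and x.role_label == y.role_label:
            raise ValueError("pseudo pairs must combine complementary "
                             "role-sequence members (one A, one B)")
        xv, yv = np.asarray(x.values, float), np.asarray(y.values, float)
        if standardize_runs:
            n = xv.shape[1] // N_JA_RUNS
            xv, yv = xv.copy(), yv.copy()
            for k in range(N_JA_RUNS):
                for v in (xv, yv):
                    blk = v[:, k * n:(k + 1) * n]
                    sd = blk.std(axis=1, keepdims=True)
                    sd[sd == 0] = 1.0
                    v[:, k * n:(k + 1) * n] = (blk - blk.mean(axis=1, keepdims=True)) / sd
        r, valid = _rowwise_pearson(xv, yv)
        z = np.where(valid, fisher_z(r, clip_eps), 0.0)
        return PairCorrelationMap(
            member_ids=(x.participant_id, y.participant_id),
            pair_type=pair_type, analysis="beta_series", r=r, z=z,
            valid=valid, grid_shape=x.grid_shape)

    if isinstance(x, ResidualSeries):
        if x.condition_type != y.condition_type:
            raise ValueError("residual series condition types differ")
        if len(x.runs) != len(y.runs):
            raise ValueError("run counts differ")
        z_sum = None
        valid_all = None
        for xr, yr in zip(x.runs, y.runs):
            if xr.shape != yr.shape:
                raise ValueError("residual run shapes differ")
            r_run, valid = _rowwise_pearson(np.asarray(xr, float),
                                            np.asarray(yr, float))
            z_run = np.where(valid, fisher_z(r_run, clip_eps), 0.0)
            z_sum = z_run if z_sum is None else z_sum + z_run
            valid_all = valid if valid_all is None else (valid_all & valid)
        z = z_sum / len(x.runs)
        z = np.where(valid_all, z, 0.0)
        return PairCorrelationMap(
            member_ids=(x.participant_id, y.participant_id),
            pair_type=pair_type, analysis="residual", r=np.tanh(z), z=z,
            valid=valid_all, condition_type=x.condition_type,
            grid_shape=x.grid_shape)

    raise TypeError(f"unsupported series type {type(x).__name__}")


def cohort_z_maps(series_by_pair: dict, analysis: str = "beta_series",
                  clip_eps: float = 1e-7):
    """Real- and pseudo-pair Fisher-z stacks for a whole cohort.

    ``series_by_pair`` maps pair_id -> (series_A, series_B).  Returns
    ``(real_z, pseudo_z, real_ids, pseudo_ids)`` with z stacks of shape
    (n_pairs, n_voxels) in deterministic order.
    """
    pair_ids = sorted(series_by_pair)
    members = {p: series_by_pair[p] for p in pair_ids}
    real_z, real_ids = [], []
    for p in pair_ids:
        a, b = members[p]
        m = pair_correlation(a, b, clip_eps)
        real_z.append(m.z)
        real_ids.append(m.member_ids)
    pseudo_z, pseudo_ids = [], []
    for i, pi in enumerate(pair_ids):
        for j, pj in enumerate(pair_ids):
            if i == j:
                continue
            m = pair_correlation(members[pi][0], members[pj][1], clip_eps)
            pseudo_z.append(m.z)
            pseudo_ids.append(m.member_ids)
    return (np.asarray(real_z), np.asarray(pseudo_z), real_ids, pseudo_ids)
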