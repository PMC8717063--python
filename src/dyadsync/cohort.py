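"""Cohort-level orchestration: simulate pairs, fit GLMs, build series, test.

This module glues the stages together for whole-cohort work: it simulates
every pair, runs the trial-wise GLMs (whitened for betas, unwhitened for
residuals, sharing the filtering pass), assembles beta and residual
series, enumerates real and pseudo pairs, and produces the Fisher-z
stacks consumed by the group tests.  A vectorized z-stack routine
(`cohort_z_maps_fast`) precomputes standardized series per participant so
the 462 pseudo-pair correlations reduce to row dot products; it is
checked against the reference per-pair path in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import TaskDesign, generate_design
from .first_level import build_design, fit_glm_both
from .group import ClusterTable, cluster_fwe, welch_two_sample_t
from .interbrain import (BetaSeries, ResidualSeries, assemble_beta_series,
                         assemble_residual_series, fisher_z)
from .simulate import SyncGroundTruth, default_ground_truth, simulate_pair


def derive_seed(master_seed: int, *context) -> int:
    """Deterministic sub-seed below 2**31 from a master seed and context."""
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF]
                                + [int(c) & 0x7FFFFFFF for c in context])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PairAnalysis:
    """First-level products of one simulated pair."""

    pair_id: str
    design: TaskDesign
    beta: tuple                     # (BetaSeries A, BetaSeries B)
    residual_ja: tuple              # (ResidualSeries A, ResidualSeries B)
    residual_control: tuple
    phi_by_run: dict                # run_index -> (phi_A, phi_B)


_design_cache: dict = {}


def _trialwise_design(design: TaskDesign, run_index: int, tr_s, n_volumes,
                      highpass_cutoff_s):
    run = next(r for r in design.runs if r.run_index == run_index)
    key = (tuple(t.onset_s for t in run.trials), run.n_trials,
           tr_s, n_volumes, highpass_cutoff_s)
    if key not in _design_cache:
        _design_cache[key] = build_design(
            design, participant="A", trialwise=True, run_index=run_index,
            tr_s=tr_s, n_volumes=n_volumes,
            highpass_cutoff_s=highpass_cutoff_s)
    return _design_cache[key]


def analyze_pair(design: TaskDesign, truth: SyncGroundTruth, seed: int,
                 n_volumes: int = 175, tr_s: float = 2.5,
                 highpass_cutoff_s: float = 128.0,
                 max_pool: int = 200) -> PairAnalysis:
    """Simulate one pair and run its trial-wise first level.

    Every run of both members is fit twice in one pass — AR(1)-whitened
    (trial betas for the beta series) and unwhitened (residual time
    courses) — and the series are assembled in canonical order.
    """
    sim = simulate_pair(design, truth, seed, n_volumes=n_volumes, tr_s=tr_s)
    task_types = {r.run_index: r.task_type for r in design.runs}
    fits_w = {"A": {}, "B": {}}
    fits_u = {"A": {}, "B": {}}
    phi_by_run = {}
    for run_a, run_b in zip(sim.runs_a, sim.runs_b):
        ridx = run_a.run_index
        X = _trialwise_design(design, ridx, tr_s, n_volumes, highpass_cutoff_s)
        w_a, u_a = fit_glm_both(run_a, X, max_pool=max_pool)
        w_b, u_b = fit_glm_both(run_b, X, max_pool=max_pool)
        fits_w["A"][ridx], fits_u["A"][ridx] = w_a, u_a
        fits_w["B"][ridx], fits_u["B"][ridx] = w_b, u_b
        phi_by_run[ridx] = (w_a.ar1_phi, w_b.ar1_phi)

    def series(member, role):
        pid = f"{design.pair_id}-{member}"
        beta = assemble_beta_series(fits_w[member], task_types,
                                    participant_id=pid, pair_id=design.pair_id,
                                    role_label=role)
        res_ja = assemble_residual_series(fits_u[member], task_types, "JA",
                                          participant_id=pid,
                                          pair_id=design.pair_id,
                                          role_label=role)
        res_ct = assemble_residual_series(fits_u[member], task_types,
                                          "control", participant_id=pid,
                                          pair_id=design.pair_id,
                                          role_label=role)
        return beta, res_ja, res_ct

    ba, ra, ca = series("A", "A")
    bb, rb, cb = series("B", "B")
    return PairAnalysis(pair_id=design.pair_id, design=design,
                        beta=(ba, bb), residual_ja=(ra, rb),
                        residual_control=(ca, cb), phi_by_run=phi_by_run)


@dataclass
class CohortSeries:
    """Per-pair series bundles for a simulated cohort."""

    pairs: list                     # list of PairAnalysis, pair_id order
    truth: SyncGroundTruth

    def series_by_pair(self, analysis: str) -> dict:
        attr = {"beta_series": "beta", "residual_ja": "residual_ja",
                "residual_control": "residual_control"}[analysis]
        return {p.pair_id: getattr(p, attr) for p in self.pairs}

    @property
    def mean_phi(self) -> float:
        vals = [phi for p in self.pairs for pair in p.phi_by_run.values()
                for phi in pair]
        return float(np.mean(vals))


def simulate_cohort(n_pairs: int, truth: SyncGroundTruth, seed: int,
                    n_volumes: int = 175, tr_s: float = 2.5,
                    highpass_cutoff_s: float = 128.0,
                    n_trials_per_run: int = 32,
                    max_pool: int = 200) -> CohortSeries:
    """Simulate and first-level-analyze a cohort of real pairs."""
    pairs = []
    for i in range(n_pairs):
        design = generate_design(derive_seed(seed, i, 1),
                                 pair_id=f"pair{i:02d}",
                                 n_trials_per_run=n_trials_per_run)
        pairs.append(analyze_pair(design, truth, derive_seed(seed, i, 2),
                                  n_volumes=n_volumes, tr_s=tr_s,
                                  highpass_cutoff_s=highpass_cutoff_s,
                                  max_pool=max_pool))
    return CohortSeries(pairs=pairs, truth=truth)


# ---------------------------------------------------------------------------
# Fast z-map stacks
# ---------------------------------------------------------------------------

def _standardize_rows(a: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    norm = np.sqrt((a * a).sum(axis=1, keepdims=True))
    norm[norm == 0] = np.inf
    return a / norm


def cohort_z_maps_fast(series_by_pair: dict, analysis: str = "beta_series",
                       clip_eps: float = 1e-7):
    """Real and pseudo Fisher-z stacks via batched voxelwise matmuls.

    All P*P member combinations are correlated at once: per voxel the
    standardized A-member series (P, T) is multiplied against the
    B-member series, giving every real (diagonal) and pseudo
    (off-diagonal, i-major order) correlation in one batched product.
    Equivalent to pairing every combination through
    :func:`dyadsync.interbrain.pair_correlation` (checked in the tests).
    Returns ``(real_z, pseudo_z)`` with shapes (P, V) and (P*(P-1), V).
    """
    pair_ids = sorted(series_by_pair)
    P = len(pair_ids)
    first = series_by_pair[pair_ids[0]][0]
    if isinstance(first, BetaSeries):
        run_lists = [[np.asarray(series_by_pair[p][m].values) for p in pair_ids]
                     for m in (0, 1)]
        run_lists = [[run_lists[0]], [run_lists[1]]]   # single "run" block
    elif isinstance(first, ResidualSeries):
        n_runs = len(first.runs)
        run_lists = [[[np.asarray(series_by_pair[p][m].runs[r])
                       for p in pair_ids] for r in range(n_runs)]
                     for m in (0, 1)]
    else:
        raise TypeError("unsupported series type")

    z_acc = None
    n_blocks = len(run_lists[0])
    for r in range(n_blocks):
        # (V, P, T) standardized stacks per member
        stacks = []
        for m in (0, 1):
            arr = np.stack([_standardize_rows(a) for a in run_lists[m][r]])
            stacks.append(np.ascontiguousarray(arr.transpose(1, 0, 2)))
        corr = np.matmul(stacks[0], stacks[1].transpose(0, 2, 1))  # (V, P, P)
        np.clip(corr, -1.0, 1.0, out=corr)
        z = fisher_z(corr, clip_eps)
        z_acc = z if z_acc is None else z_acc + z
    z_acc /= n_blocks

    real_z = np.ascontiguousarray(
        z_acc[:, np.arange(P), np.arange(P)].T)
    ii, jj = np.nonzero(~np.eye(P, dtype=bool))
    order = np.lexsort((jj, ii))                        # i-major enumeration
    pseudo_z = np.ascontiguousarray(z_acc[:, ii[order], jj[order]].T)
    return real_z, pseudo_z


def ground_truth_recovery_trial(seed: int, n_pairs: int = 22,
                                grid_shape=(24, 24, 24),
                                n_mask_voxels: int = 50,
                                coupling_task: float = 0.6,
                                coupling_residual: float = 0.5,
                                height_p: float = 0.001, alpha: float = 0.05,
                                n_perm: int = 200) -> dict:
    """One full recovery experiment on a synthetic cohort.

    Simulates the cohort with trial-amplitude coupling in one mask and
    background coupling in a disjoint mask, runs both inter-brain
    analyses plus the control-run residual analysis, and reports whether
    each analysis produced a significant real>pseudo cluster whose peak
    falls inside the matching ground-truth mask, and whether the control
    analysis stayed clean.
    """
    truth = default_ground_truth(grid_shape, n_mask_voxels=n_mask_voxels,
                                 coupling_task=coupling_task,
                                 coupling_residual=coupling_residual)
    cohort = simulate_cohort(n_pairs, truth, seed)
    masks = {"beta_series": truth.task_sync_mask,
             "residual_ja": truth.residual_sync_mask}
    out = {"seed": seed, "mean_phi": cohort.mean_phi}
    for key, mask in masks.items():
        table, tmap, real_z, pseudo_z = real_vs_pseudo_cluster_test(
            cohort.series_by_pair(key), grid_shape,
            analysis=key, height_p=height_p, alpha=alpha, n_perm=n_perm,
            seed=derive_seed(seed, 7))
        sig = table.significant()
        hit = any(mask[int(r["peak_i"]), int(r["peak_j"]), int(r["peak_k"])]
                  for _, r in sig.iterrows())
        out[f"{key}_hit"] = bool(hit)
        out[f"{key}_n_significant"] = int(len(sig))
        m = mask.ravel()
        out[f"{key}_real_minus_pseudo_z_in_mask"] = float(
            real_z[:, m].mean() - pseudo_z[:, m].mean())
    table, _, _, _ = real_vs_pseudo_cluster_test(
        cohort.series_by_pair("residual_control"), grid_shape,
        analysis="residual_control", height_p=height_p, alpha=alpha,
        n_perm=n_perm, seed=derive_seed(seed, 8))
    out["control_clean"] = table.n_significant == 0
    return out


def real_vs_pseudo_cluster_test(series_by_pair: dict, shape,
                                analysis: str = "beta_series",
                                height_p: float = 0.001, alpha: float = 0.05,
                                n_perm: int = 200, seed: int = 0):
    """Welch real-vs-pseudo comparison with permutation cluster FWE.

    Returns ``(ClusterTable, GroupTMap, real_z, pseudo_z)``.
    """
    real_z, pseudo_z = cohort_z_maps_fast(series_by_pair, analysis)
    table = cluster_fwe((real_z, pseudo_z), shape, test="welch",
                        height_p=height_p, alpha=alpha, n_perm=n_perm,
                        seed=seed)
    tmap = welch_two_sample_t(real_z, pseudo_z, analysis=analysis,
                              shape=tuple(shape))
    return table, tmap, real_z, pseudo_z
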