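"""Forward model for paired BOLD data with known inter-brain coupling.

Each participant-run is simulated as

    signal = sum_i amplitude_i * HRF-boxcar(event_i)  +  drift  +  noise

where the per-trial amplitudes, slow cosine drift and AR(1) Gaussian noise
are voxelwise.  Ground-truth coupling enters in two places, and only in
joint-attention (JA) runs:

* ``task_sync_mask`` voxels: the two partners' trial-amplitude series
  share a common random component carrying a fraction ``coupling_task``
  of the amplitude variance — the signature the beta-series correlation
  analysis detects.
* ``residual_sync_mask`` voxels: a shared smooth latent series (low-pass
  filtered Gaussian noise, emulating coherent background fluctuation)
  carries a fraction ``coupling_residual`` of the background variance —
  the signature the residual time-series analysis detects.

Control runs never receive shared components, so any apparent
synchronization there is a false positive.  All randomness derives from a
single seed through per-(run, stream) seed splitting, making output
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import nibabel as nib
import numpy as np
from scipy import ndimage, signal as sp_signal

from .design import (EVENT_DURATION_S, VERIFY_DURATION_S, TaskDesign)
from .hrf import hrf_regressor

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def mni_like_affine(grid_shape, voxel_mm: float = 3.0) -> np.ndarray:
    """Isotropic affine centered on the grid, RAS axes."""
    aff = np.diag([voxel_mm] * 3 + [1.0])
    aff[:3, 3] = -(np.asarray(grid_shape, float) - 1) / 2.0 * voxel_mm
    return aff


def compact_mask(grid_shape, center, n_voxels: int) -> np.ndarray:
    """Boolean mask of exactly ``n_voxels`` forming a compact connected blob."""
    shape = tuple(grid_shape)
    side = 1
    while side ** 3 < n_voxels:
        side += 1
    half = side // 2
    start = [max(0, min(int(c) - half, s - side)) for c, s in zip(center, shape)]
    mask = np.zeros(shape, dtype=bool)
    idx = np.stack(np.meshgrid(*[np.arange(s0, s0 + side) for s0 in start],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    for i, j, k in idx[:n_voxels]:
        mask[i, j, k] = True
    return mask


@dataclass
class SyncGroundTruth:
    """Known coupling structure injected into a simulated cohort."""

    grid_shape: tuple
    task_sync_mask: np.ndarray          # bool, shared trial-amplitude coupling
    residual_sync_mask: np.ndarray      # bool, shared background fluctuation
    coupling_task: float = 0.6          # shared fraction of amplitude variance
    coupling_residual: float = 0.5      # shared fraction of background variance
    ar1_phi: float = 0.3                # noise autocorrelation
    noise_sd: float = 1.0               # marginal noise standard deviation
    drift_amp: float = 1.0              # per-cosine drift coefficient sd
    amp_mean: float = 1.0               # mean trial amplitude
    amp_sd: float = 0.5                 # trial-amplitude variability
    verify_amp: float = 0.5             # fixed amplitude of the verify response
    residual_latent_cutoff_hz: float = 0.1

    def __post_init__(self):
        self.grid_shape = tuple(self.grid_shape)
        for name in ("task_sync_mask", "residual_sync_mask"):
            m = np.asarray(getattr(self, name), dtype=bool)
            if m.shape != self.grid_shape:
                raise ValueError(f"{name} shape {m.shape} != grid {self.grid_shape}")
            setattr(self, name, m)
        for name in ("coupling_task", "coupling_residual"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not -1.0 < self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must lie in (-1, 1)")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


def default_ground_truth(grid_shape=(24, 24, 24), n_mask_voxels: int = 50,
                         **kwargs) -> SyncGroundTruth:
    """Ground truth with two disjoint compact masks in opposite octants."""
    shape = tuple(grid_shape)
    q = [s // 4 for s in shape]
    task = compact_mask(shape, q, n_mask_voxels)
    resid = compact_mask(shape, [3 * x for x in q], n_mask_voxels)
    if (task & resid).any():
        raise ValueError("grid too small for disjoint masks")
    return SyncGroundTruth(grid_shape=shape, task_sync_mask=task,
                           residual_sync_mask=resid, **kwargs)


@dataclass
class BOLDRun:
    """One participant-run 4D image plus acquisition metadata."""

    data: np.ndarray                    # (x, y, z, time), float32
    tr_s: float
    participant_id: str
    pair_id: str
    run_index: int
    task_type: str
    affine: np.ndarray = field(default_factory=lambda: mni_like_affine((24, 24, 24)))

    def __post_init__(self):
        if np.isnan(self.data).any():
            raise ValueError("BOLD data contains NaN")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_s


@dataclass
class SimulatedPair:
    """Paired simulated runs plus the generating latents (test oracle)."""

    runs_a: list
    runs_b: list
    #: per run_index: dict with 'amp_a'/'amp_b' (n_voxels, n_trials) latent
    #: trial-amplitude series and, for JA runs, 'shared_amp' on mask voxels.
    latents: dict

    def __iter__(self) -> Iterator:
        return iter((self.runs_a, self.runs_b))


def _ar1_noise(rng: np.random.Generator, n_voxels: int, n_time: int,
               phi: float, sd: float, burn: int = 30) -> np.ndarray:
    innov = rng.standard_normal((n_voxels, n_time + burn), dtype=np.float32)
    x = sp_signal.lfilter(np.float32([1.0]), np.float32([1.0, -phi]),
                          innov, axis=1)[:, burn:]
    return np.float32(sd * np.sqrt(1.0 - phi * phi)) * x


def _smooth_latent(rng: np.random.Generator, n_series: int, n_time: int,
                   tr_s: float, cutoff_hz: float) -> np.ndarray:
    """Unit-variance low-pass Gaussian latent series, one per row."""
    white = rng.standard_normal((n_series, n_time))
    nyq = 0.5 / tr_s
    if cutoff_hz >= nyq:
        lat = white
    else:
        b, a = sp_signal.butter(4, cutoff_hz / nyq, btype="low")
        lat = sp_signal.filtfilt(b, a, white, axis=1)
    sd = lat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (lat - lat.mean(axis=1, keepdims=True)) / sd


def _drift(rng: np.random.Generator, n_voxels: int, frame_times: np.ndarray,
           amp: float, max_components: int = 3,
           min_period_s: float = 160.0) -> np.ndarray:
    # cosine components with periods comfortably above the 128 s high-pass
    # cutoff, so the filter can remove what the generator injects
    dur = frame_times[-1] + (frame_times[1] - frame_times[0])
    ks = [k for k in range(1, max_components + 1)
          if 2.0 * dur / k >= min_period_s] or [1]
    basis = np.stack([np.cos(np.pi * k * (frame_times + 0.5) / dur)
                      for k in ks]).astype(np.float32)
    coeffs = rng.standard_normal((n_voxels, len(ks)),
                                 dtype=np.float32) * np.float32(amp)
    return coeffs @ basis


_REGRESSOR_CACHE: dict = {}


def _event_regressors(onsets: tuple, duration: float,
                      frame_times_key: tuple) -> np.ndarray:
    key = (onsets, duration, frame_times_key)
    if key not in _REGRESSOR_CACHE:
        ft = np.asarray(frame_times_key)
        _REGRESSOR_CACHE[key] = np.stack(
            [hrf_regressor([on], [duration], ft) for on in onsets])
    return _REGRESSOR_CACHE[key]


def simulate_pair(design: TaskDesign, truth: SyncGroundTruth, seed: int,
                  n_volumes: int = 175, tr_s: float = 2.5) -> SimulatedPair:
    """Simulate both partners' six runs for one pair.

    Deterministic given ``(design, truth, seed)``.  The returned object
    unpacks as ``runs_a, runs_b`` and exposes the latent trial-amplitude
    series in ``.latents`` for ground-truth checks.
    """
    V = truth.n_voxels
    frame_times = np.arange(n_volumes) * tr_s
    ft_key = tuple(np.round(frame_times, 6))
    task_idx = np.flatnonzero(truth.task_sync_mask.ravel())
    resid_idx = np.flatnonzero(truth.residual_sync_mask.ravel())
    affine = mni_like_affine(truth.grid_shape)
    c_t, c_r = truth.coupling_task, truth.coupling_residual

    runs_a, runs_b, latents = [], [], {}
    for run in design.runs:
        last_offset = run.trials[-1].onset_s + sum(run.trials[-1].phase_durations_s)
        if n_volumes * tr_s < last_offset:
            raise ValueError(
                f"run {run.run_index}: {n_volumes} volumes at TR {tr_s}s do not "
                f"cover the last trial offset {last_offset}s")
        n_trials = run.n_trials
        is_ja = run.task_type != "control"
        event_onsets = tuple(tr.event_onset_s for tr in run.trials)
        verify_onsets = tuple(tr.verify_onset_s for tr in run.trials)
        X_trial = _event_regressors(event_onsets, EVENT_DURATION_S, ft_key)
        x_verify = _event_regressors(verify_onsets, VERIFY_DURATION_S, ft_key).sum(axis=0)

        def rng_for(stream: int) -> np.random.Generator:
            return np.random.default_rng(
                np.random.SeedSequence([int(seed), run.run_index, stream]))

        # trial-amplitude latents (unit-variance components)
        e_a = rng_for(1).standard_normal((V, n_trials))
        e_b = rng_for(2).standard_normal((V, n_trials))
        shared_amp = None
        if is_ja and c_t > 0 and task_idx.size:
            shared_amp = rng_for(3).standard_normal((task_idx.size, n_trials))
            mix_s, mix_i = np.sqrt(c_t), np.sqrt(1.0 - c_t)
            e_a[task_idx] = mix_s * shared_amp + mix_i * e_a[task_idx]
            e_b[task_idx] = mix_s * shared_amp + mix_i * e_b[task_idx]
        amp_a = truth.amp_mean + truth.amp_sd * e_a
        amp_b = truth.amp_mean + truth.amp_sd * e_b
        latents[run.run_index] = {"amp_a": amp_a, "amp_b": amp_b,
                                  "shared_amp": shared_amp,
                                  "task_voxels": task_idx}

        X32 = X_trial.astype(np.float32)
        xv32 = (truth.verify_amp * x_verify).astype(np.float32)
        data = {}
        for member, amp, noise_stream, drift_stream in (
                ("A", amp_a, 4, 6), ("B", amp_b, 5, 7)):
            y = amp.astype(np.float32) @ X32
            y += xv32
            if truth.drift_amp > 0:
                y += _drift(rng_for(drift_stream), V, frame_times, truth.drift_amp)
            noise = _ar1_noise(rng_for(noise_stream), V, n_volumes,
                               truth.ar1_phi, truth.noise_sd)
            if is_ja and c_r > 0 and resid_idx.size:
                shared_bg = (_smooth_latent(
                    rng_for(8), resid_idx.size, n_volumes, tr_s,
                    truth.residual_latent_cutoff_hz) * truth.noise_sd)
                noise[resid_idx] = (np.float32(np.sqrt(1.0 - c_r)) * noise[resid_idx]
                                    + np.float32(np.sqrt(c_r)) * shared_bg.astype(np.float32))
            y += noise
            data[member] = y.reshape(truth.grid_shape + (n_volumes,))

        for member, store in (("A", runs_a), ("B", runs_b)):
            store.append(BOLDRun(
                data=data[member], tr_s=tr_s,
                participant_id=f"{design.pair_id}-{member}",
                pair_id=design.pair_id, run_index=run.run_index,
                task_type=run.task_type, affine=affine))
    return SimulatedPair(runs_a=runs_a, runs_b=runs_b, latents=latents)


# ---------------------------------------------------------------------------
# Spatial smoothing
# ---------------------------------------------------------------------------

def smooth_gaussian(run: BOLDRun, fwhm_mm: float) -> BOLDRun:
    """Volume-wise 3D Gaussian smoothing; ``fwhm_mm=0`` is the identity.

    The per-axis kernel sigma is ``fwhm / (2 sqrt(2 ln 2))`` divided by
    that axis's voxel size from the affine, so anisotropic voxel grids
    are handled per axis.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return run
    voxsize = np.sqrt((run.affine[:3, :3] ** 2).sum(axis=0))
    if np.any(voxsize <= 0):
        raise ValueError("affine has a degenerate spatial axis")
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxsize
    smoothed = ndimage.gaussian_filter(
        run.data.astype(np.float64), sigma=tuple(sigma_vox) + (0.0,),
        mode="constant", cval=0.0)
    return BOLDRun(data=smoothed.astype(np.float32), tr_s=run.tr_s,
                   participant_id=run.participant_id, pair_id=run.pair_id,
                   run_index=run.run_index, task_type=run.task_type,
                   affine=run.affine)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def write_bold_nifti(run: BOLDRun, path) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
    img.header.set_xyzt_units("mm", "sec")
    img.header["pixdim"][4] = run.tr_s
    nib.save(img, str(path))


def read_bold_nifti(path, participant_id: str = "unknown",
                    pair_id: str = "unknown", run_index: int = 0,
                    task_type: str = "fJA", tr_s: float | None = None) -> BOLDRun:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D BOLD image, got shape {data.shape}")
    tr = float(img.header["pixdim"][4]) if tr_s is None else tr_s
    if tr <= 0:
        raise ValueError(f"{path}: TR not recorded in header; pass tr_s")
    return BOLDRun(data=data, tr_s=tr, participant_id=participant_id,
                   pair_id=pair_id, run_index=run_index, task_type=task_type,
                   affine=np.asarray(img.affine))


def write_mask_nifti(mask: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def read_mask_nifti(path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj).astype(bool)
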