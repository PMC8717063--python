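"""End-to-end pipeline: synth -> first level -> inter-brain -> group.

Configuration is a flat, strictly validated mapping (unknown keys are
rejected to catch typos); every stochastic stage draws from sub-seeds
derived from the single master seed, so a config fully determines all
outputs.  Each stage writes its artifacts under the output directory and
records them (with content hashes) in a run manifest; re-running an
identical config reproduces identical artifact hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .cohort import (CohortSeries, derive_seed, real_vs_pseudo_cluster_test,
                     simulate_cohort)
from .design import design_to_events, generate_design, write_events_tsv
from .first_level import (CONJUNCTIONS, CONTRASTS, build_design,
                          compute_contrast, fit_glm)
from .group import cluster_fwe, conjunction, one_sample_t
from .interbrain import enumerate_pseudo_pairs
from .simulate import (SyncGroundTruth, default_ground_truth, mni_like_affine,
                       simulate_pair, write_bold_nifti, write_mask_nifti)


class ConfigError(ValueError):
    """Invalid or unparsable pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Full configuration of a synthetic-cohort analysis run."""

    seed: int
    out_dir: str
    n_pairs: int = 22
    grid_shape: tuple = (24, 24, 24)
    n_mask_voxels: int = 50
    tr_s: float = 2.5
    n_volumes: int = 175
    n_trials_per_run: int = 32
    coupling_task: float = 0.6
    coupling_residual: float = 0.5
    ar1_phi: float = 0.3
    noise_sd: float = 1.0
    drift_amp: float = 1.0
    highpass_cutoff_s: float = 128.0
    whiten: str = "ar1"             # condition-GLM whitening
    analyses: tuple = ("beta_series", "residual")
    height_p: float = 0.001
    alpha: float = 0.05
    n_perm: int = 200
    method: str = "permutation"
    save_bold: bool = False
    smooth_fwhm_mm: float = 0.0
    run_condition_glm: bool = True

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.analyses = tuple(self.analyses)
        if self.n_pairs < 2:
            raise ConfigError("n_pairs must be at least 2")
        if self.seed is None:
            raise ConfigError("seed is mandatory (stochastic stages)")
        if self.whiten not in ("ar1", "none"):
            raise ConfigError("whiten must be 'ar1' or 'none'")
        if self.method not in ("permutation", "rft"):
            raise ConfigError("method must be 'permutation' or 'rft'")
        for name in ("coupling_task", "coupling_residual"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        bad = set(self.analyses) - {"beta_series", "residual"}
        if bad:
            raise ConfigError(f"unknown analyses {sorted(bad)}")
        if self.n_volumes * self.tr_s < self.n_trials_per_run * 12.5:
            raise ConfigError("run too short for the trial schedule")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}; "
                              f"known keys: {sorted(known)}")
        try:
            return cls(**d)
        except TypeError as e:
            raise ConfigError(str(e)) from e

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["analyses"] = list(self.analyses)
        return d


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML/JSON config file, with defaulting."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as e:
        mark = getattr(e, "problem_mark", None)
        loc = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"cannot parse {path}{loc}: {e}") from e
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return PipelineConfig.from_dict(data)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    version: str = _pkg_version
    stages: dict = field(default_factory=dict)      # stage -> wall time etc.
    artifacts: dict = field(default_factory=dict)   # relpath -> sha256
    summary: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=str)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    def reproducible_state(self) -> dict:
        """The config/hash content that must be identical across re-runs."""
        return json.loads(json.dumps(
            {"config": self.config, "artifacts": self.artifacts,
             "summary": self.summary, "version": self.version},
            default=str))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _stage(manifest, name):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.time()
            manifest.timestamps[name] = time.strftime("%Y-%m-%dT%H:%M:%S")
            return self

        def __exit__(self, etype, e, tb):
            manifest.stages[name] = {"wall_s": round(time.time() - self.t0, 3)}
            if e is not None:
                raise StageError(name, e) from e
    return _Ctx()


def run_pipeline(config: PipelineConfig, log=print) -> RunManifest:
    """Execute the full analysis on a synthetic cohort.

    Stages: generate designs and simulate paired BOLD (synth), trial-wise
    and condition GLMs (first_level), beta-series and residual inter-brain
    correlation over real and pseudo pairs (interbrain), and contrast,
    conjunction and real-vs-pseudo cluster inference (group).  Artifacts
    and a manifest land under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict())
    log(f"[dyadsync] pipeline start: {config.n_pairs} pairs, "
        f"grid {config.grid_shape}, seed {config.seed}")

    truth = default_ground_truth(
        config.grid_shape, n_mask_voxels=config.n_mask_voxels,
        coupling_task=config.coupling_task,
        coupling_residual=config.coupling_residual,
        ar1_phi=config.ar1_phi, noise_sd=config.noise_sd,
        drift_amp=config.drift_amp)
    affine = mni_like_affine(config.grid_shape)

    def record(relpath: str):
        manifest.artifacts[relpath] = _hash_file(out / relpath)

    with _stage(manifest, "synth"):
        designs = []
        for i in range(config.n_pairs):
            design = generate_design(derive_seed(config.seed, i, 1),
                                     pair_id=f"pair{i:02d}",
                                     n_trials_per_run=config.n_trials_per_run)
            designs.append(design)
            for member in ("A", "B"):
                rel = f"events_{design.pair_id}_{member}.tsv"
                write_events_tsv(design, out / rel, participant=member)
                record(rel)
            if config.save_bold:
                sim = simulate_pair(design, truth, derive_seed(config.seed, i, 2),
                                    n_volumes=config.n_volumes, tr_s=config.tr_s)
                for runs, member in ((sim.runs_a, "A"), (sim.runs_b, "B")):
                    for run in runs:
                        rel = (f"bold_{design.pair_id}_{member}"
                               f"_run{run.run_index}.nii")
                        write_bold_nifti(run, out / rel)
                        record(rel)
        write_mask_nifti(truth.task_sync_mask, affine, out / "task_sync_mask.nii")
        write_mask_nifti(truth.residual_sync_mask, affine,
                         out / "residual_sync_mask.nii")
        record("task_sync_mask.nii")
        record("residual_sync_mask.nii")
        n_trials = designs[0].n_trials
        manifest.summary["n_pairs"] = config.n_pairs
        manifest.summary["trials_per_pair"] = n_trials
        log(f"[synth] {config.n_pairs} designs, {n_trials} trials each")

    with _stage(manifest, "first_level"):
        cohort = simulate_cohort(
            config.n_pairs, truth, config.seed,
            n_volumes=config.n_volumes, tr_s=config.tr_s,
            highpass_cutoff_s=config.highpass_cutoff_s,
            n_trials_per_run=config.n_trials_per_run)
        manifest.summary["mean_ar1_phi"] = round(cohort.mean_phi, 4)
        log(f"[first_level] trial-wise GLMs done, "
            f"mean AR(1) phi {cohort.mean_phi:.3f}")
        contrast_stacks = {}
        if config.run_condition_glm:
            contrast_stacks = _condition_glm_stacks(designs, truth, config)
            log(f"[first_level] condition GLM contrasts: "
                f"{len(contrast_stacks)} maps x {2 * config.n_pairs} subjects")

    with _stage(manifest, "interbrain"):
        real_pairs = [(f"{d.pair_id}-A", f"{d.pair_id}-B") for d in designs]
        pseudo = enumerate_pseudo_pairs(real_pairs)
        manifest.summary["n_real_pairs"] = len(real_pairs)
        manifest.summary["n_pseudo_pairs"] = len(pseudo)
        rows = ([{"pair": f"{a}|{b}", "pair_type": "real"}
                 for a, b in real_pairs]
                + [{"pair": f"{a}|{b}", "pair_type": "pseudo"}
                   for a, b in pseudo])
        pd.DataFrame(rows).to_csv(out / "pair_manifest.csv", index=False)
        record("pair_manifest.csv")
        log(f"[interbrain] {len(real_pairs)} real pairs, "
            f"{len(pseudo)} pseudo pairs")

    with _stage(manifest, "group"):
        cluster_rows = []
        analysis_keys = []
        if "beta_series" in config.analyses:
            analysis_keys.append(("beta_series", "beta_series"))
        if "residual" in config.analyses:
            analysis_keys.append(("residual_JA", "residual_ja"))
            analysis_keys.append(("residual_control", "residual_control"))
        for label, key in analysis_keys:
            table, tmap, real_z, pseudo_z = real_vs_pseudo_cluster_test(
                cohort.series_by_pair(key), config.grid_shape,
                analysis=label, height_p=config.height_p, alpha=config.alpha,
                n_perm=config.n_perm, seed=derive_seed(config.seed, 97))
            rel = f"tmap_real_vs_pseudo_{label}.nii"
            _write_map(tmap.t, config.grid_shape, affine, out / rel)
            record(rel)
            rel = f"clusters_{label}.csv"
            table.clusters.to_csv(out / rel, index=False)
            record(rel)
            n_sig = table.n_significant
            manifest.summary[f"n_significant_clusters_{label}"] = n_sig
            for _, r in table.significant().iterrows():
                cluster_rows.append({"analysis": label, **r.to_dict()})
            log(f"[group] {label}: {n_sig} significant cluster(s) "
                f"(FWE p <= {config.alpha})")
        for cname, stack in contrast_stacks.items():
            tmap = one_sample_t(stack, analysis=cname,
                                shape=config.grid_shape)
            safe = cname.replace(">", "_gt_").replace("<", "_lt_")
            rel = f"tmap_contrast_{safe}.nii"
            _write_map(tmap.t, config.grid_shape, affine, out / rel)
            record(rel)
        if contrast_stacks:
            for cj_name, members in CONJUNCTIONS.items():
                maps = [one_sample_t(contrast_stacks[m], analysis=m,
                                     shape=config.grid_shape)
                        for m in members]
                mask = conjunction(maps, config.height_p)
                rel = f"conjunction_{cj_name}.nii"
                _write_map(mask.astype(np.float32), config.grid_shape,
                           affine, out / rel)
                record(rel)
        if cluster_rows:
            pd.DataFrame(cluster_rows).to_csv(
                out / "significant_clusters.csv", index=False)
            record("significant_clusters.csv")

    manifest.save(out / "manifest.json")
    log(f"[dyadsync] done; manifest at {out / 'manifest.json'}")
    return manifest


def _write_map(flat, shape, affine, path):
    import nibabel as nib
    nib.save(nib.Nifti1Image(np.asarray(flat, dtype=np.float32)
                             .reshape(shape), affine), str(path))


def _condition_glm_stacks(designs, truth: SyncGroundTruth,
                          config: PipelineConfig) -> dict:
    """Per-contrast stacks (subjects x voxels) from the condition GLM."""
    stacks = {name: [] for name in CONTRASTS}
    for i, design in enumerate(designs):
        sim = simulate_pair(design, truth, derive_seed(config.seed, i, 2),
                            n_volumes=config.n_volumes, tr_s=config.tr_s)
        for runs, member in ((sim.runs_a, "A"), (sim.runs_b, "B")):
            X = build_design(design, participant=member, trialwise=False,
                             tr_s=config.tr_s, n_volumes=config.n_volumes,
                             highpass_cutoff_s=config.highpass_cutoff_s)
            Y = np.concatenate(
                [r.data.reshape(-1, config.n_volumes) for r in runs], axis=1)
            fit = fit_glm(Y, X, whiten=config.whiten)
            for name, w in CONTRASTS.items():
                stacks[name].append(
                    compute_contrast(fit, w, f"{design.pair_id}-{member}",
                                     name).values)
    return {k: np.asarray(v) for k, v in stacks.items()}


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def write_report(manifest: RunManifest, out_dir=None) -> Path:
    """Summarize a run as ``report.csv`` and ``report.md``.

    Lists design counts, the pooled AR(1) estimate, real/pseudo pair
    counts and significant clusters per analysis.
    """
    out = Path(out_dir if out_dir is not None else manifest.config["out_dir"])
    rows = [{"item": k, "value": v} for k, v in sorted(manifest.summary.items())]
    pd.DataFrame(rows).to_csv(out / "report.csv", index=False)
    lines = ["# dyadsync run report", "",
             f"Package version: {manifest.version}", ""]
    lines += [f"- **{k}**: {v}" for k, v in sorted(manifest.summary.items())]
    lines += ["", "## Stages", ""]
    lines += [f"- {s}: {v.get('wall_s', '?')} s"
              for s, v in manifest.stages.items()]
    (out / "report.md").write_text("\n".join(lines) + "\n")
    return out / "report.md"
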