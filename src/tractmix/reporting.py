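"""End-to-end pipeline assembly, run reports and atlas map painting.

The analysis chain is simulate -> metrics -> zscore -> fit -> report.  Each
stage persists its intermediates; deterministic stages are bitwise
reproducible for a fixed seed, and every output file carries the run seed
and a hash of the configuration.

Map painting projects the tract-level posterior back onto the atlas volume:
a probability map (each labeled voxel carries its tract's probability of
belonging to the most-injured group) and a binary affiliation map (voxel
value = group label, background 0).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings as _warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import dti, synthetic, tables, zscores
from .mixture import MCMCConfig, MixtureModelSpec, TractMixture
from .tracts import ARTEFACT_SUSPECT_TRACTS

log = logging.getLogger("tractmix")

DEFAULT_CUTPOINTS = (0.1, 0.5, 0.8)


# ---------------------------------------------------------------------------
# map painting


def _posterior_by_label(posteriors: pd.DataFrame, atlas: dti.AtlasParcellation, column: str):
    by_name = dict(zip(posteriors["tract"], posteriors[column]))
    out = {}
    for label, name in atlas.label_to_name.items():
        if name in by_name:
            out[label] = by_name[name]
        else:
            _warnings.warn(f"no posterior for atlas label {label} ({name}); set to background")
    return out


def paint_probability_map(
    posteriors: pd.DataFrame, atlas: dti.AtlasParcellation
) -> np.ndarray:
    """float32 volume: each labeled voxel carries prob_group2, background 0."""
    values = _posterior_by_label(posteriors, atlas, "prob_group2")
    vol = np.zeros(atlas.labels.shape, dtype=np.float32)
    for label, value in values.items():
        vol[atlas.labels == label] = value
    return vol


def paint_affiliation_map(
    posteriors: pd.DataFrame, atlas: dti.AtlasParcellation
) -> np.ndarray:
    """uint8 volume of group labels (1 or 2) per labeled voxel, background 0."""
    values = _posterior_by_label(posteriors, atlas, "label")
    vol = np.zeros(atlas.labels.shape, dtype=np.uint8)
    for label, value in values.items():
        vol[atlas.labels == label] = value
    return vol


# ---------------------------------------------------------------------------
# run report


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    n_tracts_total: int
    n_group1: int
    n_group2: int
    n_excluded: int
    counts_above: dict
    artefact_suspect: list
    convergence_warnings: list
    seed: int
    config_hash: str
    posterior: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def summarize_run(
    posteriors: pd.DataFrame,
    n_tracts_total: int | None = None,
    cutpoints: tuple = DEFAULT_CUTPOINTS,
    seed: int = 0,
    cfg_hash: str = "",
    suspect_tracts: tuple = ARTEFACT_SUSPECT_TRACTS,
    convergence_warnings: list | None = None,
) -> RunReport:
    """Counts above probability cutpoints, group split, artefact flags.

    Tracts listed in ``suspect_tracts`` that land in group 2 are annotated
    (registration-quality caveat), never removed.
    """
    n_total = n_tracts_total if n_tracts_total is not None else len(posteriors)
    counts = {
        str(c): int((posteriors["prob_group2"] > c).sum()) for c in cutpoints
    }
    n_group2 = int((posteriors["label"] == 2).sum())
    n_group1 = int((posteriors["label"] == 1).sum())
    flagged = sorted(
        set(posteriors.loc[posteriors["label"] == 2, "tract"]) & set(suspect_tracts)
    )
    ranked = posteriors.sort_values("prob_group2", ascending=False)
    return RunReport(
        n_tracts_total=n_total,
        n_group1=n_group1,
        n_group2=n_group2,
        n_excluded=n_total - len(posteriors),
        counts_above=counts,
        artefact_suspect=flagged,
        convergence_warnings=list(convergence_warnings or []),
        seed=seed,
        config_hash=cfg_hash,
        posterior=ranked.to_dict(orient="records"),
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Stage toggles and settings for :func:`run_pipeline`."""

    out_dir: str = "tractmix_run"
    stages: tuple = ("simulate", "metrics", "zscore", "fit", "report")
    sim: synthetic.CohortSimConfig = field(default_factory=synthetic.CohortSimConfig)
    phantom: synthetic.VoxelPhantomConfig = field(
        default_factory=synthetic.VoxelPhantomConfig
    )
    spec: MixtureModelSpec = field(default_factory=MixtureModelSpec)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    threshold: float = 0.5
    seed: int = 0

    def as_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["Sigma"] = np.asarray(self.sim.Sigma).tolist()
        d["phantom"]["eigenvalues"] = np.asarray(self.phantom.eigenvalues).tolist()
        return d


def _stamp(path, seed: int, cfg_hash: str) -> None:
    """Prepend a provenance comment line to a CSV file."""
    with open(path) as fh:
        body = fh.read()
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} config={cfg_hash}\n{body}")


def _write_csv(df: pd.DataFrame, path, seed: int, cfg_hash: str) -> None:
    df.to_csv(path, index=False)
    _stamp(path, seed, cfg_hash)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in order, persisting every intermediate.

    Stage failures raise with the stage name; outputs written before the
    failure stay on disk.
    """
    from pathlib import Path

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config.as_dict())
    seed = config.seed
    sim_cfg = config.sim
    if sim_cfg.seed != seed:
        sim_cfg = synthetic.CohortSimConfig(
            **{**{f: getattr(sim_cfg, f) for f in (
                "n_tracts", "n_patients", "n_controls", "tract_names",
                "group2_tracts", "mu1", "mu2", "sigma1", "sigma2", "Sigma",
                "missing_rate", "control_noise_scale",
            )}, "seed": seed}
        )

    state: dict = {}

    def _run(stage, fn):
        if stage not in config.stages:
            return
        log.info("stage %s", stage)
        try:
            fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    def _simulate():
        controls = synthetic.simulate_control_metrics(sim_cfg)
        patients, truth = synthetic.simulate_patient_metrics(sim_cfg)
        _write_csv(controls, out / "controls.csv", seed, chash)
        _write_csv(patients, out / "patients.csv", seed, chash)
        with open(out / "sim_truth.json", "w") as fh:
            json.dump(
                {
                    "z": truth.z.tolist(),
                    "p": truth.p,
                    "tract_names": list(truth.tract_names),
                    "seed": seed,
                    "config": chash,
                },
                fh,
                indent=2,
            )
        state["controls"], state["patients"] = controls, patients

    def _metrics():
        # voxel-level demonstration path: phantom -> tensor fit -> ROI means
        tensor, labels, skeleton, signals, bvals, bvecs = synthetic.simulate_voxel_phantom(
            config.phantom
        )
        fitted, s0, valid = dti.fit_tensor(signals, bvals, bvecs)
        lam = dti.eigenspectrum(fitted)
        mets = dti.scalar_metrics(lam)
        atlas = dti.AtlasParcellation(
            labels,
            {i + 1: f"Phantom region {i + 1}" for i in range(config.phantom.n_tracts)},
        )
        table = dti.volume_metrics_to_table(mets, atlas, skeleton, "phantom")
        _write_csv(table, out / "phantom_roi_means.csv", seed, chash)
        for name, vol in mets.items():
            dti.save_volume(vol, out / f"phantom_{name}.nii.gz", dtype=np.float32)
        dti.save_volume(labels, out / "phantom_atlas.nii.gz", dtype=np.uint16)
        dti.save_volume(skeleton, out / "phantom_skeleton.nii.gz", dtype=np.uint8)
        synthetic.write_bvals_bvecs(bvals, bvecs, out / "phantom.bval", out / "phantom.bvec")

    def _zscore():
        if "controls" not in state:
            state["controls"] = tables.read_table_csv(out / "controls.csv")
            state["patients"] = tables.read_table_csv(out / "patients.csv")
        scorer = zscores.NormativeZScorer().fit(state["controls"])
        zt = scorer.transform(state["patients"])
        _write_csv(zt, out / "zscores.csv", seed, chash)
        for patient in zt["subject_id"].drop_duplicates():
            for metric in ("FA", "MD"):
                ranked = zscores.rank_table(zt, patient, metric)
                _write_csv(
                    ranked, out / f"ranked_{patient}_{metric}.csv", seed, chash
                )
        state["zscores"] = zt

    def _fit():
        if "zscores" not in state:
            state["zscores"] = tables.read_table_csv(out / "zscores.csv")
        model = TractMixture(
            n_chains=config.mcmc.n_chains,
            n_iterations=config.mcmc.n_iterations,
            burn_in=config.mcmc.burn_in,
            thinning=config.mcmc.thinning,
            threshold=config.threshold,
            ordering_constraint=config.mcmc.ordering_constraint,
            random_state=seed,
            p_prior_a=config.spec.p_prior[0],
            p_prior_b=config.spec.p_prior[1],
            mean_prior_var=config.spec.mean_prior_var,
            re_prior_shape=config.spec.re_prior_shape,
            re_prior_rate=config.spec.re_prior_rate,
            wishart_df=config.spec.wishart_df,
            wishart_scale=config.spec.wishart_scale,
        ).fit(state["zscores"])
        _write_csv(model.posterior_, out / "posterior_summary.csv", seed, chash)
        np.savez_compressed(
            out / "draws.npz",
            p=model.draws_.p,
            mu=model.draws_.mu,
            sigma_re=model.draws_.sigma_re,
            Sigma=model.draws_.Sigma,
            z=model.draws_.z,
            a=model.draws_.a,
        )
        diag = model.diagnostics_.to_dict(orient="records")
        with open(out / "diagnostics.json", "w") as fh:
            json.dump({"seed": seed, "config": chash, "parameters": diag}, fh, indent=2)
        state["model"] = model

    def _report():
        if "model" not in state:
            raise RuntimeError("fit stage must run (or its outputs exist) before report")
        model = state["model"]
        report = summarize_run(
            model.posterior_,
            n_tracts_total=sim_cfg.n_tracts,
            seed=seed,
            cfg_hash=chash,
            convergence_warnings=model.draws_.warnings,
        )
        report.to_json(out / "report.json")
        # paint onto a synthetic slab atlas so the maps are always produced
        labels = np.zeros((sim_cfg.n_tracts, 4, 4), dtype=np.uint16)
        for b in range(sim_cfg.n_tracts):
            labels[b, 1:3, 1:3] = b + 1
        atlas = dti.AtlasParcellation(
            labels, {b + 1: name for b, name in enumerate(sim_cfg.tract_names)}
        )
        dti.save_volume(
            paint_probability_map(model.posterior_, atlas),
            out / "probability_map.nii.gz",
            dtype=np.float32,
        )
        dti.save_volume(
            paint_affiliation_map(model.posterior_, atlas),
            out / "affiliation_map.nii.gz",
            dtype=np.uint8,
        )
        state["report"] = report

    _run("simulate", _simulate)
    _run("metrics", _metrics)
    _run("zscore", _zscore)
    _run("fit", _fit)
    _run("report", _report)
    return state.get("report")
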