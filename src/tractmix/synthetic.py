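"""Synthetic cohorts with known ground truth.

The generator mirrors the structure of the locked-in-syndrome study the
pipeline is built for: 48 atlas tracts observed in 7 patients and 19
controls, with patient (FA, MD) Z-scores drawn from a two-component
bivariate Gaussian mixture with per-tract random effects,

    x_bj = mu_{z_b} + a_b + eps_bj,   eps_bj ~ N2(0, Sigma),
    a_b ~ N2(0, diag(sigma1^2, sigma2^2)),

where ``z_b`` marks tract ``b`` as least-injured (1) or most-injured (2).
A small fraction of cells is masked completely at random, emulating ROI
means that could not be computed.  Everything is seed-deterministic.

Default group means are calibrated to the bundled patient fixture: the four
tracts classified most-injured in the reference cohort average about
(-9.5, -8.5) on the (FA, MD) Z-scale and the remaining tracts about
(-5.5, -6.5).

A voxel-level phantom generator produces imaging-shaped inputs (tensor
volume, diffusion-weighted signals with a b-table, integer atlas labels and
a skeleton mask) so the voxel-to-table stage can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tables
from .tracts import DEFAULT_GROUP2_TRACTS, JHU_TRACTS, METRICS

DEFAULT_MU1 = (-5.5, -6.5)
DEFAULT_MU2 = (-9.5, -8.5)


def _as_spd(m, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (2, 2) or not np.allclose(m, m.T):
        raise ValueError(f"{name} must be a symmetric 2x2 matrix")
    try:
        np.linalg.cholesky(m)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"{name} must be positive definite") from err
    return m


@dataclass
class CohortSimConfig:
    """Study-shaped simulation settings (defaults are the reference design)."""

    n_tracts: int = 48
    n_patients: int = 7
    n_controls: int = 19
    tract_names: tuple[str, ...] | None = None
    group2_tracts: tuple[str, ...] = DEFAULT_GROUP2_TRACTS
    mu1: tuple[float, float] = DEFAULT_MU1
    mu2: tuple[float, float] = DEFAULT_MU2
    sigma1: float = 1.0
    sigma2: float = 1.0
    Sigma: np.ndarray = field(default_factory=lambda: np.eye(2))
    missing_rate: float = 0.02
    control_noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_tracts < 2:
            raise ValueError("n_tracts must be at least 2")
        if self.n_patients < 1 or self.n_controls < 2:
            raise ValueError("need >=1 patient and >=2 controls")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("random-effect SDs must be non-negative")
        if self.control_noise_scale < 0:
            raise ValueError("control_noise_scale must be non-negative")
        self.Sigma = _as_spd(self.Sigma, "Sigma")
        if self.tract_names is None:
            if self.n_tracts == len(JHU_TRACTS):
                self.tract_names = JHU_TRACTS
            else:
                self.tract_names = tuple(f"Tract {i + 1:02d}" for i in range(self.n_tracts))
        self.tract_names = tuple(self.tract_names)
        if len(self.tract_names) != self.n_tracts:
            raise ValueError("tract_names length must equal n_tracts")
        unknown = set(self.group2_tracts) - set(self.tract_names)
        if unknown:
            raise ValueError(f"group2_tracts not in tract_names: {sorted(unknown)}")

    @property
    def group_indicator(self) -> np.ndarray:
        """Per-tract component label in {1, 2}."""
        g2 = set(self.group2_tracts)
        return np.array([2 if t in g2 else 1 for t in self.tract_names])


@dataclass
class SimTruth:
    """Latent ground truth realised by one simulated cohort."""

    z: np.ndarray          # (B,) component labels in {1, 2}
    a: np.ndarray          # (B, 2) per-tract random effects
    p: float               # realised weight of component 1
    tract_names: tuple[str, ...]


def simulate_zscore_cohort(config: CohortSimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw a patient (FA, MD) Z-score table from the mixture model."""
    rng = np.random.default_rng(config.seed)
    B, J = config.n_tracts, config.n_patients
    z = config.group_indicator
    mu = np.where(z[:, None] == 1, np.asarray(config.mu1), np.asarray(config.mu2))
    a = rng.normal(0.0, 1.0, size=(B, 2)) * np.array([config.sigma1, config.sigma2])
    chol = np.linalg.cholesky(config.Sigma)
    eps = rng.standard_normal(size=(B, J, 2)) @ chol.T
    x = mu[:, None, :] + a[:, None, :] + eps
    if config.missing_rate > 0:
        mask = rng.random(size=(B, J)) < config.missing_rate
        x[mask] = np.nan

    subjects = [f"patient{j + 1}" for j in range(J)]
    frames = [
        tables.make_table(x[:, :, d].T, subjects, config.tract_names, m)
        for d, m in enumerate(("FA", "MD"))
    ]
    truth = SimTruth(z=z, a=a, p=float(np.mean(z == 1)), tract_names=config.tract_names)
    return tables.validate_table(pd.concat(frames, ignore_index=True)), truth


# ---------------------------------------------------------------------------
# raw-metric cohorts (control + patient) for testing the Z-scoring stage


def normative_reference(n_tracts: int) -> pd.DataFrame:
    """Fixed per-tract normative metric means and SDs.

    Deterministic, physiologically plausible ramps across tracts: FA in
    [0.35, 0.60]; AD and RD in mm^2/s with MD = (AD + 2 RD) / 3.
    """
    i = np.arange(n_tracts)
    t = i / max(n_tracts - 1, 1)
    fa = 0.35 + 0.25 * t
    ad = (1.15 + 0.25 * t) * 1e-3
    rd = (0.60 - 0.15 * t) * 1e-3
    md = (ad + 2 * rd) / 3.0
    sds = {"FA": 0.025, "MD": 3.0e-5, "AD": 5.0e-5, "RD": 4.0e-5}
    rows = []
    for metric, mean in zip(METRICS, (fa, md, ad, rd)):
        for k in range(n_tracts):
            rows.append({"tract_index": k, "metric": metric, "mean": mean[k], "sd": sds[metric]})
    return pd.DataFrame(rows)


def simulate_control_metrics(config: CohortSimConfig) -> pd.DataFrame:
    """Control ROI-metric table: normative mean + scaled Gaussian noise."""
    rng = np.random.default_rng(config.seed + 1)
    ref = normative_reference(config.n_tracts)
    subjects = [f"control{j + 1}" for j in range(config.n_controls)]
    frames = []
    for metric in METRICS:
        sub = ref[ref["metric"] == metric].sort_values("tract_index")
        mean = sub["mean"].to_numpy()
        sd = sub["sd"].to_numpy() * config.control_noise_scale
        vals = mean[None, :] + rng.standard_normal((config.n_controls, config.n_tracts)) * sd
        frames.append(tables.make_table(vals, subjects, config.tract_names, metric))
    return tables.validate_table(pd.concat(frames, ignore_index=True))


def simulate_patient_metrics(config: CohortSimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Patient ROI-metric table consistent with :func:`simulate_zscore_cohort`.

    Patient raw metrics are reconstructed as normative mean + Z x normative
    SD, so that standardising them against the *population* reference
    recovers exactly the simulated Z-scores (FA and MD).
    """
    zs, truth = simulate_zscore_cohort(config)
    ref = normative_reference(config.n_tracts)
    frames = []
    for metric in ("FA", "MD"):
        wide = tables.to_wide(zs, metric)  # tract x subject
        sub = ref[ref["metric"] == metric].sort_values("tract_index")
        vals = sub["mean"].to_numpy()[:, None] + wide.to_numpy() * sub["sd"].to_numpy()[:, None]
        frames.append(
            tables.make_table(vals.T, list(wide.columns), config.tract_names, metric)
        )
    return tables.validate_table(pd.concat(frames, ignore_index=True)), truth


# ---------------------------------------------------------------------------
# voxel-level phantom


@dataclass
class VoxelPhantomConfig:
    """Imaging-shaped phantom: labeled regions filled with template tensors."""

    shape: tuple[int, int, int] = (16, 16, 16)
    n_tracts: int = 4
    eigenvalues: np.ndarray | None = None  # (n_tracts, 3) mm^2/s, descending
    skeleton_fraction: float = 0.5
    noise_sd: float = 0.0
    b_value: float = 1000.0
    n_directions: int = 30
    n_b0: int = 1
    s0: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if self.n_directions < 7:
            raise ValueError("at least 7 gradient directions required")
        if self.n_b0 < 1:
            raise ValueError("at least one b=0 volume required")
        if not 0 < self.skeleton_fraction <= 1:
            raise ValueError("skeleton_fraction must lie in (0, 1]")
        if self.eigenvalues is None:
            base = np.array([1.6e-3, 0.5e-3, 0.4e-3])
            scale = 1.0 + 0.1 * np.arange(self.n_tracts)[:, None] / max(self.n_tracts, 1)
            self.eigenvalues = base[None, :] * scale
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.eigenvalues.shape != (self.n_tracts, 3) or (self.eigenvalues <= 0).any():
            raise ValueError("eigenvalues must be positive with shape (n_tracts, 3)")


def fibonacci_directions(n: int) -> np.ndarray:
    """n roughly uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _region_tensor(evals: np.ndarray, axis: int) -> np.ndarray:
    """Diagonal tensor with the principal eigenvalue along a chosen axis."""
    d = np.empty(3)
    others = [k for k in range(3) if k != axis]
    d[axis] = evals[0]
    d[others[0]], d[others[1]] = evals[1], evals[2]
    return np.diag(d)


def simulate_voxel_phantom(config: VoxelPhantomConfig):
    """Build (tensor volume, atlas labels, skeleton mask, DW signals, bvals, bvecs).

    The grid's central cuboid is split into ``n_tracts`` slabs along x; the
    border stays background (label 0).  Signals follow the monoexponential
    tensor model S = S0 exp(-b g^T D g) plus optional Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    labels = np.zeros(shape, dtype=np.uint16)
    margin = [max(1, s // 8) for s in shape]
    core = tuple(slice(m, s - m) for m, s in zip(margin, shape))
    core_x = np.arange(core[0].start, core[0].stop)
    slabs = np.array_split(core_x, config.n_tracts)
    for t, xs in enumerate(slabs, start=1):
        labels[xs[0] : xs[-1] + 1, core[1], core[2]] = t

    tensor = np.zeros(shape + (3, 3), dtype=float)
    for t in range(1, config.n_tracts + 1):
        D = _region_tensor(config.eigenvalues[t - 1], axis=(t - 1) % 3)
        tensor[labels == t] = D

    labeled = np.argwhere(labels > 0)
    n_skel = max(1, int(round(config.skeleton_fraction * len(labeled))))
    pick = rng.choice(len(labeled), size=n_skel, replace=False)
    skeleton = np.zeros(shape, dtype=bool)
    skeleton[tuple(labeled[pick].T)] = True

    bvecs = np.vstack(
        [np.zeros((config.n_b0, 3)), fibonacci_directions(config.n_directions)]
    )
    bvals = np.concatenate(
        [np.zeros(config.n_b0), np.full(config.n_directions, config.b_value)]
    )
    # signal attenuation: exponent = -b * g^T D g per voxel and gradient
    quad = np.einsum("gi,...ij,gj->...g", bvecs, tensor, bvecs)
    signals = config.s0 * np.exp(-bvals * quad)
    signals[labels == 0] = config.s0  # free water-free background: flat S0
    if config.noise_sd > 0:
        signals = signals + rng.normal(0.0, config.noise_sd, size=signals.shape)
    return tensor, labels, skeleton, signals, bvals, bvecs


def write_bvals_bvecs(bvals: np.ndarray, bvecs: np.ndarray, bval_path, bvec_path) -> None:
    """FSL-dialect b-table: single-row bvals, 3-row bvecs (directions as columns)."""
    np.savetxt(bval_path, bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, bvecs.T, fmt="%.8f")


def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return bvals, bvecs
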