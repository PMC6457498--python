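"""Diffusion-tensor estimation and skeleton-restricted atlas-ROI statistics.

The tensor is estimated per voxel by ordinary log-linear least squares on
ln S = ln S0 - b g^T D g (weighted LS available behind a flag); the four
scalar coefficients follow from the eigenvalue spectrum:

    MD = (l1 + l2 + l3) / 3          AD = l1
    RD = (l2 + l3) / 2               FA = sqrt(3/2) * ||l - MD|| / ||l||

ROI means are taken over atlas-labeled voxels restricted to a white-matter
skeleton mask, the standard guard against grey-matter partial-volume
contamination; a tract contributing fewer than ``min_voxels`` skeleton
voxels is recorded as missing rather than averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .tracts import LABEL_TO_NAME

#: order of the unique tensor elements returned by :func:`fit_tensor`
TENSOR_ELEMENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


@dataclass
class AtlasParcellation:
    """Integer label volume (0 = background) with a label -> name map."""

    labels: np.ndarray
    label_to_name: dict[int, str] = field(default_factory=lambda: dict(LABEL_TO_NAME))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        present = set(np.unique(self.labels)) - {0}
        unnamed = present - set(self.label_to_name)
        if unnamed:
            raise ValueError(f"labels without names: {sorted(unnamed)}")
        names = list(self.label_to_name.values())
        if len(names) != len(set(names)):
            raise ValueError("tract names must be unique")


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]."""
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    return np.column_stack(
        [
            np.ones_like(bvals),
            -bvals * gx**2,
            -bvals * gy**2,
            -bvals * gz**2,
            -2 * bvals * gx * gy,
            -2 * bvals * gx * gz,
            -2 * bvals * gy * gz,
        ]
    )


def fit_tensor(
    signals: np.ndarray,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    weighted: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Log-linear LS tensor fit.

    Parameters
    ----------
    signals : array, shape (..., n_volumes)
        Diffusion-weighted intensities; leading axes are voxels.
    weighted : bool
        If True, weight each log-signal by the signal itself (first-order
        noise propagation); default is the ordinary unweighted fit.

    Returns
    -------
    tensor : array, shape (..., 6) — elements in :data:`TENSOR_ELEMENTS` order
    s0 : array, shape (...)
    valid : bool array, shape (...) — False where any signal is non-positive
    """
    signals = np.asarray(signals, dtype=float)
    bvals = np.asarray(bvals, dtype=float).ravel()
    bvecs = np.asarray(bvecs, dtype=float)
    if signals.shape[-1] != bvals.size or bvecs.shape != (bvals.size, 3):
        raise ValueError("signals, bvals and bvecs disagree on volume count")
    if not (bvals == 0).any():
        raise ValueError("at least one b=0 volume is required")
    X = design_matrix(bvals, bvecs)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError(
            "rank-deficient design: need >=6 non-collinear gradient directions"
        )

    lead = signals.shape[:-1]
    flat = signals.reshape(-1, bvals.size)
    valid = (flat > 0).all(axis=1)
    coef = np.zeros((flat.shape[0], 7))
    if valid.any():
        y = np.log(flat[valid])
        if weighted:
            for i, (yi, wi) in enumerate(zip(y, flat[valid])):
                w = wi / wi.max()
                coef[np.flatnonzero(valid)[i]] = np.linalg.lstsq(
                    X * w[:, None], yi * w, rcond=None
                )[0]
        else:
            coef[valid] = np.linalg.lstsq(X, y.T, rcond=None)[0].T
    tensor = coef[:, 1:]
    s0 = np.exp(coef[:, 0])
    s0[~valid] = 0.0
    return tensor.reshape(lead + (6,)), s0.reshape(lead), valid.reshape(lead)


def tensor_to_matrix(tensor: np.ndarray) -> np.ndarray:
    """(..., 6) unique elements -> (..., 3, 3) symmetric matrices."""
    t = np.asarray(tensor, dtype=float)
    m = np.zeros(t.shape[:-1] + (3, 3))
    m[..., 0, 0] = t[..., 0]
    m[..., 1, 1] = t[..., 1]
    m[..., 2, 2] = t[..., 2]
    m[..., 0, 1] = m[..., 1, 0] = t[..., 3]
    m[..., 0, 2] = m[..., 2, 0] = t[..., 4]
    m[..., 1, 2] = m[..., 2, 1] = t[..., 5]
    return m


def eigenspectrum(tensor: np.ndarray, clamp: bool = True) -> np.ndarray:
    """Eigenvalues sorted descending; negatives clamped to 0 by default."""
    m = tensor_to_matrix(tensor) if np.asarray(tensor).shape[-1] == 6 else np.asarray(tensor)
    lam = np.linalg.eigvalsh(m)[..., ::-1]
    if clamp:
        lam = np.clip(lam, 0.0, None)
    return lam


def scalar_metrics(eigenvalues: np.ndarray) -> dict[str, np.ndarray]:
    """FA, MD, AD, RD from a (..., 3) descending eigenvalue spectrum.

    The zero spectrum gets FA = 0 (isotropy convention for empty voxels).
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape[-1] != 3:
        raise ValueError("expected (..., 3) eigenvalues")
    if (np.diff(lam, axis=-1) > 1e-12 * np.abs(lam[..., :1]).clip(min=1e-300)).any():
        raise ValueError("eigenvalues must be sorted descending")
    md = lam.mean(axis=-1)
    ad = lam[..., 0]
    rd = lam[..., 1:].mean(axis=-1)
    num = np.linalg.norm(lam - md[..., None], axis=-1)
    den = np.linalg.norm(lam, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return {"FA": fa, "MD": md, "AD": ad, "RD": rd}


def roi_skeleton_means(
    metric_volume: np.ndarray,
    atlas: AtlasParcellation,
    skeleton: np.ndarray,
    min_voxels: int = 5,
) -> pd.Series:
    """Mean of a scalar volume per tract over skeleton-restricted voxels.

    Returns a Series indexed by tract name; tracts with fewer than
    ``min_voxels`` contributing voxels are NaN (missing), never 0.
    """
    metric_volume = np.asarray(metric_volume, dtype=float)
    skeleton = np.asarray(skeleton, dtype=bool)
    if metric_volume.shape != atlas.labels.shape or skeleton.shape != atlas.labels.shape:
        raise ValueError("metric volume, atlas and skeleton grids differ")
    out = {}
    for label, name in atlas.label_to_name.items():
        sel = (atlas.labels == label) & skeleton
        n = int(sel.sum())
        out[name] = float(metric_volume[sel].mean()) if n >= min_voxels else np.nan
    return pd.Series(out, name="value")


def volume_metrics_to_table(
    metric_volumes: dict[str, np.ndarray],
    atlas: AtlasParcellation,
    skeleton: np.ndarray,
    subject_id: str,
    min_voxels: int = 5,
) -> pd.DataFrame:
    """Stack per-metric ROI means into a tidy single-subject table."""
    rows = []
    for metric, vol in metric_volumes.items():
        means = roi_skeleton_means(vol, atlas, skeleton, min_voxels=min_voxels)
        for tract, value in means.items():
            rows.append(
                {"subject_id": subject_id, "tract": tract, "metric": metric, "value": value}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NIfTI helpers


def save_volume(data: np.ndarray, path, affine: np.ndarray | None = None, dtype=None) -> None:
    affine = np.eye(4) if affine is None else affine
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine
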