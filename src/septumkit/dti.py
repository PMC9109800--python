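"""Diffusion-tensor estimation and tensor metrics.

Tensors are 3x3 symmetric matrices in mm^2/s on a voxel grid. The
log-linear fit solves, per voxel, ``B d = ln(S0/S_i)`` for the six unique
tensor components, where the i-th row of the B-matrix encodes
``b_i * g_i^T D g_i`` with unit gradient direction ``g_i`` (no
imaging/diffusion cross-terms). With the minimal six noncollinear
directions the system is square; the implementation uses ordinary least
squares so richer schemes work unchanged.

Lower-triangular component order used on disk and in flattened arrays:
``(Dxx, Dxy, Dyy, Dxz, Dyz, Dzz)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "TensorVolume",
    "GradientTable",
    "fit_tensor_loglinear",
    "tensor_metrics",
    "average_tensors",
    "reorient_tensor_affine",
    "fa_from_eigenvalues",
    "save_tensor_nifti",
    "load_tensor_nifti",
    "save_gradient_table",
    "load_gradient_table",
]

# (row, col) index pairs for the lower-triangular storage order
LOWER_TRI_ORDER = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]


@dataclass
class GradientTable:
    """Diffusion gradient scheme: unit directions and b-values (s/mm^2)."""

    bvecs: np.ndarray  # (n, 3)
    bvals: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError("bvecs must be (n, 3) matching bvals")
        nz = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if nz.sum() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("nonzero-b directions must have unit norm")
        if nz.sum() < 6:
            raise ValueError("at least 6 nonzero-b directions required")
        # noncollinearity: the 6-column design matrix must have full rank
        if np.linalg.matrix_rank(design_matrix(self.bvecs[nz], self.bvals[nz])) < 6:
            raise ValueError("gradient directions are collinear/degenerate")
        if not np.any(self.bvals == 0):
            raise ValueError("at least one b=0 entry required")

    @property
    def n_dwi(self) -> int:
        return int(np.sum(self.bvals > 0))


def icosahedral_6(b_value: float = 1000.0) -> GradientTable:
    """Classic 6-direction icosahedral scheme (+/-1, +/-phi permutations) plus b0."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    dirs = np.array(
        [
            [1.0, phi, 0.0],
            [1.0, -phi, 0.0],
            [0.0, 1.0, phi],
            [0.0, 1.0, -phi],
            [phi, 0.0, 1.0],
            [-phi, 0.0, 1.0],
        ]
    )
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvecs = np.vstack([np.zeros(3), dirs])
    bvals = np.concatenate([[0.0], np.full(6, b_value)])
    return GradientTable(bvecs=bvecs, bvals=bvals)


@dataclass
class TensorVolume:
    """Voxel grid of 3x3 symmetric diffusion tensors with a tissue mask.

    ``invalid`` flags voxels whose fit failed (non-positive signal) or whose
    tensor is not positive definite; they are reported, never silently fixed.
    ``ground_truth`` optionally carries the phantom sidecar (transmural
    coordinate, true helix angle, local frame axes).
    """

    tensors: np.ndarray  # (nx, ny, nz, 3, 3)
    mask: np.ndarray  # (nx, ny, nz) bool
    voxel_size: np.ndarray  # (3,) mm
    invalid: np.ndarray | None = None
    ground_truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float)
        if self.tensors.shape[:3] != self.mask.shape or self.tensors.shape[3:] != (3, 3):
            raise ValueError("tensors must be (nx, ny, nz, 3, 3) matching mask")
        if self.invalid is None:
            self.invalid = np.zeros(self.mask.shape, dtype=bool)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    def flag_non_spd(self, tol: float = 0.0) -> np.ndarray:
        """Flag in-mask voxels whose tensor is not positive definite."""
        evals = np.linalg.eigvalsh(self.tensors)
        bad = (evals[..., 0] <= tol) & self.mask
        self.invalid |= bad
        return bad


def design_matrix(bvecs: np.ndarray, bvals: np.ndarray) -> np.ndarray:
    """B-matrix rows for the lower-triangular component order."""
    g = np.asarray(bvecs, dtype=float)
    b = np.asarray(bvals, dtype=float)
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    cols = [gx * gx, 2 * gx * gy, gy * gy, 2 * gx * gz, 2 * gy * gz, gz * gz]
    return b[:, None] * np.stack(cols, axis=1)


def components_to_tensor(d6: np.ndarray) -> np.ndarray:
    """(..., 6) lower-triangular components -> (..., 3, 3) symmetric tensors."""
    out = np.zeros(d6.shape[:-1] + (3, 3), dtype=float)
    for k, (i, j) in enumerate(LOWER_TRI_ORDER):
        out[..., i, j] = d6[..., k]
        out[..., j, i] = d6[..., k]
    return out


def tensor_to_components(D: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric tensors -> (..., 6) lower-triangular components."""
    return np.stack([D[..., i, j] for (i, j) in LOWER_TRI_ORDER], axis=-1)


def fit_tensor_loglinear(
    dwi: np.ndarray,
    gtab: GradientTable,
    mask: np.ndarray | None = None,
    voxel_size=(0.6, 0.6, 0.6),
) -> TensorVolume:
    """Ordinary least-squares log-linear tensor fit.

    Parameters
    ----------
    dwi : (nx, ny, nz, n) diffusion-weighted series, one volume per gradient
        table entry (b=0 entries included).
    gtab : gradient table matching the last axis of ``dwi``.
    mask : optional tissue mask; defaults to all voxels.

    Voxels with any non-positive signal are flagged invalid and excluded
    from the output mask (their tensor is left at zero).
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.shape[-1] != gtab.bvals.size:
        raise ValueError("dwi volume count does not match gradient table")
    if mask is None:
        mask = np.ones(dwi.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    b0_mask = gtab.bvals == 0
    dw_mask = ~b0_mask
    invalid = mask & np.any(dwi[..., :] <= 0, axis=-1)
    fit_mask = mask & ~invalid

    s0 = dwi[..., b0_mask].mean(axis=-1)
    B = design_matrix(gtab.bvecs[dw_mask], gtab.bvals[dw_mask])
    B_pinv = np.linalg.pinv(B)

    tensors = np.zeros(dwi.shape[:3] + (3, 3), dtype=float)
    if fit_mask.any():
        sig = dwi[fit_mask][:, dw_mask]
        y = np.log(s0[fit_mask][:, None] / sig)
        d6 = y @ B_pinv.T
        tensors[fit_mask] = components_to_tensor(d6)

    return TensorVolume(
        tensors=tensors,
        mask=fit_mask,
        voxel_size=np.asarray(voxel_size, dtype=float),
        invalid=invalid,
    )


def fa_from_eigenvalues(evals: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from (..., 3) eigenvalues; 0 for zero tensors."""
    evals = np.asarray(evals, dtype=float)
    mean = evals.mean(axis=-1, keepdims=True)
    num = np.linalg.norm(evals - mean, axis=-1)
    den = np.linalg.norm(evals, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


def _fix_eigenvector_signs(vecs: np.ndarray) -> np.ndarray:
    """Flip each eigenvector so its largest-magnitude component is positive.

    Eigenvectors are sign-ambiguous; this is a display convention only and
    no metric downstream may depend on it.
    """
    comp = np.argmax(np.abs(vecs), axis=-2)
    picked = np.take_along_axis(vecs, comp[..., None, :], axis=-2)[..., 0, :]
    sign = np.where(picked < 0, -1.0, 1.0)
    return vecs * sign[..., None, :]


def tensor_metrics(D: np.ndarray) -> dict:
    """Eigen-metrics of symmetric tensors (any leading shape).

    Returns a dict with ``evals`` (descending, (..., 3)), unit eigenvectors
    ``v1``/``v2``/``v3``, ``adc`` (mean diffusivity), ``fa`` and ``cfa``
    (FA-scaled |v1| components).
    """
    D = np.asarray(D, dtype=float)
    if not np.allclose(D, np.swapaxes(D, -1, -2), atol=1e-10):
        raise ValueError("tensor must be symmetric")
    evals, evecs = np.linalg.eigh(D)  # ascending
    evals = evals[..., ::-1]
    evecs = evecs[..., ::-1]
    evecs = _fix_eigenvector_signs(evecs)
    fa = fa_from_eigenvalues(evals)
    adc = evals.mean(axis=-1)
    cfa = fa[..., None] * np.abs(evecs[..., :, 0])
    return {
        "evals": evals,
        "v1": evecs[..., :, 0],
        "v2": evecs[..., :, 1],
        "v3": evecs[..., :, 2],
        "adc": adc,
        "fa": fa,
        "cfa": cfa,
    }


def _tensor_log(D: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(D)
    logl = np.log(evals)
    return np.einsum("...ij,...j,...kj->...ik", evecs, logl, evecs)


def _tensor_exp(L: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(L)
    return np.einsum("...ij,...j,...kj->...ik", evecs, np.exp(evals), evecs)


def average_tensors(volumes: list[TensorVolume], weights=None) -> TensorVolume:
    """Voxelwise log-Euclidean mean of co-registered tensor volumes.

    Log-Euclidean averaging (exp of the weighted mean of matrix logs) avoids
    the eigenvalue swelling of the Euclidean mean. Voxels where any input is
    not SPD fall back to the Euclidean mean and are flagged invalid.
    """
    if not volumes:
        raise ValueError("need at least one volume")
    shape = volumes[0].shape
    for v in volumes:
        if v.shape != shape or not np.allclose(v.voxel_size, volumes[0].voxel_size):
            raise ValueError("tensor volumes are not on the same grid")
    if weights is None:
        weights = np.ones(len(volumes))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()

    mask = np.logical_and.reduce([v.mask for v in volumes])
    stack = np.stack([v.tensors for v in volumes])  # (k, nx, ny, nz, 3, 3)
    evals = np.linalg.eigvalsh(stack)
    spd = np.all(evals[..., 0] > 0, axis=0) & mask

    out = np.einsum("k,k...->...", w, stack)  # Euclidean fallback everywhere
    if spd.any():
        logs = np.stack([_tensor_log(v.tensors[spd]) for v in volumes])
        out[spd] = _tensor_exp(np.einsum("k,k...->...", w, logs))

    invalid = mask & ~spd
    return TensorVolume(
        tensors=out,
        mask=mask,
        voxel_size=volumes[0].voxel_size.copy(),
        invalid=invalid,
    )


def reorient_tensor_affine(D: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Finite-strain tensor reorientation under an affine transform.

    The rotation part ``R = A (A^T A)^(-1/2)`` of the affine block is applied
    as ``D' = R D R^T``, preserving eigenvalues (shears only reorient, they do
    not deform the diffusion profile).
    """
    A = np.asarray(A, dtype=float)
    if A.shape != (3, 3):
        raise ValueError("affine block must be 3x3")
    if abs(np.linalg.det(A)) < 1e-12:
        raise ValueError("affine block is singular")
    U, _, Vt = np.linalg.svd(A)
    R = U @ Vt
    if np.linalg.det(R) < 0:  # keep a proper rotation
        U[:, -1] *= -1
        R = U @ Vt
    D = np.asarray(D, dtype=float)
    return np.einsum("ij,...jk,lk->...il", R, D, R)


# ---------------------------------------------------------------------------
# I/O: NIfTI tensor volumes, FSL-dialect bval/bvec
# ---------------------------------------------------------------------------

def _affine_from_voxel_size(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_tensor_nifti(vol: TensorVolume, path) -> None:
    """Write a tensor volume as a 6-component lower-triangular NIfTI.

    A JSON sidecar next to the image records the component order and units.
    """
    path = Path(path)
    comps = tensor_to_components(vol.tensors)
    img = nib.Nifti1Image(comps.astype(np.float32), _affine_from_voxel_size(vol.voxel_size))
    nib.save(img, path)
    nib.save(
        nib.Nifti1Image(vol.mask.astype(np.uint8), _affine_from_voxel_size(vol.voxel_size)),
        path.parent / (path.name.split(".")[0] + "_mask.nii.gz"),
    )
    sidecar = {
        "component_order": ["Dxx", "Dxy", "Dyy", "Dxz", "Dyz", "Dzz"],
        "units": "mm^2/s",
        "voxel_size_mm": vol.voxel_size.tolist(),
    }
    (path.parent / (path.name.split(".")[0] + ".json")).write_text(
        json.dumps(sidecar, indent=2)
    )


def load_tensor_nifti(path) -> TensorVolume:
    path = Path(path)
    img = nib.load(path)
    comps = np.asarray(img.dataobj, dtype=float)
    voxel_size = np.array(img.header.get_zooms()[:3])
    mask_path = path.parent / (path.name.split(".")[0] + "_mask.nii.gz")
    if mask_path.exists():
        mask = np.asarray(nib.load(mask_path).dataobj).astype(bool)
    else:
        mask = np.any(comps != 0, axis=-1)
    return TensorVolume(
        tensors=components_to_tensor(comps), mask=mask, voxel_size=voxel_size
    )


def save_gradient_table(gtab: GradientTable, bval_path, bvec_path) -> None:
    """FSL dialect: bvals one row, bvecs three whitespace-separated rows."""
    Path(bval_path).write_text(" ".join(f"{b:g}" for b in gtab.bvals) + "\n")
    rows = [" ".join(f"{x:.8f}" for x in gtab.bvecs[:, i]) for i in range(3)]
    Path(bvec_path).write_text("\n".join(rows) + "\n")


def load_gradient_table(bval_path, bvec_path) -> GradientTable:
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return GradientTable(bvecs=bvecs, bvals=bvals)
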