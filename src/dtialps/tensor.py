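"""Diffusion-tensor forward model, per-voxel estimation, and derived maps.

The image-coordinate convention used throughout the package is fixed:
``x`` = right-left, ``y`` = anterior-posterior, ``z`` = craniocaudal.
Gradient tables are assumed to be expressed in image coordinates already;
:func:`load_scheme` exposes a ``flip`` flag that negates individual
components for tables stored with a different sign convention.

The estimator is a weighted (signal-squared-weighted) log-linear
least-squares fit of the mono-exponential tensor model

    S_i = S0 * exp(-b_i * g_i^T D g_i)

which is closed-form, deterministic, and inverts the noiseless forward
model exactly (to floating-point precision) — sufficient at b = 1000 s/mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "AcquisitionScheme",
    "TensorField",
    "ScalarMaps",
    "synthesize_signal",
    "synthesize_signals",
    "fit_tensor",
    "scalar_maps",
    "fibonacci_directions",
    "save_dwi",
    "load_dwi",
    "save_scheme",
    "load_scheme",
    "save_labels",
    "load_labels",
]

#: Floor (mm^2/s) applied to negative tensor eigenvalues after fitting.
DIFFUSIVITY_FLOOR = 1e-6

#: Floor applied to non-positive signals before taking logarithms.
SIGNAL_FLOOR = 1e-10

#: Minimum number of non-collinear diffusion-encoding directions.
MIN_DIRECTIONS = 6


def fibonacci_directions(n: int) -> np.ndarray:
    """Return ``n`` roughly uniformly distributed unit vectors (Fibonacci sphere)."""
    i = np.arange(n)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    vecs = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    return vecs / np.linalg.norm(vecs, axis=1, keepdims=True)


def _quadratic_design(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows [b*gx^2, b*gy^2, b*gz^2, 2b*gx*gy, 2b*gx*gz, 2b*gy*gz]."""
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    return np.column_stack(
        [
            bvals * gx * gx,
            bvals * gy * gy,
            bvals * gz * gz,
            2.0 * bvals * gx * gy,
            2.0 * bvals * gx * gz,
            2.0 * bvals * gy * gz,
        ]
    )


@dataclass(frozen=True)
class AcquisitionScheme:
    """Diffusion-encoding scheme: b-values (s/mm^2) and unit gradient directions.

    Directions are stored one per volume, shape ``(n_volumes, 3)``, in image
    coordinates. At least one b = 0 volume and six non-collinear non-zero-b
    directions are required.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError("bvecs must have shape (n_volumes, 3)")
        if bvecs.shape[0] != bvals.shape[0]:
            raise ValueError("bvals and bvecs describe different numbers of volumes")
        if np.any(bvals < 0):
            raise ValueError("negative b-values are not allowed")
        b0 = bvals == 0
        if not np.any(b0):
            raise ValueError("acquisition scheme must contain at least one b=0 volume")
        dw = ~b0
        if np.count_nonzero(dw) < MIN_DIRECTIONS:
            raise ValueError(
                f"at least {MIN_DIRECTIONS} non-zero-b directions are required"
            )
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("non-zero-b gradient directions must have unit norm")
        design = _quadratic_design(bvals[dw], bvecs[dw])
        if np.linalg.matrix_rank(design) < MIN_DIRECTIONS:
            raise ValueError(
                "gradient directions are collinear/degenerate: the six unique "
                "tensor elements are not identifiable"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_volumes(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @classmethod
    def default(cls, b: float = 1000.0, n_directions: int = 20, n_b0: int = 1
                ) -> "AcquisitionScheme":
        """Single-shell scheme mirroring the study protocol: b = 0, 1000 s/mm^2,
        20 encoding directions."""
        dirs = fibonacci_directions(n_directions)
        bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b))])
        bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
        return cls(bvals=bvals, bvecs=bvecs)


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors plus baseline signal and geometry.

    Attributes
    ----------
    tensors : ndarray, shape (..., 3, 3)
        Symmetric diffusion tensors in mm^2/s.
    s0 : ndarray, shape (...)
        Baseline (b = 0) signal per voxel.
    voxel_size : tuple of float
        Voxel edge lengths in mm (x, y, z).
    clipped : ndarray of bool, shape (...)
        True where negative eigenvalues were clipped to ``DIFFUSIVITY_FLOOR``.
    invalid : ndarray of bool, shape (...)
        True where the voxel could not be fitted (all-zero signal); the
        tensor is zero there.
    """

    tensors: np.ndarray
    s0: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    clipped: np.ndarray = field(default=None)  # type: ignore[assignment]
    invalid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        if self.tensors.shape[-2:] != (3, 3):
            raise ValueError("tensors must have trailing shape (3, 3)")
        if self.tensors.shape[:-2] != self.s0.shape:
            raise ValueError("tensor grid and s0 grid differ in shape")
        if not np.allclose(self.tensors, np.swapaxes(self.tensors, -1, -2),
                           atol=1e-12):
            raise ValueError("stored tensors must be symmetric")
        grid = self.s0.shape
        if self.clipped is None:
            self.clipped = np.zeros(grid, dtype=bool)
        if self.invalid is None:
            self.invalid = np.zeros(grid, dtype=bool)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.s0.shape

    def diagonal(self) -> np.ndarray:
        """Diagonal elements (Dxx, Dyy, Dzz), shape ``(..., 3)``."""
        return np.diagonal(self.tensors, axis1=-2, axis2=-1)


def _check_tensor(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.shape != (3, 3):
        raise ValueError("tensor must be a 3x3 matrix")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("tensor must be symmetric")
    scale = max(np.abs(D).max(), 1e-30)
    if np.linalg.eigvalsh(D).min() < -1e-9 * scale:
        raise ValueError("tensor must be positive semi-definite")
    return D


def synthesize_signal(D: np.ndarray, s0: float, scheme: AcquisitionScheme
                      ) -> np.ndarray:
    """Noise-free signal ``s0 * exp(-b g^T D g)`` for a single tensor."""
    D = _check_tensor(D)
    q = np.einsum("ni,ij,nj->n", scheme.bvecs, D, scheme.bvecs)
    return float(s0) * np.exp(-scheme.bvals * q)


def synthesize_signals(tensors: np.ndarray, s0: np.ndarray,
                       scheme: AcquisitionScheme) -> np.ndarray:
    """Vectorised forward model for a grid of tensors; returns ``(..., n_volumes)``."""
    tensors = np.asarray(tensors, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    q = np.einsum("ni,...ij,nj->...n", scheme.bvecs, tensors, scheme.bvecs)
    return s0[..., None] * np.exp(-scheme.bvals * q)


def _collapse_b0(signals: np.ndarray, scheme: AcquisitionScheme
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average multiple b=0 volumes into one before fitting."""
    b0 = scheme.b0_mask
    if np.count_nonzero(b0) == 1:
        return signals, scheme.bvals, scheme.bvecs
    mean_b0 = signals[..., b0].mean(axis=-1, keepdims=True)
    rest = signals[..., ~b0]
    sig = np.concatenate([mean_b0, rest], axis=-1)
    bvals = np.concatenate([[0.0], scheme.bvals[~b0]])
    bvecs = np.vstack([np.zeros(3), scheme.bvecs[~b0]])
    return sig, bvals, bvecs


def fit_tensor(signals: np.ndarray, scheme: AcquisitionScheme,
               voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
               signal_floor: float = SIGNAL_FLOOR,
               n_reweight: int = 1) -> TensorField:
    """Fit a diffusion tensor per voxel by weighted log-linear least squares.

    Parameters
    ----------
    signals : ndarray, shape (..., n_volumes)
        DWI signals; the trailing axis matches the scheme's volumes.
    scheme : AcquisitionScheme
        Validated encoding scheme (>= 1 b=0 volume, >= 6 non-collinear
        directions).
    voxel_size : tuple of float
        Voxel geometry carried into the returned :class:`TensorField`.
    signal_floor : float
        Non-positive signals are floored at this value (and the voxel left
        fittable); voxels whose signals are all non-positive are flagged
        invalid and get a zero tensor.

    n_reweight : int
        Number of reweighting iterations after the initial
        observed-signal-weighted pass: each iteration refits with weights
        taken from the predicted (model) signals, which removes the small
        bias induced by weighting with noisy observations. On noiseless
        data predicted and observed signals coincide, so reweighting leaves
        the exact solution untouched.

    Notes
    -----
    Multiple b = 0 volumes are averaged before fitting. Weights are
    squared signals, the standard first-order variance stabilisation for
    log-transformed Gaussian noise. Negative eigenvalues of the fitted
    tensor are clipped to ``DIFFUSIVITY_FLOOR`` and the voxel flagged.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.shape[-1] != scheme.n_volumes:
        raise ValueError("signal count does not match the acquisition scheme")
    grid = signals.shape[:-1]

    sig, bvals, bvecs = _collapse_b0(signals, scheme)
    n = sig.shape[-1]
    flat = sig.reshape(-1, n)
    nvox = flat.shape[0]

    invalid = np.all(flat <= 0.0, axis=1)
    floored = flat <= 0.0
    w = np.where(floored, signal_floor, flat)
    y = np.log(w)

    design = np.column_stack([np.ones(n), -_quadratic_design(bvals, bvecs)])
    weights = w * w  # signal-squared weighting
    ok = ~invalid
    beta = np.zeros((nvox, 7))
    if np.any(ok):
        wk = weights[ok]
        for _ in range(1 + max(0, int(n_reweight))):
            A = np.einsum("vn,ni,nj->vij", wk, design, design)
            rhs = np.einsum("vn,ni->vi", wk * y[ok], design)
            beta[ok] = np.linalg.solve(A, rhs[..., None])[..., 0]
            pred = np.exp(np.clip(beta[ok] @ design.T, -700.0, 700.0))
            wk = pred * pred

    s0 = np.where(ok, np.exp(beta[:, 0]), 0.0)
    D = np.zeros((nvox, 3, 3))
    D[:, 0, 0] = beta[:, 1]
    D[:, 1, 1] = beta[:, 2]
    D[:, 2, 2] = beta[:, 3]
    D[:, 0, 1] = D[:, 1, 0] = beta[:, 4]
    D[:, 0, 2] = D[:, 2, 0] = beta[:, 5]
    D[:, 1, 2] = D[:, 2, 1] = beta[:, 6]
    D[invalid] = 0.0

    vals = np.linalg.eigvalsh(D)
    clipped = ok & (vals.min(axis=1) < DIFFUSIVITY_FLOOR)
    # isolated clipped-voxel reconstruction so unclipped voxels keep the
    # exact least-squares solution
    if np.any(clipped):
        vals_c, vecs_c = np.linalg.eigh(D[clipped])
        vals_c = np.maximum(vals_c, DIFFUSIVITY_FLOOR)
        D[clipped] = np.einsum("vij,vj,vkj->vik", vecs_c, vals_c, vecs_c)

    return TensorField(
        tensors=D.reshape(*grid, 3, 3),
        s0=s0.reshape(grid),
        voxel_size=voxel_size,
        clipped=clipped.reshape(grid),
        invalid=invalid.reshape(grid),
    )


@dataclass
class ScalarMaps:
    """FA map, principal-direction map and directionally encoded colour map."""

    fa: np.ndarray
    principal_direction: np.ndarray  # (..., 3) unit eigenvector of largest eigenvalue
    color: np.ndarray                # (..., 3) = |principal_direction| components
    degenerate: np.ndarray           # bool: zero tensor, direction arbitrary


def scalar_maps(fld: TensorField) -> ScalarMaps:
    """Eigen-decomposition derived maps of a fitted tensor field.

    FA is the normalised eigenvalue dispersion in [0, 1]; the
    directionally encoded colour map carries |x|, |y|, |z| of the principal
    eigenvector in its three channels, the convention the fiber ROIs are
    drawn on.
    """
    vals, vecs = np.linalg.eigh(fld.tensors)
    md = vals.mean(axis=-1)
    num = np.sum((vals - md[..., None]) ** 2, axis=-1)
    den = np.sum(vals ** 2, axis=-1)
    degenerate = den <= 0.0
    fa = np.zeros_like(md)
    nz = ~degenerate
    fa[nz] = np.sqrt(1.5 * num[nz] / den[nz])
    fa = np.clip(fa, 0.0, 1.0)
    principal = vecs[..., :, -1]  # eigenvector of the largest eigenvalue
    color = np.abs(principal)
    return ScalarMaps(fa=fa, principal_direction=principal, color=color,
                      degenerate=degenerate)


# ---------------------------------------------------------------------------
# NIfTI / FSL gradient-table I/O
# ---------------------------------------------------------------------------

def _affine(voxel_size) -> np.ndarray:
    return np.diag([*[float(v) for v in voxel_size], 1.0])


def save_dwi(path, data: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Write a 4-D DWI volume as NIfTI with a diagonal voxel-size affine."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_size))
    nib.save(img, str(path))


def load_dwi(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def save_labels(path, labels: np.ndarray, voxel_size=(1.0, 1.0, 1.0)) -> None:
    img = nib.Nifti1Image(np.asarray(labels, dtype=np.int16), _affine(voxel_size))
    nib.save(img, str(path))


def load_labels(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=int)


def save_scheme(bval_path, bvec_path, scheme: AcquisitionScheme) -> None:
    """Write FSL-style gradient tables (bvals one row; bvecs three rows)."""
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in scheme.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for row in scheme.bvecs.T:
            fh.write(" ".join(f"{v:.8f}" for v in row) + "\n")


def load_scheme(bval_path, bvec_path,
                flip: tuple[bool, bool, bool] = (False, False, False)
                ) -> AcquisitionScheme:
    """Read FSL bval/bvec files.

    ``flip`` negates the x/y/z bvec components for tables stored in a sign
    convention other than the package's image-coordinate convention.
    """
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.ndim == 2 and bvecs.shape[0] == 3:  # FSL stores 3 rows x N columns
        bvecs = bvecs.T
    signs = np.where(np.asarray(flip, dtype=bool), -1.0, 1.0)
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs * signs)
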