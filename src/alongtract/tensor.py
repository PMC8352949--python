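"""Single diffusion tensor model: fitting, eigen-decomposition and FA.

The tensor D is the symmetric 3x3 apparent diffusion matrix (mm**2/s) of the
mono-exponential model

    S(g) = S0 * exp(-b * g^T D g)

fitted per voxel by log-linear least squares on the measured attenuations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import AcquisitionScheme

# order of the six unique elements in the flattened representation
_TENSOR_ELEMENTS = ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")


def design_matrix(scheme: AcquisitionScheme) -> np.ndarray:
    """Rows ``-b * [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz]``.

    Maps the six unique tensor elements to log-attenuations:
    ``log(S/S0) = design @ d``.
    """
    g = scheme.directions
    b = scheme.b_value
    return -b * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def tensor_from_elements(d: np.ndarray) -> np.ndarray:
    """Symmetric 3x3 matrix from (dxx, dyy, dzz, dxy, dxz, dyz)."""
    dxx, dyy, dzz, dxy, dxz, dyz = d
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def elements_from_tensor(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    return np.array([D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]])


@dataclass(frozen=True)
class DiffusionTensor:
    """A fitted symmetric diffusion tensor with derived eigensystem.

    ``eigenvalues`` are sorted descending (lambda1 >= lambda2 >= lambda3);
    ``principal_direction`` is the unit eigenvector of lambda1.
    """

    elements: np.ndarray  # (dxx, dyy, dzz, dxy, dxz, dyz), mm**2/s

    @property
    def matrix(self) -> np.ndarray:
        return tensor_from_elements(self.elements)

    @property
    def eigenvalues(self) -> np.ndarray:
        w = np.linalg.eigvalsh(self.matrix)
        return w[::-1]

    @property
    def principal_direction(self) -> np.ndarray:
        w, v = np.linalg.eigh(self.matrix)
        return v[:, -1]

    @property
    def fa(self) -> float:
        return compute_fa(self.eigenvalues)


def compute_fa(eigenvalues, clamp_negative: bool = True) -> float:
    """Fractional anisotropy from the three tensor eigenvalues.

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||, in [0, 1].
    Invariant to permutation and positive rescaling of the eigenvalues.
    The all-zero triple is defined as FA = 0 (isotropic-limit convention).
    Negative eigenvalues (possible from noisy fits) are clamped to zero
    first unless ``clamp_negative`` is False.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape != (3,):
        raise ValueError("expected exactly three eigenvalues")
    if clamp_negative:
        lam = np.clip(lam, 0.0, None)
    denom = np.sum(lam**2)
    if denom == 0:
        return 0.0
    mean = lam.mean()
    fa = np.sqrt(1.5 * np.sum((lam - mean) ** 2) / denom)
    return float(min(fa, 1.0))


def fit_tensor(
    signals,
    scheme: AcquisitionScheme,
    weighted: bool = False,
) -> DiffusionTensor:
    """Fit a single diffusion tensor by log-linear least squares.

    Parameters
    ----------
    signals : array-like, shape (n_b0 + n_directions,)
        Measured signals, the ``n_b0`` baseline (b=0) volumes first, then
        one value per gradient direction in scheme order. All must be
        strictly positive.
    scheme : AcquisitionScheme
        Needs at least 6 directions spanning the tensor space.
    weighted : bool
        If True, weight each log-signal equation by the signal magnitude
        (first-order correction for log-transformed noise).

    Returns
    -------
    DiffusionTensor
        Minimiser of the least-squares residual of ``log(S/S0)`` against
        the linear tensor model; noiseless self-consistent input is
        recovered to numerical precision.
    """
    s = np.asarray(signals, dtype=float)
    if s.shape != (scheme.n_volumes,):
        raise ValueError(
            f"expected {scheme.n_volumes} signals (n_b0 first), got {s.shape}"
        )
    if scheme.n_directions < 6:
        raise ValueError("tensor fit needs at least 6 gradient directions")
    if np.any(s <= 0):
        raise ValueError("all signals must be strictly positive")
    X = design_matrix(scheme)
    if np.linalg.matrix_rank(X) < 6:
        raise ValueError("rank-deficient direction set: tensor not identifiable")
    s0 = s[: scheme.n_b0].mean()
    y = np.log(s[scheme.n_b0 :] / s0)
    if weighted:
        w = s[scheme.n_b0 :]
        d, *_ = np.linalg.lstsq(X * w[:, None], y * w, rcond=None)
    else:
        d, *_ = np.linalg.lstsq(X, y, rcond=None)
    return DiffusionTensor(elements=d)


def fit_tensor_volume(dwi: np.ndarray, scheme: AcquisitionScheme) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise log-linear tensor fit over a 4-D DWI array.

    Parameters
    ----------
    dwi : ndarray, shape (X, Y, Z, n_b0 + n_directions)
        b=0 volumes first. Non-positive voxels yield a zero tensor.

    Returns
    -------
    fa : ndarray (X, Y, Z)
    peaks : ndarray (X, Y, Z, 3) unit principal eigenvector per voxel
        (zero vector where the tensor is zero).
    """
    shape = dwi.shape[:3]
    X = design_matrix(scheme)
    pinv = np.linalg.pinv(X)
    flat = dwi.reshape(-1, dwi.shape[3]).astype(float)
    ok = np.all(flat > 0, axis=1)
    s0 = flat[:, : scheme.n_b0].mean(axis=1)
    logs = np.zeros((flat.shape[0], scheme.n_directions))
    logs[ok] = np.log(flat[ok, scheme.n_b0 :] / s0[ok, None])
    d = logs @ pinv.T  # (nvox, 6)
    fa = np.zeros(flat.shape[0])
    peaks = np.zeros((flat.shape[0], 3))
    for i in np.flatnonzero(ok):
        D = tensor_from_elements(d[i])
        w, v = np.linalg.eigh(D)
        fa[i] = compute_fa(w)
        peaks[i] = v[:, -1]
    return fa.reshape(shape), peaks.reshape(shape + (3,))
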