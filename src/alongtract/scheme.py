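"""Diffusion acquisition schemes (gradient tables)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class AcquisitionScheme:
    """A single-shell diffusion gradient scheme.

    Parameters
    ----------
    b_value : float
        Diffusion weighting in s/mm**2. Must be positive.
    directions : ndarray, shape (M, 3)
        Unit gradient direction vectors.
    n_b0 : int
        Number of non-diffusion-weighted (b=0) volumes, at least 1.
    """

    b_value: float
    directions: np.ndarray
    n_b0: int = 1

    def __post_init__(self):
        dirs = np.atleast_2d(np.asarray(self.directions, dtype=float))
        if dirs.shape[1] != 3:
            raise ValueError("directions must be (M, 3)")
        norms = np.linalg.norm(dirs, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("all direction vectors must be unit-norm (tol 1e-6)")
        if self.n_b0 < 1:
            raise ValueError("n_b0 must be >= 1")
        if self.b_value <= 0:
            raise ValueError("b_value must be positive")
        object.__setattr__(self, "directions", dirs)

    @property
    def n_directions(self) -> int:
        return self.directions.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.n_b0 + self.n_directions


def fibonacci_directions(n: int) -> np.ndarray:
    """``n`` approximately uniform unit vectors on the sphere.

    Uses the Fibonacci (golden-angle) spiral, a standard deterministic
    construction for well-spread gradient tables.
    """
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    dirs = np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def default_scheme(n_directions: int = 45, b_value: float = 600.0, n_b0: int = 1) -> AcquisitionScheme:
    """The package's default acquisition: 45 directions at b=600 s/mm**2."""
    return AcquisitionScheme(b_value=b_value, directions=fibonacci_directions(n_directions), n_b0=n_b0)
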