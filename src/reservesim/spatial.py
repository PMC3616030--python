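"""Linear-coastline geometry, Gaussian dispersal kernels, and recruitment.

The coastline is a row of equally sized patches.  Larvae and adults move
between patches with Gaussian weights in center-to-center distance,
row-normalized so each patch's out-movement proportions sum to one; both
kernels therefore conserve the coastline total and no larvae are lost off
the ends (edge patches trade mass with their inshore neighbors instead).  Density-dependent
recruitment uses the Beverton-Holt steepness parameterization anchored at
the unfished settlement level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Coastline",
    "DispersalKernel",
    "dispersal_matrix",
    "settle_larvae",
    "move_adults",
    "beverton_holt",
]

ZONES = ("no_take", "partial", "open")


@dataclass(frozen=True)
class Coastline:
    """A linear coastline of ``n_patches`` equal patches with zone labels."""

    n_patches: int = 100
    patch_length: float = 1.0
    zone: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_patches < 3:
            raise ValueError(f"n_patches={self.n_patches} must be >= 3")
        if self.patch_length <= 0:
            raise ValueError(f"patch_length={self.patch_length} must be > 0")
        if self.zone is None:
            object.__setattr__(self, "zone", ("open",) * self.n_patches)
        else:
            object.__setattr__(self, "zone", tuple(self.zone))
        if len(self.zone) != self.n_patches:
            raise ValueError(
                f"zone has length {len(self.zone)}, expected {self.n_patches}"
            )
        bad = sorted(set(self.zone) - set(ZONES))
        if bad:
            raise ValueError(f"unknown zone label(s) {bad}; allowed: {ZONES}")

    def distances(self) -> np.ndarray:
        """Center-to-center distance matrix, ``|i - j| * patch_length``."""
        idx = np.arange(self.n_patches)
        return np.abs(idx[:, None] - idx[None, :]) * self.patch_length

    def zone_mask(self, label: str) -> np.ndarray:
        if label not in ZONES:
            raise ValueError(f"unknown zone label {label!r}")
        return np.array([z == label for z in self.zone])


@dataclass(frozen=True)
class DispersalKernel:
    """Row-stochastic movement matrix with its range parameter ``sigma``."""

    matrix: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"kernel matrix must be square, got shape {m.shape}")
        if np.any(m < 0):
            raise ValueError("kernel matrix has negative entries")
        rows = m.sum(axis=1)
        if not np.allclose(rows, 1.0, rtol=0, atol=1e-12):
            raise ValueError("kernel rows must sum to 1 within 1e-12")

    @property
    def n_patches(self) -> int:
        return self.matrix.shape[0]


def dispersal_matrix(coast: Coastline, sigma: float) -> DispersalKernel:
    """Gaussian movement kernel ``w_ij ∝ exp(-d_ij^2 / (2 sigma^2))``.

    Rows are normalized to sum to one so the proportions moving from patch
    ``i`` to all patches form a probability distribution.
    """
    if sigma <= 0:
        raise ValueError(f"sigma={sigma!r} must be > 0")
    d = coast.distances()
    # exponent can underflow to 0 for tiny sigma; the diagonal (d=0) stays 1
    w = np.exp(-(d**2) / (2.0 * sigma**2))
    return DispersalKernel(matrix=w / w.sum(axis=1, keepdims=True), sigma=sigma)


def _apply_kernel(vec, kernel: DispersalKernel, what: str) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    if v.shape != (kernel.n_patches,):
        raise ValueError(
            f"{what} has shape {v.shape}, expected ({kernel.n_patches},)"
        )
    if np.any(v < 0):
        raise ValueError(f"{what} contains negative entries")
    return v @ kernel.matrix


def settle_larvae(eggs, kernel: DispersalKernel) -> np.ndarray:
    """Distribute per-patch egg production across settlement patches.

    ``settlement_j = sum_i eggs_i * K_ij``; the row-stochastic kernel
    conserves the total.  Eggs are carried in grams (egg production equals
    spawning biomass).
    """
    return _apply_kernel(eggs, kernel, "eggs")


def move_adults(biomass, kernel: DispersalKernel) -> np.ndarray:
    """Redistribute adult biomass with the adult-movement kernel (same contract
    as :func:`settle_larvae`, using the sigma_A kernel)."""
    return _apply_kernel(biomass, kernel, "biomass")


def beverton_holt(E, h: float, R0: float, E0) -> np.ndarray | float:
    """Beverton-Holt recruitment in the steepness parameterization.

    ``R = 4 h R0 E / ((1-h) E0 + (5h-1) E)``, where ``E0`` is the settlement
    at the unfished equilibrium (same units as ``E``, here grams).  By
    construction ``R(E0) = R0`` and ``R(0.2 E0) = h R0``.
    """
    if not 0.2 < h <= 1.0:
        raise ValueError(f"h={h!r} must be in (0.2, 1]")
    E_arr = np.asarray(E, dtype=float)
    E0_arr = np.asarray(E0, dtype=float)
    if np.any(E0_arr <= 0):
        raise ValueError("E0 must be > 0")
    if np.any(E_arr < 0):
        raise ValueError("E must be >= 0")
    denom = (1.0 - h) * E0_arr + (5.0 * h - 1.0) * E_arr
    # at h = 1 and E = 0 the ratio is 0/0; recruitment is 0 with no settlement
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(E_arr > 0, (4.0 * h * R0 * E_arr) / denom, 0.0)
    return float(out) if E_arr.ndim == 0 else out
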