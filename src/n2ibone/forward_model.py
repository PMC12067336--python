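"""Parallel-beam projection, photon-counting noise, and dose subsampling.

Dose reduction is modeled exclusively as angular subsampling at constant
per-projection exposure: a 1/n dose keeps every nth projection of the full
scan, which is how the simulated-dose datasets are built.  An explicit
exposure-scaling noise model is available through ``simulate_counts`` but is
not part of the default dose pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.transform import radon

__all__ = ["Sinogram", "DoseFraction", "project", "simulate_counts", "subsample_angles"]


@dataclass
class Sinogram:
    """Per-slice parallel-beam projection data.

    ``data`` has shape (n_angles, n_detector) and holds line integrals of the
    linear attenuation coefficient in dimensionless µ·mm units.  ``angles``
    are radians in [0, π), strictly increasing.  ``photons_per_pixel`` is the
    expected incident photon count I₀ per detector bin (``inf`` = noiseless).
    """

    data: np.ndarray
    angles: np.ndarray
    photons_per_pixel: float = np.inf
    slice_index: int = 0
    pixel_size_um: float = 1.6

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("sinogram data must be 2D (n_angles, n_detector)")
        if self.angles.ndim != 1 or len(self.angles) != self.data.shape[0]:
            raise ValueError("angles length must equal the sinogram row count")
        if len(self.angles) > 1 and not np.all(np.diff(self.angles) > 0):
            raise ValueError("angles must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram data must be finite")

    @property
    def n_angles(self) -> int:
        return self.data.shape[0]

    @property
    def n_detector(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class DoseFraction:
    """A 1/denominator dose obtained by keeping every denominator-th angle."""

    denominator: int
    offset: int = 0

    def __post_init__(self) -> None:
        if self.denominator < 1:
            raise ValueError("denominator must be ≥ 1")
        if not 0 <= self.offset < self.denominator:
            raise ValueError("offset must satisfy 0 ≤ offset < denominator")


def _check_angles(angles: np.ndarray) -> np.ndarray:
    angles = np.asarray(angles, dtype=np.float64)
    if np.any(angles < 0) or np.any(angles >= np.pi):
        raise ValueError("angles must lie in [0, π) (half-turn parallel-beam)")
    return angles


def project(
    volume, angles, voxel_size_um: float | None = None, slice_axis: int = 0
) -> list[Sinogram]:
    """Discrete Radon transform of each axial slice.

    ``volume`` may be a ``LabeledVolume`` or a plain 2D/3D array of linear
    attenuation in mm⁻¹.  Line integrals are returned in µ·mm, so the forward
    model is consistent with reconstructions in mm⁻¹.  The transform is linear
    in the input.
    """
    angles = _check_angles(angles)
    if hasattr(volume, "attenuation"):
        voxel_size_um = volume.voxel_size_um
        arr = np.asarray(volume.attenuation, dtype=np.float64)
    else:
        arr = np.asarray(volume, dtype=np.float64)
        if voxel_size_um is None:
            voxel_size_um = 1.6
    if not np.all(np.isfinite(arr)):
        raise ValueError("volume must be finite")
    if arr.ndim == 2:
        arr = arr[None]
    theta_deg = np.degrees(angles)
    voxel_mm = voxel_size_um / 1000.0
    sinos = []
    for i in range(arr.shape[0] if slice_axis == 0 else arr.shape[slice_axis]):
        sl = np.take(arr, i, axis=slice_axis)
        # radon integrates in pixel-length units; scale to mm
        data = radon(sl, theta=theta_deg, circle=False).T * voxel_mm
        sinos.append(
            Sinogram(data=data, angles=angles, slice_index=i, pixel_size_um=voxel_size_um)
        )
    return sinos


def simulate_counts(sino: Sinogram, photons: float, seed: int) -> Sinogram:
    """Apply a Poisson photon-counting noise model.

    Transmitted counts are drawn as N ~ Poisson(I₀·exp(−p)) independently per
    bin and converted back to line integrals via −ln(max(N, 1)/I₀); the clamp
    at one count avoids infinities for fully absorbed rays.  ``photons=inf``
    is a noiseless passthrough.
    """
    if np.isinf(photons):
        return replace(sino, data=sino.data.copy(), photons_per_pixel=np.inf)
    if not photons > 0:
        raise ValueError("photons must be positive or inf")
    rng = np.random.default_rng(seed)
    expected = photons * np.exp(-sino.data)
    counts = rng.poisson(expected).astype(np.float64)
    data = -np.log(np.maximum(counts, 1.0) / photons)
    return replace(sino, data=data, photons_per_pixel=float(photons))


def subsample_angles(sino: Sinogram, frac: DoseFraction | int) -> Sinogram:
    """Keep rows offset, offset+n, offset+2n, … — the 1/n dose dataset.

    The retained projection count is ceil((n_angles − offset)/n); angle list
    and data rows are subsampled identically and photon metadata is kept.
    """
    if isinstance(frac, int):
        frac = DoseFraction(frac)
    if frac.denominator > sino.n_angles:
        raise ValueError(
            f"denominator {frac.denominator} exceeds angle count {sino.n_angles}"
        )
    sel = slice(frac.offset, None, frac.denominator)
    return replace(sino, data=sino.data[sel].copy(), angles=sino.angles[sel].copy())


def uniform_angles(n: int) -> np.ndarray:
    """n equally spaced angles over the half-open interval [0, π)."""
    return np.linspace(0.0, np.pi, int(n), endpoint=False)
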