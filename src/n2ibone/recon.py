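"""Filtered back projection, sinogram splitting, and comparison baselines.

FBP uses a ramp (Ram-Lak) filter by default; a Shepp-Logan window is
available by argument.  Gray values stay in linear-attenuation units (mm⁻¹)
end-to-end and the reconstruction circle is not masked by default (the bath
fills the field of view).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import iradon

from .forward_model import Sinogram

__all__ = [
    "SubReconSet",
    "PhaseRetrievalParams",
    "fbp",
    "fbp_volume",
    "split_sinogram",
    "make_subrecons",
    "paganin_filter",
    "median_baseline",
]


@dataclass
class SubReconSet:
    """The K sub-reconstructions of one split sinogram stack.

    ``subrecons`` are K volumes of shape (n_slices, ny, nx) in mm⁻¹;
    ``source_angle_sets`` records which angles produced each.  The angle sets
    are pairwise disjoint and their union is the parent's angle set.
    """

    K: int
    subrecons: list[np.ndarray]
    source_angle_sets: list[np.ndarray]

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be ≥ 2 for Noise2Inverse use")
        if len(self.subrecons) != self.K or len(self.source_angle_sets) != self.K:
            raise ValueError("need exactly K sub-reconstructions and angle sets")
        shapes = {v.shape for v in self.subrecons}
        if len(shapes) != 1:
            raise ValueError("sub-reconstructions must share a shape")
        flat = np.concatenate(self.source_angle_sets)
        if len(np.unique(flat)) != len(flat):
            raise ValueError("sub-sinogram angle sets must be disjoint")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.subrecons[0].shape

    @property
    def n_slices(self) -> int:
        return self.subrecons[0].shape[0]


@dataclass(frozen=True)
class PhaseRetrievalParams:
    """Single-distance phase retrieval settings.

    ``delta`` and ``beta`` default to hydroxyapatite at 24 keV; the
    propagation distance has no packaged default and must be supplied.
    """

    distance_mm: float
    delta: float = 1.1378e-6
    beta: float = 4.8945e-9
    energy_keV: float = 24.0
    pixel_um: float = 1.6

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.beta <= 0:
            raise ValueError("delta and beta must be positive")
        if self.energy_keV <= 0 or self.pixel_um <= 0 or self.distance_mm < 0:
            raise ValueError("energy, pixel size must be positive; distance non-negative")

    @property
    def wavelength_m(self) -> float:
        return 1.23984193e-9 / self.energy_keV


def fbp(sino: Sinogram, filter_name: str = "ramp", output_size: int | None = None,
        mask_circle: bool = False) -> np.ndarray:
    """Ramp-filtered back projection on the sinogram's own angle list.

    Output gray values approximate the linear attenuation in mm⁻¹.  The
    operation is linear in the sinogram.
    """
    if sino.n_angles < 2:
        raise ValueError("FBP needs at least 2 angles")
    voxel_mm = sino.pixel_size_um / 1000.0
    skimage_filter = {"ramp": "ramp", "shepp-logan": "shepp-logan"}[filter_name]
    img = iradon(
        sino.data.T,
        theta=np.degrees(sino.angles),
        filter_name=skimage_filter,
        circle=False,
        output_size=output_size,
    )
    img = img / voxel_mm
    if mask_circle:
        n = img.shape[0]
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        r2 = (yy - (n - 1) / 2) ** 2 + (xx - (n - 1) / 2) ** 2
        img = np.where(r2 <= ((n - 1) / 2) ** 2, img, 0.0)
    return img


def fbp_volume(sinos: list[Sinogram], **kw) -> np.ndarray:
    """Stack per-slice FBP reconstructions into a volume (n_slices, ny, nx)."""
    return np.stack([fbp(s, **kw) for s in sinos])


def split_sinogram(sino: Sinogram, K: int) -> list[Sinogram]:
    """Split into K sub-sinograms, sub-sinogram j taking rows j, j+K, j+2K, …

    Sizes differ by at most one (the extra angle goes to split 0); the union
    of angle sets equals the parent's and the sets are disjoint.
    """
    if K < 1:
        raise ValueError("K must be ≥ 1")
    if K > sino.n_angles:
        raise ValueError(f"K={K} exceeds angle count {sino.n_angles}")
    from .forward_model import subsample_angles, DoseFraction

    return [subsample_angles(sino, DoseFraction(K, offset=j)) for j in range(K)]


def make_subrecons(sinos: Sinogram | list[Sinogram], K: int, **fbp_kw) -> SubReconSet:
    """FBP each of the K sub-sinograms of a sinogram stack.

    Accepts a single slice sinogram or a list of per-slice sinograms (one
    scan); returns K volumes with their angle provenance.
    """
    if K < 2:
        raise ValueError("K must be ≥ 2")
    if isinstance(sinos, Sinogram):
        sinos = [sinos]
    splits_per_slice = [split_sinogram(s, K) for s in sinos]
    subrecons = []
    for j in range(K):
        subrecons.append(np.stack([fbp(sp[j], **fbp_kw) for sp in splits_per_slice]))
    angle_sets = [splits_per_slice[0][j].angles for j in range(K)]
    return SubReconSet(K=K, subrecons=subrecons, source_angle_sets=angle_sets)


def paganin_filter(projections: np.ndarray, params: PhaseRetrievalParams) -> np.ndarray:
    """Single-distance Paganin phase retrieval on flat-corrected transmission.

    Each projection is low-pass filtered in Fourier space with the kernel
    1 / (1 + (λ·R·δ/(4π·β))·|k|²) and then log-transformed, so the output is
    a retrieved line-integral image.  With R → 0 the kernel is unity and the
    result reduces to plain −log(transmission).
    """
    proj = np.asarray(projections, dtype=np.float64)
    if proj.ndim == 2:
        proj = proj[None]
        squeeze = True
    else:
        squeeze = False
    if np.any(proj <= 0):
        raise ValueError("transmission values must be positive")
    h, w = proj.shape[-2:]
    pixel_m = params.pixel_um * 1e-6
    ky = 2 * np.pi * np.fft.fftfreq(h, d=pixel_m)
    kx = 2 * np.pi * np.fft.fftfreq(w, d=pixel_m)
    k2 = ky[:, None] ** 2 + kx[None, :] ** 2
    coeff = params.wavelength_m * (params.distance_mm * 1e-3) * params.delta / (
        4 * np.pi * params.beta
    )
    kernel = 1.0 / (1.0 + coeff * k2)
    filtered = np.fft.ifft2(np.fft.fft2(proj, axes=(-2, -1)) * kernel, axes=(-2, -1)).real
    filtered = np.maximum(filtered, 1e-12)
    out = -np.log(filtered)
    return out[0] if squeeze else out


def median_baseline(volume: np.ndarray, radius: int = 1) -> np.ndarray:
    """Sliding-window median with edge reflection; idempotent on constants."""
    if radius < 1:
        raise ValueError("radius must be ≥ 1")
    return ndimage.median_filter(volume, size=2 * radius + 1, mode="reflect")
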