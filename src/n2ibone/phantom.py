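"""Synthetic cortical-bone phantoms with analytically known lacunae.

A phantom is a 3D grid of linear attenuation values (mm⁻¹) containing a
centered rectangular bone prism immersed in a fluid bath, a dense cylindrical
reference inclusion in the bath (for mineral calibration), and non-overlapping
randomly oriented ellipsoidal lacunae inside the bone.  Every lacuna's
analytic volume, aspect ratio and centroid are recorded in a truth table so
each downstream stage (projection, reconstruction, denoising, morphometry)
can be validated against known ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .constants import (
    MASS_ATTENUATION_24KEV,
    REFERENCE_MATRIX_DENSITY_MGHA,
    linear_attenuation_mm,
)

__all__ = [
    "ReferenceInclusion",
    "PhantomSpec",
    "LabeledVolume",
    "generate_phantom",
    "default_bone_spec",
]


@dataclass(frozen=True)
class ReferenceInclusion:
    """A calibration material of known density placed in the bath."""

    material_name: str = "alumina"
    attenuation_mm: float = linear_attenuation_mm("alumina")
    known_density_g_cm3: float = 3.95


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic bone volume.

    ``volume_range_um3`` bounds the sampled *true* ellipsoid volumes;
    ``aspect_ratio_range`` bounds the short/long semi-axis ratio.  The bone
    prism spans the axial (z) extent of the grid and a centered fraction
    ``bone_extent_fraction`` of each transverse axis; the bath fills the rest.
    ``bone_cross_section_mm2`` is dose-budget metadata describing the real
    sample cross-section the phantom stands in for — it is not a geometric
    constraint on the grid.
    """

    grid_shape: tuple[int, int, int] = (64, 192, 192)
    voxel_size_um: float = 1.6
    n_lacunae: int = 150
    volume_range_um3: tuple[float, float] = (150.0, 1800.0)
    aspect_ratio_range: tuple[float, float] = (0.30, 0.62)
    matrix_attenuation: float = linear_attenuation_mm(
        "hydroxyapatite", REFERENCE_MATRIX_DENSITY_MGHA / 1000.0
    )
    lacuna_attenuation: float = linear_attenuation_mm("water")
    bath_attenuation: float = linear_attenuation_mm("water")
    reference_inclusion: ReferenceInclusion = field(default_factory=ReferenceInclusion)
    bone_cross_section_mm2: float = 3.28
    bone_extent_fraction: float = 0.78
    volume_mode_um3: float = 393.0
    volume_sigma_log: float = 0.55
    aspect_ratio_center: float = 0.46
    aspect_ratio_sigma: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        for name in ("matrix_attenuation", "lacuna_attenuation", "bath_attenuation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.lacuna_attenuation < self.matrix_attenuation:
            raise ValueError("lacuna_attenuation must be below matrix_attenuation")
        lo, hi = self.volume_range_um3
        if not 0 < lo < hi:
            raise ValueError("volume_range_um3 must be an increasing positive pair")
        grid_um3 = float(np.prod(self.grid_shape)) * self.voxel_size_um**3
        if hi > grid_um3:
            raise ValueError(
                f"volume_range_um3 max {hi} µm³ exceeds grid volume {grid_um3:.0f} µm³"
            )
        alo, ahi = self.aspect_ratio_range
        if not 0 < alo <= ahi <= 1:
            raise ValueError("aspect_ratio_range must lie in (0, 1]")

    @property
    def voxel_volume_um3(self) -> float:
        return self.voxel_size_um**3

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class LabeledVolume:
    """Attenuation grid plus lacuna labels and analytic ground truth.

    ``labels`` uses 0 for everything that is not a lacuna (matrix, bath,
    inclusion) and k ≥ 1 for lacuna k.  ``truth`` holds one row per lacuna
    with the *analytic* ellipsoid volume and aspect ratio alongside the
    achieved voxel count.  Boolean region masks are kept so calibration and
    region-of-interest code does not have to re-derive the geometry.
    """

    attenuation: np.ndarray
    labels: np.ndarray
    truth: pd.DataFrame
    voxel_size_um: float
    spec: PhantomSpec
    bone_mask: np.ndarray
    bath_mask: np.ndarray
    inclusion_mask: np.ndarray
    bone_box: tuple[slice, slice, slice]

    def __post_init__(self) -> None:
        if self.attenuation.shape != self.labels.shape:
            raise ValueError("attenuation and labels must share a shape")
        ids = np.unique(self.labels)
        ids = ids[ids > 0]
        if not np.array_equal(np.sort(ids), np.sort(self.truth["id"].to_numpy())):
            raise ValueError("label ids and truth table ids disagree")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.attenuation.shape

    def save(self, out_dir: str | Path) -> None:
        from . import io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_tiff_stack(out / "attenuation.tif", self.attenuation.astype(np.float32))
        io.write_tiff_stack(out / "labels.tif", self.labels.astype(np.int32))
        cols = ["id", "volume_um3", "aspect_ratio", "cx", "cy", "cz"]
        self.truth[cols].to_csv(out / "truth.csv", index=False)


def default_bone_spec() -> PhantomSpec:
    """Packaged default emulating healthy bovine cortical bone.

    Voxel size 1.6 µm, matrix gray level mapping to 1226 mgHA cm⁻³ through the
    default mineral calibration, lacunar volume distribution with mode 393 µm³
    and aspect ratios centered on 0.46.
    """
    return PhantomSpec()


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via a normalized random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _sample_truncated(rng, draw, lo, hi, max_tries=10000):
    for _ in range(max_tries):
        v = draw(rng)
        if lo <= v <= hi:
            return v
    raise RuntimeError("truncated sampling failed; range too narrow for distribution")


def _ellipsoid_fraction(
    shape: tuple[int, int, int],
    origin: np.ndarray,
    center: np.ndarray,
    rot: np.ndarray,
    semi_axes_vox: np.ndarray,
) -> np.ndarray:
    """Occupied fraction per voxel of an ellipsoid, 3× supersampled per axis.

    ``center`` is in voxel coordinates relative to the full grid; ``origin``
    is the corner of the local box of the given shape.
    """
    zz, yy, xx = np.meshgrid(
        *[np.arange(s, dtype=float) + o for s, o in zip(shape, origin)], indexing="ij"
    )
    pts = np.stack([zz, yy, xx], axis=-1) - center
    frac = np.zeros(shape)
    sub = np.array([-1.0 / 3.0, 0.0, 1.0 / 3.0])
    for dz in sub:
        for dy in sub:
            for dx in sub:
                p = pts + np.array([dz, dy, dx])
                u = p @ rot  # rot columns are the ellipsoid axes: u = rotᵀ·p
                r2 = np.sum((u / semi_axes_vox) ** 2, axis=-1)
                frac += r2 <= 1.0
    return frac / 27.0


def generate_phantom(spec: PhantomSpec, max_attempts_per_lacuna: int = 2000) -> LabeledVolume:
    """Generate a seeded synthetic bone volume.

    Lacunae are placed by rejection sampling: a candidate ellipsoid is
    voxelized (2× supersampled, a voxel belongs to the lacuna when at least
    half its sub-samples fall inside) and accepted only if it keeps at least a
    one-voxel gap from every previously placed lacuna and from the bone
    boundary, so 26-connected labeling can never merge two lacunae.

    Raises ``RuntimeError`` naming the achieved count if a lacuna cannot be
    placed within ``max_attempts_per_lacuna`` attempts.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.grid_shape
    vs = spec.voxel_size_um

    labels = np.zeros(spec.grid_shape, dtype=np.int32)

    # bone prism: full z extent, centered fraction of y and x
    wy = max(2, int(round(ny * spec.bone_extent_fraction)))
    wx = max(2, int(round(nx * spec.bone_extent_fraction)))
    y0, x0 = (ny - wy) // 2, (nx - wx) // 2
    bone_box = (slice(0, nz), slice(y0, y0 + wy), slice(x0, x0 + wx))
    bone_mask = np.zeros(spec.grid_shape, dtype=bool)
    bone_mask[bone_box] = True

    # cylindrical reference inclusion in a bath corner, axis along z
    margin = min(y0, x0)
    inclusion_mask = np.zeros(spec.grid_shape, dtype=bool)
    if margin >= 4 and spec.reference_inclusion is not None:
        r_inc = max(1.5, margin / 3.0)
        cy, cx = y0 / 2.0, x0 / 2.0
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_inc**2
        inclusion_mask[:] = disk[None, :, :]

    # lognormal true volumes with analytic mode spec.volume_mode_um3
    sigma = spec.volume_sigma_log
    mu = np.log(spec.volume_mode_um3) + sigma**2
    vlo, vhi = spec.volume_range_um3
    alo, ahi = spec.aspect_ratio_range

    rows = []
    for k in range(1, spec.n_lacunae + 1):
        volume = _sample_truncated(rng, lambda r: float(r.lognormal(mu, sigma)), vlo, vhi)
        aspect = _sample_truncated(
            rng,
            lambda r: float(r.normal(spec.aspect_ratio_center, spec.aspect_ratio_sigma)),
            alo,
            ahi,
        )
        # semi-axes a ≥ b ≥ c with c/a = aspect and b the log-midpoint
        a_um = (3.0 * volume / (4.0 * np.pi * aspect**1.5)) ** (1.0 / 3.0)
        axes_um = np.array([a_um, a_um * np.sqrt(aspect), a_um * aspect])
        axes_vox = axes_um / vs

        placed = False
        for _ in range(max_attempts_per_lacuna):
            rot = _random_rotation(rng)
            reach = float(axes_vox[0]) + 1.0
            lo_b = np.array([bone_box[i].start for i in range(3)]) + reach + 1.0
            hi_b = np.array([bone_box[i].stop for i in range(3)]) - reach - 1.0
            if np.any(hi_b <= lo_b):
                break  # lacuna cannot fit in the bone prism at all
            center = rng.uniform(lo_b, hi_b)

            o = np.floor(center - reach - 2).astype(int)
            e = np.ceil(center + reach + 2).astype(int) + 1
            o = np.maximum(o, 0)
            e = np.minimum(e, spec.grid_shape)
            box_shape = tuple(e - o)
            frac = _ellipsoid_fraction(box_shape, o.astype(float), center, rot, axes_vox)
            vox = frac >= 0.5
            if not vox.any():
                continue
            # exact one-voxel gap: nothing may sit in the 26-neighborhood of
            # the new lacuna, so 26-connected labeling can never merge two
            guard = ndimage.binary_dilation(vox, structure=np.ones((3, 3, 3), dtype=bool))
            box = tuple(slice(o[i], e[i]) for i in range(3))
            if labels[box][guard].any():
                continue
            labels[box][vox] = k
            count = int(vox.sum())
            rows.append(
                {
                    "id": k,
                    "volume_um3": 4.0 / 3.0 * np.pi * float(np.prod(axes_um)),
                    "aspect_ratio": aspect,
                    "cx": center[2] * vs,
                    "cy": center[1] * vs,
                    "cz": center[0] * vs,
                    "voxel_count": count,
                    "voxel_volume_um3": count * spec.voxel_volume_um3,
                }
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place lacuna {k} of {spec.n_lacunae} "
                f"(placed {k - 1}) — grid too small or too crowded"
            )

    truth = pd.DataFrame(
        rows,
        columns=[
            "id",
            "volume_um3",
            "aspect_ratio",
            "cx",
            "cy",
            "cz",
            "voxel_count",
            "voxel_volume_um3",
        ],
    )

    attenuation = np.full(spec.grid_shape, spec.bath_attenuation, dtype=np.float32)
    attenuation[bone_mask] = spec.matrix_attenuation
    attenuation[labels > 0] = spec.lacuna_attenuation
    if spec.reference_inclusion is not None:
        attenuation[inclusion_mask] = spec.reference_inclusion.attenuation_mm

    bath_mask = ~bone_mask & ~inclusion_mask
    return LabeledVolume(
        attenuation=attenuation,
        labels=labels,
        truth=truth,
        voxel_size_um=vs,
        spec=spec,
        bone_mask=bone_mask,
        bath_mask=bath_mask,
        inclusion_mask=inclusion_mask,
        bone_box=bone_box,
    )
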