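"""Lacuna morphometry, mineral calibration, and paired statistics.

Segmentation uses automatic histogram thresholds (Yen by default, Otsu as an
alternative) computed on 256-bin histograms.  Connected components are
labeled with 26-connectivity; particles are filtered to the 50–2000 µm³
volume window (inclusive) used in 3D lacuna studies.  The aspect ratio of a
component is the ratio of its shortest to longest principal axis, i.e. the
square root of the smallest-to-largest eigenvalue ratio of the voxel
coordinate covariance (a 2:1:1 ellipsoid scores 0.5, a sphere 1.0); the raw
eigenvalue ratio is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu, threshold_yen

from .constants import MASS_ATTENUATION_24KEV
from .metrics import percent_change

__all__ = [
    "threshold",
    "label_lacunae",
    "distribution_mode",
    "MineralCalibration",
    "calibrate_mineralization",
    "PairedComparison",
    "compare_paired",
    "VOLUME_FILTER_UM3",
]

#: inclusive particle-volume window for lacunae, µm³
VOLUME_FILTER_UM3: tuple[float, float] = (50.0, 2000.0)


def threshold(image: np.ndarray, method: str = "yen", nbins: int = 256) -> float:
    """Automatic histogram threshold (gray value inside the image range).

    Yen maximizes the maximum-correlation criterion; Otsu maximizes the
    between-class variance.  Both scan a ``nbins``-bin histogram of the image
    range exhaustively.
    """
    image = np.asarray(image)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    if np.ptp(image) == 0:
        raise ValueError("cannot threshold a constant image")
    if method == "yen":
        return float(threshold_yen(image, nbins=nbins))
    if method == "otsu":
        return float(threshold_otsu(image, nbins=nbins))
    raise ValueError(f"unknown threshold method {method!r}")


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def label_lacunae(
    mask: np.ndarray,
    voxel_size_um: float,
    volume_range_um3: tuple[float, float] = VOLUME_FILTER_UM3,
    raw_eigenvalue_ratio: bool = False,
) -> pd.DataFrame:
    """26-connected labeling and morphometry of a binary lacuna mask.

    Returns one row per retained component with columns ``id``,
    ``voxel_count``, ``volume_um3`` (= voxel_count × voxel_size³ exactly),
    ``aspect_ratio`` and centroid ``cx/cy/cz`` in µm.  The DataFrame's
    ``attrs`` record ``n_components_total`` and ``n_rejected`` so the volume
    filter is auditable (kept + rejected = total).
    """
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if mask.dtype != bool and not np.isin(vals, (0, 1)).all():
        raise ValueError("mask must be binary")
    mask = mask.astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    labels, n_total = ndimage.label(mask, structure=_STRUCT_26)
    voxel_vol = voxel_size_um**3
    counts = np.bincount(labels.ravel())[1:]
    volumes = counts * voxel_vol
    lo, hi = volume_range_um3
    keep_ids = np.flatnonzero((volumes >= lo) & (volumes <= hi)) + 1

    # voxel self-variance keeps moments meaningful for thin/small components
    self_var = voxel_size_um**2 / 12.0
    rows = []
    objects = ndimage.find_objects(labels)
    for lid in keep_ids:
        box = objects[lid - 1]
        local = labels[box] == lid
        zz, yy, xx = np.nonzero(local)
        coords = np.stack(
            [
                (zz + box[0].start) * voxel_size_um,
                (yy + box[1].start) * voxel_size_um,
                (xx + box[2].start) * voxel_size_um,
            ]
        )
        centroid = coords.mean(axis=1)
        cov = np.cov(coords, bias=True) + np.eye(3) * self_var
        eig = np.linalg.eigvalsh(cov)
        ratio = eig[0] / eig[-1]
        aspect = ratio if raw_eigenvalue_ratio else float(np.sqrt(ratio))
        rows.append(
            {
                "id": int(lid),
                "voxel_count": int(counts[lid - 1]),
                "volume_um3": float(volumes[lid - 1]),
                "aspect_ratio": float(min(aspect, 1.0)),
                "cx": float(centroid[2]),
                "cy": float(centroid[1]),
                "cz": float(centroid[0]),
            }
        )
    table = pd.DataFrame(
        rows, columns=["id", "voxel_count", "volume_um3", "aspect_ratio", "cx", "cy", "cz"]
    )
    table.attrs["n_components_total"] = int(n_total)
    table.attrs["n_rejected"] = int(n_total - len(rows))
    table.attrs["voxel_size_um"] = float(voxel_size_um)
    return table


def distribution_mode(
    values, bandwidth: float | str | None = None, grid_points: int = 512
) -> float:
    """Mode of a Gaussian kernel density estimate on a fixed grid.

    ``bandwidth`` is passed to ``scipy.stats.gaussian_kde`` (default
    Silverman's rule; a float is a multiple of the sample std).  Degenerate
    samples (single value, zero spread) return that value.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("distribution_mode needs at least one value")
    if values.size == 1 or np.ptp(values) == 0:
        return float(values[0])
    kde = stats.gaussian_kde(values, bw_method=bandwidth or "silverman")
    grid = np.linspace(values.min(), values.max(), grid_points)
    return float(grid[np.argmax(kde(grid))])


@dataclass
class MineralCalibration:
    """Linear map from reconstructed gray values to mgHA cm⁻³.

    ``reference_points`` holds (material, apparent density, known density)
    in g cm⁻³.  When fit to exactly two points the map reproduces both known
    densities exactly.
    """

    reference_points: list[tuple[str, float, float]]
    slope: float
    intercept: float
    target_mass_attenuation: float
    output_unit: str = "mgHA cm^-3"

    def __post_init__(self) -> None:
        if len(self.reference_points) < 2:
            raise ValueError("need at least 2 reference points")
        if not np.isfinite(self.slope) or self.slope == 0:
            raise ValueError("degenerate calibration slope")

    def apply(self, gray_mm: np.ndarray) -> np.ndarray:
        """Gray (mm⁻¹) → hydroxyapatite-equivalent density (mgHA cm⁻³)."""
        apparent = 10.0 * np.asarray(gray_mm) / self.target_mass_attenuation
        return (self.slope * apparent + self.intercept) * 1000.0


def calibrate_mineralization(
    recon: np.ndarray,
    regions: dict[str, np.ndarray],
    known_densities: dict[str, float],
    mass_attenuation: dict[str, float] | None = None,
    target_material: str = "hydroxyapatite",
    min_region_voxels: int = 10,
) -> tuple[np.ndarray, MineralCalibration]:
    """Density calibration against reference materials in the field of view.

    For each reference region the apparent density is the mean gray value
    divided by the material's mass attenuation coefficient; a least-squares
    line maps apparent to known densities (exact through two points).  The
    returned volume applies the map to all gray values using the µ/ρ of
    hydroxyapatite, in mgHA cm⁻³.
    """
    atten = dict(MASS_ATTENUATION_24KEV)
    if mass_attenuation:
        atten.update(mass_attenuation)
    if len(regions) < 2:
        raise ValueError("need at least 2 reference regions")
    points = []
    for name, mask in regions.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() < min_region_voxels:
            raise ValueError(f"reference region {name!r} has fewer than "
                             f"{min_region_voxels} voxels")
        gray = float(np.asarray(recon)[mask].mean())
        apparent = 10.0 * gray / atten[name]  # mm⁻¹ → cm⁻¹, then / (µ/ρ)
        points.append((name, apparent, float(known_densities[name])))
    apparents = np.array([p[1] for p in points])
    knowns = np.array([p[2] for p in points])
    if np.ptp(apparents) <= 1e-9 * max(1.0, float(np.abs(apparents).max())):
        raise ValueError("identical apparent densities across references: degenerate fit")
    slope, intercept = np.polyfit(apparents, knowns, 1)
    cal = MineralCalibration(
        reference_points=points,
        slope=float(slope),
        intercept=float(intercept),
        target_mass_attenuation=atten[target_material],
    )
    return cal.apply(recon), cal


@dataclass
class PairedComparison:
    """Paired t-test between two matched groups, with assumption checks.

    Shapiro–Wilk (on the differences) and Levene (across groups) p-values
    are reported but do not gate the t-test.  ``degenerate`` flags a
    zero-variance difference vector, where t is undefined.
    """

    a: np.ndarray
    b: np.ndarray
    shapiro_p: float
    levene_p: float
    t_statistic: float
    p_value: float
    mode_change_pct: float
    degenerate: bool = False


def compare_paired(a, b) -> PairedComparison:
    """Two-sided paired t-test of group b against reference group a.

    Positive t means b > a.  The percent change compares the group means.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1D groups with ≥ 3 pairs")
    diff = b - a
    identical = np.array_equal(a, b, equal_nan=True)
    change = (
        0.0 if identical else percent_change(float(b.mean()), float(a.mean()))
    )
    if identical or np.ptp(diff) == 0:
        return PairedComparison(
            a=a, b=b, shapiro_p=np.nan, levene_p=np.nan,
            t_statistic=np.nan, p_value=np.nan,
            mode_change_pct=change, degenerate=True,
        )
    shapiro_p = float(stats.shapiro(diff).pvalue)
    levene_p = float(stats.levene(a, b).pvalue)
    t_res = stats.ttest_rel(b, a)
    return PairedComparison(
        a=a, b=b, shapiro_p=shapiro_p, levene_p=levene_p,
        t_statistic=float(t_res.statistic), p_value=float(t_res.pvalue),
        mode_change_pct=change, degenerate=False,
    )
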