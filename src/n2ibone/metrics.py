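"""Image-quality metrics (MSE, PSNR, SSIM) and percent-change arithmetic.

The PSNR data range defaults to the reference image's max−min; the
convention is recorded in every report and can be overridden, since PSNR is
meaningless without it.  SSIM on volumes is computed slice-wise with a
7-pixel window (K1 = 0.01, K2 = 0.03) and averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["QualityReport", "image_quality", "percent_change"]


@dataclass(frozen=True)
class QualityReport:
    mse: float
    psnr: float
    ssim: float
    data_range: float
    data_range_convention: str

    def as_dict(self) -> dict:
        return {
            "mse": self.mse,
            "psnr": self.psnr,
            "ssim": self.ssim,
            "data_range": self.data_range,
            "data_range_convention": self.data_range_convention,
        }


def image_quality(
    test: np.ndarray, reference: np.ndarray, data_range: float | None = None
) -> QualityReport:
    """MSE, PSNR and SSIM of a test image/volume against a reference.

    PSNR = 10·log₁₀(range²/MSE); an exact match reports ``inf``.  ``data_range``
    defaults to the reference max−min ("auto"); pass a float to fix it.
    """
    test = np.asarray(test, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if test.shape != reference.shape:
        raise ValueError("test and reference must share a shape")
    if not np.all(np.isfinite(reference)):
        raise ValueError("reference must be finite")
    if data_range is None:
        rng = float(reference.max() - reference.min())
        convention = "auto (reference max-min)"
    else:
        rng = float(data_range)
        convention = "explicit"
    if rng == 0:
        raise ValueError("zero data range")
    mse = float(np.mean((test - reference) ** 2))
    psnr = np.inf if mse == 0 else float(10.0 * np.log10(rng**2 / mse))
    if test.ndim == 2:
        ssim = float(
            structural_similarity(test, reference, data_range=rng, win_size=7)
        )
    elif test.ndim == 3:
        ssim = float(
            np.mean(
                [
                    structural_similarity(t, r, data_range=rng, win_size=7)
                    for t, r in zip(test, reference)
                ]
            )
        )
    else:
        raise ValueError("expected a 2D image or 3D volume")
    return QualityReport(
        mse=mse, psnr=psnr, ssim=ssim, data_range=rng, data_range_convention=convention
    )


def percent_change(new: float, reference: float) -> float:
    """100 × (new − reference) / reference.

    Full precision; round to one decimal for display.
    """
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return 100.0 * (new - reference) / reference
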