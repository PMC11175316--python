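"""Structural fidelity scoring by mean SSIM.

Fidelity of a printed layer is the mean structural similarity index between
the target thickness map x and the defect-masked reconstructed map y,

    SSIM(x, y) = (2 mu_x mu_y + c1)(2 sigma_xy + c2)
                 / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2)),

computed with local (windowed) moments. The moving window is sized to the
target filament diameter; c1 = (0.01 L)^2 and c2 = (0.03 L)^2 with L the
dynamic range of the compared fields (the conventional stability constants).
Window statistics use uniform (box) weights with symmetric border padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .defect_map import DefectClass, DefectMap
from .gcode_model import TargetModelMap
from .oct_reconstruction import ReconstructedModelMap

__all__ = [
    "SSIMParams",
    "FidelityResult",
    "build_recon_full",
    "ssim",
    "fidelity_series",
    "window_from_filament_width",
]


@dataclass(frozen=True)
class SSIMParams:
    """SSIM window and stability constants."""

    window_px: int = 11
    c1: float = (0.01 * 0.25) ** 2
    c2: float = (0.03 * 0.25) ** 2
    dynamic_range: float = 0.25

    def __post_init__(self) -> None:
        if self.window_px < 3 or self.window_px % 2 == 0:
            raise ValueError("window_px must be odd and >= 3")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("stability constants must be positive")

    @classmethod
    def for_range(cls, dynamic_range: float, window_px: int = 11) -> "SSIMParams":
        return cls(
            window_px=window_px,
            c1=(0.01 * dynamic_range) ** 2,
            c2=(0.03 * dynamic_range) ** 2,
            dynamic_range=dynamic_range,
        )


def window_from_filament_width(width_mm: float, pitch_mm: float) -> int:
    """Window side length (odd px) matching the target filament diameter."""
    w = int(round(width_mm / pitch_mm))
    if w % 2 == 0:
        w += 1
    return max(w, 3)


@dataclass
class FidelityResult:
    ssim_map: np.ndarray
    mean_ssim: float
    params: SSIMParams
    round_index: int = 1
    z_mm: float = 0.0


def build_recon_full(
    dmap: DefectMap, recon: ReconstructedModelMap
) -> np.ndarray:
    """Evaluation field: reconstruction retained wherever the defect map is
    non-background (in-path states plus stringing), 0 elsewhere."""
    if dmap.grid.shape != recon.grid.shape:
        raise ValueError("defect map and reconstruction grids differ")
    keep = dmap.labels != DefectClass.BACKGROUND
    return np.where(keep, np.nan_to_num(recon.thickness_mm, nan=0.0), 0.0)


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    params: SSIMParams | None = None,
    *,
    support: np.ndarray | None = None,
    round_index: int = 1,
    z_mm: float = 0.0,
) -> FidelityResult:
    """Windowed SSIM map and its mean.

    Local means, variances and covariance are box-filtered with symmetric
    padding. The mean is taken over the full grid unless ``support``
    restricts it.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("fields must share shape")
    if params is None:
        rng = float(max(x.max(), y.max(), 1e-12))
        params = SSIMParams.for_range(rng)
    if params.window_px > min(x.shape):
        raise ValueError("window larger than image")

    def box(a: np.ndarray) -> np.ndarray:
        return uniform_filter(a, size=params.window_px, mode="reflect")

    mu_x = box(x)
    mu_y = box(y)
    # population moments within each window
    var_x = box(x * x) - mu_x * mu_x
    var_y = box(y * y) - mu_y * mu_y
    cov = box(x * y) - mu_x * mu_y
    c1, c2 = params.c1, params.c2
    ssim_map = ((2 * mu_x * mu_y + c1) * (2 * cov + c2)) / (
        (mu_x * mu_x + mu_y * mu_y + c1) * (var_x + var_y + c2)
    )
    mean = float(ssim_map[support].mean()) if support is not None else float(ssim_map.mean())
    return FidelityResult(
        ssim_map=ssim_map, mean_ssim=mean, params=params,
        round_index=round_index, z_mm=z_mm,
    )


def layer_fidelity(
    target: TargetModelMap,
    evaluation_field: np.ndarray,
    *,
    window_px: int | None = None,
    round_index: int = 1,
) -> FidelityResult:
    """Fidelity of one layer: SSIM between the target thickness map and the
    defect-masked reconstruction, window sized to the filament diameter."""
    widths = target.target_width[target.path_mask]
    width = float(widths.mean()) if widths.size else 0.41
    if window_px is None:
        window_px = window_from_filament_width(width, target.grid.pitch)
    rng = float(max(target.target_thickness.max(), evaluation_field.max(), 1e-12))
    params = SSIMParams.for_range(rng, window_px=window_px)
    return ssim(
        target.target_thickness,
        evaluation_field,
        params,
        round_index=round_index,
        z_mm=target.z_mm,
    )


def fidelity_series(results: list[FidelityResult]) -> tuple[pd.DataFrame, dict]:
    """Per-layer fidelity table plus a mean +/- sd summary.

    A single layer reports sd 0.0 by convention.
    """
    if not results:
        raise ValueError("at least one layer required")
    df = pd.DataFrame(
        {
            "round": [r.round_index for r in results],
            "z_mm": [r.z_mm for r in results],
            "mean_ssim": [r.mean_ssim for r in results],
        }
    )
    vals = df["mean_ssim"].to_numpy()
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    summary = {
        "n_layers": int(len(vals)),
        "fidelity_mean": float(vals.mean()),
        "fidelity_sd": sd,
        "fidelity_sem": sd / np.sqrt(len(vals)) if len(vals) > 1 else 0.0,
    }
    return df, summary
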