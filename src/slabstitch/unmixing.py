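"""Linear two-channel unmixing: scaled subtraction of autofluorescence.

Tissue autofluorescence is broadband, so a dedicated autofluorescence
channel captures it essentially pure; the labeled-protein channel records
signal plus a bleed-through fraction of the same texture.  Subtracting the
autofluorescence channel (scaled by ``alpha``) from the signal channel
recovers the label.  The subtraction runs in a signed intermediate and is
clamped at ``clamp_floor`` — never unsigned wraparound.

``alpha`` defaults to 1 (plain channel subtraction, the conventional
image-calculator operation).  :func:`estimate_alpha` is an optional
calibration extra that fits the bleed-through scale as a least-squares
slope over label-free voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from slabstitch.volume_core import DTYPE_MAX, Volume, clamp_to_dtype


class UnmixError(ValueError):
    """Raised for incompatible channel pairs or unidentifiable calibration."""


@dataclass(frozen=True)
class UnmixParams:
    """Scale applied to the autofluorescence channel before subtraction."""

    alpha: float = 1.0
    clamp_floor: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise UnmixError(f"alpha must be finite and >= 0, got {self.alpha}")
        if not (0 <= self.clamp_floor <= DTYPE_MAX):
            raise UnmixError(f"clamp_floor must be within [0, {DTYPE_MAX}], got {self.clamp_floor}")


def unmix(signal: Volume, autofluor: Volume, params: UnmixParams = UnmixParams()) -> Volume:
    """Per-voxel ``max(clamp_floor, signal - alpha * autofluor)``, rounded to uint16."""
    if signal.shape != autofluor.shape:
        raise UnmixError(f"shape mismatch: signal {signal.shape} vs autofluorescence {autofluor.shape}")
    if signal.voxel_size_um != autofluor.voxel_size_um:
        raise UnmixError(
            f"voxel size mismatch: {signal.voxel_size_um} vs {autofluor.voxel_size_um}"
        )
    diff = signal.data.astype(np.float64) - params.alpha * autofluor.data.astype(np.float64)
    out = clamp_to_dtype(np.maximum(diff, params.clamp_floor))
    return signal.with_data(out, channel="unmixed")


def estimate_alpha(signal: Volume, autofluor: Volume, background_mask: np.ndarray) -> float:
    """Least-squares bleed-through scale over label-free (background) voxels.

    Fits ``alpha = argmin sum_mask (signal - alpha * autofluor)^2`` —
    i.e. the no-intercept regression slope of signal on autofluorescence
    restricted to the mask — truncated at zero.  Requires the masked
    autofluorescence to be nonconstant, else the slope is unidentifiable.
    """
    if signal.shape != autofluor.shape or background_mask.shape != signal.shape:
        raise UnmixError("signal, autofluorescence and mask must share one shape")
    mask = background_mask.astype(bool)
    if mask.sum() < 10:
        raise UnmixError(f"background mask has {int(mask.sum())} voxels; >= 10 required")
    s = signal.data[mask].astype(np.float64)
    a = autofluor.data[mask].astype(np.float64)
    if np.ptp(a) == 0:
        raise UnmixError("alpha unidentifiable: autofluorescence constant under the mask")
    denom = float(np.dot(a, a))
    if denom == 0:
        raise UnmixError("alpha unidentifiable: autofluorescence is zero under the mask")
    return max(0.0, float(np.dot(s, a) / denom))
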