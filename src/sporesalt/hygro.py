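"""Hygroscopic growth factors from hydration microscopy.

Two independent routes:

* **Area growth factor** (environmental SEM): a particle is imaged dry and
  again at high relative humidity; each frame is thresholded (Otsu), the
  largest connected component is taken as the particle, and the growth
  factor is the ratio of wet-to-dry *area-equivalent diameters*
  ``d = 2 sqrt(A / π)``.

* **Mass growth factor** (STXM at the oxygen absorption edge): transmitted
  intensity maps are converted to per-pixel optical density via
  Beer–Lambert, ``OD = −ln(I / I0)``; at an element's edge the integrated
  OD over the particle is proportional to that element's mass, so the
  growth factor is the wet/dry ratio of integrated OD over the particle
  mask (union of dry and wet masks, so water taken up beyond the dry
  boundary is counted).

Both factors equal 1 for identical states by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import tifffile
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops


@dataclass
class HydrationPair:
    """Dry/wet grayscale frame pair from an ESEM hydration experiment."""

    frame_dry: np.ndarray
    frame_wet: np.ndarray
    rh_dry: float
    rh_wet: float
    pixel_size_um: float = 0.1

    def __post_init__(self) -> None:
        self.frame_dry = np.asarray(self.frame_dry, dtype=float)
        self.frame_wet = np.asarray(self.frame_wet, dtype=float)
        if self.frame_dry.shape != self.frame_wet.shape:
            raise ValueError("dry and wet frames must share a shape")
        if not self.rh_wet > self.rh_dry:
            raise ValueError("rh_wet must exceed rh_dry")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class ODMap:
    """Per-pixel optical density derived from a transmission map.

    ``od`` is computed lazily from ``intensity`` and ``i0`` when not given;
    pixels with nonpositive intensity are invalid (NaN) and never enter
    integrals.  ``mask`` marks particle pixels; when absent it is derived
    by Otsu thresholding of the OD map.
    """

    intensity: np.ndarray
    i0: float | np.ndarray = 1.0
    mask: np.ndarray | None = None
    od: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.od is None:
            self.od = optical_density(self.intensity, self.i0)
        else:
            self.od = np.asarray(self.od, dtype=float)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.od.shape:
                raise ValueError("mask and map must share a shape")

    def particle_mask(self) -> np.ndarray:
        if self.mask is not None:
            return self.mask
        od = np.nan_to_num(self.od, nan=0.0)
        thresh = threshold_otsu(od)
        return od > thresh

    def integrated_od(self, mask: np.ndarray | None = None) -> float:
        """Sum of OD over the particle mask, ignoring invalid pixels."""
        m = self.particle_mask() if mask is None else np.asarray(mask, bool)
        vals = self.od[m]
        return float(np.nansum(vals))


@dataclass
class GrowthResult:
    """Growth factors for one dry/wet pair."""

    gf_area: float | None = None
    gf_mass: float | None = None
    area_ratio: float | None = None  # = gf_area**2, reported for transparency
    rh_pair: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# segmentation and geometry
# ---------------------------------------------------------------------------

def detect_particle(frame: np.ndarray, pixel_size_um: float = 0.1,
                    threshold: float | None = None) -> tuple[np.ndarray, float]:
    """Segment the largest bright particle in a frame.

    Otsu's criterion picks the threshold unless one is given; the largest
    connected foreground component is the particle.  Returns the boolean
    mask and the projected area in µm² (pixel count × pixel size²).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    if threshold is None:
        if np.ptp(frame) == 0:
            raise ValueError("uniform frame: no foreground to segment")
        threshold = threshold_otsu(frame)
    fg = frame > threshold
    if not fg.any():
        raise ValueError("no foreground pixels above threshold")
    labels = label(fg)
    regions = regionprops(labels)
    largest = max(regions, key=lambda r: r.area)
    mask = labels == largest.label
    area = float(mask.sum()) * pixel_size_um ** 2
    return mask, area


def area_equivalent_diameter(area_um2: float) -> float:
    """Diameter of the circle with the same projected area: ``2 sqrt(A/π)``."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    return 2.0 * math.sqrt(area_um2 / math.pi)


def area_growth_factor(pair: HydrationPair) -> GrowthResult:
    """Wet/dry area-equivalent diameter ratio from an ESEM frame pair."""
    _, a_dry = detect_particle(pair.frame_dry, pair.pixel_size_um)
    _, a_wet = detect_particle(pair.frame_wet, pair.pixel_size_um)
    d_dry = area_equivalent_diameter(a_dry)
    d_wet = area_equivalent_diameter(a_wet)
    return GrowthResult(gf_area=d_wet / d_dry, area_ratio=a_wet / a_dry,
                        rh_pair=(pair.rh_dry, pair.rh_wet))


# ---------------------------------------------------------------------------
# Beer–Lambert optical density
# ---------------------------------------------------------------------------

def optical_density(intensity: np.ndarray, i0: float | np.ndarray) -> np.ndarray:
    """Per-pixel ``OD = −ln(I / I0)``; nonpositive I yields NaN (invalid)."""
    i0_arr = np.asarray(i0, dtype=float)
    if np.any(i0_arr <= 0):
        raise ValueError("reference intensity i0 must be positive")
    intensity = np.asarray(intensity, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        od = -np.log(intensity / i0_arr)
    od = np.where(intensity > 0, od, np.nan)
    return od


def estimate_i0(intensity: np.ndarray, border_px: int = 5) -> float:
    """Reference intensity from a particle-free border: median of the
    outermost ``border_px`` pixels of the frame."""
    intensity = np.asarray(intensity, dtype=float)
    b = border_px
    border = np.concatenate([
        intensity[:b].ravel(), intensity[-b:].ravel(),
        intensity[b:-b, :b].ravel(), intensity[b:-b, -b:].ravel(),
    ])
    return float(np.median(border))


def mass_growth_factor(dry: ODMap, wet: ODMap) -> GrowthResult:
    """Wet/dry ratio of integrated OD over the union particle mask.

    The union of the dry and wet masks is used so that condensed water at
    the particle margin counts toward the wet mass; background noise
    outside it never enters either integral.
    """
    mask = dry.particle_mask() | wet.particle_mask()
    if not mask.any():
        raise ValueError("empty particle mask")
    od_dry = dry.integrated_od(mask)
    od_wet = wet.integrated_od(mask)
    if od_dry <= 0:
        raise ValueError("zero dry OD integral")
    return GrowthResult(gf_mass=od_wet / od_dry)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_frame(path) -> np.ndarray:
    """Read a single-channel TIFF frame as float."""
    return np.asarray(tifffile.imread(path), dtype=float)


def write_frame(path, frame: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(frame, dtype=np.float32))
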