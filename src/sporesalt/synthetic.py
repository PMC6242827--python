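"""Synthetic inputs for every pipeline stage.

Generates (i) single-particle composition/morphology tables emulating
CC-SEM/EDX output for MOUDI impactor stages, (ii) dry/wet ESEM frame pairs
and STXM transmission-map pairs for the hygroscopicity stage, and
(iii) daily/hourly spore and sea-salt mass-concentration series emulating
chemistry-transport model output for the budget stage.  Everything is
driven by ``numpy.random.default_rng`` so a fixed seed reproduces outputs
bit for bit.

The per-class composition profiles are *calibration choices*, not measured
data: per-element means and spreads are set so that the shipped default
mixtures, when pushed through the rule-based classifier, recover the
configured number fractions to within binomial sampling error.  The
fungal-spore profile carries more Cl than Na by weight (NaCl is 61 wt% Cl),
so roughly half of spores exceed the 3 wt% sodium detection limit while Na
is rarely their dominant non-CNO element.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ELEMENTS, MORPHOLOGIES, weight_to_atomic
from .hygro import HydrationPair, ODMap

# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass
class ClassProfile:
    """Sampling distribution of one particle class.

    ``element_means``/``element_sds`` are per-element *weight* fraction
    parameters; draws are truncated at zero and renormalized to sum to 1,
    then converted to atomic fractions for storage (the inverse of the
    classifier's atomic-to-weight conversion).  Sizes are lognormal in the
    area-equivalent diameter.
    """

    class_label: str
    element_means: Mapping[str, float]
    element_sds: Mapping[str, float]
    morphology_dist: Mapping[str, float]
    size_median_um: float
    size_gsd: float

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.element_means.values()):
            raise ValueError("element means must be nonnegative")
        if sum(self.element_means.values()) > 1.0 + 1e-9:
            raise ValueError("element means must sum to at most 1")
        unknown = set(self.element_means) - set(ELEMENTS)
        if unknown:
            raise ValueError(f"unknown elements in profile: {sorted(unknown)}")
        bad = set(self.morphology_dist) - set(MORPHOLOGIES)
        if bad:
            raise ValueError(f"unknown morphologies: {sorted(bad)}")
        if not math.isclose(sum(self.morphology_dist.values()), 1.0, abs_tol=1e-9):
            raise ValueError("morphology distribution must sum to 1")
        if self.size_median_um <= 0 or self.size_gsd < 1.0:
            raise ValueError("size median must be > 0 and GSD >= 1")


@dataclass
class GeneratorConfig:
    """Configuration of one particle-table draw."""

    n_particles: int
    mixture: Mapping[str, float]
    stage_range_um: tuple[float, float] = (1.0, 3.2)
    canopy: str = "above"
    period: str = "night"
    seed: int = 0
    edge_prob: float = 0.07  # Cu-mesh edge particles, typically 5-10%

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture must sum to 1 (got {total!r})")
        if self.canopy not in ("above", "below"):
            raise ValueError("canopy must be 'above' or 'below'")
        if self.period not in ("day", "night"):
            raise ValueError("period must be 'day' or 'night'")


@dataclass
class SeriesConfig:
    """Configuration of a concentration time series.

    Medians in µg m⁻³; geometric SDs dimensionless (1 = no variability).
    ``diurnal_amplitude`` is the nighttime/daytime spore concentration
    ratio; ``scavenging_prob`` the daily probability that a precipitation
    event multiplies sea salt by ``scavenging_factor``.  Wet-season sea
    salt medians are scaled down by ``wet_seasalt_multiplier`` relative to
    the base median, emulating stronger wet removal of marine aerosol.
    """

    n_days: int = 180
    season: str = "wet"
    spore_lognormal: tuple[float, float] = (1.0, 2.0)
    seasalt_lognormal: tuple[float, float] = (0.30, 2.5)
    diurnal_amplitude: float = 2.0
    scavenging_prob: float = 0.25
    scavenging_factor: float = 0.2
    wet_seasalt_multiplier: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.season not in ("wet", "dry"):
            raise ValueError("season must be 'wet' or 'dry'")
        for name in ("spore_lognormal", "seasalt_lognormal"):
            med, gsd = getattr(self, name)
            if med <= 0:
                raise ValueError(f"{name} median must be positive")
            if gsd < 1.0:
                raise ValueError(f"{name} geometric SD must be >= 1")
        if self.diurnal_amplitude <= 0:
            raise ValueError("diurnal amplitude must be positive")
        if not 0.0 <= self.scavenging_prob <= 1.0:
            raise ValueError("scavenging probability must be in [0, 1]")


# ---------------------------------------------------------------------------
# shipped calibration profiles and mixtures
# ---------------------------------------------------------------------------

def _profile(label, means, sds, morph, median, gsd) -> ClassProfile:
    return ClassProfile(label, means, sds, morph, median, gsd)


#: Calibrated per-class composition profiles (weight-fraction parameters).
#: Calibration choices, not measured data — see module docstring.
DEFAULT_PROFILES: dict[str, ClassProfile] = {
    "na_rich": _profile(
        "na_rich",
        {"C": 0.33, "N": 0.02, "O": 0.22, "Na": 0.22, "Cl": 0.12,
         "Mg": 0.02, "S": 0.02, "K": 0.02},
        {"C": 0.04, "N": 0.005, "O": 0.03, "Na": 0.03, "Cl": 0.02,
         "Mg": 0.005, "S": 0.005, "K": 0.005},
        {"spherical": 0.3, "irregular": 0.4, "aggregate": 0.3},
        1.8, 1.5),
    "dust": _profile(
        "dust",
        {"O": 0.45, "Si": 0.18, "Al": 0.08, "Fe": 0.05, "C": 0.15,
         "K": 0.02, "Mg": 0.02, "Na": 0.01},
        {"O": 0.04, "Si": 0.04, "Al": 0.02, "Fe": 0.02, "C": 0.03,
         "K": 0.005, "Mg": 0.005, "Na": 0.005},
        {"irregular": 0.7, "aggregate": 0.3},
        2.0, 1.6),
    "mixed_bio_dust": _profile(
        "mixed_bio_dust",
        {"C": 0.40, "N": 0.05, "O": 0.25, "P": 0.02, "K": 0.02,
         "Na": 0.015, "Al": 0.04, "Si": 0.05, "Fe": 0.02, "Mg": 0.01},
        {"C": 0.04, "N": 0.01, "O": 0.03, "P": 0.005, "K": 0.005,
         "Na": 0.005, "Al": 0.01, "Si": 0.01, "Fe": 0.005, "Mg": 0.003},
        {"irregular": 0.5, "aggregate": 0.5},
        2.2, 1.5),
    "fungal_spore": _profile(
        "fungal_spore",
        {"C": 0.50, "N": 0.06, "O": 0.26, "Na": 0.030, "Mg": 0.008,
         "P": 0.020, "S": 0.012, "Cl": 0.055, "K": 0.018},
        {"C": 0.04, "N": 0.01, "O": 0.03, "Na": 0.010, "Mg": 0.002,
         "P": 0.004, "S": 0.003, "Cl": 0.010, "K": 0.004},
        {"spherical": 0.4, "rod-like": 0.3, "spheroidal": 0.3},
        2.2, 1.3),
    "sulfate": _profile(
        "sulfate",
        {"S": 0.14, "O": 0.45, "C": 0.25, "N": 0.08, "Na": 0.01,
         "K": 0.01, "Mg": 0.01},
        {"S": 0.02, "O": 0.04, "C": 0.03, "N": 0.01, "Na": 0.003,
         "K": 0.003, "Mg": 0.003},
        {"spherical": 0.6, "irregular": 0.4},
        1.4, 1.5),
    "carbonaceous": _profile(
        "carbonaceous",
        {"C": 0.65, "O": 0.30, "N": 0.03, "S": 0.01, "K": 0.005},
        {"C": 0.03, "O": 0.02, "N": 0.005, "S": 0.003, "K": 0.002},
        {"irregular": 0.5, "aggregate": 0.5},
        1.5, 1.6),
}

#: Default coarse-mode (stage 4-5) class mixture; the Na-rich, sulfate and
#: carbonaceous fractions are the reported coarse-mode number fractions,
#: the remainder split between dust and fungal spores.
COARSE_MIXTURE: dict[str, float] = {
    "na_rich": 0.48, "dust": 0.25, "fungal_spore": 0.19,
    "sulfate": 0.05, "carbonaceous": 0.03,
}

#: Below-canopy mixture: biological (fungal spore) number fraction 60%.
BELOW_CANOPY_MIXTURE: dict[str, float] = {
    "fungal_spore": 0.60, "na_rich": 0.20, "dust": 0.12,
    "sulfate": 0.05, "carbonaceous": 0.03,
}


# ---------------------------------------------------------------------------
# particle tables
# ---------------------------------------------------------------------------

def _stage_label(stage_range_um: tuple[float, float]) -> str:
    lo, hi = stage_range_um
    if (lo, hi) == (1.0, 3.2):
        return "4-5"
    if (lo, hi) == (0.32, 1.0):
        return "6-7"
    return f"{lo}-{hi}"


def gen_particle_table(config: GeneratorConfig,
                       profiles: Mapping[str, ClassProfile] | None = None
                       ) -> pd.DataFrame:
    """Draw a single-particle table.

    One row per particle with metadata, true generating class, morphology,
    area-equivalent diameter/area, grid-edge flag, and one atomic-fraction
    column per element.  Composition is drawn as weight fractions
    (truncated-normal, renormalized), then converted to atomic fractions —
    the inverse of the classifier's conversion.
    """
    profiles = DEFAULT_PROFILES if profiles is None else profiles
    missing = set(config.mixture) - set(profiles)
    if missing:
        raise KeyError(f"mixture references unknown class(es): {sorted(missing)}")
    rng = np.random.default_rng(config.seed)
    labels = sorted(config.mixture)
    probs = np.array([config.mixture[c] for c in labels])
    assigned = rng.choice(len(labels), size=config.n_particles, p=probs)

    rows = []
    for i, ci in enumerate(assigned):
        prof = profiles[labels[ci]]
        els = sorted(prof.element_means)
        draws = rng.normal([prof.element_means[e] for e in els],
                           [prof.element_sds[e] for e in els])
        draws = np.clip(draws, 0.0, None)
        total = draws.sum()
        if total <= 0:  # vanishing-probability guard
            draws = np.array([prof.element_means[e] for e in els])
            total = draws.sum()
        weights = dict(zip(els, draws / total))
        atomic = weight_to_atomic(weights)
        morphs = sorted(prof.morphology_dist)
        morph = morphs[rng.choice(len(morphs),
                                  p=[prof.morphology_dist[m] for m in morphs])]
        d = float(rng.lognormal(math.log(prof.size_median_um),
                                math.log(prof.size_gsd)))
        row = {
            "particle_id": i,
            "true_class": prof.class_label,
            "canopy": config.canopy,
            "period": config.period,
            "stage": _stage_label(config.stage_range_um),
            "morphology": morph,
            "diameter_um": d,
            "area_um2": math.pi / 4.0 * d * d,
            "on_grid_edge": bool(rng.random() < config.edge_prob),
        }
        row.update({el: atomic.get(el, 0.0) for el in ELEMENTS})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hydration imagery
# ---------------------------------------------------------------------------

def _shape_mask(shape: str, radius_px: float, side: int) -> np.ndarray:
    """Analytic filled shape centered in a ``side``×``side`` frame."""
    c = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    x, y = xx - c, yy - c
    r = radius_px
    if shape == "spherical":
        return x * x + y * y <= r * r
    if shape == "spheroidal":  # 1.4:1 ellipse, minor semi-axis r
        return (x / (1.4 * r)) ** 2 + (y / r) ** 2 <= 1.0
    if shape == "rod-like":  # capsule: half-length 1.5r, cap radius 0.5r
        hx = np.clip(x, -1.5 * r, 1.5 * r)
        return (x - hx) ** 2 + y * y <= (0.5 * r) ** 2
    raise ValueError(f"unsupported shape {shape!r}")


def gen_hydration_pair(gf_diameter: float, shape: str = "spherical",
                       noise_sd: float = 0.0, seed: int = 0,
                       dry_radius_px: float = 22.0,
                       pixel_size_um: float = 0.1,
                       rh_dry: float = 30.0, rh_wet: float = 94.0,
                       ) -> HydrationPair:
    """Dry/wet ESEM frame pair with a known diameter growth factor.

    The wet particle is the dry shape with every linear dimension scaled by
    ``gf_diameter``, so its projected area is the dry area × gf².  Frames
    are bright particle (0.8) on dark background (0.2) plus optional
    Gaussian noise.
    """
    if gf_diameter < 1.0:
        raise ValueError("gf_diameter must be >= 1")
    rng = np.random.default_rng(seed)
    extent = 1.6 * dry_radius_px * gf_diameter  # widest supported aspect
    side = 2 * (int(math.ceil(extent)) + 8)
    frames = []
    for scale in (1.0, gf_diameter):
        mask = _shape_mask(shape, dry_radius_px * scale, side)
        frame = 0.2 + 0.6 * mask.astype(float)
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, frame.shape)
        frames.append(frame)
    return HydrationPair(frames[0], frames[1], rh_dry, rh_wet, pixel_size_um)


def gen_stxm_pair(mass_ratio: float, seed: int = 0,
                  dry_radius_px: float = 18.0, area_gf: float = 1.3,
                  od_peak: float = 1.2, i0: float = 1000.0,
                  noise_sd: float = 0.0) -> tuple[ODMap, ODMap]:
    """Dry/wet STXM transmission-map pair with a known integrated-OD ratio.

    Both maps carry a hemispherical OD profile; the wet amplitude is scaled
    so that its pixel-summed OD equals exactly ``mass_ratio`` times the dry
    integral.  Intensities obey ``I = I0 exp(−OD)`` pixelwise.
    """
    if mass_ratio < 1.0:
        raise ValueError("mass_ratio must be >= 1")
    rng = np.random.default_rng(seed)
    r_wet = dry_radius_px * area_gf
    side = 2 * (int(math.ceil(r_wet)) + 6)
    c = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    rho = np.hypot(xx - c, yy - c)

    def dome(radius, peak):
        inside = rho <= radius
        od = np.zeros((side, side))
        od[inside] = peak * np.sqrt(1.0 - (rho[inside] / radius) ** 2)
        return od, inside

    od_dry, mask_dry = dome(dry_radius_px, od_peak)
    od_wet, mask_wet = dome(r_wet, 1.0)
    od_wet *= mass_ratio * od_dry.sum() / od_wet.sum()

    maps = []
    for od, mask in ((od_dry, mask_dry), (od_wet, mask_wet)):
        intensity = i0 * np.exp(-od)
        if noise_sd > 0:
            intensity = intensity + rng.normal(0.0, noise_sd * i0, od.shape)
        maps.append(ODMap(intensity=intensity, i0=i0, mask=mask))
    return maps[0], maps[1]


# ---------------------------------------------------------------------------
# concentration series
# ---------------------------------------------------------------------------

def gen_concentration_series(config: SeriesConfig, hourly: bool = False,
                             cell_id: int = 0,
                             seasalt_multiplier: float = 1.0) -> pd.DataFrame:
    """Spore and sea-salt mass-concentration series.

    Daily values are lognormal draws around the configured medians; the
    wet-season sea-salt median is scaled down and daily Bernoulli
    scavenging events deplete sea salt further.  With ``hourly=True`` the
    spore series gets a square-wave diurnal cycle: nighttime (18:00–06:00)
    concentrations exceed daytime ones by ``diurnal_amplitude`` while
    preserving the daily mean.
    """
    rng = np.random.default_rng(config.seed)
    start = "2015-01-01" if config.season == "wet" else "2015-07-01"
    dates = pd.date_range(start, periods=config.n_days, freq="D")

    med_s, gsd_s = config.spore_lognormal
    med_ss, gsd_ss = config.seasalt_lognormal
    if config.season == "wet":
        med_ss = med_ss * config.wet_seasalt_multiplier
    med_ss = med_ss * seasalt_multiplier

    spore = rng.lognormal(math.log(med_s), math.log(gsd_s), config.n_days)
    seasalt = rng.lognormal(math.log(med_ss), math.log(gsd_ss), config.n_days)
    scavenged = rng.random(config.n_days) < config.scavenging_prob
    seasalt = np.where(scavenged, seasalt * config.scavenging_factor, seasalt)

    if not hourly:
        return pd.DataFrame({
            "date": dates, "hour": pd.array([pd.NA] * config.n_days, dtype="Int64"),
            "cell_id": cell_id, "spore_ugm3": spore, "seasalt_ugm3": seasalt,
            "season": config.season,
        })

    amp = config.diurnal_amplitude
    day_level = 2.0 / (1.0 + amp)   # preserves the daily mean
    night_level = amp * day_level
    hours = np.arange(24)
    is_night = (hours >= 18) | (hours < 6)
    factor = np.where(is_night, night_level, day_level)
    rows = {
        "date": np.repeat(dates, 24),
        "hour": np.tile(hours, config.n_days),
        "cell_id": cell_id,
        "spore_ugm3": np.repeat(spore, 24) * np.tile(factor, config.n_days),
        "seasalt_ugm3": np.repeat(seasalt, 24),
        "season": config.season,
    }
    return pd.DataFrame(rows)


def gen_grid_series(n_cells: int, config: SeriesConfig,
                    gradient: Sequence[float] | None = None,
                    hourly: bool = False) -> pd.DataFrame:
    """One concentration series per grid cell, stacked.

    ``gradient`` multiplies each cell's sea-salt median (default 1
    everywhere).  Cell 0 with unit gradient is identical to
    :func:`gen_concentration_series` at the same seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if gradient is None:
        gradient = np.ones(n_cells)
    gradient = np.asarray(gradient, dtype=float)
    if gradient.shape != (n_cells,):
        raise ValueError("gradient length must equal n_cells")
    frames = []
    for i in range(n_cells):
        cfg = replace(config, seed=config.seed + i)
        frames.append(gen_concentration_series(
            cfg, hourly=hourly, cell_id=i, seasalt_multiplier=gradient[i]))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# number/mass conversion
# ---------------------------------------------------------------------------

def spore_mass_to_number(mass_ugm3, emission_diameter_um: float = 4.0,
                         density_g_cm3: float = 1.0):
    """Spore number concentration (m⁻³) from a mass concentration.

    Uses the fixed emission size: a 4 µm unit-density sphere weighs
    π/6·4³ ≈ 33.51 pg, so 1 µg m⁻³ ≈ 2.98×10⁴ spores m⁻³.
    """
    per_spore_pg = math.pi / 6.0 * emission_diameter_um ** 3 * density_g_cm3
    return np.asarray(mass_ugm3, dtype=float) * 1e6 / per_spore_pg
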