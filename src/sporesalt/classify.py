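"""Rule-based typing of single coarse-mode aerosol particles.

Computer-controlled SEM/EDX reports each detected particle as a vector of
elemental *atomic* fractions plus a projected area and an (externally
annotated) morphology label.  This module converts composition to weight
fractions, applies a configurable decision list to assign one composition
class per particle, flags fungal spores and sodium-containing particles,
and summarises group number fractions and size distributions.

The decision list mirrors the kind of scheme used in single-particle
microscopy studies of Amazonian aerosol:

1. ``na_rich``      — Na above the detection limit (3 wt% by default) and
                      the dominant element once C, N and O are set aside;
2. ``mixed_bio_dust`` — biological composition (carbonaceous with
                      phosphorus) carrying a crustal admixture (Al or Fe);
3. ``dust``         — crustal elements (Al + Si + Fe) above threshold,
                      where Si counts only when corroborated by Al or Fe
                      (bare Si is indistinguishable from substrate
                      background);
4. ``sulfate``      — S above threshold;
5. ``carbonaceous`` — essentially pure C/O;
6. ``other``        — everything else (the rule list is total).

The fungal-spore flag is independent of the composition class: a spore is a
particle with spore morphology (spherical, rod-like or spheroidal),
area-equivalent diameter 1–6 µm, carbonaceous composition (C+N+O ≥ 50 wt%)
and detectable phosphorus.  A sodium-containing spore therefore typically
*also* classifies as ``na_rich``; the two labels are cross-tabulated, never
forced disjoint.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

# IUPAC 2021 standard atomic weights, rounded to the precision EDX
# quantification warrants.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "Mg": 24.305,
    "Al": 26.982,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Fe": 55.845,
    "Cu": 63.546,
}

#: Elements carried in composition vectors.  Cu is excluded up front: the
#: particles sit on Cu mesh grids and any Cu signal is substrate background.
ELEMENTS: tuple[str, ...] = (
    "C", "N", "O", "Na", "Mg", "Al", "Si", "P", "S", "Cl", "K", "Fe",
)

SPORE_MORPHOLOGIES: frozenset[str] = frozenset(
    {"spherical", "rod-like", "spheroidal"}
)

MORPHOLOGIES: tuple[str, ...] = (
    "spherical", "rod-like", "spheroidal", "irregular", "aggregate",
)

COMPOSITION_CLASSES: tuple[str, ...] = (
    "na_rich", "mixed_bio_dust", "dust", "sulfate", "carbonaceous", "other",
)


# ---------------------------------------------------------------------------
# composition conversions
# ---------------------------------------------------------------------------

def _check_elements(fractions: Mapping[str, float]) -> None:
    unknown = set(fractions) - set(ATOMIC_MASS)
    if unknown:
        raise KeyError(f"unknown element symbol(s): {sorted(unknown)}")


def atomic_to_weight(atomic_fractions: Mapping[str, float]) -> dict[str, float]:
    """Convert atomic (mole) fractions to weight fractions.

    ``w_i = a_i * M_i / sum_j a_j * M_j``.  Output sums to 1 whenever the
    input has any mass at all.
    """
    _check_elements(atomic_fractions)
    masses = {el: a * ATOMIC_MASS[el] for el, a in atomic_fractions.items()}
    total = sum(masses.values())
    if total <= 0:
        raise ValueError("atomic fractions carry no mass")
    return {el: m / total for el, m in masses.items()}


def weight_to_atomic(weight_fractions: Mapping[str, float]) -> dict[str, float]:
    """Inverse of :func:`atomic_to_weight`: ``a_i ∝ w_i / M_i``."""
    _check_elements(weight_fractions)
    moles = {el: w / ATOMIC_MASS[el] for el, w in weight_fractions.items()}
    total = sum(moles.values())
    if total <= 0:
        raise ValueError("weight fractions carry no mass")
    return {el: n / total for el, n in moles.items()}


# ---------------------------------------------------------------------------
# ruleset
# ---------------------------------------------------------------------------

@dataclass
class RuleSet:
    """Thresholds and precedence for the particle-type decision list.

    All thresholds are weight fractions in (0, 1).

    Parameters
    ----------
    na_min_wt
        Sodium detection limit; 0.03 corresponds to the 3 wt% minimum
        detection of the EDX quantification.
    crustal_min_wt
        Minimum Al+Si+Fe weight for the dust class.
    p_min_wt
        Minimum phosphorus weight for biological composition.
    cno_min_wt
        Minimum C+N+O weight for biological composition.
    s_min_wt
        Minimum sulfur weight for the sulfate class.
    spore_size_um
        Inclusive area-equivalent-diameter window for fungal spores (µm).
    crustal_corroboration_wt
        Si counts toward the crustal sum only if Al or Fe reaches this
        weight (guards against substrate-background Si).
    """

    na_min_wt: float = 0.03
    crustal_min_wt: float = 0.10
    p_min_wt: float = 0.005
    cno_min_wt: float = 0.50
    s_min_wt: float = 0.05
    spore_size_um: tuple[float, float] = (1.0, 6.0)
    crustal_corroboration_wt: float = 0.01
    carbonaceous_min_wt: float = 0.90

    def __post_init__(self) -> None:
        for name in ("na_min_wt", "crustal_min_wt", "p_min_wt",
                     "cno_min_wt", "s_min_wt", "crustal_corroboration_wt",
                     "carbonaceous_min_wt"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        lo, hi = self.spore_size_um
        if not 0 < lo < hi:
            raise ValueError(f"invalid spore size window {self.spore_size_um}")

    @classmethod
    def from_yaml(cls, path) -> "RuleSet":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "spore_size_um" in data:
            data["spore_size_um"] = tuple(data["spore_size_um"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["spore_size_um"] = list(self.spore_size_um)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


DEFAULT_RULES = RuleSet()


# ---------------------------------------------------------------------------
# per-particle rules
# ---------------------------------------------------------------------------

def _wt(weights: Mapping[str, float], el: str) -> float:
    return float(weights.get(el, 0.0))


def flag_sodium_containing(weights: Mapping[str, float],
                           rules: RuleSet = DEFAULT_RULES) -> bool:
    """True iff Na weight fraction reaches the detection limit (3 wt%)."""
    return _wt(weights, "Na") >= rules.na_min_wt


def _biological_composition(weights: Mapping[str, float],
                            rules: RuleSet) -> bool:
    cno = _wt(weights, "C") + _wt(weights, "N") + _wt(weights, "O")
    return cno >= rules.cno_min_wt and _wt(weights, "P") >= rules.p_min_wt


def flag_fungal_spore(weights: Mapping[str, float], morphology: str,
                      diameter_um: float,
                      rules: RuleSet = DEFAULT_RULES) -> bool:
    """Fungal-spore criterion: spore morphology, 1–6 µm, carbonaceous
    composition with detectable phosphorus."""
    lo, hi = rules.spore_size_um
    return (
        morphology in SPORE_MORPHOLOGIES
        and lo <= diameter_um <= hi
        and _biological_composition(weights, rules)
    )


def assign_composition_class(weights: Mapping[str, float],
                             rules: RuleSet = DEFAULT_RULES) -> str:
    """First matching rule of the decision list wins; rule 6 is total."""
    na = _wt(weights, "Na")
    if na >= rules.na_min_wt:
        non_cno_max = max(
            (_wt(weights, el) for el in weights if el not in ("C", "N", "O", "Na")),
            default=0.0,
        )
        if na >= non_cno_max:
            return "na_rich"
    al, si, fe = _wt(weights, "Al"), _wt(weights, "Si"), _wt(weights, "Fe")
    if _biological_composition(weights, rules) and (al + fe) >= 0.01:
        return "mixed_bio_dust"
    corroborated = (al >= rules.crustal_corroboration_wt
                    or fe >= rules.crustal_corroboration_wt)
    crustal = al + fe + (si if corroborated else 0.0)
    if crustal >= rules.crustal_min_wt:
        return "dust"
    if _wt(weights, "S") >= rules.s_min_wt:
        return "sulfate"
    if _wt(weights, "C") + _wt(weights, "O") >= rules.carbonaceous_min_wt:
        return "carbonaceous"
    return "other"


# ---------------------------------------------------------------------------
# table-level operations
# ---------------------------------------------------------------------------

def _weights_frame(records: pd.DataFrame) -> pd.DataFrame:
    """Weight-fraction columns for every element present in the table."""
    elements = [el for el in ELEMENTS if el in records.columns]
    if not elements:
        raise ValueError("particle table has no element columns")
    atomic = records[elements].to_numpy(dtype=float)
    masses = np.array([ATOMIC_MASS[el] for el in elements])
    mass = atomic * masses
    total = mass.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("particle(s) with zero total composition")
    return pd.DataFrame(mass / total, columns=elements, index=records.index)


def classify_table(records: pd.DataFrame,
                   rules: RuleSet = DEFAULT_RULES) -> pd.DataFrame:
    """Classify every particle of a table.

    ``records`` follows the particle-table schema: one column per element
    symbol holding atomic fractions, plus ``particle_id``, ``morphology``,
    ``diameter_um`` (and arbitrary metadata columns, which are passed
    through).

    Returns one row per particle with ``composition_class``,
    ``is_fungal_spore``, ``is_sodium_containing`` and its alias
    ``sodium_salt_particle``.
    """
    weights = _weights_frame(records)
    rows = weights.to_dict("records")
    out = pd.DataFrame(index=records.index)
    if "particle_id" in records.columns:
        out["particle_id"] = records["particle_id"]
    out["composition_class"] = [assign_composition_class(w, rules) for w in rows]
    out["is_fungal_spore"] = [
        flag_fungal_spore(w, m, d, rules)
        for w, m, d in zip(rows, records["morphology"], records["diameter_um"])
    ]
    out["is_sodium_containing"] = [flag_sodium_containing(w, rules) for w in rows]
    out["sodium_salt_particle"] = out["is_sodium_containing"]
    return out


def exclude_edge_particles(records: pd.DataFrame) -> pd.DataFrame:
    """Drop particles sitting on the grid edge (high substrate background)."""
    if "on_grid_edge" not in records.columns:
        return records
    flagged = records["on_grid_edge"].astype(bool)
    n = int(flagged.sum())
    if n:
        logger.info("excluded %d/%d edge particles", n, len(records))
    return records.loc[~flagged]


def group_number_fractions(results: pd.DataFrame,
                           group_keys: Sequence[str] = (),
                           label_col: str = "composition_class"
                           ) -> pd.DataFrame:
    """Number fraction of each label per group, with binomial standard error.

    ``fraction = k / n``; ``standard_error = sqrt(p (1 - p) / n)`` — the
    convention used for the ± values quoted alongside number fractions.
    Boolean flag columns work as labels too (groups of True/False).
    """
    group_keys = list(group_keys)
    if results.empty:
        warnings.warn("empty results table: no fractions computed")
        return pd.DataFrame(
            columns=group_keys + [label_col, "fraction", "standard_error", "n"])
    if group_keys:
        grouped = results.groupby(group_keys, observed=True, sort=True)
    else:
        grouped = [((), results)]
    out = []
    for key, grp in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        n = len(grp)
        counts = grp[label_col].value_counts()
        for label, k in counts.items():
            p = k / n
            se = math.sqrt(p * (1.0 - p) / n)
            out.append(dict(zip(group_keys, key),
                            **{label_col: label, "fraction": p,
                               "standard_error": se, "n": n}))
    return pd.DataFrame(out)


def size_distribution(records: pd.DataFrame,
                      results: pd.DataFrame | None = None,
                      class_label: str | None = None,
                      bin_edges: Sequence[float] = (0.32, 0.56, 1.0, 1.8, 3.2, 5.6, 10.0),
                      ) -> pd.DataFrame:
    """Diameter histogram, optionally restricted to one composition class.

    Returns per-bin counts and the log-normalized density dN/dlogD.  The
    default edges are geometric (quarter-decade), spanning the accumulation
    and coarse impactor stages.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing, length >= 2")
    d = records["diameter_um"]
    if class_label is not None:
        if results is None:
            raise ValueError("results table required to filter by class")
        mask = (results["composition_class"] == class_label).to_numpy()
        d = d[mask]
    counts, _ = np.histogram(d.to_numpy(dtype=float), bins=edges)
    dlogd = np.diff(np.log10(edges))
    return pd.DataFrame({
        "bin_lo_um": edges[:-1],
        "bin_hi_um": edges[1:],
        "count": counts,
        "dN_dlogD": counts / dlogd,
    })
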