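"""Avian fuel-load estimation from morphometrics.

Lean body mass is predicted from wing length via species- and
muscle-score-specific linear calibrations; relative energy stores (fuel
load) are the fractional surplus of body mass over lean body mass,

    stores = (body_mass - lean_body_mass) / lean_body_mass,

a dimensionless quantity that may be negative for birds below their
structural mass.  The calibrations cover the combinations that occur in
migrating common redstarts (CR) and European robins (ER) scored on the
Bairlein 0-3 pectoral-muscle scale; requesting any other combination is
an explicit error rather than an extrapolation.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Tuple

import numpy as np
import pandas as pd

#: (species, muscle score) -> (intercept [g], slope [g/mm]) of the
#: lean-body-mass ~ wing-length calibration.
LEAN_MASS_EQUATIONS: Mapping[Tuple[str, int], Tuple[float, float]] = {
    ("CR", 2): (6.69, 0.08),
    ("ER", 2): (2.48, 0.17),
    ("ER", 3): (2.77, 0.17),
}


class UnsupportedMorphometrics(ValueError):
    """No lean-body-mass calibration exists for this species/score pair."""


def lean_body_mass(species: str, muscle_score: int, wing_length: float) -> float:
    """Predicted lean body mass in g for one bird.

    Parameters
    ----------
    species : "CR" (common redstart) or "ER" (European robin).
    muscle_score : Bairlein pectoral-muscle score, 0-3.
    wing_length : maximum wing length in mm (positive).
    """
    if wing_length <= 0:
        raise ValueError(f"wing_length must be positive, got {wing_length}")
    key = (species, int(muscle_score))
    try:
        intercept, slope = LEAN_MASS_EQUATIONS[key]
    except KeyError:
        raise UnsupportedMorphometrics(
            f"no lean-body-mass equation for species={species!r}, "
            f"muscle score {muscle_score}; calibrated combinations are "
            f"{sorted(LEAN_MASS_EQUATIONS)}"
        ) from None
    return intercept + slope * float(wing_length)


def energy_stores(body_mass: float, lean_mass: float) -> float:
    """Relative energy stores (body_mass - lean)/lean; may be negative."""
    lean = np.asarray(lean_mass, dtype=float)
    if np.any(lean <= 0):
        raise ValueError("lean body mass must be positive")
    out = (np.asarray(body_mass, dtype=float) - lean) / lean
    return float(out) if out.ndim == 0 else out


def scale_within_species(values: Iterable[float], species: Iterable[str]) -> np.ndarray:
    """Per-species z-score (sample SD, n-1 denominator).

    Raises if any species has fewer than two birds or zero variance.
    """
    v = np.asarray(list(values), dtype=float)
    s = pd.Series(list(species))
    out = np.empty_like(v)
    for sp, idx in s.groupby(s).groups.items():
        ix = np.asarray(idx)
        if len(ix) < 2:
            raise ValueError(f"species {sp!r} has fewer than two birds; cannot scale")
        sd = v[ix].std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero within-species variance for species {sp!r}")
        out[ix] = (v[ix] - v[ix].mean()) / sd
    return out


def add_energy_columns(birds: pd.DataFrame) -> pd.DataFrame:
    """Append lean mass, energy stores and per-species scaled stores.

    Expects the capture-table column names ``Species``, ``Muscle``,
    ``Wing``, ``Bodymass``; returns a copy with ``lean_mass``,
    ``energy_stores`` and ``stores_scaled`` columns.
    """
    out = birds.copy()
    lean = np.array(
        [
            lean_body_mass(sp, ms, w)
            for sp, ms, w in zip(out["Species"], out["Muscle"], out["Wing"])
        ]
    )
    out["lean_mass"] = lean
    out["energy_stores"] = energy_stores(out["Bodymass"].to_numpy(dtype=float), lean)
    out["stores_scaled"] = scale_within_species(out["energy_stores"], out["Species"])
    return out
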