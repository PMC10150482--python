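"""Microcosm statistics: AWCD, temporal functional stability, and biomass
resistance.

AWCD (average well color development) summarises a Biolog EcoPlate as the
mean, over the 31 carbon substrates, of the blank-corrected optical density
(substrate mean minus blank mean, negatives truncated to 0). Temporal
functional stability is the inverse CV of AWCD across subculturings.
Biomass resistance to temperature stress follows the bounded Orwin-Wardle
index

    resistance = 1 - 2|D0| / (C0 + |D0|),

with C0 the undisturbed outcome (biomass at 20 C) and D0 the
disturbed-minus-control difference (15 C minus 20 C); 1 means no effect of
the disturbance and values approach -1 as the effect grows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import BiologPlate, DegenerateInputError, ValidationError
from .trait_stability import inverse_cv


def compute_awcd(plate: BiologPlate) -> float:
    """Mean blank-corrected OD over the 31 substrates (negatives -> 0)."""
    blank = float(plate.blank_od.mean())
    corrected = plate.substrate_od.mean(axis=1) - blank
    return float(np.clip(corrected, 0.0, None).mean())


def awcd_table(plates) -> pd.DataFrame:
    """AWCD for every plate, one row per (arm, replicate, subculture)."""
    rows = [
        {"arm": p.arm, "replicate": p.replicate,
         "subculture": p.subculture_index, "awcd": compute_awcd(p)}
        for p in plates
    ]
    return (pd.DataFrame(rows)
            .sort_values(["arm", "replicate", "subculture"])
            .reset_index(drop=True))


def temporal_stability(awcd_series, ddof: int = 0) -> float:
    """Inverse CV (mu/sigma, population sigma by default) of an AWCD series
    across subculturings. Requires >= 2 readings with nonzero spread."""
    a = np.asarray(awcd_series, dtype=float)
    if (a < 0).any():
        raise ValidationError("AWCD values must be >= 0")
    return inverse_cv(a, ddof=ddof)


def stability_table(awcd: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Temporal stability per (arm, replicate) AWCD trajectory.

    Trajectories with zero variance are flagged degenerate (stability NaN)
    rather than dropped, so callers can see which arms were flat.
    """
    rows = []
    for (arm, rep), grp in awcd.groupby(["arm", "replicate"], sort=True):
        series = grp.sort_values("subculture")["awcd"].to_numpy()
        try:
            stab = temporal_stability(series, ddof=ddof)
            degenerate = False
        except DegenerateInputError:
            stab, degenerate = float("nan"), True
        rows.append({"arm": arm, "replicate": rep, "n_subcultures": len(series),
                     "stability": stab, "degenerate": degenerate})
    return pd.DataFrame(rows)


def resistance(c0: float, disturbed: float) -> float:
    """Orwin-Wardle resistance of an outcome to disturbance, in (-1, 1].

    ``c0`` is the control outcome, ``disturbed`` the outcome under stress;
    D0 = disturbed - c0. Equals 1 iff D0 = 0 and decreases with |D0|.
    """
    if c0 <= 0:
        raise ValidationError(f"control outcome C0 must be > 0, got {c0}")
    d0 = disturbed - c0
    return 1.0 - (2.0 * abs(d0)) / (c0 + abs(d0))


def resistance_table(biomass: pd.DataFrame,
                     control_temperature: float = 20.0,
                     stress_temperature: float = 15.0) -> pd.DataFrame:
    """Per-well biomass resistance for each (system, resource) arm.

    Well means (the 4 seedlings per well are averaged) at the stress
    temperature are paired with control-temperature wells by replicate order
    within the arm; one resistance value per pair.
    """
    well_means = (biomass
                  .groupby(["system", "resource", "temperature", "well_id"],
                           sort=True)["biomass_mg"]
                  .mean()
                  .reset_index())
    rows = []
    for (system, resource), grp in well_means.groupby(["system", "resource"],
                                                      sort=True):
        control = grp[grp["temperature"] == control_temperature] \
            .sort_values("well_id")["biomass_mg"].to_numpy()
        stressed = grp[grp["temperature"] == stress_temperature] \
            .sort_values("well_id")["biomass_mg"].to_numpy()
        if control.size == 0 or stressed.size == 0:
            raise ValidationError(
                f"arm ({system}, {resource}) lacks one temperature group")
        n = min(control.size, stressed.size)
        for i in range(n):
            rows.append({"system": system, "resource": resource,
                         "pair_index": i + 1,
                         "c0": control[i], "disturbed": stressed[i],
                         "resistance": resistance(control[i], stressed[i])})
    return pd.DataFrame(rows)
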