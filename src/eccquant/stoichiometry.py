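"""Oligomer-aware stoichiometry of excitation-contraction-coupling proteins.

Mass spectrometry quantifies protomers; functional channels are oligomers
(the ryanodine receptor RyR1 is a homotetramer, the store-operated calcium
channel Orai1 a hexamer), so complex concentrations divide the monomer
concentration by the subunit count. Pairwise molar ratios, cross-muscle
percentages and the Langmuir fractional occupancy of the Stac3 binding site
on DHPRalpha1s are computed from those concentrations.

Two rounding modes are exposed throughout: ``full_precision`` keeps float
arithmetic; ``as_printed`` reproduces published-table conventions (complex
concentrations rounded to 2 decimals before ratios are formed), because
published ratio tables are computed from rounded entries (0.46/0.02 = 23.0,
whereas the unrounded value would be ~25).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MODE_FULL = "full_precision"
MODE_PRINTED = "as_printed"
_MODES = (MODE_FULL, MODE_PRINTED)

#: Marker used for ratios whose denominator protein was not detected.
NOT_DETECTED = "-"


@dataclass(frozen=True)
class OccupancyParams:
    """Dissociation-constant range (uM) and the tissue density (kg wet
    weight per litre) that equates umol/kg with uM."""

    kd_low: float = 2.0
    kd_high: float = 10.0
    density_kg_per_l: float = 1.0

    def __post_init__(self):
        if not 0 < self.kd_low <= self.kd_high:
            raise ValueError("require 0 < kd_low <= kd_high")
        if self.density_kg_per_l <= 0:
            raise ValueError("density must be > 0")


def _check_mode(mode: str) -> None:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def complex_concentration(
    monomer_conc: float, k: int, mode: str = MODE_FULL
) -> float:
    """Concentration of the assembled k-mer complex from its monomer pool.

    In ``as_printed`` mode the result is rounded to 2 decimal places, the
    convention of the published concentration table.
    """
    _check_mode(mode)
    if k < 1:
        raise ValueError("subunit count k must be >= 1")
    if monomer_conc < 0:
        raise ValueError("monomer concentration must be >= 0")
    value = monomer_conc / k
    return round(value, 2) if mode == MODE_PRINTED else value


def ratio(
    numer: float,
    denom: float,
    mode: str = MODE_FULL,
    decimals: int | None = None,
) -> float:
    """Molar ratio numer/denom.

    ``as_printed`` computes from inputs rounded to 2 decimals and rounds the
    result to ``decimals`` decimal places when given, else to 3 significant
    digits.
    """
    _check_mode(mode)
    if mode == MODE_PRINTED:
        numer, denom = round(numer, 2), round(denom, 2)
    if denom <= 0:
        raise ZeroDivisionError("ratio undefined for non-positive denominator")
    value = numer / denom
    if mode == MODE_PRINTED:
        value = round(value, decimals) if decimals is not None else _round_sig(value)
    return value


def percent_of_reference(value: float, reference: float) -> int:
    """100 * value / reference, rounded to the nearest integer percent."""
    if reference <= 0:
        raise ValueError("reference must be > 0")
    return int(math.floor(100.0 * value / reference + 0.5))


def fractional_occupancy(
    conc_umol_per_kg: float,
    kd_um: float,
    params: OccupancyParams | None = None,
) -> float:
    """Single-site Langmuir occupancy C / (C + Kd).

    The ligand concentration in umol/kg wet weight is converted to uM via
    the tissue density (default 1 kg/L, i.e. umol/kg == uM).
    """
    if kd_um <= 0:
        raise ValueError("kd must be > 0")
    if conc_umol_per_kg < 0:
        raise ValueError("concentration must be >= 0")
    density = params.density_kg_per_l if params is not None else 1.0
    c_um = conc_umol_per_kg * density
    return c_um / (c_um + kd_um)


def build_stoichiometry_report(
    concentrations: pd.DataFrame,
    oligomers: Mapping[str, int],
    pairs: Sequence[tuple[str, str] | tuple[str, str, int]],
    mode: str = MODE_FULL,
) -> pd.DataFrame:
    """Pairwise complex-level molar ratios, one row per pair x condition.

    ``concentrations`` is the output of
    :func:`eccquant.absolute.protein_concentration` (columns accession,
    condition, mean_umol_per_kg, detected). Oligomer subunit counts default
    to 1. Each pair is (numerator, denominator) with an optional third
    element giving the decimal places used in ``as_printed`` mode.
    Not-detected numerators or denominators yield ``"-"`` display entries
    with NaN ratio.
    """
    _check_mode(mode)
    conc = concentrations.set_index(["accession", "condition"])
    conditions = list(dict.fromkeys(concentrations["condition"]))
    rows = []
    for pair in pairs:
        numer_acc, denom_acc = pair[0], pair[1]
        decimals = pair[2] if len(pair) > 2 else None
        for cond in conditions:
            value: float = np.nan
            display = NOT_DETECTED
            try:
                n_row = conc.loc[(numer_acc, cond)]
                d_row = conc.loc[(denom_acc, cond)]
            except KeyError:
                n_row = d_row = None
            if (
                n_row is not None
                and bool(n_row["detected"])
                and bool(d_row["detected"])
            ):
                n_val = complex_concentration(
                    float(n_row["mean_umol_per_kg"]), oligomers.get(numer_acc, 1), mode
                )
                d_val = complex_concentration(
                    float(d_row["mean_umol_per_kg"]), oligomers.get(denom_acc, 1), mode
                )
                if d_val > 0:
                    # inputs already at complex level (and 2-dp rounded in
                    # as_printed mode), so only the output rounding remains
                    value = n_val / d_val
                    if mode == MODE_PRINTED:
                        value = (
                            round(value, decimals)
                            if decimals is not None
                            else _round_sig(value)
                        )
                    display = f"{value:g}"
            rows.append((numer_acc, denom_acc, cond, value, display, mode))
    return pd.DataFrame(
        rows,
        columns=["numerator", "denominator", "condition", "ratio", "display", "mode"],
    )


def occupancy_report(
    concentrations: pd.DataFrame,
    accession: str,
    params: OccupancyParams = OccupancyParams(),
) -> pd.DataFrame:
    """Fractional occupancy of a 1:1 site across conditions at both Kd bounds."""
    sub = concentrations[concentrations["accession"] == accession]
    rows = []
    for _, row in sub.iterrows():
        if not bool(row["detected"]):
            continue
        c = float(row["mean_umol_per_kg"])
        rows.append(
            (
                accession,
                row["condition"],
                c,
                fractional_occupancy(c, params.kd_low, params),
                fractional_occupancy(c, params.kd_high, params),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "condition", "umol_per_kg",
            "occupancy_kd_low", "occupancy_kd_high",
        ],
    )
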