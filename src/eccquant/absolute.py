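"""PRM/SID absolute quantification and the iBAQ calibration curve.

Quantification chain: light/heavy peak-area ratios are normalized by each
sample's total ion chromatogram (reference = mean TIC across samples), the
known heavy spike converts a ratio into fmol analyte per ug total peptide,
the peptide yield per wet-tissue mass converts that into umol per kg wet
weight, and the per-sample protein value is the log-scale median across the
protein's peptides, back-transformed. A log2-log2 linear calibration fitted
on proteins quantified both ways (PRM/SID vs iBAQ) extrapolates absolute
amounts for proteins measured only by iBAQ, flagging values outside the
fitted (linear) domain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, FitError, QuantificationError


def tic_normalize(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Normalize light/heavy ratios by per-sample TIC.

    The reference is the mean TIC across samples; each sample's ratio is
    multiplied by reference / sample_tic, so the mean of the factors
    weighted by TIC is exactly 1. Adds ``tic_factor`` and ``ratio`` columns
    and returns the per-sample factors.
    """
    tics = table.groupby("sample_id", sort=True)["sample_tic"].first()
    if (tics <= 0).any():
        bad = list(tics.index[tics <= 0])
        raise DataError(f"samples with non-positive TIC: {bad}")
    factors = (tics.mean() / tics).rename("factor")
    out = table.copy()
    out["tic_factor"] = out["sample_id"].map(factors).astype(float)
    heavy = out["heavy_area"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(heavy > 0, out["light_area"].to_numpy(dtype=float) / np.where(heavy > 0, heavy, 1.0), np.nan)
    out["ratio"] = raw * out["tic_factor"].to_numpy()
    return out, factors


def peptide_fmol_per_ug(light_area: float, heavy_area: float, spike_S: float) -> float:
    """fmol analyte per ug total peptide from a light/heavy area pair.

    A ratio of zero is a valid "below detection" value; a non-positive
    heavy area means the reference peptide itself was not measured and the
    peptide cannot be quantified.
    """
    if spike_S <= 0:
        raise ValueError("spike_S must be > 0")
    if heavy_area <= 0:
        raise QuantificationError("heavy reference area must be > 0")
    return (light_area / heavy_area) * spike_S


def _log_median(values: np.ndarray) -> float:
    """Median on the log scale, back-transformed.

    For an odd count this equals the ordinary median; for an even count it
    is the geometric mean of the two central values (0 if either is 0).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n % 2 == 1:
        return float(v[n // 2])
    a, b = v[n // 2 - 1], v[n // 2]
    if a <= 0 or b <= 0:
        return 0.0
    return float(np.sqrt(a * b))


def protein_concentration(
    table: pd.DataFrame,
    spike_S: float = 10.0,
    yield_Y: float = 64.5,
) -> pd.DataFrame:
    """Protein concentrations in umol/kg wet weight, mean +- SD across samples.

    Per sample, the protein value is the back-transformed log-scale median
    over its quantifiable peptides of fmol/ug = ratio * spike_S, converted
    via concentration = fmol/ug * yield_Y * 1e-3. Peptides without heavy
    signal are flagged and excluded; a protein with no quantifiable peptide
    in any sample is reported as not detected (NaN mean) rather than zero.

    Expects the ``ratio`` column produced by :func:`tic_normalize`.
    """
    if "ratio" not in table.columns:
        table, _ = tic_normalize(table)
    out_rows = []
    for (acc, cond), grp in table.groupby(["accession", "condition"], sort=True):
        per_sample = []
        for _, sample_grp in grp.groupby("sample_id", sort=True):
            ratios = sample_grp["ratio"].to_numpy(dtype=float)
            ratios = ratios[np.isfinite(ratios)]
            if ratios.size == 0:
                continue
            fmol_per_ug = _log_median(ratios * spike_S)
            per_sample.append(fmol_per_ug * yield_Y * 1e-3)
        if per_sample:
            vals = np.array(per_sample)
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            out_rows.append((acc, cond, mean, sd, vals.size, True))
        else:
            out_rows.append((acc, cond, np.nan, np.nan, 0, False))
    return pd.DataFrame(
        out_rows,
        columns=[
            "accession", "condition", "mean_umol_per_kg",
            "sd_umol_per_kg", "n_samples", "detected",
        ],
    )


@dataclass(frozen=True)
class CalibrationModel:
    """log2(concentration) = slope * log2(iBAQ) + intercept, with the
    anchor-spanned (linear) domain on the log2-iBAQ axis."""

    slope: float
    intercept: float
    r_squared: float
    domain: tuple[float, float]


@dataclass(frozen=True)
class Extrapolation:
    """An extrapolated absolute concentration; ``in_domain`` is False when
    the query iBAQ value falls outside the calibration's linear domain."""

    umol_per_kg: float
    in_domain: bool


def fit_calibration(anchors) -> CalibrationModel:
    """Ordinary least squares on (log2 iBAQ, log2 concentration) anchors."""
    arr = np.asarray(anchors, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise FitError("need at least 2 (log2_ibaq, log2_conc) anchors")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise FitError("anchors have zero spread on the iBAQ axis")
    fit = stats.linregress(x, y)
    ss_res = float(((y - (fit.slope * x + fit.intercept)) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        domain=(float(x.min()), float(x.max())),
    )


def extrapolate(model: CalibrationModel, log2_ibaq: float) -> Extrapolation:
    """Absolute concentration (umol/kg) predicted from a log2 iBAQ value."""
    value = float(2.0 ** (model.slope * log2_ibaq + model.intercept))
    in_domain = model.domain[0] <= log2_ibaq <= model.domain[1]
    return Extrapolation(umol_per_kg=value, in_domain=in_domain)
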