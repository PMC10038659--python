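"""Isobaric (TMT 10-plex) relative quantification and differential testing.

The processing chain mirrors the standard reporter-ion workflow: optional
isotope-impurity deconvolution, global normalization equalizing total
reporter intensity across channels, summation of intensities per protein and
channel, empirical-Bayes moderated t-statistics on log2 intensities, and
Benjamini-Hochberg FDR control.

A PSM table is a pandas DataFrame with columns ``accession``, ``peptide``
and one intensity column per channel (default channel names in
:data:`TMT10_CHANNELS`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConsistencyError, DataError, DesignError
from .proteins import ProteinDB, count_observable_peptides

logger = logging.getLogger(__name__)

#: Reporter channels of a TMT 10-plex kit, in mass order.
TMT10_CHANNELS: tuple[str, ...] = (
    "126", "127N", "127C", "128N", "128C",
    "129N", "129C", "130N", "130C", "131",
)


@dataclass(frozen=True)
class ChannelDesign:
    """Maps reporter channels to biological conditions.

    ``labels[i]`` is the condition of ``channels[i]``; ``condition1`` is the
    reference (denominator of reported ratios).
    """

    labels: tuple[str, ...]
    condition1: str = "WT"
    condition2: str = "dHT"
    channels: tuple[str, ...] = TMT10_CHANNELS

    def __post_init__(self):
        if len(self.labels) != len(self.channels):
            raise DesignError(
                f"{len(self.labels)} labels for {len(self.channels)} channels"
            )
        for cond in (self.condition1, self.condition2):
            if cond not in self.labels:
                raise DesignError(f"condition {cond!r} absent from design")

    def channels_of(self, condition: str) -> list[str]:
        return [c for c, l in zip(self.channels, self.labels) if l == condition]


#: Default 5-vs-5 design: channels 126-128C reference, 129N-131 comparison.
DEFAULT_DESIGN = ChannelDesign(labels=("WT",) * 5 + ("dHT",) * 5)


@dataclass(frozen=True)
class ModerationHyperparams:
    """Empirical-Bayes prior on residual variances: d0 prior degrees of
    freedom (``inf`` allowed) and s0_sq prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not self.d0 > 0:
            raise ValueError("d0 must be > 0")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be > 0")


def correct_reporters(
    table: pd.DataFrame,
    impurity: np.ndarray,
    channels: tuple[str, ...] = TMT10_CHANNELS,
) -> tuple[pd.DataFrame, int]:
    """Deconvolve channel cross-leakage.

    ``impurity[i, j]`` is the fraction of channel *j*'s signal observed in
    channel *i*; observed = impurity @ true. Solves the linear system per
    PSM row; negative solutions are clipped to zero and counted.

    Returns the corrected table and the number of clipped values.
    """
    impurity = np.asarray(impurity, dtype=float)
    k = len(channels)
    if impurity.shape != (k, k):
        raise ValueError(f"impurity matrix must be {k}x{k}")
    observed = table[list(channels)].to_numpy(dtype=float)
    try:
        corrected = np.linalg.solve(impurity, observed.T).T
    except np.linalg.LinAlgError as exc:
        raise DataError(f"impurity matrix is singular: {exc}") from exc
    n_clipped = int((corrected < 0).sum())
    if n_clipped:
        logger.warning("impurity correction clipped %d negative intensities", n_clipped)
        corrected = np.clip(corrected, 0.0, None)
    out = table.copy()
    out[list(channels)] = corrected
    return out, n_clipped


def normalize_channels(
    table: pd.DataFrame, channels: tuple[str, ...] = TMT10_CHANNELS
) -> tuple[pd.DataFrame, pd.Series]:
    """Equalize the total reporter intensity across channels.

    Each channel is scaled so that every channel total equals the mean
    pre-normalization total; the grand total is therefore conserved.
    Returns the scaled table and the per-channel factors.
    """
    cols = list(channels)
    totals = table[cols].sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise DataError(f"channels with non-positive total intensity: {bad}")
    factors = totals.mean() / totals
    out = table.copy()
    out[cols] = table[cols] * factors
    return out, factors.rename("factor")


def rollup(
    table: pd.DataFrame,
    db: ProteinDB,
    channels: tuple[str, ...] = TMT10_CHANNELS,
) -> pd.DataFrame:
    """Sum reporter intensities per protein and channel.

    Returns a DataFrame indexed by accession with the channel columns plus
    ``n_peptides`` (distinct peptide sequences) and ``ibaq`` (total summed
    intensity divided by the number of observable tryptic peptides).
    """
    unknown = set(table["accession"]) - set(db.accessions)
    if unknown:
        raise ConsistencyError(f"accessions not in database: {sorted(unknown)[:5]}")
    cols = list(channels)
    grouped = table.groupby("accession", sort=True)
    quants = grouped[cols].sum()
    quants["n_peptides"] = grouped["peptide"].nunique()
    n_obs = np.array([count_observable_peptides(db.sequence(a)) for a in quants.index])
    total = quants[cols].sum(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        quants["ibaq"] = np.where(n_obs > 0, total / np.maximum(n_obs, 1), np.nan)
    return quants


def _trigamma_inverse(y: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        f = special.polygamma(1, x) - y
        if abs(f) < tol * y:
            break
        step = f / special.polygamma(2, x)  # polygamma(2) < 0 on (0, inf)
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2
        x = x_new
    return float(x)


def estimate_hyperparams(s2: np.ndarray, df: float) -> ModerationHyperparams:
    """Moment-matching estimate of the variance prior from sample variances.

    Matches the mean and variance of log sample variances against the
    scaled-inverse-chi-square prior: with z_g = log s2_g,
    e_g = z_g - psi(d/2) + log(d/2) has mean log s0^2 + psi(d0/2)... inverted
    via the trigamma function. If the observed spread of e_g does not exceed
    the sampling variance psi'(d/2), the prior degrees of freedom are
    infinite and a single pooled variance is used.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise DataError("need at least two positive sample variances")
    half_d = df / 2.0
    e = np.log(s2) - special.digamma(half_d) + np.log(half_d)
    e_bar = float(e.mean())
    e_var = float(((e - e_bar) ** 2).sum() / (e.size - 1)) - float(
        special.polygamma(1, half_d)
    )
    if e_var <= 0:
        return ModerationHyperparams(d0=np.inf, s0_sq=float(np.exp(e_bar)))
    x = _trigamma_inverse(e_var)  # x = d0 / 2
    s0_sq = float(np.exp(e_bar + special.digamma(x) - np.log(x)))
    return ModerationHyperparams(d0=2.0 * x, s0_sq=s0_sq)


def moderated_t(
    quants: pd.DataFrame,
    design: ChannelDesign,
    hyperparams: ModerationHyperparams | None = None,
) -> tuple[pd.DataFrame, ModerationHyperparams]:
    """Empirical-Bayes moderated two-sample t-test on log2 protein intensities.

    Per protein g: delta_g = mean log2(condition2) - mean log2(condition1);
    s2_g the pooled within-condition variance with d = n1+n2-2 df; the
    posterior variance shrinks s2_g toward the prior,
    s2_post = (d0*s0^2 + d*s2_g) / (d0 + d), and the moderated statistic
    t_g = delta_g / sqrt(s2_post * (1/n1 + 1/n2)) is referred to a
    t-distribution with d0 + d degrees of freedom (two-sided).

    Proteins with any non-positive channel intensity are excluded (their
    count is logged) since the log transform is undefined for them.

    Returns (results, hyperparams); results has columns ratio, log2fc,
    t_moderated, df_total, p_value, n_peptides and is indexed by accession.
    """
    ch1 = design.channels_of(design.condition1)
    ch2 = design.channels_of(design.condition2)
    n1, n2 = len(ch1), len(ch2)
    if n1 < 2 or n2 < 2:
        raise DesignError("each condition needs at least 2 channels")

    cols = list(design.channels)
    X = quants[cols].to_numpy(dtype=float)
    testable = (X > 0).all(axis=1)
    n_excluded = int((~testable).sum())
    if n_excluded:
        logger.info("excluding %d proteins with non-positive intensities", n_excluded)
    sub = quants.loc[testable]
    L = np.log2(sub[cols].to_numpy(dtype=float))
    i1 = [cols.index(c) for c in ch1]
    i2 = [cols.index(c) for c in ch2]
    delta = L[:, i2].mean(axis=1) - L[:, i1].mean(axis=1)
    v1 = L[:, i1].var(axis=1, ddof=1)
    v2 = L[:, i2].var(axis=1, ddof=1)
    d = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / d

    if hyperparams is None:
        hyperparams = estimate_hyperparams(s2, d)
    d0, s0_sq = hyperparams.d0, hyperparams.s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, delta / np.where(se > 0, se, 1.0), np.sign(delta) * np.inf)
        t = np.where((se == 0) & (delta == 0), 0.0, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    results = pd.DataFrame(
        {
            "ratio": np.exp2(delta),
            "log2fc": delta,
            "t_moderated": t,
            "df_total": df_total,
            "p_value": p,
            "n_peptides": sub["n_peptides"].to_numpy(),
        },
        index=sub.index,
    )
    return results, hyperparams


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def filter_significant(
    results: pd.DataFrame,
    q_max: float = 0.05,
    fold_min: float = 0.2,
    min_peptides: int = 2,
) -> tuple[pd.DataFrame, int, int]:
    """Apply the significance filters used for the regulated-protein lists.

    Keeps rows with q < q_max, |ratio - 1| >= fold_min (at least a 0.20-fold
    change in either direction) and n_peptides >= min_peptides. Returns the
    filtered table plus the counts of up- (ratio > 1) and down-regulated
    proteins.
    """
    keep = (
        (results["q_value"] < q_max)
        & ((results["ratio"] - 1.0).abs() >= fold_min)
        & (results["n_peptides"] >= min_peptides)
    )
    kept = results.loc[keep]
    n_up = int((kept["ratio"] > 1).sum())
    n_down = int((kept["ratio"] < 1).sum())
    return kept, n_up, n_down


def differential_analysis(
    quants: pd.DataFrame,
    design: ChannelDesign,
    q_max: float = 0.05,
    fold_min: float = 0.2,
    min_peptides: int = 2,
    hyperparams: ModerationHyperparams | None = None,
) -> tuple[pd.DataFrame, ModerationHyperparams]:
    """Moderated t-test + BH adjustment + significance flag in one call."""
    results, hp = moderated_t(quants, design, hyperparams)
    results = results.copy()
    results["q_value"] = bh_adjust(results["p_value"].to_numpy())
    results["significant"] = (
        (results["q_value"] < q_max)
        & ((results["ratio"] - 1.0).abs() >= fold_min)
        & (results["n_peptides"] >= min_peptides)
    )
    return results, hp
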