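"""Seeded generators for synthetic proteomics inputs with known ground truth.

Emulates the statistical structure the downstream analysis assumes:

* a protein database of random canonical-residue sequences,
* peptide-level TMT reporter intensities following
  ``I(p, c) = A(protein, condition(c)) * e_p * l_c * eps`` with peptide
  ionization efficiencies ``e_p`` log-normal and fixed per peptide, channel
  loading factors ``l_c``, and multiplicative reporter noise ``eps``,
* targeted PRM light/heavy peak-area pairs whose expected ratio encodes the
  true tissue concentration through the heavy-spike amount and the
  peptide-yield factor, with Gaussian-multiplicative measurement noise and
  per-sample total-ion-chromatogram drift.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError
from .proteins import AMINO_ACIDS, ProteinDB, ProteinRecord, digest
from .tmt import TMT10_CHANNELS

# Average amino-acid composition of well-annotated proteomes (fractions).
_AA_FREQS = np.array([
    0.0825, 0.0138, 0.0545, 0.0672, 0.0386, 0.0707, 0.0227, 0.0591, 0.0580,
    0.0965, 0.0241, 0.0406, 0.0474, 0.0393, 0.0553, 0.0663, 0.0535, 0.0686,
    0.0110, 0.0292,
])
_AA_FREQS = _AA_FREQS / _AA_FREQS.sum()

#: Columns of a PSM table, in canonical order.
PSM_COLUMNS = ("accession", "peptide") + TMT10_CHANNELS
#: Columns of a PRM table, in canonical order.
PRM_COLUMNS = (
    "sample_id", "condition", "accession", "peptide",
    "light_area", "heavy_area", "sample_tic",
)


@dataclass
class SimConfig:
    """Simulation parameters; defaults encode the study conditions.

    ``spike_amount_S`` is the heavy-peptide spike in fmol per ug of total
    endogenous peptide; ``yield_Y`` (ug peptide per mg wet tissue) closes
    the unit chain from fmol/ug to umol/kg wet weight, with the default
    64.5 chosen so that a light/heavy ratio of 2 maps to 1.29 umol/kg.
    """

    n_channels: int = 10
    design: tuple[str, ...] = ("WT",) * 5 + ("dHT",) * 5
    peptide_ionization_sigma: float = 1.0
    reporter_noise_cv: float = 0.10
    channel_loading: tuple[float, ...] | None = None
    spike_amount_S: float = 10.0
    yield_Y: float = 64.5
    prm_cv: float = 0.10
    tic_drift_cv: float = 0.05
    prm_n_samples: int = 5
    missingness_rate: float = 0.0
    intensity_scale: float = 1e6
    seed: int = 0

    def __post_init__(self):
        if len(self.design) != self.n_channels:
            raise ValueError("design must label every channel exactly once")
        for name in ("peptide_ionization_sigma", "reporter_noise_cv",
                     "prm_cv", "tic_drift_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.spike_amount_S <= 0:
            raise ValueError("spike_amount_S must be > 0")
        if self.yield_Y <= 0:
            raise ValueError("yield_Y must be > 0")
        if not 0 <= self.missingness_rate < 1:
            raise ValueError("missingness_rate must lie in [0, 1)")
        if self.channel_loading is not None and len(self.channel_loading) != self.n_channels:
            raise ValueError("channel_loading must have one factor per channel")

    @property
    def loading(self) -> np.ndarray:
        if self.channel_loading is None:
            return np.ones(self.n_channels)
        return np.asarray(self.channel_loading, dtype=float)

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for label in self.design:
            seen.setdefault(label)
        return tuple(seen)


@dataclass
class GroundTruth:
    """Known quantities behind a simulated dataset.

    ``concentration`` maps (accession, condition) to umol per kg wet weight;
    ``fold_change`` maps accession to the condition2/condition1 ratio;
    ``calibration_mix`` maps calibration-standard accessions to their known
    per-channel amounts (arbitrary intensity units), disjoint from the
    study proteins.
    """

    concentration: dict[tuple[str, str], float]
    fold_change: dict[str, float] = field(default_factory=dict)
    calibration_mix: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if any(v < 0 for v in self.concentration.values()):
            raise ValueError("concentrations must be >= 0")
        if any(v <= 0 for v in self.fold_change.values()):
            raise ValueError("fold changes must be > 0")
        study = {acc for acc, _ in self.concentration}
        if study & set(self.calibration_mix):
            raise ValueError("calibration-mix proteins must be disjoint from study proteins")

    @property
    def study_accessions(self) -> list[str]:
        seen: dict[str, None] = {}
        for acc, _ in self.concentration:
            seen.setdefault(acc)
        return list(seen)


def generate_protein_db(
    n_proteins: int,
    mean_length: int = 300,
    seed: int = 0,
    prefix: str = "SYN",
) -> ProteinDB:
    """Random protein database with realistic residue composition.

    Lengths are drawn around ``mean_length`` (never below 10 residues);
    the K/R content of the composition guarantees tryptic cleavage sites
    with overwhelming probability.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if mean_length < 10:
        raise ValueError("mean_length must be >= 10")
    rng = np.random.default_rng([int(seed), 101])
    aa = np.array(list(AMINO_ACIDS))
    records = []
    for i in range(n_proteins):
        length = max(10, int(round(rng.normal(mean_length, 0.2 * mean_length))))
        seq = "".join(rng.choice(aa, size=length, p=_AA_FREQS))
        records.append(
            ProteinRecord(
                accession=f"{prefix}{i + 1:04d}",
                description=f"synthetic protein {i + 1}",
                sequence=seq,
            )
        )
    return ProteinDB(records)


def make_ground_truth(
    db: ProteinDB,
    cfg: SimConfig,
    fold_change: Mapping[str, float] | None = None,
    conc_range: tuple[float, float] = (0.05, 5.0),
    n_calibration: int = 6,
    cal_base: float = 200.0,
    cal_protein_step: float = 2.0,
    cal_channel_ratio: float = 1.2,
) -> tuple[ProteinDB, GroundTruth]:
    """Assign ground-truth concentrations and build the calibration mix.

    Study-protein reference concentrations are log-uniform over
    ``conc_range`` (umol/kg); the comparison condition is the reference
    scaled by the per-protein fold change (default 1). Six calibration
    standards are appended to the database with amounts forming a geometric
    series across proteins (step ``cal_protein_step``) and across channels
    (ratio ``cal_channel_ratio``).

    Returns (database including calibration standards, truth).
    """
    rng = np.random.default_rng([cfg.seed, 211])
    conditions = cfg.conditions
    if len(conditions) != 2:
        raise ValueError("expected exactly two conditions in the design")
    ref, other = conditions
    fold_change = dict(fold_change or {})
    lo, hi = np.log(conc_range[0]), np.log(conc_range[1])
    concentration: dict[tuple[str, str], float] = {}
    for acc in db.accessions:
        base = float(np.exp(rng.uniform(lo, hi)))
        fc = fold_change.setdefault(acc, 1.0)
        concentration[(acc, ref)] = base
        concentration[(acc, other)] = base * fc

    cal_db = generate_protein_db(n_calibration, 250, seed=cfg.seed + 977, prefix="CAL")
    channels = np.arange(cfg.n_channels)
    calibration_mix = {
        rec.accession: cal_base * cal_protein_step ** j * cal_channel_ratio ** channels
        for j, rec in enumerate(cal_db.records)
    }
    truth = GroundTruth(
        concentration=concentration,
        fold_change=fold_change,
        calibration_mix=calibration_mix,
    )
    return db.merged_with(cal_db), truth


def _detectable_peptides(sequence: str) -> list[str]:
    return [p for p in digest(sequence, 0) if 7 <= len(p) <= 30]


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with the given CV and unit median."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(0.0, sigma, size=size))


def simulate_tmt(db: ProteinDB, truth: GroundTruth, cfg: SimConfig) -> pd.DataFrame:
    """Simulate a peptide-spectrum-match table with 10 reporter intensities.

    One PSM row per detectable tryptic peptide (length 7-30, no missed
    cleavages). Study-protein abundances come from the ground-truth
    concentrations scaled by ``cfg.intensity_scale``; calibration-mix rows
    use the known per-channel amounts instead. Rows are dropped
    independently at ``cfg.missingness_rate``.
    """
    missing = (set(truth.study_accessions) | set(truth.calibration_mix)) - set(db.accessions)
    if missing:
        raise ConsistencyError(f"truth accessions absent from database: {sorted(missing)[:5]}")

    rng = np.random.default_rng([cfg.seed, 307])
    loading = cfg.loading
    rows_acc: list[str] = []
    rows_pep: list[str] = []
    amounts: list[np.ndarray] = []

    for acc in sorted(truth.study_accessions):
        A = np.array(
            [truth.concentration[(acc, cond)] for cond in cfg.design]
        ) * cfg.intensity_scale
        for pep in _detectable_peptides(db.sequence(acc)):
            rows_acc.append(acc)
            rows_pep.append(pep)
            amounts.append(A)
    for acc in sorted(truth.calibration_mix):
        A = np.asarray(truth.calibration_mix[acc], dtype=float)
        for pep in _detectable_peptides(db.sequence(acc)):
            rows_acc.append(acc)
            rows_pep.append(pep)
            amounts.append(A)

    n = len(rows_acc)
    A = np.vstack(amounts) if n else np.empty((0, cfg.n_channels))
    e_p = np.exp(rng.normal(0.0, cfg.peptide_ionization_sigma, size=n))
    eps = _lognormal_noise(rng, cfg.reporter_noise_cv, (n, cfg.n_channels))
    intensities = A * e_p[:, None] * loading[None, :] * eps

    table = pd.DataFrame({"accession": rows_acc, "peptide": rows_pep})
    for j, ch in enumerate(TMT10_CHANNELS[: cfg.n_channels]):
        table[ch] = intensities[:, j]

    if cfg.missingness_rate > 0:
        keep = rng.random(n) >= cfg.missingness_rate
        table = table.loc[keep].reset_index(drop=True)
    return table


def select_target_peptides(
    db: ProteinDB,
    accessions: Sequence[str],
    n_peptides: int = 5,
    seed: int = 0,
    min_len: int = 7,
    max_len: int = 25,
) -> dict[str, list[str]]:
    """Pick proteotypic target peptides for PRM from the tryptic digest."""
    rng = np.random.default_rng([int(seed), 401])
    targets: dict[str, list[str]] = {}
    for acc in accessions:
        candidates = [
            p for p in digest(db.sequence(acc), 0) if min_len <= len(p) <= max_len
        ]
        if not candidates:
            raise ConsistencyError(f"no candidate tryptic peptides for {acc}")
        k = min(n_peptides, len(candidates))
        idx = rng.choice(len(candidates), size=k, replace=False)
        targets[acc] = [candidates[i] for i in sorted(idx)]
    return targets


def simulate_prm(
    db: ProteinDB,
    truth: GroundTruth,
    target_peptides: Mapping[str, Sequence[str]],
    cfg: SimConfig,
    conditions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate PRM light/heavy peak areas with TIC drift.

    The expected light/heavy ratio is ``C / (S * Y * 1e-3)`` where C is the
    true concentration (umol/kg), S the spike (fmol/ug) and Y the peptide
    yield (ug/mg). Per-sample injection drift multiplies the light channel
    and the sample TIC alike, so TIC normalization can remove it; ratio
    noise is Gaussian-multiplicative with CV ``cfg.prm_cv``.
    """
    if conditions is None:
        conditions = cfg.conditions
    for acc, peptides in target_peptides.items():
        if acc not in db:
            raise ConsistencyError(f"target protein {acc} not in database")
        valid = set(digest(db.sequence(acc), 3))
        for pep in peptides:
            if pep not in valid:
                raise ConsistencyError(f"{pep} is not a tryptic peptide of {acc}")

    rng = np.random.default_rng([cfg.seed, 503])
    tic_base = 1e9
    heavy_base = 1e5

    # Peptide ionization efficiencies, fixed across samples.
    e_p = {
        (acc, pep): float(np.exp(rng.normal(0.0, cfg.peptide_ionization_sigma)))
        for acc in sorted(target_peptides)
        for pep in target_peptides[acc]
    }

    rows = []
    for cond in conditions:
        for s in range(cfg.prm_n_samples):
            sample_id = f"{cond}_{s + 1}"
            drift = 1.0 + rng.normal(0.0, cfg.tic_drift_cv) if cfg.tic_drift_cv else 1.0
            drift = max(drift, 1e-6)
            tic = tic_base * drift
            for acc in sorted(target_peptides):
                conc = truth.concentration.get((acc, cond))
                if conc is None:
                    raise ConsistencyError(f"no ground-truth concentration for ({acc}, {cond})")
                r_true = conc / (cfg.spike_amount_S * cfg.yield_Y * 1e-3)
                for pep in target_peptides[acc]:
                    heavy = heavy_base * e_p[(acc, pep)]
                    noise = 1.0 + rng.normal(0.0, cfg.prm_cv) if cfg.prm_cv else 1.0
                    light = heavy * r_true * drift * max(noise, 0.0)
                    rows.append((sample_id, cond, acc, pep, light, heavy, tic))
    return pd.DataFrame(rows, columns=list(PRM_COLUMNS))
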