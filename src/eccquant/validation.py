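"""Simulation-based validation experiments.

Reusable recovery experiments that generate synthetic data from known
ground truth, run the corresponding analysis stage, and summarize how well
the truth is recovered. They back both the test suite and the
reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .absolute import protein_concentration, tic_normalize
from .proteins import ProteinDB, ProteinRecord
from .reference import condition_concentrations
from .synthetic import (
    GroundTruth,
    SimConfig,
    generate_protein_db,
    select_target_peptides,
    simulate_prm,
    simulate_tmt,
)
from .tmt import ChannelDesign, differential_analysis, normalize_channels, rollup


def _spawned_seeds(base_seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds derived from one base seed."""
    children = np.random.SeedSequence(base_seed).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def reference_protein_db(condition: str = "EDL-WT", seed: int = 0) -> ProteinDB:
    """Synthetic stand-in database carrying the nine reference ECC accessions.

    The sequences are random (synthetic); only the accessions and the
    reference concentrations attached to them are real published values.
    """
    accs = list(condition_concentrations(condition))
    raw = generate_protein_db(len(accs), 400, seed=seed)
    return ProteinDB(
        [
            ProteinRecord(acc, f"synthetic stand-in for {acc}", rec.sequence)
            for acc, rec in zip(accs, raw.records)
        ]
    )


@dataclass(frozen=True)
class RecoveryResult:
    """Across-replicate summary of a concentration-recovery experiment."""

    summary: pd.DataFrame  # accession, truth, mean, sem, n_replicates
    estimates: pd.DataFrame  # accession x replicate estimates


def prm_concentration_recovery(
    base_seed: int = 0,
    n_replicates: int = 200,
    condition: str = "EDL-WT",
    prm_cv: float = 0.10,
    tic_drift_cv: float = 0.0,
    n_samples: int = 5,
    n_peptides: int = 5,
    spike_S: float = 10.0,
    yield_Y: float = 64.5,
) -> RecoveryResult:
    """Recover the reference concentrations from replicated PRM simulations.

    For every replicate seed, a PRM table is simulated from the published
    concentrations of the chosen condition (peptide-ratio CV ``prm_cv``,
    ``n_samples`` samples, ``n_peptides`` targets per protein), TIC-
    normalized and quantified; the summary reports the across-replicate
    mean estimate and its standard error per protein.
    """
    seeds = _spawned_seeds(base_seed, n_replicates + 1)
    db_seed, rep_seeds = seeds[0], seeds[1:]
    truth_conc = condition_concentrations(condition)
    db = reference_protein_db(condition, seed=db_seed)
    targets = select_target_peptides(
        db, list(truth_conc), n_peptides=n_peptides, seed=db_seed
    )
    truth = GroundTruth(
        concentration={(a, condition): c for a, c in truth_conc.items()}
    )
    estimates: dict[str, list[float]] = {a: [] for a in truth_conc}
    for seed in rep_seeds:
        cfg = SimConfig(
            seed=seed,
            prm_cv=prm_cv,
            tic_drift_cv=tic_drift_cv,
            prm_n_samples=n_samples,
            spike_amount_S=spike_S,
            yield_Y=yield_Y,
        )
        prm = simulate_prm(db, truth, targets, cfg, conditions=[condition])
        normed, _ = tic_normalize(prm)
        conc = protein_concentration(normed, spike_S=spike_S, yield_Y=yield_Y)
        for _, row in conc.iterrows():
            estimates[row["accession"]].append(float(row["mean_umol_per_kg"]))

    est_df = pd.DataFrame(estimates)
    rows = []
    for acc in truth_conc:
        v = est_df[acc].to_numpy()
        rows.append(
            (
                acc,
                truth_conc[acc],
                float(v.mean()),
                float(v.std(ddof=1) / np.sqrt(v.size)),
                int(v.size),
            )
        )
    summary = pd.DataFrame(
        rows, columns=["accession", "truth", "mean", "sem", "n_replicates"]
    )
    return RecoveryResult(summary=summary, estimates=est_df)


@dataclass(frozen=True)
class SpikeDetection:
    """Outcome of repeated spike-in detection runs."""

    n_seeds: int
    n_detected_down: int

    @property
    def detection_rate(self) -> float:
        return self.n_detected_down / self.n_seeds


def spiked_fold_change_detection(
    base_seed: int = 0,
    n_seeds: int = 40,
    n_proteins: int = 300,
    spiked_fold: float = 0.4,
    q_max: float = 0.05,
    fold_min: float = 0.2,
    min_peptides: int = 2,
) -> SpikeDetection:
    """How often a single spiked fold change survives the significance filters.

    One protein is simulated at ``spiked_fold`` (comparison/reference) with
    all others null; the full TMT chain (normalize, roll up, moderated t,
    BH, filters) runs per seed and the spiked protein is counted as
    detected when it is flagged significant with ratio < 1.
    """
    seeds = _spawned_seeds(base_seed, n_seeds + 1)
    db_seed, rep_seeds = seeds[0], seeds[1:]
    db = generate_protein_db(n_proteins, 300, seed=db_seed)
    spiked = db.accessions[0]
    design = ChannelDesign(labels=("WT",) * 5 + ("dHT",) * 5)
    n_hit = 0
    for seed in rep_seeds:
        cfg = SimConfig(seed=seed)
        from .synthetic import make_ground_truth

        db_full, truth = make_ground_truth(db, cfg, fold_change={spiked: spiked_fold})
        psm = simulate_tmt(db_full, truth, cfg)
        normed, _ = normalize_channels(psm)
        quants = rollup(normed, db_full)
        results, _ = differential_analysis(
            quants, design, q_max=q_max, fold_min=fold_min, min_peptides=min_peptides
        )
        if spiked in results.index:
            row = results.loc[spiked]
            if bool(row["significant"]) and row["ratio"] < 1:
                n_hit += 1
    return SpikeDetection(n_seeds=n_seeds, n_detected_down=n_hit)
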