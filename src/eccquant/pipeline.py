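"""End-to-end driver wiring simulate -> TMT -> differential -> absolute ->
stoichiometry -> compare, producing a deterministic run manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .absolute import fit_calibration, protein_concentration, tic_normalize
from .compare import (
    build_display_matrices,
    comparison_set_from_results,
    shared_direction,
    venn_partition,
)
from .config import PipelineConfig
from .exceptions import FitError
from .stoichiometry import MODE_FULL, build_stoichiometry_report, occupancy_report
from .synthetic import (
    SimConfig,
    generate_protein_db,
    make_ground_truth,
    select_target_peptides,
    simulate_prm,
    simulate_tmt,
)
from .tmt import ChannelDesign, differential_analysis, normalize_channels, rollup

logger = logging.getLogger(__name__)

#: Fold change of the designed shared-down protein in every experiment,
#: mirroring a channel-protein loss shared across muscle types.
SHARED_DOWN_FOLD = 0.4
SHARED_DOWN_ACCESSION = "SYN0001"


def _experiment_seed(base_seed: int, index: int) -> int:
    return int((base_seed * 1009 + 7 * index + 13) % (2**31))


def _fold_changes(accessions, rng: np.random.Generator) -> dict[str, float]:
    """Shared-down protein plus experiment-specific up/down regulation."""
    fc = {SHARED_DOWN_ACCESSION: SHARED_DOWN_FOLD}
    eligible = [a for a in accessions if a != SHARED_DOWN_ACCESSION]
    n_each = min(10, len(eligible) // 4)
    chosen = rng.choice(len(eligible), size=2 * n_each, replace=False)
    for i in chosen[:n_each]:
        fc[eligible[i]] = float(rng.uniform(1.5, 2.5))
    for i in chosen[n_each:]:
        fc[eligible[i]] = float(rng.uniform(0.35, 0.7))
    return fc


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for each experiment and write the manifest.

    Deterministic for a fixed config seed: two runs produce identical
    outputs and manifests. Returns the manifest dictionary.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    design = ChannelDesign(labels=config.simulation.design)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "q_max": config.q_max,
            "fold_min": config.fold_min,
            "min_peptides": config.min_peptides,
            "spike_fmol_per_ug": config.spike_fmol_per_ug,
            "yield_ug_per_mg": config.yield_ug_per_mg,
            "n_proteins": config.n_proteins,
            "experiments": list(config.experiments),
        },
        "stages": {},
    }
    meta_base = {"seed": config.seed}
    comparison_sets = []

    for idx, name in enumerate(config.experiments):
        exp_dir = out_dir / name
        exp_dir.mkdir(parents=True, exist_ok=True)
        exp_seed = _experiment_seed(config.seed, idx)
        sim = dataclasses.replace(config.simulation, seed=exp_seed)
        stage: dict = {"seed": exp_seed, "outputs": []}

        # --- simulate ---------------------------------------------------
        db = generate_protein_db(config.n_proteins, config.mean_length, seed=exp_seed)
        rng = np.random.default_rng([exp_seed, 601])
        fold = _fold_changes(db.accessions, rng)
        db_full, truth = make_ground_truth(db, sim, fold_change=fold)
        psm = simulate_tmt(db_full, truth, sim)
        io.write_fasta(db_full, exp_dir / "proteins.fasta")
        io.write_tsv(psm, exp_dir / "psm.tsv", meta={**meta_base, "experiment": name})
        io.write_ground_truth(truth, exp_dir / "ground_truth.yaml")
        stage["n_psm_rows"] = int(len(psm))
        stage["outputs"] += ["proteins.fasta", "psm.tsv", "ground_truth.yaml"]

        # --- TMT relative quantification + differential testing ---------
        normed, factors = normalize_channels(psm)
        quants = rollup(normed, db_full)
        results, hyper = differential_analysis(
            quants, design,
            q_max=config.q_max, fold_min=config.fold_min,
            min_peptides=config.min_peptides,
        )
        io.write_tsv(
            factors.reset_index().rename(columns={"index": "channel"}),
            exp_dir / "channel_factors.tsv", meta=meta_base,
        )
        io.write_tsv(results.reset_index(names="accession"),
                     exp_dir / "differential.tsv", meta=meta_base)
        n_sig = int(results["significant"].sum())
        logger.info("%s: %d/%d proteins significant", name, n_sig, len(results))
        stage["n_tested"] = int(len(results))
        stage["n_significant"] = n_sig
        stage["moderation_d0"] = float(hyper.d0)
        stage["outputs"] += ["channel_factors.tsv", "differential.tsv"]

        # --- PRM/SID absolute quantification -----------------------------
        prm_targets = [SHARED_DOWN_ACCESSION] + [
            a for a in db.accessions[1: config.n_prm_targets]
        ]
        targets = select_target_peptides(db_full, prm_targets, n_peptides=5,
                                         seed=exp_seed)
        prm = simulate_prm(db_full, truth, targets, sim)
        prm_norm, tic_factors = tic_normalize(prm)
        conc = protein_concentration(
            prm_norm, spike_S=config.spike_fmol_per_ug,
            yield_Y=config.yield_ug_per_mg,
        )
        io.write_tsv(prm, exp_dir / "prm.tsv", meta=meta_base)
        io.write_tsv(conc, exp_dir / "concentrations.tsv", meta=meta_base)
        stage["outputs"] += ["prm.tsv", "concentrations.tsv"]

        # --- iBAQ calibration -------------------------------------------
        ref_cond = design.condition1
        anchors = []
        for acc in prm_targets:
            row = conc[(conc["accession"] == acc) & (conc["condition"] == ref_cond)]
            if row.empty or not bool(row["detected"].iloc[0]):
                continue
            ibaq = float(quants.loc[acc, "ibaq"])
            mean_c = float(row["mean_umol_per_kg"].iloc[0])
            if ibaq > 0 and mean_c > 0:
                anchors.append((np.log2(ibaq), np.log2(mean_c)))
        try:
            model = fit_calibration(anchors)
            io.write_tsv(
                pd.DataFrame(
                    [{
                        "slope": model.slope, "intercept": model.intercept,
                        "r_squared": model.r_squared,
                        "domain_min": model.domain[0], "domain_max": model.domain[1],
                    }]
                ),
                exp_dir / "calibration.tsv", meta=meta_base,
            )
            stage["calibration_r2"] = model.r_squared
            stage["outputs"].append("calibration.tsv")
        except FitError as exc:
            logger.warning("%s: calibration skipped (%s)", name, exc)
            stage["calibration_r2"] = None

        # --- stoichiometry -----------------------------------------------
        pairs = [
            (prm_targets[i], prm_targets[i + 1])
            for i in range(len(prm_targets) - 1)
        ]
        stoich = build_stoichiometry_report(conc, config.oligomers, pairs, MODE_FULL)
        occ = occupancy_report(conc, SHARED_DOWN_ACCESSION, config.occupancy)
        io.write_tsv(stoich, exp_dir / "stoichiometry.tsv", meta=meta_base)
        io.write_tsv(occ, exp_dir / "occupancy.tsv", meta=meta_base)
        stage["outputs"] += ["stoichiometry.tsv", "occupancy.tsv"]

        # --- display matrices --------------------------------------------
        display = build_display_matrices(results, quants, design)
        io.write_tsv(display.volcano.reset_index(names="accession"),
                     exp_dir / "volcano.tsv", meta=meta_base)
        io.write_tsv(display.heatmap.reset_index(names="accession"),
                     exp_dir / "heatmap.tsv", meta=meta_base)
        stage["outputs"] += ["volcano.tsv", "heatmap.tsv"]

        comparison_sets.append(comparison_set_from_results(name, results))
        manifest["stages"][name] = stage

    # --- cross-experiment comparison -------------------------------------
    if len(comparison_sets) >= 2:
        compare_stage: dict = {"outputs": []}
        for direction in ("up", "down"):
            regions = venn_partition(
                [getattr(cs, direction) for cs in comparison_sets[:3]],
                labels=[cs.label for cs in comparison_sets[:3]],
            )
            rows = [
                (region, len(members), ";".join(sorted(members)))
                for region, members in sorted(regions.items())
            ]
            io.write_tsv(
                pd.DataFrame(rows, columns=["region", "count", "accessions"]),
                out_dir / f"venn_{direction}.tsv", meta=meta_base,
            )
            compare_stage["outputs"].append(f"venn_{direction}.tsv")
            compare_stage[f"shared_{direction}"] = sorted(
                shared_direction(comparison_sets, direction)
            )
        manifest["stages"]["compare"] = compare_stage

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
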