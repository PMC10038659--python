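"""Readers and writers for the pipeline's on-disk formats.

Canonical tabular dialect: tab-separated UTF-8 with '.' decimal separator;
lines starting with '#' are metadata comments carrying the tool version,
parameters and seed. FASTA IO goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .exceptions import DataError
from .proteins import ProteinDB, ProteinRecord
from .synthetic import PRM_COLUMNS, GroundTruth
from .tmt import TMT10_CHANNELS


def read_fasta(path) -> ProteinDB:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            ProteinRecord(accession=rec.id, description=desc, sequence=str(rec.seq).upper())
        )
    if not records:
        raise DataError(f"no FASTA records in {path}")
    return ProteinDB(records)


def write_fasta(db: ProteinDB, path) -> None:
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.accession, description=rec.description)
        for rec in db
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def _meta_header(meta: Mapping[str, object] | None) -> str:
    lines = [f"# eccquant v{__version__}"]
    for key, value in (meta or {}).items():
        lines.append(f"# {key}: {value}")
    return "\n".join(lines) + "\n"


def write_tsv(df: pd.DataFrame, path, meta: Mapping[str, object] | None = None,
              index: bool = False) -> None:
    """Write a TSV with a commented metadata header (version, params, seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_meta_header(meta))
        df.to_csv(fh, sep="\t", index=index)


def _read_table(path, required: tuple[str, ...], numeric: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise DataError(f"cannot parse {path}: {exc}") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    for col in numeric:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"at row {row + 1}, column {col!r}"
            )
        df[col] = values
    return df


def read_psm_tsv(path, channels: tuple[str, ...] = TMT10_CHANNELS) -> pd.DataFrame:
    """Read a PSM table; the reporter block is returned in declared channel
    order regardless of its column positions in the file."""
    df = _read_table(path, required=("accession", "peptide") + tuple(channels),
                     numeric=tuple(channels))
    return df[["accession", "peptide", *channels]]


def read_prm_tsv(path) -> pd.DataFrame:
    numeric = ("light_area", "heavy_area", "sample_tic")
    df = _read_table(path, required=PRM_COLUMNS, numeric=numeric)
    return df[list(PRM_COLUMNS)]


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "concentration": {
            f"{acc}|{cond}": float(v) for (acc, cond), v in truth.concentration.items()
        },
        "fold_change": {acc: float(v) for acc, v in truth.fold_change.items()},
        "calibration_mix": {
            acc: [float(x) for x in amounts]
            for acc, amounts in truth.calibration_mix.items()
        },
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def read_ground_truth(path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    concentration = {}
    for key, value in payload.get("concentration", {}).items():
        acc, cond = key.split("|", 1)
        concentration[(acc, cond)] = float(value)
    return GroundTruth(
        concentration=concentration,
        fold_change={k: float(v) for k, v in payload.get("fold_change", {}).items()},
        calibration_mix={
            k: np.asarray(v, dtype=float)
            for k, v in payload.get("calibration_mix", {}).items()
        },
    )
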