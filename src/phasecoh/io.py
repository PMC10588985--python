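"""Reading and writing: long-format phase tables, montages, configs, and
DFT phase extraction from epoched time-series.

The canonical on-disk format is a tidy CSV with columns
``participant, condition, electrode, trial, phase, frequency`` — one row per
trial phase at one analysis frequency.  Raw EEG preprocessing (referencing,
filtering, artifact rejection, epoching) is upstream of this package; the
only time-series operation provided is extraction of the phase of the
discrete Fourier coefficient at a target frequency.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circular import wrap_angle
from .model import ExperimentLayout, PhaseDataset, PriorConfig

__all__ = [
    "PHASE_TABLE_COLUMNS",
    "read_phase_table",
    "read_phase_tables",
    "write_phase_table",
    "extract_phase",
    "read_montage",
    "load_config",
    "dump_config",
    "file_sha256",
]

PHASE_TABLE_COLUMNS = ("participant", "condition", "electrode", "trial",
                       "phase", "frequency")


def _dataset_from_frame(df: pd.DataFrame, frequency: float) -> PhaseDataset:
    participants = list(dict.fromkeys(df["participant"]))
    conditions = list(dict.fromkeys(df["condition"]))
    electrodes = list(dict.fromkeys(df["electrode"]))
    trials = df["trial"].to_numpy()
    K = int(trials.max()) + 1
    layout = ExperimentLayout(
        len(participants), len(conditions), len(electrodes), K,
        condition_labels=tuple(map(str, conditions)),
        electrode_labels=tuple(map(str, electrodes)),
        participant_labels=tuple(map(str, participants)),
    )
    p_idx = df["participant"].map({v: i for i, v in enumerate(participants)})
    c_idx = df["condition"].map({v: i for i, v in enumerate(conditions)})
    e_idx = df["electrode"].map({v: i for i, v in enumerate(electrodes)})
    phases = np.full(layout.shape, np.nan)
    phases[p_idx, c_idx, e_idx, trials] = df["phase"].to_numpy()
    return PhaseDataset(layout, phases, frequency=frequency)


def read_phase_tables(path) -> dict[float, PhaseDataset]:
    """Load a phase-table CSV into one PhaseDataset per frequency.

    Out-of-range phases are wrapped to [-pi, pi) with a warning; duplicate
    (participant, condition, electrode, trial, frequency) keys are fatal.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(PHASE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[~np.isfinite(df["phase"])]
    if len(bad):
        lines = (bad[:5] + 2).tolist()  # +2: header and 1-based numbering
        raise ValueError(f"{path}: non-finite phase values at lines {lines}")
    if df["trial"].min() < 0 or not np.allclose(df["trial"] % 1, 0):
        raise ValueError(f"{path}: trial indices must be non-negative integers")
    df["trial"] = df["trial"].astype(int)

    key_cols = ["participant", "condition", "electrode", "trial", "frequency"]
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        first = df.loc[dup.idxmax(), key_cols].to_dict()
        raise ValueError(f"{path}: duplicate key {first}")

    out_of_range = (df["phase"] < -np.pi) | (df["phase"] >= np.pi)
    if out_of_range.any():
        import logging
        logging.getLogger(__name__).warning(
            "%s: wrapped %d out-of-range phases to [-pi, pi)",
            path, int(out_of_range.sum()))
        df["phase"] = wrap_angle(df["phase"].to_numpy())

    return {float(f): _dataset_from_frame(sub, float(f))
            for f, sub in df.groupby("frequency", sort=True)}


def read_phase_table(path, frequency: float | None = None) -> PhaseDataset:
    """Load the PhaseDataset at one frequency (the only one, by default)."""
    tables = read_phase_tables(path)
    if frequency is not None:
        if float(frequency) not in tables:
            raise KeyError(f"frequency {frequency} not present in {path}")
        return tables[float(frequency)]
    if len(tables) != 1:
        raise ValueError(
            f"{path} holds {len(tables)} frequencies; pass frequency=...")
    return next(iter(tables.values()))


def write_phase_table(data: PhaseDataset, path) -> None:
    lay = data.layout
    p, c, e, k = np.nonzero(data.mask)
    df = pd.DataFrame({
        "participant": np.asarray(lay.participant_labels)[p],
        "condition": np.asarray(lay.condition_labels)[c],
        "electrode": np.asarray(lay.electrode_labels)[e],
        "trial": k,
        "phase": data.phases[p, c, e, k],
        "frequency": data.frequency,
    })
    df.to_csv(path, index=False)


def extract_phase(epoch, sample_rate: float, target_f: float
                  ) -> tuple[float, float]:
    """Phase of the DFT coefficient at the bin nearest ``target_f``.

    Returns ``(phase, realised_frequency)``; the realised bin frequency is
    reported because the target need not be an exact bin.  The convention is
    that a pure cosine at a bin frequency has phase 0 (and a sine -pi/2).
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 1 or epoch.size < 2:
        raise ValueError("epoch must be a 1-D series with at least 2 samples")
    nyquist = sample_rate / 2.0
    if not 0.0 < target_f < nyquist:
        raise ValueError(f"target frequency must lie in (0, {nyquist}) Hz")
    freqs = np.fft.rfftfreq(epoch.size, d=1.0 / sample_rate)
    bin_i = int(np.argmin(np.abs(freqs - target_f)))
    coeff = np.fft.rfft(epoch)[bin_i]
    return float(np.angle(coeff)), float(freqs[bin_i])


def read_montage(path) -> tuple[list[str], np.ndarray]:
    """Whitespace-separated montage file: ``label x y`` per line."""
    labels: list[str] = []
    coords: list[list[float]] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: expected 'label x y'")
        labels.append(parts[0])
        coords.append([float(parts[1]), float(parts[2])])
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: electrode labels must be unique")
    return labels, np.asarray(coords)


def load_config(path) -> PriorConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return PriorConfig.from_dict(d)


def dump_config(cfg: PriorConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def config_sha256(cfg: PriorConfig) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg.to_dict(), sort_keys=True).encode()).hexdigest()
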