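"""Dataset loading and validation.

A dataset directory holds TSV tables: ``lever.tsv`` (time_s, position_mm),
``trials.tsv``, ``fluor.tsv`` (frame × ROI), ``rois.tsv`` (roi_id, kind,
axon_id, position_um) and optionally ``maps.tsv`` (session, axon_id,
bouton_id, position_um).  Schema violations are reported with row numbers and
offending identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class DatasetValidationError(ValueError):
    pass


_REQUIRED_COLUMNS = {
    "lever.tsv": ["time_s", "position_mm"],
    "trials.tsv": ["trial_id", "cue_time_s", "task_window_s",
                   "reward_time_s", "punish_time_s", "trial_type"],
    "rois.tsv": ["roi_id", "kind", "axon_id", "position_um"],
    "maps.tsv": ["session", "axon_id", "bouton_id", "position_um"],
}


@dataclass
class Dataset:
    lever: pd.DataFrame
    trials: pd.DataFrame
    fluor: pd.DataFrame         # columns = roi ids (frame column removed)
    rois: pd.DataFrame
    maps: pd.DataFrame | None
    fs_hz: float
    path: Path | None = None


def _check_columns(name: str, df: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED_COLUMNS[name] if c not in df.columns]
    if missing:
        raise DatasetValidationError(f"{name}: missing columns {missing}")


def load_dataset(directory) -> Dataset:
    """Load and validate a dataset directory.

    Checks: required files/columns, strictly increasing uniformly sampled
    lever time, rewards not preceding cues, every fluorescence column resolves
    to a ROI row, and every bouton ROI carries an axon id.
    """
    d = Path(directory)
    for fname in ("lever.tsv", "trials.tsv", "fluor.tsv", "rois.tsv"):
        if not (d / fname).exists():
            raise DatasetValidationError(f"missing required table {fname} in {d}")

    lever = pd.read_csv(d / "lever.tsv", sep="\t")
    _check_columns("lever.tsv", lever)
    t = lever["time_s"].to_numpy(dtype=float)
    if len(t) >= 2:
        dt = np.diff(t)
        bad = np.flatnonzero(dt <= 0)
        if len(bad):
            raise DatasetValidationError(
                f"lever.tsv: non-monotone time at rows {bad[:5] + 1}".replace("\n", " "))
        if np.ptp(dt) > 1e-6:
            raise DatasetValidationError("lever.tsv: sampling interval not constant")
        fs = 1.0 / float(np.mean(dt))
    else:
        raise DatasetValidationError("lever.tsv: need at least two samples")

    trials = pd.read_csv(d / "trials.tsv", sep="\t")
    _check_columns("trials.tsv", trials)
    rew = trials["reward_time_s"].to_numpy(dtype=float)
    cue = trials["cue_time_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.isfinite(rew) & (rew < cue))
    if len(bad):
        ids = trials["trial_id"].iloc[bad[:5]].tolist()
        raise DatasetValidationError(f"trials.tsv: reward precedes cue at trials {ids}")

    rois = pd.read_csv(d / "rois.tsv", sep="\t")
    _check_columns("rois.tsv", rois)
    dup = rois["roi_id"][rois["roi_id"].duplicated()]
    if len(dup):
        raise DatasetValidationError(f"rois.tsv: duplicate roi ids {dup.tolist()[:5]}")
    boutons = rois[rois["kind"] == "bouton"]
    dangling = boutons["roi_id"][boutons["axon_id"].isna()].tolist()
    if dangling:
        raise DatasetValidationError(f"rois.tsv: bouton rois without axon_id: {dangling[:5]}")

    fluor = pd.read_csv(d / "fluor.tsv", sep="\t")
    if "frame" in fluor.columns:
        fluor = fluor.drop(columns=["frame"])
    known = set(rois["roi_id"])
    unknown = [c for c in fluor.columns if c not in known]
    if unknown:
        raise DatasetValidationError(
            f"fluor.tsv: roi {unknown[0]!r} absent from rois.tsv")
    if not np.isfinite(fluor.to_numpy(dtype=float)).all():
        raise DatasetValidationError("fluor.tsv: non-finite fluorescence values")

    maps = None
    if (d / "maps.tsv").exists():
        maps = pd.read_csv(d / "maps.tsv", sep="\t")
        _check_columns("maps.tsv", maps)
        for (s, a), grp in maps.groupby(["session", "axon_id"]):
            dup = grp["bouton_id"][grp["bouton_id"].duplicated()]
            if len(dup):
                raise DatasetValidationError(
                    f"maps.tsv: duplicate bouton ids in session {s}, axon {a}: "
                    f"{dup.tolist()[:5]}")

    return Dataset(lever=lever, trials=trials, fluor=fluor, rois=rois,
                   maps=maps, fs_hz=fs, path=d)
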