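"""Functional post-processing and peak-HRF snapshot extraction.

A "snapshot" is the spatial voxel pattern evoked by a single item
presentation, sampled from the cleaned run at the volume nearest the
hemodynamic peak, 4.5 s after image onset.  Post-processing of an already
motion/distortion-corrected run is minimal and fixed: discard lead-in and
tail volumes, regress out a discrete-cosine high-pass basis (1/128 Hz
cutoff), and z-score every voxel's time course.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PatternVector",
    "SnapshotMatrix",
    "SnapshotError",
    "PHASE_TRIAL_TYPES",
    "preprocess_run",
    "extract_pattern",
    "build_snapshot_matrices",
]

PEAK_OFFSET_S = 4.5

#: which event types feed each snapshot phase
PHASE_TRIAL_TYPES: dict[str, tuple[str, ...]] = {
    "pre": ("pre_snapshot_A", "pre_snapshot_B"),
    "post": ("post_snapshot_B", "post_snapshot_face"),
    "violation_evoked": ("violation_X", "violation_Y"),
}


class SnapshotError(ValueError):
    pass


@dataclass
class PatternVector:
    item_id: str
    phase: str
    roi: str
    values: np.ndarray
    volume_index: int


@dataclass
class SnapshotMatrix:
    """Item-by-voxel pattern matrix for one ROI and phase."""

    roi: str
    phase: str
    item_ids: list[str]
    data: np.ndarray  # (n_items, n_vox)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if len(self.item_ids) != self.data.shape[0]:
            raise SnapshotError("item_ids and data row count differ")
        if len(set(self.item_ids)) != len(self.item_ids):
            dupes = sorted({i for i in self.item_ids if self.item_ids.count(i) > 1})
            raise SnapshotError(f"duplicate item ids: {dupes}")
        self._index = {iid: i for i, iid in enumerate(self.item_ids)}

    @property
    def n_vox(self) -> int:
        return self.data.shape[1]

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._index

    def get(self, item_id: str) -> np.ndarray:
        try:
            return self.data[self._index[item_id]]
        except KeyError:
            raise SnapshotError(f"item {item_id!r} not in {self.roi}/{self.phase} matrix")

    # -- delimited-text round trip (item_id header column)
    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.data, columns=[f"v{j}" for j in range(self.n_vox)])
        df.insert(0, "item_id", self.item_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, roi: str, phase: str) -> "SnapshotMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(
            roi=roi,
            phase=phase,
            item_ids=df["item_id"].astype(str).tolist(),
            data=df.drop(columns="item_id").to_numpy(dtype=float),
        )


def _as_array(run4d) -> np.ndarray:
    if hasattr(run4d, "dataobj"):  # nibabel image
        return np.asanyarray(run4d.dataobj, dtype=float)
    return np.asarray(run4d, dtype=float)


def dct_basis(n: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """SPM-style discrete-cosine drift basis (without the constant term).

    Includes every cosine with period longer than 1/cutoff_hz, i.e.
    k = 1 .. floor(2 * n * tr * cutoff_hz).
    """
    order = int(math.floor(2.0 * n * tr * cutoff_hz))
    t = np.arange(n)
    return np.column_stack(
        [np.cos(math.pi * k * (2 * t + 1) / (2 * n)) for k in range(1, order + 1)]
    ) if order >= 1 else np.empty((n, 0))


def preprocess_run(
    run4d,
    tr: float,
    discard_front: int = 9,
    discard_back: int = 5,
    hp_cutoff_hz: float = 1.0 / 128.0,
    tolerant: bool = True,
):
    """Discard lead-in/tail volumes, high-pass, and z-score a run.

    High-pass removal regresses a discrete-cosine basis at the stated
    cutoff out of every voxel; z-scoring then sets each voxel's temporal
    mean to 0 and (population) SD to 1.  Constant voxels raise unless
    ``tolerant`` is on, in which case they are zeroed.

    Returns (cleaned array, time_offset) with
    ``time_offset = discard_front * tr``: cleaned volume ``i`` was acquired
    at ``i * tr + time_offset`` on the original timeline.
    """
    data = _as_array(run4d)
    n_t = data.shape[-1]
    if n_t <= discard_front + discard_back + 1:
        raise SnapshotError(
            f"run has {n_t} volumes; cannot discard {discard_front}+{discard_back}"
        )
    data = data[..., discard_front : n_t - discard_back]
    shape = data.shape
    n = shape[-1]
    flat = data.reshape(-1, n).T  # (time, voxels)

    basis = dct_basis(n, tr, hp_cutoff_hz)
    x = np.column_stack([np.ones(n), basis])
    beta, *_ = np.linalg.lstsq(x, flat, rcond=None)
    resid = flat - x @ beta

    sd = resid.std(axis=0)
    zero = sd <= 1e-300
    if zero.any() and not tolerant:
        raise SnapshotError(f"{int(zero.sum())} zero-variance voxel(s) after filtering")
    if zero.any():
        warnings.warn(f"zeroing {int(zero.sum())} constant voxel(s)", RuntimeWarning)
    sd = np.where(zero, 1.0, sd)
    z = (resid - resid.mean(axis=0)) / sd
    z[:, zero] = 0.0
    cleaned = z.T.reshape(shape)
    return cleaned, discard_front * tr


def volume_index_for(onset: float, tr: float, peak_offset: float, time_offset: float) -> int:
    """Index of the cleaned volume nearest the hemodynamic peak.

    Round-half-up on (onset + peak_offset - time_offset) / tr.
    """
    return int(math.floor((onset + peak_offset - time_offset) / tr + 0.5))


def extract_pattern(
    run4d: np.ndarray,
    mask: np.ndarray,
    onset: float,
    tr: float,
    peak_offset: float = PEAK_OFFSET_S,
    time_offset: float = 0.0,
    item_id: str = "",
    phase: str = "",
    roi: str = "",
) -> PatternVector:
    """Sample one snapshot pattern from a cleaned run.

    Voxels are returned in ascending linear (C-order) index of the mask
    volume, the fixed ordering used by every matrix in the package.
    """
    data = _as_array(run4d)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape[:-1]:
        raise SnapshotError(f"mask shape {mask.shape} != volume shape {data.shape[:-1]}")
    if not mask.any():
        raise SnapshotError("empty mask")
    idx = volume_index_for(onset, tr, peak_offset, time_offset)
    if not 0 <= idx < data.shape[-1]:
        raise SnapshotError(
            f"target volume {idx} outside run of {data.shape[-1]} volumes "
            f"(onset={onset}, peak_offset={peak_offset}, time_offset={time_offset})"
        )
    values = data[..., idx][mask]  # boolean indexing == ascending C-order
    return PatternVector(item_id=item_id, phase=phase, roi=roi, values=values, volume_index=idx)


def build_snapshot_matrices(
    runs: dict[int, tuple[np.ndarray, float]],
    events: pd.DataFrame,
    masks: dict[str, np.ndarray],
    tr: float,
    peak_offset: float = PEAK_OFFSET_S,
) -> dict[str, dict[str, SnapshotMatrix]]:
    """Assemble per-ROI, per-phase snapshot matrices from cleaned runs.

    ``runs`` maps run number to (cleaned 4D array, time_offset); ``events``
    is a BIDS-style table with onset, trial_type, item_id and run columns.
    Every item referenced by a phase must have exactly one event of that
    phase; violations are reported with the offending item ids.
    """
    out: dict[str, dict[str, SnapshotMatrix]] = {roi: {} for roi in masks}
    for phase, types in PHASE_TRIAL_TYPES.items():
        sel = events[events["trial_type"].isin(types)]
        if sel.empty:
            continue
        counts = sel["item_id"].value_counts()
        dupes = sorted(counts[counts > 1].index.tolist())
        if dupes:
            raise SnapshotError(f"phase {phase}: duplicate events for items {dupes}")
        missing_runs = sorted(set(sel["run"]) - set(runs))
        if missing_runs:
            raise SnapshotError(f"phase {phase}: no data for runs {missing_runs}")
        for roi, mask in masks.items():
            ids, rows = [], []
            for row in sel.itertuples():
                data, t_off = runs[row.run]
                pv = extract_pattern(
                    data, mask, row.onset, tr, peak_offset, t_off,
                    item_id=row.item_id, phase=phase, roi=roi,
                )
                ids.append(row.item_id)
                rows.append(pv.values)
            out[roi][phase] = SnapshotMatrix(
                roi=roi, phase=phase, item_ids=ids, data=np.array(rows)
            )
    return out
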