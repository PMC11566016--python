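"""Pairmate pattern similarity and differentiation statistics.

The central measurement: for each learned A-B scene pair, the Pearson
correlation between the pre-learning snapshot of A and the post-learning
snapshot of B, Fisher z-transformed.  The neural differentiation score is
the violation-minus-nonviolation difference of the condition means of these
z values; negative scores mean the violated pairs' representations moved
apart relative to intact pairs.  Item specificity is assessed with a
randomization test that shuffles B-to-pair assignments within condition.
Two satellite scores reuse the same machinery: B prediction (pre-B vs the
activity evoked by the violation faces X/Y) and B-X-Y integration (post-B
vs the post-learning face snapshots).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .design import Pair
from .snapshots import SnapshotMatrix

__all__ = [
    "SimilarityRecord",
    "DiffResult",
    "RandomizationResult",
    "PredictionScore",
    "CouplingResult",
    "PatsimError",
    "fisher_z",
    "inverse_fisher_z",
    "pair_similarity",
    "differentiation_score",
    "item_specificity_z",
    "b_prediction_scores",
    "coupling_correlation",
    "bxy_integration_scores",
]

R_CLAMP = 1.0 - 1e-12


class PatsimError(ValueError):
    pass


def fisher_z(r):
    """Fisher z transform, z = atanh(r); raises for |r| >= 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise PatsimError("fisher_z requires |r| < 1; clamp upstream for degenerate data")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def _safe_z(r):
    """atanh with the documented clamp policy for |r| = 1 (noise-free toys)."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("|r| >= 1 clamped before Fisher z", RuntimeWarning)
        r = np.clip(r, -R_CLAMP, R_CLAMP)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def _pearson(x: np.ndarray, y: np.ndarray, what: str = "pattern") -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
    if nx == 0 or ny == 0:
        raise PatsimError(f"zero-variance {what}")
    return float(np.dot(xc, yc) / (nx * ny))


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of every row of ``a`` with every row of ``b``."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ac, axis=1)
    nb = np.linalg.norm(bc, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise PatsimError("zero-variance pattern in matrix")
    return (ac @ bc.T) / np.outer(na, nb)


@dataclass(frozen=True)
class SimilarityRecord:
    pair_id: str
    condition: str
    r: float
    z: float


@dataclass(frozen=True)
class DiffResult:
    mean_z_violation: float
    mean_z_nonviolation: float

    @property
    def diff_score(self) -> float:
        return self.mean_z_violation - self.mean_z_nonviolation


@dataclass(frozen=True)
class RandomizationResult:
    observed: float
    null_mean: float
    null_sd: float
    z: float
    n_shuffles: int
    seed: int


@dataclass(frozen=True)
class PredictionScore:
    pair_id: str
    z_pred: float


@dataclass(frozen=True)
class CouplingResult:
    r_within: float
    z_within: float
    n_pairs: int
    condition: str


def pair_similarity(
    pre_a: SnapshotMatrix, post_b: SnapshotMatrix, pairs: Sequence[Pair]
) -> list[SimilarityRecord]:
    """preA/postB Pearson correlation (and Fisher z) for every pair."""
    records = []
    for p in pairs:
        a = pre_a.get(p.a_item.item_id)
        b = post_b.get(p.b_item.item_id)
        if len(a) != len(b):
            raise PatsimError("pre/post matrices have different voxel counts")
        r = _pearson(a, b, what=f"pattern ({p.a_item.item_id}/{p.b_item.item_id})")
        records.append(SimilarityRecord(p.pair_id, p.condition, r, _safe_z(r)))
    return records


def differentiation_score(records: Iterable[SimilarityRecord]) -> DiffResult:
    """Violation-minus-nonviolation difference of condition-mean z values."""
    by_cond: dict[str, list[float]] = {"violation": [], "nonviolation": []}
    for rec in records:
        by_cond.setdefault(rec.condition, []).append(rec.z)
    for cond in ("violation", "nonviolation"):
        if not by_cond[cond]:
            raise PatsimError(f"no records in condition {cond!r}")
    return DiffResult(
        mean_z_violation=float(np.mean(by_cond["violation"])),
        mean_z_nonviolation=float(np.mean(by_cond["nonviolation"])),
    )


def item_specificity_z(
    pre_a: SnapshotMatrix,
    post_b: SnapshotMatrix,
    pairs: Sequence[Pair],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> RandomizationResult:
    """Randomization test of item-specific differentiation.

    B-to-pair assignments are shuffled within each condition (uniform over
    all permutations, identity allowed), the differentiation score is
    recomputed per shuffle, and the observed score is z-scored against the
    null's mean and sample SD.
    """
    rng = np.random.default_rng(seed)
    conds = ("violation", "nonviolation")
    z_mats = {}
    for cond in conds:
        sub = [p for p in pairs if p.condition == cond]
        if len(sub) < 2:
            raise PatsimError(f"need >=2 pairs per condition, {cond} has {len(sub)}")
        a = np.array([pre_a.get(p.a_item.item_id) for p in sub])
        b = np.array([post_b.get(p.b_item.item_id) for p in sub])
        z_mats[cond] = _safe_z(_rowwise_corr(a, b))
    observed = float(np.mean(np.diag(z_mats["violation"])))
    observed -= float(np.mean(np.diag(z_mats["nonviolation"])))
    null = np.zeros(n_shuffles)
    for sign, cond in ((1.0, "violation"), (-1.0, "nonviolation")):
        zm = z_mats[cond]
        n = zm.shape[0]
        # uniform permutations of the B assignment, one per shuffle
        perms = np.argsort(rng.random((n_shuffles, n)), axis=1)
        null += sign * zm[np.arange(n), perms].mean(axis=1)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd <= 1e-12 * max(1.0, float(np.abs(null).max())):
        raise PatsimError("degenerate null distribution (sd = 0)")
    return RandomizationResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=(observed - null_mean) / null_sd,
        n_shuffles=n_shuffles,
        seed=seed,
    )


def b_prediction_scores(
    pre_b: SnapshotMatrix, evoked: SnapshotMatrix, pairs: Sequence[Pair]
) -> list[PredictionScore]:
    """Covert B reactivation during the two violation events of each pair.

    z_pred = mean of Fisher-z correlations of pre-B with the X-evoked and
    Y-evoked patterns; defined for violation pairs only.
    """
    scores = []
    for p in pairs:
        if p.condition != "violation":
            continue
        b = pre_b.get(p.b_item.item_id)
        zs = []
        for face in (p.x_item, p.y_item):
            if face is None or face.item_id not in evoked:
                raise PatsimError(f"pair {p.pair_id}: missing evoked pattern")
            zs.append(_safe_z(_pearson(b, evoked.get(face.item_id))))
        scores.append(PredictionScore(p.pair_id, float(np.mean(zs))))
    return scores


def bxy_integration_scores(
    post_b: SnapshotMatrix, post_faces: SnapshotMatrix, pairs: Sequence[Pair]
) -> list[PredictionScore]:
    """B-X-Y integration control: post-B vs the post-learning face snapshots."""
    scores = []
    for p in pairs:
        if p.condition != "violation":
            continue
        b = post_b.get(p.b_item.item_id)
        zs = []
        for face in (p.x_item, p.y_item):
            if face is None or face.item_id not in post_faces:
                raise PatsimError(f"pair {p.pair_id}: missing face snapshot")
            zs.append(_safe_z(_pearson(b, post_faces.get(face.item_id))))
        scores.append(PredictionScore(p.pair_id, float(np.mean(zs))))
    return scores


def coupling_correlation(
    per_pair_score: Mapping[str, float] | Sequence[PredictionScore],
    records: Iterable[SimilarityRecord],
    condition: str = "violation",
) -> CouplingResult:
    """Within-subject Pearson correlation, across pairs, of a per-pair score
    with the preA/postB similarity (Fisher z) in the named condition."""
    if not isinstance(per_pair_score, Mapping):
        per_pair_score = {s.pair_id: s.z_pred for s in per_pair_score}
    sim = {rec.pair_id: rec.z for rec in records if rec.condition == condition}
    common = [pid for pid in per_pair_score if pid in sim]
    if len(common) < 3:
        raise PatsimError(f"need >=3 matched pairs in condition {condition!r}")
    x = np.array([per_pair_score[pid] for pid in common])
    y = np.array([sim[pid] for pid in common])
    r = _pearson(x, y, what="per-pair score")
    return CouplingResult(
        r_within=r, z_within=_safe_z(r), n_pairs=len(common), condition=condition
    )
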