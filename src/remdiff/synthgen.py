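"""Synthetic subjects with planted representational effects.

The generator encodes the mechanistic account under study: every scene pair
owns mutually orthogonal latent feature blocks (shared, A-unique, B-unique,
novel) embedded in voxel space.  Learning-related representational change is
modeled as feature reallocation applied to the post-learning B snapshot
only:

* differentiation (violation condition) - B relinquishes a fraction ``d_p``
  of its shared features and acquires ``d_p`` of a novel block, so the
  post-learning B pattern moves away from the pre-learning A pattern;
* integration (nonviolation condition) - B gains shared-feature loading
  ``(1 + delta_int)``, moving toward A;
* prediction coupling - during each violation event the expected-but-absent
  B is covertly reactivated with pair-specific weight ``pi_p``; the realized
  differentiation ``d_p = clip(delta_diff + kappa * (pi_p - pred_mean), 0, 1)``
  couples reactivation strength to subsequent differentiation (a monotone
  stand-in for the weakening arm of the nonmonotonic plasticity rule).

Gaussian measurement noise is added per trial and voxel.  Ground truth
(every ``pi_p``, ``d_p``, and the latent components) is returned with each
subject so expected scores can be recomputed analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .design import DesignSpec, generate_design, generate_post_session
from .sleepmet import EPOCH_MIN, Hypnogram, SpindleEvent

__all__ = [
    "EffectConfig",
    "LatentItemModel",
    "SubjectDataset",
    "DEFAULT_EFFECTS",
    "DEFAULT_NAP_TARGETS",
    "DEFAULT_SPINDLE_RATES",
    "simulate_subject",
    "simulate_cohort",
    "render_bold",
    "simulate_hypnogram",
    "double_gamma_hrf",
]

GROUPS = ("Wake", "NREM", "REM")


@dataclass(frozen=True)
class EffectConfig:
    """Planted effect sizes for one experimental group.

    delta_diff : fraction of shared features the violation-condition post-B
        relinquishes (and of novel features it acquires), before the
        prediction-coupling adjustment.
    delta_int : shared-feature gain of the nonviolation-condition post-B
        (integration channel).
    pred_mean, pred_sd : mean and sd of the per-pair B-reactivation weight
        ``pi_p`` during violation events (truncated normal on [0, 1]).
    kappa : linear coupling of ``pi_p`` to the realized differentiation.
    noise_sd : per-voxel Gaussian measurement noise.
    """

    group: str
    delta_diff: float = 0.0
    delta_int: float = 0.0
    pred_mean: float = 0.5
    pred_sd: float = 0.2
    kappa: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self):
        vals = (
            self.delta_diff,
            self.delta_int,
            self.pred_mean,
            self.pred_sd,
            self.kappa,
            self.noise_sd,
        )
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("effect parameters must be finite")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


#: Study conditions used throughout: the REM group carries the planted
#: differentiation, integration and prediction-coupling channels; the
#: Wake and NREM groups carry none (reactivation still occurs everywhere).
DEFAULT_EFFECTS: dict[str, EffectConfig] = {
    "Wake": EffectConfig("Wake"),
    "NREM": EffectConfig("NREM"),
    "REM": EffectConfig("REM", delta_diff=0.5, delta_int=0.2, kappa=1.5),
}


@dataclass
class LatentItemModel:
    """Per-pair latent components for one ROI, exactly orthogonal blocks.

    Arrays are (n_pairs, n_vox); for each pair the shared / A-unique /
    B-unique / novel vectors live in mutually orthogonal subspaces obtained
    from a QR factorization of a Gaussian matrix.
    """

    shared: np.ndarray
    a_unique: np.ndarray
    b_unique: np.ndarray
    novel: np.ndarray
    faces: dict[str, np.ndarray]  # face item_id -> (n_vox,) pattern


@dataclass
class GroundTruth:
    pi: dict[str, float]  # violation pair_id -> reactivation weight
    d: dict[str, float]  # violation pair_id -> realized differentiation
    latents: dict[str, LatentItemModel]  # per ROI
    effect: EffectConfig


@dataclass
class SubjectDataset:
    subject_id: str
    design: DesignSpec
    group: str
    patterns: dict[str, np.ndarray]  # roi -> (n_events, n_vox), design.events order
    ground_truth: GroundTruth
    n_vox: int
    seed: int

    def snapshot_matrix(self, roi: str, phase: str):
        """Noise-carrying snapshot matrix straight from the trial patterns.

        This is the file-free shortcut past BOLD rendering + extraction;
        both routes yield one pattern per snapshot trial.
        """
        from .snapshots import SnapshotMatrix, PHASE_TRIAL_TYPES

        types = PHASE_TRIAL_TYPES[phase]
        ids, rows = [], []
        for i, ev in enumerate(self.design.events):
            if ev.trial_type in types:
                ids.append(ev.item_id)
                rows.append(self.patterns[roi][i])
        return SnapshotMatrix(roi=roi, phase=phase, item_ids=ids, data=np.array(rows))


def _component(q_block: np.ndarray, w_block: np.ndarray, norm: float) -> np.ndarray:
    """Random direction inside a pair's orthonormal block, fixed norm.

    Deterministic amplitudes make noise-free expectations exact: every
    pair's pre/post patterns have identical geometry up to rotation.
    """
    raw = np.einsum("pvd,pd->pv", q_block, w_block)
    scale = norm / np.linalg.norm(raw, axis=1, keepdims=True)
    return raw * scale


def _build_latents(
    n_pairs: int,
    pair_faces: list[tuple[int, str]],
    n_vox: int,
    k_s: int,
    k_u: int,
    k_n: int,
    rng: np.random.Generator,
) -> LatentItemModel:
    dim = k_s + 2 * k_u + k_n
    if n_vox < dim + 1:
        raise ValueError(f"n_vox={n_vox} < total feature dimension {dim} + 1")
    g = rng.standard_normal((n_pairs, n_vox, dim))
    # components live in the voxel-mean-zero hyperplane so that Pearson
    # correlations between noise-free patterns reduce to exact cosines
    g -= g.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(g)  # stacked reduced QR: orthonormal columns per pair
    w = rng.standard_normal((n_pairs, dim))
    shared = _component(q[:, :, :k_s], w[:, :k_s], math.sqrt(k_s))
    a_unique = _component(q[:, :, k_s : k_s + k_u], w[:, k_s : k_s + k_u], math.sqrt(k_u))
    b_unique = _component(
        q[:, :, k_s + k_u : k_s + 2 * k_u], w[:, k_s + k_u : k_s + 2 * k_u], math.sqrt(k_u)
    )
    # the novel block replaces relinquished shared features: matched norm
    novel = _component(q[:, :, k_s + 2 * k_u :], w[:, k_s + 2 * k_u :], math.sqrt(k_s))
    # faces live orthogonal to their own pair's scene subspace, so evoked
    # patterns mix face + pi*B without pair-varying cross terms
    face_norm = math.sqrt(k_s + k_u)
    faces = {}
    for pair_i, fid in pair_faces:
        f = rng.standard_normal(n_vox)
        f -= f.mean()
        f -= q[pair_i] @ (q[pair_i].T @ f)
        faces[fid] = f / np.linalg.norm(f) * face_norm
    return LatentItemModel(shared, a_unique, b_unique, novel, faces)


def simulate_subject(
    design: DesignSpec,
    effect: EffectConfig,
    n_vox: int = 500,
    k_s: int = 24,
    k_u: int = 12,
    k_n: int = 12,
    rois: Sequence[str] = ("ca23dg",),
    seed: int = 0,
    subject_id: str = "sub-01",
) -> SubjectDataset:
    """Generate one subject's per-trial voxel patterns for every ROI.

    The design must (or will be augmented to) contain the session-2
    snapshot runs.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    if not design.has_post_session:
        design = generate_post_session(design, seed=int(rng.integers(2**31)))
    pair_ids = [p.pair_id for p in design.pairs]
    pair_idx = {pid: i for i, pid in enumerate(pair_ids)}
    viol = [p for p in design.pairs if p.condition == "violation"]
    pair_faces = [
        (pair_idx[p.pair_id], it.item_id) for p in viol for it in (p.x_item, p.y_item)
    ]

    # per-pair reactivation weights and realized differentiation
    if effect.pred_sd > 0:
        a, b = (0 - effect.pred_mean) / effect.pred_sd, (1 - effect.pred_mean) / effect.pred_sd
        tn = stats.truncnorm(a, b, loc=effect.pred_mean, scale=effect.pred_sd)
        pi_draws = tn.rvs(size=len(viol), random_state=rng)
    else:
        pi_draws = np.full(len(viol), effect.pred_mean)
    pi = {p.pair_id: float(x) for p, x in zip(viol, pi_draws)}
    d = {
        pid: float(np.clip(effect.delta_diff + effect.kappa * (x - effect.pred_mean), 0.0, 1.0))
        for pid, x in pi.items()
    }

    patterns: dict[str, np.ndarray] = {}
    latents: dict[str, LatentItemModel] = {}
    n_events = len(design.events)
    cond = {p.pair_id: p.condition for p in design.pairs}
    face_owner = {}  # face item_id -> pair_id
    for p in viol:
        face_owner[p.x_item.item_id] = p.pair_id
        face_owner[p.y_item.item_id] = p.pair_id

    for roi in rois:
        lat = _build_latents(len(pair_ids), pair_faces, n_vox, k_s, k_u, k_n, rng)
        latents[roi] = lat
        a_pat = lat.shared + lat.a_unique
        b_pat = lat.shared + lat.b_unique
        d_vec = np.array([d.get(pid, 0.0) for pid in pair_ids])[:, None]
        int_vec = np.array(
            [effect.delta_int if cond[pid] == "nonviolation" else 0.0 for pid in pair_ids]
        )[:, None]
        is_viol = np.array([cond[pid] == "violation" for pid in pair_ids])[:, None]
        post_b = np.where(
            is_viol,
            (1.0 - d_vec) * lat.shared + lat.b_unique + d_vec * lat.novel,
            (1.0 + int_vec) * lat.shared + lat.b_unique,
        )
        out = np.empty((n_events, n_vox))
        for i, ev in enumerate(design.events):
            k = pair_idx[ev.pair_id]
            tt = ev.trial_type
            if tt in ("pre_snapshot_A", "pair_A"):
                out[i] = a_pat[k]
            elif tt in ("pre_snapshot_B", "pair_B", "restudy_B"):
                out[i] = b_pat[k]
            elif tt == "post_snapshot_B":
                out[i] = post_b[k]
            elif tt in ("violation_X", "violation_Y"):
                out[i] = lat.faces[ev.item_id] + pi[ev.pair_id] * b_pat[k]
            elif tt == "post_snapshot_face":
                out[i] = lat.faces[ev.item_id]
            else:  # pragma: no cover
                raise ValueError(f"unknown trial_type {tt}")
        out += effect.noise_sd * rng.standard_normal(out.shape)
        patterns[roi] = out

    return SubjectDataset(
        subject_id=subject_id,
        design=design,
        group=effect.group,
        patterns=patterns,
        ground_truth=GroundTruth(pi=pi, d=d, latents=latents, effect=effect),
        n_vox=n_vox,
        seed=seed,
    )


def simulate_cohort(
    n_per_group: int,
    effects: Optional[Sequence[EffectConfig] | dict[str, EffectConfig]] = None,
    seed: int = 0,
    n_vox: int = 500,
    k_s: int = 24,
    k_u: int = 12,
    k_n: int = 12,
    rois: Sequence[str] = ("ca23dg",),
    n_runs: int = 6,
    pairs_per_run: int = 16,
) -> list[SubjectDataset]:
    """Simulate independent subjects in each group, each with their own
    randomized design (seeds split from the master seed)."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if effects is None:
        effects = DEFAULT_EFFECTS
    if isinstance(effects, dict):
        effects = list(effects.values())
    labels = [e.group for e in effects]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate group labels: {labels}")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(effects) * n_per_group)
    subjects = []
    i = 0
    for eff in effects:
        for _ in range(n_per_group):
            sub_seed = int(children[i].generate_state(1)[0] % 2**31)
            i += 1
            des = generate_design(
                seed=sub_seed, n_runs=n_runs, pairs_per_run=pairs_per_run
            )
            des = generate_post_session(des, seed=sub_seed + 1)
            subjects.append(
                simulate_subject(
                    des,
                    eff,
                    n_vox=n_vox,
                    k_s=k_s,
                    k_u=k_u,
                    k_n=k_n,
                    rois=rois,
                    seed=sub_seed,
                    subject_id=f"sub-{i:03d}",
                )
            )
    return subjects


# ---------------------------------------------------------------------------
# BOLD rendering


def double_gamma_hrf(t: np.ndarray, peak: float = 6.0, undershoot: float = 16.0,
                     ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1."""
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, peak) - stats.gamma.pdf(t, undershoot) / ratio
    dense = np.linspace(0.0, 30.0, 3001)
    peak_val = np.max(stats.gamma.pdf(dense, peak) - stats.gamma.pdf(dense, undershoot) / ratio)
    return h / peak_val


def render_bold(
    subject: SubjectDataset,
    roi: str,
    run: int,
    tr: float = 1.5,
    lead_in: int = 9,
    tail: int = 5,
    noise_sd: float = 0.0,
    hrf_kwargs: Optional[dict] = None,
    decay_s: float = 24.0,
):
    """Render one run's trial patterns into a 4D BOLD-like array.

    Each trial contributes its pattern scaled by the canonical double-gamma
    HRF sampled at the volume times, summed over overlapping trials, plus
    white noise.  ``lead_in`` dummy volumes are prepended and ``tail``
    appended so the preprocessing discard step is exercised; the returned
    events table carries onsets on the acquisition timeline (task onset +
    lead_in * tr).

    Returns (bold, events) where bold has shape (n_vox, 1, 1, n_volumes).
    """
    from .io import events_dataframe

    events = [e for e in subject.design.events_for_run(run)]
    if not events:
        raise ValueError(f"run {run} has no events")
    rows = [i for i, e in enumerate(subject.design.events) if e.run == run]
    pats = subject.patterns[roi][rows]  # (n_trials, n_vox)
    onsets = np.array([e.onset for e in events]) + lead_in * tr
    task_end = onsets.max() + decay_s
    n_vols = lead_in + int(np.ceil(task_end / tr)) + tail
    if n_vols <= 0:
        raise ValueError("run duration would be non-positive")
    times = np.arange(n_vols) * tr
    hrf_kwargs = hrf_kwargs or {}
    # design matrix: volumes x trials of HRF weights
    weights = double_gamma_hrf(times[:, None] - onsets[None, :], **hrf_kwargs)
    signal = weights @ pats  # (n_vols, n_vox)
    if noise_sd > 0:
        rng = np.random.default_rng(subject.seed + 7919 * run)
        signal = signal + noise_sd * rng.standard_normal(signal.shape)
    bold = signal.T.reshape(pats.shape[1], 1, 1, n_vols)
    ev_df = events_dataframe(subject.design)
    ev_df = ev_df[ev_df["run"] == run].copy()
    ev_df["onset"] = ev_df["onset"] + lead_in * tr
    return bold, ev_df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# hypnograms

#: Table-1-scale stage targets (minutes, multiples of 0.5 epochs) per group.
DEFAULT_NAP_TARGETS: dict[str, dict[str, float]] = {
    "NREM": {"N1": 6.5, "N2": 22.5, "N3": 20.0, "REM": 0.0, "WASO": 9.0},
    "REM": {"N1": 9.0, "N2": 42.0, "N3": 22.0, "REM": 16.5, "WASO": 14.0},
}

#: spindle events per minute of stage, matching observed nap densities
DEFAULT_SPINDLE_RATES: dict[str, float] = {"N2": 4.3, "N3": 5.15}


def simulate_hypnogram(
    group: str,
    target_minutes: Optional[dict[str, float]] = None,
    seed: int = 0,
    latency_min: float = 5.0,
    tib_min: Optional[float] = None,
    spindle_rates: Optional[dict[str, float]] = None,
):
    """Emit a staged nap whose per-stage totals equal the targets exactly.

    The stage sequence follows a plausible nap course (latency wake, N1,
    descending into N3, back through N2, REM last) with wake-after-onset
    bouts inserted at random block boundaries.  Spindles are placed
    uniformly within N2/N3 epochs at Poisson rates per stage.
    """
    if target_minutes is None:
        target_minutes = DEFAULT_NAP_TARGETS.get(group, DEFAULT_NAP_TARGETS["NREM"])
    targets = {k: float(v) for k, v in target_minutes.items()}
    waso = targets.pop("WASO", 0.0)
    for name, v in {**targets, "WASO": waso, "latency": latency_min}.items():
        if v < 0 or (v / EPOCH_MIN) % 1:
            raise ValueError(f"{name} minutes must be a non-negative multiple of {EPOCH_MIN}")
    if group == "NREM" and targets.get("REM", 0.0) > 0:
        raise ValueError("REM minutes requested for group=NREM")
    tst = sum(targets.get(s, 0.0) for s in ("N1", "N2", "N3", "REM"))
    if tib_min is not None:
        latency_min = tib_min - tst - waso
        if latency_min < 0 or (latency_min / EPOCH_MIN) % 1:
            raise ValueError("tib_min inconsistent with stage + WASO targets")

    rng = np.random.default_rng(seed)
    ep = lambda m: int(round(m / EPOCH_MIN))
    n2_first = ep(targets.get("N2", 0.0)) // 2
    blocks = [
        ("N1", ep(targets.get("N1", 0.0))),
        ("N2", n2_first),
        ("N3", ep(targets.get("N3", 0.0))),
        ("N2", ep(targets.get("N2", 0.0)) - n2_first),
        ("REM", ep(targets.get("REM", 0.0))),
    ]
    blocks = [(s, n) for s, n in blocks if n > 0]
    stages = ["W"] * ep(latency_min)
    waso_left = ep(waso)
    n_gaps = max(len(blocks) - 1, 1)
    # split WASO epochs over interior block boundaries (rest goes terminal)
    cuts = rng.multinomial(waso_left, np.ones(n_gaps) / n_gaps) if waso_left else [0] * n_gaps
    for i, (s, n) in enumerate(blocks):
        stages.extend([s] * n)
        if i < len(blocks) - 1:
            stages.extend(["W"] * int(cuts[i]))
    placed = sum(int(c) for c in cuts[: max(len(blocks) - 1, 0)])
    stages.extend(["W"] * (waso_left - placed))
    h = Hypnogram(epoch_stages=stages, lights_off_epoch=0, lights_on_epoch=len(stages))

    rates = spindle_rates or DEFAULT_SPINDLE_RATES
    events: list[SpindleEvent] = []
    for i, s in enumerate(stages):
        if s not in ("N2", "N3"):
            continue
        n_ev = rng.poisson(rates.get(s, 0.0) * EPOCH_MIN)
        for _ in range(n_ev):
            dur = float(rng.uniform(0.5, 1.5))
            start = float(i * 30.0 + rng.uniform(0.0, 30.0 - dur))
            events.append(SpindleEvent(start=start, duration=dur, stage=s))
    events.sort(key=lambda e: e.start)
    return h, events
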