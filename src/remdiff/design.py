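"""Statistical-learning experimental design: pairs, conditions, trial sequences.

The paradigm presents streams of scene images with an embedded A->B pair
structure.  Each run opens with a snapshot phase in which every A and B scene
is shown once in isolation (to measure each item's baseline neural pattern),
followed by a learning phase in which pairs repeat interleaved with one
another.  Violation-condition pairs break the learned A->B prediction twice
(A is followed by novel faces X and Y) and restudy B alone after each
violation; nonviolation pairs repeat intact and receive two matched B
restudy events, so B-item exposure frequency is identical across conditions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Item",
    "Pair",
    "TrialEvent",
    "DesignSpec",
    "ValidationReport",
    "DesignError",
    "VIOLATION_TEMPLATE",
    "NONVIOLATION_TEMPLATE",
    "generate_design",
    "generate_post_session",
    "validate_design",
    "pair_event_sequence",
    "spacing_extrema",
    "respace_run",
]

# Per-pair learning-phase templates, expressed in pair-events.  "AB" is an
# intact A-then-B presentation, "AX"/"AY" are prediction violations in which
# A is followed by a novel face, and "B" is a lone restudy of B.
VIOLATION_TEMPLATE = ("AB", "AB", "AB", "AX", "B", "AY", "B")
NONVIOLATION_TEMPLATE = ("AB", "AB", "AB", "B", "B")

STIM_DURATION_S = 1.0
ISI_S = 2.0
TRIAL_SPACING_S = STIM_DURATION_S + ISI_S

MIN_PAIR_SPACING = 2
MAX_PAIR_SPACING = 20

TRIAL_TYPES = (
    "pre_snapshot_A",
    "pre_snapshot_B",
    "pair_A",
    "pair_B",
    "violation_X",
    "violation_Y",
    "restudy_B",
    "post_snapshot_B",
    "post_snapshot_face",
)


class DesignError(RuntimeError):
    """Raised when a design cannot be generated or is structurally invalid."""


@dataclass(frozen=True)
class Item:
    item_id: str
    category: str  # "scene" | "face"
    subcategory: str  # indoor/outdoor for scenes, male/female for faces


@dataclass(frozen=True)
class Pair:
    pair_id: str
    a_item: Item
    b_item: Item
    condition: str  # "violation" | "nonviolation"
    run: int
    x_item: Optional[Item] = None
    y_item: Optional[Item] = None

    def __post_init__(self):
        if self.a_item.item_id == self.b_item.item_id:
            raise DesignError(f"pair {self.pair_id}: a_item == b_item")
        has_faces = self.x_item is not None and self.y_item is not None
        if self.condition == "violation" and not has_faces:
            raise DesignError(f"violation pair {self.pair_id} lacks X/Y faces")
        if self.condition == "nonviolation" and (self.x_item or self.y_item):
            raise DesignError(f"nonviolation pair {self.pair_id} carries X/Y faces")

    @property
    def template(self) -> tuple[str, ...]:
        return VIOLATION_TEMPLATE if self.condition == "violation" else NONVIOLATION_TEMPLATE


@dataclass(frozen=True)
class TrialEvent:
    run: int
    index_in_run: int
    onset: float  # seconds from run start
    duration: float
    trial_type: str
    item_id: str
    pair_id: str
    session: int = 1


@dataclass
class DesignSpec:
    pairs: list[Pair]
    events: list[TrialEvent]
    seed: int
    n_runs: int
    pairs_per_run: int

    def pair(self, pair_id: str) -> Pair:
        return self._pair_index[pair_id]

    @property
    def _pair_index(self) -> dict[str, Pair]:
        return {p.pair_id: p for p in self.pairs}

    def events_for_run(self, run: int) -> list[TrialEvent]:
        return [e for e in self.events if e.run == run]

    def runs(self) -> list[int]:
        return sorted({e.run for e in self.events})

    @property
    def has_post_session(self) -> bool:
        return any(e.session == 2 for e in self.events)


# ---------------------------------------------------------------------------
# generation


def _make_items(n_pairs: int, n_violation: int, rng: np.random.Generator):
    scene_sub = rng.permutation(
        ["indoor", "outdoor"] * n_pairs
    )  # balanced subcategories
    scenes = [
        Item(f"scene_{i:03d}", "scene", scene_sub[i]) for i in range(2 * n_pairs)
    ]
    face_sub = rng.permutation(["male", "female"] * n_violation)
    faces = [
        Item(f"face_{i:03d}", "face", face_sub[i]) for i in range(2 * n_violation)
    ]
    return scenes, faces


def _interleave_pair_events(
    templates: dict[str, tuple[str, ...]],
    rng: np.random.Generator,
    min_gap: int = MIN_PAIR_SPACING,
    max_gap: int = MAX_PAIR_SPACING,
    max_attempts: int = 10_000,
) -> tuple[list[tuple[str, str]], int]:
    """Interleave per-pair event templates under the repetition-spacing rule.

    Between two successive events of the same pair there must be at least
    ``min_gap`` and at most ``max_gap`` intervening pair-events.  Uses
    randomized greedy construction: at each slot a pair at its maximum-gap
    deadline is placed if one exists, otherwise a uniform choice among pairs
    currently eligible under the minimum gap; infeasible partial sequences
    abort the attempt and the construction restarts.

    Returns the sequence of (pair_id, event_label) and the attempt count.
    """
    pair_ids = list(templates)
    n_total = sum(len(t) for t in templates.values())
    step = min_gap + 1  # minimum index distance between same-pair events

    for attempt in range(1, max_attempts + 1):
        idx = {p: 0 for p in pair_ids}
        last = {p: None for p in pair_ids}
        out: list[tuple[str, str]] = []
        ok = True
        for pos in range(n_total):
            active = [p for p in pair_ids if idx[p] < len(templates[p])]
            forced = [
                p for p in active if last[p] is not None and pos - last[p] - 1 == max_gap
            ]
            if len(forced) > 1:
                ok = False
                break
            if forced:
                choice = forced[0]
            else:
                eligible = [
                    p
                    for p in active
                    if last[p] is None or pos - last[p] - 1 >= min_gap
                ]
                if not eligible:
                    ok = False
                    break
                # bias toward pairs with more events left; reduces dead-ends
                weights = np.array(
                    [len(templates[p]) - idx[p] for p in eligible], dtype=float
                )
                choice = eligible[rng.choice(len(eligible), p=weights / weights.sum())]
            out.append((choice, templates[choice][idx[choice]]))
            last[choice] = pos
            idx[choice] += 1
            # feasibility: every remaining event train must still fit
            for p in pair_ids:
                r = len(templates[p]) - idx[p]
                if r == 0:
                    continue
                start = pos + 1 if last[p] is None else max(pos + 1, last[p] + step)
                if start + step * (r - 1) > n_total - 1:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return out, attempt
    raise DesignError(
        f"spacing constraint [{min_gap}, {max_gap}] unsatisfiable after "
        f"{max_attempts} interleaving attempts"
    )


def _snapshot_order(
    run_pairs: list[Pair], rng: np.random.Generator, max_attempts: int = 10_000
) -> list[tuple[str, str]]:
    """Randomize the run-start snapshot phase.

    Every A and B of the run's pairs appears once; a pair's B may never
    immediately follow its own A (so the pre-learning snapshot of B is
    uncontaminated by the pairing).
    """
    entries = []
    own_a = {}
    for p in run_pairs:
        entries.append((p.pair_id, "A"))
        entries.append((p.pair_id, "B"))
        own_a[p.pair_id] = p.a_item.item_id
    for _ in range(max_attempts):
        order = [entries[i] for i in rng.permutation(len(entries))]
        bad = any(
            order[i][0] == order[i + 1][0]
            and order[i][1] == "A"
            and order[i + 1][1] == "B"
            for i in range(len(order) - 1)
        )
        if not bad:
            return order
    raise DesignError("snapshot ordering constraint unsatisfiable")


_EVENT_TRIALS = {
    "AB": (("pair_A", "a"), ("pair_B", "b")),
    "AX": (("pair_A", "a"), ("violation_X", "x")),
    "AY": (("pair_A", "a"), ("violation_Y", "y")),
    "B": (("restudy_B", "b"),),
}


def generate_design(
    seed: int,
    n_runs: int = 6,
    pairs_per_run: int = 16,
    max_attempts: int = 10_000,
) -> DesignSpec:
    """Generate a randomized session-1 design.

    Each run holds ``pairs_per_run`` pairs (half violation, half
    nonviolation), a 2*pairs_per_run-trial snapshot phase, and a learning
    phase interleaving the per-pair templates under the 2..20 pair-event
    spacing rule.  Deterministic for a fixed seed.
    """
    if n_runs < 1:
        raise DesignError("n_runs must be >= 1")
    if pairs_per_run % 2:
        raise DesignError("pairs_per_run must be even")
    rng = np.random.default_rng(seed)
    n_pairs = n_runs * pairs_per_run
    n_violation = n_pairs // 2
    scenes, faces = _make_items(n_pairs, n_violation, rng)

    # random item-to-pair and condition assignment
    scene_order = rng.permutation(len(scenes))
    conditions = ["violation", "nonviolation"] * (pairs_per_run // 2)
    pairs: list[Pair] = []
    face_i = 0
    for k in range(n_pairs):
        run = k // pairs_per_run + 1
        cond = conditions[k % pairs_per_run]
        a = scenes[scene_order[2 * k]]
        b = scenes[scene_order[2 * k + 1]]
        if cond == "violation":
            x, y = faces[face_i], faces[face_i + 1]
            face_i += 2
        else:
            x = y = None
        pairs.append(Pair(f"pair_{k:03d}", a, b, cond, run, x, y))
    # shuffle which pair ids land in which run slot (conditions stay balanced)
    for run in range(1, n_runs + 1):
        lo = (run - 1) * pairs_per_run
        block = pairs[lo : lo + pairs_per_run]
        rng.shuffle(block)
        pairs[lo : lo + pairs_per_run] = block

    events: list[TrialEvent] = []
    by_id = {p.pair_id: p for p in pairs}
    for run in range(1, n_runs + 1):
        run_pairs = [p for p in pairs if p.run == run]
        trial_i = 0
        for pair_id, member in _snapshot_order(run_pairs, rng, max_attempts):
            p = by_id[pair_id]
            item = p.a_item if member == "A" else p.b_item
            events.append(
                TrialEvent(
                    run=run,
                    index_in_run=trial_i,
                    onset=TRIAL_SPACING_S * trial_i,
                    duration=STIM_DURATION_S,
                    trial_type=f"pre_snapshot_{member}",
                    item_id=item.item_id,
                    pair_id=pair_id,
                )
            )
            trial_i += 1
        templates = {p.pair_id: p.template for p in run_pairs}
        seq, _ = _interleave_pair_events(templates, rng, max_attempts=max_attempts)
        for pair_id, label in seq:
            p = by_id[pair_id]
            members = {"a": p.a_item, "b": p.b_item, "x": p.x_item, "y": p.y_item}
            for trial_type, member in _EVENT_TRIALS[label]:
                events.append(
                    TrialEvent(
                        run=run,
                        index_in_run=trial_i,
                        onset=TRIAL_SPACING_S * trial_i,
                        duration=STIM_DURATION_S,
                        trial_type=trial_type,
                        item_id=members[member].item_id,
                        pair_id=pair_id,
                    )
                )
                trial_i += 1
    return DesignSpec(
        pairs=pairs, events=events, seed=seed, n_runs=n_runs, pairs_per_run=pairs_per_run
    )


def generate_post_session(design: DesignSpec, seed: int) -> DesignSpec:
    """Append the session-2 snapshot runs to a design.

    One run re-presents every B scene in random order; a second run presents
    every X and Y face (from violation pairs) in random order.
    """
    rng = np.random.default_rng(seed)
    events = list(design.events)
    b_run = design.n_runs + 1
    b_entries = [(p.pair_id, p.b_item) for p in design.pairs]
    for i, k in enumerate(rng.permutation(len(b_entries))):
        pair_id, item = b_entries[k]
        events.append(
            TrialEvent(
                run=b_run,
                index_in_run=i,
                onset=TRIAL_SPACING_S * i,
                duration=STIM_DURATION_S,
                trial_type="post_snapshot_B",
                item_id=item.item_id,
                pair_id=pair_id,
                session=2,
            )
        )
    face_entries = []
    for p in design.pairs:
        if p.condition != "violation":
            continue
        if p.x_item is None or p.y_item is None:
            raise DesignError(f"violation pair {p.pair_id} missing X/Y items")
        face_entries.append((p.pair_id, p.x_item))
        face_entries.append((p.pair_id, p.y_item))
    face_run = design.n_runs + 2
    order = rng.permutation(len(face_entries)) if face_entries else []
    for i, k in enumerate(order):
        pair_id, item = face_entries[k]
        events.append(
            TrialEvent(
                run=face_run,
                index_in_run=i,
                onset=TRIAL_SPACING_S * i,
                duration=STIM_DURATION_S,
                trial_type="post_snapshot_face",
                item_id=item.item_id,
                pair_id=pair_id,
                session=2,
            )
        )
    return dataclasses.replace(design, events=events)


def respace_run(design: DesignSpec, run: int, spacing_s: float) -> DesignSpec:
    """Return a copy with one run's onsets re-spaced on a uniform grid.

    Turns a rapid event-related run into a slow variant (trial order
    untouched); used to render temporally isolated snapshot runs.
    """
    events = [
        dataclasses.replace(e, onset=spacing_s * e.index_in_run) if e.run == run else e
        for e in design.events
    ]
    return dataclasses.replace(design, events=events)


# ---------------------------------------------------------------------------
# validation


def pair_event_sequence(design: DesignSpec, run: int) -> list[tuple[str, str]]:
    """Reconstruct the learning-phase pair-event sequence of a run.

    Walks the trial stream and merges A-led trials with their continuation
    (pair_B / violation_X / violation_Y) into single pair-events.
    """
    seq: list[tuple[str, str]] = []
    open_pair: Optional[str] = None
    for ev in design.events_for_run(run):
        if ev.trial_type.startswith("pre_snapshot") or ev.session == 2:
            continue
        if ev.trial_type == "pair_A":
            open_pair = ev.pair_id
            seq.append((ev.pair_id, "A?"))
        elif ev.trial_type in ("pair_B", "violation_X", "violation_Y"):
            if open_pair != ev.pair_id:
                raise DesignError(
                    f"run {run}: {ev.trial_type} for {ev.pair_id} does not follow its pair_A"
                )
            label = {"pair_B": "AB", "violation_X": "AX", "violation_Y": "AY"}[
                ev.trial_type
            ]
            seq[-1] = (ev.pair_id, label)
            open_pair = None
        elif ev.trial_type == "restudy_B":
            seq.append((ev.pair_id, "B"))
            open_pair = None
    if any(lbl == "A?" for _, lbl in seq):
        raise DesignError(f"run {run}: dangling pair_A trial")
    return seq


def spacing_extrema(design: DesignSpec) -> tuple[int, int]:
    """Global (min, max) intervening pair-events between same-pair repetitions."""
    lo, hi = np.inf, -np.inf
    for run in range(1, design.n_runs + 1):
        seq = pair_event_sequence(design, run)
        last: dict[str, int] = {}
        for i, (pid, _) in enumerate(seq):
            if pid in last:
                gap = i - last[pid] - 1
                lo = min(lo, gap)
                hi = max(hi, gap)
            last[pid] = i
    return int(lo), int(hi)


@dataclass
class RuleResult:
    passed: bool
    offenders: list = field(default_factory=list)
    detail: str = ""


@dataclass
class ValidationReport:
    checks: dict[str, RuleResult]

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.checks.values())

    def failures(self) -> dict[str, RuleResult]:
        return {k: v for k, v in self.checks.items() if not v.passed}


def validate_design(design: DesignSpec) -> ValidationReport:
    """Check every structural invariant; pure function returning a report."""
    checks: dict[str, RuleResult] = {}
    ppr = design.pairs_per_run

    n_expected = design.n_runs * ppr
    by_cond: dict[str, int] = {}
    for p in design.pairs:
        by_cond[p.condition] = by_cond.get(p.condition, 0) + 1
    ok = len(design.pairs) == n_expected and (
        by_cond.get("violation", 0) == by_cond.get("nonviolation", 0) == n_expected // 2
    )
    checks["pair_counts"] = RuleResult(ok, detail=f"{len(design.pairs)} pairs, {by_cond}")

    offenders = []
    for run in range(1, design.n_runs + 1):
        run_events = [e for e in design.events_for_run(run) if e.session == 1]
        n_viol = sum(1 for p in design.pairs if p.run == run and p.condition == "violation")
        n_nonv = ppr - n_viol
        expect = 2 * ppr + 12 * n_viol + 8 * n_nonv  # 2 trials per AB/AX/AY, 1 per restudy
        if len(run_events) != expect:
            offenders.append((run, len(run_events), expect))
    checks["trial_counts"] = RuleResult(not offenders, offenders)

    offenders = []
    for run in range(1, design.n_runs + 1):
        snap = [
            e
            for e in design.events_for_run(run)
            if e.trial_type.startswith("pre_snapshot")
        ]
        for prev, cur in zip(snap, snap[1:]):
            if (
                prev.pair_id == cur.pair_id
                and prev.trial_type == "pre_snapshot_A"
                and cur.trial_type == "pre_snapshot_B"
            ):
                offenders.append((run, cur.pair_id))
    checks["snapshot_order"] = RuleResult(not offenders, offenders)

    offenders = []
    onset_offenders = []
    for run in design.runs():
        evs = design.events_for_run(run)
        for prev, cur in zip(evs, evs[1:]):
            if not cur.onset > prev.onset:
                onset_offenders.append((run, cur.index_in_run))
    checks["onsets_increasing"] = RuleResult(not onset_offenders, onset_offenders)

    spacing_offenders = []
    template_offenders = []
    for run in range(1, design.n_runs + 1):
        try:
            seq = pair_event_sequence(design, run)
        except DesignError as err:
            template_offenders.append((run, str(err)))
            continue
        last: dict[str, int] = {}
        per_pair: dict[str, list[str]] = {}
        for i, (pid, lbl) in enumerate(seq):
            per_pair.setdefault(pid, []).append(lbl)
            if pid in last:
                gap = i - last[pid] - 1
                if not (MIN_PAIR_SPACING <= gap <= MAX_PAIR_SPACING):
                    spacing_offenders.append((run, pid, gap))
            last[pid] = i
        for pid, labels in per_pair.items():
            if tuple(labels) != design.pair(pid).template:
                template_offenders.append((run, pid, tuple(labels)))
    checks["spacing"] = RuleResult(not spacing_offenders, spacing_offenders)
    checks["template"] = RuleResult(not template_offenders, template_offenders)

    exposure = {}
    for e in design.events:
        if e.session != 1:
            continue
        if e.trial_type in ("pre_snapshot_B", "pair_B", "restudy_B"):
            exposure[e.item_id] = exposure.get(e.item_id, 0) + 1
    bad = [(b, n) for b, n in exposure.items() if n != 6]
    checks["b_exposures"] = RuleResult(not bad, bad)

    if design.has_post_session:
        b_trials = [e for e in design.events if e.trial_type == "post_snapshot_B"]
        f_trials = [e for e in design.events if e.trial_type == "post_snapshot_face"]
        n_viol = sum(1 for p in design.pairs if p.condition == "violation")
        ok = len(b_trials) == len(design.pairs) and len(f_trials) == 2 * n_viol
        checks["post_session_counts"] = RuleResult(
            ok, detail=f"B={len(b_trials)}, faces={len(f_trials)}"
        )
    return ValidationReport(checks)
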