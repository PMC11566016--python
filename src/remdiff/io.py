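"""File contracts: BIDS-style events tables, pattern matrices, ground
truth, and run configuration."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .design import DesignSpec, DesignError, Item, Pair, TrialEvent

EVENT_COLUMNS = ["onset", "duration", "trial_type", "item_id", "pair_id", "condition", "run"]


def events_dataframe(design: DesignSpec) -> pd.DataFrame:
    """Flatten a design into a BIDS-style events table (all runs)."""
    cond = {p.pair_id: p.condition for p in design.pairs}
    rows = [
        {
            "onset": e.onset,
            "duration": e.duration,
            "trial_type": e.trial_type,
            "item_id": e.item_id,
            "pair_id": e.pair_id,
            "condition": cond[e.pair_id],
            "run": e.run,
            "session": e.session,
        }
        for e in design.events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS + ["session"])


def write_events_tsv(design: DesignSpec, out_dir, stem: str = "events") -> list[Path]:
    """One tab-separated events file per run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = events_dataframe(design)
    paths = []
    for run, sub in df.groupby("run"):
        path = out_dir / f"{stem}_run-{run:02d}.tsv"
        sub.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def read_events_tsv(paths) -> pd.DataFrame:
    frames = [pd.read_csv(p, sep="\t") for p in (paths if isinstance(paths, (list, tuple)) else [paths])]
    df = pd.concat(frames, ignore_index=True)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise DesignError(f"events table missing columns {sorted(missing)}")
    return df


def design_to_json(design: DesignSpec, path) -> None:
    def item(it: Optional[Item]):
        return None if it is None else {
            "item_id": it.item_id, "category": it.category, "subcategory": it.subcategory,
        }

    payload = {
        "seed": design.seed,
        "n_runs": design.n_runs,
        "pairs_per_run": design.pairs_per_run,
        "pairs": [
            {
                "pair_id": p.pair_id,
                "a_item": item(p.a_item),
                "b_item": item(p.b_item),
                "condition": p.condition,
                "run": p.run,
                "x_item": item(p.x_item),
                "y_item": item(p.y_item),
            }
            for p in design.pairs
        ],
        "events": [
            {
                "run": e.run,
                "index_in_run": e.index_in_run,
                "onset": e.onset,
                "duration": e.duration,
                "trial_type": e.trial_type,
                "item_id": e.item_id,
                "pair_id": e.pair_id,
                "session": e.session,
            }
            for e in design.events
        ],
    }
    Path(path).write_text(json.dumps(payload))


def design_from_json(path) -> DesignSpec:
    payload = json.loads(Path(path).read_text())

    def item(d):
        return None if d is None else Item(**d)

    pairs = [
        Pair(
            pair_id=p["pair_id"],
            a_item=item(p["a_item"]),
            b_item=item(p["b_item"]),
            condition=p["condition"],
            run=p["run"],
            x_item=item(p["x_item"]),
            y_item=item(p["y_item"]),
        )
        for p in payload["pairs"]
    ]
    events = [TrialEvent(**e) for e in payload["events"]]
    return DesignSpec(
        pairs=pairs,
        events=events,
        seed=payload["seed"],
        n_runs=payload["n_runs"],
        pairs_per_run=payload["pairs_per_run"],
    )


def write_ground_truth(subject, path) -> None:
    gt = subject.ground_truth
    payload = {
        "subject_id": subject.subject_id,
        "group": subject.group,
        "seed": subject.seed,
        "effect": {
            "group": gt.effect.group,
            "delta_diff": gt.effect.delta_diff,
            "delta_int": gt.effect.delta_int,
            "pred_mean": gt.effect.pred_mean,
            "pred_sd": gt.effect.pred_sd,
            "kappa": gt.effect.kappa,
            "noise_sd": gt.effect.noise_sd,
        },
        "pi": gt.pi,
        "d": gt.d,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(cfg, sort_keys=True).encode()
    ).hexdigest()[:12]
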