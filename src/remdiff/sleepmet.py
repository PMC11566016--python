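"""Sleep-architecture metrics from hypnograms and spindle-event lists.

Hypnograms are sequences of one stage code per 30-s epoch over the alphabet
{W, N1, N2, N3, REM}.  Derived metrics follow standard polysomnography
bookkeeping: TIB (time in bed, lights-off to lights-on), TST (total sleep
time), sleep efficiency TST/TIB, per-stage minutes and percent-of-TST, and
WASO (wake after sleep onset).  Spindle events are consumed as pre-detected
(start, duration, stage) records; density is events per minute of the
corresponding stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

EPOCH_S = 30.0
EPOCH_MIN = 0.5
STAGES = ("W", "N1", "N2", "N3", "REM")
SLEEP_STAGES = ("N1", "N2", "N3", "REM")


class SleepError(ValueError):
    pass


@dataclass
class Hypnogram:
    epoch_stages: list[str]
    lights_off_epoch: int = 0
    lights_on_epoch: Optional[int] = None
    artifact_epochs: set[int] = field(default_factory=set)

    def __post_init__(self):
        if self.lights_on_epoch is None:
            self.lights_on_epoch = len(self.epoch_stages)
        bad = sorted({s for s in self.epoch_stages} - set(STAGES))
        if bad:
            raise SleepError(f"unknown stage codes: {bad}")
        if not (0 <= self.lights_off_epoch <= self.lights_on_epoch <= len(self.epoch_stages)):
            raise SleepError("lights_off <= lights_on <= record length violated")

    def window(self) -> list[str]:
        """Stages between lights-off and lights-on."""
        return self.epoch_stages[self.lights_off_epoch : self.lights_on_epoch]

    # -- plain-text round trip: header comments, then one stage per line
    def to_file(self, path):
        path = Path(path)
        lines = [
            f"# lights_off_epoch={self.lights_off_epoch}",
            f"# lights_on_epoch={self.lights_on_epoch}",
        ]
        if self.artifact_epochs:
            lines.append(
                "# artifact_epochs=" + ",".join(str(i) for i in sorted(self.artifact_epochs))
            )
        lines.extend(self.epoch_stages)
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "Hypnogram":
        stages: list[str] = []
        meta: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
            else:
                stages.append(line)
        artifacts = meta.get("artifact_epochs", "")
        return cls(
            epoch_stages=stages,
            lights_off_epoch=int(meta.get("lights_off_epoch", 0)),
            lights_on_epoch=int(meta.get("lights_on_epoch", len(stages))),
            artifact_epochs={int(s) for s in artifacts.split(",") if s},
        )


@dataclass(frozen=True)
class SpindleEvent:
    start: float  # seconds from record start
    duration: float
    stage: str  # "N2" | "N3"
    channel: str = "CPz"

    def __post_init__(self):
        if self.start < 0 or self.duration <= 0:
            raise SleepError("spindle start must be >= 0 and duration > 0")
        if self.stage not in ("N2", "N3"):
            raise SleepError(f"spindles are defined for N2/N3, got {self.stage}")


def spindles_to_csv(events: Iterable[SpindleEvent], path) -> None:
    pd.DataFrame(
        [
            {"start_s": e.start, "duration_s": e.duration, "stage": e.stage, "channel": e.channel}
            for e in events
        ],
        columns=["start_s", "duration_s", "stage", "channel"],
    ).to_csv(path, index=False)


def spindles_from_csv(path) -> list[SpindleEvent]:
    df = pd.read_csv(path)
    return [
        SpindleEvent(row.start_s, row.duration_s, row.stage, row.channel)
        for row in df.itertuples()
    ]


@dataclass
class SleepArchitecture:
    tib_min: float
    tst_min: float
    sleep_efficiency: float
    minutes: dict[str, float]  # N1, N2, N3, REM, NREM
    waso_min: float
    percent: dict[str, float]  # percent of TST per stage (nan when TST == 0)
    waso_percent: float
    sleep_onset_latency_min: Optional[float]


@dataclass
class NapLabel:
    label: str  # "REM" | "NREM" | "WAKE_REASSIGNED"
    rationale: str


def score_architecture(h: Hypnogram) -> SleepArchitecture:
    """Score a hypnogram into Table-1-style architecture metrics.

    TIB spans lights-off to lights-on; sleep onset is the first non-wake
    epoch; WASO counts every wake epoch from sleep onset to lights-on
    (terminal wake included).  All quantities are in minutes (epochs x 0.5).
    """
    window = h.window()
    if not window:
        raise SleepError("empty lights-off/lights-on window")
    tib = EPOCH_MIN * len(window)
    counts = {s: 0 for s in STAGES}
    for s in window:
        counts[s] += 1
    minutes = {s: EPOCH_MIN * counts[s] for s in SLEEP_STAGES}
    minutes["NREM"] = minutes["N1"] + minutes["N2"] + minutes["N3"]
    tst = minutes["NREM"] + minutes["REM"]

    onset = next((i for i, s in enumerate(window) if s != "W"), None)
    if onset is None:
        waso = 0.0
        latency = None
    else:
        waso = EPOCH_MIN * sum(1 for s in window[onset:] if s == "W")
        latency = EPOCH_MIN * onset

    if tst > 0:
        percent = {s: 100.0 * minutes[s] / tst for s in ("N1", "N2", "N3", "REM", "NREM")}
        waso_percent = 100.0 * waso / tst
    else:
        percent = {s: math.nan for s in ("N1", "N2", "N3", "REM", "NREM")}
        waso_percent = math.nan
    return SleepArchitecture(
        tib_min=tib,
        tst_min=tst,
        sleep_efficiency=tst / tib if tib > 0 else 0.0,
        minutes=minutes,
        waso_min=waso,
        percent=percent,
        waso_percent=waso_percent,
        sleep_onset_latency_min=latency,
    )


def classify_nap(h: Hypnogram, min_consolidated_sleep_min: float = 10.0) -> NapLabel:
    """Assign a nap to an analysis group from its scored content.

    Any REM epoch puts the nap in the REM group.  Otherwise the nap counts
    as NREM if it contains a consolidated sleep bout (longest run of
    consecutive non-wake epochs) of at least ``min_consolidated_sleep_min``;
    shorter, fragmented sleep is reassigned to the Wake group.
    """
    window = h.window()
    if any(s == "REM" for s in window):
        return NapLabel("REM", "contains >=1 REM epoch")
    longest = run = 0
    for s in window:
        run = run + 1 if s != "W" else 0
        longest = max(longest, run)
    longest_min = EPOCH_MIN * longest
    if longest_min >= min_consolidated_sleep_min:
        return NapLabel(
            "NREM",
            f"no REM; longest consolidated sleep {longest_min:g} min >= "
            f"{min_consolidated_sleep_min:g} min",
        )
    return NapLabel(
        "WAKE_REASSIGNED",
        f"no REM; longest consolidated sleep {longest_min:g} min < "
        f"{min_consolidated_sleep_min:g} min",
    )


def spindle_density(events: Iterable[SpindleEvent], h: Hypnogram, stage: str) -> float:
    """Spindle events per minute of a stage (artifact epochs excluded)."""
    if stage not in ("N2", "N3"):
        raise SleepError(f"density defined for N2/N3, got {stage}")
    n_epochs = sum(
        1
        for i in range(h.lights_off_epoch, h.lights_on_epoch)
        if h.epoch_stages[i] == stage and i not in h.artifact_epochs
    )
    stage_min = EPOCH_MIN * n_epochs
    if stage_min == 0:
        raise SleepError(f"no artifact-free {stage} epochs: density undefined")
    count = sum(1 for e in events if e.stage == stage)
    return count / stage_min
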