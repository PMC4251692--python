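"""Descriptive statistics for the venipuncture study design.

Covers the full evaluation arithmetic of a vein-visualization field
study: per-BMI-class failure-rate tables for marked venipuncture
attempts, Likert-item summaries (mean / sample SD / mode) for the
usability questionnaire, System Usability Scale scoring with the Bangor
acceptability bands, additional-veins-per-patient summaries for a
clinical arm, and session/event analytics from usage logs.

Conventions (matching the printed precision of the study tables):
failure rates and vein summaries to 1 decimal, Likert means to 2, SDs
to 3; all rounding is half-up; SDs are sample (n-1) standard
deviations; Likert mode ties break toward the larger score. BMI classes
are opaque labels — no numeric BMI ranges are assumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AttemptRecord",
    "LikertTable",
    "SUSResponse",
    "UsageEvent",
    "MalformedLogError",
    "failure_rate_table",
    "likert_summary",
    "sus_score",
    "sus_band",
    "additional_veins_summary",
    "usage_summary",
    "expand_counts",
    "reference_attempt_counts",
    "reference_likert_table",
    "read_attempts_csv",
    "read_usage_log",
    "write_usage_log",
]

LIKERT_ITEMS = ("A", "B", "C", "D")
EVENT_KINDS = (
    "session_start",
    "session_end",
    "screen_view",
    "camera_adjust",
    "profile_select",
    "mode_select",
    "snapshot",
)


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _rate_pct(failures: int, attempts: int, ndigits: int = 1) -> float:
    """Exact rational percentage, then half-up rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(
        (Decimal(100 * failures) / Decimal(attempts)).quantize(q, ROUND_HALF_UP)
    )


# ---------------------------------------------------------------------------
# records and tables

@dataclass(frozen=True)
class AttemptRecord:
    """One marked venipuncture site: who marked it, on whom, and the outcome."""

    clinician_id: str
    subject_id: str
    bmi_class: str
    hit: bool
    point: tuple[int, int] | None = None  # (row, col) pixel, if recorded


@dataclass(frozen=True)
class LikertTable:
    """Per-respondent scores on the four usability items.

    A: 'The prototype is useful'; B: 'I am satisfied with the
    prototype'; C: 'The prototype is easy to use'; D: 'I had previous
    knowledge about vein imaging devices'. Scores are integers 1-5.
    """

    ids: tuple
    scores: np.ndarray  # (n_respondents, 4) int

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=int)
        if s.ndim != 2 or s.shape[1] != len(LIKERT_ITEMS):
            raise ValueError("scores must be (n, 4)")
        if len(self.ids) != s.shape[0]:
            raise ValueError("ids and scores length mismatch")
        if s.min() < 1 or s.max() > 5:
            raise ValueError("Likert scores must be integers in [1, 5]")
        object.__setattr__(self, "scores", s)
        object.__setattr__(self, "ids", tuple(self.ids))

    @classmethod
    def from_csv(cls, path: str | Path) -> "LikertTable":
        df = pd.read_csv(path)
        return cls(tuple(df["id"].astype(str)), df[list(LIKERT_ITEMS)].to_numpy())


@dataclass(frozen=True)
class SUSResponse:
    """Ten System Usability Scale item scores, alternating positive/negative."""

    items: tuple

    def __post_init__(self) -> None:
        items = tuple(int(v) for v in self.items)
        if len(items) != 10:
            raise ValueError(f"SUS requires exactly 10 items, got {len(items)}")
        if any(not 1 <= v <= 5 for v in items):
            raise ValueError("SUS item scores must be integers in [1, 5]")
        object.__setattr__(self, "items", items)


@dataclass(frozen=True)
class UsageEvent:
    """One entry of the usage-analytics log."""

    timestamp: datetime
    session_id: str
    kind: str
    payload: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"kind must be one of {EVENT_KINDS}, got {self.kind!r}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "timestamp": self.timestamp.isoformat(),
                "session_id": self.session_id,
                "kind": self.kind,
                "payload": self.payload,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "UsageEvent":
        d = json.loads(line)
        return cls(
            datetime.fromisoformat(d["timestamp"]),
            d["session_id"],
            d["kind"],
            d.get("payload", {}),
        )


class MalformedLogError(ValueError):
    pass


# ---------------------------------------------------------------------------
# operations

def failure_rate_table(records) -> pd.DataFrame:
    """Failure counts and rates per BMI class, plus a pooled Total row.

    rate_pct = 100 * failures / attempts, half-up to 1 decimal.
    """
    records = list(records)
    if not records:
        raise ValueError("failure_rate_table requires at least one record")
    df = pd.DataFrame(
        {"bmi_class": [r.bmi_class for r in records], "hit": [r.hit for r in records]}
    )
    rows = []
    for cls_label, grp in df.groupby("bmi_class", sort=True):
        failures = int((~grp["hit"]).sum())
        attempts = int(len(grp))
        rows.append((str(cls_label), failures, attempts, _rate_pct(failures, attempts)))
    failures = int((~df["hit"]).sum())
    rows.append(("Total", failures, len(df), _rate_pct(failures, len(df))))
    return pd.DataFrame(
        rows, columns=["class", "failures", "attempts", "rate_pct"]
    ).set_index("class")


def likert_summary(table: LikertTable) -> pd.DataFrame:
    """Mean (2 dp), sample SD (3 dp) and mode per Likert item.

    Mode ties break toward the larger score.
    """
    if table.scores.shape[0] < 2:
        raise ValueError("likert_summary requires at least 2 respondents")
    rows = []
    for j, item in enumerate(LIKERT_ITEMS):
        col = table.scores[:, j]
        mean = _round_half_up(col.mean(), 2)
        sd = _round_half_up(col.std(ddof=1), 3)
        vals, counts = np.unique(col, return_counts=True)
        mode = int(vals[counts == counts.max()].max())
        rows.append((item, mean, sd, mode))
    return pd.DataFrame(rows, columns=["item", "mean", "sd", "mode"]).set_index("item")


def sus_score(response: SUSResponse) -> float:
    """Standard SUS: odd items contribute (score-1), even items (5-score),
    total scaled by 2.5 onto [0, 100]."""
    total = sum(
        (v - 1) if (i % 2 == 0) else (5 - v) for i, v in enumerate(response.items)
    )
    return total * 2.5


def sus_band(score: float) -> str:
    """Bangor acceptability band: >70 acceptable, <50 concern, else marginal."""
    if not 0 <= score <= 100:
        raise ValueError(f"SUS score must be in [0, 100], got {score}")
    if score > 70:
        return "acceptable"
    if score < 50:
        return "concern"
    return "marginal"


def additional_veins_summary(counts, select=None) -> tuple[float, float]:
    """Mean and sample SD (1 dp each) of additional veins found per patient.

    ``select`` optionally filters to a subgroup (boolean mask or
    predicate over the counts).
    """
    counts = list(counts)
    if select is not None:
        if callable(select):
            counts = [c for c in counts if select(c)]
        else:
            counts = [c for c, keep in zip(counts, select) if keep]
    if len(counts) < 2:
        raise ValueError("additional_veins_summary requires at least 2 counts")
    if any(c < 0 for c in counts):
        raise ValueError("vein counts must be non-negative")
    arr = np.asarray(counts, dtype=float)
    return (_round_half_up(arr.mean(), 1), _round_half_up(arr.std(ddof=1), 1))


def _fmt_duration(seconds: float) -> str:
    s = int(round(seconds))
    return f"{s // 3600:02d}:{(s % 3600) // 60:02d}:{s % 60:02d}"


def _ranked(counter: dict) -> list[tuple[str, int]]:
    """Descending by count, alphabetical tie-break."""
    return sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))


def usage_summary(events) -> dict:
    """Session and event analytics from a usage log.

    Sessions are matched session_start/session_end pairs per
    session_id; durations are formatted hh:mm:ss. Ranked lists are
    sorted by descending count with alphabetical tie-break. An
    unmatched session_end (or a session running backwards in time)
    raises :class:`MalformedLogError` naming the session.
    """
    events = sorted(events, key=lambda e: e.timestamp)
    starts: dict[str, datetime] = {}
    durations: list[float] = []
    kind_counts = {k: 0 for k in EVENT_KINDS}
    screens: dict[str, int] = {}
    settings_adj: dict[str, int] = {}
    profiles: dict[str, int] = {}
    modes: dict[str, int] = {}
    snapshots = 0
    snapshots_with_veins = 0
    for ev in events:
        kind_counts[ev.kind] += 1
        if ev.kind == "session_start":
            starts[ev.session_id] = ev.timestamp
        elif ev.kind == "session_end":
            if ev.session_id not in starts:
                raise MalformedLogError(
                    f"session_end without session_start: {ev.session_id!r}"
                )
            dt = (ev.timestamp - starts.pop(ev.session_id)).total_seconds()
            if dt < 0:
                raise MalformedLogError(
                    f"session {ev.session_id!r} ends before it starts"
                )
            durations.append(dt)
        elif ev.kind == "screen_view":
            name = str(ev.payload.get("screen", "unknown"))
            screens[name] = screens.get(name, 0) + 1
        elif ev.kind == "camera_adjust":
            name = str(ev.payload.get("setting", "unknown"))
            settings_adj[name] = settings_adj.get(name, 0) + 1
        elif ev.kind == "profile_select":
            name = str(ev.payload.get("profile", "unknown"))
            profiles[name] = profiles.get(name, 0) + 1
        elif ev.kind == "mode_select":
            name = str(ev.payload.get("mode", "unknown"))
            modes[name] = modes.get(name, 0) + 1
        elif ev.kind == "snapshot":
            snapshots += 1
            if ev.payload.get("has_veins"):
                snapshots_with_veins += 1
    ranked_screens = _ranked(screens)
    ranked_modes = _ranked(modes)
    return {
        "total_sessions": len(durations),
        "average_session_duration": _fmt_duration(
            float(np.mean(durations)) if durations else 0.0
        ),
        "longest_session_duration": _fmt_duration(max(durations) if durations else 0.0),
        "most_used_screen": ranked_screens[0][0] if ranked_screens else None,
        "event_counts": dict(kind_counts),
        "camera_adjust_total": sum(settings_adj.values()),
        "camera_adjust_counts": _ranked(settings_adj),
        "profile_counts": _ranked(profiles),
        "mode_counts": ranked_modes,
        "most_used_mode": ranked_modes[0][0] if ranked_modes else None,
        "snapshots": snapshots,
        "snapshots_with_veins": snapshots_with_veins,
    }


# ---------------------------------------------------------------------------
# I/O and packaged reference data

def expand_counts(counts: pd.DataFrame) -> list[AttemptRecord]:
    """Expand per-class (failures, attempts) counts into AttemptRecords."""
    records = []
    for _, row in counts.iterrows():
        cls_label = str(row["bmi_class"])
        failures, attempts = int(row["failures"]), int(row["attempts"])
        for i in range(attempts):
            records.append(
                AttemptRecord(
                    clinician_id="pooled",
                    subject_id=f"{cls_label}-{i}",
                    bmi_class=cls_label,
                    hit=i >= failures,
                )
            )
    return records


def reference_attempt_counts() -> pd.DataFrame:
    """The educational study's per-BMI-class failure/attempt counts
    (500 supervised attempts by 20 student clinicians)."""
    with resources.files("veinviz.data").joinpath("study_attempt_counts.csv").open() as f:
        return pd.read_csv(f, dtype={"bmi_class": str})


def reference_likert_table() -> LikertTable:
    """The 20 student-clinician responses on the four usability items."""
    with resources.files("veinviz.data").joinpath("usability_likert.csv").open() as f:
        df = pd.read_csv(f)
    return LikertTable(tuple(df["id"].astype(str)), df[list(LIKERT_ITEMS)].to_numpy())


def read_attempts_csv(path: str | Path) -> list[AttemptRecord]:
    """attempts.csv: clinician_id,subject_id,bmi_class,row,col,hit."""
    df = pd.read_csv(path, dtype={"bmi_class": str})
    records = []
    for _, r in df.iterrows():
        point = None
        if "row" in df.columns and pd.notna(r.get("row")):
            point = (int(r["row"]), int(r["col"]))
        records.append(
            AttemptRecord(
                clinician_id=str(r["clinician_id"]),
                subject_id=str(r["subject_id"]),
                bmi_class=str(r["bmi_class"]),
                hit=bool(r["hit"]),
                point=point,
            )
        )
    return records


def read_usage_log(path: str | Path) -> list[UsageEvent]:
    with open(path) as f:
        return [UsageEvent.from_json(line) for line in f if line.strip()]


def write_usage_log(events, path: str | Path) -> None:
    with open(path, "w") as f:
        for ev in events:
            f.write(ev.to_json() + "\n")
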