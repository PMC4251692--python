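"""Synthetic study bundle: a complete, seeded mock of the field evaluation.

Generates everything the statistics layer consumes, with known ground
truth: 25 subject phantoms spread over 3 BMI presets, 500 venipuncture
attempts (20 clinicians x 25 subjects) whose hits are adjudicated with
the marker-hit rule against the truth masks, a 20x4 Likert table, 4 SUS
responses, a clinical additional-veins table (64 patients, 27 flagged
difficult) and a usage-event log.

BMI presets map class 1/2/3 to adipose thickness 0 / 1.5 / 3.5 mm —
purely a fixture convention so that deeper (high-BMI) veins are harder
to see and the per-class failure rates come out monotone, as in the
field data; it is not a claim about real BMI-to-adipose mapping.

Attempt marking emulates the study protocol: the student marks a
venipuncture site unaided (naked eye / palpation), and the mark is then
adjudicated against the rendered ground truth with the marker-hit rule.
Unaided vein finding is modelled as per-vein visibility decaying
exponentially with effective depth (depth + adipose, scale
``NAKED_EYE_DEPTH_MM``): if any vein is seen the mark lands near its
centerline with ~1 mm aim error, otherwise it is a blind guess — which
is what makes deeper (high-BMI) classes fail more often.
"""

from __future__ import annotations

import json
from dataclasses import replace
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .detect import DetectConfig, VeinMask, is_vein_at
from .evalstats import UsageEvent, write_usage_log
from .image import save_depth_tiff, save_image
from .phantom import PhantomSpec, generate_vein_network, render_phantom

__all__ = ["BMI_ADIPOSE_MM", "make_fixtures", "make_usage_log"]

BMI_ADIPOSE_MM = {"1": 0.0, "2": 1.5, "3": 3.5}
# 20 clinicians x subjects-per-class = per-class attempt counts 80/360/60
SUBJECTS_PER_CLASS = {"1": 4, "2": 18, "3": 3}
N_CLINICIANS = 20
AIM_ERROR_MM = 1.0
NAKED_EYE_DEPTH_MM = 2.0  # unaided visibility scale: p_seen = exp(-d_eff / this)


def make_usage_log(
    n_sessions: int,
    seed: int,
    start: datetime | None = None,
) -> list[UsageEvent]:
    """A plausible two-week usage-event log with ``n_sessions`` sessions."""
    rng = np.random.default_rng(seed)
    t = start or datetime(2014, 5, 1, 8, 0, 0)
    screens = ["Visual detection", "Camera settings", "Help"]
    settings = ["Exposure", "Contrast", "Gain"]
    profiles = ["Low light", "LED profile", "Medium light", "Very bright"]
    modes = ["dog1", "dog2", "log1", "log2"]
    events: list[UsageEvent] = []
    for s in range(n_sessions):
        sid = f"s{s:04d}"
        t += timedelta(minutes=float(rng.uniform(10, 90)))
        events.append(UsageEvent(t, sid, "session_start"))
        cursor = t
        for _ in range(int(rng.integers(2, 8))):
            cursor += timedelta(seconds=float(rng.uniform(5, 60)))
            kind = str(rng.choice(
                ["screen_view", "camera_adjust", "profile_select",
                 "mode_select", "snapshot"],
                p=[0.25, 0.35, 0.1, 0.15, 0.15],
            ))
            payload: dict = {}
            if kind == "screen_view":
                payload["screen"] = str(rng.choice(screens, p=[0.6, 0.3, 0.1]))
            elif kind == "camera_adjust":
                payload["setting"] = str(rng.choice(settings, p=[0.45, 0.35, 0.2]))
            elif kind == "profile_select":
                payload["profile"] = str(rng.choice(profiles, p=[0.4, 0.3, 0.2, 0.1]))
            elif kind == "mode_select":
                payload["mode"] = str(rng.choice(modes, p=[0.5, 0.2, 0.2, 0.1]))
            elif kind == "snapshot":
                payload["has_veins"] = bool(rng.random() < 0.75)
            events.append(UsageEvent(cursor, sid, kind, payload))
        cursor += timedelta(seconds=float(rng.uniform(30, 600)))
        events.append(UsageEvent(cursor, sid, "session_end"))
        t = cursor
    return events


def _mark_point(rng, veins, adipose_mm, shape, pitch) -> tuple[int, int]:
    """One unaided clinician mark.

    Each vein is noticed with probability exp(-(depth+adipose)/scale);
    a noticed vein gets a mark near a random centerline point with
    Gaussian aim error, an arm with no noticed vein gets a blind guess.
    """
    seen = [
        v for v in veins
        if rng.random() < np.exp(-(v.depth + adipose_mm) / NAKED_EYE_DEPTH_MM)
    ]
    if seen:
        v = seen[rng.integers(len(seen))]
        p = v.centerline[rng.integers(len(v.centerline))]
        r = (p[0] + rng.normal(0.0, AIM_ERROR_MM)) / pitch
        c = (p[1] + rng.normal(0.0, AIM_ERROR_MM)) / pitch
        return (
            int(np.clip(round(r), 0, shape[0] - 1)),
            int(np.clip(round(c), 0, shape[1] - 1)),
        )
    return int(rng.integers(shape[0])), int(rng.integers(shape[1]))


def make_fixtures(seed: int, out_dir: str | Path) -> dict:
    """Write the complete synthetic study bundle; returns a summary dict."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    detect_cfg = DetectConfig()

    attempts = []
    subject_idx = 0
    phantom_dir = out_dir / "phantoms"
    phantom_dir.mkdir(exist_ok=True)
    for bmi_class, n_subjects in SUBJECTS_PER_CLASS.items():
        for _ in range(n_subjects):
            subject_idx += 1
            sid = f"subj{subject_idx:02d}"
            spec = PhantomSpec(
                adipose_thickness=BMI_ADIPOSE_MM[bmi_class],
                rng_seed=int(rng.integers(2**31 - 1)),
            )
            veins = generate_vein_network(
                spec, n_veins=int(rng.integers(2, 5)), rng_seed=spec.rng_seed + 1
            )
            out = render_phantom(spec, veins)
            sdir = phantom_dir / sid
            sdir.mkdir(exist_ok=True)
            save_image(out.image, sdir / "image.png", bit_depth=16)
            save_image(
                out.image.with_pixels(out.truth_mask.astype(float)),
                sdir / "mask.png", bit_depth=8,
            )
            save_depth_tiff(out.depth_map, sdir / "depth.tiff")
            (sdir / "veins.json").write_text(
                json.dumps([v.to_dict() for v in veins], indent=1)
            )
            truth = VeinMask(out.truth_mask.astype(bool), (), out.image)
            for k in range(N_CLINICIANS):
                point = _mark_point(
                    rng, veins, spec.adipose_thickness, out.image.shape,
                    spec.pixel_pitch,
                )
                hit = is_vein_at(truth, point, detect_cfg.hit_tolerance)
                attempts.append(
                    {
                        "clinician_id": f"clin{k + 1:02d}",
                        "subject_id": sid,
                        "bmi_class": bmi_class,
                        "row": point[0],
                        "col": point[1],
                        "hit": hit,
                    }
                )
    pd.DataFrame(attempts).to_csv(out_dir / "attempts.csv", index=False)

    likert = pd.DataFrame(
        {
            "id": np.arange(1, 21),
            "A": rng.choice([3, 4, 5], size=20, p=[0.1, 0.45, 0.45]),
            "B": rng.choice([3, 4, 5], size=20, p=[0.1, 0.55, 0.35]),
            "C": rng.choice([3, 4, 5], size=20, p=[0.1, 0.6, 0.3]),
            "D": rng.choice([1, 2, 3], size=20, p=[0.5, 0.3, 0.2]),
        }
    )
    likert.to_csv(out_dir / "likert.csv", index=False)

    sus_rows = []
    for i in range(4):
        items = [
            int(rng.choice([4, 5])) if q % 2 == 0 else int(rng.choice([1, 2]))
            for q in range(10)
        ]
        sus_rows.append({"id": f"prof{i + 1}", **{f"q{q + 1}": v for q, v in enumerate(items)}})
    pd.DataFrame(sus_rows).to_csv(out_dir / "sus.csv", index=False)

    n_patients, n_difficult = 64, 27
    difficult = np.zeros(n_patients, dtype=bool)
    difficult[rng.choice(n_patients, size=n_difficult, replace=False)] = True
    extra = np.where(difficult, rng.poisson(2.4, n_patients), rng.poisson(1.0, n_patients))
    pd.DataFrame(
        {
            "patient_id": [f"pat{i + 1:02d}" for i in range(n_patients)],
            "difficult_flag": difficult.astype(int),
            "additional_veins": extra,
        }
    ).to_csv(out_dir / "counts.csv", index=False)

    events = make_usage_log(int(rng.integers(30, 60)), int(rng.integers(2**31 - 1)))
    write_usage_log(events, out_dir / "usage.jsonl")

    return {
        "subjects": subject_idx,
        "attempts": len(attempts),
        "likert_respondents": len(likert),
        "sus_respondents": len(sus_rows),
        "patients": n_patients,
        "usage_events": len(events),
        "out_dir": str(out_dir),
    }
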