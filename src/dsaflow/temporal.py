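"""Phase timelines and binary temporal features from per-frame detections.

A DSA run of the cerebral circulation passes through a fixed hemodynamic
sequence: contrast fills the internal carotid artery and the circle of
Willis (arterial phase), fades through the capillary bed (capillary phase,
no conspicuous vessel), then opacifies veins, venous vessels and finally
the dural venous sinuses (venous phase).  An arteriovenous malformation
(AVM) shunts blood directly from arteries to veins, so venous structures
appear *early* — during the arterial phase — and the capillary phase is
missing.  Five binary order-of-appearance features quantify exactly this:

T1  venous sinus appears before the artery has disappeared
T2  venous sinus appears before the circle of Willis has disappeared
T3  venous sinus appears before the venous vessels
T4  veins appear before the circle of Willis has disappeared
T5  no capillary phase is visible

All five are 0 for a normal run and 1 for a typical AVM run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import STRUCTURE_CLASSES

PHASES = (
    "pre_contrast",
    "early_arterial",
    "late_arterial",
    "capillary",
    "early_venous",
    "late_venous",
    "post_contrast",
)

ARTERIAL_CLASSES = ("carotid_artery", "willis_circle")
VENOUS_CLASSES = ("vein", "venous_vessel", "venous_sinus")

TEMPORAL_FEATURE_NAMES = ("T1", "T2", "T3", "T4", "T5")


@dataclass
class StructureEvents:
    """First/last frame at which each structure class is present.

    A class is *present* on a frame when some detection of that class has
    confidence >= tau; ground-truth rows (no score) always count as present.
    ``first`` / ``last`` map class name -> frame index, missing classes are
    absent from the dicts.  ``developed_first`` / ``developed_last`` bound
    the developed span: the first and last frame with any detection at all.
    """

    first: dict[str, int] = field(default_factory=dict)
    last: dict[str, int] = field(default_factory=dict)
    developed_first: int | None = None
    developed_last: int | None = None

    def present_span(self, cls: str) -> tuple[int, int] | None:
        if cls in self.first:
            return (self.first[cls], self.last[cls])
        return None


def _present_mask(detections: pd.DataFrame, tau: float) -> pd.DataFrame:
    """Rows that count as present: score >= tau, or no score (ground truth)."""
    score = pd.to_numeric(detections["score"], errors="coerce")
    keep = score.isna() | (score >= tau)
    return detections.loc[keep]


def structure_events(detections: pd.DataFrame, tau: float = 0.5) -> StructureEvents:
    """Reduce a one-case detection table to per-class appearance events.

    An empty table yields all-absent events (not an error): a run in which
    the detector saw nothing has no appearance events.
    """
    ev = StructureEvents()
    if len(detections) == 0:
        return ev
    if detections["case_id"].nunique() > 1:
        raise ValueError(
            "structure_events expects detections of a single case, got "
            f"{sorted(detections['case_id'].unique())}"
        )
    present = _present_mask(detections, tau)
    if len(present) == 0:
        return ev
    ev.developed_first = int(present["frame"].min())
    ev.developed_last = int(present["frame"].max())
    for cls, grp in present.groupby("label", observed=True):
        ev.first[str(cls)] = int(grp["frame"].min())
        ev.last[str(cls)] = int(grp["frame"].max())
    return ev


def _present_sets(detections: pd.DataFrame, tau: float, n_frames: int) -> list[set]:
    present = _present_mask(detections, tau)
    sets: list[set] = [set() for _ in range(n_frames)]
    for f, grp in present.groupby("frame"):
        if 0 <= int(f) < n_frames:
            sets[int(f)] = set(grp["label"])
    return sets


def classify_phases(
    events: StructureEvents,
    detections: pd.DataFrame,
    tau: float = 0.5,
    n_frames: int | None = None,
) -> list[str]:
    """Assign one of the seven phase labels to every frame.

    Rules, applied per frame on the classes present at confidence >= tau:

    * nothing present before the first detection -> ``pre_contrast``;
      nothing present after the last -> ``post_contrast``;
    * any venous class present -> venous phase; with a sinus ->
      ``late_venous``, without -> ``early_venous``.  Venous content takes
      precedence over co-occurring arterial structures, because venous
      definitions are stated by venous content and an arteriovenous shunt
      is precisely this co-occurrence;
    * only arterial classes present -> arterial; arterial frames strictly
      before the arterial frame of maximal summed box area are
      ``early_arterial`` (incomplete vascular tree), the rest
      ``late_arterial``; ties resolved to the earliest maximal frame, which
      starts the late phase;
    * nothing present strictly between the last arterial frame and the
      first venous frame -> ``capillary``;
    * any other interior empty frame inherits the previous frame's label
      (a documented degenerate-case policy; it cannot occur on schedules
      with contiguous structure intervals).
    """
    if n_frames is None:
        n_frames = 0 if len(detections) == 0 else int(detections["frame"].max()) + 1
    sets = _present_sets(detections, tau, n_frames)

    present_any = [len(s) > 0 for s in sets]
    arterial_frames = [
        f for f in range(n_frames)
        if any(c in sets[f] for c in ARTERIAL_CLASSES)
        and not any(c in sets[f] for c in VENOUS_CLASSES)
    ]
    venous_frames = [
        f for f in range(n_frames) if any(c in sets[f] for c in VENOUS_CLASSES)
    ]

    # early/late arterial split: frame of maximal summed box area among
    # pure-arterial frames; earliest maximal frame starts the late phase
    split_frame: int | None = None
    if arterial_frames:
        present = _present_mask(detections, tau)
        area = (present["x_max"] - present["x_min"]) * (present["y_max"] - present["y_min"])
        per_frame = area.groupby(present["frame"]).sum()
        areas = np.array([float(per_frame.get(f, 0.0)) for f in arterial_frames])
        split_frame = arterial_frames[int(np.argmax(areas))]

    last_arterial = max(arterial_frames) if arterial_frames else None
    first_venous = min(venous_frames) if venous_frames else None

    labels: list[str] = []
    for f in range(n_frames):
        s = sets[f]
        if not present_any[f]:
            if events.developed_first is None or f < events.developed_first:
                labels.append("pre_contrast")
            elif f > events.developed_last:
                labels.append("post_contrast")
            elif (
                last_arterial is not None
                and first_venous is not None
                and last_arterial < f < first_venous
            ):
                labels.append("capillary")
            else:
                labels.append(labels[-1] if labels else "pre_contrast")
        elif any(c in s for c in VENOUS_CLASSES):
            labels.append("late_venous" if "venous_sinus" in s else "early_venous")
        else:  # arterial only
            labels.append("early_arterial" if f < split_frame else "late_arterial")
    return labels


def temporal_features(events: StructureEvents, timeline: list[str]) -> tuple[int, int, int, int, int]:
    """Compute the five binary temporal features (T1..T5).

    Appearance-order comparisons with "before the end / disappearance" are
    inclusive (co-occurrence on the last frame still counts as before
    disappearance); "appears before venous vessels" is strict.  A missing
    left-hand event makes the feature 0; for T3, a sinus that appeared
    while venous vessels never did makes the feature 1.
    """
    first, last = events.first, events.last
    sinus_first = first.get("venous_sinus")
    vein_first = first.get("vein")
    artery_last = last.get("carotid_artery")
    willis_last = last.get("willis_circle")
    vv_first = first.get("venous_vessel")

    def le(a: int | None, b: int | None) -> int:
        return int(a is not None and b is not None and a <= b)

    arterial_last = None
    if artery_last is not None or willis_last is not None:
        arterial_last = max(v for v in (artery_last, willis_last) if v is not None)

    t1 = le(sinus_first, arterial_last)
    t2 = le(sinus_first, willis_last)
    if sinus_first is None:
        t3 = 0
    elif vv_first is None:
        t3 = 1  # sinus appeared, venous vessels never did
    else:
        t3 = int(sinus_first < vv_first)
    t4 = le(vein_first, willis_last)
    t5 = int(timeline.count("capillary") == 0)
    return (t1, t2, t3, t4, t5)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def select_key_frames(events: StructureEvents, n_frames: int) -> list[int]:
    """Pick five frames in equal proportion across the developed span.

    ``f_i = developed_first + round(i * span / 4)`` for i = 0..4 with
    round-half-up; short spans may repeat indices.  Requires at least one
    developed (contrast-bearing) frame.
    """
    if events.developed_first is None or events.developed_last is None:
        raise ValueError("no contrast detected: cannot select key frames")
    a, b = events.developed_first, events.developed_last
    if not (0 <= a <= b < n_frames):
        raise ValueError(
            f"developed span [{a}, {b}] outside stack of {n_frames} frames"
        )
    span = b - a
    return [a + _round_half_up(i * span / 4) for i in range(5)]


def phase_snapped_key_frames(
    events: StructureEvents, timeline: list[str]
) -> list[int]:
    """Alternative sampling: one frame per named phase where available.

    Picks the middle frame of each of early_arterial, late_arterial,
    capillary, early_venous and late_venous; phases absent from the
    timeline fall back to the equal-proportion frame for that slot.  This
    is exposed as an option only; equal-proportion sampling is the default.
    """
    eq = select_key_frames(events, len(timeline))
    wanted = ("early_arterial", "late_arterial", "capillary", "early_venous", "late_venous")
    out = []
    for i, ph in enumerate(wanted):
        frames = [f for f, lab in enumerate(timeline) if lab == ph]
        out.append(frames[len(frames) // 2] if frames else eq[i])
    return out


def case_temporal_vector(
    detections: pd.DataFrame, tau: float = 0.5, n_frames: int | None = None
) -> tuple[int, int, int, int, int]:
    """Convenience: detections of one case -> (T1..T5)."""
    ev = structure_events(detections, tau)
    tl = classify_phases(ev, detections, tau, n_frames)
    return temporal_features(ev, tl)
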