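"""Seeded synthetic DSA phantom videos with full ground truth.

The clinical material this package targets — anteroposterior cerebral DSA
runs of normal and AVM circulations — is not publicly available, so this
module generates phantom videos that reproduce the *temporal* structure of
such runs: five vascular structure classes (internal carotid artery,
circle of Willis, vein, venous vessel, venous sinus) appear and disappear
in hemodynamic order, with

* normal runs: arterial phase, a contrast-free capillary gap, then venous
  filling in the order vein -> venous vessel -> venous sinus, strictly
  after the arterial structures have washed out;
* AVM runs: early sinus filling *during* the arterial phase (the shunt),
  veins before Willis washout, and no capillary gap; a nidus blob whose
  diameter and sinus-onset advance serve as a severity (grade) surrogate.

Each structure is rendered as a dark (contrast-filled) template at a fixed
canonical layout position on a bright background, with a 2-frame intensity
ramp at onset and offset and optional additive Gaussian noise.  Videos are
20-50 frames at 166-333 ms/frame, matching clinical acquisition rates.
The generator makes no attempt at realistic vessel trees, X-ray physics or
patient motion; its purpose is exact, derivable ground truth (boxes, phase
timeline, temporal features) for testing the analysis pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .dataio import (
    DETECTION_COLUMNS,
    STRUCTURE_CLASSES,
    FrameStack,
    new_detection_table,
    write_detection_table,
)

BACKGROUND = 200.0  #: background gray value of a rendered frame
CONTRAST_DEPTH = 120.0  #: full-contrast intensity dip below background

N_FRAMES_RANGE = (20, 50)
FRAME_INTERVAL_MS_RANGE = (166, 333)


# --------------------------------------------------------------------------
# canonical spatial layout (fractions of image height/width)
# --------------------------------------------------------------------------

def canonical_layout(
    shape: tuple[int, int], nidus_diameter_px: int = 0
) -> dict[str, np.ndarray]:
    """Boolean template masks of each structure for an image of ``shape``.

    Fixed anteroposterior-projection layout: carotid artery inferior-center
    (a vertical bar), circle of Willis central (an annulus), vein and
    venous vessel superior (horizontal bars), venous sinus superior-lateral
    (a disk), and — when ``nidus_diameter_px > 0`` — a nidus disk between
    the Willis circle and the sinus.
    """
    h, w = shape
    m = min(h, w)
    yy, xx = np.mgrid[0:h, 0:w]

    def bar(r0: float, r1: float, c0: float, c1: float) -> np.ndarray:
        mask = np.zeros((h, w), dtype=bool)
        mask[int(r0 * h): int(r1 * h), int(c0 * w): int(c1 * w)] = True
        return mask

    def disk(rc: float, cc: float, radius: float) -> np.ndarray:
        return (yy - rc * h) ** 2 + (xx - cc * w) ** 2 <= radius**2

    ring_out, ring_in = 0.09 * m, 0.045 * m
    layout = {
        "carotid_artery": bar(0.65, 0.92, 0.47, 0.53),
        "willis_circle": disk(0.50, 0.50, ring_out) & ~disk(0.50, 0.50, ring_in),
        "vein": bar(0.08, 0.14, 0.30, 0.55),
        "venous_vessel": bar(0.20, 0.26, 0.06, 0.31),
        "venous_sinus": disk(0.14, 0.82, 0.07 * m),
    }
    if nidus_diameter_px > 0:
        layout["nidus"] = disk(0.42, 0.72, nidus_diameter_px / 2)
    return layout


def layout_anchors(
    shape: tuple[int, int], with_nidus: bool = True
) -> dict[str, tuple[float, float]]:
    """Centroid (row, col) of each canonical template position."""
    h, w = shape
    anchors = {
        "carotid_artery": (0.785 * h, 0.50 * w),
        "willis_circle": (0.50 * h, 0.50 * w),
        "vein": (0.11 * h, 0.425 * w),
        "venous_vessel": (0.23 * h, 0.185 * w),
        "venous_sinus": (0.14 * h, 0.82 * w),
    }
    if with_nidus:
        anchors["nidus"] = (0.42 * h, 0.72 * w)
    return anchors


def _mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight half-open (x_min, y_min, x_max, y_max) box of a boolean mask."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return int(cols[0]), int(rows[0]), int(cols[-1]) + 1, int(rows[-1]) + 1


# --------------------------------------------------------------------------
# hemodynamic schedules
# --------------------------------------------------------------------------

@dataclass
class HemodynamicSchedule:
    """Onset/offset frame of every structure plus acquisition parameters.

    ``onset[c] .. offset[c]`` (inclusive) are the frames on which class
    ``c`` is filled with contrast.  ``capillary_gap`` records whether at
    least one contrast-free frame separates arterial washout from venous
    filling (true for normal runs, false for AVM shunts).
    ``nidus_diameter_px`` is 0 for non-AVM schedules.
    """

    onset: dict[str, int]
    offset: dict[str, int]
    n_frames: int
    frame_interval_ms: float
    capillary_gap: bool
    nidus_diameter_px: int = 0
    nidus_onset: int = 0
    nidus_offset: int = -1  # empty interval by default

    def validate(self) -> None:
        lo, hi = N_FRAMES_RANGE
        if not (lo <= self.n_frames <= hi):
            raise ValueError(
                f"n_frames must lie in [{lo}, {hi}], got {self.n_frames}"
            )
        for c in STRUCTURE_CLASSES:
            if not (0 <= self.onset[c] <= self.offset[c] < self.n_frames):
                raise ValueError(
                    f"class {c}: need 0 <= onset <= offset < n_frames, got "
                    f"[{self.onset[c]}, {self.offset[c]}] in {self.n_frames} frames"
                )

    @property
    def arterial_end(self) -> int:
        return max(self.offset["carotid_artery"], self.offset["willis_circle"])

    @property
    def venous_start(self) -> int:
        return min(self.onset[c] for c in ("vein", "venous_vessel", "venous_sinus"))

    def truth_temporal(self) -> tuple[int, int, int, int, int]:
        """T1..T5 derived from the schedule alone (no rendering involved)."""
        on, off = self.onset, self.offset
        t1 = int(on["venous_sinus"] <= self.arterial_end)
        t2 = int(on["venous_sinus"] <= off["willis_circle"])
        t3 = int(on["venous_sinus"] < on["venous_vessel"])
        t4 = int(on["vein"] <= off["willis_circle"])
        t5 = int(not self.capillary_gap)
        return (t1, t2, t3, t4, t5)


def build_schedule(
    diagnosis: str,
    grade_class: str,
    n_frames: int,
    rng_seed: int,
    frame_interval_ms: float | None = None,
) -> HemodynamicSchedule:
    """Draw a diagnosis-consistent hemodynamic schedule.

    Onsets and offsets are jittered uniformly within windows that preserve
    the diagnosis orderings, so ties and near-ties occur but ground truth
    never flips.  Deterministic for fixed arguments; for AVM schedules with
    the same seed, high grade gives an earlier sinus onset and a larger
    nidus than low grade.
    """
    lo, hi = N_FRAMES_RANGE
    if not (lo <= n_frames <= hi):
        raise ValueError(f"n_frames must lie in [{lo}, {hi}], got {n_frames}")
    if diagnosis not in ("AVM", "non-AVM"):
        raise ValueError(f"diagnosis must be 'AVM' or 'non-AVM', got {diagnosis!r}")
    if diagnosis == "non-AVM" and grade_class != "none":
        raise ValueError("grade_class must be 'none' for non-AVM cases")
    if diagnosis == "AVM" and grade_class not in ("low", "high"):
        raise ValueError("AVM cases need grade_class 'low' (I-III) or 'high' (IV-V)")

    rng = np.random.default_rng(rng_seed)
    if frame_interval_ms is None:
        frame_interval_ms = float(
            rng.integers(FRAME_INTERVAL_MS_RANGE[0], FRAME_INTERVAL_MS_RANGE[1] + 1)
        )
    n = n_frames
    pre = 1 + int(rng.integers(0, 2))
    post = int(rng.integers(0, 2))

    if diagnosis == "non-AVM":
        gap = 1 + int(rng.integers(0, 3))
        art_on = pre
        willis_on = art_on + int(rng.integers(0, 2))
        arterial_end = min(round(0.40 * n) + int(rng.integers(0, 3)),
                           n - post - gap - 5)
        art_off = max(arterial_end - int(rng.integers(0, 2)), art_on)
        willis_off = arterial_end
        vein_on = arterial_end + 1 + gap
        sinus_off = n - 1 - post
        sinus_on = min(vein_on + 2 + int(rng.integers(0, 2)), n - 2 - post)
        vv_on = min(vein_on + 1 + int(rng.integers(0, 2)), sinus_on - 1)
        vein_off = max(sinus_off - int(rng.integers(0, 2)), vein_on)
        vv_off = max(sinus_off - int(rng.integers(0, 2)), vv_on)
        sched = HemodynamicSchedule(
            onset={
                "carotid_artery": art_on, "willis_circle": willis_on,
                "vein": vein_on, "venous_vessel": vv_on, "venous_sinus": sinus_on,
            },
            offset={
                "carotid_artery": art_off, "willis_circle": willis_off,
                "vein": vein_off, "venous_vessel": vv_off, "venous_sinus": sinus_off,
            },
            n_frames=n, frame_interval_ms=frame_interval_ms,
            capillary_gap=True, nidus_diameter_px=0,
        )
        assert sched.truth_temporal() == (0, 0, 0, 0, 0)
    else:
        art_on = pre
        willis_on = art_on + int(rng.integers(0, 2))
        arterial_end = min(round(0.55 * n) + int(rng.integers(0, 3)), n - 4)
        art_off = arterial_end - int(rng.integers(0, 2))
        willis_off = arterial_end
        j_sinus = int(rng.integers(0, 2))
        j_vein = int(rng.integers(0, 3))
        j_vv = int(rng.integers(0, 3))
        j_nidus = int(rng.integers(0, 4))
        # high grade: faster shunt (earlier sinus) and a larger nidus
        advance = 2 if grade_class == "high" else 4
        sinus_on = art_on + advance + j_sinus
        vein_on = min(sinus_on + j_vein, willis_off)
        vv_on = sinus_on + 1 + j_vv
        sinus_off = n - 1 - post
        vein_off = max(sinus_off - int(rng.integers(0, 2)), vein_on)
        vv_off = max(sinus_off - int(rng.integers(0, 2)), vv_on)
        nidus_d = (15 if grade_class == "high" else 9) + j_nidus
        sched = HemodynamicSchedule(
            onset={
                "carotid_artery": art_on, "willis_circle": willis_on,
                "vein": vein_on, "venous_vessel": vv_on, "venous_sinus": sinus_on,
            },
            offset={
                "carotid_artery": art_off, "willis_circle": willis_off,
                "vein": vein_off, "venous_vessel": vv_off, "venous_sinus": sinus_off,
            },
            n_frames=n, frame_interval_ms=frame_interval_ms,
            capillary_gap=False, nidus_diameter_px=nidus_d,
            nidus_onset=sinus_on, nidus_offset=sinus_off,
        )
        assert sched.truth_temporal() == (1, 1, 1, 1, 1)
    sched.validate()
    return sched


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

@dataclass
class PhantomCase:
    """One rendered phantom video with its complete ground truth."""

    frames: FrameStack
    truth_boxes: pd.DataFrame
    truth_temporal: tuple[int, int, int, int, int]
    diagnosis: str
    grade_class: str
    schedule: HemodynamicSchedule
    seed: int


def _ramp_alpha(f: int, onset: int, offset: int) -> float:
    """Contrast fill fraction on frame f: 2-frame ramp in at onset, out at offset."""
    if f < onset or f > offset:
        return 0.0
    return min(1.0, (f - onset + 1) / 2, (offset - f + 1) / 2)


def _check_layout(layout: dict[str, np.ndarray], shape: tuple[int, int]) -> None:
    h, w = shape
    if h < 64 or w < 64:
        raise ValueError(f"image size {shape} too small: each dimension must be >= 64")
    from scipy import ndimage

    names = list(layout)
    for i, a in enumerate(names):
        if not layout[a].any():
            raise ValueError(f"template {a} is empty at image size {shape}")
        x0, y0, x1, y1 = _mask_bbox(layout[a])
        if x0 < 1 or y0 < 1 or x1 > w - 1 or y1 > h - 1:
            raise ValueError(
                f"image size {shape} too small to host template {a} with a margin"
            )
        dil = ndimage.binary_dilation(layout[a], np.ones((3, 3), bool))
        for b in names[i + 1:]:
            if (dil & layout[b]).any():
                raise ValueError(
                    f"image size {shape} too small: templates {a} and {b} collide"
                )


def render_case(
    schedule: HemodynamicSchedule,
    image_size: tuple[int, int] = (96, 96),
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    case_id: str | None = None,
) -> PhantomCase:
    """Render a schedule into an 8-bit grayscale frame stack plus truth.

    Active structures appear as dark templates (intensity dips of up to
    ``CONTRAST_DEPTH`` below the ``BACKGROUND`` level) with 2-frame ramps;
    Gaussian noise of ``noise_sd`` is added before quantization.  Truth
    boxes are the tight template boxes on every frame within each class's
    [onset, offset] window.  Bit-deterministic for fixed arguments.
    """
    schedule.validate()
    shape = (int(image_size[0]), int(image_size[1]))
    layout = canonical_layout(shape, schedule.nidus_diameter_px)
    _check_layout(layout, shape)
    if case_id is None:
        case_id = f"phantom_{rng_seed:08d}"

    rng = np.random.default_rng(rng_seed)
    n = schedule.n_frames
    frames = np.empty((n, *shape), dtype=np.uint8)
    rows: list[tuple] = []
    intervals = {c: (schedule.onset[c], schedule.offset[c]) for c in STRUCTURE_CLASSES}
    if schedule.nidus_diameter_px > 0 and schedule.nidus_offset >= schedule.nidus_onset:
        intervals["nidus"] = (schedule.nidus_onset, schedule.nidus_offset)

    for f in range(n):
        img = np.full(shape, BACKGROUND, dtype=float)
        for name, (on, off) in intervals.items():
            a = _ramp_alpha(f, on, off)
            if a > 0:
                img[layout[name]] -= CONTRAST_DEPTH * a
                if name in STRUCTURE_CLASSES:
                    x0, y0, x1, y1 = _mask_bbox(layout[name])
                    rows.append((case_id, f, name, x0, y0, x1, y1, np.nan))
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=shape)
        frames[f] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    stack = FrameStack(case_id, frames, schedule.frame_interval_ms)
    diagnosis = "non-AVM" if schedule.capillary_gap else "AVM"
    if diagnosis == "non-AVM":
        grade = "none"
    else:
        grade = "high" if schedule.nidus_diameter_px >= 15 else "low"
    return PhantomCase(
        frames=stack,
        truth_boxes=new_detection_table(rows),
        truth_temporal=schedule.truth_temporal(),
        diagnosis=diagnosis,
        grade_class=grade,
        schedule=schedule,
        seed=rng_seed,
    )


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def cohort_roles(
    n_cases: int, avm_fraction: float, high_grade_fraction: float
) -> list[tuple[str, str]]:
    """(diagnosis, grade_class) role of every cohort case, before shuffling.

    Round-half-up counts: ``n_avm = round(n_cases * avm_fraction)`` and
    ``n_high = round(n_avm * high_grade_fraction)``.
    """
    if n_cases < 2:
        raise ValueError("n_cases must be >= 2")
    if not (0.0 <= avm_fraction <= 1.0 and 0.0 <= high_grade_fraction <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    n_avm = _round_half_up(n_cases * avm_fraction)
    n_high = _round_half_up(n_avm * high_grade_fraction)
    return (
        [("AVM", "high")] * n_high
        + [("AVM", "low")] * (n_avm - n_high)
        + [("non-AVM", "none")] * (n_cases - n_avm)
    )


def generate_cohort(
    n_cases: int,
    avm_fraction: float,
    high_grade_fraction: float,
    rng_seed: int,
    out_dir: str | Path,
    image_size: tuple[int, int] = (96, 96),
    noise_sd: float = 8.0,
) -> pd.DataFrame:
    """Generate a cohort of phantom cases on disk and return its manifest.

    Writes, under ``out_dir``:

    * ``cases/<case_id>/frame_%04d.png`` — 8-bit grayscale frames;
    * ``truth_boxes.csv`` — ground-truth annotation table for all cases;
    * ``labels.csv`` — case_id, diagnosis, grade_class;
    * ``manifest.csv`` — per-case seed, schedule summary and truth T1..T5.

    Class counts follow round-half-up: ``n_avm = round(n_cases *
    avm_fraction)`` and ``n_high = round(n_avm * high_grade_fraction)``.
    Case order is shuffled deterministically by ``rng_seed``.
    """
    roles = cohort_roles(n_cases, avm_fraction, high_grade_fraction)
    out_dir = Path(out_dir)
    (out_dir / "cases").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(roles))
    roles = [roles[i] for i in order]

    manifest_rows = []
    box_tables = []
    for i, (diagnosis, grade) in enumerate(roles):
        case_id = f"case_{i:04d}"
        seed_i = int(rng.integers(0, 2**31 - 1))
        n_frames = int(rng.integers(N_FRAMES_RANGE[0], N_FRAMES_RANGE[1] + 1))
        sched = build_schedule(diagnosis, grade, n_frames, seed_i)
        case = render_case(sched, image_size, noise_sd, seed_i, case_id=case_id)
        case_dir = out_dir / "cases" / case_id
        case_dir.mkdir(exist_ok=True)
        for f in range(case.frames.n_frames):
            iio.imwrite(case_dir / f"frame_{f:04d}.png", case.frames[f])
        box_tables.append(case.truth_boxes)
        t = case.truth_temporal
        manifest_rows.append(
            {
                "case_id": case_id, "seed": seed_i, "diagnosis": diagnosis,
                "grade_class": grade, "n_frames": n_frames,
                "frame_interval_ms": sched.frame_interval_ms,
                "noise_sd": noise_sd,
                "nidus_diameter_px": sched.nidus_diameter_px,
                "T1": t[0], "T2": t[1], "T3": t[2], "T4": t[3], "T5": t[4],
            }
        )

    manifest = pd.DataFrame(manifest_rows)
    write_detection_table(pd.concat(box_tables, ignore_index=True),
                          out_dir / "truth_boxes.csv")
    manifest[["case_id", "diagnosis", "grade_class"]].to_csv(
        out_dir / "labels.csv", index=False, lineterminator="\n"
    )
    manifest.to_csv(out_dir / "manifest.csv", index=False, lineterminator="\n")
    return manifest
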