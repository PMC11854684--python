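"""Configuration, file formats, longitudinal comparison and the end-to-end run.

The pipeline binds the four stages — simulate, quantify, grade, concord —
into a single deterministic run: identical ``(config, seed)`` produce
bit-identical artifacts.  All CSV/JSON outputs have fixed, documented
schemas; unknown columns on read are hard errors, because silently coerced
or ignored fields would corrupt the agreement statistics downstream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import __version__
from .concordance import build_assessments, build_report
from .errors import (
    InsufficientSeriesError,
    InvalidParameterError,
    PipelineError,
    SchemaError,
)
from .grading import GRADE_COLUMNS, PhotoGrader, PhotoGrade
from .images import FundusImage, load_image, save_image
from .phantom import DEFAULT_DIRECTION_MIX, generate_cohort
from .quantify import ESTIMATE_COLUMNS, GhostQuantifier, LandmarkDisplacementEstimator

logger = logging.getLogger(__name__)

TRUTH_COLUMNS = [
    "eye_id",
    "direction_class",
    "dx_px",
    "dy_px",
    "rotation_deg",
    "n_images",
    "noise_sigma",
    "seed",
]
CLINICAL_COLUMNS = ["eye_id", "clinical_direction", "clinical_amplitude"]
SESSION_COLUMNS = ["eye_id", "session_date", "amplitude_grade", "direction_class"]


@dataclasses.dataclass
class RunConfig:
    """Everything a full pipeline run depends on.

    Thresholds are the detection and grading defaults documented in
    :mod:`ghostgrade.quantify` and :mod:`ghostgrade.grading`; clinician
    noise parameters control the simulated clinical records.
    """

    n_eyes: int = 53
    seed: int = 0
    image_size: Tuple[int, int] = (512, 512)
    noise_sigma: float = 0.01
    p_over: float = 0.2
    p_missrot: float = 0.5
    mix: Optional[Dict[str, float]] = None
    peak_threshold: float = 0.2
    min_separation: int = 4
    displacement_floor: float = 3.0
    rotation_floor: float = 1.5
    cut_small: float = 0.15
    cut_large: float = 0.40
    angle_horizontal: float = 30.0
    angle_vertical: float = 60.0
    out_dir: str = "ghostgrade_run"

    def validate(self) -> None:
        if self.n_eyes < 1:
            raise InvalidParameterError("n_eyes must be >= 1")
        if min(self.image_size) < 256:
            raise InvalidParameterError("image_size must be at least 256x256")
        if not (0 < self.peak_threshold < 1):
            raise InvalidParameterError("peak_threshold must lie in (0, 1)")
        if not (0 < self.cut_small < self.cut_large):
            raise InvalidParameterError("grade cut-points must be positive and ordered")
        if not (0 < self.angle_horizontal <= self.angle_vertical < 90):
            raise InvalidParameterError("angle bins must satisfy 0 < low <= high < 90")
        if self.displacement_floor < 0 or self.rotation_floor < 0:
            raise InvalidParameterError("floors must be nonnegative")
        if not (0 <= self.p_over <= 1 and 0 <= self.p_missrot <= 1):
            raise InvalidParameterError("noise probabilities must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise InvalidParameterError("noise_sigma must be nonnegative")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["image_size"] = list(self.image_size)
        atomic_write_text(path, yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "image_size" in data:
            data["image_size"] = tuple(data["image_size"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# Atomic, schema-checked I/O


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write a text file atomically (temp file + rename)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_csv(df: pd.DataFrame, path: str | Path, columns: Sequence[str]) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns for {Path(path).name}: {sorted(missing)}")
    atomic_write_text(path, df[list(columns)].to_csv(index=False))


def read_csv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    """Read a documented CSV schema; unknown or missing columns are errors."""
    df = pd.read_csv(path)
    extra = set(df.columns) - set(columns)
    missing = set(columns) - set(df.columns)
    if extra or missing:
        raise SchemaError(
            f"{Path(path).name}: unknown columns {sorted(extra)}, "
            f"missing columns {sorted(missing)}"
        )
    return df[list(columns)]


def write_json(obj, path: str | Path) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Longitudinal comparison


@dataclasses.dataclass
class LongitudinalSeries:
    """Date-ordered photographic grades of one eye across visits."""

    eye_id: str
    sessions: List[Tuple[str, PhotoGrade]]  # (ISO date, grade), ascending

    def __post_init__(self) -> None:
        dates = [d for d, _ in self.sessions]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise InvalidParameterError("sessions must be strictly increasing in date")


def compare_sessions(series: LongitudinalSeries) -> Dict[str, object]:
    """Per-interval grade change, detection change, and resolution flags.

    ``resolved`` means the last session shows no ghost after an earlier
    detected one (e.g. nystagmus resolution after a null-zone-shifting
    strabismus procedure); ``intermittent`` flags detection toggling more
    than once across the series (paroxysmal or latent nystagmus appearing
    in only some sessions).
    """
    if len(series.sessions) < 2:
        raise InsufficientSeriesError("need at least two sessions to compare")
    grades = [g.amplitude_grade for _, g in series.sessions]
    dates = [d for d, _ in series.sessions]
    intervals = []
    for (d0, g0), (d1, g1) in zip(series.sessions, series.sessions[1:]):
        intervals.append(
            {
                "from_date": d0,
                "to_date": d1,
                "grade_delta": g1.amplitude_grade - g0.amplitude_grade,
                "detection_changed": (g0.amplitude_grade > 0) != (g1.amplitude_grade > 0),
                "direction_changed": g0.direction_class != g1.direction_class,
            }
        )
    detected = [g > 0 for g in grades]
    toggles = sum(a != b for a, b in zip(detected, detected[1:]))
    resolved = grades[-1] == 0 and any(g > 0 for g in grades[:-1])
    return {
        "eye_id": series.eye_id,
        "intervals": intervals,
        "total_delta": grades[-1] - grades[0],
        "resolved": resolved,
        "intermittent": toggles >= 2,
    }


def series_from_frame(df: pd.DataFrame) -> List[LongitudinalSeries]:
    """Build per-eye longitudinal series from a sessions table."""
    out = []
    for eye_id, sub in df.groupby("eye_id", sort=True):
        sub = sub.sort_values("session_date")
        sessions = [
            (
                str(row["session_date"]),
                PhotoGrade(
                    eye_id=str(eye_id),
                    amplitude_grade=int(row["amplitude_grade"]),
                    direction_class=str(row["direction_class"]),
                    arm="quantitative",
                    normalized_displacement=0.0,
                ),
            )
            for _, row in sub.iterrows()
        ]
        out.append(LongitudinalSeries(eye_id=str(eye_id), sessions=sessions))
    return out


# ---------------------------------------------------------------------------
# Stages


def simulate_stage(config: RunConfig, out_dir: Path) -> None:
    images, truths, records = generate_cohort(
        config.n_eyes,
        config.seed,
        mix=config.mix,
        image_size=config.image_size,
        noise_sigma=config.noise_sigma,
        p_over=config.p_over,
        p_missrot=config.p_missrot,
    )
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for img in images:
        save_image(img, img_dir / f"{img.eye_id}.png")
    truth_rows = [
        {
            "eye_id": t.eye_id,
            "direction_class": t.direction_class,
            "dx_px": t.displacement_px[0],
            "dy_px": t.displacement_px[1],
            "rotation_deg": t.rotation_deg,
            "n_images": t.n_images,
            "noise_sigma": t.noise_sigma,
            "seed": config.seed,
        }
        for t in truths
    ]
    write_csv(pd.DataFrame(truth_rows), out_dir / "truth.csv", TRUTH_COLUMNS)
    clin_rows = [
        {
            "eye_id": r.eye_id,
            "clinical_direction": r.clinical_direction,
            "clinical_amplitude": r.clinical_amplitude,
        }
        for r in records
    ]
    write_csv(pd.DataFrame(clin_rows), out_dir / "clinical.csv", CLINICAL_COLUMNS)


def load_cohort_images(img_dir: Path) -> List[FundusImage]:
    paths = sorted(Path(img_dir).glob("*.png"))
    if not paths:
        raise InvalidParameterError(f"no PNG images found under {img_dir}")
    return [load_image(p) for p in paths]


def quantify_stage(config: RunConfig, images: Sequence[FundusImage], out_path: Path) -> pd.DataFrame:
    quant = GhostQuantifier(
        peak_threshold=config.peak_threshold,
        min_separation=config.min_separation,
        displacement_floor=config.displacement_floor,
        rotation_floor=config.rotation_floor,
    )
    df = quant.fit(images).transform(images)
    write_csv(df, out_path, ESTIMATE_COLUMNS)
    return df


def grade_stage(config: RunConfig, images: Sequence[FundusImage], out_path: Path) -> pd.DataFrame:
    frames = []
    for arm in ("quantitative", "qualitative"):
        grader = PhotoGrader(
            arm=arm,
            cut_small=config.cut_small,
            cut_large=config.cut_large,
            angle_horizontal=config.angle_horizontal,
            angle_vertical=config.angle_vertical,
        )
        frames.append(grader.fit(images).transform(images))
    df = pd.concat(frames, ignore_index=True)
    write_csv(df, out_path, GRADE_COLUMNS)
    return df


def concord_stage(grades: pd.DataFrame, clinical: pd.DataFrame, out_dir: Path) -> Dict:
    assessments = build_assessments(grades, clinical)
    report = build_report(assessments)
    per_eye = pd.DataFrame(
        [
            {
                "eye_id": a.eye_id,
                "clinical_direction": a.clinical_direction,
                "clinical_amplitude": a.clinical_amplitude,
                "quant_direction": a.quant_grade.direction_class,
                "quant_amplitude": a.quant_grade.amplitude_grade,
                "qual_direction": a.qual_grade.direction_class,
                "qual_amplitude": a.qual_grade.amplitude_grade,
                "dir_match_quant": a.quant_grade.direction_class == a.clinical_direction,
                "amp_match_quant": a.quant_grade.amplitude_grade == a.clinical_amplitude,
            }
            for a in assessments
        ]
    )
    write_csv(per_eye, out_dir / "per_eye.csv", list(per_eye.columns))
    payload = {"report": report.as_dict(), "version": __version__}
    write_json(payload, out_dir / "report.json")
    return payload


def run_pipeline(config: RunConfig) -> Dict:
    """simulate → quantify → grade → concord, atomically and reproducibly."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "ghostgrade %s run: n_eyes=%d seed=%d", __version__, config.n_eyes, config.seed
    )
    config.to_yaml(out_dir / "config.yaml")
    stage = "simulate"
    try:
        simulate_stage(config, out_dir)
        stage = "quantify"
        images = load_cohort_images(out_dir / "images")
        quantify_stage(config, images, out_dir / "estimates.csv")
        stage = "grade"
        grades = grade_stage(config, images, out_dir / "grades.csv")
        stage = "concord"
        clinical = read_csv(out_dir / "clinical.csv", CLINICAL_COLUMNS)
        payload = concord_stage(grades, clinical, out_dir)
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    return payload
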