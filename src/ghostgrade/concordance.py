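"""Agreement analysis between photographic arms and clinical examination.

Implements the cohort-level statistics used to compare fundus-photograph
nystagmus assessment with the clinical examination: detection rates,
field-wise percent agreement (direction / amplitude, against the clinical
record or between the two photographic arms), categorical cohort summaries,
and a Mann-Whitney U comparison of the two arms' ordinal grade
distributions.

Percent agreement is raw (no chance correction); Cohen's kappa is offered
as a clearly-labelled optional extra beyond the core report.  Agreement
with the clinical record is computed, by default, over the eyes in which
the photograph shows ghost images (``denominator="detected_only"``), since
an undetected photograph expresses no direction or amplitude; the ``"all"``
denominator is also exposed.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .errors import InvalidParameterError, UndefinedDenominatorError
from .grading import PhotoGrade


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (the convention of clinical tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, decimals: int = 2) -> float:
    if total <= 0:
        raise UndefinedDenominatorError("percentage over an empty denominator")
    return round_half_up(100.0 * count / total, decimals)


@dataclasses.dataclass
class EyeAssessment:
    """All three assessments of one eye, joined on ``eye_id``."""

    eye_id: str
    clinical_direction: str
    clinical_amplitude: int
    quant_grade: PhotoGrade
    qual_grade: PhotoGrade

    def __post_init__(self) -> None:
        for g in (self.quant_grade, self.qual_grade):
            if g.eye_id and g.eye_id != self.eye_id:
                raise InvalidParameterError(
                    f"assessment eye_id mismatch: {g.eye_id!r} != {self.eye_id!r}"
                )


@dataclasses.dataclass
class ConcordanceReport:
    """Cohort-level agreement statistics (percent scale, 0-100)."""

    n_eyes: int
    detection_rate_qual: float
    detection_rate_quant: float
    dir_match_qual: float
    dir_match_quant: float
    amp_match_qual: float
    amp_match_quant: float
    cross_arm_dir: float
    cross_arm_amp: float
    mw_U: float
    mw_p: float

    def as_dict(self) -> Dict[str, float]:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Rates and agreement


def detection_rate(grades: Sequence[PhotoGrade | int]) -> float:
    """Percent of eyes with a detected ghost (amplitude grade > 0).

    Accepts :class:`PhotoGrade` objects or raw integer grades; reports two
    decimals (half-up).
    """
    if len(grades) == 0:
        raise InvalidParameterError("detection_rate of an empty list")
    vals = [g.amplitude_grade if isinstance(g, PhotoGrade) else int(g) for g in grades]
    return percent(sum(v > 0 for v in vals), len(vals), decimals=2)


def _arm_grade(a: EyeAssessment, arm: str) -> PhotoGrade:
    if arm == "quantitative":
        return a.quant_grade
    if arm == "qualitative":
        return a.qual_grade
    raise InvalidParameterError("arm must be quantitative or qualitative")


def percent_agreement(
    assessments: Sequence[EyeAssessment],
    field: Literal["direction", "amplitude"],
    arm: Literal["quantitative", "qualitative"],
    denominator: Literal["detected_only", "all"] = "detected_only",
) -> float:
    """Exact-match percentage of a photographic arm against the clinic.

    ``field="direction"`` requires identical class labels;
    ``field="amplitude"`` requires identical ordinal grades.
    """
    if len(assessments) == 0:
        raise InvalidParameterError("percent_agreement of an empty list")
    if field not in ("direction", "amplitude"):
        raise InvalidParameterError("field must be direction or amplitude")
    rows = list(assessments)
    if denominator == "detected_only":
        rows = [a for a in rows if _arm_grade(a, arm).amplitude_grade > 0]
    elif denominator != "all":
        raise InvalidParameterError("denominator must be detected_only or all")
    if not rows:
        raise UndefinedDenominatorError("no eyes in the requested denominator")
    if field == "direction":
        hits = sum(
            _arm_grade(a, arm).direction_class == a.clinical_direction for a in rows
        )
    else:
        hits = sum(
            _arm_grade(a, arm).amplitude_grade == a.clinical_amplitude for a in rows
        )
    return percent(hits, len(rows), decimals=2)


def cross_arm_agreement(
    assessments: Sequence[EyeAssessment],
    field: Literal["direction", "amplitude"],
) -> float:
    """Exact-match percentage between the two photographic arms.

    Computed over eyes detected by at least one arm (eyes blank on both
    photographs carry no photographic information to compare).
    """
    if len(assessments) == 0:
        raise InvalidParameterError("cross_arm_agreement of an empty list")
    if field not in ("direction", "amplitude"):
        raise InvalidParameterError("field must be direction or amplitude")
    rows = [
        a
        for a in assessments
        if a.quant_grade.amplitude_grade > 0 or a.qual_grade.amplitude_grade > 0
    ]
    if not rows:
        raise UndefinedDenominatorError("no eyes detected by either arm")
    if field == "direction":
        hits = sum(
            a.quant_grade.direction_class == a.qual_grade.direction_class for a in rows
        )
    else:
        hits = sum(
            a.quant_grade.amplitude_grade == a.qual_grade.amplitude_grade for a in rows
        )
    return percent(hits, len(rows), decimals=2)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return _scipy_stats.rankdata(pooled, method="average")


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of the first sample, from midranks of the pooled data."""
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    ra = ranks[: len(a)].sum()
    return float(ra - len(a) * (len(a) + 1) / 2.0)


def mann_whitney(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    mode: Literal["exact", "normal"] = "exact",
    max_enumeration: int = 2_000_000,
) -> Tuple[float, float]:
    """Mann-Whitney U with midranks; exact or normal-approximation p.

    ``exact`` enumerates the full permutation distribution of U over all
    group assignments of the pooled data (two-tailed
    ``p = P(|U - mu| >= |u_obs - mu|)``, where ``mu = n_a n_b / 2``);
    ``normal`` uses the tie-corrected Gaussian approximation with a 0.5
    continuity correction.  When every pooled observation is identical the
    comparison is degenerate and ``p = 1`` is reported.

    Returns ``(U, p)`` with U the statistic of ``sample_a``.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InvalidParameterError("both samples must be nonempty")
    na, nb = len(a), len(b)
    u_obs = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return u_obs, 1.0  # degenerate ties: all observations identical
    mu = na * nb / 2.0

    if mode == "exact":
        n = na + nb
        total = math.comb(n, na)
        if total > max_enumeration:
            raise InvalidParameterError(
                f"exact enumeration of C({n},{na}) = {total} assignments exceeds "
                f"max_enumeration={max_enumeration}; use mode='normal'"
            )
        ranks = _midranks(pooled)
        ra_offset = na * (na + 1) / 2.0
        dev_obs = abs(u_obs - mu)
        hits = 0
        for idx in itertools.combinations(range(n), na):
            u = ranks[list(idx)].sum() - ra_offset
            if abs(u - mu) >= dev_obs - 1e-9:
                hits += 1
        return u_obs, hits / total

    if mode != "normal":
        raise InvalidParameterError("mode must be exact or normal")
    n = na + nb
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = 2.0 * _scipy_stats.norm.sf(z)
    return u_obs, float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Cohort summaries


def summarize_counts(
    counts: Dict[str, int] | pd.Series, total: Optional[int] = None
) -> pd.DataFrame:
    """Per-category counts with half-up one-decimal percentages."""
    s = pd.Series(counts, dtype=int)
    denom = int(total) if total is not None else int(s.sum())
    if denom <= 0:
        raise UndefinedDenominatorError("summary over an empty cohort")
    return pd.DataFrame(
        {
            "n": s,
            "pct": [percent(int(v), denom, decimals=1) for v in s],
        }
    )


def summarize_cohort(
    assessments: Sequence[EyeAssessment],
    patient_table: Optional[pd.DataFrame] = None,
) -> Dict[str, pd.DataFrame]:
    """Cohort composition tables: per-arm direction and amplitude
    distributions over eyes, plus per-category patient summaries for any
    categorical columns of ``patient_table``."""
    if len(assessments) == 0:
        raise InvalidParameterError("summarize_cohort of an empty assessment list")
    out: Dict[str, pd.DataFrame] = {}
    dirs = {
        "clinical": [a.clinical_direction for a in assessments],
        "quantitative": [a.quant_grade.direction_class for a in assessments],
        "qualitative": [a.qual_grade.direction_class for a in assessments],
    }
    amps = {
        "clinical": [a.clinical_amplitude for a in assessments],
        "quantitative": [a.quant_grade.amplitude_grade for a in assessments],
        "qualitative": [a.qual_grade.amplitude_grade for a in assessments],
    }
    for name, values in dirs.items():
        out[f"direction_{name}"] = summarize_counts(pd.Series(values).value_counts())
    for name, values in amps.items():
        out[f"amplitude_{name}"] = summarize_counts(
            pd.Series(values).value_counts().astype(int)
        )
    if patient_table is not None and len(patient_table):
        for col in patient_table.columns:
            if patient_table[col].dtype == object or patient_table[col].nunique() <= 10:
                out[f"patients_{col}"] = summarize_counts(
                    patient_table[col].value_counts(), total=len(patient_table)
                )
    return out


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Chance-corrected agreement (optional extra beyond raw percent)."""
    from sklearn.metrics import cohen_kappa_score

    return float(cohen_kappa_score(list(labels_a), list(labels_b)))


# ---------------------------------------------------------------------------
# Assembly


def build_assessments(
    grades: pd.DataFrame, clinical: pd.DataFrame
) -> List[EyeAssessment]:
    """Join per-eye photographic grades (both arms) with clinical records.

    ``grades`` must hold one quantitative and one qualitative row per eye;
    unmatched eye ids on either side are an error listing the offenders.
    """
    need_g = {"eye_id", "arm", "amplitude_grade", "direction_class"}
    if not need_g.issubset(grades.columns):
        raise InvalidParameterError(f"grades table must have columns {sorted(need_g)}")
    need_c = {"eye_id", "clinical_direction", "clinical_amplitude"}
    if not need_c.issubset(clinical.columns):
        raise InvalidParameterError(f"clinical table must have columns {sorted(need_c)}")
    gids = set(grades["eye_id"])
    cids = set(clinical["eye_id"])
    if gids != cids:
        raise InvalidParameterError(
            f"unmatched eye ids; only in grades: {sorted(gids - cids)}, "
            f"only in clinical: {sorted(cids - gids)}"
        )
    clin = clinical.set_index("eye_id")
    out: List[EyeAssessment] = []
    for eye_id, sub in grades.groupby("eye_id", sort=True):
        arms = {}
        for _, row in sub.iterrows():
            arms[row["arm"]] = PhotoGrade(
                eye_id=str(eye_id),
                amplitude_grade=int(row["amplitude_grade"]),
                direction_class=str(row["direction_class"]),
                arm=str(row["arm"]),
                normalized_displacement=float(row.get("normalized_displacement", 0.0)),
                rotation_deg=float(row.get("rotation_deg", 0.0)),
            )
        if set(arms) != {"quantitative", "qualitative"}:
            raise InvalidParameterError(
                f"eye {eye_id!r} must have exactly one quantitative and one "
                f"qualitative grade row"
            )
        crow = clin.loc[str(eye_id)]
        # unknown labels are hard errors, never coerced: silent coercion
        # would corrupt the agreement statistics
        if str(crow["clinical_direction"]) not in (
            "horizontal",
            "vertical",
            "rotary",
            "combined",
        ):
            raise InvalidParameterError(
                f"unknown clinical_direction {crow['clinical_direction']!r} "
                f"for eye {eye_id!r}"
            )
        if int(crow["clinical_amplitude"]) not in (1, 2, 3):
            raise InvalidParameterError(
                f"clinical_amplitude for eye {eye_id!r} must be 1, 2 or 3"
            )
        out.append(
            EyeAssessment(
                eye_id=str(eye_id),
                clinical_direction=str(crow["clinical_direction"]),
                clinical_amplitude=int(crow["clinical_amplitude"]),
                quant_grade=arms["quantitative"],
                qual_grade=arms["qualitative"],
            )
        )
    return out


def build_report(
    assessments: Sequence[EyeAssessment],
    mw_mode: Literal["exact", "normal"] = "normal",
) -> ConcordanceReport:
    """Compute the full cohort agreement report.

    The Mann-Whitney comparison is applied to the two photographic arms'
    amplitude-grade distributions (which two groups the original analysis
    compared is not specified; this choice is documented).
    """
    if len(assessments) == 0:
        raise InvalidParameterError("build_report of an empty assessment list")
    quant = [a.quant_grade for a in assessments]
    qual = [a.qual_grade for a in assessments]

    def _safe(fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except UndefinedDenominatorError:
            return float("nan")

    u, p = mann_whitney(
        [g.amplitude_grade for g in quant],
        [g.amplitude_grade for g in qual],
        mode=mw_mode,
    )
    return ConcordanceReport(
        n_eyes=len(assessments),
        detection_rate_qual=detection_rate(qual),
        detection_rate_quant=detection_rate(quant),
        dir_match_qual=_safe(percent_agreement, assessments, "direction", "qualitative"),
        dir_match_quant=_safe(percent_agreement, assessments, "direction", "quantitative"),
        amp_match_qual=_safe(percent_agreement, assessments, "amplitude", "qualitative"),
        amp_match_quant=_safe(percent_agreement, assessments, "amplitude", "quantitative"),
        cross_arm_dir=_safe(cross_arm_agreement, assessments, "direction"),
        cross_arm_amp=_safe(cross_arm_agreement, assessments, "amplitude"),
        mw_U=u,
        mw_p=p,
    )
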