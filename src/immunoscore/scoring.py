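"""Quality control of CD3/CD8 density measurements and computation of the
consensus Immunoscore.

The Immunoscore summarises the adaptive immune infiltrate of a colon tumor:
CD3+ and CD8+ T-cell densities (cells/mm²) are measured in the tumor core
(CT) and at the invasive margin (IM), each density is converted to a
percentile of a reference distribution, and the mean of the four percentiles
is binned into consensus categories:

* two categories:   Lo = [0, 25],  Int+Hi = (25, 100]
* three categories: Lo = [0, 25],  Int = (25, 70],  Hi = (70, 100]
* five categories:  I0 = [0, 10],  I1 = (10, 25],  I2 = (25, 70],
                    I3 = (70, 95], I4 = (95, 100]

Lower bins are closed on the right at the printed cut-point, so a mean
percentile of exactly 25 is Lo and exactly 70 is Int.  Percentiles use the
mid-rank convention (ties in the reference count one half), which is
symmetric, deterministic and bounded in [0, 100].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CHANNELS",
    "INTENSITY_THRESHOLD_AU",
    "MarkerMeasurement",
    "ReferenceDistribution",
    "ImmunoscoreResult",
    "QCReport",
    "apply_qc",
    "density_to_percentile",
    "categorize",
    "compute_immunoscore",
    "score_cohort",
]

#: the four (marker, region) channels, in canonical column order
CHANNELS = ("cd3_ct", "cd3_im", "cd8_ct", "cd8_im")

#: default staining-intensity exclusion threshold (arbitrary units);
#: slides at or below it are excluded.  The AU scale is instrument-specific,
#: so the threshold is configurable wherever it is used.
INTENSITY_THRESHOLD_AU = 152.0

#: more than this many failed antigen-retrieval attempts excludes the slide
MAX_RETRIEVAL_ATTEMPTS = 3

# exclusion reasons in fixed priority order (first matching reason recorded)
QC_REASONS = ("missing_region", "low_intensity", "damaged_slide", "retrieval_failures")


@dataclass
class MarkerMeasurement:
    """CD3/CD8 densities for one patient with staining-quality metadata."""

    patient_id: str
    cd3_ct: float | None
    cd3_im: float | None
    cd8_ct: float | None
    cd8_im: float | None
    staining_intensity_au: float = 1000.0
    ct_available: bool = True
    im_available: bool = True
    attempts_antigen_retrieval: int = 0
    damaged_slide: bool = False

    def density(self, channel: str) -> float | None:
        return getattr(self, channel)


@dataclass
class ReferenceDistribution:
    """Sorted reference density vectors per (marker, region) channel."""

    vectors: dict[str, np.ndarray]

    def __post_init__(self):
        clean = {}
        for name, v in self.vectors.items():
            arr = np.asarray(v, dtype=float)
            if arr.size < 2:
                raise ValueError(f"reference vector {name!r} needs >= 2 values")
            if np.any(np.diff(arr) < 0):
                raise ValueError(f"reference vector {name!r} is not sorted")
            clean[name] = arr
        self.vectors = clean

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: pd.Series(v) for k, v in self.vectors.items()})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceDistribution":
        return cls({c: df[c].dropna().to_numpy() for c in CHANNELS if c in df})


@dataclass
class ImmunoscoreResult:
    patient_id: str
    percentiles: dict[str, float]
    mean_percentile: float
    category2: str
    category3: str
    category5: str


@dataclass
class QCReport:
    retained_ids: list[str]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    @property
    def excluded_ids(self) -> list[str]:
        return [pid for pid, _ in self.excluded]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"patient_id": p, "status": "retained", "reason": ""} for p in self.retained_ids]
        rows += [{"patient_id": p, "status": "excluded", "reason": r} for p, r in self.excluded]
        return pd.DataFrame(rows, columns=["patient_id", "status", "reason"])


def _qc_reason(m: MarkerMeasurement, intensity_threshold_au: float) -> str | None:
    if not (m.ct_available and m.im_available):
        return "missing_region"
    if m.staining_intensity_au <= intensity_threshold_au:
        return "low_intensity"
    if m.damaged_slide:
        return "damaged_slide"
    if m.attempts_antigen_retrieval > MAX_RETRIEVAL_ATTEMPTS:
        return "retrieval_failures"
    return None


def apply_qc(
    measurements: list[MarkerMeasurement],
    intensity_threshold_au: float = INTENSITY_THRESHOLD_AU,
) -> QCReport:
    """Partition measurements into retained and excluded with reasons.

    A measurement is excluded iff either tumor region is unavailable, the
    staining intensity is at or below the threshold, the slide is flagged
    damaged, or antigen retrieval failed more than three times.  Only the
    first matching reason (in that fixed order) is recorded.
    """
    if intensity_threshold_au < 0:
        raise ValueError("intensity threshold must be >= 0")
    seen = set()
    report = QCReport(retained_ids=[])
    for m in measurements:
        if m.patient_id in seen:
            raise ValueError(f"duplicate patient_id: {m.patient_id!r}")
        seen.add(m.patient_id)
        reason = _qc_reason(m, intensity_threshold_au)
        if reason is None:
            report.retained_ids.append(m.patient_id)
        else:
            report.excluded.append((m.patient_id, reason))
    return report


def density_to_percentile(density: float, reference_vector) -> float:
    """Mid-rank percentile of ``density`` within a sorted reference vector.

    100 * (#{ref < d} + 0.5 * #{ref == d}) / len(ref); monotone
    nondecreasing in the density and always in [0, 100].
    """
    ref = np.asarray(reference_vector, dtype=float)
    if ref.size < 2:
        raise ValueError("reference vector needs >= 2 values")
    if density is None or (isinstance(density, float) and math.isnan(density)):
        raise ValueError("density is missing: measurement is not scoreable")
    if density < 0:
        raise ValueError("density must be >= 0")
    below = np.searchsorted(ref, density, side="left")
    upto = np.searchsorted(ref, density, side="right")
    return float(100.0 * (below + 0.5 * (upto - below)) / ref.size)


def categorize(mean_percentile: float, scheme: str) -> str:
    """Bin a mean percentile into the two-, three- or five-category scheme."""
    v = mean_percentile
    if not 0.0 <= v <= 100.0:
        raise ValueError(f"mean percentile {v} outside [0, 100]")
    if scheme == "two":
        return "Lo" if v <= 25.0 else "Int+Hi"
    if scheme == "three":
        return "Lo" if v <= 25.0 else ("Int" if v <= 70.0 else "Hi")
    if scheme == "five":
        if v <= 10.0:
            return "I0"
        if v <= 25.0:
            return "I1"
        if v <= 70.0:
            return "I2"
        if v <= 95.0:
            return "I3"
        return "I4"
    raise ValueError(f"unknown scheme: {scheme!r}")


def compute_immunoscore(m: MarkerMeasurement, ref: ReferenceDistribution) -> ImmunoscoreResult:
    """Four channel percentiles, their mean, and all three category labels."""
    for ch in CHANNELS:
        if ch not in ref.vectors:
            raise ValueError(f"reference distribution lacks channel {ch!r}")
    pct = {ch: density_to_percentile(m.density(ch), ref.vectors[ch]) for ch in CHANNELS}
    mean = float(np.mean(list(pct.values())))
    return ImmunoscoreResult(
        patient_id=m.patient_id,
        percentiles=pct,
        mean_percentile=mean,
        category2=categorize(mean, "two"),
        category3=categorize(mean, "three"),
        category5=categorize(mean, "five"),
    )


# ---------------------------------------------------------------------------
# table-level interface (markers.csv -> immunoscore.csv)
# ---------------------------------------------------------------------------


def measurements_from_frame(markers: pd.DataFrame) -> list[MarkerMeasurement]:
    """Build measurement records from a markers table (see ``markers.csv``)."""
    out = []
    for row in markers.itertuples(index=False):
        d = row._asdict()
        out.append(
            MarkerMeasurement(
                patient_id=str(d["patient_id"]),
                cd3_ct=d.get("cd3_ct"),
                cd3_im=d.get("cd3_im"),
                cd8_ct=d.get("cd8_ct"),
                cd8_im=d.get("cd8_im"),
                staining_intensity_au=float(d.get("staining_intensity_au", 1000.0)),
                ct_available=bool(d.get("ct_available", True)),
                im_available=bool(d.get("im_available", True)),
                attempts_antigen_retrieval=int(d.get("attempts_antigen_retrieval", 0)),
                damaged_slide=bool(d.get("damaged_slide", False)),
            )
        )
    return out


def score_cohort(
    markers: pd.DataFrame,
    reference: ReferenceDistribution,
    intensity_threshold_au: float = INTENSITY_THRESHOLD_AU,
) -> tuple[pd.DataFrame, QCReport]:
    """QC a markers table and score every retained patient.

    Returns the score table (one row per retained patient: the four channel
    percentiles, the mean, and is2/is3/is5 labels) and the QC report.
    """
    measurements = measurements_from_frame(markers)
    report = apply_qc(measurements, intensity_threshold_au)
    retained = set(report.retained_ids)
    rows = []
    for m in measurements:
        if m.patient_id not in retained:
            continue
        res = compute_immunoscore(m, reference)
        rows.append(
            {
                "patient_id": res.patient_id,
                "p_cd3_ct": res.percentiles["cd3_ct"],
                "p_cd3_im": res.percentiles["cd3_im"],
                "p_cd8_ct": res.percentiles["cd8_ct"],
                "p_cd8_im": res.percentiles["cd8_im"],
                "mean_percentile": res.mean_percentile,
                "is2": res.category2,
                "is3": res.category3,
                "is5": res.category5,
            }
        )
    cols = ["patient_id", "p_cd3_ct", "p_cd3_im", "p_cd8_ct", "p_cd8_im",
            "mean_percentile", "is2", "is3", "is5"]
    return pd.DataFrame(rows, columns=cols), report
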