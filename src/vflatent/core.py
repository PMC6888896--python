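"""Visual-field data model: QC, laterality, normalization, splits, I/O.

A visual field is stored as its 52 total-deviation (TD) values in dB,
indexed in the reading order of the right-eye 24-2 chart (see
:mod:`vflatent.grid`).  Left-eye tests are mirrored into right-eye order so
the whole pipeline works on a single layout.  For the image model the TD
vector is embedded in the 12x12 frame, zero-padded outside the informative
cells, and affinely mapped to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grid import GridMask, build_24_2_mask, mirror_permutation

STATUSES = ("normal", "suspect", "glaucoma")

# TD range covered by the fixed normalization map (dB).  -38 dB is beyond any
# recordable loss on SAP; +6 dB covers supra-normal sensitivity.
TD_MIN = -38.0
TD_MAX = 6.0

# QC exclusion thresholds: strictly more than 33% fixation losses or strictly
# more than 15% false-positive errors.
FL_MAX = 0.33
FP_MAX = 0.15


@dataclass(frozen=True)
class NormalizationSpec:
    """Affine map [td_min, td_max] dB -> [0, 1], clipping outside the range."""

    td_min: float = TD_MIN
    td_max: float = TD_MAX

    def __post_init__(self) -> None:
        if not self.td_min < self.td_max:
            raise ValueError("td_min must be < td_max")

    def normalize(self, td: np.ndarray) -> np.ndarray:
        x = (np.asarray(td, dtype=float) - self.td_min) / (self.td_max - self.td_min)
        return np.clip(x, 0.0, 1.0)

    def denormalize(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) * (self.td_max - self.td_min) + self.td_min


@dataclass
class VisualField:
    """One 24-2 test: 52 TD values (dB) plus reliability metadata."""

    td: np.ndarray
    fl_rate: float = 0.0
    fp_rate: float = 0.0
    laterality: str = "OD"

    def __post_init__(self) -> None:
        self.td = np.asarray(self.td, dtype=float)
        if self.td.shape != (52,):
            raise ValueError(f"td must have 52 entries, got shape {self.td.shape}")
        if not np.all(np.isfinite(self.td)):
            raise ValueError("td contains non-finite values")
        for name in ("fl_rate", "fp_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")


@dataclass
class PatientSeries:
    """A patient-eye's longitudinal visual fields, times in years from baseline."""

    patient_id: str
    status: str
    times: np.ndarray
    fields: list[VisualField] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if len(self.fields) != len(self.times) or len(self.times) < 1:
            raise ValueError("times and fields must align and be non-empty")
        if self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must start at 0 and be strictly increasing")

    @property
    def n_visits(self) -> int:
        return len(self.times)

    def truncated(self, cutoff_years: float) -> "PatientSeries":
        """Visits at or before ``cutoff_years`` (baseline time is unchanged)."""
        keep = self.times <= cutoff_years
        return PatientSeries(
            self.patient_id, self.status, self.times[keep],
            [f for f, k in zip(self.fields, keep) if k],
        )


def qc_filter(field: VisualField) -> bool:
    """Keep a field unless fixation losses exceed 33% or false positives 15%."""
    return not (field.fl_rate > FL_MAX or field.fp_rate > FP_MAX)


def qc_filter_series(series: PatientSeries) -> PatientSeries | None:
    """Drop unreliable visits; re-anchor time zero to the first kept visit.

    Returns None when no visit survives.
    """
    keep = [qc_filter(f) for f in series.fields]
    if not any(keep):
        return None
    times = series.times[keep]
    return PatientSeries(
        series.patient_id, series.status, times - times[0],
        [f for f, k in zip(series.fields, keep) if k],
    )


def convert_to_right_eye(fld: VisualField, mask: GridMask | None = None) -> VisualField:
    """Mirror a left-eye field into right-eye location order (OD fields pass through)."""
    if fld.laterality == "OD":
        return fld
    mask = mask or build_24_2_mask()
    perm = mirror_permutation(mask)
    td_od = np.empty_like(fld.td)
    td_od[perm] = fld.td
    return replace(fld, td=td_od, laterality="OD")


def to_image(fld: VisualField, mask: GridMask | None = None,
             spec: NormalizationSpec = NormalizationSpec()) -> np.ndarray:
    """Embed a right-eye field in the 12x12 frame, normalized to [0, 1].

    Padding cells are exactly zero, which in normalized units coincides with
    td_min (maximal loss); see the methods note for the implications.
    """
    mask = mask or build_24_2_mask()
    if fld.laterality != "OD":
        raise ValueError("convert to right eye before imaging")
    img = np.zeros(mask.shape, dtype=float)
    img[mask.rows(), mask.cols()] = spec.normalize(fld.td)
    return img


def from_image(img: np.ndarray, mask: GridMask | None = None,
               spec: NormalizationSpec = NormalizationSpec()) -> np.ndarray:
    """Recover the 52 TD values (dB, clipped to the normalization range)."""
    mask = mask or build_24_2_mask()
    img = np.asarray(img, dtype=float)
    if img.shape != mask.shape:
        raise ValueError(f"image must have shape {mask.shape}")
    return spec.denormalize(img[mask.rows(), mask.cols()])


def images_from_series(series_list: Iterable[PatientSeries],
                       mask: GridMask | None = None,
                       spec: NormalizationSpec = NormalizationSpec()) -> np.ndarray:
    """Stack every visit of every series into an N x 12 x 12 image array."""
    mask = mask or build_24_2_mask()
    imgs = [to_image(convert_to_right_eye(f, mask), mask, spec)
            for s in series_list for f in s.fields]
    if not imgs:
        return np.zeros((0,) + mask.shape)
    return np.stack(imgs)


def compute_md(fld: VisualField) -> float:
    """Mean deviation surrogate: unweighted mean of the 52 TD values (dB)."""
    return float(np.mean(fld.td))


def compute_psd(fld: VisualField) -> float:
    """Pattern-standard-deviation surrogate: sample SD of TD about its mean (dB)."""
    return float(np.std(fld.td, ddof=1))


def split_patients(cohort: Sequence[PatientSeries],
                   probs: tuple[float, float, float] = (0.8, 0.1, 0.1),
                   seed: int = 0):
    """Assign each patient independently to train/validation/test.

    Assignment is an independent draw per patient with the given
    probabilities, so realized proportions fluctuate around ``probs``.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (3,) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("probs must be three probabilities summing to 1")
    rng = np.random.default_rng(seed)
    out: tuple[list, list, list] = ([], [], [])
    for series in cohort:
        out[rng.choice(3, p=probs)].append(series)
    return out


def make_folds(cohort: Sequence[PatientSeries], k: int = 5, seed: int = 0):
    """k patient-level (train, validation, test) splits for cross-validation.

    Patients are shuffled once and chunked into k groups; fold i uses group i
    as test, group i+1 (mod k) as validation, and the rest for training, so
    every patient is a test patient in exactly one fold.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(cohort):
        raise ValueError(f"k={k} folds require at least k patients, got {len(cohort)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort))
    groups = np.array_split(order, k)
    folds = []
    for i in range(k):
        test_idx = set(groups[i].tolist())
        val_idx = set(groups[(i + 1) % k].tolist())
        train = [cohort[j] for j in order if j not in test_idx and j not in val_idx]
        val = [cohort[j] for j in order if j in val_idx]
        test = [cohort[j] for j in order if j in test_idx]
        folds.append((train, val, test))
    return folds


# ---------------------------------------------------------------------------
# Longitudinal CSV format: one row per visit.

_META_COLS = ["patient_id", "status", "laterality", "years_from_baseline",
              "fl_rate", "fp_rate"]
_TD_COLS = [f"td_{i:02d}" for i in range(1, 53)]


def cohort_to_frame(cohort: Iterable[PatientSeries]) -> pd.DataFrame:
    rows = []
    for s in cohort:
        for t, f in zip(s.times, s.fields):
            rows.append([s.patient_id, s.status, f.laterality, t,
                         f.fl_rate, f.fp_rate, *f.td])
    return pd.DataFrame(rows, columns=_META_COLS + _TD_COLS)


def write_cohort_csv(cohort: Iterable[PatientSeries], path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[PatientSeries]:
    df = pd.read_csv(path)
    missing = [c for c in _META_COLS + _TD_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing columns: {missing[:4]}...")
    cohort = []
    for pid, g in df.groupby("patient_id", sort=False):
        g = g.sort_values("years_from_baseline")
        fields = [
            VisualField(row[_TD_COLS].to_numpy(dtype=float),
                        fl_rate=float(row["fl_rate"]), fp_rate=float(row["fp_rate"]),
                        laterality=str(row["laterality"]))
            for _, row in g.iterrows()
        ]
        times = g["years_from_baseline"].to_numpy(dtype=float)
        cohort.append(PatientSeries(str(pid), str(g["status"].iloc[0]),
                                    times - times[0], fields))
    return cohort


def save_image_tensor(images: np.ndarray, path: str | Path,
                      mask: GridMask | None = None,
                      spec: NormalizationSpec = NormalizationSpec()) -> None:
    """Write an N x 12 x 12 normalized image stack with its mask and constants."""
    mask = mask or build_24_2_mask()
    np.savez(path, images=np.asarray(images, dtype=float),
             informative=mask.informative,
             index_order=np.asarray(mask.index_order),
             td_min=spec.td_min, td_max=spec.td_max)


def load_image_tensor(path: str | Path):
    data = np.load(path)
    mask = GridMask((12, 12), data["informative"],
                    tuple(map(tuple, data["index_order"].tolist())))
    spec = NormalizationSpec(float(data["td_min"]), float(data["td_max"]))
    return data["images"], mask, spec


def qc_filter_cohort(cohort: Iterable[PatientSeries]) -> list[PatientSeries]:
    """Apply the reliability filter visit-wise across a cohort, logging counts."""
    kept, dropped = [], 0
    for s in cohort:
        n0 = s.n_visits
        filtered = qc_filter_series(s)
        if filtered is not None:
            kept.append(filtered)
            dropped += n0 - filtered.n_visits
        else:
            dropped += n0
    if dropped:
        warnings.warn(f"QC filter excluded {dropped} visual fields", stacklevel=2)
    return kept
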