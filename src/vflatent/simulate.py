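"""Synthetic longitudinal glaucoma cohorts.

Emulates the demographics of a tertiary-care perimetry cohort: a mixture of
normal / glaucoma-suspect / glaucoma eyes (17% / 58% / 25%), pooled baseline
mean deviation around -3.55 dB (SD ~5.7), on average ~7.6 visits spanning
~5 years, localized arcuate-type defects, and homoscedastic test-retest
noise.  Each simulated patient carries a ground-truth baseline pattern and
per-location progression-rate pattern so parameter-recovery and
specificity/hit-rate experiments have a known answer.

The generative model per patient-eye:

* status ~ Multinomial(p_status)
* number of visits = 2 + NegBin with mean ``mean_visits - 2`` and the
  overdispersion implied by ``visits_sd``
* inter-visit gaps ~ Uniform(0.5, 1.5) x mean gap, the mean gap chosen so the
  expected follow-up equals ``mean_followup_years``
* baseline MD ~ Normal(status mean, status SD) truncated to [-30, 2]
* baseline TD pattern = per-location jitter + diffuse shift - loading x
  defect archetype, composed so its mean equals the drawn MD; the localized
  share of the deficit is capped so no location starts below the recordable
  floor
* MD progression rate ~ min(0, Normal(status mean, status SD)); the rate
  pattern spreads it over the same archetype (localized share ``w``) plus a
  diffuse component, scaled so the mean rate equals the drawn MD rate
* visit TD = baseline + t x rate + iid Normal(0, noise_sd) per location,
  clipped to the recordable range [-38, +6] dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PatientSeries, VisualField, TD_MIN, TD_MAX, STATUSES
from .grid import build_24_2_mask

__all__ = [
    "CohortParams", "PatientTruth", "defect_archetypes",
    "simulate_patient", "simulate_cohort", "null_cohort",
    "write_truth_csv", "read_truth_csv",
]


def defect_archetypes() -> dict[str, np.ndarray]:
    """Clinically shaped nonnegative defect bases on the 52-location grid.

    Each archetype is normalized to unit mean over its support.  Shapes follow
    the classic topography of glaucomatous loss: arcuate (Bjerrum) defects
    arching over fixation in one hemifield, a nasal step, a paracentral
    defect, and a diffuse component.
    """
    mask = build_24_2_mask()
    rows, cols = mask.rows(), mask.cols()
    # Back out field coordinates (degrees) from frame cells.
    x = cols * 6 - 33
    y = 27 - rows * 6

    protos = {}
    # Bjerrum area: eccentricity between ~10 and ~24 degrees.
    ecc = np.hypot(x, y)
    bjerrum = (ecc > 9) & (ecc < 25)
    protos["superior_arcuate"] = np.where((y > 0) & bjerrum, 1.0, 0.0)
    protos["inferior_arcuate"] = np.where((y < 0) & bjerrum, 1.0, 0.0)
    protos["nasal_step"] = np.where((x <= -15) & (y > 0), 1.0, 0.0)
    protos["paracentral"] = np.where((np.abs(x) <= 9) & (np.abs(y) <= 9), 1.0, 0.0)
    protos["diffuse"] = np.ones(52)

    out = {}
    for name, v in protos.items():
        support = v > 0
        out[name] = v / v[support].mean()
    return out


@dataclass
class CohortParams:
    """Defaults describe the emulated clinical cohort; see module docstring."""

    p_status: tuple[float, float, float] = (0.17, 0.58, 0.25)
    md_baseline_mean: float = -3.55
    md_baseline_sd: float = 5.71
    # Status-specific baseline-MD components, calibrated so the mixture mean
    # matches md_baseline_mean: 0.17*(-0.5) + 0.58*(-1.5) + 0.25*mu_g = -3.55.
    md_status_mean: dict = dc_field(default_factory=lambda: {
        "normal": -0.5, "suspect": -1.5, "glaucoma": -10.38})
    md_status_sd: dict = dc_field(default_factory=lambda: {
        "normal": 1.0, "suspect": 2.5, "glaucoma": 6.0})
    md_truncation: tuple[float, float] = (-30.0, 2.0)
    mean_visits: float = 7.61
    visits_sd: float = 7.35
    mean_followup_years: float = 4.95
    noise_sd_dB: float = 2.0
    progression_rate_mean_dB_per_year: dict = dc_field(default_factory=lambda: {
        "normal": 0.0, "suspect": -0.05, "glaucoma": -0.5})
    progression_rate_sd: dict = dc_field(default_factory=lambda: {
        "normal": 0.0, "suspect": 0.05, "glaucoma": 0.4})
    localized_fraction: float = 0.7
    baseline_jitter_sd: float = 0.5
    defect_archetypes: dict = dc_field(default_factory=defect_archetypes)

    def __post_init__(self) -> None:
        p = np.asarray(self.p_status, dtype=float)
        if p.shape != (3,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("p_status must be three nonnegative probabilities summing to 1")
        if self.noise_sd_dB < 0:
            raise ValueError("noise_sd_dB must be nonnegative")
        if self.mean_visits < 2:
            raise ValueError("mean_visits must be at least 2")


@dataclass
class PatientTruth:
    """Ground truth behind one simulated series (for recovery experiments)."""

    patient_id: str
    status: str
    baseline_pattern: np.ndarray   # 52-vector, dB
    rate_pattern: np.ndarray       # 52-vector, dB/year
    archetype: str


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """Rejection-sampled truncated normal (bounds far from the bulk here)."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _n_visits(rng: np.random.Generator, params: CohortParams) -> int:
    m = params.mean_visits - 2.0
    v = params.visits_sd ** 2
    if v > m > 0:
        r = m * m / (v - m)
        p = r / (r + m)
        return 2 + int(rng.negative_binomial(r, p))
    return 2 + int(rng.poisson(max(m, 0.0)))


def _baseline_pattern(rng: np.random.Generator, params: CohortParams,
                      status: str, arch: np.ndarray) -> np.ndarray:
    target_md = _truncated_normal(
        rng, params.md_status_mean[status], params.md_status_sd[status],
        *params.md_truncation)
    jitter = rng.normal(0.0, params.baseline_jitter_sd, size=52)
    jitter -= jitter.mean()
    deficit = max(0.0, -target_md)
    w = params.localized_fraction if status != "normal" else 0.0
    a = w * deficit / arch.mean() if deficit > 0 else 0.0
    # Cap the localized loading so no location starts below the floor.
    margin = 2.0 + 3.0 * params.baseline_jitter_sd
    denom = arch.max() - arch.mean()
    if denom > 1e-12:
        a = min(a, max(0.0, (TD_MIN + margin - target_md) / -denom))
    baseline = jitter - a * arch
    baseline += target_md - baseline.mean()
    return baseline


def _rate_pattern(rng: np.random.Generator, params: CohortParams,
                  status: str, arch: np.ndarray) -> np.ndarray:
    mu = params.progression_rate_mean_dB_per_year[status]
    sd = params.progression_rate_sd[status]
    if status == "normal" or (mu == 0.0 and sd == 0.0):
        return np.zeros(52)
    rate_md = min(0.0, rng.normal(mu, sd))
    w = params.localized_fraction
    shape = w * arch / arch.mean() + (1.0 - w)
    return rate_md * shape


def simulate_patient(params: CohortParams, rng: np.random.Generator,
                     patient_id: str = "sim_0") -> tuple[PatientSeries, PatientTruth]:
    """Draw one patient-eye's longitudinal series plus its ground truth."""
    status = STATUSES[rng.choice(3, p=np.asarray(params.p_status, dtype=float))]
    arch_names = [k for k in params.defect_archetypes if k != "diffuse"]
    arch_name = arch_names[rng.integers(len(arch_names))] if arch_names else "diffuse"
    arch = params.defect_archetypes[arch_name]

    baseline = _baseline_pattern(rng, params, status, arch)
    rate = _rate_pattern(rng, params, status, arch)

    n = _n_visits(rng, params)
    gap_mean = params.mean_followup_years / (params.mean_visits - 1.0)
    gaps = gap_mean * rng.uniform(0.5, 1.5, size=n - 1)
    times = np.concatenate([[0.0], np.cumsum(gaps)])

    fields = []
    for t in times:
        td = baseline + t * rate
        if params.noise_sd_dB > 0:
            td = td + rng.normal(0.0, params.noise_sd_dB, size=52)
        td = np.clip(td, TD_MIN, TD_MAX)
        fl, fp = rng.uniform(0.0, 0.1, size=2)
        fields.append(VisualField(td, fl_rate=float(fl), fp_rate=float(fp)))
    series = PatientSeries(patient_id, status, times, fields)
    truth = PatientTruth(patient_id, status, baseline, rate, arch_name)
    return series, truth


def simulate_cohort(n_patients: int, params: CohortParams | None = None,
                    seed: int = 0) -> tuple[list[PatientSeries], list[PatientTruth]]:
    """Simulate a reproducible cohort of ``n_patients`` patient-eyes."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    params = params or CohortParams()
    rng = np.random.default_rng(seed)
    series, truths = [], []
    for i in range(n_patients):
        s, t = simulate_patient(params, rng, patient_id=f"sim_{i:05d}")
        series.append(s)
        truths.append(t)
    return series, truths


def null_cohort(n_patients: int, n_visits: int = 8, followup_years: float = 5.0,
                noise_sd_dB: float = 2.0, seed: int = 0) -> list[PatientSeries]:
    """Stable patients: baseline + noise, zero true rate everywhere.

    Used to measure specificity / type-I error of progression tests.
    """
    if n_visits < 3:
        raise ValueError("n_visits must be >= 3")
    params = CohortParams()
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, followup_years, n_visits)
    arch_names = [k for k in params.defect_archetypes if k != "diffuse"]
    cohort = []
    for i in range(n_patients):
        status = STATUSES[rng.choice(3, p=np.asarray(params.p_status, dtype=float))]
        arch = params.defect_archetypes[arch_names[rng.integers(len(arch_names))]]
        baseline = _baseline_pattern(rng, params, status, arch)
        fields = []
        for _t in times:
            td = np.clip(baseline + rng.normal(0.0, noise_sd_dB, size=52),
                         TD_MIN, TD_MAX)
            fl, fp = rng.uniform(0.0, 0.1, size=2)
            fields.append(VisualField(td, fl_rate=float(fl), fp_rate=float(fp)))
        cohort.append(PatientSeries(f"null_{i:05d}", status, times.copy(), fields))
    return cohort


def write_truth_csv(truths: list[PatientTruth], path: str | Path) -> None:
    rows = [[t.patient_id, t.status, t.archetype, *t.baseline_pattern, *t.rate_pattern]
            for t in truths]
    cols = (["patient_id", "status", "archetype"]
            + [f"base_{i:02d}" for i in range(1, 53)]
            + [f"rate_{i:02d}" for i in range(1, 53)])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_truth_csv(path: str | Path) -> list[PatientTruth]:
    df = pd.read_csv(path)
    base_cols = [f"base_{i:02d}" for i in range(1, 53)]
    rate_cols = [f"rate_{i:02d}" for i in range(1, 53)]
    return [
        PatientTruth(str(r["patient_id"]), str(r["status"]),
                     r[base_cols].to_numpy(dtype=float),
                     r[rate_cols].to_numpy(dtype=float), str(r["archetype"]))
        for _, r in df.iterrows()
    ]
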