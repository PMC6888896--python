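"""Two-stage prediction of future visual fields, and the pointwise baseline.

Stage one fits each latent dimension of the first k encoded visits
independently against time (straight line, optionally with a quadratic
term); stage two evaluates the fitted trajectories at the held-out visit's
observed time and pushes the predicted latent point through the decoder.
Because the decoder outputs a mean field through a sigmoid, predictions are
smooth and bounded within the normalization range.  The baseline is the
standard pointwise (PW) method: an independent OLS of TD on time at each of
the 52 locations, extrapolated without clamping.

Accuracy is the mean absolute error (MAE) over the 52 informative locations
only — pad cells never enter the score.  Paired one-sided Wilcoxon
signed-rank tests compare the two methods per scenario at the
Bonferroni-corrected level 0.05/900.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (NormalizationSpec, PatientSeries, convert_to_right_eye,
                   from_image, to_image)
from .grid import build_24_2_mask

__all__ = [
    "PredictionScenario", "PredictionRecord", "BONFERRONI_ALPHA",
    "predict_latent_trajectory", "predict_field_vae", "predict_field_pointwise",
    "evaluate_predictions", "compare_wilcoxon", "mae_52",
]

# 900 comparisons as printed on the comparison grid; the corrected level.
N_COMPARISONS = 900
BONFERRONI_ALPHA = 0.05 / N_COMPARISONS


@dataclass(frozen=True)
class PredictionScenario:
    """Predict the (k + horizon)-th visit from the first k visits."""

    k_input_visits: int = 3
    horizon: int = 1
    trend: str = "linear"

    def __post_init__(self) -> None:
        if self.trend not in ("linear", "quadratic"):
            raise ValueError("trend must be 'linear' or 'quadratic'")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        min_k = 4 if self.trend == "quadratic" else 3
        if self.k_input_visits < min_k:
            raise ValueError(f"{self.trend} trend needs >= {min_k} input visits")

    @property
    def target_index(self) -> int:
        """0-based index of the target visit."""
        return self.k_input_visits + self.horizon - 1


@dataclass
class PredictionRecord:
    patient_id: str
    scenario: PredictionScenario
    predicted_td: np.ndarray
    observed_td: np.ndarray
    mae: float
    method: str                  # vae | pointwise


def mae_52(predicted_td: np.ndarray, observed_td: np.ndarray) -> float:
    """MAE over the 52 informative locations (both arguments are 52-vectors)."""
    predicted_td = np.asarray(predicted_td, dtype=float)
    observed_td = np.asarray(observed_td, dtype=float)
    if predicted_td.shape != (52,) or observed_td.shape != (52,):
        raise ValueError("MAE is defined on 52-location TD vectors")
    return float(np.mean(np.abs(predicted_td - observed_td)))


def _poly_design(times: np.ndarray, quadratic: bool) -> np.ndarray:
    cols = [np.ones_like(times), times]
    if quadratic:
        cols.append(times ** 2)
    return np.column_stack(cols)


def predict_latent_trajectory(times: np.ndarray, z: np.ndarray, k: int,
                              target_times: np.ndarray,
                              trend: str = "linear") -> np.ndarray:
    """Per-dimension OLS on the first k visits, evaluated at target times.

    ``z`` is n x L; returns len(target_times) x L.
    """
    times = np.asarray(times, dtype=float)
    z = np.atleast_2d(np.asarray(z, dtype=float))
    target_times = np.atleast_1d(np.asarray(target_times, dtype=float))
    quadratic = trend == "quadratic"
    min_k = 4 if quadratic else 3
    if k < min_k:
        raise ValueError(f"{trend} trajectory needs k >= {min_k}")
    if len(times) < k:
        raise ValueError(f"series has {len(times)} visits, need {k}")
    X = _poly_design(times[:k], quadratic)
    coef, *_ = np.linalg.lstsq(X, z[:k], rcond=None)     # (2 or 3) x L
    Xt = _poly_design(target_times, quadratic)
    return Xt @ coef


def predict_field_vae(model, series: PatientSeries,
                      scenario: PredictionScenario) -> PredictionRecord:
    """Encode first k visits, extrapolate latents, decode at the target time."""
    from . import vae as _vae
    idx = scenario.target_index
    if series.n_visits <= idx:
        raise ValueError(
            f"series has {series.n_visits} visits; scenario needs {idx + 1}")
    mask = build_24_2_mask()
    k = scenario.k_input_visits
    imgs = np.stack([to_image(convert_to_right_eye(f, mask), mask, model.norm)
                     for f in series.fields[:k]])
    z = _vae.encode(model, imgs)
    z_pred = predict_latent_trajectory(series.times[:k], z, k,
                                       series.times[idx], scenario.trend)
    img_pred = _vae.decode(model, z_pred)[0]
    predicted = from_image(img_pred, mask, model.norm)
    observed = convert_to_right_eye(series.fields[idx], mask).td
    return PredictionRecord(series.patient_id, scenario, predicted, observed,
                            mae_52(predicted, observed), "vae")


def predict_field_pointwise(series: PatientSeries, scenario: PredictionScenario,
                            clamp: bool = False,
                            norm: NormalizationSpec = NormalizationSpec()
                            ) -> PredictionRecord:
    """Independent per-location OLS of TD on time, extrapolated (no clamping
    by default; ``clamp`` restricts predictions to the normalization range)."""
    idx = scenario.target_index
    if series.n_visits <= idx:
        raise ValueError(
            f"series has {series.n_visits} visits; scenario needs {idx + 1}")
    k = scenario.k_input_visits
    td_k = np.stack([convert_to_right_eye(f).td for f in series.fields[:k]])
    X = _poly_design(series.times[:k], scenario.trend == "quadratic")
    coef, *_ = np.linalg.lstsq(X, td_k, rcond=None)      # coefs x 52
    Xt = _poly_design(np.atleast_1d(series.times[idx]),
                      scenario.trend == "quadratic")
    predicted = (Xt @ coef)[0]
    if clamp:
        predicted = np.clip(predicted, norm.td_min, norm.td_max)
    observed = convert_to_right_eye(series.fields[idx]).td
    return PredictionRecord(series.patient_id, scenario, predicted, observed,
                            mae_52(predicted, observed), "pointwise")


def evaluate_predictions(test_cohort: Sequence[PatientSeries], model,
                         ks: Iterable[int] = (3, 5, 7),
                         horizons: Iterable[int] = range(1, 6),
                         trends: Iterable[str] = ("linear", "quadratic"),
                         fold: int = 0) -> pd.DataFrame:
    """One MAE record per (patient, scenario, trend, method) with enough visits."""
    rows = []
    for trend in trends:
        for k in ks:
            if trend == "quadratic" and k < 4:
                continue
            for h in horizons:
                scenario = PredictionScenario(k, h, trend)
                for series in test_cohort:
                    if series.n_visits <= scenario.target_index:
                        continue
                    rec_v = predict_field_vae(model, series, scenario)
                    rec_p = predict_field_pointwise(series, scenario)
                    for rec in (rec_v, rec_p):
                        rows.append([series.patient_id, series.status, trend,
                                     k, h, rec.method, model.latent_dim, fold,
                                     rec.mae])
    return pd.DataFrame(rows, columns=[
        "patient_id", "status", "trend", "k_input", "horizon", "method",
        "latent_dim", "fold", "mae_db"])


def summarize_predictions(records: pd.DataFrame,
                          population: str = "all") -> pd.DataFrame:
    """Per-scenario MAE summaries and the VAE-vs-PW Wilcoxon comparison."""
    df = records if population == "all" else records[records["status"] == population]
    rows = []
    for (trend, k, h), g in df.groupby(["trend", "k_input", "horizon"]):
        wide = g.pivot_table(index="patient_id", columns="method",
                             values="mae_db", aggfunc="mean")
        if not {"vae", "pointwise"} <= set(wide.columns):
            continue
        wide = wide.dropna()
        if len(wide) >= 5:
            p = compare_wilcoxon(wide["vae"].to_numpy(),
                                 wide["pointwise"].to_numpy())
        else:
            p = np.nan   # too few pairs for a signed-rank test
        rows.append([population, trend, k, h, len(wide),
                     wide["vae"].mean(), wide["pointwise"].mean(),
                     wide["vae"].median(), wide["pointwise"].median(),
                     p, p < BONFERRONI_ALPHA])
    return pd.DataFrame(rows, columns=[
        "population", "trend", "k_input", "horizon", "n_patients",
        "mae_vae_mean", "mae_pw_mean", "mae_vae_median", "mae_pw_median",
        "wilcoxon_p", "significant"])


def compare_wilcoxon(mae_vae: np.ndarray, mae_pw: np.ndarray) -> float:
    """One-sided signed-rank p for H1: VAE MAE < PW MAE (paired by patient).

    Zero differences are dropped (signed-rank convention); if every pair is
    tied the test carries no evidence and p = 1 is returned.
    """
    mae_vae = np.asarray(mae_vae, dtype=float)
    mae_pw = np.asarray(mae_pw, dtype=float)
    if mae_vae.shape != mae_pw.shape or mae_vae.ndim != 1:
        raise ValueError("paired MAE vectors must be 1-D and equal length")
    if len(mae_vae) < 5:
        raise ValueError("need at least 5 pairs for a signed-rank test")
    diff = mae_vae - mae_pw
    if np.all(diff == 0):
        warnings.warn("all paired differences are zero; no evidence", stacklevel=2)
        return 1.0
    res = stats.wilcoxon(mae_vae, mae_pw, alternative="less",
                         zero_method="wilcox", correction=True)
    return float(res.pvalue)
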