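"""Error metrics and the train/test prediction report.

The report trains both meta-models (power law and k-nearest-neighbor) on the
training runs, predicts (Q_gen, UA) for each test condition, and places the
predictions beside the direct fits and the published reference values,
mirroring how the study compared the models.  When observed profiles are
available (in practice: synthetic studies, since the raw experimental logs
were published only as figures), temperature-domain RMSEs are computed as
well by simulating each parameter set forward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .datasets import RunRecord
from .lpm_core import (
    DEFAULT_CHILLER_TEMP_C,
    LPMParams,
    TemperatureProfile,
    ThermalSystem,
    mill_heat_capacity,
    simulate_temperature,
)
from .param_models import (
    KNNModel,
    PowerLawModel,
    predict_knn,
    predict_power_law,
    train_knn,
    train_power_law,
)

__all__ = [
    "PredictionReport",
    "profile_errors",
    "profile_rmse",
    "profile_mse",
    "profile_mae",
    "build_report",
    "published_rmse_summary",
]


def _aligned_diff(
    observed: TemperatureProfile, predicted: TemperatureProfile
) -> np.ndarray:
    if len(observed) != len(predicted) or not np.allclose(
        observed.times, predicted.times, rtol=0, atol=1e-9
    ):
        raise DomainError(
            "profiles are on different time grids; resample before comparing"
        )
    return observed.temps - predicted.temps


def profile_errors(
    observed: TemperatureProfile, predicted: TemperatureProfile
) -> dict[str, float]:
    """RMSE, MSE and MAE between two profiles on the same time grid, °C."""
    d = _aligned_diff(observed, predicted)
    mse = float(np.mean(d**2))
    return {"rmse": float(np.sqrt(mse)), "mse": mse, "mae": float(np.mean(np.abs(d)))}


def profile_rmse(observed: TemperatureProfile, predicted: TemperatureProfile) -> float:
    return profile_errors(observed, predicted)["rmse"]


def profile_mse(observed: TemperatureProfile, predicted: TemperatureProfile) -> float:
    return profile_errors(observed, predicted)["mse"]


def profile_mae(observed: TemperatureProfile, predicted: TemperatureProfile) -> float:
    return profile_errors(observed, predicted)["mae"]


@dataclass(frozen=True)
class PredictionReport:
    """Per-test-run comparison of direct fits and meta-model predictions."""

    table: pd.DataFrame
    pl_models: tuple[PowerLawModel, PowerLawModel] | None
    knn_models: tuple[KNNModel, KNNModel] | None
    converged: bool = True

    def rounded(self) -> pd.DataFrame:
        """Display form: parameters to integers, RMSEs to two decimals."""
        out = self.table.copy()
        for col in out.columns:
            if col.endswith(("_qgen", "_ua")):
                out[col] = out[col].round(0).astype("Int64")
            elif col.endswith("_rmse"):
                out[col] = out[col].round(2)
        return out


def _profile_rmse_for(
    params: LPMParams, observed: TemperatureProfile, mcp: float, t_ch: float
) -> float:
    system = ThermalSystem(mcp=mcp, t_ch=t_ch, t_0=observed.t_0)
    return profile_rmse(observed, simulate_temperature(params, system, observed.times))


def build_report(
    training: Sequence[RunRecord],
    test: Sequence[RunRecord],
    k: int = 5,
    pl_mode: str = "raw_nls",
    tie_break: str = "low_omega_high_c_low_db",
    observed_profiles: Mapping[str, TemperatureProfile] | None = None,
    t_ch: float = DEFAULT_CHILLER_TEMP_C,
) -> PredictionReport:
    """Train both meta-models on the training runs and score the test runs.

    ``observed_profiles`` (keyed by run id) switches on temperature-domain
    RMSE columns; without them the report is parameters-only.
    """
    if len(test) == 0:
        return PredictionReport(
            table=pd.DataFrame(), pl_models=None, knn_models=None
        )
    conds = [r.condition for r in training]
    qgen = [r.params.q_gen for r in training]
    ua = [r.params.ua for r in training]

    pl_q = train_power_law(conds, qgen, mode=pl_mode, response_name="q_gen")
    pl_u = train_power_law(conds, ua, mode=pl_mode, response_name="ua")
    knn_q = train_knn(conds, qgen, k=k, tie_break=tie_break, response_name="q_gen")
    knn_u = train_knn(conds, ua, k=k, tie_break=tie_break, response_name="ua")

    rows = []
    for rec in test:
        cond = rec.condition
        row: dict[str, object] = {
            "run_id": cond.run_id,
            "omega_rpm": cond.omega,
            "bead_loading": cond.c,
            "bead_size_um": cond.d_b,
        }
        if rec.params is not None:
            row["fit_qgen"] = rec.params.q_gen
            row["fit_ua"] = rec.params.ua
            row["fit_rmse"] = rec.fit_rmse
        row["pl_qgen"] = predict_power_law(pl_q, cond)
        row["pl_ua"] = predict_power_law(pl_u, cond)
        row["ml_qgen"] = predict_knn(knn_q, cond)
        row["ml_ua"] = predict_knn(knn_u, cond)
        if rec.published is not None:
            pub = rec.published
            row["published_pl_qgen"] = pub.pl_params.q_gen
            row["published_pl_ua"] = pub.pl_params.ua
            row["published_ml_qgen"] = pub.ml_params.q_gen
            row["published_ml_ua"] = pub.ml_params.ua
            row["published_pl_rmse"] = pub.pl_lpm_rmse
            row["published_ml_rmse"] = pub.ml_lpm_rmse
            row["published_ebm_fit_rmse"] = pub.ebm_fit_rmse
        if observed_profiles is not None and cond.run_id in observed_profiles:
            obs = observed_profiles[cond.run_id]
            mcp = mill_heat_capacity(cond.c)
            if rec.params is not None:
                row["fit_profile_rmse"] = _profile_rmse_for(rec.params, obs, mcp, t_ch)
            row["pl_profile_rmse"] = _profile_rmse_for(
                LPMParams(row["pl_qgen"], row["pl_ua"]), obs, mcp, t_ch
            )
            row["ml_profile_rmse"] = _profile_rmse_for(
                LPMParams(row["ml_qgen"], row["ml_ua"]), obs, mcp, t_ch
            )
        rows.append(row)
    return PredictionReport(
        table=pd.DataFrame(rows),
        pl_models=(pl_q, pl_u),
        knn_models=(knn_q, knn_u),
    )


def published_rmse_summary(test: Sequence[RunRecord]) -> dict[str, float]:
    """Means of the published test-run RMSE columns.

    Returns the mean temperature RMSE of the direct fits, of the power-law
    predictions, of the nearest-neighbor predictions, and of both prediction
    families pooled.
    """
    fit = np.array([r.fit_rmse for r in test], dtype=float)
    pl = np.array([r.published.pl_lpm_rmse for r in test], dtype=float)
    ml = np.array([r.published.ml_lpm_rmse for r in test], dtype=float)
    return {
        "fit_mean_rmse": float(fit.mean()),
        "pl_mean_rmse": float(pl.mean()),
        "ml_mean_rmse": float(ml.mean()),
        "all_predictions_mean_rmse": float(np.concatenate([pl, ml]).mean()),
    }
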