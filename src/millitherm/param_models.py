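"""Meta-models mapping process conditions to LPM parameters.

Two families predict the apparent heat generation rate ``Q_gen`` or the
heat-transfer product ``UA`` from the milling conditions (stirrer speed
``omega`` in rpm, bead loading ``c``, bead size ``d_b`` in µm):

* a power law ``a * omega**p1 * c**p2 * d_b**p3``, fit either by ordinary
  least squares in log-log space (deterministic closed form) or by nonlinear
  least squares on the raw response scale;
* k-nearest-neighbor regression on z-scored features (training-set means and
  population standard deviations), predicting the unweighted mean response of
  the k nearest training runs under Euclidean distance.

On the balanced factorial grid used for training, query points midway between
grid levels produce exact distance ties at the k-th neighbor.  The default
tie-break prefers lower stirrer speed, then higher bead loading, then lower
bead size; that ordering reproduces every published nearest-neighbor
prediction, but it is a reverse-engineered policy (the original
implementation's internal ordering is not documented) and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError
from .lpm_core import ProcessCondition

__all__ = [
    "PowerLawModel",
    "KNNModel",
    "TIE_BREAK_POLICIES",
    "train_power_law",
    "predict_power_law",
    "train_knn",
    "predict_knn",
    "nearest_neighbors",
    "leave_one_out",
]


@dataclass(frozen=True)
class PowerLawModel:
    """Power-law meta-model ``response = prefactor * omega^e1 * c^e2 * d_b^e3``."""

    prefactor: float
    exp_omega: float
    exp_c: float
    exp_db: float
    response_name: str = ""
    fit_mode: str = "log_ols"

    def __post_init__(self) -> None:
        if not self.prefactor > 0:
            raise DomainError(f"prefactor must be positive, got {self.prefactor}")

    def predict(self, condition: ProcessCondition) -> float:
        return predict_power_law(self, condition)

    def to_dict(self) -> dict:
        return {
            "type": "power_law",
            "prefactor": self.prefactor,
            "exp_omega": self.exp_omega,
            "exp_c": self.exp_c,
            "exp_db": self.exp_db,
            "response_name": self.response_name,
            "fit_mode": self.fit_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PowerLawModel":
        return cls(
            prefactor=d["prefactor"],
            exp_omega=d["exp_omega"],
            exp_c=d["exp_c"],
            exp_db=d["exp_db"],
            response_name=d.get("response_name", ""),
            fit_mode=d.get("fit_mode", "log_ols"),
        )


def _tie_key_low_omega_high_c_low_db(cond: np.ndarray) -> tuple:
    """Prefer lower stirrer speed, then higher bead loading, then lower bead size."""
    return (cond[0], -cond[1], cond[2])


#: Named tie-break policies: map a raw (omega, c, d_b) row to a sort key.
TIE_BREAK_POLICIES: dict[str, Callable[[np.ndarray], tuple]] = {
    "low_omega_high_c_low_db": _tie_key_low_omega_high_c_low_db,
    "training_order": lambda cond: (),
}


@dataclass(frozen=True)
class KNNModel:
    """k-nearest-neighbor regressor on z-scored process conditions."""

    feature_means: np.ndarray
    feature_scales: np.ndarray
    training_features: np.ndarray  # standardized, shape (n, 3)
    training_conditions: np.ndarray  # raw (omega, c, d_b), shape (n, 3)
    training_responses: np.ndarray
    k: int
    tie_break: str = "low_omega_high_c_low_db"
    response_name: str = ""

    def __post_init__(self) -> None:
        n = self.training_responses.shape[0]
        if not 1 <= self.k <= n:
            raise DomainError(f"k must lie in [1, {n}], got {self.k}")
        if np.any(self.feature_scales <= 0):
            raise DomainError("feature scales must be strictly positive")
        if self.tie_break not in TIE_BREAK_POLICIES:
            raise DomainError(f"unknown tie-break policy {self.tie_break!r}")

    def predict(self, condition: ProcessCondition) -> float:
        return predict_knn(self, condition)

    def to_dict(self) -> dict:
        return {
            "type": "knn",
            "feature_means": self.feature_means.tolist(),
            "feature_scales": self.feature_scales.tolist(),
            "training_conditions": self.training_conditions.tolist(),
            "training_responses": self.training_responses.tolist(),
            "k": self.k,
            "tie_break": self.tie_break,
            "response_name": self.response_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KNNModel":
        means = np.asarray(d["feature_means"], dtype=float)
        scales = np.asarray(d["feature_scales"], dtype=float)
        conds = np.asarray(d["training_conditions"], dtype=float)
        return cls(
            feature_means=means,
            feature_scales=scales,
            training_features=(conds - means) / scales,
            training_conditions=conds,
            training_responses=np.asarray(d["training_responses"], dtype=float),
            k=int(d["k"]),
            tie_break=d.get("tie_break", "low_omega_high_c_low_db"),
            response_name=d.get("response_name", ""),
        )


def _condition_matrix(conditions: Sequence[ProcessCondition]) -> np.ndarray:
    return np.array([[c.omega, c.c, c.d_b] for c in conditions], dtype=float)


def train_power_law(
    conditions: Sequence[ProcessCondition],
    responses: Sequence[float],
    mode: str = "log_ols",
    response_name: str = "",
) -> PowerLawModel:
    """Fit the power-law meta-model to training runs.

    ``mode="log_ols"``: ordinary least squares of ln(response) on
    (ln omega, ln c, ln d_b) with intercept — deterministic and exact on
    noiseless power-law data.  ``mode="raw_nls"``: nonlinear least squares on
    the original response scale, initialized at the log-OLS solution; raw-scale
    weighting emphasizes the large-response runs and lands closer to fits
    produced by general-purpose nonlinear regression tools.
    """
    if mode not in ("log_ols", "raw_nls"):
        raise DomainError(f"unknown fit mode {mode!r}")
    X = _condition_matrix(conditions)
    y = np.asarray(responses, dtype=float)
    if X.shape[0] != y.size:
        raise DomainError("conditions and responses must have equal length")
    if X.shape[0] < 5:
        raise DomainError(f"need at least 5 rows to fit 4 constants, got {X.shape[0]}")
    if np.any(y <= 0):
        raise DomainError("responses must be strictly positive for a power-law fit")

    logX = np.column_stack([np.ones(X.shape[0]), np.log(X)])
    beta, *_ = np.linalg.lstsq(logX, np.log(y), rcond=None)

    if mode == "log_ols":
        return PowerLawModel(
            prefactor=float(np.exp(beta[0])),
            exp_omega=float(beta[1]),
            exp_c=float(beta[2]),
            exp_db=float(beta[3]),
            response_name=response_name,
            fit_mode=mode,
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        log_a, e1, e2, e3 = theta
        pred = np.exp(log_a) * X[:, 0] ** e1 * X[:, 1] ** e2 * X[:, 2] ** e3
        return pred - y

    res = least_squares(residuals, beta, method="lm", xtol=1e-14, ftol=1e-14)
    log_a, e1, e2, e3 = res.x
    return PowerLawModel(
        prefactor=float(np.exp(log_a)),
        exp_omega=float(e1),
        exp_c=float(e2),
        exp_db=float(e3),
        response_name=response_name,
        fit_mode=mode,
    )


def predict_power_law(model: PowerLawModel, condition: ProcessCondition) -> float:
    """Evaluate the power law at one process condition."""
    return float(
        model.prefactor
        * condition.omega**model.exp_omega
        * condition.c**model.exp_c
        * condition.d_b**model.exp_db
    )


def train_knn(
    conditions: Sequence[ProcessCondition],
    responses: Sequence[float],
    k: int = 5,
    tie_break: str = "low_omega_high_c_low_db",
    response_name: str = "",
) -> KNNModel:
    """Build a KNN regressor on z-scored (omega, c, d_b) features.

    Standardization uses the training-set means and *population* standard
    deviations (ddof=0); because nearest-neighbor ordering is invariant to
    any uniform rescaling of all three scales, the population-vs-sample
    choice cannot change predictions.
    """
    X = _condition_matrix(conditions)
    y = np.asarray(responses, dtype=float)
    if X.shape[0] != y.size:
        raise DomainError("conditions and responses must have equal length")
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    if np.any(scales <= 0):
        raise DomainError(
            "at least one feature has zero variance in the training set; "
            "standardization is undefined"
        )
    return KNNModel(
        feature_means=means,
        feature_scales=scales,
        training_features=(X - means) / scales,
        training_conditions=X,
        training_responses=y,
        k=k,
        tie_break=tie_break,
        response_name=response_name,
    )


def nearest_neighbors(
    model: KNNModel, condition: ProcessCondition, rtol: float = 1e-9
) -> np.ndarray:
    """Indices of the k nearest training rows, ties resolved by policy.

    Distances equal to within relative tolerance ``rtol`` are treated as tied
    (exact ties on the standardized grid differ only by floating-point
    rounding) and ordered by the model's tie-break key.
    """
    z = (
        np.array([condition.omega, condition.c, condition.d_b], dtype=float)
        - model.feature_means
    ) / model.feature_scales
    d2 = np.sum((model.training_features - z) ** 2, axis=1)
    order = np.argsort(d2, kind="stable")
    key = TIE_BREAK_POLICIES[model.tie_break]

    resolved: list[int] = []
    i = 0
    n = order.size
    while i < n:
        j = i + 1
        while j < n and d2[order[j]] <= d2[order[i]] * (1 + rtol) + 1e-12:
            j += 1
        group = sorted(
            order[i:j],
            key=lambda idx: (*key(model.training_conditions[idx]), idx),
        )
        resolved.extend(group)
        i = j
    return np.asarray(resolved[: model.k], dtype=int)


def predict_knn(
    model: KNNModel, condition: ProcessCondition, return_neighbors: bool = False
):
    """Unweighted mean response of the k nearest training runs."""
    idx = nearest_neighbors(model, condition)
    pred = float(model.training_responses[idx].mean())
    if return_neighbors:
        return pred, idx
    return pred


def leave_one_out(
    conditions: Sequence[ProcessCondition],
    responses: Sequence[float],
    trainer: Callable[[Sequence[ProcessCondition], Sequence[float]], object],
    predictor: Callable[[object, ProcessCondition], float],
) -> np.ndarray:
    """Plumbing-level leave-one-out predictions for any (trainer, predictor) pair."""
    y = np.asarray(responses, dtype=float)
    out = np.empty(y.size)
    for i in range(y.size):
        keep = [j for j in range(y.size) if j != i]
        model = trainer([conditions[j] for j in keep], y[keep])
        out[i] = predictor(model, conditions[i])
    return out
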