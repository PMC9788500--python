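"""Packaged study fixtures and synthetic-profile generation.

The package ships the full published study as delimited text: 27 training
runs on the complete 3x3x3 factorial grid of stirrer speed {2000, 3000,
4000} rpm x bead loading {0.4, 0.5, 0.6} x bead size {200, 400, 800} µm with
their directly fitted (Q_gen, UA) and fit RMSEs, and 5 test runs with direct
fits plus the published power-law, nearest-neighbor and enthalpy-balance
reference values.  Loaders verify a SHA-256 checksum so silent drift of the
fixtures is caught.

Two of the published test-run labels are inconsistent between sources: run
31's row label repeats the 2500 rpm of run 29 although its values belong to
the 3500 rpm / 0.55 condition, and run 32 is listed at 4000 rpm in the
design table but 4200 rpm in the results table (only 4200 reproduces the
published nearest-neighbor predictions).  The loaders store the corrected
speeds and keep the as-printed value in ``omega_printed_rpm``.

Because the raw experimental time-temperature logs were published only as
figures, tests and end-to-end demonstrations use a synthetic generator that
emulates the measurement setting: closed-form trajectories plus i.i.d.
Gaussian noise at the scale of the published fit RMSEs (0.15-0.90 °C), with
initial temperatures in the observed 13-18 °C window and sampling every
minute or every 30 s.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, IntegrityError
from .lpm_core import (
    DEFAULT_CHILLER_TEMP_C,
    GompertzModel,
    LPMParams,
    MCP_ANCHOR_LOADINGS,
    MCP_ANCHOR_VALUES,
    ProcessCondition,
    TemperatureProfile,
    ThermalSystem,
    mill_heat_capacity,
    simulate_temperature,
)
from .param_models import PowerLawModel

__all__ = [
    "RunRecord",
    "PublishedReference",
    "SyntheticSpec",
    "load_training_runs",
    "load_test_runs",
    "load_training_frame",
    "load_test_frame",
    "published_gompertz",
    "published_power_laws",
    "mcp_anchor_frame",
    "generate_profile",
    "generate_study",
]

_CHECKSUMS = {
    "training_runs.csv": "cc9c998b637c0bbe76e3732d40b35d44d0e39fe9c310686a0f6ea051b52221c6",
    "test_runs.csv": "803d7eefab33563fc28e7bf015a4795ccc869b794e1d795775a2a01c7b952516",
}

#: Published Gompertz correlation between the 6-min temperature rise and Q_gen.
_PUBLISHED_GOMPERTZ = GompertzModel(amplitude=26.67, shift=1.30, rate=6.02e-4)

#: Published power-law coefficients for Q_gen and UA (3 significant figures).
_PUBLISHED_PL_QGEN = PowerLawModel(
    prefactor=6.56e-8, exp_omega=3.02, exp_c=1.29, exp_db=0.22,
    response_name="q_gen", fit_mode="raw_nls",
)
_PUBLISHED_PL_UA = PowerLawModel(
    prefactor=1.32e-4, exp_omega=1.68, exp_c=0.77, exp_db=0.12,
    response_name="ua", fit_mode="raw_nls",
)


@dataclass(frozen=True)
class PublishedReference:
    """Published predictions and error statistics for one test run."""

    pl_params: LPMParams
    ml_params: LPMParams
    pl_lpm_rmse: float
    ml_lpm_rmse: float
    ebm_fit_rmse: float
    ebm_pl_rmse: float
    ebm_ml_rmse: float
    omega_printed_rpm: float


@dataclass(frozen=True)
class RunRecord:
    """One milling run: its condition, fitted parameters and role."""

    condition: ProcessCondition
    params: LPMParams | None
    fit_rmse: float | None
    role: Literal["training", "test", "synthetic"]
    published: PublishedReference | None = None


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic time-temperature log.

    Defaults mirror the experimental setting: 60 min effective milling
    sampled twice a minute, measurement noise 0.3 °C (mid-range of the
    published fit RMSEs).
    """

    params: LPMParams
    system: ThermalSystem
    duration: float = 60.0
    dt: float = 0.5
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise DomainError("duration must be positive")
        if not self.dt > 0:
            raise DomainError("dt must be positive")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("millitherm.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise IntegrityError(
            f"packaged fixture {name} fails its checksum "
            f"(got {digest[:12]}..., expected {_CHECKSUMS[name][:12]}...)"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_training_frame() -> pd.DataFrame:
    """The 27 training runs as a DataFrame, values exactly as published."""
    return _read_fixture("training_runs.csv")


def load_test_frame() -> pd.DataFrame:
    """The 5 test runs with published PL/ML/EBM reference values."""
    return _read_fixture("test_runs.csv")


def load_training_runs() -> list[RunRecord]:
    """The 27 training runs as typed records."""
    df = load_training_frame()
    records = []
    for row in df.itertuples(index=False):
        records.append(
            RunRecord(
                condition=ProcessCondition(
                    omega=row.omega_rpm,
                    c=row.bead_loading,
                    d_b=row.bead_size_um,
                    run_id=str(row.run_id),
                ),
                params=LPMParams(q_gen=row.qgen_J_min, ua=row.ua_J_min_C),
                fit_rmse=float(row.fit_rmse_C),
                role="training",
            )
        )
    return records


def load_test_runs() -> list[RunRecord]:
    """The 5 test runs, each carrying its published reference values."""
    df = load_test_frame()
    records = []
    for row in df.itertuples(index=False):
        records.append(
            RunRecord(
                condition=ProcessCondition(
                    omega=row.omega_rpm,
                    c=row.bead_loading,
                    d_b=row.bead_size_um,
                    run_id=str(row.run_id),
                ),
                params=LPMParams(q_gen=row.fit_qgen_J_min, ua=row.fit_ua_J_min_C),
                fit_rmse=float(row.fit_lpm_rmse_C),
                role="test",
                published=PublishedReference(
                    pl_params=LPMParams(q_gen=row.pl_qgen_J_min, ua=row.pl_ua_J_min_C),
                    ml_params=LPMParams(q_gen=row.ml_qgen_J_min, ua=row.ml_ua_J_min_C),
                    pl_lpm_rmse=float(row.pl_lpm_rmse_C),
                    ml_lpm_rmse=float(row.ml_lpm_rmse_C),
                    ebm_fit_rmse=float(row.fit_ebm_rmse_C),
                    ebm_pl_rmse=float(row.pl_ebm_rmse_C),
                    ebm_ml_rmse=float(row.ml_ebm_rmse_C),
                    omega_printed_rpm=float(row.omega_printed_rpm),
                ),
            )
        )
    return records


def published_gompertz() -> GompertzModel:
    """The published Gompertz rise correlation (constants as printed)."""
    return _PUBLISHED_GOMPERTZ


def published_power_laws() -> tuple[PowerLawModel, PowerLawModel]:
    """Published (Q_gen, UA) power-law models, coefficients as printed."""
    return _PUBLISHED_PL_QGEN, _PUBLISHED_PL_UA


def mcp_anchor_frame() -> pd.DataFrame:
    """The lumped heat capacity anchors as a DataFrame."""
    return pd.DataFrame(
        {"bead_loading": MCP_ANCHOR_LOADINGS, "mcp_J_per_C": MCP_ANCHOR_VALUES}
    )


def generate_profile(spec: SyntheticSpec) -> TemperatureProfile:
    """One synthetic time-temperature log: closed-form trajectory + noise.

    The grid is {0, dt, 2 dt, ..., duration}; noise is i.i.d. Gaussian with
    standard deviation ``noise_sd``.  The same seed always yields the same
    profile.
    """
    n = int(round(spec.duration / spec.dt))
    times = np.arange(n + 1) * spec.dt
    clean = simulate_temperature(spec.params, spec.system, times)
    if spec.noise_sd == 0:
        return clean
    rng = np.random.default_rng(spec.seed)
    noisy = clean.temps + rng.normal(0.0, spec.noise_sd, size=times.size)
    return TemperatureProfile(times, noisy)


_GRID_OMEGA = (2000.0, 3000.0, 4000.0)
_GRID_C = (0.4, 0.5, 0.6)
_GRID_DB = (200.0, 400.0, 800.0)


def _sample_conditions(
    n_runs: int, condition_sampler: str, rng: np.random.Generator
) -> list[ProcessCondition]:
    if condition_sampler == "grid":
        grid = [
            ProcessCondition(omega=o, c=c, d_b=d, run_id=f"S{i + 1}")
            for i, (o, c, d) in enumerate(
                (o, c, d) for o in _GRID_OMEGA for c in _GRID_C for d in _GRID_DB
            )
        ]
        return [grid[i % len(grid)] for i in range(n_runs)]
    if condition_sampler == "random":
        return [
            ProcessCondition(
                omega=float(rng.uniform(2000, 4000)),
                c=float(rng.uniform(0.4, 0.6)),
                d_b=float(np.exp(rng.uniform(np.log(200), np.log(800)))),
                run_id=f"S{i + 1}",
            )
            for i in range(n_runs)
        ]
    raise DomainError(f"unknown condition sampler {condition_sampler!r}")


def generate_study(
    n_runs: int,
    pl_models: tuple[PowerLawModel, PowerLawModel] | None = None,
    condition_sampler: str = "grid",
    param_scatter_sd: float = 0.1,
    noise_sd: float = 0.3,
    seed: int = 0,
    t_ch: float = DEFAULT_CHILLER_TEMP_C,
    duration: float = 60.0,
    dt: float = 0.5,
) -> list[tuple[RunRecord, TemperatureProfile]]:
    """A reproducible synthetic milling study for end-to-end tests.

    Ground-truth (Q_gen, UA) for each run come from a pair of power-law
    models (published coefficients by default) perturbed by multiplicative
    lognormal scatter of log-scale sd ``param_scatter_sd``; initial
    temperatures are uniform on the observed 13-18 °C window, the lumped
    heat capacity follows the bead loading, and each log carries Gaussian
    measurement noise of sd ``noise_sd``.
    """
    if n_runs < 1:
        raise DomainError("n_runs must be at least 1")
    if pl_models is None:
        pl_models = published_power_laws()
    pl_q, pl_ua = pl_models
    rng = np.random.default_rng(seed)
    conditions = _sample_conditions(n_runs, condition_sampler, rng)
    out = []
    for cond in conditions:
        q_true = pl_q.predict(cond) * float(
            np.exp(rng.normal(0.0, param_scatter_sd))
        )
        ua_true = pl_ua.predict(cond) * float(
            np.exp(rng.normal(0.0, param_scatter_sd))
        )
        params = LPMParams(q_gen=q_true, ua=ua_true)
        t0 = float(rng.uniform(13.0, 18.0))
        system = ThermalSystem(mcp=mill_heat_capacity(cond.c), t_ch=t_ch, t_0=t0)
        profile_seed = int(rng.integers(0, 2**31 - 1))
        profile = generate_profile(
            SyntheticSpec(
                params=params,
                system=system,
                duration=duration,
                dt=dt,
                noise_sd=noise_sd,
                seed=profile_seed,
            )
        )
        record = RunRecord(
            condition=cond, params=params, fit_rmse=None, role="synthetic"
        )
        out.append((record, profile))
    return out
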