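"""Calibration, trend regression, forecast and error reporting.

The experiment flow mirrors how the model is used on national data:

1. **Calibrate** — for each year in the calibration window, build the
   constraint set (selected flow rows from that year's macro-state, index
   moments referenced to the previous or current year's observed shares),
   solve the maximum-entropy problem and score the estimate against the
   observed population shares.
2. **Regress** — fit per-moment ordinary least-squares lines of the moment
   targets over the calibration years.
3. **Forecast** — for years beyond the window: per-TU flow totals are
   extrapolated by per-TU least-squares lines, per-capita rates are held at
   their last calibrated values, moment targets come from the fitted lines,
   and the national macro-state is recomputed from the extrapolated totals.
   When observations exist for a forecast year the estimate is scored
   (verification); otherwise it is a pure forecast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constraints import (
    ConstraintRow,
    FlowVariable,
    MacroState,
    Ordering,
    OrderingScheme,
    assemble_model,
    build_flow_constraint,
    build_moment_constraints,
    make_ordering,
)
from .exceptions import FeasibilityError, MaxEntError, PanelError
from .maxent_core import (
    ConstraintSet,
    MaxEntSolution,
    ProbabilityVector,
    SolverOptions,
    solve_maxent,
)
from .panel import TerritorialPanel

__all__ = [
    "ModelConfig",
    "YearResult",
    "CalibrationResult",
    "ForecastResult",
    "MomentRegression",
    "calibrate",
    "fit_moment_regressions",
    "forecast",
    "reconstruct_flows",
    "error_report",
    "ErrorReport",
]

ALL_FLOWS = (FlowVariable.STUDENTS, FlowVariable.ELECTRICITY, FlowVariable.WATER)


@dataclass(frozen=True)
class ModelConfig:
    """Which restrictions enter the model and how.

    flow_variables: any subset of {students, electricity, water}.
    m_max: number of non-centered index moments (0 disables moments).
    ordering_scheme: how TUs are reindexed before moments are formed.
    moment_reference: 'previous' takes moment targets from the previous
    year's observed shares (persistence of the spatial distribution);
    'current' takes them from the same year (upper bound on what index
    moments can deliver).
    ordering: explicit permutation override; when None the ordering is
    frozen from observed populations at the first calibration year.
    """

    flow_variables: tuple[FlowVariable, ...] = ALL_FLOWS
    m_max: int = 10
    ordering_scheme: OrderingScheme = OrderingScheme.DESCENDING
    moment_reference: str = "previous"
    ordering: Ordering | None = None
    solver: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "flow_variables", tuple(FlowVariable(v) for v in self.flow_variables)
        )
        object.__setattr__(self, "ordering_scheme", OrderingScheme(self.ordering_scheme))
        if self.moment_reference not in ("previous", "current"):
            raise ValueError("moment_reference must be 'previous' or 'current'")
        if self.m_max < 0:
            raise ValueError("m_max must be >= 0")


@dataclass(frozen=True)
class YearResult:
    """Estimate and (when truth is available) error scores for one year."""

    year: int
    p_est: ProbabilityVector | None
    p_true: ProbabilityVector | None = None
    rmse: float | None = None
    mean_rel_err_pct: float | None = None
    per_tu_rel_err_pct: np.ndarray | None = None
    solution: MaxEntSolution | None = None
    error: str | None = None  # diagnostic when the year failed

    @property
    def ok(self) -> bool:
        return self.error is None and self.p_est is not None


@dataclass(frozen=True)
class CalibrationResult:
    results: tuple[YearResult, ...]
    ordering: Ordering
    config: ModelConfig
    panel: TerritorialPanel
    # moment order -> {year: target value}
    moment_targets: Mapping[int, Mapping[int, float]] = field(default_factory=dict)

    @property
    def years(self) -> list[int]:
        return [r.year for r in self.results]

    @property
    def window_mean_rel_err_pct(self) -> float:
        vals = [r.mean_rel_err_pct for r in self.results if r.ok]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def window_rmse(self) -> float:
        vals = [r.rmse for r in self.results if r.ok]
        return float(np.mean(vals)) if vals else float("nan")


@dataclass(frozen=True)
class ForecastResult:
    results: tuple[YearResult, ...]
    regressions: tuple["MomentRegression", ...]
    warnings: tuple[str, ...] = ()

    @property
    def window_mean_rel_err_pct(self) -> float:
        vals = [r.mean_rel_err_pct for r in self.results if r.ok and r.rmse is not None]
        return float(np.mean(vals)) if vals else float("nan")


@dataclass(frozen=True)
class MomentRegression:
    """Per-moment linear trend of the target over calibration years."""

    m: int
    slope: float
    intercept: float
    correlation: float
    degenerate: bool = False

    def predict(self, year: int | float) -> float:
        return self.slope * year + self.intercept


def _score(p_true: np.ndarray, p_est: np.ndarray) -> tuple[float, float, np.ndarray]:
    rmse = float(np.sqrt(np.mean((p_est - p_true) ** 2)))
    per_tu = 100.0 * np.abs(p_est - p_true) / p_true
    return rmse, float(np.mean(per_tu)), per_tu


def _moment_rows_for(
    panel: TerritorialPanel,
    year: int,
    config: ModelConfig,
    ordering: Ordering,
) -> list[ConstraintRow]:
    if config.m_max == 0:
        return []
    ref_year = year - 1 if config.moment_reference == "previous" else year
    p_ref = panel.shares(ref_year, ordering)
    return build_moment_constraints(p_ref, config.m_max)


def build_year_model(
    panel: TerritorialPanel, year: int, config: ModelConfig, ordering: Ordering
) -> ConstraintSet:
    """Assemble the full restriction set for one observed year."""
    records = panel.records(year)
    macro = MacroState.from_records(records)
    flow_rows = [
        build_flow_constraint(records, v, macro, ordering) for v in config.flow_variables
    ]
    moment_rows = _moment_rows_for(panel, year, config, ordering)
    return assemble_model(flow_rows, moment_rows, n_units=panel.n_tu)


def calibrate(
    panel: TerritorialPanel, years: Sequence[int], config: ModelConfig | None = None
) -> CalibrationResult:
    """Fit the model year by year against observed shares.

    The TU ordering is frozen at the first calibration year and reused for
    every year so the moment-target series are comparable.  An infeasible or
    non-convergent year is recorded with its diagnostic and does not abort
    the window.
    """
    config = config or ModelConfig()
    years = sorted(int(y) for y in years)
    if not years:
        raise ValueError("empty calibration window")
    ordering = config.ordering or make_ordering(
        panel.populations(years[0]), config.ordering_scheme, reference_year=years[0]
    )

    solver = replace(config.solver, raise_on_failure=True)
    results: list[YearResult] = []
    moment_targets: dict[int, dict[int, float]] = {m: {} for m in range(1, config.m_max + 1)}
    for year in years:
        try:
            cs = build_year_model(panel, year, config, ordering)
            for label, C in zip(cs.labels, cs.C):
                if label.startswith("moment:"):
                    moment_targets[int(label.split(":")[1])][year] = float(C)
            sol = solve_maxent(cs, solver)
        except (MaxEntError, PanelError) as exc:
            results.append(YearResult(year=year, p_est=None, error=str(exc)))
            continue
        p_true = panel.shares(year, ordering)
        rmse, mre, per_tu = _score(p_true.p, sol.p.p)
        results.append(
            YearResult(
                year=year,
                p_est=sol.p,
                p_true=p_true,
                rmse=rmse,
                mean_rel_err_pct=mre,
                per_tu_rel_err_pct=per_tu,
                solution=sol,
            )
        )
    return CalibrationResult(
        results=tuple(results),
        ordering=ordering,
        config=config,
        panel=panel,
        moment_targets=moment_targets,
    )


def fit_moment_regressions(
    moment_targets: Mapping[int, Mapping[int, float]] | CalibrationResult,
) -> list[MomentRegression]:
    """Ordinary least-squares line per moment target over calibration years.

    A constant series has an undefined Pearson correlation; it is reported as
    0 with the ``degenerate`` flag set and a flat line through the constant.
    """
    if isinstance(moment_targets, CalibrationResult):
        moment_targets = moment_targets.moment_targets
    out = []
    for m in sorted(moment_targets):
        series = moment_targets[m]
        if len(series) < 2:
            raise ValueError(f"moment {m}: need at least two years to fit a line")
        x = np.array(sorted(series), dtype=float)
        y = np.array([series[int(t)] for t in x])
        if np.allclose(y, y[0], rtol=0, atol=1e-15 * max(1.0, abs(y[0]))):
            out.append(
                MomentRegression(
                    m=m, slope=0.0, intercept=float(y[0]), correlation=0.0, degenerate=True
                )
            )
            continue
        fit = stats.linregress(x, y)
        out.append(
            MomentRegression(
                m=m,
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                correlation=float(fit.rvalue),
            )
        )
    return out


def _per_tu_trends(
    panel: TerritorialPanel, years: list[int], column: str
) -> tuple[pd.Series, pd.Series]:
    """Per-TU OLS slope and intercept of one total over the given years."""
    mat = panel.totals_matrix(years, column)
    x = mat.index.to_numpy(dtype=float)
    coeffs = np.polyfit(x, mat.to_numpy(dtype=float), deg=1)
    return (
        pd.Series(coeffs[0], index=mat.columns),
        pd.Series(coeffs[1], index=mat.columns),
    )


_FLOW_COLUMN = {
    FlowVariable.STUDENTS: "students",
    FlowVariable.ELECTRICITY: "electricity_kwh",
    FlowVariable.WATER: "water_m3",
}


def forecast(
    panel: TerritorialPanel,
    calibration: CalibrationResult,
    years: Sequence[int],
    config: ModelConfig | None = None,
) -> ForecastResult:
    """Extrapolate the model beyond the calibration window.

    Per-TU totals (population and the three flows) follow per-TU OLS lines
    over the calibration years; per-capita rates are frozen at the last
    calibration year; moment targets follow the fitted per-moment lines.  An
    extrapolated total that falls to zero or below is clamped to its last
    observed value (recorded as a warning).  A forecast year whose predicted
    moment targets are infeasible is reported with the diagnostic and
    skipped.
    """
    config = config or calibration.config
    years = sorted(int(y) for y in years)
    cal_years = calibration.years
    if years and cal_years and years[0] <= cal_years[-1]:
        raise ValueError("forecast window must follow the calibration window")
    ordering = calibration.ordering
    tu_order = ordering.sorted_tu_ids()  # index order 1..N
    n = ordering.n

    last_year = cal_years[-1]
    last_frame = panel.year_frame(last_year)
    rates = panel.rates(last_year, ordering)
    regressions = tuple(fit_moment_regressions(calibration))

    trends = {
        col: _per_tu_trends(panel, cal_years, col)
        for col in ("population", "students", "electricity_kwh", "water_m3")
    }

    warnings: list[str] = []
    observed_years = set(panel.years)
    results: list[YearResult] = []
    solver = replace(config.solver, raise_on_failure=True)
    idx = np.arange(1, n + 1, dtype=float)

    for year in years:
        totals: dict[str, np.ndarray] = {}
        for col, (slope, intercept) in trends.items():
            pred = slope.loc[tu_order].to_numpy() * year + intercept.loc[tu_order].to_numpy()
            bad = pred <= 0
            if bad.any():
                for j in np.flatnonzero(bad):
                    tu = tu_order[j]
                    last = float(last_frame.loc[tu, col])
                    warnings.append(
                        f"{year}: extrapolated {col} for {tu} was {pred[j]:.4g} <= 0; "
                        f"clamped to last observed value {last:.6g}"
                    )
                    pred[j] = last
            totals[col] = pred

        B_hat = totals["population"].sum()
        flow_rows = []
        for v in config.flow_variables:
            tot = totals[_FLOW_COLUMN[v]]
            g = tot * rates[v.value]
            T = tot.sum()
            C = (tot**2).sum() / T * (T / B_hat)  # self-weighted mean x per-capita rate
            flow_rows.append(ConstraintRow(g=g, C=float(C), label=f"flow:{v.value}"))

        moment_rows = [
            ConstraintRow(g=idx**reg.m, C=float(reg.predict(year)), label=f"moment:{reg.m}")
            for reg in regressions[: config.m_max]
        ]
        try:
            cs = assemble_model(flow_rows, moment_rows, n_units=n)
            cs.check_feasible()
            sol = solve_maxent(cs, solver)
        except (FeasibilityError, MaxEntError) as exc:
            results.append(YearResult(year=year, p_est=None, error=str(exc)))
            continue

        if year in observed_years:
            p_true = panel.shares(year, ordering)
            rmse, mre, per_tu = _score(p_true.p, sol.p.p)
            results.append(
                YearResult(
                    year=year,
                    p_est=sol.p,
                    p_true=p_true,
                    rmse=rmse,
                    mean_rel_err_pct=mre,
                    per_tu_rel_err_pct=per_tu,
                    solution=sol,
                )
            )
        else:
            results.append(YearResult(year=year, p_est=sol.p, solution=sol))
    return ForecastResult(
        results=tuple(results), regressions=regressions, warnings=tuple(warnings)
    )


def reconstruct_flows(
    p_est: ProbabilityVector,
    macro: MacroState,
    rates: Mapping[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """Back out per-TU flow totals from estimated shares.

    For each requested variable, ``hat(u)_i = p_i * B * rate_i`` (and the
    electricity/water analogues).  ``rates`` maps variable names to per-TU
    rate arrays aligned with ``p_est``.
    """
    out = {}
    for name, rate in rates.items():
        FlowVariable(name)  # validate the key
        rate = np.asarray(rate, dtype=float)
        if rate.shape != p_est.p.shape or not np.all(np.isfinite(rate)):
            raise ValueError(f"rate vector for {name!r} missing or misaligned")
        out[name] = p_est.p * macro.B * rate
    return out


@dataclass(frozen=True)
class ErrorReport:
    """Per-year and window-averaged errors, plus a per-TU error profile."""

    per_year: pd.DataFrame  # columns: year, rmse, mean_rel_err_pct, ok, error
    per_tu: pd.DataFrame  # columns: index, tu_id, mean_rel_err_pct
    window_rmse: float
    window_mean_rel_err_pct: float


def error_report(
    results: Iterable[YearResult], ordering: Ordering | None = None
) -> ErrorReport:
    """Summarize scored results; highlights which units carry the error.

    Low-population units at the tail of the ordering typically show far
    larger relative errors than the populous head, so the per-TU profile is
    reported in index order.
    """
    results = list(results)
    rows = [
        {
            "year": r.year,
            "rmse": r.rmse,
            "mean_rel_err_pct": r.mean_rel_err_pct,
            "ok": r.ok,
            "error": r.error or "",
        }
        for r in results
    ]
    per_year = pd.DataFrame(rows, columns=["year", "rmse", "mean_rel_err_pct", "ok", "error"])
    scored = [r for r in results if r.ok and r.rmse is not None]
    profiles = [r.per_tu_rel_err_pct for r in scored if r.per_tu_rel_err_pct is not None]
    if profiles:
        mean_profile = np.mean(np.vstack(profiles), axis=0)
        tu_ids = ordering.sorted_tu_ids() if ordering is not None else [
            str(i + 1) for i in range(mean_profile.size)
        ]
        per_tu = pd.DataFrame(
            {
                "index": np.arange(1, mean_profile.size + 1),
                "tu_id": tu_ids,
                "mean_rel_err_pct": mean_profile,
            }
        )
    else:
        per_tu = pd.DataFrame(columns=["index", "tu_id", "mean_rel_err_pct"])
    return ErrorReport(
        per_year=per_year,
        per_tu=per_tu,
        window_rmse=float(np.mean([r.rmse for r in scored])) if scored else float("nan"),
        window_mean_rel_err_pct=(
            float(np.mean([r.mean_rel_err_pct for r in scored])) if scored else float("nan")
        ),
    )
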