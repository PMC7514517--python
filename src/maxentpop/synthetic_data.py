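"""Seeded synthetic national panels for calibration and recovery experiments.

Two generators are provided.  ``generate_panel`` draws a realistic panel: a
heavy-tailed (Zipf-like) distribution of population shares over territorial
units, TU-specific per-capita rates for students, electricity and water,
approximately linear yearly growth in totals and optional multiplicative
log-normal noise.  ``generate_planted_panel`` builds a panel whose true
yearly shares are *exactly* the maximum-entropy solution of a known
index-moment constraint set with exactly linear target trends, so that the
calibration pipeline must recover the planted distributions to solver
precision — flow rows are satisfied identically by any true shares, and a
feasible point that solves the moment-only problem also solves the full
flow+moment problem.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .constraints import (
    ConstraintRow,
    Ordering,
    OrderingScheme,
    assemble_model,
    build_moment_constraints,
)
from .maxent_core import ProbabilityVector, SolverOptions, solve_maxent
from .panel import PANEL_COLUMNS, TerritorialPanel

__all__ = [
    "GeneratorConfig",
    "PlantedSpec",
    "PlantedTruth",
    "zipf_shares",
    "zipf_exponent_for_top_share",
    "generate_panel",
    "generate_planted_panel",
]


def zipf_exponent_for_top_share(n_tu: int, top_share: float) -> float:
    """Exponent s such that ranks i^-s normalized give the leading share.

    The top share of a normalized power law over ranks 1..n is 1/H_n(s) with
    H_n(s) = sum i^-s; monotone in s, solved by bisection.
    """
    if not 1.0 / n_tu < top_share < 1.0:
        raise ValueError(f"top share {top_share} unattainable with {n_tu} units")
    i = np.arange(1, n_tu + 1, dtype=float)

    def f(s: float) -> float:
        return 1.0 / np.sum(i**-s) - top_share

    return float(brentq(f, 1e-9, 50.0, xtol=1e-12))


def zipf_shares(n_tu: int, top_share: float = 0.16) -> np.ndarray:
    """Normalized power-law shares over ranks, largest first."""
    s = zipf_exponent_for_top_share(n_tu, top_share)
    i = np.arange(1, n_tu + 1, dtype=float)
    p = i**-s
    return p / p.sum()


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic country.

    Defaults emulate the modelled setting: 33 territorial units, panel years
    2000-2015, a dominant capital holding ~16% of the population, and
    per-capita rates of plausible national magnitude (higher-education
    enrolment 0.5-6% of inhabitants, 500-2500 kWh and 30-120 m^3 per
    inhabitant per year).  Totals grow linearly at TU-specific yearly rates;
    noise, when enabled, is multiplicative log-normal on every total.
    """

    n_tu: int = 33
    years: tuple[int, int] = (2000, 2015)  # inclusive
    share_law: Literal["zipf", "dirichlet"] = "zipf"
    zipf_top_share: float = 0.16
    dirichlet_concentration: float = 1.0
    base_population: float = 4.0e7
    alpha_range: tuple[float, float] = (0.005, 0.06)
    epsilon_range: tuple[float, float] = (500.0, 2500.0)
    w_range: tuple[float, float] = (30.0, 120.0)
    growth_range: tuple[float, float] = (0.005, 0.02)  # linear, per year
    noise_cv: float = 0.0
    integer_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tu < 2:
            raise ValueError("need at least two territorial units")
        if self.years[1] < self.years[0]:
            raise ValueError("years range is empty")
        for name in ("alpha_range", "epsilon_range", "w_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must be positive and ordered")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


def _tu_ids(n: int) -> list[str]:
    return [f"TU{i:02d}" for i in range(1, n + 1)]


def _noise(rng: np.random.Generator, cv: float, shape: tuple[int, ...]) -> np.ndarray:
    """Mean-one multiplicative log-normal factors with coefficient of variation cv."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=shape))


def generate_panel(config: GeneratorConfig) -> TerritorialPanel:
    """Draw a realistic synthetic panel; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_tu
    ids = _tu_ids(n)

    if config.share_law == "zipf":
        shares = zipf_shares(n, config.zipf_top_share)
    else:
        shares = rng.dirichlet(np.full(n, config.dirichlet_concentration))
        shares = np.maximum(shares, 1e-6)
        shares = shares / shares.sum()
    # official code order is unrelated to size: shuffle shares across ids
    shares = shares[rng.permutation(n)]

    alpha = rng.uniform(*config.alpha_range, size=n)
    eps = rng.uniform(*config.epsilon_range, size=n)
    w = rng.uniform(*config.w_range, size=n)
    growth = rng.uniform(*config.growth_range, size=n)

    years = config.year_list
    t0 = years[0]
    rows = []
    b0 = shares * config.base_population
    for year in years:
        b = b0 * (1.0 + growth * (year - t0))
        b = b * _noise(rng, config.noise_cv, (n,))
        u = alpha * b * _noise(rng, config.noise_cv, (n,))
        ce = eps * b * _noise(rng, config.noise_cv, (n,))
        cw = w * b * _noise(rng, config.noise_cv, (n,))
        if config.integer_counts:
            b = np.maximum(np.round(b), 1.0)
            u = np.round(u)
        for j, t in enumerate(ids):
            rows.append((year, t, f"Unit {t[2:]}", b[j], u[j], ce[j], cw[j]))
    df = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    return TerritorialPanel(df)


@dataclass(frozen=True)
class PlantedSpec:
    """Description of the constraint set whose solution is the planted truth.

    ``m_max`` index moments are planted with targets moving along exact
    straight lines between the moment vectors of two strictly positive anchor
    distributions (a Zipf-like start and a blend of it with the uniform);
    because the attainable moment set is convex, every interpolated target is
    feasible.  ``drift`` = 0 plants a stationary truth.
    """

    m_max: int = 5
    drift: float = 0.15  # uniform-blend weight reached at the final year
    ordering_scheme: OrderingScheme = OrderingScheme.DESCENDING
    truth_mode: Literal["maxent", "linear"] = "maxent"


@dataclass(frozen=True)
class PlantedTruth:
    """Sidecar record of the planted distributions and targets."""

    ordering: Ordering
    m_max: int
    moment_reference: str  # calibration mode under which recovery is exact
    p_true: dict[int, np.ndarray] = field(default_factory=dict)  # index order
    targets: dict[int, np.ndarray] = field(default_factory=dict)  # C_1..C_m per year

    def to_json(self) -> str:
        return json.dumps(
            {
                "m_max": self.m_max,
                "moment_reference": self.moment_reference,
                "ordering_scheme": self.ordering.scheme.value,
                "reference_year": self.ordering.reference_year,
                "permutation": dict(self.ordering.permutation),
                "p_true": {str(y): v.tolist() for y, v in self.p_true.items()},
                "targets": {str(y): v.tolist() for y, v in self.targets.items()},
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        ordering = Ordering(
            scheme=OrderingScheme(d["ordering_scheme"]),
            permutation={k: int(v) for k, v in d["permutation"].items()},
            reference_year=int(d["reference_year"]),
        )
        return cls(
            ordering=ordering,
            m_max=int(d["m_max"]),
            moment_reference=d["moment_reference"],
            p_true={int(y): np.asarray(v) for y, v in d["p_true"].items()},
            targets={int(y): np.asarray(v) for y, v in d["targets"].items()},
        )


def generate_planted_panel(
    config: GeneratorConfig, planted: PlantedSpec | None = None
) -> tuple[TerritorialPanel, PlantedTruth]:
    """Build a panel whose yearly true shares solve a known moment model.

    The truth at year t is the maximum-entropy distribution matching the
    planted index-moment targets for t.  Data are rebuilt from the truth with
    constant per-TU rates and no rounding, so the three flow rows hold
    identically and end-to-end calibration (moments referenced to the
    *current* year, or to the previous year when ``drift`` is 0) must recover
    the truth to solver precision.

    With ``truth_mode='linear'`` the true shares instead move along an exact
    straight line between the two anchors and the national population is held
    constant, so *every* per-TU total and every moment target is an exact
    linear function of the year; trend extrapolation in the forecast stage is
    then exact, at the price that the truth is no longer the entropy maximizer
    of its own moments (calibration and forecast make the same, small,
    moment-reconstruction error).
    """
    planted = planted or PlantedSpec()
    rng = np.random.default_rng(config.seed)
    n = config.n_tu
    years = config.year_list
    t0, t1 = years[0], years[-1]

    p_start = zipf_shares(n, config.zipf_top_share)  # descending in index
    uniform = np.full(n, 1.0 / n)
    p_end = (1.0 - planted.drift) * p_start + planted.drift * uniform
    p_end = p_end / p_end.sum()

    idx = np.arange(1, n + 1, dtype=float)
    Gm = np.vstack([idx**m for m in range(1, planted.m_max + 1)])
    C_start, C_end = Gm @ p_start, Gm @ p_end

    # planted index i corresponds to the i-th largest unit; assign shuffled ids
    ids = _tu_ids(n)
    id_perm = rng.permutation(n)
    permutation = {ids[id_perm[i]]: i + 1 for i in range(n)}
    ordering = Ordering(
        scheme=planted.ordering_scheme, permutation=permutation, reference_year=t0
    )

    alpha = rng.uniform(*config.alpha_range, size=n)  # in index order
    eps = rng.uniform(*config.epsilon_range, size=n)
    w = rng.uniform(*config.w_range, size=n)
    growth = float(rng.uniform(*config.growth_range))

    truth = PlantedTruth(
        ordering=ordering,
        m_max=planted.m_max,
        moment_reference="current" if planted.drift != 0 else "previous",
    )
    rows = []
    span = max(t1 - t0, 1)
    index_of = {tu: i for tu, i in permutation.items()}
    for year in years:
        theta = (year - t0) / span
        C = (1.0 - theta) * C_start + theta * C_end  # exactly linear in year
        if planted.truth_mode == "linear":
            p = (1.0 - theta) * p_start + theta * p_end
            C = Gm @ p
        else:
            ref = ProbabilityVector(p_start)  # any positive vector of the right size
            mrows = build_moment_constraints(ref, planted.m_max)
            mrows = [
                ConstraintRow(g=r.g, C=float(C[i]), label=r.label)
                for i, r in enumerate(mrows)
            ]
            cs = assemble_model(moment_rows=mrows)
            sol = solve_maxent(cs, SolverOptions(tolerance=1e-12, max_iterations=500))
            p = sol.p.p
        truth.p_true[year] = p
        truth.targets[year] = C

        if planted.truth_mode == "linear":
            B = config.base_population  # constant so totals stay exactly linear
        else:
            B = config.base_population * (1.0 + growth * (year - t0))
        b = p * B
        for tu, i1 in index_of.items():
            j = i1 - 1
            rows.append(
                (
                    year,
                    tu,
                    f"Unit {tu[2:]}",
                    b[j],
                    alpha[j] * b[j],
                    eps[j] * b[j],
                    w[j] * b[j],
                )
            )
    df = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    return TerritorialPanel(df), truth
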