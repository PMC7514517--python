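"""Restriction builders: flow-variable rows, index-moment rows, TU orderings.

The model constrains the population-share distribution with two families of
restrictions:

* **Flow rows** — one per socio-ecological flow variable (higher-education
  students as the information flow, electricity consumption as the energy
  flow, water demand as the matter flow).  For students the row is
  ``g_i = u_i * alpha_i`` (count times per-capita rate) with target
  ``C = u_bar * A`` where ``u_bar = sum u_i^2 / U`` is the self-weighted mean
  per department and ``A = U/B`` the national per-capita rate.  The algebra
  makes the true shares ``p_i = b_i/B`` satisfy the row identically:
  ``sum (b_i/B) u_i alpha_i = sum u_i^2 / B = (sum u_i^2/U)(U/B)``.
  Electricity and water rows are exact analogues.

* **Moment rows** — non-centered moments of the TU *index* under a chosen
  reordering: ``g_{m,i} = i^m`` with target ``C_m = sum_i i^m p_ref,i`` taken
  from a reference distribution (typically the previous year's observed
  shares).  These encode persistence of the spatial distribution.

Because the index moments only carry information when populous units sit at
predictable positions, units are reindexed before moments are formed:
``descending`` (largest population at index 1) or ``bell`` (largest at the
center, decreasing toward both ends).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import PanelError
from .maxent_core import ConstraintSet, ProbabilityVector

__all__ = [
    "FlowVariable",
    "OrderingScheme",
    "TUYearRecord",
    "MacroState",
    "Ordering",
    "ConstraintRow",
    "build_flow_constraint",
    "build_moment_constraints",
    "make_ordering",
    "assemble_model",
]


class FlowVariable(str, enum.Enum):
    STUDENTS = "students"
    ELECTRICITY = "electricity"
    WATER = "water"


class OrderingScheme(str, enum.Enum):
    ORIGINAL = "original"
    DESCENDING = "descending"
    BELL = "bell"


@dataclass(frozen=True)
class TUYearRecord:
    """One territorial unit in one year: population and the three flow totals.

    Rates are derived: ``alpha = u/b`` (students per inhabitant), ``epsilon =
    ce/b`` (kWh per inhabitant), ``w = cw/b`` (m^3 per inhabitant).
    """

    tu_id: str
    year: int
    b: float  # population, inhabitants
    u: float  # higher-education students
    ce: float  # electricity consumption, kWh
    cw: float  # water demand, m^3

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise PanelError(f"TU {self.tu_id!r} year {self.year}: population must be > 0")
        for name, v in (("u", self.u), ("ce", self.ce), ("cw", self.cw)):
            if v < 0 or not np.isfinite(v):
                raise PanelError(
                    f"TU {self.tu_id!r} year {self.year}: {name} must be finite and >= 0"
                )

    @property
    def alpha(self) -> float:
        return self.u / self.b

    @property
    def epsilon(self) -> float:
        return self.ce / self.b

    @property
    def w(self) -> float:
        return self.cw / self.b


@dataclass(frozen=True)
class MacroState:
    """National aggregates for one year.

    B, U, CE, CW are national totals; A = U/B, E = CE/B, W = CW/B are national
    per-capita rates; u_bar, ce_bar, cw_bar are the self-weighted means
    ``sum x_i^2 / sum x_i`` (the average per department obtained when each
    unit is weighted by its own share of the national total).
    """

    year: int
    B: float
    U: float
    CE: float
    CW: float

    def __post_init__(self) -> None:
        for name, v in (("B", self.B), ("U", self.U), ("CE", self.CE), ("CW", self.CW)):
            if v <= 0:
                raise PanelError(f"national total {name} must be > 0 (year {self.year})")

    @property
    def A(self) -> float:
        return self.U / self.B

    @property
    def E(self) -> float:
        return self.CE / self.B

    @property
    def W(self) -> float:
        return self.CW / self.B

    # self-weighted means need the per-TU breakdown, so they are computed in
    # from_records and stored on the instance
    u_bar: float = 0.0
    ce_bar: float = 0.0
    cw_bar: float = 0.0

    @classmethod
    def from_records(cls, records: Sequence[TUYearRecord]) -> "MacroState":
        years = {r.year for r in records}
        if len(years) != 1:
            raise PanelError(f"records span years {sorted(years)}; expected one year")
        u = np.array([r.u for r in records])
        ce = np.array([r.ce for r in records])
        cw = np.array([r.cw for r in records])
        b = np.array([r.b for r in records])
        U, CE, CW = u.sum(), ce.sum(), cw.sum()
        if min(U, CE, CW) <= 0:
            raise PanelError(f"a national flow total is zero in year {years.pop()}")
        return cls(
            year=next(iter(years)),
            B=float(b.sum()),
            U=float(U),
            CE=float(CE),
            CW=float(CW),
            u_bar=float((u**2).sum() / U),
            ce_bar=float((ce**2).sum() / CE),
            cw_bar=float((cw**2).sum() / CW),
        )


@dataclass(frozen=True)
class Ordering:
    """A bijection from TU identifiers to 1-based indices.

    The permutation is frozen at a reference year so that index-moment series
    are comparable across years.
    """

    scheme: OrderingScheme
    permutation: Mapping[str, int]
    reference_year: int

    def __post_init__(self) -> None:
        idx = sorted(self.permutation.values())
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("permutation must be a bijection onto 1..N")

    @property
    def n(self) -> int:
        return len(self.permutation)

    def indices_for(self, tu_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.permutation[t] for t in tu_ids], dtype=int)

    def sorted_tu_ids(self) -> list[str]:
        """TU identifiers in index order 1..N."""
        return [t for t, _ in sorted(self.permutation.items(), key=lambda kv: kv[1])]


@dataclass(frozen=True)
class ConstraintRow:
    """A single restriction: row values over units in index order, target, label."""

    g: np.ndarray
    C: float
    label: str


def _bell_positions(n: int) -> list[int]:
    """Center-outward index sequence: center, then alternately right and left.

    Position k in the returned list is where the k-th largest unit goes.  The
    center is ``ceil(n/2)``; the first offset goes to the right.
    """
    center = (n + 1) // 2
    out = [center]
    offset = 1
    while len(out) < n:
        if center + offset <= n:
            out.append(center + offset)
        if len(out) < n and center - offset >= 1:
            out.append(center - offset)
        offset += 1
    return out


def make_ordering(
    populations: Mapping[str, float],
    scheme: OrderingScheme | str,
    reference_year: int = 0,
) -> Ordering:
    """Build the TU-to-index permutation for a reindexing scheme.

    descending: index 1 holds the largest population; ties broken by
    ascending tu_id.  bell: largest at the central index, next largest
    alternately to its right and left.  original: ascending tu_id (the
    official code order).
    """
    scheme = OrderingScheme(scheme)
    ids = list(populations)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate tu_id in population table")
    if scheme is OrderingScheme.ORIGINAL:
        ranked = sorted(ids)
        perm = {t: i + 1 for i, t in enumerate(ranked)}
    else:
        ranked = sorted(ids, key=lambda t: (-populations[t], t))
        if scheme is OrderingScheme.DESCENDING:
            perm = {t: i + 1 for i, t in enumerate(ranked)}
        else:
            positions = _bell_positions(len(ids))
            perm = {t: positions[i] for i, t in enumerate(ranked)}
    return Ordering(scheme=scheme, permutation=perm, reference_year=reference_year)


def build_flow_constraint(
    records: Sequence[TUYearRecord],
    variable: FlowVariable | str,
    macro: MacroState,
    ordering: Ordering | None = None,
) -> ConstraintRow:
    """One flow-variable restriction row ``g_i = total_i * rate_i``.

    The target couples the self-weighted departmental mean with the national
    per-capita rate: ``C = u_bar * A`` (students), ``ce_bar * E``
    (electricity) or ``cw_bar * W`` (water).  ``records`` must all belong to
    ``macro.year`` and their totals must reproduce the macro totals.  When an
    ``ordering`` is given the row is returned in index order 1..N; otherwise
    in record order.
    """
    variable = FlowVariable(variable)
    years = {r.year for r in records}
    if years != {macro.year}:
        raise PanelError(f"records for years {sorted(years)} do not match macro year {macro.year}")
    ids = [r.tu_id for r in records]
    if len(set(ids)) != len(ids):
        raise PanelError("duplicate tu_id among records")

    if variable is FlowVariable.STUDENTS:
        total = np.array([r.u for r in records])
        macro_total, C = macro.U, macro.u_bar * macro.A
    elif variable is FlowVariable.ELECTRICITY:
        total = np.array([r.ce for r in records])
        macro_total, C = macro.CE, macro.ce_bar * macro.E
    else:
        total = np.array([r.cw for r in records])
        macro_total, C = macro.CW, macro.cw_bar * macro.W

    if abs(total.sum() - macro_total) > 1e-9 * max(1.0, macro_total):
        raise PanelError(
            f"{variable.value} records sum to {total.sum():.6g} but the "
            f"macro-state total is {macro_total:.6g}"
        )

    b = np.array([r.b for r in records])
    g = total**2 / b  # total_i * rate_i

    if ordering is not None:
        if set(ids) != set(ordering.permutation):
            raise PanelError("record TUs do not match the ordering's TUs")
        pos = ordering.indices_for(ids) - 1
        g_ordered = np.empty_like(g)
        g_ordered[pos] = g
        g = g_ordered

    return ConstraintRow(g=g, C=float(C), label=f"flow:{variable.value}")


def build_moment_constraints(
    p_ref: ProbabilityVector, m_max: int, ordering: Ordering | None = None
) -> list[ConstraintRow]:
    """Non-centered index-moment rows ``g_{m,i} = i^m``, ``m = 1..m_max``.

    Targets are the moments of ``p_ref`` expressed in the given ordering
    (``p_ref`` must already be stated in that ordering's index space; its
    ``tu_index`` labels give each entry's index).
    """
    n = p_ref.n
    if not 1 <= m_max <= n - 1:
        raise ValueError(f"m_max={m_max} outside the valid range 1..{n - 1}")
    if ordering is not None and ordering.n != n:
        raise ValueError("ordering size does not match p_ref")
    order = np.argsort(p_ref.tu_index)
    shares = p_ref.p[order]  # shares in index order 1..N
    idx = np.arange(1, n + 1, dtype=float)
    rows = []
    for m in range(1, m_max + 1):
        g = idx**m
        rows.append(ConstraintRow(g=g, C=float(g @ shares), label=f"moment:{m}"))
    return rows


def assemble_model(
    flow_rows: Iterable[ConstraintRow] = (),
    moment_rows: Iterable[ConstraintRow] = (),
    n_units: int | None = None,
) -> ConstraintSet:
    """Concatenate flow and moment rows into a ConstraintSet.

    The natural restriction ``sum p_i = 1`` never enters the matrix; the
    solver enforces it through the partition function.  An empty selection
    yields the natural-restriction-only model (uniform solution); ``n_units``
    is then required to size the (empty) set.
    """
    rows = list(flow_rows) + list(moment_rows)
    if not rows:
        if n_units is None:
            raise ValueError("an empty model needs n_units to size the constraint set")
        return ConstraintSet.empty(n_units)
    n = rows[0].g.size
    if any(r.g.size != n for r in rows):
        raise ValueError("constraint rows have inconsistent lengths")
    G = np.vstack([r.g for r in rows])
    C = np.array([r.C for r in rows])
    return ConstraintSet(G=G, C=C, labels=tuple(r.label for r in rows))
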