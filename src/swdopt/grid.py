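"""Correlation-uncertainty handling: per-grid-point searches and the
superset design.

When the ICC and CAC are uncertain, the search is run once per point of a
correlation-parameter grid; the observed cells of the per-point optimal
designs are unioned into a single "superset" design. Because adding cells
never reduces precision, the superset is guaranteed to meet the power
constraint at every grid point whose own optimal design met it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .costs import CostSpec, total_cost
from .design import Design
from .search import RemovalTrace, greedy_removal_search, select_optimal
from .variance import (
    CorrelationSpec,
    NotEstimableError,
    PowerSpec,
    power,
    treatment_variance,
)

__all__ = [
    "CorrelationGrid",
    "GridPointSummary",
    "SupersetResult",
    "superset_search",
    "evaluate_design_over_grid",
]


@dataclass(frozen=True)
class CorrelationGrid:
    """Cartesian grid of (icc, cac) values under one correlation structure.

    Values are sorted ascending; points are visited row-major over
    (icc, cac). The union is order-independent, but a fixed order keeps
    reports reproducible.
    """

    icc_values: tuple[float, ...]
    cac_values: tuple[float, ...]
    structure: str = "discrete_time_decay"

    def __post_init__(self) -> None:
        icc = tuple(sorted(float(v) for v in self.icc_values))
        cac = tuple(sorted(float(v) for v in self.cac_values))
        if not icc or not cac:
            raise ValueError("correlation grid must be non-empty")
        object.__setattr__(self, "icc_values", icc)
        object.__setattr__(self, "cac_values", cac)
        for point in self.points():
            self.spec_at(point)  # validates ranges

    def points(self) -> list[tuple[float, float]]:
        return list(itertools.product(self.icc_values, self.cac_values))

    def spec_at(self, point: tuple[float, float]) -> CorrelationSpec:
        icc, cac = point
        return CorrelationSpec(icc=icc, cac=cac, structure=self.structure)


@dataclass(frozen=True)
class GridPointSummary:
    """Per-grid-point search outcome for reporting."""

    icc: float
    cac: float
    complete_power: float
    skipped: bool
    optimal_iteration: int | None
    optimal_power: float | None
    optimal_cost: float | None
    optimal_rce: float | None


@dataclass
class SupersetResult:
    """Union of per-point optimal designs plus its grid-wide evaluation."""

    reference: Design
    grid: CorrelationGrid
    per_point_optimal: dict[tuple[float, float], Design | None]
    superset: Design
    cell_inclusion_counts: np.ndarray
    per_point_power: dict[tuple[float, float], float]
    cost: float
    skipped_points: list[tuple[float, float]]
    per_point_summary: list[GridPointSummary] = field(default_factory=list)
    traces: dict[tuple[float, float], RemovalTrace] = field(default_factory=dict)

    @property
    def min_power(self) -> float:
        """Minimum superset power over non-skipped grid points."""
        powers = [
            p for point, p in self.per_point_power.items()
            if point not in set(self.skipped_points)
        ]
        return min(powers)


def superset_search(
    reference: Design,
    grid: CorrelationGrid,
    costs: CostSpec,
    pw: PowerSpec,
) -> SupersetResult:
    """Run the greedy search at every grid point and union the optima.

    Grid points at which even the complete (reference) design is
    under-powered cannot contribute a qualifying design; they are recorded
    in ``skipped_points`` and excluded from the union rather than aborting
    the procedure.
    """
    per_point_optimal: dict[tuple[float, float], Design | None] = {}
    skipped: list[tuple[float, float]] = []
    summaries: list[GridPointSummary] = []
    traces: dict[tuple[float, float], RemovalTrace] = {}
    union_mask = np.zeros_like(reference.observed, dtype=bool)
    counts = np.zeros(reference.observed.shape, dtype=np.int64)

    for point in grid.points():
        corr = grid.spec_at(point)
        complete_power = power(reference, corr, pw)
        if complete_power < pw.min_power - 1e-12:
            skipped.append(point)
            per_point_optimal[point] = None
            summaries.append(
                GridPointSummary(point[0], point[1], complete_power, True,
                                 None, None, None, None)
            )
            continue
        trace = greedy_removal_search(reference, corr, costs, pw)
        traces[point] = trace
        chosen = select_optimal(trace, pw)
        if chosen is None:
            # Complete design qualifies but no reduced design does; nothing
            # to contribute to the union.
            per_point_optimal[point] = None
            summaries.append(
                GridPointSummary(point[0], point[1], complete_power, False,
                                 None, None, None, None)
            )
            continue
        opt_design, opt_metrics, opt_iter = chosen
        per_point_optimal[point] = opt_design
        union_mask |= opt_design.observed
        counts += opt_design.observed
        summaries.append(
            GridPointSummary(
                point[0], point[1], complete_power, False,
                opt_iter, opt_metrics.power, opt_metrics.cost, opt_metrics.rce,
            )
        )

    if not union_mask.any():
        raise NotEstimableError(
            "no grid point produced a qualifying optimal design; "
            "the superset is undefined"
        )

    superset = reference.with_observed(union_mask)
    per_point_power = {
        point: power(superset, grid.spec_at(point), pw) for point in grid.points()
    }
    return SupersetResult(
        reference=reference,
        grid=grid,
        per_point_optimal=per_point_optimal,
        superset=superset,
        cell_inclusion_counts=counts,
        per_point_power=per_point_power,
        cost=total_cost(superset, costs),
        skipped_points=skipped,
        per_point_summary=summaries,
        traces=traces,
    )


def evaluate_design_over_grid(
    design: Design, grid: CorrelationGrid, pw: PowerSpec
) -> dict[tuple[float, float], tuple[float, float] | None]:
    """Variance and power of a fixed design at every grid point.

    Points where the design is not estimable map to None instead of
    raising, so one bad point does not abort a report.
    """
    out: dict[tuple[float, float], tuple[float, float] | None] = {}
    for point in grid.points():
        corr = grid.spec_at(point)
        try:
            var = treatment_variance(design, corr)
        except NotEstimableError:
            out[point] = None
            continue
        out[point] = (var, power(design, corr, pw))
    return out
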