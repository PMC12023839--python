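"""Cost efficiency, greedy cell-removal search and optimal-design selection.

Cost efficiency (CE) of a design is the precision of the treatment-effect
estimator divided by the total trial cost, ``1 / (var * cost)``. The
greedy search starts from a reference (usually complete) design and at
each iteration removes the single measured sequence-period cell whose
removal yields the reduced design with the highest CE, skipping removals
that would make the treatment effect non-estimable. It stops when no
removable cell leaves an estimable design, i.e. at a minimally viable
design along the greedy path. The optimal design is the trace member with
maximal CE relative to the reference (RCE) among those meeting the minimum
power constraint.

Tie-breaking is deterministic: among candidate cells whose CE is within
1e-12 relative of the maximum, the cell with the smallest sequence index,
then the smallest period index, is removed. Identical inputs therefore
always produce identical traces.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .costs import CostSpec, sequence_cost, total_cost
from .design import Design, fraction_removed
from .variance import (
    CorrelationSpec,
    NotEstimableError,
    PowerSpec,
    _sequence_terms,
    _variance_from_information,
    treatment_variance,
)

__all__ = [
    "DesignMetrics",
    "TraceStep",
    "RemovalTrace",
    "ZeroCostError",
    "cost_efficiency",
    "relative_cost_efficiency",
    "greedy_removal_search",
    "select_optimal",
    "trace_to_csv",
]

#: Relative CE slack within which two candidate removals count as tied.
TIE_REL_TOL = 1e-12


class ZeroCostError(ValueError):
    """Cost efficiency is undefined for a zero-cost design."""


@dataclass(frozen=True)
class DesignMetrics:
    """Variance, power, cost, CE and CE relative to a reference design."""

    variance: float
    power: float
    cost: float
    ce: float
    rce: float


@dataclass(frozen=True)
class TraceStep:
    """One iteration of the greedy search: the cell removed (1-based) and
    the resulting design with its metrics."""

    iteration: int
    removed_cell: tuple[int, int]
    design: Design
    metrics: DesignMetrics


@dataclass
class RemovalTrace:
    """The ordered series of reduced designs produced by the greedy search."""

    reference: Design
    reference_metrics: DesignMetrics
    steps: list[TraceStep]
    min_power: float
    optimal_index: int | None

    @property
    def optimal(self) -> TraceStep | None:
        if self.optimal_index is None:
            return None
        return self.steps[self.optimal_index - 1]


def cost_efficiency(
    design: Design, corr: CorrelationSpec, costs: CostSpec
) -> float:
    """CE = 1 / (var(theta-hat) * total cost)."""
    cost = total_cost(design, costs)
    if cost <= 0:
        raise ZeroCostError("cost efficiency is undefined when total cost is 0")
    return 1.0 / (treatment_variance(design, corr) * cost)


def relative_cost_efficiency(
    reference: Design,
    candidate: Design,
    corr: CorrelationSpec,
    costs: CostSpec,
) -> float:
    """CE of the candidate divided by CE of the reference design."""
    return cost_efficiency(candidate, corr, costs) / cost_efficiency(
        reference, corr, costs
    )


def _power_from_variance(variance: float, pw: PowerSpec) -> float:
    z_crit = norm.ppf(1.0 - pw.alpha / 2.0)
    return float(norm.cdf(pw.effect_size / np.sqrt(variance) - z_crit))


def greedy_removal_search(
    reference: Design,
    corr: CorrelationSpec,
    costs: CostSpec,
    pw: PowerSpec,
) -> RemovalTrace:
    """Run the greedy CE-maximizing cell-removal search from *reference*.

    Raises :class:`~swdopt.variance.NotEstimableError` if the reference
    itself is not estimable and :class:`ZeroCostError` if its cost is 0.
    """
    n_seq, n_per = reference.n_sequences, reference.n_periods
    m = reference.cluster_period_size
    n_clusters = reference.clusters_per_sequence

    # Per-sequence information pieces and cost contributions are cached:
    # a candidate removal only perturbs one sequence, so each candidate
    # evaluation recomputes a single small covariance inverse.
    terms = [
        _sequence_terms(reference.treatment[s], reference.observed[s], m, n_per, corr)
        for s in range(n_seq)
    ]
    seq_costs = [
        sequence_cost(reference, s + 1, costs) for s in range(n_seq)
    ]

    def combine(term_list, observed):
        a_total = 0.0
        b_total = np.zeros(n_per)
        c_total = np.zeros((n_per, n_per))
        for s in range(n_seq):
            if term_list[s] is None:
                continue
            a_total += n_clusters[s] * term_list[s][0]
            b_total += n_clusters[s] * term_list[s][1]
            c_total += n_clusters[s] * term_list[s][2]
        period_idx = np.flatnonzero(observed.any(axis=0))
        return _variance_from_information(a_total, b_total, c_total, period_idx)

    ref_variance = combine(terms, reference.observed)
    ref_cost = sum(seq_costs)
    if ref_cost <= 0:
        raise ZeroCostError("cost efficiency is undefined when total cost is 0")
    ref_ce = 1.0 / (ref_variance * ref_cost)
    reference_metrics = DesignMetrics(
        variance=ref_variance,
        power=_power_from_variance(ref_variance, pw),
        cost=ref_cost,
        ce=ref_ce,
        rce=1.0,
    )

    current = reference
    steps: list[TraceStep] = []
    iteration = 0
    while True:
        iteration += 1
        best = None  # (ce, cell, variance, cost, terms_s, seq_cost_s, observed)
        for s in range(n_seq):
            row_obs = np.flatnonzero(current.observed[s])
            for p in row_obs:
                cand_observed = current.observed.copy()
                cand_observed[s, p] = False
                cand_terms_s = _sequence_terms(
                    current.treatment[s], cand_observed[s], m, n_per, corr
                )
                trial_terms = list(terms)
                trial_terms[s] = cand_terms_s
                try:
                    variance = combine(trial_terms, cand_observed)
                except NotEstimableError:
                    continue
                cand_design = current.with_observed(cand_observed)
                cand_seq_cost = sequence_cost(cand_design, s + 1, costs)
                cost = sum(seq_costs) - seq_costs[s] + cand_seq_cost
                if cost <= 0:
                    raise ZeroCostError(
                        "cost efficiency is undefined when total cost is 0"
                    )
                ce = 1.0 / (variance * cost)
                if best is None or ce > best[0] * (1.0 + TIE_REL_TOL):
                    best = (
                        ce,
                        (s + 1, p + 1),
                        variance,
                        cost,
                        cand_terms_s,
                        cand_seq_cost,
                        cand_design,
                    )
        if best is None:
            break
        ce, cell, variance, cost, terms_s, seq_cost_s, cand_design = best
        s0 = cell[0] - 1
        terms[s0] = terms_s
        seq_costs[s0] = seq_cost_s
        current = cand_design
        metrics = DesignMetrics(
            variance=variance,
            power=_power_from_variance(variance, pw),
            cost=cost,
            ce=ce,
            rce=ce / ref_ce,
        )
        steps.append(TraceStep(iteration, cell, current, metrics))

    trace = RemovalTrace(
        reference=reference,
        reference_metrics=reference_metrics,
        steps=steps,
        min_power=pw.min_power,
        optimal_index=None,
    )
    chosen = select_optimal(trace, pw)
    if chosen is not None:
        trace.optimal_index = chosen[2]
    return trace


def select_optimal(
    trace: RemovalTrace, pw: PowerSpec
) -> tuple[Design, DesignMetrics, int] | None:
    """Among trace steps with power >= min_power, the RCE maximizer.

    Returns ``(design, metrics, iteration)`` or None when no reduced design
    meets the power constraint (the reference itself is not a member of the
    searched space). Ties keep the earliest qualifying step.
    """
    best = None
    for step in trace.steps:
        if step.metrics.power >= pw.min_power - 1e-12:
            if best is None or step.metrics.rce > best.metrics.rce * (1 + TIE_REL_TOL):
                best = step
    if best is None:
        return None
    return best.design, best.metrics, best.iteration


def trace_to_csv(trace: RemovalTrace, path=None) -> str:
    """Serialize the trace (reference row included as iteration 0) to CSV."""
    buf = io.StringIO()
    buf.write(
        "iteration,removed_sequence,removed_period,cells_remaining,"
        "fraction_removed,variance,power,cost,ce,rce,meets_power\n"
    )

    def write_row(iteration, cell, design, metrics):
        frac = fraction_removed(design, trace.reference)
        seq, per = ("", "") if cell is None else cell
        meets = int(metrics.power >= trace.min_power - 1e-12)
        buf.write(
            f"{iteration},{seq},{per},{design.n_observed_cells},"
            f"{frac:.10g},{metrics.variance:.12g},{metrics.power:.12g},"
            f"{metrics.cost:.12g},{metrics.ce:.12g},{metrics.rce:.12g},{meets}\n"
        )

    write_row(0, None, trace.reference, trace.reference_metrics)
    for step in trace.steps:
        write_row(step.iteration, step.removed_cell, step.design, step.metrics)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
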