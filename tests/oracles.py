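"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the package's computational paths: the variance
oracle works at the individual participant level with a dense stacked
covariance matrix, the gap oracle uses run-length encoding via
``itertools.groupby``, and the greedy-step oracle enumerates removals
through the public one-shot API only.
"""

from __future__ import annotations

import itertools

import numpy as np

from swdopt.design import Design


def individual_level_variance(design: Design, icc: float, cac: float,
                              structure: str = "discrete_time_decay"):
    """GLS variance of the treatment effect from the full participant-level
    model: each cluster contributes an (m * Tk)-dimensional outcome vector
    with covariance tau^2 * R (expanded to participants) + sigma_eps^2 * I,
    tau^2 = icc, sigma_eps^2 = 1 - icc. Returns None when the profiled
    treatment information is numerically singular.
    """
    tau2 = icc
    sigma2 = 1.0 - icc
    m = design.cluster_period_size
    n_periods = design.n_periods
    global_obs = np.flatnonzero(design.observed.any(axis=0))
    if global_obs.size == 0:
        return None

    info = np.zeros((1 + global_obs.size, 1 + global_obs.size))
    for s in range(design.n_sequences):
        periods = np.flatnonzero(design.observed[s])
        if periods.size == 0:
            continue
        # participant-level covariance for one cluster on this sequence
        if structure == "discrete_time_decay":
            corr = cac ** np.abs(periods[:, None] - periods[None, :]).astype(float)
        elif structure == "block_exchangeable":
            corr = np.where(periods[:, None] == periods[None, :], 1.0, cac)
        elif structure == "exchangeable":
            corr = np.ones((periods.size, periods.size))
        else:
            raise ValueError(structure)
        sigma = tau2 * np.kron(corr, np.ones((m, m))) + sigma2 * np.eye(m * periods.size)
        # columns: treatment, then one indicator per globally observed period
        dmat = np.zeros((m * periods.size, 1 + global_obs.size))
        col_of = {p: 1 + i for i, p in enumerate(global_obs)}
        for row, p in enumerate(periods):
            sl = slice(row * m, (row + 1) * m)
            dmat[sl, 0] = design.treatment[s, p]
            dmat[sl, col_of[p]] = 1.0
        contrib = dmat.T @ np.linalg.solve(sigma, dmat)
        info += int(design.clusters_per_sequence[s]) * contrib

    a = info[0, 0]
    b = info[1:, 0]
    c = info[1:, 1:]
    if np.linalg.matrix_rank(c, tol=1e-8) < c.shape[0]:
        return None
    scalar = a - b @ np.linalg.solve(c, b)
    if scalar <= max(1e-9, 1e-8 * abs(a)):
        return None
    return 1.0 / scalar


def rle_gap_counts(observed_row, treatment_row) -> tuple[int, int]:
    """(intervention gaps, control gaps) of one sequence via run-length
    encoding of the trimmed observation pattern."""
    obs = list(np.asarray(observed_row, dtype=bool))
    idx = [i for i, o in enumerate(obs) if o]
    if not idx:
        return 0, 0
    lo, hi = idx[0], idx[-1]
    gaps_int = gaps_con = 0
    pos = lo
    for value, run in itertools.groupby(obs[lo : hi + 1]):
        run_len = len(list(run))
        if not value:  # an interior unmeasured run: a gap
            resume = pos + run_len  # first measured period after the gap
            if treatment_row[resume] == 1:
                gaps_int += 1
            else:
                gaps_con += 1
        pos += run_len
    return gaps_int, gaps_con


def exhaustive_best_first_removal(design, corr, costs):
    """All CE-maximizing single-cell removals from *design*, found by
    enumerating every observed cell through the one-shot public API.
    Returns (best_cells, best_ce) with 1-based cells sharing the max CE
    within 1e-12 relative."""
    from swdopt import cost_efficiency, remove_cell
    from swdopt.variance import NotEstimableError

    results = []
    for seq, per in design.observed_cells():
        reduced = remove_cell(design, seq, per)
        try:
            ce = cost_efficiency(reduced, corr, costs)
        except NotEstimableError:
            continue
        results.append(((seq, per), ce))
    if not results:
        return [], None
    best_ce = max(ce for _, ce in results)
    best = [cell for cell, ce in results if ce >= best_ce * (1 - 1e-12)]
    return best, best_ce
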