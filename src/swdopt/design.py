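"""Sequence-by-period representation of (in)complete stepped wedge designs.

A design is a grid of S sequences by T periods. Each cell carries a
treatment indicator (0 control, 1 intervention) and an observation flag
(measured or not). All clusters randomized to a sequence share the same
schedule and observation pattern, so structural bookkeeping happens at the
sequence-period level. All public functions take 1-based sequence/period
indices; arrays are stored 0-based internally.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Design",
    "SequenceSummary",
    "make_complete_stepped_wedge",
    "remove_cell",
    "summarize_sequence",
    "fraction_removed",
    "to_schematic",
    "from_schematic",
    "design_to_csv",
]


@dataclass(frozen=True, eq=False)
class Design:
    """An (in)complete stepped wedge design.

    Parameters
    ----------
    treatment
        ``(S, T)`` array over ``{0, 1}``; 0 = control, 1 = intervention.
    observed
        ``(S, T)`` boolean array; True where the sequence-period cell is
        measured.
    clusters_per_sequence
        Length-``S`` vector of positive cluster counts (``N_s``).
    cluster_period_size
        Participants measured per cluster in each measured period (``m``).

    Notes
    -----
    Two designs compare equal when they have the same measured cells, the
    same treatment labels *at measured cells*, the same allocation and the
    same cluster-period size. Treatment labels under unobserved cells are
    computationally irrelevant and are ignored by ``==``.
    """

    treatment: np.ndarray
    observed: np.ndarray
    clusters_per_sequence: np.ndarray
    cluster_period_size: int

    def __post_init__(self) -> None:
        treatment = np.array(self.treatment, dtype=np.int8, copy=True)
        observed = np.array(self.observed, dtype=bool, copy=True)
        clusters = np.array(self.clusters_per_sequence, dtype=np.int64, copy=True)
        if treatment.ndim != 2:
            raise ValueError("treatment must be a 2-D sequence-by-period array")
        if not np.isin(treatment, (0, 1)).all():
            raise ValueError("treatment entries must be 0 or 1")
        if observed.shape != treatment.shape:
            raise ValueError(
                f"observed shape {observed.shape} != treatment shape {treatment.shape}"
            )
        if clusters.ndim != 1 or clusters.shape[0] != treatment.shape[0]:
            raise ValueError("clusters_per_sequence must have one entry per sequence")
        if (clusters < 1).any():
            raise ValueError("all cluster allocations must be >= 1")
        m = int(self.cluster_period_size)
        if m < 1:
            raise ValueError("cluster_period_size must be a positive integer")
        for arr in (treatment, observed, clusters):
            arr.setflags(write=False)
        object.__setattr__(self, "treatment", treatment)
        object.__setattr__(self, "observed", observed)
        object.__setattr__(self, "clusters_per_sequence", clusters)
        object.__setattr__(self, "cluster_period_size", m)

    @property
    def n_sequences(self) -> int:
        return self.treatment.shape[0]

    @property
    def n_periods(self) -> int:
        return self.treatment.shape[1]

    @property
    def n_clusters(self) -> int:
        return int(self.clusters_per_sequence.sum())

    @property
    def n_observed_cells(self) -> int:
        return int(self.observed.sum())

    def observed_cells(self) -> list[tuple[int, int]]:
        """Measured cells as 1-based ``(sequence, period)`` pairs, row-major."""
        return [(int(s) + 1, int(p) + 1) for s, p in zip(*np.nonzero(self.observed))]

    def with_observed(self, observed: np.ndarray) -> "Design":
        """Copy of this design with a replacement observation mask."""
        return Design(
            self.treatment,
            observed,
            self.clusters_per_sequence,
            self.cluster_period_size,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Design):
            return NotImplemented
        return (
            self.treatment.shape == other.treatment.shape
            and np.array_equal(self.observed, other.observed)
            and np.array_equal(
                self.treatment[self.observed], other.treatment[other.observed]
            )
            and np.array_equal(self.clusters_per_sequence, other.clusters_per_sequence)
            and self.cluster_period_size == other.cluster_period_size
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Design(S={self.n_sequences}, T={self.n_periods}, "
            f"K={self.n_clusters}, m={self.cluster_period_size}, "
            f"cells={self.n_observed_cells}/{self.observed.size})"
        )


@dataclass(frozen=True)
class SequenceSummary:
    """Structural counts for one sequence, as consumed by the cost formula.

    ``t_intervention``/``t_control`` count measured periods by condition;
    ``gaps_intervention``/``gaps_control`` count gaps (maximal unmeasured
    runs strictly between measured periods) attributed to the condition of
    the first measured period *after* the gap — the condition under which
    data collection restarts. ``present`` is False only for a fully
    unmeasured sequence, in which case every count is zero.
    """

    t_intervention: int
    t_control: int
    gaps_intervention: int
    gaps_control: int
    present: bool
    has_intervention_period: bool
    has_control_period: bool


def make_complete_stepped_wedge(
    n_sequences: int,
    clusters_per_sequence,
    cluster_period_size: int,
) -> Design:
    """Build the standard complete stepped wedge design.

    ``S`` sequences span ``T = S + 1`` periods; sequence ``s`` (1-based) is
    under control in periods ``1..s`` and under intervention thereafter.
    Every cell is measured.
    """
    n_sequences = int(n_sequences)
    if n_sequences < 2:
        raise ValueError("a stepped wedge design needs at least 2 sequences")
    clusters = np.asarray(clusters_per_sequence, dtype=np.int64)
    if clusters.ndim != 1 or clusters.shape[0] != n_sequences:
        raise ValueError("clusters_per_sequence must have one entry per sequence")
    if (clusters < 1).any():
        raise ValueError("all cluster allocations must be >= 1")
    n_periods = n_sequences + 1
    treatment = np.zeros((n_sequences, n_periods), dtype=np.int8)
    for s in range(n_sequences):
        treatment[s, s + 1 :] = 1
    observed = np.ones_like(treatment, dtype=bool)
    return Design(treatment, observed, clusters, cluster_period_size)


def remove_cell(design: Design, sequence: int, period: int) -> Design:
    """Return a new design with the given measured cell (1-based) unmeasured.

    The input design is left unchanged. Removing a cell that is already
    unmeasured raises, as that signals a bookkeeping bug in the caller.
    """
    s, p = _check_cell(design, sequence, period)
    if not design.observed[s, p]:
        raise ValueError(
            f"cell (sequence {sequence}, period {period}) is already unobserved"
        )
    observed = design.observed.copy()
    observed[s, p] = False
    return design.with_observed(observed)


def summarize_sequence(design: Design, sequence: int) -> SequenceSummary:
    """Compute the :class:`SequenceSummary` for a 1-based sequence index."""
    if not 1 <= sequence <= design.n_sequences:
        raise IndexError(f"sequence index {sequence} out of range")
    s = sequence - 1
    obs = design.observed[s]
    treat = design.treatment[s]
    idx = np.flatnonzero(obs)
    if idx.size == 0:
        return SequenceSummary(0, 0, 0, 0, False, False, False)
    t_int = int(treat[idx].sum())
    t_con = int(idx.size - t_int)
    gaps_int = 0
    gaps_con = 0
    # Gaps are unmeasured runs strictly between measured periods; leading and
    # trailing unmeasured runs do not count. A gap belongs to the condition
    # of the cell where measurement resumes.
    for prev, nxt in zip(idx[:-1], idx[1:]):
        if nxt - prev > 1:
            if treat[nxt] == 1:
                gaps_int += 1
            else:
                gaps_con += 1
    return SequenceSummary(
        t_intervention=t_int,
        t_control=t_con,
        gaps_intervention=gaps_int,
        gaps_control=gaps_con,
        present=True,
        has_intervention_period=t_int > 0,
        has_control_period=t_con > 0,
    )


def fraction_removed(design: Design, reference: Design) -> float:
    """Fraction of the reference design's measured cells absent from *design*."""
    if design.observed.shape != reference.observed.shape:
        raise ValueError(
            f"grid shapes differ: {design.observed.shape} vs {reference.observed.shape}"
        )
    n_ref = reference.n_observed_cells
    if n_ref == 0:
        raise ValueError("reference design has no observed cells")
    return (n_ref - design.n_observed_cells) / n_ref


def to_schematic(design: Design) -> str:
    """Render the design as text: one row per sequence, one char per period.

    ``'0'`` = measured control cell, ``'1'`` = measured intervention cell,
    ``'.'`` = unmeasured cell.
    """
    rows = []
    for s in range(design.n_sequences):
        chars = [
            str(int(design.treatment[s, p])) if design.observed[s, p] else "."
            for p in range(design.n_periods)
        ]
        rows.append("".join(chars))
    return "\n".join(rows)


def from_schematic(
    rows,
    clusters_per_sequence,
    cluster_period_size: int,
) -> Design:
    """Parse a schematic (string or list of row strings) back into a Design.

    Unmeasured cells get treatment label 0; that label is never consulted
    by any computation and is ignored by design equality.
    """
    if isinstance(rows, str):
        rows = [line for line in rows.splitlines() if line.strip()]
    rows = [row.strip() for row in rows]
    if not rows:
        raise ValueError("schematic has no rows")
    widths = {len(row) for row in rows}
    if len(widths) != 1:
        raise ValueError("schematic rows have unequal lengths")
    treatment = np.zeros((len(rows), widths.pop()), dtype=np.int8)
    observed = np.zeros_like(treatment, dtype=bool)
    for s, row in enumerate(rows):
        for p, char in enumerate(row):
            if char == ".":
                continue
            if char not in "01":
                raise ValueError(f"invalid schematic character {char!r} in row {s + 1}")
            treatment[s, p] = int(char)
            observed[s, p] = True
    return Design(treatment, observed, clusters_per_sequence, cluster_period_size)


def design_to_csv(design: Design, path=None) -> str:
    """Write the design as long-format CSV (1-based indices); return the text."""
    buf = io.StringIO()
    buf.write("sequence,period,treatment,observed,clusters\n")
    for s in range(design.n_sequences):
        for p in range(design.n_periods):
            buf.write(
                f"{s + 1},{p + 1},{int(design.treatment[s, p])},"
                f"{int(design.observed[s, p])},{int(design.clusters_per_sequence[s])}\n"
            )
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _check_cell(design: Design, sequence: int, period: int) -> tuple[int, int]:
    if not 1 <= sequence <= design.n_sequences:
        raise IndexError(f"sequence index {sequence} out of range")
    if not 1 <= period <= design.n_periods:
        raise IndexError(f"period index {period} out of range")
    return sequence - 1, period - 1
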