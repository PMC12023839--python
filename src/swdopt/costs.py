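"""Total trial cost of an (in)complete stepped wedge design.

The cost formula charges: a per-cluster cost for every cluster on a
sequence with at least one measured period; per-cluster condition
implementation costs for clusters whose sequence has at least one measured
period under that condition; per-participant costs for every measured
cluster-period; and per-gap restart costs whenever data collection resumes
after a pause, split by the condition under which it resumes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .design import Design, summarize_sequence

__all__ = ["CostSpec", "total_cost", "sequence_cost"]


@dataclass(frozen=True)
class CostSpec:
    """The seven cost parameters. All must be non-negative.

    Attributes map to the conventional symbols: ``cost_per_cluster`` (c),
    ``cluster_cost_intervention``/``_control`` (k, k'),
    ``participant_cost_intervention``/``_control`` (p, p'),
    ``restart_cost_intervention``/``_control`` (g, g').
    """

    cost_per_cluster: float = 0.0
    cluster_cost_intervention: float = 0.0
    cluster_cost_control: float = 0.0
    participant_cost_intervention: float = 0.0
    participant_cost_control: float = 0.0
    restart_cost_intervention: float = 0.0
    restart_cost_control: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")


def sequence_cost(design: Design, sequence: int, costs: CostSpec) -> float:
    """Cost contribution of one (1-based) sequence: the per-cluster
    contribution times its cluster allocation."""
    summary = summarize_sequence(design, sequence)
    if not summary.present:
        return 0.0
    m = design.cluster_period_size
    per_cluster = (
        costs.cost_per_cluster
        + costs.cluster_cost_intervention * summary.has_intervention_period
        + costs.cluster_cost_control * summary.has_control_period
        + m * costs.participant_cost_intervention * summary.t_intervention
        + m * costs.participant_cost_control * summary.t_control
        + costs.restart_cost_intervention * summary.gaps_intervention
        + costs.restart_cost_control * summary.gaps_control
    )
    return int(design.clusters_per_sequence[sequence - 1]) * per_cluster


def total_cost(design: Design, costs: CostSpec) -> float:
    """Total trial cost of the design; exact for integer inputs."""
    return sum(
        sequence_cost(design, s, costs) for s in range(1, design.n_sequences + 1)
    )
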