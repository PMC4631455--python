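"""Additivity-aware assembly of multiple-point mutants.

Two individually stabilizing substitutions can be antagonistic: the
predicted ΔΔG of their double mutant falls short of what additivity would
give. A pair is flagged antagonistic when the double-mutant ΔΔG (mean over
structures) is above −3.0 kcal/mol, strictly. The combiner:

1. keeps the most favorable substitution at each position
   (:func:`best_per_position`);
2. scans candidates from most to least stabilizing, admitting each one only
   if it is non-antagonistic with every already-admitted mutation
   (:func:`greedy_combine`) — the admitted set is therefore a clique in the
   additivity graph;
3. merges independently designed plans (e.g. the energy-based and the
   evolution-based mutant) into a hybrid (:func:`merge_designs`).

Pair ΔΔG values come from the same ingestion path as singles; the combiner
never invents energies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .energetics import Mutation

logger = logging.getLogger(__name__)

ANTAGONISM_THRESHOLD = -3.0  # kcal/mol, double-mutant ddG above this is antagonistic


@dataclass(frozen=True)
class PairAssessment:
    """Additivity evidence for one pair of candidate mutations."""

    pair: frozenset  # of Mutation
    double_ddg: float
    antagonistic: bool
    threshold_used: float

    def __post_init__(self) -> None:
        if len(self.pair) != 2:
            raise ValueError("pair must contain two distinct mutations")


@dataclass
class DesignPlan:
    """A multiple-point mutant under construction.

    ``mutations`` records admission order; ``provenance`` tags each mutation
    as coming from the energy arm, the evolution arm, or manual entry.
    """

    mutations: list[Mutation] = field(default_factory=list)
    provenance: dict[Mutation, str] = field(default_factory=dict)
    name: str = ""
    predicted_multi_ddg: float | None = None

    def __post_init__(self) -> None:
        positions = [m.position for m in self.mutations]
        if len(positions) != len(set(positions)):
            raise ValueError(f"plan {self.name!r} has two mutations at one position")

    @property
    def positions(self) -> set[int]:
        return {m.position for m in self.mutations}

    @property
    def notation(self) -> str:
        """Table-style '+'-joined mutation list, e.g. 'C128F + T148L'."""
        return " + ".join(str(m) for m in self.mutations)

    def __len__(self) -> int:
        return len(self.mutations)

    @classmethod
    def from_notation(
        cls, text: str, name: str = "", provenance: str = "manual"
    ) -> "DesignPlan":
        muts = [Mutation.parse(tok) for tok in text.replace("+", " ").split()]
        return cls(
            mutations=muts, provenance={m: provenance for m in muts}, name=name
        )


def assess_pair(
    a: Mutation,
    b: Mutation,
    double_ddg: float,
    threshold: float = ANTAGONISM_THRESHOLD,
) -> PairAssessment:
    """Flag a candidate pair as antagonistic when its double-mutant ΔΔG
    exceeds the threshold (strict; exactly −3.0 counts as additive)."""
    if a.position == b.position:
        raise ValueError(
            f"{a} and {b} share position {a.position}: not a valid double mutant"
        )
    return PairAssessment(
        pair=frozenset((a, b)),
        double_ddg=double_ddg,
        antagonistic=double_ddg > threshold,
        threshold_used=threshold,
    )


def best_per_position(
    candidates: Mapping[Mutation, float] | Iterable[tuple[Mutation, float]],
) -> dict[Mutation, float]:
    """Keep the most favorable (lowest mean ΔΔG) candidate at each position.

    Exact ties break alphabetically by substitution letter.
    """
    items = list(candidates.items() if isinstance(candidates, Mapping) else candidates)
    best: dict[int, tuple[Mutation, float]] = {}
    for mut, ddg in items:
        cur = best.get(mut.position)
        if cur is None or (ddg, mut.substitution) < (cur[1], cur[0].substitution):
            best[mut.position] = (mut, ddg)
    return {mut: ddg for mut, ddg in (best[p] for p in sorted(best))}


def greedy_combine(
    candidates: Mapping[Mutation, float] | Iterable[tuple[Mutation, float]],
    assessments: Iterable[PairAssessment],
    name: str = "design",
    provenance: str = "energy",
    secondary_rank: Mapping[Mutation, float] | None = None,
) -> DesignPlan:
    """Greedily assemble an additive multiple-point design.

    Candidates (one per position) are scanned from most to least
    stabilizing by their ranking ΔΔG; ties break on ``secondary_rank``
    (e.g. the other tool's mean, more negative first) and then position
    order. A candidate is admitted only when non-antagonistic with every
    already-admitted mutation; a missing pair assessment for a needed pair
    is an error naming the pair.
    """
    items = list(candidates.items() if isinstance(candidates, Mapping) else candidates)
    positions = [m.position for m, _ in items]
    if len(positions) != len(set(positions)):
        raise ValueError("candidates must be one per position (use best_per_position)")
    table: dict[frozenset, PairAssessment] = {a.pair: a for a in assessments}

    def rank_key(item: tuple[Mutation, float]):
        mut, ddg = item
        sec = secondary_rank.get(mut, 0.0) if secondary_rank else 0.0
        return (ddg, sec, mut.position)

    admitted: list[Mutation] = []
    for mut, _ in sorted(items, key=rank_key):
        compatible = True
        for prev in admitted:
            key = frozenset((prev, mut))
            if key not in table:
                raise KeyError(f"missing pair assessment for ({prev}, {mut})")
            if table[key].antagonistic:
                compatible = False
                break
        if compatible:
            admitted.append(mut)
    return DesignPlan(
        mutations=admitted,
        provenance={m: provenance for m in admitted},
        name=name,
    )


def merge_designs(
    plan_a: DesignPlan,
    plan_b: DesignPlan,
    conflict_policy: str = "error",
    name: str | None = None,
) -> DesignPlan:
    """Merge two independent designs into a hybrid plan.

    The result is the union of the two mutation sets in plan-A-then-plan-B
    order. Two different substitutions at the same position are a conflict:
    policy ``error`` (default) raises naming the position; ``prefer_A``
    keeps plan A's mutation. Provenance is preserved.
    """
    if conflict_policy not in ("error", "prefer_A"):
        raise ValueError(f"unknown conflict_policy: {conflict_policy!r}")
    merged: list[Mutation] = list(plan_a.mutations)
    provenance = dict(plan_a.provenance)
    by_pos = {m.position: m for m in plan_a.mutations}
    for m in plan_b.mutations:
        clash = by_pos.get(m.position)
        if clash is None:
            merged.append(m)
            by_pos[m.position] = m
            provenance[m] = plan_b.provenance.get(m, "manual")
        elif clash == m:
            continue
        elif conflict_policy == "error":
            raise ValueError(
                f"position {m.position} mutated differently in both plans "
                f"({clash} vs {m})"
            )
        else:
            logger.info("conflict at position %d: keeping %s over %s", m.position, clash, m)
    return DesignPlan(
        mutations=merged,
        provenance=provenance,
        name=name or f"{plan_a.name}+{plan_b.name}",
    )


def validate_plan(
    plan: DesignPlan, assessments: Iterable[PairAssessment]
) -> bool:
    """Re-test every admitted pair: the plan must be an additive clique."""
    table = {a.pair: a for a in assessments}
    for i, a in enumerate(plan.mutations):
        for b in plan.mutations[i + 1:]:
            assessment = table.get(frozenset((a, b)))
            if assessment is None or assessment.antagonistic:
                return False
    return True


def write_plan_tsv(plan: DesignPlan, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "order": range(1, len(plan) + 1),
            "mutation": [str(m) for m in plan.mutations],
            "provenance": [plan.provenance.get(m, "") for m in plan.mutations],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def plan_summary(plan: DesignPlan) -> str:
    lines = [
        f"design {plan.name or '(unnamed)'}: {len(plan)} mutations",
        f"  {plan.notation}",
    ]
    if plan.predicted_multi_ddg is not None:
        lines.append(f"  predicted multi-point ddG: {plan.predicted_multi_ddg:.2f} kcal/mol")
    by_src: dict[str, int] = {}
    for m in plan.mutations:
        by_src[plan.provenance.get(m, "manual")] = by_src.get(plan.provenance.get(m, "manual"), 0) + 1
    lines.append("  provenance: " + ", ".join(f"{k}={v}" for k, v in sorted(by_src.items())))
    return "\n".join(lines)
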