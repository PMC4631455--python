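"""Ingestion and classification of predicted folding free-energy changes.

Per-mutation ΔΔG predictions (kcal/mol, negative = stabilizing) computed by
external energy calculators on one or more crystal structures are parsed,
averaged — replicates within a structure first, then across structures —
and classified per tool:

* FoldX-style calls: stabilizing below −1.0 kcal/mol (strict), destabilizing
  above +0.5 kcal/mol (strict), neutral in between.
* Rosetta-style calls: stabilizing below −2.0 kcal/mol, same destabilizing
  bound.

The energy-based candidate set is the intersection of both tools'
stabilizing calls, restricted to positions that are neither highly conserved
(grade < 8) nor evolutionarily correlated with other positions
(score < 0.8). A destabilizing call by either tool vetoes candidacy.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .msa import AMINO_ACIDS, ConservationProfile, CorrelationProfile

logger = logging.getLogger(__name__)

#: default (stabilizing, destabilizing) thresholds per tool, kcal/mol
TOOL_THRESHOLDS: dict[str, tuple[float, float]] = {
    "foldx": (-1.0, 0.5),
    "rosetta": (-2.0, 0.5),
}

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class DdgParseError(ValueError):
    """A ΔΔG table line could not be interpreted."""


@dataclass(frozen=True, order=True)
class Mutation:
    """A single-point substitution in wtPOSsub notation (e.g. C128F)."""

    position: int
    wild_type: str
    substitution: str

    def __post_init__(self) -> None:
        for aa in (self.wild_type, self.substitution):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"not an amino-acid letter: {aa!r}")
        if self.wild_type == self.substitution:
            raise ValueError(
                f"wild type equals substitution at position {self.position}"
            )
        if self.position < 1:
            raise ValueError("position must be >= 1")

    @classmethod
    def parse(cls, token: str) -> "Mutation":
        m = _MUTATION_RE.match(token.strip().upper())
        if not m:
            raise DdgParseError(f"malformed mutation token: {token!r}")
        wt, pos, sub = m.groups()
        return cls(position=int(pos), wild_type=wt, substitution=sub)

    def __str__(self) -> str:
        return f"{self.wild_type}{self.position}{self.substitution}"


@dataclass(frozen=True)
class DdgRecord:
    """One predicted ΔΔG for one mutation on one structure (one replicate)."""

    mutation: Mutation
    structure_id: str
    tool: str  # foldx | rosetta | generic
    ddg: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.ddg):
            raise ValueError(f"non-finite ddg for {self.mutation}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


@dataclass(frozen=True)
class DdgSummary:
    """Per-mutation, per-tool mean ΔΔG over structures (replicates averaged first)."""

    mutation: Mutation
    tool: str
    mean_ddg: float
    n_structures: int
    n_replicates_per_structure: int


@dataclass(frozen=True)
class StabilityCall:
    mutation: Mutation
    tool: str
    call: str  # stabilizing | neutral | destabilizing
    threshold_used: float


# ---------------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------------

def parse_ddg_table(
    path: str | Path,
    dialect: str = "generic_tsv",
    tool: str | None = None,
    structure_id: str | None = None,
) -> list[DdgRecord]:
    """Parse a ΔΔG table into records.

    Supported dialects:

    ``generic_tsv``
        Tab-separated columns ``mutation  structure_id  ddg  [replicate]``;
        a header row whose first field is ``mutation`` is skipped, as are
        blank lines and ``#`` comments. ``tool`` defaults to ``generic``.

    ``foldx_buildmodel``
        BuildModel difference-file style: banner/comment lines are skipped
        until a header line whose first tab-field is ``Pdb``; each data row
        starts with a model filename ``<structure>_<mutation>_<replicate>.pdb``
        followed by the total energy difference. ``tool`` defaults to
        ``foldx``.

    ``rosetta_ddg_monomer``
        ddg_monomer predictions style: lines beginning with ``ddG:``
        followed by a description tag and the ΔΔG. The tag is either
        ``<mutation>`` or ``<structure>_<mutation>``; when it carries no
        structure the ``structure_id`` argument (or ``"model1"``) is used.
        ``tool`` defaults to ``rosetta``.
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "generic_tsv":
        records = _parse_generic(text, tool or "generic")
    elif dialect == "foldx_buildmodel":
        records = _parse_foldx(text, tool or "foldx")
    elif dialect == "rosetta_ddg_monomer":
        records = _parse_rosetta(text, tool or "rosetta", structure_id)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    if not records:
        raise DdgParseError(f"no ΔΔG records found in {path}")
    return records


def _parse_generic(text: str, tool: str) -> list[DdgRecord]:
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0].lower() == "mutation":
            continue
        if len(fields) < 3:
            raise DdgParseError(f"line {lineno}: expected >= 3 tab-separated fields")
        try:
            mut = Mutation.parse(fields[0])
            ddg = float(fields[2])
            rep = int(fields[3]) if len(fields) > 3 and fields[3] else 1
        except (DdgParseError, ValueError) as e:
            raise DdgParseError(f"line {lineno}: {e}") from e
        out.append(DdgRecord(mut, fields[1], tool, ddg, rep))
    return out


def _parse_foldx(text: str, tool: str) -> list[DdgRecord]:
    out = []
    in_table = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        fields = stripped.split("\t")
        if fields[0] == "Pdb":
            in_table = True
            continue
        if not in_table:
            continue
        name = fields[0]
        if name.lower().endswith(".pdb"):
            name = name[:-4]
        parts = name.split("_")
        if len(parts) < 3:
            raise DdgParseError(
                f"line {lineno}: model name {fields[0]!r} not "
                "<structure>_<mutation>_<replicate>"
            )
        try:
            rep = int(parts[-1])
            mut = Mutation.parse(parts[-2])
            ddg = float(fields[1])
        except (DdgParseError, ValueError) as e:
            raise DdgParseError(f"line {lineno}: {e}") from e
        out.append(DdgRecord(mut, "_".join(parts[:-2]), tool, ddg, rep))
    return out


def _parse_rosetta(text: str, tool: str, structure_id: str | None) -> list[DdgRecord]:
    out = []
    counts: dict[tuple[str, Mutation], int] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped.startswith("ddG:"):
            continue
        fields = stripped.split()
        if len(fields) < 3:
            raise DdgParseError(f"line {lineno}: expected 'ddG: <tag> <value>'")
        tag = fields[1]
        if tag.lower() == "description":  # column-header line
            continue
        try:
            if "_" in tag:
                struct, mut_token = tag.rsplit("_", 1)
            else:
                struct, mut_token = structure_id or "model1", tag
            mut = Mutation.parse(mut_token)
            ddg = float(fields[2])
        except (DdgParseError, ValueError) as e:
            raise DdgParseError(f"line {lineno}: {e}") from e
        key = (struct, mut)
        counts[key] = counts.get(key, 0) + 1
        out.append(DdgRecord(mut, struct, tool, ddg, counts[key]))
    return out


def write_ddg_tsv(records: Sequence[DdgRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "mutation": [str(r.mutation) for r in records],
            "structure_id": [r.structure_id for r in records],
            "ddg": [r.ddg for r in records],
            "replicate": [r.replicate for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Averaging and classification
# ---------------------------------------------------------------------------

def summarize_ddg(
    records: Iterable[DdgRecord],
    require_all_structures: bool = True,
    expected_structures: Iterable[str] | None = None,
) -> list[DdgSummary]:
    """Average ΔΔG per mutation: replicates within structure, then structures.

    With ``require_all_structures`` (the default), a mutation missing from
    any expected structure is excluded with a logged reason; the expected
    set defaults to the union of structure ids seen per tool. The relaxed
    mode averages whatever structures are available, with a warning.
    """
    records = list(records)
    if not records:
        raise ValueError("no ΔΔG records to summarize")
    by_tool: dict[str, list[DdgRecord]] = {}
    for r in records:
        by_tool.setdefault(r.tool, []).append(r)

    out: list[DdgSummary] = []
    for tool, recs in sorted(by_tool.items()):
        expected = (
            set(expected_structures)
            if expected_structures is not None
            else {r.structure_id for r in recs}
        )
        per_mut: dict[Mutation, dict[str, list[float]]] = {}
        for r in recs:
            per_mut.setdefault(r.mutation, {}).setdefault(r.structure_id, []).append(r.ddg)
        for mut in sorted(per_mut):
            structs = per_mut[mut]
            if require_all_structures and set(structs) != expected:
                missing = sorted(expected - set(structs))
                logger.info(
                    "excluding %s (%s): missing structures %s", mut, tool, missing
                )
                continue
            if not require_all_structures and set(structs) != expected:
                logger.warning(
                    "%s (%s): averaging over %d of %d structures",
                    mut, tool, len(structs), len(expected),
                )
            struct_means = [float(np.mean(v)) for _, v in sorted(structs.items())]
            n_rep = max(len(v) for v in structs.values())
            out.append(
                DdgSummary(
                    mutation=mut,
                    tool=tool,
                    mean_ddg=float(np.mean(struct_means)),
                    n_structures=len(structs),
                    n_replicates_per_structure=n_rep,
                )
            )
    return out


def call_stability(
    summary: DdgSummary,
    stabilizing_threshold: float | None = None,
    destabilizing_threshold: float | None = None,
) -> StabilityCall:
    """Classify a mean ΔΔG as stabilizing / neutral / destabilizing.

    Stabilizing strictly below the stabilizing threshold; destabilizing
    strictly above the destabilizing threshold; neutral otherwise. Defaults
    come from :data:`TOOL_THRESHOLDS` keyed by the summary's tool.
    """
    default = TOOL_THRESHOLDS.get(summary.tool, (-1.0, 0.5))
    stab = default[0] if stabilizing_threshold is None else stabilizing_threshold
    destab = default[1] if destabilizing_threshold is None else destabilizing_threshold
    if not stab < destab:
        raise ValueError("stabilizing threshold must be below destabilizing threshold")
    if summary.mean_ddg < stab:
        call = "stabilizing"
    elif summary.mean_ddg > destab:
        call = "destabilizing"
    else:
        call = "neutral"
    return StabilityCall(summary.mutation, summary.tool, call, stab)


def call_all(
    summaries: Iterable[DdgSummary],
    stabilizing_threshold: float | None = None,
    destabilizing_threshold: float | None = None,
) -> dict[Mutation, StabilityCall]:
    return {
        s.mutation: call_stability(s, stabilizing_threshold, destabilizing_threshold)
        for s in summaries
    }


def energy_candidates(
    foldx_calls: Mapping[Mutation, StabilityCall],
    rosetta_calls: Mapping[Mutation, StabilityCall],
    conservation: ConservationProfile | None = None,
    correlation: CorrelationProfile | None = None,
    grade_cutoff: int = 8,
    correlation_cutoff: float = 0.8,
    veto_destabilizing: bool = True,
) -> list[Mutation]:
    """Energy-based candidates: both tools stabilizing, position mutable.

    A mutation qualifies when both tools call it stabilizing and its
    position is neither immutable (conservation grade ≥ ``grade_cutoff``,
    inclusive) nor correlated (score ≥ ``correlation_cutoff``, inclusive).
    A destabilizing call by either tool vetoes candidacy even if the other
    calls stabilizing (on by default). Mutations known to only one tool
    are excluded with a logged reason. The same filters may equivalently be
    applied before the energy calls (the usual order, to cut compute); the
    result set is identical either way.
    """
    out = []
    for mut in sorted(set(foldx_calls) | set(rosetta_calls)):
        fx, rs = foldx_calls.get(mut), rosetta_calls.get(mut)
        if fx is None or rs is None:
            logger.info("excluding %s: present in only one tool's calls", mut)
            continue
        if veto_destabilizing and "destabilizing" in (fx.call, rs.call):
            continue
        if not (fx.call == "stabilizing" and rs.call == "stabilizing"):
            continue
        if conservation is not None:
            grade = conservation.grade(mut.position)
            if grade is not None and grade >= grade_cutoff:
                continue
        if correlation is not None and correlation.score(mut.position) >= correlation_cutoff:
            continue
        out.append(mut)
    return out


def filter_mutable_positions(
    mutations: Iterable[Mutation],
    conservation: ConservationProfile | None = None,
    correlation: CorrelationProfile | None = None,
    grade_cutoff: int = 8,
    correlation_cutoff: float = 0.8,
) -> list[Mutation]:
    """Drop mutations at immutable (grade ≥ cutoff) or correlated positions.

    Used as the pre-filter before energy evaluation in the pipeline driver.
    """
    out = []
    for mut in mutations:
        if conservation is not None:
            grade = conservation.grade(mut.position)
            if grade is not None and grade >= grade_cutoff:
                continue
        if correlation is not None and correlation.score(mut.position) >= correlation_cutoff:
            continue
        out.append(mut)
    return out
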