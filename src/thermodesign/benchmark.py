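"""Benchmark curation and evaluation of stability predictors.

Experimental stability records (ProTherm-style: measured ΔΔG of folding for
single-point mutants, with pH/temperature metadata) are curated into a
labeled benchmark:

* records with |ΔΔG| below 0.5 kcal/mol are dropped (the experimental error
  of ΔΔG measurements is about 0.48 kcal/mol, so smaller effects are not
  reliably signed); the bound is inclusive — exactly 0.5 is kept;
* when one (protein, mutation) has several measurements, the one closest to
  physiological pH 7 is retained;
* labels follow the canonical internal sign convention, negative ΔΔG =
  stabilizing; files using the opposite convention declare it and are
  flipped on read.

Predictor calls are scored with precision (truly stabilizing / predicted
stabilizing) and false positive rate (destabilizing called stabilizing /
all destabilizing), over a decision-threshold grid from −2.5 to +2.5
kcal/mol in steps of 0.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .energetics import DdgSummary, Mutation, StabilityCall
from .msa import ConservationProfile

logger = logging.getLogger(__name__)

DEFAULT_GRID = tuple(np.arange(-2.5, 2.5 + 1e-9, 0.5).round(1))

SIGN_CONVENTIONS = ("stabilizing_negative", "stabilizing_positive")


@dataclass(frozen=True)
class ExperimentalRecord:
    """One experimental ΔΔG measurement (canonical sign: negative = stabilizing)."""

    protein_id: str
    mutation: Mutation
    ddg_exp: float
    pH: float | None = None
    temperature: float | None = None
    record_id: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.ddg_exp):
            raise ValueError("ddg_exp must be finite")
        if self.pH is not None and not 0 <= self.pH <= 14:
            raise ValueError(f"pH {self.pH} outside [0, 14]")


@dataclass
class BenchmarkDataset:
    """Curated, deduplicated experimental records with stability labels."""

    records: list[ExperimentalRecord]
    min_abs_ddg: float = 0.5

    @property
    def labels(self) -> dict[tuple[str, Mutation], str]:
        return {
            (r.protein_id, r.mutation): "stabilizing" if r.ddg_exp < 0 else "destabilizing"
            for r in self.records
        }

    @property
    def n_stabilizing(self) -> int:
        return sum(1 for r in self.records if r.ddg_exp < 0)

    @property
    def n_destabilizing(self) -> int:
        return len(self.records) - self.n_stabilizing


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class MetricRow:
    """Precision / FPR of one tool at one decision threshold.

    ``precision`` is ``None`` (undefined) when nothing was predicted
    stabilizing; metrics are stored at full precision — whole-percent
    rounding happens only in reports.
    """

    tool: str
    threshold: float
    precision: float | None
    fpr: float | None
    n_predicted_stabilizing: int
    tp: int


# ---------------------------------------------------------------------------
# Reading and curation
# ---------------------------------------------------------------------------

def read_experimental_tsv(
    path: str | Path, sign_convention: str | None = None
) -> list[ExperimentalRecord]:
    """Read a ProTherm-style TSV of experimental stability records.

    Columns: ``protein_id  mutation  ddg_exp  pH  temperature  record_id``
    (pH/temperature may be empty). The sign convention is declared either by
    a leading ``# sign_convention=...`` comment line or by the argument;
    ``stabilizing_positive`` files are flipped to the canonical
    negative-is-stabilizing convention on read.
    """
    path = Path(path)
    header_convention = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "sign_convention" in line:
                header_convention = line.split("=", 1)[1].strip()
            elif not line.startswith("#"):
                break
    convention = sign_convention or header_convention
    if convention not in SIGN_CONVENTIONS:
        raise ValueError(
            f"sign convention must be declared as one of {SIGN_CONVENTIONS}"
        )
    flip = -1.0 if convention == "stabilizing_positive" else 1.0
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for i, row in df.iterrows():
        out.append(
            ExperimentalRecord(
                protein_id=str(row["protein_id"]),
                mutation=Mutation.parse(str(row["mutation"])),
                ddg_exp=flip * float(row["ddg_exp"]),
                pH=None if pd.isna(row.get("pH")) else float(row["pH"]),
                temperature=(
                    None if pd.isna(row.get("temperature")) else float(row["temperature"])
                ),
                record_id=str(row.get("record_id", i)),
            )
        )
    return out


def curate(
    records: Iterable[ExperimentalRecord] | BenchmarkDataset,
    min_abs_ddg: float = 0.5,
    target_pH: float = 7.0,
) -> BenchmarkDataset:
    """Curate experimental records into a labeled benchmark dataset.

    Records with |ΔΔG| below ``min_abs_ddg`` are removed (exactly the bound
    is kept). Duplicates of one (protein, mutation) collapse to the record
    closest to ``target_pH``; ties prefer the lower pH, then the smaller
    deviation from 25 °C, then the lexicographically smallest record id.
    A record with missing pH always loses to one with a pH. Idempotent.
    """
    if isinstance(records, BenchmarkDataset):
        records = records.records
    filtered = [r for r in records if abs(r.ddg_exp) >= min_abs_ddg]

    def dedup_key(r: ExperimentalRecord):
        has_ph = r.pH is not None
        ph_dist = abs(r.pH - target_pH) if has_ph else math.inf
        ph_val = r.pH if has_ph else math.inf
        t_dist = abs(r.temperature - 25.0) if r.temperature is not None else math.inf
        return (not has_ph, ph_dist, ph_val, t_dist, r.record_id)

    by_mut: dict[tuple[str, Mutation], list[ExperimentalRecord]] = {}
    for r in filtered:
        by_mut.setdefault((r.protein_id, r.mutation), []).append(r)
    kept = [min(group, key=dedup_key) for group in by_mut.values()]
    kept.sort(key=lambda r: (r.protein_id, r.mutation, r.record_id))
    return BenchmarkDataset(records=kept, min_abs_ddg=min_abs_ddg)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def precision(c: ConfusionCounts) -> float | None:
    """Truly stabilizing / predicted stabilizing; None when nothing predicted."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else None


def false_positive_rate(c: ConfusionCounts) -> float | None:
    """Destabilizing called stabilizing / all destabilizing; None if no negatives."""
    denom = c.fp + c.tn
    return c.fp / denom if denom else None


def as_percent(value: float | None) -> int | None:
    """Whole-percent rounding, half away from zero (report formatting only)."""
    if value is None:
        return None
    return int(math.floor(abs(value) * 100 + 0.5)) * (1 if value >= 0 else -1)


def confusion_from_predictions(
    predicted_stabilizing: set, dataset: BenchmarkDataset
) -> ConfusionCounts:
    """Count a prediction set against dataset labels.

    ``predicted_stabilizing`` holds (protein_id, Mutation) keys — or bare
    Mutations for single-protein datasets.
    """
    tp = fp = tn = fn = 0
    for key, label in dataset.labels.items():
        hit = key in predicted_stabilizing or key[1] in predicted_stabilizing
        if label == "stabilizing":
            tp, fn = (tp + 1, fn) if hit else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if hit else (fp, tn + 1)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def threshold_sweep(
    summaries_by_tool: Mapping[str, Sequence[DdgSummary]],
    dataset: BenchmarkDataset,
    grid: Sequence[float] = DEFAULT_GRID,
    missing_prediction: str = "error",
) -> list[MetricRow]:
    """Precision/FPR of each tool across the decision-threshold grid.

    At threshold t a mutation is predicted stabilizing iff its mean ΔΔG is
    strictly below t. Dataset mutations with no prediction raise by default
    (``missing_prediction="skip"`` drops them with a log message).
    """
    if not dataset.records:
        raise ValueError("empty benchmark dataset")
    rows: list[MetricRow] = []
    for tool, summaries in sorted(summaries_by_tool.items()):
        means = {s.mutation: s.mean_ddg for s in summaries}
        keys = []
        for key in dataset.labels:
            if key[1] not in means:
                if missing_prediction == "error":
                    raise KeyError(f"no {tool} prediction for {key[1]}")
                logger.info("skipping %s: no %s prediction", key[1], tool)
                continue
            keys.append(key)
        subset = BenchmarkDataset(
            records=[r for r in dataset.records if (r.protein_id, r.mutation) in set(keys)],
            min_abs_ddg=dataset.min_abs_ddg,
        )
        for t in grid:
            predicted = {k for k in keys if means[k[1]] < t}
            c = confusion_from_predictions(predicted, subset)
            rows.append(
                MetricRow(
                    tool=tool,
                    threshold=float(t),
                    precision=precision(c),
                    fpr=false_positive_rate(c),
                    n_predicted_stabilizing=c.tp + c.fp,
                    tp=c.tp,
                )
            )
    return rows


def evaluate_pipeline(
    foldx_calls: Mapping[Mutation, StabilityCall],
    rosetta_calls: Mapping[Mutation, StabilityCall],
    conservation: ConservationProfile | None,
    dataset: BenchmarkDataset,
    grade_cutoff: int = 8,
) -> MetricRow:
    """Score the combined rule: both tools stabilizing, position mutable.

    The prediction set is the intersection of both tools' stabilizing calls
    at their own thresholds, minus mutations at positions with conservation
    grade ≥ ``grade_cutoff``; it is scored against the dataset labels.
    """
    predicted = set()
    for mut, fx in foldx_calls.items():
        rs = rosetta_calls.get(mut)
        if rs is None:
            continue
        if fx.call == "stabilizing" and rs.call == "stabilizing":
            if conservation is not None:
                grade = conservation.grade(mut.position)
                if grade is not None and grade >= grade_cutoff:
                    continue
            predicted.add(mut)
    c = confusion_from_predictions(predicted, dataset)
    return MetricRow(
        tool="combined",
        threshold=math.nan,
        precision=precision(c),
        fpr=false_positive_rate(c),
        n_predicted_stabilizing=c.tp + c.fp,
        tp=c.tp,
    )


def write_metrics_tsv(rows: Sequence[MetricRow], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "tool": [r.tool for r in rows],
            "threshold": [r.threshold for r in rows],
            "tp": [r.tp for r in rows],
            "predicted_positive": [r.n_predicted_stabilizing for r in rows],
            "precision": [r.precision for r in rows],
            "fpr": [r.fpr for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False)
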