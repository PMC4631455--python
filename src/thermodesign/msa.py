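"""Multiple-sequence-alignment ingestion and back-to-consensus analysis.

This module turns an alignment of homologs into per-column residue
statistics and proposes *back-to-consensus* substitutions — positions where
the query protein deviates from the residue that dominates the column among
its homologs. Two selection rules are provided:

* **simple consensus** — a residue present in at least ``cutoff`` (default
  50%) of the analyzed sequences is the consensus residue; a candidate is
  emitted wherever the consensus differs from the query's wild type.
* **frequency ratio** — the most frequent residue must reach a minimal
  frequency (default 0.4) and the wild-type/consensus frequency ratio must
  not exceed a cutoff (default 0.2).

It also houses conservation grading (a 1–9 discretization of site-specific
evolutionary rates; grade ≥ 8 marks positions treated as immutable) and a
normalized-mutual-information stand-in for correlated-mutation scores, both
used downstream to veto candidates at functionally constrained positions.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
WILDCARD = "X"  # unknown residues; never counted in frequencies


class AlignmentShapeError(ValueError):
    """Rows of the alignment do not all have the same length."""


class QueryLookupError(KeyError):
    """The declared query identifier is absent from the alignment."""


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """An aligned set of homolog sequences with a designated query row.

    ``records`` is an ordered list of ``(identifier, aligned_sequence)``
    pairs; sequences are upper-case strings over the 20 amino-acid letters,
    the gap symbol ``-`` and the wildcard ``X``. Query coordinates used
    throughout the package are 1-based over the gap-free query sequence.
    """

    records: list[tuple[str, str]]
    query_id: str

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment has no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"aligned rows have unequal lengths: {sorted(lengths)}"
            )
        ids = [rid for rid, _ in self.records]
        if self.query_id not in ids:
            raise QueryLookupError(
                f"query_id {self.query_id!r} not among alignment identifiers"
            )
        if all(c == GAP for c in self.query_row):
            raise ValueError("query row contains only gaps")

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def query_row(self) -> str:
        for rid, seq in self.records:
            if rid == self.query_id:
                return seq
        raise QueryLookupError(self.query_id)  # pragma: no cover

    @property
    def query_sequence(self) -> str:
        """Gap-free query sequence."""
        return self.query_row.replace(GAP, "")

    def column(self, column_index: int) -> list[str]:
        if not 0 <= column_index < self.length:
            raise IndexError(f"column {column_index} out of range")
        return [seq[column_index] for _, seq in self.records]

    def query_position_to_column(self) -> dict[int, int]:
        """Map 1-based gap-free query positions to alignment column indices."""
        mapping: dict[int, int] = {}
        pos = 0
        for i, c in enumerate(self.query_row):
            if c != GAP:
                pos += 1
                mapping[pos] = i
        return mapping

    def column_to_query_position(self) -> dict[int, int]:
        return {col: pos for pos, col in self.query_position_to_column().items()}


def _clean(seq: str) -> str:
    out = []
    for c in seq.upper():
        if c in (".", "-", "~"):
            out.append(GAP)
        elif c in AMINO_ACIDS:
            out.append(c)
        else:
            out.append(WILDCARD)
    return "".join(out)


def read_alignment(path: str | Path, query_id: str, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Clustal file into an :class:`Alignment`.

    Residues are upper-cased; ``.``/``~`` gap variants are normalized to
    ``-``; characters outside the 20 canonical amino-acid letters become the
    wildcard ``X``, which is excluded from all frequency counts.
    """
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    msa = AlignIO.read(str(path), format)
    records = [(rec.id, _clean(str(rec.seq))) for rec in msa]
    return Alignment(records=records, query_id=query_id)


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.records
    )
    AlignIO.write(msa, str(path), format)


# ---------------------------------------------------------------------------
# Column statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ColumnProfile:
    """Residue frequencies of one alignment column, in query coordinates."""

    query_position: int
    column_index: int
    frequencies: Mapping[str, float]
    gap_fraction: float
    n_sequences: int


def column_profile(
    aln: Alignment, column_index: int, gap_policy: str = "exclude_gaps"
) -> ColumnProfile:
    """Residue frequencies of a column.

    ``exclude_gaps`` divides counts by the number of non-gap residues;
    ``count_gaps`` divides by the full number of sequences (so frequencies
    sum to ``1 - gap_fraction``). Wildcard residues are never counted and
    are excluded from either denominator.
    """
    if gap_policy not in ("exclude_gaps", "count_gaps"):
        raise ValueError(f"unknown gap_policy: {gap_policy!r}")
    qpos = aln.column_to_query_position().get(column_index)
    if qpos is None:
        raise ValueError(
            f"column {column_index} has a gap in the query; no query position"
        )
    col = aln.column(column_index)
    counts = Counter(c for c in col if c in AMINO_ACIDS)
    n_gap = sum(1 for c in col if c == GAP)
    n_wild = sum(1 for c in col if c == WILDCARD)
    n_total = len(col) - n_wild
    denom = (n_total - n_gap) if gap_policy == "exclude_gaps" else n_total
    freqs = {aa: n / denom for aa, n in sorted(counts.items())} if denom else {}
    return ColumnProfile(
        query_position=qpos,
        column_index=column_index,
        frequencies=freqs,
        gap_fraction=n_gap / n_total if n_total else 0.0,
        n_sequences=aln.n_sequences,
    )


def _consensus_residue(freqs: Mapping[str, float], wild_type: str) -> tuple[str, float] | None:
    """Most frequent residue; ties prefer non-wild-type, then alphabetical."""
    if not freqs:
        return None
    best = max(freqs.values())
    tied = sorted(aa for aa, f in freqs.items() if f == best)
    non_wt = [aa for aa in tied if aa != wild_type]
    return (non_wt[0] if non_wt else tied[0]), best


# ---------------------------------------------------------------------------
# Back-to-consensus candidate generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsensusCandidate:
    """A proposed back-to-consensus substitution at one query position."""

    query_position: int
    wild_type: str
    proposed: str
    method: str  # simple_consensus | frequency_ratio
    consensus_frequency: float
    wild_type_frequency: float

    def __post_init__(self) -> None:
        if self.wild_type == self.proposed:
            raise ValueError("candidate proposes wild-type -> wild-type")
        if self.consensus_frequency < self.wild_type_frequency:
            raise ValueError("consensus frequency below wild-type frequency")

    @property
    def notation(self) -> str:
        return f"{self.wild_type}{self.query_position}{self.proposed}"


def _iter_query_columns(aln: Alignment, mask: Iterable[int], gap_policy: str):
    masked = set(mask or ())
    for qpos, col in aln.query_position_to_column().items():
        if qpos in masked:
            continue
        wt = aln.query_row[col]
        if wt == WILDCARD:
            continue
        yield qpos, column_profile(aln, col, gap_policy), wt


def simple_consensus(
    aln: Alignment,
    cutoff: float = 0.5,
    mask: Iterable[int] = (),
    gap_policy: str = "exclude_gaps",
) -> list[ConsensusCandidate]:
    """Back-to-consensus candidates under the simple-consensus rule.

    A residue must be present at the position in at least ``cutoff`` of the
    analyzed sequences (inclusive) to be the consensus residue; a candidate
    is emitted where the consensus differs from the query's wild type.
    Positions in ``mask`` (poorly aligned regions, supplied as 1-based query
    positions) are skipped.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    out: list[ConsensusCandidate] = []
    for qpos, prof, wt in _iter_query_columns(aln, mask, gap_policy):
        top = _consensus_residue(prof.frequencies, wt)
        if top is None:
            continue
        residue, freq = top
        if freq >= cutoff and residue != wt:
            out.append(
                ConsensusCandidate(
                    query_position=qpos,
                    wild_type=wt,
                    proposed=residue,
                    method="simple_consensus",
                    consensus_frequency=freq,
                    wild_type_frequency=prof.frequencies.get(wt, 0.0),
                )
            )
    return out


def frequency_ratio(
    aln: Alignment,
    ratio_cutoff: float = 0.2,
    min_consensus_freq: float = 0.4,
    mask: Iterable[int] = (),
    gap_policy: str = "exclude_gaps",
) -> list[ConsensusCandidate]:
    """Back-to-consensus candidates under the frequency-ratio rule.

    The most frequent (consensus) residue must differ from the wild type,
    reach ``min_consensus_freq``, and the ratio of wild-type to consensus
    frequency must not exceed ``ratio_cutoff`` (both bounds inclusive).
    """
    if not (0 < ratio_cutoff <= 1 and 0 < min_consensus_freq <= 1):
        raise ValueError("cutoffs must lie in (0, 1]")
    out: list[ConsensusCandidate] = []
    for qpos, prof, wt in _iter_query_columns(aln, mask, gap_policy):
        top = _consensus_residue(prof.frequencies, wt)
        if top is None:
            continue
        residue, freq = top
        if residue == wt or freq < min_consensus_freq:
            continue
        wt_freq = prof.frequencies.get(wt, 0.0)
        if wt_freq / freq <= ratio_cutoff:
            out.append(
                ConsensusCandidate(
                    query_position=qpos,
                    wild_type=wt,
                    proposed=residue,
                    method="frequency_ratio",
                    consensus_frequency=freq,
                    wild_type_frequency=wt_freq,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Conservation grades and correlation scores
# ---------------------------------------------------------------------------

@dataclass
class ConservationProfile:
    """Per-position normalized evolutionary rates and 1–9 conservation grades.

    More negative rates mean slower evolution, i.e. stronger conservation;
    grade 9 is the most conserved. Grade ≥ 8 marks immutable positions.
    """

    rates: dict[int, float]
    grades: dict[int, int]

    def grade(self, position: int) -> int | None:
        return self.grades.get(position)


@dataclass
class CorrelationProfile:
    """Per-position maximum pairwise correlated-mutation score in [0, 1]."""

    scores: dict[int, float]

    def score(self, position: int) -> float:
        return self.scores.get(position, 0.0)


def grades_from_rates(rates: Mapping[int, float]) -> ConservationProfile:
    """Convert normalized evolutionary rates into 1–9 conservation grades.

    Equal-width binning of the observed rate range into nine bins; the
    most-negative (most conserved) bin maps to grade 9. A degenerate range
    (constant rates, or a single position) yields grade 5 everywhere. This
    is a declared stand-in for the ConSurf partition; externally computed
    grades can be imported verbatim with :func:`read_profile_tsv` and take
    precedence when supplied.
    """
    if not rates:
        raise ValueError("no rates supplied")
    values = np.array(list(rates.values()), dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        grades = {p: 5 for p in rates}
    else:
        width = (hi - lo) / 9.0
        grades = {}
        for p, r in rates.items():
            b = min(int((r - lo) / width), 8)
            grades[p] = 9 - b
    return ConservationProfile(rates=dict(rates), grades=grades)


def _entropy(labels: Sequence[str]) -> float:
    counts = np.array(list(Counter(labels).values()), dtype=float)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _mutual_information(x: Sequence[str], y: Sequence[str]) -> float:
    joint = Counter(zip(x, y))
    n = len(x)
    px = Counter(x)
    py = Counter(y)
    mi = 0.0
    for (a, b), c in joint.items():
        mi += (c / n) * math.log(c * n / (px[a] * py[b]))
    return mi


def correlation_scores(
    aln: Alignment, mask: Iterable[int] = ()
) -> CorrelationProfile:
    """Per-position maximum normalized mutual information with any partner.

    The score of a column pair is MI divided by the smaller of the two
    column entropies, giving a co-variation statistic in [0, 1]; a constant
    column scores 0 by convention. This is a documented approximation to
    correlated-mutation-analysis scores; externally computed scores can be
    imported instead. With fewer than 3 sequences the statistic is
    meaningless and all positions score 0 (with a warning).
    """
    masked = set(mask or ())
    pos_to_col = {
        p: c for p, c in aln.query_position_to_column().items() if p not in masked
    }
    if len(pos_to_col) < 2:
        raise ValueError("need at least 2 non-masked columns")
    if aln.n_sequences < 3:
        logger.warning(
            "correlation scores degenerate: alignment has %d sequences",
            aln.n_sequences,
        )
        return CorrelationProfile(scores={p: 0.0 for p in pos_to_col})

    cols = {}
    for p, c in pos_to_col.items():
        col = aln.column(c)
        cols[p] = col
    positions = sorted(pos_to_col)
    # residue vectors restricted to rows where both columns are informative
    scores = {p: 0.0 for p in positions}
    entropies = {}
    informative = {}
    for p in positions:
        obs = [(i, c) for i, c in enumerate(cols[p]) if c in AMINO_ACIDS]
        informative[p] = dict(obs)
        entropies[p] = _entropy([c for _, c in obs]) if obs else 0.0
    for i, p in enumerate(positions):
        for q in positions[i + 1:]:
            rows = sorted(set(informative[p]) & set(informative[q]))
            if len(rows) < 3:
                continue
            x = [informative[p][r] for r in rows]
            y = [informative[q][r] for r in rows]
            hx, hy = _entropy(x), _entropy(y)
            if hx == 0.0 or hy == 0.0:
                continue  # constant column: score 0 by convention
            nmi = _mutual_information(x, y) / min(hx, hy)
            nmi = min(max(nmi, 0.0), 1.0)
            if nmi > scores[p]:
                scores[p] = nmi
            if nmi > scores[q]:
                scores[q] = nmi
    return CorrelationProfile(scores=scores)


# ---------------------------------------------------------------------------
# Redundancy reduction
# ---------------------------------------------------------------------------

def pairwise_identity(a: str, b: str) -> float:
    """Matches over shared non-gap columns; 0 if no shared columns."""
    shared = matches = 0
    for x, y in zip(a, b):
        if x != GAP and y != GAP:
            shared += 1
            if x == y:
                matches += 1
    return matches / shared if shared else 0.0


def reduce_redundancy(aln: Alignment, identity_cutoff: float) -> Alignment:
    """Greedy identity-based redundancy reduction; the query is always kept.

    Sequences are scanned in input order and dropped when their pairwise
    identity to any already-kept sequence strictly exceeds the cutoff.
    """
    if not 0 < identity_cutoff <= 1:
        raise ValueError("identity_cutoff must lie in (0, 1]")
    kept: list[tuple[str, str]] = [(aln.query_id, aln.query_row)]
    for rid, seq in aln.records:
        if rid == aln.query_id:
            continue
        if all(pairwise_identity(seq, k) <= identity_cutoff for _, k in kept):
            kept.append((rid, seq))
    # restore input order
    order = {rid: i for i, (rid, _) in enumerate(aln.records)}
    kept.sort(key=lambda rec: order[rec[0]])
    return Alignment(records=kept, query_id=aln.query_id)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def write_candidates_tsv(candidates: Sequence[ConsensusCandidate], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "position": [c.query_position for c in candidates],
            "wt": [c.wild_type for c in candidates],
            "proposed": [c.proposed for c in candidates],
            "method": [c.method for c in candidates],
            "consensus_freq": [c.consensus_frequency for c in candidates],
            "wt_freq": [c.wild_type_frequency for c in candidates],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_profile_tsv(path: str | Path) -> dict[int, float]:
    """Read a two-column (position, value) TSV of external rates/grades/scores."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError("profile TSV needs columns: position, value")
    pos_col, val_col = df.columns[0], df.columns[1]
    return {int(p): float(v) for p, v in zip(df[pos_col], df[val_col])}


def conservation_from_grades(grades: Mapping[int, float]) -> ConservationProfile:
    """Build a profile from externally computed grades (imported verbatim)."""
    g = {int(p): int(v) for p, v in grades.items()}
    if any(not 1 <= v <= 9 for v in g.values()):
        raise ValueError("grades must lie in 1..9")
    return ConservationProfile(rates={}, grades=g)
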