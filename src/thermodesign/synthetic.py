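"""Seeded synthetic data for end-to-end testing of the design pipeline.

Real inputs for this workflow — curated alignments of homologs, ΔΔG tables
from external energy calculators, crystal structures — cannot be bundled or
downloaded at test time, so every stage has a generator that emulates its
input with planted, recoverable ground truth:

* :func:`generate_msa` — an alignment whose background columns are
  dominated by the query's residue (so they yield no candidates), with
  back-to-consensus deviations planted at chosen positions and
  frequencies;
* :func:`generate_ddg` — single-mutant ΔΔG values drawn from a mixture of
  a stabilizing tail and a near-neutral bulk, replicated per structure
  with Gaussian noise, and double-mutant values built additively except
  for planted antagonistic pairs, whose epistasis offset pushes them above
  the antagonism threshold;
* :func:`generate_structure` — a minimal PDB with charged side-chain
  atoms placed at exact requested salt-bridge distances.

Each generator draws from its own pseudo-random stream derived from the
master seed by a fixed label, so adding one generator never perturbs the
output of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .energetics import DdgRecord, Mutation
from .msa import AMINO_ACIDS, Alignment

# fixed stream labels: adding a generator must not perturb existing streams
_STREAM = {"msa": 11, "ddg": 22, "structure": 33}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAM[stream]])


@dataclass(frozen=True)
class PlantedSite:
    """A back-to-consensus deviation planted into the synthetic alignment."""

    position: int
    wild_type: str
    consensus: str
    consensus_freq: float = 0.8
    wild_type_freq: float = 0.05

    def __post_init__(self) -> None:
        if self.wild_type == self.consensus:
            raise ValueError("planted consensus equals wild type")
        if not (0 < self.consensus_freq <= 1 and 0 < self.wild_type_freq <= 1):
            raise ValueError("planted frequencies must lie in (0, 1]")


@dataclass(frozen=True)
class PlantedPair:
    """An antagonistic pair: epistasis offset added to the additive double ΔΔG."""

    mutation_a: Mutation
    mutation_b: Mutation
    epistasis_offset: float  # kcal/mol; > 0 pushes the pair toward antagonism


@dataclass(frozen=True)
class BridgeSpec:
    """A salt bridge to realize in the toy structure at an exact N–O distance."""

    acidic_residue: int
    basic_residue: int
    distance: float  # Å

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("requested distance must be positive")


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic project.

    Defaults mirror the conditions exercised throughout the test suite: a
    50-sequence alignment with planted consensus residues at frequency 0.8
    against a wild-type frequency of 0.05, three structures with
    0.2 kcal/mol replicate noise on ΔΔG, and antagonism offsets large
    enough to push a planted pair's double mutant above −3.0 kcal/mol.
    """

    seed: int = 0
    n_sequences: int = 50
    length: int = 40
    planted_consensus_sites: list[PlantedSite] = field(default_factory=list)
    planted_antagonistic_pairs: list[PlantedPair] = field(default_factory=list)
    ddg_noise_sd: float = 0.2
    structures: list[BridgeSpec] = field(default_factory=list)
    structure_ids: tuple[str, ...] = ("S1", "S2", "S3")
    n_replicates: int = 3
    stabilizing_fraction: float = 0.25


# ---------------------------------------------------------------------------
# Alignment generator
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def generate_msa(spec: SyntheticSpec) -> tuple[Alignment, list[PlantedSite]]:
    """Generate an alignment with planted back-to-consensus deviations.

    Background columns carry the query's wild-type residue in ~70% of
    sequences (drawn i.i.d.), so neither consensus rule fires there. At
    planted sites the consensus and wild-type residues are realized at
    deterministically rounded counts; the returned ground truth records the
    realized frequencies.

    Returns the alignment (query id ``"query"``) and the realized planted
    sites.
    """
    n, length = spec.n_sequences, spec.length
    if n < 2:
        raise ValueError("need at least 2 sequences")
    planted = {s.position: s for s in spec.planted_consensus_sites}
    for site in planted.values():
        if not 1 <= site.position <= length:
            raise ValueError(f"planted position {site.position} outside 1..{length}")
    rng = _rng(spec.seed, "msa")

    aa = np.array(list(AMINO_ACIDS))
    query = rng.choice(aa, size=length)
    for site in planted.values():
        query[site.position - 1] = site.wild_type

    columns = np.empty((n, length), dtype="<U1")
    columns[0] = query  # row 0 is the query
    realized: list[PlantedSite] = []
    for j in range(length):
        pos = j + 1
        site = planted.get(pos)
        if site is None:
            # background: query residue dominant, rest random non-query
            others = aa[aa != query[j]]
            draw = rng.random(n - 1)
            col = np.where(
                draw < 0.7, query[j], rng.choice(others, size=n - 1)
            )
            columns[1:, j] = col
        else:
            n_cons = _round_half_up(site.consensus_freq * n)
            n_wt = max(1, _round_half_up(site.wild_type_freq * n))  # query included
            n_other = n - n_cons - n_wt
            if n_other < 0:
                raise ValueError(f"planted frequencies at {pos} exceed n_sequences")
            others = aa[(aa != site.consensus) & (aa != site.wild_type)]
            fill = np.concatenate(
                [
                    np.repeat(site.consensus, n_cons),
                    np.repeat(site.wild_type, n_wt - 1),
                    rng.choice(others, size=n_other),
                ]
            )
            rng.shuffle(fill)
            columns[1:, j] = fill
            realized.append(
                PlantedSite(
                    position=pos,
                    wild_type=site.wild_type,
                    consensus=site.consensus,
                    consensus_freq=n_cons / n,
                    wild_type_freq=n_wt / n,
                )
            )
    records = [("query", "".join(columns[0]))]
    records += [(f"hom{i:03d}", "".join(columns[i])) for i in range(1, n)]
    return Alignment(records=records, query_id="query"), realized


# ---------------------------------------------------------------------------
# ΔΔG generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDdg:
    """Generated ΔΔG tables plus the ground truth behind them."""

    singles: dict[str, list[DdgRecord]]  # tool -> records
    doubles: list[tuple[frozenset, str, float]]  # (pair, structure_id, ddg)
    true_singles: dict[Mutation, float]
    true_doubles: dict[frozenset, float]
    antagonistic_pairs: set[frozenset]

    def double_means(self) -> dict[frozenset, float]:
        """Observed double-mutant ΔΔG averaged over structures, per pair."""
        acc: dict[frozenset, list[float]] = {}
        for pair, _, ddg in self.doubles:
            acc.setdefault(pair, []).append(ddg)
        return {pair: float(np.mean(v)) for pair, v in acc.items()}


def generate_ddg(
    spec: SyntheticSpec,
    mutations: Sequence[Mutation],
    pairs: Iterable[tuple[Mutation, Mutation]] = (),
    tools: Sequence[str] = ("foldx", "rosetta"),
) -> SyntheticDdg:
    """Generate per-structure single- and double-mutant ΔΔG tables.

    True single values come from a two-component mixture: with probability
    ``spec.stabilizing_fraction`` a stabilizing tail (uniform on
    [−4.5, −2.2]), otherwise a near-neutral bulk (normal, mean 0, sd 0.6).
    Each (tool, structure, replicate) observation adds Gaussian noise of sd
    ``spec.ddg_noise_sd``. A double mutant's true value is the sum of its
    singles plus the planted epistasis offset (zero for unplanted pairs);
    a planted pair referencing an unknown mutation is an error.
    """
    rng = _rng(spec.seed, "ddg")
    mutations = list(mutations)
    known = set(mutations)
    planted = {}
    for p in spec.planted_antagonistic_pairs:
        if p.mutation_a not in known or p.mutation_b not in known:
            raise ValueError(
                f"planted pair ({p.mutation_a}, {p.mutation_b}) references "
                "a mutation outside the universe"
            )
        planted[frozenset((p.mutation_a, p.mutation_b))] = p.epistasis_offset

    true_singles: dict[Mutation, float] = {}
    for mut in mutations:
        if rng.random() < spec.stabilizing_fraction:
            true_singles[mut] = float(rng.uniform(-4.5, -2.2))
        else:
            true_singles[mut] = float(rng.normal(0.0, 0.6))

    def observe(tool: str, mut_label, truth: float) -> list[DdgRecord]:
        recs = []
        for sid in spec.structure_ids:
            for rep in range(1, spec.n_replicates + 1):
                noise = rng.normal(0.0, spec.ddg_noise_sd) if spec.ddg_noise_sd else 0.0
                recs.append(
                    DdgRecord(
                        mutation=mut_label, structure_id=sid, tool=tool,
                        ddg=truth + float(noise), replicate=rep,
                    )
                )
        return recs

    singles: dict[str, list[DdgRecord]] = {t: [] for t in tools}
    for tool in tools:
        for mut in mutations:
            singles[tool].extend(observe(tool, mut, true_singles[mut]))

    true_doubles: dict[frozenset, float] = {}
    antagonistic: set[frozenset] = set()
    doubles: list[tuple[frozenset, str, float]] = []
    for a, b in pairs:
        key = frozenset((a, b))
        truth = true_singles[a] + true_singles[b] + planted.get(key, 0.0)
        true_doubles[key] = truth
        if truth > -3.0:
            antagonistic.add(key)
        for sid in spec.structure_ids:
            noise = rng.normal(0.0, spec.ddg_noise_sd) if spec.ddg_noise_sd else 0.0
            doubles.append((key, sid, truth + float(noise)))
    return SyntheticDdg(
        singles=singles,
        doubles=doubles,
        true_singles=true_singles,
        true_doubles=true_doubles,
        antagonistic_pairs=antagonistic,
    )


# ---------------------------------------------------------------------------
# Structure generator
# ---------------------------------------------------------------------------

_PDB_ATOM = (
    "ATOM  {serial:>5d} {name:<4s}{resname:>4s} {chain}{resnum:>4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}\n"
)


def _atom_line(serial, name, resname, chain, resnum, xyz, element) -> str:
    pdb_name = f" {name}" if len(name) < 4 else name
    return _PDB_ATOM.format(
        serial=serial, name=pdb_name, resname=resname, chain=chain,
        resnum=resnum, x=xyz[0], y=xyz[1], z=xyz[2], occ=1.0, b=0.0,
        element=element,
    )


def generate_structure(
    bridges: Sequence[BridgeSpec], chain: str = "A", structure_id: str = "synthetic"
) -> str:
    """Emit PDB text realizing the requested salt bridges exactly.

    Each bridge becomes an Asp residue and a Lys residue whose OD1 and NZ
    atoms sit exactly ``distance`` Å apart along x; successive bridge pairs
    are offset 50 Å along z so they cannot interact with each other. Both
    residues get a CA and minimal side-chain atoms, giving valid ATOM
    records that any PDB reader accepts.
    """
    if not bridges:
        raise ValueError("no bridges requested")
    lines = []
    serial = 1
    for k, spec in enumerate(bridges):
        z = 50.0 * k
        # Asp: CA, CB, CG, OD1, OD2 — OD1 at origin of this pair frame
        asp = {
            "CA": (-2.4, 0.8, z), "CB": (-1.6, 0.6, z), "CG": (-0.8, 0.3, z),
            "OD1": (0.0, 0.0, z), "OD2": (-1.0, -0.9, z),
        }
        for name, xyz in asp.items():
            lines.append(
                _atom_line(serial, name, "ASP", chain, spec.acidic_residue, xyz,
                           "O" if name.startswith("O") else "C")
            )
            serial += 1
        d = spec.distance
        lys = {
            "CA": (d + 2.4, 0.8, z), "CB": (d + 1.8, 0.5, z),
            "CG": (d + 1.4, 0.4, z), "CD": (d + 1.0, 0.3, z),
            "CE": (d + 0.6, 0.2, z), "NZ": (d, 0.0, z),
        }
        for name, xyz in lys.items():
            lines.append(
                _atom_line(serial, name, "LYS", chain, spec.basic_residue, xyz,
                           "N" if name == "NZ" else "C")
            )
            serial += 1
    lines.append("END\n")
    return "".join(lines)
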