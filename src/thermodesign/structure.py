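"""Structure-based exclusion filters for candidate mutations.

Candidate substitutions whose wild-type side chain takes part in a salt
bridge (or, optionally, a hydrophobic or aromatic contact) are discarded:
disrupting such an interaction tends to destabilize regardless of the
predicted ΔΔG of the isolated substitution. Interactions are detected per
structure (and per chain for oligomers), then unioned — an interaction
present in at least one analyzed structure or chain is considered
important.

The salt-bridge criterion is geometric: any Asp/Glu side-chain carboxyl
oxygen within 4.0 Å (inclusive) of an Arg/Lys/His side-chain nitrogen.
His is counted as positively charged. Atom sets and the cutoff are
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .energetics import Mutation

logger = logging.getLogger(__name__)

#: acidic side-chain oxygens and basic side-chain nitrogens (heavy atoms)
ACIDIC_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
BASIC_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NH1", "NH2", "NE"),
    "HIS": ("ND1", "NE2"),
}

#: aliphatic carbons used by the optional hydrophobic-contact stand-in
_ALIPHATIC = {
    "ALA": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "MET": ("CB", "CG", "CE"),
    "PRO": ("CB", "CG", "CD"),
}
_AROMATIC_RING = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


@dataclass(frozen=True)
class Atom:
    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    coords: tuple[float, float, float]


@dataclass
class StructureModel:
    """Protein atoms of one structure (first model, waters/ligands removed)."""

    structure_id: str
    atoms: list[Atom]

    def residues(self) -> dict[tuple[str, int], str]:
        """Map (chain, residue_number) -> residue_name."""
        return {(a.chain, a.residue_number): a.residue_name for a in self.atoms}

    @property
    def chains(self) -> list[str]:
        return sorted({a.chain for a in self.atoms})


@dataclass(frozen=True)
class InteractionRecord:
    """One detected side-chain interaction between two residues."""

    kind: str  # salt_bridge | hydrophobic | aromatic
    residues: frozenset  # of (chain, residue_number)
    min_distance: float
    structure_id: str

    def __post_init__(self) -> None:
        if len(self.residues) != 2:
            raise ValueError("interaction needs two distinct residues")
        if self.min_distance <= 0:
            raise ValueError("min_distance must be positive")


@dataclass
class InteractionSet:
    """Union of interactions across structures, deduplicated by kind + pair."""

    records: list[InteractionRecord]
    provenance: dict = field(default_factory=dict)  # (kind, pair) -> [structure_id]

    def positions(self) -> set[int]:
        """All residue numbers participating in any interaction."""
        return {
            resnum for rec in self.records for (_, resnum) in rec.residues
        }

    def kinds_at(self, position: int) -> set[str]:
        return {
            rec.kind
            for rec in self.records
            if any(resnum == position for (_, resnum) in rec.residues)
        }


# ---------------------------------------------------------------------------
# Reading structures
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, structure_id: str | None = None) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Only the first model is used; waters and hetero compounds (ligands,
    ions) are excluded; where alternate locations exist, the
    highest-occupancy conformer of each atom is kept.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as e:
        raise ValueError(f"cannot parse PDB file {path}: {e}") from e
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    st.setup_entities()
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            if residue.is_water():
                continue
            info = gemmi.find_tabulated_residue(residue.name)
            if info is None or not info.is_amino_acid():
                continue
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for name, atom in best.items():
                pos = atom.pos
                if not all(np.isfinite([pos.x, pos.y, pos.z])):
                    raise ValueError(f"non-finite coordinates in {path}")
                atoms.append(
                    Atom(
                        chain=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=name,
                        coords=(pos.x, pos.y, pos.z),
                    )
                )
    if not atoms:
        raise ValueError(f"no protein atoms in {path}")
    return StructureModel(structure_id=structure_id or path.stem, atoms=atoms)


# ---------------------------------------------------------------------------
# Interaction detection
# ---------------------------------------------------------------------------

def _group_atoms(
    s: StructureModel, spec: Mapping[str, tuple[str, ...]]
) -> dict[tuple[str, int], list[tuple[float, float, float]]]:
    out: dict[tuple[str, int], list] = {}
    for a in s.atoms:
        if a.atom_name in spec.get(a.residue_name, ()):
            out.setdefault((a.chain, a.residue_number), []).append(a.coords)
    return out


def _pairwise_min(
    groups_a: Mapping, groups_b: Mapping, cutoff: float, same_chain_only: bool
) -> dict[frozenset, float]:
    found: dict[frozenset, float] = {}
    for ra, coords_a in groups_a.items():
        xa = np.asarray(coords_a)
        for rb, coords_b in groups_b.items():
            if ra == rb:
                continue
            if same_chain_only and ra[0] != rb[0]:
                continue
            d = float(cdist(xa, np.asarray(coords_b)).min())
            if d <= cutoff:
                key = frozenset((ra, rb))
                if key not in found or d < found[key]:
                    found[key] = d
    return found


def find_salt_bridges(
    s: StructureModel,
    cutoff: float = 4.0,
    include_his: bool = True,
    intra_chain_only: bool = True,
) -> list[InteractionRecord]:
    """Detect salt bridges by the charged-heavy-atom distance criterion.

    Every Asp/Glu carboxyl oxygen within ``cutoff`` Å (inclusive) of a
    Lys/Arg/His side-chain nitrogen defines a bridge; the minimum distance
    over the atom pairs of the two residues is reported. Intra-chain pairs
    only by default (inter-chain contacts can be enabled for interface
    analysis).
    """
    if len(s.residues()) < 2:
        raise ValueError("structure must contain at least 2 residues")
    basic = dict(BASIC_ATOMS)
    if not include_his:
        basic.pop("HIS")
    acidic_groups = _group_atoms(s, ACIDIC_ATOMS)
    basic_groups = _group_atoms(s, basic)
    found = _pairwise_min(acidic_groups, basic_groups, cutoff, intra_chain_only)
    return [
        InteractionRecord("salt_bridge", pair, d, s.structure_id)
        for pair, d in sorted(found.items(), key=lambda kv: sorted(kv[0]))
    ]


def find_hydrophobic_contacts(
    s: StructureModel, cutoff: float = 5.0, intra_chain_only: bool = True
) -> list[InteractionRecord]:
    """Aliphatic-carbon contacts below ``cutoff`` Å (optional stand-in filter)."""
    groups = _group_atoms(s, _ALIPHATIC)
    found = _pairwise_min(groups, groups, cutoff, intra_chain_only)
    return [
        InteractionRecord("hydrophobic", pair, d, s.structure_id)
        for pair, d in sorted(found.items(), key=lambda kv: sorted(kv[0]))
    ]


def find_aromatic_contacts(
    s: StructureModel,
    min_dist: float = 4.5,
    max_dist: float = 7.0,
    intra_chain_only: bool = True,
) -> list[InteractionRecord]:
    """Aromatic ring-centroid pairs within [min_dist, max_dist] Å (optional)."""
    centroids: dict[tuple[str, int], list] = {}
    for (key, coords) in _group_atoms(s, _AROMATIC_RING).items():
        centroids[key] = [tuple(np.mean(np.asarray(coords), axis=0))]
    found = _pairwise_min(centroids, centroids, max_dist, intra_chain_only)
    return [
        InteractionRecord("aromatic", pair, d, s.structure_id)
        for pair, d in sorted(found.items(), key=lambda kv: sorted(kv[0]))
        if d >= min_dist
    ]


def union_interactions(
    per_structure: Iterable[Sequence[InteractionRecord]],
) -> InteractionSet:
    """Union interactions across structures/chains, dedup by kind + pair.

    A pair is retained when present in at least one analyzed structure or
    chain; provenance lists every contributing structure. The deduplicated
    record keeps the smallest observed distance.
    """
    per_structure = list(per_structure)
    if not per_structure:
        raise ValueError("no structures analyzed")
    merged: dict[tuple, InteractionRecord] = {}
    provenance: dict[tuple, list[str]] = {}
    for records in per_structure:
        for rec in records:
            key = (rec.kind, rec.residues)
            provenance.setdefault(key, []).append(rec.structure_id)
            if key not in merged or rec.min_distance < merged[key].min_distance:
                merged[key] = rec
    return InteractionSet(
        records=[merged[k] for k in sorted(merged, key=lambda k: (k[0], sorted(k[1])))],
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Candidate filtering
# ---------------------------------------------------------------------------

_POSITIVE = set("RKH")
_NEGATIVE = set("DE")


def _charge_class(aa: str) -> str:
    if aa in _POSITIVE:
        return "+"
    if aa in _NEGATIVE:
        return "-"
    return "0"


def filter_interacting(
    candidates: Sequence[Mutation],
    interactions: InteractionSet,
    charge_preserving_exempt: bool = False,
    position_map: Mapping[int, int] | None = None,
    structure_positions: set[int] | None = None,
) -> tuple[list[Mutation], list[tuple[Mutation, str]]]:
    """Discard candidates whose wild-type side chain is in an interaction.

    Sequence positions map to structure residue numbers through
    ``position_map`` (identity when omitted). With ``structure_positions``
    supplied, a candidate whose mapped position is absent from the
    structure raises an error naming it. ``charge_preserving_exempt``
    keeps a salt-bridge candidate whose substitution preserves the
    wild type's charge class (the bridge survives the mutation).

    Returns ``(kept, discarded)`` with machine-readable reasons; the two
    lists partition the input.
    """
    kept: list[Mutation] = []
    discarded: list[tuple[Mutation, str]] = []
    for mut in candidates:
        if position_map is not None and mut.position not in position_map:
            raise KeyError(f"position {mut.position} not resolvable to a structure residue")
        struct_pos = (
            position_map[mut.position] if position_map is not None else mut.position
        )
        if structure_positions is not None and struct_pos not in structure_positions:
            raise KeyError(
                f"position {mut.position} (structure residue {struct_pos}) "
                "not present in structure"
            )
        kinds = interactions.kinds_at(struct_pos)
        if kinds and charge_preserving_exempt and kinds == {"salt_bridge"}:
            if _charge_class(mut.substitution) == _charge_class(mut.wild_type):
                kept.append(mut)
                continue
        if kinds:
            discarded.append((mut, sorted(kinds)[0]))
        else:
            kept.append(mut)
    return kept, discarded


def write_interactions_tsv(interactions: InteractionSet, path: str | Path) -> None:
    rows = []
    for rec in interactions.records:
        (ca, ra), (cb, rb) = sorted(rec.residues)
        prov = interactions.provenance.get((rec.kind, rec.residues), [rec.structure_id])
        rows.append(
            {
                "kind": rec.kind,
                "chainA": ca,
                "resA": ra,
                "chainB": cb,
                "resB": rb,
                "min_distance": rec.min_distance,
                "structures": ",".join(prov),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_filter_report_tsv(
    kept: Sequence[Mutation],
    discarded: Sequence[tuple[Mutation, str]],
    path: str | Path,
) -> None:
    rows = [{"mutation": str(m), "decision": "kept", "reason": ""} for m in kept]
    rows += [
        {"mutation": str(m), "decision": "discarded", "reason": r} for m, r in discarded
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
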