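"""Contact and adjacency preprocessing.

Turns the selected chain of a parsed structure into the three relations the
pattern engine queries:

* residue--residue contacts (``distance_amino_amino``): for every unordered
  residue pair whose minimum inter-atomic distance is within the cutoff
  (7.0 A by default -- beyond that no interaction is assumed), one canonical
  record with ``amino1_number < amino2_number``;
* ligand--residue contacts (``distance_ligand_amino``), same rule over
  (het group, residue) pairs;
* sequence adjacency (``next_amino_amino``): one record per consecutive
  residue pair.

Records carry denormalized provenance: protein id, element ids
(``<pdb>_<chain>_<number>``), residue symbols, polarity classes and
processed sequence numbers.  Adjacency and gap semantics are defined on
the processed ``seq_index`` (1..n per chain), not on author numbering.
"""

from __future__ import annotations

import csv
from dataclasses import astuple, dataclass, fields
from typing import IO, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .amino import polarity_of
from .pdbio import Atom, ChainModel, HetGroup, Residue

DEFAULT_CUTOFF = 7.0


@dataclass
class PreprocessConfig:
    """Preprocessing knobs; ``cutoff`` is the interaction cutoff in angstroms."""

    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self):
        if not self.cutoff > 0:
            raise ValueError(f"cutoff must be > 0, got {self.cutoff}")


@dataclass(frozen=True)
class AminoDistanceRecord:
    protein_id: str
    amino1_id: str
    amino1_symbol: str
    amino1_class: str
    amino1_number: int
    amino2_id: str
    amino2_symbol: str
    amino2_class: str
    amino2_number: int
    dist: float


@dataclass(frozen=True)
class LigandDistanceRecord:
    protein_id: str
    ligand_id: str
    ligand_symbol: str
    ligand_number: int
    amino_id: str
    amino_symbol: str
    amino_class: str
    amino_number: int
    dist: float


@dataclass(frozen=True)
class NextRecord:
    protein_id: str
    amino1_id: str
    amino1_symbol: str
    amino1_class: str
    amino1_number: int
    amino2_id: str
    amino2_symbol: str
    amino2_class: str
    amino2_number: int


def make_ids(pdb_id: str, chain_id: str, entity_number, atom_number=None) -> str:
    """Provenance identifier: underscore-joined components.

    ``make_ids("1B38", "A", 1, 4)`` is the id of atom 4 of amino acid 1 of
    chain A of protein 1B38; omitting the atom component yields the amino
    acid's own id.
    """
    parts = [str(pdb_id), str(chain_id), str(entity_number)]
    if atom_number is not None:
        parts.append(str(atom_number))
    if any(not p for p in parts):
        raise ValueError("id components must be non-empty")
    return "_".join(parts)


def _coords(atoms: Sequence[Atom]) -> np.ndarray:
    if not atoms:
        raise ValueError("atom list must be non-empty")
    return np.array([[a.x, a.y, a.z] for a in atoms], dtype=float)


def residue_min_distance(a: Sequence[Atom], b: Sequence[Atom]) -> float:
    """Minimum Euclidean distance over all cross pairs of atoms."""
    return float(cdist(_coords(a), _coords(b)).min())


def _amino_fields(protein_id: str, chain: ChainModel, r: Residue, prefix: str) -> dict:
    return {
        f"{prefix}_id": make_ids(protein_id, chain.chain_id, r.seq_index),
        f"{prefix}_symbol": r.symbol,
        f"{prefix}_class": polarity_of(r.symbol),
        f"{prefix}_number": r.seq_index,
    }


def compute_amino_distances(chain: ChainModel, cfg: PreprocessConfig = PreprocessConfig(),
                            *, protein_id: str) -> list[AminoDistanceRecord]:
    """Residue-pair contact records within the cutoff, canonically ordered
    (``amino1_number < amino2_number``); symmetric storage happens at load
    time, not here."""
    out: list[AminoDistanceRecord] = []
    res = chain.residues
    coords = [_coords(r.atoms) for r in res]
    for i in range(len(res)):
        for j in range(i + 1, len(res)):
            d = float(cdist(coords[i], coords[j]).min())
            if d <= cfg.cutoff:
                out.append(AminoDistanceRecord(
                    protein_id=protein_id,
                    **_amino_fields(protein_id, chain, res[i], "amino1"),
                    **_amino_fields(protein_id, chain, res[j], "amino2"),
                    dist=d))
    return out


def compute_ligand_distances(chain: ChainModel, cfg: PreprocessConfig = PreprocessConfig(),
                             *, protein_id: str) -> list[LigandDistanceRecord]:
    """Het-group/residue contact records within the cutoff."""
    out: list[LigandDistanceRecord] = []
    res_coords = [_coords(r.atoms) for r in chain.residues]
    for h in chain.hetgroups:
        hc = _coords(h.atoms)
        for r, rc in zip(chain.residues, res_coords):
            d = float(cdist(hc, rc).min())
            if d <= cfg.cutoff:
                out.append(LigandDistanceRecord(
                    protein_id=protein_id,
                    ligand_id=make_ids(protein_id, chain.chain_id, h.author_number),
                    ligand_symbol=h.code,
                    ligand_number=h.author_number,
                    **_amino_fields(protein_id, chain, r, "amino"),
                    dist=d))
    return out


def compute_next(chain: ChainModel, *, protein_id: str) -> list[NextRecord]:
    """Adjacency records: one per consecutive residue pair (n-1 records)."""
    out = []
    for r1, r2 in zip(chain.residues, chain.residues[1:]):
        out.append(NextRecord(
            protein_id=protein_id,
            **_amino_fields(protein_id, chain, r1, "amino1"),
            **_amino_fields(protein_id, chain, r2, "amino2")))
    return out


@dataclass
class ChainRelations:
    """All preprocessing outputs for one protein's selected chain."""

    protein_id: str
    chain: ChainModel
    amino_distances: list[AminoDistanceRecord]
    ligand_distances: list[LigandDistanceRecord]
    next_records: list[NextRecord]


def preprocess_chain(chain: ChainModel, cfg: PreprocessConfig = PreprocessConfig(),
                     *, protein_id: str) -> ChainRelations:
    return ChainRelations(
        protein_id=protein_id,
        chain=chain,
        amino_distances=compute_amino_distances(chain, cfg, protein_id=protein_id),
        ligand_distances=compute_ligand_distances(chain, cfg, protein_id=protein_id),
        next_records=compute_next(chain, protein_id=protein_id),
    )


def write_records_csv(records: Sequence, out: IO[str]) -> None:
    """Write one relation's records as CSV with the denormalized column
    names as the header row."""
    if not records:
        return
    cols = [f.name for f in fields(records[0])]
    w = csv.writer(out)
    w.writerow(cols)
    for r in records:
        w.writerow(astuple(r))
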