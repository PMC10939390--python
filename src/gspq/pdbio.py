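"""Reading textual PDB files into a lightweight structure model.

Parsing itself is delegated to :mod:`gemmi`; this module reduces gemmi's
rich structure to the flat model the contact pipeline needs: one protein,
its chains, each chain's residues in file order plus its non-water het
groups.  Policy applied while reducing:

* first MODEL only;
* alternate locations: blank or ``A`` only;
* water (HOH/WAT/DOD) is never a het group;
* nucleotide residues are dropped from the residue list (nucleic-acid
  content is not part of the contact relations);
* ATOM-record residues whose code is outside the 21-entry standard table
  are kept with symbol ``UND``;
* HETATM groups become het groups (candidate ligands).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi

from .amino import STANDARD_CODES

WATER_CODES = frozenset({"HOH", "WAT", "DOD"})
NUCLEOTIDE_CODES = frozenset(
    {"A", "C", "G", "U", "I", "T", "N",
     "DA", "DC", "DG", "DT", "DU", "DI", "DN"})


class PdbError(ValueError):
    pass


class PdbParseError(PdbError):
    """Malformed PDB record (message cites the offending line)."""


class EmptyStructureError(PdbError):
    """The document contains no usable ATOM/HETATM content."""


@dataclass
class Atom:
    serial: int
    atom_name: str
    x: float
    y: float
    z: float


@dataclass
class Residue:
    seq_index: int  # 1-based position in the processed chain
    author_number: int
    symbol: str  # three-letter code, UND if non-standard
    atoms: list[Atom] = field(default_factory=list)


@dataclass
class HetGroup:
    code: str
    author_number: int
    atoms: list[Atom] = field(default_factory=list)


@dataclass
class ChainModel:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    hetgroups: list[HetGroup] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.residues) + len(self.hetgroups)


@dataclass
class StructureModel:
    pdb_id: str
    chains: list[ChainModel] = field(default_factory=list)

    def chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)


def _keep_atom(atom: gemmi.Atom) -> bool:
    return atom.altloc in ("\0", "", "A")


def _to_atoms(res: gemmi.Residue, where: str) -> list[Atom]:
    out = []
    for a in res:
        if not _keep_atom(a):
            continue
        if not all(math.isfinite(v) for v in (a.pos.x, a.pos.y, a.pos.z)):
            raise PdbParseError(f"non-finite coordinate in {where}")
        out.append(Atom(a.serial, a.name, a.pos.x, a.pos.y, a.pos.z))
    return out


def parse_pdb(text: str) -> StructureModel:
    """Parse a PDB-format document into a :class:`StructureModel`.

    Residues are grouped by (chain, author number, insertion code) in file
    order and assigned consecutive ``seq_index`` values starting at 1.
    Raises :class:`EmptyStructureError` when no atoms survive the policy,
    :class:`PdbParseError` for malformed records.
    """
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as e:
        raise PdbParseError(str(e)) from None
    raw_id = st.info["_entry.id"] if "_entry.id" in st.info else ""
    pdb_id = raw_id.strip().upper() or "XXXX"

    chains: list[ChainModel] = []
    n_atoms = 0
    for model in st:  # first model only
        for ch in model:
            cm = ChainModel(chain_id=ch.name or " ")
            for res in ch:
                name = res.name.strip().upper()
                if name in WATER_CODES or name in NUCLEOTIDE_CODES:
                    continue
                where = f"{ch.name}/{name} {res.seqid.num}"
                atoms = _to_atoms(res, where)
                if not atoms:
                    continue
                n_atoms += len(atoms)
                if res.het_flag == "H":
                    cm.hetgroups.append(HetGroup(name, res.seqid.num, atoms))
                else:
                    symbol = name if name in STANDARD_CODES else "UND"
                    cm.residues.append(
                        Residue(len(cm.residues) + 1, res.seqid.num, symbol, atoms))
            if cm.residues or cm.hetgroups:
                chains.append(cm)
        break
    if not chains or n_atoms == 0:
        raise EmptyStructureError("document contains no usable ATOM/HETATM records")
    return StructureModel(pdb_id=pdb_id, chains=chains)


def select_primary_chain(s: StructureModel) -> ChainModel:
    """The single chain that is processed: the one holding the most
    information (residue count + het-group count), ties broken by the
    lexicographically smallest chain id."""
    if not s.chains:
        raise EmptyStructureError(f"structure {s.pdb_id} has no chains")
    return min(s.chains, key=lambda c: (-c.size, c.chain_id))
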