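"""Typed structural data model plus PDB/FASTA input and output.

The central container is :class:`Assembly` — an ordered list of chains of
residues of heavy atoms — used uniformly for templates, models and
references. Parsing and serialisation of PDB files is delegated to
``gemmi``; this module enforces the package's own conventions on top:

* only ATOM records of one model are kept (HETATM, waters, hydrogens and
  non-winning altlocs are dropped);
* residues are renumbered 1..N per chain, the author numbering being
  retained in a provenance map;
* the oligomeric state (monomer / homo-oligomer / hetero-oligomer) is
  derived from the chain sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from Bio import SeqIO

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Assembly",
    "StructureFormatError",
    "EmptyStructureError",
    "read_structure",
    "write_structure",
    "read_fasta",
    "write_fasta",
    "three_to_one",
    "one_to_three",
]


class StructureFormatError(ValueError):
    """Raised for unparseable or invalid structure/sequence files."""


class EmptyStructureError(ValueError):
    """Raised when a file yields no protein atoms."""


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "UNK": "X",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}

AMINO_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


def three_to_one(name: str) -> str:
    return _THREE_TO_ONE.get(name.upper(), "X")


def one_to_three(letter: str) -> str:
    return _ONE_TO_THREE.get(letter.upper(), "UNK")


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")


@dataclass
class Residue:
    number: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_backbone(self) -> bool:
        return all(self.atom(n) is not None for n in ("N", "CA", "C"))

    def validate(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValueError(f"residue {self.number} {self.name}: duplicate atom names")
        n, ca, c = self.atom("N"), self.atom("CA"), self.atom("C")
        if n is not None and ca is not None and c is not None:
            for other in (n, c):
                d = float(np.linalg.norm(ca.coord - other.coord))
                if not (0.5 < d < 3.0):
                    raise ValueError(
                        f"residue {self.number} {self.name}: backbone bond {d:.2f} Å outside (0.5, 3.0)"
                    )


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(three_to_one(r.name) for r in self.residues)

    def validate(self) -> None:
        if len(self.id) != 1:
            raise ValueError(f"chain id {self.id!r} must be a single character")
        numbers = [r.number for r in self.residues]
        if any(b <= a for a, b in zip(numbers, numbers[1:])):
            raise ValueError(f"chain {self.id}: residue numbers not strictly increasing")
        for r in self.residues:
            r.validate()


@dataclass
class Assembly:
    id: str
    chains: list[Chain] = field(default_factory=list)
    provenance: str = ""
    # (chain id, normalized number) -> original author numbering string
    author_numbering: dict[tuple[str, int], str] = field(default_factory=dict)

    @property
    def oligo_state(self) -> str:
        if len(self.chains) == 1:
            return "monomer"
        seqs = {c.sequence for c in self.chains}
        return "homo-oligomer" if len(seqs) == 1 else "hetero-oligomer"

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in assembly {self.id}")

    def validate(self) -> None:
        if not self.chains:
            raise ValueError("assembly must contain at least one chain")
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("chain ids must be unique")
        for c in self.chains:
            c.validate()

    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coord for c in self.chains for r in c.residues for a in r.atoms]
        return np.array(coords) if coords else np.empty((0, 3))

    def copy(self) -> "Assembly":
        return Assembly(
            id=self.id,
            chains=[
                Chain(
                    id=c.id,
                    residues=[
                        Residue(
                            number=r.number,
                            name=r.name,
                            insertion_code=r.insertion_code,
                            atoms=[
                                Atom(a.name, a.element, a.coord.copy(), a.occupancy, a.bfactor)
                                for a in r.atoms
                            ],
                        )
                        for r in c.residues
                    ],
                )
                for c in self.chains
            ],
            provenance=self.provenance,
            author_numbering=dict(self.author_numbering),
        )


def _element_of(atom: gemmi.Atom) -> str:
    el = atom.element.name.strip()
    if el:
        return el.upper()
    return atom.name.strip()[0].upper()


def read_structure(path: str, model_index: int = 1) -> Assembly:
    """Load the ATOM records of one model of a PDB file into an Assembly.

    HETATM records, waters, hydrogens and losing altlocs (ties resolved to
    the first in file) are dropped. Residues are renumbered 1..N per chain;
    the author numbering is kept in ``Assembly.author_numbering``.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models found")
    if model_index < 1 or model_index > len(st):
        raise StructureFormatError(
            f"{path}: model index {model_index} not in 1..{len(st)}"
        )
    model = st[model_index - 1]
    assembly = Assembly(id=st.name or "structure", provenance=f"read from {path}")
    for ch in model:
        chain = Chain(id=(ch.name or " ")[0])
        for res in ch:
            if res.het_flag != "A":  # ATOM records only
                continue
            name = res.name.upper()
            if name == "HOH":
                continue
            residue = Residue(
                number=len(chain.residues) + 1,
                name=name if name in _THREE_TO_ONE else "UNK",
                insertion_code=(res.seqid.icode or "").strip(),
            )
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                if at.element.is_hydrogen:
                    continue
                aname = at.name.strip()
                prev = best.get(aname)
                if prev is None or at.occ > prev.occ:
                    best[aname] = at
            for aname, at in best.items():
                residue.atoms.append(
                    Atom(
                        name=aname,
                        element=_element_of(at),
                        coord=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=float(at.occ),
                        bfactor=float(at.b_iso),
                    )
                )
            if residue.atoms:
                chain.residues.append(residue)
                assembly.author_numbering[(chain.id, residue.number)] = (
                    f"{res.seqid.num}{res.seqid.icode}".strip()
                )
        if chain.residues:
            assembly.chains.append(chain)
    if not assembly.chains:
        raise EmptyStructureError(f"{path}: no protein ATOM records")
    assembly.validate()
    return assembly


def write_structure(assembly: Assembly, path: str) -> None:
    """Write an Assembly as a PDB file (coordinates at 3 decimals).

    The bfactor field is written as stored, so per-residue quality scores
    injected there survive the round trip.
    """
    assembly.validate()
    st = gemmi.Structure()
    st.name = assembly.id
    model = gemmi.Model("1")
    for chain in assembly.chains:
        gch = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            gres.het_flag = "A"
            for atom in res.atoms:
                gat = gemmi.Atom()
                gat.name = atom.name
                gat.element = gemmi.Element(atom.element)
                gat.pos = gemmi.Position(*[float(x) for x in atom.coord])
                gat.occ = float(atom.occupancy)
                gat.b_iso = float(atom.bfactor)
                gres.add_atom(gat)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def read_fasta(path: str, aligned: bool = False) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence) pairs.

    Ids are taken up to the first whitespace and sequences uppercased.
    In ``aligned`` mode gap characters '-' are preserved and all records
    must have equal length; otherwise gaps are rejected along with any
    other non-amino-acid symbol.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise StructureFormatError(f"{path}: no FASTA records")
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in records:
        rid = rec.id
        if rid in seen:
            raise StructureFormatError(f"{path}: duplicate id {rid!r}")
        seen.add(rid)
        seq = str(rec.seq).upper()
        allowed = AMINO_ALPHABET | ({"-"} if aligned else set())
        bad = set(seq) - allowed
        if bad:
            raise StructureFormatError(
                f"{path}: record {rid!r} has invalid symbols {sorted(bad)}"
            )
        out.append((rid, seq))
    if aligned:
        lengths = {len(s) for _, s in out}
        if len(lengths) > 1:
            raise StructureFormatError(f"{path}: aligned records of unequal length")
    return out


def write_fasta(records: list[tuple[str, str]], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
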