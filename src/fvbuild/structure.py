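"""In-memory Fv structure model and PDB input/output (via gemmi).

Residue identifiers in written PDB files are the Chothia scheme positions
(number + insertion code), the convention used by curated antibody structure
databases; this makes scheme-aligned atom matching a residue-id lookup.
Structures are modeled at backbone + CB resolution (N, CA, C, O, CB).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")
ALL_ATOMS = ("N", "CA", "C", "O", "CB")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass
class Residue:
    position: int
    icode: str
    aa: str                                  # one-letter code
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def key(self) -> tuple[int, str]:
        return (self.position, self.icode)

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)

    def copy(self) -> "Residue":
        return Residue(self.position, self.icode, self.aa,
                       {k: v.copy() for k, v in self.atoms.items()})


@dataclass
class ChainStructure:
    role: str                                # light | heavy
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def index(self) -> dict[tuple[int, str], Residue]:
        return {r.key: r for r in self.residues}

    def coords(self, atom_names=BACKBONE_ATOMS,
               keys: list[tuple[int, str]] | None = None) -> np.ndarray:
        """Stacked coordinates for the given atoms over the given residue keys
        (all residues by default); atoms missing from a residue are skipped."""
        idx = self.index()
        residues = self.residues if keys is None else [idx[k] for k in keys if k in idx]
        rows = [r.atoms[a] for r in residues for a in atom_names if a in r.atoms]
        return np.array(rows, dtype=float).reshape(-1, 3)

    def set_coords(self, coords: np.ndarray, atom_names=ALL_ATOMS) -> None:
        """Inverse of ``coords`` over all residues, in the same atom order."""
        i = 0
        for r in self.residues:
            for a in atom_names:
                if a in r.atoms:
                    r.atoms[a] = coords[i].copy()
                    i += 1
        if i != len(coords):
            raise ValueError("coordinate array does not match chain atom count")

    def atom_count(self, atom_names=ALL_ATOMS) -> int:
        return sum(1 for r in self.residues for a in atom_names if a in r.atoms)

    def copy(self) -> "ChainStructure":
        return ChainStructure(self.role, self.chain_id, [r.copy() for r in self.residues])


@dataclass
class FvStructure:
    light: ChainStructure
    heavy: ChainStructure
    meta: dict = field(default_factory=dict)

    def chains(self) -> list[ChainStructure]:
        return [self.light, self.heavy]

    def chain(self, role: str) -> ChainStructure:
        return self.light if role == "light" else self.heavy

    def copy(self) -> "FvStructure":
        return FvStructure(self.light.copy(), self.heavy.copy(), dict(self.meta))

    def all_coords(self, atom_names=ALL_ATOMS) -> np.ndarray:
        return np.vstack([c.coords(atom_names) for c in self.chains()])

    def set_all_coords(self, coords: np.ndarray, atom_names=ALL_ATOMS) -> None:
        n_l = self.light.atom_count(atom_names)
        self.light.set_coords(coords[:n_l], atom_names)
        self.heavy.set_coords(coords[n_l:], atom_names)

    def transform(self, R: np.ndarray, t: np.ndarray) -> "FvStructure":
        out = self.copy()
        for c in out.chains():
            for r in c.residues:
                for a in r.atoms:
                    r.atoms[a] = R @ r.atoms[a] + t
        return out


# ---------------------------------------------------------------------------
# PDB round-trip

def to_gemmi(fv: FvStructure, name: str = "fv") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    for cs in fv.chains():
        chain = gemmi.Chain(cs.chain_id)
        for res in cs.residues:
            gr = gemmi.Residue()
            gr.name = ONE_TO_THREE[res.aa]
            gr.seqid = gemmi.SeqId(res.position, res.icode if res.icode else " ")
            for aname in ALL_ATOMS:
                if aname not in res.atoms:
                    continue
                at = gemmi.Atom()
                at.name = aname
                at.element = gemmi.Element(aname[0])
                x, y, z = res.atoms[aname]
                at.pos = gemmi.Position(float(x), float(y), float(z))
                at.occ = 1.0
                gr.add_atom(at)
            chain.add_residue(gr)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(fv: FvStructure, path: str, remarks: list[str] | None = None) -> None:
    st = to_gemmi(fv)
    text = st.make_pdb_string()
    if remarks:
        header = "".join(f"REMARK 299 {r}\n" for r in remarks)
        text = header + text
    with open(path, "w") as fh:
        fh.write(text)


def read_pdb_chains(path: str) -> dict[str, list[Residue]]:
    """Read protein chains from a PDB file.

    Altloc handling keeps the highest-occupancy conformer per atom; non-standard
    residues are skipped.  Returned residues keep the file's residue numbers and
    insertion codes.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    out: dict[str, list[Residue]] = {}
    if len(st) == 0:
        return out
    model = st[0]
    for chain in model:
        residues: list[Residue] = []
        for gr in chain:
            if gr.name not in THREE_TO_ONE:
                continue
            atoms: dict[str, np.ndarray] = {}
            occ: dict[str, float] = {}
            for at in gr:
                if at.name not in ALL_ATOMS:
                    continue
                if at.name in atoms and occ[at.name] >= at.occ:
                    continue
                atoms[at.name] = np.array([at.pos.x, at.pos.y, at.pos.z])
                occ[at.name] = at.occ
            icode = gr.seqid.icode.strip()
            residues.append(Residue(gr.seqid.num, icode, THREE_TO_ONE[gr.name], atoms))
        if residues:
            out[chain.name] = residues
    return out
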