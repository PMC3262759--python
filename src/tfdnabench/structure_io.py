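"""Macromolecular structure model and PDB/mmCIF input/output.

Everything downstream (contact counting, buried surface area, RMSD) is
defined on *heavy atoms* of a single model, so reading a structure here
means: keep model 1 only, drop hydrogens and waters, resolve alternate
locations to the highest-occupancy copy, and assign every remaining atom
to exactly one class of a four-way taxonomy (protein backbone / protein
sidechain / nucleotide base / nucleotide backbone, plus ``other`` for
non-polymer leftovers).  The taxonomy is what makes "sidechain-to-base
contact" a well-defined predicate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AtomClass",
    "MolType",
    "ChainType",
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "DuplexInfo",
    "classify_atom",
    "extract_sequence",
    "read_structure",
    "detect_duplex",
    "write_structure",
    "write_case_files",
]


class AtomClass(str, Enum):
    PROTEIN_BACKBONE = "protein_backbone"
    PROTEIN_SIDECHAIN = "protein_sidechain"
    NUCLEOTIDE_BASE = "nucleotide_base"
    NUCLEOTIDE_BACKBONE = "nucleotide_backbone"
    OTHER = "other"


class MolType(str, Enum):
    AMINO_ACID = "amino_acid"
    NUCLEOTIDE = "nucleotide"
    OTHER = "other"


class ChainType(str, Enum):
    PROTEIN = "protein"
    DNA = "dna"
    RNA = "rna"
    HYBRID = "hybrid"
    OTHER = "other"


# --- residue vocabularies -------------------------------------------------

AMINO3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# common modified residues mapped to their standard parent
MODIFIED_PARENT = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
    "KCX": "LYS", "MLY": "LYS", "CME": "CYS", "FME": "MET",
    "5CM": "DC", "5MC": "DC", "6OG": "DG", "8OG": "DG",
    "BRU": "DT", "5IU": "DT", "DI": "DG",
}

DNA_RESIDUES = {"DA", "DC", "DG", "DT", "DI", "DU"}
RNA_RESIDUES = {"A", "C", "G", "U", "I"}
DNA_TO_1 = {"DA": "A", "DC": "C", "DG": "G", "DT": "T", "DU": "U", "DI": "I"}
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

PROTEIN_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
# sugar-phosphate moiety; everything else on a nucleotide belongs to the base
NUCLEOTIDE_BACKBONE_ATOMS = {
    "P", "OP1", "OP2", "OP3",
    "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
}

WATSON_CRICK = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
                ("A", "U"), ("U", "A")}


def _normalize_atom_name(name: str) -> str:
    """Normalize star-dialect sugar names (O3* -> O3') and phosphate oxygens."""
    name = name.strip().replace("*", "'")
    if name in ("O1P", "O2P", "O3P"):
        name = "OP" + name[1]
    return name


def _moltype_of(res_name: str) -> MolType:
    name = MODIFIED_PARENT.get(res_name, res_name)
    if name in AMINO3_TO_1:
        return MolType.AMINO_ACID
    if name in DNA_RESIDUES or name in RNA_RESIDUES:
        return MolType.NUCLEOTIDE
    return MolType.OTHER


def classify_atom(res_name: str, atom_name: str, moltype: MolType) -> AtomClass:
    """Assign the heavy atom of a residue to its taxonomy class.

    Amino acids: N, CA, C, O (and terminal OXT) are backbone, every other
    heavy atom is sidechain — hence glycine never contributes a sidechain
    atom.  Nucleotides: the 12-atom sugar-phosphate set is backbone, all
    remaining heavy atoms belong to the base.  Unknown atom names on a
    standard residue fall back on a prime/P rule with a logged warning.
    """
    name = _normalize_atom_name(atom_name)
    if moltype is MolType.AMINO_ACID:
        return (AtomClass.PROTEIN_BACKBONE if name in PROTEIN_BACKBONE_ATOMS
                else AtomClass.PROTEIN_SIDECHAIN)
    if moltype is MolType.NUCLEOTIDE:
        if name in NUCLEOTIDE_BACKBONE_ATOMS:
            return AtomClass.NUCLEOTIDE_BACKBONE
        if name[0] in "NCOS" and not name.endswith("'"):
            return AtomClass.NUCLEOTIDE_BASE
        logger.warning("unknown atom %s on nucleotide %s; fallback rule used",
                       atom_name, res_name)
        return (AtomClass.NUCLEOTIDE_BACKBONE if "'" in name or name.startswith("P")
                else AtomClass.NUCLEOTIDE_BASE)
    return AtomClass.OTHER


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) float, Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    atom_class: AtomClass = AtomClass.OTHER

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    res_name: str
    moltype: MolType
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.icode)

    def get_atom(self, name: str) -> Atom | None:
        name = _normalize_atom_name(name)
        for a in self.atoms:
            if _normalize_atom_name(a.name) == name:
                return a
        return None

    def atoms_of_class(self, cls: AtomClass) -> list[Atom]:
        return [a for a in self.atoms if a.atom_class is cls]

    def one_letter(self) -> str:
        parent = MODIFIED_PARENT.get(self.res_name, self.res_name)
        if parent in AMINO3_TO_1:
            return AMINO3_TO_1[parent]
        if parent in DNA_TO_1:
            return DNA_TO_1[parent]
        if parent in RNA_RESIDUES:
            return parent
        return "X"


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def chain_type(self) -> ChainType:
        n = len(self.residues)
        if n == 0:
            return ChainType.OTHER
        parents = [MODIFIED_PARENT.get(r.res_name, r.res_name) for r in self.residues]
        n_aa = sum(1 for p in parents if p in AMINO3_TO_1)
        n_dna = sum(1 for p in parents if p in DNA_RESIDUES)
        n_rna = sum(1 for p in parents if p in RNA_RESIDUES)
        # 80% majority rule tolerates a stray modified residue
        if n_aa / n > 0.8:
            return ChainType.PROTEIN
        if n_dna / n > 0.8:
            return ChainType.DNA
        if n_rna / n > 0.8:
            return ChainType.RNA
        if (n_dna + n_rna) / n > 0.8:
            return ChainType.HYBRID
        return ChainType.OTHER

    def atoms(self) -> Iterable[Atom]:
        for r in self.residues:
            yield from r.atoms

    def coords(self) -> np.ndarray:
        pts = [a.coords for a in self.atoms()]
        return np.array(pts) if pts else np.empty((0, 3))


@dataclass
class Structure:
    entry_id: str
    chains: list[Chain] = field(default_factory=list)
    model_index: int = 1
    method: str = "other"       # xray | nmr | other
    resolution: float | None = None

    def get_chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in {self.entry_id}")

    @property
    def protein_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.chain_type is ChainType.PROTEIN]

    @property
    def dna_chains(self) -> list[Chain]:
        return [c for c in self.chains if c.chain_type is ChainType.DNA]


@dataclass
class DuplexInfo:
    strand_ids: tuple[str, str]
    paired_positions: list[tuple[Residue, Residue]]

    @property
    def n_pairs(self) -> int:
        return len(self.paired_positions)


class StructureError(ValueError):
    pass


# --- reading --------------------------------------------------------------

def _method_of(gst: gemmi.Structure) -> str:
    info = dict(gst.info)
    m = (info.get("_exptl.method") or "").upper()
    if "X-RAY" in m:
        return "xray"
    if "NMR" in m:
        return "nmr"
    return "other"


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into the heavy-atom structure model.

    Model 1 only; hydrogens, deuteriums and waters are dropped; for
    alternate locations the highest-occupancy atom wins (ties broken in
    favour of altloc 'A'); HETATM residues are kept only when they map to
    a standard parent residue (e.g. MSE -> MET), otherwise dropped with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    try:
        if fmt == "pdb":
            gst = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            gst = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            gst = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    if len(gst) == 0:
        raise StructureError(f"{path}: no models")

    st = Structure(entry_id=(gst.name or path.stem).lower(),
                   method=_method_of(gst))
    if gst.resolution and gst.resolution > 0:
        st.resolution = float(gst.resolution)

    model = gst[0]
    for gchain in model:
        chain = Chain(chain_id=gchain.name.strip() or gchain.name)
        for gres in gchain:
            res_name = gres.name.strip()
            if res_name in WATER_NAMES:
                continue
            moltype = _moltype_of(res_name)
            if moltype is MolType.OTHER:
                if gres.het_flag == "H":
                    logger.warning("%s: dropping unmapped HETATM residue %s %s%d",
                                   st.entry_id, res_name, gchain.name, gres.seqid.num)
                    continue
                # keep unknown polymer residues so sequences show an 'X'
            residue = Residue(chain_id=chain.chain_id, seq_id=gres.seqid.num,
                              res_name=res_name, moltype=moltype,
                              icode=(gres.seqid.icode or "").strip())
            best: dict[str, Atom] = {}
            for gatom in gres:
                if gatom.is_hydrogen():
                    continue
                name = _normalize_atom_name(gatom.name)
                atom = Atom(
                    name=name,
                    element=gatom.element.name,
                    coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    occupancy=gatom.occ,
                    altloc=(gatom.altloc or "").strip(),
                    atom_class=classify_atom(res_name, name, moltype),
                )
                prev = best.get(name)
                if prev is None or (atom.occupancy, -ord(atom.altloc or "~")) > (
                        prev.occupancy, -ord(prev.altloc or "~")):
                    best[name] = atom
            residue.atoms = list(best.values())
            if residue.atoms:
                chain.residues.append(residue)
        if chain.residues:
            st.chains.append(chain)

    if not any(c.chain_type in (ChainType.PROTEIN, ChainType.DNA, ChainType.RNA)
               for c in st.chains):
        raise StructureError(f"{path}: no polymer chains after standardization")
    return st


def extract_sequence(chain: Chain) -> str:
    """One-letter sequence in coordinate-record order ('X' for unknowns)."""
    return "".join(r.one_letter() for r in chain.residues)


# --- duplex detection -----------------------------------------------------

def _base_letter(res: Residue) -> str:
    return res.one_letter()


def detect_duplex(dna_chains: Sequence[Chain],
                  pairing_cutoff: float = 10.5,
                  min_consecutive: int = 4) -> list[DuplexInfo]:
    """Find double-helical strand pairs among DNA chains.

    Residues on two different strands are Watson-Crick paired when their
    C1' atoms lie within ``pairing_cutoff`` (default 10.5 A) and their
    bases are complementary; mutual-nearest matching keeps the pairing
    one-to-one.  A duplex is reported when at least ``min_consecutive``
    consecutive base pairs exist (antiparallel or parallel register).
    """
    duplexes: list[DuplexInfo] = []
    for i in range(len(dna_chains)):
        for j in range(i + 1, len(dna_chains)):
            a, b = dna_chains[i], dna_chains[j]
            pairs, run = _pair_strands(a, b, pairing_cutoff)
            if run >= min_consecutive:
                duplexes.append(DuplexInfo(
                    strand_ids=(a.chain_id, b.chain_id),
                    paired_positions=[(a.residues[p], b.residues[q])
                                      for p, q in pairs]))
    # self-pairing hairpin duplex within one long strand is out of scope
    return duplexes


def _pair_strands(a: Chain, b: Chain,
                  cutoff: float) -> tuple[list[tuple[int, int]], int]:
    """One-to-one pairing of two strands and its longest consecutive run.

    Candidate pairs need C1' atoms within the cutoff and Watson-Crick
    complementary bases; among candidates the register (diagonal in the
    i,j pair matrix, antiparallel preferred) carrying the longest run of
    consecutive pairs is selected, which keeps each residue in at most
    one pair and is symmetric in strand order.
    """
    ca = [(k, at) for k, at in ((k, r.get_atom("C1'"))
                                for k, r in enumerate(a.residues))
          if at is not None]
    cb = [(k, at) for k, at in ((k, r.get_atom("C1'"))
                                for k, r in enumerate(b.residues))
          if at is not None]
    if not ca or not cb:
        return [], 0
    pa = np.array([at.coords for _, at in ca])
    pb = np.array([at.coords for _, at in cb])
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    candidates = []
    for x, (k, _) in enumerate(ca):
        for y, (m, _) in enumerate(cb):
            if d[x, y] <= cutoff and (
                    (_base_letter(a.residues[k]), _base_letter(b.residues[m]))
                    in WATSON_CRICK):
                candidates.append((k, m, d[x, y]))
    if not candidates:
        return [], 0

    best: tuple[int, float] | None = None   # (-run, mean distance)
    best_pairs: list[tuple[int, int]] = []
    for orientation in ("anti", "para"):
        diagonals: dict[int, list[tuple[int, int, float]]] = {}
        for k, m, dist in candidates:
            key = k + m if orientation == "anti" else k - m
            diagonals.setdefault(key, []).append((k, m, dist))
        for members in diagonals.values():
            members.sort()
            run = best_run = 1
            for (k0, _, _), (k1, _, _) in zip(members, members[1:]):
                run = run + 1 if k1 - k0 == 1 else 1
                best_run = max(best_run, run)
            score = (-best_run, float(np.mean([t[2] for t in members])))
            if best is None or score < best:
                best = score
                best_pairs = [(k, m) for k, m, _ in members]
    return best_pairs, -best[0]


# --- writing --------------------------------------------------------------

def _pdb_atom_line(serial: int, atom: Atom, res: Residue) -> str:
    name = atom.name
    # PDB name column convention: element right-justified in cols 13-14
    if len(name) < 4 and len(atom.element) < 2:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    return (f"ATOM  {serial:5d} {name_field}{'':1s}{res.res_name:>3s} "
            f"{res.chain_id[:1]:1s}{res.seq_id:4d}{res.icode or ' ':1s}   "
            f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
            f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}")


def write_structure(structure: Structure, path: str | Path,
                    chain_ids: Sequence[str] | None = None) -> Path:
    """Write (a subset of) a structure as a standard PDB file."""
    path = Path(path)
    lines = []
    if structure.method == "xray":
        lines.append("EXPDTA    X-RAY DIFFRACTION")
    elif structure.method == "nmr":
        lines.append("EXPDTA    SOLUTION NMR")
    if structure.resolution is not None:
        lines.append(f"REMARK   2 RESOLUTION. {structure.resolution:7.2f} ANGSTROMS.")
    serial = 0
    for chain in structure.chains:
        if chain_ids is not None and chain.chain_id not in chain_ids:
            continue
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                lines.append(_pdb_atom_line(serial, atom, res))
        serial += 1
        lines.append(f"TER   {serial:5d}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_case_files(case, out_dir: str | Path) -> list[Path]:
    """Write one benchmark case: bound TF-DNA unit and, when present, the
    unbound TF structure.  A rigid-only case (no unbound partner) gets a
    ``<id>.rigid_only`` marker file instead of the unbound PDB."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unit = case.bound
    structure = case.bound_structure
    paths = []
    bound_path = out_dir / f"{unit.entry_id}_bound.pdb"
    write_structure(structure, bound_path,
                    chain_ids=list(unit.tf_chain_ids) + list(unit.dna_chain_ids))
    paths.append(bound_path)
    if case.unbound is not None:
        unbound_path = out_dir / f"{unit.entry_id}_unbound.pdb"
        write_structure(case.unbound, unbound_path)
        paths.append(unbound_path)
    else:
        marker = out_dir / f"{unit.entry_id}.rigid_only"
        marker.write_text("no unbound TF structure; rigid benchmark only\n")
        paths.append(marker)
    return paths
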