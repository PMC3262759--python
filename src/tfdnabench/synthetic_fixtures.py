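"""Synthetic protein-DNA complexes with known ground truth.

Every metric in the toolkit (duplex detection, contact counts, NRBC,
BSA, RMSD_c/RMSD_u, difficulty labels) can be exercised on generated toy
complexes: an idealized fiber-model B-DNA duplex (rise 3.38 A, twist 36
deg/step, all standard heavy atoms with correct base/backbone classes)
plus peptides with ideal backbone geometry and simplified single-
conformer sidechains.  ``place_with_contacts`` rigidly docks a peptide
against the duplex so that *exactly* k residues have a sidechain heavy
atom within 4.5 A of a base heavy atom — verified by a built-in
brute-force audit, never assumed.  ``perturb_unbound`` manufactures an
"unbound" copy with known per-chain rigid motions, optional chain
relabeling and optional coordinate noise, returning the exact transforms
so superposition results can be checked against ground truth.

The geometry is deliberately schematic (single sugar pucker, no
sequence-dependent shape, idealized rotamers): the benchmarks treat
bound DNA as fixed input, so base/backbone identity and engineered
contact counts are what matter, not energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interface_analysis import CONTACT_CUTOFF
from .structure_io import (
    Atom,
    AtomClass,
    Chain,
    MolType,
    Residue,
    Structure,
    classify_atom,
)

RISE = 3.38          # A per base-pair step
TWIST = 36.0         # deg per step
C1_RADIUS = 5.9      # A, C1' distance from helix axis
C1_HALF_ANGLE = 60.0  # deg, half the azimuthal separation of paired C1'

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

# planar base templates: (atom name, x, y) with the glycosidic nitrogen at
# the origin, x pointing from C1' toward the pair partner
_PURINE_RING = [
    ("N9", 0.00, 0.00), ("C8", 0.90, 1.10), ("N7", 2.25, 0.85),
    ("C5", 2.30, -0.55), ("C4", 1.00, -1.05), ("N3", 0.65, -2.40),
    ("C2", 1.70, -3.20), ("N1", 3.00, -2.90), ("C6", 3.40, -1.55),
]
_PYRIMIDINE_RING = [
    ("N1", 0.00, 0.00), ("C2", 0.65, -1.20), ("N3", 2.00, -1.30),
    ("C4", 2.80, -0.20), ("C5", 2.10, 1.05), ("C6", 0.75, 1.10),
    ("O2", 0.05, -2.25),
]
BASE_TEMPLATES = {
    "A": _PURINE_RING + [("N6", 4.70, -1.30)],
    "G": _PURINE_RING + [("O6", 4.55, -1.35), ("N2", 1.40, -4.50)],
    "C": _PYRIMIDINE_RING + [("N4", 4.15, -0.30)],
    "T": _PYRIMIDINE_RING + [("O4", 4.00, -0.30), ("C7", 2.85, 2.30)],
}

# sugar-phosphate offsets from C1' in the local (u, v, w) frame where u
# points toward the helix axis, w along the axis
_BACKBONE_OFFSETS = [
    ("O4'", -0.80, 0.80, 0.50), ("C2'", -0.90, -0.90, -0.30),
    ("C3'", -2.20, -0.50, 0.20), ("C4'", -2.20, 0.90, 0.40),
    ("C5'", -3.30, 1.60, 0.90), ("O5'", -3.30, 2.80, 0.40),
    ("O3'", -3.10, -1.40, 0.60), ("P", -3.50, 3.30, 1.90),
    ("OP1", -4.60, 4.00, 2.10), ("OP2", -2.60, 4.20, 2.40),
]

SIDECHAIN_ATOMS = {
    "ALA": ["CB"],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "CYS": ["CB", "SG"],
    "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "GLY": [],
    "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "MET": ["CB", "CG", "SD", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["CB", "CG", "CD"],
    "SER": ["CB", "OG"],
    "THR": ["CB", "OG1", "CG2"],
    "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "VAL": ["CB", "CG1", "CG2"],
}
AA1_TO_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class UnboundPerturbation:
    """Recipe for manufacturing an unbound copy of a bound TF unit."""
    chain_rotations: dict[str, np.ndarray] = field(default_factory=dict)
    chain_translations: dict[str, np.ndarray] = field(default_factory=dict)
    noise_sigma: float = 0.0
    relabel: dict[str, str] = field(default_factory=dict)
    seed: int = 0


@dataclass
class FixtureSpec:
    dna_sequence: str
    peptide_sequences: list[str]
    target_contacts: list[int]       # per peptide, audited at build time
    perturbation: UnboundPerturbation = field(default_factory=UnboundPerturbation)
    seed: int = 0


class FixtureError(RuntimeError):
    pass


def _mkatom(name: str, pos: np.ndarray, res_name: str, moltype: MolType) -> Atom:
    element = name[0] if name[0] in "CNOSP" else name[:1]
    if name.startswith("SE"):
        element = "SE"
    return Atom(name=name, element=element, coords=np.asarray(pos, float),
                atom_class=classify_atom(res_name, name, moltype))


# --- B-DNA ----------------------------------------------------------------

def build_bdna(sequence: str, chain_ids: tuple[str, str] = ("C", "D"),
               entry_id: str = "fixture") -> Structure:
    """Fiber-model B-DNA duplex for the given strand-1 sequence.

    Strand 2 is the reverse complement; paired C1' atoms sit 10.2 A
    apart, well inside the 10.5 A pairing cutoff used by duplex
    detection.  All standard heavy atoms are present with correct
    base/backbone classification.
    """
    sequence = sequence.upper()
    if len(sequence) < 4:
        raise ValueError("need at least 4 base pairs")
    if any(b not in "ACGT" for b in sequence):
        raise ValueError("DNA alphabet is ACGT")
    n = len(sequence)
    half = np.deg2rad(C1_HALF_ANGLE)

    def nucleotide(base: str, pair_idx: int, strand: int, seq_id: int,
                   chain_id: str) -> Residue:
        theta = np.deg2rad(TWIST * pair_idx)
        sgn = 1.0 if strand == 0 else -1.0
        ang = theta + sgn * half
        c1 = np.array([C1_RADIUS * np.cos(ang), C1_RADIUS * np.sin(ang),
                       RISE * pair_idx])
        axis_pt = np.array([0.0, 0.0, RISE * pair_idx])
        u = axis_pt - c1
        u /= np.linalg.norm(u)
        w = np.array([0.0, 0.0, 1.0]) * sgn   # flip frame on strand 2
        v = np.cross(w, u)
        res_name = "D" + base
        res = Residue(chain_id=chain_id, seq_id=seq_id, res_name=res_name,
                      moltype=MolType.NUCLEOTIDE)
        glyco = c1 + 1.47 * u
        res.atoms.append(_mkatom("C1'", c1, res_name, MolType.NUCLEOTIDE))
        for name, x, y in BASE_TEMPLATES[base]:
            res.atoms.append(_mkatom(name, glyco + x * u + y * v,
                                     res_name, MolType.NUCLEOTIDE))
        for name, du, dv, dw in _BACKBONE_OFFSETS:
            res.atoms.append(_mkatom(name, c1 + du * u + dv * v + dw * w,
                                     res_name, MolType.NUCLEOTIDE))
        return res

    strand1 = Chain(chain_id=chain_ids[0])
    for i, base in enumerate(sequence):
        strand1.residues.append(nucleotide(base, i, 0, i + 1, chain_ids[0]))
    strand2 = Chain(chain_id=chain_ids[1])
    # 5'->3' order of strand 2 runs against the pair index
    for j, pair_idx in enumerate(range(n - 1, -1, -1)):
        base = COMPLEMENT[sequence[pair_idx]]
        strand2.residues.append(nucleotide(base, pair_idx, 1, j + 1,
                                           chain_ids[1]))
    return Structure(entry_id=entry_id, chains=[strand1, strand2],
                     method="xray", resolution=1.0)


# --- peptides -------------------------------------------------------------

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place the next atom from three predecessors (natural extension
    reference frame)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.cos(torsion) * np.sin(angle),
                  bond * np.sin(torsion) * np.sin(angle)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_peptide(sequence: str, conformation: str = "helix",
                  chain_id: str = "A") -> Chain:
    """Ideal-geometry peptide chain (alpha-helix phi=-57/psi=-47 or
    extended phi=-139/psi=135) with simplified idealized sidechains."""
    sequence = sequence.upper()
    if any(aa not in AA1_TO_3 for aa in sequence):
        raise ValueError("non-standard amino acid in sequence")
    if conformation == "helix":
        phi, psi = -57.0, -47.0
    elif conformation == "extended":
        phi, psi = -139.0, 135.0
    else:
        raise ValueError("conformation must be 'helix' or 'extended'")
    omega = 180.0

    # seed backbone
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([1.458, 0.0, 0.0])
    c0 = ca0 + 1.525 * np.array([np.cos(np.deg2rad(180 - 111.2)),
                                 np.sin(np.deg2rad(180 - 111.2)), 0.0])
    backbone = [(n0, ca0, c0)]
    for _ in range(1, len(sequence)):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_i = _nerf(n_prev, ca_prev, c_prev, 1.329, 116.2, psi)
        ca_i = _nerf(ca_prev, c_prev, n_i, 1.458, 121.7, omega)
        c_i = _nerf(c_prev, n_i, ca_i, 1.525, 111.2, phi)
        backbone.append((n_i, ca_i, c_i))

    chain = Chain(chain_id=chain_id)
    for idx, aa in enumerate(sequence):
        res_name = AA1_TO_3[aa]
        res = Residue(chain_id=chain_id, seq_id=idx + 1, res_name=res_name,
                      moltype=MolType.AMINO_ACID)
        n_i, ca_i, c_i = backbone[idx]
        o_i = _nerf(n_i, ca_i, c_i, 1.231, 120.5,
                    psi + 180.0 if idx + 1 < len(sequence) else 0.0)
        for name, pos in (("N", n_i), ("CA", ca_i), ("C", c_i), ("O", o_i)):
            res.atoms.append(_mkatom(name, pos, res_name, MolType.AMINO_ACID))
        names = SIDECHAIN_ATOMS[res_name]
        if names:
            cb = _nerf(n_i, c_i, ca_i, 1.53, 110.5, 122.5)
            res.atoms.append(_mkatom(names[0], cb, res_name, MolType.AMINO_ACID))
            d = cb - ca_i
            d /= np.linalg.norm(d)
            perp = np.cross(d, c_i - n_i)
            perp /= np.linalg.norm(perp)
            # compact curled pseudo-rotamer: short zig-zag outward from CB
            for m, name in enumerate(names[1:], start=1):
                pos = cb + d * (0.9 * m) + perp * (0.8 * (m % 2))
                res.atoms.append(_mkatom(name, pos, res_name, MolType.AMINO_ACID))
        chain.residues.append(res)
    return chain


# --- rigid placement with an engineered contact count ---------------------

def _chain_arrays(chain: Chain, cls: AtomClass):
    xyz, res_idx = [], []
    for i, res in enumerate(chain.residues):
        for atom in res.atoms:
            if atom.atom_class is cls:
                xyz.append(atom.coords)
                res_idx.append(i)
    return np.array(xyz), np.array(res_idx)


def audit_contact_count(peptide: Chain, dna_chains: list[Chain],
                        cutoff: float = CONTACT_CUTOFF) -> int:
    """Brute-force count of peptide residues with a sidechain heavy atom
    within ``cutoff`` of any DNA base heavy atom."""
    side_xyz, side_res = _chain_arrays(peptide, AtomClass.PROTEIN_SIDECHAIN)
    base_xyz = np.concatenate([
        _chain_arrays(c, AtomClass.NUCLEOTIDE_BASE)[0] for c in dna_chains])
    if side_xyz.size == 0 or base_xyz.size == 0:
        return 0
    d2 = ((side_xyz[:, None, :] - base_xyz[None, :, :]) ** 2).sum(axis=2)
    hit = (d2 <= cutoff ** 2).any(axis=1)
    return len(set(side_res[hit]))


def _min_gap(peptide: Chain, dna_chains: list[Chain]) -> float:
    p = np.array([a.coords for a in peptide.atoms()])
    d = np.concatenate([c.coords() for c in dna_chains])
    return float(np.sqrt(((p[:, None, :] - d[None, :, :]) ** 2).sum(axis=2).min()))


def _rotation_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def transform_chain(chain: Chain, rotation: np.ndarray,
                    translation: np.ndarray) -> Chain:
    out = Chain(chain_id=chain.chain_id)
    for res in chain.residues:
        new = Residue(chain_id=res.chain_id, seq_id=res.seq_id,
                      res_name=res.res_name, moltype=res.moltype,
                      icode=res.icode)
        for atom in res.atoms:
            new.atoms.append(Atom(name=atom.name, element=atom.element,
                                  coords=rotation @ atom.coords + translation,
                                  occupancy=atom.occupancy, altloc=atom.altloc,
                                  atom_class=atom.atom_class))
        out.residues.append(new)
    return out


def _pair_windows(q: np.ndarray, targets: np.ndarray, direction: np.ndarray,
                  cutoff: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """For moving points q + r*direction, the window of slide parameter r
    in which each (moving, fixed) pair is within cutoff.  Returns flat
    arrays (i_idx, r_lo, r_hi) for pairs with a non-empty window."""
    w = q[:, None, :] - targets[None, :, :]
    b = 2.0 * (w @ direction)
    c = (w ** 2).sum(axis=2) - cutoff ** 2
    disc = b ** 2 - 4.0 * c
    ii, jj = np.nonzero(disc > 0)
    root = np.sqrt(disc[ii, jj])
    lo = (-b[ii, jj] - root) / 2.0
    hi = (-b[ii, jj] + root) / 2.0
    return ii, lo, hi


def place_with_contacts(peptide: Chain, duplex: Structure, k: int,
                        seed: int = 0, cutoff: float = CONTACT_CUTOFF,
                        azimuth: float = 0.0,
                        max_attempts: int = 400) -> Structure:
    """Rigidly place the peptide so exactly ``k`` residues make a
    sidechain-to-base contact, verified by brute-force audit.

    Random orientations are tried (helix roughly parallel to the DNA
    axis, randomized roll/tilt and axial offset, seeded).  For each
    orientation the peptide approaches the duplex radially; the contact
    count as a function of the approach coordinate is resolved exactly
    from per-atom-pair quadratic windows, and the outermost clash-free
    position with an audited count of exactly ``k`` is accepted.
    Exhausting ``max_attempts`` raises.
    """
    n_side = sum(1 for r in peptide.residues if SIDECHAIN_ATOMS[r.res_name])
    if k > n_side:
        raise FixtureError(f"k={k} exceeds {n_side} sidechain-bearing residues")
    dna_chains = duplex.dna_chains
    z_mid = float(np.concatenate([c.coords() for c in dna_chains])[:, 2].mean())
    pep_xyz = np.array([a.coords for a in peptide.atoms()])
    pep_center = pep_xyz.mean(axis=0)
    # principal axis of the peptide, to be aligned with the helix axis
    _, _, vt = np.linalg.svd(pep_xyz - pep_center)
    pep_axis = vt[0]
    z_axis = np.array([0.0, 0.0, 1.0])
    rot_align = _align_vectors(pep_axis, z_axis)
    direction = np.array([np.cos(azimuth), np.sin(azimuth), 0.0])

    side_xyz, side_res = _chain_arrays(peptide, AtomClass.PROTEIN_SIDECHAIN)
    base_xyz = np.concatenate([
        _chain_arrays(c, AtomClass.NUCLEOTIDE_BASE)[0] for c in dna_chains])
    all_dna = np.concatenate([c.coords() for c in dna_chains])

    rng = np.random.default_rng(seed)
    if k == 0:
        target = np.array([0.0, 0.0, z_mid]) + 60.0 * direction
        placed = transform_chain(peptide, rot_align,
                                 target - rot_align @ pep_center)
        assert audit_contact_count(placed, dna_chains, cutoff) == 0
        return _assemble(duplex, placed)

    for _ in range(max_attempts):
        roll = _rotation_z(rng.uniform(0, 2 * np.pi))
        tilt = _align_vectors(z_axis, _jitter(z_axis, rng, 0.45))
        rot = tilt @ _rotation_z(azimuth) @ roll @ rot_align
        dz = rng.uniform(-4.0, 4.0)
        offset = np.array([0.0, 0.0, z_mid + dz]) - rot @ pep_center
        q_side = side_xyz @ rot.T + offset
        q_all = pep_xyz @ rot.T + offset

        ii, lo, hi = _pair_windows(q_side, base_xyz, direction, cutoff)
        if ii.size == 0:
            continue
        # clash windows: any peptide atom closer than 1.2 A to any DNA atom
        _, clo, chi = _pair_windows(q_all, all_dna, direction, 1.2)
        endpoints = np.unique(np.concatenate([lo, hi]))
        endpoints = endpoints[(endpoints > 6.0) & (endpoints < 45.0)]
        # probe a little inside/outside every window boundary (0.02 A
        # margin keeps engineered contacts stable under 3-decimal PDB
        # coordinate rounding), outermost first
        probes = np.unique(np.concatenate([endpoints - 0.02,
                                           endpoints + 0.02]))[::-1]
        for r in probes:
            inside = (lo <= r) & (r <= hi)
            count = len(set(side_res[ii[inside]]))
            if count != k:
                continue
            if clo.size and np.any((clo <= r) & (r <= chi)):
                continue
            placed = transform_chain(peptide, rot,
                                     offset + r * direction)
            if audit_contact_count(placed, dna_chains, cutoff) == k:
                return _assemble(duplex, placed)
    raise FixtureError(f"could not realize exactly {k} contacts "
                       f"in {max_attempts} attempts")


def _jitter(v: np.ndarray, rng: np.random.Generator, scale: float) -> np.ndarray:
    out = v + rng.normal(scale=scale, size=3)
    return out / np.linalg.norm(out)


def _align_vectors(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector a onto unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _assemble(duplex: Structure, *chains: Chain) -> Structure:
    st = Structure(entry_id=duplex.entry_id, method="xray",
                   resolution=duplex.resolution)
    old_protein = [c for c in duplex.chains if c.chain_type.value == "protein"]
    nucleic = [c for c in duplex.chains if c.chain_type.value != "protein"]
    st.chains = old_protein + list(chains) + nucleic
    return st


# --- unbound manufacture --------------------------------------------------

def perturb_unbound(bound: Structure, spec: UnboundPerturbation,
                    protein_only: bool = True,
                    ) -> tuple[Structure, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Make an 'unbound' copy of the bound structure's protein chains.

    Applies the per-chain rigid transforms of ``spec``, then optional
    iid Gaussian coordinate noise, then optional chain relabeling.
    Returns the structure and the exact (rotation, translation) applied
    per original chain id, for oracle checks.
    """
    rng = np.random.default_rng(spec.seed)
    unbound = Structure(entry_id=bound.entry_id + "_unbound", method="xray",
                        resolution=bound.resolution)
    truth: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chain in bound.chains:
        if protein_only and chain.chain_type.value != "protein":
            continue
        rot = spec.chain_rotations.get(chain.chain_id, np.eye(3))
        trans = spec.chain_translations.get(chain.chain_id, np.zeros(3))
        new = transform_chain(chain, np.asarray(rot, float),
                              np.asarray(trans, float))
        if spec.noise_sigma > 0:
            for res in new.residues:
                for atom in res.atoms:
                    atom.coords = atom.coords + rng.normal(
                        scale=spec.noise_sigma, size=3)
        new.chain_id = spec.relabel.get(chain.chain_id, chain.chain_id)
        for res in new.residues:
            res.chain_id = new.chain_id
        truth[chain.chain_id] = (np.asarray(rot, float), np.asarray(trans, float))
        unbound.chains.append(new)
    unbound.chains.sort(key=lambda c: c.chain_id)
    return unbound, truth


# --- end-to-end fixture cases ---------------------------------------------

def make_fixture_case(spec: FixtureSpec):
    """Build a complete benchmark case from a fixture recipe: bound
    complex, audited contact counts, perturbed unbound partner, interface
    and conformational metrics, and both difficulty labels."""
    from .benchmark_builder import analyze_complex

    duplex = build_bdna(spec.dna_sequence)
    structure = duplex
    chain_ids = "AB"[:len(spec.peptide_sequences)] or "A"
    for idx, (seq, k) in enumerate(zip(spec.peptide_sequences,
                                       spec.target_contacts)):
        peptide = build_peptide(seq, "helix", chain_id=chain_ids[idx])
        azimuth = np.pi * idx   # opposite faces of the duplex
        structure = place_with_contacts(peptide, structure, k,
                                        seed=spec.seed + idx, azimuth=azimuth)
    unbound, truth = perturb_unbound(structure, spec.perturbation)
    case = analyze_complex(structure, unbound, sasa_points=240)
    case.ground_truth_transforms = truth
    return case
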