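"""Bound/unbound comparison: sequence-aligned Calpha RMSD at chain and
unit level.

Residue correspondence between a bound TF chain and its unbound partner
comes from optimal global sequence alignment (Needleman-Wunsch, BLOSUM62,
affine gaps 10/0.5, free end gaps — the EMBOSS needle defaults).  The
rigid superposition is least-squares (Kabsch) on the aligned Calpha
atoms.  RMSD_c superposes one chain pair at a time; RMSD_u performs a
single joint superposition over all chains of the unit, so a rearrangement
of near-rigid chains (the classic p53 tetramer case) shows up in RMSD_u
while every RMSD_c stays small.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structure_io import Chain, ChainType, Structure, extract_sequence

GAP_OPEN = 10.0
GAP_EXTEND = 0.5
MATRIX = "BLOSUM62"
MIN_IDENTITY = 95.0   # % — unbound partner admissibility
MIN_COVERAGE = 95.0   # %


@dataclass
class AlignmentMapping:
    aligned_pairs: list[tuple[int, int]]  # (index in A, index in B)
    identity: float                        # % identical / core alignment length
    coverage: float                        # % of A residues aligned to non-gap
    score: float
    n_identical: int = 0


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # (3,3), proper
    translation: np.ndarray   # (3,)
    rmsd: float
    degenerate: bool = False  # collinear/planar-degenerate input


@dataclass
class ConformationalMetrics:
    rmsd_c_per_chain: list[tuple[str, str, float]]
    rmsd_u: float
    chain_assignment: dict[str, str]


class AlignmentError(ValueError):
    pass


def _make_aligner(matrix: str = MATRIX, gap_open: float = GAP_OPEN,
                  gap_extend: float = GAP_EXTEND) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    try:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    except FileNotFoundError as exc:
        raise AlignmentError(f"unknown substitution matrix {matrix!r}") from exc
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    # needle's endweight default is off: end gaps are free
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # biopython < 1.86 attribute names
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    aligner.mode = "global"
    return aligner


def global_align(seq_a: str, seq_b: str, matrix: str = MATRIX,
                 gap_open: float = GAP_OPEN,
                 gap_extend: float = GAP_EXTEND) -> AlignmentMapping:
    """Optimal global alignment of two protein sequences.

    Identity is identical positions over the alignment length between the
    first and last aligned columns (end gaps excluded); coverage is the
    fraction of ``seq_a`` residues aligned to a non-gap.
    """
    if not seq_a or not seq_b:
        raise AlignmentError("empty sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignment = aligner.align(seq_a.upper(), seq_b.upper())[0]
    pairs: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    if not pairs:
        return AlignmentMapping([], 0.0, 0.0, float(alignment.score))
    identities = sum(seq_a[i].upper() == seq_b[j].upper() for i, j in pairs)
    span_a = pairs[-1][0] - pairs[0][0] + 1
    span_b = pairs[-1][1] - pairs[0][1] + 1
    core_len = span_a + span_b - len(pairs)  # pairs + internal gap columns
    return AlignmentMapping(
        aligned_pairs=pairs,
        identity=100.0 * identities / core_len,
        coverage=100.0 * len(pairs) / len(seq_a),
        score=float(alignment.score),
        n_identical=identities,
    )


# --- superposition --------------------------------------------------------

def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid superposition (Kabsch, proper rotation).

    Returns the rotation/translation mapping ``coords_a`` onto
    ``coords_b`` and the minimized RMSD.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both be N x 3")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to superpose")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    # collinear sets leave a free rotation axis; flag, don't fail
    degenerate = np.linalg.matrix_rank(a0, tol=1e-8) < 2
    resid = a0 @ rot.T - b0
    rmsd = float(np.sqrt((resid ** 2).sum() / n))
    trans = cb - rot @ ca
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd,
                               degenerate=degenerate)


def _ca_coords(chain: Chain) -> dict[int, np.ndarray]:
    out = {}
    for idx, res in enumerate(chain.residues):
        ca = res.get_atom("CA")
        if ca is not None:
            out[idx] = ca.coords
    return out


def _aligned_ca_pairs(bound: Chain, unbound: Chain) -> tuple[np.ndarray, np.ndarray]:
    mapping = global_align(extract_sequence(bound), extract_sequence(unbound))
    ca_b, ca_u = _ca_coords(bound), _ca_coords(unbound)
    pts_b, pts_u = [], []
    for i, j in mapping.aligned_pairs:
        if i in ca_b and j in ca_u:   # residues missing Calpha skip symmetrically
            pts_b.append(ca_b[i])
            pts_u.append(ca_u[j])
    return np.array(pts_b), np.array(pts_u)


def compute_rmsd_c(bound_chain: Chain, unbound_chain: Chain) -> float:
    """Chain-level RMSD on sequence-aligned Calpha atoms."""
    a, b = _aligned_ca_pairs(bound_chain, unbound_chain)
    if len(a) < 3:
        raise AlignmentError("fewer than 3 aligned Calpha pairs")
    return superpose(a, b).rmsd


def compute_rmsd_u(bound_unit, unbound: Structure,
                   assignment: dict[str, str]) -> float:
    """Unit-level RMSD: one joint superposition over the concatenated
    aligned Calpha pairs of every assigned chain pair."""
    pts_b, pts_u = [], []
    for bound_chain in bound_unit.tf_chains:
        unbound_chain = unbound.get_chain(assignment[bound_chain.chain_id])
        a, b = _aligned_ca_pairs(bound_chain, unbound_chain)
        pts_b.append(a)
        pts_u.append(b)
    a = np.concatenate(pts_b)
    b = np.concatenate(pts_u)
    if len(a) < 3:
        raise AlignmentError("fewer than 3 aligned Calpha pairs in unit")
    return superpose(a, b).rmsd


def pair_chains(bound_unit, unbound: Structure,
                min_identity: float = MIN_IDENTITY) -> dict[str, str]:
    """Assign bound chains to unbound chains.

    All injective assignments with pairwise identity >= ``min_identity``
    are evaluated and the one minimizing RMSD_u wins — this resolves the
    label-swap ambiguity of homo-oligomers.
    """
    bound_chains = bound_unit.tf_chains
    unbound_chains = [c for c in unbound.chains if c.chain_type is ChainType.PROTEIN]
    if len(unbound_chains) < len(bound_chains):
        raise AlignmentError(
            f"unbound structure has {len(unbound_chains)} protein chains, "
            f"unit needs {len(bound_chains)}")
    seqs_b = [extract_sequence(c) for c in bound_chains]
    seqs_u = [extract_sequence(c) for c in unbound_chains]
    ident = np.array([[global_align(sb, su).identity for su in seqs_u]
                      for sb in seqs_b])
    best_assign, best_rmsd = None, np.inf
    for perm in itertools.permutations(range(len(unbound_chains)),
                                       len(bound_chains)):
        if all(ident[i, j] >= min_identity for i, j in enumerate(perm)):
            assignment = {bound_chains[i].chain_id: unbound_chains[j].chain_id
                          for i, j in enumerate(perm)}
            try:
                rmsd = compute_rmsd_u(bound_unit, unbound, assignment)
            except AlignmentError:
                continue
            if rmsd < best_rmsd:
                best_assign, best_rmsd = assignment, rmsd
    if best_assign is None:
        raise AlignmentError("no admissible bound-to-unbound chain assignment")
    return best_assign


def compute_conformational_metrics(bound_unit,
                                   unbound: Structure) -> ConformationalMetrics:
    assignment = pair_chains(bound_unit, unbound)
    per_chain = []
    for bound_chain in bound_unit.tf_chains:
        unbound_chain = unbound.get_chain(assignment[bound_chain.chain_id])
        per_chain.append((bound_chain.chain_id, unbound_chain.chain_id,
                          compute_rmsd_c(bound_chain, unbound_chain)))
    rmsd_u = compute_rmsd_u(bound_unit, unbound, assignment)
    return ConformationalMetrics(rmsd_c_per_chain=per_chain, rmsd_u=rmsd_u,
                                 chain_assignment=assignment)


# --- unbound matching -----------------------------------------------------

def match_unbound(bound_unit, candidates: list[Structure],
                  min_identity: float = MIN_IDENTITY,
                  min_coverage: float = MIN_COVERAGE) -> Structure | None:
    """Pick the unbound partner among candidate structures.

    A candidate is admissible when every bound chain maps (injectively) to
    some candidate protein chain at >= ``min_identity`` % identity and
    >= ``min_coverage`` % coverage of the bound sequence.  X-ray
    candidates are preferred over NMR outright; within a method class the
    highest mean identity wins, ties broken by better (lower) resolution.
    Returns None when nothing passes — such a case stays rigid-only.
    """
    scored = []
    for cand in candidates:
        chains = [c for c in cand.chains if c.chain_type is ChainType.PROTEIN]
        if len(chains) < len(bound_unit.tf_chains):
            continue
        seqs_u = [extract_sequence(c) for c in chains]
        stats = [[global_align(extract_sequence(bc), su) for su in seqs_u]
                 for bc in bound_unit.tf_chains]
        best_mean = None
        for perm in itertools.permutations(range(len(chains)),
                                           len(bound_unit.tf_chains)):
            ms = [stats[i][j] for i, j in enumerate(perm)]
            if all(m.identity >= min_identity and m.coverage >= min_coverage
                   for m in ms):
                mean_id = float(np.mean([m.identity for m in ms]))
                if best_mean is None or mean_id > best_mean:
                    best_mean = mean_id
        if best_mean is not None:
            scored.append((cand, best_mean))
    if not scored:
        return None
    xray = [s for s in scored if s[0].method == "xray"]
    pool = xray if xray else scored
    pool.sort(key=lambda s: (-s[1], s[0].resolution if s[0].resolution is not None
                             else np.inf, s[0].entry_id))
    return pool[0][0]
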