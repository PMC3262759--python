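"""Benchmark assembly: entry filtering, redundancy clustering, and the
easy/hard difficulty rules for flexible and rigid TF-DNA docking.

A flexible-docking case starts from the *unbound* TF structure, so both
the conformational change upon binding (RMSD_u) and the interface
strength (NRBC) decide its difficulty:

    Easy  iff  RMSD_u <= 2.5 A  and  NRBC >= 5

A rigid-docking case starts from the bound TF conformation, leaving
interface strength as the only criterion:

    Easy  iff  NRBC >= 10

Both thresholds are inclusive.  The module also ships machine-readable
transcriptions of the published benchmark composition (37 flexible / 38
rigid cases) for table-driven regression checks.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .conformational_analysis import (
    ConformationalMetrics,
    compute_conformational_metrics,
    global_align,
    match_unbound,
)
from .interface_analysis import (
    BindingUnit,
    InterfaceMetrics,
    compute_bsa,
    identify_binding_units,
    select_representative_unit,
)
from .structure_io import Structure, detect_duplex, extract_sequence, write_case_files

FLEXIBLE_RMSD_U_MAX = 2.5   # Angstrom, inclusive
FLEXIBLE_NRBC_MIN = 5       # inclusive
RIGID_NRBC_MIN = 10         # inclusive
REDUNDANCY_IDENTITY = 35.0  # % single-linkage clustering cutoff
RESOLUTION_MAX = 3.0        # Angstrom, inclusive


@dataclass
class CaseFilterReport:
    entry_id: str
    checks: dict[str, bool]
    reasons: dict[str, str] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.checks.values())


@dataclass
class BenchmarkCase:
    bound: BindingUnit
    bound_structure: Structure
    unbound: Structure | None = None
    metrics: InterfaceMetrics | None = None
    conf: ConformationalMetrics | None = None
    flexible_label: str | None = None   # Easy | Hard | None (no unbound)
    rigid_label: str | None = None

    @property
    def entry_id(self) -> str:
        return self.bound.entry_id


@dataclass
class BenchmarkTable:
    cases: list[BenchmarkCase]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "flexible_easy": sum(c.flexible_label == "Easy" for c in self.cases),
            "flexible_hard": sum(c.flexible_label == "Hard" for c in self.cases),
            "rigid_easy": sum(c.rigid_label == "Easy" for c in self.cases),
            "rigid_hard": sum(c.rigid_label == "Hard" for c in self.cases),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cases:
            rows.append({
                "pdb_id": c.entry_id,
                "protein_chains": ",".join(c.bound.tf_chain_ids),
                "dna_chains": ",".join(c.bound.dna_chain_ids),
                "oligo_state": c.bound.oligo_state,
                "nrbc": c.metrics.nrbc if c.metrics else None,
                "bsa": round(c.metrics.bsa, 2) if c.metrics else None,
                "unbound_pdb": c.unbound.entry_id if c.unbound else None,
                "rmsd_u": round(c.conf.rmsd_u, 3) if c.conf else None,
                "rmsd_c_max": (round(max(r for _, _, r in c.conf.rmsd_c_per_chain), 3)
                               if c.conf else None),
                "flexible_label": c.flexible_label,
                "rigid_label": c.rigid_label,
            })
        return pd.DataFrame(rows)


# --- classification rules -------------------------------------------------

def classify_flexible(nrbc: int, rmsd_u: float,
                      rmsd_u_max: float = FLEXIBLE_RMSD_U_MAX,
                      nrbc_min: int = FLEXIBLE_NRBC_MIN) -> str:
    """Flexible-docking difficulty: Easy iff the conformational change is
    small (RMSD_u <= 2.5 A) AND the interface is strong (NRBC >= 5)."""
    return "Easy" if (rmsd_u <= rmsd_u_max and nrbc >= nrbc_min) else "Hard"


def classify_rigid(nrbc: int, nrbc_min: int = RIGID_NRBC_MIN) -> str:
    """Rigid-docking difficulty: Easy iff NRBC >= 10."""
    return "Easy" if nrbc >= nrbc_min else "Hard"


# --- filtering ------------------------------------------------------------

def filter_candidates(structure: Structure, is_tf: bool,
                      resolution_max: float = RESOLUTION_MAX) -> CaseFilterReport:
    """Entry-level gate: X-ray, resolution <= 3.0 A (inclusive), has a DNA
    duplex, and carries a transcription-factor annotation (the annotation
    is an input flag — TF identification is curation, not computation)."""
    checks, reasons = {}, {}
    checks["is_xray"] = structure.method == "xray"
    if structure.resolution is None:
        checks["resolution_ok"] = False
        reasons["resolution_ok"] = "no resolution recorded"
    else:
        checks["resolution_ok"] = structure.resolution <= resolution_max
    checks["has_duplex"] = bool(detect_duplex(structure.dna_chains))
    checks["is_tf"] = bool(is_tf)
    return CaseFilterReport(entry_id=structure.entry_id, checks=checks,
                            reasons=reasons)


# --- redundancy clustering ------------------------------------------------

def case_identity(case_a: BenchmarkCase, case_b: BenchmarkCase) -> float:
    """Max pairwise identity between any TF chain of one case and any TF
    chain of the other.

    Identity here is identical aligned positions over the length of the
    shorter sequence, so a fortuitous short aligned core between
    unrelated chains does not read as high identity — the normalization
    a culling server uses for redundancy removal.
    """
    best = 0.0
    for ca in case_a.bound.tf_chains:
        for cb in case_b.bound.tf_chains:
            sa, sb = extract_sequence(ca), extract_sequence(cb)
            if not sa or not sb:
                continue
            m = global_align(sa, sb)
            best = max(best, 100.0 * m.n_identical / min(len(sa), len(sb)))
    return best


def cluster_redundancy(cases: list[BenchmarkCase],
                       identity_cutoff: float = REDUNDANCY_IDENTITY,
                       ) -> list[list[BenchmarkCase]]:
    """Single-linkage clusters on the relation identity >= cutoff.

    The first case in each returned cluster is its representative: best
    (lowest) resolution, then most interface contacts resolved, then
    lexicographic entry id.
    """
    n = len(cases)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if case_identity(cases[i], cases[j]) >= identity_cutoff:
                parent[find(i)] = find(j)

    groups: dict[int, list[BenchmarkCase]] = {}
    for i, case in enumerate(cases):
        groups.setdefault(find(i), []).append(case)

    def rep_key(c: BenchmarkCase):
        res = (c.bound_structure.resolution
               if c.bound_structure.resolution is not None else float("inf"))
        return (res, -len(c.bound.contacts), c.entry_id)

    clusters = []
    for members in groups.values():
        members = sorted(members, key=rep_key)
        clusters.append(members)
    return sorted(clusters, key=lambda m: m[0].entry_id)


# --- end-to-end -----------------------------------------------------------

def analyze_complex(structure: Structure,
                    unbound: Structure | None = None,
                    sasa_points: int = 960) -> BenchmarkCase:
    """Metrics for one complex: representative binding unit, NRBC, BSA,
    and (when an unbound structure is given) RMSD_c / RMSD_u and both
    difficulty labels."""
    units = identify_binding_units(structure)
    if not units:
        raise ValueError(f"{structure.entry_id}: no TF-DNA binding unit found")
    unit = select_representative_unit(units, n_sphere_points=sasa_points)
    case = BenchmarkCase(bound=unit, bound_structure=structure)
    case.metrics = compute_bsa(unit, n_sphere_points=sasa_points)
    case.rigid_label = classify_rigid(case.metrics.nrbc)
    if unbound is not None:
        case.unbound = unbound
        case.conf = compute_conformational_metrics(unit, unbound)
        case.flexible_label = classify_flexible(case.metrics.nrbc,
                                                case.conf.rmsd_u)
    return case


def build_benchmark(cases: list[BenchmarkCase],
                    out_dir: str | Path | None = None) -> BenchmarkTable:
    """Label every case with both classifiers and optionally write the
    per-case PDB files plus a summary TSV."""
    for case in cases:
        if case.metrics is None:
            raise ValueError(f"{case.entry_id}: missing interface metrics")
        case.rigid_label = classify_rigid(case.metrics.nrbc)
        if case.conf is not None:
            case.flexible_label = classify_flexible(case.metrics.nrbc,
                                                    case.conf.rmsd_u)
        else:
            case.flexible_label = None
    table = BenchmarkTable(cases=cases)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_frame().to_csv(out_dir / "benchmark.tsv", sep="\t", index=False)
        for case in cases:
            write_case_files(case, out_dir / "cases")
    return table


def pair_with_unbound(case: BenchmarkCase,
                      candidates: list[Structure]) -> BenchmarkCase:
    """Attach the best-matching unbound structure (95/95 identity and
    coverage rule) and its conformational metrics, when one exists."""
    match = match_unbound(case.bound, candidates)
    if match is not None:
        case.unbound = match
        case.conf = compute_conformational_metrics(case.bound, match)
    return case


# --- packaged benchmark composition tables --------------------------------

def load_published_table(benchmark: str) -> pd.DataFrame:
    """The packaged transcription of the published benchmark composition.

    ``benchmark`` is ``"flexible"`` (37 cases: NRBC, RMSD_u, RMSD_c and
    unbound partners) or ``"rigid"`` (38 cases: NRBC and BSA).
    """
    names = {"flexible": "flexible_benchmark_table.tsv",
             "rigid": "rigid_benchmark_table.tsv"}
    if benchmark not in names:
        raise ValueError("benchmark must be 'flexible' or 'rigid'")
    src = importlib.resources.files("tfdnabench.data") / names[benchmark]
    with importlib.resources.as_file(src) as path:
        return pd.read_csv(path, sep="\t")


def label_published_table(benchmark: str) -> pd.DataFrame:
    """Re-apply the difficulty rules to the published metric columns and
    return the table with a ``label`` column."""
    df = load_published_table(benchmark).copy()
    if benchmark == "flexible":
        df["label"] = [classify_flexible(n, r)
                       for n, r in zip(df["nrbc"], df["rmsd_u"])]
    else:
        df["label"] = [classify_rigid(n) for n in df["nrbc"]]
    return df
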