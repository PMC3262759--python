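"""Dataset-level statistics over interface metrics.

Supports the comparison of DNA-binding protein groups — transcription
factors (TF), type II restriction endonucleases (RE) and non-specific
binders (NS) — by NRBC/BSA distributions, the NRBC-BSA correlation, and
the oligomeric-state census of benchmark cases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .interface_analysis import ResidueContactProfile, residue_contact_profile

GROUPS = ("TF", "RE", "NS")


@dataclass
class GroupProfile:
    group: str
    nrbc_values: list[float]
    bsa_values: list[float]

    @property
    def median_nrbc(self) -> float:
        return float(np.median(self.nrbc_values))

    @property
    def median_bsa(self) -> float:
        return float(np.median(self.bsa_values))

    def quartiles(self, which: str = "nrbc") -> tuple[float, float, float]:
        vals = self.nrbc_values if which == "nrbc" else self.bsa_values
        q1, q2, q3 = np.percentile(vals, [25, 50, 75])
        return float(q1), float(q2), float(q3)


class StatsError(ValueError):
    pass


def summarize_groups(metrics: Sequence[Mapping], labels: Sequence[str],
                     ) -> list[GroupProfile]:
    """Per-group NRBC/BSA value lists and medians.

    ``metrics`` is a sequence of mappings with ``nrbc`` and ``bsa`` keys,
    ``labels`` the parallel group assignment (TF/RE/NS).  Groups with no
    entries are omitted rather than returned with NaN summaries.
    """
    if len(metrics) != len(labels):
        raise StatsError("metrics and labels differ in length")
    for lab in labels:
        if lab not in GROUPS:
            raise StatsError(f"unknown group label {lab!r}")
    profiles = []
    for group in GROUPS:
        nrbc = [float(m["nrbc"]) for m, g in zip(metrics, labels) if g == group]
        bsa = [float(m["bsa"]) for m, g in zip(metrics, labels) if g == group]
        if nrbc:
            profiles.append(GroupProfile(group=group, nrbc_values=nrbc,
                                         bsa_values=bsa))
    return profiles


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("inputs must be equal-length 1-D sequences")
    if len(x) < 3:
        raise StatsError("need at least 3 observations")
    xd, yd = x - x.mean(), y - y.mean()
    sx, sy = np.sqrt((xd ** 2).sum()), np.sqrt((yd ** 2).sum())
    if sx == 0 or sy == 0:
        raise StatsError("undefined correlation: zero variance")
    return float((xd * yd).sum() / (sx * sy))


def oligomer_census(oligo_states: Sequence[str]) -> float:
    """Percentage of cases whose TF unit is a homodimer or homotetramer."""
    states = list(oligo_states)
    if not states:
        return 0.0
    n_homo = sum(s in ("homodimer", "homotetramer") for s in states)
    return 100.0 * n_homo / len(states)
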