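"""Pair force-field-minimized conformers with QM references.

Each FF conformer is assigned to its nearest QM reference (symmetry-aware
RMSD, hydrogens included) when within the threshold; when several FF
conformers share a QM reference only the lowest-RMSD one survives; QM
references with no surviving partner are dropped from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import FFBenchError
from .geometry_metrics import (
    DEFAULT_AUTOMORPHISM_CAP,
    AutomorphismSet,
    enumerate_automorphisms,
    min_rmsd_matrix,
)
from .io_dataset import MoleculeGroup

__all__ = ["DEFAULT_MATCH_THRESHOLD", "MatchResult", "match_conformers"]

DEFAULT_MATCH_THRESHOLD = 1.0  # Angstrom

NO_REFERENCE = "no-reference-within-threshold"
DUPLICATE = "duplicate-superseded"


@dataclass
class MatchResult:
    """Outcome of QM <-> FF conformer pairing for one group and force field.

    Invariants: pair RMSDs <= threshold; QM and FF indices unique across
    pairs; |pairs| + |dropped_ff| = FF conformer count and
    |pairs| + |dropped_qm| = QM conformer count.
    """

    key: str
    ff_id: str
    threshold: float
    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    dropped_qm: list[int] = field(default_factory=list)
    dropped_ff: list[tuple[int, str]] = field(default_factory=list)

    def validate(self, n_qm: int, n_ff: int) -> None:
        qm_idx = [q for q, _f, _r in self.pairs]
        ff_idx = [f for _q, f, _r in self.pairs]
        if len(set(qm_idx)) != len(qm_idx):
            raise FFBenchError("duplicate QM index across pairs")
        if len(set(ff_idx)) != len(ff_idx):
            raise FFBenchError("duplicate FF index across pairs")
        if any(r > self.threshold for _q, _f, r in self.pairs):
            raise FFBenchError("pair RMSD above threshold")
        if len(self.pairs) + len(self.dropped_ff) != n_ff:
            raise FFBenchError("FF conformer accounting identity violated")
        if len(self.pairs) + len(self.dropped_qm) != n_qm:
            raise FFBenchError("QM conformer accounting identity violated")


def _rmsd_matrix(
    group: MoleculeGroup,
    ff_id: str,
    automorphisms: AutomorphismSet,
) -> np.ndarray:
    qm_coords = [r.qm.coordinates for r in group.records]
    ff_coords = [r.ff_results[ff_id].coordinates for r in group.records]
    return min_rmsd_matrix(qm_coords, ff_coords, automorphisms.permutations)


def match_conformers(
    group: MoleculeGroup,
    ff_id: str,
    threshold: float = DEFAULT_MATCH_THRESHOLD,
    optimal: bool = False,
    automorphisms: Optional[AutomorphismSet] = None,
    cap: int = DEFAULT_AUTOMORPHISM_CAP,
    rmsd_matrix: Optional[np.ndarray] = None,
) -> MatchResult:
    """Match a group's FF conformers to QM references under an RMSD cap.

    The default greedy procedure assigns each FF conformer to its nearest
    QM reference if within ``threshold``, then keeps only the lowest-RMSD FF
    conformer per reference (ties toward the lower FF index). With
    ``optimal=True`` a minimum-cost bipartite assignment over the within-
    threshold pairs is used instead. ``rmsd_matrix`` (QM x FF) may be
    supplied to bypass geometry computation, e.g. in property tests.
    """
    if threshold <= 0:
        raise FFBenchError("threshold must be positive")
    n = group.n_records
    if rmsd_matrix is None:
        if automorphisms is None:
            automorphisms = enumerate_automorphisms(group.graph, cap=cap)
        mat = _rmsd_matrix(group, ff_id, automorphisms)
    else:
        mat = np.asarray(rmsd_matrix, dtype=float)
        if mat.shape[0] != mat.shape[1]:
            raise FFBenchError("rmsd_matrix must be square (QM x FF)")
        n = mat.shape[0]

    result = MatchResult(key=group.key, ff_id=ff_id, threshold=threshold)
    if n == 0:
        return result

    if optimal:
        cost = np.where(mat <= threshold, mat, 1e9)
        rows, cols = linear_sum_assignment(cost)
        matched_ff = set()
        for q, f in zip(rows, cols):
            if mat[q, f] <= threshold:
                result.pairs.append((int(q), int(f), float(mat[q, f])))
                matched_ff.add(int(f))
        for f in range(n):
            if f not in matched_ff:
                result.dropped_ff.append((f, NO_REFERENCE))
    else:
        nearest: dict[int, list[tuple[float, int]]] = {}
        for f in range(n):
            q = int(np.argmin(mat[:, f]))
            d = float(mat[q, f])
            if d > threshold:
                result.dropped_ff.append((f, NO_REFERENCE))
            else:
                nearest.setdefault(q, []).append((d, f))
        for q, cands in nearest.items():
            cands.sort()  # by rmsd then ff index
            d, f = cands[0]
            result.pairs.append((q, f, d))
            for dd, ff in cands[1:]:
                result.dropped_ff.append((ff, DUPLICATE))

    paired_qm = {q for q, _f, _r in result.pairs}
    result.dropped_qm = [q for q in range(n) if q not in paired_qm]
    result.pairs.sort()
    result.dropped_ff.sort()
    result.validate(n_qm=n, n_ff=n)
    return result
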