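"""Geometric agreement between conformers of one molecular graph.

Two metrics: the minimum RMSD over proper rigid motions and graph
automorphisms (hydrogens included by default), and a torsion fingerprint
deviation (TFD) in [0, 1] built from one dihedral per acyclic non-terminal
bond plus one pseudo-torsion per ring system, Gaussian-weighted by
topological distance from the molecule's bond-graph centre.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .errors import FFBenchError, MetricError
from .io_dataset import Conformer, MolecularGraph

__all__ = [
    "AutomorphismSet",
    "RmsdResult",
    "TorsionEntry",
    "TorsionSet",
    "kabsch_superpose",
    "min_rmsd_matrix",
    "enumerate_automorphisms",
    "best_rmsd",
    "dihedral_angle",
    "build_torsion_set",
    "tfd",
]

logger = logging.getLogger(__name__)

DEFAULT_AUTOMORPHISM_CAP = 10_000


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``coords_a`` onto ``coords_b``.

    Returns ``(rmsd, rotation, translation)`` such that
    ``coords_a @ rotation.T + translation`` is the optimal overlay. Only
    proper rotations are considered (no reflections).
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise FFBenchError(
            f"mismatched coordinate shapes {a.shape} vs {b.shape}"
        )
    if a.shape[0] < 1:
        raise FFBenchError("at least one atom is required")
    ca = a.mean(axis=0)
    cb = b.mean(axis=0)
    a0 = a - ca
    b0 = b - cb
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = (u @ np.diag([1.0, 1.0, d]) @ vt).T
    diff = a0 @ rot.T - b0
    rmsd = float(np.sqrt((diff**2).sum() / a.shape[0]))
    trans = cb - ca @ rot.T
    return rmsd, rot, trans


def _batched_min_rmsd(
    a: np.ndarray, b: np.ndarray, perms: np.ndarray, subset: Optional[np.ndarray]
) -> tuple[float, int]:
    """Minimum Kabsch RMSD of ``a`` vs ``b[perm]`` over a batch of perms.

    ``subset`` optionally restricts the fit to those atom rows (applied
    after permuting, valid because automorphisms map the subset onto
    itself). Returns (rmsd, argmin perm index).
    """
    bp = b[perms]  # (P, N, 3)
    if subset is not None:
        a = a[subset]
        bp = bp[:, subset, :]
    n = a.shape[0]
    a0 = a - a.mean(axis=0)
    bp0 = bp - bp.mean(axis=1, keepdims=True)
    h = np.einsum("ni,pnj->pij", a0, bp0)
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("pij,pjk->pik", u, vt))
    # proper-rotation correction: flip the smallest singular value's sign
    trace = s[:, 0] + s[:, 1] + det * s[:, 2]
    sq = (a0**2).sum() + (bp0**2).sum(axis=(1, 2)) - 2.0 * trace
    msd = np.maximum(sq, 0.0) / n
    idx = int(np.argmin(msd))
    return float(np.sqrt(msd[idx])), idx


def min_rmsd_matrix(
    coords_a: Sequence[np.ndarray],
    coords_b: Sequence[np.ndarray],
    perms: np.ndarray,
) -> np.ndarray:
    """Symmetry-minimized Kabsch RMSD for every (a, b) conformer pair.

    ``perms`` is an (P, N) automorphism array applied to the ``b`` side;
    returns a (len(a), len(b)) matrix. Vectorized over permutations and the
    ``a`` axis for use in conformer matching.
    """
    a = np.asarray(coords_a, dtype=float)  # (Q, N, 3)
    b = np.asarray(coords_b, dtype=float)  # (F, N, 3)
    q, n, _ = a.shape
    f = b.shape[0]
    a0 = a - a.mean(axis=1, keepdims=True)
    out = np.empty((q, f), dtype=float)
    sa = (a0**2).sum(axis=(1, 2))  # (Q,)
    for k in range(f):
        bp = b[k][perms]  # (P, N, 3)
        bp0 = bp - bp.mean(axis=1, keepdims=True)
        h = np.einsum("qni,pnj->qpij", a0, bp0)
        u, s, vt = np.linalg.svd(h)
        det = np.linalg.det(np.einsum("qpij,qpjk->qpik", u, vt))
        trace = s[..., 0] + s[..., 1] + det * s[..., 2]
        sq = sa[:, None] + (bp0**2).sum(axis=(1, 2))[None, :] - 2.0 * trace
        out[:, k] = np.sqrt(np.maximum(sq, 0.0).min(axis=1) / n)
    return out


# ---------------------------------------------------------------------------
# Graph automorphisms
# ---------------------------------------------------------------------------


@dataclass
class AutomorphismSet:
    """Label-preserving atom permutations; identity always first."""

    permutations: np.ndarray  # (P, N) int
    truncated: bool = False

    def __len__(self) -> int:
        return int(self.permutations.shape[0])


def _vf2_automorphisms(graph: MolecularGraph, cap: int) -> AutomorphismSet:
    g = graph.to_networkx()
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        g,
        g,
        node_match=lambda x, y: x["element"] == y["element"]
        and x["charge"] == y["charge"],
        edge_match=lambda x, y: x["order"] == y["order"],
    )
    n = graph.n_atoms
    identity = tuple(range(n))
    perms: list[tuple[int, ...]] = [identity]
    seen = {identity}
    truncated = False
    for mapping in matcher.isomorphisms_iter():
        perm = tuple(mapping[i] for i in range(n))
        if perm in seen:
            continue
        if len(perms) >= cap:
            truncated = True
            break
        perms.append(perm)
        seen.add(perm)
    return AutomorphismSet(
        permutations=np.array(perms, dtype=np.intp), truncated=truncated
    )


def enumerate_automorphisms(
    graph: MolecularGraph, cap: int = DEFAULT_AUTOMORPHISM_CAP
) -> AutomorphismSet:
    """All atom permutations preserving elements, charges and bond orders.

    Enumeration stops at ``cap`` permutations, in which case the result is
    flagged truncated; the identity permutation is always included first.

    The group is enumerated factored: VF2 runs on the leaf-pruned core
    (with per-node leaf profiles in the labels), and each core automorphism
    is extended by all consistent permutations of equivalent leaves. This
    is an exact decomposition: leaves (degree-1 atoms on a parent of higher
    degree) of equal element, charge and bond order attached to matching
    parents are freely interchangeable.
    """
    if cap < 1:
        raise FFBenchError("automorphism cap must be >= 1")
    n = graph.n_atoms
    g = graph.to_networkx()
    deg = dict(g.degree())
    order_of = {(min(i, j), max(i, j)): o for i, j, o in graph.bonds}

    leaves_of: dict[int, dict[tuple, list[int]]] = {}
    is_leaf = [False] * n
    for i in range(n):
        if deg[i] != 1:
            continue
        parent = next(iter(g[i]))
        if deg[parent] <= 1:
            continue
        is_leaf[i] = True
        label = (
            graph.atoms[i][0],
            graph.atoms[i][1],
            order_of[(min(i, parent), max(i, parent))],
        )
        leaves_of.setdefault(parent, {}).setdefault(label, []).append(i)
    core = [i for i in range(n) if not is_leaf[i]]
    if not core or len(core) == n:
        return _vf2_automorphisms(graph, cap)
    for classes in leaves_of.values():
        for members in classes.values():
            members.sort()

    core_g = nx.Graph()
    for i in core:
        profile = tuple(
            sorted(
                (label, len(members))
                for label, members in leaves_of.get(i, {}).items()
            )
        )
        core_g.add_node(
            i,
            element=graph.atoms[i][0],
            charge=graph.atoms[i][1],
            profile=profile,
        )
    for i, j, order in graph.bonds:
        if not is_leaf[i] and not is_leaf[j]:
            core_g.add_edge(i, j, order=order)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        core_g,
        core_g,
        node_match=lambda x, y: x["element"] == y["element"]
        and x["charge"] == y["charge"]
        and x["profile"] == y["profile"],
        edge_match=lambda x, y: x["order"] == y["order"],
    )
    identity_core = {i: i for i in core}
    core_autos = [identity_core]
    truncated = False
    for mapping in matcher.isomorphisms_iter():
        if mapping == identity_core:
            continue
        if len(core_autos) >= cap:
            truncated = True
            break
        core_autos.append(mapping)

    parents = sorted(leaves_of)
    perms: list[np.ndarray] = []
    done = False
    for core_map in core_autos:
        if done:
            break
        base = np.arange(n, dtype=np.intp)
        for i in core:
            base[i] = core_map[i]
        # per (parent, leaf class) bijections onto the image parent's class
        slots: list[list[int]] = []
        choice_sets: list[list[tuple[int, ...]]] = []
        for p in parents:
            q = core_map[p]
            for label, members in sorted(leaves_of[p].items()):
                targets = leaves_of[q][label]
                slots.append(members)
                choice_sets.append(list(itertools.permutations(targets)))
        for combo in itertools.product(*choice_sets):
            if len(perms) >= cap:
                truncated = True
                done = True
                break
            perm = base.copy()
            for members, assigned in zip(slots, combo):
                perm[members] = assigned
            perms.append(perm)
    return AutomorphismSet(
        permutations=np.array(perms, dtype=np.intp), truncated=truncated
    )


@dataclass
class RmsdResult:
    """Symmetry-minimized RMSD; an upper bound if enumeration truncated."""

    value: float
    upper_bound: bool = False
    best_permutation: Optional[np.ndarray] = None

    def __float__(self) -> float:
        return self.value


def best_rmsd(
    graph: MolecularGraph,
    conf_a: Conformer | np.ndarray,
    conf_b: Conformer | np.ndarray,
    include_hydrogens: bool = True,
    automorphisms: Optional[AutomorphismSet] = None,
    cap: int = DEFAULT_AUTOMORPHISM_CAP,
) -> RmsdResult:
    """Minimum Kabsch RMSD over the graph's automorphisms, in Angstrom.

    Hydrogens are included by default; with ``include_hydrogens=False`` the
    fit is restricted to heavy atoms (automorphisms are still derived from
    the full graph). A precomputed ``AutomorphismSet`` may be supplied to
    amortize enumeration across many pairs.
    """
    a = conf_a.coordinates if isinstance(conf_a, Conformer) else np.asarray(conf_a)
    b = conf_b.coordinates if isinstance(conf_b, Conformer) else np.asarray(conf_b)
    if a.shape[0] != graph.n_atoms or b.shape[0] != graph.n_atoms:
        raise FFBenchError("conformer atom count does not match graph")
    if automorphisms is None:
        automorphisms = enumerate_automorphisms(graph, cap=cap)
    subset = None
    if not include_hydrogens:
        heavy = np.array(graph.heavy_indices, dtype=np.intp)
        if heavy.size == 0:
            raise MetricError("no heavy atoms to superpose")
        subset = heavy
    value, idx = _batched_min_rmsd(a, b, automorphisms.permutations, subset)
    return RmsdResult(
        value=value,
        upper_bound=automorphisms.truncated,
        best_permutation=automorphisms.permutations[idx],
    )


# ---------------------------------------------------------------------------
# Torsion fingerprint deviation
# ---------------------------------------------------------------------------


def dihedral_angle(coords: np.ndarray, quad: Sequence[int]) -> Optional[float]:
    """Signed dihedral in degrees, wrapped to (-180, 180].

    Returns None for colinear quadruples, where the angle is undefined.
    """
    p = np.asarray(coords, dtype=float)[list(quad)]
    b0 = p[1] - p[0]
    b1 = p[2] - p[1]
    b2 = p[3] - p[2]
    n0 = np.cross(b0, b1)
    n1 = np.cross(b1, b2)
    if np.linalg.norm(n0) < 1e-10 or np.linalg.norm(n1) < 1e-10:
        return None
    b1n = b1 / np.linalg.norm(b1)
    x = n0 @ n1
    y = np.cross(n0, n1) @ b1n
    angle = float(np.degrees(np.arctan2(y, x)))
    if angle <= -180.0:
        angle += 360.0
    return angle


def _wrap(delta: float) -> float:
    """Wrap an angle difference into (-180, 180]."""
    wrapped = (delta + 180.0) % 360.0 - 180.0
    if wrapped == -180.0:
        wrapped = 180.0
    return wrapped


@dataclass(frozen=True)
class TorsionEntry:
    kind: str  # "dihedral" | "ring"
    quads: tuple[tuple[int, int, int, int], ...]  # one quad; rings may have many
    period: float  # degrees
    weight: float
    central_bond: tuple[int, int]


@dataclass
class TorsionSet:
    """Weighted (pseudo)torsion entries derived from one graph."""

    graph: MolecularGraph
    entries: tuple[TorsionEntry, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.entries)


def _side_symmetry(graph: MolecularGraph, center: int, exclude: int) -> int:
    """Rotational symmetry order contributed by ``center``'s substituents.

    n identical terminal substituents (same element and charge, degree 1)
    give n-fold symmetry, e.g. a methyl group gives 3.
    """
    g = graph.to_networkx()
    subs = [n for n in g.neighbors(center) if n != exclude]
    if len(subs) < 2:
        return 1
    labels = set()
    for s in subs:
        if g.degree(s) != 1:
            return 1
        labels.add((graph.atoms[s][0], graph.atoms[s][1]))
    return len(subs) if len(labels) == 1 else 1


def _ring_quads(system_nodes: set[int], g: nx.Graph) -> list[tuple[int, int, int, int]]:
    """Consecutive 4-windows around each basis cycle of a ring system."""
    sub = g.subgraph(system_nodes)
    quads: list[tuple[int, int, int, int]] = []
    seen = set()
    for cycle in nx.cycle_basis(sub):
        k = len(cycle)
        if k < 4:
            continue
        for i in range(k):
            quad = tuple(cycle[(i + j) % k] for j in range(4))
            key = min(quad, quad[::-1])
            if key not in seen:
                seen.add(key)
                quads.append(quad)
    return quads


def build_torsion_set(graph: MolecularGraph) -> TorsionSet:
    """Derive the molecule's torsion fingerprint definition.

    One dihedral per non-ring bond between two non-terminal atoms, with
    representative end atoms chosen by highest atomic number then lowest
    index, and a symmetry period from terminal-group topology; one
    pseudo-torsion per ring system. Weights are Gaussian in the topological
    distance of each entry's central bond from the bond-graph centre with
    sigma = max(1, bond-graph radius), normalized to sum to one.
    """
    g = graph.to_networkx()
    ring_bonds: set[tuple[int, int]] = set()
    ring_nodes: set[int] = set()
    for cycle in nx.cycle_basis(g):
        k = len(cycle)
        ring_nodes.update(cycle)
        for i in range(k):
            u, v = cycle[i], cycle[(i + 1) % k]
            ring_bonds.add((min(u, v), max(u, v)))

    def pick_end(center: int, exclude: int) -> int:
        cands = [n for n in g.neighbors(center) if n != exclude]
        return max(cands, key=lambda n: (graph.atomic_number(n), -n))

    entries: list[tuple[str, tuple, float, tuple[int, int]]] = []
    for i, j, _order in graph.bonds:
        b = (min(i, j), max(i, j))
        if b in ring_bonds:
            continue
        if g.degree(i) < 2 or g.degree(j) < 2:
            continue
        a = pick_end(i, j)
        d = pick_end(j, i)
        sym = max(_side_symmetry(graph, i, j), _side_symmetry(graph, j, i))
        period = 360.0 / sym
        entries.append(("dihedral", ((a, i, j, d),), period, b))

    # one pseudo-torsion per fused ring system
    ring_graph = nx.Graph()
    ring_graph.add_nodes_from(ring_nodes)
    for u, v in ring_bonds:
        ring_graph.add_edge(u, v)
    for component in nx.connected_components(ring_graph):
        quads = _ring_quads(component, g)
        if not quads:
            continue
        system_bonds = [
            (min(u, v), max(u, v))
            for u, v in ring_graph.subgraph(component).edges()
        ]
        entries.append(("ring", tuple(quads), 360.0, system_bonds))

    if not entries:
        return TorsionSet(graph=graph, entries=())

    # Gaussian weights in bond-graph (line graph) topological distance
    line = nx.Graph()
    all_bonds = [(min(i, j), max(i, j)) for i, j, _ in graph.bonds]
    line.add_nodes_from(all_bonds)
    for b1, b2 in itertools.combinations(all_bonds, 2):
        if set(b1) & set(b2):
            line.add_edge(b1, b2)
    if line.number_of_nodes() > 0 and nx.is_connected(line):
        ecc = nx.eccentricity(line)
        radius = min(ecc.values())
        centers = [n for n, e in ecc.items() if e == radius]
        dist = {}
        for c in centers:
            for node, d in nx.single_source_shortest_path_length(line, c).items():
                if node not in dist or d < dist[node]:
                    dist[node] = d
    else:
        radius = 0
        dist = {b: 0 for b in all_bonds}

    sigma = max(1.0, float(radius))
    raw = []
    finals: list[TorsionEntry] = []
    for kind, quads, period, central in entries:
        if kind == "dihedral":
            d = dist.get(central, 0)
            central_bond = central
        else:
            d = min(dist.get(b, 0) for b in central)
            central_bond = min(central, key=lambda b: dist.get(b, 0))
        raw.append(np.exp(-(d**2) / (2.0 * sigma**2)))
        finals.append(
            TorsionEntry(
                kind=kind,
                quads=quads,
                period=period,
                weight=0.0,
                central_bond=central_bond,
            )
        )
    weights = np.array(raw) / np.sum(raw)
    finals = [
        TorsionEntry(e.kind, e.quads, e.period, float(w), e.central_bond)
        for e, w in zip(finals, weights)
    ]
    return TorsionSet(graph=graph, entries=tuple(finals))


def _entry_deviation(
    entry: TorsionEntry, ca: np.ndarray, cb: np.ndarray
) -> float:
    if entry.kind == "dihedral":
        quad = entry.quads[0]
        ta = dihedral_angle(ca, quad)
        tb = dihedral_angle(cb, quad)
        if ta is None or tb is None:
            logger.warning(
                "colinear dihedral %s: deviation set to 0", quad
            )
            return 0.0
        delta = _wrap(ta - tb)
    else:
        diffs = []
        for quad in entry.quads:
            ta = dihedral_angle(ca, quad)
            tb = dihedral_angle(cb, quad)
            if ta is None or tb is None:
                logger.warning(
                    "colinear ring dihedral %s: skipped in pseudo-torsion", quad
                )
                continue
            diffs.append(_wrap(ta - tb))
        if not diffs:
            return 0.0
        delta = float(np.mean(diffs))
    x = abs(delta) % entry.period
    return min(x, entry.period - x) / (entry.period / 2.0)


def tfd(
    torsion_set: TorsionSet,
    conf_a: Conformer | np.ndarray,
    conf_b: Conformer | np.ndarray,
) -> float:
    """Torsion fingerprint deviation between two conformers, in [0, 1]."""
    if len(torsion_set) == 0:
        raise MetricError(
            "TFD is undefined: the molecule has no torsion entries"
        )
    ca = conf_a.coordinates if isinstance(conf_a, Conformer) else np.asarray(conf_a)
    cb = conf_b.coordinates if isinstance(conf_b, Conformer) else np.asarray(conf_b)
    n = torsion_set.graph.n_atoms
    if ca.shape[0] != n or cb.shape[0] != n:
        raise FFBenchError("conformer atom count does not match torsion set")
    score = 0.0
    for entry in torsion_set.entries:
        score += entry.weight * _entry_deviation(entry, ca, cb)
    return float(min(max(score, 0.0), 1.0))
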