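"""Synthetic benchmark datasets with known ground truth.

Generates valence-legal random molecules (C/N/O/S/F/Cl plus explicit
hydrogens), toy 3-D conformers, per-force-field perturbed geometries and
biased energies, occasional tautomer-flipped records and rare hydrogen-
collapse pathologies, plus a parameter-assignment table with planted
enrichment among high-torsion-kick molecules. Geometric realism is
deliberately minimal: the analysis contracts, not chemistry, are under
test. All randomness flows from one seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .errors import FFBenchError
from .io_dataset import (
    Conformer,
    MolecularGraph,
    StructureRecord,
    canonical_graph_key,
    write_conformer_sdf,
)
from .parameter_enrichment import ParameterAssignment

__all__ = [
    "COLLAPSE_ENERGY",
    "FFSpec",
    "EnrichmentSpec",
    "SynthConfig",
    "GroundTruth",
    "SyntheticBenchmark",
    "generate_benchmark",
    "perturb_conformer",
    "random_molecule",
    "embed_graph",
]

COLLAPSE_ENERGY = -1.0e6  # kcal/mol, planted hydrogen-collapse energy

_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "H": 1}
_ELEMENTS = ("C", "N", "O", "S", "F", "Cl")
_ELEMENT_WEIGHTS = (0.60, 0.15, 0.13, 0.04, 0.04, 0.04)


@dataclass
class FFSpec:
    """Planted statistical structure for one synthetic force field."""

    bias: float = 0.0  # b, kcal/mol, on relative conformer energies
    energy_noise: float = 0.5  # s, kcal/mol
    cart_sigma: float = 0.02  # Angstrom, per-coordinate displacement
    torsion_kick: float = 2.0  # degrees, std of per-bond kicks


@dataclass
class EnrichmentSpec:
    planted_ids: tuple[str, ...] = ("t_planted_1", "t_planted_2")
    planted_class: str = "proper torsion"
    target_subset_proportion: float = 0.8
    background_proportion: float = 0.3
    background_params: dict[str, int] = field(
        default_factory=lambda: {
            "bond": 8,
            "angle": 8,
            "proper torsion": 10,
            "improper torsion": 2,
            "vdW": 6,
        }
    )


@dataclass
class SynthConfig:
    seed: int
    n_molecules: int = 200
    heavy_atoms: tuple[int, int] = (4, 8)
    conformers: tuple[int, int] = (2, 8)
    force_fields: dict[str, FFSpec] = field(
        default_factory=lambda: {
            "ffA": FFSpec(bias=-1.0),
            "ffB": FFSpec(bias=0.0),
            "ffC": FFSpec(bias=2.0),
        }
    )
    tautomer_flip_rate: float = 0.05
    collapse_rate: float = 0.01
    collapse_ff: Optional[str] = None  # defaults to the first force field
    high_tfd_fraction: float = 0.3
    high_torsion_kick: float = 75.0  # degrees, std for high-kick molecules
    ring_probability: float = 0.4
    keto_probability: float = 0.9
    enrichment: EnrichmentSpec = field(default_factory=EnrichmentSpec)

    def __post_init__(self) -> None:
        for rate in (self.tautomer_flip_rate, self.collapse_rate,
                     self.high_tfd_fraction):
            if not 0.0 <= rate <= 1.0:
                raise FFBenchError("rates must lie in [0, 1]")
        if self.n_molecules < 1:
            raise FFBenchError("n_molecules must be >= 1")
        if self.heavy_atoms[0] < 2 or self.heavy_atoms[0] > self.heavy_atoms[1]:
            raise FFBenchError("invalid heavy-atom range")
        if self.conformers[0] < 1 or self.conformers[0] > self.conformers[1]:
            raise FFBenchError("invalid conformer range")
        for spec in self.force_fields.values():
            if spec.cart_sigma < 0 or spec.energy_noise < 0:
                raise FFBenchError("sigma and noise must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path) as handle:
            payload = yaml.safe_load(handle)
        if "force_fields" in payload:
            payload["force_fields"] = {
                name: FFSpec(**spec)
                for name, spec in payload["force_fields"].items()
            }
        if "enrichment" in payload:
            payload["enrichment"] = EnrichmentSpec(**payload["enrichment"])
        for key in ("heavy_atoms", "conformers"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Everything planted: recoverable by downstream analysis stages."""

    ff_params: dict[str, dict[str, float]]
    molecule_keys: list[str]
    flipped_titles: list[str]
    flipped_keys: list[str]
    collapse_records: list[dict[str, str]]  # {title, ff_id, key}
    planted_parameter_ids: list[str]
    high_kick_keys: list[str]
    n_molecules: int
    n_records: int

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(dataclasses.asdict(self), handle, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as handle:
            return cls(**json.load(handle))


# ---------------------------------------------------------------------------
# Random molecule construction
# ---------------------------------------------------------------------------


def _grow_heavy_skeleton(
    rng: np.random.Generator, n_heavy: int, ring_probability: float,
    keto_probability: float,
) -> tuple[list[str], list[tuple[int, int, int]], Optional[tuple[int, int, int]]]:
    elements = ["C"]
    bonds: list[tuple[int, int, int]] = []
    free = [4]
    for _ in range(n_heavy - 1):
        hosts = [i for i, f in enumerate(free) if f >= 1]
        host = int(rng.choice(hosts))
        sym = str(rng.choice(_ELEMENTS, p=_ELEMENT_WEIGHTS))
        elements.append(sym)
        idx = len(elements) - 1
        free.append(_VALENCE[sym] - 1)
        free[host] -= 1
        bonds.append((host, idx, 1))

    motif = None
    if rng.random() < keto_probability:
        # alpha-C(H)-C(=O): the alpha carbon keeps a free valence for H
        alphas = [
            i for i, (s, f) in enumerate(zip(elements, free))
            if s == "C" and f >= 2
        ]
        if alphas:
            alpha = int(rng.choice(alphas))
            ck = len(elements)
            elements.append("C")
            free.append(4 - 1)
            free[alpha] -= 1
            bonds.append((alpha, ck, 1))
            ox = len(elements)
            elements.append("O")
            free.append(0)
            free[ck] -= 2
            bonds.append((ck, ox, 2))
            motif = (alpha, ck, ox)

    if rng.random() < ring_probability:
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(elements)))
        g.add_edges_from((i, j) for i, j, _ in bonds)
        lengths = dict(nx.all_pairs_shortest_path_length(g))
        candidates = [
            (i, j)
            for i in range(len(elements))
            for j in range(i + 1, len(elements))
            if free[i] >= 1 and free[j] >= 1 and 3 <= lengths[i].get(j, 99) <= 5
        ]
        if candidates:
            i, j = candidates[int(rng.integers(len(candidates)))]
            bonds.append((i, j, 1))
            free[i] -= 1
            free[j] -= 1

    # explicit hydrogens fill every remaining valence
    n = len(elements)
    for i in range(n):
        for _ in range(free[i]):
            elements.append("H")
            bonds.append((i, len(elements) - 1, 1))
    return elements, bonds, motif


def random_molecule(
    rng: np.random.Generator,
    n_heavy: int,
    ring_probability: float = 0.4,
    keto_probability: float = 0.9,
    title: str = "",
) -> tuple[MolecularGraph, Optional[tuple[int, int, int]]]:
    """One valence-legal random molecule with explicit hydrogens.

    Returns the graph plus the keto motif atom triple (alpha C, carbonyl C,
    O) when one was planted, for use by the tautomer flip.
    """
    elements, bonds, motif = _grow_heavy_skeleton(
        rng, n_heavy, ring_probability, keto_probability
    )
    atoms = tuple((sym, 0, None) for sym in elements)
    graph = MolecularGraph(atoms=atoms, bonds=tuple(bonds), title=title)
    return graph, motif


# ---------------------------------------------------------------------------
# Toy 3-D embedding and torsion perturbation
# ---------------------------------------------------------------------------

_BOND_LENGTH = {1: 1.5, 2: 1.35, 3: 1.2, 4: 1.4}


def _ideal_length(graph: MolecularGraph, i: int, j: int, order: int) -> float:
    if graph.atoms[i][0] == "H" or graph.atoms[j][0] == "H":
        return 1.05
    return _BOND_LENGTH[order]


def _relax(
    graph: MolecularGraph, coords: np.ndarray, steps: int = 120, lr: float = 0.05
) -> np.ndarray:
    """Gradient steps on a toy potential: harmonic bonds + soft repulsion."""
    n = graph.n_atoms
    bonds = [(i, j, _ideal_length(graph, i, j, o)) for i, j, o in graph.bonds]
    bonded = np.zeros((n, n), dtype=bool)
    for i, j, _ in graph.bonds:
        bonded[i, j] = bonded[j, i] = True
    np.fill_diagonal(bonded, True)
    x = coords.copy()
    for _ in range(steps):
        force = np.zeros_like(x)
        for i, j, r0 in bonds:
            d = x[j] - x[i]
            r = np.linalg.norm(d) + 1e-12
            f = (r - r0) * d / r
            force[i] += f
            force[j] -= f
        diff = x[None, :, :] - x[:, None, :]
        dist = np.linalg.norm(diff, axis=-1) + 1e-12
        close = (~bonded) & (dist < 2.0)
        if close.any():
            push = np.where(close, (2.0 - dist) / dist, 0.0)
            force -= (push[:, :, None] * diff).sum(axis=1) * 0.5
        x += lr * force
    return x


def embed_graph(graph: MolecularGraph, rng: np.random.Generator) -> np.ndarray:
    """Rough 3-D coordinates: BFS placement plus toy-potential relaxation."""
    n = graph.n_atoms
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for i, j, o in graph.bonds:
        adj[i].append((j, o))
        adj[j].append((i, o))
    coords = np.zeros((n, 3))
    placed = [False] * n
    coords[0] = 0.0
    placed[0] = True
    queue = [0]
    while queue:
        cur = queue.pop(0)
        for nbr, order in adj[cur]:
            if placed[nbr]:
                continue
            direction = rng.normal(size=3)
            # bias away from already-placed neighbours of cur
            for other, _ in adj[cur]:
                if placed[other] and other != nbr:
                    direction += 0.8 * (coords[cur] - coords[other])
            direction /= np.linalg.norm(direction) + 1e-12
            coords[nbr] = coords[cur] + _ideal_length(
                graph, cur, nbr, order
            ) * direction
            placed[nbr] = True
            queue.append(nbr)
    return _relax(graph, coords)


def _rotatable_bonds(graph: MolecularGraph) -> list[tuple[int, int]]:
    import networkx as nx

    g = graph.to_networkx()
    ring_bonds = set()
    for cycle in nx.cycle_basis(g):
        k = len(cycle)
        for i in range(k):
            u, v = cycle[i], cycle[(i + 1) % k]
            ring_bonds.add((min(u, v), max(u, v)))
    out = []
    for i, j, _ in graph.bonds:
        b = (min(i, j), max(i, j))
        if b in ring_bonds:
            continue
        if g.degree(i) >= 2 and g.degree(j) >= 2:
            out.append(b)
    return out


def _moving_side(graph: MolecularGraph, bond: tuple[int, int]) -> list[int]:
    import networkx as nx

    g = graph.to_networkx()
    g.remove_edge(*bond)
    return sorted(nx.node_connected_component(g, bond[1]))


def _rotate_about_bond(
    coords: np.ndarray, bond: tuple[int, int], moving: Sequence[int], angle_deg: float
) -> np.ndarray:
    b, c = bond
    axis = coords[c] - coords[b]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        return coords
    axis = axis / norm
    theta = np.radians(angle_deg)
    k = axis
    out = coords.copy()
    moving = [m for m in moving if m != c]
    v = out[moving] - coords[c]
    cos, sin = np.cos(theta), np.sin(theta)
    rotated = (
        v * cos
        + np.cross(k, v) * sin
        + np.outer(v @ k, k) * (1.0 - cos)
    )
    out[moving] = rotated + coords[c]
    return out


def _apply_torsion_kicks(
    graph: MolecularGraph,
    coords: np.ndarray,
    kicks: Sequence[tuple[tuple[int, int], float]],
) -> np.ndarray:
    out = coords
    for bond, angle in kicks:
        if angle == 0.0:
            continue
        moving = _moving_side(graph, bond)
        out = _rotate_about_bond(out, bond, moving, angle)
    return out


def perturb_conformer(
    graph: MolecularGraph,
    conformer: Conformer,
    sigma: float,
    torsion_kicks: float | Sequence[tuple[tuple[int, int], float]] = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Conformer:
    """Torsion kicks plus isotropic Cartesian noise on a conformer.

    ``torsion_kicks`` is either a standard deviation in degrees (a random
    kick is drawn for every rotatable bond) or an explicit sequence of
    ``((i, j), angle)`` rotations. ``sigma`` is the per-coordinate Normal
    displacement in Angstrom. With ``sigma=0`` and no kicks the conformer
    is returned unchanged (copied).
    """
    if sigma < 0:
        raise FFBenchError("sigma must be >= 0")
    if rng is None:
        rng = np.random.default_rng(0)
    coords = conformer.coordinates.copy()
    if isinstance(torsion_kicks, (int, float)):
        std = float(torsion_kicks)
        kicks = [
            (bond, float(rng.normal(0.0, std)) if std > 0 else 0.0)
            for bond in _rotatable_bonds(graph)
        ]
    else:
        kicks = [(tuple(b), float(a)) for b, a in torsion_kicks]
    coords = _apply_torsion_kicks(graph, coords, kicks)
    if sigma > 0:
        coords = coords + rng.normal(0.0, sigma, size=coords.shape)
    return Conformer(coords, conformer.energy, source=conformer.source)


# ---------------------------------------------------------------------------
# Tautomer flip (keto -> enol on the planted motif)
# ---------------------------------------------------------------------------


def _tautomer_flip(
    graph: MolecularGraph, coords: np.ndarray, motif: tuple[int, int, int]
) -> Optional[tuple[MolecularGraph, np.ndarray]]:
    alpha, ck, ox = motif
    h_on_alpha = None
    for i, j, o in graph.bonds:
        if o != 1:
            continue
        if i == alpha and graph.atoms[j][0] == "H":
            h_on_alpha = j
            break
        if j == alpha and graph.atoms[i][0] == "H":
            h_on_alpha = i
            break
    if h_on_alpha is None:
        return None
    new_bonds = []
    for i, j, o in graph.bonds:
        pair = {i, j}
        if pair == {alpha, h_on_alpha}:
            new_bonds.append((ox, h_on_alpha, 1))
        elif pair == {alpha, ck}:
            new_bonds.append((i, j, 2))
        elif pair == {ck, ox}:
            new_bonds.append((i, j, 1))
        else:
            new_bonds.append((i, j, o))
    flipped = MolecularGraph(
        atoms=graph.atoms, bonds=tuple(new_bonds), title=graph.title
    )
    new_coords = coords.copy()
    direction = coords[ox] - coords[ck]
    direction /= np.linalg.norm(direction) + 1e-12
    new_coords[h_on_alpha] = coords[ox] + 0.97 * direction
    return flipped, new_coords


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticBenchmark:
    """In-memory dataset plus ground truth; writable as plain-text files."""

    config: SynthConfig
    records: list[StructureRecord]
    assignment: ParameterAssignment
    truth: GroundTruth

    @property
    def ff_ids(self) -> tuple[str, ...]:
        return tuple(self.config.force_fields)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_conformer_sdf(
            out / "qm.sdf", [(r.graph, r.qm) for r in self.records]
        )
        for ff_id in self.ff_ids:
            write_conformer_sdf(
                out / f"ff_{ff_id}.sdf",
                [(r.graph, r.ff_results[ff_id]) for r in self.records],
            )
        self.assignment.to_csv(out / "assignments.csv")
        self.truth.to_json(out / "truth.json")


def _assign_parameters(
    rng: np.random.Generator,
    spec: EnrichmentSpec,
    molecule_keys: Sequence[str],
    high_kick_keys: set[str],
) -> ParameterAssignment:
    prefix = {
        "bond": "b",
        "angle": "a",
        "proper torsion": "t",
        "improper torsion": "i",
        "vdW": "n",
    }
    background: list[tuple[str, str, float]] = []
    for cls, count in spec.background_params.items():
        for k in range(count):
            pid = f"{prefix[cls]}{k + 1:02d}"
            prevalence = float(rng.uniform(0.1, 0.7))
            background.append((pid, cls, prevalence))

    by_molecule: dict[str, set[str]] = {k: set() for k in molecule_keys}
    classes: dict[str, str] = {}
    for pid, cls, prevalence in background:
        classes[pid] = cls
        for key in molecule_keys:
            if rng.random() < prevalence:
                by_molecule[key].add(pid)
    for pid in spec.planted_ids:
        classes[pid] = spec.planted_class
        for key in molecule_keys:
            p = (
                spec.target_subset_proportion
                if key in high_kick_keys
                else spec.background_proportion
            )
            if rng.random() < p:
                by_molecule[key].add(pid)
    return ParameterAssignment(by_molecule=by_molecule, classes=classes)


def generate_benchmark(config: SynthConfig) -> SyntheticBenchmark:
    """Generate a complete benchmark dataset with known ground truth.

    Base molecule keys are guaranteed pairwise distinct and tautomer-flip
    keys distinct from everything else, so the molecule-group count equals
    ``n_molecules`` plus the number of planted flips exactly. Collapse
    pathologies are planted only on non-reference conformers so that ddE
    anchoring is unaffected.
    """
    root = np.random.SeedSequence(config.seed)
    mol_ss, conf_ss, energy_ss, assign_ss, patho_ss = root.spawn(5)
    mol_rng = np.random.default_rng(mol_ss)
    conf_rng = np.random.default_rng(conf_ss)
    energy_rng = np.random.default_rng(energy_ss)
    assign_rng = np.random.default_rng(assign_ss)
    patho_rng = np.random.default_rng(patho_ss)

    ff_ids = tuple(config.force_fields)
    collapse_ff = config.collapse_ff or ff_ids[0]
    if collapse_ff not in config.force_fields:
        raise FFBenchError(f"collapse_ff {collapse_ff!r} is not a force field")

    # --- molecules, unique by constitutional key -------------------------
    molecules: list[tuple[MolecularGraph, Optional[tuple[int, int, int]]]] = []
    base_keys: list[str] = []
    seen_keys: set[str] = set()
    lo, hi = config.heavy_atoms
    for _m in range(config.n_molecules):
        for _attempt in range(100):
            n_heavy = int(mol_rng.integers(lo, hi + 1))
            graph, motif = random_molecule(
                mol_rng,
                n_heavy,
                ring_probability=config.ring_probability,
                keto_probability=config.keto_probability,
            )
            key = canonical_graph_key(graph)
            if key in seen_keys:
                continue
            # require conformational freedom: at least one rotatable bond
            # (implies a non-empty torsion set downstream)
            if not _rotatable_bonds(graph):
                continue
            seen_keys.add(key)
            molecules.append((graph, motif))
            base_keys.append(key)
            break
        else:
            raise FFBenchError(
                "could not generate enough unique molecules; widen the "
                "heavy-atom range"
            )

    n_high = int(round(config.high_tfd_fraction * config.n_molecules))
    high_idx = set(
        int(i)
        for i in mol_rng.choice(config.n_molecules, size=n_high, replace=False)
    ) if n_high else set()
    high_kick_keys = {base_keys[i] for i in high_idx}

    # --- conformers, flips, energies, FF perturbations -------------------
    records: list[StructureRecord] = []
    flipped_titles: list[str] = []
    flipped_keys: list[str] = []
    collapse_records: list[dict[str, str]] = []
    all_emitted_keys: list[str] = []

    for m, (graph, motif) in enumerate(molecules):
        n_conf = int(conf_rng.integers(config.conformers[0],
                                       config.conformers[1] + 1))
        base_coords = embed_graph(graph, conf_rng)
        rot_bonds = _rotatable_bonds(graph)
        qm_energies = energy_rng.normal(0.0, 2.0, size=n_conf)
        mol_offset = float(energy_rng.normal(0.0, 1.0))
        ref = int(np.argmin(qm_energies))

        # at most one flip per molecule, never the QM-minimum conformer
        flip_conf = None
        if (
            motif is not None
            and n_conf >= 2
            and mol_rng.random() < config.tautomer_flip_rate
        ):
            candidates = [j for j in range(n_conf) if j != ref]
            flip_conf = int(mol_rng.choice(candidates))

        mol_records: list[StructureRecord] = []
        for j in range(n_conf):
            title = f"mol{m:04d}_conf{j:02d}"
            coords = base_coords
            if rot_bonds:
                kicks = [
                    (b, float(conf_rng.uniform(-180.0, 180.0)))
                    for b in rot_bonds
                ]
                coords = _apply_torsion_kicks(graph, coords, kicks)
            rec_graph = MolecularGraph(
                atoms=graph.atoms, bonds=graph.bonds, title=title
            )
            rec_coords = coords
            if j == flip_conf:
                flip = _tautomer_flip(graph, coords, motif)
                if flip is not None:
                    fg, fc = flip
                    fkey = canonical_graph_key(fg)
                    if fkey not in seen_keys:
                        seen_keys.add(fkey)
                        rec_graph = MolecularGraph(
                            atoms=fg.atoms, bonds=fg.bonds, title=title
                        )
                        rec_coords = fc
                        flipped_titles.append(title)
                        flipped_keys.append(fkey)

            record = StructureRecord(
                graph=rec_graph,
                qm=Conformer(rec_coords, float(qm_energies[j]), source="QM"),
            )
            mol_records.append(record)

        for ff_id in ff_ids:
            spec = config.force_fields[ff_id]
            kick = (
                config.high_torsion_kick
                if m in high_idx
                else spec.torsion_kick
            )
            for j, record in enumerate(mol_records):
                # bias + noise act on relative energies: the molecule's
                # reference conformer carries only the arbitrary offset
                if j == ref:
                    energy = float(qm_energies[j] + mol_offset)
                else:
                    energy = float(
                        qm_energies[j]
                        + mol_offset
                        + spec.bias
                        + energy_rng.normal(0.0, spec.energy_noise)
                    )
                conf = perturb_conformer(
                    record.graph,
                    Conformer(record.qm.coordinates, energy, source=ff_id),
                    sigma=spec.cart_sigma,
                    torsion_kicks=kick,
                    rng=conf_rng,
                )
                record.ff_results[ff_id] = conf

        # hydrogen-collapse pathology: non-reference, non-flipped records
        for j, record in enumerate(mol_records):
            if j == ref or j == flip_conf or n_conf < 2:
                continue
            if patho_rng.random() < config.collapse_rate:
                conf = record.ff_results[collapse_ff]
                h_atoms = [
                    i for i, a in enumerate(record.graph.atoms) if a[0] == "H"
                ]
                if not h_atoms:
                    continue
                h = h_atoms[int(patho_rng.integers(len(h_atoms)))]
                parent = record.graph.neighbors(h)[0]
                direction = patho_rng.normal(size=3)
                direction /= np.linalg.norm(direction) + 1e-12
                coords = conf.coordinates.copy()
                coords[h] = coords[parent] + 0.05 * direction
                record.ff_results[collapse_ff] = Conformer(
                    coords, COLLAPSE_ENERGY, source=collapse_ff
                )
                collapse_records.append(
                    {
                        "title": record.title,
                        "ff_id": collapse_ff,
                        "key": canonical_graph_key(record.graph),
                    }
                )

        records.extend(mol_records)

    all_emitted_keys = base_keys + flipped_keys
    assignment = _assign_parameters(
        assign_rng, config.enrichment, all_emitted_keys, high_kick_keys
    )

    truth = GroundTruth(
        ff_params={
            ff_id: {
                "bias": spec.bias,
                "energy_noise": spec.energy_noise,
                "cart_sigma": spec.cart_sigma,
                "torsion_kick": spec.torsion_kick,
            }
            for ff_id, spec in config.force_fields.items()
        },
        molecule_keys=list(base_keys),
        flipped_titles=flipped_titles,
        flipped_keys=flipped_keys,
        collapse_records=collapse_records,
        planted_parameter_ids=list(config.enrichment.planted_ids),
        high_kick_keys=sorted(high_kick_keys),
        n_molecules=config.n_molecules,
        n_records=len(records),
    )
    return SyntheticBenchmark(
        config=config, records=records, assignment=assignment, truth=truth
    )
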