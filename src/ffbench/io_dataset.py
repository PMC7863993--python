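"""Conformer ensemble I/O and molecule identity.

Reads/writes V2000 SDF files carrying per-record energies in data tags,
derives a canonical connectivity key per molecular graph, and partitions
structure records into molecule groups keyed on that identity. Identity is
taken from the explicit SDF bond table (never perceived from coordinates),
so two records are the same molecule iff their element/charge/bond-order
labelled graphs are isomorphic; tautomers therefore land in distinct groups.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

from .errors import GraphError, ParseError

RDLogger.DisableLog("rdApp.warning")

__all__ = [
    "AROMATIC",
    "HARTREE_TO_KCALMOL",
    "DEFAULT_ENERGY_TAG",
    "MolecularGraph",
    "Conformer",
    "StructureRecord",
    "MoleculeGroup",
    "GroupingResult",
    "read_conformer_sdf",
    "write_conformer_sdf",
    "canonical_graph_key",
    "build_records",
    "group_by_identity",
    "group_manifest",
]

#: SDF bond-order code used for aromatic bonds (stored verbatim in bonds).
AROMATIC = 4

#: Energy unit conversion offered for upstream convenience; never applied
#: implicitly anywhere in this package.
HARTREE_TO_KCALMOL = 627.509474

DEFAULT_ENERGY_TAG = "ENERGY_KCAL"

_VALID_ORDERS = (1, 2, 3, AROMATIC)

_PT = Chem.GetPeriodicTable()

_BOND_TYPE = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    AROMATIC: Chem.BondType.AROMATIC,
}


@dataclass(frozen=True)
class MolecularGraph:
    """Element/charge/bond-order labelled molecular graph.

    ``atoms`` is a tuple of ``(element, formal_charge, stereo)`` triples where
    ``stereo`` is an optional SDF parity flag (``None`` when absent). ``bonds``
    is a tuple of ``(i, j, order)`` with ``order`` in {1, 2, 3, AROMATIC}.
    """

    atoms: tuple[tuple[str, int, Optional[int]], ...]
    bonds: tuple[tuple[int, int, int], ...]
    title: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n == 0:
            raise GraphError("graph has no atoms")
        for sym, charge, stereo in self.atoms:
            try:
                if _PT.GetAtomicNumber(sym) == 0:
                    raise GraphError(f"unknown element symbol {sym!r}")
            except RuntimeError:
                raise GraphError(f"unknown element symbol {sym!r}") from None
        seen = set()
        for i, j, order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise GraphError(f"bond ({i}, {j}) out of range for {n} atoms")
            if order not in _VALID_ORDERS:
                raise GraphError(f"unsupported bond order {order!r}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise GraphError(f"duplicate bond {key}")
            seen.add(key)
        if n > 1:
            if not nx.is_connected(self.to_networkx()):
                raise GraphError(
                    f"graph {self.title!r} is disconnected; "
                    "multi-molecule records are unsupported"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(a[0] for a in self.atoms)

    def atomic_number(self, i: int) -> int:
        return _PT.GetAtomicNumber(self.atoms[i][0])

    @property
    def heavy_indices(self) -> tuple[int, ...]:
        return tuple(i for i, a in enumerate(self.atoms) if a[0] != "H")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, (sym, charge, _stereo) in enumerate(self.atoms):
            g.add_node(i, element=sym, charge=charge)
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out


@dataclass
class Conformer:
    """One 3-D geometry with an energy in kcal/mol and a source label."""

    coordinates: np.ndarray  # (N, 3) in Angstrom
    energy: float
    source: str = "QM"

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise GraphError("coordinates must have shape (N, 3)")
        if np.isnan(self.coordinates).any():
            raise GraphError("NaN coordinates are forbidden")

    @property
    def n_atoms(self) -> int:
        return int(self.coordinates.shape[0])


@dataclass
class StructureRecord:
    """A QM-optimized conformer plus its per-force-field minimized results."""

    graph: MolecularGraph
    qm: Conformer
    ff_results: dict[str, Conformer] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.qm.n_atoms != self.graph.n_atoms:
            raise GraphError(
                f"record {self.graph.title!r}: QM conformer has "
                f"{self.qm.n_atoms} atoms, graph has {self.graph.n_atoms}"
            )
        for ff_id, conf in self.ff_results.items():
            if conf.n_atoms != self.graph.n_atoms:
                raise GraphError(
                    f"record {self.graph.title!r}: {ff_id} conformer atom "
                    "count does not match graph"
                )

    @property
    def title(self) -> str:
        return self.graph.title


@dataclass
class MoleculeGroup:
    """All structure records sharing one canonical connectivity key."""

    key: str
    records: list[StructureRecord]
    reference_index: int = 0

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def graph(self) -> MolecularGraph:
        return self.records[0].graph

    @property
    def qm_energies(self) -> np.ndarray:
        return np.array([r.qm.energy for r in self.records], dtype=float)


@dataclass
class GroupingResult:
    """Groups plus the records dropped for lacking a dataset-wide FF."""

    groups: list[MoleculeGroup]
    dropped: list[tuple[StructureRecord, str]]
    ff_ids: tuple[str, ...]


# ---------------------------------------------------------------------------
# SDF reading / writing
# ---------------------------------------------------------------------------

_TAG_RE = re.compile(r">\s*<(?P<tag>[^>]+)>")


def _split_sdf(text: str) -> list[str]:
    records = []
    current: list[str] = []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            records.append("\n".join(current))
            current = []
        else:
            current.append(line)
    if any(l.strip() for l in current):
        records.append("\n".join(current))
    return records


def _parse_data_tags(tail: str) -> dict[str, str]:
    tags: dict[str, str] = {}
    lines = tail.splitlines()
    i = 0
    while i < len(lines):
        m = _TAG_RE.match(lines[i])
        if m:
            values = []
            i += 1
            while i < len(lines) and lines[i].strip() != "":
                values.append(lines[i])
                i += 1
            tags[m.group("tag")] = "\n".join(values)
        else:
            i += 1
    return tags


def _graph_from_molblock(block: str, index: int) -> tuple[MolecularGraph, np.ndarray]:
    mol = Chem.MolFromMolBlock(
        block, sanitize=False, removeHs=False, strictParsing=False
    )
    if mol is None or mol.GetNumAtoms() == 0:
        raise ParseError(f"malformed SDF record {index}: mol block unreadable")

    # Stereo parity lives in columns 39-42 of each atom line; RDKit does not
    # surface it without sanitization, so pull it from the raw text.
    lines = block.splitlines()
    n_atoms = mol.GetNumAtoms()
    parities: list[Optional[int]] = []
    atom_lines = lines[4 : 4 + n_atoms]
    for line in atom_lines:
        try:
            parity = int(line[39:42])
        except (ValueError, IndexError):
            parity = 0
        parities.append(parity if parity in (1, 2) else None)

    atoms = tuple(
        (atom.GetSymbol(), atom.GetFormalCharge(), parities[atom.GetIdx()])
        for atom in mol.GetAtoms()
    )
    order_of = {
        Chem.BondType.SINGLE: 1,
        Chem.BondType.DOUBLE: 2,
        Chem.BondType.TRIPLE: 3,
        Chem.BondType.AROMATIC: AROMATIC,
    }
    bonds = []
    for bond in mol.GetBonds():
        try:
            order = order_of[bond.GetBondType()]
        except KeyError:
            raise ParseError(
                f"malformed SDF record {index}: unsupported bond type "
                f"{bond.GetBondType()}"
            ) from None
        bonds.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order))

    title = lines[0].strip() if lines else ""
    coords = mol.GetConformer().GetPositions().astype(float)
    try:
        graph = MolecularGraph(atoms=atoms, bonds=tuple(bonds), title=title)
    except GraphError as exc:
        raise ParseError(f"malformed SDF record {index}: {exc}") from exc
    return graph, coords


def read_conformer_sdf(
    path,
    energy_tag: str = DEFAULT_ENERGY_TAG,
    source: str = "QM",
) -> list[tuple[MolecularGraph, Conformer]]:
    """Read a V2000 SDF into ``(graph, conformer)`` pairs in file order.

    Each record must carry ``energy_tag`` as a data tag parseable as a
    decimal energy in kcal/mol.
    """
    with open(path) as handle:
        text = handle.read()
    out = []
    for index, record in enumerate(_split_sdf(text)):
        if "M  END" not in record:
            raise ParseError(f"malformed SDF record {index}: no 'M  END' line")
        head, _, tail = record.partition("M  END")
        graph, coords = _graph_from_molblock(head + "M  END", index)
        tags = _parse_data_tags(tail)
        if energy_tag not in tags:
            raise ParseError(
                f"SDF record {index} ({graph.title!r}) is missing the "
                f"energy tag <{energy_tag}>"
            )
        try:
            energy = float(tags[energy_tag].strip())
        except ValueError:
            raise ParseError(
                f"SDF record {index}: energy tag <{energy_tag}> value "
                f"{tags[energy_tag]!r} is not a decimal number"
            ) from None
        out.append((graph, Conformer(coords, energy, source=source)))
    return out


def _format_molblock(graph: MolecularGraph, coords: np.ndarray) -> str:
    lines = [graph.title, "  ffbench           3D", ""]
    lines.append(
        f"{graph.n_atoms:3d}{len(graph.bonds):3d}  0  0  0  0  0  0  0  0999 V2000"
    )
    for (sym, _charge, stereo), (x, y, z) in zip(graph.atoms, coords):
        parity = stereo if stereo is not None else 0
        lines.append(
            f"{x:10.4f}{y:10.4f}{z:10.4f} {sym:<3s} 0  0{parity:3d}  0  0  0  0  0  0  0  0  0"
        )
    for i, j, order in graph.bonds:
        lines.append(f"{i + 1:3d}{j + 1:3d}{order:3d}  0  0  0  0")
    charged = [(i, c) for i, (_s, c, _p) in enumerate(graph.atoms) if c != 0]
    for start in range(0, len(charged), 8):
        chunk = charged[start : start + 8]
        line = f"M  CHG{len(chunk):3d}"
        for i, c in chunk:
            line += f"{i + 1:4d}{c:4d}"
        lines.append(line)
    lines.append("M  END")
    return "\n".join(lines)


def write_conformer_sdf(
    path,
    entries: Iterable[tuple[MolecularGraph, Conformer]],
    energy_tag: str = DEFAULT_ENERGY_TAG,
) -> None:
    """Write ``(graph, conformer)`` pairs as a V2000 SDF with energy tags.

    Coordinates are printed at the format's standard %10.4f precision;
    energies are printed with ``repr`` so they survive a read round-trip
    bit-identically as floats.
    """
    chunks = []
    for graph, conf in entries:
        if conf.n_atoms != graph.n_atoms:
            raise GraphError(
                f"record {graph.title!r}: conformer/graph atom count mismatch"
            )
        block = _format_molblock(graph, conf.coordinates)
        chunks.append(
            f"{block}\n> <{energy_tag}>\n{conf.energy!r}\n\n$$$$\n"
        )
    with open(path, "w") as handle:
        handle.write("".join(chunks))


# ---------------------------------------------------------------------------
# Canonical identity and grouping
# ---------------------------------------------------------------------------


def _to_rdkit(graph: MolecularGraph, use_stereo: bool) -> Chem.Mol:
    mol = Chem.RWMol()
    for sym, charge, stereo in graph.atoms:
        atom = Chem.Atom(sym)
        atom.SetFormalCharge(charge)
        atom.SetNoImplicit(True)
        if use_stereo and stereo == 1:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CW)
        elif use_stereo and stereo == 2:
            atom.SetChiralTag(Chem.ChiralType.CHI_TETRAHEDRAL_CCW)
        mol.AddAtom(atom)
    for i, j, order in graph.bonds:
        mol.AddBond(i, j, _BOND_TYPE[order])
        if order == AROMATIC:
            mol.GetBondBetweenAtoms(i, j).SetIsAromatic(True)
            mol.GetAtomWithIdx(i).SetIsAromatic(True)
            mol.GetAtomWithIdx(j).SetIsAromatic(True)
    mol = mol.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    return mol


def canonical_graph_key(graph: MolecularGraph, use_stereo: bool = True) -> str:
    """Canonical text key; equal keys iff the labelled graphs are isomorphic.

    Stereo parity flags participate when present and ``use_stereo`` is True;
    with ``use_stereo=False`` the key is purely constitutional.
    """
    if graph.n_atoms > 1 and not nx.is_connected(graph.to_networkx()):
        raise GraphError("disconnected graph: multi-molecule records unsupported")
    mol = _to_rdkit(graph, use_stereo=use_stereo)
    return Chem.MolToSmiles(mol, canonical=True)


def build_records(
    qm_entries: Sequence[tuple[MolecularGraph, Conformer]],
    ff_entries: Mapping[str, Sequence[tuple[MolecularGraph, Conformer]]],
) -> list[StructureRecord]:
    """Assemble structure records by aligning QM and FF files.

    Alignment is by record title when every title is unique and present in
    both files, otherwise by record order; any mismatch is an error.
    """
    records = [
        StructureRecord(graph=g, qm=c, ff_results={}) for g, c in qm_entries
    ]
    qm_titles = [r.title for r in records]
    titles_usable = len(set(qm_titles)) == len(qm_titles) and all(qm_titles)
    by_title = {r.title: r for r in records} if titles_usable else {}

    for ff_id, entries in ff_entries.items():
        ff_titles = [g.title for g, _ in entries]
        if titles_usable and set(ff_titles) <= set(qm_titles) and all(ff_titles):
            aligned = []
            for g, c in entries:
                aligned.append((by_title[g.title], g, c))
        else:
            if len(entries) != len(records):
                raise ParseError(
                    f"force field {ff_id!r}: {len(entries)} records cannot be "
                    f"aligned by order with {len(records)} QM records"
                )
            aligned = [(records[k], g, c) for k, (g, c) in enumerate(entries)]
        for record, g, conf in aligned:
            if g.elements != record.graph.elements:
                raise ParseError(
                    f"force field {ff_id!r} record {g.title!r}: element "
                    "sequence differs from the QM record"
                )
            conf.source = ff_id
            record.ff_results[ff_id] = conf
    return records


def group_by_identity(
    records: Sequence[StructureRecord],
    ff_ids: Optional[Sequence[str]] = None,
    use_stereo: bool = True,
) -> GroupingResult:
    """Partition records into molecule groups by canonical graph key.

    Records lacking any dataset-wide force field are dropped and reported.
    Each group's ``reference_index`` is the member with minimal QM energy
    (ties resolved toward the lowest input index).
    """
    if ff_ids is None:
        seen: list[str] = []
        for r in records:
            for ff_id in r.ff_results:
                if ff_id not in seen:
                    seen.append(ff_id)
        ff_ids = seen
    ff_ids = tuple(ff_ids)

    dropped: list[tuple[StructureRecord, str]] = []
    grouped: dict[str, list[StructureRecord]] = {}
    for record in records:
        missing = [f for f in ff_ids if f not in record.ff_results]
        if missing:
            dropped.append(
                (record, f"missing force field result(s): {', '.join(missing)}")
            )
            continue
        key = canonical_graph_key(record.graph, use_stereo=use_stereo)
        grouped.setdefault(key, []).append(record)

    groups = []
    for key, members in grouped.items():
        energies = np.array([m.qm.energy for m in members])
        reference_index = int(np.argmin(energies))
        groups.append(
            MoleculeGroup(key=key, records=members, reference_index=reference_index)
        )
    return GroupingResult(groups=groups, dropped=dropped, ff_ids=ff_ids)


def group_manifest(groups: Sequence[MoleculeGroup]) -> pd.DataFrame:
    """Tabulate groups as (key, n_records, reference title)."""
    rows = [
        {
            "key": g.key,
            "n_records": g.n_records,
            "reference_title": g.records[g.reference_index].title,
        }
        for g in groups
    ]
    return pd.DataFrame(rows, columns=["key", "n_records", "reference_title"])
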