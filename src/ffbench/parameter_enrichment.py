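"""Force-field parameter overrepresentation among high-TFD molecules.

A molecule enters the high-TFD subset when any of its structures exceeds
the TFD cutoff (default 0.12). For each parameter, the representation ratio
is the fraction of molecules applying it at least once; subset vs full-set
ratios are compared with a one-sample Z-test for proportions with Wald 95%
confidence intervals, and parameters applied by 20 or fewer subset
molecules are excluded as inconclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import norm

from .errors import FFBenchError, ParseError
from .io_dataset import MoleculeGroup

__all__ = [
    "DEFAULT_TFD_CUTOFF",
    "DEFAULT_MIN_SUBSET_COUNT",
    "PARAMETER_CLASSES",
    "ParameterAssignment",
    "EnrichmentResult",
    "SubstructurePattern",
    "DEFAULT_PATTERNS",
    "select_high_tfd_molecules",
    "representation_ratio",
    "proportion_z_test",
    "enrichment_report",
    "enrichment_table",
    "flag_substructures",
]

DEFAULT_TFD_CUTOFF = 0.12
DEFAULT_MIN_SUBSET_COUNT = 21  # parameters on <= 20 subset molecules excluded

PARAMETER_CLASSES = ("bond", "angle", "proper torsion", "improper torsion", "vdW")


@dataclass
class ParameterAssignment:
    """Molecule key -> unique set of applied parameter ids."""

    by_molecule: dict[str, set[str]]
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls in self.classes.values():
            if cls not in PARAMETER_CLASSES:
                raise FFBenchError(f"unknown parameter class {cls!r}")

    @property
    def parameter_ids(self) -> list[str]:
        ids: set[str] = set()
        for params in self.by_molecule.values():
            ids |= params
        return sorted(ids)

    @classmethod
    def from_csv(cls, path) -> "ParameterAssignment":
        df = pd.read_csv(path, dtype=str)
        required = {"molecule_key", "parameter_id"}
        if not required <= set(df.columns):
            raise ParseError(
                f"assignment table must have columns {sorted(required)}"
            )
        by_molecule: dict[str, set[str]] = {}
        classes: dict[str, str] = {}
        for _, row in df.iterrows():
            by_molecule.setdefault(row["molecule_key"], set()).add(
                row["parameter_id"]
            )
            if "class" in df.columns and isinstance(row.get("class"), str):
                classes[row["parameter_id"]] = row["class"]
        return cls(by_molecule=by_molecule, classes=classes)

    @classmethod
    def from_json(cls, path) -> "ParameterAssignment":
        with open(path) as handle:
            payload = json.load(handle)
        return cls(
            by_molecule={
                k: set(v) for k, v in payload["by_molecule"].items()
            },
            classes=payload.get("classes", {}),
        )

    def to_csv(self, path) -> None:
        rows = [
            {
                "molecule_key": key,
                "parameter_id": pid,
                "class": self.classes.get(pid, ""),
            }
            for key in sorted(self.by_molecule)
            for pid in sorted(self.by_molecule[key])
        ]
        pd.DataFrame(
            rows, columns=["molecule_key", "parameter_id", "class"]
        ).to_csv(path, index=False)


@dataclass
class EnrichmentResult:
    parameter_id: str
    parameter_class: str
    ratio_full: float  # population proportion p0
    ratio_subset: float  # sample proportion p_hat
    n_subset: int
    z: Optional[float]
    p_value: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    significant: bool
    excluded_small_sample: bool


def select_high_tfd_molecules(
    tfd_table: pd.DataFrame,
    ff_id: Optional[str] = None,
    cutoff: float = DEFAULT_TFD_CUTOFF,
) -> set[str]:
    """Keys of molecules with any structure's TFD above the cutoff.

    ``tfd_table`` needs columns ``key``, ``ff_id`` and ``tfd``; rows with an
    undefined TFD are ignored.
    """
    if tfd_table.empty:
        return set()
    table = tfd_table
    if ff_id is not None:
        table = table[table["ff_id"] == ff_id]
    table = table.dropna(subset=["tfd"])
    hits = table[table["tfd"] > cutoff]
    return set(hits["key"].unique())


def representation_ratio(
    parameter_id: str,
    molecule_keys: Iterable[str],
    assignment: ParameterAssignment,
) -> float:
    """Fraction of molecules in the set applying the parameter at least once."""
    keys = list(molecule_keys)
    if not keys:
        raise FFBenchError("representation ratio undefined on an empty set")
    hits = sum(
        1 for k in keys if parameter_id in assignment.by_molecule.get(k, ())
    )
    return hits / len(keys)


def proportion_z_test(
    p_hat: float, p0: float, n: int, alpha: float = 0.05
) -> tuple[float, float, float, float]:
    """One-sample Z-test for a proportion against population value p0.

    Returns (z, two-sided p-value, ci_low, ci_high) where the CI is the
    Wald interval on the sample proportion at level 1 - alpha.
    """
    if not 0.0 <= p_hat <= 1.0:
        raise FFBenchError("p_hat must lie in [0, 1]")
    if not 0.0 < p0 < 1.0:
        raise FFBenchError("degenerate null: p0 must lie strictly in (0, 1)")
    if n < 1:
        raise FFBenchError("n must be >= 1")
    z = (p_hat - p0) / (p0 * (1.0 - p0) / n) ** 0.5
    p_value = 2.0 * norm.sf(abs(z))
    z_crit = norm.ppf(1.0 - alpha / 2.0)
    half = z_crit * (p_hat * (1.0 - p_hat) / n) ** 0.5
    return float(z), float(p_value), float(p_hat - half), float(p_hat + half)


def enrichment_report(
    assignment: ParameterAssignment,
    subset_keys: Iterable[str],
    full_keys: Iterable[str],
    alpha: float = 0.05,
    min_subset_count: int = DEFAULT_MIN_SUBSET_COUNT,
) -> list[EnrichmentResult]:
    """Per-parameter overrepresentation results for the high-TFD subset.

    A parameter is significant iff it is not excluded for small sample,
    its two-sided p-value is below ``alpha``, and its subset ratio exceeds
    the full-set ratio (directional overrepresentation).
    """
    subset = sorted(set(subset_keys))
    full = sorted(set(full_keys))
    if not set(subset) <= set(full):
        raise FFBenchError("subset keys must be contained in the full set")
    if not full:
        raise FFBenchError("full molecule set is empty")
    n = len(subset)
    results = []
    for pid in assignment.parameter_ids:
        p0 = representation_ratio(pid, full, assignment)
        applied = sum(
            1 for k in subset if pid in assignment.by_molecule.get(k, ())
        )
        p_hat = applied / n if n else 0.0
        excluded = applied < min_subset_count
        z = p_value = ci_low = ci_high = None
        significant = False
        if not excluded and 0.0 < p0 < 1.0:
            z, p_value, ci_low, ci_high = proportion_z_test(
                p_hat, p0, n, alpha=alpha
            )
            significant = p_value < alpha and p_hat > p0
        results.append(
            EnrichmentResult(
                parameter_id=pid,
                parameter_class=assignment.classes.get(pid, ""),
                ratio_full=p0,
                ratio_subset=p_hat,
                n_subset=n,
                z=z,
                p_value=p_value,
                ci_low=ci_low,
                ci_high=ci_high,
                significant=significant,
                excluded_small_sample=excluded,
            )
        )
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Flatten enrichment results for CSV export."""
    rows = []
    for r in results:
        disposition = (
            "excluded-small-sample"
            if r.excluded_small_sample
            else ("significant" if r.significant else "not-significant")
        )
        rows.append(
            {
                "parameter_id": r.parameter_id,
                "class": r.parameter_class,
                "ratio_full": r.ratio_full,
                "ratio_subset": r.ratio_subset,
                "n_subset": r.n_subset,
                "z": r.z,
                "p_value": r.p_value,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "disposition": disposition,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "parameter_id",
            "class",
            "ratio_full",
            "ratio_subset",
            "n_subset",
            "z",
            "p_value",
            "ci_low",
            "ci_high",
            "disposition",
        ],
    )


# ---------------------------------------------------------------------------
# Substructure tagging
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubstructurePattern:
    """Labelled-subgraph query: elements per node, optional bond orders.

    ``atoms`` lists element symbols (None matches any element); ``bonds``
    lists (i, j, order) with ``order=None`` matching any order. Matching is
    by subgraph monomorphism, so extra bonds in the target are allowed.
    """

    name: str
    atoms: tuple[Optional[str], ...]
    bonds: tuple[tuple[int, int, Optional[int]], ...]

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n == 0:
            raise FFBenchError(f"pattern {self.name!r}: no atoms")
        for i, j, _order in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise FFBenchError(
                    f"pattern {self.name!r}: bond ({i}, {j}) out of range"
                )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, sym in enumerate(self.atoms):
            g.add_node(i, element=sym)
        for i, j, order in self.bonds:
            g.add_edge(i, j, order=order)
        return g


#: N-N single bond and azetidine (4-ring with exactly one nitrogen).
DEFAULT_PATTERNS = (
    SubstructurePattern(
        name="N-N single bond",
        atoms=("N", "N"),
        bonds=((0, 1, 1),),
    ),
    SubstructurePattern(
        name="azetidine",
        atoms=("N", "C", "C", "C"),
        bonds=((0, 1, 1), (1, 2, 1), (2, 3, 1), (3, 0, 1)),
    ),
)


def flag_substructures(
    groups: Sequence[MoleculeGroup],
    patterns: Sequence[SubstructurePattern] = DEFAULT_PATTERNS,
) -> dict[str, list[str]]:
    """Tag each molecule with every pattern embedding into its graph."""

    def node_match(target, query):
        return query["element"] is None or target["element"] == query["element"]

    def edge_match(target, query):
        return query["order"] is None or target["order"] == query["order"]

    tags: dict[str, list[str]] = {}
    for group in groups:
        g = group.graph.to_networkx()
        hits = []
        for pattern in patterns:
            matcher = nx.algorithms.isomorphism.GraphMatcher(
                g,
                pattern.to_networkx(),
                node_match=node_match,
                edge_match=edge_match,
            )
            if matcher.subgraph_is_monomorphic():
                hits.append(pattern.name)
        tags[group.key] = hits
    return tags
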