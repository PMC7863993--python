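"""parameter_enrichment: ratios, Z-test, report, substructure tags."""

import math

import numpy as np
import pandas as pd
import pytest

from ffbench.errors import FFBenchError
from ffbench.io_dataset import Conformer, MoleculeGroup, StructureRecord
from ffbench.parameter_enrichment import (
    DEFAULT_PATTERNS,
    ParameterAssignment,
    SubstructurePattern,
    enrichment_report,
    enrichment_table,
    flag_substructures,
    proportion_z_test,
    representation_ratio,
    select_high_tfd_molecules,
)

from conftest import make_graph


class TestSelectHighTfd:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["key", "title", "ff_id", "tfd"])

    def test_any_structure_above_cutoff(self):
        table = self._table([
            ("m1", "a", "ffX", 0.05),
            ("m1", "b", "ffX", 0.20),
            ("m2", "c", "ffX", 0.05),
        ])
        assert select_high_tfd_molecules(table, "ffX") == {"m1"}

    def test_all_below_cutoff_empty(self):
        table = self._table([("m1", "a", "ffX", 0.11)])
        assert select_high_tfd_molecules(table, "ffX") == set()

    def test_default_cutoff(self):
        table = self._table([("m1", "a", "ffX", 0.121), ("m2", "b", "ffX", 0.12)])
        assert select_high_tfd_molecules(table, "ffX") == {"m1"}

    def test_empty_table(self):
        assert select_high_tfd_molecules(self._table([]), "ffX") == set()


class TestRepresentationRatio:
    def test_two_of_four(self):
        assignment = ParameterAssignment(
            by_molecule={"a": {"p"}, "b": {"p"}, "c": set(), "d": set()}
        )
        assert representation_ratio("p", ["a", "b", "c", "d"], assignment) == 0.5

    def test_multiplicity_ignored(self, tmp_path):
        path = tmp_path / "assign.csv"
        pd.DataFrame(
            {
                "molecule_key": ["a", "a", "a", "b"],
                "parameter_id": ["p", "p", "p", "q"],
                "class": ["bond"] * 4,
            }
        ).to_csv(path, index=False)
        assignment = ParameterAssignment.from_csv(path)
        assert representation_ratio("p", ["a", "b"], assignment) == 0.5

    def test_everywhere(self):
        assignment = ParameterAssignment(by_molecule={"a": {"p"}, "b": {"p"}})
        assert representation_ratio("p", ["a", "b"], assignment) == 1.0

    def test_empty_set_error(self):
        assignment = ParameterAssignment(by_molecule={})
        with pytest.raises(FFBenchError):
            representation_ratio("p", [], assignment)


class TestZTest:
    def test_closed_form(self):
        z, p, lo, hi = proportion_z_test(0.5, 0.2, 25)
        assert z == pytest.approx(3.75, abs=1e-12)
        assert p == pytest.approx(math.erfc(3.75 / math.sqrt(2)), abs=1e-12)

    def test_null_case(self):
        z, p, *_ = proportion_z_test(0.2, 0.2, 50)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_sqrt_n_scaling(self):
        z25, *_ = proportion_z_test(0.5, 0.2, 25)
        z100, *_ = proportion_z_test(0.5, 0.2, 100)
        assert z100 == pytest.approx(2.0 * z25)

    def test_degenerate_null_error(self):
        for p0 in (0.0, 1.0):
            with pytest.raises(FFBenchError):
                proportion_z_test(0.5, p0, 10)

    def test_wald_ci(self):
        _z, _p, lo, hi = proportion_z_test(0.5, 0.2, 25, alpha=0.05)
        half = 1.959963984540054 * math.sqrt(0.25 / 25)
        assert lo == pytest.approx(0.5 - half)
        assert hi == pytest.approx(0.5 + half)


def _planted_assignment(rng, n_full=200, n_subset=60, p_sub=0.8, p_bg=0.3):
    full = [f"m{i}" for i in range(n_full)]
    subset = full[:n_subset]
    by_molecule = {}
    for key in full:
        params = set()
        p = p_sub if key in subset else p_bg
        if rng.random() < p:
            params.add("planted")
        if rng.random() < 0.6:
            params.add("background")
        by_molecule[key] = params
    assignment = ParameterAssignment(
        by_molecule=by_molecule,
        classes={"planted": "proper torsion", "background": "bond"},
    )
    return assignment, subset, full


class TestEnrichmentReport:
    def test_planted_parameter_significant(self):
        rng = np.random.default_rng(0)
        assignment, subset, full = _planted_assignment(rng)
        results = {r.parameter_id: r
                   for r in enrichment_report(assignment, subset, full)}
        assert results["planted"].significant
        assert not results["background"].significant

    def test_small_sample_excluded(self):
        # parameter applied by exactly 20 subset molecules -> excluded
        full = [f"m{i}" for i in range(100)]
        subset = full[:40]
        by_molecule = {k: set() for k in full}
        for k in subset[:20]:
            by_molecule[k].add("p")
        for k in full[40:]:
            by_molecule[k].add("p")
        assignment = ParameterAssignment(by_molecule=by_molecule)
        (result,) = enrichment_report(assignment, subset, full)
        assert result.excluded_small_sample and not result.significant

    def test_underrepresented_never_significant(self):
        full = [f"m{i}" for i in range(200)]
        subset = full[:60]
        by_molecule = {k: set() for k in full}
        # applied by 25 subset molecules (>20) but at a lower rate than full
        for k in subset[:25]:
            by_molecule[k].add("p")
        for k in full[60:]:
            by_molecule[k].add("p")
        assignment = ParameterAssignment(by_molecule=by_molecule)
        (result,) = enrichment_report(assignment, subset, full)
        assert not result.excluded_small_sample
        assert result.ratio_subset < result.ratio_full
        assert not result.significant

    def test_subset_must_be_contained(self):
        assignment = ParameterAssignment(by_molecule={"a": {"p"}})
        with pytest.raises(FFBenchError):
            enrichment_report(assignment, ["zz"], ["a"])

    def test_disposition_accounting(self):
        rng = np.random.default_rng(1)
        assignment, subset, full = _planted_assignment(rng)
        results = enrichment_report(assignment, subset, full)
        table = enrichment_table(results)
        assert len(table) == len(assignment.parameter_ids)
        assert table["disposition"].isin(
            ["significant", "not-significant", "excluded-small-sample"]
        ).all()

    def test_empty_subset_all_excluded(self):
        assignment = ParameterAssignment(by_molecule={"a": {"p"}})
        (result,) = enrichment_report(assignment, [], ["a"])
        assert result.excluded_small_sample and not result.significant


class TestSubstructures:
    def _group(self, graph):
        rec = StructureRecord(
            graph=graph, qm=Conformer(np.zeros((graph.n_atoms, 3)), 0.0)
        )
        from ffbench.io_dataset import canonical_graph_key

        return MoleculeGroup(
            key=canonical_graph_key(graph), records=[rec], reference_index=0
        )

    def test_hydrazine_tagged_nn(self):
        g = make_graph(
            ["N", "N", "H", "H", "H", "H"],
            [(0, 1, 1), (0, 2, 1), (0, 3, 1), (1, 4, 1), (1, 5, 1)],
        )
        tags = flag_substructures([self._group(g)])
        assert tags[next(iter(tags))] == ["N-N single bond"]

    def test_azetidine_tagged(self):
        # azetidine ring plus a methyl substituent
        g = make_graph(
            ["N", "C", "C", "C", "C"],
            [(0, 1, 1), (1, 2, 1), (2, 3, 1), (3, 0, 1), (1, 4, 1)],
        )
        tags = flag_substructures([self._group(g)])
        assert "azetidine" in tags[next(iter(tags))]

    def test_benzene_untagged(self, benzene_graph):
        tags = flag_substructures([self._group(benzene_graph)])
        assert tags[next(iter(tags))] == []

    def test_double_bonded_nn_not_tagged(self):
        g = make_graph(
            ["N", "N", "H", "H"], [(0, 1, 2), (0, 2, 1), (1, 3, 1)]
        )
        tags = flag_substructures([self._group(g)])
        assert tags[next(iter(tags))] == []

    def test_malformed_pattern_named(self):
        with pytest.raises(FFBenchError, match="bad-pattern"):
            SubstructurePattern(name="bad-pattern", atoms=("C",),
                                bonds=((0, 5, 1),))

    def test_oracle_agreement_on_random_graphs(self):
        """Tagging agrees with a direct networkx monomorphism check."""
        from conftest import random_heavy_graph

        rng = np.random.default_rng(3)
        pattern = DEFAULT_PATTERNS[0]  # N-N single bond
        for _ in range(25):
            g = random_heavy_graph(rng, int(rng.integers(3, 8)))
            expected = any(
                o == 1
                and g.atoms[i][0] == "N"
                and g.atoms[j][0] == "N"
                for i, j, o in g.bonds
            )
            tags = flag_substructures([self._group(g)], [pattern])
            assert (pattern.name in next(iter(tags.values()))) == expected
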