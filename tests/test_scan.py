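"""Pathway x marker scan mechanics: genotype splitting, planted-signal
recovery, determinism and module selection."""

import numpy as np
import pytest

from netcov.datasets import make_planted_scan_dataset
from netcov.io import ModuleResult, write_results
from netcov.kernel import KernelSpec
from netcov.scan import (
    GroupedSamples,
    ScanConfig,
    SkipSignal,
    module_seed,
    scan_report,
    select_modules,
    split_by_genotype,
)


class TestSplitByGenotype:
    def test_two_class_sizes(self):
        g = split_by_genotype(np.array([0, 0, 1, 1, 0], dtype=float), min_group_size=2)
        assert isinstance(g, GroupedSamples)
        assert g.sizes == (3, 2)
        np.testing.assert_array_equal(g.groups[0], [0, 1, 4])

    def test_monomorphic_skipped(self):
        g = split_by_genotype(np.zeros(6), min_group_size=2)
        assert isinstance(g, SkipSignal)
        assert "monomorphic" in g.reason

    def test_three_classes_route_to_three_groups(self):
        codes = np.array([0, 0, 1, 1, 2, 2, 0, 1, 2], dtype=float)
        g = split_by_genotype(codes, min_group_size=2)
        assert isinstance(g, GroupedSamples)
        assert len(g.groups) == 3

    def test_missing_samples_dropped(self):
        codes = np.array([0, np.nan, 1, 1, 0, 0])
        g = split_by_genotype(codes, min_group_size=2)
        assert g.sizes == (3, 2)

    def test_small_class_skipped(self):
        codes = np.array([0, 0, 0, 0, 1], dtype=float)
        g = split_by_genotype(codes, min_group_size=2)
        assert isinstance(g, SkipSignal)


@pytest.fixture(scope="module")
def planted():
    return make_planted_scan_dataset(seed=20240)


@pytest.fixture(scope="module")
def report(planted):
    cfg = ScanConfig(B=200, seed=77)
    return scan_report(planted.expr, planted.geno, planted.sets, cfg)


class TestScan:
    def test_causal_module_ranks_first(self, planted, report):
        top = report.results[0]
        assert (top.pathway, top.marker) == (
            planted.causal_pathway,
            planted.causal_marker,
        )
        assert top.fdr_q == min(r.fdr_q for r in report.results)

    def test_each_module_evaluated_exactly_once_per_method(self, planted, report):
        n_modules = len(planted.sets) * planted.geno.n_markers
        # balanced fixture: nothing skipped, so every module evaluated once
        assert report.n_evaluated["linear"] + len(report.skipped) == n_modules
        keys = [(r.pathway, r.marker, r.method) for r in report.results]
        assert len(keys) == len(set(keys))
        assert len(keys) <= n_modules

    def test_same_seed_gives_byte_identical_results_file(self, planted, tmp_path):
        cfg = ScanConfig(B=50, seed=5)
        paths = []
        for tag in ("a", "b"):
            res = scan_report(planted.expr, planted.geno, planted.sets, cfg).results
            path = tmp_path / f"res_{tag}.tsv"
            write_results(res, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_results_invariant_to_pathway_and_marker_order(self, planted):
        from netcov.io import GeneSetCollection, GenotypeMatrix

        cfg = ScanConfig(B=50, seed=5)
        base = scan_report(planted.expr, planted.geno, planted.sets, cfg).results
        rev_sets = GeneSetCollection(
            dict(reversed(list(planted.sets.sets.items()))),
            planted.sets.descriptions,
        )
        order = list(reversed(range(planted.geno.n_markers)))
        rev_geno = GenotypeMatrix(
            [planted.geno.marker_ids[i] for i in order],
            planted.geno.sample_ids,
            planted.geno.values[order],
        )
        other = scan_report(planted.expr, rev_geno, rev_sets, cfg).results
        key = lambda r: (r.pathway, r.marker, r.method)
        assert {key(r): (r.T, r.p_nominal, r.fdr_q) for r in base} == {
            key(r): (r.T, r.p_nominal, r.fdr_q) for r in other
        }

    def test_parallel_matches_serial(self, planted):
        serial = scan_report(planted.expr, planted.geno, planted.sets, ScanConfig(B=30, seed=3))
        parallel = scan_report(
            planted.expr, planted.geno, planted.sets, ScanConfig(B=30, seed=3, n_jobs=2)
        )
        for a, b in zip(serial.results, parallel.results):
            assert (a.pathway, a.marker, a.T, a.fdr_q) == (b.pathway, b.marker, b.T, b.fdr_q)

    def test_all_monomorphic_markers_give_empty_results(self, planted):
        from netcov.io import GenotypeMatrix

        geno = GenotypeMatrix(
            ["m1", "m2"],
            planted.geno.sample_ids,
            np.vstack([np.zeros(120), np.ones(120)]),
        )
        report = scan_report(planted.expr, geno, planted.sets, ScanConfig(B=10, seed=1))
        assert report.results == []
        reasons = {s[2] for s in report.skipped}
        assert any("monomorphic" in r for r in reasons)

    def test_multiple_methods_get_separate_fdr(self, planted):
        cfg = ScanConfig(
            methods=[KernelSpec("linear"), KernelSpec("rbf", bandwidth=10.0)],
            B=30,
            seed=9,
        )
        report = scan_report(planted.expr, planted.geno, planted.sets, cfg)
        methods = {r.method for r in report.results}
        assert methods == {"linear", "rbf:10"}

    def test_empty_gene_sets_rejected(self, planted):
        from netcov.io import GeneSetCollection

        empty = GeneSetCollection(sets={})
        with pytest.raises(ValueError, match="empty"):
            scan_report(planted.expr, planted.geno, empty, ScanConfig(B=10))


class TestSelectModules:
    def _mk(self, q):
        return ModuleResult("pw", f"m{q}", "linear", 2, (10, 10), 1.0, 0.1, 1.0, q)

    def test_threshold_one_keeps_all(self):
        res = [self._mk(q) for q in (0.1, 0.9, 1.0)]
        assert len(select_modules(res, 1.0)) == 3

    def test_threshold_zero_keeps_only_zero_q(self):
        res = [self._mk(q) for q in (0.0, 0.1)]
        assert [r.fdr_q for r in select_modules(res, 0.0)] == [0.0]

    def test_enumerated_filter(self):
        res = [self._mk(q) for q in (0.1, 0.3, 0.25)]
        assert len(select_modules(res, 0.25)) == 2


def test_module_seed_stable_and_in_range():
    a = module_seed(7, "pw", "m1")
    assert a == module_seed(7, "pw", "m1")
    assert a != module_seed(7, "pw", "m2")
    assert 0 <= a < 2**31
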