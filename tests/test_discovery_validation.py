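import numpy as np
import pytest

from robustgi.alterations import DriverGeneRule
from robustgi.association import AssociationResult
from robustgi.core_data import DataError, GeneSet
from robustgi.discovery_validation import (
    ONCOGENE_ADDICTION,
    SYNTHETIC_LETHALITY,
    aggregate_robust,
    exclude_self,
    make_pair,
    run_pipeline,
    split_common_lines,
    split_within_dataset,
    validate_pair,
    DatasetPair,
    ValidationRecord,
)
from robustgi.synthetic_data import SyntheticConfig, generate_world
from conftest import make_alterations, make_dataset


def dataset_with_lines(lines, dataset_id="DS", n_genes=3):
    return make_dataset(np.zeros((n_genes, len(lines))), lines=list(lines),
                        dataset_id=dataset_id)


def alt_all(lines, drivers=("d1",), k=None):
    k = len(lines) if k is None else k
    return make_alterations(
        {d: [i < k for i in range(len(lines))] for d in drivers}, list(lines)
    )


def result(driver="d1", target="g1", p=0.01, fdr=0.1, coef=-1.0, ds="DS"):
    return AssociationResult(
        dataset_id=ds, driver=driver, target=target, n_altered=5, n_wt=10,
        coefficient=coef, p_value=p, cles=0.8, fdr=fdr,
    )


class TestMakePair:
    def test_overlap_purged(self):
        disc = dataset_with_lines(["A", "B", "C"], "D1")
        val = dataset_with_lines(["B", "C", "D", "E"], "D2")
        pair = make_pair(disc, val, alt_all(disc.cell_line_ids),
                         alt_all(val.cell_line_ids), min_altered=1)
        assert pair.validation.cell_line_ids == ["D", "E"]
        assert set(pair.discovery.cell_line_ids).isdisjoint(pair.validation.cell_line_ids)

    def test_contained_validation_errors(self):
        disc = dataset_with_lines(["A", "B", "C"], "D1")
        val = dataset_with_lines(["B", "C"], "D2")
        with pytest.raises(DataError, match="no exclusive validation lines"):
            make_pair(disc, val, alt_all(disc.cell_line_ids), alt_all(val.cell_line_ids))

    def test_min_altered_applies_per_purged_panel(self):
        disc = dataset_with_lines([f"A{i}" for i in range(10)], "D1")
        val_lines = disc.cell_line_ids[:2] + [f"B{i}" for i in range(8)]
        val = dataset_with_lines(val_lines, "D2")
        # driver altered 5x in discovery but only 3x among exclusive validation lines
        alt_d = alt_all(disc.cell_line_ids, k=5)
        alt_v = make_alterations(
            {"d1": [True] * 2 + [True] * 3 + [False] * 5}, val_lines
        )
        pair = make_pair(disc, val, alt_d, alt_v, min_altered=5)
        assert "d1" not in pair.testable_drivers

    def test_overlapping_panels_rejected_by_invariant(self):
        disc = dataset_with_lines(["A", "B"], "D1")
        val = dataset_with_lines(["B", "C"], "D2")
        with pytest.raises(DataError, match="share lines"):
            DatasetPair(disc, val, GeneSet("t", frozenset(disc.genes)))


class TestValidatePair:
    def make_pair_obj(self):
        disc = dataset_with_lines(["A", "B"], "D1", n_genes=2)
        val = dataset_with_lines(["C", "D"], "D2", n_genes=2)
        return DatasetPair(disc, val, GeneSet("t", frozenset({"g1", "g2"})),
                           GeneSet("d", frozenset({"d1"})))

    def test_all_criteria_met(self):
        pair = self.make_pair_obj()
        out = validate_pair(pair, [result(fdr=0.1)],
                            [result(p=0.01, fdr=0.15, ds="D2")], 0.2)
        assert len(out) == 1
        rec = out[0]
        assert rec.discovery_id == "D1" and rec.validation_id == "D2"
        assert rec.direction == "sensitivity"

    def test_opposite_sign_not_validated(self):
        pair = self.make_pair_obj()
        out = validate_pair(pair, [result(fdr=0.1, coef=-1.0)],
                            [result(p=0.01, fdr=0.15, coef=+1.0, ds="D2")], 0.2)
        assert out == []

    def test_validation_fdr_criterion(self):
        pair = self.make_pair_obj()
        out = validate_pair(pair, [result(fdr=0.1)],
                            [result(p=0.04, fdr=0.35, ds="D2")], 0.2)
        assert out == []

    def test_validation_p_criterion(self):
        pair = self.make_pair_obj()
        out = validate_pair(pair, [result(fdr=0.1)],
                            [result(p=0.08, fdr=0.15, ds="D2")], 0.2)
        assert out == []

    def test_missing_validation_fit_counts_as_not_validated(self):
        pair = self.make_pair_obj()
        assert validate_pair(pair, [result(fdr=0.1)], [], 0.2) == []

    def test_undiscovered_never_validated(self):
        pair = self.make_pair_obj()
        out = validate_pair(pair, [result(fdr=0.5)],
                            [result(p=0.001, fdr=0.01, ds="D2")], 0.2)
        assert out == []


def vrecord(driver="d1", target="g1", direction="sensitivity",
            pair=("D1", "D2"), vp=0.01):
    return ValidationRecord(
        driver=driver, target=target, direction=direction,
        discovery_id=pair[0], validation_id=pair[1],
        discovery_fdr=0.1, validation_fdr=0.1, validation_p=vp,
    )


class TestAggregateRobust:
    def test_pair_counting(self):
        recs = [vrecord(pair=("D1", "D2")), vrecord(pair=("D3", "D4"))]
        (robust,) = aggregate_robust(recs)
        assert robust.n_pairs == 2

    def test_self_oncogene_sensitivity_is_addiction(self):
        recs = [vrecord(driver="KRAS", target="KRAS")]
        rules = [DriverGeneRule("KRAS", "oncogene", frozenset({12}))]
        (robust,) = aggregate_robust(recs, rules)
        assert robust.is_self
        assert robust.interaction_class == ONCOGENE_ADDICTION
        assert exclude_self([robust]) == []

    def test_non_self_sensitivity_is_synthetic_lethality(self):
        (robust,) = aggregate_robust([vrecord()])
        assert robust.interaction_class == SYNTHETIC_LETHALITY

    def test_unvalidated_absent(self):
        assert aggregate_robust([]) == []


class TestSplits:
    def test_common_lines_restriction(self):
        a = dataset_with_lines(["A", "B", "C"], "D1")
        b = dataset_with_lines(["B", "C", "D"], "D2")
        pair = split_common_lines(a, b)
        assert pair.discovery.cell_line_ids == ["B", "C"]
        assert pair.validation.cell_line_ids == ["B", "C"]
        assert pair.mode == "common_lines"

    def test_identical_panels(self):
        a = dataset_with_lines(["A", "B"], "D1")
        b = dataset_with_lines(["A", "B"], "D2")
        pair = split_common_lines(a, b)
        assert pair.discovery.n_lines == 2 and pair.validation.n_lines == 2

    def test_disjoint_panels_error(self):
        a = dataset_with_lines(["A"], "D1")
        b = dataset_with_lines(["B"], "D2")
        with pytest.raises(DataError):
            split_common_lines(a, b)

    def test_within_dataset_partition(self):
        lines = [f"c{i}" for i in range(100)]
        ds = dataset_with_lines(lines, "D1")
        rng = np.random.default_rng(0)
        labels = {l: ("discovery" if rng.random() < 0.5 else "validation")
                  for l in lines}
        pair = split_within_dataset(ds, labels)
        assert set(pair.discovery.cell_line_ids).isdisjoint(pair.validation.cell_line_ids)
        assert pair.discovery.n_lines + pair.validation.n_lines == 100

    def test_within_dataset_reference_panel_mode(self):
        lines = [f"c{i}" for i in range(10)]
        ds = dataset_with_lines(lines, "D1")
        pair = split_within_dataset(ds, lines[:4])  # shared lines -> validation
        assert pair.validation.cell_line_ids == lines[:4]
        assert pair.discovery.cell_line_ids == lines[4:]

    def test_partition_omitting_line_errors(self):
        ds = dataset_with_lines(["a", "b"], "D1")
        with pytest.raises(DataError, match="omits"):
            split_within_dataset(ds, {"a": "discovery"})


class TestPipeline:
    def world(self, seed=0, **kw):
        cfg = SyntheticConfig(seed=seed, n_studies=3, lines_per_study=60,
                              n_driver_genes=5, n_target_genes=40,
                              n_planted_interactions=8,
                              ppi_n_background_edges=100, **kw)
        return generate_world(cfg)

    def test_nesting_and_disjointness(self):
        w = self.world()
        res = run_pipeline(w.datasets, w.alterations,
                           GeneSet("t", frozenset(w.datasets[0].genes)),
                           w.driver_rules)
        assert res.validated_pairs <= res.discovered_pairs <= res.tested_pairs
        for r in res.robust:
            assert r.validated_pairs

    def test_deterministic_rerun(self):
        w1, w2 = self.world(seed=5), self.world(seed=5)
        args = dict(fdr_threshold=0.2, min_altered=5)
        r1 = run_pipeline(w1.datasets, w1.alterations,
                          GeneSet("t", frozenset(w1.datasets[0].genes)),
                          w1.driver_rules, **args)
        r2 = run_pipeline(w2.datasets, w2.alterations,
                          GeneSet("t", frozenset(w2.datasets[0].genes)),
                          w2.driver_rules, **args)
        assert r1.summary() == r2.summary()
        assert {(r.driver, r.target) for r in r1.robust} == \
               {(r.driver, r.target) for r in r2.robust}

    def test_discovery_nestedness_across_fdr(self):
        """BH rejections at FDR 0.1 are a subset of those at 0.3."""
        w = self.world(seed=2)
        targets = GeneSet("t", frozenset(w.datasets[0].genes))
        strict = run_pipeline(w.datasets, w.alterations, targets, w.driver_rules,
                              fdr_threshold=0.1)
        loose = run_pipeline(w.datasets, w.alterations, targets, w.driver_rules,
                             fdr_threshold=0.3)
        assert strict.discovered_pairs <= loose.discovered_pairs

    def test_validation_family_modes_agree_on_strong_effects(self):
        w = self.world(seed=1, planted_effect_size=-1.5, noise_sd=0.3)
        targets = GeneSet("t", frozenset(w.datasets[0].genes))
        full = run_pipeline(w.datasets, w.alterations, targets, w.driver_rules,
                            validation_family="full")
        sub = run_pipeline(w.datasets, w.alterations, targets, w.driver_rules,
                           validation_family="discovered")
        truth = w.truth.interaction_pairs
        for res in (full, sub):
            found = {(r.driver, r.target) for r in res.robust_interactions}
            assert truth <= found | (truth - res.tested_pairs)
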