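"""Tests for substitute mapping, dataset expansion, labeling, and ratio rules."""

import math

import numpy as np
import pytest

from dacsaug import (
    LabeledInstance,
    SynergyInstance,
    ValidationError,
    augment_dataset,
    build_substitute_map,
    label_instances,
    ratio_preserving_augment,
    synergy_distribution_summary,
)
from dacsaug.augmentation import ANTAGONISTIC, SYNERGISTIC, LabelReport, SubstituteMap
from dacsaug.similarity import DACS_MAX


def make_instance(i, a, b, cell, score, **kw):
    return SynergyInstance(
        instance_id=f"O{i:05d}", drug_a=a, drug_b=b, cell_line=cell,
        synergy_score=score, **kw,
    )


def make_labeled(i, a, b, cell, score, label, parent=None):
    return LabeledInstance(
        instance_id=i, drug_a=a, drug_b=b, cell_line=cell, synergy_score=score,
        label=label,
        provenance="original" if parent is None else "augmented",
        parent_id=parent,
        substituted_position="none" if parent is None else "a",
    )


class TestSubstituteMap:
    # fixture DACS values, brute-forced by hand:
    #   s1: d1 -> 1.2669, d2 -> 0.9069, d3 -> 0.0667, d4 -> 0.3651
    #   s2: d1 -> 0.0667, d2 -> 0.1429, d3 -> 1.0773, d4 -> 0.3651
    #   (s2/d3: tc = 7/9, mcc = 10/sqrt(180) -> sqrt((7/9)^2 + 100/180))
    def test_exact_membership_at_cutoff(self, fixture_cohort):
        fx = fixture_cohort
        subs = build_substitute_map(
            list(fx.originals), list(fx.candidates), fx.profiles, fx.universe, 0.5
        )
        assert [c for c, _ in subs.for_drug("d1")] == ["s1"]
        assert [c for c, _ in subs.for_drug("d2")] == ["s1"]
        assert [c for c, _ in subs.for_drug("d3")] == ["s2"]
        assert subs.for_drug("d4") == ()
        assert subs.for_drug("d1")[0][1] == pytest.approx(1.2669, abs=1e-4)
        assert subs.for_drug("d3")[0][1] == pytest.approx(
            math.hypot(7 / 9, 10 / math.sqrt(180)), abs=1e-12
        )

    def test_cutoff_above_sqrt2_rejected(self, fixture_cohort):
        fx = fixture_cohort
        with pytest.raises(ValidationError):
            build_substitute_map(
                list(fx.originals), list(fx.candidates), fx.profiles, fx.universe, 1.5
            )

    def test_self_substitution_excluded(self, fixture_cohort):
        fx = fixture_cohort
        subs = build_substitute_map(
            list(fx.originals), list(fx.originals)[:1], fx.profiles, fx.universe, 0.0
        )
        assert "d1" not in [c for c, _ in subs.for_drug("d1")]

    def test_sorted_by_descending_dacs(self, small_cohort):
        subs = build_substitute_map(
            list(small_cohort.originals),
            list(small_cohort.candidates),
            small_cohort.profiles,
            small_cohort.universe,
            0.0,
        )
        for hits in subs.substitutes.values():
            values = [v for _, v in hits]
            assert values == sorted(values, reverse=True)


class TestAugmentDataset:
    def test_hand_enumeration(self):
        inst = make_instance(1, "D1", "D2", "C1", 30.0)
        subs = SubstituteMap(
            cutoff=0.5,
            substitutes={"D1": (("S1", 1.0), ("S2", 0.9)), "D2": (("S3", 0.8),)},
        )
        out = augment_dataset([inst], subs)
        assert len(out) == 4  # 1 original + 3 generated
        generated = [o for o in out if o.provenance == "augmented"]
        pairs = {o.pair for o in generated}
        assert pairs == {("D2", "S1"), ("D2", "S2"), ("D1", "S3")}
        assert all(o.synergy_score == 30.0 for o in generated)
        assert all(o.cell_line == "C1" for o in generated)
        assert all(o.parent_id == inst.instance_id for o in generated)

    def test_empty_map_is_identity(self):
        inst = make_instance(1, "D1", "D2", "C1", 30.0)
        out = augment_dataset([inst], SubstituteMap(cutoff=0.5, substitutes={}))
        assert out == [inst]

    def test_self_pair_dropped(self):
        inst = make_instance(1, "D1", "D2", "C1", 30.0)
        subs = SubstituteMap(cutoff=0.5, substitutes={"D1": (("D2", 1.0),)})
        out = augment_dataset([inst], subs)
        assert len(out) == 1

    def test_rejects_already_augmented_input(self):
        inst = make_instance(
            1, "D1", "D2", "C1", 30.0, provenance="augmented", parent_id="O1",
            substituted_position="a",
        )
        with pytest.raises(ValidationError):
            augment_dataset([inst], SubstituteMap(cutoff=0.5, substitutes={}))

    def test_duplicates_keep_first_and_originals_win(self):
        # both parents generate (C, S1) on C1 -> one copy, first parent's score
        i1 = make_instance(1, "A", "C", "C1", 30.0)
        i2 = make_instance(2, "B", "C", "C1", -25.0)
        i3 = make_instance(3, "C", "S1", "C1", 5.0)  # original with the same pair
        subs = SubstituteMap(
            cutoff=0.5, substitutes={"A": (("S1", 1.0),), "B": (("S1", 1.0),)}
        )
        out = augment_dataset([i1, i2, i3], subs)
        generated = [o for o in out if o.provenance == "augmented"]
        # (C,S1,C1) exists as an original -> no generated duplicate at all
        assert [o.pair for o in generated] == []

    def test_score_inheritance_and_cell_invariance(self, fixture_cohort):
        fx = fixture_cohort
        subs = build_substitute_map(
            list(fx.originals), list(fx.candidates), fx.profiles, fx.universe, 0.5
        )
        out = augment_dataset(list(fx.instances), subs)
        by_id = {i.instance_id: i for i in fx.instances}
        for gen in (o for o in out if o.provenance == "augmented"):
            assert gen.synergy_score == by_id[gen.parent_id].synergy_score
            assert gen.cell_line == by_id[gen.parent_id].cell_line
        assert {o.cell_line for o in out} == {i.cell_line for i in fx.instances}

    def test_fixture_augmentation_enumerated(self, fixture_cohort):
        """At cutoff 0.5 the fixture yields exactly six generated instances."""
        fx = fixture_cohort
        subs = build_substitute_map(
            list(fx.originals), list(fx.candidates), fx.profiles, fx.universe, 0.5
        )
        out = augment_dataset(list(fx.instances), subs)
        generated = {(o.pair, o.cell_line) for o in out if o.provenance == "augmented"}
        assert generated == {
            (("d2", "s1"), "c1"),
            (("d1", "s1"), "c1"),
            (("d3", "s1"), "c2"),
            (("d1", "s2"), "c2"),
            (("d4", "s1"), "c3"),
            (("d4", "s2"), "c1"),
        }

    def test_count_law_pre_dedup(self, small_cohort):
        """Generated count equals sum of substitute-list sizes minus drops."""
        cohort = small_cohort
        subs = build_substitute_map(
            list(cohort.originals), list(cohort.candidates), cohort.profiles,
            cohort.universe, 0.6,
        )
        out = augment_dataset(list(cohort.instances), subs)
        n_generated = sum(1 for o in out if o.provenance == "augmented")
        expected = 0
        seen = {(i.pair, i.cell_line) for i in cohort.instances}
        for inst in cohort.instances:
            for replaced, partner in (
                (inst.drug_a, inst.drug_b), (inst.drug_b, inst.drug_a)
            ):
                for cand, _ in subs.for_drug(replaced):
                    if cand == partner:
                        continue
                    key = (tuple(sorted((cand, partner))), inst.cell_line)
                    if key in seen:
                        continue
                    seen.add(key)
                    expected += 1
        assert n_generated == expected

    def test_substitutes_stay_in_cluster_above_separation(self, small_cohort):
        """With a high cutoff, substitutes come from the replaced drug's cluster."""
        cohort = small_cohort
        subs = build_substitute_map(
            list(cohort.originals), list(cohort.candidates), cohort.profiles,
            cohort.universe, 0.6,
        )
        same = total = 0
        for drug, hits in subs.substitutes.items():
            for cand, _ in hits:
                total += 1
                same += cohort.drug_cluster[cand] == cohort.drug_cluster[drug]
        assert total > 0
        assert same / total > 1 / cohort.spec.n_clusters  # beats the base rate
        assert same == total  # at 0.6 the separation is in fact complete


class TestLabeling:
    def test_boundary_values(self):
        instances = [
            make_instance(1, "A", "B", "C1", 20.0),
            make_instance(2, "A", "C", "C1", 0.0),
            make_instance(3, "A", "D", "C1", -20.0),
        ]
        labeled, report = label_instances(instances)
        assert [l.label for l in labeled] == [SYNERGISTIC, ANTAGONISTIC]
        assert report.n_synergistic == 1
        assert report.n_antagonistic == 1
        assert report.n_excluded == 1

    def test_report_totals_and_prevalence(self):
        report = LabelReport(n_synergistic=3, n_antagonistic=1)
        assert report.total == 4
        assert report.synergistic_prevalence == pytest.approx(0.75)

    def test_invalid_cut_order_rejected(self):
        with pytest.raises(ValidationError):
            label_instances([], syn_cut=-20, ant_cut=20)


class TestRatioPreservingAugment:
    def _train(self):
        return [
            make_labeled("T1", "A", "B", "C1", 30, SYNERGISTIC),
            make_labeled("T2", "A", "C", "C1", 25, SYNERGISTIC),
            make_labeled("T3", "B", "C", "C2", 40, SYNERGISTIC),
            make_labeled("T4", "A", "D", "C1", -30, ANTAGONISTIC),
        ]

    def _pool(self, n_syn, n_ant):
        pool = []
        for i in range(n_syn):
            pool.append(
                make_labeled(f"PS{i}", "A", f"S{i}", "C1", 30, SYNERGISTIC, parent="T1")
            )
        for i in range(n_ant):
            pool.append(
                make_labeled(f"PA{i}", "D", f"S{i}", "C1", -30, ANTAGONISTIC,
                             parent="T4")
            )
        return pool

    def test_three_to_one_ratio(self):
        out, report = ratio_preserving_augment(
            self._train(), self._pool(60, 60), seed=0, max_total=40
        )
        assert report.added_synergistic == 30
        assert report.added_antagonistic == 10

    def test_empty_pool_is_identity(self):
        train = self._train()
        out, report = ratio_preserving_augment(train, [], seed=0)
        assert out == train
        assert report.added_synergistic == report.added_antagonistic == 0

    def test_one_sided_pool_bounded_with_shortfall(self):
        out, report = ratio_preserving_augment(self._train(), self._pool(50, 0), seed=0)
        # only synergistic available: additions stop at the ratio bound
        assert report.added_antagonistic == 0
        assert 0 < report.added_synergistic <= 3
        assert report.shortfall[SYNERGISTIC] == 50 - report.added_synergistic

    def test_leakage_rule_enforced(self):
        bad = [make_labeled("PX", "A", "S9", "C1", 30, SYNERGISTIC, parent="OUTSIDE")]
        with pytest.raises(ValidationError):
            ratio_preserving_augment(self._train(), bad, seed=0)

    def test_deterministic_for_a_seed(self):
        a, _ = ratio_preserving_augment(self._train(), self._pool(20, 20), seed=7,
                                        max_total=10)
        b, _ = ratio_preserving_augment(self._train(), self._pool(20, 20), seed=7,
                                        max_total=10)
        assert [i.instance_id for i in a] == [i.instance_id for i in b]

    def test_large_addition_tracks_ratio(self):
        out, report = ratio_preserving_augment(self._train(), self._pool(90, 20),
                                               seed=1)
        added = report.added_synergistic + report.added_antagonistic
        assert added > 0
        # added class counts follow the 3:1 train ratio within one instance
        assert abs(report.added_synergistic - 3 * report.added_antagonistic) <= 3


class TestDistributionSummary:
    def test_constant_scores(self):
        s = synergy_distribution_summary(
            [make_instance(1, "A", "B", "C", 10.0), make_instance(2, "A", "C", "C", 10.0)]
        )
        assert s.mean == 10.0 and s.sd == 0.0

    def test_population_sd(self):
        s = synergy_distribution_summary(
            [make_instance(1, "A", "B", "C", 0.0), make_instance(2, "A", "C", "C", 20.0)]
        )
        assert s.mean == 10.0 and s.sd == 10.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            synergy_distribution_summary([])

    def test_histogram_conserves_counts(self, small_cohort):
        s = synergy_distribution_summary(list(small_cohort.instances))
        assert s.counts.sum() == len(small_cohort.instances)

    def test_augmented_mean_close_to_original(self, small_cohort):
        """Score inheritance keeps the augmented distribution near the original."""
        from dacsaug import augment_dataset, build_substitute_map

        cohort = small_cohort
        subs = build_substitute_map(
            list(cohort.originals), list(cohort.candidates), cohort.profiles,
            cohort.universe, 0.6,
        )
        out = augment_dataset(list(cohort.instances), subs)
        orig = synergy_distribution_summary(list(cohort.instances))
        aug = synergy_distribution_summary(out)
        assert abs(aug.mean - orig.mean) < orig.sd
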