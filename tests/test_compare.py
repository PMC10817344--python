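"""Group completion profiles, variability selection, phi association, and
classical test statistics."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from phycomet.compare import (
    GroupCompletionProfile,
    block_presence_matrix,
    completion_rate,
    core_module_sets,
    group_completion_profiles,
    presence_group_correlation,
    stat_tests,
    variable_modules,
    write_correlations,
    write_profiles,
    write_variable_modules,
    write_venn_regions,
)
from phycomet.completeness import AnnotationSet, Category, CompletenessResult
from phycomet.module_model import parse_definition


def _result(grade: int, assembly="a", module="M90001") -> CompletenessResult:
    blocks_total = 4
    blocks_present = {1: 4, 2: 3, 3: 2, 4: 1, 5: 0}[grade]
    return CompletenessResult(
        module_id=module,
        assembly_id=assembly,
        blocks_total=blocks_total,
        blocks_present=blocks_present,
        steps_total=blocks_total,
        steps_present=blocks_present,
        category=Category(grade),
    )


class TestCompletionRate:
    def test_loose_counts_one_block_missing(self):
        results = [_result(1), _result(2), _result(2), _result(4)]
        assert completion_rate(results, loose=True) == 0.75
        assert completion_rate(results, loose=False) == 0.25

    def test_extremes(self):
        assert completion_rate([_result(5)] * 3) == 0.0
        assert completion_rate([_result(1)] * 3) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            completion_rate([])


class TestVariableModules:
    def _profile(self, module_id, *rates, threshold=0.2):
        sd = float(np.std(rates, ddof=0))
        return GroupCompletionProfile(
            module_id, dict(enumerate(rates)), sd, sd >= threshold
        )

    def test_population_sd_closed_forms(self):
        assert self._profile("M1", 1, 1, 1, 1).sd == 0.0
        assert self._profile("M2", 1, 0).sd == 0.5
        assert self._profile("M3", 1, 1, 1, 0.2).sd == pytest.approx(
            math.sqrt(0.12)
        )  # = 0.3464...

    def test_selection_and_ordering(self):
        profiles = [
            self._profile("M2", 1, 0),
            self._profile("M1", 1, 1, 1, 1),
            self._profile("M3", 1, 1, 1, 0.2),
        ]
        selected = variable_modules(profiles, 0.2)
        assert [p.module_id for p in selected] == ["M2", "M3"]

    def test_threshold_zero_selects_everything(self):
        profiles = [self._profile("M1", 1, 1), self._profile("M2", 1, 0)]
        assert len(variable_modules(profiles, 0.0)) == 2

    @pytest.mark.parametrize("bad", [-0.1, 1.01])
    def test_threshold_bounds(self, bad):
        with pytest.raises(ValueError):
            variable_modules([], bad)


class TestProfiles:
    def test_requires_two_groups(self, graded):
        with pytest.raises(ValueError, match="two groups"):
            group_completion_profiles(graded, {a: "only" for a in graded.grades.index})

    def test_never_loose_modules_are_dropped(self, dataset, graded):
        profiles = group_completion_profiles(graded, dataset.group_assignment)
        kept = {p.module_id for p in profiles}
        for module in dataset.modules:
            loose_any = any(
                graded.results[(a.assembly_id, module.module_id)].loosely_complete
                for a in dataset.annotations
            )
            assert (module.module_id in kept) == loose_any

    def test_rates_in_unit_interval(self, dataset, graded):
        profiles = group_completion_profiles(graded, dataset.group_assignment)
        for p in profiles:
            assert all(0.0 <= r <= 1.0 for r in p.rates.values())
            assert p.sd >= 0.0
            assert p.variable == (p.sd >= 0.2)


class TestCoreModuleSets:
    def _matrix(self, grades_by_assembly, module="M90001"):
        from phycomet.completeness import GradeMatrix
        import pandas as pd

        results = {
            (a, module): _result(g, assembly=a, module=module)
            for a, g in grades_by_assembly.items()
        }
        frame = pd.DataFrame(
            {module: [g for g in grades_by_assembly.values()]},
            index=list(grades_by_assembly),
        )
        return GradeMatrix(results=results, grades=frame)

    def test_half_prevalence_boundary_inclusive(self):
        gm = self._matrix({"a1": 1, "a2": 2, "a3": 5, "a4": 5, "b1": 1, "b2": 1})
        groups = {"a1": "A", "a2": "A", "a3": "A", "a4": "A", "b1": "B", "b2": "B"}
        core, regions = core_module_sets(gm, groups, prevalence=0.5)
        assert core == {"A": {"M90001"}, "B": {"M90001"}}  # 2 of 4 makes the cut
        assert regions[("A", "B")] == 1 and regions[("A",)] == 0

    def test_region_sum_equals_union(self, dataset, graded):
        core, regions = core_module_sets(graded, dataset.group_assignment)
        assert sum(regions.values()) == len(set().union(*core.values()))

    @pytest.mark.parametrize("bad", [0.0, 1.5, -0.2])
    def test_prevalence_bounds(self, graded, dataset, bad):
        with pytest.raises(ValueError):
            core_module_sets(graded, dataset.group_assignment, prevalence=bad)


class TestPhi:
    def test_perfect_association(self):
        indicator = [1] * 5 + [0] * 6
        assert presence_group_correlation(indicator, indicator).phi == pytest.approx(1.0)

    def test_perfect_anti_association(self):
        indicator = [1] * 5 + [0] * 6
        complement = [1 - v for v in indicator]
        assert presence_group_correlation(complement, indicator).phi == pytest.approx(-1.0)

    def test_closed_form_half(self):
        presence = [1, 1, 1, 0, 1, 0, 0, 0]
        indicator = [1, 1, 1, 1, 0, 0, 0, 0]  # n11=3 n10=1 n01=1 n00=3
        assert presence_group_correlation(presence, indicator).phi == pytest.approx(0.5)

    def test_undefined_when_margin_zero(self):
        res = presence_group_correlation([1, 1, 1], [1, 0, 1])
        assert res.undefined and res.phi is None

    def test_matches_pearson_on_raw_vectors(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            x = rng.integers(0, 2, size=12)
            y = rng.integers(0, 2, size=12)
            res = presence_group_correlation(x, y)
            if res.undefined:
                assert x.std() == 0 or y.std() == 0
            else:
                assert res.phi == pytest.approx(
                    float(np.corrcoef(x, y)[0, 1]), abs=1e-12
                )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(17)
        x = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        y = np.array([1, 1, 0, 1, 0, 0, 1, 0])
        base = presence_group_correlation(x, y).phi
        perm = rng.permutation(len(x))
        assert presence_group_correlation(x[perm], y[perm]).phi == pytest.approx(base)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            presence_group_correlation([1, 0], [1, 0, 1])


class TestBlockPresenceMatrix:
    def test_feature_ids_and_values(self):
        modules = [parse_definition("K00001 K00002,K00003", module_id="M90001")]
        anns = [
            AnnotationSet("a1", frozenset({"K00001", "K00003"})),
            AnnotationSet("a2", frozenset()),
        ]
        frame = block_presence_matrix(modules, anns)
        assert list(frame.columns) == ["M90001.1", "M90001.2"]
        assert frame.loc["a1"].tolist() == [1, 1]
        assert frame.loc["a2"].tolist() == [0, 0]

    def test_row_sums_equal_blocks_present(self, dataset, graded):
        frame = block_presence_matrix(dataset.modules, dataset.annotations)
        for ann in dataset.annotations[:4]:
            for module in dataset.modules[:25]:
                cols = [
                    f"{module.module_id}.{i}" for i in range(1, module.blocks_total + 1)
                ]
                expected = graded.results[(ann.assembly_id, module.module_id)]
                assert frame.loc[ann.assembly_id, cols].sum() == expected.blocks_present


class TestStatTests:
    def test_identical_groups(self):
        out = stat_tests([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert out["welch_t"].statistic == 0.0
        assert out["welch_t"].pvalue == 1.0

    def test_zero_within_variance_flags_error(self):
        out = stat_tests([0, 0, 1, 1], ["a", "a", "b", "b"])
        assert out["one_way_anova_F"].error is not None
        assert out["welch_t"].error is not None

    def test_welch_hand_calculation(self):
        # {1,2,3} vs {2,4,6}: t = -2/sqrt(5/3), Welch-Satterthwaite df = 450/153
        out = stat_tests([1, 2, 3, 2, 4, 6], ["a"] * 3 + ["b"] * 3)
        t = out["welch_t"]
        assert t.statistic == pytest.approx(-2 / math.sqrt(5 / 3))
        assert t.df == pytest.approx(450 / 153)
        sp_t, sp_p = sps.ttest_ind([1, 2, 3], [2, 4, 6], equal_var=False)[:2]
        assert t.statistic == pytest.approx(float(sp_t))
        assert t.pvalue == pytest.approx(float(sp_p))

    def test_anova_and_levene_match_scipy(self):
        rng = np.random.default_rng(23)
        values = rng.normal(size=15)
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        out = stat_tests(values, groups)
        f, p = sps.f_oneway(values[:5], values[5:10], values[10:])
        assert out["one_way_anova_F"].statistic == pytest.approx(float(f))
        assert out["one_way_anova_F"].pvalue == pytest.approx(float(p))
        w, wp = sps.levene(values[:5], values[5:10], values[10:], center="mean")
        assert out["levene_W"].statistic == pytest.approx(float(w))
        assert out["levene_W"].pvalue == pytest.approx(float(wp))
        assert out["welch_t"].error is not None  # three groups

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="fewer than two"):
            stat_tests([1, 2, 3], ["a", "a", "b"])


def test_tsv_exports_are_deterministic(tmp_path, dataset, graded):
    profiles = group_completion_profiles(graded, dataset.group_assignment)
    _, regions = core_module_sets(graded, dataset.group_assignment)
    correlations = [
        presence_group_correlation([1, 0, 1, 0], [1, 0, 1, 0], feature_id="K00001",
                                   grouping="order")
    ]
    for writer, payload, name in (
        (write_profiles, profiles, "profiles.tsv"),
        (write_variable_modules, profiles, "variable.tsv"),
        (write_venn_regions, regions, "venn.tsv"),
        (write_correlations, correlations, "corr.tsv"),
    ):
        first, second = tmp_path / ("a_" + name), tmp_path / ("b_" + name)
        writer(payload, first)
        writer(payload, second)
        assert first.read_text() == second.read_text()
        assert first.read_text().count("\n") >= 1
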