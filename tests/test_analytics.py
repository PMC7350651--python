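import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isotrace import analytics
from isotrace.analytics import (
    NormalizationSpec,
    SampleGroup,
    compare_metabolites,
    enrichment,
    group_stats,
    isotopologue_view,
    kinetic_series,
    mid,
    normalize_abundances,
    quantitative_abundance,
    sample_values,
    total_abundance,
)
from isotrace.exceptions import MissingInputError


class TestMid:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([10, 0, 0], [1, 0, 0]),
            ([50, 30, 20], [0.5, 0.3, 0.2]),
            ([2, 2, 2, 2], [0.25] * 4),
        ],
    )
    def test_examples(self, counts, expected):
        assert np.allclose(mid(counts), expected)

    def test_all_zero_flagged_missing(self):
        assert mid([0.0, 0.0]) is None

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mid([1.0, -0.5])

    @settings(max_examples=80, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1e9, allow_nan=False),
            min_size=1, max_size=10,
        ).filter(lambda v: sum(v) > 0)
    )
    def test_always_sums_to_one(self, counts):
        assert math.isclose(mid(counts).sum(), 1.0, abs_tol=1e-12)


class TestEnrichment:
    @pytest.mark.parametrize(
        "vec,n,expected",
        [
            ([0, 0, 0, 0, 0, 1], 5, 1.0),
            ([1, 0, 0, 0], 5, 0.0),
            ([0.5, 0, 0.5], 2, 0.5),
        ],
    )
    def test_examples(self, vec, n, expected):
        assert math.isclose(enrichment(vec, n), expected, abs_tol=1e-12)

    def test_zero_atoms_rejected(self):
        with pytest.raises(ValueError):
            enrichment([1.0], 0)

    def test_overlong_mid_rejected(self):
        with pytest.raises(ValueError):
            enrichment([0.5, 0.5, 0.0], 1)

    @settings(max_examples=80, deadline=None)
    @given(
        st.integers(min_value=1, max_value=8),
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1, max_size=9,
        ).filter(lambda v: sum(v) > 0),
    )
    def test_bounded_and_weighted_mean(self, n, raw):
        vec = np.asarray(raw[: n + 1])
        if vec.sum() == 0:
            return
        vec = vec / vec.sum()
        e = enrichment(vec, n)
        assert 0.0 <= e <= 1.0
        assert math.isclose(e, float(np.arange(len(vec)) @ vec) / n, abs_tol=1e-12)

    def test_monotone_under_upward_mass_move(self):
        base = np.array([0.4, 0.3, 0.2, 0.1])
        shifted = np.array([0.3, 0.3, 0.2, 0.2])  # mass moved M0 -> M3
        assert enrichment(shifted, 3) > enrichment(base, 3)


class TestTotalAbundance:
    @pytest.mark.parametrize(
        "counts,expected", [([50, 30, 20], 100.0), ([0, 0], 0.0), ([7], 7.0)]
    )
    def test_examples(self, counts, expected):
        assert total_abundance(counts) == expected


class TestGroupStats:
    def test_mean_and_sample_sd(self):
        stats = group_stats({"a": 1.0, "b": 2.0, "c": 3.0}, [SampleGroup("g", ["a", "b", "c"])])
        assert stats[0].mean == 2.0
        assert math.isclose(stats[0].sd, 1.0)
        assert stats[0].n == 3

    def test_singleton_sd_zero(self):
        (s,) = group_stats({"a": 5.0}, [SampleGroup("g", ["a"])])
        assert (s.mean, s.sd, s.n) == (5.0, 0.0, 1)

    def test_constant_values_sd_zero(self):
        (s,) = group_stats(
            {"a": 0.1, "b": 0.1, "c": 0.1}, [SampleGroup("g", ["a", "b", "c"])]
        )
        assert s.sd == 0.0

    def test_missing_values_excluded(self):
        (s,) = group_stats(
            {"a": 1.0, "b": None, "c": float("nan"), "d": 3.0},
            [SampleGroup("g", ["a", "b", "c", "d"])],
        )
        assert s.n == 2 and s.mean == 2.0

    def test_empty_group_flagged_absent(self):
        (s,) = group_stats({"a": None}, [SampleGroup("g", ["a"])])
        assert s.absent and s.n == 0

    def test_duplicated_samples_double_n_preserve_mean(self):
        g1 = group_stats({"a": 1.0, "b": 3.0}, [SampleGroup("g", ["a", "b"])])[0]
        g2 = group_stats(
            {"a": 1.0, "b": 3.0, "a2": 1.0, "b2": 3.0},
            [SampleGroup("g", ["a", "b", "a2", "b2"])],
        )[0]
        assert g2.n == 2 * g1.n
        assert g2.mean == g1.mean


class TestNormalization:
    def test_internal_standard_division(self, corrected):
        spec = NormalizationSpec(internal_standard="nor260")
        normalize_abundances(corrected, spec)
        raw = analytics.abundance_frame(corrected)
        expected = raw.loc["cit459"] / raw.loc["nor260"]
        assert np.allclose(
            corrected.normalized_abundance.loc["cit459"], expected
        )

    def test_reference_group_mean_exactly_one(self, corrected):
        spec = NormalizationSpec(
            internal_standard="nor260", reference_group="Normoxia"
        )
        normalize_abundances(corrected, spec)
        ref = corrected.group("Normoxia").samples
        for name in corrected.fragments:
            assert math.isclose(
                corrected.normalized_abundance.loc[name, ref].mean(), 1.0,
                rel_tol=1e-12,
            )

    def test_cell_counts_scale_groups(self, corrected):
        spec = NormalizationSpec(
            cell_counts={"Normoxia": 638333.0, "Hypoxia": 668750.0}
        )
        normalize_abundances(corrected, spec)
        raw = analytics.abundance_frame(corrected)
        for group, count in (("Normoxia", 638333.0), ("Hypoxia", 668750.0)):
            cols = corrected.group(group).samples
            assert np.allclose(
                corrected.normalized_abundance.loc["cit459", cols],
                raw.loc["cit459", cols] / count,
            )

    def test_steps_compose_like_one_shot_scaling(self, corrected):
        # standard -> cells -> reference must equal a single composite scale
        spec = NormalizationSpec(
            internal_standard="nor260",
            cell_counts={"Normoxia": 638333.0, "Hypoxia": 668750.0},
            reference_group="Normoxia",
        )
        normalize_abundances(corrected, spec)
        stepwise = corrected.normalized_abundance.copy()

        raw = analytics.abundance_frame(corrected)
        composite = raw / raw.loc["nor260"]
        for g in corrected.groups:
            composite[g.samples] = composite[g.samples] / g.cell_count
        ref = corrected.group("Normoxia").samples
        composite = composite.div(composite[ref].mean(axis=1), axis=0)
        assert np.allclose(stepwise.to_numpy(), composite.to_numpy(), rtol=1e-12)

    def test_simple_ratio_example(self, corrected):
        # A(m)=100, A(std)=50 -> 2.0, no other steps
        frame = analytics.abundance_frame(corrected)
        spec = NormalizationSpec(internal_standard="nor260")
        normalize_abundances(corrected, spec)
        sample = corrected.samples[0]
        assert math.isclose(
            corrected.normalized_abundance.loc["suc289", sample],
            frame.loc["suc289", sample] / frame.loc["nor260", sample],
            rel_tol=1e-12,
        )

    def test_zero_standard_sample_flagged(self, corrected, caplog):
        corrected.fragments["nor260"].raw[corrected.samples[0]] = 0.0
        spec = NormalizationSpec(internal_standard="nor260")
        normalize_abundances(corrected, spec)
        assert np.isnan(
            corrected.normalized_abundance.loc["cit459", corrected.samples[0]]
        )
        values = corrected.normalized_abundance.loc["cit459"].to_dict()
        stats = group_stats(values, corrected.groups)
        assert stats[0].n == len(corrected.group("Normoxia").samples) - 1

    def test_unknown_standard_rejected(self, corrected):
        with pytest.raises(KeyError):
            normalize_abundances(corrected, NormalizationSpec(internal_standard="nope"))

    def test_missing_cell_count_rejected(self, corrected):
        with pytest.raises(MissingInputError):
            normalize_abundances(
                corrected, NormalizationSpec(cell_counts={"Normoxia": 1.0})
            )


class TestQuantitativeAbundance:
    def test_linear_calibration(self, corrected):
        frame = analytics.abundance_frame(corrected)
        a = frame.loc["cit459", corrected.samples[0]]
        spec = NormalizationSpec(standards={"cit459": (10.0, 100.0)})
        amounts, unquantified = quantitative_abundance(corrected, spec)
        assert math.isclose(
            amounts.loc["cit459", corrected.samples[0]], a * 10.0 / 100.0
        )
        assert "suc289" in unquantified

    def test_zero_response_unquantified(self, corrected):
        spec = NormalizationSpec(standards={"cit459": (10.0, 0.0)})
        amounts, unquantified = quantitative_abundance(corrected, spec)
        assert "cit459" in unquantified

    def test_zero_abundance_zero_amount(self, corrected):
        corrected.fragments["cit459"].raw[:] = 0.0
        spec = NormalizationSpec(standards={"cit459": (10.0, 100.0)})
        amounts, _ = quantitative_abundance(corrected, spec)
        assert (amounts.loc["cit459"] == 0.0).all()


class TestKineticSeries:
    def _with_times(self, corrected, times):
        for g, t in zip(corrected.groups, times):
            g.time = t
        return corrected

    def test_time_ordered(self, corrected):
        self._with_times(corrected, [4.0, 2.0])
        series = kinetic_series(corrected, "cit459", "enrichment")
        assert [s.group for s in series] == ["Hypoxia", "Normoxia"]
        assert [s.time for s in series] == [2.0, 4.0]

    def test_duplicate_times_name_tiebreak(self, corrected):
        self._with_times(corrected, [1.0, 1.0])
        series = kinetic_series(corrected, "cit459", "enrichment")
        assert [s.group for s in series] == ["Hypoxia", "Normoxia"]

    def test_missing_time_rejected_with_names(self, corrected):
        self._with_times(corrected, [1.0, None])
        with pytest.raises(MissingInputError, match="Hypoxia"):
            kinetic_series(corrected, "cit459", "enrichment")


class TestCompareMetabolites:
    def test_cardinality(self, corrected):
        table, skipped = compare_metabolites(
            corrected,
            ["cit459", "akg346", "suc289", "fum287"],
            ["Normoxia", "Hypoxia"],
            "enrichment",
        )
        assert len(table) == 8 and not skipped

    def test_empty_selection(self, corrected):
        table, skipped = compare_metabolites(corrected, [], ["Normoxia"], "enrichment")
        assert table == {} and skipped == []

    def test_absent_metabolite_skipped(self, corrected):
        table, skipped = compare_metabolites(
            corrected, ["nothere", "cit459"], ["Normoxia"], "abundance"
        )
        assert ("nothere", "not in dataset") in skipped
        assert ("cit459", "Normoxia") in table

    def test_out_of_range_isotopologue_skipped(self, corrected):
        # pyr174 has 4 channels; M5 is out of range
        table, skipped = compare_metabolites(
            corrected, ["pyr174"], ["Normoxia"], "isotopologue_fraction", isotopologue=5
        )
        assert table == {}
        assert skipped and skipped[0][0] == "pyr174"
        assert "out of range" in skipped[0][1]

    def test_hypoxia_enrichment_signature(self, corrected, huh7):
        table, _ = compare_metabolites(
            corrected, ["cit459"], ["Normoxia", "Hypoxia"], "enrichment"
        )
        n = huh7.spec.true_mids[("cit459", "Normoxia")]
        h = huh7.spec.true_mids[("cit459", "Hypoxia")]
        assert math.isclose(
            table[("cit459", "Normoxia")].mean, enrichment(n, 6), abs_tol=1e-8
        )
        assert math.isclose(
            table[("cit459", "Hypoxia")].mean, enrichment(h, 6), abs_tol=1e-8
        )


class TestIsotopologueView:
    def test_truncates_without_renormalizing(self, corrected):
        view = isotopologue_view(corrected, "cit459", 6)
        assert list(view.index) == [f"M{i}" for i in range(6)]
        assert (view.sum(axis=0) < 1.0 + 1e-12).all()
        # underlying data unchanged
        assert corrected.fragments["cit459"].corrected.shape[0] == 7

    def test_full_limit_is_identity(self, corrected):
        view = isotopologue_view(corrected, "cit459", 7)
        assert np.allclose(
            view.to_numpy(), analytics.mid_frame(corrected, "cit459").to_numpy()
        )

    @pytest.mark.parametrize("limit", [0, 8, -1])
    def test_out_of_range_rejected(self, corrected, limit):
        with pytest.raises(ValueError):
            isotopologue_view(corrected, "cit459", limit)


class TestSampleValues:
    def test_enrichment_requires_labelable_count(self, corrected):
        fd = corrected.fragments["cit459"]
        object.__setattr__(fd.spec, "n_labelable", 0)
        with pytest.raises(MissingInputError, match="element count"):
            sample_values(corrected, "cit459", "enrichment")

    def test_unknown_quantity_rejected(self, corrected):
        with pytest.raises(ValueError):
            sample_values(corrected, "cit459", "zorp")

    def test_normalized_before_normalizing_rejected(self, corrected):
        with pytest.raises(MissingInputError):
            sample_values(corrected, "cit459", "normalized_abundance")
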