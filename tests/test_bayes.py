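"""Naive Bayes core: training, interval lookup, posteriors, chunk round trips."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import antbayes as ab
from antbayes.bayes import Dataset, locate_interval

from conftest import make_comp, make_model


def _dataset(values, labels, kind="continuous", name="x"):
    X = pd.DataFrame({name: values})
    return Dataset(X, pd.Series(labels), [(name, kind)])


class TestTraining:
    def test_laplace_smoothed_bin_frequency(self):
        # 10 class-A rows all in the lower of two equal-width bins, 4 class-B
        # rows in the upper: p(bin0 | A) = (10 + 1) / (10 + 2)
        values = list(np.linspace(0.0, 0.9, 10)) + [6.0, 7.0, 8.0, 10.0]
        labels = ["A"] * 10 + ["B"] * 4
        model = ab.train_naive_bayes(
            _dataset(values, labels), n_bins=2, binning="equal_width", smoothing=1.0
        )
        comp = model.composition("x")
        assert comp.boundaries == pytest.approx([0.0, 5.0, 10.0])
        a = model.class_labels.index("A")
        assert comp.chunks[0].cond_probs[a] == pytest.approx(11 / 12)

    def test_equal_class_counts_give_uniform_priors(self):
        model = ab.train_naive_bayes(
            _dataset([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1]), n_bins=2, smoothing=0.0
        )
        assert model.class_priors == pytest.approx([0.5, 0.5])

    def test_conditionals_sum_to_one_per_class(self, cohort):
        model = ab.train_naive_bayes(cohort, n_bins=6)
        for comp in model.continuous_attrs:
            assert comp.probs_matrix().sum(axis=0) == pytest.approx([1.0, 1.0], abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="degenerate labels"):
            ab.train_naive_bayes(_dataset([1.0, 2.0], [0, 0]))

    def test_excess_bins_merged_with_warning(self):
        with pytest.warns(UserWarning, match="merged"):
            model = ab.train_naive_bayes(
                _dataset([1.0, 1.0, 1.0, 2.0], [0, 0, 1, 1]), n_bins=4
            )
        bounds = model.composition("x").boundaries
        assert np.all(np.diff(bounds) > 0)

    def test_discrete_attribute_table(self):
        model = ab.train_naive_bayes(
            _dataset(["a", "a", "b", "b"], [0, 0, 1, 1], kind="discrete"),
            smoothing=0.0,
        )
        table = model.discrete_table("x")
        assert table.value_probs["a"] == pytest.approx([1.0, 0.0])
        for c in range(2):
            assert sum(p[c] for p in table.value_probs.values()) == pytest.approx(1.0)

    def test_refining_bins_never_hurts_separable_training_j(self):
        data = ab.generate_dataset(
            ab.CohortConfig(
                600, 0.5, [ab.continuous_spec("m", separation=6.0)], seed=3
            )
        )
        js = [
            ab.j_score(ab.train_naive_bayes(data, n_bins=k), data) for k in (2, 4, 8)
        ]
        assert js == sorted(js)


class TestLocateInterval:
    comp = make_comp("x", [0, 3, 5, 10], [0.2, 0.3, 0.5], [0.5, 0.3, 0.2])

    @pytest.mark.parametrize(
        "value,expected",
        [(4.0, 1), (10.0, 2), (-1.0, 0), (0.0, 0), (3.0, 1), (11.0, 2)],
    )
    def test_half_open_with_clamping(self, value, expected):
        assert locate_interval(self.comp, value) == expected


class TestPosterior:
    def test_hand_computed_posterior(self):
        # priors (0.6, 0.4) and interval conditionals (0.5, 0.25):
        # unnormalized (0.30, 0.10) -> (0.75, 0.25)
        model = make_model(
            [make_comp("x", [0, 1, 2], [0.5, 0.5], [0.25, 0.75])], priors=(0.6, 0.4)
        )
        assert ab.posterior(model, {"x": 0.5}) == pytest.approx([0.75, 0.25])

    def test_symmetric_model_is_uninformative(self):
        model = make_model([make_comp("x", [0, 1, 2], [0.5, 0.5], [0.5, 0.5])])
        assert ab.posterior(model, {"x": 1.5}) == pytest.approx([0.5, 0.5])

    def test_posterior_normalized_nonnegative(self, cohort):
        model = ab.train_naive_bayes(cohort)
        post = model.posterior_frame(cohort.X)
        assert post.sum(axis=1) == pytest.approx(np.ones(len(cohort)), abs=1e-12)
        assert (post >= 0).all()

    def test_tie_breaks_to_first_label(self):
        model = make_model([make_comp("x", [0, 1, 2], [0.5, 0.5], [0.5, 0.5])])
        assert ab.predict(model, {"x": 0.5}) == 0

    def test_schema_mismatch_names_attribute(self, cohort):
        model = ab.train_naive_bayes(cohort)
        with pytest.raises(ValueError, match="marker"):
            model.predict_frame(cohort.X.drop(columns=["marker"]))

    def test_zero_probability_chunk_stays_finite(self):
        model = make_model([make_comp("x", [0, 1, 2], [0.0, 1.0], [1.0, 0.0])])
        post = ab.posterior(model, {"x": 0.5})
        assert np.isfinite(post).all() and post.sum() == pytest.approx(1.0)


class TestDecomposeAssemble:
    def test_decompose_yields_one_chunk_per_interval(self, cohort):
        model = ab.train_naive_bayes(cohort, n_bins=4)
        chunks = ab.decompose(model)
        assert len(chunks["marker"]) == model.composition("marker").n_chunks
        for c in chunks["marker"]:
            assert len(c.cond_probs) == 2

    def test_assemble_decompose_round_trip(self, cohort):
        model = ab.train_naive_bayes(cohort, n_bins=4)
        rebuilt = ab.assemble(
            model,
            {
                name: ab.AttributeComposition(
                    name,
                    model.composition(name).domain_lower,
                    model.composition(name).domain_upper,
                    chunks,
                )
                for name, chunks in ab.decompose(model).items()
                if chunks
            },
        )
        for comp, orig in zip(rebuilt.continuous_attrs, model.continuous_attrs):
            assert np.array_equal(comp.boundaries, orig.boundaries)
            assert np.allclose(comp.probs_matrix(), orig.probs_matrix(), atol=1e-12)

    def test_assemble_leaves_other_attributes_untouched(self, cohort):
        model = ab.train_naive_bayes(cohort, n_bins=4)
        replacement = make_comp("marker", [0, 1, 2], [0.7, 0.3], [0.3, 0.7])
        out = ab.assemble(model, {"marker": replacement})
        assert out.composition("noise0") is model.composition("noise0") or np.array_equal(
            out.composition("noise0").probs_matrix(),
            model.composition("noise0").probs_matrix(),
        )
        # base unmodified
        assert model.composition("marker").n_chunks != 2

    def test_assemble_renormalizes_replacement(self, cohort):
        model = ab.train_naive_bayes(cohort, n_bins=4)
        lopsided = make_comp("marker", [0, 1, 2], [0.8, 0.6], [0.1, 0.2])
        out = ab.assemble(model, {"marker": lopsided})
        assert out.composition("marker").probs_matrix().sum(axis=0) == pytest.approx(
            [1.0, 1.0], abs=1e-9
        )

    def test_assemble_unknown_attribute_raises(self, cohort):
        model = ab.train_naive_bayes(cohort)
        with pytest.raises(KeyError):
            ab.assemble(model, {"nope": make_comp("nope", [0, 1], [1.0], [1.0])})


class TestSerialization:
    def test_json_round_trip_is_exact(self, cohort):
        model = ab.train_naive_bayes(cohort, n_bins=5)
        back = ab.NaiveBayesClassifier.from_json(model.to_json())
        assert back.class_priors == model.class_priors
        for a, b in zip(back.continuous_attrs, model.continuous_attrs):
            assert a.boundaries.tolist() == b.boundaries.tolist()
            assert a.probs_matrix().tolist() == b.probs_matrix().tolist()

    def test_json_file_round_trip(self, cohort, tmp_path):
        model = ab.train_naive_bayes(cohort)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ab.NaiveBayesClassifier.from_json(path)
        assert back.to_json() == model.to_json()


class TestDataset:
    def test_missing_values_rejected_with_row_index(self):
        X = pd.DataFrame({"x": [1.0, np.nan, 3.0]})
        with pytest.raises(ValueError, match=r"rows \[1\]"):
            Dataset(X, pd.Series([0, 1, 0]), [("x", "continuous")])

    def test_csv_round_trip(self, cohort, tmp_path):
        path = tmp_path / "d.csv"
        cohort.to_csv(path)
        back = Dataset.from_csv(path)
        assert back.schema == cohort.schema
        assert np.allclose(back.X.to_numpy(), cohort.X.to_numpy())


@given(
    st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
    st.lists(st.floats(0.01, 1.0), min_size=6, max_size=6),
)
def test_renormalized_compositions_always_sum_to_one(p0, p1):
    n = len(p0)
    comp = make_comp("x", list(range(n + 1)), p0, p1[:n])
    assert comp.renormalized().probs_matrix().sum(axis=0) == pytest.approx(
        [1.0, 1.0], abs=1e-9
    )
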