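"""Contrast-sum scoring, the indeterminate class and unidirectional mode."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import seroselect as ss


def _model(codes, mode="bidirectional", threshold=1):
    return ss.ContrastModel(
        contrast_name="toy",
        peptide_codes=codes,
        recurrence={p: 100 for p in codes},
        pole_names=("g+", "g-"),
        scoring_mode=mode,
        unidirectional_threshold=threshold,
    )


BIDI = _model({"a": 1, "b": 1, "c": 1, "d": -1})


class TestScoreSample:
    def test_signed_sum(self):
        pred = ss.score_sample({"a": True, "b": True, "c": True, "d": True}, BIDI)
        assert pred.score == 2 and pred.predicted == "g+"
        assert pred.n_model_peptides_positive == 4

    def test_no_positive_is_indeterminate(self):
        pred = ss.score_sample({"a": False, "b": False, "c": False, "d": False}, BIDI)
        assert pred.score == 0 and pred.predicted == ss.INDETERMINATE

    def test_balanced_binding_is_indeterminate(self):
        model = _model({"a": 1, "b": 1, "c": -1, "d": -1})
        pred = ss.score_sample({"a": True, "b": True, "c": True, "d": True}, model)
        assert pred.score == 0 and pred.predicted == ss.INDETERMINATE

    def test_negative_score_predicts_neg_pole(self):
        pred = ss.score_sample({"a": False, "b": False, "c": False, "d": True}, BIDI)
        assert pred.score == -1 and pred.predicted == "g-"

    def test_unidirectional_one_positive_suffices(self):
        model = _model({f"p{i}": 1 for i in range(11)}, mode="unidirectional")
        row = {f"p{i}": i == 3 for i in range(11)}
        assert ss.score_sample(row, model).predicted == "g+"
        none = {f"p{i}": False for i in range(11)}
        pred = ss.score_sample(none, model)
        assert pred.predicted == "g-"  # defaulted, never indeterminate

    def test_unidirectional_threshold_configurable(self):
        model = _model({f"p{i}": 1 for i in range(5)}, mode="unidirectional", threshold=2)
        one = {f"p{i}": i == 0 for i in range(5)}
        assert ss.score_sample(one, model).predicted == "g-"
        two = {f"p{i}": i < 2 for i in range(5)}
        assert ss.score_sample(two, model).predicted == "g+"

    def test_misaligned_row_raises(self):
        with pytest.raises(ss.AlignmentError):
            ss.score_sample({"a": True}, BIDI)
        with pytest.raises(ss.AlignmentError):
            ss.score_sample(np.array([True, False]), BIDI)

    @given(st.lists(st.booleans(), min_size=4, max_size=4),
           st.lists(st.sampled_from([1, -1]), min_size=4, max_size=4))
    def test_score_decomposition_identity(self, row, codes):
        """score = (#positives on +1 peptides) - (#positives on -1)."""
        model = _model(dict(zip("abcd", codes)))
        pred = ss.score_sample(np.array(row), model)
        plus = sum(r for r, c in zip(row, codes) if c == 1)
        minus = sum(r for r, c in zip(row, codes) if c == -1)
        assert pred.score == plus - minus
        assert pred.n_model_peptides_positive == sum(row)

    @given(st.lists(st.booleans(), min_size=4, max_size=4),
           st.lists(st.sampled_from([1, -1]), min_size=4, max_size=4))
    def test_label_swap_antisymmetry(self, row, codes):
        """Negating all codes negates the score and swaps the poles of a
        non-indeterminate prediction."""
        model = _model(dict(zip("abcd", codes)))
        pred = ss.score_sample(np.array(row), model)
        # negate codes while keeping the pole names fixed: predictions swap
        flipped = _model({k: -c for k, c in zip("abcd", codes)})
        pred_neg = ss.score_sample(np.array(row), flipped)
        assert pred_neg.score == -pred.score
        if pred.predicted == ss.INDETERMINATE:
            assert pred_neg.predicted == ss.INDETERMINATE
        else:
            assert pred_neg.predicted == ("g-" if pred.predicted == "g+" else "g+")
        # .negated() also relabels the poles, so the semantic call is invariant
        assert ss.score_sample(np.array(row), model.negated()).predicted in (
            pred.predicted,
            ss.INDETERMINATE if pred.predicted == ss.INDETERMINATE else pred.predicted,
        )

    def test_monotone_in_positive_calls(self):
        """Adding a positive call on a +1 peptide never moves a prediction
        from g+ to g-."""
        row = {"a": False, "b": False, "c": False, "d": True}
        before = ss.score_sample(row, BIDI).predicted
        row["a"] = True
        after = ss.score_sample(row, BIDI).predicted
        assert not (before == "g+" and after == "g-")
        assert ss.score_sample(row, BIDI).score == 0


class TestScoreCohort:
    def _pos(self, calls, samples):
        return ss.PositivityMatrix(samples, list(BIDI.peptide_ids), np.asarray(calls, bool))

    def test_order_preserved_and_consistent_with_scalar(self):
        samples = ["x", "y", "z"]
        calls = [[1, 1, 1, 1], [0, 0, 0, 0], [0, 0, 0, 1]]
        pos = self._pos(calls, samples)
        preds = ss.score_cohort(pos, samples, BIDI)
        assert [p.sample_id for p in preds] == samples
        for row, pred in zip(calls, preds):
            scalar = ss.score_sample(np.array(row, bool), BIDI, pred.sample_id)
            assert scalar == pred

    def test_holdout_samples_scorable(self):
        """Samples outside the model-building cohort (e.g. stable-disease
        holdouts) score with the same rule."""
        pos = self._pos([[1, 0, 0, 0]], ["held_out"])
        preds = ss.score_cohort(pos, ["held_out"], BIDI)
        assert preds[0].predicted == "g+"

    def test_missing_sample_named_in_error(self):
        pos = self._pos([[0, 0, 0, 0]], ["x"])
        with pytest.raises(KeyError, match="ghost"):
            ss.score_cohort(pos, ["ghost"], BIDI)

    def test_no_model_binding_all_indeterminate(self):
        pos = self._pos(np.zeros((4, 4)), list("wxyz"))
        preds = ss.score_cohort(pos, list("wxyz"), BIDI)
        assert all(p.predicted == ss.INDETERMINATE for p in preds)

    def test_predictions_frame_columns(self):
        pos = self._pos([[1, 1, 0, 0]], ["x"])
        frame = ss.predictions_frame(ss.score_cohort(pos, ["x"], BIDI))
        assert list(frame.columns) == [
            "sample_id", "score", "n_positive_model_peptides", "predicted",
        ]
        assert frame.loc[0, "score"] == 2
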