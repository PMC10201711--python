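"""Chi-square correctness and stability-selection behaviour."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

import seroselect as ss
from seroselect.selection import _chisq_vec


def _pearson_oracle(a, b, c, d):
    """Independent expected-count formula: sum (O-E)^2 / E."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    n = obs.sum()
    exp = np.outer(obs.sum(1), obs.sum(0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (obs - exp) ** 2 / exp
    return float(np.nansum(np.where(exp > 0, terms, 0.0)))


class TestChisq2x2:
    def test_identical_proportions(self):
        stat, p = ss.chisq_2x2(5, 5, 5, 5)
        assert stat == 0.0 and p == 1.0

    def test_hand_derived_table(self):
        # (ad-bc)^2 * N / (r1 r2 c1 c2) = 200^2 * 40 / 120000
        stat, p = ss.chisq_2x2(10, 10, 0, 20)
        assert stat == pytest.approx(40000 * 40 / 120000)
        assert p == pytest.approx(2.607296e-4, rel=1e-5)

    def test_zero_margin_convention(self):
        assert ss.chisq_2x2(0, 20, 0, 20) == (0.0, 1.0)
        assert ss.chisq_2x2(20, 0, 20, 0) == (0.0, 1.0)

    def test_all_zero_raises(self):
        with pytest.raises(ss.DegenerateTableError):
            ss.chisq_2x2(0, 0, 0, 0)

    def test_negative_counts_raise(self):
        with pytest.raises(ss.ConfigError):
            ss.chisq_2x2(-1, 2, 3, 4)

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    def test_matches_expected_count_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        stat, _ = ss.chisq_2x2(a, b, c, d)
        if min(a + b, c + d, a + c, b + d) == 0:
            assert stat == 0.0
        else:
            assert stat == pytest.approx(_pearson_oracle(a, b, c, d), abs=1e-10)

    @given(st.integers(1, 30), st.integers(1, 30), st.integers(1, 30), st.integers(1, 30))
    def test_matches_scipy_contingency(self, a, b, c, d):
        """Independent library route agrees, with and without the
        continuity correction."""
        stat, p = ss.chisq_2x2(a, b, c, d)
        res = chi2_contingency([[a, b], [c, d]], correction=False)
        assert stat == pytest.approx(res.statistic, abs=1e-10)
        assert p == pytest.approx(res.pvalue, abs=1e-12)
        stat_y, _ = ss.chisq_2x2(a, b, c, d, yates=True)
        res_y = chi2_contingency([[a, b], [c, d]], correction=True)
        assert stat_y == pytest.approx(res_y.statistic, abs=1e-10)

    def test_vectorised_agrees_with_scalar(self):
        rng = np.random.default_rng(7)
        tables = rng.integers(0, 25, size=(200, 4))
        tables = tables[tables.sum(1) > 0]
        stat_v, p_v = _chisq_vec(*tables.T)
        for row, sv, pv in zip(tables, stat_v, p_v):
            s, p = ss.chisq_2x2(*row)
            assert sv == pytest.approx(s, abs=1e-12)
            assert pv == pytest.approx(p, abs=1e-12)


def _two_group_matrix(n_per_group=20, prev_pos=0.6, prev_neg=0.0, n_null=5):
    """Deterministic positivity matrix: one planted peptide with the given
    per-pole positive fractions plus balanced null peptides."""
    n = 2 * n_per_group
    samples = [f"s{i}" for i in range(n)]
    labels = {s: ("g+" if i < n_per_group else "g-") for i, s in enumerate(samples)}
    cohort = ss.ContrastCohort("toy", samples, labels, "g+", "g-")
    calls = np.zeros((n, 1 + n_null), dtype=bool)
    calls[: int(prev_pos * n_per_group), 0] = True
    calls[n_per_group : n_per_group + int(prev_neg * n_per_group), 0] = True
    for j in range(n_null):  # same prevalence in both poles
        calls[:10, 1 + j] = True
        calls[n_per_group : n_per_group + 10, 1 + j] = True
    peptides = ["planted"] + [f"null{j}" for j in range(n_null)]
    pos = ss.PositivityMatrix(samples, peptides, calls)
    return pos, cohort, peptides


class TestResampleSelect:
    def test_degenerate_resampling_equals_full_cohort_test(self):
        pos, cohort, peptides = _two_group_matrix()
        cfg = ss.SelectionConfig(subsample_fraction=1.0, n_iterations=1,
                                 recurrence_threshold=1, seed=0)
        rec = ss.resample_select(pos, cohort, peptides, cfg)
        for pep in peptides:
            a = sum(
                pos.submatrix([s], [pep])[0, 0]
                for s in cohort.pole_samples("g+")
            )
            c = sum(
                pos.submatrix([s], [pep])[0, 0]
                for s in cohort.pole_samples("g-")
            )
            _, p = ss.chisq_2x2(a, 20 - a, c, 20 - c)
            assert rec[pep] == int(p < cfg.p_threshold)

    def test_planted_peptide_recurs_null_does_not(self):
        pos, cohort, peptides = _two_group_matrix()
        cfg = ss.SelectionConfig(seed=13)
        rec = ss.resample_select(pos, cohort, peptides, cfg)
        assert rec["planted"] >= cfg.recurrence_threshold
        for j in range(5):
            assert rec[f"null{j}"] < cfg.recurrence_threshold

    def test_determinism_across_runs(self):
        pos, cohort, peptides = _two_group_matrix()
        cfg = ss.SelectionConfig(seed=99)
        assert ss.resample_select(pos, cohort, peptides, cfg) == ss.resample_select(
            pos, cohort, peptides, cfg
        )

    def test_returns_all_candidates_including_zero(self):
        pos, cohort, peptides = _two_group_matrix()
        rec = ss.resample_select(pos, cohort, peptides, ss.SelectionConfig(seed=1))
        assert set(rec) == set(peptides)

    def test_label_swap_leaves_recurrence_unchanged(self):
        pos, cohort, peptides = _two_group_matrix()
        cfg = ss.SelectionConfig(seed=5)
        rec = ss.resample_select(pos, cohort, peptides, cfg)
        rec_swapped = ss.resample_select(pos, cohort.swapped(), peptides, cfg)
        assert rec == rec_swapped


class TestAssignDirections:
    def test_majority_rule_codes(self):
        pos, cohort, _ = _two_group_matrix(prev_pos=0.5, prev_neg=0.0)
        model = ss.assign_directions(pos, cohort, ["planted"])
        assert model.peptide_codes == {"planted": 1}

    def test_minority_codes_negative(self):
        pos, cohort, _ = _two_group_matrix(prev_pos=0.15, prev_neg=0.35)
        model = ss.assign_directions(pos, cohort, ["planted"])
        assert model.peptide_codes == {"planted": -1}

    def test_tie_dropped_with_warning(self, caplog):
        # 'planted' is directional; 'null0' is balanced 10 vs 10 (a tie)
        pos, cohort, _ = _two_group_matrix(prev_pos=0.5, prev_neg=0.0)
        with caplog.at_level("WARNING"):
            model = ss.assign_directions(pos, cohort, ["planted", "null0"])
        assert model.peptide_codes == {"planted": 1}
        assert any("tied" in r.message for r in caplog.records)

    def test_all_tied_raises(self):
        pos, cohort, _ = _two_group_matrix(prev_pos=0.2, prev_neg=0.2)
        with pytest.raises(ss.EmptyModelError):
            ss.assign_directions(pos, cohort, ["planted"])

    def test_empty_retained_raises(self):
        pos, cohort, _ = _two_group_matrix()
        with pytest.raises(ss.EmptyModelError):
            ss.assign_directions(pos, cohort, [])

    def test_label_swap_negates_codes(self):
        pos, cohort, peptides = _two_group_matrix()
        cfg = ss.SelectionConfig(seed=5)
        m1 = ss.build_model(pos, cohort, peptides, cfg, auto_unidirectional=False)
        m2 = ss.build_model(pos, cohort.swapped(), peptides, cfg, auto_unidirectional=False)
        assert m2.peptide_codes == {p: -c for p, c in m1.peptide_codes.items()}
        assert m2.recurrence == m1.recurrence


class TestBuildModel:
    def test_one_sided_model_switches_to_unidirectional(self):
        pos, cohort, peptides = _two_group_matrix()
        model = ss.build_model(pos, cohort, peptides, ss.SelectionConfig(seed=2))
        assert model.scoring_mode == "unidirectional"
        assert set(model.peptide_codes.values()) == {1}

    def test_model_json_round_trip(self, tmp_path):
        pos, cohort, peptides = _two_group_matrix()
        model = ss.build_model(pos, cohort, peptides, ss.SelectionConfig(seed=2))
        path = tmp_path / "model.json"
        model.to_json(path)
        assert ss.ContrastModel.from_json(path) == model

    def test_seed_robustness_jaccard(self):
        pos, cohort, peptides = _two_group_matrix()
        m1 = ss.build_model(pos, cohort, peptides, ss.SelectionConfig(seed=1))
        m2 = ss.build_model(pos, cohort, peptides, ss.SelectionConfig(seed=2))
        assert ss.model_jaccard(m1, m2) == 1.0
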