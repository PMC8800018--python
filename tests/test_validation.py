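"""Docking-power and screening-power metrics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from ensemblevs.validation import (
    HIGHER_IS_ACTIVE,
    LOWER_IS_ACTIVE,
    ScoreTable,
    ValidationReport,
    choose_mode,
    docking_power,
    enrichment_factor,
    pose_rmsd,
    roc_auc,
    two_sample_ttest,
)


class FakePose:
    def __init__(self, elements, coords):
        self.atoms = [type("A", (), {"element": e, "xyz": tuple(x)})()
                      for e, x in zip(elements, coords)]


class TestPoseRMSD:
    def test_identical_pose_is_zero(self):
        p = FakePose("CCO", np.arange(9.0).reshape(3, 3))
        assert pose_rmsd(p, p) == 0.0

    def test_single_atom_displacement(self):
        a = FakePose("C", [[0, 0, 0]])
        b = FakePose("C", [[0, 0, 2.0]])
        assert pose_rmsd(a, b) == pytest.approx(2.0)

    def test_hydrogens_excluded(self):
        a = FakePose(["C", "H"], [[0, 0, 0], [0, 0, 0]])
        b = FakePose(["C", "H"], [[0, 0, 1.0], [9, 9, 9]])
        assert pose_rmsd(a, b) == pytest.approx(1.0)

    def test_hungarian_beats_ordered_and_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            coords = rng.uniform(-3, 3, size=(4, 3))
            elements = ["C", "C", "O", "O"]
            # swap the symmetric C pair and jitter
            perm = [1, 0, 2, 3]
            other = coords[perm] + rng.normal(0, 0.1, size=(4, 3))
            a, b = FakePose(elements, coords), FakePose(elements, other)
            hung = pose_rmsd(a, b, matching="element_hungarian")
            ordered = pose_rmsd(a, b, matching="ordered")
            assert hung <= ordered + 1e-12
            # brute force over within-element permutations
            best = np.inf
            for pc in itertools.permutations([0, 1]):
                for po in itertools.permutations([2, 3]):
                    idx = list(pc) + list(po)
                    msd = np.mean(np.sum((coords - other[idx]) ** 2, axis=1))
                    best = min(best, np.sqrt(msd))
            assert hung == pytest.approx(best, abs=1e-10)

    def test_atom_count_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            pose_rmsd(FakePose("C", [[0, 0, 0]]), FakePose("CC", [[0, 0, 0], [1, 1, 1]]))


class TestDockingPower:
    @pytest.mark.parametrize(
        "rmsd,expected", [(0.776, True), (2.0, True), (2.01, False), (0.0, True)]
    )
    def test_threshold_inclusive(self, rmsd, expected):
        assert docking_power(rmsd) is expected

    def test_negative_rmsd_is_error(self):
        with pytest.raises(ValueError):
            docking_power(-0.1)


class TestTTest:
    def test_identical_samples(self):
        t, p = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_student(self):
        # pooled s^2 = 1, df = 4 -> t = -sqrt(3/2), p ~ 0.2879
        t, p = two_sample_ttest([1, 2, 3], [2, 3, 4], variant="student")
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert p == pytest.approx(0.2879, abs=1e-4)

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, 100)
        b = rng.normal(3.0, 1.0, 100)
        _, p = two_sample_ttest(a, b)
        assert p < 1e-10

    def test_student_equals_welch_for_balanced_equal_variance(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 50)
        b = a + 0.5  # identical sample variance, shifted mean
        ts, ps = two_sample_ttest(a, b, variant="student")
        tw, pw = two_sample_ttest(a, b, variant="welch")
        assert ts == pytest.approx(tw, abs=1e-12)
        assert ps == pytest.approx(pw, abs=1e-12)

    def test_degenerate_zero_variance(self):
        assert two_sample_ttest([1.0, 1.0], [1.0, 1.0])[1] == 1.0
        assert two_sample_ttest([1.0, 1.0], [2.0, 2.0])[1] == 0.0

    def test_too_small_sample(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0], [1.0, 2.0])


def pairwise_auc(scores, labels, orientation):
    """Brute-force oracle: count active-decoy pairs, ties half."""
    s = np.asarray(scores, float)
    if orientation == LOWER_IS_ACTIVE:
        s = -s
    act = s[np.asarray(labels) == 1]
    dec = s[np.asarray(labels) == 0]
    wins = sum((a > d) + 0.5 * (a == d) for a in act for d in dec)
    return wins / (len(act) * len(dec))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([-9, -8, -5, -4], [1, 1, 0, 0], LOWER_IS_ACTIVE) == 1.0

    def test_all_ties(self):
        assert roc_auc([1.0] * 6, [1, 1, 1, 0, 0, 0], LOWER_IS_ACTIVE) == 0.5

    def test_worked_examples(self):
        assert roc_auc([-9, -7, -8, -6], [1, 0, 1, 0], LOWER_IS_ACTIVE) == 1.0
        assert roc_auc([-9, -8, -7, -6], [1, 0, 1, 0], LOWER_IS_ACTIVE) == 0.75

    def test_complement_identity_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = rng.integers(0, 10, 30).astype(float)
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            assert roc_auc(s, y, LOWER_IS_ACTIVE) + roc_auc(s, 1 - y, LOWER_IS_ACTIVE) == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        a1 = roc_auc(s, y, LOWER_IS_ACTIVE)
        a2 = roc_auc(np.exp(3 * s) + 7, y, LOWER_IS_ACTIVE)
        assert a1 == pytest.approx(a2, abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_rank_method_equals_pairwise_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 200))
        scores = rng.integers(-10, 0, n).astype(float)  # duplicates guaranteed
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        ours = roc_auc(scores, labels, LOWER_IS_ACTIVE)
        assert ours == pytest.approx(pairwise_auc(scores, labels, LOWER_IS_ACTIVE), abs=1e-12)

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        s = rng.normal(size=300)
        y = rng.integers(0, 2, 300)
        y[:2] = [0, 1]
        assert roc_auc(s, y, HIGHER_IS_ACTIVE) == pytest.approx(
            sk.roc_auc_score(y, s), abs=1e-12
        )

    def test_gaussian_closed_form(self):
        # AUC -> Phi(delta / (sigma sqrt 2)) for equal-variance Gaussians
        rng = np.random.default_rng(6)
        n = 2000
        a = rng.normal(-3.0, 1.0, n)
        d = rng.normal(0.0, 1.0, n)
        s = np.concatenate([a, d])
        y = np.array([1] * n + [0] * n)
        expected = norm.cdf(3.0 / np.sqrt(2.0))
        assert roc_auc(s, y, LOWER_IS_ACTIVE) == pytest.approx(expected, abs=0.01)

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1], LOWER_IS_ACTIVE)

    def test_missing_scores_dropped(self):
        s = [-9.0, np.nan, -5.0, -4.0]
        y = [1, 1, 0, 0]
        assert roc_auc(s, y, LOWER_IS_ACTIVE) == 1.0


class TestEnrichmentFactor:
    def test_perfect_ranking_closed_form(self):
        y = np.array([1] * 5 + [0] * 95)
        s = np.concatenate([np.full(5, -9.0), np.full(95, -5.0)])
        assert enrichment_factor(s, y, 0.05) == pytest.approx(20.0)

    def test_random_labels_near_one(self):
        rng = np.random.default_rng(7)
        n = 20000
        s = rng.normal(size=n)
        y = rng.random(n) < 0.05
        assert enrichment_factor(s, y.astype(int), 0.2) == pytest.approx(1.0, abs=0.15)

    def test_worked_ten_compound_table(self):
        s = [-10, -9, -8, -7, -6, -5, -4, -3, -2, -1]
        y = [1, 0, 1, 0, 0, 0, 0, 1, 0, 0]
        # top 30% = 3 compounds, 2 actives -> (2/3)/(3/10) = 20/9
        assert enrichment_factor(s, y, 0.3) == pytest.approx(20.0 / 9.0)

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            enrichment_factor([1.0], [1], 0.0)


def _report(rows):
    df = pd.DataFrame(rows).set_index(["conformation_id", "mode"])
    return ValidationReport(table=df)


class TestChooseMode:
    def test_smaller_p_wins(self):
        rep = _report([
            {"conformation_id": "2A5U", "mode": "SP", "log10_p": -157.79, "auc": 0.77},
            {"conformation_id": "2A5U", "mode": "XP", "log10_p": -127.01, "auc": 0.77},
        ])
        assert choose_mode(rep) == {"2A5U": "SP"}

    def test_xp_wins_when_its_p_is_smaller(self):
        rep = _report([
            {"conformation_id": "4WWO", "mode": "SP", "log10_p": -83.31, "auc": 0.72},
            {"conformation_id": "4WWO", "mode": "XP", "log10_p": -102.10, "auc": 0.73},
        ])
        assert choose_mode(rep) == {"4WWO": "XP"}

    def test_ties_break_to_auc_then_first_listed(self):
        rep = _report([
            {"conformation_id": "C1", "mode": "SP", "log10_p": -50.0, "auc": 0.70},
            {"conformation_id": "C1", "mode": "XP", "log10_p": -50.0, "auc": 0.80},
            {"conformation_id": "C2", "mode": "SP", "log10_p": -50.0, "auc": 0.75},
            {"conformation_id": "C2", "mode": "XP", "log10_p": -50.0, "auc": 0.75},
        ])
        assert choose_mode(rep) == {"C1": "XP", "C2": "SP"}


class TestScoreTableIO:
    def test_csv_roundtrip_lossless(self, tmp_path):
        idx = ["CPD0", "CPD1", "CPD2"]
        cols = pd.MultiIndex.from_tuples(
            [("C1", "SP"), ("C1", "XP"), ("C2", "SP")],
            names=["conformation_id", "mode"],
        )
        df = pd.DataFrame(
            [[-9.0, -8.5, np.nan], [-7.0, -6.5, -7.2], [-5.0, -5.5, -5.2]],
            index=idx, columns=cols,
        )
        table = ScoreTable(scores=df, labels=pd.Series([1, 0, 0], index=idx))
        path = tmp_path / "scores.csv"
        table.to_csv(path)
        back = ScoreTable.from_csv(path)
        pd.testing.assert_frame_equal(
            back.scores.sort_index(axis=1), df.sort_index(axis=1), check_names=False
        )
        assert dict(back.labels) == {"CPD0": 1, "CPD1": 0, "CPD2": 0}

    def test_label_validation(self):
        idx = ["A", "B"]
        cols = pd.MultiIndex.from_tuples([("C1", "SP")])
        df = pd.DataFrame([[1.0], [2.0]], index=idx, columns=cols)
        with pytest.raises(ValueError, match="0/1"):
            ScoreTable(scores=df, labels=pd.Series([1, 2], index=idx))
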