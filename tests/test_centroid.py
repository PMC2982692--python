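"""Shrunken-centroid core: brute-force oracles, shrinkage laws, baseline."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snpshrink.centroid import (NumericShrunkenCentroid, ShrunkenCentroid,
                                soft_threshold)
from snpshrink.io import CATEGORIES, GenotypeMatrix, SNPMeta
from snpshrink.simulate import SyntheticSpec, generate

from conftest import make_matrix


# --------------------------------------------------------------------------
# independent straight-line recomputation (dict/loop arithmetic only)

def brute_force(g: GenotypeMatrix, n_categories=4, m_rule="subtract",
                s0_rule="median"):
    classes = sorted(set(g.labels))
    n, p = g.calls.shape
    K = len(classes)
    members = {c: [j for j in range(n) if g.labels[j] == c] for c in classes}

    def dist(sample_idx, snp):
        cnt = Counter(int(g.calls[j, snp]) for j in sample_idx)
        return [cnt.get(c, 0) / len(sample_idx) for c in range(n_categories)]

    f_class = {(i, c): dist(members[c], i) for i in range(p) for c in classes}
    f_all = {i: dist(range(n), i) for i in range(p)}
    s = []
    for i in range(p):
        total = 0.0
        for c in classes:
            f = f_class[(i, c)]
            for j in members[c]:
                e = [1.0 if int(g.calls[j, i]) == cat else 0.0
                     for cat in range(n_categories)]
                total += sum((a - b) ** 2 for a, b in zip(e, f))
        s.append(math.sqrt(total / (n - K)))
    s0 = sorted(s)[len(s) // 2] if len(s) % 2 else \
        (sorted(s)[len(s) // 2 - 1] + sorted(s)[len(s) // 2]) / 2
    if s0_rule != "median":
        s0 = float(s0_rule)
    d = {}
    for i in range(p):
        for c in classes:
            nk = len(members[c])
            mk = math.sqrt(1 / nk - 1 / n) if m_rule == "subtract" else \
                math.sqrt(1 / nk + 1 / n)
            norm = math.sqrt(sum((a - b) ** 2 for a, b in
                                 zip(f_class[(i, c)], f_all[i])))
            d[(i, c)] = norm / (mk * (s[i] + s0))
    return {"classes": classes, "members": members, "f_class": f_class,
            "f_all": f_all, "s": s, "s0": s0, "d": d}


def brute_scores(g, oracle, delta, t_calls, priors):
    """delta_k(t) for one sample via plain loops."""
    classes = oracle["classes"]
    p = g.calls.shape[1]
    scores = {}
    for c in classes:
        total = 0.0
        for i in range(p):
            dik = oracle["d"][(i, c)]
            dsh = max(dik - delta, 0.0)
            fi = oracle["f_all"][i]
            fc = oracle["f_class"][(i, c)]
            if dik > 0:
                f = [a + (b - a) * dsh / dik for a, b in zip(fi, fc)]
            else:
                f = list(fi)
            e = [1.0 if int(t_calls[i]) == cat else 0.0 for cat in range(len(f))]
            total += sum((a - b) ** 2 for a, b in zip(e, f)) / \
                (oracle["s"][i] + oracle["s0"]) ** 2
        scores[c] = total - 2 * math.log(priors[c])
    return scores


def random_matrix(seed, n=10, p=6, K=2):
    rng = np.random.default_rng(seed)
    calls = rng.integers(0, 4, size=(n, p)).astype(np.int8)
    labels = np.array([f"c{k}" for k in rng.integers(0, K, size=n)], dtype=object)
    labels[:K] = [f"c{k}" for k in range(K)]  # every class non-empty
    return GenotypeMatrix(
        samples=[f"S{i}" for i in range(n)],
        labels=labels,
        snps=[SNPMeta(snp_id=f"snp{j}") for j in range(p)],
        calls=calls,
    )


# --------------------------------------------------------------------------

class TestSoftThreshold:
    @pytest.mark.parametrize("d,delta,expected", [
        (2.3, 1.5, 0.8), (1.0, 1.5, 0.0), (0.7, 0.0, 0.7), (0.0, 0.0, 0.0)])
    def test_values(self, d, delta, expected):
        assert soft_threshold(d, delta) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(-0.1, 0.0)
        with pytest.raises(ValueError):
            soft_threshold(0.1, -1.0)

    @settings(derandomize=True, max_examples=50)
    @given(d=st.floats(0, 1e6), delta=st.floats(0, 1e6))
    def test_contraction_properties(self, d, delta):
        out = soft_threshold(d, delta)
        assert 0.0 <= out <= d
        assert out == 0.0 or out == pytest.approx(d - delta)
        # thresholding twice with split amounts never keeps more than once
        half = soft_threshold(soft_threshold(d, delta / 2), delta / 2)
        assert half <= soft_threshold(d, delta) + 1e-9


class TestCentroidFit:
    def test_mode_of_reported_distribution_is_heterozygote(self):
        # class distribution (aa, aA, AA) = (0.0667, 0.5111, 0.4222):
        # the heterozygote is the most frequent category, hence the mode
        rows = [["Aa"]] * 23 + [["AA"]] * 19 + [["aa"]] * 3
        g = make_matrix(rows + [["AA"]] * 45,
                        labels=["YRI"] * 45 + ["CEU"] * 45)
        model = ShrunkenCentroid(g)
        k_yri = model.class_labels.index("YRI")
        assert CATEGORIES[model.class_modes[k_yri, 0]] == "Aa"
        np.testing.assert_allclose(
            model.class_dists[k_yri, 0, :3],
            [19 / 45, 23 / 45, 3 / 45], atol=1e-12)  # (AA, Aa, aa)

    def test_constant_snp_zero_distance(self):
        g = make_matrix([["AA", "AA"], ["AA", "Aa"], ["AA", "aa"],
                         ["AA", "aa"]], labels=["u", "u", "v", "v"])
        model = ShrunkenCentroid(g)
        assert model.s[0] == 0.0
        np.testing.assert_allclose(model.d[0], 0.0, atol=1e-15)

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random_matrices(self, seed):
        """d_ik, scores and labels match loop-arithmetic recomputation."""
        g = random_matrix(seed, n=12, p=8, K=3 if seed % 2 else 2)
        model = ShrunkenCentroid(g)
        oracle = brute_force(g)
        for i in range(g.n_snps):
            for k, c in enumerate(model.class_labels):
                assert model.d[i, k] == pytest.approx(oracle["d"][(i, c)],
                                                      abs=1e-10)
        assert model.s0 == pytest.approx(oracle["s0"], abs=1e-12)
        priors = dict(zip(model.class_labels, model.priors))
        for delta in (0.0, 0.5, 1.7):
            res = model.fit(delta)
            scores = res.predict_scores(g.calls)
            labels = res.predict(g.calls)
            for j in range(g.n_samples):
                expected = brute_scores(g, oracle, delta, g.calls[j], priors)
                for k, c in enumerate(model.class_labels):
                    assert scores[j, k] == pytest.approx(expected[c], abs=1e-10)
                best = min(expected.values())
                cand = [c for c in model.class_labels
                        if abs(expected[c] - best) < 1e-12]
                pick = min(cand, key=lambda c: (-priors[c],
                                                model.class_labels.index(c)))
                assert labels[j] == pick

    def test_six_sample_hand_computation(self, six_sample_matrix):
        model = ShrunkenCentroid(six_sample_matrix)
        oracle = brute_force(six_sample_matrix)
        np.testing.assert_allclose(
            model.d, [[oracle["d"][(i, c)] for c in oracle["classes"]]
                      for i in range(2)], atol=1e-12)

    def test_empty_class_rejected(self):
        g = make_matrix([["AA"], ["Aa"]], labels=["u", "u"])
        with pytest.raises(ValueError):
            ShrunkenCentroid(g)

    def test_three_category_distributions_exclude_missing(self):
        g = make_matrix([["AA"], ["missing"], ["Aa"], ["aa"]],
                        labels=["u", "u", "v", "v"])
        model = ShrunkenCentroid(g, include_missing=False)
        k_u = model.class_labels.index("u")
        # class u has one non-missing call (AA) -> distribution (1, 0, 0)
        np.testing.assert_allclose(model.class_dists[k_u, 0], [1, 0, 0])


class TestShrinkage:
    def test_delta_zero_is_identity(self, six_sample_matrix):
        model = ShrunkenCentroid(six_sample_matrix)
        res = model.fit(0.0)
        np.testing.assert_array_equal(res.shrunk_dists,
                                      model.class_dists)
        assert set(res.selected) == {i for i in range(model.p)
                                     if model.d[i].max() > 0}

    def test_full_shrinkage_collapses_to_overall(self, six_sample_matrix):
        model = ShrunkenCentroid(six_sample_matrix)
        res = model.fit(model.d.max() + 1.0)
        for k in range(model.K):
            np.testing.assert_allclose(res.shrunk_dists[k],
                                       model.overall_dists, atol=1e-12)
        assert len(res.selected) == 0

    def test_half_shrinkage_is_midpoint(self, six_sample_matrix):
        model = ShrunkenCentroid(six_sample_matrix)
        i, k = np.unravel_index(np.argmax(model.d), model.d.shape)
        delta = model.d[i, k] / 2.0
        res = model.fit(delta)
        mid = (model.class_dists[k, i] + model.overall_dists[i]) / 2.0
        np.testing.assert_allclose(res.shrunk_dists[k, i], mid, atol=1e-12)
        assert res.shrunk_dists[k, i].sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_distributions_remain_valid(self, seed):
        model = ShrunkenCentroid(random_matrix(seed, n=12, p=8))
        for delta in (0.0, 0.3, 1.0, 5.0):
            sd = model.fit(delta).shrunk_dists
            assert np.all(sd >= -1e-12)
            np.testing.assert_allclose(sd.sum(axis=2), 1.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_selection_monotone_in_delta(self, seed):
        model = ShrunkenCentroid(random_matrix(seed, n=12, p=10))
        grid = [0.0, 0.2, 0.5, 1.0, 2.0, 4.0]
        prev = None
        for delta in grid:
            cur = set(model.fit(delta).selected)
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_fully_shrunk_predicts_by_prior(self):
        g = make_matrix([["AA"], ["Aa"], ["aa"], ["AA"]],
                        labels=["u", "u", "u", "v"])
        model = ShrunkenCentroid(g)  # priors 0.75 / 0.25
        res = model.fit(model.d.max() + 1.0)
        assert all(lab == "u" for lab in res.predict(g.calls))


class TestClassify:
    def test_one_hot_match_wins(self):
        g = make_matrix([["AA"], ["AA"], ["Aa"], ["Aa"]],
                        labels=["u", "u", "v", "v"])
        res = ShrunkenCentroid(g, s0=0.5).fit(0.0)
        assert res.predict(np.array([[0]]))[0] == "u"   # AA
        assert res.predict(np.array([[1]]))[0] == "v"   # Aa

    def test_invalid_category_rejected(self):
        g = make_matrix([["AA"], ["Aa"], ["aa"], ["AA"]],
                        labels=["u", "u", "v", "v"])
        res = ShrunkenCentroid(g).fit(0.0)
        with pytest.raises(ValueError):
            res.predict(np.array([[7]]))

    def test_selected_snps_sorted_descending(self):
        g = random_matrix(3, n=12, p=10)
        rows = ShrunkenCentroid(g).fit(0.2).selected_snps()
        vals = [d.max() for _, d in rows]
        assert vals == sorted(vals, reverse=True)


class TestPermutationInvariance:
    def test_sample_and_snp_permutations(self):
        g = random_matrix(11, n=12, p=7)
        model = ShrunkenCentroid(g)
        rng = np.random.default_rng(0)
        sperm = rng.permutation(g.n_samples)
        jperm = rng.permutation(g.n_snps)
        g2 = g.subset_samples(sperm).subset_snps(jperm)
        model2 = ShrunkenCentroid(g2)
        np.testing.assert_allclose(model2.d, model.d[jperm], atol=1e-12)
        assert model2.s0 == pytest.approx(model.s0)
        res, res2 = model.fit(0.4), model2.fit(0.4)
        pred = res.predict(g.calls)[sperm]
        pred2 = res2.predict(g2.calls)
        assert list(pred) == list(pred2)


class TestNumericBaseline:
    def test_identical_means_select_nothing(self):
        g = make_matrix([["AA", "Aa"], ["aa", "AA"], ["AA", "Aa"],
                         ["aa", "AA"]], labels=["u", "u", "v", "v"])
        model = NumericShrunkenCentroid(g)
        np.testing.assert_allclose(model.d, 0.0, atol=1e-12)
        assert len(model.fit(0.0).selected) == 0

    def test_hand_computed_statistic(self):
        # one SNP, class means 1.0 (AA,AA) vs 3.0 (aa,aa); n=4, K=2
        g = make_matrix([["AA"], ["AA"], ["aa"], ["aa"]],
                        labels=["u", "u", "v", "v"])
        model = NumericShrunkenCentroid(g, s0=0.5)  # s_i = 0 within classes
        # d = (mean_k - overall)/ (m_k (s+s0)); overall = 2, m_k = sqrt(1/2-1/4)
        mk = math.sqrt(1 / 2 - 1 / 4)
        expected = (1.0 - 2.0) / (mk * 0.5)
        assert model.d[0, 0] == pytest.approx(expected, abs=1e-12)
        assert model.d[0, 1] == pytest.approx(-expected, abs=1e-12)

    def test_baseline_finds_planted_signal(self):
        g, man = generate(SyntheticSpec(seed=1))
        res = NumericShrunkenCentroid(g).fit(1.0)
        picked = {sid for sid, _ in res.selected_snps()}
        assert picked & set(man.informative_snps)


class TestSerialization:
    def test_json_round_trip_fields(self, six_sample_matrix, tmp_path):
        import json

        res = ShrunkenCentroid(six_sample_matrix).fit(0.5)
        path = tmp_path / "model.json"
        res.to_json(path)
        obj = json.loads(path.read_text())
        assert obj["delta"] == 0.5
        np.testing.assert_allclose(obj["d"], res.model.d)
        assert obj["selected_snp_ids"] == [s for s, _ in res.selected_snps()]
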