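import numpy as np
import pandas as pd
import pytest

from seqdx.exceptions import DataFormatError, DegenerateDataError
from seqdx.expression import ExpressionMatrix, normalize_log_cpm
from seqdx.subtypes import (SUBTYPE_CLASSES, classify_nsc, pam50_genes, train_nsc)


def brute_force_nsc(X, y, classes, delta, mk_plus=True):
    """Independent loop-based reimplementation of the shrunken-centroid
    training equations for small instances."""
    g, n = X.shape
    overall = X.mean(axis=1)
    nk = {c: int((y == c).sum()) for c in classes}
    cent = {c: X[:, y == c].mean(axis=1) for c in classes}
    ss = np.zeros(g)
    for c in classes:
        for j in np.nonzero(y == c)[0]:
            ss += (X[:, j] - cent[c]) ** 2
    s = np.sqrt(ss / (n - len(classes)))
    s0 = float(np.median(s))
    d, d_shrunk, shrunken = {}, {}, {}
    for c in classes:
        mk = np.sqrt(1.0 / nk[c] + (1.0 / n if mk_plus else -1.0 / n))
        denom = mk * (s + s0)
        d[c] = (cent[c] - overall) / denom
        d_shrunk[c] = np.sign(d[c]) * np.maximum(np.abs(d[c]) - delta, 0.0)
        shrunken[c] = overall + denom * d_shrunk[c]
    return overall, s, s0, d, d_shrunk, shrunken


def _matrix(X, classes=None):
    g, n = X.shape
    return ExpressionMatrix(pd.DataFrame(X, index=[f"g{i}" for i in range(g)],
                                         columns=[f"s{i}" for i in range(n)]),
                            scale="log2")


class TestTraining:
    def test_delta_zero_keeps_raw_centroids(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 1, (6, 12))
        y = np.array(["Basal", "LumA"] * 6)
        model = train_nsc(_matrix(X), y, delta=0.0)
        for j, c in enumerate(model.classes):
            np.testing.assert_allclose(model.shrunken_centroids[:, j],
                                       X[:, y == c].mean(axis=1), atol=1e-12)

    def test_full_shrinkage_collapses_to_overall_centroid(self):
        rng = np.random.default_rng(1)
        X = rng.normal(5, 1, (5, 10))
        y = np.array(["Basal", "LumA"] * 5)
        model = train_nsc(_matrix(X), y, delta=0.0)
        big = np.abs(model.d_shrunk).max() + np.abs(
            (model.shrunken_centroids - model.overall_centroid[:, None])).max() + 10
        shrunk = train_nsc(_matrix(X), y, delta=big)
        for j in range(len(shrunk.classes)):
            np.testing.assert_allclose(shrunk.shrunken_centroids[:, j],
                                       shrunk.overall_centroid, atol=1e-12)

    def test_worked_instance_matches_brute_force(self):
        # 2 genes, 2 classes, 4 samples
        X = np.array([[1.0, 2.0, 5.0, 6.0],
                      [3.0, 3.5, 2.0, 1.5]])
        y = np.array(["Basal", "Basal", "LumA", "LumA"])
        for delta in (0.0, 0.3, 1.0):
            model = train_nsc(_matrix(X), y, delta=delta)
            _, s, s0, d, d_shrunk, shrunken = brute_force_nsc(X, y,
                                                              model.classes, delta)
            np.testing.assert_allclose(model.s, s, atol=1e-10)
            assert model.s0 == pytest.approx(s0, abs=1e-10)
            for j, c in enumerate(model.classes):
                np.testing.assert_allclose(model.d_shrunk[:, j], d_shrunk[c], atol=1e-10)
                np.testing.assert_allclose(model.shrunken_centroids[:, j],
                                           shrunken[c], atol=1e-10)

    def test_minus_variant_normalization(self):
        X = np.array([[1.0, 2.0, 5.0, 6.0], [3.0, 3.5, 2.0, 1.5]])
        y = np.array(["Basal", "Basal", "LumA", "LumA"])
        model = train_nsc(_matrix(X), y, delta=0.2, minus_variant=True)
        _, _, _, _, d_shrunk, shrunken = brute_force_nsc(X, y, model.classes, 0.2,
                                                         mk_plus=False)
        for j, c in enumerate(model.classes):
            np.testing.assert_allclose(model.shrunken_centroids[:, j], shrunken[c],
                                       atol=1e-10)

    def test_small_class_rejected(self):
        X = np.random.default_rng(2).normal(0, 1, (3, 5))
        y = np.array(["Basal"] * 4 + ["LumA"])
        with pytest.raises(DegenerateDataError, match="LumA"):
            train_nsc(_matrix(X), y)

    def test_active_gene_count_non_increasing_in_delta(self):
        rng = np.random.default_rng(3)
        X = rng.normal(5, 1, (30, 40))
        X[:10, :20] += 1.0  # class-specific shift for some genes
        y = np.array(["Basal"] * 20 + ["LumA"] * 20)
        counts, maxima = [], []
        for delta in (0.0, 0.2, 0.5, 1.0, 2.0, 5.0):
            model = train_nsc(_matrix(X), y, delta=delta)
            counts.append(len(model.active_genes))
            maxima.append(np.abs(model.d_shrunk))
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        for a, b in zip(maxima, maxima[1:]):
            assert (b <= a + 1e-12).all()


class TestClassification:
    def test_sample_at_centroid_assigned_to_class(self):
        rng = np.random.default_rng(4)
        X = np.concatenate([rng.normal(3, 0.5, (8, 10)), rng.normal(6, 0.5, (8, 10))],
                           axis=1)
        y = np.array(["Basal"] * 10 + ["LumA"] * 10)
        model = train_nsc(_matrix(X), y, delta=0.0, priors=[0.5, 0.5])
        j = model.classes.index("LumA")
        call, scores = classify_nsc(model, dict(zip(model.genes,
                                                    model.shrunken_centroids[:, j])))
        assert call == "LumA"

    def test_full_shrinkage_defers_to_priors(self):
        rng = np.random.default_rng(5)
        X = rng.normal(5, 1, (6, 40))
        y = np.array((["Basal", "LumA", "LumB", "Her2"]) * 10)
        base = train_nsc(_matrix(X), y, delta=0.0)
        big = np.abs(base.d_shrunk).max() + 1
        model = train_nsc(_matrix(X), y, delta=big,
                          priors={"Basal": 0.1, "LumA": 0.7, "LumB": 0.1, "Her2": 0.1})
        rngq = np.random.default_rng(6)
        for _ in range(5):
            call, _ = classify_nsc(model, dict(zip(model.genes, rngq.normal(5, 1, 6))))
            assert call == "LumA"

    @pytest.mark.parametrize("seed", range(5))
    def test_delta_zero_equals_brute_force_nearest_centroid(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(5, 1, (10, 24))
        y = np.array(["Basal", "LumA", "LumB", "Her2"] * 6)
        model = train_nsc(_matrix(X), y, delta=0.0)
        _, s, s0, _, _, shrunken = brute_force_nsc(X, y, model.classes, 0.0)
        priors = {c: (y == c).mean() for c in model.classes}
        for _ in range(4):
            q = rng.normal(5, 1, 10)
            call, _ = classify_nsc(model, dict(zip(model.genes, q)))
            disc = {c: float(np.sum((q - shrunken[c]) ** 2 / (s + s0) ** 2)
                             - 2 * np.log(priors[c])) for c in model.classes}
            assert call == min(disc, key=disc.get)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.normal(5, 1, (8, 16))
        y = np.array(["Basal", "LumA"] * 8)
        model = train_nsc(_matrix(X), y, delta=0.1)
        q = dict(zip(model.genes, rng.normal(5, 1, 8)))
        call_a, _ = classify_nsc(model, q)
        shuffled = dict(reversed(list(q.items())))
        call_b, _ = classify_nsc(model, shuffled)
        assert call_a == call_b

    def test_missing_genes_listed(self):
        rng = np.random.default_rng(8)
        X = rng.normal(5, 1, (4, 8))
        y = np.array(["Basal", "LumA"] * 4)
        model = train_nsc(_matrix(X), y)
        with pytest.raises(DataFormatError, match="g3"):
            classify_nsc(model, {"g0": 1.0, "g1": 1.0, "g2": 1.0})


class TestCohortAccuracy:
    def test_holdout_accuracy_on_separated_centroids(self, strong_cohort):
        m = normalize_log_cpm(strong_cohort.expression)
        panel = m.subset_genes(pam50_genes())
        truth = strong_cohort.truth["subtype"]
        ids = list(panel.sample_ids)
        train_ids, test_ids = ids[::2], ids[1::2]
        train = ExpressionMatrix(panel.values[train_ids], scale="log2")
        test = ExpressionMatrix(panel.values[test_ids], scale="log2")
        model = train_nsc(train, truth.loc[train_ids], delta=0.0)
        calls, _ = classify_nsc(model, test)
        assert (calls == truth.loc[test_ids]).mean() >= 0.95

    def test_packaged_gene_list(self):
        genes = pam50_genes()
        assert len(genes) == 50 and len(set(genes)) == 50
        assert {"ESR1", "PGR", "ERBB2", "MKI67"} <= set(genes)
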