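"""Etiology classifiers: published tree, criteria rules, CART learner."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cementum.etiology import (
    FeatureVector,
    apply_published_tree,
    build_published_tree,
    classify_table3,
    fit_cart,
    leaf_purity,
    route_frame,
)


def _features(records):
    return pd.DataFrame([{
        "pref": r.pref, "ant": r.ant, "max_thi_um": r.max_thi_um,
        "wear_deg": r.wear_deg, "max_ve_um": r.max_ve_um,
    } for r in records])


class TestPublishedTree:
    def test_preferential_with_antagonist_is_hyperfunctional(self):
        res = apply_published_tree(FeatureVector(pref=True, ant=1,
                                                max_thi_um=1000, wear_deg=6))
        assert res.label == "HYPER" and res.leaf_id == "HYPER_pure"

    def test_nonpreferential_unscorable_wear_is_infected(self):
        res = apply_published_tree(FeatureVector(pref=False, ant=1,
                                                max_thi_um=2000, wear_deg=0))
        assert res.label == "INF"

    def test_mixed_premolar_lands_in_hyper_leaf(self, study_sample):
        r = next(x for x in study_sample if x.tooth_id == "Sp735_45")
        res = apply_published_tree(FeatureVector.from_record(r))
        assert res.leaf_id == "HYPER_worn" and res.label == "HYPER"

    def test_missing_elevation_on_worn_nonpref_path_unroutable(self):
        res = apply_published_tree(FeatureVector(pref=False, ant=1,
                                                max_thi_um=1400, wear_deg=3,
                                                max_ve_um=None))
        assert not res.routable
        assert any("unroutable" in t for t in res.trace)

    def test_leaf_compositions_on_study_sample(self, study_sample):
        tree = build_published_tree()
        results = route_frame(tree, _features(study_sample))
        comp = {}
        for res, rec in zip(results, study_sample):
            comp.setdefault(res.leaf_id, []).append(rec.etiology)
        counts = {k: sorted(v) for k, v in comp.items()}
        assert counts["HYPER_pure"] == ["HYPER"] * 8
        assert counts["MIX_thick"] == ["MIX"] * 5
        assert counts["IMP_pure"] == ["IMP"] * 2
        assert counts["HYPER_worn"] == ["HYPER"] * 4 + ["MIX"]
        assert counts["INF_pure"] == ["INF"] * 4
        assert counts["HYPO_pure"] == ["HYPO"] * 5
        assert counts["MIX_rough"] == ["MIX"] * 4

    def test_purity_six_of_seven(self, study_sample):
        tree = build_published_tree()
        n_pure, n_leaves, mis = leaf_purity(
            tree, _features(study_sample),
            [r.etiology for r in study_sample],
            ids=[r.tooth_id for r in study_sample],
        )
        assert (n_pure, n_leaves) == (6, 7)
        assert mis == ["Sp735_45"]

    def test_routing_is_permutation_invariant(self, study_sample):
        tree = build_published_tree()
        X = _features(study_sample)
        base = {r.tooth_id: res.leaf_id
                for r, res in zip(study_sample, route_frame(tree, X))}
        perm = np.random.default_rng(0).permutation(len(X))
        shuffled = [study_sample[i] for i in perm]
        out = {r.tooth_id: res.leaf_id
               for r, res in zip(shuffled, route_frame(tree, _features(shuffled)))}
        assert out == base


class TestTable3Rules:
    def test_impacted_profile(self, study_sample):
        r = next(x for x in study_sample if x.tooth_id == "Sp755_13")
        label, scores = classify_table3(r)
        assert label == "IMP"
        assert scores["IMP"] == (scores["IMP"][1], scores["IMP"][1])

    def test_pulp_exposure_nonpreferential_is_infected(self, study_sample):
        r = next(x for x in study_sample if x.tooth_id == "Sp1172_15")
        assert classify_table3(r)[0] == "INF"

    def test_featureless_vector_indeterminate(self):
        v = FeatureVector(pref=False, ant=3, max_thi_um=2000, wear_deg=5,
                          max_ve_um=500.0, pulp_exp="none", caries=False,
                          hc_stage=None)
        label, scores = classify_table3(v)
        assert label == "indeterminate"
        assert set(scores) == {"IMP", "INF", "HYPO", "HYPER"}


class TestCART:
    def test_single_class_gives_single_leaf(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        tree = fit_cart(X, ["a"] * 4)
        assert tree.root.is_leaf and tree.root.counts == {"a": 4}

    def test_separable_1d_splits_at_midpoint(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]})
        tree = fit_cart(X, list("aaabbb"), min_leaf=1)
        assert tree.root.variable == "x"
        assert tree.root.threshold == pytest.approx(6.5)
        assert tree.root.left.is_leaf and tree.root.right.is_leaf

    def test_first_split_matches_exhaustive_oracle(self, study_sample):
        X = pd.DataFrame({
            "pref": [str(r.pref) for r in study_sample],
            "ant": [str(r.ant) for r in study_sample],
            "max_thi_um": [r.max_thi_um for r in study_sample],
            "wear_deg": [float(r.wear_deg) for r in study_sample],
        })
        y = [r.etiology for r in study_sample]
        tree = fit_cart(X, y)

        def gini(labels):
            n = len(labels)
            if n == 0:
                return 0.0
            _, counts = np.unique(labels, return_counts=True)
            return 1.0 - ((counts / n) ** 2).sum()

        ya = np.asarray(y, dtype=object)
        n = len(ya)
        best = (0.0, None, None)
        for col in X.columns:
            vals = X[col]
            if vals.dtype == object:
                levels = sorted(vals.unique())
                for k in range(1, len(levels)):
                    for sub in itertools.combinations(levels, k):
                        m = vals.isin(sub).to_numpy()
                        if not m.any() or m.all():
                            continue
                        g = gini(ya) - (m.mean() * gini(ya[m])
                                        + (1 - m.mean()) * gini(ya[~m]))
                        if g > best[0] + 1e-12:
                            best = (g, col, frozenset(sub))
            else:
                sv = np.sort(vals.unique())
                for lo, hi in zip(sv, sv[1:]):
                    m = (vals < (lo + hi) / 2).to_numpy()
                    g = gini(ya) - (m.mean() * gini(ya[m])
                                    + (1 - m.mean()) * gini(ya[~m]))
                    if g > best[0] + 1e-12:
                        best = (g, col, (lo + hi) / 2)
        assert tree.root.variable == best[1]
        chosen = tree.root.threshold if tree.root.threshold is not None else tree.root.left_levels
        assert chosen == best[2]

    def test_matches_sklearn_on_separable_blobs(self):
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(5)
        X = pd.DataFrame({
            "u": np.concatenate([rng.normal(0, 1, 30), rng.normal(6, 1, 30)]),
            "v": rng.normal(size=60),
        })
        y = ["a"] * 30 + ["b"] * 30
        mine = fit_cart(X, y, min_leaf=2, max_depth=3)
        ref = DecisionTreeClassifier(min_samples_leaf=2, max_depth=3).fit(X, y)
        my_pred = [res.label for res in route_frame(mine, X)]
        assert my_pred == y
        assert list(ref.predict(X)) == y

    def test_tree_text_export_mentions_splits(self, study_sample):
        X = _features(study_sample).drop(columns=["max_ve_um"])
        X["pref"] = X["pref"].astype(str)
        X["ant"] = X["ant"].astype(str)
        tree = fit_cart(X, [r.etiology for r in study_sample])
        text = tree.to_text()
        assert "pref" in text and "leaf" in text
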