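"""Signature construction, scoring, rescaling and CV classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ilcsig.signature import (
    SignatureModel,
    build_signature,
    classify,
    compute_score,
    cv_train_classify,
    deceased_label,
    filter_prognostic,
    rescale_0_100,
    roc_optimal_cutoff,
)


class TestRescale:
    def test_three_point_closed_form(self):
        m = pd.DataFrame({"s1": [2.0, 4.0, 6.0]}, index=["g1", "g2", "g3"])
        out = rescale_0_100(m)
        np.testing.assert_allclose(out["s1"], [0.0, 50.0, 100.0])

    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=2, max_size=12, unique=True,
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_bounds_property(self, values):
        m = pd.DataFrame({"s": values}, index=[f"g{i}" for i in range(len(values))])
        out = rescale_0_100(m)
        assert out["s"].min() == pytest.approx(0.0, abs=1e-9)
        assert out["s"].max() == pytest.approx(100.0, abs=1e-9)

    def test_idempotent_up_to_affine(self, rng):
        m = pd.DataFrame(rng.normal(size=(8, 3)), columns=list("abc"))
        once = rescale_0_100(m)
        twice = rescale_0_100(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_constant_sample_raises_naming_sample(self):
        m = pd.DataFrame({"sGood": [1.0, 2.0], "sFlat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="sFlat"):
            rescale_0_100(m)


class TestComputeScore:
    def _expr(self, rng, genes, n_samples):
        return pd.DataFrame(
            rng.uniform(0, 100, size=(len(genes), n_samples)),
            index=genes, columns=[f"s{i}" for i in range(n_samples)],
        )

    def test_all_positive_collapses_to_mean(self, rng):
        genes = [f"g{i}" for i in range(5)]
        model = SignatureModel(genes, [1] * 5)
        expr = self._expr(rng, genes, 4)
        score = compute_score(model, expr, rescale=False)
        np.testing.assert_allclose(score, expr.mean(axis=0))

    def test_balanced_arms_identical_expression_zero(self):
        genes = ["a", "b", "c", "d"]
        model = SignatureModel(genes, [1, 1, -1, -1])
        expr = pd.DataFrame(
            [[5.0], [7.0], [5.0], [7.0]], index=genes, columns=["s"]
        )
        score = compute_score(model, expr, rescale=False)
        assert score["s"] == pytest.approx(0.0)

    def test_matches_brute_force_signed_sum(self, rng):
        """score = ((sum_pos)/Np)(Np/N) - ((sum_neg)/Nn)(Nn/N), evaluated
        term by term."""
        for _ in range(25):
            n_genes = int(rng.integers(2, 20))
            genes = [f"g{i}" for i in range(n_genes)]
            coefs = [int(c) for c in rng.choice([1, -1], n_genes)]
            model = SignatureModel(genes, coefs)
            expr = self._expr(rng, genes, int(rng.integers(2, 8)))
            got = compute_score(model, expr, rescale=False)
            for s in expr.columns:
                pos = [g for g, c in zip(genes, coefs) if c == 1]
                neg = [g for g, c in zip(genes, coefs) if c == -1]
                np_, nn, n = len(pos), len(neg), n_genes
                expect = 0.0
                if np_:
                    expect += (expr.loc[pos, s].sum() / np_) * (np_ / n)
                if nn:
                    expect -= (expr.loc[neg, s].sum() / nn) * (nn / n)
                assert got[s] == pytest.approx(expect, abs=1e-12)

    def test_invariant_to_gene_order(self, rng):
        genes = [f"g{i}" for i in range(6)]
        coefs = [1, -1, 1, -1, 1, -1]
        expr = self._expr(rng, genes, 3)
        m1 = SignatureModel(genes, coefs)
        perm = rng.permutation(6)
        m2 = SignatureModel([genes[i] for i in perm], [coefs[i] for i in perm])
        pd.testing.assert_series_equal(
            compute_score(m1, expr), compute_score(m2, expr)
        )

    def test_missing_gene_policies(self, rng):
        genes = [f"g{i}" for i in range(20)]
        model = SignatureModel(genes, [1] * 10 + [-1] * 10)
        expr = self._expr(rng, genes[:19], 3)   # 5% missing -> renormalize
        score = compute_score(model, expr, rescale=False)
        assert np.isfinite(score).all()
        expr_bad = self._expr(rng, genes[:10], 3)  # 50% missing -> error
        with pytest.raises(ValueError):
            compute_score(model, expr_bad, rescale=False)


class TestFilterPrognostic:
    def _planted_cohort(self, rng, direction=+1, n=120):
        samples = [f"s{i}" for i in range(n)]
        risk = rng.normal(size=n)
        expr_val = direction * risk + rng.normal(0, 0.3, n)
        expr = pd.DataFrame(
            {s: [expr_val[i], rng.normal()] for i, s in enumerate(samples)},
            index=["gRisk_p1", "gNull_p1"],
        )
        pmap = pd.DataFrame(
            {"probe": ["gRisk_p1", "gNull_p1"], "gene": ["gRisk", "gNull"]}
        )
        haz = 0.02 * 2.5**risk
        clin = pd.DataFrame(
            {
                "sample": samples,
                "time_months": rng.exponential(1 / haz),
                "event": 1,
            }
        )
        return expr, pmap, clin

    def test_planted_risk_gene_passes_with_positive_direction(self, rng):
        expr, pmap, clin = self._planted_cohort(rng)
        recs = {r.gene: r for r in filter_prognostic(["gRisk", "gNull"], expr, pmap, clin)}
        assert recs["gRisk"].passed and recs["gRisk"].direction == +1

    def test_protective_gene_gets_negative_direction(self, rng):
        expr, pmap, clin = self._planted_cohort(rng, direction=-1)
        recs = {r.gene: r for r in filter_prognostic(["gRisk"], expr, pmap, clin)}
        assert recs["gRisk"].passed and recs["gRisk"].direction == -1

    def test_opposite_probes_fail_consistency(self, rng):
        expr, pmap, clin = self._planted_cohort(rng)
        expr2 = pd.concat(
            [expr, (-expr.loc[["gRisk_p1"]]).rename(index={"gRisk_p1": "gRisk_p2"})]
        )
        pmap2 = pd.concat(
            [pmap, pd.DataFrame({"probe": ["gRisk_p2"], "gene": ["gRisk"]})]
        ).reset_index(drop=True)
        recs = {r.gene: r for r in filter_prognostic(["gRisk"], expr2, pmap2, clin)}
        assert not recs["gRisk"].probes_consistent
        assert not recs["gRisk"].passed

    def test_quartile_split_supported(self, rng):
        expr, pmap, clin = self._planted_cohort(rng)
        recs = filter_prognostic(["gRisk"], expr, pmap, clin, split="quartile")
        assert recs[0].passed

    def test_unknown_split_rejected(self, rng):
        expr, pmap, clin = self._planted_cohort(rng)
        with pytest.raises(ValueError):
            filter_prognostic(["gRisk"], expr, pmap, clin, split="quintile")

    def test_null_gene_pass_rate_near_alpha(self):
        """Expression independent of survival passes rarely; the pass rate
        is bounded by the log-rank alpha=0.01 times the monotonicity
        probability (1/3 for tertiles)."""
        rng = np.random.default_rng(5)
        n_pass = 0
        reps = 400
        for _ in range(reps):
            n = 60
            expr = pd.DataFrame(
                rng.normal(size=(1, n)), index=["g_p1"],
                columns=[f"s{i}" for i in range(n)],
            )
            pmap = pd.DataFrame({"probe": ["g_p1"], "gene": ["g"]})
            clin = pd.DataFrame(
                {
                    "sample": [f"s{i}" for i in range(n)],
                    "time_months": rng.exponential(50, n),
                    "event": (rng.random(n) > 0.3).astype(int),
                }
            )
            recs = filter_prognostic(["g"], expr, pmap, clin)
            n_pass += recs[0].passed
        assert n_pass / reps <= 0.02    # well under the nominal 1%+MC noise


class TestBuildSignature:
    def _records(self):
        from ilcsig.signature import GeneFilterRecord

        return [
            GeneFilterRecord("gA", {"p": 1e-4}, True, True, +1, True),
            GeneFilterRecord("gB", {"p": 1e-3}, True, True, -1, True),
            GeneFilterRecord("gC", {"p": 0.5}, False, True, None, False),
        ]

    def test_union_with_boosting(self):
        boost = pd.Series({"gB": 0.2, "gD": -0.4})
        model = build_signature(self._records(), boost, combine="union")
        assert model.genes == ["gA", "gB", "gD"]
        # direction from filter wins for gB; boosting sign for gD
        assert dict(zip(model.genes, model.coefficients)) == {
            "gA": 1, "gB": -1, "gD": -1,
        }

    def test_intersection(self):
        boost = pd.Series({"gB": 0.2, "gD": -0.4})
        model = build_signature(self._records(), boost, combine="intersection")
        assert model.genes == ["gB"]

    def test_empty_signature_rejected(self):
        with pytest.raises(ValueError):
            build_signature([], None)

    def test_serialization_roundtrip(self, tmp_path):
        model = build_signature(self._records(), None)
        model.cutoff = 12.5
        model.to_json(tmp_path / "m.json")
        back = SignatureModel.from_json(tmp_path / "m.json")
        assert back.genes == model.genes
        assert back.coefficients == model.coefficients
        assert back.cutoff == 12.5
        model.to_tsv(tmp_path / "m.tsv")
        tsv = pd.read_csv(tmp_path / "m.tsv", sep="\t")
        assert list(tsv["gene"]) == model.genes


def _brute_force_cutoff(scores, labels):
    uniq = np.unique(scores)
    cands = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]])
    best, best_j = None, -np.inf
    for c in cands:
        pred = scores > c
        sens = (pred & (labels == 1)).sum() / max(labels.sum(), 1)
        spec = (~pred & (labels == 0)).sum() / max((labels == 0).sum(), 1)
        if sens + spec > best_j + 1e-12:
            best_j, best = sens + spec, c
    return best


class TestCVClassification:
    def test_perfect_separation_all_correct(self, rng):
        n = 40
        y = pd.Series(np.r_[np.ones(20, int), np.zeros(20, int)],
                      index=[f"s{i}" for i in range(n)])
        scores = pd.Series(np.r_[rng.uniform(10, 20, 20), rng.uniform(0, 5, 20)],
                           index=y.index)
        cv = cv_train_classify(scores, y, seed=1)
        assert ((cv.classes == "High") == (y == 1)).all()

    def test_every_sample_labeled_exactly_once(self, rng):
        y = pd.Series(rng.integers(0, 2, 53), index=[f"s{i}" for i in range(53)])
        scores = pd.Series(rng.normal(size=53), index=y.index)
        cv = cv_train_classify(scores, y, seed=2)
        assert cv.classes.notna().all()
        assert set(cv.classes) <= {"High", "Low"}
        assert len(cv.fold_cutoffs) == 5

    def test_reproducible_under_seed(self, rng):
        y = pd.Series(rng.integers(0, 2, 40), index=[f"s{i}" for i in range(40)])
        scores = pd.Series(rng.normal(size=40), index=y.index)
        c1 = cv_train_classify(scores, y, seed=7)
        c2 = cv_train_classify(scores, y, seed=7)
        pd.testing.assert_series_equal(c1.classes, c2.classes)
        assert c1.fold_cutoffs == c2.fold_cutoffs

    def test_fold_cutoff_equals_exhaustive_scan(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            assert roc_optimal_cutoff(scores, labels) == pytest.approx(
                _brute_force_cutoff(scores, labels)
            )

    def test_null_score_accuracy_near_prevalence(self):
        rng = np.random.default_rng(9)
        accs = []
        for _ in range(100):
            n = 60
            y = pd.Series(rng.integers(0, 2, n), index=[f"s{i}" for i in range(n)])
            if y.nunique() < 2:
                continue
            scores = pd.Series(rng.normal(size=n), index=y.index)
            cv = cv_train_classify(scores, y, seed=int(rng.integers(1e6)))
            acc = ((cv.classes == "High") == (y == 1)).mean()
            accs.append(acc)
        prev = 0.5
        assert abs(np.mean(accs) - prev) < 0.06

    def test_single_class_training_split_rejected(self):
        y = pd.Series([1] * 10 + [0], index=[f"s{i}" for i in range(11)])
        scores = pd.Series(np.arange(11.0), index=y.index)
        with pytest.raises(ValueError, match="stratified"):
            cv_train_classify(scores, y, seed=0, stratify=False, k=11)

    def test_classify_uses_deployable_cutoff(self):
        model = SignatureModel(["g"], [1], cutoff=5.0)
        scores = pd.Series([4.0, 5.0, 6.0], index=["a", "b", "c"])
        out = classify(model, scores)
        assert list(out) == ["Low", "Low", "High"]

    def test_deceased_label_horizon(self):
        clin = pd.DataFrame(
            {
                "sample": ["a", "b", "c"],
                "time_months": [50.0, 130.0, 80.0],
                "event": [1, 1, 0],
            }
        )
        assert deceased_label(clin).tolist() == [1, 1, 0]
        assert deceased_label(clin, horizon_months=120).tolist() == [1, 0, 0]
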