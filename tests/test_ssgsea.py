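import numpy as np
import pandas as pd
import pytest

from fdgsig.expression import ExpressionMatrix
from fdgsig.ssgsea import (
    GeneSetCollection,
    correlate_scores_with_phenotype,
    read_gmt,
    ssgsea_scores,
    summarize_probes_to_genes,
    write_gmt,
)


def walk_oracle(expr, members, alpha):
    """Independent hand-coded walk of the weighted-ECDF definition:
    explicit position-by-position loop over the descending-expression
    ordering."""
    genes = list(expr.index)
    order = sorted(range(len(genes)), key=lambda i: (-expr.iloc[i], i))
    n = len(genes)
    in_set = [genes[i].upper() in members for i in order]
    weights = [(n - pos) ** alpha for pos in range(n)]  # rank N..1 downward
    total_in = sum(w for w, m in zip(weights, in_set) if m)
    n_out = sum(1 for m in in_set if not m)
    es, cum_in, cum_out = 0.0, 0.0, 0.0
    for w, m in zip(weights, in_set):
        if m:
            cum_in += w / total_in
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es


@pytest.fixture()
def gene_expr():
    # 6 genes x 3 samples, distinct orderings per sample
    return pd.DataFrame(
        {
            "s1": [9.0, 7.0, 5.0, 3.0, 2.0, 1.0],
            "s2": [1.0, 2.0, 9.0, 8.0, 3.0, 4.0],
            "s3": [5.0, 5.0, 5.0, 2.0, 8.0, 1.0],
        },
        index=["G1", "G2", "G3", "G4", "G5", "G6"],
    )


class TestScores:
    def test_top_gene_set_alpha_zero_frozen_value(self):
        expr = pd.DataFrame({"s": [3.0, 2.0, 1.0]}, index=["A", "B", "C"])
        coll = GeneSetCollection(sets={"top": {"A"}})
        score = ssgsea_scores(expr, coll, alpha=0.0, normalize=False).loc["top", "s"]
        # walk: (1-0) + (1-1/2) + (1-1) = 1.5
        assert score == pytest.approx(1.5, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_matches_hand_walk_oracle(self, gene_expr, alpha):
        coll = GeneSetCollection(
            sets={"a": {"G1", "G4"}, "b": {"G2", "G3", "G5"}, "c": {"G6"}}
        )
        scores = ssgsea_scores(gene_expr, coll, alpha=alpha, normalize=False)
        for name, members in coll:
            for s in gene_expr.columns:
                assert scores.loc[name, s] == pytest.approx(
                    walk_oracle(gene_expr[s], members, alpha), abs=1e-10
                )

    def test_all_genes_set_equals_in_set_cumulative_sum(self, gene_expr):
        coll = GeneSetCollection(sets={"all": set(gene_expr.index)})
        scores = ssgsea_scores(gene_expr, coll, alpha=0.25, normalize=False)
        for s in gene_expr.columns:
            assert scores.loc["all", s] == pytest.approx(
                walk_oracle(gene_expr[s], set(gene_expr.index), 0.25), abs=1e-10
            )

    def test_identical_samples_identical_scores(self, gene_expr):
        expr = gene_expr[["s1"]].copy()
        expr["s1b"] = expr["s1"]
        coll = GeneSetCollection(sets={"a": {"G1", "G4"}})
        scores = ssgsea_scores(expr, coll, normalize=False)
        assert scores["s1"].iloc[0] == scores["s1b"].iloc[0]

    def test_monotone_in_set_rank_boost(self, rng):
        """Pushing every in-set gene above every out-of-set gene never
        decreases that sample's enrichment score."""
        for _ in range(20):
            n = int(rng.integers(5, 12))
            expr = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
            members = {f"G{i}" for i in rng.choice(n, size=int(rng.integers(1, n)),
                                                   replace=False)}
            boosted = expr.copy()
            in_mask = expr.index.str.upper().isin(members)
            boosted[in_mask] = boosted.max() + 1 + rng.random(int(in_mask.sum()))
            base = walk_oracle(expr, members, 0.25)
            frame = pd.DataFrame({"s": expr}), pd.DataFrame({"s": boosted})
            coll = GeneSetCollection(sets={"m": members})
            lo = ssgsea_scores(frame[0], coll, normalize=False).loc["m", "s"]
            hi = ssgsea_scores(frame[1], coll, normalize=False).loc["m", "s"]
            assert hi >= lo - 1e-12
            assert lo == pytest.approx(base, abs=1e-10)

    def test_invariant_to_gene_and_sample_order(self, gene_expr, rng):
        coll = GeneSetCollection(sets={"a": {"G1", "G4", "G5"}})
        ref = ssgsea_scores(gene_expr, coll, normalize=False)
        shuffled = gene_expr.iloc[rng.permutation(len(gene_expr))]
        shuffled = shuffled[["s3", "s1", "s2"]]
        out = ssgsea_scores(shuffled, coll, normalize=False)
        for s in gene_expr.columns:
            assert out.loc["a", s] == pytest.approx(ref.loc["a", s], abs=1e-12)

    def test_disjoint_set_scores_missing(self, gene_expr):
        coll = GeneSetCollection(sets={"gone": {"ZZZ"}})
        with pytest.warns(UserWarning, match="no gene"):
            scores = ssgsea_scores(gene_expr, coll, normalize=False)
        assert scores.loc["gone"].isna().all()

    def test_normalization_divides_by_global_range(self, gene_expr):
        coll = GeneSetCollection(sets={"a": {"G1"}, "b": {"G6"}})
        raw = ssgsea_scores(gene_expr, coll, normalize=False)
        norm = ssgsea_scores(gene_expr, coll, normalize=True)
        rng_ = raw.to_numpy().max() - raw.to_numpy().min()
        np.testing.assert_allclose(norm, raw / rng_, atol=1e-12)


class TestProbeSummarization:
    def test_one_probe_per_gene_is_identity(self):
        X = ExpressionMatrix(
            values=pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["p1", "p2"],
                                columns=["s1", "s2"]),
            gene_symbols=pd.Series(["GA", "GB"], index=["p1", "p2"]),
        )
        out = summarize_probes_to_genes(X)
        np.testing.assert_allclose(out.loc["GA"], [1.0, 2.0])
        np.testing.assert_allclose(out.loc["GB"], [3.0, 4.0])

    def test_dominant_probe_retained(self, tiny_matrix):
        out = summarize_probes_to_genes(tiny_matrix)
        # p4 dominates p1 for gene GA; the unannotated p3 is dropped
        np.testing.assert_allclose(out.loc["GA"], tiny_matrix.values.loc["p4"])
        assert set(out.index) == {"GA", "GB"}

    def test_matches_brute_force_max_mean_oracle(self, rng):
        genes = ["GA", "GB", "GC"]
        symbols = pd.Series([genes[i % 3] for i in range(9)],
                            index=[f"p{i}" for i in range(9)])
        X = ExpressionMatrix(
            values=pd.DataFrame(rng.normal(size=(9, 4)), index=symbols.index,
                                columns=[f"s{i}" for i in range(4)]),
            gene_symbols=symbols,
        )
        out = summarize_probes_to_genes(X, mode="probe")
        for g in genes:
            probes = symbols.index[symbols == g]
            best = X.values.loc[probes].mean(axis=1).idxmax()
            np.testing.assert_allclose(out.loc[g], X.values.loc[best])

    def test_per_sample_mode(self, rng):
        symbols = pd.Series(["GA", "GA"], index=["p1", "p2"])
        vals = pd.DataFrame([[1.0, 9.0], [5.0, 2.0]], index=symbols.index,
                            columns=["s1", "s2"])
        X = ExpressionMatrix(values=vals, gene_symbols=symbols)
        out = summarize_probes_to_genes(X, mode="sample")
        np.testing.assert_allclose(out.loc["GA"], [5.0, 9.0])

    def test_no_annotation_rejected(self):
        X = ExpressionMatrix(values=pd.DataFrame([[1.0]], index=["p"], columns=["s"]))
        with pytest.raises(ValueError):
            summarize_probes_to_genes(X)


class TestGMT:
    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(sets={"SET1": {"A", "B"}, "SET2": {"C"}},
                                 descriptions={"SET1": "d1", "SET2": "d2"})
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert back.sets == coll.sets

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("SET1\tdesc\tA\nBADLINE\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gmt(path)

    def test_empty_member_list_rejected(self, tmp_path):
        path = tmp_path / "empty.gmt"
        path.write_text("SET1\tdesc\t\n")
        with pytest.raises(ValueError):
            read_gmt(path)

    def test_duplicates_deduplicated_with_warning(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("SET1\tdesc\tA\tB\ta\n")
        with pytest.warns(UserWarning, match="duplicate"):
            coll = read_gmt(path)
        assert coll.sets["SET1"] == frozenset({"A", "B"})


class TestPhenotypeCorrelation:
    def test_proportional_scores_correlate_perfectly(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        scores = pd.DataFrame({"a": [2.0], "b": [4.0], "c": [6.0], "d": [8.0]},
                              index=["set"])
        out = correlate_scores_with_phenotype(scores, y)
        assert out.loc[0, "pearson_r"] == pytest.approx(1.0)

    def test_anti_proportional(self):
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        scores = pd.DataFrame({"a": [8.0], "b": [6.0], "c": [4.0], "d": [2.0]},
                              index=["set"])
        assert correlate_scores_with_phenotype(scores, y).loc[0, "pearson_r"] == pytest.approx(-1.0)

    def test_matches_explicit_pearson_sums(self, rng):
        y = pd.Series(rng.normal(size=5), index=list("abcde"))
        scores = pd.DataFrame(rng.normal(size=(1, 5)), index=["set"],
                              columns=list("abcde"))
        out = correlate_scores_with_phenotype(scores, y)
        v = scores.iloc[0].to_numpy()
        yv = y.to_numpy()
        num = ((v - v.mean()) * (yv - yv.mean())).sum()
        den = np.sqrt(((v - v.mean()) ** 2).sum() * ((yv - yv.mean()) ** 2).sum())
        assert out.loc[0, "pearson_r"] == pytest.approx(num / den, rel=1e-10)

    def test_too_few_samples(self):
        y = pd.Series([1.0, 2.0], index=list("ab"))
        scores = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["set"])
        with pytest.raises(ValueError):
            correlate_scores_with_phenotype(scores, y)


def test_matches_gseapy_cross_check(rng):
    """Independent cross-check: raw enrichment scores coincide with the
    gseapy ssGSEA implementation (rank sample normalization) on a random
    matrix, for sets large enough to pass gseapy's size filter."""
    gseapy = pytest.importorskip("gseapy")
    expr = pd.DataFrame(
        rng.uniform(1, 10, (60, 4)),
        index=[f"G{i}" for i in range(60)],
        columns=list("abcd"),
    )
    gs = {"S1": [f"G{i}" for i in range(0, 20)], "S2": [f"G{i}" for i in range(25, 45)]}
    res = gseapy.ssgsea(data=expr, gene_sets=gs, outdir=None,
                        sample_norm_method="rank", no_plot=True, threads=1)
    theirs = res.res2d.pivot(index="Term", columns="Name", values="ES").astype(float)
    ours = ssgsea_scores(
        expr, GeneSetCollection(sets={k: set(v) for k, v in gs.items()}),
        alpha=0.25, normalize=False,
    )
    np.testing.assert_allclose(
        theirs.to_numpy(), ours.loc[theirs.index, theirs.columns].to_numpy(),
        rtol=1e-8,
    )


def test_planted_sets_correlate_with_sign_over_seeds():
    """Enrichment scores of planted positive sets correlate positively
    with log2 SUV; null sets hover near zero (Monte-Carlo over seeds)."""
    from fdgsig.synthetic import SyntheticConfig, generate_cohort, generate_genesets

    pos_r, null_r = [], []
    for seed in range(20):
        cfg = SyntheticConfig(
            n_probes=300, n_samples=50, n_signal_probes=60, n_signal_blocks=2,
            effect_size_range=(0.05, 0.12), noise_sd=0.3, validation_n=0,
            unannotated_fraction=0.05, seed=seed,
        )
        cohort = generate_cohort(cfg)
        coll, kinds = generate_genesets(
            cohort.expression.gene_symbols, cohort.truth,
            n_sets=6, set_size_range=(8, 15), seed=seed,
        )
        gene_expr = summarize_probes_to_genes(cohort.expression)
        scores = ssgsea_scores(gene_expr, coll)
        corr = correlate_scores_with_phenotype(scores, cohort.log2_suv)
        corr = corr.set_index("geneset")["pearson_r"]
        for name in kinds.index:
            if kinds[name] == "enriched_positive":
                pos_r.append(corr[name])
            elif kinds[name] == "null":
                null_r.append(corr[name])
    assert np.mean(pos_r) > 0.2
    assert np.mean(np.asarray(pos_r) > 0) >= 0.75  # sign test style margin
    assert abs(np.mean(null_r)) < 0.15
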