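import numpy as np
import pandas as pd
import pytest

from poolpop import landscape as land
from tests.conftest import make_afm


@pytest.fixture
def env(rng):
    n = 40
    idx = [f"P{i:03d}" for i in range(1, n + 1)]
    data = {f"Bio{i}": rng.normal(size=n) for i in range(1, 8)}
    return pd.DataFrame(data, index=idx)


class TestPruneCollinear:
    def test_duplicate_dropped(self, env):
        env = env.copy()
        env["Bio2"] = env["Bio1"]
        retained = land.prune_collinear(env)
        assert ("Bio1" in retained) != ("Bio2" in retained)

    def test_independent_all_kept(self, env):
        retained = land.prune_collinear(env)
        assert set(retained) == set(env.columns)

    def test_constant_dropped_first(self, env):
        env = env.copy()
        env["Bio3"] = 1.0
        retained = land.prune_collinear(env)
        assert "Bio3" not in retained

    def test_deterministic(self, env):
        env = env.copy()
        env["Bio4"] = env["Bio1"] + 0.01 * env["Bio2"]
        assert land.prune_collinear(env) == land.prune_collinear(env)

    def test_matches_rule_oracle(self, rng):
        # oracle: independent re-implementation of the stated greedy rule
        n = 60
        idx = [f"P{i}" for i in range(n)]
        base = {f"Bio{i}": rng.normal(size=n) for i in range(1, 9)}
        df = pd.DataFrame(base, index=idx)
        df["Bio2"] = df["Bio1"] + rng.normal(scale=0.2, size=n)
        df["Bio5"] = df["Bio4"] + rng.normal(scale=0.1, size=n)
        df["Bio6"] = df["Bio4"] + rng.normal(scale=0.3, size=n)

        def oracle(frame, threshold=0.8):
            cols = list(frame.columns)
            while True:
                corr = frame[cols].corr().abs()
                np.fill_diagonal(corr.values, 0)
                if corr.values.max() < threshold:
                    return cols
                i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
                a, b = corr.index[i], corr.columns[j]
                ma = corr.loc[a].drop(b).mean()
                mb = corr.loc[b].drop(a).mean()
                if np.isclose(ma, mb):
                    drop = max(a, b, key=land._bio_rank)
                else:
                    drop = a if ma > mb else b
                cols.remove(drop)

        assert land.prune_collinear(df) == oracle(df)

    def test_needs_two_variables(self, env):
        with pytest.raises(ValueError):
            land.prune_collinear(env[["Bio1"]])


def rda_oracle(Y, X):
    """Naive RDA: explicit regression, then eigendecomposition of the
    fitted-value covariance."""
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    Yc = Y - Y.mean(axis=0)
    B = np.linalg.lstsq(Xs, Yc, rcond=None)[0]
    F = Xs @ B
    evals = np.linalg.eigvalsh(F.T @ F)[::-1]
    evals = evals[evals > 1e-10]
    return evals / (Yc**2).sum()


class TestRDA:
    def test_exactly_linear_response(self, env, rng):
        B = rng.normal(size=(env.shape[1], 5))
        Y = pd.DataFrame(env.to_numpy() @ B, index=env.index)
        res = land.rda(Y, env)
        assert res.constrained_proportion == pytest.approx(1.0, abs=1e-10)

    def test_independent_response_null(self):
        rng = np.random.default_rng(0)
        n, q, p = 500, 5, 30
        idx = [f"P{i}" for i in range(n)]
        X = pd.DataFrame(rng.normal(size=(n, q)), index=idx)
        Y = pd.DataFrame(rng.normal(size=(n, p)), index=idx)
        res = land.rda(Y, X)
        expected = q / (n - 1)
        assert res.constrained_proportion == pytest.approx(expected, rel=0.35)

    def test_axis_orthogonality(self, env, rng):
        Y = pd.DataFrame(rng.normal(size=(len(env), 12)), index=env.index)
        res = land.rda(Y, env)
        S = res.site_scores.to_numpy()
        cross = S.T @ S
        np.testing.assert_allclose(cross - np.diag(np.diag(cross)), 0.0, atol=1e-8)

    def test_matches_naive_oracle(self, rng):
        n, q, p = 10, 4, 20
        idx = [f"P{i}" for i in range(n)]
        X = pd.DataFrame(rng.normal(size=(n, q)), index=idx)
        Y = pd.DataFrame(rng.normal(size=(n, p)), index=idx)
        res = land.rda(Y, X)
        oracle_fracs = rda_oracle(Y.to_numpy(), X.to_numpy())
        np.testing.assert_allclose(res.eigenvalue_fractions, oracle_fracs, atol=1e-8)

    def test_rank_deficient_predictors_named(self, env):
        bad = env.copy()
        bad["Bio7"] = bad["Bio1"] * 2.0
        Y = pd.DataFrame(np.outer(np.arange(len(env)), [1.0, 2.0]), index=env.index)
        with pytest.raises(ValueError, match="aliased"):
            land.rda(Y, bad)

    def test_too_few_populations(self, env, rng):
        small_env = env.iloc[:5]
        Y = pd.DataFrame(rng.normal(size=(5, 3)), index=small_env.index)
        with pytest.raises(ValueError, match="more populations"):
            land.rda(Y, small_env)


class TestDetectCandidates:
    def test_planted_outlier_flagged(self, env, rng):
        Y = pd.DataFrame(
            rng.normal(size=(len(env), 200)),
            index=env.index,
            columns=[f"chr1:{1000 + i}" for i in range(200)],
        )
        # one locus exactly linear in Bio1: giant loading on some axis
        Y["chr1:1000"] = env["Bio1"] * 10
        res = land.rda(Y, env)
        cands = land.detect_candidates(res, n_axes=3)
        assert "chr1:1000" in set(cands["locus"])

    def test_axis_bound(self, env, rng):
        Y = pd.DataFrame(rng.normal(size=(len(env), 10)), index=env.index)
        res = land.rda(Y, env)
        with pytest.raises(ValueError, match="exceeds"):
            land.detect_candidates(res, n_axes=res.axes_used + 1)

    def test_exceedance_definition(self, env, rng):
        Y = pd.DataFrame(rng.normal(size=(len(env), 100)), index=env.index)
        res = land.rda(Y, env)
        cands = land.detect_candidates(res, n_axes=2, sd_mult=1.5)
        L = res.loadings.iloc[:, :2]
        z = ((L - L.mean()) / L.std(ddof=0)).abs()
        expected = set(L.index[(z > 1.5).any(axis=1)])
        assert set(cands["locus"]) == expected


class TestAssignPredictor:
    def test_planted_driver_recovered(self, env, rng):
        n = len(env)
        values = rng.uniform(0.2, 0.8, size=(n, 3))
        # locus 0 monotone in Bio3
        ranks = env["Bio3"].rank().to_numpy()
        values[:, 0] = 0.1 + 0.8 * (ranks - 1) / (n - 1)
        afm = make_afm(values, populations=list(env.index))
        cands = pd.DataFrame({"locus": [afm.locus_ids()[0]], "axis": "RDA1", "loading": 0.5})
        out = land.assign_predictor(cands, afm, env)
        assert out.loc[0, "variable"] == "Bio3"
        assert out.loc[0, "r"] > 0.9

    def test_tie_breaks_to_lower_bio_index(self, rng):
        n = 30
        idx = [f"P{i:03d}" for i in range(1, n + 1)]
        x = rng.normal(size=n)
        env = pd.DataFrame({"Bio5": x, "Bio2": x}, index=idx)  # identical predictors
        values = rng.uniform(0.2, 0.8, size=(n, 1))
        afm = make_afm(values, populations=idx)
        cands = pd.DataFrame({"locus": [afm.locus_ids()[0]], "axis": "RDA1", "loading": 0.1})
        out = land.assign_predictor(cands, afm, env)
        assert out.loc[0, "variable"] == "Bio2"

    def test_bh_q_monotone_in_p_rank(self, env, rng):
        n = len(env)
        values = rng.uniform(0.2, 0.8, size=(n, 12))
        afm = make_afm(values, populations=list(env.index))
        cands = pd.DataFrame(
            {"locus": afm.locus_ids(), "axis": "RDA1", "loading": 0.1}
        )
        out = land.assign_predictor(cands, afm, env).sort_values("p")
        assert (out["q"].diff().dropna() >= -1e-12).all()
        assert (out["q"] >= out["p"] - 1e-12).all()

    def test_empty_candidates_rejected(self, env, rng):
        afm = make_afm(rng.uniform(0.2, 0.8, size=(len(env), 2)), populations=list(env.index))
        with pytest.raises(ValueError, match="empty"):
            land.assign_predictor(pd.DataFrame(columns=["locus"]), afm, env)


class TestChisqClusterAssociation:
    def test_hand_computed_2x2(self):
        # contingency (10,30 / 30,10): chi-square without continuity
        # correction = N(ad-bc)^2 / (r1 r2 c1 c2) = 80*(-800)^2/40^4 = 20
        from scipy.stats import chi2_contingency

        stat, _, _, _ = chi2_contingency([[10, 30], [30, 10]], correction=False)
        assert stat == pytest.approx(20.0)
        # same table through the module: 2 clusters x 1 pop, pool_size
        # chosen so rounded counts reproduce the table
        afm = make_afm([[0.25], [0.75]])
        clusters = pd.Series(["a", "b"], index=afm.populations)
        cands = pd.DataFrame({"locus": [afm.locus_ids()[0]]})
        out = land.chisq_cluster_association(cands, afm, clusters, pool_size=20)
        assert out.loc[0, "chi2"] == pytest.approx(20.0)

    def test_identical_frequencies_null(self):
        afm = make_afm([[0.5, 0.4], [0.5, 0.4], [0.5, 0.4], [0.5, 0.4]])
        clusters = pd.Series(["a", "a", "b", "b"], index=afm.populations)
        cands = pd.DataFrame({"locus": afm.locus_ids()})
        out = land.chisq_cluster_association(cands, afm, clusters)
        assert (out["chi2"] < 1e-9).all()
        assert (out["chi2_p"] > 0.99).all()

    def test_differentiated_locus_significant(self, rng):
        values = np.vstack([np.full((5, 1), 0.1), np.full((5, 1), 0.9)])
        afm = make_afm(values)
        clusters = pd.Series(["a"] * 5 + ["b"] * 5, index=afm.populations)
        cands = pd.DataFrame({"locus": afm.locus_ids()})
        out = land.chisq_cluster_association(cands, afm, clusters)
        assert (out["chi2_q"] < 0.05).all()

    def test_low_reliability_flag(self):
        afm = make_afm([[0.0], [0.0]])
        clusters = pd.Series(["a", "b"], index=afm.populations)
        cands = pd.DataFrame({"locus": afm.locus_ids()})
        out = land.chisq_cluster_association(cands, afm, clusters, pool_size=1)
        assert out.loc[0, "low_reliability"]


def gene_row(gene_id, start, end, strand="+", seqid="chr1"):
    return {"seqid": seqid, "start": start, "end": end, "strand": strand, "gene_id": gene_id}


class TestNearestGene:
    def cands(self, *positions, seqid="chr1"):
        return pd.DataFrame({"locus": [f"{seqid}:{p}" for p in positions]})

    def test_within(self):
        genes = pd.DataFrame([gene_row("g1", 4000, 6000)])
        out = land.nearest_gene(self.cands(5000), genes)
        assert out.loc[0, "gene"] == "g1"
        assert out.loc[0, "relation"] == "within"
        assert out.loc[0, "distance"] == 0

    @pytest.mark.parametrize(
        "pos,expect_gene", [(1001, True), (999, False), (9000 + 2999, True), (9000 + 3001, False)]
    )
    def test_window_boundary_both_sides(self, pos, expect_gene):
        genes = pd.DataFrame([gene_row("g1", 4000, 9000)])
        out = land.nearest_gene(self.cands(pos), genes, window=3000)
        assert (out.loc[0, "gene"] == "g1") is expect_gene

    def test_nearer_gene_chosen(self):
        genes = pd.DataFrame([gene_row("near", 11000, 12000), gene_row("far", 5000, 7500)])
        # SNP at 10000: 1000 bp left of "near", 2500 bp right of "far"
        out = land.nearest_gene(self.cands(10000), genes)
        assert out.loc[0, "gene"] == "near"
        assert out.loc[0, "distance"] == 1000

    def test_strand_aware_relations(self):
        plus = pd.DataFrame([gene_row("gp", 5000, 6000, "+")])
        minus = pd.DataFrame([gene_row("gm", 5000, 6000, "-")])
        left, right = self.cands(4500), self.cands(6500)
        assert land.nearest_gene(left, plus).loc[0, "relation"] == "upstream"
        assert land.nearest_gene(right, plus).loc[0, "relation"] == "downstream"
        assert land.nearest_gene(left, minus).loc[0, "relation"] == "downstream"
        assert land.nearest_gene(right, minus).loc[0, "relation"] == "upstream"

    def test_strand_naive_mode(self):
        minus = pd.DataFrame([gene_row("gm", 5000, 6000, "-")])
        out = land.nearest_gene(self.cands(4500), minus, strand_aware=False)
        assert out.loc[0, "relation"] == "upstream"

    def test_absent_chromosome(self):
        genes = pd.DataFrame([gene_row("g1", 100, 200, seqid="chr9")])
        out = land.nearest_gene(self.cands(150), genes)
        assert out.loc[0, "gene"] is None

    def test_matches_brute_force_scan(self, rng):
        genes = pd.DataFrame(
            [gene_row(f"g{i}", s, s + 800) for i, s in enumerate(range(1000, 60000, 4000))]
        )
        positions = rng.integers(1, 65000, size=40)
        out = land.nearest_gene(self.cands(*positions), genes, window=3000)
        for pos, (_, row) in zip(positions, out.iterrows()):
            best = None
            for g in genes.itertuples():
                if g.start <= pos <= g.end:
                    d = 0
                elif pos < g.start:
                    d = g.start - pos
                else:
                    d = pos - g.end
                if d <= 3000 and (best is None or d < best[0]):
                    best = (d, g.gene_id)
            if best is None:
                assert row["gene"] is None
            else:
                assert row["distance"] == best[0]
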