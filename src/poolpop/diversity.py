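"""Genetic distance, diversity, differentiation, gene flow and AMOVA."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from poolpop.poolfreq import AlleleFrequencyMatrix


@dataclass
class DistanceMatrix:
    """Symmetric population distance matrix with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(v < -1e-12):
            raise ValueError("distances must be non-negative")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def modified_rogers_distance(freqs: AlleleFrequencyMatrix) -> DistanceMatrix:
    """Modified Rogers Distance between all population pairs.

    For biallelic loci the per-locus ref and alt squared differences are
    equal, so MRD(x, y) = sqrt(mean_l (p_xl - p_yl)^2), bounded in [0, 1].
    Requires a complete (imputed) matrix.
    """
    if freqs.has_missing():
        raise ValueError("MRD requires a complete (imputed) frequency matrix")
    v = freqs.values
    sq = np.sum(v**2, axis=1)
    d2 = (sq[:, None] + sq[None, :] - 2.0 * v @ v.T) / freqs.n_loci
    np.fill_diagonal(d2, 0.0)
    return DistanceMatrix(list(freqs.populations), np.sqrt(np.clip(d2, 0.0, None)))


def expected_heterozygosity(
    freqs: AlleleFrequencyMatrix, groups: pd.Series | None = None
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Per-population expected heterozygosity, mean over loci of 2p(1-p).

    With a population -> cluster assignment, also returns per-cluster
    summaries (mean, min, max, n).
    """
    if freqs.has_missing():
        raise ValueError("He requires a complete (imputed) frequency matrix")
    v = freqs.values
    he = pd.Series((2.0 * v * (1.0 - v)).mean(axis=1), index=freqs.populations, name="He")
    summary = None
    if groups is not None:
        g = groups.reindex(he.index)
        if g.isna().any():
            raise ValueError("group assignment missing for some populations")
        summary = he.groupby(g).agg(["mean", "min", "max", "count"])
        if (summary["count"] == 0).any():
            raise ValueError("empty group in assignment")
    return he, summary


def pairwise_fst(freqs: AlleleFrequencyMatrix, groups: pd.Series) -> pd.DataFrame:
    """Nei-type FST (GST) between every pair of clusters, as ratio of sums.

    Per locus, HS is the mean within-population heterozygosity 2p(1-p)
    across member populations of the two clusters; HT uses the mean
    frequency across those populations.  FST = sum(HT - HS) / sum(HT),
    clipped to [0, 1]; defined as 0 when HT vanishes at every locus.
    """
    if freqs.has_missing():
        raise ValueError("FST requires a complete (imputed) frequency matrix")
    g = groups.reindex(freqs.populations)
    if g.isna().any():
        raise ValueError("group assignment missing for some populations")
    labels = sorted(g.unique())
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    v = freqs.values
    members = {lab: np.where((g == lab).to_numpy())[0] for lab in labels}
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            idx = np.concatenate([members[a], members[b]])
            p = v[idx]
            hs = (2.0 * p * (1.0 - p)).mean(axis=0)
            pbar = p.mean(axis=0)
            ht = 2.0 * pbar * (1.0 - pbar)
            denom = ht.sum()
            fst = 0.0 if denom == 0 else float(np.clip((ht - hs).sum() / denom, 0.0, 1.0))
            out.loc[a, b] = out.loc[b, a] = fst
    return out


def gene_flow(fst: float) -> float:
    """Island-model gene flow Nm = (1 - FST) / (4 * FST)."""
    if not np.isfinite(fst) or fst <= 0.0 or fst > 1.0:
        raise ValueError(f"gene flow is undefined for FST = {fst}")
    return (1.0 - fst) / (4.0 * fst)


def classify_differentiation(fst: float) -> str:
    """Half-open, lower-inclusive FST differentiation bins."""
    if fst < 0:
        raise ValueError("FST must be non-negative")
    if fst < 0.05:
        return "little"
    if fst < 0.15:
        return "moderate"
    if fst < 0.25:
        return "great"
    return "very great"  # beyond the published bins, flagged as extension


def classify_gene_flow(nm: float) -> str:
    """Half-open, lower-inclusive gene-flow grades."""
    if nm < 0:
        raise ValueError("Nm must be non-negative")
    if nm < 0.25:
        return "low"
    if nm < 1.0:
        return "medium"
    return "high"


def fst_nm_table(fst: pd.DataFrame) -> pd.DataFrame:
    """FST in the lower triangle, Nm in the upper, diagonal NaN."""
    labels = list(fst.index)
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i > j:
                out.iloc[i, j] = fst.iloc[i, j]
            elif i < j:
                out.iloc[i, j] = gene_flow(float(fst.iloc[i, j]))
    return out


def mean_square(ss: float, df: int) -> float:
    """Mean square SS / df of one AMOVA stratum."""
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    return ss / df


# ---------------------------------------------------------------------------
# AMOVA


def _ss_within(d2: np.ndarray, groups: np.ndarray) -> float:
    """Sum over groups of (sum of squared distances among members) / size."""
    total = 0.0
    for lab in np.unique(groups):
        idx = np.where(groups == lab)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            total += sub.sum() / (2.0 * len(idx))
    return total


def _amova_ss(d2, clusters, countries):
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within_cluster = _ss_within(d2, clusters)
    ss_within_country = _ss_within(d2, countries)
    return {
        "total": ss_total,
        "clusters": ss_total - ss_within_cluster,
        "countries": ss_within_cluster - ss_within_country,
        "populations": ss_within_country,
    }


def _amova_components(ss, df, clusters, countries):
    """Variance components via standard nested-design coefficients."""
    n = len(clusters)
    cluster_labels, cluster_sizes = np.unique(clusters, return_counts=True)
    pairs = pd.DataFrame({"cluster": clusters, "country": countries})
    sub_sizes = pairs.groupby(["cluster", "country"]).size()
    size_of_cluster = dict(zip(cluster_labels, cluster_sizes))
    sum_nk2_over_ng = sum(
        s**2 / size_of_cluster[cl] for (cl, _), s in sub_sizes.items()
    )
    sum_nk2_over_n = sum(s**2 for s in sub_sizes) / n
    sum_ng2_over_n = sum(s**2 for s in cluster_sizes) / n
    g = len(cluster_labels)
    k = len(sub_sizes)
    # nested-ANOVA expected-mean-square coefficients
    n_prime = (n - sum_nk2_over_ng) / max(k - g, 1)
    n_dprime = (sum_nk2_over_ng - sum_nk2_over_n) / max(g - 1, 1)
    n_tprime = (n - sum_ng2_over_n) / max(g - 1, 1)
    ms = {lev: ss[lev] / df[lev] for lev in ("clusters", "countries", "populations")}
    sigma_c = ms["populations"]
    sigma_b = (ms["countries"] - sigma_c) / n_prime if k > g else 0.0
    sigma_a = (ms["clusters"] - sigma_c - n_dprime * sigma_b) / n_tprime
    return sigma_a, sigma_b, sigma_c


def amova(
    dist: DistanceMatrix,
    clusters: pd.Series,
    countries: pd.Series | None = None,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Distance-based hierarchical AMOVA on squared distances.

    Strata: clusters, countries within clusters, populations within
    countries.  With ``countries=None`` the middle stratum collapses
    (each population its own country is *not* used; instead the design is
    two-level: clusters / populations within clusters).  Permutation
    p-values (seeded) permute populations across groups at each level.

    Returns a table with one row per stratum plus the total: df, SS, MS,
    variance component, percent variance, Phi and p-value.
    """
    ids = dist.ids
    cl = clusters.reindex(ids)
    if cl.isna().any():
        raise ValueError("cluster assignment missing for some populations")
    cl = cl.to_numpy()
    d2 = dist.values**2
    n = len(ids)
    rng = np.random.default_rng(seed)

    if countries is not None:
        co = countries.reindex(ids)
        if co.isna().any():
            raise ValueError("country assignment missing for some populations")
        co = co.to_numpy()
        # nesting check: a country must not span clusters
        span = pd.DataFrame({"cl": cl, "co": co}).groupby("co")["cl"].nunique()
        if (span > 1).any():
            bad = span[span > 1].index.tolist()
            raise ValueError(f"countries span multiple clusters (non-nested strata): {bad}")
        g = len(np.unique(cl))
        k = pd.DataFrame({"cl": cl, "co": co}).drop_duplicates().shape[0]
        df = {"clusters": g - 1, "countries": k - g, "populations": n - k, "total": n - 1}
        if df["countries"] <= 0 or df["populations"] <= 0:
            raise ValueError("degenerate nesting: no within-stratum degrees of freedom")
        ss = _amova_ss(d2, cl, co)
        sigma_a, sigma_b, sigma_c = _amova_components(ss, df, cl, co)
        sigmas = {"clusters": sigma_a, "countries": sigma_b, "populations": sigma_c}
    else:
        g = len(np.unique(cl))
        df = {"clusters": g - 1, "populations": n - g, "total": n - 1}
        ss_total = d2.sum() / (2.0 * n)
        ss_within = _ss_within(d2, cl)
        ss = {"total": ss_total, "clusters": ss_total - ss_within, "populations": ss_within}
        ms_cl = ss["clusters"] / df["clusters"]
        ms_pop = ss["populations"] / df["populations"]
        _, sizes = np.unique(cl, return_counts=True)
        n0 = (n - (sizes**2).sum() / n) / (g - 1)
        sigma_c = ms_pop
        sigma_a = (ms_cl - ms_pop) / n0
        sigmas = {"clusters": sigma_a, "populations": sigma_c}

    total_sigma = sum(sigmas.values())
    strata = [s for s in ("clusters", "countries", "populations") if s in sigmas]

    # permutation p-values on Phi statistics, permuting populations across
    # groups: Phi_CT for clusters, Phi_SC for countries-within-clusters,
    # Phi_ST for the among-populations level
    def _phis(cl_p, co_p):
        if countries is not None:
            ss_p = _amova_ss(d2, cl_p, co_p)
            sa, sb, sc = _amova_components(ss_p, df, cl_p, co_p)
        else:
            ss_tot = d2.sum() / (2.0 * n)
            w = _ss_within(d2, cl_p)
            ms_cl = (ss_tot - w) / df["clusters"]
            ms_pop = w / df["populations"]
            _, sizes_p = np.unique(cl_p, return_counts=True)
            n0_p = (n - (sizes_p**2).sum() / n) / (len(sizes_p) - 1)
            sc = ms_pop
            sa = (ms_cl - ms_pop) / n0_p
            sb = 0.0
        tot = sa + sb + sc
        return {
            "clusters": sa / tot if tot else 0.0,
            "countries": sb / (sb + sc) if (sb + sc) else 0.0,
            "populations": (sa + sb) / tot if tot else 0.0,
        }

    obs_phi = _phis(cl, co if countries is not None else None)
    hits = {level: 0 for level in strata}
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        cl_p = cl[perm]
        co_p = co[perm] if countries is not None else None
        perm_phi = _phis(cl_p, co_p)
        for level in strata:
            if perm_phi[level] >= obs_phi[level] - 1e-12:
                hits[level] += 1
    pvals = {level: (hits[level] + 1) / (n_permutations + 1) for level in strata}

    rows = []
    for level in strata:
        rows.append(
            {
                "stratum": level,
                "df": df[level],
                "sum_of_squares": ss[level],
                "mean_square": mean_square(ss[level], df[level]),
                "variance_component": sigmas[level],
                "percent_variance": 100.0 * sigmas[level] / total_sigma,
                "phi": obs_phi[level],
                "p_value": pvals[level],
            }
        )
    rows.append(
        {
            "stratum": "total",
            "df": df["total"],
            "sum_of_squares": ss.get("total", sum(ss[s] for s in strata)),
            "mean_square": mean_square(
                ss.get("total", sum(ss[s] for s in strata)), df["total"]
            ),
            "variance_component": total_sigma,
            "percent_variance": 100.0,
            "phi": np.nan,
            "p_value": np.nan,
        }
    )
    table = pd.DataFrame(rows).set_index("stratum")
    return table
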