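"""RDA-based landscape genomics.

Collinearity pruning of bioclimatic predictors, redundancy analysis of
trait or SNP-frequency responses, 3-SD candidate-SNP detection, predictor
assignment with FDR, cluster chi-square tests, and nearest-gene annotation
within a flanking window.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from poolpop.poolfreq import AlleleFrequencyMatrix

logger = logging.getLogger(__name__)


def _bio_rank(name: str) -> tuple:
    """Sort key putting Bio2 before Bio10; non-Bio names sort after, alphabetically."""
    m = re.fullmatch(r"Bio(\d+)", str(name))
    return (0, int(m.group(1)), "") if m else (1, 0, str(name))


def prune_collinear(bioclim: pd.DataFrame, threshold: float = 0.8) -> list[str]:
    """Iteratively drop one member of each highly correlated variable pair.

    While any pair has |Pearson r| >= threshold, the worst pair's member
    with the larger mean absolute correlation to all remaining variables is
    dropped (tie -> the higher Bio index goes).  Zero-variance variables
    are dropped first with a warning.  Deterministic.
    """
    if bioclim.shape[1] < 2:
        raise ValueError("need at least two variables")
    cols = list(bioclim.columns)
    constant = [c for c in cols if bioclim[c].std(ddof=0) == 0]
    for c in constant:
        logger.warning("dropping constant variable %s", c)
    cols = [c for c in cols if c not in constant]
    while len(cols) > 1:
        corr = bioclim[cols].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        max_r = corr.values.max()
        if max_r < threshold:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = corr.index[i], corr.columns[j]
        mean_a = corr.loc[a].drop(b).mean() if len(cols) > 2 else 0.0
        mean_b = corr.loc[b].drop(a).mean() if len(cols) > 2 else 0.0
        if np.isclose(mean_a, mean_b):
            drop = max(a, b, key=_bio_rank)
        else:
            drop = a if mean_a > mean_b else b
        cols.remove(drop)
    return cols


@dataclass
class RDAResult:
    """Constrained-ordination output on centered/standardized data."""

    eigenvalue_fractions: np.ndarray  # per constrained axis, of total inertia
    constrained_proportion: float
    site_scores: pd.DataFrame  # population x axis
    loadings: pd.DataFrame  # response feature x axis (unit-norm columns)
    biplot_scores: pd.DataFrame  # predictor x axis correlations
    axes_used: int


def rda(
    response: pd.DataFrame, predictors: pd.DataFrame, scale_response: bool = False
) -> RDAResult:
    """Redundancy analysis: multivariate regression then SVD of the fit.

    Predictors are z-scored; the response is centered (and optionally
    standardized, as for trait responses).  Eigenvalue fractions are squared
    singular values of the fitted matrix over the total response inertia.
    """
    if response.isna().any().any() or predictors.isna().any().any():
        raise ValueError("RDA requires complete data")
    common = response.index.intersection(predictors.index)
    if len(common) < len(response):
        raise ValueError("response and predictor tables do not share all populations")
    Xdf = predictors.loc[response.index]
    n, q = Xdf.shape
    if n <= q:
        raise ValueError(f"need more populations ({n}) than predictors ({q})")
    sds = Xdf.std(ddof=0)
    if (sds == 0).any():
        raise ValueError(f"constant predictor(s): {list(sds[sds == 0].index)}")
    X = ((Xdf - Xdf.mean()) / sds).to_numpy()
    rank = np.linalg.matrix_rank(X)
    if rank < q:
        corr = pd.DataFrame(X, columns=Xdf.columns).corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.max().idxmax()
        raise ValueError(f"rank-deficient predictors (aliased with {worst})")
    Y = response.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0)
    if scale_response:
        ysd = Y.std(axis=0, ddof=0)
        ysd[ysd == 0] = 1.0
        Y = Y / ysd
    total_inertia = float((Y**2).sum())
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ B
    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    n_axes = int((s > 1e-10 * max(s[0], 1e-300)).sum()) if s.size else 0
    U, s, Vt = U[:, :n_axes], s[:n_axes], Vt[:n_axes]
    fracs = s**2 / total_inertia if total_inertia > 0 else np.zeros_like(s)
    axis_names = [f"RDA{i + 1}" for i in range(n_axes)]
    site = pd.DataFrame(U * s, index=response.index, columns=axis_names)
    loadings = pd.DataFrame(Vt.T, index=response.columns, columns=axis_names)
    with np.errstate(invalid="ignore"):
        biplot = pd.DataFrame(
            np.corrcoef(X.T, site.to_numpy().T)[:q, q:], index=Xdf.columns, columns=axis_names
        )
    return RDAResult(
        eigenvalue_fractions=fracs,
        constrained_proportion=float(fracs.sum()),
        site_scores=site,
        loadings=loadings,
        biplot_scores=biplot,
        axes_used=n_axes,
    )


def detect_candidates(result: RDAResult, n_axes: int = 3, sd_mult: float = 3.0) -> pd.DataFrame:
    """Flag response features whose loading departs more than ``sd_mult``
    standard deviations from the mean loading, per axis; union over axes.

    Each candidate is tagged with the axis of maximal exceedance (in SD
    units) and its loading on that axis.
    """
    if n_axes > result.axes_used:
        raise ValueError(f"n_axes={n_axes} exceeds available axes ({result.axes_used})")
    L = result.loadings.iloc[:, :n_axes]
    z = (L - L.mean()) / L.std(ddof=0)
    flagged = z.abs() > sd_mult
    any_flag = flagged.any(axis=1)
    out = []
    for feature in L.index[any_flag]:
        zrow = z.loc[feature].abs()
        axis = zrow.idxmax()
        out.append(
            {
                "locus": feature,
                "axis": axis,
                "loading": float(L.loc[feature, axis]),
                "exceedance_sd": float(zrow.max()),
            }
        )
    return pd.DataFrame(out, columns=["locus", "axis", "loading", "exceedance_sd"])


def assign_predictor(
    candidates: pd.DataFrame,
    freqs: AlleleFrequencyMatrix,
    bioclim: pd.DataFrame,
    retained: list[str] | None = None,
) -> pd.DataFrame:
    """Per candidate, the most strongly correlated bioclim variable.

    Pearson r against each retained variable; ties break to the lower Bio
    index; p from the two-sided correlation test; q by Benjamini-Hochberg
    across the candidate set.
    """
    if candidates.empty:
        raise ValueError("candidate set is empty")
    variables = retained if retained is not None else list(bioclim.columns)
    variables = sorted(variables, key=_bio_rank)
    env = bioclim.loc[freqs.populations, variables]
    locus_ids = freqs.locus_ids()
    pos = {lid: i for i, lid in enumerate(locus_ids)}
    rows = []
    for _, cand in candidates.iterrows():
        locus = cand["locus"]
        x = freqs.values[:, pos[locus]]
        if np.std(x) == 0:
            raise ValueError(f"zero-variance locus {locus}")
        best = None
        for var in variables:
            r, p = stats.pearsonr(x, env[var].to_numpy())
            if best is None or abs(r) > abs(best[1]) + 1e-12:
                best = (var, r, p)
        rows.append({**cand.to_dict(), "variable": best[0], "r": best[1], "p": best[2]})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def chisq_cluster_association(
    candidates: pd.DataFrame,
    freqs: AlleleFrequencyMatrix,
    clusters: pd.Series,
    pool_size: int = 30,
) -> pd.DataFrame:
    """Chi-square independence test of allele counts vs cluster membership.

    Builds a cluster x allele contingency table from rounded allele counts
    (2 * pool_size * AAF summed over member populations), tests without
    continuity correction, and applies Benjamini-Hochberg across the
    candidate set.  Tables with > 20% of expected cells below 1 are flagged
    low-reliability.
    """
    if candidates.empty:
        raise ValueError("candidate set is empty")
    g = clusters.reindex(freqs.populations)
    if g.isna().any():
        raise ValueError("cluster assignment missing for some populations")
    labels = sorted(g.unique())
    if len(labels) < 2:
        raise ValueError("need at least two clusters")
    members = {lab: np.where((g == lab).to_numpy())[0] for lab in labels}
    locus_ids = freqs.locus_ids()
    pos = {lid: i for i, lid in enumerate(locus_ids)}
    rows = []
    for _, cand in candidates.iterrows():
        locus = cand["locus"]
        p = freqs.values[:, pos[locus]]
        table = np.zeros((len(labels), 2))
        for i, lab in enumerate(labels):
            alt = np.round(2 * pool_size * p[members[lab]]).sum()
            total = 2 * pool_size * len(members[lab])
            table[i] = (alt, total - alt)
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            chi2_stat, pval, low = 0.0, 1.0, True  # degenerate margin
        else:
            chi2_stat, pval, _, expected = stats.chi2_contingency(table, correction=False)
            low = float((expected < 1).mean()) > 0.2
        rows.append(
            {
                "locus": locus,
                "chi2": float(chi2_stat),
                "chi2_p": float(pval),
                "low_reliability": low,
            }
        )
    out = pd.DataFrame(rows)
    out["chi2_q"] = multipletests(out["chi2_p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# gene annotation


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene records (seqid, start, end, strand, gene_id) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    rows = []
    for gene in db.features_of_type("gene"):
        gid = gene.attributes.get("ID", [gene.id])[0]
        rows.append(
            {
                "seqid": gene.seqid,
                "start": gene.start,
                "end": gene.end,
                "strand": gene.strand,
                "gene_id": gid,
            }
        )
    return pd.DataFrame(rows, columns=["seqid", "start", "end", "strand", "gene_id"])


def nearest_gene(
    candidates: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 3000,
    strand_aware: bool = True,
) -> pd.DataFrame:
    """Assign each candidate SNP its nearest gene within ``window`` bp.

    A SNP inside [start, end] is "within" at distance 0; otherwise the
    nearest gene on the same chromosome within the window of the nearer
    boundary is taken (ties -> smaller distance, then lower gene start).
    Upstream/downstream is relative to gene strand (5' flank = upstream)
    unless ``strand_aware=False``, which reports plain left/right.
    """
    rows = []
    genes_by_chrom = {c: sub for c, sub in genes.groupby("seqid")} if len(genes) else {}
    for _, cand in candidates.iterrows():
        chrom, pos_str = str(cand["locus"]).split(":")
        pos = int(pos_str)
        sub = genes_by_chrom.get(chrom)
        best = None  # (distance, start, gene row, side)
        if sub is None:
            logger.warning("chromosome %s absent from annotation", chrom)
        else:
            for g in sub.itertuples():
                if g.start <= pos <= g.end:
                    cand_rec = (0, g.start, g, "within")
                elif pos < g.start:
                    d = g.start - pos
                    if d > window:
                        continue
                    cand_rec = (d, g.start, g, "left")
                else:
                    d = pos - g.end
                    if d > window:
                        continue
                    cand_rec = (d, g.start, g, "right")
                if best is None or (cand_rec[0], cand_rec[1]) < (best[0], best[1]):
                    best = cand_rec
        if best is None:
            rows.append({**cand.to_dict(), "gene": None, "relation": None, "distance": np.nan})
            continue
        d, _, g, side = best
        if side == "within":
            relation = "within"
        elif strand_aware and g.strand == "-":
            # the 5' flank of a minus-strand gene lies to its right
            relation = "upstream" if side == "right" else "downstream"
        else:
            relation = "upstream" if side == "left" else "downstream"
        rows.append({**cand.to_dict(), "gene": g.gene_id, "relation": relation, "distance": d})
    return pd.DataFrame(rows)
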