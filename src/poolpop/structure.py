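"""DAPC-style population clustering.

PCA of allele frequencies, a-score principal-component selection, k-means
with BIC model choice, and linear discriminant analysis with membership
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.cluster import KMeans

from poolpop.poolfreq import AlleleFrequencyMatrix


@dataclass
class PCAResult:
    scores: np.ndarray  # populations x components
    loadings: np.ndarray  # features x components
    percent_variance: np.ndarray  # per retained component, of total variance
    singular_values: np.ndarray
    mean: np.ndarray
    scale: np.ndarray | None = None


def pca_frequencies(
    freqs: AlleleFrequencyMatrix | np.ndarray,
    n_components: int | None = None,
    scale: bool = False,
) -> PCAResult:
    """Column-centered (optionally unit-scaled) SVD of the frequency matrix.

    Percent variance is each eigenvalue's share of the *total* variance,
    not just of the retained components.
    """
    X = freqs.values if isinstance(freqs, AlleleFrequencyMatrix) else np.asarray(freqs, float)
    if np.isnan(X).any():
        raise ValueError("PCA requires a complete (imputed) matrix")
    n, p = X.shape
    max_comp = min(n - 1, p)
    if n_components is None:
        n_components = max_comp
    if not (1 <= n_components <= max_comp):
        raise ValueError(f"n_components must lie in [1, {max_comp}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    sd = None
    if scale:
        sd = Xc.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = (s**2).sum()
    pct = 100.0 * s**2 / total_var
    k = n_components
    return PCAResult(
        scores=U[:, :k] * s[:k],
        loadings=Vt[:k].T,
        percent_variance=pct[:k],
        singular_values=s[:k],
        mean=mean,
        scale=sd,
    )


def kmeans_bic(wss: float, n: int, k: int) -> float:
    """Gaussian-profile BIC for a k-means solution: n*ln(WSS/n) + k*ln(n)."""
    return n * np.log(wss / n) + k * np.log(n)


def find_clusters(
    scores: np.ndarray,
    k_range: range | list[int] = range(1, 21),
    seed: int = 0,
    n_restarts: int = 25,
    max_iter: int = 300,
) -> tuple[pd.Series, int]:
    """K-means over a K range; BIC profile and its argmin.

    Returns (bic_by_k indexed by K, chosen_k).  K = 1 uses the total
    centered within-sum-of-squares with no clustering step.
    """
    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    ks = sorted(k_range)
    if ks[0] < 1 or ks[-1] >= n:
        raise ValueError(f"K range must lie in [1, {n - 1}]")
    bics = {}
    for k in ks:
        if k == 1:
            wss = float(((X - X.mean(axis=0)) ** 2).sum())
        else:
            km = KMeans(
                n_clusters=k, n_init=n_restarts, max_iter=max_iter, random_state=seed
            ).fit(X)
            wss = float(km.inertia_)
        bics[k] = kmeans_bic(max(wss, 1e-12), n, k)
    bic_by_k = pd.Series(bics, name="BIC")
    return bic_by_k, int(bic_by_k.idxmin())


def kmeans_assign(scores: np.ndarray, k: int, seed: int = 0, n_restarts: int = 25) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(np.asarray(scores, float))
    return km.labels_


@dataclass
class ClusteringResult:
    """DAPC output: discriminant axes, memberships and bookkeeping."""

    retained_pcs: int
    hard_assignments: pd.Series  # population -> cluster label
    memberships: pd.DataFrame  # population x cluster, rows sum to 1
    discriminant_scores: pd.DataFrame  # population x axis
    axes: np.ndarray  # pc-space coefficients per discriminant axis
    percent_variance: np.ndarray | None = None  # of the upstream PCA
    bic_by_k: pd.Series | None = None
    chosen_k: int | None = None
    ascore_profile: pd.Series | None = None


def dapc(
    scores: np.ndarray,
    assignments,
    n_pcs: int | None = None,
    ids: list[str] | None = None,
    ridge: float = 1e-8,
) -> ClusteringResult:
    """Linear discriminant analysis of retained PC scores.

    Membership probabilities come from squared distances to class centroids
    in discriminant space via the standard-normal-density posterior with
    equal priors; ties in the argmax resolve to the lowest cluster index.
    A ridge proportional to the within-class scatter trace guards against
    singular scatter (single-member clusters).
    """
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(assignments)
    if n_pcs is not None:
        if n_pcs > X.shape[1]:
            raise ValueError("n_pcs exceeds available components")
        X = X[:, :n_pcs]
    n, d = X.shape
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("DAPC needs at least two clusters")
    grand = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    centroids = {}
    for c in classes:
        Xi = X[labels == c]
        mu = Xi.mean(axis=0)
        centroids[c] = mu
        Sw += (Xi - mu).T @ (Xi - mu)
        Sb += len(Xi) * np.outer(mu - grand, mu - grand)
    Sw += ridge * max(np.trace(Sw), 1.0) * np.eye(d)
    n_axes = min(len(classes) - 1, d)
    evals, evecs = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1][:n_axes]
    # eigh normalizes v' Sw v = 1; rescale so the pooled within-class
    # *variance* per axis is 1, making exp(-d^2/2) the standard posterior
    axes = evecs[:, order] * np.sqrt(max(n - len(classes), 1))
    disc = X @ axes
    cents = np.stack([centroids[c] @ axes for c in classes])
    d2 = ((disc[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    logpost = -0.5 * d2
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    index = ids if ids is not None else list(range(n))
    memberships = pd.DataFrame(post, index=index, columns=classes)
    hard = memberships.idxmax(axis=1)  # pandas idxmax takes the first (lowest) on ties
    return ClusteringResult(
        retained_pcs=d,
        hard_assignments=hard,
        memberships=memberships,
        discriminant_scores=pd.DataFrame(
            disc, index=index, columns=[f"LD{i + 1}" for i in range(n_axes)]
        ),
        axes=axes,
    )


def select_pcs_ascore(
    scores: np.ndarray,
    groups,
    candidate_pc_counts: list[int] | None = None,
    n_permutations: int = 10,
    seed: int = 0,
) -> tuple[int, pd.Series]:
    """A-score selection of the number of retained PCs.

    For each candidate count, the a-score is the observed proportion of
    correct reassignment by the discriminant step minus the mean
    reassignment proportion over label permutations.  Returns the count
    maximizing the a-score, with the full profile.
    """
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(groups)
    n = X.shape[0]
    if candidate_pc_counts is None:
        candidate_pc_counts = list(range(1, X.shape[1] + 1))
    if any(c >= n for c in candidate_pc_counts):
        raise ValueError("candidate PC count must be < number of populations")
    rng = np.random.default_rng(seed)
    profile = {}
    for c in candidate_pc_counts:
        fit = dapc(X, labels, n_pcs=c)
        observed = float((fit.hard_assignments.to_numpy() == labels).mean())
        null = []
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            pfit = dapc(X, perm, n_pcs=c)
            null.append(float((pfit.hard_assignments.to_numpy() == perm).mean()))
        profile[c] = observed - float(np.mean(null))
    profile = pd.Series(profile, name="a_score")
    return int(profile.idxmax()), profile


def run_dapc_pipeline(
    freqs: AlleleFrequencyMatrix,
    k_range: range | list[int] = range(1, 21),
    n_pcs: int | None = None,
    chosen_k: int | None = None,
    seed: int = 0,
    scale: bool = False,
) -> ClusteringResult:
    """PCA -> (a-score PC selection) -> k-means/BIC -> DAPC in one call.

    ``chosen_k`` overrides the BIC argmin, mirroring the judgment call of
    picking a biologically interpretable K from a flat BIC profile.
    """
    pca = pca_frequencies(freqs, scale=scale)
    bic_by_k, k_star = find_clusters(pca.scores, k_range=k_range, seed=seed)
    k = chosen_k or k_star
    labels = kmeans_assign(pca.scores, k, seed=seed)
    ascore_profile = None
    if n_pcs is None:
        max_count = min(pca.scores.shape[1], freqs.n_populations - 1, 20)
        n_pcs, ascore_profile = select_pcs_ascore(
            pca.scores, labels, candidate_pc_counts=list(range(1, max_count + 1)), seed=seed
        )
    result = dapc(pca.scores, labels, n_pcs=n_pcs, ids=freqs.populations)
    result.percent_variance = pca.percent_variance
    result.bic_by_k = bic_by_k
    result.chosen_k = k
    result.ascore_profile = ascore_profile
    return result
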