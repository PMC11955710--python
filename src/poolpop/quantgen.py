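"""REML variance components, GBLUP and narrow-sense heritability.

The mixed model is y = Xb + sum_u Z_u u_u + e with u_u ~ N(0, s2_u K_u)
(K_u the genomic relationship matrix for the population term, identity
otherwise) and e ~ N(0, s2_e I).  Estimation is restricted maximum
likelihood by average-information updates with step-halving and
boundary fixing at zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import chi2

from poolpop.kinship import RelationshipMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RandomTerm:
    """One random effect: its name and the factor columns whose
    combination defines the levels.  ``use_g`` routes the genomic
    relationship matrix (keyed on the first factor) into the covariance."""

    name: str
    factors: tuple[str, ...]
    use_g: bool = False


@dataclass
class ModelSpec:
    """Fixed factor columns (intercept implicit) plus random terms."""

    fixed: list[str] = field(default_factory=list)
    random: list[RandomTerm] = field(default_factory=list)

    def drop_term(self, name: str) -> "ModelSpec":
        if name not in {t.name for t in self.random}:
            raise ValueError(f"no random term named {name!r}")
        return ModelSpec(
            fixed=list(self.fixed), random=[t for t in self.random if t.name != name]
        )


def population_model(interactions: tuple[str, ...] = ("season", "year")) -> ModelSpec:
    """The default analysis model: fixed design factors, random population
    (genomic covariance) and population-by-factor interactions."""
    fixed = ["year", "location", "season"]
    random = [RandomTerm("population", ("population",), use_g=True)]
    for f in interactions:
        random.append(RandomTerm(f"population:{f}", ("population", f)))
    return ModelSpec(fixed=fixed, random=random)


@dataclass
class VarianceComponentFit:
    """REML estimates with standard errors, GBLUPs and fit metadata."""

    estimates: dict[str, float]
    std_errors: dict[str, float]
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    spec: ModelSpec
    gblups: pd.Series | None = None
    fixed_effects: pd.Series | None = None
    boundary: set[str] = field(default_factory=set)

    def table(self) -> pd.DataFrame:
        rows = [
            {"term": k, "estimate": self.estimates[k], "se": self.std_errors[k]}
            for k in self.estimates
        ]
        return pd.DataFrame(rows).set_index("term")


def _design_fixed(data: pd.DataFrame, fixed: list[str]) -> tuple[np.ndarray, list[str]]:
    n = len(data)
    X = [np.ones((n, 1))]
    names = ["(Intercept)"]
    for f in fixed:
        if f not in data.columns:
            raise ValueError(f"fixed factor {f!r} not in data")
        d = pd.get_dummies(data[f].astype(str), prefix=f, drop_first=True, dtype=float)
        X.append(d.to_numpy())
        names.extend(d.columns)
    X = np.hstack(X)
    # drop aliased columns via pivoted QR
    q, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int((diag > 1e-8 * diag.max()).sum())
    keep = np.sort(piv[:rank])
    if rank < X.shape[1]:
        dropped = [names[i] for i in piv[rank:]]
        logger.warning("dropping aliased fixed-effect column(s): %s", dropped)
    return X[:, keep], [names[i] for i in keep]


def _design_random(
    data: pd.DataFrame, term: RandomTerm, G: RelationshipMatrix | None
) -> tuple[np.ndarray, list[str], np.ndarray | None]:
    for f in term.factors:
        if f not in data.columns:
            raise ValueError(f"random factor {f!r} not in data")
    key = data[list(term.factors)].astype(str).agg(":".join, axis=1)
    levels = sorted(key.unique())
    Z = pd.get_dummies(pd.Categorical(key, categories=levels), dtype=float).to_numpy()
    K = None
    if term.use_g:
        if G is None:
            raise ValueError(f"term {term.name!r} needs a relationship matrix")
        if len(term.factors) != 1:
            raise ValueError("genomic covariance only supported on a single factor")
        missing = [lv for lv in levels if lv not in set(G.ids)]
        if missing:
            raise ValueError(f"relationship matrix does not cover levels: {missing[:5]}")
        sub = G.to_frame().loc[levels, levels].to_numpy()
        K = 0.5 * (sub + sub.T)
    return Z, levels, K


class _REMLWorkspace:
    """Precomputed V_i = Z_i K_i Z_i' per random term (+ residual identity)."""

    def __init__(self, y, X, Vis, names):
        self.y = y
        self.X = X
        self.Vis = Vis  # list of n x n arrays, residual last (identity)
        self.names = names  # term names, residual last
        self.n, self.p = X.shape

    def loglik(self, theta):
        V = sum(t * Vi for t, Vi in zip(theta, self.Vis))
        c, low = scipy.linalg.cho_factor(V, lower=True, check_finite=False)
        logdet_v = 2.0 * np.log(np.diag(c)).sum()
        ViX = scipy.linalg.cho_solve((c, low), self.X, check_finite=False)
        Viy = scipy.linalg.cho_solve((c, low), self.y, check_finite=False)
        XtViX = self.X.T @ ViX
        cx = scipy.linalg.cho_factor(XtViX, lower=True)
        logdet_x = 2.0 * np.log(np.diag(cx[0])).sum()
        beta = scipy.linalg.cho_solve(cx, self.X.T @ Viy)
        Py = Viy - ViX @ beta
        ll = -0.5 * (logdet_v + logdet_x + float(self.y @ Py))
        return ll, (c, low), Py, beta, cx

    def full_state(self, theta):
        ll, chol, Py, beta, cx = self.loglik(theta)
        n = self.n
        Vinv = scipy.linalg.cho_solve(chol, np.eye(n), check_finite=False)
        ViX = Vinv @ self.X
        P = Vinv - ViX @ scipy.linalg.cho_solve(cx, ViX.T)
        r = len(theta)
        score = np.empty(r)
        W = np.empty((n, r))
        for i, Vi in enumerate(self.Vis):
            w = Vi @ Py
            W[:, i] = w
            score[i] = -0.5 * (float(np.sum(P * Vi)) - float(Py @ w))
        PW = P @ W
        AI = 0.5 * (W.T @ PW)
        return ll, score, AI, Py, beta


def fit_lmm(
    data: pd.DataFrame,
    spec: ModelSpec,
    G: RelationshipMatrix | None = None,
    trait: str | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> VarianceComponentFit:
    """REML fit of the declared mixed model for one trait.

    ``data`` is the long phenotype table; if it carries several traits,
    ``trait`` selects one.  Components are constrained non-negative with
    active-set fixing at the boundary; convergence is on the change in the
    restricted log-likelihood.
    """
    df = data
    if trait is not None:
        df = df[df["trait"] == trait]
    if "value" not in df.columns:
        raise ValueError("phenotype table needs a 'value' column")
    df = df.reset_index(drop=True)
    y = df["value"].to_numpy(dtype=float)
    if np.isnan(y).any():
        df = df[~df["value"].isna()].reset_index(drop=True)
        y = df["value"].to_numpy(dtype=float)
    n = len(y)
    X, fixed_names = _design_fixed(df, spec.fixed)

    Vis, names, Zs, Ks, levels_per_term = [], [], {}, {}, {}
    for term in spec.random:
        Z, levels, K = _design_random(df, term, G)
        if Z.shape[1] >= n:
            raise ValueError(f"random term {term.name!r} is confounded with the residual")
        Vi = Z @ (K @ Z.T) if K is not None else Z @ Z.T
        Vis.append(Vi)
        names.append(term.name)
        Zs[term.name] = Z
        Ks[term.name] = K
        levels_per_term[term.name] = levels
    Vis.append(np.eye(n))
    names.append("residual")
    ws = _REMLWorkspace(y, X, Vis, names)

    vary = float(np.var(y)) or 1.0
    r = len(Vis)
    theta = np.full(r, vary / r)
    min_resid = 1e-8 * vary
    frozen = np.zeros(r, dtype=bool)

    ll, score, AI, Py, beta = ws.full_state(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        free = ~frozen
        # unfreeze boundary components whose gradient points inward
        for i in np.where(frozen)[0]:
            if score[i] > 0:
                frozen[i] = False
                free = ~frozen
        AI_f = AI[np.ix_(free, free)]
        try:
            delta = np.linalg.solve(AI_f + 1e-12 * np.eye(free.sum()), score[free])
        except np.linalg.LinAlgError:
            delta = score[free] / max(np.abs(np.diag(AI_f)).max(), 1.0)
        accepted = False
        alpha = 1.0
        for _ in range(40):
            prop = theta.copy()
            prop[free] = theta[free] + alpha * delta
            prop = np.maximum(prop, 0.0)
            prop[-1] = max(prop[-1], min_resid)
            try:
                new_ll, *_ = ws.loglik(prop)
            except (np.linalg.LinAlgError, ValueError):
                alpha *= 0.5
                continue
            if new_ll >= ll - 1e-12:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            converged = abs(float(np.max(np.abs(score[free]))) if free.any() else 0.0) < 1e-2
            break
        # freeze components that landed on the boundary
        for i in range(r - 1):
            if prop[i] <= 1e-10 * vary:
                prop[i] = 0.0
                frozen[i] = True
        new_full = ws.full_state(np.maximum(prop, [0] * (r - 1) + [min_resid]))
        new_ll, score, AI, Py, beta = new_full
        dll = new_ll - ll
        theta, ll = prop, new_ll
        if abs(dll) < tol:
            converged = True
            break

    se = np.zeros(r)
    free = ~frozen
    if free.any():
        try:
            cov = np.linalg.inv(AI[np.ix_(free, free)])
            se[free] = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se[free] = np.nan
    estimates = dict(zip(names, theta.tolist()))
    std_errors = dict(zip(names, se.tolist()))

    gblups = None
    g_terms = [t for t in spec.random if t.use_g]
    if g_terms:
        t0 = g_terms[0]
        Z, K = Zs[t0.name], Ks[t0.name]
        u = estimates[t0.name] * (K @ (Z.T @ Py))
        gblups = pd.Series(u, index=levels_per_term[t0.name], name="gblup")

    return VarianceComponentFit(
        estimates=estimates,
        std_errors=std_errors,
        loglik=ll,
        converged=converged,
        n_iter=it,
        n_obs=n,
        spec=spec,
        gblups=gblups,
        fixed_effects=pd.Series(beta, index=fixed_names),
        boundary={names[i] for i in np.where(frozen)[0]},
    )


def p_to_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def lrt_component(
    fit_full: VarianceComponentFit, fit_reduced: VarianceComponentFit
) -> tuple[float, float, str]:
    """Boundary-mixture likelihood-ratio test for one variance component.

    The reduced model must nest the full one by removing exactly one
    random term.  p comes from the 0.5*chi2_0 + 0.5*chi2_1 mixture.
    """
    full_terms = {t.name for t in fit_full.spec.random}
    red_terms = {t.name for t in fit_reduced.spec.random}
    if not (red_terms < full_terms and len(full_terms - red_terms) == 1):
        raise ValueError("reduced model must drop exactly one random term of the full model")
    stat = max(2.0 * (fit_full.loglik - fit_reduced.loglik), 0.0)
    p = 0.5 * float(chi2.sf(stat, 1)) if stat > 0 else 0.5
    return stat, p, p_to_stars(p)


@dataclass
class HeritabilityInputs:
    """Variance components and effective design sizes for the h2 ratio.

    Absent interaction terms enter as 0 with divisor 1.  ``n_resid_divisor``
    defaults to the product n_r * n_s * n_y * n_l.
    """

    sigma2_p: float
    sigma2_e: float
    sigma2_pb: float = 0.0
    sigma2_ps: float = 0.0
    sigma2_py: float = 0.0
    sigma2_pl: float = 0.0
    n_r: int = 1
    n_s: int = 1
    n_y: int = 1
    n_l: int = 1
    n_resid_divisor: int | None = None

    def validate(self) -> None:
        for name in ("sigma2_p", "sigma2_e", "sigma2_pb", "sigma2_ps", "sigma2_py", "sigma2_pl"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a non-negative real, got {v}")
        for name in ("n_r", "n_s", "n_y", "n_l"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_resid_divisor is not None and self.n_resid_divisor < 1:
            raise ValueError("n_resid_divisor must be >= 1")


def heritability(inputs: HeritabilityInputs) -> float:
    """Population-mean narrow-sense heritability.

    h2 = s2_p / (s2_p + s2_pb/n_r + s2_ps/n_s + s2_py/n_y + s2_pl/n_l
    + s2_e/d) with d the product of the effective replicate / season /
    year / location counts of the analysis at hand.
    """
    inputs.validate()
    d = inputs.n_resid_divisor or (inputs.n_r * inputs.n_s * inputs.n_y * inputs.n_l)
    denom = (
        inputs.sigma2_p
        + inputs.sigma2_pb / inputs.n_r
        + inputs.sigma2_ps / inputs.n_s
        + inputs.sigma2_py / inputs.n_y
        + inputs.sigma2_pl / inputs.n_l
        + inputs.sigma2_e / d
    )
    if denom == 0:
        raise ValueError("heritability undefined: all variance components are zero")
    return inputs.sigma2_p / denom


def heritability_from_fit(fit: VarianceComponentFit, **design_sizes) -> float:
    """h2 from a fitted model, mapping term names to the ratio's slots."""
    est = fit.estimates
    inputs = HeritabilityInputs(
        sigma2_p=est.get("population", 0.0),
        sigma2_e=est.get("residual", 0.0),
        sigma2_pb=est.get("population:replicate", 0.0),
        sigma2_ps=est.get("population:season", 0.0),
        sigma2_py=est.get("population:year", 0.0),
        sigma2_pl=est.get("population:location", 0.0),
        **design_sizes,
    )
    return heritability(inputs)


def gblup_matrix(fits: dict[str, VarianceComponentFit]) -> pd.DataFrame:
    """Population x trait matrix of per-trait standardized GBLUPs."""
    cols = {}
    for trait, fit in fits.items():
        if fit.gblups is None:
            raise ValueError(f"fit for {trait!r} carries no GBLUPs")
        u = fit.gblups
        sd = u.std(ddof=0)
        if sd == 0:
            logger.warning("trait %r has zero GBLUP variance; dropped", trait)
            continue
        cols[trait] = (u - u.mean()) / sd
    if not cols:
        raise ValueError("no traits with non-degenerate GBLUPs")
    return pd.DataFrame(cols)


def trait_pca(gblups: pd.DataFrame, n_components: int | None = None):
    """PCA of the standardized GBLUP matrix (populations x traits)."""
    from poolpop.structure import pca_frequencies

    return pca_frequencies(gblups.to_numpy(), n_components=n_components)
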