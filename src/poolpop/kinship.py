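"""Genomic and pedigree relationship matrices."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from poolpop.poolfreq import AlleleFrequencyMatrix

logger = logging.getLogger(__name__)


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix, genomic (G) or pedigree (A) kind."""

    ids: list[str]
    values: np.ndarray
    kind: str  # "genomic" | "pedigree"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")
        self.values = 0.5 * (v + v.T)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path, kind: str = "genomic") -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id")
        return cls(list(df.index), df.to_numpy(), kind)


def build_gmatrix(
    freqs: AlleleFrequencyMatrix, denominator: str = "observed", ridge: float = 0.0
) -> RelationshipMatrix:
    """VanRaden-type genomic relationship matrix from pooled frequencies.

    Dosage M = 2*AAF in [0, 2] is recoded to Z = M - 1 in [-1, 1] and
    centered by locus means; G = Zc Zc' / (2 * sum_l pbar_l (1 - pbar_l)).
    ``denominator="observed"`` uses the mean AAF across populations for
    pbar; ``"half"`` fixes pbar = 0.5.  Monomorphic loci (pbar in {0, 1})
    are dropped with a warning.  An optional diagonal ridge guarantees
    invertibility for mixed-model use.
    """
    if freqs.has_missing():
        raise ValueError("G-matrix requires a complete (imputed) frequency matrix")
    v = freqs.values
    pbar = v.mean(axis=0)
    keep = (pbar > 0.0) & (pbar < 1.0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d monomorphic locus/loci from G-matrix", n_dropped)
    if keep.sum() < 2:
        raise ValueError("fewer than two polymorphic loci; cannot build G-matrix")
    v = v[:, keep]
    pbar = pbar[keep]
    Z = 2.0 * v - 1.0
    Zc = Z - Z.mean(axis=0)
    if denominator == "observed":
        denom = 2.0 * np.sum(pbar * (1.0 - pbar))
    elif denominator == "half":
        denom = 2.0 * 0.25 * len(pbar)
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    G = (Zc @ Zc.T) / denom
    if ridge:
        G = G + ridge * np.eye(G.shape[0])
    return RelationshipMatrix(list(freqs.populations), G, kind="genomic")


UNKNOWN_PARENTS = {"0", "", ".", "NA", "na", None}


def _normalize_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    cols = {c.lower(): c for c in ped.columns}
    needed = ["id", "sire", "dam"]
    if not all(k in cols for k in needed):
        raise ValueError(f"pedigree needs columns {needed}, got {list(ped.columns)}")
    out = ped.rename(columns={cols[k]: k for k in needed})[needed].copy()
    out = out.astype(object).where(out.notna(), None)
    for c in ("sire", "dam"):
        out[c] = out[c].map(lambda x: None if x in UNKNOWN_PARENTS else str(x))
    out["id"] = out["id"].astype(str)
    if out["id"].duplicated().any():
        raise ValueError("duplicate individual ids in pedigree")
    return out


def _toposort(ped: pd.DataFrame) -> list[str]:
    """Order ids so parents precede offspring; raises on cycles.

    Parents referenced without their own row are appended as implicit
    founders (logged).
    """
    parents_of = {r.id: [p for p in (r.sire, r.dam) if p is not None] for r in ped.itertuples()}
    implicit = {
        p for ps in parents_of.values() for p in ps if p not in parents_of
    }
    if implicit:
        logger.warning("treating %d referenced-but-unlisted parent(s) as founders", len(implicit))
    for p in implicit:
        parents_of[p] = []
    order, state = [], {}

    def visit(node, stack):
        if state.get(node) == 2:
            return
        if state.get(node) == 1:
            raise ValueError(f"pedigree cycle detected involving {node!r}")
        state[node] = 1
        for p in parents_of[node]:
            visit(p, stack)
        state[node] = 2
        order.append(node)

    for node in parents_of:
        visit(node, [])
    return order


def build_amatrix(ped: pd.DataFrame) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular (recursive) method.

    A(i,i) = 1 + 0.5*A(sire_i, dam_i); A(i,j) = 0.5*(A(j, sire_i) +
    A(j, dam_i)); unknown parents contribute 0.  An all-founder pedigree
    yields the identity.
    """
    ped = _normalize_pedigree(ped)
    order = _toposort(ped)
    parent = {
        r.id: (r.sire, r.dam) for r in ped.itertuples()
    }
    for x in order:
        parent.setdefault(x, (None, None))
    idx = {x: i for i, x in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for i, x in enumerate(order):
        s, d = parent[x]
        si = idx.get(s)
        di = idx.get(d)
        for j in range(i):
            a = 0.0
            if si is not None:
                a += 0.5 * A[j, si]
            if di is not None:
                a += 0.5 * A[j, di]
            A[i, j] = A[j, i] = a
        A[i, i] = 1.0 + (0.5 * A[si, di] if si is not None and di is not None else 0.0)
    # report in the original row order, implicit founders appended
    listed = list(ped["id"])
    extra = [x for x in order if x not in set(listed)]
    final = listed + extra
    perm = [idx[x] for x in final]
    return RelationshipMatrix(final, A[np.ix_(perm, perm)], kind="pedigree")


def inbreeding(ped: pd.DataFrame) -> pd.Series:
    """Per-individual inbreeding coefficient F_i = 0.5*A(sire_i, dam_i)."""
    A = build_amatrix(ped)
    norm = _normalize_pedigree(ped)
    idx = {x: i for i, x in enumerate(A.ids)}
    out = {}
    for r in norm.itertuples():
        if r.sire is not None and r.dam is not None:
            out[r.id] = 0.5 * A.values[idx[r.sire], idx[r.dam]]
        else:
            out[r.id] = 0.0
    return pd.Series(out, name="F")
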