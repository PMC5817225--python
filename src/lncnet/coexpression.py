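"""Coding-noncoding (CNC) coexpression network and GO-based lncRNA function
annotation.

Edges link a lncRNA to an mRNA when their expression profiles correlate:
the Pearson correlation's p-value comes from Fisher's asymptotic z
transform (atanh(r)*sqrt(n-3) ~ Normal(0,1) under the null), adjusted per
lncRNA by Benjamini-Hochberg, and only correlations ranking in the top or
bottom ``percentile`` of that lncRNA's PCC distribution survive. A lncRNA
is then annotated with any GO biological-process term that is
hypergeometrically enriched (p <= 0.01, >= 5 genes) among its connected
coding genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

_TINY = 5e-324  # smallest subnormal double: cap for p -> 0 at |r| -> 1


@dataclass
class CoexpressionEdge:
    lnc_id: str
    mrna_id: str
    pcc: float
    p_value: float
    adjusted_p: float

    @property
    def sign(self) -> str:
        return "positive" if self.pcc >= 0 else "negative"


@dataclass
class LncRnaFunctionCall:
    lnc_id: str
    go_id: str
    n_neighborhood_term_genes: int
    p_value: float
    annotated: bool


def pcc_with_p(x, y) -> tuple[float, float]:
    """Pearson correlation and its two-sided Fisher-asymptotic p-value.

    Constant input vectors make the correlation undefined: returns
    (nan, nan) so callers can exclude the pair."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 samples for the Fisher z approximation")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    p = fisher_z_pvalue(r, n)
    return r, p


def fisher_z_pvalue(r: float, n: int) -> float:
    """Two-sided normal tail of atanh(r)*sqrt(n-3); capped below at the
    smallest positive double for |r| = 1."""
    if abs(r) >= 1.0:
        return _TINY
    z = math.atanh(r) * math.sqrt(n - 3)
    p = 2.0 * stats.norm.sf(abs(z))
    return max(float(p), _TINY)


def build_cnc_network(
    lnc_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    percentile: float = 0.0001,
    adj_p_max: float = 0.01,
    log_transform: bool = True,
    pseudocount: float = 1.0,
) -> list[CoexpressionEdge]:
    """Correlate every lncRNA against every mRNA and keep, per lncRNA, the
    pairs whose BH-adjusted Fisher-z p < ``adj_p_max`` AND whose PCC ranks
    within the top or bottom ``percentile`` of that lncRNA's correlations
    (ties at the rank boundary are all kept).

    Expression values are log2(x + pseudocount)-transformed by default.
    Matrices must share their sample columns; constant-profile genes are
    excluded from ranking and from the network."""
    shared = [c for c in lnc_expr.columns if c in set(mrna_expr.columns)]
    if not shared:
        raise ValueError("expression matrices share no sample columns")
    L = lnc_expr[shared].to_numpy(float)
    M = mrna_expr[shared].to_numpy(float)
    if log_transform:
        L = np.log2(L + pseudocount)
        M = np.log2(M + pseudocount)
    n = len(shared)
    if n < 4:
        raise ValueError("need >= 4 shared samples")

    Lc = L - L.mean(axis=1, keepdims=True)
    Mc = M - M.mean(axis=1, keepdims=True)
    Lsd = np.sqrt((Lc**2).sum(axis=1))
    Msd = np.sqrt((Mc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Lc @ Mc.T) / np.outer(Lsd, Msd)  # lnc x mrna correlation matrix
    R = np.clip(R, -1.0, 1.0)

    edges: list[CoexpressionEdge] = []
    lnc_ids = list(lnc_expr.index)
    mrna_ids = np.array(mrna_expr.index)
    for i, lnc in enumerate(lnc_ids):
        r = R[i]
        ok = ~np.isnan(r)
        if not ok.any():
            continue
        rv = r[ok]
        ids = mrna_ids[ok]
        with np.errstate(divide="ignore"):
            z = np.arctanh(np.clip(np.abs(rv), 0.0, 1.0 - 1e-16)) * math.sqrt(n - 3)
        p = np.maximum(2.0 * stats.norm.sf(z), _TINY)
        p[np.abs(rv) >= 1.0 - 1e-16] = _TINY
        adj = multipletests(p, method="fdr_bh")[1]

        k = max(1, math.ceil(percentile * rv.size))
        order = np.argsort(rv, kind="mergesort")
        lo_bound = rv[order[k - 1]]
        hi_bound = rv[order[-k]]
        in_rank = (rv <= lo_bound) | (rv >= hi_bound)  # ties kept
        keep = in_rank & (adj < adj_p_max)
        for j in np.flatnonzero(keep):
            edges.append(
                CoexpressionEdge(
                    lnc_id=str(lnc),
                    mrna_id=str(ids[j]),
                    pcc=float(rv[j]),
                    p_value=float(p[j]),
                    adjusted_p=float(adj[j]),
                )
            )
    return edges


def hypergeometric_enrichment(
    neighborhood_genes: set[str], term_genes: set[str], universe: set[str]
) -> float:
    """Upper-tail hypergeometric p-value, P(X >= observed overlap), for the
    overlap between a lncRNA's coding neighbourhood and a GO term's genes."""
    if not universe:
        raise ValueError("empty gene universe")
    if not neighborhood_genes <= universe or not term_genes <= universe:
        raise ValueError("neighborhood and term genes must lie within the universe")
    N = len(universe)
    K = len(term_genes)
    n = len(neighborhood_genes)
    k = len(neighborhood_genes & term_genes)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def annotate_lncrna_functions(
    edges: list[CoexpressionEdge],
    gene2go: pd.DataFrame,
    universe: set[str] | None = None,
    p_max: float = 0.01,
    min_genes: int = 5,
    namespace: str = "biological_process",
) -> list[LncRnaFunctionCall]:
    """Assign functions to lncRNAs by GO enrichment of their network
    neighbourhoods.

    The universe defaults to every gene carrying at least one annotation in
    the requested namespace. A call is annotated when p <= ``p_max`` and at
    least ``min_genes`` neighbourhood genes carry the term. lncRNAs without
    coding neighbours simply produce no calls."""
    g2g = gene2go[gene2go["namespace"] == namespace] if "namespace" in gene2go else gene2go
    term_to_genes: dict[str, set[str]] = {
        term: set(sub["gene_id"]) for term, sub in g2g.groupby("go_id")
    }
    annotated_universe = set(g2g["gene_id"])
    if universe is None:
        universe = annotated_universe

    neighborhoods: dict[str, set[str]] = {}
    for e in edges:
        neighborhoods.setdefault(e.lnc_id, set()).add(e.mrna_id)

    calls: list[LncRnaFunctionCall] = []
    for lnc in sorted(neighborhoods):
        hood = neighborhoods[lnc] & universe
        if not hood:
            continue
        terms = {t for g in hood for t in g2g[g2g["gene_id"] == g]["go_id"]}
        for term in sorted(terms):
            tg = term_to_genes[term] & universe
            k = len(hood & tg)
            p = hypergeometric_enrichment(hood, tg, universe)
            calls.append(
                LncRnaFunctionCall(
                    lnc_id=lnc,
                    go_id=term,
                    n_neighborhood_term_genes=k,
                    p_value=p,
                    annotated=bool(p <= p_max and k >= min_genes),
                )
            )
    return calls


def edges_table(edges: list[CoexpressionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lnc_id": [e.lnc_id for e in edges],
            "mrna_id": [e.mrna_id for e in edges],
            "pcc": [e.pcc for e in edges],
            "p_value": [e.p_value for e in edges],
            "adjusted_p": [e.adjusted_p for e in edges],
            "sign": [e.sign for e in edges],
        }
    )
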