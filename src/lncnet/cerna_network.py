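"""ceRNA (lncRNA-miRNA-mRNA) network construction.

miRNA response elements (MREs) are predicted on lncRNAs and mRNA 3'UTRs
with a miRanda-style local complementarity alignment: antiparallel
Watson-Crick matches score +5, G:U wobbles +1, mismatches -3, affine gaps
(-9 open / -4 extend), and contributions from miRNA seed positions 2-8 are
multiplied by a seed weight of 4. Sites pass when the alignment score is
>= 150 (inclusive) and the hybridization ΔG — computed with the same
nearest-neighbor engine the SMD analysis uses — is < -20 kcal/mol
(strict). Edges must additionally be expression-anticorrelated (negative
PCC, Fisher-z p <= 0.05). The lncRNA-miRNA and miRNA-mRNA edge sets are
merged on shared miRNA nodes; miRNAs bridging both sides define ceRNA
triads.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from . import smd_duplex
from .coexpression import pcc_with_p
from .seqs import to_dna
from .types import MreSite

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE = {("G", "T"), ("T", "G")}  # target base vs (DNA-coded) miRNA base


@dataclass
class MreParams:
    match: float = 5.0
    wobble: float = 1.0
    mismatch: float = -3.0
    gap_open: float = -9.0
    gap_extend: float = -4.0
    seed_scale: float = 4.0  # multiplier on miRNA positions 2-8 (1-based, 5' end)
    seed_start: int = 2
    seed_end: int = 8
    report_floor: float = 100.0
    max_sites: int = 5


def _pair_score(target_base: str, mir_base: str, params: MreParams) -> float:
    if target_base == _COMPLEMENT.get(mir_base, "?"):
        return params.match
    if (target_base, mir_base) in _WOBBLE:
        return params.wobble
    return params.mismatch


def scan_mre(
    mirna_seq: str,
    target_seq: str,
    params: MreParams | None = None,
    mirna_id: str = "",
    target_id: str = "",
) -> list[MreSite]:
    """Predict miRNA binding sites on one target.

    The miRNA (given 5'->3') binds antiparallel, so its reverse is aligned
    against the target with complementarity scoring; seed-position scores
    are multiplied by ``seed_scale``. Local alignment with affine gaps;
    non-overlapping sites above ``report_floor`` are returned best-first,
    each with its hybridization ΔG. A target shorter than the miRNA yields
    an empty list."""
    P = params or MreParams()
    mir = to_dna(mirna_seq)
    if not 18 <= len(mir) <= 26:
        raise ValueError(f"miRNA length {len(mir)} outside 18-26 nt")
    tgt = to_dna(target_seq)
    if len(tgt) < len(mir):
        return []
    rmir = mir[::-1]  # rmir[i] is miRNA position len(mir)-i (1-based)
    L, N = len(rmir), len(tgt)
    scale = np.ones(L)
    for i in range(L):
        pos = L - i  # original 1-based miRNA position
        if P.seed_start <= pos <= P.seed_end:
            scale[i] = P.seed_scale

    NEG = -1e9
    blocked = np.zeros(N, dtype=bool)
    sites: list[MreSite] = []
    for _ in range(P.max_sites):
        # affine-gap local alignment (Gotoh): rows = reversed miRNA, cols = target
        M = np.full((L + 1, N + 1), 0.0)
        Ix = np.full((L + 1, N + 1), NEG)  # gap in target (miRNA base unaligned)
        Iy = np.full((L + 1, N + 1), NEG)  # gap in miRNA (target base unaligned)
        back = np.zeros((L + 1, N + 1), dtype=np.int8)
        best, bi, bj = 0.0, 0, 0
        for i in range(1, L + 1):
            for j in range(1, N + 1):
                if blocked[j - 1]:
                    M[i, j] = 0.0
                    Ix[i, j] = Iy[i, j] = NEG
                    continue
                s = _pair_score(tgt[j - 1], rmir[i - 1], P) * scale[i - 1]
                diag = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
                m = diag + s
                Ix[i, j] = max(M[i - 1, j] + P.gap_open, Ix[i - 1, j] + P.gap_extend)
                Iy[i, j] = max(M[i, j - 1] + P.gap_open, Iy[i, j - 1] + P.gap_extend)
                if m < 0:
                    m = 0.0
                M[i, j] = m
                if m > best:
                    best, bi, bj = m, i, j
        if best < P.report_floor:
            break
        # traceback along M to find the site span on the target
        i, j = bi, bj
        end_j = j
        seed_matches = 0
        while i > 0 and j > 0 and M[i, j] > 0:
            s = _pair_score(tgt[j - 1], rmir[i - 1], P) * scale[i - 1]
            diag = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            if abs(M[i, j] - (diag + s)) < 1e-9:
                pos = L - (i - 1)
                if P.seed_start <= pos <= P.seed_end and tgt[j - 1] == _COMPLEMENT.get(rmir[i - 1]):
                    seed_matches += 1
                i, j = i - 1, j - 1
            elif abs(M[i, j] - Ix[i, j]) < 1e-9:
                i -= 1
            else:
                j -= 1
        start_j = j
        if end_j <= start_j:
            break
        site_seq = tgt[start_j:end_j]
        dres = (
            smd_duplex.duplex_energy(mir, site_seq) if len(site_seq) >= 8 else None
        )
        delta_g = dres.delta_g if dres is not None else 0.0
        sites.append(
            MreSite(
                mirna_id=mirna_id,
                target_id=target_id,
                start=start_j,
                end=end_j,
                score=float(best),
                delta_g=float(delta_g),
                seed_matches=seed_matches,
            )
        )
        blocked[start_j:end_j] = True
    return sites


def filter_mre(sites: list[MreSite], min_score: float = 150.0, max_delta_g: float = -20.0) -> list[MreSite]:
    """Score >= min_score (inclusive) AND ΔG < max_delta_g (strict)."""
    return [s for s in sites if s.score >= min_score and s.delta_g < max_delta_g]


def anticorrelation_filter(
    edges: list[tuple[str, str]],
    mirna_expr: pd.DataFrame,
    target_expr: pd.DataFrame,
    p_max: float = 0.05,
    log_transform: bool = True,
    pseudocount: float = 1.0,
) -> list[tuple[str, str, float, float]]:
    """Keep (miRNA, target) edges whose expression profiles are negatively
    correlated with Fisher-z p <= p_max; returns (mirna, target, pcc, p).

    Edges whose endpoints lack an expression profile are dropped with a
    warning."""
    import warnings

    shared = [c for c in mirna_expr.columns if c in set(target_expr.columns)]
    if not shared:
        raise ValueError("expression matrices share no sample columns")
    kept = []
    for mir, tgt in edges:
        if mir not in mirna_expr.index or tgt not in target_expr.index:
            warnings.warn(f"expression profile missing for edge ({mir}, {tgt}); dropped")
            continue
        x = mirna_expr.loc[mir, shared].to_numpy(float)
        y = target_expr.loc[tgt, shared].to_numpy(float)
        if log_transform:
            x = np.log2(x + pseudocount)
            y = np.log2(y + pseudocount)
        r, p = pcc_with_p(x, y)
        if np.isnan(r):
            continue
        if r < 0 and p <= p_max:
            kept.append((mir, tgt, r, p))
    return kept


def merge_cerna(
    lnc_mir_edges: list[tuple[str, str, float, float]],
    mir_mrna_edges: list[tuple[str, str, float, float]],
) -> tuple[nx.Graph, list[tuple[str, str, str]]]:
    """Merge the two filtered edge sets on shared miRNA nodes.

    Edges arrive as (miRNA, partner, pcc, p). Returns the typed graph and
    the enumerated (lncRNA, miRNA, mRNA) triads; one-sided components stay
    in the graph flagged with ``in_triad=False``."""
    g = nx.Graph()
    lnc_by_mir: dict[str, list[str]] = {}
    mrna_by_mir: dict[str, list[str]] = {}
    for mir, lnc, r, p in lnc_mir_edges:
        g.add_node(mir, type="miRNA")
        g.add_node(lnc, type="lncRNA")
        g.add_edge(mir, lnc, kind="MRE_lnc", pcc=r, p=p)
        lnc_by_mir.setdefault(mir, []).append(lnc)
    for mir, mrna, r, p in mir_mrna_edges:
        g.add_node(mir, type="miRNA")
        g.add_node(mrna, type="mRNA")
        g.add_edge(mir, mrna, kind="MRE_mrna", pcc=r, p=p)
        mrna_by_mir.setdefault(mir, []).append(mrna)
    triads = []
    for mir in sorted(set(lnc_by_mir) & set(mrna_by_mir)):
        for lnc in sorted(lnc_by_mir[mir]):
            for mrna in sorted(mrna_by_mir[mir]):
                triads.append((lnc, mir, mrna))
    in_triad = {n for tri in triads for n in tri}
    for n in g.nodes:
        g.nodes[n]["in_triad"] = n in in_triad
    return g, triads


def load_precomputed_targets(path, min_score: float | None = None) -> list[tuple[str, str, float]]:
    """Load a precomputed miRNA->mRNA target table (TSV with mirna_id,
    gene_id, score columns); duplicates keep the best score."""
    df = pd.read_csv(path, sep="\t")
    required = {"mirna_id", "gene_id", "score"}
    if not required <= set(df.columns):
        raise ValueError(f"target table must have columns {sorted(required)}")
    df = df.sort_values("score", ascending=False).drop_duplicates(["mirna_id", "gene_id"])
    if min_score is not None:
        df = df[df["score"] >= min_score]
    df = df.sort_values(["mirna_id", "gene_id"]).reset_index(drop=True)
    return [(str(r.mirna_id), str(r.gene_id), float(r.score)) for r in df.itertuples()]


def build_cerna_network(
    mirna_seqs: dict[str, str],
    lnc_seqs: dict[str, str],
    utr_seqs: dict[str, str],
    mirna_expr: pd.DataFrame,
    lnc_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    min_score: float = 150.0,
    max_delta_g: float = -20.0,
    pcc_p_max: float = 0.05,
    params: MreParams | None = None,
    precomputed_mrna_edges: list[tuple[str, str, float]] | None = None,
) -> tuple[nx.Graph, list[tuple[str, str, str]]]:
    """End-to-end ceRNA construction on (typically DE-restricted) gene sets:
    scan MREs, apply score/energy thresholds, apply the anticorrelation
    filter to both edge sets, and merge on miRNA nodes."""
    lnc_pairs: set[tuple[str, str]] = set()
    mrna_pairs: set[tuple[str, str]] = set()
    for mir_id in sorted(mirna_seqs):
        for tid in sorted(lnc_seqs):
            if filter_mre(
                scan_mre(mirna_seqs[mir_id], lnc_seqs[tid], params, mir_id, tid),
                min_score,
                max_delta_g,
            ):
                lnc_pairs.add((mir_id, tid))
        if precomputed_mrna_edges is None:
            for tid in sorted(utr_seqs):
                if filter_mre(
                    scan_mre(mirna_seqs[mir_id], utr_seqs[tid], params, mir_id, tid),
                    min_score,
                    max_delta_g,
                ):
                    mrna_pairs.add((mir_id, tid))
    if precomputed_mrna_edges is not None:
        mrna_pairs = {(m, g) for m, g, _ in precomputed_mrna_edges}
    lnc_edges = anticorrelation_filter(sorted(lnc_pairs), mirna_expr, lnc_expr, pcc_p_max)
    mrna_edges = anticorrelation_filter(sorted(mrna_pairs), mirna_expr, mrna_expr, pcc_p_max)
    return merge_cerna(lnc_edges, mrna_edges)
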