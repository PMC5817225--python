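"""SINE-mediated Staufen-decay (SMD) duplex calling.

A lncRNA carrying a SINE in sense orientation can base-pair with a reverse
SINE copy in an mRNA 3'UTR; the resulting intermolecular duplex recruits
Staufen1 and destabilises the mRNA. This module finds SINE intervals on
both partners (from RepeatMasker annotations or a built-in consensus
scanner), computes an intermolecular hybridization free energy ΔG by
dynamic programming over nearest-neighbor stacking terms, fits a log-normal
null to the |ΔG| population, assigns each duplex an upper-tail p-value, and
keeps duplexes with p <= 0.05 — optionally restricted to differentially
expressed partners.

The energy model is hybridization-only (no intramolecular structure):
Watson-Crick and G:U pairs, stacking free energies from a packaged
editable nearest-neighbor parameter table, affine interior/bulge loop
penalties, and a duplex-initiation term.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import networkx as nx
import numpy as np
from Bio import Align
from scipy import stats

from .seqs import revcomp, to_dna
from .types import DuplexCandidate, RepeatHit

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_PAIRS = [(0, 3), (3, 0), (1, 2), (2, 1), (2, 3), (3, 2)]  # AU UA CG GC GU UG
_PAIR_ID = -np.ones((4, 4), dtype=np.int64)
for _k, (_x, _y) in enumerate(_PAIRS):
    _PAIR_ID[_x, _y] = _k
_LETTER = "ACGU"


@dataclass
class EnergyParams:
    """Nearest-neighbor stack table plus initiation and loop penalties."""

    stacks: np.ndarray  # [prev pair id, cur pair id] -> kcal/mol
    initiation: float
    loop_open: float
    loop_per_nt: float
    max_loop: int = 4  # per-side cap on interior/bulge loop length

    @classmethod
    def load_default(cls) -> "EnergyParams":
        text = resources.files("lncnet.data").joinpath("nn_stacks.tsv").read_text()
        table: dict[tuple[str, str], float] = {}
        init = loop_open = loop_per_nt = None
        for line in text.splitlines():
            if not line or line.startswith("#") or line.startswith("top\t"):
                continue
            top, bottom, val = line.split("\t")
            if top == "INIT":
                init = float(val)
            elif top == "LOOP_OPEN":
                loop_open = float(val)
            elif top == "LOOP_PER_NT":
                loop_per_nt = float(val)
            else:
                table[(top, bottom)] = float(val)
        stacks = np.full((6, 6), np.inf)
        for q, (x1, y1) in enumerate(_PAIRS):
            for p, (x2, y2) in enumerate(_PAIRS):
                key = (_LETTER[x1] + _LETTER[x2], _LETTER[y1] + _LETTER[y2])
                if key in table:
                    stacks[q, p] = table[key]
        return cls(stacks=stacks, initiation=init, loop_open=loop_open, loop_per_nt=loop_per_nt)


_DEFAULT_PARAMS: EnergyParams | None = None


def default_params() -> EnergyParams:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = EnergyParams.load_default()
    return _DEFAULT_PARAMS


def _encode(seq: str) -> np.ndarray:
    seq = to_dna(seq)
    bad = sum(b not in _BASE_CODE for b in seq)
    if len(seq) and bad / len(seq) > 0.10:
        raise ValueError(f"sequence has >10% ambiguous bases ({bad}/{len(seq)})")
    return np.array([_BASE_CODE.get(b, -1) for b in seq], dtype=np.int64)


@dataclass
class DuplexResult:
    delta_g: float
    a_interval: tuple[int, int]  # 0-based half-open on sequence a
    b_interval: tuple[int, int]


def duplex_energy(seq_a: str, seq_b: str, params: EnergyParams | None = None) -> DuplexResult | None:
    """Minimum-free-energy intermolecular duplex between two RNAs.

    Dynamic programming over duplex states: a pair (a_i, b_j) extends a
    previous pair (a_{i-k1-1}, b_{j+k2+1}) either by direct stacking
    (k1 = k2 = 0, nearest-neighbor term) or across an interior/bulge loop
    (affine penalty, each side capped at ``max_loop`` nt). ΔG includes one
    initiation term. Returns None when no duplex reaches ΔG < 0 (e.g. no
    complementarity: a lone pair never beats the initiation cost).
    Deterministic, and symmetric in its two arguments."""
    if len(seq_a) < 8 or len(seq_b) < 8:
        raise ValueError("duplex prediction needs sequences of >= 8 nt")
    P = params or default_params()
    a = _encode(seq_a)
    b = _encode(seq_b)
    la, lb = len(a), len(b)
    ok_a = a >= 0
    ok_b = b >= 0
    pid = np.where(
        np.outer(ok_a, ok_b), _PAIR_ID[np.clip(a, 0, 3)[:, None], np.clip(b, 0, 3)[None, :]], -1
    )
    pairable = pid >= 0

    INF = np.inf
    E = np.full((la, lb), INF)
    Sa = np.zeros((la, lb), dtype=np.int64)  # start index on a of the duplex
    Sb = np.zeros((la, lb), dtype=np.int64)  # start (max) index on b

    offsets = [(k1, k2) for k1 in range(P.max_loop + 1) for k2 in range(P.max_loop + 1)]
    jj = np.arange(lb)
    for i in range(la):
        row_p = pid[i]
        cand_E = [np.where(pairable[i], P.initiation, INF)]
        cand_Sa = [np.full(lb, i, dtype=np.int64)]
        cand_Sb = [jj.copy()]
        for k1, k2 in offsets:
            ip = i - 1 - k1
            if ip < 0:
                continue
            shift = 1 + k2
            prevE = np.full(lb, INF)
            prevSa = np.zeros(lb, dtype=np.int64)
            prevSb = np.zeros(lb, dtype=np.int64)
            prevE[: lb - shift] = E[ip, shift:]
            prevSa[: lb - shift] = Sa[ip, shift:]
            prevSb[: lb - shift] = Sb[ip, shift:]
            if k1 == 0 and k2 == 0:
                prev_p = np.full(lb, -1, dtype=np.int64)
                prev_p[: lb - 1] = pid[ip, 1:]
                gain = np.where(
                    (prev_p >= 0) & (row_p >= 0),
                    P.stacks[np.clip(prev_p, 0, 5), np.clip(row_p, 0, 5)],
                    INF,
                )
            else:
                gain = np.where(row_p >= 0, P.loop_open + P.loop_per_nt * (k1 + k2), INF)
            cand_E.append(prevE + gain)
            cand_Sa.append(prevSa)
            cand_Sb.append(prevSb)
        stackE = np.vstack(cand_E)
        choice = np.argmin(stackE, axis=0)
        E[i] = stackE[choice, jj]
        Sa[i] = np.vstack(cand_Sa)[choice, jj]
        Sb[i] = np.vstack(cand_Sb)[choice, jj]

    best = np.unravel_index(np.argmin(E), E.shape)
    dg = float(E[best])
    if not np.isfinite(dg) or dg >= 0.0:
        return None
    i, j = int(best[0]), int(best[1])
    return DuplexResult(
        delta_g=dg,
        a_interval=(int(Sa[i, j]), i + 1),
        b_interval=(j, int(Sb[i, j]) + 1),
    )


# ---------------------------------------------------------------------------
# SINE discovery on host sequences
# ---------------------------------------------------------------------------


def scan_sines(
    sequence: str,
    consensus_library: dict[str, str],
    host_id: str = "",
    min_score: float = 100.0,
) -> list[RepeatHit]:
    """Naive consensus scanner (fallback when no RepeatMasker .out exists).

    Each consensus is locally aligned against the host in both orientations
    (match +2, mismatch -3, gap open -5, extend -2); hits above
    ``min_score`` are reported and overlapping same-family hits are merged
    keeping the best score."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    host = to_dna(sequence)
    hits: list[RepeatHit] = []
    for family in sorted(consensus_library):
        cons = to_dna(consensus_library[family])
        for strand, probe in (("+", cons), ("-", revcomp(cons))):
            if not host or not probe:
                continue
            aln = aligner.align(host, probe)
            if len(aln) == 0 or aln.score < min_score:
                continue
            blocks = aln[0].aligned[0]
            start, end = int(blocks[0][0]), int(blocks[-1][1])
            hits.append(
                RepeatHit(
                    host_id=host_id,
                    family=family,
                    start=start,
                    end=end,
                    strand=strand,
                    score=float(aln.score),
                )
            )
    merged: list[RepeatHit] = []
    for h in sorted(hits, key=lambda h: (h.family, -h.score, h.start)):
        clash = next(
            (m for m in merged if m.family == h.family and h.start < m.end and h.end > m.start),
            None,
        )
        if clash is None:
            merged.append(h)
    merged.sort(key=lambda h: (h.start, h.family))
    return merged


# ---------------------------------------------------------------------------
# duplex candidates across partner sets
# ---------------------------------------------------------------------------


def find_duplex_candidates(
    lnc_seqs: dict[str, str],
    utr_seqs: dict[str, str],
    lnc_hits: list[RepeatHit],
    utr_hits: list[RepeatHit],
    params: EnergyParams | None = None,
    pairs: list[tuple[str, str]] | None = None,
) -> list[DuplexCandidate]:
    """Compute ΔG for every lncRNA-SINE x 3'UTR-SINE combination.

    Paired regions are restricted to annotated SINE intervals on both
    partners (the SINE-to-SINE design). ``pairs`` optionally limits which
    (lncRNA, mRNA) combinations are evaluated."""
    by_lnc: dict[str, list[RepeatHit]] = {}
    for h in lnc_hits:
        if h.host_id in lnc_seqs:
            by_lnc.setdefault(h.host_id, []).append(h)
    by_utr: dict[str, list[RepeatHit]] = {}
    for h in utr_hits:
        if h.host_id in utr_seqs:
            by_utr.setdefault(h.host_id, []).append(h)

    wanted = set(pairs) if pairs is not None else None
    out: list[DuplexCandidate] = []
    for lnc_id in sorted(by_lnc):
        for utr_id in sorted(by_utr):
            if wanted is not None and (lnc_id, utr_id) not in wanted:
                continue
            for hl in by_lnc[lnc_id]:
                sl = lnc_seqs[lnc_id][hl.start : hl.end]
                for hu in by_utr[utr_id]:
                    su = utr_seqs[utr_id][hu.start : hu.end]
                    if len(sl) < 8 or len(su) < 8:
                        continue
                    res = duplex_energy(sl, su, params)
                    if res is None:
                        continue
                    out.append(
                        DuplexCandidate(
                            lnc_id=lnc_id,
                            lnc_interval=(
                                hl.start + res.a_interval[0],
                                hl.start + res.a_interval[1],
                            ),
                            mrna_id=utr_id,
                            utr_interval=(
                                hu.start + res.b_interval[0],
                                hu.start + res.b_interval[1],
                            ),
                            delta_g=res.delta_g,
                            family_pair=(hl.family, hu.family),
                        )
                    )
    return out


# ---------------------------------------------------------------------------
# log-normal null and significance
# ---------------------------------------------------------------------------


@dataclass
class LognormalNull:
    """Maximum-likelihood log-normal fit on |ΔG| (ΔG is always negative)."""

    meanlog: float
    sdlog: float
    n: int
    ks_distance: float

    def __post_init__(self) -> None:
        if self.sdlog <= 0:
            raise ValueError("degenerate log-normal fit: sdlog must be > 0")


def fit_lognormal_null(delta_gs, min_n: int = 30) -> LognormalNull:
    """Fit the null |ΔG| distribution: meanlog = mean(log|ΔG|), sdlog = MLE
    standard deviation; stores a Kolmogorov-Smirnov distance as diagnostic.
    Requires >= ``min_n`` strictly negative energies."""
    dg = np.asarray(delta_gs, dtype=float)
    if dg.size < min_n:
        raise ValueError(f"need >= {min_n} duplex energies to fit the null (got {dg.size})")
    if (dg >= 0).any():
        raise ValueError("all duplex energies must be negative")
    logs = np.log(np.abs(dg))
    meanlog = float(logs.mean())
    sdlog = float(logs.std(ddof=0))
    if sdlog == 0.0:
        raise ValueError("degenerate log-normal fit: all |dG| values identical")
    ks = stats.kstest(np.abs(dg), "lognorm", args=(sdlog, 0.0, np.exp(meanlog))).statistic
    return LognormalNull(meanlog=meanlog, sdlog=sdlog, n=int(dg.size), ks_distance=float(ks))


def duplex_pvalue(delta_g: float, null: LognormalNull) -> float:
    """Upper-tail probability P(|ΔG_null| >= |ΔG_obs|) under the fitted
    log-normal: more negative ΔG means a smaller p."""
    z = (np.log(abs(delta_g)) - null.meanlog) / null.sdlog
    return float(stats.norm.sf(z))


def assign_pvalues(
    candidates: list[DuplexCandidate],
    per_family: bool = True,
    min_n: int = 30,
) -> dict[str, LognormalNull]:
    """Fit the null (per lncRNA-side SINE family by default, pooled as
    fallback for small families) and write p-values onto the candidates."""
    pooled = fit_lognormal_null([c.delta_g for c in candidates], min_n=min_n)
    nulls: dict[str, LognormalNull] = {"pooled": pooled}
    if per_family:
        fams = sorted({c.family_pair[0] for c in candidates})
        for fam in fams:
            dgs = [c.delta_g for c in candidates if c.family_pair[0] == fam]
            if len(dgs) >= min_n:
                try:
                    nulls[fam] = fit_lognormal_null(dgs, min_n=min_n)
                except ValueError:
                    pass
    for c in candidates:
        null = nulls.get(c.family_pair[0], pooled) if per_family else pooled
        c.p_value = duplex_pvalue(c.delta_g, null)
    return nulls


def build_smd_network(
    candidates: list[DuplexCandidate],
    de_ids: set[str] | None = None,
    p_max: float = 0.05,
    restrict_to_de: bool = True,
) -> nx.Graph:
    """Bipartite lncRNA-mRNA graph of significant duplexes (p <= p_max),
    optionally keeping only pairs where both partners are differentially
    expressed."""
    g = nx.Graph()
    for c in candidates:
        if c.p_value is None or c.p_value > p_max:
            continue
        if restrict_to_de:
            if de_ids is None or c.lnc_id not in de_ids or c.mrna_id not in de_ids:
                continue
        g.add_node(c.lnc_id, type="lncRNA")
        g.add_node(c.mrna_id, type="mRNA")
        prev = g.get_edge_data(c.lnc_id, c.mrna_id)
        if prev is None or c.delta_g < prev["delta_g"]:
            g.add_edge(
                c.lnc_id,
                c.mrna_id,
                kind="SMD",
                delta_g=c.delta_g,
                p=c.p_value,
                family=c.family_pair[0],
            )
    return g
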