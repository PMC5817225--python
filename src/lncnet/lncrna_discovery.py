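"""Novel-lncRNA discovery: structural filters, novelty by class code and
annotation overlap, coding-potential scoring with a calibrated cutoff, and a
protein-homology exclusion.

The coding-potential scorer follows the CPAT design: four sequence features
(longest-ORF length, ORF coverage, Fickett TESTCODE score, in-frame hexamer
log-odds) combined by logistic regression trained on labelled coding and
noncoding sequences. The classification cutoff is not fixed a priori: it is
calibrated on the training scores by maximising Youden's J
(sensitivity + specificity), the same procedure that yields a data-specific
threshold (≈0.487 on rat brain data) rather than a universal constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .seqs import to_dna
from .types import TranscriptModel

# ---------------------------------------------------------------------------
# structural and novelty filters
# ---------------------------------------------------------------------------


def filter_transcripts(
    transcripts: list[TranscriptModel],
    min_samples: int = 5,
    min_length: int = 200,
    min_exons: int = 2,
) -> list[TranscriptModel]:
    """Keep bona fide transcripts: detected in at least ``min_samples``
    samples, multi-exon, and at least ``min_length`` nt of exonic sequence.
    Input order is preserved."""
    return [
        t
        for t in transcripts
        if t.detected_in >= min_samples and t.n_exons >= min_exons and t.length >= min_length
    ]


def build_exon_index(known: list[TranscriptModel]) -> dict[tuple[str, str], np.ndarray]:
    """Index known exons as sorted (start, end) arrays per (chrom, strand)."""
    buckets: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for t in known:
        for iv in t.exons:
            buckets.setdefault((t.chrom, t.strand), []).append(iv)
    return {k: np.array(sorted(v), dtype=np.int64) for k, v in buckets.items()}


def _overlaps(exons: list[tuple[int, int]], index: np.ndarray) -> bool:
    if index.size == 0:
        return False
    starts, ends = index[:, 0], index[:, 1]
    for a, b in exons:
        # any known exon with start < b and end > a overlaps by >= 1 bp
        lo = np.searchsorted(starts, b)  # candidates have start < b
        if np.any(ends[:lo] > a):
            return True
    return False


def select_novel_candidates(
    transcripts: list[TranscriptModel],
    known: list[TranscriptModel],
    novel_codes: tuple[str, ...] = ("i", "r", "u", "x", "."),
) -> list[TranscriptModel]:
    """Novel long-transcript candidates: assembler class code in
    ``novel_codes`` and no exonic same-strand overlap (>=1 bp) with any known
    exon. Unstranded transcripts ('.') are checked against both strands.
    Unknown class codes produce a warning and exclusion."""
    index = build_exon_index(known)
    valid = set(novel_codes) | {"=", "c", "j", "e", "o", "p", "s"}
    out = []
    for t in transcripts:
        if t.class_code not in valid:
            warnings.warn(f"transcript {t.id}: unknown class code {t.class_code!r}; excluded")
            continue
        if t.class_code not in novel_codes:
            continue
        strands = ("+", "-") if t.strand == "." else (t.strand,)
        hit = any(
            _overlaps(t.exons, index.get((t.chrom, s), np.empty((0, 2), dtype=np.int64)))
            for s in strands
        )
        if not hit:
            out.append(t)
    return out


# ---------------------------------------------------------------------------
# coding-potential features
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")

# Fickett TESTCODE lookup tables: interval thresholds and the probability
# that a sequence with that position/content statistic is coding.
_POSITION_PARA = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)
_CONTENT_PARA = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)
_POSITION_PROB = {
    "A": (0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36),
    "C": (0.29, 0.44, 0.55, 0.49, 0.52, 0.60, 0.60, 0.56, 0.51, 0.38),
    "G": (0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.52, 0.41, 0.31, 0.17),
    "T": (0.51, 0.60, 0.69, 0.64, 0.62, 0.67, 0.58, 0.48, 0.39, 0.24),
}
_POSITION_WEIGHT = {"A": 0.22, "C": 0.23, "G": 0.24, "T": 0.18}
_CONTENT_PROB = {
    "A": (0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38, 0.19),
    "C": (0.50, 0.63, 0.59, 0.50, 0.41, 0.30, 0.33, 0.29, 0.29, 0.17),
    "G": (0.21, 0.40, 0.47, 0.50, 0.52, 0.60, 0.57, 0.52, 0.48, 0.28),
    "T": (0.30, 0.49, 0.56, 0.53, 0.48, 0.48, 0.52, 0.57, 0.60, 0.58),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


def _lookup(value: float, para: tuple, probs: tuple) -> float:
    for threshold, prob in zip(para, probs):
        if value >= threshold:
            return prob
    return probs[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE statistic over the whole sequence.

    For each base: the position value is max/(min+1) of its counts in the
    three codon frames; the content value is its overall fraction. Both map
    through the published lookup tables and weighted-sum to the score."""
    seq = to_dna(seq)
    seq = "".join(b for b in seq if b in "ACGT")
    if len(seq) < 2:
        return 0.0
    score = 0.0
    for base in "ACGT":
        counts = [seq[i::3].count(base) for i in range(3)]
        position = max(counts) / (min(counts) + 1.0)
        content = sum(counts) / len(seq)
        score += _lookup(position, _POSITION_PARA, _POSITION_PROB[base]) * _POSITION_WEIGHT[base]
        score += _lookup(content, _CONTENT_PARA, _CONTENT_PROB[base]) * _CONTENT_WEIGHT[base]
    return score


def longest_orf(seq: str) -> tuple[int, int]:
    """(start, end) of the longest ATG..stop open reading frame on the given
    strand (0-based half-open, stop codon included); (0, 0) if none."""
    seq = to_dna(seq)
    best = (0, 0)
    for frame in range(3):
        start = None
        i = frame
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                if (i + 3 - start) > (best[1] - best[0]):
                    best = (start, i + 3)
                start = None
            i += 3
    return best


_HEXAMERS = ["".join(p) for p in product("ACGT", repeat=6)]
_HEX_INDEX = {h: i for i, h in enumerate(_HEXAMERS)}


def _hexamer_counts(seqs: list[str], step: int) -> np.ndarray:
    counts = np.ones(4096)  # pseudocount covers all 4096 hexamers
    for s in seqs:
        s = to_dna(s)
        for i in range(0, len(s) - 5, step):
            idx = _HEX_INDEX.get(s[i : i + 6])
            if idx is not None:
                counts[idx] += 1
    return counts


def train_hexamer_table(coding: list[str], noncoding: list[str]) -> np.ndarray:
    """Per-hexamer log-odds (coding vs noncoding background), pseudocounted.

    Coding counts are taken in-frame (step 3) over each sequence's longest
    ORF; the noncoding background uses every overlapping hexamer."""
    orfs = []
    for s in coding:
        a, b = longest_orf(s)
        if b - a >= 6:
            orfs.append(to_dna(s)[a:b])
    cod = _hexamer_counts(orfs, step=3)
    non = _hexamer_counts(noncoding, step=1)
    return np.log(cod / cod.sum()) - np.log(non / non.sum())


def hexamer_score(seq: str, table: np.ndarray) -> float:
    """Mean per-hexamer log-odds over the longest ORF, stepping in frame."""
    seq = to_dna(seq)
    a, b = longest_orf(seq)
    if b - a < 6:
        return 0.0
    vals = [
        table[_HEX_INDEX[seq[i : i + 6]]]
        for i in range(a, b - 5, 3)
        if seq[i : i + 6] in _HEX_INDEX
    ]
    return float(np.mean(vals)) if vals else 0.0


def features(seq: str, hexamer_table: np.ndarray) -> np.ndarray:
    """[log ORF length, ORF coverage, Fickett score, hexamer score]."""
    seq = to_dna(seq)
    n_ambig = sum(b not in "ACGT" for b in seq)
    if len(seq) and n_ambig / len(seq) > 0.10:
        raise ValueError(f"sequence has >10% ambiguous bases ({n_ambig}/{len(seq)})")
    a, b = longest_orf(seq)
    orf_len = b - a
    coverage = orf_len / len(seq) if seq else 0.0
    return np.array(
        [np.log1p(orf_len), coverage, fickett_score(seq), hexamer_score(seq, hexamer_table)]
    )


# ---------------------------------------------------------------------------
# model, training and calibration
# ---------------------------------------------------------------------------


@dataclass
class CodingPotentialModel:
    """Logistic model over the four coding features plus the calibrated cutoff."""

    hexamer_table: np.ndarray
    coef: np.ndarray
    intercept: float
    cutoff: float
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must lie strictly inside (0, 1)")
        if self.hexamer_table.shape != (4096,):
            raise ValueError("hexamer table must cover all 4096 hexamers")

    def score(self, seq: str) -> float:
        x = features(seq, self.hexamer_table)
        z = float(self.coef @ x + self.intercept)
        return float(1.0 / (1.0 + np.exp(-z)))

    def is_coding(self, seq: str) -> bool:
        return self.score(seq) >= self.cutoff


def coding_score(seq: str, model: CodingPotentialModel) -> float:
    """Coding probability in [0, 1]; depends only on the spliced sequence."""
    return model.score(seq)


def youden_cutoff(coding_scores: np.ndarray, noncoding_scores: np.ndarray) -> tuple[float, float, float]:
    """Threshold maximising sensitivity + specificity over all midpoints
    between adjacent sorted unique scores; ties -> lowest threshold.

    Returns (cutoff, sensitivity, specificity) where a score >= cutoff calls
    coding."""
    scores = np.unique(np.concatenate([coding_scores, noncoding_scores]))
    if scores.size == 1:
        candidates = np.array([float(scores[0])])
    else:
        candidates = (scores[:-1] + scores[1:]) / 2.0
    best = (-np.inf, None, None, None)
    for t in candidates:
        sens = float(np.mean(coding_scores >= t))
        spec = float(np.mean(noncoding_scores < t))
        j = sens + spec
        if j > best[0] + 1e-12:
            best = (j, float(t), sens, spec)
    return best[1], best[2], best[3]


def train_and_calibrate(
    coding_train: list[str], noncoding_train: list[str]
) -> CodingPotentialModel:
    """Fit the logistic model and calibrate the cutoff by Youden's J.

    Raises if either class has fewer than 20 sequences or if the fitted
    scores rank noncoding above coding (AUC < 0.5: swapped labels)."""
    if len(coding_train) < 20 or len(noncoding_train) < 20:
        raise ValueError("each training class needs at least 20 sequences")
    table = train_hexamer_table(coding_train, noncoding_train)
    X = np.array([features(s, table) for s in coding_train + noncoding_train])
    y = np.r_[np.ones(len(coding_train)), np.zeros(len(noncoding_train))]
    # direction-fixed sanity check BEFORE fitting: ORF length must rank the
    # coding class higher, otherwise the labels are swapped (the logistic fit
    # itself would happily learn inverted weights and hide the mistake)
    ranks = pd.Series(X[:, 0]).rank().to_numpy()
    n1, n0 = int(y.sum()), int((1 - y).sum())
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    if auc < 0.5:
        raise ValueError(f"training labels look swapped: ORF-length AUC = {auc:.3f} < 0.5")
    clf = LogisticRegression(max_iter=2000)
    clf.fit(X, y)
    probs = clf.predict_proba(X)[:, 1]
    cod_scores, non_scores = probs[y == 1], probs[y == 0]
    cutoff, sens, spec = youden_cutoff(cod_scores, non_scores)
    cutoff = float(np.clip(cutoff, 1e-9, 1 - 1e-9))
    return CodingPotentialModel(
        hexamer_table=table,
        coef=clf.coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        cutoff=cutoff,
        training_meta={
            "n_coding": len(coding_train),
            "n_noncoding": len(noncoding_train),
            "sensitivity": sens,
            "specificity": spec,
            "auc": float(auc),
        },
    )


# ---------------------------------------------------------------------------
# homology filter and pipeline
# ---------------------------------------------------------------------------


def read_blast_tab(path) -> dict[str, float]:
    """Best (smallest) e-value per query from BLAST tabular (outfmt 6)."""
    best: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 11:
                raise ValueError("BLAST tabular line with fewer than 11 columns")
            q, e = parts[0], float(parts[10])
            if q not in best or e < best[q]:
                best[q] = e
    return best


def apply_homology_filter(
    candidates: list[TranscriptModel],
    hits: dict[str, float],
    evalue_max: float = 1e-3,
) -> list[TranscriptModel]:
    """Keep candidates without a protein hit at e-value <= threshold and mark
    the survivors as novel lncRNAs."""
    known_ids = {t.id for t in candidates}
    for q in hits:
        if q not in known_ids:
            warnings.warn(f"homology hit for unknown query id {q!r}; ignored")
    out = []
    for t in candidates:
        if hits.get(t.id, np.inf) <= evalue_max:
            continue
        t.biotype = "novel_lncRNA"
        out.append(t)
    return out


def discover_lncrnas(
    transcripts: list[TranscriptModel],
    known: list[TranscriptModel],
    model: CodingPotentialModel,
    blast_hits: dict[str, float] | None = None,
    min_samples: int = 5,
    min_length: int = 200,
    min_exons: int = 2,
    evalue_max: float = 1e-3,
) -> tuple[list[TranscriptModel], pd.DataFrame]:
    """Run the full discovery cascade and return (novel lncRNAs, metrics).

    Each successive stage returns a subset of its input; the metrics table
    records every candidate's coding score and per-stage verdicts."""
    bona_fide = filter_transcripts(transcripts, min_samples, min_length, min_exons)
    candidates = select_novel_candidates(bona_fide, known)
    rows = []
    noncoding = []
    for t in candidates:
        s = coding_score(t.sequence, model)
        keep = s < model.cutoff
        rows.append({"transcript_id": t.id, "coding_score": s, "passes_coding_filter": keep})
        if keep:
            noncoding.append(t)
    novel = apply_homology_filter(noncoding, blast_hits or {}, evalue_max)
    novel_ids = {t.id for t in novel}
    metrics = pd.DataFrame(rows, columns=["transcript_id", "coding_score", "passes_coding_filter"])
    if not metrics.empty:
        metrics["is_novel_lncrna"] = metrics["transcript_id"].isin(novel_ids)
    return novel, metrics
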