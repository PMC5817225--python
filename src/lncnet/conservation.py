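"""Per-transcript conservation metrics and FDR-calibrated cutoffs.

Metrics operate on base-wise conservation tracks (phyloP or phastCons) held
as NaN-gapped per-chromosome arrays. All metrics are computed over a
transcript's exonic bases in spliced (exon-concatenated) coordinates;
unscored bases are ignored. Cutoffs for nominating conserved transcripts
are calibrated empirically against labelled positive (e.g. protein-coding)
and negative (e.g. intron/background) metric sets at a target false
discovery rate, reporting the sensitivity achieved at the chosen cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import TranscriptModel

Track = dict[str, np.ndarray]


def exonic_scores(transcript: TranscriptModel, track: Track) -> np.ndarray:
    """Concatenated base scores over the transcript's exons (NaN = unscored).

    Exons are concatenated in genomic order; for the metrics below only the
    multiset/adjacency of scores matters, not 5'->3' orientation."""
    arr = track.get(transcript.chrom)
    if arr is None:
        return np.full(transcript.length, np.nan)
    out = []
    for a, b in transcript.exons:
        if a < 0 or b > len(arr):
            raise ValueError(
                f"transcript {transcript.id}: exon [{a},{b}) outside chromosome bounds"
            )
        out.append(arr[a:b])
    return np.concatenate(out)


def mean_exonic_score(transcript: TranscriptModel, track: Track) -> float:
    """Arithmetic mean over scored exonic bases; NaN if no base has a score."""
    scores = exonic_scores(transcript, track)
    good = ~np.isnan(scores)
    if not good.any():
        return float("nan")
    return float(scores[good].mean())


def fraction_conserved(
    transcript: TranscriptModel, phylop_track: Track, base_threshold: float = 2.0
) -> float:
    """Fraction of scored exonic bases strictly above ``base_threshold``
    (the significantly conserved bases); NaN if no base has a score."""
    scores = exonic_scores(transcript, track=phylop_track)
    good = ~np.isnan(scores)
    if not good.any():
        return float("nan")
    return float((scores[good] > base_threshold).mean())


def max_window_mean(
    transcript: TranscriptModel,
    phastcons_track: Track,
    window: int = 200,
    min_scored_frac: float = 0.5,
) -> float:
    """Maximum mean score over sliding windows on the spliced transcript.

    Windows slide by 1 nt over exon-concatenated coordinates. A transcript
    shorter than the window contributes a single whole-transcript window.
    Unscored bases are excluded from a window's mean, and windows with fewer
    than ``min_scored_frac`` scored bases are skipped; NaN if every window
    is skipped."""
    scores = exonic_scores(transcript, phastcons_track)
    n = len(scores)
    w = min(window, n)
    good = ~np.isnan(scores)
    vals = np.where(good, scores, 0.0)
    csum = np.r_[0.0, np.cumsum(vals)]
    ccnt = np.r_[0, np.cumsum(good)]
    sums = csum[w:] - csum[:-w]
    cnts = ccnt[w:] - ccnt[:-w]
    ok = cnts >= min_scored_frac * w
    if not ok.any():
        return float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums[ok] / cnts[ok]
    return float(means.max())


@dataclass
class ConservationSummary:
    transcript_id: str
    mean_phylop: float
    mean_phastcons: float
    frac_conserved: float
    max_window_mean: float


def summarize(
    transcripts: list[TranscriptModel],
    phylop: Track,
    phastcons: Track,
    base_threshold: float = 2.0,
    window: int = 200,
) -> list[ConservationSummary]:
    return [
        ConservationSummary(
            transcript_id=t.id,
            mean_phylop=mean_exonic_score(t, phylop),
            mean_phastcons=mean_exonic_score(t, phastcons),
            frac_conserved=fraction_conserved(t, phylop, base_threshold),
            max_window_mean=max_window_mean(t, phastcons, window),
        )
        for t in transcripts
    ]


def calibrate_cutoff_fdr(
    metric_values_positive: list[float] | np.ndarray,
    metric_values_negative: list[float] | np.ndarray,
    fdr: float = 0.01,
) -> tuple[float, float]:
    """Smallest cutoff t with empirical FDR(t) < ``fdr``; returns
    (cutoff, sensitivity at cutoff).

    The metric must be oriented "higher = more conserved"; a value >= t is
    called conserved. FDR(t) = FP(t) / (FP(t) + TP(t)) with positives the
    labelled conserved class (e.g. protein-coding transcripts) and negatives
    the background class. Candidate thresholds are the observed unique
    values. Raises if no threshold achieves the FDR, reporting the best
    achievable value."""
    pos = np.asarray(metric_values_positive, dtype=float)
    neg = np.asarray(metric_values_negative, dtype=float)
    pos = pos[~np.isnan(pos)]
    neg = neg[~np.isnan(neg)]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both labelled metric sets must be non-empty")
    candidates = np.unique(np.concatenate([pos, neg]))
    best_fdr = np.inf
    for t in candidates:
        tp = int((pos >= t).sum())
        fp = int((neg >= t).sum())
        if tp + fp == 0:
            continue
        this_fdr = fp / (fp + tp)
        best_fdr = min(best_fdr, this_fdr)
        if this_fdr < fdr:
            return float(t), tp / pos.size
    raise ValueError(f"no cutoff achieves FDR < {fdr}; best achievable FDR = {best_fdr:.4g}")
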