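"""Paired differential expression between ischemic (ipsilateral) and
control (contralateral) hemispheres.

Each animal contributes one sample per hemisphere, so the test statistic is
a two-sided paired t-test on the per-animal log2 abundance differences
d_a = log2(x_ipsi,a + pc) - log2(x_contra,a + pc). The reported log2 fold
change is the mean of the d_a (ipsilateral over contralateral).
Benjamini-Hochberg adjusted p-values are reported alongside, but the
default call uses the raw p-value threshold; miRNAs additionally require
|log2FC| > 1 by convention of the small-RNA analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ExpressionMatrix


@dataclass
class DEResult:
    gene_id: str
    log2fc: float  # ipsilateral over contralateral
    p_value: float
    adjusted_p: float = float("nan")
    is_de: bool = False
    direction: str = "none"  # 'up' | 'down' | 'none'


def paired_de(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> list[DEResult]:
    """Per-gene paired t-test on log2(x + pseudocount) differences.

    Genes whose difference vector has zero variance get p = 1 (the paired t
    statistic is undefined there; a deterministic p keeps downstream
    filtering stable). Requires >= 2 complete animal pairs."""
    ipsi, contra, animals = matrix.paired_arrays()
    if len(animals) < 2:
        raise ValueError("paired differential expression needs >= 2 animal pairs")
    d = np.log2(ipsi + pseudocount) - np.log2(contra + pseudocount)
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    n = d.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 1)
    p = np.where(sd == 0.0, 1.0, p)
    adj = multipletests(p, method="fdr_bh")[1]
    return [
        DEResult(gene_id=g, log2fc=float(mean[i]), p_value=float(p[i]), adjusted_p=float(adj[i]))
        for i, g in enumerate(matrix.values.index)
    ]


def classify_de(
    results: list[DEResult],
    p_thresh: float = 0.05,
    abs_log2fc_thresh: float = 0.0,
    use_adjusted: bool = False,
) -> list[DEResult]:
    """Mark differential genes: p < p_thresh (strict) and |log2fc| strictly
    above the fold-change threshold; direction follows the sign of log2fc."""
    for r in results:
        p = r.adjusted_p if use_adjusted else r.p_value
        r.is_de = bool(p < p_thresh and abs(r.log2fc) > abs_log2fc_thresh)
        r.direction = ("up" if r.log2fc > 0 else "down") if r.is_de else "none"
    return results


def de_table(results: list[DEResult], biotype: str = ""):
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "log2fc": [r.log2fc for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "is_de": [r.is_de for r in results],
            "direction": [r.direction for r in results],
            "biotype": biotype,
        }
    )
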