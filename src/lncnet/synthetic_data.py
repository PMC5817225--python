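"""Generate a fully specified miniature ischemic-stroke "study".

The generator emulates the design of a paired rodent focal-ischemia
transcriptome experiment: ``n_animals`` animals each contribute an
ipsilateral (ischemic) and a contralateral (control) cortex sample. It
produces every input the downstream stages consume — genome and transcript
sequences, a GTF with assembler-style class codes, 3'UTR sequences, repeat
annotations, base-wise conservation tracks, expression matrices, a gene→GO
map — together with a machine-readable ground-truth manifest of everything
planted (differential expression, SINE duplex pairs, miRNA response
elements), so that each stage's recovery can be scored offline.

Abundance model (per long-RNA gene g, animal a, condition c):

    FPKM = exp(baseline_g) * 2^(animal_ga + effect_g*[c == ipsilateral]
                                + beta*f_a*triad_sign + noise)

with baseline ~ Normal(fpkm_logmean, fpkm_logsd) on the natural-log scale,
a per-(gene, animal) effect shared by the two hemispheres, a planted
condition effect for differential genes, a per-animal latent factor f_a
that couples each ceRNA triad (positively for the lncRNA and mRNA,
negatively for the miRNA) without disturbing the paired contrast, and
log2-scale Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import child_rng
from .io import gtf as gtf_io
from .io import rmout as rmout_io
from .io import wig as wig_io
from .seqs import random_cds, random_seq, revcomp
from .types import ExpressionMatrix, GroundTruth, RepeatHit, TranscriptModel

NOVEL_CODES = ("u", "i", "x", "r", ".")


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study; defaults mirror the emulated design.

    The paired design is 5 animals x 2 hemispheres; the differential
    fraction, SINE carrier frequencies (~39% of lncRNAs, ~9% of 3'UTRs) and
    log-normal FPKM scale are set to values typical of bulk brain RNA-seq.
    """

    seed: int = 0
    n_animals: int = 5
    n_mrna: int = 100
    n_known_lnc: int = 15
    n_novel_lnc: int = 30
    n_mirna: int = 10
    de_fraction: float = 0.05
    de_log2fc_mean: float = 2.0
    fpkm_logmean: float = 1.5
    fpkm_logsd: float = 1.0
    sine_insert_prob_lnc: float = 0.39
    sine_insert_prob_utr: float = 0.093
    n_cerna_triads: int = 3
    n_smd_pairs: int = 3
    noise_sd: float = 0.25
    animal_sd: float = 0.3  # per-(gene, animal) log2 effect shared by hemispheres
    triad_beta: float = 1.0  # latent-factor loading coupling each ceRNA triad
    single_exon_frac: float = 0.10  # noise transcripts exercising the exon filter
    short_frac: float = 0.05  # noise transcripts exercising the length filter

    def validate(self) -> None:
        if self.n_animals < 2:
            raise ValueError("n_animals must be >= 2")
        for name in ("n_mrna", "n_known_lnc", "n_novel_lnc", "n_mirna",
                     "n_cerna_triads", "n_smd_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("de_fraction", "sine_insert_prob_lnc", "sine_insert_prob_utr",
                     "single_exon_frac", "short_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.noise_sd < 0 or self.fpkm_logsd < 0:
            raise ValueError("scale parameters must be non-negative")


@dataclass
class SyntheticStudy:
    """Everything the generator produced, in memory."""

    config: SyntheticConfig
    transcripts: list[TranscriptModel]  # all assembled transcripts incl. noise
    known_annotation: list[TranscriptModel]  # reference DB (coding + known lnc)
    chrom_sizes: dict[str, int]
    utr3: dict[str, tuple[int, int]]  # mRNA id -> 3'UTR interval on transcript
    mirna_seqs: dict[str, str]
    repeats: list[RepeatHit] = field(default_factory=list)
    expression: dict[str, ExpressionMatrix] = field(default_factory=dict)
    phylop: dict[str, np.ndarray] = field(default_factory=dict)
    phastcons: dict[str, np.ndarray] = field(default_factory=dict)
    gene2go: pd.DataFrame | None = None
    ground_truth: GroundTruth = field(default_factory=GroundTruth)

    def transcript(self, tid: str) -> TranscriptModel:
        return next(t for t in self.transcripts if t.id == tid)

    def utr3_seq(self, mrna_id: str) -> str:
        a, b = self.utr3[mrna_id]
        return self.transcript(mrna_id).sequence[a:b]


def load_sine_consensi() -> dict[str, str]:
    """Packaged synthetic SINE consensi keyed by family label."""
    fam_by_name = {"B1_Alu_synthetic": "B1/Alu", "B2_synthetic": "B2", "B4_synthetic": "B4"}
    out: dict[str, str] = {}
    text = resources.files("lncnet.data").joinpath("sine_consensi.fa").read_text()
    name = None
    for line in text.splitlines():
        if line.startswith(">"):
            name = fam_by_name[line[1:].strip()]
            out[name] = ""
        elif name:
            out[name] += line.strip()
    return out


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(config: SyntheticConfig) -> SyntheticStudy:
    """Lay out loci on two chromosomes and build every transcript model.

    mRNAs are 3-exon with an embedded codon-biased ORF flanked by UTRs;
    lncRNAs are multi-exon with noncoding composition. Noise transcripts
    (single-exon, <200 nt, or sporadically detected) are added to exercise
    the discovery filters. Loci never overlap, so novel transcripts are
    guaranteed free of known-exon overlap by construction.
    """
    config.validate()
    rng = child_rng(config.seed, "annotation")

    n_detect_hi = config.n_animals  # bona fide transcripts: detected in >= half
    n_samples = 2 * config.n_animals

    plan: list[tuple[str, str]] = []
    plan += [("mrna", f"MRNA{i:05d}") for i in range(config.n_mrna)]
    plan += [("known_lnc", f"KNLNC{i:05d}") for i in range(config.n_known_lnc)]
    plan += [("novel_lnc", f"TCONS{i:05d}") for i in range(config.n_novel_lnc)]
    n_noise_se = int(round(config.single_exon_frac * len(plan)))
    n_noise_short = int(round(config.short_frac * len(plan)))
    plan += [("noise_single", f"NOISE_SE{i:04d}") for i in range(n_noise_se)]
    plan += [("noise_short", f"NOISE_SH{i:04d}") for i in range(n_noise_short)]

    order = rng.permutation(len(plan))
    chroms = ["chr1", "chr2"]
    cursor = {c: 1000 for c in chroms}
    transcripts: list[TranscriptModel] = []
    known: list[TranscriptModel] = []
    utr3: dict[str, tuple[int, int]] = {}

    for idx in order:
        kind, tid = plan[idx]
        chrom = chroms[int(idx) % 2]
        if kind == "mrna":
            n_cod = int(rng.integers(250, 450))
            cds = random_cds(rng, n_cod)
            utr5 = random_seq(rng, int(rng.integers(80, 150)))
            u3len = int(rng.integers(400, 800))
            utr3_seq = random_seq(rng, u3len)
            seq = utr5 + cds + utr3_seq
            n_ex = 3
            detected = int(rng.integers(n_detect_hi, n_samples + 1))
            cc, biotype = "=", "known_coding"
        elif kind == "known_lnc":
            seq = random_seq(rng, int(rng.integers(500, 1200)))
            n_ex = int(rng.integers(2, 4))
            detected = int(rng.integers(n_detect_hi, n_samples + 1))
            cc, biotype = "=", "known_noncoding"
        elif kind == "novel_lnc":
            seq = random_seq(rng, int(rng.integers(500, 1200)))
            n_ex = int(rng.integers(2, 5))
            detected = int(rng.integers(n_detect_hi, n_samples + 1))
            cc = NOVEL_CODES[int(rng.integers(len(NOVEL_CODES)))]
            biotype = "candidate"
        elif kind == "noise_single":
            seq = random_seq(rng, int(rng.integers(300, 900)))
            n_ex = 1
            detected = int(rng.integers(1, n_samples + 1))
            cc, biotype = "u", "candidate"
        else:  # noise_short: multi-exon but < 200 nt
            seq = random_seq(rng, int(rng.integers(80, 199)))
            n_ex = 2
            detected = int(rng.integers(1, n_samples + 1))
            cc, biotype = "u", "candidate"

        # split the spliced sequence into exons separated by introns
        cuts = sorted(rng.choice(np.arange(30, len(seq) - 30), size=n_ex - 1, replace=False)) if n_ex > 1 else []
        pieces = np.split(np.arange(len(seq)), cuts)
        exons = []
        g = cursor[chrom]
        for piece in pieces:
            exons.append((g, g + len(piece)))
            g += len(piece) + int(rng.integers(80, 400))  # intron
        cursor[chrom] = g + int(rng.integers(500, 1500))  # intergenic gap

        t = TranscriptModel(
            id=tid, chrom=chrom, strand="+", exons=exons, class_code=cc,
            detected_in=detected, sequence=seq, biotype=biotype,
        )
        transcripts.append(t)
        if kind == "mrna":
            utr3[tid] = (len(utr5) + len(cds), len(seq))
            known.append(t)
        elif kind == "known_lnc":
            known.append(t)

    chrom_sizes = {c: cursor[c] + 1000 for c in chroms}
    study = SyntheticStudy(
        config=config,
        transcripts=transcripts,
        known_annotation=known,
        chrom_sizes=chrom_sizes,
        utr3=utr3,
        mirna_seqs={},
    )
    _plan_ground_truth(study)
    return study


def _plan_ground_truth(study: SyntheticStudy) -> None:
    """Choose planted DE genes, ceRNA triads and SMD pairs."""
    cfg = study.config
    rng = child_rng(cfg.seed, "ground_truth")
    gt = study.ground_truth

    mrna_ids = [t.id for t in study.transcripts if t.biotype == "known_coding"]
    novel_ids = [t.id for t in study.transcripts if t.id.startswith("TCONS")]
    lnc_ids = [t.id for t in study.transcripts if t.biotype == "known_noncoding"] + novel_ids
    gt.true_lncrna_ids = set(novel_ids)
    study.mirna_seqs = {
        f"miR-{i + 1:03d}": random_seq(rng, 22, p=(0.25, 0.25, 0.25, 0.25))
        for i in range(cfg.n_mirna)
    }
    mirna_ids = sorted(study.mirna_seqs)

    if cfg.n_cerna_triads > len(lnc_ids) or cfg.n_cerna_triads > len(mrna_ids) or \
       cfg.n_cerna_triads > len(mirna_ids):
        raise ValueError("n_cerna_triads exceeds available genes")
    if cfg.n_smd_pairs > len(lnc_ids) - cfg.n_cerna_triads or \
       cfg.n_smd_pairs > len(mrna_ids) - cfg.n_cerna_triads:
        raise ValueError("n_smd_pairs exceeds available genes")

    lnc_pool = [str(x) for x in rng.permutation(lnc_ids)]
    mrna_pool = [str(x) for x in rng.permutation(mrna_ids)]
    mir_pool = [str(x) for x in rng.permutation(mirna_ids)]
    for _ in range(cfg.n_cerna_triads):
        gt.planted_triads.append((lnc_pool.pop(), mir_pool.pop(), mrna_pool.pop()))
    families = sorted(load_sine_consensi())
    for k in range(cfg.n_smd_pairs):
        fam = families[k % len(families)]
        gt.planted_smd_pairs.append((lnc_pool.pop(), mrna_pool.pop(), fam))

    # planted DE: all triad/SMD members, topped up to de_fraction of long genes
    long_ids = mrna_ids + lnc_ids
    n_de = int(round(cfg.de_fraction * len(long_ids)))
    forced = []
    for L, m, M in gt.planted_triads:
        forced += [L, M]
    for L, M, _ in gt.planted_smd_pairs:
        forced += [L, M]
    de_ids = list(dict.fromkeys(forced))
    extra_pool = [str(g) for g in rng.permutation(long_ids) if g not in de_ids]
    while len(de_ids) < n_de and extra_pool:
        de_ids.append(extra_pool.pop())
    for g in de_ids:
        mag = cfg.de_log2fc_mean + abs(rng.normal(0.0, 0.5))
        gt.de_genes[g] = float(mag * rng.choice([-1.0, 1.0]))
    # triad miRNAs are differential too (opposite sign to their partners)
    for L, m, M in gt.planted_triads:
        sign = np.sign(gt.de_genes[L]) or 1.0
        gt.de_genes[m] = float(-sign * (cfg.de_log2fc_mean + abs(rng.normal(0.0, 0.5))))
        gt.de_genes[M] = float(abs(gt.de_genes[M]) * sign)


# ---------------------------------------------------------------------------
# sequence planting
# ---------------------------------------------------------------------------

def plant_sines_and_mres(study: SyntheticStudy) -> None:
    """Write SINE copies and miRNA response elements into host sequences.

    Planted SMD pairs receive the family consensus in the lncRNA body and
    its reverse complement in the partner mRNA 3'UTR (so the two copies can
    hybridise). Background copies — controlled by the per-class insertion
    probabilities — go in sense orientation with ~10% point mutations and
    provide the null ΔG population. Planted ceRNA triads receive the exact
    reverse complement of their miRNA in both the lncRNA and the mRNA 3'UTR.
    All placements overwrite a same-length window, keeping coordinates and
    the genome consistent; every site is recorded in the ground truth.
    """
    cfg = study.config
    rng = child_rng(cfg.seed, "planting")
    gt = study.ground_truth
    consensi = load_sine_consensi()
    by_id = {t.id: t for t in study.transcripts}

    def overwrite(t: TranscriptModel, lo: int, hi: int, insert: str) -> tuple[int, int]:
        width = hi - lo - len(insert)
        if width < 0:
            raise ValueError(
                f"consensus ({len(insert)} nt) longer than host window on {t.id}")
        start = lo + int(rng.integers(0, width + 1))
        t.sequence = t.sequence[:start] + insert + t.sequence[start + len(insert):]
        return start, start + len(insert)

    def decayed_copy(seq: str) -> str:
        """A background repeat copy: truncated and diverged, the way genomic
        SINE copies age (random fragment, 15-40% point substitutions)."""
        frac = rng.uniform(0.4, 1.0)
        width = max(40, int(frac * len(seq)))
        start = int(rng.integers(0, len(seq) - width + 1))
        chars = list(seq[start : start + width])
        rate = rng.uniform(0.15, 0.40)
        for i in range(len(chars)):
            if rng.random() < rate:
                chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
        return "".join(chars)

    def record_sine(host: str, fam: str, iv: tuple[int, int], strand: str, planted: bool):
        study.repeats.append(RepeatHit(host_id=host, family=fam, start=iv[0],
                                       end=iv[1], strand=strand,
                                       score=float(2 * (iv[1] - iv[0]))))
        gt.sine_sites.append({"host": host, "family": fam, "start": iv[0],
                              "end": iv[1], "strand": strand, "planted_pair": planted})

    # planted, complementary SMD pairs
    for lnc_id, mrna_id, fam in gt.planted_smd_pairs:
        cons = consensi[fam]
        lnc = by_id[lnc_id]
        iv = overwrite(lnc, 0, lnc.length, cons)
        record_sine(lnc_id, fam, iv, "+", True)
        mrna = by_id[mrna_id]
        lo, hi = study.utr3[mrna_id]
        iv = overwrite(mrna, lo, hi, revcomp(cons))
        record_sine(mrna_id, fam, (iv[0] - lo, iv[1] - lo), "-", True)

    # background (sense, mutated) copies
    smd_hosts = {g for pair in gt.planted_smd_pairs for g in pair[:2]}
    fams = sorted(consensi)
    for t in study.transcripts:
        if t.id in smd_hosts:
            continue
        if t.biotype == "known_noncoding" or t.id.startswith("TCONS"):
            if rng.random() < cfg.sine_insert_prob_lnc:
                fam = fams[int(rng.integers(len(fams)))]
                cons = decayed_copy(consensi[fam])
                if t.length > len(cons):
                    iv = overwrite(t, 0, t.length, cons)
                    record_sine(t.id, fam, iv, "+", False)
        elif t.biotype == "known_coding":
            if rng.random() < cfg.sine_insert_prob_utr:
                fam = fams[int(rng.integers(len(fams)))]
                cons = decayed_copy(consensi[fam])
                lo, hi = study.utr3[t.id]
                if hi - lo > len(cons):
                    iv = overwrite(t, lo, hi, cons)
                    record_sine(t.id, fam, (iv[0] - lo, iv[1] - lo), "+", False)

    # planted miRNA response elements (full reverse complement of the miRNA,
    # so seed positions 2-8 are exactly complementary by construction)
    for lnc_id, mir_id, mrna_id in gt.planted_triads:
        site = revcomp(study.mirna_seqs[mir_id])
        lnc = by_id[lnc_id]
        iv = overwrite(lnc, 0, lnc.length, site)
        gt.mre_sites.append({"mirna": mir_id, "host": lnc_id, "start": iv[0], "end": iv[1]})
        mrna = by_id[mrna_id]
        lo, hi = study.utr3[mrna_id]
        iv = overwrite(mrna, lo, hi, site)
        # recorded relative to the 3'UTR, the coordinate system MRE scans use
        gt.mre_sites.append(
            {"mirna": mir_id, "host": mrna_id, "start": iv[0] - lo, "end": iv[1] - lo}
        )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression_matrix(
    config: SyntheticConfig,
    gene_ids: list[str],
    rng: np.random.Generator,
    de_effects: dict[str, float] | None = None,
    loadings: dict[str, tuple[int, float]] | None = None,
    factors: np.ndarray | None = None,
    logmean_shift: float = 0.0,
) -> ExpressionMatrix:
    """Draw one paired abundance matrix from the generative model.

    ``de_effects`` maps gene id -> condition log2 effect; ``loadings`` maps
    gene id -> (factor index, loading) into the per-animal ``factors``
    array. With both empty this is the global null (no condition effect)."""
    de_effects = de_effects or {}
    loadings = loadings or {}
    animals = [f"rat{i + 1}" for i in range(config.n_animals)]
    sample_ids = [f"{a}_{tag}" for a in animals for tag in ("ipsi", "contra")]
    meta = {f"{a}_ipsi": (a, "ipsilateral") for a in animals}
    meta.update({f"{a}_contra": (a, "contralateral") for a in animals})
    is_ipsi = np.array([sid.endswith("_ipsi") for sid in sample_ids], dtype=float)
    animal_idx = np.repeat(np.arange(config.n_animals), 2)
    vals = np.empty((len(gene_ids), len(sample_ids)))
    for i, g in enumerate(gene_ids):
        baseline = rng.normal(config.fpkm_logmean + logmean_shift, config.fpkm_logsd)
        animal_eff = rng.normal(0.0, config.animal_sd, size=config.n_animals)[animal_idx]
        log2part = (
            animal_eff
            + de_effects.get(g, 0.0) * is_ipsi
            + rng.normal(0.0, config.noise_sd, len(sample_ids))
        )
        if g in loadings:
            k, beta = loadings[g]
            log2part = log2part + beta * factors[k][animal_idx]
        vals[i] = np.exp(baseline) * np.exp2(log2part)
    return ExpressionMatrix(pd.DataFrame(vals, index=gene_ids, columns=sample_ids), dict(meta))


def generate_expression(study: SyntheticStudy) -> None:
    """Simulate the paired expression matrices for mRNA, lncRNA and miRNA."""
    cfg = study.config
    rng = child_rng(cfg.seed, "expression")
    gt = study.ground_truth
    missing = [g for g in gt.de_genes
               if g not in {t.id for t in study.transcripts} and g not in study.mirna_seqs]
    if missing:
        raise ValueError(f"ground-truth ids absent from annotation: {missing}")

    # latent per-animal factors (shared by both hemispheres so they cancel in
    # paired differences), one per planted triad
    factors = rng.normal(0.0, 1.0, size=(max(len(gt.planted_triads), 1), cfg.n_animals))
    loadings: dict[str, tuple[int, float]] = {}
    for k, (L, m, M) in enumerate(gt.planted_triads):
        loadings[L] = (k, +cfg.triad_beta)
        loadings[M] = (k, +cfg.triad_beta)
        loadings[m] = (k, -cfg.triad_beta)

    mrna_ids = sorted(t.id for t in study.transcripts if t.biotype == "known_coding")
    lnc_ids = sorted(t.id for t in study.transcripts
                     if t.biotype == "known_noncoding" or t.id.startswith("TCONS"))
    study.expression = {
        "mrna": simulate_expression_matrix(cfg, mrna_ids, rng, gt.de_genes, loadings, factors),
        "lncrna": simulate_expression_matrix(cfg, lnc_ids, rng, gt.de_genes, loadings, factors),
        # miRNAs enter as small-RNA counts, typically orders of magnitude
        # above long-RNA FPKM; the higher scale keeps pseudocounted fold
        # changes close to the planted effects
        "mirna": simulate_expression_matrix(
            cfg, sorted(study.mirna_seqs), rng, gt.de_genes, loadings, factors,
            logmean_shift=2.5,
        ),
    }


# ---------------------------------------------------------------------------
# conservation tracks and GO map
# ---------------------------------------------------------------------------

def generate_tracks(study: SyntheticStudy) -> None:
    """Base-wise phyloP / phastCons tracks elevated over coding exons.

    Only the rank structure matters downstream: coding exon bases score high
    (phyloP ~ N(3,1); phastCons ~ N(0.92,0.05) clipped to [0,1]) against a
    low background, with ~5% of bases left unscored.
    """
    rng = child_rng(study.config.seed, "tracks")
    phylop, phastcons = {}, {}
    for chrom, size in sorted(study.chrom_sizes.items()):
        p = rng.normal(0.0, 1.0, size)
        c = np.clip(rng.normal(0.15, 0.10, size), 0.0, 1.0)
        for t in study.transcripts:
            if t.chrom == chrom and t.biotype == "known_coding":
                for a, b in t.exons:
                    p[a:b] = rng.normal(3.0, 1.0, b - a)
                    c[a:b] = np.clip(rng.normal(0.92, 0.05, b - a), 0.0, 1.0)
        gap = rng.random(size) < 0.05
        p[gap] = np.nan
        c[gap] = np.nan
        phylop[chrom] = p
        phastcons[chrom] = c
    study.phylop = phylop
    study.phastcons = phastcons


def generate_gene2go(study: SyntheticStudy) -> None:
    """Random biological-process annotations plus a shared 'injury' term on
    planted differential mRNAs (so coexpression neighbourhoods are enrichable)."""
    rng = child_rng(study.config.seed, "gene2go")
    mrna_ids = sorted(t.id for t in study.transcripts if t.biotype == "known_coding")
    n_terms = max(10, len(mrna_ids) // 5)
    terms = [f"GO:{i + 2:07d}" for i in range(n_terms)]
    rows = []
    for g in mrna_ids:
        for term in rng.choice(np.array(terms), size=int(rng.integers(1, 5)), replace=False):
            rows.append((g, term, "biological_process"))
    injury = "GO:0000001"
    for g in sorted(study.ground_truth.de_genes):
        if g in study.utr3:  # mRNA
            rows.append((g, injury, "biological_process"))
    study.gene2go = pd.DataFrame(sorted(set(rows)), columns=["gene_id", "go_id", "namespace"])


# ---------------------------------------------------------------------------
# orchestration and writing
# ---------------------------------------------------------------------------

def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Run every generation step in order; fully deterministic in the seed."""
    study = generate_annotation(config)
    plant_sines_and_mres(study)
    generate_expression(study)
    generate_tracks(study)
    generate_gene2go(study)
    return study


def generate_training_sequences(
    seed: int, n_each: int = 300, min_codons: int = 120, max_codons: int = 400,
) -> tuple[list[str], list[str]]:
    """Labelled training sets for the coding-potential model.

    Coding examples are UTR-flanked codon-biased ORFs; noncoding examples
    mimic intron sequence (random, mildly AT-rich). Lengths span the same
    range so the classifier cannot separate on length alone trivially.
    """
    rng = child_rng(seed, "cpat_training")
    coding, noncoding = [], []
    for _ in range(n_each):
        cds = random_cds(rng, int(rng.integers(min_codons, max_codons)))
        coding.append(random_seq(rng, int(rng.integers(30, 120))) + cds
                      + random_seq(rng, int(rng.integers(50, 300))))
    for _ in range(n_each):
        noncoding.append(random_seq(rng, int(rng.integers(3 * min_codons, 3 * max_codons))))
    return coding, noncoding


def assemble_genome(study: SyntheticStudy) -> dict[str, str]:
    """Build chromosome sequences consistent with every transcript sequence."""
    rng = child_rng(study.config.seed, "genome_background")
    genome = {c: np.array(list(random_seq(rng, n)))
              for c, n in sorted(study.chrom_sizes.items())}
    for t in study.transcripts:
        offset = 0
        for a, b in t.exons:
            piece = t.sequence[offset:offset + (b - a)]
            genome[t.chrom][a:b] = list(piece)
            offset += b - a
    return {c: "".join(arr) for c, arr in genome.items()}


def write_study(study: SyntheticStudy, outdir) -> dict[str, Path]:
    """Write every artifact; byte-identical for identical configs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def fasta(path: Path, records: list[tuple[str, str]]):
        with open(path, "w") as fh:
            for name, seq in records:
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")

    genome = assemble_genome(study)
    paths["genome_fasta"] = out / "genome.fa"
    fasta(paths["genome_fasta"], sorted(genome.items()))

    paths["transcripts_gtf"] = out / "transcripts.gtf"
    gtf_io.write_transcripts(study.transcripts, paths["transcripts_gtf"])
    paths["known_gtf"] = out / "known_annotation.gtf"
    gtf_io.write_transcripts(study.known_annotation, paths["known_gtf"])

    paths["transcripts_fasta"] = out / "transcripts.fa"
    fasta(paths["transcripts_fasta"], [(t.id, t.sequence) for t in study.transcripts])
    paths["utr3_fasta"] = out / "utr3.fa"
    fasta(paths["utr3_fasta"], [(m, study.utr3_seq(m)) for m in sorted(study.utr3)])
    paths["mirna_fasta"] = out / "mirna.fa"
    fasta(paths["mirna_fasta"], sorted(study.mirna_seqs.items()))

    paths["repeats_out"] = out / "repeats.out"
    rmout_io.write_rmout(study.repeats, paths["repeats_out"])

    for name, expr in sorted(study.expression.items()):
        paths[f"expr_{name}"] = out / f"expression_{name}.tsv"
        expr.to_tsv(paths[f"expr_{name}"])

    paths["phylop_wig"] = out / "phylop.wig"
    wig_io.write_wig(study.phylop, paths["phylop_wig"], name="phyloP")
    paths["phastcons_wig"] = out / "phastcons.wig"
    wig_io.write_wig(study.phastcons, paths["phastcons_wig"], name="phastCons")

    paths["gene2go"] = out / "gene2go.tsv"
    study.gene2go.to_csv(paths["gene2go"], sep="\t", index=False)

    paths["ground_truth"] = out / "ground_truth.json"
    manifest = {"config": asdict(study.config), **study.ground_truth.to_json_dict()}
    with open(paths["ground_truth"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
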