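# Methods

## Scope and data model

The pipeline analyses a fully paired bulk transcriptome design: every
animal contributes one ischemic (ipsilateral) and one control
(contralateral) hemisphere sample. Long RNAs are quantified as FPKM,
miRNAs as small-RNA abundances; all tests operate on log2(x + 1) unless
stated. Transcript models carry 0-based half-open exon intervals, an
assembler class code relating them to reference annotation, and a
`detected_in` sample count taken as given (whether "detected" means an
assembler call or an abundance floor is upstream of this package).

## Novel lncRNA discovery

Filters apply in a fixed cascade, each returning a subset of its input:

1. bona fide: `detected_in >= min_samples` (default 5, i.e. half of a
   10-sample study), `>= 2` exons, `>= 200` nt exonic length;
2. novelty: class code in {i, r, u, x, .} and no same-strand exonic
   overlap (>= 1 bp) with any known exon; unstranded transcripts are
   checked against both strands;
3. coding potential below the calibrated cutoff;
4. no protein homology hit at e-value <= 1e-3 (threshold configurable; the
   homology search itself is external and consumed as BLAST outfmt-6).

The coding-potential scorer mirrors the CPAT design: a logistic regression
over four features — log(longest ORF length + 1), ORF coverage, the
Fickett TESTCODE statistic (published position/content lookup tables), and
the mean in-frame hexamer log-odds over the longest ORF, with the hexamer
table estimated from the training sets themselves (coding counts in-frame
over longest ORFs, noncoding counts over all frames, pseudocount 1 over
all 4096 hexamers). The classification cutoff is **not** a constant: it is
chosen on training scores by maximising Youden's J (sensitivity +
specificity) over midpoints between adjacent sorted unique scores, ties
resolved to the lowest qualifying threshold. On real rat brain data this
procedure lands near 0.487; on synthetic training sets it lands wherever
the score distributions dictate, which is the point of re-running it.
A direction-fixed sanity check (ORF-length AUC >= 0.5) runs before the
fit, because the logistic regression itself would silently absorb swapped
training labels. The logistic fit uses scikit-learn's solver with its
default mild L2 regularisation, which keeps the near-separable training
geometry stable.

## Conservation

Metrics are computed over exonic bases only; unscored bases (NaN in the
track) are ignored. The sliding-window maximum runs over spliced
(exon-concatenated) coordinates — the metric describes the transcript, not
the locus — with three conventions chosen where the procedure is otherwise
underdetermined: transcripts shorter than the window contribute one
whole-transcript window; unscored bases inside a window are excluded from
its mean; windows with fewer than 50% scored bases are skipped.

Cutoff calibration is empirical, not parametric: given labelled positive
(e.g. protein-coding) and negative (e.g. intron/background) metric sets,
the cutoff is the smallest observed value t with FDR(t) = FP/(FP+TP) <
the target (default 0.01), and the sensitivity achieved at t is reported.
Both labelled sets must be supplied by the caller; the package does not
presume what the negative set should be.

## Paired differential expression

Per gene, differences d_a = log2(x_ipsi,a + 1) − log2(x_contra,a + 1) feed
a two-sided one-sample t-test (df = n_animals − 1); log2FC is mean(d_a).
Zero-variance difference vectors get p = 1 — deterministic downstream
filtering matters more than distinguishing "undefined" from "null" there.
BH-adjusted p-values are computed and reported but the default call uses
raw P < 0.05; miRNAs additionally require |log2FC| > 1. Both thresholds
are strict inequalities.

## Coexpression and function annotation

Fisher's asymptotic distribution gives the PCC p-value: z = atanh(r)·√(n−3)
against the standard normal, two-sided, capped below at the smallest
positive double as |r| → 1. Edge selection is per-lncRNA: BH adjustment
over that lncRNA's tests (selection is per-lncRNA, so adjustment scope
follows) and rank truncation to the top/bottom `percentile` of its PCC
distribution, keeping all ties at the boundary. The percentile default is
0.0001 (0.01%); 0.001 (0.1%) is a documented alternative convention and is
a plain config knob.

GO annotation tests, per lncRNA, every biological-process term present in
its coding neighbourhood by upper-tail hypergeometric p (P(X ≥ overlap)),
accepting raw p ≤ 0.01 with ≥ 5 neighbourhood genes carrying the term. The
universe defaults to all genes with ≥ 1 BP annotation. No GO-hierarchy
propagation is attempted.

## SINE duplexes and the log-normal ΔG null

A Staufen-decay candidate is an intermolecular duplex between a SINE
element in a lncRNA and a SINE element in an mRNA 3'UTR. Duplex search is
restricted to annotated SINE intervals on both partners. The free energy
comes from a hybridization-only dynamic program: Watson–Crick and G:U
pairs, nearest-neighbor stacking free energies from a packaged editable
table (canonical WC stack values; stacks containing a wobble share one
moderate term), affine interior/bulge loop penalties (1.0 + 0.5·nt,
each side capped at 4 nt), and one duplex-initiation term (+4.09
kcal/mol). No intramolecular structure is modelled, and external tools'
absolute ΔG values are not reproduction targets — orderings and the null
calibration are what downstream decisions consume. The DP is symmetric in
its arguments (the stack table is strand-symmetric by construction) and
returns "no duplex" when nothing beats ΔG < 0.

The null models |ΔG| as log-normal: meanlog = mean(log|ΔG|), sdlog = the
MLE standard deviation, with a Kolmogorov–Smirnov distance stored as a fit
diagnostic. A duplex's p-value is the upper tail P(|ΔG_null| ≥ |ΔG_obs|).
Nulls are fitted per lncRNA-side SINE family when that family has ≥ 30
candidates, falling back to the pooled fit otherwise (whether a single
global null or family-wise nulls are more faithful is genuinely open; both
are exposed). The final network keeps duplexes with p ≤ 0.05 and, by
default, only pairs whose two partners are both differentially expressed.

## ceRNA network

The MRE scanner follows the miRanda scheme rather than reproducing any
specific implementation bit-for-bit: the reversed miRNA is locally aligned
(Gotoh affine gaps, open −9 / extend −4) against the target with +5 for
antiparallel Watson–Crick matches, +1 for G:U, −3 for mismatches, and all
contributions from miRNA seed positions 2–8 multiplied by 4. A perfect
22-nt complement scores 15·5 + 7·5·4 = 215, comfortably above the working
threshold of 150. Each reported site's ΔG is computed with the same
nearest-neighbor engine as the SMD stage, for internal consistency. Edges
require score ≥ 150 (inclusive) and ΔG < −20 kcal/mol (strict), then
negative expression correlation with Fisher-z p ≤ 0.05 — applied to both
the lncRNA and mRNA sides. Precomputed target tables can replace the mRNA
scan (duplicates deduplicated keeping the best score). Merging on shared
miRNA nodes enumerates (lncRNA, miRNA, mRNA) triads; one-sided components
stay in the graph flagged `in_triad=False`. Following the study design,
network construction is applied to differentially expressed genes.

## The synthetic study

The generator's defaults are the study conditions: 5 animals × 2
hemispheres; ~5% differential genes with |log2FC| ≥ 2; residual noise 0.25
on the log2 scale; a per-(gene, animal) effect (sd 0.3) shared by the two
hemispheres, which is what makes the design paired; SINE carrier rates of
39% for lncRNAs and 9.3% for 3'UTRs; log-normal FPKM (meanlog 1.5, sdlog
1.0 natural-log). miRNAs are simulated 2.5 natural-log units higher —
small-RNA counts run orders of magnitude above long-RNA FPKM, and the
higher scale keeps pseudocounted fold changes close to the planted
effects. Each ceRNA triad shares one per-animal latent factor, loaded +1
on the lncRNA and mRNA and −1 on the miRNA: correlation across samples is
induced without disturbing the paired ipsi−contra contrast.

Sequence planting overwrites same-length windows, so coordinates, the GTF
and the regenerated genome stay mutually consistent. Planted SMD pairs get
the exact family consensus in the lncRNA and its reverse complement in the
partner 3'UTR; background SINE copies are "aged" — random fragments
(40–100% of consensus length) with 15–40% point substitutions, inserted in
sense orientation — and it is this background that populates the null ΔG
distribution. Planted MREs are the full reverse complement of the miRNA,
which makes seed positions 2–8 exactly complementary by construction.
Conservation tracks draw coding-exon bases from N(3, 1) phyloP and
clipped N(0.92, 0.05) phastCons against low-scoring background, with 5% of
bases unscored; only this rank structure, not any real substitution-rate
model, is represented. The three packaged ~150-nt SINE consensi are
synthetic sequences labelled after the rodent B1/Alu, B2 and B4 families
(real consensi can be substituted); they are not Repbase entries.

What the generator does **not** emulate: read-level noise, assembly
artefacts, positional biases, GC/length confounding between expression and
sequence features, overlapping gene structures, and realistic GO topology.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under the stated generative model, not performance
on real libraries.

All randomness descends from one master seed through named child streams
(crc32 of the stream name), so regenerating one artifact never shifts the
draws of another and identical configs give byte-identical output files.

## Numerical conventions and problem sizes

Correlation p-values are capped at the smallest positive double; Youden
and FDR sweeps break ties toward the lowest qualifying threshold; the
duplex DP caps each loop side at 4 nt (energies are upper bounds for
duplexes that would need longer loops, a negligible regime for SINE-scale
complementarity). Validation runs use miniature studies (tens of genes,
two chromosomes, 10–20 seeds per claim) and larger dedicated draws where a
claim is about a distribution (2,000-gene null matrices for type-I error;
10,000 draws for log-normal parameter recovery and p-value uniformity);
these sizes give the binomial/KS bounds quoted in the test suite
reasonable power while keeping a full run in the low minutes.

## Known limitations

- The coding-potential model is trained per run on synthetic labelled
  sets; it is not a drop-in replacement for a tool trained on curated
  transcripts, and its cutoff is meaningful only relative to its own
  training distribution.
- The duplex energy model omits intramolecular folding, dangling ends,
  terminal-AU penalties and temperature dependence.
- The MRE scanner's parameters are a faithful re-expression of the
  published scoring scheme, not a byte-level reimplementation of any
  released scanner; absolute scores should not be compared across tools.
- GO enrichment treats terms independently; parent/child redundancy is
  not collapsed.
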