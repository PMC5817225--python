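"""End-to-end orchestration: one config, staged outputs, provenance manifest.

Stages run in dependency order: synthetic study (optional) -> lncRNA
discovery -> conservation -> differential expression -> coexpression ->
SMD duplexes -> ceRNA network. Every threshold any stage uses lives in
``PipelineConfig`` with the analysis defaults pre-filled, and the manifest
records the config hash and per-stage row counts so a run can be audited
and reproduced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from . import cerna_network as cerna
from . import conservation as cons
from . import coexpression as coex
from . import expression_de as de
from . import lncrna_discovery as disc
from . import smd_duplex as smd
from .io import gtf as gtf_io
from .io import rmout as rmout_io
from .io import wig as wig_io
from .synthetic_data import (
    SyntheticConfig,
    generate_study,
    generate_training_sequences,
    write_study,
)
from .types import ExpressionMatrix


@dataclass
class PipelineConfig:
    """All inputs and thresholds of the full pipeline."""

    seed: int = 0
    # discovery
    min_samples: int = 5
    min_len: int = 200
    min_exons: int = 2
    coding_cutoff: str = "auto"  # 'auto' (Youden-calibrated) or a float as string
    blastx_evalue_max: float = 1e-3
    # conservation
    phylop_base_threshold: float = 2.0
    window: int = 200
    conservation_fdr: float = 0.01
    # differential expression
    de_p: float = 0.05
    mirna_abs_log2fc: float = 1.0
    pseudocount: float = 1.0
    # coexpression
    coexpr_percentile: float = 0.0001
    coexpr_adj_p: float = 0.01
    go_p: float = 0.01
    go_min_genes: int = 5
    # SMD
    duplex_p: float = 0.05
    smd_per_family_null: bool = True
    # ceRNA
    mre_min_score: float = 150.0
    mre_max_delta_g: float = -20.0
    pcc_p: float = 0.05

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_all(
    config: PipelineConfig,
    outdir,
    synthetic: SyntheticConfig | None = None,
) -> dict:
    """Run every stage on a synthetic study and return the manifest.

    With ``synthetic`` unset, a default study at the pipeline seed is
    generated. All outputs are TSV/GraphML/JSON under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    syn = synthetic or SyntheticConfig(seed=config.seed)
    study = generate_study(syn)
    write_study(study, out / "study")
    counts["transcripts"] = len(study.transcripts)

    # --- discovery ------------------------------------------------------
    cod_train, non_train = generate_training_sequences(config.seed)
    model = disc.train_and_calibrate(cod_train, non_train)
    if config.coding_cutoff != "auto":
        model.cutoff = float(config.coding_cutoff)
    novel, metrics = disc.discover_lncrnas(
        study.transcripts,
        study.known_annotation,
        model,
        min_samples=config.min_samples,
        min_length=config.min_len,
        min_exons=config.min_exons,
        evalue_max=config.blastx_evalue_max,
    )
    gtf_io.write_transcripts(novel, out / "novel_lncrna.gtf")
    metrics.to_csv(out / "discovery_metrics.tsv", sep="\t", index=False)
    counts["novel_lncrna"] = len(novel)

    # --- conservation ---------------------------------------------------
    lnc_like = [t for t in study.transcripts
                if t.biotype == "known_noncoding" or t.id in {x.id for x in novel}]
    summaries = cons.summarize(
        lnc_like + [t for t in study.transcripts if t.biotype == "known_coding"],
        study.phylop,
        study.phastcons,
        base_threshold=config.phylop_base_threshold,
        window=config.window,
    )
    pd.DataFrame([vars(s) for s in summaries]).to_csv(
        out / "conservation_summary.tsv", sep="\t", index=False
    )
    coding_ids = {t.id for t in study.transcripts if t.biotype == "known_coding"}
    noise_ids = {t.id for t in study.transcripts if t.id.startswith("NOISE")}
    pos = [s.mean_phylop for s in summaries if s.transcript_id in coding_ids]
    neg_ts = [t for t in study.transcripts if t.id in noise_ids] or lnc_like
    neg = [cons.mean_exonic_score(t, study.phylop) for t in neg_ts]
    try:
        cutoff, sens = cons.calibrate_cutoff_fdr(pos, neg, fdr=config.conservation_fdr)
        conservation_calib = {"phylop_cutoff": cutoff, "sensitivity": sens}
    except ValueError as exc:
        conservation_calib = {"error": str(exc)}
    counts["conservation_summaries"] = len(summaries)

    # --- differential expression ---------------------------------------
    de_tables = {}
    de_ids: set[str] = set()
    for klass, expr in sorted(study.expression.items()):
        res = de.paired_de(expr, pseudocount=config.pseudocount)
        thresh = config.mirna_abs_log2fc if klass == "mirna" else 0.0
        de.classify_de(res, p_thresh=config.de_p, abs_log2fc_thresh=thresh)
        table = de.de_table(res, biotype=klass)
        table.to_csv(out / f"de_{klass}.tsv", sep="\t", index=False)
        de_tables[klass] = table
        de_ids |= {r.gene_id for r in res if r.is_de}
        counts[f"de_{klass}"] = int(table["is_de"].sum())

    # --- coexpression ---------------------------------------------------
    edges = coex.build_cnc_network(
        study.expression["lncrna"].values,
        study.expression["mrna"].values,
        percentile=config.coexpr_percentile,
        adj_p_max=config.coexpr_adj_p,
    )
    coex.edges_table(edges).to_csv(out / "cnc_edges.tsv", sep="\t", index=False)
    counts["cnc_edges"] = len(edges)
    if study.gene2go is not None:
        calls = coex.annotate_lncrna_functions(
            edges, study.gene2go, p_max=config.go_p, min_genes=config.go_min_genes
        )
        pd.DataFrame([vars(c) for c in calls]).to_csv(
            out / "lncrna_go_annotation.tsv", sep="\t", index=False
        )
        counts["go_calls"] = sum(c.annotated for c in calls)

    # --- SMD duplexes ---------------------------------------------------
    lnc_ids = {t.id for t in study.transcripts
               if t.biotype == "known_noncoding" or t.id.startswith("TCONS")}
    lnc_seqs = {t.id: t.sequence for t in study.transcripts if t.id in lnc_ids}
    utr_seqs = {m: study.utr3_seq(m) for m in study.utr3}
    repeats = rmout_io.read_rmout(out / "study" / "repeats.out")
    lnc_hits = [h for h in repeats if h.host_id in lnc_ids]
    utr_hits = [h for h in repeats if h.host_id in study.utr3]
    duplexes = smd.find_duplex_candidates(lnc_seqs, utr_seqs, lnc_hits, utr_hits)
    counts["duplex_candidates"] = len(duplexes)
    smd_graph = nx.Graph()
    if len(duplexes) >= 30:
        smd.assign_pvalues(duplexes, per_family=config.smd_per_family_null)
        pd.DataFrame(
            [
                {
                    "lnc_id": c.lnc_id,
                    "lnc_start": c.lnc_interval[0],
                    "lnc_end": c.lnc_interval[1],
                    "mrna_id": c.mrna_id,
                    "utr_start": c.utr_interval[0],
                    "utr_end": c.utr_interval[1],
                    "delta_g": c.delta_g,
                    "p_value": c.p_value,
                    "family": c.family_pair[0],
                }
                for c in duplexes
            ]
        ).to_csv(out / "smd_duplexes.tsv", sep="\t", index=False)
        smd_graph = smd.build_smd_network(duplexes, de_ids, p_max=config.duplex_p)
        nx.write_graphml(smd_graph, out / "smd_network.graphml")
    counts["smd_edges"] = smd_graph.number_of_edges()

    # --- ceRNA network --------------------------------------------------
    de_lnc = {g for g in de_ids if g in lnc_seqs}
    de_mrna = {g for g in de_ids if g in study.utr3}
    de_mir = {g for g in de_ids if g in study.mirna_seqs}
    graph, triads = cerna.build_cerna_network(
        {m: study.mirna_seqs[m] for m in sorted(de_mir)},
        {g: lnc_seqs[g] for g in sorted(de_lnc)},
        {g: utr_seqs[g] for g in sorted(de_mrna)},
        study.expression["mirna"].values,
        study.expression["lncrna"].values,
        study.expression["mrna"].values,
        min_score=config.mre_min_score,
        max_delta_g=config.mre_max_delta_g,
        pcc_p_max=config.pcc_p,
    )
    nx.write_graphml(graph, out / "cerna_network.graphml")
    pd.DataFrame(triads, columns=["lnc_id", "mirna_id", "mrna_id"]).to_csv(
        out / "cerna_triads.tsv", sep="\t", index=False
    )
    counts["cerna_triads"] = len(triads)

    manifest = {
        "version": __version__,
        "config_digest": config.digest(),
        "config": asdict(config),
        "synthetic_config": asdict(syn),
        "coding_cutoff": model.cutoff,
        "conservation_calibration": conservation_calib,
        "counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def load_expression(path) -> ExpressionMatrix:
    return ExpressionMatrix.from_tsv(path)


def read_tracks(phylop_path, phastcons_path):
    return wig_io.read_wig(phylop_path), wig_io.read_wig(phastcons_path)
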