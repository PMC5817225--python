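"""Core domain containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class TranscriptModel:
    """One transcript: the unit flowing through discovery and conservation.

    exons are 0-based half-open genomic intervals, sorted, non-overlapping.
    ``sequence`` is the spliced (exon-concatenated) sequence 5'->3' on the
    transcript strand. ``class_code`` is the assembler-assigned relation to
    reference annotation ('=' known, 'i' intronic, 'u' intergenic, 'x'
    antisense, 'r' repeat, '.' unknown, ...). ``detected_in`` counts the
    samples in which the transcript was assembled.
    """

    id: str
    chrom: str
    strand: str  # '+', '-' or '.' (unstranded)
    exons: list[tuple[int, int]]
    class_code: str = "="
    detected_in: int = 0
    sequence: Optional[str] = None
    biotype: str = "candidate"  # known_coding | known_noncoding | candidate | novel_lncRNA

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has an empty exon list")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = None
        for a, b in self.exons:
            if b <= a:
                raise ValueError(f"transcript {self.id}: empty/negative exon [{a},{b})")
            if prev_end is not None and a < prev_end:
                raise ValueError(f"transcript {self.id}: overlapping exons")
            prev_end = b
        if self.detected_in < 0:
            raise ValueError(f"transcript {self.id}: detected_in < 0")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"transcript {self.id}: sequence length {len(self.sequence)} != exonic length {self.length}"
            )

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass
class ExpressionMatrix:
    """genes x samples abundance values with a paired sample design.

    ``samples`` maps sample id -> (animal id, condition), condition in
    {'ipsilateral', 'contralateral'}: ipsilateral is the ischemic hemisphere,
    contralateral the within-animal control.
    """

    values: pd.DataFrame  # rows: gene ids; columns: sample ids
    samples: dict[str, tuple[str, str]]

    CONDITIONS = ("ipsilateral", "contralateral")

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.samples]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        if (self.values.values < 0).any():
            raise ValueError("negative abundance values")
        per_animal: dict[str, set[str]] = {}
        for sid in self.values.columns:
            animal, cond = self.samples[sid]
            if cond not in self.CONDITIONS:
                raise ValueError(f"unknown condition {cond!r} for sample {sid}")
            per_animal.setdefault(animal, set()).add(cond)
        bad = [a for a, conds in per_animal.items() if conds != set(self.CONDITIONS)]
        if bad:
            raise ValueError(f"animals without exactly one sample per condition: {bad}")

    @property
    def animals(self) -> list[str]:
        seen: list[str] = []
        for sid in self.values.columns:
            a = self.samples[sid][0]
            if a not in seen:
                seen.append(a)
        return seen

    def paired_arrays(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Return (ipsi, contra) value arrays with animals in matched column order."""
        animals = self.animals
        cols_by = {(a, c): sid for sid, (a, c) in self.samples.items() if sid in self.values.columns}
        ipsi = self.values[[cols_by[(a, "ipsilateral")] for a in animals]].to_numpy(float)
        contra = self.values[[cols_by[(a, "contralateral")] for a in animals]].to_numpy(float)
        return ipsi, contra, animals

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        """Read a TSV whose sample headers encode animal and condition as
        ``<animal>_<ipsi|contra>`` (e.g. ``rat3_ipsi``)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        samples = {}
        for sid in df.columns:
            stem, _, tag = sid.rpartition("_")
            cond = {"ipsi": "ipsilateral", "contra": "contralateral"}.get(tag)
            if cond is None or not stem:
                raise ValueError(f"sample header {sid!r} does not encode animal_condition")
            samples[sid] = (stem, cond)
        return cls(df, samples)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t")


@dataclass
class RepeatHit:
    """One repeat-element hit on a host sequence (transcript or 3'UTR)."""

    host_id: str
    family: str  # 'B1/Alu' | 'B2' | 'B4' | 'other'
    start: int  # 0-based half-open on host
    end: int
    strand: str  # '+' or '-' relative to host
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"bad repeat interval [{self.start},{self.end}) on {self.host_id}")


@dataclass
class DuplexCandidate:
    """One lncRNA-SINE : mRNA-3'UTR-SINE hybrid with its free energy."""

    lnc_id: str
    lnc_interval: tuple[int, int]
    mrna_id: str
    utr_interval: tuple[int, int]
    delta_g: float  # kcal/mol, negative = stable
    family_pair: tuple[str, str]
    alignment: Optional[str] = None
    p_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.delta_g > 0:
            raise ValueError("reported duplexes must have delta_g <= 0")


@dataclass
class MreSite:
    """One predicted miRNA response element on a target RNA."""

    mirna_id: str
    target_id: str
    start: int
    end: int
    score: float
    delta_g: float
    seed_matches: int = 0  # matched positions among miRNA positions 2-8

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("MRE score must be >= 0")
        if self.end <= self.start:
            raise ValueError("empty MRE interval")


@dataclass
class GroundTruth:
    """Machine-readable manifest of everything the generator planted."""

    de_genes: dict[str, float] = field(default_factory=dict)  # id -> true log2 effect
    planted_triads: list[tuple[str, str, str]] = field(default_factory=list)
    planted_smd_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    true_lncrna_ids: set[str] = field(default_factory=set)
    mre_sites: list[dict] = field(default_factory=list)
    sine_sites: list[dict] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "de_genes": dict(sorted(self.de_genes.items())),
            "planted_triads": [list(t) for t in self.planted_triads],
            "planted_smd_pairs": [list(t) for t in self.planted_smd_pairs],
            "true_lncrna_ids": sorted(self.true_lncrna_ids),
            "mre_sites": self.mre_sites,
            "sine_sites": self.sine_sites,
        }
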