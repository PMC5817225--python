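"""Minimal GTF reader/writer for transcript models.

Only ``exon`` features are consumed; transcript-level attributes carried are
``gene_id``, ``transcript_id``, ``class_code``, ``detected_in`` and
``biotype``. Coordinates follow the GTF convention (1-based inclusive) on
disk and are converted to 0-based half-open in memory.
"""

from __future__ import annotations

import re
from collections import OrderedDict
from typing import Iterable, Optional

from ..types import TranscriptModel

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_transcripts(path, sequences: Optional[dict[str, str]] = None) -> list[TranscriptModel]:
    """Parse a GTF into TranscriptModel objects (exon features only).

    ``sequences`` optionally maps transcript id -> spliced sequence.
    """
    exons: "OrderedDict[str, dict]" = OrderedDict()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns, got {len(parts)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = parts
            if feature != "exon":
                continue
            a = _parse_attributes(attrs)
            tid = a.get("transcript_id")
            if tid is None:
                raise ValueError(f"{path}:{lineno}: exon without transcript_id")
            rec = exons.setdefault(
                tid,
                {
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "class_code": a.get("class_code", "="),
                    "detected_in": int(a.get("detected_in", 0)),
                    "biotype": a.get("biotype", "candidate"),
                },
            )
            rec["exons"].append((int(start) - 1, int(end)))
    out = []
    for tid, rec in exons.items():
        seq = sequences.get(tid) if sequences else None
        out.append(
            TranscriptModel(
                id=tid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=rec["exons"],
                class_code=rec["class_code"],
                detected_in=rec["detected_in"],
                sequence=seq,
                biotype=rec["biotype"],
            )
        )
    return out


def write_transcripts(transcripts: Iterable[TranscriptModel], path, source: str = "lncnet") -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.id}"; transcript_id "{t.id}"; '
                f'class_code "{t.class_code}"; detected_in "{t.detected_in}"; '
                f'biotype "{t.biotype}";'
            )
            for a, b in t.exons:
                fh.write(
                    "\t".join(
                        [t.chrom, source, "exon", str(a + 1), str(b), ".", t.strand, ".", attrs]
                    )
                    + "\n"
                )
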