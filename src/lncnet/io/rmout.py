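"""Parser for RepeatMasker ``.out`` annotation tables.

The .out layout is whitespace-separated with a 3-line header; query
coordinates are 1-based inclusive and converted here to 0-based half-open.
Repeat class/family strings are mapped onto the rodent SINE families the
duplex analysis cares about (SINE/Alu -> B1/Alu, SINE/B2, SINE/B4); anything
else becomes family ``other``.
"""

from __future__ import annotations

from ..types import RepeatHit

_FAMILY_MAP = {
    "SINE/Alu": "B1/Alu",
    "SINE/B1": "B1/Alu",
    "SINE/B2": "B2",
    "SINE/B4": "B4",
}

SINE_FAMILIES = ("B1/Alu", "B2", "B4")


def map_family(repclass: str) -> str:
    return _FAMILY_MAP.get(repclass, "other")


def read_rmout(path) -> list[RepeatHit]:
    hits: list[RepeatHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if not s:
                continue
            # header lines start with the column banner or its underline
            if s.startswith(("SW", "score", "There were no")):
                continue
            parts = s.split()
            if len(parts) < 11:
                raise ValueError(f"{path}:{lineno}: malformed RepeatMasker line ({len(parts)} fields)")
            try:
                score = float(parts[0])
                query = parts[4]
                qbegin = int(parts[5])
                qend = int(parts[6])
                strand = "-" if parts[8] in ("C", "-") else "+"
                repclass = parts[10]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed RepeatMasker line: {exc}") from exc
            hits.append(
                RepeatHit(
                    host_id=query,
                    family=map_family(repclass),
                    start=qbegin - 1,
                    end=qend,
                    strand=strand,
                    score=score,
                )
            )
    return hits


def write_rmout(hits: list[RepeatHit], path) -> None:
    """Write hits back in .out column layout (used by the synthetic generator)."""
    inv = {"B1/Alu": "SINE/Alu", "B2": "SINE/B2", "B4": "SINE/B4"}
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query      position in query           matching  repeat        position in  repeat\n"
            "score  div. del. ins.  sequence    begin     end    (left)    repeat    class/family    begin  end (left)   ID\n"
            "\n"
        )
        for i, h in enumerate(hits, 1):
            strand = "C" if h.strand == "-" else "+"
            repclass = inv.get(h.family, "Unknown")
            name = h.family.split("/")[0]
            fh.write(
                f"{h.score:5.0f}  0.0  0.0  0.0  {h.host_id}  {h.start + 1}  {h.end}  (0)  "
                f"{strand}  {name}  {repclass}  1  {h.end - h.start}  (0)  {i}\n"
            )
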