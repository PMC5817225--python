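"""Read/write base-wise conservation tracks (fixedStep wiggle, bedGraph).

Tracks are held as dense per-chromosome float arrays with NaN marking bases
that have no score — the same convention the conservation metrics use.
Wiggle positions are 1-based on disk, 0-based in memory.
"""

from __future__ import annotations

import numpy as np


def read_wig(path, chrom_sizes: dict[str, int] | None = None) -> dict[str, np.ndarray]:
    """Parse a fixedStep (or variableStep) wiggle file into NaN-padded arrays."""
    chunks: dict[str, list[tuple[int, np.ndarray]]] = {}
    mode = None
    chrom = None
    pos = step = span = 1
    buf: list[float] = []

    def flush():
        nonlocal buf
        if chrom is not None and buf:
            chunks.setdefault(chrom, []).append((start0, np.asarray(buf, dtype=float)))
        buf = []

    start0 = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("fixedStep"):
                flush()
                fields = dict(kv.split("=") for kv in line.split()[1:])
                mode = "fixed"
                chrom = fields["chrom"]
                pos = int(fields["start"])
                step = int(fields.get("step", 1))
                span = int(fields.get("span", 1))
                if step != 1 or span != 1:
                    raise ValueError("only step=1 span=1 fixedStep tracks are supported")
                start0 = pos - 1
            elif line.startswith("variableStep"):
                flush()
                fields = dict(kv.split("=") for kv in line.split()[1:])
                mode = "variable"
                chrom = fields["chrom"]
            elif mode == "fixed":
                buf.append(float(line))
            elif mode == "variable":
                p, v = line.split()
                chunks.setdefault(chrom, []).append((int(p) - 1, np.asarray([float(v)])))
            else:
                raise ValueError(f"data line before any step declaration in {path}")
    flush()

    track: dict[str, np.ndarray] = {}
    for c, parts in chunks.items():
        size = (chrom_sizes or {}).get(c, max(s + len(v) for s, v in parts))
        arr = np.full(size, np.nan)
        for s, v in parts:
            arr[s : s + len(v)] = v
        track[c] = arr
    return track


def write_wig(track: dict[str, np.ndarray], path, name: str = "track") -> None:
    """Write NaN-gapped arrays as fixedStep blocks of contiguous scored bases."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        for chrom in sorted(track):
            arr = track[chrom]
            scored = ~np.isnan(arr)
            if not scored.any():
                continue
            # contiguous runs of scored bases
            edges = np.flatnonzero(np.diff(scored.astype(int)))
            starts = [int(i) for i in np.r_[np.flatnonzero(scored)[:1], edges + 1] if scored[i]]
            for s in starts:
                e = s
                while e < len(arr) and scored[e]:
                    e += 1
                fh.write(f"fixedStep chrom={chrom} start={s + 1} step=1\n")
                fh.write("\n".join(f"{v:.4f}" for v in arr[s:e]) + "\n")
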