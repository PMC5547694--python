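"""Plain-text persistence: tissue snapshots, event tables, run manifests.

Snapshots use a small OFF-like text format -- a header, one line per vertex,
one line per cell (vertex count followed by the CCW vertex indices), then a
per-cell state table.  Floats are written with ``repr`` so a read-back
snapshot is bit-identical to the saved tissue.  ``save_run`` writes a
directory with the snapshot, events/sizes/traits TSV tables and a JSON
manifest carrying the configuration and SHA-256 checksums of every file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np

from .config import SimConfig
from .growth import Event, EventLog, RunResult
from .tissue import Tissue

__all__ = [
    "write_snapshot",
    "read_snapshot",
    "write_events_tsv",
    "read_events_tsv",
    "save_run",
    "load_run",
]

_MAGIC = "epivertex-snapshot 1"
_STATE_COLS = ["uid", "lam", "gam", "trait", "clock", "cycle_len",
               "natural_area", "mitotic", "premit_area"]


def _f(x: float) -> str:
    return repr(float(x))


def write_snapshot(tissue: Tissue, path: Union[str, Path],
                   time: float = 0.0,
                   extra: Optional[dict] = None) -> None:
    """Write a tissue to the plain-text snapshot format."""
    path = Path(path)
    meta = {"time": float(time), "next_uid": int(tissue.next_uid)}
    if extra:
        meta.update(extra)
    lines = [_MAGIC,
             json.dumps(meta, sort_keys=True),
             f"{tissue.vertices.shape[0]} {len(tissue.cells)}"]
    for x, y in tissue.vertices:
        lines.append(f"{_f(x)} {_f(y)}")
    for c in tissue.cells:
        lines.append(str(len(c)) + " " + " ".join(str(int(v)) for v in c))
    lines.append("\t".join(_STATE_COLS))
    for i in range(len(tissue.cells)):
        lines.append("\t".join([
            str(int(tissue.uid[i])), _f(tissue.lam[i]), _f(tissue.gam[i]),
            str(int(tissue.trait[i])), _f(tissue.clock[i]),
            _f(tissue.cycle_len[i]), _f(tissue.natural_area[i]),
            "1" if tissue.mitotic[i] else "0", _f(tissue.premit_area[i]),
        ]))
    path.write_text("\n".join(lines) + "\n")


def read_snapshot(path: Union[str, Path]) -> Tuple[Tissue, dict]:
    """Read a snapshot; returns (tissue, metadata dict)."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != _MAGIC:
        raise ValueError(f"{path}: not a tissue snapshot")
    meta = json.loads(lines[1])
    nv, nc = (int(t) for t in lines[2].split())
    k = 3
    verts = np.array([[float(t) for t in lines[k + i].split()]
                      for i in range(nv)], dtype=float)
    k += nv
    cells = []
    for i in range(nc):
        toks = lines[k + i].split()
        n = int(toks[0])
        if len(toks) != n + 1:
            raise ValueError(f"{path}: malformed cell line {k + i + 1}")
        cells.append(np.array([int(t) for t in toks[1:]], dtype=np.int64))
    k += nc
    if lines[k].split("\t") != _STATE_COLS:
        raise ValueError(f"{path}: unexpected state columns")
    k += 1
    tissue = Tissue(verts, cells)
    for i in range(nc):
        toks = lines[k + i].split("\t")
        tissue.uid[i] = int(toks[0])
        tissue.lam[i] = float(toks[1])
        tissue.gam[i] = float(toks[2])
        tissue.trait[i] = int(toks[3])
        tissue.clock[i] = float(toks[4])
        tissue.cycle_len[i] = float(toks[5])
        tissue.natural_area[i] = float(toks[6])
        tissue.mitotic[i] = toks[7] == "1"
        tissue.premit_area[i] = float(toks[8])
    tissue.next_uid = int(meta.get("next_uid", int(tissue.uid.max()) + 1))
    return tissue, meta


# --------------------------------------------------------------------- tables

_EVENT_COLS = ["time", "kind", "cell_uid", "x", "y", "parent_trait",
               "daughter_uids", "daughter_traits", "last_area",
               "before_S", "after_S", "before_cv", "after_cv"]


def write_events_tsv(log: EventLog, path: Union[str, Path]) -> None:
    lines = ["\t".join(_EVENT_COLS)]
    for e in log.events:
        lines.append("\t".join([
            _f(e.time), e.kind, str(e.cell_uid), _f(e.location[0]),
            _f(e.location[1]), str(e.parent_trait),
            ",".join(str(u) for u in e.daughter_uids),
            ",".join(str(t) for t in e.daughter_traits),
            _f(e.last_area), _f(e.before_S), _f(e.after_S),
            _f(e.before_cv), _f(e.after_cv),
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_events_tsv(path: Union[str, Path]) -> EventLog:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != _EVENT_COLS:
        raise ValueError(f"{path}: unexpected event columns")
    log = EventLog()
    for ln in lines[1:]:
        t = ln.split("\t")
        log.events.append(Event(
            kind=t[1], time=float(t[0]), cell_uid=int(t[2]),
            location=(float(t[3]), float(t[4])), parent_trait=int(t[5]),
            daughter_uids=tuple(int(u) for u in t[6].split(",") if u),
            daughter_traits=tuple(int(u) for u in t[7].split(",") if u),
            last_area=float(t[8]), before_S=float(t[9]), after_S=float(t[10]),
            before_cv=float(t[11]), after_cv=float(t[12])))
    return log


def _write_sizes(log: EventLog, path: Path) -> None:
    lines = ["time\tn_cells"]
    lines += [f"{_f(t)}\t{int(n)}" for t, n in zip(log.times, log.sizes)]
    path.write_text("\n".join(lines) + "\n")


def _write_traits(log: EventLog, path: Path) -> None:
    times, counts = log.trait_series()
    if counts.size == 0:
        return
    header = "time\t" + "\t".join(f"trait_{i}"
                                  for i in range(counts.shape[1]))
    lines = [header]
    for t, row in zip(times, counts):
        lines.append(_f(t) + "\t" + "\t".join(str(int(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_run(result: RunResult, outdir: Union[str, Path]) -> Path:
    """Persist a growth run: snapshot, TSV tables, JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_snapshot(result.tissue, outdir / "tissue.txt", time=result.t_end)
    write_events_tsv(result.log, outdir / "events.tsv")
    _write_sizes(result.log, outdir / "sizes.tsv")
    _write_traits(result.log, outdir / "traits.tsv")
    files = sorted(p.name for p in outdir.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "format": "epivertex-run 1",
        "t_end": result.t_end,
        "n_cells": len(result.tissue.cells),
        "S_bar_init": result.S_bar_init,
        "aborted": result.aborted,
        "config": result.config.to_dict(),
        "checksums": {name: _sha256(outdir / name) for name in files},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir


def load_run(outdir: Union[str, Path], verify: bool = True) -> RunResult:
    """Load a saved run; optionally verify file checksums."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    if manifest.get("format") != "epivertex-run 1":
        raise ValueError(f"{outdir}: not a saved run")
    if verify:
        for name, digest in manifest["checksums"].items():
            actual = _sha256(outdir / name)
            if actual != digest:
                raise ValueError(f"{outdir / name}: checksum mismatch")
    tissue, _ = read_snapshot(outdir / "tissue.txt")
    log = read_events_tsv(outdir / "events.tsv")
    for ln in (outdir / "sizes.tsv").read_text().splitlines()[1:]:
        t, n = ln.split("\t")
        log.record_size(float(t), int(n))
    traits_path = outdir / "traits.tsv"
    if traits_path.exists():
        rows = traits_path.read_text().splitlines()[1:]
        for ln in rows:
            toks = ln.split("\t")
            log.trait_times.append(float(toks[0]))
            log.trait_counts.append(np.array([int(v) for v in toks[1:]],
                                             dtype=np.int64))
    config = SimConfig.from_dict(manifest["config"])
    return RunResult(tissue=tissue, log=log, config=config,
                     t_end=float(manifest["t_end"]),
                     S_bar_init=float(manifest["S_bar_init"]),
                     aborted=bool(manifest["aborted"]))
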