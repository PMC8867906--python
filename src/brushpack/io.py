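"""Readers/writers for the XYZ, CSV, TSV and YAML artifacts, plus run
manifests.

Snapshot format: extended XYZ — a particle count line, then a comment line
of ``key=value`` pairs carrying at least the box (``box="Lx Ly"``) and
optionally eta, sigma and the MC step index, then one ``P x y z`` line per
particle with z = 0 for these quasi-2D systems.  Coordinate CSVs use
columns (frame,id,x,y) for tracks or (x,y) for single configurations with
the box in a ``# box: Lx Ly`` header comment.

All writes are atomic: content goes to a temporary file in the target
directory which is then renamed over the destination, so interrupted
reruns never corrupt earlier outputs.
"""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from brushpack.dynamics import TrackSet
from brushpack.mc import Configuration2D

__all__ = [
    "atomic_write_text",
    "write_xyz",
    "read_configuration",
    "read_tracks_csv",
    "write_tracks_csv",
    "load_yaml_config",
    "write_manifest",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write ``text`` to ``path`` via a temp file + rename (atomic on POSIX)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_xyz(path: str | Path, configs: Iterable[Configuration2D],
              metadata: Iterable[dict] | None = None) -> None:
    """Write configurations as (multi-frame) extended XYZ."""
    configs = list(configs)
    metas = list(metadata) if metadata is not None else [{}] * len(configs)
    chunks = []
    for cfg, meta in zip(configs, metas):
        fields = {"box": f"\"{cfg.box[0]:.17g} {cfg.box[1]:.17g}\"",
                  "periodic": str(cfg.periodic)}
        for k, v in meta.items():
            fields[k] = f"{v:.17g}" if isinstance(v, float) else str(v)
        comment = " ".join(f"{k}={v}" for k, v in fields.items())
        lines = [str(cfg.n), comment]
        for x, y in cfg.positions:
            lines.append(f"P {x:.17g} {y:.17g} 0")
        chunks.append("\n".join(lines))
    atomic_write_text(path, "\n".join(chunks) + "\n")


def _parse_xyz_comment(comment: str, lineno: int) -> dict:
    fields: dict[str, str] = {}
    rest = comment.strip()
    while rest:
        if "=" not in rest:
            break
        key, rest = rest.split("=", 1)
        if rest.startswith('"'):
            end = rest.find('"', 1)
            if end < 0:
                raise ParseError(f"line {lineno}: unterminated quote in comment")
            fields[key.strip()] = rest[1:end]
            rest = rest[end + 1:].strip()
        else:
            parts = rest.split(None, 1)
            fields[key.strip()] = parts[0]
            rest = parts[1] if len(parts) > 1 else ""
    return fields


def read_configuration(path: str | Path,
                       box: Sequence[float] | None = None) -> list[Configuration2D]:
    """Read configurations from an XYZ snapshot file or a coordinate CSV.

    XYZ files may hold multiple frames; the comment line must carry the
    box unless ``box`` is given.  CSVs need columns x,y (a ``frame``
    column splits multiple configurations) and take the box from a
    ``# box: Lx Ly`` header comment or the ``box`` argument.  Nonzero z
    coordinates are dropped with a warning (2D contract).
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _read_configuration_csv(path, box)
    lines = path.read_text().splitlines()
    configs: list[Configuration2D] = []
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"line {i + 1}: expected a particle count") from None
        if i + 1 >= len(lines):
            raise ParseError(f"line {i + 1}: missing comment line")
        meta = _parse_xyz_comment(lines[i + 1], i + 2)
        if "box" in meta:
            try:
                bx, by = (float(v) for v in meta["box"].split())
            except ValueError:
                raise ParseError(f"line {i + 2}: malformed box metadata") from None
        elif box is not None:
            bx, by = float(box[0]), float(box[1])
        else:
            raise ParseError(f"line {i + 2}: missing box metadata")
        periodic = meta.get("periodic", "True") != "False"
        pos = np.empty((n, 2))
        z_warn = False
        for k in range(n):
            ln = i + 2 + k
            if ln >= len(lines):
                raise ParseError(f"line {ln + 1}: truncated frame {frame}")
            parts = lines[ln].split()
            if len(parts) < 3:
                raise ParseError(f"line {ln + 1}: expected 'symbol x y [z]'")
            try:
                pos[k, 0] = float(parts[1])
                pos[k, 1] = float(parts[2])
                z = float(parts[3]) if len(parts) > 3 else 0.0
            except ValueError:
                raise ParseError(f"line {ln + 1}: non-numeric coordinate") from None
            if z != 0.0:
                z_warn = True
        if np.isnan(pos).any():
            raise ParseError(f"frame {frame}: NaN coordinates")
        if z_warn:
            warnings.warn(f"{path.name}: nonzero z coordinates dropped (2D)")
        configs.append(Configuration2D(pos, (bx, by), periodic=periodic))
        i += 2 + n
        frame += 1
    if not configs:
        raise ParseError(f"{path}: no frames found")
    return configs


def _read_header_box(path: Path) -> tuple[float, float] | None:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "box:" in line:
                vals = line.split("box:", 1)[1].split()
                if len(vals) >= 2:
                    return float(vals[0]), float(vals[1])
    return None


def _read_configuration_csv(path: Path,
                            box: Sequence[float] | None) -> list[Configuration2D]:
    hdr_box = _read_header_box(path)
    df = pd.read_csv(path, comment="#")
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: CSV missing columns {sorted(missing)}")
    if df[["x", "y"]].isna().any().any():
        raise ParseError(f"{path}: NaN coordinates")
    if hdr_box is not None:
        bx, by = hdr_box
    elif box is not None:
        bx, by = float(box[0]), float(box[1])
    else:
        raise ParseError(f"{path}: missing box metadata (use a '# box: Lx Ly' "
                         "header or pass box=)")
    groups = df.groupby("frame") if "frame" in df.columns else [(0, df)]
    return [
        Configuration2D(g[["x", "y"]].to_numpy(), (bx, by), periodic=False)
        for _, g in groups
    ]


def read_tracks_csv(path: str | Path, frame_interval: float = 1.0 / 15.0) -> TrackSet:
    """Read a (frame,id,x,y) track table; the 15 fps experimental rate is
    the default frame interval."""
    df = pd.read_csv(path, comment="#")
    missing = {"frame", "id", "x", "y"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: track CSV missing columns {sorted(missing)}")
    return TrackSet(df, frame_interval)


def write_tracks_csv(path: str | Path, ts: TrackSet) -> None:
    atomic_write_text(path, ts.data.to_csv(index=False))


def load_yaml_config(path: str | Path) -> dict:
    """Plain key/value YAML config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg


def write_manifest(out_dir: str | Path, command: str, config: dict,
                   seeds: Sequence[int], inputs: Sequence[str] = (),
                   outputs: Sequence[str] = ()) -> Path:
    """Write the run manifest (one per output directory)."""
    from brushpack import __version__

    out_dir = Path(out_dir)
    manifest = {
        "command": command,
        "config": config,
        "seeds": list(map(int, seeds)),
        "version": __version__,
        "inputs": list(map(str, inputs)),
        "outputs": list(map(str, outputs)),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    atomic_write_text(path, json.dumps(manifest, indent=2, default=str) + "\n")
    return path
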