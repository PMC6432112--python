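"""Deterministic, self-describing output formats.

CSV tables carry 17 significant digits (lossless float round-trip) and
every artifact gets a JSON sidecar with the effective configuration,
tolerances achieved, seeds and a format version tag, so any result can
be regenerated from its own metadata.  Chain conformations export as
standard XYZ (element tag "C", one frame per snapshot).
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

FORMAT_VERSION = "wlcbuckle-1"

__all__ = ["write_table", "read_table", "write_xyz", "FORMAT_VERSION"]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_table(df: pd.DataFrame, path: str | Path,
                meta: dict | None = None) -> Path:
    """CSV at 17 significant digits plus a .json metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".json")
    payload = {
        "format_version": FORMAT_VERSION,
        "written": datetime.now(timezone.utc).isoformat(),
        "columns": list(df.columns),
        "n_rows": int(len(df)),
        "meta": _jsonify(meta or {}),
    }
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return df, meta


def write_xyz(frames, path: str | Path, element: str = "C",
              comment: str = "") -> Path:
    """Standard XYZ trajectory: one block per (Nb, 3) coordinate frame."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for idx, pos in enumerate(frames):
            pos = np.asarray(pos, dtype=float)
            fh.write(f"{len(pos)}\n")
            fh.write(f"{comment} frame {idx}\n")
            for x, y, z in pos:
                fh.write(f"{element} {x:.10f} {y:.10f} {z:.10f}\n")
    return path
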