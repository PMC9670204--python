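"""File-format adapters: multi-channel TIFF + JSON sidecar, CSV tables,
YAML run configuration and output manifests."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .calcium import CalciumTrace
from .imaging import FieldImage
from .phospho import validate_table
from .simulate.images import CHANNEL_NAMES, CellTruth, SyntheticField

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ("cell_id", "time_s", "f340", "f380")
PEPTIDE_COLUMNS = ("peptide_id", "is_phospho", "sample_id", "condition", "area")


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(tiff_path.suffix + ".json")


def write_field_tiff(field: FieldImage | SyntheticField, path: str | Path) -> Path:
    """Write channels as a multi-channel TIFF with a JSON sidecar.

    The sidecar records pixel size, channel names, and — for synthetic
    fields — the planted ground truth.
    """
    path = Path(path)
    names = list(field.channels)
    stack = np.stack([np.asarray(field.channels[n]) for n in names])
    tifffile.imwrite(path, stack.astype(np.float32), photometric="minisblack")
    sidecar: dict = {
        "pixel_size_um": field.pixel_size_um,
        "channel_names": names,
        "field_id": getattr(field, "field_id", path.stem),
    }
    truth = getattr(field, "truth", None)
    if truth is not None:
        sidecar["truth"] = [t.to_jsonable() for t in truth]
    _sidecar_path(path).write_text(json.dumps(sidecar))
    return path


def read_field_tiff(path: str | Path, pixel_size_um: float | None = None,
                    channel_names: Sequence[str] | None = None
                    ) -> tuple[FieldImage, list[CellTruth] | None]:
    """Read a multi-channel TIFF (+ sidecar); returns the field and any truth.

    Pixel size and channel names come from the sidecar unless supplied;
    missing metadata raises an error naming the missing piece.
    """
    path = Path(path)
    data = np.asarray(tifffile.imread(path))
    sidecar = {}
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())
    if pixel_size_um is None:
        pixel_size_um = sidecar.get("pixel_size_um")
    if pixel_size_um is None:
        raise ValueError(f"{path}: pixel_size_um not given and no sidecar provides it")
    names = list(channel_names) if channel_names is not None else sidecar.get("channel_names")
    if names is None:
        raise ValueError(f"{path}: channel names not given and no sidecar provides them")
    if data.ndim == 2:
        data = data[None]
    if len(names) != data.shape[0]:
        raise ValueError(f"{path}: {len(names)} channel names for {data.shape[0]} channels")
    channels = {n: data[i].astype(float) for i, n in enumerate(names)}
    truth = None
    if "truth" in sidecar:
        truth = [CellTruth.from_jsonable(t) for t in sidecar["truth"]]
    field = FieldImage(channels=channels, pixel_size_um=float(pixel_size_um),
                       field_id=sidecar.get("field_id", path.stem))
    return field, truth


def _normalize_headers(df: pd.DataFrame) -> pd.DataFrame:
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def write_trace_csv(traces: Sequence[CalciumTrace], path: str | Path) -> Path:
    rows = []
    for t in traces:
        for i in range(len(t.time_s)):
            rows.append({"cell_id": t.cell_id, "time_s": t.time_s[i],
                         "f340": t.f340[i], "f380": t.f380[i]})
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_trace_csv(path: str | Path) -> list[CalciumTrace]:
    """Long-format CSV (cell_id, time_s, F340, F380; case-insensitive headers)."""
    df = _normalize_headers(pd.read_csv(path))
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    traces = []
    for cell_id, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("time_s")
        traces.append(CalciumTrace(cell_id=str(cell_id),
                                   time_s=sub["time_s"].to_numpy(),
                                   f340=sub["f340"].to_numpy(),
                                   f380=sub["f380"].to_numpy()))
    if not traces:
        raise ValueError(f"{path}: no traces found")
    return traces


def read_peptide_csv(path: str | Path) -> pd.DataFrame:
    """Long-format peptide peak-area table; malformed rows are reported with
    their line numbers (header = line 1)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = _normalize_headers(pd.read_csv(path, sep=sep))
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df.index[pd.to_numeric(df["area"], errors="coerce").isna() | (pd.to_numeric(df["area"], errors="coerce") < 0)]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:10]]
        raise ValueError(f"{path}: invalid (negative or non-numeric) area at lines {lines}")
    df["area"] = df["area"].astype(float)
    df["is_phospho"] = df["is_phospho"].astype(bool)
    return validate_table(df)


def read_groups_csv(path: str | Path) -> dict[str, np.ndarray]:
    df = _normalize_headers(pd.read_csv(path))
    for c in ("group", "value"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    return {str(g): sub["value"].to_numpy(dtype=float) for g, sub in df.groupby("group", sort=False)}


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> Path:
    """Write named tables as CSV and a manifest of content hashes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        manifest[p.name] = sha256_of(p)
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return mpath


# ---------------------------------------------------------------------------
# Run configuration

KNOWN_CONFIG_KEYS = {
    "seed", "out_dir", "log_level",
    "images", "traces", "peptides", "groups",   # simulate blocks
    "quantify", "calcium", "phospho", "compare",
}


def load_config(path: str | Path) -> dict:
    """Strict YAML config: unknown top-level keys are rejected."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - KNOWN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


def persist_resolved_config(cfg: dict, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p = out_dir / "resolved_config.yaml"
    p.write_text(yaml.safe_dump(cfg, sort_keys=True))
    return p
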