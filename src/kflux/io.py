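"""File-format dialects shared by all modules.

CSV/TSV with ``#key=value`` metadata header lines for tabular data, JSON
for site maps, protocols and results.  Every results JSON carries a
reproducibility block (config echo, seed, package version).  All writers
round-trip through their readers with value equality.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .permeation import SiteMap
from .traces import Recording, Segment

__all__ = [
    "read_table",
    "write_table",
    "read_recording_csv",
    "write_recording_csv",
    "read_sitemap_json",
    "write_sitemap_json",
    "write_results_json",
    "read_results_json",
]

_VERSION = "0.1.0"


def _parse_header(lines: list[str]) -> dict:
    meta = {}
    for ln in lines:
        body = ln[1:].strip()
        if "=" in body:
            k, v = body.split("=", 1)
            meta[k.strip()] = v.strip()
    return meta


def read_table(path, required: tuple[str, ...] = (), sep: str = None):
    """Read a CSV/TSV table with optional ``#key=value`` header lines.

    Returns (DataFrame, metadata dict).  Missing required columns raise a
    parse error naming the column.
    """
    path = Path(path)
    header_lines = []
    with open(path) as fh:
        pos = 0
        for ln in fh:
            if ln.startswith("#"):
                header_lines.append(ln)
                pos += 1
            else:
                break
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, skiprows=pos, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}; "
                         f"found {list(df.columns)}")
    return df, _parse_header(header_lines)


def write_table(df: pd.DataFrame, path, metadata: dict | None = None,
                sep: str = None):
    """Write a table with ``#key=value`` header lines."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"#{k}={v}\n")
        df.to_csv(fh, sep=sep, index=False)


def write_recording_csv(rec: Recording, path):
    """Write a recording with its protocol embedded in the header."""
    seg_labels, seg_volts = [], []
    for t in rec.sweeps["time_s"]:
        seg = next((s for s in rec.protocol
                    if s.t_start <= t < s.t_end), rec.protocol[-1])
        seg_labels.append(seg.label)
        seg_volts.append(seg.voltage_mV)
    df = rec.sweeps.copy()
    df["segment"] = seg_labels
    df["voltage_mV"] = seg_volts
    meta = {"sample_rate_hz": rec.sample_rate,
            "protocol": json.dumps([[s.label, s.t_start, s.t_end,
                                     s.voltage_mV] for s in rec.protocol]),
            **{k: v for k, v in rec.metadata.items()
               if isinstance(v, (str, int, float))}}
    write_table(df, path, meta, sep=",")


def read_recording_csv(path) -> Recording:
    df, meta = read_table(path, required=("sweep", "time_s", "current"))
    if "protocol" not in meta:
        raise ValueError(f"{Path(path).name}: missing #protocol header")
    protocol = [Segment(lbl, float(t0), float(t1), float(v))
                for lbl, t0, t1, v in json.loads(meta["protocol"])]
    extra = {k: v for k, v in meta.items()
             if k not in ("protocol", "sample_rate_hz")}
    return Recording(df[["sweep", "time_s", "current"]],
                     protocol, float(meta.get("sample_rate_hz", 0) or 0),
                     metadata=extra)


def write_sitemap_json(sites: SiteMap, path):
    Path(path).write_text(json.dumps(sites.to_dict(), indent=2))


def read_sitemap_json(path) -> SiteMap:
    return SiteMap.from_dict(json.loads(Path(path).read_text()))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    return obj


def write_results_json(results: dict, path, config: dict | None = None,
                       seed: int | None = None):
    """Write a results JSON with a reproducibility block."""
    payload = {"results": _jsonable(results),
               "reproducibility": {"config": _jsonable(config or {}),
                                   "seed": seed, "version": _VERSION}}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_results_json(path) -> dict:
    return json.loads(Path(path).read_text())
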