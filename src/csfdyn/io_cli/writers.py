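"""Result serialization: JSON for scalar summaries, CSV for tabular parts.

Every JSON summary embeds the full parameter set used (filter band,
windows, seeds) so a run can be reproduced from its own output.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import CsfdynError


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(summary: dict, path) -> Path:
    path = Path(path)
    try:
        path.write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n")
    except OSError as exc:
        raise CsfdynError(f"cannot write {path}: {exc}") from exc
    return path


def write_csv(rows, path, columns=None) -> Path:
    path = Path(path)
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows, columns=columns)
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise CsfdynError(f"cannot write {path}: {exc}") from exc
    return path


def write_results(result, out_dir, stem: str, params: dict | None = None, table=None) -> dict:
    """Write a stage result as ``<stem>.json`` (+ ``<stem>.csv`` if tabular).

    ``params`` is merged into the JSON under "params"; ``table`` (DataFrame
    or list of dicts) becomes the CSV. Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = _jsonable(result) if dataclasses.is_dataclass(result) else _jsonable(dict(result))
    if params:
        summary["params"] = _jsonable(params)
    paths = {"json": str(write_json(summary, out_dir / f"{stem}.json"))}
    if table is not None:
        paths["csv"] = str(write_csv(table, out_dir / f"{stem}.csv"))
    return paths
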