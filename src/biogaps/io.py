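"""CSV / JSON round-tripping and run manifests.

All tabular artifacts are RFC-4180 CSV (pandas' csv writer quotes and
escapes correctly); generator parameters, mechanism provenance and seeds
travel in JSON sidecars next to each CSV.  Readers reject ragged rows.
"""
from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable

import pandas as pd

from .datatypes import AbundanceData, Estimate, Mask
from .exceptions import BiogapsError

__all__ = [
    "read_table",
    "write_abundance",
    "read_abundance",
    "write_mask",
    "write_estimates",
    "write_manifest",
]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def read_table(path) -> pd.DataFrame:
    """Strict CSV reader: ragged rows are an error, not a warning."""
    try:
        return pd.read_csv(path, on_bad_lines="error")
    except Exception as exc:
        raise BiogapsError(f"failed to read CSV {path}: {exc}") from exc


def write_abundance(data: AbundanceData, csv_path) -> Path:
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    data.table.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"unit_cols": list(data.unit_cols), "meta": _jsonable(data.meta)},
            indent=2, sort_keys=True,
        )
    )
    return csv_path


def read_abundance(csv_path) -> AbundanceData:
    csv_path = Path(csv_path)
    table = read_table(csv_path)
    sidecar = csv_path.with_suffix(".json")
    if sidecar.exists():
        info = json.loads(sidecar.read_text())
        unit_cols = tuple(info.get("unit_cols", ()))
        meta = info.get("meta", {})
    else:
        guess = [c for c in ("cell_id", "site_id", "year", "visit")
                 if c in table.columns]
        unit_cols = tuple(guess) if guess else (table.columns[0],)
        meta = {}
    missing = [c for c in unit_cols if c not in table.columns]
    if missing:
        raise BiogapsError(f"CSV {csv_path} lacks unit columns {missing}")
    if "count" not in table.columns:
        raise BiogapsError(f"CSV {csv_path} lacks required column 'count'")
    return AbundanceData(table=table, unit_cols=unit_cols, meta=meta)


def write_mask(mask: Mask, csv_path) -> Path:
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    df = mask.included.reset_index()
    df["pi"] = mask.design.pi.to_numpy()
    df.to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "mechanism": mask.design.mechanism,
                "params": _jsonable(mask.design.params),
                "target_fraction": mask.design.target_fraction,
                "dimension": mask.dimension,
                "seed": mask.seed,
                "realized_fraction": mask.realized_fraction,
            },
            indent=2, sort_keys=True,
        )
    )
    return csv_path


def write_estimates(estimates: Iterable[Estimate], csv_path) -> Path:
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    ests = list(estimates)
    pd.DataFrame([e.to_row() for e in ests]).to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            [dict(e.to_row(), extras=_jsonable(e.extras)) for e in ests],
            indent=2, sort_keys=True,
        )
    )
    return csv_path


def write_manifest(out_dir, command: str, cfg_hash: str, seed: int,
                   outputs: list[str]) -> Path:
    """A manifest sufficient to re-run the command exactly."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    missing = [o for o in outputs if not (out_dir / o).exists()]
    if missing:
        raise BiogapsError(f"manifest lists outputs that do not exist: {missing}")
    manifest = {
        "command": command,
        "config_hash": cfg_hash,
        "master_seed": seed,
        "package_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "outputs": outputs,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
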