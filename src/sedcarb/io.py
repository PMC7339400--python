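"""CSV and manifest I/O.

All tables are plain CSV with a header row, ISO-8601 dates and '.'
decimals; floats are written at full repr precision so a write/read
round-trip reproduces values exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .forcing import FORCING_COLUMNS
from .simulate import SimulationResult

__all__ = [
    "read_forcing_csv",
    "write_forcing_csv",
    "write_run_outputs",
    "read_table",
    "write_table",
]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    if "date" in out.columns:
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"])
    return df


def write_forcing_csv(forcing: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in FORCING_COLUMNS if c not in forcing.columns]
    if missing:
        raise ValueError(f"forcing table missing columns: {missing}")
    write_table(forcing[FORCING_COLUMNS], path)


def read_forcing_csv(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    missing = [c for c in FORCING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"forcing CSV {path} missing columns: {missing}")
    return df


def write_run_outputs(
    result: SimulationResult,
    outdir: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write state/flux/outlet CSVs plus a run manifest; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("states", result.states),
        ("fluxes", result.fluxes),
        ("outlet", result.outlet),
        ("balance", result.balance),
    ):
        p = outdir / f"{name}.csv"
        write_table(df, p)
        paths[name] = p
    manifest = (config or RunConfig()).manifest(seed)
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2))
    paths["manifest"] = mp
    return paths
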