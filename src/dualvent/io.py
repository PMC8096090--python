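"""Result writing with provenance headers.

CSV dialect is fixed (comma separator, '.' decimal, UTF-8, header row) so
outputs do not drift with locale.  Every file carries a short comment
header with the package version, a hash of the resolved configuration and
the seed; identical (config, seed) pairs produce byte-identical bodies.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigError


def config_hash(resolved: dict) -> str:
    return hashlib.sha256(
        json.dumps(resolved, sort_keys=True).encode()
    ).hexdigest()[:12]


def _header(resolved: dict, seed: int) -> str:
    return (
        f"# dualvent {__version__} config={config_hash(resolved)} seed={seed}\n"
    )


def prepare_out_dir(out_dir: str | Path, force: bool = False) -> Path:
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ConfigError(f"output directory {out} is not empty (use --force)")
    out.mkdir(parents=True, exist_ok=True)
    return out


def write_csv(df: pd.DataFrame, path: Path, resolved: dict, seed: int):
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_header(resolved, seed))
        df.to_csv(fh, index=False, lineterminator="\n")


def write_json(obj: dict, path: Path):
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def write_run_outputs(result, resolved: dict, seed: int, out_dir: Path, log: str = ""):
    """Standard simulate outputs: timeseries.csv, cycles.csv, run.json."""
    write_csv(result.to_dataframe(), out_dir / "timeseries.csv", resolved, seed)
    write_csv(result.cycles, out_dir / "cycles.csv", resolved, seed)
    write_json(
        {
            "version": __version__,
            "config": resolved,
            "config_hash": config_hash(resolved),
            "seed": seed,
            "solver_stats": result.solver_stats,
            "periodic": result.periodic,
            "cycles_to_converge": result.cycles_to_converge,
            "log": log,
        },
        out_dir / "run.json",
    )
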