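"""CSV/JSON writers and the run manifest.

Every tabular output is a plain CSV whose header comments carry the
manifest hash, so any file can be traced back to the exact parameters and
solver settings that produced it; scalars and diagnostics go to JSON
sidecars.  All commands are deterministic, so identical configs produce
byte-identical outputs (timestamps live only in the manifest file).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

__all__ = ["RunManifest", "write_profile", "write_trace", "write_table", "write_json"]


@dataclass
class RunManifest:
    """Provenance record for one CLI invocation."""

    command: str
    parameters: dict
    solver: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")

    @property
    def hash(self) -> str:
        payload = json.dumps(
            {"command": self.command, "parameters": self.parameters, "solver": self.solver},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def write(self, outdir: Path) -> Path:
        path = Path(outdir) / f"manifest-{self.hash}.json"
        with open(path, "w") as fh:
            json.dump(asdict(self) | {"hash": self.hash}, fh, indent=2, default=str)
            fh.write("\n")
        return path


def _header(manifest: RunManifest | None) -> str:
    return f"# manifest: {manifest.hash}\n" if manifest is not None else ""


def write_table(df: pd.DataFrame, path: Path, manifest: RunManifest | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header(manifest))
        df.to_csv(fh, index=False, lineterminator="\n")
    return path


def write_profile(profile, path_stem: Path, manifest: RunManifest | None = None) -> tuple[Path, Path]:
    """Write a steady profile as CSV (theta_rad, V_volts) + JSON diagnostics."""
    from .steady import input_resistance, leak_integral

    stem = Path(path_stem)
    csv_path = stem.with_suffix(".csv")
    df = pd.DataFrame({"theta_rad": profile.grid.nodes, "V_volts": profile.V})
    write_table(df, csv_path, manifest)
    side = {
        "I_ext_A": profile.I_ext,
        "b_volts": None if np.isnan(profile.b) else profile.b,
        "R_in_ohm": input_resistance(profile) if profile.I_ext else None,
        "leak_integral_A": leak_integral(profile),
        "conservation_error": profile.diagnostics.get("conservation_error"),
        "theta_a_rad": profile.electrode.theta_a,
        "rho_m": profile.geom.rho,
        "d_m": profile.geom.d,
        "method": profile.diagnostics.get("method"),
    }
    json_path = stem.with_suffix(".json")
    write_json(side, json_path, manifest)
    return csv_path, json_path


def write_trace(solution, path: Path, manifest: RunManifest | None = None,
                long_format: bool = False) -> Path:
    """Write a time solution: compact trace CSV or long (t, theta, V) CSV."""
    if long_format:
        t, th = np.meshgrid(solution.times, solution.grid.nodes)
        df = pd.DataFrame({
            "t_s": t.ravel(), "theta_rad": th.ravel(), "V_volts": solution.V.ravel(),
        })
    else:
        df = pd.DataFrame({
            "t_s": solution.times,
            "V_pipette_volts": solution.V_pipette,
            "V_southpole_volts": solution.V_southpole,
        })
        if solution.I_clamp is not None:
            df["I_clamp_amps"] = solution.I_clamp
    return write_table(df, Path(path), manifest)


def write_json(payload: dict, path: Path, manifest: RunManifest | None = None) -> Path:
    path = Path(path)
    if manifest is not None:
        payload = {"manifest": manifest.hash, **payload}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
        fh.write("\n")
    return path
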