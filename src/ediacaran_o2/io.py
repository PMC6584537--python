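"""Tabular output writing and the reproducibility manifest.

Every stage writes plain CSV and JSON only.  The manifest records the
package version, the seed, a hash of the fully resolved configuration and
per-file content hashes, so a re-run with an identical manifest provably
reproduces identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ensemble import EnsembleResult, band_statistics, o2_change_distribution

BAND_VARIABLES = (
    "o2_pal", "RCO2", "mocb", "mccb", "mpsb", "mgsb", "f_org", "f_py",
    "d13C_carb", "d34S_sw", "sr_ocean", "SO4_mM",
)


def _canonical_json(obj) -> str:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return str(o)

    return json.dumps(obj, sort_keys=True, default=default)


def config_hash(config: dict, seed: int) -> str:
    return hashlib.sha256(
        _canonical_json({"config": config, "seed": seed}).encode()
    ).hexdigest()


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir: Path, config: dict, seed: int, files: list[Path]) -> Path:
    manifest = {
        "package": "ediacaran-o2",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config, seed),
        "config": json.loads(_canonical_json(config)),
        "files": {f.name: _file_sha256(f) for f in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def write_frame(frame: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    # 6 significant digits: compact files, ample for every quantity the
    # analyses compare (isotope ratios carry ~5 meaningful decimals)
    frame.to_csv(path, index=False, float_format="%.6g")
    return path


def write_ensemble_outputs(
    ens: EnsembleResult, out_dir: Path, config: dict, seed: int,
    band_variables: tuple[str, ...] = BAND_VARIABLES,
    include_run_summary: bool = True,
) -> dict:
    """Bands CSV per variable, per-run summary CSV, O2-change histogram CSV
    and a JSON report; returns the report dictionary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    for var in band_variables:
        files.append(write_frame(band_statistics(ens, var), out_dir / f"bands_{var}.csv"))

    dist = o2_change_distribution(ens)
    hist = pd.DataFrame(
        {
            "bin_left": dist.hist_edges[:-1],
            "bin_right": dist.hist_edges[1:],
            "count": dist.hist_counts,
        }
    )
    files.append(write_frame(hist, out_dir / "o2_change_histogram.csv"))

    # per-run summary: administrative fields + the sampled draw + the O2
    # change; closure-derived constants are omitted (recomputable from the
    # draw) to keep the table compact
    from .params import RANGE_FIELDS

    if include_run_summary:
        admin = ["run_index", "valid", "reason", "n_rejections", "clamp_Myr"]
        summary = ens.draws[admin + list(RANGE_FIELDS)].copy()
        changes = np.full(ens.n_runs, np.nan)
        changes[ens.valid] = dist.changes_percent
        summary["o2_change_percent"] = changes
        path = out_dir / "run_summary.csv"
        summary.to_csv(path, index=False, float_format="%.6g")
        files.append(path)

    report = {
        "n_runs": ens.n_runs,
        "n_valid": ens.n_valid,
        "n_excluded": ens.n_runs - ens.n_valid,
        "exclusion_reasons": [
            r for r in ens.draws.loc[~ens.draws["valid"], "reason"]
        ],
        "master_seed": ens.master_seed,
        "fraction_positive_o2_change": dist.fraction_positive,
        "fraction_o2_change_25_75": dist.fraction_25_75,
        "mean_o2_change_percent": float(np.mean(dist.changes_percent)),
        "median_o2_change_percent": float(np.median(dist.changes_percent)),
    }
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2))
    files.append(report_path)
    write_manifest(out_dir, config, seed, files)
    return report


def write_trajectory_outputs(traj, out_dir: Path, config: dict, seed: int) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = write_frame(traj.frame, out_dir / "trajectory.csv")
    write_manifest(out_dir, config, seed, [path])
    return path


def write_table_outputs(
    frame: pd.DataFrame, name: str, out_dir: Path, config: dict, seed: int
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = write_frame(frame, out_dir / name)
    write_manifest(out_dir, config, seed, [path])
    return path
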