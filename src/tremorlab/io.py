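"""Plain-text file formats, run configuration and provenance manifests.

Signal files are tab-delimited text with ``#``-prefixed metadata header
lines, then ``t`` (s) and one or two acceleration columns (m/s²)::

    # tremorlab signal v1
    # sampling_rate_hz=128.0
    # subject=W001 condition=rest side=R
    t\tax\tay
    0.0000000\t0.123456789\t-0.04...

Cohort and metrics tables are TSV with one row per subject/record.  All
outputs embed the tool version, seed and a configuration hash, so a fixed
seed and config reproduce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .records import AccelRecord

SIGNAL_MAGIC = "# tremorlab signal v1"


def write_signal(record: AccelRecord, path: str | Path, extra_meta: dict | None = None) -> Path:
    path = Path(path)
    lines = [
        SIGNAL_MAGIC,
        f"# sampling_rate_hz={record.sampling_rate!r}",
        f"# subject={record.subject_id} condition={record.condition} side={record.side}",
        f"# version={__version__}",
    ]
    for key, value in (extra_meta or {}).items():
        lines.append(f"# {key}={value}")
    cols = ["t", "ax"] + (["ay"] if record.n_axes == 2 else [])
    lines.append("\t".join(cols))
    t = record.times
    for i in range(record.n_samples):
        vals = [f"{t[i]:.7f}"] + [f"{record.data[i, k]:.9g}" for k in range(record.n_axes)]
        lines.append("\t".join(vals))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_signal(path: str | Path) -> AccelRecord:
    path = Path(path)
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != SIGNAL_MAGIC:
            raise ValueError(f"{path}: not a tremorlab signal file")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].strip().split():
                    if "=" in token:
                        k, v = token.split("=", 1)
                        meta[k] = v
                continue
            if header is None:
                header = line.split("\t")
                continue
            rows.append([float(v) for v in line.split("\t")])
    if header is None or not rows:
        raise ValueError(f"{path}: no samples found")
    arr = np.asarray(rows, dtype=float)
    if arr.shape[1] != len(header) or arr.shape[1] < 2:
        raise ValueError(f"{path}: malformed sample table")
    try:
        fs = float(meta["sampling_rate_hz"])
    except (KeyError, ValueError) as exc:
        raise ValueError(f"{path}: missing or invalid sampling_rate_hz header") from exc
    return AccelRecord(
        data=arr[:, 1:],
        sampling_rate=fs,
        subject_id=meta.get("subject", ""),
        condition=meta.get("condition", "rest"),
        side=meta.get("side", "R"),
        meta=meta,
    )


def signal_filename(record: AccelRecord) -> str:
    return f"{record.subject_id}_{record.condition}_{record.side}.tsv"


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# run configuration


class ConfigError(ValueError):
    pass


_KNOWN_KEYS = {
    "seed": int,
    "n_per_group": list,
    "sampling_rate": (int, float),
    "duration": (int, float),
    "segment_seconds": (int, float),
    "overlap": (int, float),
    "cf_rest_threshold": (int, float),
    "postural_ratio_threshold": (int, float),
    "cf_postural_threshold": (int, float),
    "archetype_overrides": dict,
    "normative_table": dict,
    "log_level": str,
}


def validate_config(config: dict) -> dict:
    """Schema check of a JSON run configuration; unknown keys are rejected."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a JSON object")
    unknown = set(config) - set(_KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key, value in config.items():
        if not isinstance(value, _KNOWN_KEYS[key]):
            raise ConfigError(f"config key {key!r} has invalid type {type(value).__name__}")
    if "n_per_group" in config:
        npg = config["n_per_group"]
        if len(npg) != 3 or any((not isinstance(v, int)) or v < 1 for v in npg):
            raise ConfigError("n_per_group must be three integers >= 1")
    return config


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return validate_config(json.load(fh))


def config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_manifest(path: str | Path, seed, config: dict, outputs: list[str]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "tremorlab",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "outputs": sorted(outputs),
        "note": "fixed seed + config reproduce these outputs byte-identically",
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# normative lookup (optional user-supplied table of healthy-control values)


def load_normative_table(table: dict) -> pd.DataFrame:
    """Validate a per-age-decade normative table of healthy-control postural
    tremor (intensity mean in m/s², Cf mean in Hz).

    Expected JSON shape: {"decades": [3, 4, ...],
    "postural_intensity": [...], "postural_cf": [...]}.  Values must be
    positive and decades ordered; the table is user-supplied, never bundled.
    """
    try:
        df = pd.DataFrame(
            {
                "decade": table["decades"],
                "postural_intensity": table["postural_intensity"],
                "postural_cf": table["postural_cf"],
            }
        )
    except KeyError as exc:
        raise ConfigError(f"normative table missing key {exc}") from exc
    if not df["decade"].is_monotonic_increasing:
        raise ConfigError("normative table decades must be ordered")
    if (df[["postural_intensity", "postural_cf"]] <= 0).any().any():
        raise ConfigError("normative values must be positive")
    return df
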