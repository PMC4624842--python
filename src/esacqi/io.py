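"""CSV/TOML readers and writers binding the pipeline stages.

All exchange formats are plain text: UTF-8 CSV with a header row, "."
decimal separator, "NA" for undefined indicator values, and a provenance
comment header (``# key: value`` lines) recording package version, seed
and config hash so every output is reproducible and diffable.  Floats are
written with 6 significant digits.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from . import __version__
from .aqpa import ReferenceStandard
from .atc import normalize_panels, normalize_prescriptions

__all__ = [
    "RunConfig",
    "read_table",
    "write_table",
    "read_prescriptions",
    "read_panels",
    "read_attitudes",
    "read_reference_standard",
]

_FLOAT_FORMAT = "%.6g"


def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    provenance: Optional[Mapping[str, object]] = None,
) -> None:
    """Write a CSV with a ``#``-comment provenance header.

    The header carries only deterministic fields (version, seed, config
    hash), so re-running a stage on identical input yields identical
    bytes.
    """
    buf = _io.StringIO()
    buf.write(f"# esacqi-version: {__version__}\n")
    for key, value in (provenance or {}).items():
        buf.write(f"# {key}: {value}\n")
    frame.to_csv(buf, index=False, float_format=_FLOAT_FORMAT, na_rep="NA")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (comment lines skipped)."""
    return pd.read_csv(path, comment="#", na_values=["NA"])


def read_prescriptions(path: str | Path) -> pd.DataFrame:
    """Read and validate a prescription table (physician_id, year, month, atc, ddd_total)."""
    try:
        return normalize_prescriptions(read_table(path))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def read_panels(path: str | Path) -> pd.DataFrame:
    """Read and validate a panel table (physician_id, year, persons)."""
    try:
        return normalize_panels(read_table(path))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def read_attitudes(path: str | Path) -> pd.DataFrame:
    """Read a questionnaire table (physician_id, item_id, score, ...)."""
    frame = read_table(path)
    required = ["physician_id", "item_id", "score"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: attitude table missing columns {missing}")
    frame["physician_id"] = frame["physician_id"].astype(str)
    frame["item_id"] = frame["item_id"].astype(int)
    bad = frame.index[(frame["score"] < 0) | (frame["score"] > 10)]
    if len(bad):
        raise ValueError(f"{path}: VAS score outside [0, 10] at row(s) {list(bad[:5])}")
    if frame.duplicated(["physician_id", "item_id"]).any():
        raise ValueError(f"{path}: duplicate (physician_id, item_id) responses")
    return frame


def read_reference_standard(path: str | Path) -> ReferenceStandard:
    """Load a reference standard from CSV or a TOML ``[reference]`` block."""
    path = Path(path)
    if path.suffix == ".toml":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        block = doc.get("reference", doc)
        rows = [
            {
                "indicator": name,
                "reference_value": entry["value"],
                "better_direction": entry["better"],
            }
            for name, entry in block.items()
        ]
        return ReferenceStandard.from_frame(pd.DataFrame(rows))
    return ReferenceStandard.from_frame(read_table(path))


_KNOWN_CONFIG_KEYS = {
    "prescriptions", "panels", "attitudes", "out_dir", "seed",
    "reference", "covariates", "adjusted", "quantile_method",
    "n_physicians", "years", "verbosity",
}


@dataclass(frozen=True)
class RunConfig:
    """Pipeline run configuration loaded from TOML; unknown keys rejected."""

    prescriptions: Optional[str] = None
    panels: Optional[str] = None
    attitudes: Optional[str] = None
    out_dir: str = "."
    seed: int = 0
    reference: Optional[str] = None
    covariates: tuple[str, ...] = ("on_call", "night_shifts", "mean_panel_k")
    adjusted: bool = True
    quantile_method: str = "median_unbiased"
    n_physicians: int = 1428
    years: tuple[int, ...] = (2008, 2009, 2010)
    verbosity: str = "info"
    extras: dict = field(default_factory=dict, compare=False)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        unknown = set(doc) - _KNOWN_CONFIG_KEYS
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        kwargs = dict(doc)
        if "covariates" in kwargs:
            kwargs["covariates"] = tuple(kwargs["covariates"])
        if "years" in kwargs:
            kwargs["years"] = tuple(int(y) for y in kwargs["years"])
        cfg = cls(**kwargs)
        paths = [p for p in (cfg.prescriptions, cfg.panels, cfg.attitudes) if p]
        if len(paths) != len(set(paths)):
            raise ValueError(f"{path}: input paths must be distinct")
        return cfg

    def config_hash(self) -> str:
        payload = {
            k: v for k, v in self.__dict__.items() if k != "extras"
        }
        raw = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(raw).hexdigest()[:12]
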