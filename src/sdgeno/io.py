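"""File I/O: well tables (TSV with sidecar metadata in header comments),
truth tables, configs (YAML), calibration snapshots (JSON) and run
manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import ChannelIntensityModel, SimulationConfig
from .types import (
    ArrayData,
    TemplateKind,
    ValidationError,
    N_CHANNELS,
    WELLS_PER_CHANNEL,
    WELL_TABLE_COLUMNS,
)

_META_PREFIX = "#"


def write_well_table(array: ArrayData, path: str | Path) -> Path:
    """Write an array as TSV with its metadata in leading comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{_META_PREFIX} array_id: {array.array_id}\n")
        fh.write(f"{_META_PREFIX} template_kind: {array.template_kind.value}\n")
        cols = [c for c in array.wells.columns if c in WELL_TABLE_COLUMNS or c == "I_HEX_corr"]
        array.wells[cols].to_csv(fh, sep="\t", index=False, float_format="%.17g")
    return path


def read_well_table(path: str | Path) -> ArrayData:
    """Read a well-table TSV back into a validated :class:`ArrayData`.

    Rejects missing columns, duplicate well coordinates and out-of-range
    well indices (the chip addresses a 16 x 64 grid).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith(_META_PREFIX):
                key, _, value = line.lstrip(_META_PREFIX).partition(":")
                meta[key.strip()] = value.strip()
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        wells = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    missing = [c for c in WELL_TABLE_COLUMNS if c not in wells.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if "template_kind" not in meta:
        raise ValidationError(f"{path}: no template_kind metadata (expected '# template_kind: ...')")
    dup = wells.duplicated(subset=["well_row", "well_col"])
    if dup.any():
        first = wells.loc[dup.idxmax(), ["well_row", "well_col"]].tolist()
        raise ValidationError(f"{path}: duplicate well coordinates, first at {first}")
    rows, cols = wells["well_row"], wells["well_col"]
    if ((rows < 0) | (rows >= N_CHANNELS) | (cols < 0) | (cols >= WELLS_PER_CHANNEL)).any():
        raise ValidationError(f"{path}: well indices outside the {N_CHANNELS}x{WELLS_PER_CHANNEL} grid")
    return ArrayData(
        array_id=meta.get("array_id", path.stem),
        template_kind=TemplateKind(meta["template_kind"]),
        wells=wells,
        metadata={k: v for k, v in meta.items() if k not in ("array_id", "template_kind")},
    )


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    truth.to_csv(path, sep="\t", index=False)
    return path


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# simulation config round trip (YAML-style key-value text)


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["template_kind"] = cfg.template_kind.value
    d["zygosity_mix"] = list(cfg.zygosity_mix)
    d["intensity"] = {k: dataclasses.asdict(m) for k, m in cfg.intensity.items()}
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if "intensity" in d:
        d["intensity"] = {k: ChannelIntensityModel(**v) for k, v in d["intensity"].items()}
    if "zygosity_mix" in d:
        d["zygosity_mix"] = tuple(d["zygosity_mix"])
    return SimulationConfig(**d)


def save_config(cfg: SimulationConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
    return path


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# calibration snapshot


def save_calibration(payload: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def load_calibration(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# run manifest


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a pipeline run bit-for-bit."""

    run_id: str
    seed: int
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    package_version: str = ""
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(**d)
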