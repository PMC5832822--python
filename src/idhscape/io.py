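"""Plain-text readers/writers shared by the pipeline stages.

All tabular outputs are CSV with a fixed float format so that identical
runs produce byte-identical files; point clouds are whitespace-separated
``x y z class`` text.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

FLOAT_FORMAT = "%.10g"


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT,
              lineterminator="\n")


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_xyz(points: pd.DataFrame, path) -> None:
    """Point list as ``x y z class`` text, one point per line."""
    with open(path, "w") as fh:
        for x, y, z, c in points[["x", "y", "z", "cls"]].itertuples(index=False):
            fh.write(f"{x:.4f} {y:.4f} {z:.4f} {c}\n")


def read_xyz(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=" ", names=["x", "y", "z", "cls"])
    df["cls"] = df["cls"].astype(str)
    return df


def config_hash(config_dict: dict) -> str:
    """SHA-256 of the canonical YAML rendering of a config mapping."""
    text = yaml.safe_dump(config_dict, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()


def write_meta(path, cfg_hash: str, seed: int, outputs: list) -> None:
    """Stage sidecar recording provenance for every file the stage wrote."""
    meta = {"config_sha256": cfg_hash, "seed": seed,
            "outputs": [str(Path(o).name) for o in outputs]}
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
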