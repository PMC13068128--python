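"""File formats: hypnogram CSV, waveform HDF5/CSV, feature tables, manifests.

Documented layouts
------------------
Hypnograms: CSV with columns ``epoch_index, onset_s, stage`` (stages "W",
"N1", "N2", "N3", "R" or "W", "NREM", "R"), one row per 30 s epoch.

Waveforms: HDF5 with one group per node (``/node_<k>/inphase`` and
``/node_<k>/quadrature``) and a root attribute ``fs_hz``; or, for tiny
fixtures, a CSV with columns ``node_<k>_inphase``/``node_<k>_quadrature``
and the sampling rate in a ``# fs_hz=...`` header comment.

Feature tables: CSV with the documented header, preceded by a
``# radarsleep-feature-table v1`` schema-version comment.

Manifests: JSON (or YAML) with split membership and per-night seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .hypnogram import Hypnogram, SCHEME_AASM5, SCHEME_MERGED3
from .simulate import Cohort, RadarNight
from .config import config_to_dict, sim_config_from_dict

__all__ = [
    "save_hypnogram", "load_hypnogram",
    "save_radar_night", "load_radar_night",
    "save_feature_table", "load_feature_table",
    "save_manifest", "load_manifest",
]

FEATURE_TABLE_MAGIC = "# radarsleep-feature-table v1"


def save_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    df = pd.DataFrame({
        "epoch_index": np.arange(len(hyp)),
        "onset_s": hyp.onsets_s,
        "stage": hyp.stages,
    })
    df.to_csv(path, index=False)


def load_hypnogram(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path)
    for col in ("epoch_index", "onset_s", "stage"):
        if col not in df.columns:
            raise ValueError(f"hypnogram CSV missing column {col!r}")
    stages = df["stage"].astype(str).to_numpy(dtype=object)
    scheme = SCHEME_MERGED3 if "NREM" in set(stages) else SCHEME_AASM5
    return Hypnogram(stages, scheme)


def save_radar_night(night: RadarNight, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        cols = {}
        for k, node in enumerate(night.node_ids):
            cols[f"{node}_inphase"] = night.inphase[k]
            cols[f"{node}_quadrature"] = night.quadrature[k]
        with open(path, "w") as fh:
            fh.write(f"# fs_hz={night.fs_hz}\n")
            pd.DataFrame(cols).to_csv(fh, index=False)
        return
    with h5py.File(path, "w") as fh:
        fh.attrs["fs_hz"] = night.fs_hz
        fh.attrs["participant_id"] = night.participant_id
        for k, node in enumerate(night.node_ids):
            grp = fh.create_group(node)
            grp.create_dataset("inphase", data=night.inphase[k], compression="gzip")
            grp.create_dataset("quadrature", data=night.quadrature[k], compression="gzip")


def load_radar_night(path: str | Path) -> RadarNight:
    path = Path(path)
    if path.suffix == ".csv":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("# fs_hz="):
                raise ValueError("waveform CSV must start with '# fs_hz=...'")
            fs = float(header.split("=", 1)[1])
            df = pd.read_csv(fh)
        nodes = sorted({c.rsplit("_", 1)[0] for c in df.columns})
        inphase = np.stack([df[f"{n}_inphase"].to_numpy(float) for n in nodes])
        quadrature = np.stack([df[f"{n}_quadrature"].to_numpy(float) for n in nodes])
        return RadarNight(inphase, quadrature, fs, nodes)
    with h5py.File(path, "r") as fh:
        fs = float(fh.attrs["fs_hz"])
        pid = str(fh.attrs.get("participant_id", ""))
        nodes = sorted(fh.keys())
        inphase = np.stack([fh[n]["inphase"][...] for n in nodes])
        quadrature = np.stack([fh[n]["quadrature"][...] for n in nodes])
    return RadarNight(inphase, quadrature, fs, nodes, pid)


def save_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(FEATURE_TABLE_MAGIC + "\n")
        table.to_csv(fh, index=False)


def load_feature_table(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != FEATURE_TABLE_MAGIC:
            raise ValueError(f"not a radarsleep feature table (header {magic!r})")
        return pd.read_csv(fh)


def save_manifest(cohort: Cohort, path: str | Path, extra: dict | None = None) -> None:
    payload = {
        "nights": cohort.manifest.to_dict(orient="records"),
        "sim_config": config_to_dict(cohort.config),
    }
    if extra:
        payload.update(extra)
    path = Path(path)
    text = (yaml.safe_dump(payload, sort_keys=False) if path.suffix in (".yml", ".yaml")
            else json.dumps(payload, indent=2))
    path.write_text(text)


def load_manifest(path: str | Path) -> Cohort:
    path = Path(path)
    text = path.read_text()
    payload = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    config = sim_config_from_dict(payload["sim_config"])
    manifest = pd.DataFrame(payload["nights"])
    return Cohort(config, manifest)
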