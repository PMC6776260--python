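"""Recording containers on disk, montage selection, configs and run manifests.

Recordings travel as a channels x time numeric matrix (CSV for small files,
``.npy``/``.npz`` for runs) with a JSON sidecar holding the sampling rate and
channel names, so every artifact stays inspectable without special tooling.
EDF/FIF files are read through mne when it is installed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .model import ModelConfig, SimulationRun
from .signals import SpaceTimeMap, TimeSeriesSet

__all__ = [
    "MONTAGES",
    "RunManifest",
    "save_recording",
    "load_recording",
    "save_run",
    "load_run",
    "load_config",
    "config_hash",
]

# Electrode lines used for wave detection: the posterior-to-anterior midline
# and the left-to-right central line (a control axis with no expected
# hierarchy). "levels" keeps rows in stored order (model levels).
MONTAGES = {
    "midline": ["Oz", "POz", "Pz", "CPz", "Cz", "FCz", "Fz"],
    "central": ["C5", "C3", "C1", "Cz", "C2", "C4", "C6"],
    "levels": None,
}


@dataclass
class RunManifest:
    """Provenance record written next to every CLI/pipeline output."""

    seed: int | None
    config_hash: str
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    package_version: str = __version__
    timestamp: str = ""

    def write(self, path) -> None:
        rec = asdict(self)
        rec["timestamp"] = rec["timestamp"] or time.strftime("%Y-%m-%dT%H:%M:%S")
        Path(path).write_text(json.dumps(rec, indent=2))


def config_hash(obj) -> str:
    """Stable short hash of a config mapping or dataclass."""
    if hasattr(obj, "__dataclass_fields__"):
        obj = asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_recording(path, data: np.ndarray, fs: float, channel_names=None) -> None:
    """Write a channels x time matrix plus its JSON sidecar.

    ``.csv`` writes delimited text; ``.npy`` a binary array. The sidecar is
    ``<path>.json``.
    """
    path = Path(path)
    data = np.asarray(data, dtype=float)
    if path.suffix == ".csv":
        np.savetxt(path, data, delimiter=",")
    elif path.suffix == ".npy":
        np.save(path, data)
    else:
        raise ValueError(f"unsupported recording format {path.suffix!r} (use .csv or .npy)")
    meta = {"fs": fs, "n_channels": int(data.shape[0]), "n_samples": int(data.shape[1])}
    if channel_names is not None:
        meta["channel_names"] = list(channel_names)
    path.with_name(path.name + ".json").write_text(json.dumps(meta, indent=2))


def _load_matrix(path: Path) -> tuple[np.ndarray, dict]:
    sidecar = path.with_name(path.name + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if path.suffix == ".csv":
        data = np.loadtxt(path, delimiter=",")
    elif path.suffix == ".npy":
        data = np.load(path)
    else:
        raise ValueError(f"unsupported recording format {path.suffix!r}")
    return np.atleast_2d(np.asarray(data, dtype=float)), meta


def _load_mne(path: Path) -> tuple[np.ndarray, dict]:
    try:
        import mne
    except ImportError as e:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF/FIF recordings requires mne") from e
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_fif(path, preload=True, verbose="error")
    meta = {"fs": float(raw.info["sfreq"]), "channel_names": list(raw.ch_names)}
    return raw.get_data(), meta


def load_recording(path, montage: str | list[str] = "levels") -> SpaceTimeMap:
    """Load a recording and order its rows according to a montage.

    ``montage`` is a montage name (``midline``, ``central``, ``levels``) or an
    explicit channel-name list; matching against the file's channel labels is
    case-insensitive. A missing channel raises an error naming it and listing
    the labels that are available.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".edf", ".fif"):
        data, meta = _load_mne(path)
    else:
        data, meta = _load_matrix(path)
    if "fs" not in meta:
        raise ValueError(f"sidecar for {path} lacks the sampling rate 'fs'")

    wanted = MONTAGES.get(montage, montage) if isinstance(montage, str) else list(montage)
    names = meta.get("channel_names")
    if wanted is None:
        return SpaceTimeMap(data, float(meta["fs"]), channel_names=names)
    if isinstance(wanted, str):
        raise ValueError(f"unknown montage {montage!r}; known: {sorted(MONTAGES)}")
    if names is None:
        raise ValueError("recording has no channel names; cannot apply a montage")
    lookup = {n.lower(): i for i, n in enumerate(names)}
    rows = []
    for ch in wanted:
        if ch.lower() not in lookup:
            raise KeyError(
                f"channel {ch!r} not found in recording; available: {names}"
            )
        rows.append(lookup[ch.lower()])
    return SpaceTimeMap(data[rows], float(meta["fs"]), channel_names=list(wanted))


def save_run(out_dir, run: SimulationRun, seed: int | None = None) -> Path:
    """Persist a simulation run: traces as ``.npz``, config + manifest as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        out / "traces.npz",
        predictions=run.prediction_array(),
        residuals=np.stack([r.data for r in run.residuals], axis=1),
    )
    cfg = asdict(run.config)
    (out / "config.json").write_text(json.dumps({"config": cfg, "fs": run.fs, "meta": run.meta}, indent=2))
    RunManifest(seed=seed, config_hash=config_hash(cfg), outputs=["traces.npz", "config.json"]).write(
        out / "manifest.json"
    )
    return out


def load_run(run_dir) -> SimulationRun:
    """Inverse of :func:`save_run`."""
    run_dir = Path(run_dir)
    blob = json.loads((run_dir / "config.json").read_text())
    cfg = ModelConfig(**blob["config"])
    with np.load(run_dir / "traces.npz") as z:
        preds = z["predictions"]
        resid = z["residuals"]
    fs = blob["fs"]
    return SimulationRun(
        cfg,
        [TimeSeriesSet(preds[:, l], fs) for l in range(preds.shape[1])],
        [TimeSeriesSet(resid[:, l], fs) for l in range(resid.shape[1])],
        meta=blob.get("meta", {}),
    )


def load_config(path) -> dict:
    """Read a YAML/JSON run configuration file."""
    text = Path(path).read_text()
    return yaml.safe_load(text)
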