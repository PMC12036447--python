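"""Session bundles on disk, model checkpoints, configuration, manifests.

A session is one HDF5 file: ``/spikes`` (uint16, trials x neurons x bins),
``/wheel`` and ``/whisker`` (float32, trials x bins), ``/choice`` and
``/block`` (int8), ``/regions`` (string array), with attributes
``bin_width_s``, ``trial_length_s``, ``session_id``, ``seed`` and
``schema_version``; ground truth, when present, lives in a ``/ground_truth``
group.  Round trips are lossless.
"""

from __future__ import annotations

import hashlib
import io
import json
from pathlib import Path

import h5py
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__
from .errors import ConfigError, DataError
from .simulate import SessionBundle, SimConfig, SplitSpec
from .training import TrainConfig
from .transformer import ModelConfig, ModelState

__all__ = ["SCHEMA_VERSION", "write_session", "read_session", "FullConfig",
           "load_config", "dump_config", "save_checkpoint", "load_checkpoint",
           "write_manifest"]

SCHEMA_VERSION = 1

_DATASET_DTYPES = {
    "spikes": np.uint16,
    "wheel": np.float32,
    "whisker": np.float32,
    "choice": np.int8,
    "block": np.int8,
}


def write_session(bundle: SessionBundle, path) -> None:
    if bundle.n_trials == 0:
        raise DataError("refusing to write a session with 0 trials")
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("spikes", data=bundle.spikes.astype(np.uint16))
        f.create_dataset("wheel", data=bundle.wheel.astype(np.float32))
        f.create_dataset("whisker", data=bundle.whisker.astype(np.float32))
        f.create_dataset("choice", data=bundle.choice.astype(np.int8))
        f.create_dataset("block", data=bundle.block.astype(np.int8))
        f.create_dataset(
            "regions", data=np.asarray(bundle.region_label, dtype=h5py.string_dtype())
        )
        f.attrs["bin_width_s"] = bundle.bin_width_s
        f.attrs["trial_length_s"] = bundle.trial_length_s
        f.attrs["session_id"] = bundle.session_id
        f.attrs["seed"] = bundle.seed
        f.attrs["schema_version"] = SCHEMA_VERSION
        if bundle.ground_truth is not None:
            grp = f.create_group("ground_truth")
            for key, value in bundle.ground_truth.items():
                grp.create_dataset(key, data=np.asarray(value))


def read_session(path) -> SessionBundle:
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version is None or int(version) != SCHEMA_VERSION:
            raise DataError(
                f"{path.name}: unknown schema version {version!r} "
                f"(this reader understands version {SCHEMA_VERSION})"
            )
        for name, dtype in _DATASET_DTYPES.items():
            if name not in f:
                raise DataError(f"{path.name}: missing dataset '/{name}'")
            if f[name].dtype != dtype:
                raise DataError(
                    f"{path.name}: dataset '/{name}' has dtype {f[name].dtype}, "
                    f"expected {np.dtype(dtype)}"
                )
        if "regions" not in f:
            raise DataError(f"{path.name}: missing dataset '/regions'")
        ground_truth = None
        if "ground_truth" in f:
            ground_truth = {key: f["ground_truth"][key][()] for key in f["ground_truth"]}
        return SessionBundle(
            session_id=str(f.attrs["session_id"]),
            spikes=f["spikes"][()],
            wheel=f["wheel"][()],
            whisker=f["whisker"][()],
            choice=f["choice"][()],
            block=f["block"][()],
            region_label=f["regions"].asstr()[()],
            bin_width_s=float(f.attrs["bin_width_s"]),
            trial_length_s=float(f.attrs["trial_length_s"]),
            seed=int(f.attrs["seed"]),
            ground_truth=ground_truth,
        )


# ---------------------------------------------------------------------------
# configuration


class FullConfig(BaseModel):
    """Top-level configuration: one section per pipeline stage, every field
    defaulted, unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    simulate: SimConfig = SimConfig()
    model: ModelConfig = ModelConfig()
    training: TrainConfig = TrainConfig()
    finetune: TrainConfig = TrainConfig(epochs=30)
    split: SplitSpec = SplitSpec()


def load_config(path) -> FullConfig:
    """Parse a YAML config file; an empty file yields the full defaults."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if text.strip() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return FullConfig(**raw)
    except ValidationError as err:
        details = "; ".join(
            ".".join(str(loc) for loc in e["loc"]) + f": {e['msg']}" for e in err.errors()
        )
        raise ConfigError(f"{path}: {details}") from err


def dump_config(cfg: FullConfig, path) -> None:
    """Write the fully-resolved config next to the outputs, for provenance."""
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True))


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(state: ModelState, path) -> None:
    """Single-archive checkpoint: backbone weights, per-session modules,
    config, and the session registry (versioned)."""
    arrays = {name: p.data for name, p in state.all_parameters()}
    meta = {
        "schema_version": SCHEMA_VERSION,
        "model_config": state.cfg.model_dump(mode="json"),
        "sessions": {sid: state.sessions[sid]["n_neurons"] for sid in state.sessions},
        "history": {
            "train_loss": state.history.get("train_loss", []),
            "valid_loss": state.history.get("valid_loss", []),
            "best_epoch": state.history.get("best_epoch"),
        },
    }
    buf = io.BytesIO()
    np.savez(buf, __meta__=np.bytes_(json.dumps(meta).encode()), **arrays)
    Path(path).write_bytes(buf.getvalue())


def load_checkpoint(path) -> ModelState:
    with np.load(Path(path), allow_pickle=False) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if meta.get("schema_version") != SCHEMA_VERSION:
            raise DataError(
                f"checkpoint schema version {meta.get('schema_version')!r} not understood"
            )
        state = ModelState(ModelConfig(**meta["model_config"]))
        for sid, n_neurons in meta["sessions"].items():
            state.register_session(sid, n_neurons)
        for name, p in state.all_parameters():
            p.data = archive[name].copy()
        state.history.update(meta.get("history", {}))
    return state


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def write_manifest(path, config: FullConfig, seeds: dict[str, int],
                   inputs: list[str] | None = None) -> None:
    """Record enough to reproduce a CLI run: config hash, seeds, package
    version, and input file hashes."""
    manifest = {
        "package_version": __version__,
        "config_sha256": _sha256(
            json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
        ),
        "seeds": seeds,
        "inputs": {
            str(p): _sha256(Path(p).read_bytes()) for p in (inputs or [])
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
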