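"""Persistence of trajectories and configurations.

Frames are stored in HDF5: ``/config`` holds the serialized run
configuration (YAML text attribute), ``/frames/<j>`` holds ``z_re``,
``z_im``, ``o_<i>`` datasets with attributes t, dt, energy, power per field.
The analysis tooling reads frames without needing the model code that
produced them; a schema attribute guards against version mismatch.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np
import yaml

from .grid import GridSpec
from .integrate import FrameSet, IntegratorConfig
from .model import CouplingSpec, FieldState, ModelSpec, RealFieldSpec

SCHEMA = 1


# ---------------------------------------------------------------------------
# config serialization
# ---------------------------------------------------------------------------

def model_to_dict(model: ModelSpec) -> dict:
    d = {"r_z": model.r_z,
         "fields": [asdict(f) for f in model.fields],
         "couplings": [{"kind": c.kind, "strength": c.strength,
                        "pair": list(c.pair)} for c in model.couplings]}
    if model.grid is not None:
        d["grid"] = {"nx": model.grid.nx, "ny": model.grid.ny,
                     "lx": model.grid.lx, "ly": model.grid.ly}
    return d


def model_from_dict(d: dict) -> ModelSpec:
    grid = None
    if "grid" in d:
        grid = GridSpec(**d["grid"])
    return ModelSpec(
        r_z=d["r_z"],
        fields=tuple(RealFieldSpec(**f) for f in d.get("fields", ())),
        couplings=tuple(CouplingSpec(kind=c["kind"], strength=c["strength"],
                                     pair=tuple(c["pair"]))
                        for c in d.get("couplings", ())),
        grid=grid)


def config_to_dict(config: IntegratorConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> IntegratorConfig:
    return IntegratorConfig(**d)


def config_hash(d: dict) -> str:
    """Stable short hash of a configuration dictionary."""
    import hashlib
    payload = json.dumps(d, sort_keys=True, default=float).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# HDF5 frames
# ---------------------------------------------------------------------------

def write_frames(path, fs: FrameSet) -> None:
    """Write a FrameSet to HDF5 (layout documented in the module docstring).

    Frames are written incrementally and each frame group is complete before
    the next begins, so a reader can recover all complete frames from a
    partial file.
    """
    cfg = {"model": model_to_dict(fs.model),
           "integrator": config_to_dict(fs.config),
           "seed": fs.seed}
    with h5py.File(path, "w") as h5:
        h5.attrs["schema"] = SCHEMA
        h5.attrs["config_hash"] = config_hash(cfg)
        if fs.stationary_at is not None:
            h5.attrs["stationary_at"] = fs.stationary_at
        g = h5.create_group("config")
        g.attrs["yaml"] = yaml.safe_dump(cfg, sort_keys=True)
        grp = h5.create_group("frames")
        for j, st in enumerate(fs.frames):
            fg = grp.create_group(str(j))
            fg.create_dataset("z_re", data=st.z.real)
            fg.create_dataset("z_im", data=st.z.imag)
            for i, o in enumerate(st.os):
                fg.create_dataset(f"o_{i + 1}", data=o)
            fg.attrs["t"] = st.t
            diag = fs.diagnostics[j] if j < len(fs.diagnostics) else {}
            for key, val in diag.items():
                if isinstance(val, (int, float, bool, np.floating, np.integer)):
                    fg.attrs[key] = val
            fg.attrs["complete"] = True


def read_frames(path) -> FrameSet:
    """Read a FrameSet written by :func:`write_frames`.

    Incomplete trailing frames (missing the ``complete`` marker) are
    skipped. Raises on schema mismatch.
    """
    with h5py.File(path, "r") as h5:
        schema = int(h5.attrs.get("schema", -1))
        if schema != SCHEMA:
            raise ValueError(f"frame file schema {schema} != {SCHEMA}")
        cfg = yaml.safe_load(h5["config"].attrs["yaml"])
        model = model_from_dict(cfg["model"])
        config = config_from_dict(cfg["integrator"])
        frames = []
        diags = []
        keys = sorted(h5["frames"].keys(), key=int)
        for k in keys:
            fg = h5["frames"][k]
            if not fg.attrs.get("complete", False):
                continue
            z = fg["z_re"][()] + 1j * fg["z_im"][()]
            os_ = []
            i = 1
            while f"o_{i}" in fg:
                os_.append(fg[f"o_{i}"][()])
                i += 1
            frames.append(FieldState(float(fg.attrs["t"]), z, tuple(os_)))
            diags.append({key: fg.attrs[key] for key in fg.attrs
                          if key != "complete"})
        fs = FrameSet(frames, model, config, seed=cfg.get("seed"),
                      diagnostics=diags)
        if "stationary_at" in h5.attrs:
            fs.stationary_at = float(h5.attrs["stationary_at"])
        return fs
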