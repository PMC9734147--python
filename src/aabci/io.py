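"""Serialization: sessions, NPLS models and recursive decoder states.

Sessions are stored as a single NPZ array container (feature-tensor
stack, telemetry arrays, config snapshot as JSON) with a JSON sidecar
carrying seed and provenance; models and states are NPZ files with a
JSON header entry.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .npls import NplsModel
from .rew import RewNplsState
from .simulator import SessionStream, SimConfig

_FORMAT_VERSION = 1


def save_session(stream: SessionStream, path: str | Path) -> None:
    path = Path(path)
    header = {
        "version": _FORMAT_VERSION,
        "session_id": stream.session_id,
        "paradigm": stream.paradigm,
        "config": dataclasses.asdict(stream.config),
        "telemetry_keys": sorted(stream.telemetry),
    }
    arrays = {f"telemetry_{k}": v for k, v in stream.telemetry.items()}
    np.savez_compressed(
        path,
        header=np.array(json.dumps(header)),
        times=stream.times,
        features=stream.features,
        **arrays,
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "session_id": stream.session_id,
                "paradigm": stream.paradigm,
                "seed": stream.config.seed,
                "n_epochs": int(stream.n_epochs),
            },
            indent=2,
        )
    )


def load_session(path: str | Path) -> SessionStream:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        telemetry = {
            k: data[f"telemetry_{k}"] for k in header["telemetry_keys"]
        }
        return SessionStream(
            session_id=header["session_id"],
            paradigm=header["paradigm"],
            times=data["times"],
            features=data["features"],
            telemetry=telemetry,
            config=SimConfig(**header["config"]),
        )


def save_model(model: NplsModel, path: str | Path) -> None:
    header = {
        "version": _FORMAT_VERSION,
        "kind": "npls",
        "mode_shapes": list(model.mode_shapes),
        "n_factors": model.n_factors,
    }
    coefs = {f"coef_{k}": c for k, c in enumerate(model.coefs)}
    np.savez(
        path,
        header=np.array(json.dumps(header)),
        w_tau=model.w_tau,
        w_f=model.w_f,
        w_s=model.w_s,
        x_mean=model.x_mean,
        y_mean=model.y_mean,
        **coefs,
    )


def load_model(path: str | Path) -> NplsModel:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        n = header["n_factors"]
        return NplsModel(
            mode_shapes=tuple(header["mode_shapes"]),
            n_factors=n,
            w_tau=data["w_tau"],
            w_f=data["w_f"],
            w_s=data["w_s"],
            coefs=[data[f"coef_{k}"] for k in range(n)],
            x_mean=data["x_mean"],
            y_mean=data["y_mean"],
        )


def save_rew_state(state: RewNplsState, path: str | Path) -> None:
    header = {
        "version": _FORMAT_VERSION,
        "kind": "rew_npls",
        "mode_shapes": list(state.mode_shapes),
        "n_targets": state.n_targets,
        "lam": state.lam,
        "f_max": state.f_max,
        "n_eff": state.n_eff,
        "val_weight": state.val_weight,
        "f_star": state.f_star,
        "n_updates": state.n_updates,
        "has_model": state.model is not None,
    }
    arrays = {
        "sx": state.sx,
        "sy": state.sy,
        "sxy": state.sxy,
        "sxx": state.sxx,
        "val_errors": state.val_errors,
    }
    if state.model is not None:
        arrays.update(
            model_w_tau=state.model.w_tau,
            model_w_f=state.model.w_f,
            model_w_s=state.model.w_s,
            model_x_mean=state.model.x_mean,
            model_y_mean=state.model.y_mean,
            **{f"model_coef_{k}": c for k, c in enumerate(state.model.coefs)},
        )
        header["model_n_factors"] = state.model.n_factors
    np.savez(path, header=np.array(json.dumps(header)), **arrays)


def load_rew_state(path: str | Path) -> RewNplsState:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        model = None
        if header["has_model"]:
            n = header["model_n_factors"]
            model = NplsModel(
                mode_shapes=tuple(header["mode_shapes"]),
                n_factors=n,
                w_tau=data["model_w_tau"],
                w_f=data["model_w_f"],
                w_s=data["model_w_s"],
                coefs=[data[f"model_coef_{k}"] for k in range(n)],
                x_mean=data["model_x_mean"],
                y_mean=data["model_y_mean"],
            )
        return RewNplsState(
            mode_shapes=tuple(header["mode_shapes"]),
            n_targets=header["n_targets"],
            lam=header["lam"],
            f_max=header["f_max"],
            n_eff=header["n_eff"],
            sx=data["sx"],
            sy=data["sy"],
            sxy=data["sxy"],
            sxx=data["sxx"],
            val_errors=data["val_errors"],
            val_weight=header["val_weight"],
            f_star=header["f_star"],
            n_updates=header["n_updates"],
            model=model,
        )
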