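"""File formats: NIfTI stacks with JSON sidecars, HDF5 signal databases,
JSON network weights, and CSV exports.

The on-disk dialects are deliberately plain: a MOLLI stack is a NIfTI volume
of shape (H, W, 8) plus a JSON sidecar carrying the 8 effective TIs and the
scheme label; a signal database is an HDF5 file with datasets ``t1``, ``t2``,
``signals`` (N x 8) and ``tis``; a trained network is a JSON file holding the
weight matrices, hyperparameters and the schedule fingerprint it was trained
for.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .database import GridSpec, NoiseConfig, SignalDatabase
from .mapping import ImageStack, T1Map
from .network import PTNNRegressor, TrainedNetwork

__all__ = [
    "save_stack",
    "load_stack",
    "save_t1_map",
    "save_database",
    "load_database",
    "save_network",
    "load_network",
    "export_pulse_csv",
]


def save_stack(stack: ImageStack, nifti_path, sidecar_path=None) -> None:
    import nibabel as nib

    nifti_path = Path(nifti_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else nifti_path.with_suffix(".json")
    vol = np.moveaxis(stack.data, 0, -1)  # (H, W, 8)
    nib.save(nib.Nifti1Image(vol.astype(np.float64), affine=np.eye(4)), nifti_path)
    sidecar = {
        "effective_tis_ms": [float(t) for t in stack.effective_tis],
        "scheme": stack.scheme_label,
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=2))


def load_stack(nifti_path, sidecar_path=None) -> ImageStack:
    import nibabel as nib

    nifti_path = Path(nifti_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else nifti_path.with_suffix(".json")
    vol = np.asarray(nib.load(nifti_path).dataobj, dtype=float)
    sidecar = json.loads(Path(sidecar_path).read_text())
    return ImageStack(
        data=np.moveaxis(vol, -1, 0),
        effective_tis=np.asarray(sidecar["effective_tis_ms"], dtype=float),
        scheme_label=sidecar.get("scheme"),
    )


def save_t1_map(t1_map: T1Map, path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(t1_map.values.astype(np.float64), affine=np.eye(4)),
             Path(path))


def save_database(db: SignalDatabase, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("t1", data=db.t1)
        f.create_dataset("t2", data=db.t2)
        f.create_dataset("signals", data=db.signals)
        f.create_dataset("tis", data=db.tis)
        f.attrs["schedule_fingerprint"] = db.schedule_fingerprint
        f.attrs["normalized"] = db.normalized
        if db.grid_spec is not None:
            for k in ("t1_min", "t1_max", "t1_step", "t2_min", "t2_max", "t2_step"):
                f.attrs[f"grid_{k}"] = getattr(db.grid_spec, k)
        if db.noise_config is not None:
            f.attrs["noise_snr"] = db.noise_config.snr
            f.attrs["noise_n_instances"] = db.noise_config.n_instances
            f.attrs["noise_seed"] = db.noise_config.seed


def load_database(path) -> SignalDatabase:
    with h5py.File(path, "r") as f:
        grid = None
        if "grid_t1_min" in f.attrs:
            grid = GridSpec(**{k: float(f.attrs[f"grid_{k}"]) for k in
                               ("t1_min", "t1_max", "t1_step",
                                "t2_min", "t2_max", "t2_step")})
        noise = None
        if "noise_snr" in f.attrs:
            noise = NoiseConfig(snr=float(f.attrs["noise_snr"]),
                                n_instances=int(f.attrs["noise_n_instances"]),
                                seed=int(f.attrs["noise_seed"]))
        return SignalDatabase(
            t1=f["t1"][:], t2=f["t2"][:], signals=f["signals"][:],
            tis=f["tis"][:],
            schedule_fingerprint=str(f.attrs["schedule_fingerprint"]),
            grid_spec=grid, noise_config=noise,
            normalized=bool(f.attrs["normalized"]),
        )


def save_network(net: TrainedNetwork, path) -> None:
    payload = {
        "schedule_fingerprint": net.schedule_fingerprint,
        "seed": net.seed,
        "params": net.model.get_params(),
        "coefs": [w.tolist() for w in net.model.coefs_],
        "intercepts": [b.tolist() for b in net.model.intercepts_],
        "x_offset": net.model.x_offset_.tolist(),
        "x_scale": net.model.x_scale_.tolist(),
        "final_train_loss": getattr(net.model, "final_train_loss_", None),
        "loss_curve": net.loss_curve,
        "validation_loss_curve": net.validation_loss_curve,
    }
    payload["params"]["hidden_layer_sizes"] = list(
        payload["params"]["hidden_layer_sizes"])
    Path(path).write_text(json.dumps(payload))


def load_network(path) -> TrainedNetwork:
    payload = json.loads(Path(path).read_text())
    params = dict(payload["params"])
    params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
    model = PTNNRegressor(**params)
    model.coefs_ = [np.asarray(w, dtype=float) for w in payload["coefs"]]
    model.intercepts_ = [np.asarray(b, dtype=float) for b in payload["intercepts"]]
    model.x_offset_ = np.asarray(payload["x_offset"], dtype=float)
    model.x_scale_ = np.asarray(payload["x_scale"], dtype=float)
    model.final_train_loss_ = payload.get("final_train_loss")
    model.n_features_in_ = model.coefs_[0].shape[0]
    model.loss_curve_ = payload["loss_curve"]
    model.validation_loss_curve_ = payload["validation_loss_curve"]
    return TrainedNetwork(
        model=model,
        schedule_fingerprint=payload["schedule_fingerprint"],
        seed=payload["seed"],
        loss_curve=payload["loss_curve"],
        validation_loss_curve=payload["validation_loss_curve"],
    )


def export_pulse_csv(pulse, path) -> None:
    """Dump a pulse waveform as (time_us, amplitude, phase) CSV rows."""
    table = pulse.waveform_table()
    header = "time_us,amplitude_rad_per_s,phase_rad"
    np.savetxt(path, table, delimiter=",", header=header, comments="")
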