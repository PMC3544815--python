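"""Persistence: movies + label tracks in HDF5, cells in JSON, rasters in CSV."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .lnp import LNPCell, Nonlinearity, SpikeRaster, TemporalBasis
from .stimulus import StimulusMovie


def save_movie(path, movie: StimulusMovie, labels: np.ndarray | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=movie.frames)
        if labels is not None:
            f.create_dataset("labels", data=np.asarray(labels, dtype="S"))
        f.attrs["frame_rate"] = movie.frame_rate
        f.attrs["deg_per_pixel"] = movie.deg_per_pixel
        f.attrs["mean_luminance"] = movie.mean_luminance
        f.attrs["rms_contrast"] = movie.rms_contrast


def load_movie(path) -> tuple[StimulusMovie, np.ndarray | None]:
    with h5py.File(path, "r") as f:
        movie = StimulusMovie(
            frames=f["frames"][...],
            frame_rate=float(f.attrs["frame_rate"]),
            deg_per_pixel=float(f.attrs["deg_per_pixel"]),
            mean_luminance=float(f.attrs["mean_luminance"]),
            rms_contrast=float(f.attrs["rms_contrast"]),
        )
        labels = None
        if "labels" in f:
            labels = np.array([s.decode() for s in f["labels"][...]], dtype=object)
    return movie, labels


def cell_to_dict(cell: LNPCell) -> dict:
    nl = cell.nonlinearity
    d = {
        "rf_center": list(cell.rf_center),
        "spatial_weights": cell.spatial_weights.ravel().tolist(),  # row-major
        "temporal_coeffs": cell.temporal_coeffs.tolist(),
        "polarity": cell.polarity,
        "cell_id": cell.cell_id,
        "basis": {
            "n_basis": cell.basis.n_basis,
            "n_bins": cell.basis.n_bins,
            "bin_width": cell.basis.bin_width,
            "stretch": cell.basis.stretch,
        },
        "nonlinearity": {"kind": nl.kind, "rate_floor": nl.rate_floor},
    }
    if nl.kind == "exponential":
        d["nonlinearity"].update(gain=nl.gain, offset=nl.offset)
    else:
        d["nonlinearity"].update(knots=nl.knots.tolist(), coeffs=nl.coeffs.tolist())
    return d


def cell_from_dict(d: dict) -> LNPCell:
    from .lnp import raised_cosine_basis

    b = d["basis"]
    basis = raised_cosine_basis(n_basis=b["n_basis"], n_bins=b["n_bins"],
                                bin_width=b["bin_width"], stretch=b["stretch"])
    nd = d["nonlinearity"]
    if nd["kind"] == "exponential":
        nl = Nonlinearity(kind="exponential", gain=nd["gain"], offset=nd["offset"],
                          rate_floor=nd.get("rate_floor", 1e-3))
    else:
        nl = Nonlinearity(kind="cubic_spline", knots=np.array(nd["knots"]),
                          coeffs=np.array(nd["coeffs"]),
                          rate_floor=nd.get("rate_floor", 1e-3))
    n = b["n_bins"]
    return LNPCell(
        rf_center=tuple(d["rf_center"]),
        spatial_weights=np.array(d["spatial_weights"]).reshape(10, 10),
        temporal_coeffs=np.array(d["temporal_coeffs"]),
        basis=basis, nonlinearity=nl,
        polarity=d.get("polarity", "untyped"), cell_id=d.get("cell_id"),
    )


def save_cells(path, cells: list[LNPCell]) -> None:
    with open(path, "w") as fh:
        json.dump([cell_to_dict(c) for c in cells], fh, indent=1)


def load_cells(path) -> list[LNPCell]:
    with open(path) as fh:
        return [cell_from_dict(d) for d in json.load(fh)]


def save_raster(path, raster: SpikeRaster) -> None:
    rows = [(tr, t) for tr, spikes in enumerate(raster.trials) for t in spikes]
    df = pd.DataFrame(rows, columns=["trial", "spike_time_s"])
    df.attrs = {}
    header = f"# duration_s={raster.duration} n_trials={raster.n_trials}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def load_raster(path, cell_id: str | None = None) -> SpikeRaster:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        df = pd.read_csv(fh)
    duration = float(meta["duration_s"])
    n_trials = int(meta["n_trials"])
    trials = [np.sort(df.loc[df.trial == tr, "spike_time_s"].to_numpy())
              for tr in range(n_trials)]
    return SpikeRaster(trials=trials, duration=duration, cell_id=cell_id)


def save_labels(path, labels: np.ndarray) -> None:
    pd.DataFrame({"frame": np.arange(len(labels)), "label": labels}).to_csv(
        path, index=False)


def load_labels(path) -> np.ndarray:
    return pd.read_csv(path)["label"].to_numpy(dtype=object)
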