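"""Dataset serialisation: long-format CSV (portable) or HDF5 (large
tensors), each alongside a JSON metadata file.

A dataset bundle on disk is a directory:

    metadata.json            schema version, frame rate, onset frame,
                             stage, per-trial stimuli, per-neuron mouse
                             and neuron ids, optional config echo
    tensor.csv | tensor.h5   dF/F values; CSV is long format with columns
                             neuron,trial,frame,value
    licks.csv                optional: mouse,trial,time_s
    eye.csv                  optional: mouse,trial,frame,area
    behavior_scalars.csv     optional: mouse,trial,lick_count,blink_magnitude
    ground_truth.json        optional: generator ground truth

Values round-trip exactly in HDF5 mode and to better than 1e-12 in CSV
mode; metadata round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import BehaviorSeries
from .preprocessing import TrialTensor
from .synthetic import SCHEMA_VERSION, GroundTruth, SyntheticDataset

__all__ = ["DatasetBundle", "write_dataset", "read_dataset"]

_REQUIRED_METADATA = (
    "schema_version", "frame_rate", "onset_frame", "stage", "stimuli",
    "mouse_ids", "neuron_ids", "shape",
)


@dataclass
class DatasetBundle:
    tensor: TrialTensor
    behavior: list[BehaviorSeries] | None = None
    ground_truth: dict | None = None
    metadata: dict | None = None

    @classmethod
    def from_synthetic(cls, ds: SyntheticDataset) -> "DatasetBundle":
        gt = ds.ground_truth
        truth = {
            "archetypes": [str(a) for a in gt.archetypes],
            "shared_loadings": gt.shared_loadings.tolist(),
            "latent": None if gt.latent is None else gt.latent.tolist(),
            "change_point": gt.change_point,
            "amp_pre": None if gt.amp_pre is None else gt.amp_pre.tolist(),
            "amp_post": None if gt.amp_post is None else gt.amp_post.tolist(),
            "behavior_latent": (None if gt.behavior_latent is None
                                else gt.behavior_latent.tolist()),
        }
        cfg = dataclasses.asdict(ds.config)
        cfg["reversal_block_lengths"] = {
            k: list(v) for k, v in cfg["reversal_block_lengths"].items()}
        return cls(ds.tensor, ds.behavior, truth,
                   metadata={"config": cfg,
                             "schema_version": ds.schema_version})


def _metadata_of(bundle: DatasetBundle) -> dict:
    t = bundle.tensor
    meta = {
        "schema_version": SCHEMA_VERSION,
        "frame_rate": t.frame_rate,
        "onset_frame": int(t.onset_frame),
        "stage": t.stage,
        "stimuli": [str(s) for s in t.stimuli],
        "mouse_ids": t.mouse_ids.tolist(),
        "neuron_ids": t.neuron_ids.tolist(),
        "shape": list(t.values.shape),
    }
    if bundle.metadata:
        for k, v in bundle.metadata.items():
            if k not in meta:
                meta[k] = v
        if "schema_version" in bundle.metadata:
            meta["schema_version"] = bundle.metadata["schema_version"]
    return meta


def write_dataset(bundle: DatasetBundle | SyntheticDataset, path: str | Path,
                  fmt: str = "csv") -> Path:
    """Serialise a dataset bundle into `path` (a directory)."""
    if isinstance(bundle, SyntheticDataset):
        bundle = DatasetBundle.from_synthetic(bundle)
    if fmt not in ("csv", "hdf5"):
        raise ValueError("fmt must be 'csv' or 'hdf5'")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = _metadata_of(bundle)
    (path / "metadata.json").write_text(json.dumps(meta, indent=1))

    values = bundle.tensor.values
    if fmt == "hdf5":
        with h5py.File(path / "tensor.h5", "w") as f:
            f.create_dataset("dff", data=values)
    else:
        n, t, fr = values.shape
        idx = np.indices((n, t, fr)).reshape(3, -1)
        df = pd.DataFrame({
            "neuron": idx[0], "trial": idx[1], "frame": idx[2],
            "value": values.ravel(),
        })
        df.to_csv(path / "tensor.csv", index=False,
                  float_format="%.17g")

    if bundle.behavior is not None:
        lick_rows, eye_rows, scalar_rows = [], [], []
        for m, beh in enumerate(bundle.behavior):
            for trial, times in enumerate(beh.lick_times):
                for s in np.asarray(times, dtype=float):
                    lick_rows.append((m, trial, s))
            nt, nf = beh.eye_area.shape
            eidx = np.indices((nt, nf)).reshape(2, -1)
            eye_rows.append(pd.DataFrame({
                "mouse": m, "trial": eidx[0], "frame": eidx[1],
                "area": beh.eye_area.ravel()}))
            for trial in range(nt):
                scalar_rows.append((m, trial, beh.lick_counts[trial],
                                    beh.blink_magnitudes[trial]))
        pd.DataFrame(lick_rows, columns=["mouse", "trial", "time_s"]).to_csv(
            path / "licks.csv", index=False, float_format="%.17g")
        pd.concat(eye_rows).to_csv(path / "eye.csv", index=False,
                                   float_format="%.17g")
        pd.DataFrame(
            scalar_rows,
            columns=["mouse", "trial", "lick_count", "blink_magnitude"],
        ).to_csv(path / "behavior_scalars.csv", index=False,
                 float_format="%.17g")
        meta_beh = {
            "frame_rate": bundle.behavior[0].frame_rate,
            "cs_onset_s": bundle.behavior[0].cs_onset_s,
            "us_onset_s": bundle.behavior[0].us_onset_s,
        }
        (path / "behavior_meta.json").write_text(json.dumps(meta_beh))

    if bundle.ground_truth is not None:
        (path / "ground_truth.json").write_text(
            json.dumps(bundle.ground_truth))
    return path


def _read_csv_checked(fname: Path, dtypes: dict) -> pd.DataFrame:
    try:
        return pd.read_csv(fname, dtype=dtypes)
    except (ValueError, TypeError):
        # locate the offending cell for a useful error message
        df = pd.read_csv(fname, dtype=str)
        for col, want in dtypes.items():
            as_num = pd.to_numeric(df[col], errors="coerce")
            bad = np.flatnonzero(as_num.isna() & df[col].notna())
            if bad.size:
                line = int(bad[0]) + 2  # header + 1-based
                raise ValueError(
                    f"{fname.name}: non-numeric value in column {col!r} "
                    f"at line {line}") from None
        raise


def read_dataset(path: str | Path) -> DatasetBundle:
    """Load a dataset bundle written by `write_dataset`."""
    path = Path(path)
    meta_file = path / "metadata.json"
    if not meta_file.exists():
        raise FileNotFoundError(f"no metadata.json under {path}")
    meta = json.loads(meta_file.read_text())
    for key in _REQUIRED_METADATA:
        if key not in meta:
            raise KeyError(f"metadata.json missing required key {key!r}")
    if str(meta["schema_version"]) != SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema version {meta['schema_version']!r} "
            f"(expected {SCHEMA_VERSION!r})")
    shape = tuple(meta["shape"])

    if (path / "tensor.h5").exists():
        with h5py.File(path / "tensor.h5", "r") as f:
            values = f["dff"][()]
    elif (path / "tensor.csv").exists():
        df = _read_csv_checked(path / "tensor.csv",
                               {"neuron": int, "trial": int, "frame": int,
                                "value": float})
        values = np.empty(shape, dtype=float)
        values[df["neuron"], df["trial"], df["frame"]] = df["value"]
    else:
        raise FileNotFoundError(f"no tensor.csv or tensor.h5 under {path}")
    if values.shape != shape:
        raise ValueError(
            f"tensor shape {values.shape} inconsistent with metadata {shape}")

    tensor = TrialTensor(
        values, meta["frame_rate"], meta["onset_frame"],
        np.asarray(meta["stimuli"]), meta["stage"],
        np.asarray(meta["mouse_ids"]), np.asarray(meta["neuron_ids"]))

    behavior = None
    if (path / "behavior_scalars.csv").exists():
        bm = json.loads((path / "behavior_meta.json").read_text())
        scal = _read_csv_checked(
            path / "behavior_scalars.csv",
            {"mouse": int, "trial": int, "lick_count": float,
             "blink_magnitude": float})
        licks = _read_csv_checked(path / "licks.csv",
                                  {"mouse": int, "trial": int,
                                   "time_s": float})
        eye = _read_csv_checked(path / "eye.csv",
                                {"mouse": int, "trial": int, "frame": int,
                                 "area": float})
        behavior = []
        for m in sorted(scal["mouse"].unique()):
            sm = scal[scal["mouse"] == m].sort_values("trial")
            n_trials = len(sm)
            lt = [np.sort(licks[(licks["mouse"] == m)
                                & (licks["trial"] == t)]["time_s"].values)
                  for t in range(n_trials)]
            em = eye[eye["mouse"] == m]
            n_frames = int(em["frame"].max()) + 1
            area = np.empty((n_trials, n_frames))
            area[em["trial"], em["frame"]] = em["area"]
            behavior.append(BehaviorSeries(
                lick_times=lt, eye_area=area, frame_rate=bm["frame_rate"],
                cs_onset_s=bm["cs_onset_s"], us_onset_s=bm["us_onset_s"],
                lick_counts=sm["lick_count"].values.astype(float),
                blink_magnitudes=sm["blink_magnitude"].values.astype(float)))

    truth = None
    if (path / "ground_truth.json").exists():
        truth = json.loads((path / "ground_truth.json").read_text())
    return DatasetBundle(tensor, behavior, truth, metadata=meta)


def ground_truth_from_dict(d: dict) -> GroundTruth:
    """Rehydrate a GroundTruth read back from ground_truth.json."""
    arr = lambda x: None if x is None else np.asarray(x)  # noqa: E731
    return GroundTruth(
        archetypes=np.asarray(d["archetypes"], dtype=object),
        shared_loadings=np.asarray(d["shared_loadings"], dtype=float),
        latent=arr(d.get("latent")),
        change_point=d.get("change_point"),
        amp_pre=arr(d.get("amp_pre")),
        amp_post=arr(d.get("amp_post")),
        behavior_latent=arr(d.get("behavior_latent")),
    )
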