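"""HDF5 / CSV persistence: cohorts, window datasets, checkpoints, reports.

Layout of a cohort file::

    /subjects/<id>/radar_i, radar_q, bp_wave, displacement_mm
    /subjects/<id>/truth_{beat_time,sbp,dbp}
    attrs: radar_fs, bp_fs, scenario, seed, t0_offset, wavelength, config

Window datasets store ``channels (N, 2, L)``, labels, subject ids, window
grid indices and split tags.  Checkpoints store a model's parameter and
buffer arrays in a stable order together with the configuration hash;
loading validates every shape against a freshly constructed model.
"""

from __future__ import annotations

import json
from typing import Dict, List, Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .config import SimConfig
from .segmentation import WindowSample
from .simulate import SubjectRecord

__all__ = ["save_cohort", "load_cohort", "truth_to_csv", "save_windows",
           "load_windows", "save_checkpoint", "load_checkpoint"]


def save_cohort(records: Sequence[SubjectRecord], path) -> None:
    with h5py.File(path, "w") as f:
        root = f.create_group("subjects")
        for rec in records:
            g = root.create_group(rec.subject_id)
            g.create_dataset("radar_i", data=rec.radar_i)
            g.create_dataset("radar_q", data=rec.radar_q)
            g.create_dataset("bp_wave", data=rec.bp_wave)
            if rec.displacement_mm is not None:
                g.create_dataset("displacement_mm", data=rec.displacement_mm)
            g.create_dataset("truth_beat_time",
                             data=rec.truth["beat_time"].to_numpy())
            g.create_dataset("truth_sbp", data=rec.truth["sbp"].to_numpy())
            g.create_dataset("truth_dbp", data=rec.truth["dbp"].to_numpy())
            g.attrs["radar_fs"] = rec.radar_fs
            g.attrs["bp_fs"] = rec.bp_fs
            g.attrs["scenario"] = rec.scenario
            g.attrs["seed"] = rec.seed
            g.attrs["t0_offset"] = rec.t0_offset
            if rec.config is not None:
                g.attrs["wavelength"] = rec.config.wavelength
                g.attrs["config_json"] = json.dumps(
                    {k: list(v) if isinstance(v, tuple) else v
                     for k, v in rec.config.__dict__.items()})


def load_cohort(path) -> List[SubjectRecord]:
    records = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f["subjects"]):
            g = f["subjects"][sid]
            cfg = None
            if "config_json" in g.attrs:
                raw = json.loads(g.attrs["config_json"])
                cfg = SimConfig(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in raw.items()})
            truth = pd.DataFrame({
                "beat_time": g["truth_beat_time"][()],
                "sbp": g["truth_sbp"][()],
                "dbp": g["truth_dbp"][()]})
            records.append(SubjectRecord(
                radar_i=g["radar_i"][()], radar_q=g["radar_q"][()],
                radar_fs=float(g.attrs["radar_fs"]),
                bp_wave=g["bp_wave"][()], bp_fs=float(g.attrs["bp_fs"]),
                truth=truth, scenario=str(g.attrs["scenario"]),
                seed=int(g.attrs["seed"]),
                t0_offset=float(g.attrs["t0_offset"]),
                displacement_mm=g["displacement_mm"][()]
                if "displacement_mm" in g else None,
                subject_id=sid, config=cfg))
    return records


def truth_to_csv(records: Sequence[SubjectRecord], path) -> None:
    frames = []
    for rec in records:
        df = rec.truth.copy()
        df.insert(0, "subject_id", rec.subject_id)
        df["scenario"] = rec.scenario
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def save_windows(windows: Sequence[WindowSample], path,
                 split_tags: Optional[Sequence[str]] = None) -> None:
    tags = list(split_tags) if split_tags is not None \
        else ["unsplit"] * len(windows)
    if len(tags) != len(windows):
        raise ValueError("split tags must match window count")
    with h5py.File(path, "w") as f:
        f.create_dataset("channels",
                         data=np.stack([w.channels for w in windows]))
        f.create_dataset("sbp", data=[w.sbp_label for w in windows])
        f.create_dataset("dbp", data=[w.dbp_label for w in windows])
        f.create_dataset("subject_id",
                         data=[w.subject_id for w in windows])
        f.create_dataset("scenario", data=[w.scenario for w in windows])
        f.create_dataset("window_start_s",
                         data=[w.window_start_s for w in windows])
        f.create_dataset("window_index",
                         data=[w.window_index for w in windows])
        f.create_dataset("split", data=tags)


def load_windows(path) -> Dict[str, List[WindowSample]]:
    """Windows grouped by split tag."""
    out: Dict[str, List[WindowSample]] = {}
    with h5py.File(path, "r") as f:
        ch = f["channels"][()]
        sbp, dbp = f["sbp"][()], f["dbp"][()]
        sids = [s.decode() for s in f["subject_id"][()]]
        scen = [s.decode() for s in f["scenario"][()]]
        start = f["window_start_s"][()]
        widx = f["window_index"][()]
        tags = [s.decode() for s in f["split"][()]]
    for i, tag in enumerate(tags):
        out.setdefault(tag, []).append(WindowSample(
            channels=ch[i], sbp_label=float(sbp[i]), dbp_label=float(dbp[i]),
            subject_id=sids[i], scenario=scen[i],
            window_start_s=float(start[i]), window_index=int(widx[i])))
    return out


def save_checkpoint(model, path, config_hash: str = "", kind: str = "") -> None:
    arrays = model.state_arrays()
    with h5py.File(path, "w") as f:
        f.attrs["config_hash"] = config_hash
        f.attrs["kind"] = kind
        f.attrs["n_arrays"] = len(arrays)
        for i, a in enumerate(arrays):
            f.create_dataset(f"arr_{i:04d}", data=a)


def load_checkpoint(model, path, expected_hash: Optional[str] = None):
    """Load arrays into ``model`` with strict shape validation."""
    from .training import _set_state
    with h5py.File(path, "r") as f:
        if expected_hash is not None and f.attrs["config_hash"] != expected_hash:
            raise ValueError("checkpoint config hash mismatch")
        arrays = [f[f"arr_{i:04d}"][()] for i in range(int(f.attrs["n_arrays"]))]
    current = model.state_arrays()
    if len(arrays) != len(current):
        raise ValueError("checkpoint array count mismatch")
    for a, c in zip(arrays, current):
        if a.shape != c.shape:
            raise ValueError(f"shape mismatch {a.shape} vs {c.shape}")
    _set_state(model, arrays)
    return model
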