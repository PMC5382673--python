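"""Plain-text persistence for every pipeline artifact.

Time courses and motion travel as TSV with a JSON sidecar carrying the
sampling interval and component labels; assignments, profiles and sample
sheets are CSV; state centroids and edge lists are TSV.  All round trips
are lossless to float representation (repr-precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import MotionParams, TimeCoursePanel
from .windows import DFCSeries

_FLOAT_FMT = "%.17g"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_timecourse_table(panel: TimeCoursePanel, path) -> None:
    path = Path(path)
    df = pd.DataFrame(panel.data, columns=panel.component_ids)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    meta = {
        "tr_seconds": panel.tr_seconds,
        "subject_id": panel.subject_id,
        "component_ids": panel.component_ids,
        "subnetwork_labels": panel.subnetwork_labels,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_timecourse_table(path) -> TimeCoursePanel:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: ragged or malformed table: {e}") from e
    for ci, col in enumerate(df.columns):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric cell at row {row + 1}, column "
                f"{col!r} (column {ci + 1})")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in time-course table")
    if list(df.columns) != list(meta["component_ids"]):
        raise ValueError(
            f"{path}: header does not match sidecar component ids "
            f"({len(df.columns)} vs {len(meta['component_ids'])})")
    return TimeCoursePanel(data=df.to_numpy(float),
                           tr_seconds=float(meta["tr_seconds"]),
                           component_ids=list(meta["component_ids"]),
                           subnetwork_labels=list(meta["subnetwork_labels"]),
                           subject_id=str(meta.get("subject_id", "")))


def write_motion_table(motion: MotionParams, path) -> None:
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    pd.DataFrame(motion.data, columns=cols).to_csv(
        Path(path), sep="\t", index=False, float_format=_FLOAT_FMT)


def read_motion_table(path, subject_id: str = "") -> MotionParams:
    df = pd.read_csv(Path(path), sep="\t")
    if df.shape[1] != 6:
        raise ValueError(f"{path}: motion table must have 6 columns, "
                         f"found {df.shape[1]}")
    return MotionParams(df.to_numpy(float), subject_id=subject_id)


def write_dfc_series(series: DFCSeries, path) -> None:
    path = Path(path)
    np.savetxt(path, series.values, delimiter="\t", fmt=_FLOAT_FMT)
    meta = {
        "window_starts": series.window_starts.tolist(),
        "rect_len": series.rect_len,
        "step": series.step,
        "n_components": series.n_components,
        "fisher_z": series.fisher_z,
        "lambda_l1": series.lambda_l1,
        "subject_id": series.subject_id,
        "component_ids": series.component_ids,
        "subnetwork_labels": series.subnetwork_labels,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_dfc_series(path) -> DFCSeries:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    values = np.loadtxt(path, delimiter="\t", ndmin=2)
    return DFCSeries(values=values,
                     window_starts=np.asarray(meta["window_starts"]),
                     rect_len=meta["rect_len"], step=meta["step"],
                     n_components=meta["n_components"],
                     fisher_z=meta["fisher_z"],
                     lambda_l1=meta["lambda_l1"],
                     subject_id=meta["subject_id"],
                     component_ids=meta["component_ids"],
                     subnetwork_labels=meta["subnetwork_labels"])


def write_assignments(assignments: dict[str, np.ndarray], path) -> None:
    rows = []
    for sid in sorted(assignments):
        for w, state in enumerate(assignments[sid]):
            rows.append({"subject_id": sid, "window_index": w,
                         "state": int(state)})
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_assignments(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(Path(path))
    out = {}
    for sid, grp in df.groupby("subject_id"):
        grp = grp.sort_values("window_index")
        out[str(sid)] = grp["state"].to_numpy(int)
    return out


def write_edge_list(adjacency: np.ndarray, node_ids, path) -> None:
    iu = np.triu_indices(len(node_ids), 1)
    rows = [{"node_i": node_ids[i], "node_j": node_ids[j],
             "weight": adjacency[i, j]}
            for i, j in zip(*iu) if adjacency[i, j] != 0]
    pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]).to_csv(
        Path(path), sep="\t", index=False, float_format=_FLOAT_FMT)


def write_ground_truth(truths, path) -> None:
    payload = {
        sid: {
            "state_sequence": gt.state_sequence.tolist(),
            "transition_count": int(gt.transition_count),
            "occupancy": gt.occupancy.tolist(),
        } for sid, gt in truths.items()
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path) -> dict:
    from .simulate import GroundTruth
    payload = json.loads(Path(path).read_text())
    return {sid: GroundTruth(state_sequence=np.asarray(d["state_sequence"]),
                             transition_count=d["transition_count"],
                             occupancy=np.asarray(d["occupancy"]))
            for sid, d in payload.items()}
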