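"""Cohort file I/O, trajectory validation, and tensor assembly.

A cohort is a set of *instances*: one gait cycle per (subject, week after
stroke onset), each described by six sagittal-plane trajectories on the
affected side — angle and angular velocity for hip, knee and ankle — all
time-normalized to the 0–100% gait-cycle grid with ``T`` samples.
Optionally the unaffected side and scalar spatiotemporal/clinical metadata
are attached.

The model-ready representation is an N × 6T matrix: per instance the six
channels concatenated in a recorded layout order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

JOINTS = ("hip", "knee", "ankle")
SIGNALS = ("angle", "velocity")
SIDES = ("affected", "unaffected")
VALID_WEEKS = (2, 3, 4, 6, 8, 10, 12, 24)

#: default channel order of the feature matrix: angles first, then velocities
DEFAULT_LAYOUT: tuple[tuple[str, str], ...] = (
    ("hip", "angle"),
    ("knee", "angle"),
    ("ankle", "angle"),
    ("hip", "velocity"),
    ("knee", "velocity"),
    ("ankle", "velocity"),
)

#: scalar metadata columns recognized in cohort files, in canonical order
METADATA_COLUMNS = (
    "velocity",
    "cadence",
    "stride_length",
    "step_length_aff",
    "sls_aff",
    "stance_aff",
    "step_length_unaff",
    "sls_unaff",
    "stance_unaff",
    "fma",
    "fac",
)


@dataclass
class JointTrajectory:
    """One signal of one joint over the time-normalized gait cycle."""

    joint: str
    signal: str
    samples: np.ndarray
    side: str = "affected"

    def __post_init__(self):
        if self.joint not in JOINTS:
            raise ValueError(f"unknown joint {self.joint!r}")
        if self.signal not in SIGNALS:
            raise ValueError(f"unknown signal {self.signal!r}")
        if self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"{self.joint} {self.signal}: non-finite samples")

    @property
    def T(self) -> int:
        return self.samples.size


@dataclass
class GaitInstance:
    """One subject-week gait cycle: six affected-side trajectories plus
    optional unaffected side and scalar metadata."""

    subject_id: str
    week: int
    trajectories: list[JointTrajectory]
    unaffected_trajectories: list[JointTrajectory] | None = None
    metadata: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.week not in VALID_WEEKS:
            raise ValueError(f"week {self.week} not in {VALID_WEEKS}")
        self._check_side(self.trajectories, "affected")
        if self.unaffected_trajectories is not None:
            self._check_side(self.unaffected_trajectories, "unaffected")
            if self.unaffected_trajectories[0].T != self.T:
                raise ValueError("unaffected side has a different T")

    @staticmethod
    def _check_side(trajs: list[JointTrajectory], side: str):
        keys = [(t.joint, t.signal) for t in trajs]
        expected = {(j, s) for j in JOINTS for s in SIGNALS}
        if set(keys) != expected or len(keys) != 6:
            raise ValueError(
                f"{side} side must hold exactly one trajectory per "
                f"(joint, signal); got {sorted(keys)}"
            )
        lengths = {t.T for t in trajs}
        if len(lengths) != 1:
            raise ValueError(f"trajectory lengths differ on {side} side: {lengths}")
        for t in trajs:
            if t.side != side:
                raise ValueError(f"trajectory marked {t.side!r} on {side} side")

    @property
    def T(self) -> int:
        return self.trajectories[0].T

    @property
    def instance_id(self) -> str:
        return f"{self.subject_id}_w{self.week}"

    def get(self, joint: str, signal: str, side: str = "affected") -> JointTrajectory:
        trajs = (
            self.trajectories if side == "affected" else self.unaffected_trajectories
        )
        if trajs is None:
            raise KeyError(f"no {side} trajectories on {self.instance_id}")
        for t in trajs:
            if t.joint == joint and t.signal == signal:
                return t
        raise KeyError((joint, signal, side))


@dataclass
class GaitTensor:
    """N × F feature matrix (F = 6T) with its channel layout descriptor."""

    matrix: np.ndarray
    layout: tuple[tuple[str, str], ...]
    instance_index: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if len(self.layout) != 6 or len(set(self.layout)) != 6:
            raise ValueError("layout must list the 6 (joint, signal) channels once")
        if self.matrix.shape[1] % 6 != 0:
            raise ValueError("feature count not divisible by 6 channels")
        if len(self.instance_index) != self.matrix.shape[0]:
            raise ValueError("instance_index length != number of rows")

    @property
    def n_instances(self) -> int:
        return self.matrix.shape[0]

    @property
    def T(self) -> int:
        return self.matrix.shape[1] // 6

    def channel(self, joint: str, signal: str) -> np.ndarray:
        """Slice the N × T block of one channel."""
        b = self.layout.index((joint, signal))
        return self.matrix[:, b * self.T : (b + 1) * self.T]


def compute_angular_velocity(
    angle: JointTrajectory, cycle_duration: float = 1.0
) -> JointTrajectory:
    """Derive angular velocity [deg/s] from an angle trajectory [deg].

    Central differences on the periodic cycle grid: the gait cycle is
    cyclic by construction, so the endpoints wrap.
    """
    if angle.signal != "angle":
        raise ValueError("input trajectory must be an angle signal")
    if cycle_duration <= 0:
        raise ValueError("cycle_duration must be positive")
    a = angle.samples
    h = cycle_duration / a.size
    v = (np.roll(a, -1) - np.roll(a, 1)) / (2.0 * h)
    return JointTrajectory(angle.joint, "velocity", v, side=angle.side)


def build_tensor(
    instances: list[GaitInstance],
    layout: tuple[tuple[str, str], ...] = DEFAULT_LAYOUT,
) -> GaitTensor:
    """Concatenate the six affected-side channels of every instance into
    one row each, in `layout` order."""
    if not instances:
        raise ValueError("empty instance list")
    if len(set(layout)) != len(layout):
        raise ValueError("duplicate channel in layout")
    t_set = {inst.T for inst in instances}
    if len(t_set) != 1:
        raise ValueError(f"instances have heterogeneous T: {sorted(t_set)}")
    rows = [
        np.concatenate([inst.get(j, s).samples for j, s in layout])
        for inst in instances
    ]
    return GaitTensor(
        matrix=np.vstack(rows),
        layout=tuple(layout),
        instance_index=[inst.instance_id for inst in instances],
    )


def standardize_tensor(tensor: GaitTensor) -> GaitTensor:
    """Per-feature z-scoring (columns to mean 0, sd 1; constant columns to 0)."""
    m = tensor.matrix
    mu = m.mean(axis=0)
    sd = m.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return GaitTensor((m - mu) / sd, tensor.layout, list(tensor.instance_index))


# ---------------------------------------------------------------------------
# cohort files: wide delimited text, one row per instance
# ---------------------------------------------------------------------------


def _traj_columns(T: int, side_suffix: str = "") -> list[str]:
    cols = []
    for joint, signal in DEFAULT_LAYOUT:
        cols += [f"{joint}_{signal}{side_suffix}_{k}" for k in range(T)]
    return cols


def write_cohort(instances: list[GaitInstance], path: str | Path, sep: str = ","):
    """Write a cohort to a wide delimited text file."""
    if not instances:
        raise ValueError("empty cohort")
    T = instances[0].T
    has_unaff = all(i.unaffected_trajectories is not None for i in instances)
    records = []
    for inst in instances:
        rec: dict[str, object] = {"subject_id": inst.subject_id, "week": inst.week}
        for joint, signal in DEFAULT_LAYOUT:
            tr = inst.get(joint, signal)
            for k in range(T):
                rec[f"{joint}_{signal}_{k}"] = tr.samples[k]
        if has_unaff:
            for joint, signal in DEFAULT_LAYOUT:
                tr = inst.get(joint, signal, side="unaffected")
                for k in range(T):
                    rec[f"{joint}_{signal}_unaff_{k}"] = tr.samples[k]
        for name in METADATA_COLUMNS:
            if name in inst.metadata:
                rec[name] = inst.metadata[name]
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, sep=sep, index=False)


def read_cohort(
    path: str | Path, sep: str = ",", cycle_duration: float = 1.0
) -> list[GaitInstance]:
    """Read a cohort file written in the wide format.

    Instances with a missing or non-finite channel block are dropped with a
    logged warning; an inconsistent sample count across channels is a hard
    error.  If velocity columns are absent they are derived from the angles
    by periodic central differences (present columns win).
    """
    df = pd.read_csv(path, sep=sep)
    if "subject_id" not in df.columns or "week" not in df.columns:
        raise ValueError("cohort file must have subject_id and week columns")

    def block_cols(joint, signal, suffix=""):
        prefix = f"{joint}_{signal}{suffix}_"
        cols = [c for c in df.columns if c.startswith(prefix) and c[len(prefix):].isdigit()]
        return sorted(cols, key=lambda c: int(c[len(prefix):]))

    lengths = set()
    blocks: dict[tuple, list[str]] = {}
    for suffix in ("", "_unaff"):
        for joint in JOINTS:
            for signal in SIGNALS:
                cols = block_cols(joint, signal, suffix)
                if cols:
                    blocks[(joint, signal, suffix)] = cols
                    lengths.add(len(cols))
    if not blocks:
        raise ValueError("no trajectory columns found")
    if len(lengths) != 1:
        raise ValueError(f"inconsistent T across channel blocks: {sorted(lengths)}")

    missing_angles = [
        j for j in JOINTS if (j, "angle", "") not in blocks
    ]
    if missing_angles:
        raise ValueError(f"affected-side angle block missing for: {missing_angles}")

    has_unaff = all((j, "angle", "_unaff") in blocks for j in JOINTS)

    instances: list[GaitInstance] = []
    for _, row in df.iterrows():
        sid, week = str(row["subject_id"]), int(row["week"])
        try:
            trajs = _row_side(row, blocks, "", "affected", cycle_duration)
            unaff = (
                _row_side(row, blocks, "_unaff", "unaffected", cycle_duration)
                if has_unaff
                else None
            )
            meta = {
                name: float(row[name])
                for name in METADATA_COLUMNS
                if name in df.columns and np.isfinite(row[name])
            }
            instances.append(
                GaitInstance(sid, week, trajs, unaffected_trajectories=unaff,
                             metadata=meta)
            )
        except ValueError as exc:
            logger.warning("dropping instance %s week %s: %s", sid, week, exc)
    return instances


def _row_side(row, blocks, suffix, side, cycle_duration) -> list[JointTrajectory]:
    trajs = []
    for joint in JOINTS:
        vals = row[blocks[(joint, "angle", suffix)]].to_numpy(dtype=np.float64)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"{joint} angle{suffix} block incomplete")
        angle = JointTrajectory(joint, "angle", vals, side=side)
        trajs.append(angle)
        key = (joint, "velocity", suffix)
        if key in blocks:
            vv = row[blocks[key]].to_numpy(dtype=np.float64)
            if not np.all(np.isfinite(vv)):
                raise ValueError(f"{joint} velocity{suffix} block incomplete")
            trajs.append(JointTrajectory(joint, "velocity", vv, side=side))
        else:
            trajs.append(compute_angular_velocity(angle, cycle_duration))
    return trajs


def save_tensor(tensor: GaitTensor, path: str | Path):
    """Dump the feature matrix as delimited text with a JSON layout sidecar."""
    path = Path(path)
    np.savetxt(path, tensor.matrix, delimiter=",")
    manifest = {
        "layout": [list(ch) for ch in tensor.layout],
        "instance_index": tensor.instance_index,
        "T": tensor.T,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=1))


def load_tensor(path: str | Path) -> GaitTensor:
    path = Path(path)
    matrix = np.atleast_2d(np.loadtxt(path, delimiter=","))
    manifest = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return GaitTensor(
        matrix,
        tuple(tuple(ch) for ch in manifest["layout"]),
        list(manifest["instance_index"]),
    )
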