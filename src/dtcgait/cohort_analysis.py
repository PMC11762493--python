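"""Post-hoc characterization of the selected gait groups.

Given a final grouping, this module extracts the standard sagittal
kinematic peaks per instance (hip flexion/extension over the cycle, knee
flexion/extension split at the stance/swing boundary, ankle dorsi- and
plantarflexion), tabulates per-group mean +/- sd for kinematic and
metadata features, runs classical one-way ANOVA per feature across groups,
and quantifies each group's deviation from a normative reference as the
RMSE of its mean hip/knee/ankle angle trajectories pooled over all
3T cycle points.

Sign conventions: flexion and dorsiflexion positive; peak extension is the
signed minimum (it may be positive in a collapsed arc); peak
plantarflexion is reported as the positive magnitude of the minimum ankle
angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gait_io import GaitInstance
from .synthetic_cohort import ControlReference

KINEMATIC_FEATURES = (
    "peak_hip_flexion",
    "peak_hip_extension",
    "peak_knee_flexion_stance",
    "peak_knee_extension_stance",
    "peak_knee_flexion_swing",
    "peak_knee_extension_swing",
    "peak_plantar_flexion",
    "peak_dorsiflexion",
)


@dataclass
class AnovaResult:
    feature: str
    F_value: float
    p_value: float
    df_between: int
    df_within: int
    degenerate: bool = False  # zero within-group variance with unequal means


def extract_kinematic_features(
    instance: GaitInstance,
    stance_boundary: float = 60.0,
    use_metadata_boundary: bool = True,
) -> dict[str, float]:
    """Per-instance kinematic peaks in degrees.

    Hip peaks are the max/min over the full cycle; knee peaks are windowed
    max/min over stance [0, boundary) and swing [boundary, 100]; ankle
    dorsiflexion is the cycle max and plantarflexion the magnitude of the
    cycle min.  The stance/swing boundary defaults to the canonical 60% of
    the cycle but uses the instance's measured stance percentage when that
    metadata is present.
    """
    hip = instance.get("hip", "angle").samples
    knee = instance.get("knee", "angle").samples
    ankle = instance.get("ankle", "angle").samples
    T = hip.size
    boundary = stance_boundary
    if use_metadata_boundary and "stance_aff" in instance.metadata:
        boundary = float(instance.metadata["stance_aff"])
    split = int(round(boundary / 100.0 * T))
    split = min(max(split, 1), T - 1)
    stance, swing = knee[:split], knee[split:]
    return {
        "peak_hip_flexion": float(hip.max()),
        "peak_hip_extension": float(hip.min()),
        "peak_knee_flexion_stance": float(stance.max()),
        "peak_knee_extension_stance": float(stance.min()),
        "peak_knee_flexion_swing": float(swing.max()),
        "peak_knee_extension_swing": float(swing.min()),
        "peak_plantar_flexion": float(-ankle.min()),
        "peak_dorsiflexion": float(ankle.max()),
    }


def feature_table(
    instances: list[GaitInstance],
    stance_boundary: float = 60.0,
    use_metadata_boundary: bool = True,
) -> pd.DataFrame:
    """Per-instance feature matrix: kinematic peaks plus any metadata."""
    rows = []
    for inst in instances:
        rec = dict(
            extract_kinematic_features(inst, stance_boundary, use_metadata_boundary)
        )
        rec.update(inst.metadata)
        rec["instance_id"] = inst.instance_id
        rows.append(rec)
    return pd.DataFrame(rows).set_index("instance_id")


def group_statistics(
    features: pd.DataFrame, labels: np.ndarray, group_names: list[str] | None = None
) -> pd.DataFrame:
    """Long-form per-group and overall mean +/- sd table.

    `labels` aligns with the rows of `features`; label -1 marks excluded
    instances, which are dropped.  sd uses sample (n-1) normalization; a
    group of size one reports sd 0.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != len(features):
        raise ValueError("labels length != feature rows")
    kept = labels >= 0
    feats = features.loc[kept]
    labs = labels[kept]
    groups = np.unique(labs)
    names = group_names or [_default_group_name(g) for g in groups]
    out = []
    for col in feats.columns:
        vals = feats[col].to_numpy(dtype=np.float64)
        for g, name in zip(groups, names):
            v = vals[labs == g]
            v = v[np.isfinite(v)]
            sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
            out.append({"feature": col, "group": name, "mean": float(np.mean(v)),
                        "sd": sd, "n": int(v.size)})
        vv = vals[np.isfinite(vals)]
        out.append({"feature": col, "group": "overall", "mean": float(np.mean(vv)),
                    "sd": float(np.std(vv, ddof=1)) if vv.size > 1 else 0.0,
                    "n": int(vv.size)})
    return pd.DataFrame(out)


def _default_group_name(g: int) -> str:
    return chr(ord("A") + int(g)) if 0 <= int(g) < 26 else f"G{g}"


def anova_by_group(values: np.ndarray, labels: np.ndarray,
                   feature: str = "") -> AnovaResult:
    """Classical one-way ANOVA: F = (SSB/dfB) / (SSW/dfW), upper-tail p."""
    values = np.asarray(values, dtype=np.float64)
    labels = np.asarray(labels)
    kept = (labels >= 0) & np.isfinite(values)
    values, labels = values[kept], labels[kept]
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    n = values.size
    df_between = groups.size - 1
    df_within = n - groups.size
    if df_within < 1:
        raise ValueError("no within-group degrees of freedom")
    grand = values.mean()
    ssb = sum(
        (labels == g).sum() * (values[labels == g].mean() - grand) ** 2
        for g in groups
    )
    ssw = sum(((values[labels == g] - values[labels == g].mean()) ** 2).sum()
              for g in groups)
    if ssw == 0.0:
        if ssb == 0.0:
            return AnovaResult(feature, 0.0, 1.0, df_between, df_within)
        return AnovaResult(feature, float("inf"), 0.0, df_between, df_within,
                           degenerate=True)
    F = (ssb / df_between) / (ssw / df_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return AnovaResult(feature, float(F), p, df_between, df_within)


def anova_table(
    features: pd.DataFrame, labels: np.ndarray, bonferroni: bool = False
) -> pd.DataFrame:
    """One-way ANOVA across groups for every feature column.

    Raw p-values by default; `bonferroni=True` multiplies by the number of
    tests (capped at 1).
    """
    results = [
        anova_by_group(features[col].to_numpy(dtype=np.float64), labels, col)
        for col in features.columns
    ]
    df = pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "F_value": [r.F_value for r in results],
            "p_value": [r.p_value for r in results],
            "df_between": [r.df_between for r in results],
            "df_within": [r.df_within for r in results],
        }
    )
    if bonferroni:
        df["p_value"] = np.minimum(df["p_value"] * len(df), 1.0)
    return df


def group_mean_trajectories(
    instances: list[GaitInstance],
    labels: np.ndarray,
    side: str = "affected",
    signal: str = "angle",
) -> dict[int, dict[str, tuple[np.ndarray, np.ndarray]]]:
    """Pointwise mean and sd curve per (group, joint); label -1 excluded."""
    labels = np.asarray(labels)
    if labels.shape[0] != len(instances):
        raise ValueError("labels length != instances")
    out: dict[int, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for g in np.unique(labels[labels >= 0]):
        members = [inst for inst, l in zip(instances, labels) if l == g]
        if not members:
            raise ValueError(f"empty group {g}")
        out[int(g)] = {}
        for joint in ("hip", "knee", "ankle"):
            stack = np.vstack(
                [m.get(joint, signal, side=side).samples for m in members]
            )
            out[int(g)][joint] = (stack.mean(axis=0), stack.std(axis=0, ddof=0))
    return out


def rmse_vs_control(
    group_mean: dict[str, np.ndarray] | dict[str, tuple[np.ndarray, np.ndarray]],
    control: ControlReference,
) -> float:
    """RMSE of the three mean angle curves against the normative reference,
    pooled over all 3T points (angles only)."""
    total, n = 0.0, 0
    for joint in ("hip", "knee", "ankle"):
        curve = group_mean[joint]
        if isinstance(curve, tuple):
            curve = curve[0]
        curve = np.asarray(curve, dtype=np.float64)
        ref = control.curve(joint)
        if curve.size != ref.size:
            raise ValueError(f"{joint}: length {curve.size} != control {ref.size}")
        total += float(((curve - ref) ** 2).sum())
        n += curve.size
    return float(np.sqrt(total / n))


def rmse_table(
    instances: list[GaitInstance],
    labels: np.ndarray,
    control: ControlReference,
) -> pd.DataFrame:
    """Per-group RMSE of the group-mean angle trajectories vs. the control."""
    means = group_mean_trajectories(instances, labels)
    rows = [
        {"group": _default_group_name(g),
         "rmse": rmse_vs_control(curves, control)}
        for g, curves in sorted(means.items())
    ]
    return pd.DataFrame(rows)


# -- plotting ---------------------------------------------------------------


def plot_group_trajectories(
    instances: list[GaitInstance],
    labels: np.ndarray,
    control: ControlReference | None,
    path,
    signal: str = "angle",
):
    """Mean angle trajectory per group and joint, control dashed."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    means = group_mean_trajectories(instances, labels, signal=signal)
    fig, axes = plt.subplots(1, 3, figsize=(14, 4))
    for ax, joint in zip(axes, ("hip", "knee", "ankle")):
        for g, curves in sorted(means.items()):
            mean, _ = curves[joint]
            t = np.linspace(0, 100, mean.size, endpoint=False)
            ax.plot(t, mean, label=f"Group {_default_group_name(g)}")
        if control is not None and signal == "angle":
            ref = control.curve(joint)
            t = np.linspace(0, 100, ref.size, endpoint=False)
            ax.plot(t, ref, "k--", label="control")
        ax.set_title(joint)
        ax.set_xlabel("% gait cycle")
        ax.set_ylabel("angle [deg]")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_affected_vs_unaffected(
    instances: list[GaitInstance],
    labels: np.ndarray,
    group: int,
    path,
):
    """Group-mean angle curves with +/-1 sd bands on both sides."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(14, 4))
    for side, color in (("affected", "tab:red"), ("unaffected", "tab:blue")):
        means = group_mean_trajectories(instances, labels, side=side)
        curves = means[group]
        for ax, joint in zip(axes, ("hip", "knee", "ankle")):
            mean, sd = curves[joint]
            t = np.linspace(0, 100, mean.size, endpoint=False)
            ax.plot(t, mean, color=color, label=side)
            ax.fill_between(t, mean - sd, mean + sd, color=color, alpha=0.2)
            ax.set_title(joint)
            ax.set_xlabel("% gait cycle")
            ax.set_ylabel("angle [deg]")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
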