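"""Seeded synthetic gait cohorts with known cluster structure.

The clinical cohorts this package targets cannot be redistributed, so every
downstream stage is exercised on generated data.  A cohort is built from K
*archetypes*: low-order Fourier templates per joint (hip, knee, ankle
sagittal angle curves), each a perturbation of a normative reference whose
morphology follows patterns described for hemiplegic gait — collapsed hip
flexion/extension arc, suppressed loading response, reduced peak
dorsiflexion.  Instances are drawn from an archetype by jittering amplitude
and phase, adding smooth periodic noise, and deriving angular velocities by
periodic central differences; scalar metadata (walking speed, cadence,
stride/step lengths, single-limb-support and stance percentages, FMA, FAC)
are sampled from archetype-specific means so that group-statistics tables
are meaningful.

The metadata profiles and perturbation magnitudes are package fixtures
chosen to look plausible for sub-acute post-stroke cohorts; they are not
estimates of any clinical population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .gait_io import (
    VALID_WEEKS,
    GaitInstance,
    JointTrajectory,
    compute_angular_velocity,
)

N_HARMONICS = 5

# landmark control points (% cycle, degrees) of the normative reference;
# flexion / dorsiflexion positive
_LANDMARKS = {
    "hip": [(0, 30), (10, 27), (30, 8), (50, -10), (60, -4), (72, 14), (85, 30), (95, 31)],
    "knee": [(0, 6), (8, 15), (15, 18), (40, 5), (55, 15), (72, 60), (90, 18), (97, 7)],
    "ankle": [(0, 0), (7, -5), (30, 6), (45, 10), (55, 4), (62, -18), (75, -5), (90, 2)],
}


def _fourier_eval(a0: float, a: np.ndarray, b: np.ndarray, t_pct: np.ndarray) -> np.ndarray:
    h = np.arange(1, a.size + 1)
    ang = 2.0 * np.pi * np.outer(t_pct / 100.0, h)
    return a0 + np.cos(ang) @ a + np.sin(ang) @ b


def _fit_fourier(curve: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Project a periodic curve on the first N_HARMONICS harmonics."""
    n = curve.size
    t = np.arange(n) / n
    a0 = curve.mean()
    h = np.arange(1, N_HARMONICS + 1)
    cos = np.cos(2 * np.pi * np.outer(t, h))
    sin = np.sin(2 * np.pi * np.outer(t, h))
    a = 2.0 / n * cos.T @ curve
    b = 2.0 / n * sin.T @ curve
    return float(a0), a, b


def _reference_coefficients() -> dict[str, tuple[float, np.ndarray, np.ndarray]]:
    coeffs = {}
    for joint, pts in _LANDMARKS.items():
        ts = np.array([p[0] for p in pts] + [100.0])
        ys = np.array([p[1] for p in pts] + [pts[0][1]])
        spline = CubicSpline(ts, ys, bc_type="periodic")
        fine = spline(np.linspace(0, 100, 400, endpoint=False))
        coeffs[joint] = _fit_fourier(fine)
    return coeffs


@dataclass
class ControlReference:
    """Normative (healthy-adult) hip/knee/ankle angle curves of length T."""

    hip: np.ndarray
    knee: np.ndarray
    ankle: np.ndarray

    @property
    def T(self) -> int:
        return self.hip.size

    def curve(self, joint: str) -> np.ndarray:
        return getattr(self, joint)


def make_control_reference(T: int) -> ControlReference:
    """Deterministic smooth normative gait cycle on a T-sample grid.

    Built once from landmark control points via a periodic spline and kept
    to the first five Fourier harmonics, so archetype templates at zero
    perturbation reproduce it exactly.
    """
    if T < 10:
        raise ValueError("T must be >= 10")
    t_pct = np.arange(T) * 100.0 / T
    coeffs = _reference_coefficients()
    return ControlReference(
        *(_fourier_eval(*coeffs[j], t_pct) for j in ("hip", "knee", "ankle"))
    )


@dataclass
class ArchetypeSpec:
    """Fourier template of one synthetic gait cluster plus its jitter levels."""

    cluster_id: int
    template: dict[str, tuple[float, np.ndarray, np.ndarray]]
    amplitude_sd: float = 0.05
    phase_sd: float = 1.0  # percent of cycle
    noise_sd: float = 1.0  # degrees, pointwise sd of the smooth noise
    metadata_means: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.noise_sd < 0 or self.amplitude_sd < 0 or self.phase_sd < 0:
            raise ValueError("jitter levels must be nonnegative")

    def angle_curve(self, joint: str, T: int, phase: float = 0.0,
                    amplitude: float = 1.0) -> np.ndarray:
        a0, a, b = self.template[joint]
        t_pct = np.arange(T) * 100.0 / T + phase
        return _fourier_eval(a0, amplitude * a, amplitude * b, t_pct)


@dataclass
class SyntheticCohort:
    instances: list[GaitInstance]
    true_labels: np.ndarray
    seed: int
    spec: list[ArchetypeSpec]


# perturbation vocabulary: (harmonic scale per joint, mean shift per joint),
# at full severity, echoing qualitative hemiplegic-gait morphologies
_VOCABULARY: list[dict] = [
    # elevated hip posture with markedly reduced dorsiflexion
    {"scale": {"hip": 1.05, "knee": 1.0, "ankle": 0.40}, "shift": {"hip": 10.0, "knee": 2.0, "ankle": -3.0}},
    # globally collapsed arcs: flat hip/knee/ankle, no loading response
    {"scale": {"hip": 0.45, "knee": 0.30, "ankle": 0.20}, "shift": {"hip": 6.0, "knee": -10.0, "ankle": -2.0}},
    # collapsed hip arc shifted toward extension, stiff knee in stance
    {"scale": {"hip": 0.55, "knee": 0.70, "ankle": 0.80}, "shift": {"hip": -16.0, "knee": -6.0, "ankle": 1.0}},
    # close to normative, good walker
    {"scale": {"hip": 1.0, "knee": 1.05, "ankle": 1.0}, "shift": {"hip": -4.0, "knee": 1.0, "ankle": 2.0}},
    # exaggerated hip extension arc, stiff ankle
    {"scale": {"hip": 1.35, "knee": 0.85, "ankle": 0.55}, "shift": {"hip": -8.0, "knee": 8.0, "ankle": -5.0}},
    # absent loading response, stiff knee in stance, preserved hip
    {"scale": {"hip": 0.95, "knee": 0.50, "ankle": 0.45}, "shift": {"hip": 2.0, "knee": -12.0, "ankle": -1.0}},
]

# metadata profiles per vocabulary entry: name -> (mean, sd); magnitudes
# graded with how deviant the archetype is
_METADATA_PROFILES: list[dict[str, tuple[float, float]]] = [
    {"velocity": (66.0, 12.0), "cadence": (88.0, 4.0), "stride_length": (85.0, 11.0),
     "step_length_aff": (44.0, 6.0), "sls_aff": (31.0, 3.5), "stance_aff": (65.8, 2.5),
     "step_length_unaff": (41.0, 7.0), "sls_unaff": (34.3, 2.5), "stance_unaff": (68.9, 3.5),
     "fma": (78.0, 10.0), "fac": (4.0, 0.6)},
    {"velocity": (33.0, 8.0), "cadence": (64.0, 4.0), "stride_length": (61.0, 9.0),
     "step_length_aff": (37.0, 5.0), "sls_aff": (20.6, 2.6), "stance_aff": (60.5, 2.5),
     "step_length_unaff": (25.0, 6.0), "sls_unaff": (39.5, 2.5), "stance_unaff": (79.4, 2.6),
     "fma": (57.0, 12.0), "fac": (3.4, 0.6)},
    {"velocity": (70.0, 12.0), "cadence": (76.0, 4.0), "stride_length": (95.5, 10.0),
     "step_length_aff": (47.4, 5.5), "sls_aff": (32.4, 2.3), "stance_aff": (65.4, 2.0),
     "step_length_unaff": (48.0, 4.7), "sls_unaff": (34.6, 2.0), "stance_unaff": (67.6, 2.3),
     "fma": (81.0, 8.0), "fac": (4.2, 0.4)},
    {"velocity": (85.0, 8.0), "cadence": (98.0, 4.0), "stride_length": (106.0, 7.5),
     "step_length_aff": (53.5, 3.6), "sls_aff": (34.6, 2.1), "stance_aff": (64.1, 1.3),
     "step_length_unaff": (52.6, 4.3), "sls_unaff": (35.9, 1.3), "stance_unaff": (65.4, 2.1),
     "fma": (86.0, 6.0), "fac": (4.6, 0.3)},
    {"velocity": (56.5, 14.0), "cadence": (84.0, 4.0), "stride_length": (76.0, 12.5),
     "step_length_aff": (37.4, 7.0), "sls_aff": (29.9, 4.0), "stance_aff": (68.7, 3.0),
     "step_length_unaff": (38.8, 7.0), "sls_unaff": (31.3, 3.0), "stance_unaff": (70.1, 4.0),
     "fma": (76.0, 9.0), "fac": (3.4, 0.6)},
    {"velocity": (64.7, 8.0), "cadence": (70.0, 4.0), "stride_length": (102.0, 5.0),
     "step_length_aff": (52.5, 3.0), "sls_aff": (28.5, 1.6), "stance_aff": (63.8, 2.0),
     "step_length_unaff": (50.3, 1.9), "sls_unaff": (36.2, 2.0), "stance_unaff": (71.5, 1.6),
     "fma": (84.0, 8.0), "fac": (4.2, 0.6)},
]


def make_archetypes(K: int, severity: float = 1.0, seed: int = 0,
                    noise_sd: float = 1.0, amplitude_sd: float = 0.05,
                    phase_sd: float = 1.0) -> list[ArchetypeSpec]:
    """Build K archetype templates as severity-scaled perturbations of the
    normative reference.

    severity 0 leaves every template equal to the reference; severity 1
    applies the full perturbation vocabulary.  Archetypes beyond the
    vocabulary get additional seeded random low-order perturbations so that
    templates stay pairwise distinct.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    base = _reference_coefficients()
    specs = []
    for k in range(K):
        vocab = _VOCABULARY[k % len(_VOCABULARY)]
        template = {}
        for joint in ("hip", "knee", "ankle"):
            a0, a, b = base[joint]
            scale = 1.0 + severity * (vocab["scale"][joint] - 1.0)
            shift = severity * vocab["shift"][joint]
            a_k, b_k = scale * a, scale * b
            if k >= len(_VOCABULARY):
                # extra seeded distinctness for archetypes past the vocabulary
                a_k = a_k + severity * rng.normal(0.0, 2.0, a.size)
                b_k = b_k + severity * rng.normal(0.0, 2.0, b.size)
                shift += severity * rng.normal(0.0, 4.0)
            template[joint] = (a0 + shift, a_k, b_k)
        meta = dict(_METADATA_PROFILES[k % len(_METADATA_PROFILES)])
        specs.append(
            ArchetypeSpec(
                cluster_id=k,
                template=template,
                amplitude_sd=amplitude_sd,
                phase_sd=phase_sd,
                noise_sd=noise_sd,
                metadata_means=meta,
            )
        )
    return specs


def _smooth_noise(rng: np.random.Generator, T: int, sd: float,
                  n_harm: int = 8) -> np.ndarray:
    """Smooth zero-mean periodic noise with pointwise standard deviation sd."""
    if sd == 0:
        return np.zeros(T)
    sigma_c = sd / np.sqrt(n_harm)
    a = rng.normal(0.0, sigma_c, n_harm)
    b = rng.normal(0.0, sigma_c, n_harm)
    return _fourier_eval(0.0, a, b, np.arange(T) * 100.0 / T)


def sample_cohort(specs: list[ArchetypeSpec], n_per_cluster: int = 30,
                  T: int = 100, seed: int = 0,
                  with_unaffected: bool = False) -> SyntheticCohort:
    """Draw n_per_cluster instances from each archetype.

    Angles = template with jittered amplitude and phase plus smooth noise;
    velocities derived by periodic central differences, with the cycle
    duration implied by the sampled cadence (two steps per cycle).
    """
    if not specs:
        raise ValueError("empty archetype list")
    if n_per_cluster < 1:
        raise ValueError("n_per_cluster must be >= 1")
    rng = np.random.default_rng(seed)
    ref = make_control_reference(T)
    instances, labels = [], []
    idx = 0
    for spec in specs:
        for _ in range(n_per_cluster):
            meta = {
                name: float(rng.normal(mu, sd))
                for name, (mu, sd) in spec.metadata_means.items()
            }
            if "fac" in meta:
                meta["fac"] = float(np.clip(round(meta["fac"]), 0, 5))
            cadence = meta.get("cadence", 110.0)
            duration = 120.0 / max(cadence, 30.0)  # s per gait cycle
            phase = rng.normal(0.0, spec.phase_sd)
            amplitude = 1.0 + rng.normal(0.0, spec.amplitude_sd)
            trajs = []
            for joint in ("hip", "knee", "ankle"):
                curve = spec.angle_curve(joint, T, phase=phase, amplitude=amplitude)
                curve = curve + _smooth_noise(rng, T, spec.noise_sd)
                angle = JointTrajectory(joint, "angle", curve)
                trajs += [angle, compute_angular_velocity(angle, duration)]
            unaff = None
            if with_unaffected:
                # unaffected side approximated by the normative reference
                # plus independent smooth noise
                unaff = []
                for joint in ("hip", "knee", "ankle"):
                    curve = ref.curve(joint) + _smooth_noise(rng, T, max(spec.noise_sd, 0.5))
                    angle = JointTrajectory(joint, "angle", curve, side="unaffected")
                    unaff += [angle, compute_angular_velocity(angle, duration)]
            week = int(rng.choice(VALID_WEEKS))
            instances.append(
                GaitInstance(f"S{idx:03d}", week, trajs,
                             unaffected_trajectories=unaff, metadata=meta)
            )
            labels.append(spec.cluster_id)
            idx += 1
    return SyntheticCohort(instances, np.array(labels), seed, list(specs))


def template_instance(spec: ArchetypeSpec, T: int = 100) -> GaitInstance:
    """Materialize the noise-free template of an archetype as an instance,
    with velocities at the archetype's nominal cycle duration."""
    cadence = spec.metadata_means.get("cadence", (110.0, 0.0))[0]
    duration = 120.0 / max(cadence, 30.0)
    trajs = []
    for joint in ("hip", "knee", "ankle"):
        angle = JointTrajectory(joint, "angle", spec.angle_curve(joint, T))
        trajs += [angle, compute_angular_velocity(angle, duration)]
    return GaitInstance(f"template{spec.cluster_id}", 2, trajs)
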