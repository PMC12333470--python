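"""Markov-switching keypoint simulator with known ground truth.

Generates multi-animal open-field sessions as 2D keypoint trajectories whose
behavioral structure (per-frame syllable labels, per-syllable speeds, sticky
transition matrix) is known exactly, so every downstream stage of the
pipeline can be validated without real recordings.

The generative model is deliberately minimal:

- a per-frame Markov chain over syllables with a sticky (duration-targeted)
  transition matrix;
- a constant centroid speed per syllable, with a smoothed random heading and
  reflecting arena walls;
- stable linear-autoregressive pose dynamics per syllable around a mouse-like
  body template, expressed in the egocentric frame;
- common-mode Gaussian tracking jitter calibrated so that a motionless animal
  still shows a configurable baseline velocity.

Condition transforms scale syllable speeds in proportion to their control
speed (so fast syllables lose more), bias usage, and inflate stickiness;
a velocity-only "treatment" transform undoes the speed scaling while leaving
the usage/transition effects in place.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_BODY_PARTS",
    "SyllableRepertoire",
    "ConditionTransform",
    "GroundTruth",
    "KeypointRecording",
    "build_repertoire",
    "build_transition_model",
    "apply_condition",
    "calibrate_noise",
    "lesion_transform",
    "treatment_transform",
    "sample_markov_chain",
    "simulate_session",
]

DEFAULT_BODY_PARTS = (
    "nose",
    "left_ear",
    "right_ear",
    "spine1",
    "spine2",
    "spine3",
    "tail_base",
    "tail_tip",
)

# Top-down body template in mm, nose-forward along +x; centered below.
_TEMPLATE = {
    "nose": (45.0, 0.0),
    "left_ear": (32.0, 10.0),
    "right_ear": (32.0, -10.0),
    "spine1": (20.0, 0.0),
    "spine2": (5.0, 0.0),
    "spine3": (-12.0, 0.0),
    "tail_base": (-30.0, 0.0),
    "tail_tip": (-52.0, 0.0),
}


def body_template(body_parts=DEFAULT_BODY_PARTS) -> np.ndarray:
    """Return the (parts, 2) egocentric body template, centered on its mean."""
    pts = np.array([_TEMPLATE[p] for p in body_parts], dtype=float)
    return pts - pts.mean(axis=0)


@dataclass(frozen=True)
class SyllableRepertoire:
    """Per-syllable kinematic and postural parameters.

    Attributes
    ----------
    speeds : (n,) array, mm/s, sorted descending; the slowest entry is the
        freezing-like syllable.
    ar_coefs : list of (F, F) arrays; stable (spectral radius < 1) linear
        maps on the flattened egocentric pose offsets.
    pose_noise : (n,) array, mm; per-syllable pose innovation scale.
    heading_drift : (n,) array, rad/frame; systematic turning rate.
    """

    speeds: np.ndarray
    ar_coefs: list
    pose_noise: np.ndarray
    heading_drift: np.ndarray

    @property
    def n_syllables(self) -> int:
        return len(self.speeds)

    def validate(self) -> None:
        if np.any(self.speeds < 0):
            raise ValueError("syllable speeds must be non-negative")
        for k, A in enumerate(self.ar_coefs):
            rho = np.max(np.abs(np.linalg.eigvals(A)))
            if rho >= 1.0:
                raise ValueError(f"AR dynamics of syllable {k} unstable (spectral radius {rho:.3f})")


@dataclass(frozen=True)
class ConditionTransform:
    """Parameterized perturbation of a control repertoire + transition matrix.

    ``severity = 0`` is the identity. ``restore_velocity_only`` models a
    treatment that rescues kinematics but not usage/transition structure.
    """

    severity: float = 0.0
    velocity_slope: float = 0.0
    usage_bias: np.ndarray | None = None
    stickiness_gain: float = 1.0
    restore_velocity_only: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.severity <= 1.0:
            raise ValueError(f"severity must be in [0, 1], got {self.severity}")
        if self.stickiness_gain < 1.0:
            raise ValueError("stickiness_gain must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Oracle record for a simulated session."""

    labels: np.ndarray
    transition_matrix: np.ndarray
    speeds: np.ndarray
    seed: int

    def validate(self) -> None:
        if np.any(self.labels < 0) or np.any(self.labels >= len(self.speeds)):
            raise ValueError("labels out of range")
        rows = self.transition_matrix.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")


@dataclass
class KeypointRecording:
    """Per-frame 2D keypoints with confidences, in arena coordinates (mm)."""

    body_parts: tuple
    coords: np.ndarray  # (frames, parts, 2)
    likelihood: np.ndarray  # (frames, parts)
    fps: float = 30.0
    arena_size: float = 400.0

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def validate(self, likelihood_threshold: float = 0.0) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        confident = self.likelihood >= likelihood_threshold
        if not np.all(np.isfinite(self.coords[confident])):
            raise ValueError("non-finite coordinates at confident frames")


def build_repertoire(n_syllables: int, speed_range=(0.0, 172.0), seed: int = 0) -> SyllableRepertoire:
    """Draw a repertoire whose speeds cover ``speed_range``, sorted descending.

    The endpoints of the range are always realized exactly, so index 0 is the
    fastest syllable and the last index the slowest (zero-speed / freezing-like
    when the range starts at 0).
    """
    if n_syllables < 2:
        raise ValueError("n_syllables must be >= 2")
    lo, hi = float(speed_range[0]), float(speed_range[1])
    if lo < 0 or hi < lo:
        raise ValueError("speed_range must satisfy 0 <= min <= max")
    rng = np.random.default_rng(seed)
    if n_syllables == 2:
        speeds = np.array([hi, lo])
    else:
        interior = rng.uniform(lo, hi, size=n_syllables - 2)
        speeds = np.sort(np.concatenate([[hi], interior, [lo]]))[::-1]
    F = 2 * len(DEFAULT_BODY_PARTS)
    ar_coefs = []
    for _ in range(n_syllables):
        q, _r = np.linalg.qr(rng.standard_normal((F, F)))
        rho = rng.uniform(0.6, 0.95)
        ar_coefs.append(rho * q)
    pose_noise = rng.uniform(0.3, 1.2, size=n_syllables)
    heading_drift = rng.uniform(-0.04, 0.04, size=n_syllables)
    # freezing-like syllables do not turn
    heading_drift[speeds == lo] *= 0.0 if lo == 0 else 1.0
    rep = SyllableRepertoire(speeds, ar_coefs, pose_noise, heading_drift)
    rep.validate()
    return rep


def build_transition_model(
    n_syllables: int, target_mean_duration: float, fps: float = 30.0, seed: int = 0
) -> np.ndarray:
    """Sticky row-stochastic matrix with geometric mean run length matched to target.

    ``p_stay = 1 - 1/(target_mean_duration * fps)`` so the expected run length
    of the per-frame chain equals ``target_mean_duration`` seconds; the
    off-diagonal mass is Dirichlet-distributed.
    """
    if target_mean_duration <= 1.0 / fps:
        raise ValueError("target_mean_duration must exceed one frame (1/fps)")
    p_stay = 1.0 - 1.0 / (target_mean_duration * fps)
    rng = np.random.default_rng(seed)
    P = np.zeros((n_syllables, n_syllables))
    for i in range(n_syllables):
        off = rng.dirichlet(np.ones(n_syllables - 1))
        P[i, :i] = off[:i]
        P[i, i + 1:] = off[i:]
        P[i] *= (1.0 - p_stay)
        P[i, i] = p_stay
        P[i] /= P[i].sum()
    return P


def calibrate_noise(target_baseline_speed: float, fps: float = 30.0) -> float:
    """Per-coordinate jitter s.d. (mm) producing a given motionless baseline speed.

    With i.i.d. ``N(0, sigma^2)`` jitter on each coordinate, the per-frame
    displacement of a stationary point has ``N(0, 2 sigma^2)`` components, so
    its magnitude is Rayleigh with mean ``sigma * sqrt(pi)``; solving
    ``fps * sigma * sqrt(pi) = v`` gives sigma.
    """
    if target_baseline_speed < 0:
        raise ValueError("target_baseline_speed must be >= 0")
    return target_baseline_speed / (fps * np.sqrt(np.pi))


def apply_condition(
    repertoire: SyllableRepertoire, transitions: np.ndarray, transform: ConditionTransform
):
    """Apply a condition transform, returning a new (repertoire, transitions) pair.

    Speed scaling: ``s' = s * (1 - severity * velocity_slope * s / s_max)``
    clamped at 0, so the reduction grows linearly with the control speed.
    Transition rows are re-weighted per destination by
    ``exp(severity * usage_bias)`` and the diagonal inflated by
    ``1 + severity * (stickiness_gain - 1)`` before renormalization.
    ``restore_velocity_only`` skips only the speed scaling.
    """
    transform.validate()
    s = repertoire.speeds
    sev = transform.severity
    if transform.restore_velocity_only or s.max() == 0:
        new_speeds = s.copy()
    else:
        new_speeds = np.clip(s * (1.0 - sev * transform.velocity_slope * s / s.max()), 0.0, None)
    new_rep = dataclasses.replace(repertoire, speeds=new_speeds)

    P = np.asarray(transitions, dtype=float).copy()
    if transform.usage_bias is not None:
        w = np.exp(sev * np.asarray(transform.usage_bias, dtype=float))
        P = P * w[None, :]
    gain = 1.0 + sev * (transform.stickiness_gain - 1.0)
    idx = np.arange(P.shape[0])
    P[idx, idx] *= gain
    P /= P.sum(axis=1, keepdims=True)
    return new_rep, P


def lesion_transform(
    repertoire: SyllableRepertoire,
    severity: float,
    velocity_slope: float = 0.5,
    usage_bias_scale: float = 0.8,
    stickiness_gain: float = 1.6,
) -> ConditionTransform:
    """Parkinsonian-like transform: fast syllables slow down and lose usage,
    slow syllables gain usage, and runs lengthen (fewer transitions)."""
    s = repertoire.speeds
    rel = s / s.max() if s.max() > 0 else np.zeros_like(s)
    bias = -usage_bias_scale * (2.0 * rel - 1.0)  # fast down, slow up
    return ConditionTransform(
        severity=severity,
        velocity_slope=velocity_slope,
        usage_bias=bias,
        stickiness_gain=stickiness_gain,
    )


def treatment_transform(lesion: ConditionTransform) -> ConditionTransform:
    """Velocity-only rescue of a lesion transform (usage/stickiness retained)."""
    return dataclasses.replace(lesion, restore_velocity_only=True)


def sample_markov_chain(
    P: np.ndarray, n_frames: int, rng: np.random.Generator, init: np.ndarray | None = None
) -> np.ndarray:
    """Sample a label path of length ``n_frames`` from a row-stochastic matrix."""
    K = P.shape[0]
    cdf = np.cumsum(P, axis=1)
    labels = np.empty(n_frames, dtype=np.int64)
    if init is None:
        labels[0] = rng.integers(K)
    else:
        labels[0] = rng.choice(K, p=init)
    u = rng.random(n_frames)
    for t in range(1, n_frames):
        labels[t] = np.searchsorted(cdf[labels[t - 1]], u[t])
    return labels


def sample_markov_chains(
    P: np.ndarray, n_frames: int, n_chains: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``n_chains`` independent label paths at once -> (n_chains, n_frames)."""
    K = P.shape[0]
    cdf = np.cumsum(P, axis=1)
    labels = np.empty((n_chains, n_frames), dtype=np.int64)
    labels[:, 0] = rng.integers(K, size=n_chains)
    u = rng.random((n_chains, n_frames))
    for t in range(1, n_frames):
        labels[:, t] = (cdf[labels[:, t - 1]] < u[:, t, None]).sum(axis=1)
    return labels


def _reflect(x: float, lo: float, hi: float) -> float:
    # fold a scalar into [lo, hi]
    span = hi - lo
    y = (x - lo) % (2.0 * span)
    if y > span:
        y = 2.0 * span - y
    return lo + y


def simulate_session(
    repertoire: SyllableRepertoire,
    transitions: np.ndarray,
    duration: float,
    fps: float = 30.0,
    jitter_sd: float = 0.0,
    seed: int = 0,
    arena_size: float = 400.0,
    body_parts=DEFAULT_BODY_PARTS,
    heading_sd: float = 0.06,
    wall_margin: float = 55.0,
):
    """Simulate one open-field session.

    Returns ``(KeypointRecording, GroundTruth)``. The centroid advances at the
    active syllable's speed along a smoothed random heading and is folded back
    at the walls; the pose evolves by the active syllable's AR dynamics in the
    egocentric frame; common-mode jitter is added to all keypoints so the
    extracted centroid carries exactly the calibrated tracking noise.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration * fps))
    P = np.asarray(transitions, dtype=float)
    labels = sample_markov_chain(P, n_frames, rng)

    template = body_template(body_parts)
    n_parts = len(body_parts)
    F = 2 * n_parts
    dt = 1.0 / fps

    heading = np.empty(n_frames)
    centroid = np.empty((n_frames, 2))
    offsets = np.empty((n_frames, F))
    heading[0] = rng.uniform(0, 2 * np.pi)
    centroid[0] = rng.uniform(wall_margin, arena_size - wall_margin, size=2)
    offsets[0] = 0.0

    dheads = rng.standard_normal(n_frames) * heading_sd
    innov = rng.standard_normal((n_frames, F))
    lo, hi = wall_margin, arena_size - wall_margin
    for t in range(1, n_frames):
        k = labels[t - 1]  # the step out of frame t-1 belongs to its syllable,
        # so forward-difference speeds attribute exactly to the label sequence
        h = heading[t - 1] + repertoire.heading_drift[k] + dheads[t]
        step = repertoire.speeds[k] * dt
        cx = centroid[t - 1, 0] + step * np.cos(h)
        cy = centroid[t - 1, 1] + step * np.sin(h)
        # bounce: fold the position and mirror the heading so the animal
        # turns away instead of grinding along the wall
        if cx < lo or cx > hi:
            cx = _reflect(cx, lo, hi)
            h = np.pi - h
        if cy < lo or cy > hi:
            cy = _reflect(cy, lo, hi)
            h = -h
        heading[t] = h
        centroid[t] = (cx, cy)
        kp = labels[t]  # pose at frame t evolves under frame t's syllable
        offsets[t] = repertoire.ar_coefs[kp] @ offsets[t - 1] + repertoire.pose_noise[kp] * innov[t]

    # egocentric pose = template + AR offsets, re-centered so the part-mean is
    # exactly zero (the extracted centroid then equals the simulated one).
    pose = template[None, :, :] + offsets.reshape(n_frames, n_parts, 2)
    pose -= pose.mean(axis=1, keepdims=True)

    if jitter_sd > 0:
        centroid = centroid + rng.normal(0.0, jitter_sd, size=centroid.shape)

    cos_h, sin_h = np.cos(heading), np.sin(heading)
    rot = np.empty((n_frames, 2, 2))
    rot[:, 0, 0] = cos_h
    rot[:, 0, 1] = -sin_h
    rot[:, 1, 0] = sin_h
    rot[:, 1, 1] = cos_h
    coords = np.einsum("tij,tpj->tpi", rot, pose) + centroid[:, None, :]
    np.clip(coords, 0.0, arena_size, out=coords)

    rec = KeypointRecording(
        body_parts=tuple(body_parts),
        coords=coords,
        likelihood=np.ones((n_frames, n_parts)),
        fps=fps,
        arena_size=arena_size,
    )
    truth = GroundTruth(labels=labels, transition_matrix=P, speeds=repertoire.speeds.copy(), seed=seed)
    return rec, truth
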