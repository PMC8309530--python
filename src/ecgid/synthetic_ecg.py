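"""Synthetic multi-session, multi-placement ECG cohort generator.

Each subject is a Gaussian-wave PQRST template (five waves, each with an
angular position, amplitude and width on the beat's phase circle, as in
classic dynamical ECG synthesizers) plus beat-to-beat RR variability.  A
recording is the template traversed beat by beat, with:

* **placement** effects — an amplitude gain, placement-specific additive
  sensor noise (dry finger electrodes noisier than wet wrist/chest gel
  sensors), and a mild fixed morphology perturbation standing in for the
  different projection of the cardiac vector seen at each site;
* **session** effects — a fixed per-(subject, session, placement)
  perturbation of the template parameters emulating electrode repositioning
  and physiological drift between visits, largest on the chest (broad
  placement area) and smallest on the fingers;
* **movement** artifacts — band-limited noise bursts plus amplified
  baseline wander, scaled by the proximity of the moved body part to the
  electrodes (hand movement hits wrist/finger electrodes hardest, chest
  movement barely matters anywhere but the chest).

All randomness flows from one master seed through named substreams, so a
cohort regenerates byte-identically, and the three placements of one
recording block share the same beat train (they are acquired
simultaneously).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

from .errors import EcgidError, InvalidParameterError
from .signal_prep import RawECG

__all__ = [
    "PLACEMENTS",
    "CONDITIONS",
    "SubjectTemplate",
    "AcquisitionContext",
    "CohortSpec",
    "Cohort",
    "sample_subject",
    "synthesize_recording",
    "generate_cohort",
]

PLACEMENTS = ("fingers", "wrists", "chest")
CONDITIONS = ("rest", "move_hands", "move_feet", "move_chest")

# Canonical PQRST wave parameters: angular position (rad), amplitude (mV),
# width (rad).  Population means for template sampling.
_THETA0 = np.array([-1.0472, -0.2618, 0.0, 0.2618, 1.3090])  # -60, -15, 0, 15, 75 deg
_AMP0 = np.array([0.12, -0.10, 1.00, -0.18, 0.30])
_WIDTH0 = np.array([0.25, 0.10, 0.10, 0.10, 0.40])

_WAVE_NAMES = ("P", "Q", "R", "S", "T")


@dataclass(frozen=True)
class SubjectTemplate:
    """Per-subject PQRST morphology and rhythm parameters."""

    thetas: np.ndarray  # radians, strictly increasing, in (-pi, pi]
    amps: np.ndarray  # mV
    widths: np.ndarray  # radians, > 0
    rr_mean: float  # seconds
    rr_sd: float  # seconds
    subject_id: str = ""

    def __post_init__(self) -> None:
        thetas = np.asarray(self.thetas, dtype=float)
        object.__setattr__(self, "thetas", thetas)
        object.__setattr__(self, "amps", np.asarray(self.amps, dtype=float))
        widths = np.asarray(self.widths, dtype=float)
        object.__setattr__(self, "widths", widths)
        if not np.all(np.diff(thetas) > 0):
            raise InvalidParameterError("wave positions must satisfy P < Q < R < S < T")
        if not np.all(widths > 0):
            raise InvalidParameterError("wave widths must be positive")
        if not 0.5 <= self.rr_mean <= 1.2:
            raise InvalidParameterError("mean RR must lie in [0.5, 1.2] s")

    def parameter_vector(self) -> np.ndarray:
        """Flat parameter vector used for pairwise template distances."""
        return np.concatenate([self.thetas, self.amps, self.widths, [self.rr_mean]])


@dataclass(frozen=True)
class AcquisitionContext:
    """Session / placement / condition plus the physical-effect magnitudes."""

    session: int = 1
    placement: str = "chest"
    condition: str = "rest"
    session_drift_sd: float = 0.0  # relative template perturbation (session 2)
    placement_gain: float = 1.0
    placement_noise_sd: float = 0.03  # mV
    placement_morph_sd: float = 0.0  # relative morphology perturbation per placement
    artifact_intensity: float = 0.0  # mV
    drift_seed: int = 0  # pins the per-(subject, session, placement) drift draw
    morph_seed: int = 0  # pins the per-(subject, placement) morphology draw

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise InvalidParameterError(f"unknown placement {self.placement!r}")
        if self.condition not in CONDITIONS:
            raise InvalidParameterError(f"unknown condition {self.condition!r}")


def _perturb(template: SubjectTemplate, rel_sd: float, rng: np.random.Generator) -> SubjectTemplate:
    """Multiplicative N(1, rel_sd) jitter on the morphology parameters.

    Wave ordering is preserved by perturbing the gaps between wave
    positions rather than the positions themselves.  The rhythm (RR) is
    left untouched: simultaneous placements and electrode repositioning
    change what the electrodes see, not the heartbeat itself.
    """
    if rel_sd <= 0:
        return template
    gaps = np.diff(template.thetas)
    gaps = gaps * np.abs(rng.normal(1.0, rel_sd, gaps.size))
    thetas = template.thetas[0] * rng.normal(1.0, rel_sd) + np.concatenate([[0.0], np.cumsum(gaps)])
    amps = template.amps * rng.normal(1.0, rel_sd, 5)
    widths = template.widths * np.abs(rng.normal(1.0, rel_sd, 5))
    return replace(template, thetas=thetas, amps=amps, widths=widths)


def sample_subject(
    rng: np.random.Generator,
    subject_id: str = "",
    spread: float = 0.12,
    min_distance: float = 0.35,
    existing: list[SubjectTemplate] | None = None,
    max_tries: int = 200,
) -> SubjectTemplate:
    """Draw a subject template around the canonical PQRST values.

    ``spread`` is the relative between-subject sd per parameter; a draw is
    rejected until its Euclidean parameter distance to every ``existing``
    template exceeds ``min_distance``, guaranteeing pairwise-distinguishable
    morphologies.
    """
    existing = existing or []
    for _ in range(max_tries):
        gaps = np.diff(_THETA0) * np.abs(rng.normal(1.0, spread, 4))
        thetas = _THETA0[0] * rng.normal(1.0, spread) + np.concatenate([[0.0], np.cumsum(gaps)])
        amps = _AMP0 * rng.normal(1.0, spread, 5)
        widths = _WIDTH0 * np.abs(rng.normal(1.0, spread, 5))
        rr_mean = float(np.clip(rng.normal(0.85, 0.10), 0.6, 1.1))
        rr_sd = float(np.abs(rng.normal(0.04, 0.01))) + 0.005
        candidate = SubjectTemplate(
            thetas=thetas,
            amps=amps,
            widths=np.maximum(widths, 0.02),
            rr_mean=rr_mean,
            rr_sd=rr_sd,
            subject_id=subject_id,
        )
        vec = candidate.parameter_vector()
        if all(
            np.linalg.norm(vec - other.parameter_vector()) > min_distance for other in existing
        ):
            return candidate
    raise EcgidError(
        f"could not draw a template {min_distance} away from {len(existing)} others "
        f"in {max_tries} tries"
    )


def _beat_train(rr_mean: float, rr_sd: float, duration: float, rng: np.random.Generator):
    """Cumulative beat boundary times covering [0, duration]."""
    n_beats = int(np.ceil(duration / max(rr_mean - 4 * rr_sd, 0.3))) + 4
    rr = rng.normal(rr_mean, rr_sd, n_beats)
    rr = np.clip(rr, 0.3, None)
    bounds = np.concatenate([[0.0], np.cumsum(rr)])
    while bounds[-1] < duration:
        extra = max(float(rng.normal(rr_mean, rr_sd)), 0.3)
        bounds = np.append(bounds, bounds[-1] + extra)
    return bounds


def _pqrst(template: SubjectTemplate, phase: np.ndarray) -> np.ndarray:
    ecg = np.zeros_like(phase)
    for theta, amp, width in zip(template.thetas, template.amps, template.widths):
        ecg += amp * np.exp(-((phase - theta) ** 2) / (2 * width**2))
    return ecg


def synthesize_recording(
    template: SubjectTemplate,
    ctx: AcquisitionContext,
    duration: float,
    fs: float = 500.0,
    rng: np.random.Generator | None = None,
    beat_rng: np.random.Generator | None = None,
) -> RawECG:
    """Render one labeled recording of ``round(duration * fs)`` samples.

    ``beat_rng`` drives the beat train (shared across simultaneous
    placements); ``rng`` drives noise and artifacts.  Session 2 applies the
    fixed drift perturbation seeded by ``ctx.drift_seed``; every placement
    applies its fixed morphology perturbation seeded by ``ctx.morph_seed``.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    rng = rng if rng is not None else np.random.default_rng(0)
    beat_rng = beat_rng if beat_rng is not None else rng
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    effective = template
    if ctx.placement_morph_sd > 0:
        effective = _perturb(
            effective, ctx.placement_morph_sd, np.random.default_rng(ctx.morph_seed)
        )
    if ctx.session >= 2 and ctx.session_drift_sd > 0:
        effective = _perturb(
            effective, ctx.session_drift_sd, np.random.default_rng(ctx.drift_seed)
        )

    bounds = _beat_train(effective.rr_mean, effective.rr_sd, duration, beat_rng)
    beat_idx = np.clip(np.searchsorted(bounds, t, side="right") - 1, 0, bounds.size - 2)
    rr = bounds[beat_idx + 1] - bounds[beat_idx]
    phase = 2 * np.pi * (t - bounds[beat_idx]) / rr - np.pi
    clean = _pqrst(effective, phase)

    # Baseline wander: two slow sinusoids with random phase, ~0.05 mV at rest.
    wander_scale = 0.05 * (1.0 + 8.0 * ctx.artifact_intensity)
    wander = wander_scale * (
        np.sin(2 * np.pi * 0.21 * t + rng.uniform(0, 2 * np.pi))
        + 0.6 * np.sin(2 * np.pi * 0.37 * t + rng.uniform(0, 2 * np.pi))
    )

    noise = rng.normal(0.0, ctx.placement_noise_sd, n)

    artifact = np.zeros(n)
    if ctx.artifact_intensity > 0:
        raw = rng.normal(0.0, 1.0, n)
        sos = _sig.butter(4, [2.0, min(45.0, 0.45 * fs)], btype="band", fs=fs, output="sos")
        band = _sig.sosfilt(sos, raw)
        band /= max(band.std(), 1e-12)
        # Burst envelope: random on/off epochs, ~55% duty cycle.
        env = np.zeros(n)
        pos = 0
        while pos < n:
            on = int(rng.uniform(0.3, 1.5) * fs)
            off = int(rng.uniform(0.2, 1.2) * fs)
            env[pos : pos + on] = 1.0
            pos += on + off
        env = _sig.sosfiltfilt(_sig.butter(2, 3.0, fs=fs, output="sos"), env)
        artifact = ctx.artifact_intensity * band * np.clip(env, 0.0, None)

    samples = ctx.placement_gain * clean + wander + noise + artifact
    return RawECG(
        samples=samples,
        fs=fs,
        subject_id=template.subject_id,
        session=ctx.session,
        placement=ctx.placement,
        condition=ctx.condition,
    )


def _default_artifact_table() -> dict[tuple[str, str], float]:
    """Artifact amplitude (mV) per (placement, condition).

    Encodes proximity of the moved body part to the electrodes: hand
    movement is worst at the wrists and fingers, chest movement is nearly
    harmless everywhere (the chest electrodes barely move with the torso
    relative to the heart).  The amplitudes are on the scale of the sensor
    noise, not of the ECG itself: the pipeline works on consecutive
    differences, where broadband artifact energy is amplified relative to
    the smooth cardiac waveform, so small absolute amplitudes already
    produce the large identification losses seen with proximal movement.
    """
    return {
        ("fingers", "rest"): 0.0,
        ("fingers", "move_hands"): 0.014,
        ("fingers", "move_feet"): 0.009,
        ("fingers", "move_chest"): 0.010,
        ("wrists", "rest"): 0.0,
        ("wrists", "move_hands"): 0.017,
        ("wrists", "move_feet"): 0.011,
        ("wrists", "move_chest"): 0.011,
        ("chest", "rest"): 0.0,
        ("chest", "move_hands"): 0.004,
        ("chest", "move_feet"): 0.004,
        ("chest", "move_chest"): 0.008,
    }


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for a synthetic cohort.

    Defaults mirror the emulated acquisition protocol: 20 subjects, two
    sessions two weeks apart, three simultaneous placements; session 1 is
    10 min of rest followed by three 2-min movement blocks, session 2 is
    5 min of rest; 500 Hz throughout.
    """

    n_subjects: int = 20
    fs: float = 500.0
    rest1_duration: float = 600.0  # s
    movement_duration: float = 120.0  # s
    rest2_duration: float = 300.0  # s
    seed: int = 0
    placements: tuple[str, ...] = PLACEMENTS
    movements: tuple[str, ...] = ("move_hands", "move_feet", "move_chest")
    placement_gain: dict = field(
        default_factory=lambda: {"fingers": 0.55, "wrists": 0.65, "chest": 1.0}
    )
    # Dry finger electrodes are noisiest; wet gel wrist/chest sensors cleaner.
    placement_noise_sd: dict = field(
        default_factory=lambda: {"fingers": 0.010, "wrists": 0.006, "chest": 0.004}
    )
    # Fixed per-(subject, placement) morphology perturbation (lead projection).
    placement_morph_sd: dict = field(
        default_factory=lambda: {"fingers": 0.40, "wrists": 0.30, "chest": 0.0}
    )
    # Session-to-session drift, largest on the chest (broad placement area).
    session_drift_sd: dict = field(
        default_factory=lambda: {"fingers": 0.015, "wrists": 0.09, "chest": 0.12}
    )
    artifact_intensity: dict = field(default_factory=_default_artifact_table)

    def __post_init__(self) -> None:
        for name in ("rest1_duration", "movement_duration", "rest2_duration"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.n_subjects < 1:
            raise InvalidParameterError("need at least one subject")

    def subject_ids(self) -> list[str]:
        width = max(2, len(str(self.n_subjects)))
        return [f"S{i + 1:0{width}d}" for i in range(self.n_subjects)]


@dataclass(frozen=True)
class Cohort:
    """In-memory synthetic dataset: recordings plus their design labels."""

    spec: CohortSpec
    templates: dict[str, SubjectTemplate]
    recordings: list[RawECG]

    def get(self, subject_id: str, session: int, placement: str, condition: str) -> RawECG:
        for rec in self.recordings:
            if (
                rec.subject_id == subject_id
                and rec.session == session
                and rec.placement == placement
                and rec.condition == condition
            ):
                return rec
        raise KeyError((subject_id, session, placement, condition))

    def manifest_rows(self) -> list[dict]:
        return [
            {
                "subject_id": r.subject_id,
                "session": r.session,
                "placement": r.placement,
                "condition": r.condition,
                "fs": r.fs,
                "duration": r.duration,
                "n_samples": r.samples.size,
            }
            for r in self.recordings
        ]


def _seed_for(master: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master, spawn_key=tuple(key))


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full labeled cohort deterministically from the master seed.

    Session-1 blocks are rest plus one block per movement; session 2 is rest
    only.  With default placements and movements this yields 15 recordings
    per subject.  The beat train of a block is shared across its three
    placements (simultaneous acquisition); noise, drift and morphology
    substreams are keyed by (subject, session, block, placement) so any
    single recording regenerates independently.
    """
    template_rng = np.random.default_rng(_seed_for(spec.seed, 0))
    templates: dict[str, SubjectTemplate] = {}
    existing: list[SubjectTemplate] = []
    for sid in spec.subject_ids():
        tpl = sample_subject(template_rng, subject_id=sid, existing=existing)
        templates[sid] = tpl
        existing.append(tpl)

    session_plans = {
        1: [("rest", spec.rest1_duration)]
        + [(m, spec.movement_duration) for m in spec.movements],
        2: [("rest", spec.rest2_duration)],
    }

    recordings: list[RawECG] = []
    for si, sid in enumerate(spec.subject_ids()):
        for session, plan in session_plans.items():
            for bi, (condition, dur) in enumerate(plan):
                for pi, placement in enumerate(spec.placements):
                    noise_rng = np.random.default_rng(
                        _seed_for(spec.seed, 2, si, session, bi, pi)
                    )
                    ctx = AcquisitionContext(
                        session=session,
                        placement=placement,
                        condition=condition,
                        session_drift_sd=spec.session_drift_sd[placement],
                        placement_gain=spec.placement_gain[placement],
                        placement_noise_sd=spec.placement_noise_sd[placement],
                        placement_morph_sd=spec.placement_morph_sd[placement],
                        artifact_intensity=spec.artifact_intensity[(placement, condition)],
                        drift_seed=int(
                            _seed_for(spec.seed, 3, si, session, pi).generate_state(1)[0]
                        ),
                        morph_seed=int(_seed_for(spec.seed, 4, si, pi).generate_state(1)[0]),
                    )
                    # Fresh generator from the same block seed per placement:
                    # simultaneous placements share one beat train.
                    beat_rng = np.random.default_rng(_seed_for(spec.seed, 1, si, session, bi))
                    recordings.append(
                        synthesize_recording(
                            templates[sid],
                            ctx,
                            duration=dur,
                            fs=spec.fs,
                            rng=noise_rng,
                            beat_rng=beat_rng,
                        )
                    )
    return Cohort(spec=spec, templates=templates, recordings=recordings)
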