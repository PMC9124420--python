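"""Synthetic multi-subject MoCap cohorts with planted FOG episodes.

The generator emulates the structure of a standardized gait-lab FOG
protocol: multiple variable-length trials per subject at 100 Hz, a 9-marker
lower-limb configuration, quasi-periodic gait oscillations, and FOG
episodes of sub-second to multi-second duration whose boundaries fall at
gait-event-like instants.  It makes no claim of biomechanical fidelity —
its purpose is to provide trainable, fully annotated data with the same
shape and label statistics as the real protocol.

Kinematic model (per trial, in the velocity domain, then integrated):

* the pelvis cluster (sacrum, both ASIS) progresses forward at the
  subject's walking speed with lateral sway and vertical bounce at the
  stride/cadence frequencies;
* leg markers (knee, ankle, toe) superimpose two harmonics of the stride
  frequency, amplitudes growing distally, the two legs half a cycle out of
  phase;
* during a planted FOG episode the forward progression of the leg markers
  collapses to approximately zero.  The *akinetic* freeze style suppresses
  the oscillation as well; the *trembling* style replaces it with
  low-amplitude 3-8 Hz shank oscillation on the ankle/toe markers;
* episode onsets/offsets are snapped to zero-crossings of the stride
  oscillation (gait-event-like anchoring), and additive Gaussian marker
  noise is applied to the positions.

Within planted FOG intervals the mean forward displacement of the toe
markers stays below 20% of the non-FOG mean (asserted by the test-suite) so
the planted labels are physically coupled to the kinematics.

A cohort draws per-subject gait parameters once, generates every trial from
a seed-derived stream (the seed fully determines the cohort), and records
all planted episodes in a manifest — the synthetic stand-in for the expert
annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .graph import DEFAULT_NODE_NAMES
from .io import MarkerTrial, events_to_labels

__all__ = ["GaitParams", "FogParams", "CohortSpec", "generate_trial",
           "generate_cohort", "plan_episodes"]


class EpisodePlanError(ValueError):
    """Planted FOG episodes overlap or fall outside the trial."""


@dataclass
class GaitParams:
    """Per-subject gait characteristics."""

    cadence_hz: float = 1.8          # steps/s; stride frequency = cadence/2
    step_amplitude_mm: float = 220.0  # forward swing amplitude at the toe
    walking_speed_mm_s: float = 1100.0
    stance_asymmetry: float = 0.0    # relative left/right amplitude imbalance
    noise_sd_mm: float = 1.5         # additive marker noise SD


@dataclass
class FogParams:
    """Per-subject FOG episode statistics."""

    episode_probability: float = 0.8   # P(a trial contains >= 1 episode)
    episodes_per_trial: float = 1.6    # mean of a shifted-Poisson count
    duration_log_mean: float = 0.7     # log-normal, median ~2 s
    duration_log_sd: float = 0.8
    duration_range_s: tuple = (0.3, 15.0)
    freeze_style: str = "akinetic"     # or "trembling"
    trembling_band_hz: tuple = (3.0, 8.0)


@dataclass
class CohortSpec:
    """Cohort-level generation parameters; the seed determines everything."""

    n_subjects: int = 10
    trials_per_subject: int = 5
    rate_hz: float = 100.0
    trial_duration_s: tuple = (15.0, 25.0)
    nonfreezer_fraction: float = 0.3
    seed: int = 0
    marker_names: tuple = tuple(DEFAULT_NODE_NAMES)


def plan_episodes(n_samples: int, rate_hz: float, fog: FogParams, rng) -> list:
    """Draw non-overlapping (onset, offset) half-open episode intervals."""
    if rng.uniform() >= fog.episode_probability:
        return []
    count = 1 + rng.poisson(max(fog.episodes_per_trial - 1.0, 0.0))
    lo, hi = fog.duration_range_s
    episodes = []
    margin = int(0.5 * rate_hz)              # keep gait at the trial edges
    free = [(margin, n_samples - margin)]
    for _ in range(count):
        dur_s = float(np.clip(rng.lognormal(fog.duration_log_mean,
                                            fog.duration_log_sd), lo, hi))
        dur = int(round(dur_s * rate_hz))
        fits = [iv for iv in free if iv[1] - iv[0] >= dur + 2 * margin]
        if not fits:
            continue
        s0, s1 = fits[rng.integers(len(fits))]
        onset = int(rng.integers(s0 + margin, s1 - margin - dur + 1))
        episodes.append((onset, onset + dur))
        free.remove((s0, s1))
        free.extend([(s0, onset), (onset + dur, s1)])
    episodes.sort()
    for (a0, a1), (b0, b1) in zip(episodes, episodes[1:]):
        if a1 > b0:
            raise EpisodePlanError("planted episodes overlap")
    return episodes


def _snap_to_zero_crossings(episodes, phase, n_samples):
    """Snap boundaries to gait-event-like instants.

    Candidate instants are the zero-crossings (both directions, roughly two
    per stride cycle) of the stride oscillation.  The onset moves to its
    nearest crossing and the offset to the nearest crossing strictly after
    the onset, so no episode collapses below one half-cycle.
    """
    s = np.sin(phase)
    zc = np.flatnonzero(np.signbit(s[:-1]) != np.signbit(s[1:])) + 1
    if len(zc) < 2:
        return episodes
    out = []
    for onset, offset in episodes:
        on = int(zc[np.abs(zc - onset).argmin()])
        later = zc[zc > on]
        if len(later) == 0:
            continue
        off = int(later[np.abs(later - offset).argmin()])
        out.append((max(0, on), min(off, n_samples)))
    # snapping may merge close episodes; drop overlaps conservatively
    merged = []
    for ep in out:
        if merged and ep[0] < merged[-1][1]:
            continue
        merged.append(ep)
    return merged


# marker layout constants: static offsets from the pelvis origin (mm) and
# oscillation amplitude scales relative to the toe swing
_OFFSETS = {
    "SACR": (0.0, 0.0, 980.0),
    "LASI": (-120.0, 80.0, 960.0), "RASI": (120.0, 80.0, 960.0),
    "LKNE": (-110.0, 30.0, 500.0), "RKNE": (110.0, 30.0, 500.0),
    "LANK": (-110.0, -30.0, 90.0), "RANK": (110.0, -30.0, 90.0),
    "LTOE": (-100.0, 80.0, 40.0), "RTOE": (100.0, 80.0, 40.0),
}
_SWING_SCALE = {"SACR": 0.0, "LASI": 0.05, "RASI": 0.05,
                "LKNE": 0.45, "RKNE": 0.45, "LANK": 0.85, "RANK": 0.85,
                "LTOE": 1.0, "RTOE": 1.0}
_LEG_SIGN = {"L": 0.0, "R": np.pi}   # legs half a cycle out of phase


def generate_trial(gait: GaitParams, episodes, n_samples: int,
                   rate_hz: float = 100.0, fog: FogParams = None,
                   subject_id: str = "S1", trial_id: str = "T1",
                   seed=None, rng=None,
                   marker_names=tuple(DEFAULT_NODE_NAMES)) -> MarkerTrial:
    """Generate one trial with the given planted FOG ``episodes``.

    ``episodes`` is a list of half-open (onset, offset) sample intervals;
    they are snapped to stride zero-crossings before synthesis.  ``seed``
    (or an explicit ``rng``) determines the noise and phase draws.
    """
    fog = fog or FogParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    episodes = sorted((int(a), int(b)) for a, b in episodes)
    for (a0, a1), (b0, b1) in zip(episodes, episodes[1:]):
        if a1 > b0:
            raise EpisodePlanError("planted episodes overlap")
    if episodes and (episodes[0][0] < 0 or episodes[-1][1] > n_samples):
        raise EpisodePlanError("episode outside the trial")

    T = int(n_samples)
    dt = 1.0 / rate_hz
    t = np.arange(T) * dt
    stride_hz = gait.cadence_hz / 2.0
    phase0 = rng.uniform(0, 2 * np.pi)
    phase = 2 * np.pi * stride_hz * t + phase0
    episodes = _snap_to_zero_crossings(episodes, phase, T)
    labels = events_to_labels(T, episodes)

    # smooth freeze gate: 1 during gait, ~0 inside an episode
    gate = 1.0 - labels.astype(float)
    k = max(int(0.08 * rate_hz), 1)
    kernel = np.hanning(2 * k + 1)
    kernel /= kernel.sum()
    gate = np.convolve(np.pad(gate, k, mode="edge"), kernel, mode="valid")

    trem_hz = rng.uniform(*fog.trembling_band_hz)
    trembling = fog.freeze_style == "trembling"
    fog_frac = labels.mean()

    N = len(marker_names)
    pos = np.empty((T, N, 3))
    sway = 25.0 * np.sin(phase)                       # lateral, at stride freq
    bounce = 12.0 * np.sin(2 * phase)                 # vertical, at cadence
    for i, name in enumerate(marker_names):
        ox, oy, oz = _OFFSETS.get(name, (0.0, 0.0, 0.0))
        side = name[0] if name[0] in "LR" else ""
        leg_phase = phase + _LEG_SIGN.get(side, 0.0)
        scale = _SWING_SCALE.get(name, 0.3)
        if side == "L":
            scale *= 1.0 + gait.stance_asymmetry
        elif side == "R":
            scale *= 1.0 - gait.stance_asymmetry
        # forward velocity: progression + swing harmonics, gated by freezes
        swing = (np.sin(leg_phase) + 0.35 * np.sin(2 * leg_phase + 0.8))
        v_fwd = gate * (gait.walking_speed_mm_s
                        + scale * gait.step_amplitude_mm
                        * 2 * np.pi * stride_hz * swing)
        if trembling and scale >= 0.8:                # shank markers tremble
            # constant velocity amplitude (~2.5 mm/sample peak displacement)
            v_fwd = v_fwd + (1.0 - gate) * 250.0 * np.sin(
                2 * np.pi * trem_hz * t + phase0)
        y = oy + np.cumsum(v_fwd) * dt
        x = ox + (sway if scale < 0.3 else scale * 18.0 * np.sin(leg_phase)) * gate
        z = oz + (bounce if scale < 0.3 else
                  scale * 45.0 * np.clip(np.sin(leg_phase), 0, None)) * gate
        pos[:, i, 0], pos[:, i, 1], pos[:, i, 2] = x, y, z
    pos += rng.normal(0.0, gait.noise_sd_mm, size=pos.shape)

    trial = MarkerTrial(subject_id=subject_id, trial_id=trial_id,
                        rate_hz=rate_hz, marker_names=marker_names,
                        positions=pos, labels=labels)
    return trial


def _draw_subject(rng, freezer: bool) -> tuple:
    gait = GaitParams(
        cadence_hz=rng.uniform(1.5, 2.2),
        step_amplitude_mm=rng.uniform(180.0, 260.0),
        walking_speed_mm_s=rng.uniform(900.0, 1300.0),
        stance_asymmetry=rng.uniform(-0.15, 0.15),
        noise_sd_mm=rng.uniform(1.0, 2.0),
    )
    fog = FogParams(
        episode_probability=rng.uniform(0.6, 0.95) if freezer else 0.0,
        episodes_per_trial=rng.uniform(1.0, 2.5),
        freeze_style="trembling" if rng.uniform() < 0.4 else "akinetic",
    )
    return gait, fog


def generate_cohort(spec: CohortSpec = None, **overrides):
    """Generate a full cohort.

    Returns ``(trials, manifest)``: a list of :class:`MarkerTrial` and a
    manifest dict recording per-subject parameters and every planted episode
    (the synthetic expert annotation).  A ``nonfreezer_fraction`` of the
    subjects (the last ones by index) have zero episodes in every trial.
    """
    spec = spec or CohortSpec(**overrides)
    if spec.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects for LOSO")
    root = np.random.default_rng(spec.seed)
    n_nonfreezers = int(round(spec.nonfreezer_fraction * spec.n_subjects))
    trials, manifest = [], {"seed": spec.seed, "subjects": {}}
    for s in range(spec.n_subjects):
        subject_id = f"S{s + 1:02d}"
        freezer = s < spec.n_subjects - n_nonfreezers
        srng = np.random.default_rng(root.integers(2 ** 31))
        gait, fog = _draw_subject(srng, freezer)
        subj = {"freezer": freezer, "gait": asdict(gait), "fog": asdict(fog),
                "trials": {}}
        for k in range(spec.trials_per_subject):
            trial_id = f"{subject_id}_T{k + 1:02d}"
            dur = srng.uniform(*spec.trial_duration_s)
            T = int(round(dur * spec.rate_hz))
            episodes = plan_episodes(T, spec.rate_hz, fog, srng)
            trial = generate_trial(gait, episodes, T, spec.rate_hz, fog,
                                   subject_id=subject_id, trial_id=trial_id,
                                   rng=srng, marker_names=spec.marker_names)
            # the manifest records the episodes as actually planted (snapped)
            from .metrics import labels_to_segments
            segs = labels_to_segments(trial.labels).of_class(1)
            subj["trials"][trial_id] = {
                "n_samples": T, "episodes": [list(e) for e in segs]}
            trials.append(trial)
        manifest["subjects"][subject_id] = subj
    return trials, manifest
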