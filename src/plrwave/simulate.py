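"""Synthetic chromatic-pupillometry cohorts.

The generator emulates binocular four-condition pupillary-light-reflex
recordings with the qualitative structure of clinical chromatic
pupillometry: a latency, a fast exponential constriction, a plateau that is
largely *sustained* under blue light (melanopsin / ipRGC drive) but escapes
toward baseline under red light (rod-cone transience), post-stimulus
recovery, and for the bright-blue condition a post-illumination pupil
response (PIPR) — residual constriction after light offset.

The waveform model is a piecewise exponential envelope, not a physiological
ODE: downstream analysis uses waveform *shape* only, so the simplest form
reproducing the observed morphology is preferred.

Condition constriction amplitudes are parameterized as fractions of the
baseline diameter, calibrated so that at the healthy reference baseline of
6.46 mm the mean diameter over the 10-s stimulus window hits the reference
values 4.82 / 4.30 / 3.74 / 3.16 mm for r10 / r100 / b10 / b100. Because
amplitudes scale with baseline, a smaller (elderly) baseline rescales the
whole waveform affinely, leaving shape and standardized-amplitude features
unchanged — the age effect is a pure size effect, as intended.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .io import CONDITIONS, Pupillogram, RecordingSet

__all__ = [
    "PLRParams",
    "CohortSpec",
    "simulate_plr",
    "simulate_cohort",
    "noiseless_waveform",
]


@dataclass
class PLRParams:
    """Parameters of a single simulated pupillary light reflex.

    Attributes
    ----------
    baseline : float
        Pre-stimulus pupil diameter, mm.
    latency : float
        Delay between light onset and the start of constriction, s.
    constriction_amplitude : float
        Maximum constriction depth, mm (diameter falls toward
        ``baseline - constriction_amplitude``).
    constriction_tau : float
        Time constant of the initial constriction, s.
    sustain_fraction : float in [0, 1]
        Fraction of the constriction held for the remainder of the
        stimulus. Near 1 under blue light (melanopsin-sustained plateau);
        low under red light (partial redilation during the pulse).
    recovery_tau : float
        Time constant of the escape/recovery phases, s.
    pipr_fraction : float in [0, 1]
        Fraction of the constriction retained after light offset
        (post-illumination pupil response); nonzero only for bright blue.
    noise_sd : float
        SD of additive Gaussian measurement noise, mm.
    dropout_rate : float
        Per-sample probability of a dropout (sample forced to 0, as left
        by a blink or tracking loss).
    """

    baseline: float
    latency: float = 0.25
    constriction_amplitude: float = 1.5
    constriction_tau: float = 0.4
    sustain_fraction: float = 0.8
    recovery_tau: float = 2.0
    pipr_fraction: float = 0.0
    noise_sd: float = 0.05
    dropout_rate: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.sustain_fraction <= 1.0:
            raise ParameterError("sustain_fraction must be in [0, 1]")
        if not 0.0 <= self.pipr_fraction <= 1.0:
            raise ParameterError("pipr_fraction must be in [0, 1]")
        if self.constriction_tau <= 0 or self.recovery_tau <= 0:
            raise ParameterError("time constants must be positive")
        if self.latency < 0:
            raise ParameterError("latency must be non-negative")
        if self.constriction_amplitude < 0:
            raise ParameterError("constriction_amplitude must be non-negative")
        if self.baseline <= self.constriction_amplitude:
            raise ParameterError("baseline must exceed constriction amplitude")
        if self.noise_sd < 0 or not 0.0 <= self.dropout_rate < 1.0:
            raise ParameterError("invalid noise_sd or dropout_rate")


# The constriction phase is treated as complete after this many time
# constants; the waveform then switches to the sustain/escape phase.
_CONSTRICTION_SPAN_TAUS = 5.0


def noiseless_waveform(
    t: np.ndarray, params: PLRParams, stimulus_duration: float = 10.0
) -> np.ndarray:
    """Evaluate the piecewise-exponential PLR envelope at times ``t`` (s).

    Phases (light onset at t = 0):

    1. ``t < latency`` — flat at baseline.
    2. constriction — exponential approach (``constriction_tau``) toward
       ``baseline - amplitude``, lasting 5 constriction time constants.
    3. sustain/escape — exponential relaxation (``recovery_tau``) toward
       ``baseline - sustain_fraction * amplitude`` until light offset.
    4. recovery — exponential relaxation (``recovery_tau``) toward
       ``baseline - pipr_fraction * amplitude``.

    The envelope is continuous at every phase boundary.
    """
    p = params
    t = np.asarray(t, dtype=float)
    b, amp = p.baseline, p.constriction_amplitude
    t_con_end = min(p.latency + _CONSTRICTION_SPAN_TAUS * p.constriction_tau,
                    stimulus_duration)

    def constriction(tt: np.ndarray) -> np.ndarray:
        return b - amp * (1.0 - np.exp(-(tt - p.latency) / p.constriction_tau))

    d_con_end = float(constriction(np.array(t_con_end)))
    sustain_target = b - p.sustain_fraction * amp

    def sustain(tt: np.ndarray) -> np.ndarray:
        return sustain_target + (d_con_end - sustain_target) * np.exp(
            -(tt - t_con_end) / p.recovery_tau
        )

    d_off = float(sustain(np.array(stimulus_duration)))
    recovery_target = b - p.pipr_fraction * amp

    def recovery(tt: np.ndarray) -> np.ndarray:
        return recovery_target + (d_off - recovery_target) * np.exp(
            -(tt - stimulus_duration) / p.recovery_tau
        )

    out = np.full(t.shape, b, dtype=float)
    m1 = (t >= p.latency) & (t < t_con_end)
    m2 = (t >= t_con_end) & (t < stimulus_duration)
    m3 = t >= stimulus_duration
    out[m1] = constriction(t[m1])
    out[m2] = sustain(t[m2])
    out[m3] = recovery(t[m3])
    return out


def simulate_plr(
    params: PLRParams,
    condition: str,
    duration: float = 20.0,
    rate: float = 30.0,
    seed: int | np.random.SeedSequence = 0,
    stimulus_duration: float = 10.0,
    subject_id: str = "sim",
    eye: str = "left",
    eye_status: str = "unknown",
) -> Pupillogram:
    """Simulate one pupillogram: envelope + Gaussian noise + dropouts.

    Deterministic given ``seed``. The record starts at light onset
    (``stimulus_onset_index = 0``).
    """
    params.validate()
    if condition not in CONDITIONS:
        raise ParameterError(f"unknown condition {condition!r}")
    if duration < stimulus_duration:
        raise ParameterError("duration must cover the stimulus")
    if rate <= 0:
        raise ParameterError("rate must be positive")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    d = noiseless_waveform(t, params, stimulus_duration)
    rng = np.random.default_rng(seed)
    if params.noise_sd > 0:
        d = d + rng.normal(0.0, params.noise_sd, size=n)
    if params.dropout_rate > 0:
        # boundary samples are kept valid so dropout repair is always possible
        drop = rng.random(n) < params.dropout_rate
        drop[0] = drop[-1] = False
        d[drop] = 0.0
    return Pupillogram(
        subject_id=subject_id,
        eye=eye,
        condition=condition,
        diameters=d,
        sampling_rate=rate,
        stimulus_onset_index=0,
        stimulus_duration=stimulus_duration,
        eye_status=eye_status,
    )


def _default_targets() -> dict[str, float]:
    return {"r10": 4.82, "r100": 4.30, "b10": 3.74, "b100": 3.16}


def _default_sustain() -> dict[str, float]:
    return {"r10": 0.35, "r100": 0.45, "b10": 0.85, "b100": 0.95}


def _default_pipr() -> dict[str, float]:
    return {"r10": 0.0, "r100": 0.0, "b10": 0.0, "b100": 0.40}


@dataclass
class CohortSpec:
    """Specification of a synthetic binocular four-condition cohort.

    Healthy subjects get two similar eyes; each patient gets one
    age-affected normal (N) eye — a healthy-shaped response at a smaller
    elderly baseline — and one diseased (D) eye with reduced constriction
    amplitude, reduced blue sustain, and larger inter-eye asymmetry.

    The expected constriction amplitudes are ordered
    r10 < r100 < b10 < b100 by construction (equivalently, mean stimulated
    diameters ordered r10 > r100 > b10 > b100).
    """

    n_healthy: int = 6
    n_patients: int = 6
    seed: int = 0
    duration: float = 20.0
    rate: float = 30.0
    stimulus_duration: float = 10.0

    healthy_baseline_mean: float = 6.46
    healthy_baseline_sd: float = 0.45
    patient_baseline_mean: float = 4.87  # age effect: smaller elderly baseline
    patient_baseline_sd: float = 0.45

    #: mean stimulated-window diameters (mm) at the healthy reference
    #: baseline; amplitude fractions are calibrated against these.
    target_diameters: dict[str, float] = field(default_factory=_default_targets)
    sustain_fraction: dict[str, float] = field(default_factory=_default_sustain)
    pipr_fraction: dict[str, float] = field(default_factory=_default_pipr)

    latency: float = 0.25
    constriction_tau: float = 0.4
    recovery_tau: float = 2.0
    noise_sd: float = 0.05
    dropout_rate: float = 0.0

    #: multiplicative log-normal jitter (CV) on amplitude fractions
    between_subject_cv: float = 0.08
    inter_eye_cv: float = 0.02

    # disease effects (D eye only); defaults mild enough that the
    # class-mean diameter ordering r10 > r100 > b10 > b100 survives in the
    # diseased class, as observed clinically
    disease_amplitude_reduction: float = 0.30
    disease_sustain_reduction: float = 0.20  # relative, blue conditions
    disease_asymmetry_cv: float = 0.10

    def validate(self) -> None:
        if self.n_healthy < 0 or self.n_patients < 0:
            raise ParameterError("cohort sizes must be non-negative")
        if not self.healthy_baseline_mean > self.patient_baseline_mean:
            raise ParameterError("healthy mean baseline must exceed patient mean")
        t = self.target_diameters
        if not (t["r10"] > t["r100"] > t["b10"] > t["b100"]):
            raise ParameterError(
                "target stimulated diameters must be ordered r10 > r100 > b10 > b100"
            )
        for c in CONDITIONS:
            if not 0 < t[c] < self.healthy_baseline_mean:
                raise ParameterError(f"target diameter for {c} out of range")


def _unit_window_mean(spec: CohortSpec, condition: str) -> float:
    """Mean over the stimulus window of the unit-amplitude response profile.

    The envelope is linear in (baseline, amplitude):
    ``d(t) = baseline - amplitude * f(t)`` with f the unit profile, so the
    window mean is ``baseline - amplitude * mean(f)``.
    """
    p = PLRParams(
        baseline=1.0,
        latency=spec.latency,
        constriction_amplitude=0.5,
        constriction_tau=spec.constriction_tau,
        sustain_fraction=spec.sustain_fraction[condition],
        recovery_tau=spec.recovery_tau,
        pipr_fraction=spec.pipr_fraction[condition],
        noise_sd=0.0,
    )
    n = int(round(spec.stimulus_duration * spec.rate))
    t = np.arange(n) / spec.rate
    d = noiseless_waveform(t, p, spec.stimulus_duration)
    return float(np.mean((1.0 - d) / 0.5))


def amplitude_fractions(spec: CohortSpec) -> dict[str, float]:
    """Calibrated per-condition amplitude-to-baseline fractions.

    Solves ``baseline - frac * baseline * M_c = target_c`` at the healthy
    reference baseline, where ``M_c`` is the window mean of the
    unit-amplitude profile for condition c.
    """
    b = spec.healthy_baseline_mean
    out = {}
    for c in CONDITIONS:
        m = _unit_window_mean(spec, c)
        out[c] = (b - spec.target_diameters[c]) / (b * m)
    return out


def _substream(seed: int, *key: str) -> np.random.SeedSequence:
    """Stable per-record random substream independent of generation order."""
    tag = zlib.crc32("|".join(key).encode("utf-8"))
    return np.random.SeedSequence(entropy=seed, spawn_key=(tag,))


def _eye_params(
    spec: CohortSpec,
    fractions: dict[str, float],
    baseline: float,
    subj_amp_jitter: dict[str, float],
    rng: np.random.Generator,
    diseased: bool,
) -> dict[str, PLRParams]:
    """Draw per-condition PLRParams for one eye."""
    params = {}
    eye_jitter = np.exp(rng.normal(0.0, spec.inter_eye_cv, size=len(CONDITIONS)))
    for i, c in enumerate(CONDITIONS):
        frac = fractions[c] * subj_amp_jitter[c] * eye_jitter[i]
        sustain = spec.sustain_fraction[c]
        if diseased:
            frac *= (1.0 - spec.disease_amplitude_reduction) * np.exp(
                rng.normal(0.0, spec.disease_asymmetry_cv)
            )
            if c.startswith("b"):
                sustain *= 1.0 - spec.disease_sustain_reduction
        amp = min(frac, 0.95) * baseline
        params[c] = PLRParams(
            baseline=baseline,
            latency=spec.latency,
            constriction_amplitude=amp,
            constriction_tau=spec.constriction_tau,
            sustain_fraction=float(np.clip(sustain, 0.0, 1.0)),
            recovery_tau=spec.recovery_tau,
            pipr_fraction=spec.pipr_fraction[c],
            noise_sd=spec.noise_sd,
            dropout_rate=spec.dropout_rate,
        )
    return params


def simulate_cohort(spec: CohortSpec) -> RecordingSet:
    """Generate a labelled binocular cohort, reproducible from ``spec.seed``.

    Returns a :class:`RecordingSet` with ``2 * (n_healthy + n_patients)``
    eyes x 4 conditions, eye statuses set to healthy / patient_normal /
    patient_diseased.
    """
    spec.validate()
    fractions = amplitude_fractions(spec)
    rs = RecordingSet()

    def make_subject(sid: str, healthy: bool) -> None:
        srng = np.random.default_rng(_substream(spec.seed, sid, "subject"))
        if healthy:
            b_mean, b_sd = spec.healthy_baseline_mean, spec.healthy_baseline_sd
        else:
            b_mean, b_sd = spec.patient_baseline_mean, spec.patient_baseline_sd
        baseline = float(np.clip(srng.normal(b_mean, b_sd), 2.5, 9.5))
        subj_amp_jitter = {
            c: float(np.exp(srng.normal(0.0, spec.between_subject_cv)))
            for c in CONDITIONS
        }
        if healthy:
            statuses = {"left": "healthy", "right": "healthy"}
        else:
            diseased_eye = "left" if srng.random() < 0.5 else "right"
            statuses = {
                eye: ("patient_diseased" if eye == diseased_eye else "patient_normal")
                for eye in ("left", "right")
            }
        for eye, status in statuses.items():
            erng = np.random.default_rng(_substream(spec.seed, sid, eye, "params"))
            params = _eye_params(
                spec,
                fractions,
                baseline,
                subj_amp_jitter,
                erng,
                diseased=(status == "patient_diseased"),
            )
            for c in CONDITIONS:
                rs.add(
                    simulate_plr(
                        params[c],
                        c,
                        duration=spec.duration,
                        rate=spec.rate,
                        seed=_substream(spec.seed, sid, eye, c),
                        stimulus_duration=spec.stimulus_duration,
                        subject_id=sid,
                        eye=eye,
                        eye_status=status,
                    )
                )

    for i in range(spec.n_healthy):
        make_subject(f"H{i + 1:02d}", healthy=True)
    for i in range(spec.n_patients):
        make_subject(f"P{i + 1:02d}", healthy=False)
    return rs


def null_spec(**overrides) -> CohortSpec:
    """A CohortSpec with all disease effects switched off.

    D eyes then share the H-eye shape distribution exactly (the age-related
    baseline shift rescales the waveform affinely and cancels in every
    shape and standardized-amplitude feature).
    """
    base = dict(
        disease_amplitude_reduction=0.0,
        disease_sustain_reduction=0.0,
        disease_asymmetry_cv=0.0,
    )
    base.update(overrides)
    return CohortSpec(**base)
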