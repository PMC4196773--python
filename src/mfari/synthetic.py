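"""Synthetic thigh-cuff manoeuvres with known ground truth.

The generator emulates the study protocol: a pre-release ABP plateau, an
abrupt drop at cuff release, optional exponential recovery toward baseline,
and a CBFV response produced by the second-order autoregulation model at a
chosen true ARI, plus additive white noise on the 5 Hz beat-mean series.
An optional raw-recording variant adds a per-beat raised half-sine pulse so
the beat-detection stage can be exercised.

Everything is driven by an integer seed: the same seed yields bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import InvalidParameterError
from .preprocess import Manoeuvre, RawRecording
from .reliability import ReliabilityTable
from .tiecks import CANONICAL_TABLE, TiecksParams, tiecks_response

__all__ = [
    "SimSpec",
    "params_at",
    "simulate_abp",
    "simulate_manoeuvre",
    "simulate_raw_recording",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SimSpec:
    """Ground-truth description of one simulated manoeuvre.

    ``drop_fraction`` is the relative ABP drop at release (0.25 ~ a typical
    thigh-cuff drop of ~22 mmHg from a 90 mmHg baseline);
    ``abp_recovery_rate`` is the exponential return rate toward baseline
    (0 = ideal sustained step, the stimulus the standardisation templates
    use); ``noise_sd`` is the white-noise standard deviation as a fraction
    of each channel's drop amplitude.
    """

    ari_true: float = 5.0
    abp_baseline: float = 90.0
    cbfv_baseline: float = 55.0
    crcp: float = 12.0
    drop_fraction: float = 0.25
    abp_recovery_rate: float = 0.0
    noise_sd: float = 0.0
    rate: float = 5.0
    t0: float = 5.0
    duration: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.drop_fraction < 1.0:
            raise InvalidParameterError("drop_fraction must lie in (0, 1)")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")
        if not 0.0 <= self.ari_true <= 9.0:
            raise InvalidParameterError("ari_true must lie in [0, 9]")
        if self.duration < self.t0 + 16.0 or self.t0 < 4.0:
            raise InvalidParameterError(
                "duration must cover a 4 s baseline and >= 16 s post-release"
            )


def params_at(ari: float) -> TiecksParams:
    """Model parameters at a continuous ARI via the canonical-table spline."""
    nodes = np.arange(10.0)
    table = np.asarray(CANONICAL_TABLE)
    T, D, K = (float(CubicSpline(nodes, table[:, j])(ari)) for j in range(3))
    return TiecksParams(float(ari), T, D, min(max(K, 0.0), 1.0))


def _clean_abp(spec: SimSpec) -> np.ndarray:
    t = np.arange(int(round(spec.duration * spec.rate)) + 1) / spec.rate
    abp = np.full(t.size, spec.abp_baseline)
    post = t >= spec.t0
    depth = spec.drop_fraction * spec.abp_baseline
    abp[post] = spec.abp_baseline - depth * np.exp(
        -spec.abp_recovery_rate * (t[post] - spec.t0)
    )
    return abp


def simulate_abp(spec: SimSpec) -> tuple[np.ndarray, float]:
    """ABP series (mmHg, 5 Hz beat-mean level) and the release time t0."""
    rng = np.random.default_rng(spec.seed)
    abp = _clean_abp(spec)
    if spec.noise_sd > 0:
        abp = abp + rng.normal(
            0.0, spec.noise_sd * spec.drop_fraction * spec.abp_baseline, abp.size
        )
    return abp, spec.t0


def simulate_manoeuvre(spec: SimSpec) -> Manoeuvre:
    """Paired ABP/CBFV manoeuvre with ground-truth labels in ``meta``.

    CBFV is the model response (at the spline-interpolated parameters for
    ``ari_true``) to the noiseless ABP; noise is then added independently to
    each channel, scaled to that channel's drop amplitude.
    """
    rng = np.random.default_rng(spec.seed)
    abp_clean = _clean_abp(spec)
    cbfv_clean = tiecks_response(
        abp_clean,
        params_at(spec.ari_true),
        spec.rate,
        crcp=spec.crcp,
        abp_baseline=spec.abp_baseline,
        cbfv_baseline=spec.cbfv_baseline,
    )
    abp, cbfv = abp_clean, cbfv_clean
    if spec.noise_sd > 0:
        abp_depth = spec.drop_fraction * spec.abp_baseline
        # drop amplitude seen by the CBFV channel, via the pressure scaling
        cbfv_depth = (
            spec.cbfv_baseline
            * abp_depth
            / (spec.abp_baseline - spec.crcp)
        )
        abp = abp + rng.normal(0.0, spec.noise_sd * abp_depth, abp.size)
        cbfv = cbfv + rng.normal(0.0, spec.noise_sd * cbfv_depth, cbfv.size)
    return Manoeuvre(
        abp=abp,
        cbfv=cbfv,
        rate=spec.rate,
        t0=spec.t0,
        meta={"ari_true": spec.ari_true, "spec": spec},
    )


def simulate_raw_recording(
    spec: SimSpec,
    sample_rate: float = 200.0,
    beat_rate: float = 1.0,
    pulse_amplitude: float = 40.0,
) -> RawRecording:
    """High-rate two-channel recording with a per-beat raised half-sine pulse.

    The pulse is zero at each beat onset (the diastolic minimum) and peaks
    mid-cycle, so onset detection at diastolic minima recovers the beat
    grid. CBFV pulsatility is scaled down proportionally to its baseline.
    """
    rng = np.random.default_rng(spec.seed + 1)
    t = np.arange(int(round(spec.duration * sample_rate)) + 1) / sample_rate
    base_spec = replace(spec, noise_sd=0.0)
    m = simulate_manoeuvre(base_spec)
    abp_base = np.interp(t, m.time, m.abp)
    cbfv_base = np.interp(t, m.time, m.cbfv)
    phase = (t * beat_rate) % 1.0
    pulse = np.sin(np.pi * phase)
    abp = abp_base + pulse_amplitude * pulse
    cbfv = cbfv_base + pulse_amplitude * (spec.cbfv_baseline / spec.abp_baseline) * pulse
    if spec.noise_sd > 0:
        depth = spec.drop_fraction * spec.abp_baseline
        abp = abp + rng.normal(0.0, spec.noise_sd * depth, t.size)
        cbfv = cbfv + rng.normal(
            0.0, spec.noise_sd * depth * spec.cbfv_baseline / spec.abp_baseline, t.size
        )
    return RawRecording(time=t, abp=abp, cbfv=cbfv, sample_rate=sample_rate)


@dataclass
class Cohort:
    """A simulated test-retest cohort with its ground truth."""

    table: ReliabilityTable
    manoeuvres: list[Manoeuvre]
    true_subject_ari: np.ndarray
    within_sd: float
    between_sd: float


def simulate_cohort(
    n_subjects: int = 16,
    reps: int = 6,
    between_sd: float = 1.0,
    within_sd: float = 0.5,
    mean_ari: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    with_manoeuvres: bool = True,
) -> Cohort:
    """Test-retest cohort: subject-level true ARI plus per-manoeuvre jitter.

    Subject means are drawn N(mean_ari, between_sd); each repetition's true
    ARI adds N(0, within_sd); both are clipped to [0.2, 8.8] to stay inside
    the index scale. The returned table holds the per-repetition true ARI
    values (so reliability statistics can be checked against ``within_sd``
    directly); the manoeuvres are generated at those values with
    measurement noise ``noise_sd`` and can be re-indexed by any method.
    """
    if reps < 2:
        raise InvalidParameterError("reps must be >= 2")
    rng = np.random.default_rng(seed)
    subj = np.clip(rng.normal(mean_ari, between_sd, n_subjects), 0.2, 8.8)
    table = np.clip(
        subj[:, None] + rng.normal(0.0, within_sd, (n_subjects, reps)), 0.0, 9.0
    )
    manoeuvres: list[Manoeuvre] = []
    if with_manoeuvres:
        for i in range(n_subjects):
            for j in range(reps):
                spec = SimSpec(
                    ari_true=float(table[i, j]),
                    noise_sd=noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                m = simulate_manoeuvre(spec)
                m.meta.update(subject=i, repetition=j)
                manoeuvres.append(m)
    return Cohort(
        table=ReliabilityTable(values=table),
        manoeuvres=manoeuvres,
        true_subject_ari=subj,
        within_sd=within_sd,
        between_sd=between_sd,
    )
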