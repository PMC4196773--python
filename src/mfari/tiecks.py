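"""Second-order Aaslid-Tiecks autoregulation model and classic ARI estimation.

The model maps an ABP disturbance to a CBFV response through a discrete
second-order system with three parameters: time constant T (s), damping D,
and autoregulatory gain K. Ten canonical (T, D, K) combinations grade the
response from ARI 0 (no autoregulation, CBFV passively follows pressure) to
ARI 9 (fast, near-complete flow restoration). With the normalised pressure
deviation

    dP(n) = (ABP(n) - ABP_base) / (ABP_base - CrCP)

the state recursion at sample rate f is

    x1(n) = x1(n-1) + (dP(n) - x2(n-1)) / (f T)
    x2(n) = x2(n-1) + (x1(n-1) - 2 D x2(n-1)) / (f T)
    CBFV(n) = CBFV_base * (1 + dP(n) - K x2(n))

with both states starting at zero. CrCP is the critical closing pressure
(12 mmHg in the classic least-squares fit).

The classic ARI is the template (model response to the observed ABP) that
best matches the observed CBFV, either by least squares on the raw scale or
by Pearson correlation on normalised signals followed by parabolic
interpolation to a non-integer value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import (
    DegenerateInputError,
    InvalidParameterError,
    NumericInstabilityError,
)
from .preprocess import Manoeuvre, NormalisedResponse, normalise_drop

__all__ = [
    "TiecksParams",
    "TemplateSet",
    "CANONICAL_TABLE",
    "canonical_params",
    "interpolate_params",
    "tiecks_response",
    "step_stimulus",
    "generate_templates",
    "classic_ari_lsq",
    "classic_ari_corr",
    "parabolic_vertex",
]

# Canonical (T, D, K) rows for integer ARI 0..9 (Tiecks et al. 1995).
CANONICAL_TABLE: tuple[tuple[float, float, float], ...] = (
    (2.00, 0.00, 0.00),  # ARI 0
    (2.00, 1.60, 0.20),  # ARI 1
    (2.00, 1.50, 0.40),  # ARI 2
    (2.00, 1.15, 0.60),  # ARI 3
    (2.00, 0.90, 0.80),  # ARI 4
    (1.90, 0.75, 0.90),  # ARI 5
    (1.60, 0.65, 0.94),  # ARI 6
    (1.20, 0.55, 0.96),  # ARI 7
    (0.87, 0.52, 0.97),  # ARI 8
    (0.65, 0.50, 0.98),  # ARI 9
)

#: Critical closing pressure (mmHg) used by the classic least-squares fit.
DEFAULT_CRCP = 12.0


@dataclass(frozen=True)
class TiecksParams:
    """One (ARI, T, D, K) parameter combination."""

    ari: float
    T: float
    D: float
    K: float

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise InvalidParameterError(f"T must be positive, got {self.T}")
        if self.D < 0:
            raise InvalidParameterError(f"D must be non-negative, got {self.D}")
        if not 0.0 <= self.K <= 1.0:
            raise InvalidParameterError(f"K must lie in [0, 1], got {self.K}")


@dataclass
class TemplateSet:
    """Normalised model step responses on the 0.1-resolution ARI grid.

    ``responses[i]`` is the drop-normalised CBFV response for ``params[i]``,
    all driven by the same ``stimulus`` (a normalised negative pressure step
    sampled at ``rate``).
    """

    params: list[TiecksParams]
    responses: list[NormalisedResponse]
    stimulus: np.ndarray
    rate: float
    t0: float

    @property
    def ari_values(self) -> np.ndarray:
        return np.array([p.ari for p in self.params])


def canonical_params(ari: int) -> TiecksParams:
    """The published (T, D, K) combination for an integer ARI grade."""
    if ari not in range(10):
        raise InvalidParameterError(f"ari must be an integer in 0..9, got {ari!r}")
    T, D, K = CANONICAL_TABLE[ari]
    return TiecksParams(float(ari), T, D, K)


def interpolate_params(
    step: float = 0.1, bc_type: str = "not-a-knot"
) -> list[TiecksParams]:
    """Cubic-spline interpolation of the canonical table to a finer ARI grid.

    Each of T, D, K is splined through its ten canonical nodes and evaluated
    at ARI = 0, step, 2*step, ..., 9; node values are reproduced exactly.
    The default 0.1 step yields 91 combinations.
    """
    n_steps = 9.0 / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise InvalidParameterError(f"step {step} must divide 9 exactly")
    grid = np.linspace(0.0, 9.0, int(round(n_steps)) + 1)
    nodes = np.arange(10.0)
    table = np.asarray(CANONICAL_TABLE)
    cols = [CubicSpline(nodes, table[:, j], bc_type=bc_type)(grid) for j in range(3)]
    # splined K can stray marginally outside [0, 1] between nodes
    cols[2] = np.clip(cols[2], 0.0, 1.0)
    return [
        TiecksParams(float(a), float(T), float(D), float(K))
        for a, T, D, K in zip(grid, *cols)
    ]


def tiecks_response(
    abp: np.ndarray,
    params: TiecksParams,
    rate: float,
    crcp: float = DEFAULT_CRCP,
    abp_baseline: float | None = None,
    cbfv_baseline: float = 1.0,
    baseline_window: float = 4.0,
    t0: float | None = None,
) -> np.ndarray:
    """Model CBFV response to an ABP series.

    ``abp_baseline`` defaults to the mean over ``baseline_window`` seconds
    before ``t0`` (or the first sample when neither is given). The model is
    linear in ``cbfv_baseline``, which merely sets the output scale.

    Raises
    ------
    InvalidParameterError
        If ``abp_baseline <= crcp`` (pressure normalisation undefined).
    NumericInstabilityError
        If the state recursion diverges (T too small for the sample rate).
    """
    abp = np.asarray(abp, dtype=float)
    if rate <= 0:
        raise InvalidParameterError("rate must be positive")
    if abp_baseline is None:
        if t0 is not None:
            i0 = int(round(t0 * rate))
            ib = max(0, i0 - int(round(baseline_window * rate)))
            abp_baseline = float(abp[ib:i0].mean()) if i0 > ib else float(abp[0])
        else:
            abp_baseline = float(abp[0])
    if abp_baseline <= crcp:
        raise InvalidParameterError(
            f"abp_baseline {abp_baseline} must exceed CrCP {crcp}"
        )

    dP = (abp - abp_baseline) / (abp_baseline - crcp)
    fT = rate * params.T
    x1 = x2 = 0.0
    out = np.empty_like(dP)
    for n in range(dP.size):
        x1_new = x1 + (dP[n] - x2) / fT
        x2_new = x2 + (x1 - 2.0 * params.D * x2) / fT
        x1, x2 = x1_new, x2_new
        out[n] = cbfv_baseline * (1.0 + dP[n] - params.K * x2)
    if not np.all(np.isfinite(out)):
        raise NumericInstabilityError(
            f"model state diverged for T={params.T}, rate={rate}; "
            "the time constant is too small for this sample rate"
        )
    return out


def step_stimulus(
    rate: float = 5.0,
    baseline: float = 4.0,
    post: float = 26.0,
) -> tuple[np.ndarray, float]:
    """Normalised negative pressure step: 1.0 for ``baseline`` seconds, then 0.0.

    Returns ``(series, t0)``; long enough by default to cover the minimum
    search window, the maximum transient duration and the steady window of
    the two-line characterisation.
    """
    nb = int(round(baseline * rate))
    np_ = int(round(post * rate))
    return np.concatenate([np.ones(nb), np.zeros(np_)]), baseline


def generate_templates(
    paramset: list[TiecksParams] | None = None,
    rate: float = 5.0,
    stimulus: np.ndarray | None = None,
    t0: float | None = None,
    search_window: float = 6.0,
) -> TemplateSet:
    """Drive each parameter combination with a normalised pressure step.

    The stimulus is already in normalised units (baseline 1, drop to 0), so
    the model is run with ``abp_baseline=1`` and ``crcp=0``: the pressure
    deviation equals the normalised drop directly. Each response is then
    drop-normalised exactly as an observed CBFV response would be.
    """
    if paramset is None:
        paramset = interpolate_params()
    if stimulus is None:
        stimulus, t0 = step_stimulus(rate)
    elif t0 is None:
        raise InvalidParameterError("t0 required with an explicit stimulus")
    responses = []
    for p in paramset:
        raw = tiecks_response(
            stimulus, p, rate, crcp=0.0, abp_baseline=1.0, cbfv_baseline=1.0
        )
        responses.append(
            normalise_drop(raw, rate, t0, search_window=search_window)
        )
    return TemplateSet(
        params=list(paramset), responses=responses, stimulus=stimulus, rate=rate, t0=t0
    )


def _fit_window(m: Manoeuvre, window: float) -> slice:
    i0 = int(round(m.t0 * m.rate))
    i1 = min(m.abp.size, i0 + int(round(window * m.rate)) + 1)
    return slice(i0, i1)


def classic_ari_lsq(
    m: Manoeuvre,
    crcp: float = DEFAULT_CRCP,
    window: float = 16.0,
    grid: str = "integer",
) -> tuple[float, float]:
    """Classic least-squares ARI: best-matching model template on the raw scale.

    Templates are generated by driving the model with the observed ABP
    (baseline over the 4 s before release, critical closing pressure
    ``crcp``) and scaled by the observed CBFV baseline. The template
    minimising the mean squared error against the observed CBFV over
    ``[t0, t0 + window]`` wins.

    ``grid`` selects the candidate set: ``"integer"`` for the ten canonical
    combinations, ``"interpolated"`` for the 91-point 0.1 grid.

    Returns ``(ari, mse)``.
    """
    if grid == "integer":
        candidates = [canonical_params(k) for k in range(10)]
    elif grid == "interpolated":
        candidates = interpolate_params()
    else:
        raise InvalidParameterError(f"unknown grid {grid!r}")
    i0 = int(round(m.t0 * m.rate))
    ib = max(0, i0 - int(round(4.0 * m.rate)))
    cbfv_base = float(m.cbfv[ib:i0].mean()) if i0 > ib else float(m.cbfv[0])
    sl = _fit_window(m, window)
    best_ari, best_mse = 0.0, np.inf
    for p in candidates:
        tmpl = tiecks_response(
            m.abp, p, m.rate, crcp=crcp, cbfv_baseline=cbfv_base, t0=m.t0
        )
        mse = float(np.mean((m.cbfv[sl] - tmpl[sl]) ** 2))
        if mse < best_mse:
            best_ari, best_mse = p.ari, mse
    return best_ari, best_mse


def parabolic_vertex(k: float, c_lo: float, c_mid: float, c_hi: float) -> float:
    """Vertex abscissa of the parabola through (k-1, c_lo), (k, c_mid), (k+1, c_hi)."""
    denom = c_lo - 2.0 * c_mid + c_hi
    if denom == 0:
        return float(k)
    return float(k + 0.5 * (c_lo - c_hi) / denom)


def classic_ari_corr(m: Manoeuvre, window: float = 16.0) -> float:
    """Correlation-variant classic ARI with parabolic interpolation.

    Both signals are drop-normalised (so no critical closing pressure is
    needed) and the ten canonical templates are driven by the normalised
    ABP. The integer template with the highest Pearson correlation against
    the normalised CBFV over ``[t0, t0 + window]`` is refined by fitting a
    parabola through the correlations at its two neighbours; the vertex,
    clipped to [0, 9], is returned. Boundary maxima are returned unrefined.

    Raises
    ------
    DegenerateInputError
        If the observed CBFV is flat over the window (correlation undefined).
    """
    abp_n = normalise_drop(m.abp, m.rate, m.t0, search_window=2.0)
    cbfv_n = normalise_drop(m.cbfv, m.rate, m.t0)
    sl = _fit_window(m, window)
    obs = cbfv_n.values[sl]
    if np.ptp(obs) == 0:
        raise DegenerateInputError("flat CBFV over the fit window")
    corrs = np.empty(10)
    for k in range(10):
        tmpl = tiecks_response(
            abp_n.values, canonical_params(k), m.rate, crcp=0.0, abp_baseline=1.0
        )[sl]
        sd = tmpl.std()
        corrs[k] = np.corrcoef(obs, tmpl)[0, 1] if sd > 0 else -np.inf
    k = int(np.argmax(corrs))
    if k in (0, 9) or not np.isfinite(corrs[k - 1 : k + 2]).all():
        return float(k)
    vertex = parabolic_vertex(k, corrs[k - 1], corrs[k], corrs[k + 1])
    return float(np.clip(vertex, 0.0, 9.0))
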