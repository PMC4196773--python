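"""Rate of Regulation (RoR) from the cerebrovascular-resistance slope.

After cuff release, an intact autoregulation dilates cerebral vessels, so
cerebrovascular resistance CVR = ABP/CBFV falls. RoR quantifies how fast:
both channels are divided by their 4 s pre-release baselines, CVR(t) is the
ratio of the normalised signals, and RoR is the least-squares slope of CVR
over 1-3.6 s post-release divided by the magnitude of the normalised ABP
drop over the same interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, MfariError, NoDropError
from .preprocess import Manoeuvre

__all__ = ["RorResult", "compute_ror", "ROR_INTERVAL"]

#: Post-release interval (s) over which the CVR slope is measured.
ROR_INTERVAL = (1.0, 3.6)


class InvalidSignalError(MfariError):
    """Normalised CBFV non-positive somewhere: CVR undefined."""


@dataclass(frozen=True)
class RorResult:
    """RoR together with its two factors and the drop under both conventions.

    ``abp_drop`` is ``1 - mean(ABPn)`` over the slope interval (the
    convention used for ``ror``); ``abp_drop_literal`` is ``mean(ABPn)``
    itself, the alternative reading of "the normalised mean ABP during the
    same interval", with the corresponding ``ror_literal``.
    """

    ror: float
    cvr_slope: float
    abp_drop: float
    abp_drop_literal: float
    ror_literal: float
    interval: tuple[float, float] = ROR_INTERVAL


def compute_ror(
    m: Manoeuvre,
    interval: tuple[float, float] = ROR_INTERVAL,
    baseline_window: float = 4.0,
    drop_convention: str = "one-minus-mean",
    tolerance: float = 1e-9,
) -> RorResult:
    """Rate of Regulation for one manoeuvre.

    ``drop_convention`` selects which ABP-drop definition divides the CVR
    slope in the headline ``ror`` field: ``"one-minus-mean"`` (default,
    drop = 1 - mean normalised ABP over the interval) or ``"mean"`` (the
    literal normalised mean itself). Both variants are always reported.

    Raises
    ------
    InsufficientDataError
        If the recording does not cover the baseline or the slope interval.
    NoDropError
        If the ABP drop is at or below ``tolerance``.
    InvalidSignalError
        If normalised CBFV is non-positive anywhere in the interval.
    """
    rate = m.rate
    i0 = int(round(m.t0 * rate))
    ib = i0 - int(round(baseline_window * rate))
    lo = i0 + int(round(interval[0] * rate))
    hi = i0 + int(round(interval[1] * rate)) + 1
    if ib < 0:
        raise InsufficientDataError("4 s pre-release baseline not recorded")
    if hi > m.abp.size:
        raise InsufficientDataError(
            f"recording ends before t0 + {interval[1]} s"
        )
    abp_base = m.abp[ib:i0].mean()
    cbfv_base = m.cbfv[ib:i0].mean()
    abp_n = m.abp[lo:hi] / abp_base
    cbfv_n = m.cbfv[lo:hi] / cbfv_base
    if np.any(cbfv_n <= 0):
        raise InvalidSignalError("normalised CBFV non-positive in the RoR interval")
    cvr = abp_n / cbfv_n
    t = np.arange(lo, hi) / rate
    tm = t - t.mean()
    cvr_slope = float(tm @ (cvr - cvr.mean()) / (tm @ tm))
    mean_abp = float(abp_n.mean())
    drop = 1.0 - mean_abp
    if drop <= tolerance:
        raise NoDropError(f"ABP drop {drop:.3g} <= tolerance; no usable manoeuvre")
    ror_std = cvr_slope / drop
    ror_lit = cvr_slope / mean_abp
    if drop_convention == "one-minus-mean":
        ror = ror_std
    elif drop_convention == "mean":
        ror = ror_lit
    else:
        raise ValueError(f"unknown drop_convention {drop_convention!r}")
    return RorResult(
        ror=ror,
        cvr_slope=cvr_slope,
        abp_drop=drop,
        abp_drop_literal=mean_abp,
        ror_literal=ror_lit,
        interval=interval,
    )
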