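"""Stage 3: smooth the Shannon energy into an envelope and pick candidates.

Two cascaded rectangular (boxcar) moving averages of length ``L`` turn the
spiky per-sample Shannon energy into a smooth envelope whose lobes span whole
QRS complexes (the cascade is equivalent to one triangular kernel of support
``2L - 1``). Each causal length-``L`` FIR pass delays the signal by
``(L - 1)/2`` samples, so after both passes the envelope is shifted left by
``L - 1`` samples to re-align its lobes with the underlying QRS — this is
what keeps the end-to-end detection lag in the low-millisecond range.

Candidate R locations are the strict local maxima of the envelope, found as
the +/- sign changes of its first difference; flat-topped maxima resolve to
the leftmost sample of the plateau so results are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .energy import EnergySignal
from .errors import InputError, ParameterError

__all__ = [
    "Envelope",
    "CandidatePeaks",
    "moving_average",
    "difference",
    "sign_of",
    "build_envelope",
    "find_candidates",
]


@dataclass
class Envelope:
    """Smoothed-energy envelope and its first difference.

    ``m`` is the first moving-average pass, ``m2`` the second (delay
    compensated), ``d`` the first difference of ``m2`` (``len(m2) - 1`` long).
    """

    m: np.ndarray
    m2: np.ndarray
    d: np.ndarray
    L: int
    fs: float


@dataclass
class CandidatePeaks:
    """Strict local maxima of the envelope: sample positions and heights."""

    indices: np.ndarray
    heights: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.heights = np.asarray(self.heights, dtype=float)

    def __len__(self) -> int:
        return int(self.indices.size)


def moving_average(x: Sequence[float], L: int) -> np.ndarray:
    """Causal length-``L`` boxcar average with unity DC gain.

    Implemented as the FIR filter with numerator ``ones(L)`` and scalar
    denominator ``L``, zero initial state: output length equals input length
    and the first ``L - 1`` samples form the zero-prefilled startup region.
    """
    x = np.asarray(x, dtype=float).ravel()
    if int(L) != L or L < 1:
        raise ParameterError(f"window length must be an integer >= 1, got {L}")
    if x.size < 1:
        raise InputError("moving_average requires at least one sample")
    return sps.lfilter(np.ones(int(L)) / float(L), [1.0], x)


def difference(x: Sequence[float]) -> np.ndarray:
    """First difference ``d[k] = x[k+1] - x[k]``; output one sample shorter."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise InputError("difference requires at least two samples")
    return np.diff(x)


def sign_of(x: float) -> int:
    """Signum: -1, 0 or +1."""
    return int(np.sign(x))


def build_envelope(s_std: EnergySignal | Sequence[float], L: int, fs: float | None = None) -> Envelope:
    """Cascade two boxcar passes over the standardized energy and difference.

    Parameters
    ----------
    s_std : EnergySignal or sequence
        Standardized Shannon energy (an :class:`EnergySignal` whose ``s_std``
        is populated, or a bare array).
    L : int
        Boxcar length in samples.
    fs : float, optional
        Required when ``s_std`` is a bare array.

    Notes
    -----
    The second pass is delay-compensated by an ``L - 1`` sample left shift
    (the cascade's total group delay), zero-padded at the tail so all stage
    signals keep the source length.
    """
    if isinstance(s_std, EnergySignal):
        if s_std.s_std is None:
            raise InputError("EnergySignal has no standardized values; call standardize() first")
        x, fs = s_std.s_std, s_std.fs
    else:
        x = np.asarray(s_std, dtype=float).ravel()
        if fs is None:
            raise ParameterError("fs is required when passing a bare array")
    L = int(L)
    if x.size < 2 * L:
        raise InputError(f"signal of {x.size} samples is shorter than 2L = {2 * L}")
    m = moving_average(x, L)
    m2 = moving_average(m, L)
    if L > 1:
        m2 = np.concatenate([m2[L - 1 :], np.zeros(L - 1)])
    d = difference(m2)
    return Envelope(m=m, m2=m2, d=d, L=L, fs=fs)


def find_candidates(env: Envelope | Sequence[float]) -> CandidatePeaks:
    """Strict local maxima of the envelope via sign changes of its difference.

    A sample ``k`` is a candidate when the difference is positive just before
    it and non-positive at it — i.e. the envelope rises into ``k`` and does
    not rise out of it. Plateaus therefore yield their leftmost sample.
    """
    if isinstance(env, Envelope):
        values, d = env.m2, env.d
    else:
        values = np.asarray(env, dtype=float).ravel()
        d = np.diff(values)
    if d.size < 2:
        return CandidatePeaks(indices=np.empty(0, dtype=np.int64), heights=np.empty(0))
    rising_before = d[:-1] > 0
    not_rising_at = d[1:] <= 0
    idx = np.nonzero(rising_before & not_rising_at)[0] + 1
    return CandidatePeaks(indices=idx, heights=values[idx])
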