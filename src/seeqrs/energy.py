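"""Stage 2: Shannon energy of the normalized signal, and its z-scoring.

For a normalized amplitude ``a`` in [-1, 1], the per-sample Shannon energy is

    s[n] = -a^2[n] * log(a^2[n]),   with 0*log 0 := 0 by continuity.

Compared with the classic squared energy ``a^2``, the Shannon transform
emphasizes medium amplitudes: it is 0 at |a| = 0 and |a| = 1 and peaks at
1/e for |a| = e^(-1/2). This compresses the spread between large R waves and
the flanks of the QRS, making the subsequent envelope less sensitive to
sudden amplitude changes and to QRS polarity.

The standardized energy ``(s - mu)/sigma`` (population sigma) puts records
of different morphology on a common scale for the envelope/threshold stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateSignalError, InputError, ParameterError
from .preprocess import NormalizedSignal

__all__ = ["EnergySignal", "classic_energy", "shannon_energy", "shannon_entropy", "standardize"]

_LOG_SCALE = {"e": 1.0, "2": 1.0 / np.log(2.0), "10": 1.0 / np.log(10.0)}


@dataclass
class EnergySignal:
    """Per-sample Shannon energy and, after :func:`standardize`, its z-score."""

    s: np.ndarray
    fs: float
    s_std: np.ndarray | None = None
    mu: float | None = None
    sigma: float | None = None


def classic_energy(x: Sequence[float]) -> float:
    """Total energy of a finite discrete signal: the sum of squared samples."""
    x = np.asarray(x, dtype=float).ravel()
    return float(np.sum(x * x))


def _neg_xlogx(p: np.ndarray, scale: float) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = -p[nz] * np.log(p[nz]) * scale
    return out + 0.0  # normalize IEEE -0.0 (from p == 1) to +0.0


def shannon_energy(
    a: NormalizedSignal | Sequence[float],
    fs: float | None = None,
    log_base: str = "e",
) -> EnergySignal:
    """Elementwise Shannon energy ``-a^2 log(a^2)`` of a normalized signal.

    ``log_base`` may be ``"e"`` (default), ``"2"`` or ``"10"``; the base only
    rescales the output by a constant. Samples with ``a == 0`` map to 0 by the
    continuity convention (no epsilon is added, so s(|a|=1) is exactly 0 and
    the transform is exactly even in ``a``).
    """
    if isinstance(a, NormalizedSignal):
        arr, fs = a.a, a.fs
    else:
        arr = np.asarray(a, dtype=float).ravel()
        if fs is None:
            raise ParameterError("fs is required when passing a bare array")
    if log_base not in _LOG_SCALE:
        raise ParameterError(f"log_base must be one of {sorted(_LOG_SCALE)}, got {log_base!r}")
    if arr.size and np.max(np.abs(arr)) > 1.0 + 1e-9:
        raise ParameterError(
            "Shannon energy requires |a| <= 1; normalize the signal first "
            f"(max |a| = {np.max(np.abs(arr)):.6g})"
        )
    p = np.minimum(arr * arr, 1.0)
    return EnergySignal(s=_neg_xlogx(p, _LOG_SCALE[log_base]), fs=fs)


def shannon_entropy(
    a: NormalizedSignal | Sequence[float],
    fs: float | None = None,
    log_base: str = "e",
) -> EnergySignal:
    """Alternative first-order form ``-|a| log |a|`` (not used by the detector)."""
    if isinstance(a, NormalizedSignal):
        arr, fs = a.a, a.fs
    else:
        arr = np.asarray(a, dtype=float).ravel()
        if fs is None:
            raise ParameterError("fs is required when passing a bare array")
    if log_base not in _LOG_SCALE:
        raise ParameterError(f"log_base must be one of {sorted(_LOG_SCALE)}, got {log_base!r}")
    return EnergySignal(s=_neg_xlogx(np.abs(arr), _LOG_SCALE[log_base]), fs=fs)


def standardize(es: EnergySignal) -> EnergySignal:
    """Z-score the energy sequence with its population (1/N) statistics.

    Populates ``s_std``, ``mu`` and ``sigma`` on a copy of the input.

    Raises
    ------
    DegenerateSignalError
        If the energy sequence is constant (sigma == 0).
    """
    s = np.asarray(es.s, dtype=float)
    if s.size == 0:
        raise InputError("cannot standardize an empty energy sequence")
    mu = float(np.mean(s))
    sigma = float(np.std(s))  # population (divide-by-N)
    if sigma == 0.0:
        raise DegenerateSignalError("constant energy sequence: standard deviation is zero")
    return EnergySignal(s=s, fs=es.fs, s_std=(s - mu) / sigma, mu=mu, sigma=sigma)
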