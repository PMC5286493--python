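"""Stage 4: adaptive thresholding, refractory pruning and R-peak localization.

The full detector composes the four stages:

1. zero-phase Butterworth band-pass (5–16 Hz) + max-abs normalization,
2. per-sample Shannon energy,
3. z-scoring, double boxcar smoothing into the envelope, differencing,
4. envelope local maxima -> adaptive threshold -> refractory pruning ->
   R localization as the argmax of |filtered signal| around each lobe.

The threshold is computed once per lead from the mean mu and population
standard deviation sigma of the smoothed envelope:

    thr = kappa * mu * (1 - sigma^2)   if sigma < mu
    thr = kappa * sigma * (1 - mu^2)   otherwise

(the two branches coincide at sigma == mu, so the tie is well defined).
On the standardized envelope mu is near 0 and sigma < 1, so the working
branch is effectively ``kappa * sigma`` — a noise-floor multiple.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np

from .envelope import CandidatePeaks, build_envelope, find_candidates
from .energy import shannon_energy, standardize
from .errors import InputError, ParameterError
from .io_ecg import ECGRecord
from .preprocess import FilteredSignal, bandpass_filter, normalize_amplitude

__all__ = [
    "DetectorConfig",
    "QRSDetections",
    "compute_threshold",
    "apply_threshold",
    "enforce_refractory",
    "localize_r_peaks",
    "detect_qrs",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Every free constant of the detection pipeline.

    Attributes
    ----------
    band_low, band_high : float
        Band-pass corner frequencies, Hz.
    filter_order : int
        Butterworth design order (applied forward-backward).
    L : int or float
        Envelope boxcar length: an ``int`` is taken as samples, a ``float``
        as seconds (default 0.10 s, i.e. 100 samples at 1 kHz).
    kappa : float
        Threshold scale constant.
    refractory_s : float
        Minimum spacing between accepted beats, seconds (default 250 ms,
        i.e. a 240 bpm ceiling). Besides suppressing double detections,
        this is what rejects tall T waves: a T lobe peaking ~200 ms after
        the R lobe falls inside the interval and loses to the taller lobe.
    search_window_s : float
        Half-width of the R-localization window around each envelope lobe.
    match_tolerance_s : float
        Beat-matching tolerance used by evaluation (ANSI/AAMI-style 150 ms).
    log_base : str
        Base of the Shannon-energy logarithm: "e", "2" or "10".
    """

    band_low: float = 5.0
    band_high: float = 16.0
    filter_order: int = 2
    L: int | float = 0.10
    kappa: float = 0.5
    refractory_s: float = 0.250
    search_window_s: float = 0.100
    match_tolerance_s: float = 0.150
    log_base: str = "e"

    def __post_init__(self) -> None:
        if self.band_low <= 0 or self.band_high <= self.band_low:
            raise ParameterError("require 0 < band_low < band_high")
        for name in ("filter_order", "L", "kappa", "refractory_s", "search_window_s", "match_tolerance_s"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")

    def window_samples(self, fs: float) -> int:
        """Resolve ``L`` to an integer sample count at sampling rate ``fs``."""
        if isinstance(self.L, int):
            return max(1, self.L)
        return max(1, int(round(self.L * fs)))

    @classmethod
    def from_file(cls, path: str) -> "DetectorConfig":
        """Load a config from JSON or TOML; unknown keys are rejected."""
        if path.endswith(".json"):
            with open(path) as fh:
                data = json.load(fh)
        else:
            import tomllib

            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class QRSDetections:
    """Detected R-peak locations for one lead (0-based sample indices)."""

    record_id: str
    lead_name: str
    r_samples: np.ndarray
    envelope_heights: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.r_samples = np.asarray(self.r_samples, dtype=np.int64)
        self.envelope_heights = np.asarray(self.envelope_heights, dtype=float)
        if self.r_samples.size and np.any(np.diff(self.r_samples) <= 0):
            raise InputError("detection sample indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.r_samples.size)

    def times_s(self) -> np.ndarray:
        return self.r_samples / self.fs


def compute_threshold(env_values: Sequence[float], kappa: float) -> float:
    """Adaptive envelope threshold from the envelope's own statistics."""
    v = np.asarray(env_values, dtype=float).ravel()
    if v.size == 0:
        raise InputError("cannot compute a threshold from an empty envelope")
    mu = float(np.mean(v))
    sigma = float(np.std(v))  # population
    if sigma < mu:
        return kappa * mu * (1.0 - sigma**2)
    return kappa * sigma * (1.0 - mu**2)


def apply_threshold(cands: CandidatePeaks, thr: float) -> CandidatePeaks:
    """Keep candidates whose envelope height strictly exceeds the threshold."""
    keep = cands.heights > thr
    return CandidatePeaks(indices=cands.indices[keep], heights=cands.heights[keep])


def enforce_refractory(cands: CandidatePeaks, refractory: int) -> CandidatePeaks:
    """Greedy left-to-right pruning so survivors are >= ``refractory`` apart.

    When two would-be survivors are closer than the refractory interval, the
    taller envelope lobe wins (ties go to the earlier one).
    """
    if len(cands) == 0:
        return cands
    kept_idx: list[int] = [int(cands.indices[0])]
    kept_h: list[float] = [float(cands.heights[0])]
    for i in range(1, len(cands)):
        idx, h = int(cands.indices[i]), float(cands.heights[i])
        if idx - kept_idx[-1] < refractory:
            if h > kept_h[-1]:
                kept_idx[-1], kept_h[-1] = idx, h
        else:
            kept_idx.append(idx)
            kept_h.append(h)
    return CandidatePeaks(indices=np.array(kept_idx), heights=np.array(kept_h))


def localize_r_peaks(
    dets: CandidatePeaks,
    f: FilteredSignal,
    window: int,
    *,
    record_id: str = "",
    lead_name: str = "",
) -> QRSDetections:
    """Refine each envelope lobe to the extremum of |f| within +/- ``window``.

    Using the absolute filtered amplitude makes localization symmetric in
    QRS polarity. Ties resolve to the leftmost sample; refined indices are
    re-sorted and deduplicated (the taller lobe's height is kept).
    """
    if window < 0:
        raise ParameterError("search window must be >= 0 samples")
    sig = np.abs(f.f)
    n = sig.size
    refined: dict[int, float] = {}
    for idx, h in zip(dets.indices, dets.heights):
        lo = max(0, int(idx) - window)
        hi = min(n, int(idx) + window + 1)
        j = lo + int(np.argmax(sig[lo:hi]))
        if j not in refined or h > refined[j]:
            refined[j] = float(h)
    order = sorted(refined)
    return QRSDetections(
        record_id=record_id,
        lead_name=lead_name,
        r_samples=np.array(order, dtype=np.int64),
        envelope_heights=np.array([refined[j] for j in order]),
        fs=f.fs,
    )


def detect_qrs(
    rec: ECGRecord, lead: str | None = None, cfg: DetectorConfig | None = None
) -> QRSDetections:
    """Run the full four-stage detector on one lead of a record.

    Parameters
    ----------
    rec : ECGRecord
    lead : str, optional
        Lead name; defaults to the record's first lead.
    cfg : DetectorConfig, optional
        Defaults to :class:`DetectorConfig()`.
    """
    cfg = cfg or DetectorConfig()
    lead = lead if lead is not None else rec.lead_names[0]
    x = rec.lead(lead)
    fs = rec.fs
    L = cfg.window_samples(fs)
    if x.size <= 2 * L:
        raise InputError(f"record of {x.size} samples is too short for envelope window L={L}")

    filt = bandpass_filter(x, fs, cfg.band_low, cfg.band_high, cfg.filter_order)
    norm = normalize_amplitude(filt)
    es = standardize(shannon_energy(norm, log_base=cfg.log_base))
    env = build_envelope(es, L)
    cands = find_candidates(env)
    thr = compute_threshold(env.m2, cfg.kappa)
    cands = apply_threshold(cands, thr)
    refractory = max(1, int(round(cfg.refractory_s * fs)))
    cands = enforce_refractory(cands, refractory)
    dets = localize_r_peaks(
        cands,
        filt,
        window=int(round(cfg.search_window_s * fs)),
        record_id=rec.record_id,
        lead_name=lead,
    )
    # localization can pull neighbours toward the same extremum region;
    # re-run the refractory rule on the refined indices
    pruned = enforce_refractory(
        CandidatePeaks(indices=dets.r_samples, heights=dets.envelope_heights), refractory
    )
    return QRSDetections(
        record_id=rec.record_id,
        lead_name=lead,
        r_samples=pruned.indices,
        envelope_heights=pruned.heights,
        fs=fs,
    )
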