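"""Summary statistics: tone responses, CSI, onset-aligned correlation,
excitatory/inhibitory balance, and tuning-curve light-on/off ratios."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "tone_response",
    "CSIResult",
    "csi",
    "CorrelationResult",
    "onset_aligned_correlation",
    "BalanceResult",
    "ei_balance",
    "tuning_light_ratio",
]


def tone_response(
    time_ms: np.ndarray,
    trace: np.ndarray,
    onset: float,
    offset: float,
    measure: str = "mean",
) -> float:
    """Mean or peak of a trace over a tone window [onset, offset)."""
    m = (time_ms >= onset) & (time_ms < offset)
    if not np.any(m):
        raise ValueError("empty tone window")
    seg = trace[m]
    if measure == "mean":
        return float(seg.mean())
    if measure == "peak":
        return float(seg.max())
    raise ValueError("measure must be 'mean' or 'peak'")


@dataclass
class CSIResult:
    """Common-contrast SSA index from the four mean responses.

    csi = (d1 + d2 - s1 - s2) / (d1 + d2 + s1 + s2); 1 means full
    adaptation (standards silent), 0 means none.  The result is masked
    invalid when a standard response falls below ``min_standard`` (the
    response floor) or when the excitatory response saturates.
    """

    d_f1: float
    d_f2: float
    s_f1: float
    s_f2: float
    csi: float
    valid: bool


def csi(
    d_f1: float,
    d_f2: float,
    s_f1: float,
    s_f2: float,
    min_standard: float = 0.1,
    saturated: bool = False,
) -> CSIResult:
    """Common-contrast SSA index of the four deviant/standard responses."""
    vals = (d_f1, d_f2, s_f1, s_f2)
    if any(v < 0 for v in vals):
        raise ValueError("responses must be nonnegative")
    denom = sum(vals)
    if denom <= 0:
        return CSIResult(d_f1, d_f2, s_f1, s_f2, np.nan, False)
    value = (d_f1 + d_f2 - s_f1 - s_f2) / denom
    valid = (min(s_f1, s_f2) >= min_standard) and not saturated
    return CSIResult(d_f1, d_f2, s_f1, s_f2, float(value), valid)


@dataclass
class CorrelationResult:
    r_control: float
    r_perturbed: float
    shift_ms: float  # applied to the perturbed trace only
    window_ms: tuple[float, float]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _onset_index(x: np.ndarray, frac: float = 0.1) -> int:
    peak = x.max()
    if peak <= 0:
        return 0
    idx = np.nonzero(x >= frac * peak)[0]
    return int(idx[0]) if len(idx) else 0


def aligned_correlation(
    x: np.ndarray,
    ref: np.ndarray,
    align: str = "max_xcorr",
    onset_of: np.ndarray | None = None,
    max_shift: int | None = None,
) -> tuple[float, int]:
    """Pearson correlation of ``x`` against ``ref`` after alignment.

    ``align``: "none"; "onset" shifts ``x`` so its onset (first sample over
    10 % of peak, or of ``onset_of`` when given) matches the reference
    onset; "max_xcorr" picks the shift maximizing the correlation.
    Returns (r, shift in samples, positive = x delayed relative to ref).
    """
    if len(x) != len(ref):
        raise ValueError("traces must share a time grid")
    if align == "none":
        return _pearson(x, ref), 0
    if align == "onset":
        src = x if onset_of is None else onset_of
        shift = _onset_index(src) - _onset_index(ref)
        return _pearson(np.roll(x, -shift), ref), shift
    if align == "max_xcorr":
        n = len(x)
        if max_shift is None:
            max_shift = n // 4
        best_r, best_s = -np.inf, 0
        for s in range(-max_shift, max_shift + 1):
            r = _pearson(np.roll(x, -s), ref)
            if np.isfinite(r) and r > best_r:
                best_r, best_s = r, s
        return best_r, best_s
    raise ValueError("align must be 'none', 'onset' or 'max_xcorr'")


def onset_aligned_correlation(
    exc_control: np.ndarray,
    exc_perturbed: np.ndarray,
    reference: np.ndarray,
    align: str = "max_xcorr",
    dt_ms: float = 1.0,
) -> CorrelationResult:
    """Control and perturbed Pearson correlations against a reference trace.

    The control trace is compared as-is; only the perturbed trace is
    aligned (by onset or by the cross-correlation peak) before comparison,
    mirroring how a delayed, sharpened response is scored against the
    thalamic input.
    """
    r_c = _pearson(exc_control, reference)
    r_p, shift = aligned_correlation(exc_perturbed, reference, align=align)
    return CorrelationResult(
        r_control=r_c, r_perturbed=r_p, shift_ms=shift * dt_ms,
        window_ms=(0.0, len(reference) * dt_ms),
    )


@dataclass
class BalanceResult:
    """E/I balance: peak current pairs across input strengths and the
    least-squares slope (through the origin) of excitatory on inhibitory."""

    exc_peaks: np.ndarray
    inh_peaks: np.ndarray
    slope: float
    residual: float


def ei_balance(
    exc_peaks,
    inh_peaks,
) -> BalanceResult:
    """Fit E = slope * I through the origin over per-run peak currents.

    Runs that never reached suprathreshold activity must be excluded by
    the caller (they contribute no point).
    """
    exc = np.asarray(exc_peaks, dtype=float)
    inh = np.asarray(inh_peaks, dtype=float)
    if len(exc) != len(inh) or len(exc) < 1:
        raise ValueError("need matched, nonempty current-peak arrays")
    denom = float(inh @ inh)
    if denom == 0:
        raise ValueError("all inhibitory peaks are zero")
    slope = float(exc @ inh) / denom
    residual = float(np.sqrt(np.mean((exc - slope * inh) ** 2)))
    return BalanceResult(exc, inh, slope, residual)


def tuning_light_ratio(
    responses_on: dict,
    responses_off: dict,
) -> dict:
    """Light-on/light-off response ratios per (frequency distance, tone index).

    Both inputs map (distance, tone_index) -> response.  Missing light-off
    responses (zero) yield NaN ratios rather than raising.
    """
    if set(responses_on) != set(responses_off):
        raise ValueError("light-on and light-off conditions must match")
    out = {}
    for key, on in responses_on.items():
        off = responses_off[key]
        out[key] = {
            "on": on,
            "off": off,
            "ratio": on / off if off > 0 else np.nan,
        }
    return out
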