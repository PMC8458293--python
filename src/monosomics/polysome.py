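"""Polysome-profile quantification.

A polysome profile is the UV absorbance measured along a sucrose gradient:
free 40S and 60S ribosomal subunits, the assembled 80S monosome, and the
polysome region appear as successive peaks.  The analysis smooths the raw
trace with a Savitzky-Golay filter (window 51-61 points, cubic), locates
the 40S/60S/80S peak maxima inside user-supplied search windows, rescales
profiles to a common 80S peak height for overlay, and reports the peak
height ratios (60S/40S etc.) that summarize subunit imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .simulate import PolysomeProfile

__all__ = [
    "SmoothingParams",
    "PeakSet",
    "smooth_profile",
    "locate_subunit_peaks",
    "scale_to_reference",
    "subunit_ratios",
]

SPECIES = ("40S", "60S", "80S")


@dataclass(frozen=True)
class SmoothingParams:
    """Savitzky-Golay window (odd, default 57 = midpoint of 51-61) and
    polynomial order (3)."""

    window: int = 57
    polyorder: int = 3

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if self.window <= self.polyorder:
            raise ValueError("window must exceed the polynomial order")


@dataclass
class PeakSet:
    """Located peaks: species -> (position, height), None if not detected."""

    peaks: dict[str, tuple[float, float] | None]
    windows: dict[str, tuple[float, float]]
    baseline: float

    def height(self, species: str) -> float:
        peak = self.peaks.get(species)
        if peak is None:
            raise ValueError(f"{species} peak not detected")
        return peak[1]


def _uniform(profile: PolysomeProfile) -> PolysomeProfile:
    """Resample onto a uniform grid by linear interpolation if needed."""
    steps = np.diff(profile.positions)
    if np.allclose(steps, steps[0], rtol=1e-6, atol=0):
        return profile
    grid = np.linspace(profile.positions[0], profile.positions[-1], len(profile.positions))
    return PolysomeProfile(grid, np.interp(grid, profile.positions, profile.absorbance),
                           profile.label)


def smooth_profile(profile: PolysomeProfile, params: SmoothingParams | None = None) -> PolysomeProfile:
    """Savitzky-Golay smoothing: local cubic least-squares fits.

    The filter reproduces any polynomial up to its order exactly, so true
    peak shapes are preserved while white noise is suppressed.  Edges are
    handled by evaluating the edge-window polynomial fit (no shortening of
    the trace).  Unevenly sampled traces are first resampled to a uniform
    grid, as the filter assumes equal spacing.
    """
    params = params or SmoothingParams()
    if len(profile.positions) < params.window:
        raise ValueError("trace shorter than the smoothing window")
    uni = _uniform(profile)
    smoothed = savgol_filter(uni.absorbance, params.window, params.polyorder, mode="interp")
    return PolysomeProfile(uni.positions, smoothed, profile.label)


def locate_subunit_peaks(
    profile: PolysomeProfile,
    search_windows: dict[str, tuple[float, float]],
    baseline: float | None = None,
    eps: float = 1e-3,
) -> PeakSet:
    """Global maximum of the (smoothed) trace within each species window.

    ``search_windows`` maps species (40S/60S/80S) to position intervals;
    they must be ordered 40S < 60S < 80S along the gradient and must not
    overlap.  A species whose window maximum does not rise above
    ``baseline + eps`` (baseline defaults to the trace minimum) is flagged
    not-detected rather than reported as a spurious peak.
    """
    lo_hi = [search_windows[s] for s in SPECIES if s in search_windows]
    for (a1, b1), (a2, b2) in zip(lo_hi, lo_hi[1:]):
        if b1 > a2:
            raise ValueError("species search windows must be ordered and non-overlapping")
    x, y = profile.positions, profile.absorbance
    if baseline is None:
        baseline = float(np.min(y))
    peaks: dict[str, tuple[float, float] | None] = {}
    for species, (lo, hi) in search_windows.items():
        if lo < x[0] or hi > x[-1]:
            raise ValueError(f"{species} window [{lo}, {hi}] outside trace range")
        mask = (x >= lo) & (x <= hi)
        if not mask.any():
            peaks[species] = None
            continue
        idx = np.argmax(y[mask])
        height = float(y[mask][idx])
        if height <= baseline + eps:
            peaks[species] = None
        else:
            peaks[species] = (float(x[mask][idx]), height)
    return PeakSet(peaks=peaks, windows=dict(search_windows), baseline=float(baseline))


def scale_to_reference(
    profile: PolysomeProfile,
    reference: PolysomeProfile,
    search_windows: dict[str, tuple[float, float]],
    params: SmoothingParams | None = None,
    smoothed: bool = False,
) -> PolysomeProfile:
    """Rescale a profile so its 80S peak matches the reference's 80S peak.

    The scaling factor is reference-80S-height / sample-80S-height, so
    overlaid profiles agree at the 80S monosome peak.  Peak-height ratios
    within a profile are invariant to this scaling.  Set ``smoothed`` when
    the inputs are already smoothed.
    """
    def _height(p: PolysomeProfile) -> float:
        sm = p if smoothed else smooth_profile(p, params)
        return locate_subunit_peaks(sm, search_windows).height("80S")

    factor = _height(reference) / _height(profile)
    return PolysomeProfile(profile.positions.copy(), profile.absorbance * factor, profile.label)


def subunit_ratios(peaks: PeakSet, subtract_baseline: bool = False) -> dict[str, float]:
    """Peak-height ratios 60S/40S, 80S/40S and 80S/60S.

    With ``subtract_baseline`` the estimated baseline is removed from each
    height before forming ratios.
    """
    def h(species: str) -> float:
        height = peaks.height(species)
        return height - peaks.baseline if subtract_baseline else height

    return {
        "60S/40S": h("60S") / h("40S"),
        "80S/40S": h("80S") / h("40S"),
        "80S/60S": h("80S") / h("60S"),
    }
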