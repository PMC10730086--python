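"""Axial intensity profiles and expression-domain metrics.

The reporter signal inside the paraboloid mask is collapsed to a 1D depth
profile (sum of masked voxel intensities per slice, depth 0 at the apex),
smoothed with a robust local quadratic (LOESS-style) filter, and the
expression domain along the apical-basal axis is delimited at 10% of the
profile maximum:

* ``ini(ED)`` — apical (upper) domain boundary, um below the apex;
* ``pos(Imax)`` — depth of the intensity maximum;
* ``end(ED)`` — basal (lower) boundary;
* extent = end(ED) - ini(ED); total intensity = sum of profile values
  within the domain.

If a side of the profile never drops below the threshold the boundary is
clamped to the sample nearest the threshold and flagged, so that diffuse
domains reaching the stack limits are still measured.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .maskfit import RegionMask
from .stack import ImageStack
from .stats import compact_letters, mannwhitney_u


@dataclass
class DepthProfile:
    """Ordered (depth, intensity) samples; depth 0 at the apex slice."""

    depth_um: np.ndarray
    intensity: np.ndarray
    state: str = "raw"  # "raw" | "smoothed"

    def __post_init__(self) -> None:
        self.depth_um = np.asarray(self.depth_um, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.depth_um.shape != self.intensity.shape or self.depth_um.ndim != 1:
            raise ValueError("depth and intensity must be matching 1D arrays")
        if np.any(np.diff(self.depth_um) <= 0):
            raise ValueError("depths must be strictly increasing")
        if self.state == "raw" and np.any(self.intensity < 0):
            raise ValueError("raw intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.depth_um)

    @property
    def dz(self) -> float:
        return float(self.depth_um[1] - self.depth_um[0])


@dataclass
class DomainMetrics:
    """Domain boundaries, peak position and integrated intensity for one SAM."""

    ini_ed: float
    pos_imax: float
    end_ed: float
    total_intensity: float
    ini_flag: str = "crossed"   # "crossed" | "clamped-to-nearest"
    end_flag: str = "crossed"

    @property
    def extent(self) -> float:
        return self.end_ed - self.ini_ed

    def __post_init__(self) -> None:
        if not (self.ini_ed <= self.pos_imax <= self.end_ed):
            raise ValueError("boundary ordering ini <= pos <= end violated")


def extract_profile(
    reporter: ImageStack,
    mask: RegionMask,
    apex_um: tuple[float, float, float],
    statistic: str = "sum",
) -> DepthProfile:
    """Sum-of-the-slices projection of the masked reporter channel.

    For each slice at or below the apex, the profile value is the sum (or
    mean, with ``statistic='mean'``) of reporter voxels inside the mask.
    Slices above the apex are excluded; depth is measured from the apex.
    """
    if mask.mask.shape != reporter.data.shape:
        raise ValueError("mask shape does not match the stack")
    if not mask.mask.any():
        raise ValueError("empty mask")
    k0 = int(round(apex_um[2] / reporter.dz))
    data = reporter.data.astype(float)
    masked = np.where(mask.mask, data, 0.0)
    sums = masked[k0:].sum(axis=(1, 2))
    if statistic == "mean":
        counts = mask.mask[k0:].sum(axis=(1, 2))
        sums = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    elif statistic != "sum":
        raise ValueError("statistic must be 'sum' or 'mean'")
    depths = (np.arange(k0, reporter.nz) - k0) * reporter.dz
    return DepthProfile(depths, sums, state="raw")


def smooth_profile(
    profile: DepthProfile, span: float = 0.25, iterations: int = 2
) -> DepthProfile:
    """Robust local quadratic (degree-2 LOESS) smoothing of a depth profile.

    At each sample a quadratic is fitted by weighted least squares to the
    ``ceil(span * n)`` nearest samples using tricube distance weights; after
    each full pass residuals are bisquare-reweighted (Tukey biweight on
    residuals scaled by 6x the median absolute residual) for ``iterations``
    robustness passes, down-weighting outlier samples.  Deterministic; a
    pure quadratic input is reproduced exactly.
    """
    n = len(profile)
    if n < 7:
        raise ValueError("need at least 7 samples to smooth")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    d = profile.depth_um
    y = profile.intensity
    k = max(7, int(np.ceil(span * n)))
    k = min(k, n)

    robust = np.ones(n)
    fitted = y.copy()
    for it in range(iterations + 1):
        fitted = np.empty(n)
        for i in range(n):
            # nearest-k window is contiguous on a sorted grid
            lo = max(0, i - k + 1)
            best_lo, best_span = lo, np.inf
            for start in range(lo, min(i, n - k) + 1):
                h = max(d[i] - d[start], d[start + k - 1] - d[i])
                if h < best_span:
                    best_span, best_lo = h, start
            sl = slice(best_lo, best_lo + k)
            du = d[sl] - d[i]
            h = max(best_span, 1e-12)
            w = (1.0 - np.minimum(np.abs(du) / h, 1.0) ** 3) ** 3
            w = w * robust[sl]
            if np.count_nonzero(w) < 3:
                w = robust[sl] + 1e-12
            coeffs = np.polyfit(du, y[sl], 2, w=np.sqrt(w))
            fitted[i] = coeffs[-1]
        if it == iterations:
            break
        resid = y - fitted
        # floor the bisquare scale at a relative tolerance so that machine-
        # precision residuals on exactly-fitted data never zero out weights
        s = max(np.median(np.abs(resid)), 1e-9 * max(1.0, float(np.max(np.abs(y)))))
        robust = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    return DepthProfile(d.copy(), fitted, state="smoothed")


def locate_peak(profile: DepthProfile) -> tuple[float, float]:
    """Depth and value of the profile maximum; ties broken toward the apex."""
    if np.all(profile.intensity <= 0):
        raise ValueError("no signal: profile has no positive intensity")
    i = int(np.argmax(profile.intensity))  # argmax returns the first maximum
    return float(profile.depth_um[i]), float(profile.intensity[i])


def _boundary_one_side(
    d: np.ndarray, y: np.ndarray, i_peak: int, thr: float, side: int
) -> tuple[float, str]:
    """Scan outward from the peak; side=-1 apical, side=+1 basal."""
    idx = range(i_peak - 1, -1, -1) if side < 0 else range(i_peak + 1, len(y))
    prev = i_peak
    for j in idx:
        if y[j] <= thr:
            # linear interpolation between the inner (above) and outer sample
            y0, y1 = y[prev], y[j]
            if y1 == y0:
                return float(d[j]), "crossed"
            frac = (y0 - thr) / (y0 - y1)
            return float(d[prev] + frac * (d[j] - d[prev])), "crossed"
        prev = j
    # never dropped below the threshold on this side: the sample nearest the
    # threshold wins, ties resolved away from the peak (the domain is taken
    # to extend as far as the data allow)
    sl = slice(0, i_peak + 1) if side < 0 else slice(i_peak, len(y))
    offset = 0 if side < 0 else i_peak
    diffs = np.abs(y[sl] - thr)
    if side < 0:
        j = offset + int(np.argmin(diffs))
    else:
        j = offset + len(diffs) - 1 - int(np.argmin(diffs[::-1]))
    return float(d[j]), "clamped-to-nearest"


def detect_boundaries(
    profile: DepthProfile,
    pos_imax: float,
    threshold_frac: float = 0.1,
) -> tuple[float, float, dict[str, str]]:
    """Domain boundaries at ``threshold_frac`` of the profile maximum.

    Scanning apically (and basally) from the peak, the boundary is the
    linearly interpolated depth at which the intensity first reaches the
    threshold.  A side that never falls below the threshold is clamped to
    its sample nearest the threshold and flagged ``clamped-to-nearest``.
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold fraction must be in (0, 1)")
    d, y = profile.depth_um, profile.intensity
    i_peak = int(np.argmin(np.abs(d - pos_imax)))
    imax = y[i_peak]
    if imax <= 0:
        raise ValueError("no signal: maximum intensity is zero")
    thr = threshold_frac * imax
    ini, ini_flag = _boundary_one_side(d, y, i_peak, thr, side=-1)
    end, end_flag = _boundary_one_side(d, y, i_peak, thr, side=+1)
    return ini, end, {"ini": ini_flag, "end": end_flag}


def integrate_domain(profile: DepthProfile, ini_ed: float, end_ed: float) -> float:
    """Sum of profile samples with depth in the closed interval [ini, end]."""
    if ini_ed > end_ed:
        raise ValueError("ini_ed must not exceed end_ed")
    d = profile.depth_um
    if ini_ed < d[0] - 1e-9 or end_ed > d[-1] + 1e-9:
        raise ValueError("integration interval lies outside the profile")
    sel = (d >= ini_ed - 1e-9) & (d <= end_ed + 1e-9)
    return float(profile.intensity[sel].sum())


def quantify_profile(
    profile: DepthProfile, threshold_frac: float = 0.1
) -> DomainMetrics:
    """Peak, boundaries and integrated intensity of one smoothed profile."""
    pos, _ = locate_peak(profile)
    ini, end, flags = detect_boundaries(profile, pos, threshold_frac)
    total = integrate_domain(profile, ini, end)
    return DomainMetrics(
        ini_ed=ini,
        pos_imax=pos,
        end_ed=end,
        total_intensity=total,
        ini_flag=flags["ini"],
        end_flag=flags["end"],
    )


def compare_groups(
    samples: dict[str, np.ndarray], alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Pairwise two-sided Mann-Whitney U tests with a compact letter display.

    Returns a table (group1, group2, u, p, method) and a letters dict;
    groups sharing a letter are not significantly different at ``alpha``.
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for g in names:
        if len(samples[g]) < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")
    rows = []
    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            u, p, method = mannwhitney_u(samples[a], samples[b])
            rows.append({"group1": a, "group2": b, "u": u, "p": p, "method": method})
            pairwise[(a, b)] = p
    means = {g: float(np.mean(samples[g])) for g in names}
    letters = compact_letters(names, pairwise, means, alpha=alpha)
    return pd.DataFrame(rows), letters
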