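"""Fragment sizing: ROX ladder matching and Local Southern size calling.

Electrophoretic mobility and fragment length are reciprocally related: to a
good approximation the arrival scan of a fragment of length ``L`` follows

    m(L) = m0 + c / (L - L0)

for instrument constants ``c``, ``m0``, ``L0``.  The Local Southern method
exploits this locally: for an unknown fragment it takes the four nearest
internal size standards (two below, two above), fits the reciprocal law
exactly through each group of three consecutive standards, and averages the
two predicted sizes.  Two comparator methods are provided: Global Southern
(one reciprocal curve least-squares fitted to all standards) and a
third-order polynomial fit (``cubic_ls``).

The internal standard is a ROX-labeled ladder (GS500-style, 35-500 nt).
Ladder matching assigns the known fragment sizes to a monotone subset of
detected ROX apexes, choosing the subset whose scan/size pairs are best
explained by a single reciprocal-law curve.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .peaks import Peak

#: canonical GS500-style ladder fragment sizes (nt)
GS500_SIZES = (35, 50, 75, 100, 139, 150, 160, 200, 250, 300, 340, 350, 400, 450, 490, 500)


class SizingError(RuntimeError):
    """A sizing computation could not be carried out."""


class LadderError(SizingError):
    """The internal size standard could not be matched; the run is unusable."""


class UnsizedPeakError(SizingError):
    """The scan lies outside the usable interpolation interval."""


@dataclass(frozen=True)
class LadderSpec:
    """Internal size-standard definition: dye and ascending fragment sizes (nt)."""

    dye: str = "ROX"
    sizes: tuple[float, ...] = GS500_SIZES

    def __post_init__(self) -> None:
        s = np.asarray(self.sizes, dtype=float)
        if len(s) < 4:
            raise ValueError("ladder needs at least 4 fragments")
        if not np.all(np.diff(s) > 0):
            raise ValueError("ladder sizes must be strictly increasing")
        if s[0] < 35 or s[-1] > 500:
            raise ValueError("ladder sizes must lie within [35, 500] nt")


@dataclass
class LadderFit:
    """Matched (apex scan, known size) pairs and the usable interval.

    Local Southern needs two standards on each side, so the usable
    interpolation interval spans the 2nd to the (n-1)th matched standard.
    """

    scans: np.ndarray
    sizes: np.ndarray
    rms_bp: float = 0.0
    partial: bool = False
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.scans = np.asarray(self.scans, dtype=float)
        self.sizes = np.asarray(self.sizes, dtype=float)
        if len(self.scans) != len(self.sizes) or len(self.scans) < 4:
            raise LadderError("need at least 4 matched (scan, size) pairs")
        if not (np.all(np.diff(self.scans) > 0) and np.all(np.diff(self.sizes) > 0)):
            raise LadderError("matched pairs must be monotone in both coordinates")

    @property
    def interval(self) -> tuple[float, float]:
        return float(self.scans[1]), float(self.scans[-2])


# ---------------------------------------------------------------------------
# Reciprocal-law fitting


def reciprocal_through_3(scans, sizes) -> tuple[float, float, float]:
    """Exact reciprocal-law fit L = c/(m - m0) + L0 through three points.

    Closed-form solve; raises :class:`SizingError` for degenerate
    (collinear) configurations where the curvature vanishes.
    """
    (m1, m2, m3), (l1, l2, l3) = (map(float, scans), map(float, sizes))
    den = (l2 - l3) * (m2 - m1)
    if den == 0:
        raise SizingError("degenerate standards (coincident points)")
    rho = (l1 - l2) * (m3 - m2) / den
    if abs(rho - 1.0) < 1e-12:
        raise SizingError("degenerate standards (collinear points)")
    m0 = (m3 - rho * m1) / (1.0 - rho)
    c = (l1 - l2) * (m1 - m0) * (m2 - m0) / (m2 - m1)
    l0 = l1 - c / (m1 - m0)
    return c, m0, l0


def _predict(scan: float, params: tuple[float, float, float]) -> float:
    c, m0, l0 = params
    return c / (scan - m0) + l0


def fit_reciprocal_lsq(scans, sizes) -> tuple[float, float, float]:
    """Least-squares fit of one reciprocal curve to all (scan, size) pairs."""
    scans = np.asarray(scans, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if len(scans) < 3:
        raise SizingError("need >= 3 standards for a reciprocal fit")
    mid = len(scans) // 2
    try:
        x0 = reciprocal_through_3(scans[[0, mid, -1]], sizes[[0, mid, -1]])
    except SizingError:
        x0 = (-(scans[-1] - scans[0]) * 100.0, scans[-1] + 1000.0, 0.0)

    def resid(x):
        c, m0, l0 = x
        return c / (scans - m0) + l0 - sizes

    sol = least_squares(resid, x0, method="lm", max_nfev=200)
    return tuple(sol.x)


# ---------------------------------------------------------------------------
# Ladder matching


def _subset_rms(scans: np.ndarray, sizes: np.ndarray) -> float:
    params = fit_reciprocal_lsq(scans, sizes)
    return float(np.sqrt(np.mean((sizes - _predict(scans, params)) ** 2)))


def _cheap_rms(scans: np.ndarray, sizes: np.ndarray) -> float:
    coef = np.polynomial.polynomial.polyfit(scans, sizes, 3)
    resid = sizes - np.polynomial.polynomial.polyval(scans, coef)
    return float(np.sqrt(np.mean(resid**2)))


def match_ladder(
    rox_peaks: list[Peak],
    ladder: LadderSpec,
    *,
    strict: bool = True,
    max_rms_bp: float = 2.0,
    max_extra: int = 6,
) -> LadderFit:
    """Assign ladder fragment sizes to a monotone subset of ROX apexes.

    Candidate apexes are taken in scan order; because ladder sizes ascend,
    any chosen subset is automatically a monotone assignment.  Among all
    subsets of the right cardinality the one minimizing the RMS residual of
    a single reciprocal-law fit is kept; artifacts (e.g. a surviving tall
    spike) distort that fit and are excluded.  A best RMS above
    ``max_rms_bp`` raises :class:`LadderError`.

    With ``strict=False`` a deficit of up to two apexes is tolerated by
    dropping ladder fragments, returning a fit flagged ``partial``.
    """
    cands = sorted(rox_peaks, key=lambda p: p.apex_scan)
    sizes = np.asarray(ladder.sizes, dtype=float)
    n_lad = len(sizes)

    if len(cands) < n_lad:
        if strict or len(cands) < n_lad - 2:
            raise LadderError(
                f"only {len(cands)} ROX candidates for {n_lad} ladder fragments"
            )
        return _match_partial(cands, sizes, max_rms_bp)

    if len(cands) > n_lad + max_extra:  # keep the tallest plausible candidates
        keep = sorted(
            sorted(cands, key=lambda p: p.height, reverse=True)[: n_lad + max_extra],
            key=lambda p: p.apex_scan,
        )
        cands = keep

    scans = np.array([p.apex_scan for p in cands])
    n = len(scans)
    combos = list(itertools.combinations(range(n), n_lad))
    if len(combos) > 1:
        scored = sorted(
            combos, key=lambda ix: _cheap_rms(scans[list(ix)], sizes)
        )[:20]
    else:
        scored = combos

    best, best_rms = None, np.inf
    for ix in scored:
        sub = scans[list(ix)]
        try:
            rms = _subset_rms(sub, sizes)
        except SizingError:
            continue
        if rms < best_rms:
            best, best_rms = sub, rms

    if best is None or best_rms > max_rms_bp:
        raise LadderError(
            f"no ladder assignment fits a reciprocal curve "
            f"(best RMS {best_rms:.2f} bp > {max_rms_bp:g} bp)"
        )
    return LadderFit(scans=best, sizes=sizes, rms_bp=best_rms)


def _match_partial(cands, sizes, max_rms_bp) -> LadderFit:
    scans = np.array([p.apex_scan for p in cands])
    deficit = len(sizes) - len(scans)
    best, best_rms, best_sizes = None, np.inf, None
    for drop in itertools.combinations(range(len(sizes)), deficit):
        sub_sizes = np.delete(sizes, drop)
        try:
            rms = _subset_rms(scans, sub_sizes)
        except SizingError:
            continue
        if rms < best_rms:
            best, best_rms, best_sizes = scans, rms, sub_sizes
    if best is None or best_rms > max_rms_bp:
        raise LadderError("partial ladder match failed")
    return LadderFit(scans=best, sizes=best_sizes, rms_bp=best_rms, partial=True)


# ---------------------------------------------------------------------------
# Size calling


def local_southern_size(scan: float, fit: LadderFit) -> float:
    """Size one fragment by the Local Southern method.

    Takes the four matched standards nearest ``scan`` (two below, two
    above), fits the reciprocal law exactly through each run of three
    consecutive standards, and returns the mean of the two predictions.
    A scan coinciding with a matched standard returns that standard's size
    exactly (the curves pass through it).
    """
    ms, ls = fit.scans, fit.sizes
    hit = np.nonzero(np.isclose(ms, scan, rtol=0.0, atol=1e-9))[0]
    if hit.size:
        return float(ls[hit[0]])
    i = int(np.searchsorted(ms, scan))
    if i < 2 or i > len(ms) - 2:
        raise UnsizedPeakError(
            f"scan {scan:g} lacks two matched standards on each side"
        )
    lo = reciprocal_through_3(ms[i - 2 : i + 1], ls[i - 2 : i + 1])
    hi = reciprocal_through_3(ms[i - 1 : i + 2], ls[i - 1 : i + 2])
    return 0.5 * (_predict(scan, lo) + _predict(scan, hi))


def comparator_size(scan: float, fit: LadderFit, method: str) -> float:
    """Size one fragment with a whole-ladder comparator method.

    ``global_southern`` fits one reciprocal curve to all matched standards;
    ``cubic_ls`` fits one third-order polynomial size(scan).  Fit
    parameters are cached on the :class:`LadderFit`.
    """
    if method == "global_southern":
        if "global" not in fit._cache:
            fit._cache["global"] = fit_reciprocal_lsq(fit.scans, fit.sizes)
        return float(_predict(scan, fit._cache["global"]))
    if method == "cubic_ls":
        if len(fit.scans) < 4:
            raise SizingError("cubic_ls needs >= 4 standards")
        if "cubic" not in fit._cache:
            fit._cache["cubic"] = np.polynomial.polynomial.polyfit(
                fit.scans, fit.sizes, 3
            )
        return float(np.polynomial.polynomial.polyval(scan, fit._cache["cubic"]))
    raise ValueError(f"unknown sizing method {method!r}")


@dataclass
class SizedPeak:
    """A detected peak with an assigned base-pair size (or an unsized flag)."""

    channel: str
    apex_scan: float
    height: float
    half_width_points: float
    area: float
    size_bp: float | None
    method: str
    sized: bool

    @classmethod
    def from_peak(cls, peak: Peak, size_bp: float | None, method: str) -> "SizedPeak":
        return cls(
            channel=peak.channel,
            apex_scan=peak.apex_scan,
            height=peak.height,
            half_width_points=peak.half_width_points,
            area=peak.area,
            size_bp=size_bp,
            method=method,
            sized=size_bp is not None,
        )


def size_peaks(
    peaks: list[Peak], fit: LadderFit, method: str = "local_southern"
) -> list[SizedPeak]:
    """Size every peak; peaks outside the usable interval are flagged, not dropped."""
    out: list[SizedPeak] = []
    for p in peaks:
        try:
            if method == "local_southern":
                size = local_southern_size(p.apex_scan, fit)
            else:
                size = comparator_size(p.apex_scan, fit, method)
                lo, hi = fit.interval
                if not lo <= p.apex_scan <= hi:
                    raise UnsizedPeakError("outside interpolation interval")
        except UnsizedPeakError:
            size = None
        out.append(SizedPeak.from_peak(p, size, method))
    return out
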