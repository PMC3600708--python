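"""Allele calling: range filters, binning, stutter handling, mono cut-off.

Sized peaks become allele calls in four steps:

1. **Range filtering** -- peaks falling inside the dye/group exclusion
   interval (the gap between same-dye marker windows, where bleed-through
   artifacts land) are removed.
2. **Marker assignment** -- remaining peaks are assigned to the marker of
   their dye whose analysis window contains them.
3. **Binning** -- each peak size is snapped to the nearest integer bin
   center if within the maximum offset (+/-0.5 bp by default); exact ties
   break toward the lower center.
4. **Calling** -- dinucleotide markers: peaks one repeat unit below a
   taller peak at <= the stutter threshold are discarded as polymerase
   stutter, then the tallest one or two binned survivors are called.
   Mononucleotide (quasimonomorphic) markers: the tallest peak is allele 1
   and any other in-window peak whose height ratio strictly exceeds the
   mono cut-off (0.95) is an additional allele.

Because PCR is run under conditions promoting full 3' adenylation, apparent
fragment sizes sit one nucleotide above the template lattice; bin centers
(seeded from reference observations) absorb that +1 shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import AnalysisParams, MarkerDef, PanelConfig
from .peaks import Trace, detect_peaks
from .sizing import LadderError, LadderFit, SizedPeak, match_ladder, size_peaks

#: default dinucleotide stutter-rejection height-ratio threshold
STUTTER_THRESHOLD = 0.8
#: size tolerance (bp) when deciding whether two peaks are one repeat apart
REPEAT_MATCH_TOL = 0.5
#: apparent-size shift from full 3' adenylation
ADENYLATION_SHIFT = 1


@dataclass(frozen=True)
class BinSet:
    """Integer bin centers for one marker, with the maximum allowed offset."""

    marker: str
    centers: tuple[int, ...]
    max_offset: float = 0.5

    def __post_init__(self) -> None:
        if not self.centers:
            raise ValueError(f"{self.marker}: empty bin set")
        diffs = np.diff(self.centers)
        if len(diffs) and np.any(diffs <= 0):
            raise ValueError(f"{self.marker}: bin centers must ascend")
        spacing = int(diffs.min()) if len(diffs) else 1
        if not 0 < self.max_offset <= spacing / 2:
            raise ValueError(
                f"{self.marker}: max_offset must lie in (0, {spacing / 2}]"
            )


@dataclass
class AlleleCall:
    """One called allele: observed size, bin label, height and height rank."""

    marker: str
    size_bp: float
    bin: int
    height: float
    ratio: float  # height / tallest in-window peak height
    rank: int  # 1 = tallest


@dataclass
class GenotypeProfile:
    """Per-marker allele calls for one amplification run."""

    run_id: str
    calls: dict[str, list[AlleleCall]] = field(default_factory=dict)
    flags: dict[str, list[str]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def bins(self, marker: str) -> list[int]:
        return [c.bin for c in self.calls.get(marker, [])]

    def genotype_bins(self, marker: str) -> tuple[int, ...] | None:
        """Allele pair as bins; a single call is expanded to a homozygote."""
        b = sorted(self.bins(marker))
        if not b:
            return None
        if len(b) == 1:
            return (b[0], b[0])
        return tuple(b[:2]) if len(b) == 2 else tuple(b)

    def merged(self, other: "GenotypeProfile") -> "GenotypeProfile":
        """Combine the profiles of the two multiplex groups of one sample."""
        out = GenotypeProfile(self.run_id, dict(self.calls), dict(self.flags),
                              {**self.meta, **other.meta})
        out.calls.update(other.calls)
        for m, f in other.flags.items():
            out.flags.setdefault(m, []).extend(f)
        return out


# ---------------------------------------------------------------------------
# Bin construction


def default_binsets(
    panel: PanelConfig, shift: int = ADENYLATION_SHIFT
) -> dict[str, BinSet]:
    """Default bins on each marker's apparent-size lattice.

    Mononucleotide markers get a bin at every integer in the window.
    Dinucleotide markers get bins two apart on the allele lattice shifted
    by the adenylation offset.
    """
    bins: dict[str, BinSet] = {}
    for m in panel.markers:
        if m.repeat_unit == 1:
            lo, hi = int(np.ceil(m.window_min)), int(np.floor(m.window_max))
            centers = tuple(range(lo, hi + 1))
        else:
            centers = tuple(c + shift for c in m.allele_lattice())
        bins[m.name] = BinSet(marker=m.name, centers=centers)
    return bins


def bins_from_observations(
    sizes_by_marker: dict[str, list[float]],
    panel: PanelConfig,
    max_offset: float = 0.5,
) -> dict[str, BinSet]:
    """Seed bins from observed reference-run sizes.

    Observed modal sizes are rounded to integers; the lattice is then
    extended by the repeat unit across the whole marker window so unseen
    alleles of the same parity are also callable.  This mirrors defining
    bins from a large reference dataset of sized alleles.
    """
    bins: dict[str, BinSet] = {}
    for m in panel.markers:
        obs = sizes_by_marker.get(m.name, [])
        if not obs:
            continue
        anchors = sorted({int(round(s)) for s in obs})
        lo, hi = int(np.ceil(m.window_min)), int(np.floor(m.window_max))
        step = m.repeat_unit
        origin = anchors[0]
        first = origin - ((origin - lo) // step) * step
        centers = tuple(c for c in range(first, hi + 1, step))
        bins[m.name] = BinSet(marker=m.name, centers=centers, max_offset=max_offset)
    return bins


# ---------------------------------------------------------------------------
# Core operations


def range_filter(
    sized_peaks: list[SizedPeak], params: AnalysisParams, group: int
) -> list[SizedPeak]:
    """Drop peaks inside the exclusion interval of their dye for ``group``.

    The filter intervals (closed) occupy the gap between same-dye marker
    windows, so bleed-through artifacts landing there never reach marker
    assignment.  Unsized peaks pass through untouched (they are flagged
    elsewhere, never silently dropped).
    """
    filters = params.range_filters.get(group, {})
    out = []
    for p in sized_peaks:
        iv = filters.get(p.channel)
        if iv is not None and p.sized and iv[0] <= p.size_bp <= iv[1]:
            continue
        out.append(p)
    return out


def assign_bin(size_bp: float, bins: BinSet) -> int | None:
    """Nearest bin center within the maximum offset, ties toward the lower center."""
    centers = np.asarray(bins.centers)
    dist = np.abs(centers - size_bp)
    i = int(np.argmin(dist))  # argmin takes the first (lower) center on ties
    if dist[i] <= bins.max_offset:
        return int(centers[i])
    return None


def _in_window(peaks: list[SizedPeak], marker: MarkerDef) -> list[SizedPeak]:
    return [
        p
        for p in peaks
        if p.sized and p.channel == marker.dye and marker.contains(p.size_bp)
    ]


def call_dinucleotide(
    marker_peaks: list[SizedPeak],
    marker: MarkerDef,
    bins: BinSet,
    stutter_threshold: float = STUTTER_THRESHOLD,
) -> tuple[list[AlleleCall], list[str]]:
    """Call up to two alleles for a dinucleotide marker.

    A peak lying one repeat unit below a taller peak with a height ratio at
    or below ``stutter_threshold`` is discarded as stutter (a true
    heterozygote one repeat apart keeps a near-1 ratio and survives).  The
    tallest binned survivor is allele 1; the second tallest, if any, is
    allele 2.  Extra binned survivors raise a nonspecific-interference
    flag; a low second-allele ratio raises an unequal-amplification flag.
    """
    flags: list[str] = []
    if not marker_peaks:
        return [], ["no-call"]
    tallest = max(p.height for p in marker_peaks)
    unit = marker.repeat_unit

    survivors = []
    for p in marker_peaks:
        is_stutter = any(
            q.height > p.height
            and abs((q.size_bp - p.size_bp) - unit) <= REPEAT_MATCH_TOL
            and p.height / q.height <= stutter_threshold
            for q in marker_peaks
        )
        if not is_stutter:
            survivors.append(p)

    binned = [(p, assign_bin(p.size_bp, bins)) for p in survivors]
    binned = [(p, b) for p, b in binned if b is not None]
    if not binned:
        return [], ["no-call"]
    if len(binned) > 2:
        flags.append("nonspecific-interference")
    binned.sort(key=lambda t: (-t[0].height, t[1]))
    calls = [
        AlleleCall(marker.name, p.size_bp, b, p.height, p.height / tallest, rank)
        for rank, (p, b) in enumerate(binned[:2], start=1)
    ]
    if len(calls) == 2 and calls[1].ratio < 0.5:
        flags.append("unequal-amplification")
    return calls, flags


def call_mono(
    marker_peaks: list[SizedPeak],
    marker: MarkerDef,
    bins: BinSet,
    mono_cutoff: float = 0.95,
) -> tuple[list[AlleleCall], list[str]]:
    """Call alleles of a quasimonomorphic mononucleotide marker.

    Allele 1 is the tallest in-window peak (height ties break toward the
    smaller size); every other peak whose height ratio is strictly greater
    than ``mono_cutoff`` is an additional allele.  With typical stutter
    (adjacent ratio r), the second stutter sits at r^2 < 0.95, so a stable
    sample yields at most two alleles.
    """
    if not marker_peaks:
        return [], ["no-call"]
    ordered = sorted(marker_peaks, key=lambda p: (-p.height, p.size_bp))
    top = ordered[0]
    calls = []
    rank = 1
    for p in ordered:
        ratio = p.height / top.height
        if p is not top and ratio <= mono_cutoff:
            continue
        b = assign_bin(p.size_bp, bins)
        if b is None:
            continue
        calls.append(AlleleCall(marker.name, p.size_bp, b, p.height, ratio, rank))
        rank += 1
    flags = ["instability?"] if len(calls) > 2 else []
    return calls, flags


def genotype_run(
    source: Trace | list[SizedPeak],
    panel: PanelConfig,
    group: int,
    *,
    method: str = "local_southern",
    run_id: str = "run",
    stutter_threshold: float = STUTTER_THRESHOLD,
    strict_ladder: bool = True,
) -> GenotypeProfile:
    """Full per-run genotyping: detect, size, filter, and call one group.

    ``source`` may be a raw :class:`Trace` (peaks are detected and sized
    here) or an already sized peak list.  A ladder failure propagates as a
    run-level no-call profile flagged ``ladder-failure``.
    """
    if isinstance(source, Trace):
        try:
            detected = detect_peaks(source, panel.params, group)
            fit = match_ladder(
                detected[panel.ladder.dye], panel.ladder, strict=strict_ladder
            )
        except LadderError as err:
            prof = GenotypeProfile(run_id, meta={"group": group, "method": method})
            for m in panel.group_markers(group):
                prof.calls[m.name] = []
                prof.flags[m.name] = ["ladder-failure"]
            prof.meta["error"] = str(err)
            return prof
        sized = []
        for dye in ("FAM", "HEX", "NED"):
            sized.extend(size_peaks(detected[dye], fit, method))
    else:
        sized = list(source)

    retained = range_filter(sized, panel.params, group)
    prof = GenotypeProfile(run_id, meta={"group": group, "method": method})
    for m in panel.group_markers(group):
        in_win = _in_window(retained, m)
        if m.repeat_unit == 1:
            calls, flags = call_mono(in_win, m, panel.bins[m.name],
                                     panel.params.mono_cutoff)
        else:
            calls, flags = call_dinucleotide(in_win, m, panel.bins[m.name],
                                             stutter_threshold)
        prof.calls[m.name] = calls
        prof.flags[m.name] = flags
    return prof


def genotype_sample(
    traces: dict[int, Trace], panel: PanelConfig, run_id: str = "sample", **kw
) -> GenotypeProfile:
    """Genotype both multiplex groups of one sample and merge the profiles."""
    profiles = [
        genotype_run(trace, panel, group, run_id=run_id, **kw)
        for group, trace in sorted(traces.items())
    ]
    out = profiles[0]
    for p in profiles[1:]:
        out = out.merged(p)
    return out
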