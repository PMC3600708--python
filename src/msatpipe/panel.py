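"""Assay definition for the 11-marker multiplexed microsatellite panel.

The assay amplifies 11 microsatellite loci in two multiplex PCR groups
(6 markers in group 1, 5 in group 2), each primer pair labeled with one of
three fluorescent dyes (FAM, HEX, NED) and co-electrophoresed with a
ROX-labeled internal size standard.  Same-dye markers within a group are
placed at least 40 nt apart in product size so their signals never overlap
on the size axis.

This module houses the panel data model (:class:`MarkerDef`,
:class:`AnalysisParams`, :class:`PanelConfig`), the bundled canonical panel,
JSON (de)serialization, and design-rule validation.

Range filters
-------------
Each dye/group pair carries a *range filter*: a closed size interval lying
between the windows of the two same-dye markers of that group (or, for a
lone marker, beyond its window).  Peaks inside the filter interval are
**excluded** before marker assignment; this is what removes spectral
bleed-through artifacts (HEX leaking into FAM) that land between marker
windows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from importlib import resources
from pathlib import Path
from typing import Iterable

from .sizing import LadderSpec

DYES = ("FAM", "HEX", "NED")
MIN_PRODUCT_GAP_NT = 40.0  # same-dye products must be at least this far apart


class PanelError(ValueError):
    """A panel definition violates a structural invariant."""


@dataclass(frozen=True)
class MarkerDef:
    """One microsatellite locus of the assay.

    Sizes are in base pairs.  ``window_min``/``window_max`` delimit the
    analysis window used for allele identification; ``product_range`` is the
    expected PCR product size range in the population (may collapse to a
    single value); ``primer_conc`` (uM) is metadata only.
    """

    name: str
    group: int
    dye: str
    window_min: float
    window_max: float
    repeat_unit: int
    product_range: tuple[float, float] | None = None
    primer_conc: float | None = None

    def __post_init__(self) -> None:
        if self.dye not in DYES:
            raise PanelError(f"{self.name}: unknown dye {self.dye!r}")
        if self.group not in (1, 2):
            raise PanelError(f"{self.name}: group must be 1 or 2")
        if not self.window_min < self.window_max:
            raise PanelError(f"{self.name}: window_min must be < window_max")
        if self.repeat_unit not in (1, 2):
            raise PanelError(f"{self.name}: repeat_unit must be 1 or 2")
        if self.product_range is not None:
            lo, hi = self.product_range
            if lo > hi:
                raise PanelError(f"{self.name}: inverted product_range")
            if lo < self.window_min - 15 or hi > self.window_max + 15:
                raise PanelError(
                    f"{self.name}: product_range {self.product_range} strays "
                    f"more than 15 bp outside window "
                    f"[{self.window_min}, {self.window_max}]"
                )

    def contains(self, size_bp: float) -> bool:
        return self.window_min <= size_bp <= self.window_max

    def allele_lattice(self) -> list[int]:
        """Template (pre-adenylation) allele sizes: repeat-unit steps inside
        the window, with a margin so stutter ladders stay in range."""
        lo = int(np.ceil(self.window_min))
        hi = int(np.floor(self.window_max))
        if self.repeat_unit == 1:
            return list(range(lo + 3, hi - 2))
        return list(range(lo + 5, hi - 3, 2))


@dataclass(frozen=True)
class AnalysisParams:
    """Peak-detection / allele-identification parameters.

    ``min_peak_half_width`` maps multiplex group -> minimum peak half-width
    (half-width at half height, in scan points); group 1 uses a wider
    minimum to reject narrow nonspecific spikes.  ``mono_cutoff`` is the
    height-ratio threshold above which secondary peaks of a mononucleotide
    marker are called additional alleles.  ``range_filters`` maps
    group -> dye -> closed exclusion interval in bp (see module docstring).
    """

    peak_algorithm: str = "advanced"
    sizing_method: str = "local_southern"
    min_peak_half_width: dict[int, float] = field(
        default_factory=lambda: {1: 4.0, 2: 2.0}
    )
    mono_cutoff: float = 0.95
    range_filters: dict[int, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )
    peak_height_threshold: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 < self.mono_cutoff < 1.0:
            raise PanelError("mono_cutoff must lie in (0, 1)")
        if any(w < 1 for w in self.min_peak_half_width.values()):
            raise PanelError("min_peak_half_width entries must be >= 1")
        for group, per_dye in self.range_filters.items():
            for dye, (lo, hi) in per_dye.items():
                if lo > hi:
                    raise PanelError(
                        f"range filter for group {group} dye {dye} is empty"
                    )


@dataclass
class PanelConfig:
    """A complete, analysis-ready panel: markers, parameters, ladder, bins."""

    name: str
    markers: list[MarkerDef]
    params: AnalysisParams
    ladder: LadderSpec
    bins: dict[str, "BinSet"] = field(default_factory=dict)  # noqa: F821
    version: str = "1.0"

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise PanelError("marker names must be unique")
        for m in self.markers:
            if m.dye not in self.params.range_filters.get(m.group, {}):
                raise PanelError(
                    f"{m.name}: no range filter defined for dye {m.dye} "
                    f"in group {m.group}"
                )

    def marker(self, name: str) -> MarkerDef:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    def group_markers(self, group: int) -> list[MarkerDef]:
        return [m for m in self.markers if m.group == group]

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]


# ---------------------------------------------------------------------------
# Serialization


def _panel_to_dict(panel: PanelConfig) -> dict:
    from .calling import BinSet  # local import, see module note

    return {
        "name": panel.name,
        "version": panel.version,
        "units": {"sizes": "bp", "primer_conc": "uM"},
        "markers": [
            {
                **asdict(m),
                "product_range": list(m.product_range) if m.product_range else None,
            }
            for m in panel.markers
        ],
        "params": {
            "peak_algorithm": panel.params.peak_algorithm,
            "sizing_method": panel.params.sizing_method,
            "min_peak_half_width": {
                str(g): w for g, w in panel.params.min_peak_half_width.items()
            },
            "mono_cutoff": panel.params.mono_cutoff,
            "peak_height_threshold": panel.params.peak_height_threshold,
            "range_filters": {
                str(g): {dye: list(iv) for dye, iv in per_dye.items()}
                for g, per_dye in panel.params.range_filters.items()
            },
        },
        "ladder": {"dye": panel.ladder.dye, "sizes": list(panel.ladder.sizes)},
        "bins": {
            name: {"centers": list(bs.centers), "max_offset": bs.max_offset}
            for name, bs in panel.bins.items()
        },
    }


def _panel_from_dict(doc: dict) -> PanelConfig:
    from .calling import BinSet

    markers = [
        MarkerDef(
            name=m["name"],
            group=int(m["group"]),
            dye=m["dye"],
            window_min=float(m["window_min"]),
            window_max=float(m["window_max"]),
            repeat_unit=int(m["repeat_unit"]),
            product_range=tuple(m["product_range"]) if m.get("product_range") else None,
            primer_conc=m.get("primer_conc"),
        )
        for m in doc["markers"]
    ]
    p = doc["params"]
    params = AnalysisParams(
        peak_algorithm=p.get("peak_algorithm", "advanced"),
        sizing_method=p.get("sizing_method", "local_southern"),
        min_peak_half_width={
            int(g): float(w) for g, w in p["min_peak_half_width"].items()
        },
        mono_cutoff=float(p["mono_cutoff"]),
        range_filters={
            int(g): {dye: tuple(iv) for dye, iv in per_dye.items()}
            for g, per_dye in p["range_filters"].items()
        },
        peak_height_threshold=float(p.get("peak_height_threshold", 50.0)),
    )
    ladder = LadderSpec(dye=doc["ladder"]["dye"], sizes=tuple(doc["ladder"]["sizes"]))
    bins = {
        name: BinSet(
            marker=name,
            centers=tuple(int(c) for c in b["centers"]),
            max_offset=float(b.get("max_offset", 0.5)),
        )
        for name, b in doc.get("bins", {}).items()
    }
    return PanelConfig(
        name=doc.get("name", "panel"),
        markers=markers,
        params=params,
        ladder=ladder,
        bins=bins,
        version=doc.get("version", "1.0"),
    )


def save_panel(panel: PanelConfig, path: str | Path) -> None:
    """Write a panel to JSON (sizes in bp, concentrations in uM)."""
    Path(path).write_text(json.dumps(_panel_to_dict(panel), indent=2) + "\n")


def load_panel(path: str | Path) -> PanelConfig:
    """Read a panel from JSON produced by :func:`save_panel` (or the bundled file)."""
    return _panel_from_dict(json.loads(Path(path).read_text()))


def builtin_panel() -> PanelConfig:
    """The canonical 11-marker panel bundled with the package.

    Includes all 11 loci (6 in group 1, 5 in group 2), their dyes,
    analysis windows, repeat units, expected product ranges, the default
    analysis parameters, the GS500-style ROX ladder and default bins.
    D5S346 has no published product range and carries ``product_range=None``.
    """
    doc = json.loads(
        resources.files("msatpipe").joinpath("data/panel.json").read_text()
    )
    panel = _panel_from_dict(doc)
    if not panel.bins:
        from .calling import default_binsets

        panel.bins = default_binsets(panel)
    return panel


# ---------------------------------------------------------------------------
# Validation


@dataclass
class GapRecord:
    group: int
    dye: str
    marker_low: str
    marker_high: str
    gap: float
    passed: bool


@dataclass
class ValidationReport:
    """Outcome of panel design-rule validation."""

    basis: str
    gaps: list[GapRecord]
    messages: list[str]
    passed: bool

    @property
    def min_gap(self) -> float | None:
        if not self.gaps:
            return None
        return min(g.gap for g in self.gaps)


def _interval(marker: MarkerDef, basis: str) -> tuple[float, float] | None:
    if basis == "product_ranges":
        return marker.product_range
    if basis == "marker_windows":
        return (marker.window_min, marker.window_max)
    raise PanelError(f"unknown basis {basis!r}")


def validate_panel(panel: PanelConfig, basis: str = "product_ranges") -> ValidationReport:
    """Check the assay design rules of a panel.

    Per multiplex group and dye, computes the minimum size gap between the
    ranges of same-dye markers (on ``basis``: ``product_ranges`` or
    ``marker_windows``) and flags pairs closer than 40 nt.  Also flags
    marker windows that extend beyond the ladder's usable interpolation
    range, and marker windows overlapping their own dye's exclusion filter.
    """
    gaps: list[GapRecord] = []
    messages: list[str] = []
    ok = True

    for group in (1, 2):
        by_dye: dict[str, list[MarkerDef]] = {}
        for m in panel.group_markers(group):
            by_dye.setdefault(m.dye, []).append(m)
        for dye, markers in sorted(by_dye.items()):
            with_iv = [(m, _interval(m, basis)) for m in markers]
            missing = [m.name for m, iv in with_iv if iv is None]
            if missing:
                messages.append(
                    f"group {group} {dye}: no {basis} for {', '.join(missing)}; "
                    "pair(s) involving them not assessed"
                )
            usable = sorted(
                ((m, iv) for m, iv in with_iv if iv is not None),
                key=lambda t: t[1][0],
            )
            for (m1, iv1), (m2, iv2) in zip(usable, usable[1:]):
                gap = iv2[0] - iv1[1]
                passed = gap >= MIN_PRODUCT_GAP_NT
                gaps.append(GapRecord(group, dye, m1.name, m2.name, gap, passed))
                if not passed:
                    ok = False
                    messages.append(
                        f"group {group} {dye}: {m1.name}/{m2.name} separated by "
                        f"only {gap:g} nt (< {MIN_PRODUCT_GAP_NT:g})"
                    )

    # ladder coverage: Local Southern needs two standards on each side
    lad = panel.ladder.sizes
    lo, hi = lad[1], lad[-2]
    for m in panel.markers:
        if m.window_min < lo or m.window_max > hi:
            ok = False
            messages.append(
                f"{m.name}: window [{m.window_min:g}, {m.window_max:g}] extends "
                f"outside the ladder interpolation range [{lo:g}, {hi:g}]"
            )

    # exclusion filters must not swallow their own markers
    for m in panel.markers:
        flo, fhi = panel.params.range_filters[m.group][m.dye]
        if m.window_min <= fhi and m.window_max >= flo:
            ok = False
            messages.append(
                f"{m.name}: window overlaps its {m.dye} group-{m.group} "
                f"exclusion filter [{flo:g}, {fhi:g}]"
            )

    return ValidationReport(basis=basis, gaps=gaps, messages=messages, passed=ok)
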