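"""Ground-truthed simulation of multiplexed microsatellite electropherograms.

Real deposited traces for this assay do not exist, so testing and
calibration rest on a generative model that emulates the statistical
structure of multiplexed microsatellite PCR read out by capillary
electrophoresis:

* **Genotypes** drawn from per-marker allele frequencies; the
  quasimonomorphic mononucleotide markers (Bat25, Bat26) carry a single
  modal allele with high probability.
* **Stutter**: polymerase slippage produces shadow peaks at one repeat
  unit (and multiples) below each allele, with the k-th stutter at
  (adjacent ratio)^k of the main height.
* **Adenylation**: PCR conditions (GTGTCTT-tailed primers, long final
  extension) drive non-templated +A addition, shifting apparent sizes one
  nucleotide above the template lattice.
* **Instrument effects**: reciprocal size-to-scan mobility, per-fragment
  migration noise, HEX-into-FAM spectral bleed-through, one-scan electrical
  spikes, broad nonspecific products outside marker windows, baseline and
  white noise, and a co-electrophoresed ROX ladder.

All stochastic draws flow through an explicit :class:`numpy.random.Generator`
(or integer seed); identical seeds yield identical traces.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import PanelConfig
from .peaks import Trace
from .sizing import LadderSpec

#: modal template (pre-adenylation) allele of each quasimonomorphic marker
MONO_MODAL_TRUTH = {"BAT25": 126, "BAT26": 121}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Genotypes


@dataclass
class GenotypeTruth:
    """Ground-truth genotype: template allele sizes (bp) per marker."""

    subject: str
    alleles: dict[str, tuple[float, float]]
    flags: list[str] = field(default_factory=list)

    def expected_bins(self, shift: int = 1) -> dict[str, tuple[int, int]]:
        """Expected called bins: template sizes plus the adenylation shift."""
        return {
            m: tuple(sorted(int(round(a)) + shift for a in pair))
            for m, pair in self.alleles.items()
        }

    def copy(self, subject: str | None = None) -> "GenotypeTruth":
        return GenotypeTruth(
            subject or self.subject, copy.deepcopy(self.alleles), list(self.flags)
        )


def truth_lattice(marker) -> list[int]:
    """Template allele lattice of a marker (see ``MarkerDef.allele_lattice``)."""
    return marker.allele_lattice()


def default_frequencies(panel: PanelConfig, mono_modal_p: float = 0.98) -> dict:
    """Population allele frequencies used by :func:`sample_genotype`.

    Dinucleotide markers get a triangular distribution over their allele
    lattice (high heterozygosity, as for the polymorphic loci of the
    panel).  Mononucleotide markers are quasimonomorphic: the modal allele
    carries ``mono_modal_p``, with rare variants 3 bp below and 2 bp above.
    """
    freqs: dict[str, dict[float, float]] = {}
    for m in panel.markers:
        lattice = truth_lattice(m)
        if m.repeat_unit == 1:
            modal = MONO_MODAL_TRUTH.get(m.name, lattice[len(lattice) // 2])
            rare = (1.0 - mono_modal_p) / 2.0
            freqs[m.name] = {modal: mono_modal_p, modal - 3: rare, modal + 2: rare}
        else:
            n = len(lattice)
            w = np.minimum(np.arange(1, n + 1), np.arange(n, 0, -1)).astype(float)
            w /= w.sum()
            freqs[m.name] = dict(zip(lattice, w))
    return freqs


def sample_genotype(
    panel: PanelConfig,
    allele_freqs: dict | None = None,
    rng=None,
    subject: str = "S1",
) -> GenotypeTruth:
    """Draw one genotype: two independent alleles per marker."""
    rng = _rng(rng)
    if allele_freqs is None:
        allele_freqs = default_frequencies(panel)
    alleles = {}
    for m in panel.markers:
        table = allele_freqs.get(m.name)
        if not table:
            raise ValueError(f"no allele frequencies for marker {m.name}")
        sizes = np.array(list(table.keys()), dtype=float)
        probs = np.array(list(table.values()), dtype=float)
        probs = probs / probs.sum()
        pair = rng.choice(sizes, size=2, p=probs)
        alleles[m.name] = tuple(sorted(map(float, pair)))
    return GenotypeTruth(subject=subject, alleles=alleles)


def make_family(
    parent1: GenotypeTruth,
    parent2: GenotypeTruth,
    n_children: int,
    twins: bool = False,
    rng=None,
) -> list[GenotypeTruth]:
    """Mendelian children: one allele per marker inherited from each parent.

    With ``twins=True`` (and at least two children) the second child is an
    identical copy of the first, emulating monozygotic twins.
    """
    rng = _rng(rng)
    if set(parent1.alleles) != set(parent2.alleles):
        raise ValueError("parents must share the same panel")
    children = []
    for i in range(n_children):
        alleles = {}
        for m in parent1.alleles:
            a = parent1.alleles[m][rng.integers(2)]
            b = parent2.alleles[m][rng.integers(2)]
            alleles[m] = tuple(sorted((a, b)))
        children.append(GenotypeTruth(subject=f"child{i + 1}", alleles=alleles))
    if twins and n_children >= 2:
        children[1] = children[0].copy(subject="child2")
    return children


def apply_msi(
    genotype: GenotypeTruth, panel: PanelConfig, marker: str, shift_bp: float,
    allele_index: int = 0,
) -> GenotypeTruth:
    """Shift one allele of one marker by ``shift_bp`` (an instability event).

    A shifted allele falling outside the marker window is flagged on the
    returned genotype but still applied.
    """
    m = panel.marker(marker)
    out = genotype.copy()
    pair = list(out.alleles[marker])
    pair[allele_index] += shift_bp
    out.alleles[marker] = tuple(sorted(pair))
    if not m.contains(pair[allele_index]):
        out.flags.append(f"msi-out-of-window:{marker}")
    return out


# ---------------------------------------------------------------------------
# Amplicon peak model


@dataclass(frozen=True)
class StutterModel:
    """PCR artifact model: stutter ratios per repeat unit and +A fraction.

    ``ratio_range`` maps repeat unit -> (low, high) of the uniform
    distribution of the adjacent-stutter height ratio; the k-th stutter is
    the adjacent ratio to the k-th power.  ``adenylation_fraction`` is the
    fraction of product carrying the non-templated +A (1.0 under the
    tailed-primer design).  Peaks below ``min_rel_height`` of the main peak
    are dropped.
    """

    ratio_range: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (0.85, 0.97), 2: (0.30, 0.60)}
    )
    adenylation_fraction: float = 1.0
    min_rel_height: float = 0.01

    def __post_init__(self) -> None:
        for unit, (lo, hi) in self.ratio_range.items():
            if not (0.0 < lo <= hi < 1.0):
                raise ValueError(f"stutter ratios for unit {unit} must lie in (0,1)")
        if not 0.0 <= self.adenylation_fraction <= 1.0:
            raise ValueError("adenylation_fraction must lie in [0, 1]")

    def draw_ratio(self, unit: int, rng) -> float:
        lo, hi = self.ratio_range[unit]
        return float(_rng(rng).uniform(lo, hi))


@dataclass
class IdealPeak:
    """One size-domain peak before instrument rendering."""

    dye: str
    marker: str | None
    size_bp: float
    height: float
    kind: str  # allele | stutter | spike | nonspecific | ladder | bleed
    truth_allele_bp: float | None = None


def stutter_series(
    allele_bp: float,
    height: float,
    unit: int,
    adjacent_ratio: float,
    adenylation_fraction: float = 1.0,
    min_rel_height: float = 0.01,
    floor_bp: float | None = None,
) -> list[tuple[float, float, str]]:
    """Size-domain peaks of one amplified allele.

    Returns ``(size, height, kind)`` tuples: the main product plus its
    geometric stutter ladder (k-th stutter at ``adjacent_ratio**k``),
    each split between the +A (+1 bp) and template forms according to
    ``adenylation_fraction``.
    """
    series = [(allele_bp, height, "allele")]
    k = 1
    while True:
        h = height * adjacent_ratio**k
        size = allele_bp - unit * k
        if h < min_rel_height * height or (floor_bp is not None and size < floor_bp):
            break
        series.append((size, h, "stutter"))
        k += 1
    out = []
    f = adenylation_fraction
    for size, h, kind in series:
        if f > 0:
            out.append((size + 1.0, h * f, kind))
        if f < 1:
            out.append((size, h * (1.0 - f), kind))
    return out


def amplicon_peaks(
    genotype: GenotypeTruth,
    panel: PanelConfig,
    stutter: StutterModel | None = None,
    rng=None,
    group: int | None = None,
    base_height: float = 1200.0,
    amp_sigma: float = 0.08,
) -> list[IdealPeak]:
    """Ideal size-domain peak list for one amplification.

    Each allele copy contributes ``base_height`` scaled by a lognormal
    unequal-amplification factor (sigma ``amp_sigma`` in log space);
    homozygotes therefore present one roughly double-height product.
    """
    rng = _rng(rng)
    stutter = stutter or StutterModel()
    markers = panel.markers if group is None else panel.group_markers(group)
    out: list[IdealPeak] = []
    for m in markers:
        pair = genotype.alleles.get(m.name)
        if pair is None:
            continue
        distinct: dict[float, int] = {}
        for a in pair:
            distinct[a] = distinct.get(a, 0) + 1
        for allele, copies in sorted(distinct.items()):
            h = base_height * copies * rng.lognormal(0.0, amp_sigma)
            ratio = stutter.draw_ratio(m.repeat_unit, rng)
            for size, height, kind in stutter_series(
                allele,
                h,
                m.repeat_unit,
                ratio,
                stutter.adenylation_fraction,
                stutter.min_rel_height,
                floor_bp=m.window_min - 10,
            ):
                out.append(
                    IdealPeak(m.dye, m.name, size, height, kind, truth_allele_bp=allele)
                )
    return out


# ---------------------------------------------------------------------------
# Instrument model


@dataclass(frozen=True)
class MobilityModel:
    """Reciprocal size-to-scan mapping m(L) = m0 + c/(L - L0).

    Defaults give a strictly increasing, invertible mapping over
    [35, 500] nt (c < 0, L0 below the smallest fragment).
    """

    m0: float = 9000.0
    c: float = -1.0e6
    L0: float = -100.0

    def __post_init__(self) -> None:
        if self.c >= 0 or self.L0 >= 35:
            raise ValueError("need c < 0 and L0 < 35 for an increasing mapping")

    def scan(self, size_bp):
        return self.m0 + self.c / (np.asarray(size_bp, dtype=float) - self.L0)

    def size(self, scan):
        return self.c / (np.asarray(scan, dtype=float) - self.m0) + self.L0


@dataclass(frozen=True)
class RunConditions:
    """Instrument/noise model of one electrophoresis run.

    migration_sd      per-fragment migration noise, bp-equivalent SD
    bleed             HEX -> FAM spectral bleed-through coefficient (beta)
    spike_rate        expected one-scan spikes per channel
    nonspecific_rate  expected broad nonspecific products per dye channel
    nonspecific_height  exponential height scale of nonspecific products
    baseline_level / noise_sd   additive baseline and white noise (FU)
    peak_sigma_scans  Gaussian pulse width (HWHM ~ 1.18 sigma points)
    """

    migration_sd: float = 0.08
    bleed: float = 0.05
    spike_rate: float = 0.5
    nonspecific_rate: float = 0.4
    nonspecific_height: float = 250.0
    baseline_level: float = 80.0
    noise_sd: float = 5.0
    peak_sigma_scans: float = 4.2
    ladder_height: float = 800.0
    saturation: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.bleed < 1.0:
            raise ValueError("bleed coefficient must lie in [0, 1)")
        for name in ("migration_sd", "spike_rate", "nonspecific_rate",
                     "noise_sd", "baseline_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def render_trace(
    ideal_peaks: list[IdealPeak],
    mobility: MobilityModel,
    run: RunConditions,
    ladder: LadderSpec,
    rng=None,
    subject: str = "S1",
    avoid_windows: dict[str, list[tuple[float, float]]] | None = None,
) -> tuple[Trace, pd.DataFrame]:
    """Render size-domain peaks into a four-channel trace plus a truth table.

    Every peak becomes a Gaussian pulse at scan ``m(size + N(0, sd))``; the
    ROX channel carries the ladder; the FAM channel additionally receives
    ``bleed`` times the HEX signal; spikes and broad nonspecific products
    are injected at their Poisson rates.  The returned truth table lists
    every injected apex (including bleed replicas) with its scan and height.
    """
    rng = _rng(rng)
    n = int(np.ceil(mobility.scan(ladder.sizes[-1] + 5))) + 80
    scans = np.arange(n)
    channels = {name: np.zeros(n) for name in ("FAM", "HEX", "NED", "ROX")}
    sigma = run.peak_sigma_scans
    rows = []

    def add_pulse(channel: str, center: float, height: float, width: float):
        lo = max(0, int(center - 6 * width))
        hi = min(n, int(center + 6 * width) + 1)
        x = scans[lo:hi]
        channels[channel][lo:hi] += height * np.exp(
            -0.5 * ((x - center) / width) ** 2
        )

    def record(dye, marker, size, scan, height, kind, truth=None):
        rows.append(
            dict(subject=subject, dye=dye, marker=marker, size_bp=size,
                 apex_scan=scan, height=height, kind=kind,
                 truth_allele_bp=truth)
        )

    for p in ideal_peaks:
        apparent = p.size_bp + rng.normal(0.0, run.migration_sd)
        center = float(mobility.scan(apparent))
        add_pulse(p.dye, center, p.height, sigma)
        record(p.dye, p.marker, p.size_bp, center, p.height, p.kind,
               p.truth_allele_bp)

    for size in ladder.sizes:
        apparent = size + rng.normal(0.0, run.migration_sd)
        center = float(mobility.scan(apparent))
        add_pulse(ladder.dye, center, run.ladder_height, sigma)
        record(ladder.dye, None, float(size), center, run.ladder_height, "ladder")

    # nonspecific broad products, placed outside marker windows of their dye
    for dye in ("FAM", "HEX", "NED"):
        windows = (avoid_windows or {}).get(dye, [])
        for _ in range(rng.poisson(run.nonspecific_rate)):
            for _ in range(100):
                size = rng.uniform(45.0, ladder.sizes[-1] - 15.0)
                if not any(lo <= size <= hi for lo, hi in windows):
                    break
            height = rng.exponential(run.nonspecific_height) + 60.0
            center = float(mobility.scan(size))
            add_pulse(dye, center, height, sigma * 1.6)
            record(dye, None, size, center, height, "nonspecific")

    # spectral bleed-through of HEX into FAM
    if run.bleed > 0:
        channels["FAM"] += run.bleed * channels["HEX"]
        for r in list(rows):
            if r["dye"] == "HEX":
                record("FAM", r["marker"], r["size_bp"], r["apex_scan"],
                       r["height"] * run.bleed, "bleed", r["truth_allele_bp"])

    # one-scan electrical spikes
    for name in channels:
        for _ in range(rng.poisson(run.spike_rate)):
            pos = int(rng.integers(50, n - 50))
            height = float(rng.uniform(300.0, 3000.0))
            channels[name][pos] += height
            record(name, None, None, float(pos), height, "spike")

    for name in channels:
        channels[name] += run.baseline_level + rng.normal(0.0, run.noise_sd, size=n)
        if run.saturation is not None:
            np.clip(channels[name], None, run.saturation, out=channels[name])

    truth = pd.DataFrame(
        rows,
        columns=["subject", "dye", "marker", "size_bp", "apex_scan", "height",
                 "kind", "truth_allele_bp"],
    )
    return Trace(scans=scans, channels=channels), truth


def simulate_run(
    genotype: GenotypeTruth,
    panel: PanelConfig,
    group: int,
    *,
    stutter: StutterModel | None = None,
    run: RunConditions | None = None,
    mobility: MobilityModel | None = None,
    rng=None,
) -> tuple[Trace, pd.DataFrame]:
    """Simulate one multiplex-group amplification end to end.

    Draws the amplicon peak ladder for the group's markers, then renders a
    full four-channel trace with the ROX ladder and all noise processes.
    """
    rng = _rng(rng)
    run = run or RunConditions()
    mobility = mobility or MobilityModel()
    peaks = amplicon_peaks(genotype, panel, stutter, rng, group=group)
    windows: dict[str, list[tuple[float, float]]] = {}
    for m in panel.group_markers(group):
        windows.setdefault(m.dye, []).append((m.window_min - 12, m.window_max + 6))
    return render_trace(
        peaks, mobility, run, panel.ladder, rng,
        subject=genotype.subject, avoid_windows=windows,
    )


def control_genotype(panel: PanelConfig) -> GenotypeTruth:
    """The fixed pooled-control genotype used for replicate QC studies.

    Mononucleotide alleles match the published control profile (apparent
    Bat25 127 bp, Bat26 122 bp after the +1 adenylation shift);
    dinucleotide control alleles are fixed mid-window lattice choices.
    """
    truth = {
        "BAT25": (126.0, 126.0),
        "BAT26": (121.0, 121.0),
        "D3S3623": (211.0, 217.0),
        "D5S346": (95.0, 103.0),
        "D6S262": (169.0, 175.0),
        "D7S481": (186.0, 192.0),
        "D2S123": (213.0, 219.0),
        "D3S1262": (131.0, 137.0),
        "D9S171": (109.0, 115.0),
        "D17S250": (186.0, 194.0),
        "D18S61": (156.0, 164.0),
    }
    alleles = {m.name: truth[m.name] for m in panel.markers}
    return GenotypeTruth(subject="control", alleles=alleles)
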