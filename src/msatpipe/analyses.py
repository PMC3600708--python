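"""Downstream applications: MSI classification, LOH ratios, lineage checks.

The panel contains the five NCI-recommended MSI loci (Bat25, Bat26,
D2S123, D5S346, D17S250) plus six additional dinucleotide markers, and
places polymorphic markers near the mismatch-repair genes MLH1 (D3S3623),
MSH2 (Bat26), MSH6 (D2S123) and PMS2 (D7S481) so that loss of
heterozygosity at those regions can be scored from the same profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .calling import GenotypeProfile

#: the NCI workshop marker set used for overall MSI status
NCI_MARKERS = ("BAT25", "BAT26", "D2S123", "D5S346", "D17S250")

#: markers adjacent to mismatch-repair genes, for LOH scoring
MMR_LOH_MARKERS = {"MLH1": "D3S3623", "MSH2": "BAT26", "MSH6": "D2S123",
                   "PMS2": "D7S481"}


@dataclass(frozen=True)
class MsiThresholds:
    """Instability thresholds for MSI classification.

    Mononucleotide deviations of +1 nt are normal amplification slippage;
    shifts of at least 3 bp (Bat25) or 4 bp (Bat26) are treated as true
    somatic alterations.  Any novel dinucleotide bin is unstable.
    """

    mono_shift_bp: dict[str, int] = field(
        default_factory=lambda: {"BAT25": 3, "BAT26": 4}
    )
    plus_one_normal: bool = True

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.mono_shift_bp.values()):
            raise ValueError("instability thresholds must be positive")


@dataclass
class MsiResult:
    per_marker: dict[str, str]  # stable | unstable
    status: str  # MSS | MSI-L | MSI-H
    n_unstable: int
    notes: list[str] = field(default_factory=list)


def _marker_unstable(
    sample_bins: list[int],
    reference_bins: list[int],
    mono_threshold: int | None,
    plus_one_normal: bool,
) -> bool:
    if mono_threshold is None:  # dinucleotide: any novel bin is unstable
        return any(b not in reference_bins for b in sample_bins)
    for b in sample_bins:
        deltas = [b - r for r in reference_bins]
        if any(d == 0 for d in deltas):
            continue
        if plus_one_normal and any(d == 1 for d in deltas):
            continue
        if min(abs(d) for d in deltas) >= mono_threshold:
            return True
    return False


def msi_classify(
    sample: GenotypeProfile,
    reference: GenotypeProfile,
    thresholds: MsiThresholds | None = None,
    status_markers: tuple[str, ...] = NCI_MARKERS,
) -> MsiResult:
    """Classify microsatellite instability of ``sample`` against ``reference``.

    Per marker: a mononucleotide marker is unstable iff a sample allele
    deviates from every reference allele by at least its threshold (+1 nt
    deviations are normal); a dinucleotide marker is unstable iff any
    sample bin is absent from the reference.  Overall status counts
    unstable loci among the NCI five: >= 2 is MSI-H, exactly 1 MSI-L,
    0 MSS.  Markers without reference calls are excluded and noted.
    """
    thresholds = thresholds or MsiThresholds()
    per_marker: dict[str, str] = {}
    notes: list[str] = []
    for marker, calls in sample.calls.items():
        ref_bins = reference.bins(marker)
        if not ref_bins:
            notes.append(f"{marker}: no reference calls; excluded")
            continue
        unstable = _marker_unstable(
            [c.bin for c in calls],
            ref_bins,
            thresholds.mono_shift_bp.get(marker),
            thresholds.plus_one_normal,
        )
        per_marker[marker] = "unstable" if unstable else "stable"

    n_unstable = sum(
        1 for m in status_markers if per_marker.get(m) == "unstable"
    )
    status = "MSI-H" if n_unstable >= 2 else ("MSI-L" if n_unstable == 1 else "MSS")
    return MsiResult(per_marker=per_marker, status=status,
                     n_unstable=n_unstable, notes=notes)


@dataclass
class LohResult:
    marker: str
    informative: bool
    ratio: float | None  # (tumor h1/h2) / (normal h1/h2)
    loh: bool
    note: str = ""


def loh_score(
    tumor: GenotypeProfile,
    normal: GenotypeProfile,
    marker: str,
    lower: float = 0.5,
    upper: float = 2.0,
) -> LohResult:
    """Allele-ratio LOH statistic at one marker.

    Requires a heterozygous normal (otherwise uninformative).  With allele
    heights matched by bin, ``R = (tumor h1/h2) / (normal h1/h2)``; LOH is
    called when R < 0.5 or R > 2.0 (strict inequalities, community-standard
    bounds).  Swapping the allele labels maps R to 1/R and leaves the call
    unchanged.
    """
    n_calls = {c.bin: c.height for c in normal.calls.get(marker, [])}
    if len(n_calls) != 2:
        return LohResult(marker, False, None, False, "normal not heterozygous")
    t_calls = {c.bin: c.height for c in tumor.calls.get(marker, [])}
    b1, b2 = sorted(n_calls)
    if b1 not in t_calls or b2 not in t_calls:
        return LohResult(marker, False, None, False,
                         "tumor allele height missing")
    r = (t_calls[b1] / t_calls[b2]) / (n_calls[b1] / n_calls[b2])
    return LohResult(marker, True, float(r), bool(r < lower or r > upper))


@dataclass
class LineageReport:
    """Mendelian-consistency table for a putative family."""

    consistent: dict[str, dict[str, bool]]  # child -> marker -> ok
    twin_pairs: list[tuple[str, str]]

    def child_consistent(self, child: str) -> bool:
        return all(self.consistent[child].values())


def _mendelian_ok(
    child: tuple[int, ...], p1: tuple[int, ...], p2: tuple[int, ...]
) -> bool:
    a, b = child
    return (a in p1 and b in p2) or (a in p2 and b in p1)


def lineage_check(
    children: dict[str, GenotypeProfile],
    parents: dict[str, GenotypeProfile],
    markers: list[str] | None = None,
) -> LineageReport:
    """Check segregation of alleles from parents to children.

    A child is consistent at a marker iff its allele pair can be split one
    from each parent.  Two children identical at every assessed marker are
    flagged as (monozygotic) twins.  ``markers`` restricts the assessment;
    with profiles called from noisy traces, restricting to the dinucleotide
    markers mirrors practice, since quasimonomorphic mononucleotide calls
    carry inherent +/-1 nt ambiguity.
    """
    if len(parents) != 2:
        raise ValueError("exactly two parental profiles required")
    (pa_id, pa), (pb_id, pb) = sorted(parents.items())
    consistent: dict[str, dict[str, bool]] = {}
    for cid, child in sorted(children.items()):
        per_marker: dict[str, bool] = {}
        for marker in child.calls:
            if markers is not None and marker not in markers:
                continue
            cg = child.genotype_bins(marker)
            g1 = pa.genotype_bins(marker)
            g2 = pb.genotype_bins(marker)
            if cg is None or g1 is None or g2 is None:
                per_marker[marker] = False
                continue
            per_marker[marker] = _mendelian_ok(cg, g1, g2)
        consistent[cid] = per_marker

    twin_pairs = []
    ids = sorted(children)
    for i, c1 in enumerate(ids):
        for c2 in ids[i + 1:]:
            assessed = set(children[c1].calls) | set(children[c2].calls)
            if markers is not None:
                assessed &= set(markers)
            if assessed and all(
                children[c1].genotype_bins(m) == children[c2].genotype_bins(m)
                for m in assessed
            ):
                twin_pairs.append((c1, c2))
    return LineageReport(consistent=consistent, twin_pairs=twin_pairs)
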