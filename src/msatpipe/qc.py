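"""Process-quality statistics for replicate microsatellite runs.

Two statistics summarize process quality:

* **Sizing %CV** -- for each allele of a control sample run repeatedly,
  ``100 * sample SD / mean`` of its Local Southern size across runs
  (sample, n-1, standard deviation).  This captures the combined variation
  of amplification, electrophoresis, peak detection and sizing.
* **Percent deviation** -- the percentage of alleles whose automated call
  differs from the expected genotype after tolerance rules: dinucleotide
  alleles must match their expected bin exactly; mononucleotide alleles may
  deviate by +1 nt (polymerase slippage on mononucleotide tracts makes the
  +1 call biochemically normal).  Deviations are counted per allele (two
  per marker per sample, homozygotes included), so a nonspecific peak
  called in place of an allele counts each displaced expected allele as
  miscalled.

A known control sample co-processed with every run separates process
failures from sample-integrity failures: deviations on runs whose control
was concordant are attributed to the sample, not the process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calling import GenotypeProfile


@dataclass
class RunSeries:
    """Ordered replicate runs of the same underlying sample."""

    sample: str
    runs: list[GenotypeProfile]

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("empty run series")


@dataclass
class DeviationReport:
    """Allele-level concordance of observed calls against expected genotypes."""

    total: int
    miscalled: int
    per_day: pd.DataFrame
    per_marker: pd.DataFrame
    tolerance: str

    @property
    def percent(self) -> float:
        return 100.0 * self.miscalled / self.total if self.total else 0.0


def sizing_cv(series: RunSeries) -> pd.DataFrame:
    """Per-allele sizing %CV across the runs of a replicate series.

    Observations are grouped by (marker, called bin); singleton groups get
    ``NaN`` (a CV from one observation is undefined, not zero).  Returns a
    table with columns marker, allele, n, mean_bp, sd_bp, cv_pct.
    """
    obs: dict[tuple[str, int], list[float]] = {}
    for prof in series.runs:
        for marker, calls in prof.calls.items():
            for call in calls:
                obs.setdefault((marker, call.bin), []).append(call.size_bp)
    rows = []
    for (marker, allele), sizes in sorted(obs.items()):
        arr = np.asarray(sizes)
        n = len(arr)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if n > 1 else np.nan
        rows.append(
            dict(marker=marker, allele=allele, n=n, mean_bp=mean, sd_bp=sd,
                 cv_pct=100.0 * sd / mean if n > 1 else np.nan)
        )
    return pd.DataFrame(rows, columns=["marker", "allele", "n", "mean_bp",
                                       "sd_bp", "cv_pct"])


def cv_summary(cv_table: pd.DataFrame) -> dict:
    """Cumulative min/max %CV over all identified alleles (n >= 2)."""
    valid = cv_table["cv_pct"].dropna()
    if valid.empty:
        return {"min_cv_pct": None, "max_cv_pct": None, "n_alleles": 0}
    return {
        "min_cv_pct": float(valid.min()),
        "max_cv_pct": float(valid.max()),
        "n_alleles": int(valid.size),
    }


def _match_alleles(
    observed: tuple[int, ...] | None,
    expected: tuple[int, int],
    mono: bool,
    plus_one_tolerance: bool,
) -> int:
    """Number of expected alleles (out of two) without a concordant call."""
    if observed is None:
        return 2
    obs = list(observed)
    if len(obs) == 1:
        obs = obs * 2  # a single call represents a homozygote
    allowed = (0, 1) if (mono and plus_one_tolerance) else (0,)
    miscalled = 0
    for e in expected:
        hit = next((o for o in obs if o - e in allowed), None)
        if hit is None:
            miscalled += 1
        else:
            obs.remove(hit)
    return miscalled


def percent_deviation(
    observed: dict[str, GenotypeProfile],
    expected: dict[str, dict[str, tuple[int, int]]],
    *,
    markers: list[str] | None = None,
    mono_markers: set[str] | None = None,
    plus_one_tolerance: bool = True,
) -> DeviationReport:
    """Percent of alleles miscalled relative to expected genotypes.

    ``observed`` and ``expected`` are keyed by sample id; ``expected``
    values map marker -> expected bin pair.  Samples present on one side
    only raise an error listing them.  Profiles may carry a ``day`` entry
    in their metadata for the per-day breakdown.
    """
    missing = sorted(set(observed) ^ set(expected))
    if missing:
        raise ValueError(f"unmatched samples: {', '.join(missing)}")
    mono_markers = mono_markers or set()

    day_counts: dict[str, list[int]] = {}
    marker_counts: dict[str, list[int]] = {}
    total = miscalled = 0
    for sample, prof in observed.items():
        day = str(prof.meta.get("day", "all"))
        for marker, exp_pair in expected[sample].items():
            if markers is not None and marker not in markers:
                continue
            bad = _match_alleles(
                prof.genotype_bins(marker),
                exp_pair,
                mono=marker in mono_markers,
                plus_one_tolerance=plus_one_tolerance,
            )
            total += 2
            miscalled += bad
            day_counts.setdefault(day, [0, 0])
            day_counts[day][0] += 2
            day_counts[day][1] += bad
            marker_counts.setdefault(marker, [0, 0])
            marker_counts[marker][0] += 2
            marker_counts[marker][1] += bad

    def table(counts: dict[str, list[int]], key: str) -> pd.DataFrame:
        rows = [
            {key: k, "total": t, "miscalled": b,
             "percent": 100.0 * b / t if t else 0.0}
            for k, (t, b) in sorted(counts.items())
        ]
        return pd.DataFrame(rows, columns=[key, "total", "miscalled", "percent"])

    tol = "+1 nt accepted for mononucleotide markers; exact bins otherwise" \
        if plus_one_tolerance else "exact bin match"
    return DeviationReport(
        total=total,
        miscalled=miscalled,
        per_day=table(day_counts, "day"),
        per_marker=table(marker_counts, "marker"),
        tolerance=tol,
    )


@dataclass
class ControlChart:
    """Per-run control-sample concordance and deviation attribution."""

    table: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def attribution(self, run_id: str) -> str:
        """Attribute a deviation on ``run_id`` to process or sample integrity."""
        row = self.table[self.table["run"] == run_id]
        if row.empty:
            return "unknown (no control on this run)"
        return "process" if not bool(row.iloc[0]["control_pass"]) else "sample integrity"


def control_chart(
    controls: dict[str, GenotypeProfile],
    reference: dict[str, tuple[int, int]],
    mono_markers: set[str] | None = None,
) -> ControlChart:
    """Track the co-processed control sample across runs.

    Each run's control profile is compared to the control's reference bins
    (mono markers with the +1 tolerance); discordant runs are flagged so
    that sample deviations on those runs are attributed to the process.
    """
    warnings = []
    if not controls:
        warnings.append("no control runs present; attribution unavailable")
    rows = []
    for run_id, prof in controls.items():
        bad = 0
        for marker, exp_pair in reference.items():
            bad += _match_alleles(
                prof.genotype_bins(marker), exp_pair,
                mono=marker in (mono_markers or set()), plus_one_tolerance=True,
            )
        rows.append(dict(run=run_id, miscalled_alleles=bad, control_pass=bad == 0))
    table = pd.DataFrame(rows, columns=["run", "miscalled_alleles", "control_pass"])
    return ControlChart(table=table, warnings=warnings)
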