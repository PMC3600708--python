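"""File formats and run manifests.

Canonical interchange is plain text: traces as TSV (one row per scan,
columns ``scan, FAM, HEX, NED, ROX``), peak and truth tables as CSV,
genotype profiles as JSON.  Every writer embeds provenance metadata
(panel name/version, method, seed, parameters) in ``#``-prefixed header
lines (TSV/CSV) or a ``meta`` object (JSON), so any output can be traced
back to the run that produced it.

ABIF containers (.fsa/.ab1 from ABI genetic analyzers) can be ingested
best-effort through :func:`read_abif`; plain-text TSV remains the
canonical format.
"""

from __future__ import annotations

import io as _stdio
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calling import AlleleCall, GenotypeProfile
from .peaks import CHANNELS, Peak, Trace
from .sizing import SizedPeak


def _meta_header(meta: dict) -> str:
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def _read_meta(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line[1:].strip().split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


# ---------------------------------------------------------------------------
# Traces


def write_trace(trace: Trace, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    buf = _stdio.StringIO()
    buf.write(_meta_header(meta or {}))
    df = pd.DataFrame({"scan": trace.scans})
    for name in CHANNELS:
        df[name] = trace.channels[name]
    df.to_csv(buf, sep="\t", index=False, float_format="%.3f")
    path.write_text(buf.getvalue())


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("scan", *CHANNELS) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    return Trace(
        scans=df["scan"].to_numpy(),
        channels={name: df[name].to_numpy(dtype=float) for name in CHANNELS},
    )


# ---------------------------------------------------------------------------
# Peak tables


def write_peaks(peaks: list[Peak], path: str | Path, meta: dict | None = None) -> None:
    rows = [
        dict(channel=p.channel, apex_scan=p.apex_scan, height=p.height,
             half_width_points=p.half_width_points, area=p.area)
        for p in peaks
    ]
    df = pd.DataFrame(rows, columns=["channel", "apex_scan", "height",
                                     "half_width_points", "area"])
    Path(path).write_text(_meta_header(meta or {}) + df.to_csv(index=False))


def read_peaks(path: str | Path) -> list[Peak]:
    df = pd.read_csv(path, comment="#")
    return [
        Peak(r.channel, float(r.apex_scan), float(r.height),
             float(r.half_width_points), float(r.area))
        for r in df.itertuples()
    ]


def write_sized_peaks(
    peaks: list[SizedPeak], path: str | Path, meta: dict | None = None
) -> None:
    rows = [
        dict(channel=p.channel, apex_scan=p.apex_scan, height=p.height,
             half_width_points=p.half_width_points, area=p.area,
             size_bp=None if p.size_bp is None else round(p.size_bp, 2),
             method=p.method, sized=p.sized)
        for p in peaks
    ]
    df = pd.DataFrame(rows, columns=["channel", "apex_scan", "height",
                                     "half_width_points", "area", "size_bp",
                                     "method", "sized"])
    Path(path).write_text(_meta_header(meta or {}) + df.to_csv(index=False))


def read_sized_peaks(path: str | Path) -> list[SizedPeak]:
    df = pd.read_csv(path, comment="#")
    out = []
    for r in df.itertuples():
        size = None if pd.isna(r.size_bp) else float(r.size_bp)
        out.append(
            SizedPeak(r.channel, float(r.apex_scan), float(r.height),
                      float(r.half_width_points), float(r.area),
                      size, r.method, bool(r.sized))
        )
    return out


# ---------------------------------------------------------------------------
# Genotype profiles


def profile_to_dict(profile: GenotypeProfile) -> dict:
    return {
        "run_id": profile.run_id,
        "meta": profile.meta,
        "calls": {
            marker: [asdict(c) for c in calls]
            for marker, calls in profile.calls.items()
        },
        "flags": profile.flags,
    }


def write_profile(profile: GenotypeProfile, path: str | Path) -> None:
    Path(path).write_text(json.dumps(profile_to_dict(profile), indent=2,
                                     default=float) + "\n")


def read_profile(path: str | Path) -> GenotypeProfile:
    doc = json.loads(Path(path).read_text())
    calls = {
        marker: [AlleleCall(**c) for c in cs]
        for marker, cs in doc.get("calls", {}).items()
    }
    return GenotypeProfile(run_id=doc["run_id"], calls=calls,
                           flags=doc.get("flags", {}), meta=doc.get("meta", {}))


def write_genotype_report(
    profile: GenotypeProfile, path: str | Path, meta: dict | None = None
) -> None:
    """Flat CSV report: run, marker, allele_bin, size_bp, height, ratio, flags."""
    rows = []
    for marker, calls in profile.calls.items():
        flags = ";".join(profile.flags.get(marker, []))
        if not calls:
            rows.append(dict(run=profile.run_id, marker=marker, allele_bin=None,
                             size_bp=None, height=None, ratio=None, flags=flags))
        for c in calls:
            rows.append(dict(run=profile.run_id, marker=marker, allele_bin=c.bin,
                             size_bp=round(c.size_bp, 2), height=c.height,
                             ratio=round(c.ratio, 4), flags=flags))
    df = pd.DataFrame(rows, columns=["run", "marker", "allele_bin", "size_bp",
                                     "height", "ratio", "flags"])
    Path(path).write_text(_meta_header(meta or {}) + df.to_csv(index=False))


# ---------------------------------------------------------------------------
# Manifests


@dataclass
class RunManifest:
    """Everything needed to reproduce a pipeline run bit-identically."""

    inputs: list[str]
    panel: str = "builtin"
    sizing_method: str = "local_southern"
    seed: int | None = None
    out_dir: str = "."
    strict_ladder: bool = True
    extra: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# ABIF ingestion (optional)

#: default mapping of ABIF raw data tags to dye channels (DS-30 filter order)
ABIF_CHANNEL_TAGS = {"FAM": "DATA1", "HEX": "DATA2", "NED": "DATA3", "ROX": "DATA4"}


def read_abif(path: str | Path, channel_tags: dict[str, str] | None = None) -> Trace:
    """Best-effort extraction of a four-channel :class:`Trace` from an ABIF file.

    Uses Biopython's ABIF reader; raw data tags DATA1-DATA4 map to
    FAM/HEX/NED/ROX by default (override ``channel_tags`` for other filter
    sets).  Unrecognized containers raise a ``ValueError`` advising TSV
    conversion.
    """
    from Bio import SeqIO

    channel_tags = channel_tags or ABIF_CHANNEL_TAGS
    try:
        record = SeqIO.read(str(path), "abi")
    except Exception as err:
        raise ValueError(
            f"{path}: not a readable ABIF container ({err}); convert the trace "
            "to the TSV format (scan, FAM, HEX, NED, ROX) instead"
        ) from err
    raw = record.annotations.get("abif_raw", {})
    channels = {}
    for name, tag in channel_tags.items():
        if tag not in raw:
            raise ValueError(
                f"{path}: ABIF tag {tag} (channel {name}) missing; convert to TSV"
            )
        channels[name] = np.asarray(raw[tag], dtype=float)
    n = min(len(v) for v in channels.values())
    channels = {k: v[:n] for k, v in channels.items()}
    return Trace(scans=np.arange(n), channels=channels)
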