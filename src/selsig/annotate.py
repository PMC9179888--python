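"""Interval-overlap annotation of signature regions against a feature BED.

A generic, network-free replacement for database lookups: users export QTL
or gene tracks to BED themselves (name in column 4, free-text category in
column 5) and every region/feature pair with positive overlap is reported.
Intervals are 1-based closed internally (BED converts on read); overlap is
measured span-style, ``min(end) - max(start)``, consistent with the
``end - start`` run-length convention used throughout the package, and must
be strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class FeatureInterval:
    chrom: int
    start_bp: int
    end_bp: int
    name: str
    category: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("feature start > end")


def read_features_bed(path) -> list[FeatureInterval]:
    """Read features from BED (0-based half-open -> 1-based closed)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            category = f[4] if len(f) > 4 else ""
            out.append(FeatureInterval(chrom=int(f[0]), start_bp=int(f[1]) + 1,
                                       end_bp=int(f[2]), name=name,
                                       category=category))
    return sorted(out, key=lambda x: (x.chrom, x.start_bp))


def overlap_annotate(regions, features, flank_bp: int = 0) -> pd.DataFrame:
    """All region/feature pairs with positive overlap after symmetric flank
    extension of the regions; sweep-line over the sorted inputs."""
    import numpy as np

    regions = sorted(regions, key=lambda r: (r.chrom, r.start_bp))
    rows = []
    by_chrom: dict[int, list[FeatureInterval]] = {}
    for f in sorted(features, key=lambda x: (x.chrom, x.start_bp)):
        by_chrom.setdefault(f.chrom, []).append(f)
    arrays = {c: (np.array([f.start_bp for f in fs]),
                  np.array([f.end_bp for f in fs]))
              for c, fs in by_chrom.items()}
    for r in regions:
        if r.chrom not in arrays:
            continue
        fs_start, fs_end = arrays[r.chrom]
        rs, re = r.start_bp - flank_bp, r.end_bp + flank_bp
        hi = np.searchsorted(fs_start, re, side="right")
        overlap = np.minimum(re, fs_end[:hi]) - np.maximum(rs, fs_start[:hi])
        for k in np.flatnonzero(overlap > 0):
            f = by_chrom[r.chrom][k]
            rows.append((r.chrom, r.start_bp, r.end_bp, r.source,
                         r.peak_snp_id, f.name, f.category,
                         f.start_bp, f.end_bp, int(overlap[k])))
    return pd.DataFrame(rows, columns=[
        "chrom", "region_start_bp", "region_end_bp", "source", "peak_snp_id",
        "feature", "category", "feature_start_bp", "feature_end_bp",
        "overlap_bp"])
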