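"""Shared helpers for threshold-based signature-region calling.

Both ROH islands and varLD regions flag the top fraction of a per-position
score track and merge adjacent flagged positions into regions; the threshold
is the empirical order statistic (the smallest of the top ``ceil(n * f)``
values), with ties included, since interpolating between small integer
counts would be fictitious.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("selsig")


@dataclass(frozen=True)
class SignatureRegion:
    """Merged interval of threshold-exceeding positions, with its peak."""

    chrom: int
    start_bp: int
    end_bp: int
    peak_snp_id: str
    peak_value: float
    n_snps_in_region: int
    source: str  # "roh_island" or "varld"

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("region start > end")


def top_fraction_threshold(values: np.ndarray, top_fraction: float) -> float:
    """Smallest value among the top ``ceil(n * top_fraction)`` order stats."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty score track")
    if not 0.0 < top_fraction < 1.0:
        raise ValueError("top_fraction must lie in (0,1)")
    k = int(np.ceil(v.size * top_fraction))
    k = min(max(k, 1), v.size)
    return float(np.partition(v, v.size - k)[v.size - k])


def merge_flagged(chrom: np.ndarray, pos: np.ndarray, snp_ids: np.ndarray,
                  values: np.ndarray, flagged: np.ndarray,
                  merge_gap: int, source: str) -> list[SignatureRegion]:
    """Merge runs of flagged positions into regions (per chromosome).

    Runs separated by at most ``merge_gap`` unflagged positions on the same
    chromosome are joined.  The peak is the flagged position with the highest
    value (leftmost on ties).
    """
    regions: list[SignatureRegion] = []
    idx = np.flatnonzero(flagged)
    if idx.size == 0:
        return regions
    prev = idx[0]
    members = [idx[0]]
    for i in idx[1:]:
        if chrom[i] == chrom[prev] and i - prev - 1 <= merge_gap:
            members.append(i)
        else:
            regions.append(_build_region(chrom, pos, snp_ids, values, members, source))
            members = [i]
        prev = i
    regions.append(_build_region(chrom, pos, snp_ids, values, members, source))
    return regions


def _build_region(chrom, pos, snp_ids, values, members, source) -> SignatureRegion:
    members = np.asarray(members)
    vals = values[members]
    peak = members[int(np.argmax(vals))]  # argmax is leftmost on ties
    return SignatureRegion(
        chrom=int(chrom[members[0]]),
        start_bp=int(pos[members[0]]),
        end_bp=int(pos[members[-1]]),
        peak_snp_id=str(snp_ids[peak]),
        peak_value=float(values[peak]),
        n_snps_in_region=int(members.size),
        source=source,
    )
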