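"""Runs of homozygosity: detection, F_ROH, incidence tracks and ROH islands.

A run of homozygosity (ROH) is a contiguous stretch of homozygous genotype
calls in one individual, interpreted as autozygosity.  Detection follows a
length-class scheme: each class sets a minimum run length in bp together with
a small allowance of missing and (for the longest class) heterozygous calls,
so that genotyping artifacts do not fragment long runs while short runs stay
strict.  All classes additionally require at least 15 consecutive SNPs and
forbid inter-SNP gaps above 1 Mb.

The reported segment set is defined exactly: every index window satisfying
the full constraint set whose extension in either direction violates a
constraint, with windows contained in another reported window dropped.  This
is equivalent to the set of *containment-maximal* valid windows, which is
what both the vectorized detector here and the exhaustive test oracle
compute.  Run endpoints must be called homozygous SNPs — an uncalled
endpoint would inflate the run length.

The genomic inbreeding coefficient is

    F_ROH = (union length of a sample's ROH) / L,

with L the SNP-covered autosomal genome length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._regions import SignatureRegion, merge_flagged, top_fraction_threshold
from .io import MISSING, GenomeMap, GenotypePanel

logger = logging.getLogger("selsig")

__all__ = [
    "RohClassRule", "RohSegment", "IncidenceTrack", "SignatureRegion",
    "DEFAULT_CLASS_RULES", "CLASS_GENERATION_DEPTH",
    "detect_roh", "detect_roh_panel", "froh", "froh_table",
    "roh_incidence", "call_islands",
]


@dataclass(frozen=True)
class RohClassRule:
    """Constraints defining one ROH length class."""

    min_length_bp: int
    allowed_missing: int = 0
    allowed_het: int = 0
    min_snps: int = 15
    max_gap_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if self.min_snps < 2:
            raise ValueError("min_snps must be >= 2")


#: The five length classes with their missing/het allowances, keyed by the
#: class minimum length in Mb (1 and 2 Mb strict; relaxed for longer runs).
DEFAULT_CLASS_RULES: dict[int, RohClassRule] = {
    1: RohClassRule(min_length_bp=1_000_000, allowed_missing=0, allowed_het=0),
    2: RohClassRule(min_length_bp=2_000_000, allowed_missing=0, allowed_het=0),
    4: RohClassRule(min_length_bp=4_000_000, allowed_missing=1, allowed_het=0),
    8: RohClassRule(min_length_bp=8_000_000, allowed_missing=2, allowed_het=0),
    16: RohClassRule(min_length_bp=16_000_000, allowed_missing=4, allowed_het=1),
}

#: Approximate number of generations to the common ancestor probed by each
#: class minimum length (expected autozygous segment length ~ 100/(2g) cM).
CLASS_GENERATION_DEPTH = {16: 3, 8: 6, 4: 12, 2: 25, 1: 50}


@dataclass(frozen=True)
class RohSegment:
    """One homozygous run for one sample (1-based inclusive bp span)."""

    sample_id: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int
    class_min_length: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


@dataclass
class IncidenceTrack:
    """Per-SNP count of samples covered by >= 1 ROH, plus population size."""

    markers: pd.DataFrame  # snp_id, chrom, pos_bp
    counts: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.markers):
            raise ValueError("counts/markers length mismatch")
        if self.counts.size and (self.counts.min() < 0
                                 or self.counts.max() > self.n_samples):
            raise ValueError("counts outside [0, n_samples]")


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _detect_windows(pos: np.ndarray, g: np.ndarray, rule: RohClassRule
                    ) -> list[tuple[int, int]]:
    """Containment-maximal valid windows on one chromosome.

    For every homozygous start i the farthest budget-feasible end index is
    found with order-statistics over the het/missing event positions; the
    window end is pulled back to the last homozygous call.  Since that end is
    non-decreasing in i, containment removal reduces to keeping the first
    start per distinct end.
    """
    n = len(pos)
    if n == 0:
        return []
    het = g == 1
    miss = g == MISSING
    hom = ~het & ~miss

    # unconditional split at gaps > max_gap_bp
    seg_id = np.concatenate([[0], np.cumsum(np.diff(pos) > rule.max_gap_bp)])
    boundary = np.concatenate([np.flatnonzero(np.diff(seg_id) > 0),
                               [n - 1]])  # last index of each segment
    seg_last = np.repeat(boundary, np.diff(np.concatenate([[-1], boundary])))

    het_idx = np.flatnonzero(het)
    miss_idx = np.flatnonzero(miss)
    starts = np.flatnonzero(hom)
    if starts.size == 0:
        return []

    def _first_violation(event_idx: np.ndarray, budget: int) -> np.ndarray:
        """Index of the (budget+1)-th event at/after each start, else n."""
        if len(event_idx) == 0:
            return np.full(starts.shape, n)
        rank = np.searchsorted(event_idx, starts) + budget
        return np.where(rank < len(event_idx),
                        event_idx[np.minimum(rank, len(event_idx) - 1)], n)

    viol_h = _first_violation(het_idx, rule.allowed_het)
    viol_m = _first_violation(miss_idx, rule.allowed_missing)
    j_lim = np.minimum(np.minimum(viol_h, viol_m) - 1, seg_last[starts])

    # pull back to the last homozygous call at or before j_lim
    hom_idx = np.flatnonzero(hom)
    prev_hom = hom_idx[np.searchsorted(hom_idx, j_lim, side="right") - 1]
    j_end = prev_hom  # j_lim >= start and start is hom, so always defined

    valid = (j_end >= starts) \
        & (j_end - starts + 1 >= rule.min_snps) \
        & (pos[j_end] - pos[starts] >= rule.min_length_bp)
    starts, j_end = starts[valid], j_end[valid]
    if starts.size == 0:
        return []
    # keep the first (leftmost) start per distinct end; j_end non-decreasing
    _, first = np.unique(j_end, return_index=True)
    return [(int(starts[k]), int(j_end[k])) for k in first]


def detect_roh(genotypes: np.ndarray, markers: pd.DataFrame,
               rule: RohClassRule, sample_id: str = "sample",
               class_label: int | None = None) -> list[RohSegment]:
    """Detect all maximal qualifying ROH for one sample across chromosomes."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos_bp"].to_numpy()
    label = class_label if class_label is not None else rule.min_length_bp
    segments: list[RohSegment] = []
    for chrom in pd.unique(chrom_arr):
        sel = chrom_arr == chrom
        pos, g = pos_arr[sel], genotypes[sel]
        for i, j in _detect_windows(pos, g, rule):
            win = g[i:j + 1]
            segments.append(RohSegment(
                sample_id=sample_id, chrom=int(chrom),
                start_bp=int(pos[i]), end_bp=int(pos[j]),
                n_snps=j - i + 1,
                n_het=int((win == 1).sum()),
                n_missing=int((win == MISSING).sum()),
                class_min_length=label,
            ))
    return segments


def detect_roh_panel(panel: GenotypePanel, rule: RohClassRule,
                     class_label: int | None = None) -> pd.DataFrame:
    """Per-sample ROH for a whole panel, as a tidy segment table."""
    rows = []
    ids = panel.samples["sample_id"].to_numpy()
    for i in range(panel.n_samples):
        for s in detect_roh(panel.dosage[i], panel.markers, rule,
                            sample_id=str(ids[i]), class_label=class_label):
            rows.append((s.sample_id, s.chrom, s.start_bp, s.end_bp, s.n_snps,
                         s.n_het, s.n_missing, s.length_bp, s.class_min_length))
    return pd.DataFrame(rows, columns=[
        "sample_id", "chrom", "start_bp", "end_bp", "n_snps",
        "n_het", "n_missing", "length_bp", "class_min_length"])


# ---------------------------------------------------------------------------
# F_ROH
# ---------------------------------------------------------------------------

def _union_length(starts: np.ndarray, ends: np.ndarray) -> int:
    """Total bp covered by the union of [start, end] spans (end−start each)."""
    order = np.argsort(starts)
    total = 0
    cur_s = cur_e = None
    for s, e in zip(starts[order], ends[order]):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return int(total)


def froh(segments, genome: GenomeMap) -> float:
    """F_ROH for one sample: union of its ROH spans divided by L.

    Overlapping segments (possible when a class allows heterozygous calls)
    are counted once via interval union.
    """
    if genome.L <= 0:
        raise ValueError("genome length L must be positive")
    if isinstance(segments, pd.DataFrame):
        df = segments
    else:
        df = pd.DataFrame([(s.chrom, s.start_bp, s.end_bp) for s in segments],
                          columns=["chrom", "start_bp", "end_bp"])
    if df.empty:
        return 0.0
    total = 0
    for _, sub in df.groupby("chrom"):
        total += _union_length(sub["start_bp"].to_numpy(),
                               sub["end_bp"].to_numpy())
    value = total / genome.L
    if not 0.0 <= value <= 1.0 + 1e-12:
        raise AssertionError(f"F_ROH={value} outside [0,1]")
    return min(value, 1.0)


def froh_table(panel: GenotypePanel, genome: GenomeMap,
               rules: dict[int, RohClassRule] = DEFAULT_CLASS_RULES
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample and population-summary F_ROH for every length class.

    Columns are ordered longest-first (16 … 1 Mb), i.e. from the most recent
    inbreeding (common ancestors ~3 generations back) to the deepest
    (~50 generations).  The column for minimum length c aggregates the runs
    of *every* class with min length >= c: a long run rescued by its
    length-appropriate error allowances still counts as a run >= c, which
    also makes F_ROH non-increasing in c by construction (the strict short
    classes alone could lose coverage around an allowed missing call).
    Returns ``(per_sample, summary)`` with mean and SD per population.
    """
    class_keys = sorted(rules, reverse=True)
    data = {}
    cumulative = None
    for key in class_keys:
        seg = detect_roh_panel(panel, rules[key], class_label=key)
        cumulative = seg if cumulative is None else pd.concat(
            [cumulative, seg], ignore_index=True)
        by_sample = {sid: sub for sid, sub in cumulative.groupby("sample_id")}
        empty = cumulative.iloc[0:0]
        data[key] = [froh(by_sample.get(str(sid), empty), genome)
                     for sid in panel.samples["sample_id"]]
    per_sample = pd.DataFrame({"sample_id": panel.samples["sample_id"],
                               "population": panel.samples["population"]})
    for key in class_keys:
        gen = CLASS_GENERATION_DEPTH.get(key)
        col = f"froh_{key}mb" + (f"_gen{gen}" if gen else "")
        per_sample[col] = data[key]
    value_cols = [c for c in per_sample.columns if c.startswith("froh_")]
    summary = per_sample.groupby("population")[value_cols].agg(["mean", "std"])
    return per_sample, summary


# ---------------------------------------------------------------------------
# Incidence and islands
# ---------------------------------------------------------------------------

def roh_incidence(segments: pd.DataFrame, markers: pd.DataFrame,
                  n_samples: int) -> IncidenceTrack:
    """Per-SNP count of samples whose ROH cover that SNP.

    A sample is counted at most once per SNP even if several of its segments
    overlap there.
    """
    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos_bp"].to_numpy()
    counts = np.zeros(len(markers), dtype=np.int64)
    if segments.empty:
        return IncidenceTrack(markers=markers[["snp_id", "chrom", "pos_bp"]],
                              counts=counts, n_samples=n_samples)
    for _, sub in segments.groupby("sample_id"):
        covered = np.zeros(len(markers), dtype=bool)
        for r in sub.itertuples(index=False):
            sel = np.flatnonzero(chrom_arr == r.chrom)
            a = np.searchsorted(pos_arr[sel], r.start_bp, side="left")
            b = np.searchsorted(pos_arr[sel], r.end_bp, side="right")
            covered[sel[a:b]] = True
        counts += covered
    return IncidenceTrack(markers=markers[["snp_id", "chrom", "pos_bp"]].copy(),
                          counts=counts, n_samples=n_samples)


def call_islands(track: IncidenceTrack, top_fraction: float = 0.01,
                 merge_gap_snps: int = 0
                 ) -> tuple[list[SignatureRegion], float]:
    """Call ROH islands: the top fraction of most-covered SNPs, merged.

    Returns the merged regions and the incidence threshold (ties included,
    so more than ``top_fraction`` of SNPs may be flagged).  A constant track
    flags every SNP and logs a degenerate-track warning.
    """
    if len(track.counts) == 0:
        raise ValueError("empty incidence track")
    threshold = top_fraction_threshold(track.counts, top_fraction)
    if track.counts.min() == track.counts.max():
        logger.warning("degenerate incidence track (all counts equal %d); "
                       "every SNP ties the threshold", int(track.counts[0]))
    flagged = track.counts >= threshold
    regions = merge_flagged(
        chrom=track.markers["chrom"].to_numpy(),
        pos=track.markers["pos_bp"].to_numpy(),
        snp_ids=track.markers["snp_id"].to_numpy(),
        values=track.counts.astype(float),
        flagged=flagged, merge_gap=merge_gap_snps, source="roh_island")
    return regions, threshold
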