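"""Pairwise linkage disequilibrium (r²) and the LD-decay curve.

LD is measured as the squared Pearson correlation of unphased genotype
dosages (composite LD), computed on pairwise-complete samples, between all
same-chromosome SNP pairs up to a physical distance cut-off (1000 kb by
default).  The decay summary orders the pairs by inter-marker distance and
averages r² within consecutive non-overlapping blocks of five pairs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import MISSING, GenotypePanel

logger = logging.getLogger("selsig")

#: Minimum pairwise-complete sample count for a defined correlation.
MIN_COMPLETE = 3


def _banded_r2(dosage: np.ndarray, pos: np.ndarray, max_dist_bp: int):
    """All (i, j>i) pairs on one chromosome within max_dist_bp, vectorized
    per column offset.  Returns (i_idx, j_idx, r2) with NaN where undefined
    (zero variance or < MIN_COMPLETE complete samples)."""
    n_snps = dosage.shape[1]
    called = dosage != MISSING
    x = np.where(called, dosage, 0).astype(np.float64)
    out_i, out_j, out_r2 = [], [], []
    for d in range(1, n_snps):
        dist = pos[d:] - pos[:-d]
        keep = dist <= max_dist_bp
        if not keep.any():
            break
        a = np.flatnonzero(keep)          # left column index
        b = a + d
        va, vb = called[:, a], called[:, b]
        both = va & vb
        n = both.sum(axis=0).astype(np.float64)
        xa, xb = x[:, a], x[:, b]
        sx = (xa * both).sum(axis=0)
        sy = (xb * both).sum(axis=0)
        sxx = (xa * xa * both).sum(axis=0)
        syy = (xb * xb * both).sum(axis=0)
        sxy = (xa * xb * both).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = n * sxy - sx * sy
            var_x = n * sxx - sx * sx
            var_y = n * syy - sy * sy
            r2 = (cov * cov) / (var_x * var_y)
        r2[(n < MIN_COMPLETE) | (var_x <= 0) | (var_y <= 0)] = np.nan
        out_i.append(a)
        out_j.append(b)
        out_r2.append(r2)
    if not out_i:
        empty = np.array([], dtype=np.int64)
        return empty, empty, np.array([], dtype=float)
    return (np.concatenate(out_i), np.concatenate(out_j),
            np.concatenate(out_r2))


def ld_pairs(panel: GenotypePanel, max_dist_bp: int = 1_000_000) -> pd.DataFrame:
    """r² for every same-chromosome SNP pair within ``max_dist_bp``.

    Undefined pairs (zero variance at either SNP, or fewer than three
    pairwise-complete samples) carry ``r2 = NaN`` and are excluded from the
    decay curve; their count is logged.
    """
    frames = []
    ids = panel.markers["snp_id"].to_numpy()
    pos_all = panel.markers["pos_bp"].to_numpy()
    for chrom, sl in panel.chrom_slices():
        i, j, r2 = _banded_r2(panel.dosage[:, sl], pos_all[sl], max_dist_bp)
        if len(i) == 0:
            continue
        off = sl.start
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "snp_a": ids[off + i], "snp_b": ids[off + j],
            "pos_a": pos_all[off + i], "pos_b": pos_all[off + j],
            "distance_bp": pos_all[off + j] - pos_all[off + i],
            "r2": r2,
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "snp_a", "snp_b", "pos_a",
                                     "pos_b", "distance_bp", "r2"])
    out = pd.concat(frames, ignore_index=True)
    n_undef = int(out["r2"].isna().sum())
    if n_undef:
        logger.info("%d of %d LD pairs undefined (zero variance or <%d "
                    "complete samples)", n_undef, len(out), MIN_COMPLETE)
    return out


def decay_curve(pairs: pd.DataFrame, block_size: int = 5) -> pd.DataFrame:
    """Average r² in consecutive blocks of ``block_size`` distance-ordered
    pairs (the final short block is averaged over its own size)."""
    defined = pairs.dropna(subset=["r2"])
    if defined.empty:
        raise ValueError("no defined LD pairs to build a decay curve from")
    ordered = defined.sort_values(
        ["distance_bp", "chrom", "pos_a", "pos_b"], kind="mergesort")
    block = np.arange(len(ordered)) // block_size
    grouped = ordered.groupby(block)
    out = pd.DataFrame({
        "mean_distance_bp": grouped["distance_bp"].mean(),
        "mean_r2": grouped["r2"].mean(),
        "n_pairs": grouped.size(),
    }).reset_index(drop=True)
    assert out["mean_distance_bp"].is_monotonic_increasing
    return out


def binned_decay(pairs: pd.DataFrame, n_bins: int = 10,
                 max_dist_bp: int = 1_000_000) -> pd.DataFrame:
    """Mean r² in ``n_bins`` equal-width distance bins (for curve-vs-curve
    comparison and plotting; each bin aggregates many pairs)."""
    defined = pairs.dropna(subset=["r2"])
    edges = np.linspace(0, max_dist_bp, n_bins + 1)
    idx = np.clip(np.digitize(defined["distance_bp"], edges) - 1, 0, n_bins - 1)
    grouped = defined.groupby(idx)["r2"]
    return pd.DataFrame({
        "bin_mid_bp": (edges[:-1] + edges[1:]) / 2,
        "mean_r2": grouped.mean().reindex(range(n_bins)),
        "n_pairs": grouped.size().reindex(range(n_bins), fill_value=0),
    })
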