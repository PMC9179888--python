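"""Between-population selection signatures from variance in LD (varLD).

For each window of consecutive SNPs (default 50, step 1, never spanning a
chromosome break) the two populations' windowed LD matrices — pairwise
signed Pearson correlations of dosages by default — are compared through
their ordered eigenvalue spectra:

    raw = sum_i | lambda_A,(i) - lambda_B,(i) |,

with eigenvalues sorted descending.  Raw scores are standardized genome-wide
to mean 0 / SD 1, each window is anchored to its middle SNP, and regions
exceeding the empirical top-1% / 0.1% / 0.01% thresholds of the standardized
score are reported as between-population selection signatures.

Both panels must sit on the identical (intersected, QC'd) marker map.  A
direct matrix-difference comparison (sum |r_A − r_B|) is available behind
``comparison="matrix_diff"`` for sensitivity analysis; the eigenvalue
spectrum comparison is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._regions import SignatureRegion, merge_flagged, top_fraction_threshold
from .io import MISSING, GenotypePanel
from .ld import MIN_COMPLETE

logger = logging.getLogger("selsig")


@dataclass(frozen=True)
class VarLdConfig:
    window_snps: int = 50
    ld_measure: str = "signed_r"          # or "r2"
    comparison: str = "eigen"             # or "matrix_diff"
    top_fractions: tuple[float, ...] = (0.01, 0.001, 0.0001)

    def __post_init__(self) -> None:
        if self.window_snps < 2:
            raise ValueError("window_snps must be >= 2")
        if self.ld_measure not in ("signed_r", "r2"):
            raise ValueError(f"unknown ld_measure {self.ld_measure!r}")
        if self.comparison not in ("eigen", "matrix_diff"):
            raise ValueError(f"unknown comparison {self.comparison!r}")
        if list(self.top_fractions) != sorted(self.top_fractions, reverse=True):
            raise ValueError("top_fractions must be descending")


def _corr_matrix(dosage: np.ndarray) -> np.ndarray:
    """Pairwise-complete signed correlation matrix of dosage columns.

    Diagonal is 1; undefined entries (zero variance or < MIN_COMPLETE
    complete sample pairs) are set to 0 off-diagonal.
    """
    called = (dosage != MISSING)
    m = called.astype(np.float64)
    x = np.where(called, dosage, 0).astype(np.float64)
    n = m.T @ m
    sx = x.T @ m          # sum of x over samples complete for the pair
    sxx = (x * x).T @ m
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        var = n * sxx - sx * sx
        denom = np.sqrt(var * var.T)
        r = cov / denom
    undef = (n < MIN_COMPLETE) | (var <= 0) | (var.T <= 0)
    r[undef] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def ld_matrix(panel: GenotypePanel, snp_range: slice,
              measure: str = "signed_r") -> np.ndarray:
    """Windowed LD matrix for the SNP index range (one chromosome)."""
    chroms = panel.markers["chrom"].to_numpy()[snp_range]
    if len(np.unique(chroms)) > 1:
        raise ValueError("window spans more than one chromosome")
    r = _corr_matrix(panel.dosage[:, snp_range])
    return r * r if measure == "r2" else r


def varld_raw(matrix_a: np.ndarray, matrix_b: np.ndarray) -> float:
    """Sum of absolute differences of the two ordered eigenvalue spectra."""
    matrix_a = np.asarray(matrix_a, dtype=float)
    matrix_b = np.asarray(matrix_b, dtype=float)
    if matrix_a.shape != matrix_b.shape:
        raise ValueError(f"dimension mismatch {matrix_a.shape} vs {matrix_b.shape}")
    ev_a = np.linalg.eigvalsh(matrix_a)   # ascending; abs-diff is order-free
    ev_b = np.linalg.eigvalsh(matrix_b)
    return float(np.abs(ev_a - ev_b).sum())


def _matrix_diff_raw(matrix_a: np.ndarray, matrix_b: np.ndarray) -> float:
    """Non-default direct comparison: sum |r_A - r_B| over the upper triangle."""
    iu = np.triu_indices(matrix_a.shape[0], k=1)
    return float(np.abs(matrix_a[iu] - matrix_b[iu]).sum())


def varld_scan(panel_a: GenotypePanel, panel_b: GenotypePanel,
               config: VarLdConfig = VarLdConfig()) -> pd.DataFrame:
    """Sliding-window varLD scan over the shared marker map.

    Returns a track with one row per window: chrom, anchor SNP (the window's
    middle SNP) id and position, raw score and genome-wide standardized
    score.  Chromosomes shorter than the window are skipped with a warning;
    if all raw scores are identical (e.g. identical panels) the standardized
    scores are set to 0 with a degeneracy warning.
    """
    if not panel_a.markers[["snp_id", "chrom", "pos_bp"]].reset_index(drop=True).equals(
            panel_b.markers[["snp_id", "chrom", "pos_bp"]].reset_index(drop=True)):
        raise ValueError("panels must share an identical marker map "
                         "(run intersect_snps first)")
    w = config.window_snps
    ids = panel_a.markers["snp_id"].to_numpy()
    pos = panel_a.markers["pos_bp"].to_numpy()
    rows_chrom, rows_anchor, rows_raw = [], [], []
    compare = varld_raw if config.comparison == "eigen" else _matrix_diff_raw
    for chrom, sl in panel_a.chrom_slices():
        n_chrom = sl.stop - sl.start
        if n_chrom < w:
            logger.warning("chromosome %d has %d SNPs < window %d; skipped",
                           chrom, n_chrom, w)
            continue
        ra = _corr_matrix(panel_a.dosage[:, sl])
        rb = _corr_matrix(panel_b.dosage[:, sl])
        if config.ld_measure == "r2":
            ra, rb = ra * ra, rb * rb
        for k in range(n_chrom - w + 1):
            rows_chrom.append(chrom)
            rows_anchor.append(sl.start + k + w // 2)
            rows_raw.append(compare(ra[k:k + w, k:k + w], rb[k:k + w, k:k + w]))
    if not rows_raw:
        raise ValueError("no chromosome long enough for the varLD window")
    raw = np.array(rows_raw)
    sd = raw.std(ddof=0)
    if sd == 0:
        logger.warning("degenerate varLD track: all raw scores equal %.3g; "
                       "standardized scores set to 0", raw[0] if len(raw) else 0)
        std = np.zeros_like(raw)
    else:
        std = (raw - raw.mean()) / sd
    anchor = np.array(rows_anchor)
    return pd.DataFrame({
        "chrom": np.array(rows_chrom),
        "anchor_snp_id": ids[anchor],
        "anchor_pos_bp": pos[anchor],
        "raw_score": raw,
        "std_score": std,
    })


def call_varld_regions(track: pd.DataFrame,
                       top_fractions: tuple[float, ...] = (0.01, 0.001, 0.0001)
                       ) -> dict[float, list[SignatureRegion]]:
    """Signature regions per top fraction (nested across fractions).

    Adjacent flagged window anchors on one chromosome merge into a region;
    an isolated flagged anchor becomes a single-SNP region.  A degenerate
    track (all scores equal) yields no regions.
    """
    std = track["std_score"].to_numpy()
    out: dict[float, list[SignatureRegion]] = {}
    if len(std) == 0 or std.min() == std.max():
        logger.warning("degenerate varLD track; no regions called")
        return {f: [] for f in top_fractions}
    for f in top_fractions:
        threshold = top_fraction_threshold(std, f)
        flagged = std >= threshold
        out[f] = merge_flagged(
            chrom=track["chrom"].to_numpy(),
            pos=track["anchor_pos_bp"].to_numpy(),
            snp_ids=track["anchor_snp_id"].to_numpy(),
            values=std, flagged=flagged, merge_gap=0, source="varld")
    return out
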