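"""SNP-array quality control.

Two marker profiles are produced downstream of the same thresholds: the
ROH profile keeps low-MAF SNPs (``apply_maf=False``) because homozygosity
estimation must not discard nearly-fixed sites, while the LD profile removes
them (``apply_maf=True``).  Filter order mirrors PLINK: non-autosomes, then
samples by call rate, then SNPs (missingness → MAF → Hardy–Weinberg exact
test) recomputed on the kept samples only.  HWE is tested within each
population panel separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .io import MISSING, GenotypePanel

logger = logging.getLogger("selsig")


@dataclass(frozen=True)
class QcThresholds:
    """QC cut-offs (fractions in [0,1]; ``hwe_alpha`` a p-value)."""

    max_sample_missing: float = 0.10
    max_snp_missing: float = 0.10
    min_maf: float = 0.01
    hwe_alpha: float = 1e-7
    apply_maf: bool = True

    def __post_init__(self) -> None:
        for name in ("max_sample_missing", "max_snp_missing", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if not 0.0 < self.hwe_alpha <= 1.0:
            raise ValueError(f"hwe_alpha={self.hwe_alpha} outside (0,1]")


@dataclass
class QcReport:
    """Per-removal bookkeeping; kept + removed = input counts per axis."""

    removed_samples: pd.DataFrame  # sample_id, reason
    removed_snps: pd.DataFrame     # snp_id, reason
    n_samples_kept: int
    n_snps_kept: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# samples kept\t{self.n_samples_kept}\n")
            fh.write(f"# snps kept\t{self.n_snps_kept}\n")
            fh.write("axis\tid\treason\n")
            for r in self.removed_samples.itertuples(index=False):
                fh.write(f"sample\t{r.sample_id}\t{r.reason}\n")
            for r in self.removed_snps.itertuples(index=False):
                fh.write(f"snp\t{r.snp_id}\t{r.reason}\n")


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=65536)
def _het_probabilities(n_rare: int, n_genotypes: int):
    """Conditional distribution of the heterozygote count.

    Given ``n_genotypes`` diploid genotypes and ``n_rare`` copies of the rarer
    allele, returns (possible het counts, their probabilities) under random
    union of gametes.  Uses the standard mid-out multiplicative recurrence.
    """
    mid = n_rare * (2 * n_genotypes - n_rare) // (2 * n_genotypes)
    if mid % 2 != n_rare % 2:
        mid += 1
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    probs = np.zeros(len(hets), dtype=float)
    i_mid = (mid - hets[0]) // 2
    probs[i_mid] = 1.0
    # going down: P(h-2)/P(h) = h(h-1) / ((r/2 - ...)) style ratios
    for i in range(i_mid, 0, -1):
        h = hets[i]
        hom_r = (n_rare - h) // 2
        hom_c = n_genotypes - h - hom_r
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
    for i in range(i_mid, len(hets) - 1):
        h = hets[i]
        hom_r = (n_rare - h) // 2
        hom_c = n_genotypes - h - hom_r
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((h + 1) * (h + 2))
    probs /= probs.sum()
    return hets, probs


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy–Weinberg p-value.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the probabilities no larger than that of the observed count.
    Monomorphic SNPs return 1.0 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = n_Aa + 2 * n_aa
    n_rare = min(n_a, 2 * n - n_a)
    if n_rare == 0:
        return 1.0
    hets, probs = _het_probabilities(int(n_rare), int(n))
    p_obs = probs[(hets == n_Aa).argmax()]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def _hwe_pvalues(dosage: np.ndarray) -> np.ndarray:
    """Vector of HWE p-values, one per SNP column (MISSING ignored)."""
    n_AA = (dosage == 2).sum(axis=0)
    n_Aa = (dosage == 1).sum(axis=0)
    n_aa = (dosage == 0).sum(axis=0)
    out = np.ones(dosage.shape[1])
    for j in range(dosage.shape[1]):
        if n_AA[j] + n_Aa[j] + n_aa[j] > 0:
            out[j] = hwe_exact_test(int(n_AA[j]), int(n_Aa[j]), int(n_aa[j]))
    return out


# ---------------------------------------------------------------------------
# Panel-level QC
# ---------------------------------------------------------------------------

def apply_qc(panel: GenotypePanel, thresholds: QcThresholds = QcThresholds()
             ) -> tuple[GenotypePanel, QcReport]:
    """Filter a panel; returns the kept panel and a removal report.

    Order: samples by missing fraction, then per-SNP statistics recomputed on
    the kept samples — missingness, MAF (iff ``apply_maf``), HWE.  Each
    removed SNP is recorded with its first triggering reason.  Non-autosomes
    are expected to have been dropped at read time.
    """
    t = thresholds
    called = panel.dosage != MISSING

    samp_missing = 1.0 - called.mean(axis=1) if panel.n_snps else np.zeros(panel.n_samples)
    keep_s = samp_missing <= t.max_sample_missing
    removed_samples = pd.DataFrame({
        "sample_id": panel.samples["sample_id"].to_numpy()[~keep_s],
        "reason": [f"missing_fraction={samp_missing[i]:.4f}>"
                   f"{t.max_sample_missing}" for i in np.flatnonzero(~keep_s)],
    })
    if not keep_s.any():
        raise ValueError("QC removed every sample")
    kept = panel.subset(sample_idx=np.flatnonzero(keep_s))

    called = kept.dosage != MISSING
    n_called = called.sum(axis=0)
    snp_missing = 1.0 - n_called / kept.n_samples
    reasons = np.full(kept.n_snps, "", dtype=object)

    fail = snp_missing > t.max_snp_missing
    # SNPs with zero called genotypes fall under missingness as well
    fail |= n_called == 0
    reasons[fail] = "missingness"

    with np.errstate(invalid="ignore"):
        p_a1 = np.where(n_called > 0,
                        (kept.dosage * called).sum(axis=0) / (2 * np.maximum(n_called, 1)),
                        0.0)
    maf = np.minimum(p_a1, 1.0 - p_a1)
    if t.apply_maf:
        m = (maf < t.min_maf) & (reasons == "")
        reasons[m] = "maf"

    todo = np.flatnonzero(reasons == "")
    if len(todo):
        pvals = _hwe_pvalues(kept.dosage[:, todo])
        h = todo[pvals < t.hwe_alpha]
        reasons[h] = "hwe"

    keep_m = reasons == ""
    if not keep_m.any():
        raise ValueError("QC removed every SNP")
    removed_snps = pd.DataFrame({
        "snp_id": kept.markers["snp_id"].to_numpy()[~keep_m],
        "reason": reasons[~keep_m],
    })
    out = kept.subset(snp_idx=np.flatnonzero(keep_m))
    report = QcReport(removed_samples=removed_samples, removed_snps=removed_snps,
                      n_samples_kept=out.n_samples, n_snps_kept=out.n_snps)
    logger.info("QC: kept %d/%d samples, %d/%d SNPs",
                out.n_samples, panel.n_samples, out.n_snps, panel.n_snps)
    return out, report


def intersect_snps(panel_a: GenotypePanel, panel_b: GenotypePanel
                   ) -> tuple[GenotypePanel, GenotypePanel]:
    """Restrict both panels to their common snp_id set, same column order."""
    ids_a = panel_a.markers["snp_id"]
    common = set(ids_a) & set(panel_b.markers["snp_id"])
    if not common:
        raise ValueError("no SNPs shared between the two panels")
    idx_a = np.flatnonzero(ids_a.isin(common).to_numpy())
    out_a = panel_a.subset(snp_idx=idx_a)
    order_b = panel_b.markers.reset_index().set_index("snp_id")
    idx_b = order_b.loc[out_a.markers["snp_id"], "index"].to_numpy()
    out_b = panel_b.subset(snp_idx=idx_b)
    ma = out_a.markers[["snp_id", "chrom", "pos_bp"]].reset_index(drop=True)
    mb = out_b.markers[["snp_id", "chrom", "pos_bp"]].reset_index(drop=True)
    if not ma.equals(mb):
        raise ValueError("shared snp_ids disagree on chrom/pos between panels")
    return out_a, out_b
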