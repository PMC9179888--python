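"""PLINK-format genotype I/O and the canonical in-memory data model.

The central container is :class:`GenotypePanel`: a sample × SNP matrix of
A1-allele dosages ({0, 1, 2}, with ``MISSING = -1`` as a distinct sentinel)
plus a marker map sorted by (chromosome, position) and per-sample metadata.
Both the PLINK 1.9 binary fileset (``.bed/.bim/.fam``, SNP-major) and the
text fileset (``.ped/.map``) are supported, round-trip exactly, and yield
identical panels for the same data.

Coordinates are 1-based inclusive base pairs internally; BED exports convert
to 0-based half-open.  Dosage counts the BIM A1 allele; every downstream
statistic in this package (homozygosity, correlation) is invariant to allele
relabeling, so no strand/flip handling is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("selsig")

#: Sentinel for an uncalled genotype in the dosage matrix (int8).
MISSING = np.int8(-1)

#: Default autosome count (sheep).
DEFAULT_AUTOSOME_COUNT = 26

MARKER_COLUMNS = ["snp_id", "chrom", "pos_bp", "a1", "a2"]
SAMPLE_COLUMNS = ["sample_id", "sex", "population"]


class PlinkFormatError(ValueError):
    """A PLINK fileset is malformed (bad magic bytes, truncated records...)."""


@dataclass
class GenotypePanel:
    """Diploid SNP-array genotypes for one population sample.

    Parameters
    ----------
    markers
        DataFrame with columns ``snp_id, chrom, pos_bp, a1, a2``, sorted by
        (chrom, pos_bp) with strictly increasing positions per chromosome.
    samples
        DataFrame with columns ``sample_id, sex, population``.
    dosage
        ``int8`` array of shape (n_samples, n_snps); per-entry count of the
        A1 allele in {0, 1, 2} or ``MISSING``.
    """

    markers: pd.DataFrame
    samples: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)} samples, {len(self.markers)} snps)"
            )
        if len(self.markers):
            ids = self.markers["snp_id"]
            if ids.duplicated().any():
                dups = sorted(ids[ids.duplicated()].unique())
                raise ValueError(f"duplicate snp_id values: {dups[:10]}")
            if not _is_sorted(self.markers):
                raise ValueError("markers must be sorted by (chrom, pos_bp), "
                                 "strictly increasing within chromosome")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"{bad.sum()} dosage entries outside {{0,1,2,MISSING}}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.markers)

    def subset(self, sample_idx=None, snp_idx=None) -> "GenotypePanel":
        """Row/column subset by positional index, preserving order."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypePanel(
            markers=self.markers.iloc[mi],
            samples=self.samples.iloc[si],
            dosage=self.dosage[np.ix_(si, mi)],
        )

    def chrom_slices(self):
        """Yield (chrom, slice) pairs of the contiguous per-chromosome blocks."""
        chroms = self.markers["chrom"].to_numpy()
        if not len(chroms):
            return
        bounds = np.flatnonzero(np.diff(chroms)) + 1
        starts = np.concatenate([[0], bounds])
        stops = np.concatenate([bounds, [len(chroms)]])
        for a, b in zip(starts, stops):
            yield int(chroms[a]), slice(int(a), int(b))

    def equals(self, other: "GenotypePanel") -> bool:
        return (
            self.markers.reset_index(drop=True).equals(other.markers.reset_index(drop=True))
            and self.samples.reset_index(drop=True).equals(other.samples.reset_index(drop=True))
            and np.array_equal(self.dosage, other.dosage)
        )


@dataclass
class GenomeMap:
    """Per-chromosome SNP coverage spans and the total covered length L."""

    table: pd.DataFrame  # chrom, first_snp_bp, last_snp_bp, n_snps
    L: int = field(init=False)

    def __post_init__(self) -> None:
        spans = (self.table["last_snp_bp"] - self.table["first_snp_bp"]).to_numpy()
        self.L = int(spans.sum())
        if self.L <= 0:
            raise ValueError("covered genome length L must be positive")


def _is_sorted(markers: pd.DataFrame) -> bool:
    chrom = markers["chrom"].to_numpy()
    pos = markers["pos_bp"].to_numpy()
    key_ok = np.all(np.diff(chrom) >= 0)
    within = (np.diff(chrom) > 0) | (np.diff(pos) > 0)
    return bool(key_ok and within.all())


def sort_markers(markers: pd.DataFrame, dosage: np.ndarray):
    order = np.lexsort((markers["pos_bp"].to_numpy(), markers["chrom"].to_numpy()))
    return markers.iloc[order], dosage[:, order]


def genome_map(panel: GenotypePanel) -> GenomeMap:
    """Covered autosomal genome: per-chromosome (first, last, n) and total L.

    A chromosome carrying a single SNP contributes zero length (logged).
    """
    if panel.n_snps == 0:
        raise ValueError("cannot build a genome map from an empty panel")
    rows = []
    for chrom, sl in panel.chrom_slices():
        pos = panel.markers["pos_bp"].to_numpy()[sl]
        if len(pos) == 1:
            logger.warning("chromosome %d has a single SNP; contributes 0 bp", chrom)
        rows.append((chrom, int(pos[0]), int(pos[-1]), len(pos)))
    table = pd.DataFrame(rows, columns=["chrom", "first_snp_bp", "last_snp_bp", "n_snps"])
    return GenomeMap(table)


# ---------------------------------------------------------------------------
# PLINK binary (.bed/.bim/.fam)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes (SNP-major): 00=hom A1, 01=missing, 10=het, 11=hom A2.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0, 1: 2, 0: 3, int(MISSING): 1}


def _read_bim(path: Path) -> pd.DataFrame:
    try:
        bim = pd.read_csv(path, sep=r"\s+", header=None,
                          names=["chrom", "snp_id", "cm", "pos_bp", "a1", "a2"],
                          dtype={"chrom": int, "snp_id": str, "pos_bp": int,
                                 "a1": str, "a2": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=MARKER_COLUMNS)
    return bim[["snp_id", "chrom", "pos_bp", "a1", "a2"]]


def _read_fam(path: Path) -> pd.DataFrame:
    fam = pd.read_csv(path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"fid": str, "iid": str, "sex": int})
    return pd.DataFrame({"sample_id": fam["iid"], "sex": fam["sex"],
                         "population": fam["fid"]})


def _read_bed_matrix(path: Path, n_samples: int, n_snps: int) -> np.ndarray:
    raw = np.fromfile(path, dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:3]) != _BED_MAGIC:
        raise PlinkFormatError(
            f"{path}: bad magic bytes at offset 0: "
            f"{bytes(raw[:3])!r} (expected {_BED_MAGIC!r}, SNP-major)")
    body = raw[3:]
    bytes_per_snp = (n_samples + 3) // 4
    if len(body) != bytes_per_snp * n_snps:
        raise PlinkFormatError(
            f"{path}: record-length mismatch at byte offset {3 + len(body)}: "
            f"{len(body)} data bytes, expected {bytes_per_snp * n_snps} "
            f"({n_snps} SNPs x {bytes_per_snp} bytes)")
    if n_snps == 0:
        return np.zeros((n_samples, 0), dtype=np.int8)
    blocks = body.reshape(n_snps, bytes_per_snp)
    # unpack 4 two-bit codes per byte, little-end first
    codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    return _CODE_TO_DOSAGE[codes[:, :n_samples]].T.copy()


def _write_bed_matrix(path: Path, dosage: np.ndarray) -> None:
    n_samples, n_snps = dosage.shape
    bytes_per_snp = (n_samples + 3) // 4
    codes = np.zeros((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for d, c in _DOSAGE_TO_CODE.items():
        lut[d & 0xFF] = c
    codes[:, :n_samples] = lut[dosage.T.astype(np.uint8)]
    packed = np.zeros((n_snps, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)
    with open(path, "wb") as fh:
        fh.write(_BED_MAGIC)
        packed.tofile(fh)


# ---------------------------------------------------------------------------
# PLINK text (.ped/.map)
# ---------------------------------------------------------------------------

def _read_text(prefix: Path) -> GenotypePanel:
    # 4-column PLINK map, or the 6-column extended map written by
    # _write_text (a1/a2 appended so allele roles survive a round trip)
    try:
        mp = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None)
    except pd.errors.EmptyDataError:
        mp = pd.DataFrame(columns=["chrom", "snp_id", "cm", "pos_bp"])
    if mp.shape[1] == 6:
        mp.columns = ["chrom", "snp_id", "cm", "pos_bp", "map_a1", "map_a2"]
    else:
        mp.columns = ["chrom", "snp_id", "cm", "pos_bp"]
    mp = mp.astype({"chrom": int, "snp_id": str, "pos_bp": int})
    n_snps = len(mp)
    sample_rows, geno_rows, allele_obs = [], [], [set() for _ in range(n_snps)]
    with open(prefix.with_suffix(".ped")) as fh:
        for line_no, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * n_snps:
                raise PlinkFormatError(
                    f"{prefix.with_suffix('.ped')}: line {line_no} has "
                    f"{len(fields)} fields, expected {6 + 2 * n_snps}")
            sample_rows.append((fields[1], int(fields[4]), fields[0]))
            geno_rows.append(fields[6:])
    alleles = np.array(geno_rows, dtype="U8").reshape(len(geno_rows), n_snps, 2) \
        if geno_rows else np.empty((0, n_snps, 2), dtype="U8")
    if "map_a1" in mp.columns:
        a1 = mp["map_a1"].to_numpy(dtype=object)
        a2 = mp["map_a2"].to_numpy(dtype=object)
    else:
        # allele roles not stored in plain ped/map: first seen non-missing
        # allele becomes A1 (logged, since roles are a convention here)
        logger.info("plain .map lacks allele columns; inferring A1/A2 from "
                    "first occurrence in the .ped")
        a1 = np.full(n_snps, "A", dtype=object)
        a2 = np.full(n_snps, "B", dtype=object)
        for j in range(n_snps):
            seen = [a for a in pd.unique(alleles[:, j, :].ravel()) if a != "0"]
            if len(seen) > 2:
                raise PlinkFormatError(f"SNP {mp['snp_id'][j]}: >2 alleles {seen}")
            if len(seen) >= 1:
                a1[j] = seen[0]
            if len(seen) == 2:
                a2[j] = seen[1]
    dosage = np.full((len(sample_rows), n_snps), MISSING, dtype=np.int8)
    if len(sample_rows):
        missing = (alleles == "0").any(axis=2)
        n_a1 = (alleles == a1[None, :, None]).sum(axis=2).astype(np.int8)
        dosage = np.where(missing, MISSING, n_a1)
    markers = pd.DataFrame({"snp_id": mp["snp_id"], "chrom": mp["chrom"],
                            "pos_bp": mp["pos_bp"], "a1": a1, "a2": a2})
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "sex", "population"])
    markers, dosage = sort_markers(markers, dosage)
    return GenotypePanel(markers=markers, samples=samples, dosage=dosage)


def _write_text(panel: GenotypePanel, prefix: Path) -> None:
    m = panel.markers
    with open(prefix.with_suffix(".map"), "w") as fh:
        for r in m.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.pos_bp}\t{r.a1}\t{r.a2}\n")
    a1 = m["a1"].to_numpy(dtype=object)
    a2 = m["a2"].to_numpy(dtype=object)
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, s in enumerate(panel.samples.itertuples(index=False)):
            d = panel.dosage[i]
            first = np.where(d >= 1, a1, a2)
            second = np.where(d == 2, a1, a2)
            first = np.where(d == MISSING, "0", first)
            second = np.where(d == MISSING, "0", second)
            geno = "\t".join(f"{x}\t{y}" for x, y in zip(first, second))
            fh.write(f"{s.population}\t{s.sample_id}\t0\t0\t{s.sex}\t-9"
                     + ("\t" + geno if panel.n_snps else "") + "\n")


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_plink(path_prefix, format: str | None = None,
               drop_non_autosomes: bool = True,
               autosome_count: int = DEFAULT_AUTOSOME_COUNT) -> GenotypePanel:
    """Read a PLINK fileset (``binary`` bed/bim/fam or ``text`` ped/map).

    The marker map is sorted by (chrom, pos_bp) — columns are permuted if the
    file is unsorted — and chromosome codes outside ``1..autosome_count`` are
    dropped (with a logged count) unless ``drop_non_autosomes=False``.
    """
    prefix = Path(path_prefix)
    if format is None:
        format = "binary" if prefix.with_suffix(".bed").exists() else "text"
    if format == "binary":
        markers = _read_bim(prefix.with_suffix(".bim"))
        samples = _read_fam(prefix.with_suffix(".fam"))
        dosage = _read_bed_matrix(prefix.with_suffix(".bed"),
                                  len(samples), len(markers))
        markers, dosage = sort_markers(markers, dosage)
        panel = GenotypePanel(markers=markers, samples=samples, dosage=dosage)
    elif format == "text":
        panel = _read_text(prefix)
    else:
        raise ValueError(f"unknown format {format!r}")
    if drop_non_autosomes:
        chrom = panel.markers["chrom"].to_numpy()
        keep = (chrom >= 1) & (chrom <= autosome_count)
        if not keep.all():
            logger.info("dropping %d non-autosomal SNPs (chrom codes outside "
                        "1..%d)", (~keep).sum(), autosome_count)
            panel = panel.subset(snp_idx=np.flatnonzero(keep))
    return panel


def write_plink(panel: GenotypePanel, path_prefix, format: str = "binary") -> None:
    """Write a panel as a PLINK fileset readable by :func:`read_plink`."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "binary":
        m = panel.markers
        with open(prefix.with_suffix(".bim"), "w") as fh:
            for r in m.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.pos_bp}\t{r.a1}\t{r.a2}\n")
        with open(prefix.with_suffix(".fam"), "w") as fh:
            for s in panel.samples.itertuples(index=False):
                fh.write(f"{s.population}\t{s.sample_id}\t0\t0\t{s.sex}\t-9\n")
        _write_bed_matrix(prefix.with_suffix(".bed"), panel.dosage)
    elif format == "text":
        _write_text(panel, prefix)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_regions_bed(regions, path) -> None:
    """Write SignatureRegions as BED (0-based half-open) with peak info."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t"
                     f"{r.source}:{r.peak_snp_id}\t{r.peak_value}\n")
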