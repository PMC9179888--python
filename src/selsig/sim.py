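"""Forward-in-time two-population diploid SNP-panel simulator.

The generator produces the study design every other module assumes: two
populations descending from a common base pool — one long-isolated with a
small effective size (accumulating runs of homozygosity and strong LD), one
recently admixed with external donor pools (diluted homozygosity, broken-up
LD) — with optional injected sweep regions of known location as ground
truth.

Model
-----
* Founder haplotypes are drawn per ancestral pool with per-SNP allele
  frequencies ~ Beta(0.8, 0.8) truncated to [0.05, 0.95] (a U-shaped,
  ascertained-array-like spectrum without monomorphic founders), sites
  independent.
* Each generation samples parent pairs (with replacement, selfing excluded)
  from the previous one; the small effective size induces autozygosity.
* Gametes recombine as a Markov process along each chromosome at 1 cM/Mb:
  between adjacent SNPs the parental haplotype switches with the Haldane
  probability (1 - exp(-2d))/2, d in Morgans, and restarts at random on
  each new chromosome.  Marginally this matches Poisson crossovers at the
  SNP loci.
* The admixture event, at a stated generation, augments the parent pool
  with enough fresh donor-pool individuals that the expected parental
  contribution of donors equals the stated proportion.
* A ``fix_haplotype`` sweep copies one pool haplotype over the interval
  into both gametes of a fraction (default 0.9) of final-generation
  individuals of the target population(s); ``differ_LD`` does the same in
  exactly one population, creating a between-population LD contrast.
* Per-genotype missingness is i.i.d. at ``missing_rate``.

Pedigree inbreeding (exact, from the kinship recursion over the simulated
pedigree) is recorded per sample as ground truth for F_ROH recovery;
everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypePanel

logger = logging.getLogger("selsig")

CM_PER_MB = 1.0  # uniform recombination map
_MORGAN_PER_BP = CM_PER_MB * 1e-8


@dataclass(frozen=True)
class AdmixtureEvent:
    """Donor gene flow: at ``generation`` (0-based, counted from the
    founders), the parent pool is opened to donor pools with the given
    expected contribution proportions (summing with the base to 1)."""

    generation: int
    donor_proportions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.donor_proportions.values())
        if not 0.0 < total < 1.0:
            raise ValueError("total donor proportion must lie in (0,1)")


@dataclass(frozen=True)
class SweepSpec:
    """An injected selective-sweep interval with known coordinates."""

    chrom: int
    start_bp: int
    end_bp: int
    populations: tuple[str, ...]
    mode: str = "fix_haplotype"           # or "differ_LD"
    carrier_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.mode not in ("fix_haplotype", "differ_LD"):
            raise ValueError(f"unknown sweep mode {self.mode!r}")
        if self.mode == "differ_LD" and len(self.populations) != 1:
            raise ValueError("differ_LD targets exactly one population")


@dataclass(frozen=True)
class PopulationHistory:
    name: str
    effective_size: int = 200
    n_samples: int = 96
    admixture: AdmixtureEvent | None = None
    full_sib_final: bool = False          # last generation from sib matings
    founder_pool_size: int | None = None  # defaults to effective_size

    def __post_init__(self) -> None:
        pool = self.founder_pool_size
        if pool is not None and self.effective_size > pool:
            raise ValueError(
                f"{self.name}: effective_size {self.effective_size} exceeds "
                f"founder pool {pool}")


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults: 26 autosomes x 1500 SNPs on 100 Mb chromosomes
    (~39K markers, 50K-array density over a ~2.6 Gb autosomal genome); an
    isolated population (Ne=200, 50 generations) vs a population receiving a
    50% two-donor admixture pulse 15 generations before sampling."""

    seed: int
    n_chrom: int = 26
    snps_per_chrom: int = 1500
    chrom_length_bp: int = 100_000_000
    generations: int = 50
    populations: tuple[PopulationHistory, ...] = (
        PopulationHistory(name="isolated", effective_size=100, n_samples=96),
        PopulationHistory(name="admixed", effective_size=400, n_samples=68,
                          admixture=AdmixtureEvent(
                              generation=35,
                              donor_proportions={"donor1": 0.25, "donor2": 0.25})),
    )
    sweeps: tuple[SweepSpec, ...] = ()
    missing_rate: float = 0.002
    founder_beta: float = 0.8
    founder_freq_bounds: tuple[float, float] = (0.05, 0.95)
    donor_fst: float = 0.10               # donor-pool differentiation from base

    def __post_init__(self) -> None:
        for s in self.sweeps:
            if not (1 <= s.chrom <= self.n_chrom
                    and 0 < s.start_bp < s.end_bp <= self.chrom_length_bp):
                raise ValueError(f"sweep {s} outside chromosome bounds")
            known = {p.name for p in self.populations}
            if not set(s.populations) <= known:
                raise ValueError(f"sweep targets unknown population {s.populations}")


@dataclass
class SimTruth:
    """Ground truth: exact pedigree inbreeding per sample, sweep interval
    coordinates, and per-pool founder allele frequencies."""

    pedigree_f: dict[str, np.ndarray]
    sweeps: tuple[SweepSpec, ...]
    founder_freqs: dict[str, np.ndarray]


# ---------------------------------------------------------------------------
# Machinery
# ---------------------------------------------------------------------------

@dataclass
class _RecombMap:
    """Per-chromosome SNP map positions for the crossover sampler:
    (first column index, cumulative Morgan position per SNP, map length)."""

    blocks: list[tuple[int, np.ndarray, float]]
    n_sites: int


def _marker_layout(cfg: SimConfig, rng: np.random.Generator):
    """Sorted random marker positions; returns (markers df, recomb map)."""
    chroms, positions = [], []
    for c in range(1, cfg.n_chrom + 1):
        pos = np.unique(rng.integers(1, cfg.chrom_length_bp + 1,
                                     size=cfg.snps_per_chrom))
        while len(pos) < cfg.snps_per_chrom:   # collisions are rare
            extra = rng.integers(1, cfg.chrom_length_bp + 1,
                                 size=cfg.snps_per_chrom - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        chroms.append(np.full(cfg.snps_per_chrom, c))
        positions.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    markers = pd.DataFrame({
        "snp_id": [f"snp{c}_{p}" for c, p in zip(chrom, pos)],
        "chrom": chrom, "pos_bp": pos,
        "a1": "A", "a2": "B"})
    blocks = []
    start = 0
    for c_pos in positions:
        map_pos = (c_pos - c_pos[0]) * _MORGAN_PER_BP
        blocks.append((start, map_pos, float(map_pos[-1])))
        start += len(c_pos)
    return markers, _RecombMap(blocks=blocks, n_sites=len(pos))


def _draw_founder_freqs(cfg: SimConfig, n_snps: int,
                        rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.founder_freq_bounds
    p = rng.beta(cfg.founder_beta, cfg.founder_beta, size=n_snps)
    return np.clip(p, lo, hi)


def _draw_donor_freqs(base: np.ndarray, fst: float, bounds,
                      rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols donor frequencies at the given FST from the base pool
    (breeds on a shared array are correlated, not independent)."""
    lo, hi = bounds
    scale = (1.0 - fst) / fst
    return np.clip(rng.beta(base * scale, (1.0 - base) * scale), lo, hi)


def _founder_haplotypes(freqs: np.ndarray, n_ind: int,
                        rng: np.random.Generator) -> np.ndarray:
    """(n_ind, 2, n_snps) int8 haplotypes; allele 1 = A1 with prob freqs."""
    return (rng.random((n_ind, 2, len(freqs))) < freqs).astype(np.int8)


def _gametes(parent_haps: np.ndarray, recomb: _RecombMap,
             rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete per parent row of (n, 2, S) haplotypes.

    Crossovers are Poisson on the genetic map (1 cM/Mb); the origin parity
    at each SNP is the cumulative crossover count, with a fresh random phase
    at each chromosome start.
    """
    n, _, s = parent_haps.shape
    switches = np.zeros((n, s), dtype=np.uint8)
    for start_col, map_pos, map_len in recomb.blocks:
        switches[:, start_col] = rng.integers(0, 2, n, dtype=np.uint8)
        if map_len <= 0:
            continue
        k = rng.poisson(map_len, n)
        total = int(k.sum())
        if total:
            gid = np.repeat(np.arange(n), k)
            col = start_col + np.searchsorted(map_pos, rng.random(total) * map_len)
            np.add.at(switches, (gid, col), 1)
    # parity survives uint8 wraparound: (x mod 256) mod 2 == x mod 2
    origin = (np.cumsum(switches, axis=1, dtype=np.uint8) & 1).astype(bool)
    return np.where(origin, parent_haps[:, 1, :], parent_haps[:, 0, :])


def _pick_parents(n_parents: int, n_off: int, rng: np.random.Generator):
    mothers = rng.integers(0, n_parents, n_off)
    fathers = rng.integers(0, n_parents, n_off)
    clash = mothers == fathers
    while clash.any():                    # no selfing
        fathers[clash] = rng.integers(0, n_parents, clash.sum())
        clash = mothers == fathers
    return mothers, fathers


def _next_kinship(k_prev: np.ndarray, mothers: np.ndarray,
                  fathers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Kinship matrix of the offspring + their inbreeding coefficients."""
    f_off = k_prev[mothers, fathers]
    k = 0.25 * (k_prev[np.ix_(mothers, mothers)]
                + k_prev[np.ix_(mothers, fathers)]
                + k_prev[np.ix_(fathers, mothers)]
                + k_prev[np.ix_(fathers, fathers)])
    np.fill_diagonal(k, 0.5 * (1.0 + f_off))
    return k, f_off


def _simulate_population(hist: PopulationHistory, cfg: SimConfig,
                         base_freqs: np.ndarray, donor_freqs: dict,
                         recomb: _RecombMap, rng: np.random.Generator):
    """Run one population history; returns (haplotypes, pedigree F)."""
    ne = hist.effective_size
    haps = _founder_haplotypes(base_freqs, ne, rng)
    kin = np.zeros((ne, ne))
    np.fill_diagonal(kin, 0.5)
    f_cur = np.zeros(ne)

    for g in range(1, cfg.generations + 1):
        if hist.admixture is not None and g == hist.admixture.generation:
            total_donor = sum(hist.admixture.donor_proportions.values())
            n_prev = haps.shape[0]
            extra_haps, n_extra = [], 0
            for pool, prop in hist.admixture.donor_proportions.items():
                # expected parental share prop => n_d/(n_prev+n_total_extra)
                n_d = int(round(n_prev * prop / (1.0 - total_donor)))
                extra_haps.append(_founder_haplotypes(donor_freqs[pool], n_d, rng))
                n_extra += n_d
            haps = np.concatenate([haps] + extra_haps, axis=0)
            grown = np.zeros((n_prev + n_extra, n_prev + n_extra))
            grown[:n_prev, :n_prev] = kin
            np.fill_diagonal(grown[n_prev:, n_prev:], 0.5)
            kin = grown
            logger.info("%s: admixture pulse at generation %d (+%d donors)",
                        hist.name, g, n_extra)

        last = g == cfg.generations
        if last and hist.full_sib_final:
            # penultimate generation re-drawn as sib pairs, offspring from
            # within-pair matings: pedigree F is exactly the sib kinship
            n_pairs = (hist.n_samples + 1) // 2
            pm, pf = _pick_parents(haps.shape[0], n_pairs, rng)
            pm2 = np.repeat(pm, 2)        # each couple -> 2 full sibs
            pf2 = np.repeat(pf, 2)
            sib_haps = np.stack([_gametes(haps[pm2], recomb, rng),
                                 _gametes(haps[pf2], recomb, rng)], axis=1)
            sib_kin, sib_f = _next_kinship(kin, pm2, pf2)
            mothers = np.arange(n_pairs) * 2
            fathers = mothers + 1
            mothers = np.repeat(mothers, 2)[:hist.n_samples]
            fathers = np.repeat(fathers, 2)[:hist.n_samples]
            haps, kin = sib_haps, sib_kin
        else:
            n_off = hist.n_samples if last else ne
            mothers, fathers = _pick_parents(haps.shape[0], n_off, rng)
        off = np.stack([_gametes(haps[mothers], recomb, rng),
                        _gametes(haps[fathers], recomb, rng)], axis=1)
        kin, f_cur = _next_kinship(kin, mothers, fathers)
        haps = off
    return haps, f_cur


def _apply_sweeps(haps_by_pop: dict, cfg: SimConfig, markers: pd.DataFrame,
                  base_freqs: np.ndarray, rng: np.random.Generator) -> None:
    chrom = markers["chrom"].to_numpy()
    pos = markers["pos_bp"].to_numpy()
    for sweep in cfg.sweeps:
        in_iv = (chrom == sweep.chrom) & (pos >= sweep.start_bp) \
            & (pos <= sweep.end_bp)
        idx = np.flatnonzero(in_iv)
        sweep_hap = (rng.random(idx.size) < base_freqs[idx]).astype(np.int8)
        for pop in sweep.populations:
            haps = haps_by_pop[pop]
            n = haps.shape[0]
            # per-gamete replacement at the stated haplotype frequency: the
            # hard-sweep endpoint keeps genotypes in Hardy-Weinberg
            # proportions (both-gamete copying would plant a het deficit
            # that the HWE QC filter removes, hiding the sweep downstream)
            for gamete in (0, 1):
                carriers = rng.random(n) < sweep.carrier_fraction
                haps[np.ix_(np.flatnonzero(carriers), [gamete], idx)] = \
                    sweep_hap[None, None, :]


def _to_panel(haps: np.ndarray, markers: pd.DataFrame, name: str,
              missing_rate: float, rng: np.random.Generator) -> GenotypePanel:
    dosage = haps.sum(axis=1).astype(np.int8)
    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = MISSING
    n = haps.shape[0]
    samples = pd.DataFrame({
        "sample_id": [f"{name}_{i:04d}" for i in range(n)],
        "sex": rng.integers(1, 3, n),
        "population": name,
    })
    return GenotypePanel(markers=markers.copy(), samples=samples, dosage=dosage)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def simulate_panels(config: SimConfig
                    ) -> tuple[list[GenotypePanel], SimTruth]:
    """Simulate every configured population; deterministic given the seed.

    Returns the panels (in config order) and the ground truth.  For the
    default two-population config the first panel is the isolated population
    and the second the admixed one.
    """
    rng = np.random.default_rng(config.seed)
    markers, recomb = _marker_layout(config, rng)
    n_snps = len(markers)
    base_freqs = _draw_founder_freqs(config, n_snps, rng)
    donor_pools: dict[str, np.ndarray] = {}
    for hist in config.populations:
        if hist.admixture:
            for pool in hist.admixture.donor_proportions:
                if pool not in donor_pools:
                    donor_pools[pool] = _draw_donor_freqs(
                        base_freqs, config.donor_fst,
                        config.founder_freq_bounds, rng)

    haps_by_pop, f_by_pop = {}, {}
    for hist in config.populations:
        pop_rng = np.random.default_rng(rng.integers(0, 2**31))
        haps, f = _simulate_population(hist, config, base_freqs, donor_pools,
                                       recomb, pop_rng)
        haps_by_pop[hist.name] = haps
        f_by_pop[hist.name] = f
    _apply_sweeps(haps_by_pop, config, markers, base_freqs, rng)

    panels = [_to_panel(haps_by_pop[h.name], markers, h.name,
                        config.missing_rate, rng)
              for h in config.populations]
    truth = SimTruth(pedigree_f=f_by_pop, sweeps=config.sweeps,
                     founder_freqs={"base": base_freqs, **donor_pools})
    return panels, truth


def full_sib_config(n_offspring: int = 200, seed: int = 0,
                    n_chrom: int = 26, snps_per_chrom: int = 1500,
                    chrom_length_bp: int = 100_000_000) -> SimConfig:
    """Parameter-recovery design: unrelated founders, one generation of sib
    pairs, offspring of full-sib matings (pedigree F exactly 0.25)."""
    # generations=1: sib pairs are bred directly from unrelated founders, so
    # the offspring's pedigree F is the sib kinship 1/4 with no drift term
    return SimConfig(
        seed=seed, n_chrom=n_chrom, snps_per_chrom=snps_per_chrom,
        chrom_length_bp=chrom_length_bp, generations=1,
        populations=(PopulationHistory(
            name="fullsib", effective_size=2 * n_offspring,
            n_samples=n_offspring, full_sib_final=True),),
        missing_rate=0.002)


# ---------------------------------------------------------------------------
# Unit-test fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, seed: int = 0):
    """Small deterministic panels with hand-checkable expected outputs.

    Returns ``(panel(s), expected)`` per kind:

    * ``roh_toy`` — one 5 Mb chromosome, sample 0 fully homozygous (one
      expected run), the others run-free; expected = the ROH table.
    * ``qc_toy`` — planted violations: sample ``s3`` 15% missing, SNP ``m7``
      monomorphic (MAF 0 < 1%); expected = removal table.
    * ``varld_toy`` — two identical panels; expected raw scores all zero.
    * ``decay_toy`` — hand-built dosage columns with known pairwise r².
    """
    rng = np.random.default_rng(seed)
    if kind == "roh_toy":
        n_snps = 25
        pos = np.linspace(100_000, 5_000_000, n_snps).astype(int)
        markers = pd.DataFrame({"snp_id": [f"t{i}" for i in range(n_snps)],
                                "chrom": 1, "pos_bp": pos,
                                "a1": "A", "a2": "B"})
        dosage = np.ones((3, n_snps), dtype=np.int8)       # all het: no runs
        dosage[0] = 2                                      # fully homozygous
        samples = pd.DataFrame({"sample_id": ["h0", "h1", "h2"],
                                "sex": 1, "population": "toy"})
        panel = GenotypePanel(markers=markers, samples=samples, dosage=dosage)
        expected = pd.DataFrame([{
            "sample_id": "h0", "chrom": 1, "start_bp": int(pos[0]),
            "end_bp": int(pos[-1]), "n_snps": n_snps}])
        return panel, expected
    if kind == "qc_toy":
        n_samples, n_snps = 10, 20
        freqs = np.full(n_snps, 0.5)
        dosage = (rng.random((n_samples, n_snps)) < freqs).astype(np.int8) \
            + (rng.random((n_samples, n_snps)) < freqs).astype(np.int8)
        dosage[:, 7] = 2                                   # m7 monomorphic
        dosage[3, :3] = MISSING                            # s3: 3/20 missing
        markers = pd.DataFrame({"snp_id": [f"m{j}" for j in range(n_snps)],
                                "chrom": 1,
                                "pos_bp": np.arange(1, n_snps + 1) * 100_000,
                                "a1": "A", "a2": "B"})
        samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n_samples)],
                                "sex": 1, "population": "toy"})
        panel = GenotypePanel(markers=markers, samples=samples, dosage=dosage)
        expected = pd.DataFrame({"axis": ["sample", "snp"],
                                 "id": ["s3", "m7"],
                                 "reason": ["missingness", "maf"]})
        return panel, expected
    if kind == "varld_toy":
        n_samples, n_snps = 20, 120
        pos = np.arange(1, n_snps + 1) * 50_000
        markers = pd.DataFrame({"snp_id": [f"v{j}" for j in range(n_snps)],
                                "chrom": np.repeat([1, 2], n_snps // 2),
                                "pos_bp": np.concatenate([pos[:n_snps // 2]] * 2),
                                "a1": "A", "a2": "B"})
        dosage = rng.integers(0, 3, (n_samples, n_snps)).astype(np.int8)
        samples_a = pd.DataFrame({"sample_id": [f"a{i}" for i in range(n_samples)],
                                  "sex": 1, "population": "A"})
        samples_b = samples_a.assign(population="B")
        pa = GenotypePanel(markers=markers, samples=samples_a, dosage=dosage)
        pb = GenotypePanel(markers=markers.copy(), samples=samples_b,
                           dosage=dosage.copy())
        return (pa, pb), 0.0
    if kind == "decay_toy":
        base = rng.integers(0, 3, (12, 1)).astype(np.int8)
        flipped = (2 - base).astype(np.int8)               # r = -1, r2 = 1
        random_col = rng.integers(0, 3, (12, 1)).astype(np.int8)
        dosage = np.hstack([base, base, flipped, random_col])
        markers = pd.DataFrame({"snp_id": ["d0", "d1", "d2", "d3"],
                                "chrom": 1,
                                "pos_bp": [100_000, 200_000, 400_000, 800_000],
                                "a1": "A", "a2": "B"})
        samples = pd.DataFrame({"sample_id": [f"d{i}" for i in range(12)],
                                "sex": 1, "population": "toy"})
        panel = GenotypePanel(markers=markers, samples=samples, dosage=dosage)
        expected = {("d0", "d1"): 1.0, ("d0", "d2"): 1.0, ("d1", "d2"): 1.0}
        return panel, expected
    raise ValueError(f"unknown fixture kind {kind!r}")
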