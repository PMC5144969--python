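"""Nuclear-family cohort simulator with fully known crossover truth.

The generator emulates the statistical structure the downstream analysis
assumes: two-generation families with two or more children, sex-specific
Poisson crossover counts (female rate ~1.5x male), partial historical-hotspot
usage (a crossover lands inside a hotspot interval with probability ``h``),
genotyping error that creates spurious tight double-recombinants, and an
optional trans-acting QTL whose parental minor-allele dosage additively shifts
either the parent's expected crossover count or their hotspot usage.

Parents' haplotypes are drawn marker-wise from per-marker allele frequencies
(linkage equilibrium); each child receives one recombined gamete per parent.
Crossover counts are Poisson (no interference, no obligate chiasma).  All
randomness flows from a single numpy Generator seeded from the config, so a
given config reproduces a byte-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (MISSING, Family, GenotypeTable, IntervalTrack, MarkerMap,
                         Pedigree, SEX_FEMALE, SEX_MALE)

MOTIF_WIDTH_BP = 13  # degenerate 13-mer associated with hotspot activity


@dataclass(frozen=True)
class QtlConfig:
    """Trans-acting QTL on the parent's own recombination phenotype.

    ``beta_count`` shifts the parent's expected genome-wide crossover count per
    minor-allele dosage (spread evenly over chromosomes); ``beta_usage`` shifts
    the hotspot-usage probability h per dosage (clipped to [0, 1]).
    ``beta_count_male``, when set, replaces ``beta_count`` in fathers —
    sex-antagonistic count effects of the kind reported for RNF212.  ``maf``
    fixes the causal marker's allele frequency so the minor-allele orientation
    is stable across simulated cohorts.
    """

    marker_index: int = 0  # global marker index (map order)
    beta_count: float = 0.0
    beta_usage: float = 0.0
    beta_count_male: float | None = None
    maf: float = 0.3


@dataclass(frozen=True)
class SimConfig:
    n_families: int = 200
    children_per_family: int | dict[int, float] = 2
    n_chromosomes: int = 1
    chrom_length_bp: int = 100_000_000
    n_markers_per_chrom: int = 1000
    maf_range: tuple[float, float] = (0.25, 0.5)
    # expected crossovers per meiosis per chromosome; defaults emulate the
    # observed per-autosome averages (female:male ratio ~1.5)
    lambda_male: float = 1.2
    lambda_female: float = 1.8
    hotspot_usage_male: float = 0.4
    hotspot_usage_female: float = 0.4
    n_hotspots: int = 200           # per chromosome
    hotspot_width_bp: int = 2000
    motif_per_hotspot_prob: float = 0.5
    motif_background_per_mb: float = 1.0
    genotype_error_rate: float = 0.0
    qtl: QtlConfig | None = None
    cohort: str = "sim"
    seed: int = 0

    def __post_init__(self):
        for name in ("hotspot_usage_male", "hotspot_usage_female",
                     "motif_per_hotspot_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} not in [0, 1]")
        if not 0.0 <= self.genotype_error_rate < 1.0:
            raise ValueError("genotype_error_rate must be in [0, 1)")
        if min(self.lambda_male, self.lambda_female) < 0:
            raise ValueError("lambda must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_markers_per_chrom < 2:
            raise ValueError("need at least 2 markers per chromosome for the switch scan")


@dataclass
class SimulatedCohort:
    pedigree: Pedigree
    marker_map: MarkerMap
    genotypes: GenotypeTable
    hotspots: IntervalTrack
    motifs: IntervalTrack
    truth: pd.DataFrame  # parent, child, chrom, pos (1-based bp), in_hotspot
    config: SimConfig
    allele_freqs: np.ndarray = field(default=None, repr=False)
    # populated only when simulate_cohort(..., keep_gametes=True):
    # parent_haplotypes[pid] -> (2, M) array; gametes[(pid, child, chrom)] ->
    # (start_phase, gamete haplotype over that chromosome's markers)
    parent_haplotypes: dict = field(default=None, repr=False)
    gametes: dict = field(default=None, repr=False)

    def __iter__(self):  # tuple-unpacking convenience
        return iter((self.pedigree, self.marker_map, self.genotypes,
                     self.hotspots, self.motifs, self.truth))


# ---------------------------------------------------------------------------
# crossover placement and meiosis
# ---------------------------------------------------------------------------

def place_crossovers(k: int, h: float, hotspots: np.ndarray, chrom_length: int,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw k distinct crossover positions (1-based bp) on one chromosome.

    Each position independently lands inside a hotspot with probability ``h``
    (hotspot chosen with probability proportional to its length, position
    uniform within), otherwise uniform over non-hotspot sequence.  Duplicate
    positions are rejected and redrawn.  Returns (sorted positions, in-hotspot
    flags aligned to them).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    hotspots = np.asarray(hotspots, dtype=np.int64).reshape(-1, 2)
    if h > 0 and len(hotspots) == 0:
        raise ValueError("hotspot usage > 0 requires a non-empty hotspot track")
    if k == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    lengths = hotspots[:, 1] - hotspots[:, 0] if len(hotspots) else np.empty(0)
    weights = lengths / lengths.sum() if len(hotspots) else None
    taken: set[int] = set()
    pos, flag = [], []
    while len(pos) < k:
        in_hs = bool(rng.random() < h)
        if in_hs:
            i = rng.choice(len(hotspots), p=weights)
            s, e = hotspots[i]
            p = int(s) + 1 + int(rng.integers(e - s))  # 1-based within [s+1, e]
        else:
            p = 1 + int(rng.integers(chrom_length))
            # redraw if it fell in a hotspot (coverage is tiny)
            if len(hotspots):
                j = np.searchsorted(hotspots[:, 0], p, side="left")
                if j > 0 and hotspots[j - 1, 1] >= p:
                    continue
        if p in taken:
            continue
        taken.add(p)
        pos.append(p)
        flag.append(in_hs)
    order = np.argsort(pos)
    return np.asarray(pos, dtype=np.int64)[order], np.asarray(flag)[order]


def simulate_meiosis(hap_a: np.ndarray, hap_b: np.ndarray, marker_bp: np.ndarray,
                     lam: float, h: float, hotspots: np.ndarray, chrom_length: int,
                     rng: np.random.Generator):
    """One meiosis on one chromosome: Poisson(lam) crossovers, fair start phase.

    Returns (gamete haplotype, crossover positions, in-hotspot flags, start
    phase).  A crossover at position x separates markers with bp <= x from
    markers with bp > x; the start phase says which haplotype the gamete copies
    before the first crossover.
    """
    k = int(rng.poisson(lam))
    pos, flags = place_crossovers(k, h, hotspots, chrom_length, rng)
    start = int(rng.integers(2))
    gamete = gamete_from_truth(hap_a, hap_b, marker_bp, pos, start)
    return gamete, pos, flags, start


def gamete_from_truth(hap_a: np.ndarray, hap_b: np.ndarray, marker_bp: np.ndarray,
                      positions: np.ndarray, start: int) -> np.ndarray:
    """Reconstruct a gamete from parental haplotypes + listed crossovers (oracle)."""
    parity = (np.searchsorted(positions, marker_bp, side="left") + start) % 2
    return np.where(parity == 0, hap_a, hap_b).astype(np.int8)


def apply_genotype_error(genos: GenotypeTable, epsilon: float,
                         rng: np.random.Generator) -> GenotypeTable:
    """Flip each non-missing dosage with probability epsilon to one of the other
    two values (uniformly).  The input table is not modified."""
    if not 0.0 <= epsilon < 1.0:
        raise ValueError("epsilon must be in [0, 1)")
    values = genos.values.copy()
    if epsilon > 0:
        hit = (values != MISSING) & (rng.random(values.shape) < epsilon)
        shift = rng.integers(1, 3, size=values.shape, dtype=np.int8)
        values[hit] = (values[hit] + shift[hit]) % 3
    return GenotypeTable(list(genos.individuals), genos.marker_ids, values)


# ---------------------------------------------------------------------------
# tracks and maps
# ---------------------------------------------------------------------------

def _simulate_tracks(config: SimConfig, rng: np.random.Generator):
    """Non-overlapping hotspot intervals per chromosome + motif occurrences.

    Hotspot starts use the classic spacing trick (sorted uniforms on the
    length shrunk by n*w, shifted by i*w) so placement is uniform among
    non-overlapping configurations.  Motifs: one 13-bp interval inside a
    random fraction of hotspots, plus a uniform background.
    """
    L, w, n = config.chrom_length_bp, config.hotspot_width_bp, config.n_hotspots
    if n * w >= L:
        raise ValueError("hotspots do not fit on the chromosome")
    hs, mot = {}, {}
    for c in range(1, config.n_chromosomes + 1):
        base = np.sort(rng.integers(0, L - n * w, size=n))
        starts = base + np.arange(n) * w
        iv = np.stack([starts, starts + w], axis=1)
        hs[str(c)] = iv
        motifs = []
        for s, e in iv:
            if rng.random() < config.motif_per_hotspot_prob:
                ms = int(s + rng.integers(e - s - MOTIF_WIDTH_BP))
                motifs.append((ms, ms + MOTIF_WIDTH_BP))
        n_bg = int(rng.poisson(config.motif_background_per_mb * L / 1e6))
        for ms in rng.integers(0, L - MOTIF_WIDTH_BP, size=n_bg):
            motifs.append((int(ms), int(ms) + MOTIF_WIDTH_BP))
        mot[str(c)] = np.asarray(motifs, dtype=np.int64) if motifs \
            else np.empty((0, 2), dtype=np.int64)
    return IntervalTrack("hotspot", hs), IntervalTrack("motif", mot)


def _simulate_map(config: SimConfig, rng: np.random.Generator):
    rows = []
    L, n = config.chrom_length_bp, config.n_markers_per_chrom
    if n > L:
        raise ValueError("more markers than basepairs")
    for c in range(1, config.n_chromosomes + 1):
        bp = np.unique(rng.integers(1, L + 1, size=n))
        while bp.size < n:  # top up duplicates (rare for n << L)
            bp = np.unique(np.concatenate([bp, rng.integers(1, L + 1, size=n - bp.size + 8)]))
        if bp.size > n:
            bp = np.sort(rng.choice(bp, size=n, replace=False))
        for i, p in enumerate(bp):
            rows.append((str(c), f"c{c}m{i:05d}", 0.0, int(p), "A", "B"))
    df = pd.DataFrame(rows, columns=["chrom", "id", "cm", "bp", "a1", "a2"])
    mmap = MarkerMap(df)
    freqs = rng.uniform(*config.maf_range, size=len(mmap))
    if config.qtl is not None:
        if not 0 <= config.qtl.marker_index < len(mmap):
            raise ValueError("QTL marker index outside the map")
        freqs[config.qtl.marker_index] = config.qtl.maf
    return mmap, freqs


def _draw_children_counts(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    spec = config.children_per_family
    if isinstance(spec, int):
        if spec < 2:
            raise ValueError("families need >= 2 children")
        return np.full(config.n_families, spec, dtype=int)
    ks = np.asarray(sorted(spec), dtype=int)
    if ks.min() < 2:
        raise ValueError("families need >= 2 children")
    probs = np.asarray([spec[int(k)] for k in ks], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(ks, size=config.n_families, p=probs)


# ---------------------------------------------------------------------------
# whole-cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig,
                    marker_map: MarkerMap | None = None,
                    allele_freqs: np.ndarray | None = None,
                    hotspots: IntervalTrack | None = None,
                    motifs: IntervalTrack | None = None,
                    keep_gametes: bool = False) -> SimulatedCohort:
    """Generate a full cohort (pedigree, map, genotypes, tracks, truth table).

    Pass ``marker_map``/``allele_freqs``/``hotspots``/``motifs`` from a
    previous cohort to simulate a second cohort on the identical marker panel
    (multi-study meta-analysis designs).
    """
    rng = np.random.default_rng(config.seed)
    if marker_map is None:
        marker_map, allele_freqs = _simulate_map(config, rng)
    if hotspots is None:
        hotspots, motifs = _simulate_tracks(config, rng)
    M = len(marker_map)
    chrom_slices = {c: marker_map.chrom_slice(c) for c in marker_map.chromosomes}
    chrom_bp = {c: marker_map.bp(c) for c in marker_map.chromosomes}
    n_children = _draw_children_counts(config, rng)
    C = config.n_chromosomes

    qtl = config.qtl
    families, sex = [], {}
    ind_ids, hap_rows = [], []
    truth_rows = []
    kept_haps = {} if keep_gametes else None
    kept_gametes = {} if keep_gametes else None

    for f in range(config.n_families):
        fid = f"F{f:04d}"
        father, mother = f"{fid}_P1", f"{fid}_P2"
        sex[father], sex[mother] = SEX_MALE, SEX_FEMALE
        kids = [f"{fid}_C{j + 1}" for j in range(n_children[f])]
        for k_id in kids:
            sex[k_id] = SEX_MALE if rng.random() < 0.5 else SEX_FEMALE
        families.append(Family(fid, father, mother, kids))

        par_haps, lam_h = {}, {}
        for pid, lam_sex, h_sex in ((father, config.lambda_male, config.hotspot_usage_male),
                                    (mother, config.lambda_female, config.hotspot_usage_female)):
            haps = (rng.random((2, M)) < allele_freqs).astype(np.int8)
            par_haps[pid] = haps
            ind_ids.append(pid)
            hap_rows.append(haps.sum(axis=0))
            # trans-acting QTL: the parent's own dosage shifts lambda and/or h
            lam_c, h_c = lam_sex, h_sex
            if qtl is not None:
                d = int(haps[:, qtl.marker_index].sum())
                bc = qtl.beta_count
                if pid == father and qtl.beta_count_male is not None:
                    bc = qtl.beta_count_male
                lam_c = max(lam_sex + bc * d / C, 0.0)
                h_c = float(np.clip(h_sex + qtl.beta_usage * d, 0.0, 1.0))
            lam_h[pid] = (lam_c, h_c)
            if keep_gametes:
                kept_haps[pid] = haps.copy()

        for k_id in kids:
            child_dose = np.zeros(M, dtype=np.int8)
            for pid in (father, mother):
                lam_c, h_c = lam_h[pid]
                for chrom in marker_map.chromosomes:
                    sl = chrom_slices[chrom]
                    haps = par_haps[pid][:, sl]
                    gamete, pos, flags, start = simulate_meiosis(
                        haps[0], haps[1], chrom_bp[chrom], lam_c, h_c,
                        hotspots.chrom(chrom), config.chrom_length_bp, rng)
                    child_dose[sl] += gamete
                    for p, fl in zip(pos, flags):
                        truth_rows.append((pid, k_id, chrom, int(p), bool(fl)))
                    if keep_gametes:
                        kept_gametes[(pid, k_id, chrom)] = (start, gamete.copy())
            ind_ids.append(k_id)
            hap_rows.append(child_dose)

    values = np.asarray(hap_rows, dtype=np.int8)

    # canonical minor-allele orientation from founders; at an exact tie the
    # lexicographically smaller symbol ('A' here) is minor, as on file re-read
    founder_rows = np.asarray([i for i, iid in enumerate(ind_ids)
                               if iid.endswith(("_P1", "_P2"))], dtype=int)
    ffreq = values[founder_rows].mean(axis=0) / 2.0
    flip = ffreq >= 0.5
    values[:, flip] = 2 - values[:, flip]
    mdf = marker_map.df.copy()
    a1, a2 = mdf["a1"].to_numpy().copy(), mdf["a2"].to_numpy().copy()
    a1[flip], a2[flip] = mdf["a2"].to_numpy()[flip], mdf["a1"].to_numpy()[flip]
    mdf["a1"], mdf["a2"] = a1, a2
    marker_map = MarkerMap(mdf)

    pedigree = Pedigree(families, sex)
    genotypes = GenotypeTable(ind_ids, marker_map.ids, values)
    if config.genotype_error_rate > 0:
        genotypes = apply_genotype_error(genotypes, config.genotype_error_rate, rng)
    truth = pd.DataFrame(truth_rows,
                         columns=["parent", "child", "chrom", "pos", "in_hotspot"])
    return SimulatedCohort(pedigree, marker_map, genotypes, hotspots, motifs,
                           truth, config, np.where(flip, 1 - allele_freqs, allele_freqs),
                           kept_haps, kept_gametes)


def paired_cohorts(config: SimConfig, seed_b: int | None = None,
                   cohort_a: str = "GDCS", cohort_b: str = "AGRE"):
    """Two cohorts on one shared marker panel (for cross-study meta-analysis)."""
    ca = simulate_cohort(replace(config, cohort=cohort_a))
    cb_cfg = replace(config, cohort=cohort_b,
                     seed=config.seed + 1 if seed_b is None else seed_b)
    cb = simulate_cohort(cb_cfg, marker_map=ca.marker_map,
                         allele_freqs=ca.allele_freqs,
                         hotspots=ca.hotspots, motifs=ca.motifs)
    return ca, cb
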