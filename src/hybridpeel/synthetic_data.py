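"""Synthetic pedigreed populations with marker panels and low-coverage reads.

Emulates the data a livestock breeding nucleus produces: a multi-generation
pedigree under truncation-style parent selection, phased genotypes dropped
through the pedigree with recombination, nested HD/LD marker arrays, and
sequence read counts from a Poisson-gamma model (per-site sequenceability
times per-individual nominal coverage).

Founder haplotypes are drawn site-independently from Hardy-Weinberg at
Beta-distributed allele frequencies; there is no ancestral linkage
disequilibrium.  Pedigree-based imputation exploits linkage within the
recorded pedigree, not population LD, so this keeps the desk-scale study
conditions faithful while staying cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import UNKNOWN, GeneticMap, GenotypeMatrix, PanelSet, Pedigree, ReadCounts, RunConfig

#: segregation states, first letter = origin of the paternal gamete within
#: the sire (p = sire's paternal haplotype), second likewise for the dam
SEG_STATES = ("pp", "pm", "mp", "mm")


@dataclass
class SimParams:
    """Simulation knobs; see :class:`~hybridpeel.core.RunConfig` for units."""

    n_founders: int = 100
    n_generations: int = 5
    litter_mean: float = 6.0
    sire_fraction: float = 0.05
    dam_fraction: float = 0.5
    population_size: int | None = 2000
    founder_beta: tuple[float, float] = (0.3, 0.3)
    gamma_shape: float = 4.0
    seq_error: float = 0.001
    status_early: tuple[float, float, float] = (0.4, 0.0, 0.6)
    status_late: tuple[float, float, float] = (0.02, 0.68, 0.30)
    early_generations: int = 1

    def __post_init__(self):
        if self.n_founders <= 0 or self.n_generations < 0:
            raise ValueError("counts must be positive")
        if not (0 < self.seq_error <= 0.1):
            raise ValueError("sequencing error must be in (0, 0.1]")

    @classmethod
    def from_config(cls, cfg: RunConfig) -> "SimParams":
        return cls(
            n_founders=cfg.n_founders,
            n_generations=cfg.n_generations,
            litter_mean=cfg.litter_mean,
            sire_fraction=cfg.sire_fraction,
            dam_fraction=cfg.dam_fraction,
            population_size=cfg.population_size,
            founder_beta=cfg.founder_beta,
            gamma_shape=cfg.gamma_shape,
            seq_error=cfg.seq_error,
            status_early=cfg.status_early,
            status_late=cfg.status_late,
            early_generations=cfg.early_generations,
        )


@dataclass
class TrueHaplotypes:
    """Phased truth: paternal/maternal alleles and true segregation states.

    ``seg`` holds, for each non-founder and variant, the index into
    :data:`SEG_STATES` of the grandparental origins actually simulated;
    founder rows are zero-filled and meaningless.
    """

    pat: np.ndarray  # int8, individuals x variants
    mat: np.ndarray
    seg: np.ndarray  # int8, individuals x variants
    founder_freqs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def genotypes(self) -> np.ndarray:
        return (self.pat + self.mat).astype(np.int8)

    def allele_freqs(self) -> np.ndarray:
        """Realized alt-allele frequency per variant over all individuals."""
        return (self.pat.mean(axis=0) + self.mat.mean(axis=0)) / 2.0


# ---------------------------------------------------------------------------
# Pedigree generation
# ---------------------------------------------------------------------------

def generate_pedigree(params: SimParams, rng) -> Pedigree:
    """Discrete-generation pedigree under random truncation of parents.

    Generation 0 founders are split evenly by sex.  In each later
    generation a fraction of the previous generation's males and females is
    selected (at random; the analyses only need the shape of the pedigree,
    not a trait under selection) and litters of Poisson size, truncated at
    one, are produced until either the per-generation target or the total
    ``population_size`` cap is reached.
    """
    rng = np.random.default_rng(rng)
    nf = params.n_founders
    sex = np.empty(0, dtype=np.int8)
    sire: list[int] = [UNKNOWN] * nf
    dam: list[int] = [UNKNOWN] * nf
    gen: list[int] = [0] * nf
    sex = list(np.where(np.arange(nf) % 2 == 0, 1, 2).astype(np.int8))
    prev = list(range(nf))
    total_target = params.population_size
    per_gen = None
    if total_target is not None and params.n_generations > 0:
        per_gen = max(1, (total_target - nf) // params.n_generations)
    for g in range(1, params.n_generations + 1):
        males = [i for i in prev if sex[i] == 1]
        females = [i for i in prev if sex[i] == 2]
        n_sires = max(1, int(round(params.sire_fraction * len(males))))
        n_dams = max(1, int(round(params.dam_fraction * len(females))))
        if not males or not females:
            raise ValueError("no selected parents of one sex")
        sires = rng.choice(males, size=min(n_sires, len(males)), replace=False)
        dams = rng.choice(females, size=min(n_dams, len(females)), replace=False)
        cur: list[int] = []
        target = per_gen if per_gen is not None else None
        di = 0
        while True:
            d = dams[di % len(dams)]
            di += 1
            s = sires[rng.integers(len(sires))]
            litter = max(1, int(rng.poisson(params.litter_mean)))
            for _ in range(litter):
                idx = len(sire)
                sire.append(int(s))
                dam.append(int(d))
                gen.append(g)
                sex.append(int(rng.integers(1, 3)))
                cur.append(idx)
                if target is not None and len(cur) >= target:
                    break
            if target is None and di >= len(dams):
                break
            if target is not None and len(cur) >= target:
                break
        prev = cur
    ids = [f"G{g}_{k}" for k, g in enumerate(gen)]
    return Pedigree(ids, np.array(sire), np.array(dam), sex=np.array(sex, np.int8),
                    generation=np.array(gen))


# ---------------------------------------------------------------------------
# Genetic map and gene dropping
# ---------------------------------------------------------------------------

def uniform_map(n_chromosomes: int, length_cm: float, variants_per_chromosome: int) -> GeneticMap:
    """Evenly spaced variants on equal-length chromosomes."""
    chroms, pos, vids = [], [], []
    for c in range(1, n_chromosomes + 1):
        p = (np.arange(variants_per_chromosome) + 0.5) / variants_per_chromosome * length_cm
        chroms.extend([str(c)] * variants_per_chromosome)
        pos.extend(p)
        vids.extend(f"c{c}_v{k + 1}" for k in range(variants_per_chromosome))
    return GeneticMap(np.array(chroms), np.array(pos), vids)


def draw_founder_freqs(params: SimParams, n_variants: int, n_individuals: int, rng) -> np.ndarray:
    """Beta(a, b) alt-allele frequencies truncated away from fixation.

    Truncation bounds are 0.5/(2N) and 1 - 0.5/(2N) so that a variant is
    expected to segregate in the founders.
    """
    rng = np.random.default_rng(rng)
    a, b = params.founder_beta
    lo = 0.5 / (2 * n_individuals)
    p = rng.beta(a, b, size=n_variants)
    return np.clip(p, lo, 1 - lo)


def _walk_indicators(rng, n_walks: int, r: np.ndarray) -> np.ndarray:
    """Random origin walks along a chromosome: start uniform, switch w.p. r."""
    L = len(r) + 1
    start = rng.integers(0, 2, size=(n_walks, 1))
    switches = rng.random((n_walks, L - 1)) < r[None, :]
    return (start + np.concatenate(
        [np.zeros((n_walks, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1
    )) % 2


def drop_genotypes(ped: Pedigree, gmap: GeneticMap, params: SimParams, rng) -> TrueHaplotypes:
    """Gene-drop phased haplotypes through the pedigree.

    Founders are Hardy-Weinberg at drawn frequencies; each gamete is formed
    by a crossover process with no interference (origin switches between
    adjacent variants with the Haldane recombination fraction, equivalent
    to one expected crossover per Morgan).
    """
    rng = np.random.default_rng(rng)
    n, L = ped.n, gmap.n_variants
    freqs = draw_founder_freqs(params, L, n, rng)
    pat = np.zeros((n, L), dtype=np.int8)
    mat = np.zeros((n, L), dtype=np.int8)
    seg = np.zeros((n, L), dtype=np.int8)
    fmask = ped.founders
    nf = int(fmask.sum())
    pat[fmask] = rng.random((nf, L)) < freqs
    mat[fmask] = rng.random((nf, L)) < freqs
    nonf = np.flatnonzero(~fmask)
    if np.any((ped.sire[nonf] == UNKNOWN) | (ped.dam[nonf] == UNKNOWN)):
        raise ValueError("gene dropping requires both parents known for non-founders")
    chrom_idx = [gmap.chrom_slice(c) for c in gmap.chromosomes]
    rs = [gmap.recomb_fractions(ix) for ix in chrom_idx]
    # process in pedigree order so parents are filled before progeny; group by
    # generation implicitly via the sorted order
    for ix, r in zip(chrom_idx, rs):
        ip = _walk_indicators(rng, len(nonf), r)  # paternal gamete origin in sire
        im = _walk_indicators(rng, len(nonf), r)
        for k, i in enumerate(nonf):
            s, d = ped.sire[i], ped.dam[i]
            pat[i, ix] = np.where(ip[k] == 0, pat[s, ix], mat[s, ix])
            mat[i, ix] = np.where(im[k] == 0, pat[d, ix], mat[d, ix])
            seg[i, ix] = 2 * ip[k] + im[k]
    return TrueHaplotypes(pat, mat, seg, founder_freqs=freqs)


# ---------------------------------------------------------------------------
# Marker panels and array observation
# ---------------------------------------------------------------------------

def make_panels(gmap: GeneticMap, hd_per_chr: int, ld_per_chr: int,
                maf: np.ndarray | None = None) -> PanelSet:
    """Evenly spaced nested panels, preferring informative sites.

    HD sites are chosen near evenly spaced targets along each chromosome,
    snapping to the nearest variant with MAF >= 0.05 where one exists in
    the local window; LD is an evenly spaced subset of HD.
    """
    if ld_per_chr > hd_per_chr:
        raise ValueError("LD panel cannot exceed HD panel")
    hd = np.zeros(gmap.n_variants, dtype=bool)
    ld = np.zeros(gmap.n_variants, dtype=bool)
    for c in gmap.chromosomes:
        ix = gmap.chrom_slice(c)
        m = len(ix)
        if hd_per_chr > m:
            raise ValueError(f"not enough variants on chromosome {c} for HD panel")
        targets = np.round((np.arange(hd_per_chr) + 0.5) / hd_per_chr * m - 0.5).astype(int)
        chosen: list[int] = []
        taken = np.zeros(m, dtype=bool)
        half = max(1, m // (2 * hd_per_chr))
        for t in targets:
            lo, hi = max(0, t - half), min(m, t + half + 1)
            window = np.arange(lo, hi)
            window = window[~taken[window]]
            if len(window) == 0:
                window = np.flatnonzero(~taken)
            if maf is not None:
                good = window[np.minimum(maf[ix[window]], 1 - maf[ix[window]]) >= 0.05]
                if len(good):
                    window = good
            pick = window[np.argmin(np.abs(window - t))]
            taken[pick] = True
            chosen.append(pick)
        chosen = np.sort(np.array(chosen))
        hd[ix[chosen]] = True
        stride = np.round(np.linspace(0, hd_per_chr - 1, ld_per_chr)).astype(int)
        ld[ix[chosen[stride]]] = True
    return PanelSet(hd, ld)


def assign_statuses(ped: Pedigree, params: SimParams, rng) -> np.ndarray:
    """Genotyping status per individual from per-generation-band fractions."""
    rng = np.random.default_rng(rng)
    if ped.generation is not None:
        early = ped.generation < params.early_generations
    else:  # fall back on relative pedigree position
        early = ped.relative_position() < 0.2
    status = np.empty(ped.n, dtype="<U4")
    for mask, fracs in ((early, params.status_early), (~early, params.status_late)):
        k = int(mask.sum())
        if k == 0:
            continue
        u = rng.random(k)
        none_f, ld_f, _ = fracs
        s = np.full(k, "HD", dtype="<U4")
        s[u < none_f + ld_f] = "LD"
        s[u < none_f] = "none"
        status[mask] = s
    return status


def observe_arrays(truth: TrueHaplotypes, panels: PanelSet, status: np.ndarray) -> GenotypeMatrix:
    """Noise-free marker-array genotypes at each individual's panel sites."""
    g = truth.genotypes()
    values = np.full(g.shape, -1, dtype=np.int8)
    for st in ("LD", "HD"):
        mask = panels.mask_for(st)
        rows = status == st
        values[np.ix_(rows, mask)] = g[np.ix_(rows, mask)]
    return GenotypeMatrix(values, status)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_reads(truth: TrueHaplotypes, coverage: np.ndarray, params: SimParams,
                   rng) -> ReadCounts:
    """Poisson-gamma read counts with sequencing error.

    Per-site sequenceability s_v ~ Gamma(shape, mean 1) is drawn once; the
    read total for individual i at site v is Poisson(c_i * s_v).  Each read
    reports the allele of a uniformly chosen haplotype, flipped with
    probability ``seq_error``.
    """
    rng = np.random.default_rng(rng)
    coverage = np.asarray(coverage, dtype=float)
    if (coverage < 0).any():
        raise ValueError("negative coverage")
    n, L = truth.pat.shape
    alpha = params.gamma_shape
    s_v = rng.gamma(alpha, 1.0 / alpha, size=L) if np.isfinite(alpha) else np.ones(L)
    ref = np.zeros((n, L), dtype=np.int32)
    alt = np.zeros((n, L), dtype=np.int32)
    seq = np.flatnonzero(coverage > 0)
    if len(seq):
        lam = coverage[seq, None] * s_v[None, :]
        tot = rng.poisson(lam)
        e = params.seq_error
        p_alt = (truth.pat[seq] + truth.mat[seq]) / 2.0
        p_read_alt = p_alt * (1 - e) + (1 - p_alt) * e
        a = rng.binomial(tot, p_read_alt)
        alt[seq] = a
        ref[seq] = tot - a
    return ReadCounts(ref, alt, coverage)


# ---------------------------------------------------------------------------
# One-call dataset bundle
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    """Everything one simulated study run carries between stages."""

    config: RunConfig
    pedigree: Pedigree
    gmap: GeneticMap
    panels: PanelSet
    truth: TrueHaplotypes
    genotypes: GenotypeMatrix
    reads: ReadCounts
    plan: "object" = None  # BudgetPlan, set when sequencing was allocated

    def copy_observations(self) -> "Dataset":
        """Copy with independent genotype/read arrays (for perturbations)."""
        return Dataset(self.config, self.pedigree, self.gmap, self.panels,
                       self.truth, self.genotypes.copy(), self.reads.copy(), self.plan)


def add_high_coverage(dataset: Dataset, ids: list[str], coverage: float = 30.0,
                      seed: int = 0) -> Dataset:
    """Return a dataset in which ``ids`` are sequenced at high coverage.

    Used to assemble a deep-sequenced validation set on small simulated
    populations whose budget plan alone funds few high-coverage
    individuals; all read counts are re-drawn (seeded) from the same truth
    with the updated coverage vector.
    """
    params = SimParams.from_config(dataset.config)
    coverage_vec = dataset.reads.coverage.copy()
    for iid in ids:
        coverage_vec[dataset.pedigree.index[iid]] = coverage
    reads = simulate_reads(dataset.truth, coverage_vec, params,
                           np.random.default_rng(seed))
    return Dataset(dataset.config, dataset.pedigree, dataset.gmap, dataset.panels,
                   dataset.truth, dataset.genotypes, reads, dataset.plan)


def simulate_dataset(config: RunConfig, seed: int | None = None) -> Dataset:
    """Simulate pedigree, truth, arrays, sequencing plan and reads."""
    from .seq_strategy import build_plan  # deferred: seq_strategy imports core only

    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    params = SimParams.from_config(config)
    ped = generate_pedigree(params, rng)
    gmap = uniform_map(config.n_chromosomes, config.chrom_length_cm,
                       config.variants_per_chromosome)
    truth = drop_genotypes(ped, gmap, params, rng)
    panels = make_panels(gmap, config.hd_per_chromosome, config.ld_per_chromosome,
                         maf=truth.allele_freqs())
    status = assign_statuses(ped, params, rng)
    genotypes = observe_arrays(truth, panels, status)
    genotyped = {ped.ids[i] for i in np.flatnonzero(status != "none")}
    budget = config.budget_fraction * ped.n * config.budget_base_coverage
    plan = build_plan(ped, genotyped, budget, config.split_fractions,
                      coverage_menu=config.coverage_menu)
    coverage = np.zeros(ped.n)
    for iid, c in plan.assignment.items():
        coverage[ped.index[iid]] = c
    reads = simulate_reads(truth, coverage, params, rng)
    return Dataset(config, ped, gmap, panels, truth, genotypes, reads, plan)
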