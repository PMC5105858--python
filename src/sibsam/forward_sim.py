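"""Forward-in-time simulation of BSA and IM mapping experiments.

Two implementations of the same breeding model live in this package:

* a readable individual/tract representation (:class:`AncestryChromosome`,
  :class:`Individual`, :func:`recombine_gamete`, :func:`breed_generation`,
  :func:`phenotype`) used for small-scale work and as an independent check;
* a vectorized engine (:mod:`sibsam._engine`) evaluating ancestry at window
  midpoints, used by :func:`run_bsa_experiment` / :func:`run_im_experiment`.

Model summary: parental-strain ancestry (HIGH = the strain with the higher
trait value) is tracked along chromosomes X, 2 and 3 from the F1 generation
on.  Each generation, every offspring draws a random mother and father from
the previous generation.  Crossover counts per female gamete are Poisson
with mean equal to the chromosome's genetic length in Morgans (no
interference); males do not recombine and transmit whole chromosome copies.
Phenotypes are genetic scores (effect ``f`` per HIGH allele per QTL) plus
Gaussian noise; selection keeps phenotypic tails; pooled sequencing draws a
binomial number of ancestry-informative reads per window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .genome_map import GenomeMap

__all__ = [
    "HIGH",
    "LOW",
    "EXPLORATORY",
    "SIBSAM_NOISE",
    "ExperimentConfig",
    "QTL",
    "QTLModel",
    "AncestryChromosome",
    "Individual",
    "PoolAncestry",
    "recombine_gamete",
    "make_f1",
    "breed_generation",
    "phenotype",
    "select_tails",
    "sample_pool_reads",
    "ancestry_difference",
    "run_bsa_experiment",
    "run_im_experiment",
    "im_neutral_ancestry",
    "combine_crosses",
]

HIGH = 1
LOW = 0

#: Noise models.  EXPLORATORY: Gaussian with SD equal to the design-mean
#: trait value (used in the experimental-design study).  SIBSAM_NOISE:
#: 0.5 x N(0,1) per individual (used throughout the inference pipeline).
EXPLORATORY = "exploratory"
SIBSAM_NOISE = "sibsam"


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class ExperimentConfig:
    """Parameters of one mapping experiment.

    ``q`` is the selected proportion per phenotypic tail; ``depth`` the
    number of ancestry-informative reads per window per pool; ``n_pheno``
    the number of final-generation individuals phenotyped (default: all).
    """

    mode: str = "bsa"
    N: int = 600
    G: int = 10
    q: float = 0.20
    depth: int = 300
    n_pheno: int | None = None
    females_only: bool = False
    crosses: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("bsa", "im"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.G < 2:
            raise ValueError("G must be >= 2")
        qmax = 0.5 if self.mode == "bsa" else 1.0
        if not (0 < self.q <= qmax):
            raise ValueError(f"q must be in (0, {qmax}] for mode {self.mode}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass(frozen=True)
class QTL:
    """A causative locus: chromosome, genetic position, and effect ``f``
    added to the phenotype per HIGH allele carried."""

    chrom: str
    cm: float
    f: float

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError("QTL effect f must be >= 0")


@dataclass
class QTLModel:
    """A set of QTL plus the phenotypic noise model."""

    loci: list[QTL] = field(default_factory=list)
    noise_model: str = SIBSAM_NOISE
    noise_sd: float | None = None

    def noise_scale(self) -> float:
        """SD of the Gaussian noise added to each phenotype."""
        if self.noise_model == SIBSAM_NOISE:
            return 0.5
        if self.noise_model == EXPLORATORY:
            if self.noise_sd is not None:
                return self.noise_sd
            return self.design_mean()
        raise ValueError(f"unknown noise model {self.noise_model!r}")

    def design_mean(self) -> float:
        """Expected genetic trait value of the design (diploid loci at
        ancestry frequency 1/2 contribute ``f`` each on average)."""
        return float(sum(q.f for q in self.loci))

    def engine_loci(self, gmap: GenomeMap):
        """Loci resolved to (chrom_index, window_index, f), snapping each
        genetic position to its containing window's midpoint."""
        out = []
        for q in self.loci:
            ci = gmap.chrom_index(q.chrom)
            out.append((ci, gmap.chromosomes[ci].window_at(q.cm), q.f))
        return out


# ---------------------------------------------------------------------------
# Tract-level reference implementation
# ---------------------------------------------------------------------------


@dataclass
class AncestryChromosome:
    """One chromosome copy as ancestry tracts.

    ``breakpoints`` are strictly increasing cM positions; ``origins`` has
    one more entry than ``breakpoints`` and gives the parental strain
    (HIGH/LOW) of each tract, tiling ``[0, total_cM]``.
    """

    breakpoints: np.ndarray
    origins: np.ndarray

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=np.float64)
        self.origins = np.asarray(self.origins, dtype=np.int8)
        if len(self.origins) != len(self.breakpoints) + 1:
            raise ValueError("origins must have len(breakpoints) + 1 entries")
        if len(self.breakpoints) and np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")

    @classmethod
    def pure(cls, origin: int) -> "AncestryChromosome":
        return cls(np.empty(0), np.array([origin], dtype=np.int8))

    def origin_at(self, cm_pos) -> np.ndarray:
        """Parental origin at one or many genetic positions."""
        idx = np.searchsorted(self.breakpoints, cm_pos, side="right")
        return self.origins[idx]

    def simplified(self) -> "AncestryChromosome":
        """Merge adjacent tracts of equal origin."""
        if len(self.breakpoints) == 0:
            return self
        keep = np.flatnonzero(np.diff(self.origins) != 0)
        return AncestryChromosome(self.breakpoints[keep], self.origins[np.r_[keep, len(self.breakpoints)]])


def recombine_gamete(
    copy_a: AncestryChromosome,
    copy_b: AncestryChromosome,
    total_cm: float,
    is_male: bool,
    rng,
) -> AncestryChromosome:
    """Form one gamete from a parent's two chromosome copies.

    Females: crossover count ~ Poisson(total_cM/100), positions uniform on
    [0, total_cM], starting copy random, no interference.  Males: zero
    crossovers; one copy is transmitted whole at random.
    """
    rng = _as_rng(rng)
    copies = (copy_a, copy_b)
    start = int(rng.integers(0, 2))
    if is_male or total_cm == 0:
        c = copies[start]
        return AncestryChromosome(c.breakpoints.copy(), c.origins.copy())
    k = rng.poisson(total_cm / 100.0)
    cuts = np.sort(rng.uniform(0.0, total_cm, k))
    edges = np.concatenate([[0.0], cuts, [total_cm]])
    bps: list[float] = []
    origs: list[int] = []
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        src = copies[(start + i) % 2]
        inner = src.breakpoints[(src.breakpoints > lo) & (src.breakpoints < hi)]
        seg_edges = np.concatenate([[lo], inner])
        for j, seg_lo in enumerate(seg_edges):
            origs.append(int(src.origin_at(seg_lo)))
            if not (i == 0 and j == 0):
                bps.append(float(seg_lo))
    return AncestryChromosome(np.asarray(bps), np.asarray(origs)).simplified()


@dataclass
class Individual:
    """One mapping-population individual; males carry a single X copy."""

    is_male: bool
    genome: dict  # chrom label -> tuple of AncestryChromosome

    def copies(self, chrom: str):
        return self.genome[chrom]


def make_f1(gmap: GenomeMap, n: int, rng) -> list[Individual]:
    """F1 of reciprocal parental crosses, combined (see engine docstring)."""
    rng = _as_rng(rng)
    out = []
    for _ in range(n):
        is_male = bool(rng.random() < 0.5)
        genome = {}
        for c in gmap.chromosomes:
            if c.is_x and is_male:
                origin = HIGH if rng.random() < 0.5 else LOW
                genome[c.label] = (AncestryChromosome.pure(origin),)
            else:
                genome[c.label] = (
                    AncestryChromosome.pure(HIGH),
                    AncestryChromosome.pure(LOW),
                )
        out.append(Individual(is_male, genome))
    return out


def breed_generation(
    pop: list[Individual], gmap: GenomeMap, rng, n_offspring: int | None = None
) -> list[Individual]:
    """One generation of random mating (tract-level reference path)."""
    rng = _as_rng(rng)
    females = [i for i in pop if not i.is_male]
    males = [i for i in pop if i.is_male]
    if not females or not males:
        raise _engine.SingleSexError("cannot breed from a single-sex generation")
    n = len(pop) if n_offspring is None else n_offspring
    out = []
    for _ in range(n):
        mother = females[rng.integers(len(females))]
        father = males[rng.integers(len(males))]
        child_male = bool(rng.random() < 0.5)
        genome = {}
        for c in gmap.chromosomes:
            mat = recombine_gamete(*mother.copies(c.label)[:2], c.total_cm, False, rng)
            if c.is_x:
                if child_male:
                    genome[c.label] = (mat,)
                else:
                    genome[c.label] = (mat, father.copies(c.label)[0])
            else:
                pat = recombine_gamete(*father.copies(c.label), c.total_cm, True, rng)
                genome[c.label] = (mat, pat)
        out.append(Individual(child_male, genome))
    return out


def phenotype(ind: Individual, qtl_model: QTLModel, rng) -> float:
    """Genetic score (sum of f x HIGH-dosage over loci) plus Gaussian noise."""
    rng = _as_rng(rng)
    score = 0.0
    for q in qtl_model.loci:
        dosage = sum(int(c.origin_at(q.cm)) for c in ind.copies(q.chrom))
        score += q.f * dosage
    return score + qtl_model.noise_scale() * rng.standard_normal()


# ---------------------------------------------------------------------------
# Shared array-level operations
# ---------------------------------------------------------------------------


def select_tails(phenotypes: np.ndarray, q: float, mode: str = "bsa"):
    """Select phenotypic-tail pools.

    BSA: returns ``(high_idx, low_idx)``, the indices of the top and bottom
    ``floor(q * n)`` phenotypes.  IM: returns the single high tail (toward
    the non-backcross parental strain).  Ties at the cutoff are broken by
    stable sort order of individual index.
    """
    phenotypes = np.asarray(phenotypes)
    n = len(phenotypes)
    npool = int(np.floor(q * n))
    if npool < 1:
        raise ValueError(f"selected pool size is zero (q={q}, n={n})")
    order = np.argsort(phenotypes, kind="stable")
    high = order[n - npool:]
    if mode == "im":
        return high
    return high, order[:npool]


@dataclass
class PoolAncestry:
    """Per-window HIGH-ancestry frequencies of a sequenced pool."""

    freq_true: np.ndarray
    reads_high: np.ndarray
    depth: np.ndarray

    @property
    def freq_est(self) -> np.ndarray:
        return self.reads_high / self.depth


def sample_pool_reads(pool: list[Individual], gmap: GenomeMap, depth, rng) -> PoolAncestry:
    """Sequence a pool of individuals: true HIGH frequency per window over
    all chromosome copies (at window midpoints), then Binomial(depth, p)
    informative reads."""
    rng = _as_rng(rng)
    if not pool:
        raise ValueError("empty pool")
    freqs = []
    for c in gmap.chromosomes:
        mids = c.cm_mid
        n_high = np.zeros(c.n_windows)
        n_cop = 0
        for ind in pool:
            for cp in ind.copies(c.label):
                n_high += cp.origin_at(mids)
                n_cop += 1
        freqs.append(n_high / n_cop)
    freq = np.concatenate(freqs)
    depth_arr = np.broadcast_to(np.asarray(depth, dtype=np.int64), freq.shape)
    reads = rng.binomial(depth_arr, freq)
    return PoolAncestry(freq, reads, depth_arr.copy())


def ancestry_difference(high, low) -> np.ndarray:
    """a_d per window: HIGH-pool minus LOW-pool estimated HIGH-ancestry
    frequency (difference in ancestry from the high-phenotype strain)."""
    fh = high.freq_est if isinstance(high, PoolAncestry) else np.asarray(high)
    fl = low.freq_est if isinstance(low, PoolAncestry) else np.asarray(low)
    if fh.shape != fl.shape:
        raise ValueError("pool window sets differ")
    return fh - fl


def combine_crosses(profiles) -> np.ndarray:
    """Sum a_d (or a_p) profiles across independent crosses, per window."""
    profiles = [np.asarray(p) for p in profiles]
    if not profiles:
        raise ValueError("no profiles to combine")
    if len({p.shape for p in profiles}) != 1:
        raise ValueError("profiles have mismatched window sets")
    return np.sum(profiles, axis=0)


# ---------------------------------------------------------------------------
# Experiment runners (vectorized path)
# ---------------------------------------------------------------------------


@dataclass
class BSAResult:
    """Outcome of one BSA experiment: the raw a_d profile plus pool data."""

    ad: np.ndarray
    freq_high: np.ndarray
    freq_low: np.ndarray
    true_high: np.ndarray
    true_low: np.ndarray


def _phenotyping_subset(pop: _engine.Population, config: ExperimentConfig, rng):
    cand = np.flatnonzero(~pop.is_male) if config.females_only else np.arange(pop.size)
    n_ph = pop.size if config.n_pheno is None else config.n_pheno
    n_ph = min(n_ph, len(cand))
    if n_ph < 1:
        raise ValueError("no individuals available for phenotyping")
    if n_ph < len(cand):
        cand = rng.choice(cand, n_ph, replace=False)
    return cand


def bsa_readout(
    pop: _engine.Population,
    config: ExperimentConfig,
    qtl_model: QTLModel,
    rng,
    depth_high=None,
    depth_low=None,
) -> BSAResult:
    """Phenotype the final generation, select tails, and sequence the pools.

    ``depth_high``/``depth_low`` may override ``config.depth`` with
    per-window informative-depth arrays (e.g. mirroring empirical data).
    """
    rng = _as_rng(rng)
    gmap = pop.gmap
    subset = _phenotyping_subset(pop, config, rng)
    scores = _engine.genetic_scores(pop, qtl_model.engine_loci(gmap))[subset]
    phenos = scores + qtl_model.noise_scale() * rng.standard_normal(len(subset))
    hi, lo = select_tails(phenos, config.q, mode="bsa")
    true_high = pop.pool_freq(subset[hi])
    true_low = pop.pool_freq(subset[lo])
    dh = config.depth if depth_high is None else depth_high
    dl = config.depth if depth_low is None else depth_low
    freq_high = _engine.sample_read_freqs(true_high, dh, rng)
    freq_low = _engine.sample_read_freqs(true_low, dl, rng)
    return BSAResult(freq_high - freq_low, freq_high, freq_low, true_high, true_low)


def run_bsa_experiment(
    config: ExperimentConfig, qtl_model: QTLModel, gmap: GenomeMap, rng
) -> BSAResult:
    """Run one full BSA experiment: breed ``G`` generations with no
    selection before the last, then phenotype, select tails, and sequence.
    Deterministic for a fixed seed."""
    rng = _as_rng(rng)
    pop = _engine.simulate_population(gmap, config.N, config.G, rng)
    return bsa_readout(pop, config, qtl_model, rng)


def im_neutral_ancestry(G: int) -> float:
    """Expected neutral non-backcross-strain ancestry after ``G`` total
    generations of the IM schedule (backcrossing after each intermediate
    even-numbered selection generation): 0.5 halved per backcross round."""
    b = max(0, (G - 2) // 2) if G % 2 == 0 else max(0, (G - 1) // 2)
    return 0.5 ** (b + 1)


@dataclass
class IMResult:
    """Outcome of one IM experiment: the a_p profile of the final pool."""

    ap: np.ndarray
    true_ap: np.ndarray


def run_im_experiment(
    config: ExperimentConfig, qtl_model: QTLModel, gmap: GenomeMap, rng
) -> IMResult:
    """Run one introgression-mapping experiment.

    Phenotypic selection (single tail toward the non-backcross HIGH strain,
    proportion ``q``) occurs in every second generation starting at F2;
    selected individuals are mated to unlimited pure backcross-strain
    partners.  At the final generation the selected pool is sequenced and
    a_p (HIGH-strain ancestry proportion) is reported per window.
    """
    rng = _as_rng(rng)
    loci = qtl_model.engine_loci(gmap)
    pop = _engine.f1_population(gmap, config.N, rng)
    for g in range(2, config.G + 1):
        pop = _breed_im_step(pop, g, config, qtl_model, loci, rng)
    # final generation: select and sequence
    scores = _engine.genetic_scores(pop, loci)
    phenos = scores + qtl_model.noise_scale() * rng.standard_normal(pop.size)
    sel = select_tails(phenos, config.q, mode="im")
    true_ap = pop.pool_freq(sel)
    ap = _engine.sample_read_freqs(true_ap, config.depth, rng)
    return IMResult(ap, true_ap)


def _breed_im_step(pop, g, config, qtl_model, loci, rng):
    """Form generation ``g`` from the previous one under the IM schedule."""
    prev_gen = g - 1
    select_here = prev_gen >= 2 and prev_gen % 2 == 0
    if select_here:
        scores = _engine.genetic_scores(pop, loci)
        phenos = scores + qtl_model.noise_scale() * rng.standard_normal(pop.size)
        sel = select_tails(phenos, config.q, mode="im")
        return _engine.breed_backcross(pop, sel, config.N, rng)
    return _engine.breed(pop, config.N, rng)
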