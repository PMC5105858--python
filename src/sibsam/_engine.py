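"""Array-based population engine used by the experiment runners.

Ancestry is represented exactly at window midpoints: a gamete's ancestry at
a midpoint is determined by the parity of the number of crossovers to its
left (crossover count Poisson with mean = chromosome length in Morgans,
positions uniform, starting copy random).  At the evaluation points this is
distributionally identical to explicit tract tracking — crossover
interference is not modeled, so only the parity of crossover counts between
points matters — while permitting whole-generation vectorization.

Conventions
-----------
* genotype arrays ``geno[c]`` have shape ``(N, 2, P_c)`` with 1 = ancestry
  from the HIGH parental strain;
* males carry a single X: it lives in copy slot 0 and slot 1 mirrors it;
  dosage and pool-frequency computations count male X once;
* no recombination in males (whole-copy transmission, Drosophila-style);
* the X is transmitted with standard X-linkage (sons: mother's recombinant
  X; daughters: mother's recombinant X plus father's X).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_map import GenomeMap


class SingleSexError(ValueError):
    """Raised when a generation lacks one sex and cannot be bred from."""


@dataclass
class Population:
    """One generation of the mapping population."""

    geno: list[np.ndarray]  # per chromosome, (N, 2, P) uint8
    is_male: np.ndarray     # (N,) bool
    gmap: GenomeMap

    @property
    def size(self) -> int:
        return len(self.is_male)

    def dosage(self, chrom_i: int, win_idx: int) -> np.ndarray:
        """Per-individual count of HIGH alleles at a window midpoint (0-2; 0-1 male X)."""
        g = self.geno[chrom_i]
        d = g[:, 0, win_idx].astype(np.int64) + g[:, 1, win_idx]
        if self.gmap.chromosomes[chrom_i].is_x:
            d = np.where(self.is_male, g[:, 0, win_idx], d)
        return d

    def pool_freq(self, pool: np.ndarray) -> np.ndarray:
        """True HIGH-ancestry frequency per window (genome-flat) in a pool.

        Counts two chromosome copies per female and, on the X, one per male.
        """
        out = []
        males = self.is_male[pool]
        for c, g in zip(self.gmap.chromosomes, self.geno):
            sub = g[pool]
            if c.is_x:
                n_high = sub[:, 0, :].sum(axis=0, dtype=np.int64)
                n_high = n_high + sub[~males][:, 1, :].sum(axis=0, dtype=np.int64)
                denom = 2 * int((~males).sum()) + int(males.sum())
            else:
                n_high = sub.sum(axis=(0, 1), dtype=np.int64)
                denom = 2 * len(pool)
            out.append(n_high / denom)
        return np.concatenate(out)


def f1_population(gmap: GenomeMap, n: int, rng: np.random.Generator) -> Population:
    """F1 of reciprocal HIGH x LOW crosses, combined.

    Autosomes: every individual carries one all-HIGH and one all-LOW copy.
    X: females carry one of each; each male's single X comes from his mother
    and is HIGH or LOW with equal probability (reciprocal crosses pooled).
    """
    is_male = rng.random(n) < 0.5
    geno = []
    for c in gmap.chromosomes:
        g = np.zeros((n, 2, c.n_windows), dtype=np.uint8)
        g[:, 0, :] = 1
        if c.is_x:
            male_x_high = rng.random(n) < 0.5
            g[is_male & ~male_x_high, 0, :] = 0
            g[is_male, 1, :] = g[is_male, 0, :]
        geno.append(g)
    return Population(geno, is_male, gmap)


def _recombinant_gametes(
    geno_c: np.ndarray,
    parent_idx: np.ndarray,
    mids: np.ndarray,
    total_cm: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Female gametes for one chromosome, vectorized over offspring.

    Crossover count ~ Poisson(total_cM / 100) per gamete, positions uniform
    on [0, total_cM]; the transmitted copy at each midpoint follows from the
    crossover parity left of it, starting from a random copy.
    """
    m = len(parent_idx)
    p = len(mids)
    k = rng.poisson(total_cm / 100.0, m)
    start = rng.integers(0, 2, m).astype(np.int16)
    flips = np.zeros((m, p), dtype=np.int16)
    total = int(k.sum())
    if total:
        pos = rng.uniform(0.0, total_cm, total)
        owner = np.repeat(np.arange(m), k)
        idx = np.searchsorted(mids, pos, side="left")
        keep = idx < p  # crossovers beyond the last midpoint flip nothing
        np.add.at(flips, (owner[keep], idx[keep]), 1)
    parity = (start[:, None] + np.cumsum(flips, axis=1)) % 2
    pg = geno_c[parent_idx]
    return np.where(parity == 0, pg[:, 0, :], pg[:, 1, :]).astype(np.uint8)


def breed(pop: Population, n_next: int, rng: np.random.Generator) -> Population:
    """One generation of random mating: each offspring draws an independent
    random mother and random father; sex assigned 50/50."""
    females = np.flatnonzero(~pop.is_male)
    males = np.flatnonzero(pop.is_male)
    if len(females) == 0 or len(males) == 0:
        raise SingleSexError("cannot breed from a single-sex generation")
    mothers = rng.choice(females, n_next)
    fathers = rng.choice(males, n_next)
    child_male = rng.random(n_next) < 0.5
    geno = []
    for c, g in zip(pop.gmap.chromosomes, pop.geno):
        mids = c.cm_mid
        mat = _recombinant_gametes(g, mothers, mids, c.total_cm, rng)
        new = np.empty((n_next, 2, c.n_windows), dtype=np.uint8)
        new[:, 0, :] = mat
        if c.is_x:
            pat_x = g[fathers, 0, :]
            new[:, 1, :] = np.where(child_male[:, None], mat, pat_x)
        else:
            cpick = rng.integers(0, 2, n_next)
            new[:, 1, :] = g[fathers, cpick, :]
        geno.append(new)
    return Population(geno, child_male, pop.gmap)


def breed_backcross(
    pop: Population,
    selected: np.ndarray,
    n_next: int,
    rng: np.random.Generator,
) -> Population:
    """Backcross generation: each offspring has one parent drawn from the
    selected pool and one pure LOW-strain (backcross-parent) mate of the
    opposite sex.  Selected males transmit whole copies (no recombination)."""
    if len(selected) == 0:
        raise ValueError("empty selected pool")
    sel = rng.choice(selected, n_next)
    sel_male = pop.is_male[sel]
    child_male = rng.random(n_next) < 0.5
    geno = []
    for c, g in zip(pop.gmap.chromosomes, pop.geno):
        rec = _recombinant_gametes(g, sel, c.cm_mid, c.total_cm, rng)
        new = np.zeros((n_next, 2, c.n_windows), dtype=np.uint8)
        if c.is_x:
            # maternal X: recombinant if the selected parent is the mother,
            # else from the pure LOW mother (all zeros)
            mat_x = np.where(sel_male[:, None], 0, rec).astype(np.uint8)
            pat_x = np.where(sel_male[:, None], g[sel, 0, :], 0).astype(np.uint8)
            new[:, 0, :] = mat_x
            new[:, 1, :] = np.where(child_male[:, None], mat_x, pat_x)
        else:
            cpick = rng.integers(0, 2, n_next)
            whole = g[sel, cpick, :]
            new[:, 0, :] = np.where(sel_male[:, None], whole, rec)
            # other slot is from the pure LOW mate: all zeros
        geno.append(new)
    return Population(geno, child_male, pop.gmap)


def simulate_population(
    gmap: GenomeMap, n: int, generations: int, rng: np.random.Generator
) -> Population:
    """Breed ``generations`` total generations (F1 counts as generation 1)
    with no phenotypic selection; returns the final generation."""
    if generations < 2:
        raise ValueError("need at least 2 generations")
    pop = f1_population(gmap, n, rng)
    for _ in range(generations - 1):
        pop = breed(pop, n, rng)
    return pop


def genetic_scores(pop: Population, loci) -> np.ndarray:
    """Sum of effect x HIGH-allele dosage over loci ((chrom_i, win_idx, f))."""
    score = np.zeros(pop.size)
    for chrom_i, win_idx, f in loci:
        score += f * pop.dosage(chrom_i, win_idx)
    return score


def sample_read_freqs(
    true_freq: np.ndarray, depth, rng: np.random.Generator
) -> np.ndarray:
    """Binomial read sampling: estimated frequency = HIGH reads / depth."""
    depth = np.broadcast_to(np.asarray(depth, dtype=np.int64), true_freq.shape)
    if np.any(depth < 1):
        raise ValueError("informative depth must be >= 1 at every window")
    return rng.binomial(depth, true_freq) / depth
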