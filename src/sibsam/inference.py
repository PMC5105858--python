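"""The three SIBSAM simulation-based inference stages.

1. **Null stage** — BSA simulations with no true QTL (phenotypes are pure
   noise) build a reference distribution of primary-peak heights; the
   false-positive probability of an empirical peak follows from the
   enrichment ``e`` of peaks at least that tall in the data relative to the
   null (``P = 1/e``; ``P = 1`` when there is no enrichment).
2. **Single-QTL stage** — for each significant primary peak, simulations
   with one QTL fixed at the empirical peak window, strength ``s`` drawn
   from a Uniform(0, 1) prior, feed a rejection-sampling (ABC) posterior:
   replicates whose maximum a_d matches the empirical peak height within a
   tolerance are accepted, yielding strength quantiles, a genomic
   confidence interval (from accepted simulated peak locations, relying on
   the transitivity of true-QTL-to-peak distances), and P-values for the
   peak's secondary peaks (from the accepted replicates' maximum secondary
   deviations, which conditions away the unknown primary strength).
3. **Cluster stage** — a primary peak with significant secondaries is
   re-simulated as a cluster of linked QTL at the empirical peak windows;
   cluster strength is drawn Uniform(0, 1) and apportioned uniformly on
   the simplex (symmetric Dirichlet); a replicate is accepted only if the
   local maximum in *every* member's valley-bounded analysis zone matches
   its empirical height within tolerance.  Member posteriors replace the
   single-QTL estimates, since they account for linked-QTL inflation.

Strength and per-allele effect are linked by ``s = f / (1 + f)`` — the
noise recipe (0.5 x N(0,1)) is pegged so that a locus with ``f = 1`` is
nominally half the variance — hence ``f = s / (1 - s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _engine
from .forward_sim import (
    SIBSAM_NOISE,
    ExperimentConfig,
    QTLModel,
    bsa_readout,
)
from .genome_map import GenomeMap
from .peaks import (
    Peak,
    Thresholds,
    assign_secondary_deviations,
    find_secondary_peaks,
    detect_peaks,
    smooth_profile,
    _positive_runs,
)

__all__ = [
    "strength_to_effect",
    "NullPeakDistribution",
    "null_stage",
    "primary_pvalue",
    "SingleQTLRecords",
    "single_qtl_stage",
    "PosteriorSummary",
    "rejection_posterior",
    "secondary_pvalue",
    "ClusterRecords",
    "cluster_stage",
    "QTLReport",
    "write_report",
    "run_pipeline",
]


def strength_to_effect(s: float) -> float:
    """Per-allele effect for a nominal strength: f = s / (1 - s)."""
    s = float(s)
    if not (0.0 <= s < 1.0):
        raise ValueError("strength s must satisfy 0 <= s < 1")
    return s / (1.0 - s)


def _stage_rng(seed, stage: int, rep: int | None = None) -> np.random.Generator:
    """Deterministic per-stage / per-replicate generators from one master
    seed, so that replicate shards are independent and mergeable."""
    entropy = (int(seed), stage) if rep is None else (int(seed), stage, rep)
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# Stage 1: null simulations and primary-peak significance
# ---------------------------------------------------------------------------


@dataclass
class NullPeakDistribution:
    """All primary-peak heights (> a_dt) pooled from no-QTL replicates."""

    heights: np.ndarray
    n_reps: int

    def mean_count_at_least(self, h: float) -> float:
        """Mean number of null primary peaks >= h per simulated genome scan."""
        return float(np.count_nonzero(self.heights >= h)) / self.n_reps

    def merged(self, other: "NullPeakDistribution") -> "NullPeakDistribution":
        return NullPeakDistribution(
            np.concatenate([self.heights, other.heights]), self.n_reps + other.n_reps
        )


def null_stage(
    gmap: GenomeMap,
    config: ExperimentConfig,
    thresholds: Thresholds,
    n_reps: int,
    seed: int,
    depth_high=None,
    depth_low=None,
    rep_offset: int = 0,
) -> NullPeakDistribution:
    """Simulate ``n_reps`` no-QTL BSA experiments through the identical
    smoothing/peak-calling path and pool all primary-peak heights."""
    null_model = QTLModel([], SIBSAM_NOISE)
    heights: list[float] = []
    for r in range(rep_offset, rep_offset + n_reps):
        rng = _stage_rng(seed, 1, r)
        pop = _engine.simulate_population(gmap, config.N, config.G, rng)
        res = bsa_readout(pop, config, null_model, rng, depth_high, depth_low)
        sp = smooth_profile(res.ad, thresholds.m, gmap)
        for pk in detect_peaks(sp, gmap, thresholds):
            heights.append(pk.height)
    return NullPeakDistribution(np.asarray(heights), n_reps)


def primary_pvalue(
    peak_height: float,
    empirical_heights,
    null: NullPeakDistribution,
) -> tuple[float, bool]:
    """False-positive probability of a primary peak via null enrichment.

    ``empirical_heights`` are all primary-peak heights from the one
    observed genome scan.  The enrichment of peaks at least as tall as the
    focal one is ``e = freq_real / freq_null`` (both as counts per genome
    scan); ``P = 1/e`` when ``e > 1``, else 1.  If no null peak reaches
    this height the ECDF resolution floor is reported with a flag (never
    an exact zero).
    """
    emp = np.asarray(empirical_heights, dtype=float)
    freq_real = float(np.count_nonzero(emp >= peak_height))
    if freq_real < 1:
        raise ValueError("peak_height must be one of the empirical peaks' heights")
    freq_null = null.mean_count_at_least(peak_height)
    if freq_null == 0.0:
        return 1.0 / (null.n_reps * freq_real), True
    e = freq_real / freq_null
    return (1.0 / e, False) if e > 1.0 else (1.0, False)


# ---------------------------------------------------------------------------
# Stage 2: single-QTL simulations and rejection posteriors
# ---------------------------------------------------------------------------


@dataclass
class SingleQTLRecords:
    """Per-replicate summaries from single-QTL simulations at one fixed
    QTL position: prior strength draw, genome-wide maximum of the smoothed
    a_d profile (height / chromosome / genetic position), and the maximum
    adjusted secondary deviation of the peak containing that maximum."""

    chrom: str
    window: int
    qtl_cm: float
    s: np.ndarray
    height: np.ndarray
    peak_chrom: np.ndarray
    peak_cm: np.ndarray
    max_v: np.ndarray

    def merged(self, other: "SingleQTLRecords") -> "SingleQTLRecords":
        if (self.chrom, self.window) != (other.chrom, other.window):
            raise ValueError("cannot merge records for different QTL positions")
        cat = np.concatenate
        return SingleQTLRecords(
            self.chrom, self.window, self.qtl_cm,
            cat([self.s, other.s]), cat([self.height, other.height]),
            cat([self.peak_chrom, other.peak_chrom]), cat([self.peak_cm, other.peak_cm]),
            cat([self.max_v, other.max_v]),
        )


def _profile_summary(sp, gmap: GenomeMap, thresholds: Thresholds):
    """(height, chrom_index, cm, max_v) of the genome-wide smoothed maximum."""
    x = np.asarray(sp)
    gidx = int(np.argmax(x))
    off = gmap.offsets
    ci = int(np.searchsorted(off, gidx, side="right")) - 1
    c = gmap.chromosomes[ci]
    w = gidx - int(off[ci])
    height = float(x[gidx])
    max_v = 0.0
    seg = x[gmap.slices()[ci]]
    for start, end in _positive_runs(seg):
        if start <= w < end:
            prim = Peak("primary", c.label, w, height, run_start=int(start), run_end=int(end))
            secs = find_secondary_peaks(sp, gmap, prim, thresholds)
            if secs:
                assign_secondary_deviations(sp, gmap, prim, secs)
                max_v = max(s.v for s in secs)
            break
    return height, ci, float(c.cm_mid[w]), max_v


def single_qtl_stage(
    peak_positions,
    gmap: GenomeMap,
    config: ExperimentConfig,
    thresholds: Thresholds,
    n_reps: int,
    seed: int,
    depth_high=None,
    depth_low=None,
    rep_offset: int = 0,
) -> list[SingleQTLRecords]:
    """Single-QTL prior simulations for each empirical peak position.

    Each replicate draws one strength ``s ~ Uniform(0,1)`` and simulates the
    mapping-population ancestries once; the QTL (effect ``f = s/(1-s)``,
    noise 0.5 x N(0,1)) is then placed at each peak position in turn, with
    phenotyping, tail selection and read sampling performed separately —
    the simulated ancestries are reused across positions.

    ``peak_positions`` is a list of ``(chrom_label, window_index)``.
    """
    positions = []
    for chrom, window in peak_positions:
        ci = gmap.chrom_index(chrom)
        positions.append((chrom, int(window), ci, float(gmap.chromosomes[ci].cm_mid[window])))
    store = [([], [], [], [], []) for _ in positions]
    for r in range(rep_offset, rep_offset + n_reps):
        rng = _stage_rng(seed, 2, r)
        s = float(rng.uniform())
        f = strength_to_effect(s)
        pop = _engine.simulate_population(gmap, config.N, config.G, rng)
        for (chrom, window, ci, _), acc in zip(positions, store):
            model = QTLModel([], SIBSAM_NOISE)
            res = _readout_with_engine_loci(
                pop, config, model, [(ci, window, f)], rng, depth_high, depth_low
            )
            sp = smooth_profile(res.ad, thresholds.m, gmap)
            h, pci, pcm, mv = _profile_summary(sp, gmap, thresholds)
            acc[0].append(s)
            acc[1].append(h)
            acc[2].append(pci)
            acc[3].append(pcm)
            acc[4].append(mv)
    out = []
    for (chrom, window, ci, qtl_cm), acc in zip(positions, store):
        out.append(
            SingleQTLRecords(
                chrom, window, qtl_cm,
                np.asarray(acc[0]), np.asarray(acc[1]),
                np.asarray(acc[2], dtype=int), np.asarray(acc[3]), np.asarray(acc[4]),
            )
        )
    return out


def _readout_with_engine_loci(pop, config, model, engine_loci, rng, depth_high, depth_low):
    """bsa_readout with loci already resolved to engine coordinates."""
    from .forward_sim import select_tails, _phenotyping_subset

    subset = _phenotyping_subset(pop, config, rng)
    scores = _engine.genetic_scores(pop, engine_loci)[subset]
    phenos = scores + model.noise_scale() * rng.standard_normal(len(subset))
    hi, lo = select_tails(phenos, config.q, mode="bsa")
    true_high = pop.pool_freq(subset[hi])
    true_low = pop.pool_freq(subset[lo])
    dh = config.depth if depth_high is None else depth_high
    dl = config.depth if depth_low is None else depth_low
    freq_high = _engine.sample_read_freqs(true_high, dh, rng)
    freq_low = _engine.sample_read_freqs(true_low, dl, rng)
    from .forward_sim import BSAResult

    return BSAResult(freq_high - freq_low, freq_high, freq_low, true_high, true_low)


@dataclass
class PosteriorSummary:
    """Rejection-sampling posterior for one peak."""

    n_accepted: int
    tolerance_used: float
    widened: bool
    s_lo: float | None
    s_hat: float | None
    s_hi: float | None
    ci_cm_lo: float | None
    ci_cm_hi: float | None
    n_other_chrom: int = 0
    accepted: np.ndarray | None = None  # indices into the record arrays


def rejection_posterior(
    records: SingleQTLRecords,
    empirical_height: float,
    gmap: GenomeMap,
    tolerance: float = 0.025,
    min_accept: int = 200,
    quantiles: tuple[float, float] = (0.05, 0.95),
    empirical_cm: float | None = None,
) -> PosteriorSummary:
    """ABC posterior for one primary peak.

    Accepts replicates with ``|max a_d - empirical height| <= tolerance``;
    if fewer than ``min_accept`` are accepted the tolerance is doubled once
    (flagged).  The strength point estimate is the accepted-``s`` median
    with (0.05, 0.95) quantile bounds; the genomic CI takes the same
    quantiles of accepted peak genetic positions on the QTL's chromosome,
    re-centered on the empirical peak position (simulated true-QTL-to-peak
    distances proxy the empirical peak-to-true-QTL distances).
    """
    tol, widened = tolerance, False
    acc = np.flatnonzero(np.abs(records.height - empirical_height) <= tol)
    if len(acc) < min_accept:
        tol, widened = 2.0 * tolerance, True
        acc = np.flatnonzero(np.abs(records.height - empirical_height) <= tol)
    if len(acc) == 0:
        return PosteriorSummary(0, tol, widened, None, None, None, None, None)
    s_acc = records.s[acc]
    qlo, qhi = quantiles
    s_lo, s_hat, s_hi = np.quantile(s_acc, [qlo, 0.5, qhi])
    ci = gmap.chrom_index(records.chrom)
    same = acc[records.peak_chrom[acc] == ci]
    n_other = len(acc) - len(same)
    ci_lo = ci_hi = None
    if len(same):
        lo, hi = np.quantile(records.peak_cm[same], [qlo, qhi])
        center = records.qtl_cm if empirical_cm is None else empirical_cm
        shift = center - records.qtl_cm
        total = gmap.chromosomes[ci].total_cm
        ci_lo = float(np.clip(lo + shift, 0.0, total))
        ci_hi = float(np.clip(hi + shift, 0.0, total))
    return PosteriorSummary(
        len(acc), tol, widened, float(s_lo), float(s_hat), float(s_hi),
        ci_lo, ci_hi, n_other, acc,
    )


def secondary_pvalue(v_obs: float, accepted_max_v) -> float | None:
    """P-value for an empirical secondary peak: the fraction of accepted
    single-QTL replicates whose maximum secondary deviation is at least
    the observed (adjusted) deviation — the probability of a deviation
    this extreme when the true model is a single QTL of the matched
    height.  An observed deviation of zero therefore gives P = 1; a
    deviation beyond every accepted replicate reports the ECDF resolution
    floor ``1/n_accepted`` rather than an exact zero.  ``None`` if no
    replicates were accepted (flagged upstream)."""
    v = np.asarray(accepted_max_v)
    if len(v) == 0:
        return None
    p = float(np.count_nonzero(v >= v_obs)) / len(v)
    return max(p, 1.0 / len(v))


# ---------------------------------------------------------------------------
# Stage 3: cluster simulations
# ---------------------------------------------------------------------------


@dataclass
class ClusterRecords:
    """Per-replicate summaries from linked-QTL cluster simulations.

    ``member_s`` rows sum to the drawn cluster strength; ``zone_height``
    and ``zone_cm`` hold each analysis zone's local maximum of the smoothed
    profile and its genetic position.
    """

    chrom: str
    member_windows: list[int]
    zone_bounds: list[tuple[int, int]]
    cluster_s: np.ndarray
    member_s: np.ndarray
    zone_height: np.ndarray
    zone_cm: np.ndarray


def cluster_zones(smoothed, gmap: GenomeMap, chrom: str, member_windows) -> list[tuple[int, int]]:
    """Valley-bounded analysis zones for a sorted cluster of peak windows:
    interior boundaries at the empirical valleys (local minima of the
    smoothed profile between adjacent peaks); outer boundaries at the
    chromosome ends.  Returned as per-chromosome [start, end) ranges."""
    x = np.asarray(smoothed)
    ci = gmap.chrom_index(chrom)
    seg = x[gmap.slices()[ci]]
    wins = sorted(int(w) for w in member_windows)
    cuts = [0]
    for a, b in zip(wins[:-1], wins[1:]):
        cuts.append(a + 1 + int(np.argmin(seg[a + 1 : b])) if b > a + 1 else b)
    cuts.append(len(seg))
    return [(cuts[i], cuts[i + 1]) for i in range(len(wins))]


def cluster_stage(
    smoothed_empirical,
    gmap: GenomeMap,
    chrom: str,
    member_windows,
    empirical_heights,
    config: ExperimentConfig,
    thresholds: Thresholds,
    n_reps: int,
    seed: int,
    depth_high=None,
    depth_low=None,
    rep_offset: int = 0,
) -> ClusterRecords:
    """Joint simulations of a linked-QTL cluster at fixed empirical peak
    windows.  Cluster strength ~ Uniform(0,1), apportioned by a symmetric
    Dirichlet(1, ..., 1); each member's effect is f = s/(1-s)."""
    ci = gmap.chrom_index(chrom)
    c = gmap.chromosomes[ci]
    wins = sorted(int(w) for w in member_windows)
    k = len(wins)
    zones = cluster_zones(smoothed_empirical, gmap, chrom, wins)
    sl = gmap.slices()[ci]
    cs, ms, zh, zc = [], [], [], []
    for r in range(rep_offset, rep_offset + n_reps):
        rng = _stage_rng(seed, 3, r)
        s_cluster = float(rng.uniform())
        shares = rng.dirichlet(np.ones(k))
        s_members = s_cluster * shares
        loci = [(ci, w, strength_to_effect(s)) for w, s in zip(wins, s_members)]
        pop = _engine.simulate_population(gmap, config.N, config.G, rng)
        res = _readout_with_engine_loci(
            pop, config, QTLModel([], SIBSAM_NOISE), loci, rng, depth_high, depth_low
        )
        sp = np.asarray(smooth_profile(res.ad, thresholds.m, gmap))[sl]
        heights, cms = [], []
        for lo, hi in zones:
            j = lo + int(np.argmax(sp[lo:hi]))
            heights.append(float(sp[j]))
            cms.append(float(c.cm_mid[j]))
        cs.append(s_cluster)
        ms.append(s_members)
        zh.append(heights)
        zc.append(cms)
    return ClusterRecords(
        chrom, wins, zones,
        np.asarray(cs), np.asarray(ms), np.asarray(zh), np.asarray(zc),
    )


def cluster_posteriors(
    records: ClusterRecords,
    empirical_heights,
    tolerance: float = 0.05,
    min_accept: int = 200,
    quantiles: tuple[float, float] = (0.05, 0.95),
) -> list[PosteriorSummary]:
    """Accept replicates where every zone's local maximum matches its
    empirical peak height within tolerance; member-wise posteriors as in
    the single-QTL stage.  Tolerance doubles once under starvation."""
    emp = np.asarray(empirical_heights, dtype=float)
    tol, widened = tolerance, False
    ok = np.all(np.abs(records.zone_height - emp) <= tol, axis=1)
    if int(ok.sum()) < min_accept:
        tol, widened = 2.0 * tolerance, True
        ok = np.all(np.abs(records.zone_height - emp) <= tol, axis=1)
    acc = np.flatnonzero(ok)
    out = []
    for j in range(len(records.member_windows)):
        if len(acc) == 0:
            out.append(PosteriorSummary(0, tol, widened, None, None, None, None, None))
            continue
        qlo, qhi = quantiles
        s_lo, s_hat, s_hi = np.quantile(records.member_s[acc, j], [qlo, 0.5, qhi])
        ci_lo, ci_hi = np.quantile(records.zone_cm[acc, j], [qlo, qhi])
        out.append(
            PosteriorSummary(
                len(acc), tol, widened, float(s_lo), float(s_hat), float(s_hi),
                float(ci_lo), float(ci_hi), 0, acc,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Reports and the full pipeline
# ---------------------------------------------------------------------------


@dataclass
class QTLReport:
    """Final per-peak inference: significance, location, and strength."""

    peak_id: str
    kind: str
    chrom: str
    peak_window: int
    peak_bp: int
    peak_cm: float
    pvalue: float | None
    ci_cm_lo: float | None
    ci_cm_hi: float | None
    ci_bp_lo: int | None
    ci_bp_hi: int | None
    s_hat: float | None
    s_lo: float | None
    s_hi: float | None
    stage: str
    flags: str = ""


_REPORT_COLS = [
    "peak_id", "kind", "chrom", "peak_window", "peak_bp", "peak_cm",
    "pvalue", "ci_cm_lo", "ci_cm_hi", "ci_bp_lo", "ci_bp_hi",
    "s_hat", "s_lo", "s_hi", "stage", "flags",
]


def write_report(reports: list[QTLReport], path) -> None:
    """Write the final TSV: one row per significant peak with its P-value,
    peak coordinates, genomic CI, and strength estimate with CI."""
    rows = [{c: getattr(r, c) for c in _REPORT_COLS} for r in reports]
    pd.DataFrame(rows, columns=_REPORT_COLS).to_csv(path, sep="\t", index=False)


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


@dataclass
class PipelineResult:
    reports: list[QTLReport]
    primaries: list[Peak]
    null: NullPeakDistribution
    pvalues: list[tuple[float, bool]]
    smoothed: np.ndarray


def run_pipeline(
    gmap: GenomeMap,
    ad,
    config: ExperimentConfig,
    thresholds: Thresholds = Thresholds(),
    n_null: int = 1000,
    n_single: int = 1000,
    n_cluster: int = 1000,
    alpha: float = 0.05,
    single_tolerance: float = 0.025,
    cluster_tolerance: float = 0.05,
    min_accept: int = 200,
    seed: int = 0,
    depth_high=None,
    depth_low=None,
    null: NullPeakDistribution | None = None,
) -> PipelineResult:
    """Run the full SIBSAM pipeline on one empirical a_d profile.

    Stages: smoothing and peak extraction; null-simulation significance for
    primary peaks; single-QTL rejection posteriors and secondary P-values
    for significant primaries; cluster refinement where secondaries are
    significant.  A precomputed ``null`` distribution may be supplied.
    """
    sp = smooth_profile(ad, thresholds.m, gmap)
    primaries = detect_peaks(sp, gmap, thresholds)
    if null is None:
        null = null_stage(gmap, config, thresholds, n_null, seed, depth_high, depth_low)
    emp_heights = [p.height for p in primaries]
    pvals = [primary_pvalue(p.height, emp_heights, null) for p in primaries]
    significant = [
        (p, pv) for p, pv in zip(primaries, pvals) if pv[0] < alpha
    ]
    reports: list[QTLReport] = []
    if significant:
        positions = [(p.chrom, p.window) for p, _ in significant]
        rec_list = single_qtl_stage(
            positions, gmap, config, thresholds, n_single, seed, depth_high, depth_low
        )
        for idx, ((prim, (pval, floored)), rec) in enumerate(zip(significant, rec_list)):
            c = gmap.chrom(prim.chrom)
            post = rejection_posterior(
                rec, prim.height, gmap, single_tolerance, min_accept
            )
            acc_v = rec.max_v[post.accepted] if post.accepted is not None else np.empty(0)
            sec_p = [secondary_pvalue(s.v, acc_v) for s in prim.secondaries]
            sig_secs = [
                (s, p) for s, p in zip(prim.secondaries, sec_p)
                if p is not None and p < alpha
            ]
            flags = []
            if floored:
                flags.append("pvalue_at_floor")
            if post.widened:
                flags.append("tolerance_widened")
            if post.n_accepted == 0:
                flags.append("no_accepted_replicates")
            pid = f"P{idx + 1}"
            if sig_secs:
                member_peaks = sorted([prim] + [s for s, _ in sig_secs], key=lambda p: p.window)
                wins = [p.window for p in member_peaks]
                heights = [p.height for p in member_peaks]
                crec = cluster_stage(
                    sp, gmap, prim.chrom, wins, heights, config, thresholds,
                    n_cluster, seed, depth_high, depth_low,
                )
                posts = cluster_posteriors(crec, heights, cluster_tolerance, min_accept)
                for k, (mp, mpost) in enumerate(zip(member_peaks, posts)):
                    mflags = list(flags) if mp is prim else []
                    if mpost.widened:
                        mflags.append("cluster_tolerance_widened")
                    if mpost.n_accepted == 0:
                        mflags.append("no_accepted_replicates")
                    mp_p = pval if mp is prim else dict(sec_p_map(sig_secs))[id(mp)]
                    reports.append(
                        _make_report(
                            f"{pid}.{k + 1}" if mp is not prim else pid,
                            mp, c, mp_p, mpost, "cluster", ";".join(mflags),
                        )
                    )
            else:
                reports.append(
                    _make_report(pid, prim, c, pval, post, "single", ";".join(flags))
                )
    return PipelineResult(reports, primaries, null, pvals, np.asarray(sp))


def sec_p_map(sig_secs):
    for s, p in sig_secs:
        yield id(s), p


def _make_report(pid, peak, chrom, pval, post, stage, flags) -> QTLReport:
    cm = float(chrom.cm_mid[peak.window])
    return QTLReport(
        peak_id=pid,
        kind=peak.kind,
        chrom=peak.chrom,
        peak_window=peak.window,
        peak_bp=chrom.bp_at(cm),
        peak_cm=cm,
        pvalue=pval,
        ci_cm_lo=post.ci_cm_lo,
        ci_cm_hi=post.ci_cm_hi,
        ci_bp_lo=None if post.ci_cm_lo is None else chrom.bp_at(post.ci_cm_lo),
        ci_bp_hi=None if post.ci_cm_hi is None else chrom.bp_at(post.ci_cm_hi),
        s_hat=post.s_hat,
        s_lo=post.s_lo,
        s_hi=post.s_hi,
        stage=stage,
        flags=flags,
    )
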