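"""Performance-testing harness: synthetic test replicates with known QTL
and end-to-end evaluation of the inference pipeline.

The focal test scenario mirrors a contemporary Drosophila BSA experiment:
1200 individuals interbreed for 16 generations, 600 females are phenotyped
in the last generation, 10% phenotypic tails are selected, and each window
yields 1000 informative reads per pool.  Scaled variants multiply the
population size, phenotyped count, and depth jointly by ``scale``.
Canonical single-QTL test positions correspond to the pigmentation loci
*tan* (X) and *ebony* (chromosome 3, arm 3R).

Everything here is generated programmatically — no external data — and all
randomness descends deterministically from one master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _engine
from .forward_sim import (
    EXPLORATORY,
    SIBSAM_NOISE,
    ExperimentConfig,
    QTL,
    QTLModel,
    bsa_readout,
)
from .genome_map import GenomeMap, make_synthetic_map, write_window_table
from .inference import (
    NullPeakDistribution,
    SingleQTLRecords,
    _stage_rng,
    null_stage,
    primary_pvalue,
    rejection_posterior,
    secondary_pvalue,
    single_qtl_stage,
    strength_to_effect,
)
from .peaks import Thresholds, detect_peaks, smooth_profile

__all__ = [
    "TAN_X_CM",
    "EBONY_3_CM",
    "focal_config",
    "desk_map",
    "TestScenario",
    "scenario_model",
    "generate_test_replicates",
    "write_replicate",
    "read_truth",
    "ReplicateOutcome",
    "run_test_scan",
    "null_false_positive_rate",
    "detection_power",
    "false_secondary_rate",
    "evaluate_replicate",
    "evaluate_pipeline",
    "two_qtl_secondary_fraction",
]

#: Canonical test-QTL genetic positions (classical map positions of the
#: pigmentation genes tan and ebony).
TAN_X_CM = 27.5
EBONY_3_CM = 70.7

# Harness stage ids for deterministic seed derivation (inference stages use 1-3).
_STAGE_TEST = 10


def focal_config(scale: int = 1) -> ExperimentConfig:
    """The focal BSA test scenario, optionally scaled: population size,
    phenotyped count and sequencing depth are multiplied jointly."""
    return ExperimentConfig(
        mode="bsa",
        N=1200 * scale,
        G=16,
        q=0.10,
        depth=1000 * scale,
        n_pheno=600 * scale,
        females_only=True,
    )


def desk_map(n_windows_per_chrom: int = 200, seed: int = 0) -> GenomeMap:
    """Reduced synthetic Drosophila-like map used for desk-scale runs."""
    return make_synthetic_map(n_windows_per_chrom, seed=seed)


@dataclass
class TestScenario:
    """Ground-truth QTL set plus experiment scale for test simulations.

    ``qtl`` entries are ``(chrom, cm, strength s)``; ``noise_sd = None``
    selects the standard 0.5 x N(0,1) residual noise, while an explicit
    value (possibly 0 for pure multi-QTL variance) overrides it.
    """

    qtl: list = field(default_factory=lambda: [("3", EBONY_3_CM, 0.2)])
    scale: int = 1
    n_replicates: int = 100
    seed: int = 0
    noise_sd: float | None = None

    def config(self) -> ExperimentConfig:
        return focal_config(self.scale)


def scenario_model(ts: TestScenario) -> QTLModel:
    loci = [QTL(chrom, cm, strength_to_effect(s)) for chrom, cm, s in ts.qtl]
    if ts.noise_sd is None:
        return QTLModel(loci, SIBSAM_NOISE)
    return QTLModel(loci, EXPLORATORY, noise_sd=ts.noise_sd)


def generate_test_replicates(ts: TestScenario, gmap: GenomeMap, stage: int = _STAGE_TEST):
    """Yield ``(replicate_index, ad_profile)`` for a test scenario."""
    config = ts.config()
    model = scenario_model(ts)
    for r in range(ts.n_replicates):
        rng = _stage_rng(ts.seed, stage, r)
        pop = _engine.simulate_population(gmap, config.N, config.G, rng)
        yield r, bsa_readout(pop, config, model, rng).ad


def write_replicate(prefix, gmap: GenomeMap, ad, ts: TestScenario) -> None:
    """Write one replicate as a window table plus a truth JSON sidecar."""
    config = ts.config()
    depths = np.full(gmap.n_windows, config.depth)
    write_window_table(
        f"{prefix}.tsv", gmap, {"ad": ad, "depth_high": depths, "depth_low": depths}
    )
    truth = {
        "qtl": [list(q) for q in ts.qtl],
        "scale": ts.scale,
        "seed": ts.seed,
        "noise_sd": ts.noise_sd,
    }
    with open(f"{prefix}.truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)


def read_truth(path) -> dict:
    with open(path) as fh:
        truth = json.load(fh)
    truth["qtl"] = [tuple(q) for q in truth["qtl"]]
    return truth


# ---------------------------------------------------------------------------
# Scan evaluation
# ---------------------------------------------------------------------------


@dataclass
class ReplicateOutcome:
    """Significance scan of one test replicate against a null distribution."""

    detected: bool
    peak_chrom: str | None = None
    peak_window: int | None = None
    peak_cm: float | None = None
    peak_height: float | None = None
    secondary_vs: list = field(default_factory=list)


def run_test_scan(
    ad,
    gmap: GenomeMap,
    thresholds: Thresholds,
    null: NullPeakDistribution,
    alpha: float = 0.05,
    zone=None,
) -> ReplicateOutcome:
    """Smooth, call peaks, and test primaries against the null.

    ``zone`` is an optional ``(chrom, cm_lo, cm_hi)`` truth zone; detection
    then requires a significant primary peak inside it, and the outcome
    describes the tallest such peak.  Without a zone, any significant
    primary counts.
    """
    sp = smooth_profile(ad, thresholds.m, gmap)
    prims = detect_peaks(sp, gmap, thresholds)
    heights = [p.height for p in prims]
    sig = [p for p in prims if primary_pvalue(p.height, heights, null)[0] < alpha]
    if zone is not None:
        chrom, lo, hi = zone
        c = gmap.chrom(chrom)
        sig = [
            p
            for p in sig
            if p.chrom == chrom and lo <= float(c.cm_mid[p.window]) <= hi
        ]
    if not sig:
        return ReplicateOutcome(False)
    best = max(sig, key=lambda p: p.height)
    c = gmap.chrom(best.chrom)
    return ReplicateOutcome(
        True,
        best.chrom,
        best.window,
        float(c.cm_mid[best.window]),
        best.height,
        [s.v for s in best.secondaries],
    )


def truth_zone(chrom: str, cm: float, gmap: GenomeMap, halfwidth_cm: float = 15.0):
    c = gmap.chrom(chrom)
    return (chrom, max(0.0, cm - halfwidth_cm), min(c.total_cm, cm + halfwidth_cm))


def null_false_positive_rate(
    gmap: GenomeMap,
    config: ExperimentConfig,
    thresholds: Thresholds,
    n_null: int,
    n_test: int,
    alpha: float = 0.05,
    seed: int = 0,
    null: NullPeakDistribution | None = None,
):
    """Fraction (%) of independent no-QTL replicates in which the
    null-comparison procedure declares at least one significant primary
    peak anywhere in the genome."""
    if null is None:
        null = null_stage(gmap, config, thresholds, n_null, seed)
    ts = TestScenario(qtl=[], n_replicates=n_test, seed=seed)
    hits = 0
    for _, ad in _replicates_with_config(ts, gmap, config):
        if run_test_scan(ad, gmap, thresholds, null, alpha).detected:
            hits += 1
    return 100.0 * hits / n_test, null


def _replicates_with_config(ts: TestScenario, gmap, config, stage: int = _STAGE_TEST):
    model = scenario_model(ts)
    for r in range(ts.n_replicates):
        rng = _stage_rng(ts.seed, stage, r)
        pop = _engine.simulate_population(gmap, config.N, config.G, rng)
        yield r, bsa_readout(pop, config, model, rng).ad


def detection_power(
    ts: TestScenario,
    gmap: GenomeMap,
    thresholds: Thresholds,
    null: NullPeakDistribution,
    alpha: float = 0.05,
    zone_halfwidth_cm: float = 15.0,
    stage: int = _STAGE_TEST + 1,
):
    """Power (%) to place a significant primary peak in the truth zone of
    the scenario's first QTL; also returns the per-replicate outcomes."""
    chrom, cm, _ = ts.qtl[0]
    zone = truth_zone(chrom, cm, gmap, zone_halfwidth_cm)
    outcomes = []
    for _, ad in _replicates_with_config(ts, gmap, ts.config(), stage):
        outcomes.append(run_test_scan(ad, gmap, thresholds, null, alpha, zone))
    power = 100.0 * np.mean([o.detected for o in outcomes])
    return float(power), outcomes


def false_secondary_rate(
    outcomes: list[ReplicateOutcome],
    pool: SingleQTLRecords,
    gmap: GenomeMap,
    tolerance: float = 0.025,
    min_accept: int = 200,
    alpha: float = 0.05,
):
    """Among detected primaries, the fraction (%) with any secondary peak
    at P < alpha under the single-QTL rejection stage (using a shared
    prior-simulation pool)."""
    detected = [o for o in outcomes if o.detected]
    if not detected:
        return float("nan"), 0
    n_false = 0
    for o in detected:
        post = rejection_posterior(
            pool, o.peak_height, gmap, tolerance, min_accept, empirical_cm=o.peak_cm
        )
        acc_v = pool.max_v[post.accepted] if post.accepted is not None else np.empty(0)
        pvals = [secondary_pvalue(v, acc_v) for v in o.secondary_vs]
        if any(p is not None and p < alpha for p in pvals):
            n_false += 1
    return 100.0 * n_false / len(detected), len(detected)


def evaluate_replicate(
    outcome: ReplicateOutcome,
    pool: SingleQTLRecords,
    gmap: GenomeMap,
    tolerance: float = 0.025,
    min_accept: int = 200,
    alpha: float = 0.05,
):
    """Full single-QTL inference for one detected replicate: strength
    posterior, genomic CI, and secondary significance."""
    if not outcome.detected:
        return None
    post = rejection_posterior(
        pool, outcome.peak_height, gmap, tolerance, min_accept,
        empirical_cm=outcome.peak_cm,
    )
    acc_v = pool.max_v[post.accepted] if post.accepted is not None else np.empty(0)
    sec_p = [secondary_pvalue(v, acc_v) for v in outcome.secondary_vs]
    return {
        "s_hat": post.s_hat,
        "s_lo": post.s_lo,
        "s_hi": post.s_hi,
        "ci_cm_lo": post.ci_cm_lo,
        "ci_cm_hi": post.ci_cm_hi,
        "any_false_secondary": any(p is not None and p < alpha for p in sec_p),
    }


def evaluate_pipeline(evaluations, true_s: float, true_cm: float) -> dict:
    """Aggregate per-replicate evaluations into the four performance
    measures: detection power, false-secondary rate, median strength
    estimate, and strength/genomic CI coverage (all in %, coverage and
    rates among detected replicates)."""
    n = len(evaluations)
    detected = [e for e in evaluations if e is not None]
    out = {"power": 100.0 * len(detected) / n if n else float("nan")}
    if detected:
        out["false_secondary_rate"] = 100.0 * np.mean(
            [e["any_false_secondary"] for e in detected]
        )
        s_hats = [e["s_hat"] for e in detected if e["s_hat"] is not None]
        out["median_s_hat"] = 100.0 * float(np.median(s_hats)) if s_hats else float("nan")
        cov_s = [
            e["s_lo"] <= true_s <= e["s_hi"]
            for e in detected
            if e["s_lo"] is not None
        ]
        out["strength_ci_coverage"] = 100.0 * np.mean(cov_s) if cov_s else float("nan")
        cov_g = [
            e["ci_cm_lo"] <= true_cm <= e["ci_cm_hi"]
            for e in detected
            if e["ci_cm_lo"] is not None
        ]
        out["genomic_ci_coverage"] = 100.0 * np.mean(cov_g) if cov_g else float("nan")
    return out


def shared_single_qtl_pool(
    gmap: GenomeMap,
    config: ExperimentConfig,
    thresholds: Thresholds,
    n_reps: int,
    seed: int,
    chrom: str = "3",
    cm: float = EBONY_3_CM,
) -> SingleQTLRecords:
    """Single-QTL prior simulations at the canonical test position, shared
    across test replicates (nearby windows of the synthetic map are
    statistically exchangeable)."""
    window = gmap.chrom(chrom).window_at(cm)
    return single_qtl_stage([(chrom, window)], gmap, config, thresholds, n_reps, seed)[0]


def two_qtl_secondary_fraction(
    gmap: GenomeMap,
    config: ExperimentConfig,
    thresholds: Thresholds,
    s_pair=(0.15, 0.15),
    separation_cm: float = 25.0,
    chrom: str = "3",
    center_cm: float = EBONY_3_CM,
    n_reps: int = 200,
    seed: int = 0,
    stage: int = _STAGE_TEST + 2,
):
    """Fraction (%) of two-linked-QTL replicates in which one true QTL is
    expressed as a secondary peak of the other's primary.

    The two QTL straddle ``center_cm`` at the given separation; each QTL's
    zone extends half the separation around its true position, and a
    replicate counts when a primary peak sits in one zone while one of its
    secondary peaks sits in the other.
    """
    half = separation_cm / 2.0
    c = gmap.chrom(chrom)
    cm1, cm2 = center_cm - half, center_cm + half
    if not (0 <= cm1 and cm2 <= c.total_cm):
        raise ValueError("linked pair does not fit on the chromosome")
    ts = TestScenario(
        qtl=[(chrom, cm1, s_pair[0]), (chrom, cm2, s_pair[1])],
        n_replicates=n_reps,
        seed=seed,
    )
    zones = [(cm1 - half, cm1 + half), (cm2 - half, cm2 + half)]

    def in_zone(cm, z):
        return z[0] <= cm <= z[1]

    hits = 0
    for _, ad in _replicates_with_config(ts, gmap, config, stage):
        sp = smooth_profile(ad, thresholds.m, gmap)
        prims = detect_peaks(sp, gmap, thresholds)
        found = False
        for p in prims:
            if p.chrom != chrom:
                continue
            pcm = float(c.cm_mid[p.window])
            for za, zb in ((zones[0], zones[1]), (zones[1], zones[0])):
                if in_zone(pcm, za) and any(
                    in_zone(float(c.cm_mid[s.window]), zb) for s in p.secondaries
                ):
                    found = True
        hits += found
    return 100.0 * hits / n_reps
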