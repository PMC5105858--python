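"""Smoothing and peak identification on ancestry-difference profiles.

A *primary peak* is the window with the highest smoothed a_d within a
maximal run of consecutive windows with a_d > 0 (zero being the expected
value in the absence of causative loci), conditional on that maximum
exceeding the height threshold ``a_dt``.  *Secondary peaks* are other local
maxima within the same run, found by scanning outward from the primary:
a recovery of more than ``v_t`` above the running minimum since the last
peak opens a secondary peak, and a drop of more than ``v_t`` below its
running maximum closes it.

Each secondary peak carries a *secondary deviation* ``v``: its height minus
the relevant valley toward the primary peak (or a taller secondary peak,
whichever valley is higher).  Taller peaks are assigned first, so that a
short secondary sandwiched between the primary and a taller secondary is
judged against the higher of the valleys on either side of it — this
prevents a short nearby peak from absorbing the deviation that properly
belongs to a taller peak beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_map import GenomeMap

__all__ = [
    "Thresholds",
    "SmoothedProfile",
    "Peak",
    "smooth_profile",
    "find_primary_peaks",
    "find_secondary_peaks",
    "assign_secondary_deviations",
    "detect_peaks",
]


@dataclass(frozen=True)
class Thresholds:
    """Peak-calling thresholds: primary height ``a_dt``, secondary
    deviation ``v_t`` (both default 0.1) and smoothing half-width ``m``
    (default 4 flanking windows per side)."""

    a_dt: float = 0.1
    v_t: float = 0.1
    m: int = 4

    def __post_init__(self) -> None:
        if self.a_dt <= 0 or self.v_t <= 0:
            raise ValueError("a_dt and v_t must be positive")
        if self.m < 0:
            raise ValueError("m must be >= 0")


@dataclass
class SmoothedProfile:
    """A smoothed per-window profile (genome-flat) with its half-width."""

    values: np.ndarray
    m: int

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def triangular_weights(m: int) -> np.ndarray:
    """Weights m+1 at the focal window declining linearly to 1 at the mth
    flanking window on each side."""
    return np.concatenate([np.arange(1, m + 1), [m + 1], np.arange(m, 0, -1)]).astype(float)


def smooth_profile(values, m: int = 4, gmap: GenomeMap | None = None) -> SmoothedProfile:
    """Triangular-weighted moving average, confined within chromosomes.

    At chromosome edges the missing flank is dropped and the weights are
    renormalized over the available windows, so a constant profile stays
    constant everywhere.  ``m = 0`` is the identity.
    """
    x = np.asarray(values, dtype=float)
    if m == 0:
        return SmoothedProfile(x.copy(), 0)
    w = triangular_weights(m)
    slices = gmap.slices() if gmap is not None else [slice(0, len(x))]
    out = np.empty_like(x)
    for sl in slices:
        seg = x[sl]
        # full convolution sliced to the centered window; robust when the
        # segment is shorter than the kernel
        num = np.convolve(seg, w)[m : m + len(seg)]
        den = np.convolve(np.ones_like(seg), w)[m : m + len(seg)]
        out[sl] = num / den
    return SmoothedProfile(out, m)


@dataclass
class Peak:
    """A primary or secondary local maximum of the smoothed profile."""

    kind: str
    chrom: str
    window: int          # per-chromosome window index of the maximum
    height: float
    run_start: int = 0   # per-chromosome [run_start, run_end) of the a_d > 0 run
    run_end: int = 0
    side: int = 0        # secondary: -1 left of primary, +1 right
    v: float | None = None
    parent: "Peak | None" = None
    secondaries: list = field(default_factory=list)

    def __repr__(self) -> str:  # compact, avoids recursing through parent
        extra = f", v={self.v:.4g}" if self.v is not None else ""
        return (
            f"Peak({self.kind}, chrom={self.chrom}, window={self.window}, "
            f"height={self.height:.4g}{extra})"
        )


def _positive_runs(x: np.ndarray):
    """Maximal [start, end) runs of strictly positive values."""
    pos = np.concatenate([[0], (x > 0).astype(np.int8), [0]])
    d = np.diff(pos)
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def find_primary_peaks(
    smoothed, gmap: GenomeMap, thresholds: Thresholds = Thresholds()
) -> list[Peak]:
    """One primary peak per maximal run of windows with smoothed a_d > 0
    whose maximum exceeds ``a_dt``; argmax ties break to the lowest index.
    Runs never span chromosomes."""
    x = np.asarray(smoothed)
    peaks = []
    for c, sl in zip(gmap.chromosomes, gmap.slices()):
        seg = x[sl]
        for start, end in _positive_runs(seg):
            imax = int(start + np.argmax(seg[start:end]))
            h = float(seg[imax])
            if h > thresholds.a_dt:
                peaks.append(
                    Peak("primary", c.label, imax, h, run_start=int(start), run_end=int(end))
                )
    return peaks


def _scan_side(seg: np.ndarray, start: int, stop: int, step: int, v_t: float):
    """Open/close scan for secondary peaks on one side of the primary.

    ``seg`` is the chromosome profile, scanning from ``start`` (the primary
    window, exclusive) toward ``stop`` (exclusive bound of the run).
    Both the opening recovery and the closing drop are strict (> v_t);
    a peak still open when the run ends is closed and recorded there.
    """
    found = []
    run_min = seg[start]
    open_max = None
    open_idx = None
    i = start + step
    while (step > 0 and i < stop) or (step < 0 and i > stop):
        v = seg[i]
        if open_max is None:
            run_min = min(run_min, v)
            if v - run_min > v_t:
                open_max, open_idx = v, i
        else:
            if v > open_max:
                open_max, open_idx = v, i
            elif open_max - v > v_t:
                found.append((int(open_idx), float(open_max)))
                open_max = None
                run_min = v
        i += step
    if open_max is not None:
        found.append((int(open_idx), float(open_max)))
    return found


def find_secondary_peaks(
    smoothed, gmap: GenomeMap, primary: Peak, thresholds: Thresholds = Thresholds()
) -> list[Peak]:
    """Secondary peaks within the primary's run, on both flanks.

    Returned peaks carry their side and raw height; deviations ``v`` are
    assigned afterwards by :func:`assign_secondary_deviations` (which
    implements the taller-peak priority) and peaks with adjusted
    ``v <= v_t`` are dropped there.
    """
    x = np.asarray(smoothed)
    sl = gmap.slices()[gmap.chrom_index(primary.chrom)]
    seg = x[sl]
    out = []
    for side, stop in ((-1, primary.run_start - 1), (1, primary.run_end)):
        for idx, h in _scan_side(seg, primary.window, stop, side, thresholds.v_t):
            out.append(
                Peak(
                    "secondary",
                    primary.chrom,
                    idx,
                    h,
                    run_start=primary.run_start,
                    run_end=primary.run_end,
                    side=side,
                    parent=primary,
                )
            )
    return out


def _valley(seg: np.ndarray, i: int, j: int) -> float:
    """Minimum strictly between two windows; adjacent peaks have no dip,
    giving a valley equal to the lower peak (hence v = 0)."""
    lo, hi = (i, j) if i < j else (j, i)
    inner = seg[lo + 1 : hi]
    if len(inner) == 0:
        return float(min(seg[lo], seg[hi]))
    return float(inner.min())


def assign_secondary_deviations(
    smoothed, gmap: GenomeMap, primary: Peak, secondaries: list[Peak]
) -> None:
    """Assign each secondary peak its deviation ``v``, tallest first.

    The tallest secondary on a side is judged against the lowest value
    between itself and the primary peak (even across shorter secondaries).
    A shorter secondary lying between taller peaks takes the higher of the
    valleys on either side of it; a secondary with no taller peak on its
    outer side uses only its inner valley.
    """
    x = np.asarray(smoothed)
    seg = x[gmap.slices()[gmap.chrom_index(primary.chrom)]]
    anchors = [primary.window]
    order = sorted(secondaries, key=lambda p: (-p.height, abs(p.window - primary.window)))
    for pk in order:
        left = [a for a in anchors if a < pk.window]
        right = [a for a in anchors if a > pk.window]
        valleys = []
        if left:
            valleys.append(_valley(seg, max(left), pk.window))
        if right:
            valleys.append(_valley(seg, min(right), pk.window))
        pk.v = pk.height - max(valleys)
        anchors.append(pk.window)


def secondary_deviation(smoothed, gmap, primary, secondary, all_secondaries) -> float:
    """Deviation of one secondary peak under the taller-first rules."""
    assign_secondary_deviations(smoothed, gmap, primary, list(all_secondaries))
    return secondary.v


def detect_peaks(
    smoothed, gmap: GenomeMap, thresholds: Thresholds = Thresholds()
) -> list[Peak]:
    """Full peak extraction: primary peaks with attached secondary peaks
    (adjusted deviations, filtered to v > v_t)."""
    primaries = find_primary_peaks(smoothed, gmap, thresholds)
    for prim in primaries:
        secs = find_secondary_peaks(smoothed, gmap, prim, thresholds)
        assign_secondary_deviations(smoothed, gmap, prim, secs)
        prim.secondaries = sorted(
            (s for s in secs if s.v is not None and s.v > thresholds.v_t),
            key=lambda p: p.window,
        )
    return primaries
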