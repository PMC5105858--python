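"""Windowed genome maps for BSA/IM simulation and inference.

A :class:`GenomeMap` holds, per chromosome, an ordered set of contiguous
genomic windows with both physical (bp) and genetic (cM) coordinates.  The
genetic coordinate is what drives recombination in the simulator; the
physical coordinate is only carried through for reporting.  Windows are
half-open ``[start, end)`` in both coordinate systems (0-based internally,
1-based bp in files); the last window of a chromosome is closed on the
right so that every genetic position in ``[0, total_cM]`` maps to a window.

The module also ships a synthetic map generator emulating a Drosophila-like
genome (chromosomes X, 2 and 3; variable cM per window) so that the entire
pipeline can run without any external data, and readers/writers for the
plain TSV window-table format used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Window",
    "Chromosome",
    "GenomeMap",
    "DROSOPHILA_CHROMS",
    "make_synthetic_map",
    "load_window_table",
    "write_window_table",
]

#: Shipped defaults approximating D. melanogaster: (label, is_x, total cM, total bp).
#: Genetic lengths are explicit configuration, not biological constants.
DROSOPHILA_CHROMS = (
    ("X", True, 73.0, 23_000_000),
    ("2", False, 108.0, 48_000_000),
    ("3", False, 110.0, 52_000_000),
)


@dataclass(frozen=True)
class Window:
    """One genomic window (half-open in bp and cM)."""

    chrom: str
    phys_start: int
    phys_end: int
    cm_start: float
    cm_end: float
    index: int

    def __post_init__(self) -> None:
        if self.phys_end <= self.phys_start:
            raise ValueError(f"window {self.chrom}:{self.index}: phys_end <= phys_start")
        if self.cm_end < self.cm_start:
            raise ValueError(f"window {self.chrom}:{self.index}: cm_end < cm_start")

    @property
    def cm_mid(self) -> float:
        return 0.5 * (self.cm_start + self.cm_end)

    @property
    def phys_mid(self) -> int:
        return (self.phys_start + self.phys_end) // 2


@dataclass
class Chromosome:
    """Ordered, contiguous windows of one chromosome (struct-of-arrays)."""

    label: str
    is_x: bool
    phys_start: np.ndarray
    phys_end: np.ndarray
    cm_start: np.ndarray
    cm_end: np.ndarray

    def __post_init__(self) -> None:
        for name in ("phys_start", "phys_end"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        for name in ("cm_start", "cm_end"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        n = len(self.phys_start)
        if n == 0:
            raise ValueError(f"chromosome {self.label}: zero windows")
        if not (len(self.phys_end) == len(self.cm_start) == len(self.cm_end) == n):
            raise ValueError(f"chromosome {self.label}: ragged window arrays")
        if np.any(self.phys_end <= self.phys_start):
            raise ValueError(f"chromosome {self.label}: non-positive physical span")
        if np.any(self.cm_end < self.cm_start):
            raise ValueError(f"chromosome {self.label}: cm_end < cm_start")
        if np.any(np.diff(self.cm_start) < 0) or np.any(self.cm_start[1:] != self.cm_end[:-1]):
            raise ValueError(f"chromosome {self.label}: windows not contiguous/sorted in cM")

    @property
    def n_windows(self) -> int:
        return len(self.cm_start)

    @property
    def total_cm(self) -> float:
        return float(self.cm_end[-1])

    @property
    def cm_mid(self) -> np.ndarray:
        return 0.5 * (self.cm_start + self.cm_end)

    def window_at(self, cm_pos: float) -> int:
        """Index of the window containing ``cm_pos`` ([start, end); last closed-right)."""
        if not (0.0 <= cm_pos <= self.total_cm):
            raise ValueError(
                f"position {cm_pos} cM outside chromosome {self.label} "
                f"[0, {self.total_cm}]"
            )
        idx = int(np.searchsorted(self.cm_start, cm_pos, side="right")) - 1
        return min(max(idx, 0), self.n_windows - 1)

    def bp_at(self, cm_pos: float) -> int:
        """Physical position interpolated linearly within the containing window."""
        i = self.window_at(cm_pos)
        c0, c1 = self.cm_start[i], self.cm_end[i]
        frac = 0.0 if c1 == c0 else (cm_pos - c0) / (c1 - c0)
        return int(round(self.phys_start[i] + frac * (self.phys_end[i] - self.phys_start[i])))

    def windows(self):
        for i in range(self.n_windows):
            yield Window(
                self.label,
                int(self.phys_start[i]),
                int(self.phys_end[i]),
                float(self.cm_start[i]),
                float(self.cm_end[i]),
                i,
            )


@dataclass
class GenomeMap:
    """An ordered collection of chromosomes; at most one flagged as X."""

    chromosomes: list[Chromosome] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sum(c.is_x for c in self.chromosomes) > 1:
            raise ValueError("at most one chromosome may be flagged as X")
        labels = [c.label for c in self.chromosomes]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate chromosome labels")

    @property
    def n_windows(self) -> int:
        return sum(c.n_windows for c in self.chromosomes)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.chromosomes]

    @property
    def offsets(self) -> np.ndarray:
        """Start offset of each chromosome in genome-flat window indexing."""
        return np.concatenate([[0], np.cumsum([c.n_windows for c in self.chromosomes])])

    def chrom(self, label: str) -> Chromosome:
        for c in self.chromosomes:
            if c.label == label:
                return c
        raise KeyError(f"no chromosome labelled {label!r}")

    def chrom_index(self, label: str) -> int:
        for i, c in enumerate(self.chromosomes):
            if c.label == label:
                return i
        raise KeyError(f"no chromosome labelled {label!r}")

    def window_at(self, label: str, cm_pos: float) -> int:
        """Per-chromosome window index containing a genetic position."""
        return self.chrom(label).window_at(cm_pos)

    def flat_index(self, label: str, window: int) -> int:
        ci = self.chrom_index(label)
        return int(self.offsets[ci]) + window

    def slices(self) -> list[slice]:
        off = self.offsets
        return [slice(int(off[i]), int(off[i + 1])) for i in range(len(self.chromosomes))]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for c in self.chromosomes:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": c.label,
                        "phys_start": c.phys_start,
                        "phys_end": c.phys_end,
                        "cm_start": c.cm_start,
                        "cm_end": c.cm_end,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, GenomeMap):
            return NotImplemented
        if self.labels != other.labels:
            return False
        for a, b in zip(self.chromosomes, other.chromosomes):
            if a.is_x != b.is_x or a.n_windows != b.n_windows:
                return False
            if not (
                np.array_equal(a.phys_start, b.phys_start)
                and np.array_equal(a.phys_end, b.phys_end)
                and np.allclose(a.cm_start, b.cm_start)
                and np.allclose(a.cm_end, b.cm_end)
            ):
                return False
        return True


def make_synthetic_map(
    n_windows_per_chrom=200,
    chroms=DROSOPHILA_CHROMS,
    seed: int = 0,
    concentration: float = 3.0,
) -> GenomeMap:
    """Generate a synthetic windowed map with variable cM-per-window.

    Window genetic widths are drawn as symmetric Dirichlet shares of each
    chromosome's total genetic length, emulating heterogeneous recombination
    along real chromosomes; physical spans get proportional widths with
    independent jitter.  Deterministic under a fixed ``seed``.

    Parameters
    ----------
    n_windows_per_chrom
        Either a single count applied to every chromosome or a sequence of
        per-chromosome counts.
    chroms
        Iterable of ``(label, is_x, total_cM, total_bp)``.
    concentration
        Dirichlet concentration; larger values give more even windows.
    """
    chroms = list(chroms)
    if np.isscalar(n_windows_per_chrom):
        counts = [int(n_windows_per_chrom)] * len(chroms)
    else:
        counts = [int(n) for n in n_windows_per_chrom]
    if len(counts) != len(chroms):
        raise ValueError("n_windows_per_chrom length does not match chromosomes")
    if any(n <= 0 for n in counts):
        raise ValueError("window counts must be positive")

    rng = np.random.default_rng(seed)
    out = []
    for (label, is_x, total_cm, total_bp), n in zip(chroms, counts):
        if total_cm <= 0 or total_bp <= 0:
            raise ValueError(f"chromosome {label}: non-positive length")
        cm_w = rng.dirichlet(np.full(n, concentration)) * total_cm
        cm_edges = np.concatenate([[0.0], np.cumsum(cm_w)])
        cm_edges[-1] = total_cm  # exact conservation despite float rounding
        bp_w = rng.dirichlet(np.full(n, 4.0 * concentration)) * total_bp
        bp_w = np.maximum(np.round(bp_w).astype(np.int64), 1)
        bp_edges = np.concatenate([[0], np.cumsum(bp_w)])
        out.append(
            Chromosome(
                label=label,
                is_x=is_x,
                phys_start=bp_edges[:-1],
                phys_end=bp_edges[1:],
                cm_start=cm_edges[:-1],
                cm_end=cm_edges[1:],
            )
        )
    return GenomeMap(out)


_BSA_COLUMNS = ["chrom", "phys_start", "phys_end", "cm_start", "cm_end", "ad", "depth_high", "depth_low"]
_IM_COLUMNS = ["chrom", "phys_start", "phys_end", "cm_start", "cm_end", "ap", "depth"]


def write_window_table(path, gmap: GenomeMap, values=None, mode: str = "bsa") -> None:
    """Write a window table TSV (1-based bp in the file).

    ``values`` is an optional dict of genome-flat arrays.  BSA tables carry
    ``ad``/``depth_high``/``depth_low`` columns, IM tables ``ap``/``depth``;
    missing value columns are written as zeros.
    """
    df = gmap.to_frame()
    df["phys_start"] = df["phys_start"] + 1  # 1-based, closed start in files
    cols = _BSA_COLUMNS if mode == "bsa" else _IM_COLUMNS
    values = values or {}
    for col in cols[5:]:
        df[col] = np.asarray(values.get(col, np.zeros(len(df))))
    x_labels = ",".join(c.label for c in gmap.chromosomes if c.is_x)
    with open(path, "w") as fh:
        fh.write(f"# sibsam window table; mode={mode}; x={x_labels}\n")
        df[cols].to_csv(fh, sep="\t", index=False)


def load_window_table(path, mode: str | None = None):
    """Read a window table TSV into a :class:`GenomeMap` plus value columns.

    Returns ``(gmap, values)`` where ``values`` is a DataFrame of the
    non-coordinate columns (``ad`` and per-pool depths for BSA; ``ap`` and
    ``depth`` for IM), indexed genome-flat in file order.

    Raises
    ------
    ValueError
        On malformed rows (naming the offending line) or non-monotone cM.
    """
    x_labels: set[str] = set()
    with open(path) as fh:
        header_comments = []
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            header_comments.append(line)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        try:
            df = pd.read_csv(fh, sep="\t", comment="#")
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise ValueError(f"{path}: cannot parse window table: {exc}") from exc
    for c in header_comments:
        if "x=" in c:
            x_labels = {s for s in c.split("x=")[-1].strip().split(",") if s}

    if mode is None:
        mode = "im" if "ap" in df.columns else "bsa"
    cols = _BSA_COLUMNS if mode == "bsa" else _IM_COLUMNS
    missing = [c for c in cols[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in ("phys_start", "phys_end"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{path}: malformed {col} at data row {row + 1}")
        df[col] = df[col].astype(np.int64)
    for col in ("cm_start", "cm_end"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{path}: malformed {col} at data row {row + 1}")
        df[col] = df[col].astype(np.float64)

    chroms = []
    for label, sub in df.groupby("chrom", sort=False):
        cm_start = sub["cm_start"].to_numpy()
        drops = np.flatnonzero(np.diff(cm_start) < 0)
        if len(drops):
            row = int(sub.index[drops[0] + 1])
            raise ValueError(
                f"{path}: cm_start decreases at data row {row + 1} (chromosome {label})"
            )
        try:
            chroms.append(
                Chromosome(
                    label=str(label),
                    is_x=str(label) in x_labels,
                    phys_start=sub["phys_start"].to_numpy() - 1,
                    phys_end=sub["phys_end"].to_numpy(),
                    cm_start=cm_start,
                    cm_end=sub["cm_end"].to_numpy(),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    gmap = GenomeMap(chroms)
    value_cols = [c for c in df.columns if c not in cols[:5]]
    return gmap, df[value_cols].reset_index(drop=True)
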