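"""Sliding-window screening of MNP markers from a multi-sample SNP matrix.

An MNP (multiple nucleotide polymorphism) marker is a short genomic window
(130 bp by default) whose joint SNP haplotype acts as a multi-allelic
fingerprint locus. A window's discriminative power is

    DP = t / C(N, 2)

where N is the number of samples and t the number of unordered sample
pairs that the window tells apart — a pair counts only if it differs at
two or more dispersed SNP positions inside the window (both samples called
at both positions). Windows with DP above a strict threshold (0.4 by
default) are candidates for the marker panel.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Symbol for a missing allele call.
MISSING = "."


@dataclass
class SnpMatrix:
    """Per-position, per-sample allele symbols on one reference contig.

    ``alleles`` is a (P positions × N samples) array of single characters:
    A/C/G/T, IUPAC ambiguity codes for heterozygous (dikaryotic) calls, or
    ``.`` for missing. Positions are 0-based and strictly increasing.
    """

    contig: str
    positions: np.ndarray  # (P,) int64, 0-based, strictly increasing
    alleles: np.ndarray  # (P, N) '<U1'
    samples: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype="<U1")
        if self.alleles.ndim != 2 or self.alleles.shape != (len(self.positions), len(self.samples)):
            raise ValueError(
                f"alleles shape {self.alleles.shape} inconsistent with "
                f"{len(self.positions)} positions × {len(self.samples)} samples"
            )
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None


@dataclass
class Window:
    """A scored candidate window; ``dp == t / C(N, 2)`` exactly."""

    contig: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    t: int
    dp: float
    marker_id: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Window") -> bool:
        return self.contig == other.contig and self.start < other.end and other.start < self.end


@dataclass
class MarkerPanel:
    """Ordered, pairwise non-overlapping selection of marker windows."""

    markers: list[Window]
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.markers)

    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]


def pair_distinguished(
    matrix: SnpMatrix,
    window: tuple[int, int],
    pair: tuple[str, str],
    min_separation: int = 1,
) -> bool:
    """Whether a window tells a sample pair apart.

    True iff there are at least two positions inside ``[start, end)`` at
    which both samples are non-missing and their alleles differ, with the
    two positions at least ``min_separation`` bp apart (the default of 1
    accepts any two distinct positions). Positions where either sample is
    missing never count.
    """
    i = matrix.sample_index(pair[0])
    j = matrix.sample_index(pair[1])
    start, end = window
    lo, hi = np.searchsorted(matrix.positions, [start, end])
    a = matrix.alleles[lo:hi, i]
    b = matrix.alleles[lo:hi, j]
    diff = (a != b) & (a != MISSING) & (b != MISSING)
    if int(diff.sum()) < 2:
        return False
    pos = matrix.positions[lo:hi][diff]
    return int(pos[-1] - pos[0]) >= min_separation


def window_dp(matrix: SnpMatrix, window: tuple[int, int], min_separation: int = 1) -> Window:
    """Score one window: count distinguishing pairs t and DP = t/C(N,2)."""
    n = matrix.n_samples
    if n < 2:
        raise ValueError("window_dp requires at least 2 samples")
    t = 0
    for a, b in itertools.combinations(matrix.samples, 2):
        if pair_distinguished(matrix, window, (a, b), min_separation):
            t += 1
    n_pairs = n * (n - 1) // 2
    return Window(contig=matrix.contig, start=window[0], end=window[1], t=t, dp=t / n_pairs)


def _pair_diff_matrix(matrix: SnpMatrix) -> np.ndarray:
    """(P × n_pairs) boolean: pair differs, both called, at each position."""
    alle = matrix.alleles
    called = alle != MISSING
    idx_i, idx_j = np.triu_indices(matrix.n_samples, k=1)
    return (alle[:, idx_i] != alle[:, idx_j]) & called[:, idx_i] & called[:, idx_j]


def scan_windows(
    matrix: SnpMatrix,
    contig_length: int,
    window: int = 130,
    step: int = 10,
    min_separation: int = 1,
    keep_empty: bool = True,
) -> list[Window]:
    """Score every sliding window ``[k*step, k*step + window)`` on the contig.

    Emits ``floor((contig_length - window)/step) + 1`` windows. Windows with
    no SNP positions get DP = 0 and are suppressed when ``keep_empty`` is
    False. The default ``min_separation=1`` uses an O(1)-per-window prefix-sum
    path; larger separations fall back to the direct per-window count.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if contig_length < window:
        raise ValueError(f"contig_length {contig_length} shorter than window {window}")
    n = matrix.n_samples
    if n < 2:
        raise ValueError("scan_windows requires at least 2 samples")
    n_pairs = n * (n - 1) // 2
    starts = np.arange(0, contig_length - window + 1, step, dtype=np.int64)

    diff = _pair_diff_matrix(matrix)  # (P, n_pairs)
    # prefix[k] = number of differing positions among the first k SNP rows
    prefix = np.zeros((diff.shape[0] + 1, n_pairs), dtype=np.int32)
    np.cumsum(diff, axis=0, out=prefix[1:])

    lo = np.searchsorted(matrix.positions, starts)
    hi = np.searchsorted(matrix.positions, starts + window)

    fast = min_separation <= 1
    out: list[Window] = []
    for s, l, h in zip(starts, lo, hi):
        if h == l:
            if keep_empty:
                out.append(Window(matrix.contig, int(s), int(s + window), 0, 0.0))
            continue
        if fast:
            counts = prefix[h] - prefix[l]
            t = int(np.count_nonzero(counts >= 2))
            w = Window(matrix.contig, int(s), int(s + window), t, t / n_pairs)
        else:
            w = window_dp(matrix, (int(s), int(s + window)), min_separation)
        out.append(w)
    return out


def select_panel(
    windows: list[Window],
    dp_min: float = 0.4,
    max_markers: int | None = None,
) -> MarkerPanel:
    """Greedy non-overlapping selection of high-DP windows into a panel.

    Candidates are windows with DP strictly above ``dp_min``. They are
    visited in order of (DP descending, start ascending, contig ascending);
    a candidate overlapping an already-selected marker is discarded.
    Selection stops at ``max_markers`` (None or 0 = unbounded). Marker ids
    ``M0001, M0002, ...`` are assigned in genomic order after selection.
    """
    candidates = sorted(
        (w for w in windows if w.dp > dp_min),
        key=lambda w: (-w.dp, w.start, w.contig),
    )
    selected: list[Window] = []
    limit = max_markers if max_markers else None
    for cand in candidates:
        if limit is not None and len(selected) >= limit:
            break
        if any(cand.overlaps(s) for s in selected):
            continue
        selected.append(cand)
    selected.sort(key=lambda w: (w.contig, w.start))
    pad = max(4, len(str(len(selected))))
    markers = [
        Window(w.contig, w.start, w.end, w.t, w.dp, marker_id=f"M{i + 1:0{pad}d}")
        for i, w in enumerate(selected)
    ]
    if not markers:
        logger.warning("select_panel: no window passed DP > %g; empty panel", dp_min)
    return MarkerPanel(
        markers=markers,
        params={"dp_min": dp_min, "max_markers": max_markers},
    )
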