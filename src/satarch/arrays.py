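"""Satellite array detection, length distributions and periodicity analysis.

An array is a maximal run of same-family satellite segments on one read,
allowing small unannotated gaps but split by any intervening annotation of
another class (SSR expansions, LINE insertions). Arrays cut by a read end
are flagged ``truncated`` — their lengths are lower bounds on the genomic
array length, so length histograms tally complete and truncated arrays
separately and weight each array by its length in bp (bars then reflect
genomic fraction rather than array counts).

Array lengths of a satellite with monomer length L concentrate on the
lattice ``n·L`` (complete terminal monomers) and ``n·L + t`` (arrays
terminated by a partial monomer of t bp); :func:`fit_periodicity` recovers
(L, t) by a grid search maximizing the concentration of array lengths
around the two dominant circular modes of ``length mod L``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import AnnotatedRead, SimilarityHit

logger = logging.getLogger(__name__)


@dataclass
class SatelliteArray:
    """A contiguous run of one satellite family on a read."""

    read_id: str
    start: int
    end: int
    family: str
    strand: str
    status: str  # complete | truncated
    mixed_strand: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LengthHistogram:
    """bp-weighted (or count-weighted) array length histogram.

    The last bin is right-open and collects every length above its lower
    edge. ``complete_weight + truncated_weight`` sums to the total weight.
    """

    bin_edges: np.ndarray
    complete_weight: np.ndarray
    truncated_weight: np.ndarray
    resolution: int

    @property
    def total_weight(self) -> float:
        return float(self.complete_weight.sum() + self.truncated_weight.sum())


@dataclass
class PeriodicityFit:
    """Result of the array-length periodicity grid search."""

    period_L: int
    offset_t: int
    concentration: float
    n_arrays: int
    mode_positions: tuple[int, int] = (0, 0)

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["mode_positions"] = list(self.mode_positions)
        return json.dumps(d, indent=2, sort_keys=True)


class UndefinedFitError(ValueError):
    """Too few arrays for a periodicity fit."""


# ---------------------------------------------------------------------------
# Array detection
# ---------------------------------------------------------------------------

def detect_arrays(annotated_read: AnnotatedRead, family: str,
                  split_gap: int = 100, edge_tol: int = 10
                  ) -> list[SatelliteArray]:
    """Group same-family segments of one read into maximal arrays.

    Consecutive segments of ``family`` (either strand) merge when separated
    by at most ``split_gap`` unannotated bases; any intervening segment of a
    different family or class splits the run. Arrays reaching within
    ``edge_tol`` of a read end are flagged truncated.
    """
    segs = annotated_read.segments
    n = annotated_read.length
    arrays: list[SatelliteArray] = []
    run: list = []
    prev_end_any = None

    def close_run() -> None:
        if not run:
            return
        start = run[0].start
        end = run[-1].end
        fwd = sum(s.length for s in run if s.strand == "+")
        rev = sum(s.length for s in run if s.strand == "-")
        strand = "+" if fwd >= rev else "-"
        status = "truncated" if (start <= edge_tol or end >= n - edge_tol) \
            else "complete"
        arrays.append(SatelliteArray(
            read_id=annotated_read.read_id, start=start, end=end,
            family=family, strand=strand, status=status,
            mixed_strand=(fwd > 0 and rev > 0)))
        run.clear()

    for seg in segs:
        if seg.family == family:
            if run and seg.start - run[-1].end > split_gap:
                close_run()
            run.append(seg)
        else:
            # any other annotation between family segments splits the run
            if run and seg.start >= run[-1].end:
                close_run()
    close_run()
    return arrays


def detect_arrays_all(annotated_reads: Iterable[AnnotatedRead], family: str,
                      split_gap: int = 100, edge_tol: int = 10
                      ) -> list[SatelliteArray]:
    out: list[SatelliteArray] = []
    for ar in annotated_reads:
        out.extend(detect_arrays(ar, family, split_gap=split_gap,
                                 edge_tol=edge_tol))
    return out


# ---------------------------------------------------------------------------
# Length distributions
# ---------------------------------------------------------------------------

def length_histogram(arrays: Sequence[SatelliteArray], bin_size: int = 5_000,
                     last_bin_floor: int = 120_000,
                     weight: str = "bp") -> LengthHistogram:
    """Binned array-length histogram, complete vs truncated tallied apart.

    ``weight="bp"`` weights each array by its length (the default, so bars
    are proportional to the genomic fraction each bin represents);
    ``weight="count"`` gives plain counts. The last bin spans
    ``[last_bin_floor, inf)``.
    """
    if weight not in ("bp", "count"):
        raise ValueError("weight must be 'bp' or 'count'")
    edges = np.arange(0, last_bin_floor + bin_size, bin_size, dtype=np.int64)
    nbins = len(edges)  # final bin is the open one starting at last edge
    cw = np.zeros(nbins, dtype=np.float64)
    tw = np.zeros(nbins, dtype=np.float64)
    for arr in arrays:
        idx = min(arr.length // bin_size, nbins - 1)
        if arr.length >= last_bin_floor:
            idx = nbins - 1
        w = arr.length if weight == "bp" else 1
        (cw if arr.status == "complete" else tw)[idx] += w
    return LengthHistogram(bin_edges=edges, complete_weight=cw,
                           truncated_weight=tw, resolution=bin_size)


def fine_distribution(arrays: Sequence[SatelliteArray], resolution: int = 1,
                      max_length: int | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """1 bp (or coarser) resolution length distribution: (lengths, counts)."""
    lengths = np.array([a.length for a in arrays], dtype=np.int64)
    if lengths.size == 0:
        return np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    if max_length is None:
        max_length = int(lengths.max())
    grid = np.arange(0, max_length + resolution, resolution)
    counts, _ = np.histogram(lengths, bins=np.append(grid, grid[-1] + resolution))
    return grid, counts


def periodicity_lengths(annotated_reads: Iterable[AnnotatedRead],
                        family: str, split_gap: int = 100,
                        edge_tol: int = 10,
                        exclusion_gap: int = 50) -> list[int]:
    """Complete-array lengths suitable for the periodicity fit.

    Arrays directly adjacent (gap <= ``exclusion_gap``) to a LINE segment
    are excluded: an element insertion cuts an array at the insertion site,
    so the cut pieces' lengths encode the target position rather than the
    monomer-lattice termination process the fit models. Read-truncated
    arrays are excluded as length lower bounds.
    """
    lengths: list[int] = []
    for ar in annotated_reads:
        arrays = detect_arrays(ar, family, split_gap=split_gap,
                               edge_tol=edge_tol)
        line_segs = [s for s in ar.segments if s.repeat_class == "LINE"]
        for a in arrays:
            if a.status != "complete":
                continue
            cut = any(0 <= s.start - a.end <= exclusion_gap
                      or 0 <= a.start - s.end <= exclusion_gap
                      for s in line_segs)
            if not cut:
                lengths.append(a.length)
    return lengths


# ---------------------------------------------------------------------------
# Periodicity
# ---------------------------------------------------------------------------

def _window_counts(counts: np.ndarray, L: int, tol: int) -> np.ndarray:
    """smooth[r] = number of residues within ``tol`` of r, circularly."""
    win = 2 * tol + 1
    if win == 1:
        return counts.astype(np.float64)
    ext = np.concatenate([counts, counts[:win]])
    smooth = np.convolve(ext, np.ones(win), mode="valid")[:L]
    return np.roll(smooth, tol)  # center the window on r


def _refine_mode(counts: np.ndarray, L: int, tol: int, center: int) -> int:
    """Snap a windowed-argmax plateau position to the circular centroid of
    the raw counts within tol of it (exact for noise-free residues, robust
    to symmetric boundary noise)."""
    offs = np.arange(-tol, tol + 1)
    cand = (center + offs) % L
    c = counts[cand]
    total = c.sum()
    if total == 0:
        return int(center % L)
    return int((center + round(float((offs * c).sum() / total))) % L)


def _circular_modes(residues: np.ndarray, L: int, tol: int
                    ) -> tuple[int, int, float]:
    """Two dominant circular modes of residues in [0, L) and the fraction of
    residues within ``tol`` of either (the concentration).

    The second mode maximizes *additional* coverage: it is fitted on the
    residues the first mode's tol-window does not already cover, so closely
    spaced bimodal patterns (offset barely above tol) are still resolved.
    """
    counts = np.bincount(residues, minlength=L).astype(np.float64)
    m1 = _refine_mode(counts, L, tol,
                      int(np.argmax(_window_counts(counts, L, tol))))
    d1 = np.minimum((residues - m1) % L, (m1 - residues) % L)
    uncovered = residues[d1 > tol]
    if uncovered.size:
        u_counts = np.bincount(uncovered, minlength=L).astype(np.float64)
        m2 = _refine_mode(u_counts, L, tol,
                          int(np.argmax(_window_counts(u_counts, L, tol))))
    else:
        m2 = m1
    d2 = np.minimum((residues - m2) % L, (m2 - residues) % L)
    near = np.minimum(d1, d2)
    covered = np.count_nonzero(near <= tol)
    # sharpness: mean circular distance to the nearest mode, capped just
    # beyond tol so uncovered residues contribute a bounded penalty
    sharp = float(np.minimum(near, tol + 1).mean()) / (tol + 1)
    return m1, m2, covered / residues.size, sharp


def _mode_drift(res: np.ndarray, lengths: np.ndarray, L: int,
                m1: int, m2: int, tol: int) -> float:
    """Ladder-alias statistic: |correlation| of the signed mode deviation
    with array length, over covered residues that actually deviate,
    weighted by how many of the covered residues deviate at all.

    Near-miss periods (L* ± small) turn every residue into a ladder that
    drifts with length (weight ~1, correlation ~1); at the true period the
    deviating residues are a small noisy subset, so chance correlations
    among them are damped by the weight.
    """
    s1 = (res - m1 + L // 2) % L - L // 2
    s2 = (res - m2 + L // 2) % L - L // 2
    signed = np.where(np.abs(s1) <= np.abs(s2), s1, s2)
    covered = np.abs(signed) <= tol
    n_cov = int(covered.sum())
    if n_cov < 3:
        return 0.0
    dev = signed[covered].astype(np.float64)
    ln = lengths[covered].astype(np.float64)
    moving = dev != 0
    if moving.sum() < 3:
        return 0.0
    d, l2 = dev[moving], ln[moving]
    if d.std() == 0 or l2.std() == 0:
        return 0.0
    corr = float(abs(np.corrcoef(d, l2)[0, 1]))
    return corr * float(moving.sum()) / n_cov


def _lattice_support(res: np.ndarray, lengths: np.ndarray, L: int,
                     m1: int, m2: int, tol: int) -> float:
    """Fraction of predicted lattice peaks actually observed.

    A candidate (L, modes) predicts peaks at q·L + mode for every quotient
    q in the observed range and each mode family. Sub-periods and
    offset-reparametrized half-periods predict peaks the data never shows;
    the true period has (nearly) every predicted cell occupied.
    """
    d1 = np.minimum((res - m1) % L, (m1 - res) % L)
    d2 = np.minimum((res - m2) % L, (m2 - res) % L)
    covered = (d1 <= tol) | (d2 <= tol)
    if not covered.any():
        return 0.0
    q = lengths[covered] // L
    span = int(q.max() - q.min()) + 1
    fam1 = np.unique(q[d1[covered] <= tol]).size
    if m2 == m1:
        return fam1 / span
    fam2 = np.unique(q[(d2[covered] <= tol) & (d1[covered] > tol)]).size
    return (fam1 + fam2) / (2 * span)


def _period_candidates(lengths: np.ndarray, lo: int, hi: int,
                       smooth: int = 3, top: int = 12) -> list[int]:
    """Candidate periods from the autocorrelation of the length distribution.

    The array-length distribution of a tandem repeat peaks on the lattice
    n·L (+t); shifting it by the monomer length maps every peak family onto
    its n+1 counterpart, so the autocorrelation has a dominant maximum at L
    (and its multiples). Spurious rational-fraction aliases of L do not
    appear as autocorrelation peaks. The top local maxima are returned for
    rescoring; a flat autocorrelation falls back to the full grid.
    """
    counts = np.bincount(lengths).astype(np.float64)
    if smooth > 1:
        counts = np.convolve(counts, np.ones(2 * smooth + 1), mode="same")
    n = counts.size
    hi = min(hi, n - 1)
    if hi < lo:
        return list(range(lo, hi + 1)) or [lo]
    ac = np.array([float(np.dot(counts[:-d], counts[d:]))
                   for d in range(lo, hi + 1)])
    if not np.any(ac > 0):
        return list(range(lo, hi + 1))
    # local maxima (plateau-tolerant), ranked by autocorrelation value
    peaks = [i for i in range(len(ac))
             if (i == 0 or ac[i] >= ac[i - 1])
             and (i == len(ac) - 1 or ac[i] > ac[i + 1])]
    peaks.sort(key=lambda i: (-ac[i], i))
    cand = sorted(lo + i for i in peaks[:top])
    return cand or list(range(lo, hi + 1))


def fit_periodicity(array_lengths: Sequence[int],
                    L_range: tuple[int, int] = (100, 800),
                    tol: int = 20) -> PeriodicityFit:
    """Grid-search the monomer period and truncation offset from array lengths.

    For each candidate period L (1 bp steps over ``L_range``), the residues
    ``length mod L`` are reduced to their two dominant circular modes; the
    concentration is the fraction of residues within ``tol`` of either mode.
    Candidates are ranked by concentration minus a sharpness penalty (mean
    capped distance to the nearest mode), which rejects aliased sub-periods
    whose wide windows cover a spread residue ladder; the smallest L wins
    exact ties (a period's integer multiples tie by construction). The
    offset is the circular lag
    from the base mode — the mode closest to residue 0, i.e. arrays of
    complete monomers — to the secondary mode, in [0, L); 0 when the
    secondary mode adds no coverage (unimodal distributions).
    """
    lengths = np.asarray([int(x) for x in array_lengths], dtype=np.int64)
    if lengths.size < 2:
        raise UndefinedFitError("periodicity fit needs at least 2 arrays")
    if lengths.size < 20:
        warnings.warn("fewer than 20 arrays: periodicity fit is unreliable",
                      stacklevel=2)
    lo, hi = L_range
    candidates = _period_candidates(lengths, lo, hi)
    best = None  # (score, L, m1, m2, conc); smallest L wins exact ties
    for L in candidates:
        res = lengths % L
        m1, m2, conc, sharp = _circular_modes(res, L, tol)
        # Aliased sub-periods of the true lattice can park every residue
        # inside the wide mode windows, but there the residues drift with
        # array length (a ladder), whereas at the true period the residue
        # is independent of the unit count. Penalize both the mode spread
        # (sharpness) and the |correlation| of the signed mode deviation
        # with array length (drift).
        drift = _mode_drift(res, lengths, L, m1, m2, tol)
        support = _lattice_support(res, lengths, L, m1, m2, tol)
        # chance baseline: two tol-windows on a short period cover most of
        # the circle, so score the concentration in excess of that coverage
        w = min(2 * (2 * tol + 1), L) / L
        excess = max(0.0, conc - w) / (1.0 - w) if w < 1.0 else 0.0
        score = (excess - 0.5 * sharp) * (1.0 - drift) * support
        if best is None or score > best[0] + 1e-12:
            best = (score, L, m1, m2, conc)
    _, L, m1, m2, conc = best
    # base mode = circularly closest to 0 (complete arrays are n*L)
    cand = sorted([m1, m2], key=lambda m: (min(m % L, (L - m) % L), m))
    base, other = cand[0], cand[1]
    # a secondary mode that adds no residues is noise: unimodal -> offset 0
    d_base = np.minimum((lengths % L - base) % L, (base - lengths % L) % L)
    d_other = np.minimum((lengths % L - other) % L, (other - lengths % L) % L)
    extra = np.count_nonzero((d_other <= tol) & (d_base > tol))
    offset = 0 if (other == base or extra == 0) else (other - base) % L
    return PeriodicityFit(period_L=int(L), offset_t=int(offset),
                          concentration=float(conc), n_arrays=int(lengths.size),
                          mode_positions=(int(base), int(other)))


# ---------------------------------------------------------------------------
# Junction truncation lengths
# ---------------------------------------------------------------------------

def junction_truncation_lengths(annotated_reads: Iterable[AnnotatedRead],
                                family: str, monomer_length: int,
                                hits: Iterable[SimilarityHit] | None = None,
                                adjacency_gap: int = 50,
                                split_gap: int = 100,
                                edge_tol: int = 10) -> list[int]:
    """Terminal partial-monomer lengths at satellite/SSR junctions.

    For every array side directly adjacent (gap <= ``adjacency_gap``) to an
    SSR segment, report the length of the terminal partial monomer: the
    extent on the reference monomer of the similarity hit spanning the
    junction-side array boundary when hit-level detail is available
    (``hits``), else the array length modulo the monomer length. A full
    terminal monomer reports 0.
    """
    hit_index: dict[str, list[SimilarityHit]] = {}
    if hits is not None:
        for h in hits:
            hit_index.setdefault(h.read_id, []).append(h)

    out: list[int] = []
    for ar in annotated_reads:
        arrays = detect_arrays(ar, family, split_gap=split_gap,
                               edge_tol=edge_tol)
        ssr = [s for s in ar.segments if s.repeat_class == "SSR"]
        read_hits = hit_index.get(ar.read_id)
        for arr in arrays:
            for side in ("left", "right"):
                boundary = arr.start if side == "left" else arr.end
                adjacent = any(
                    (s.start - arr.end <= adjacency_gap if side == "right"
                     else arr.start - s.end <= adjacency_gap)
                    and (s.start >= arr.end if side == "right"
                         else s.end <= arr.start)
                    for s in ssr)
                if not adjacent:
                    continue
                t = None
                if read_hits is not None:
                    t = _terminal_hit_extent(read_hits, arr, boundary, side,
                                             family, monomer_length)
                if t is None:
                    t = arr.length % monomer_length
                out.append(int(t % monomer_length))
    return out


def _terminal_hit_extent(read_hits: Sequence[SimilarityHit],
                         arr: SatelliteArray, boundary: int, side: str,
                         family: str, monomer_length: int) -> int | None:
    """Reference-extent of the hit covering the junction-side array boundary."""
    best = None
    for h in read_hits:
        if h.ref_name != family:
            continue
        # the terminal hit: contains (or ends at) the boundary base
        if side == "right" and h.read_start < boundary <= h.read_end:
            if best is None or h.read_end > best.read_end:
                best = h
        elif side == "left" and h.read_start <= boundary < h.read_end:
            if best is None or h.read_start < best.read_start:
                best = h
    if best is None:
        return None
    return (best.ref_end - best.ref_start) % monomer_length
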