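"""Flank composition profiles and adjacency summaries around focal features.

For every focal feature (satellite array or LINE segment), the ±window
flanks are read out in focal-forward coordinates: features on the minus
strand have upstream/downstream swapped and neighbor orientations flipped,
so profiles from both strands pool coherently. Each flank offset is labeled
by the annotation covering that base; the label carries the neighbor's
orientation *relative to the focal feature* (neighbor strand XOR focal
strand). Offsets falling beyond the read end are excluded from the
denominator rather than counted as unannotated, so read-length truncation
does not dilute the profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotatedRead
from .arrays import SatelliteArray, detect_arrays

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Feature:
    """Generic focal feature: an interval with a strand on a read."""

    read_id: str
    start: int
    end: int
    strand: str


@dataclass
class FlankProfile:
    """Per-offset repeat-label proportions over the ±window flanks.

    ``proportions[label][i]`` is the proportion at offset ``offsets[i]``;
    offsets run −window..−1, +1..+window (no offset 0). Labels are
    ``(family, relative_orientation)`` with orientation ``forward`` or
    ``reverse`` with respect to the focal feature.
    """

    focal_type: str
    window: int
    offsets: np.ndarray
    proportions: dict[tuple[str, str], np.ndarray]
    coverage: np.ndarray
    n_features: int

    def to_frame(self, min_proportion: float = 0.0) -> pd.DataFrame:
        """Long-format table (offset, label, orientation, proportion, coverage).

        ``min_proportion`` drops labels whose maximum proportion never
        reaches it (the plotting threshold).
        """
        rows = []
        for (label, orient), prop in sorted(self.proportions.items()):
            if prop.max(initial=0.0) < min_proportion:
                continue
            for off, p, cov in zip(self.offsets, prop, self.coverage):
                rows.append((int(off), label, orient, float(p), int(cov)))
        return pd.DataFrame(
            rows, columns=["offset", "label", "orientation",
                           "proportion", "coverage"])


@dataclass
class AdjacencySummary:
    """Immediate-neighbor tallies per array side.

    ``fractions[(label, orientation)]`` = fraction of scored array sides
    whose nearest annotated neighbor within ``adjacency_gap`` carries that
    label; sides whose nearest neighbor is farther (or absent) count toward
    ``none_fraction``. Sides at a read end are excluded entirely.
    """

    focal_family: str
    n_sides_scored: int
    fractions: dict[tuple[str, str], float]
    none_fraction: float

    def to_frame(self) -> pd.DataFrame:
        rows = [(lab, orient, frac)
                for (lab, orient), frac in sorted(self.fractions.items())]
        rows.append(("(none)", ".", self.none_fraction))
        return pd.DataFrame(rows, columns=["label", "orientation", "fraction"])


def _segment_label(seg) -> str:
    if seg.repeat_class == "SSR":
        return "SSR"
    if seg.repeat_class == "LINE" and seg.lineage:
        return f"LINE/{seg.lineage}"
    return seg.family


def _relative(neighbor_strand: str, focal_strand: str) -> str:
    return "forward" if neighbor_strand == focal_strand else "reverse"


def flank_profile(annotated_reads: Iterable[AnnotatedRead],
                  features: Sequence[Feature],
                  window: int = 10_000,
                  focal_type: str = "feature") -> FlankProfile:
    """Pool per-offset flank composition over all focal features.

    ``features`` typically come from :func:`satarch.arrays.detect_arrays`
    (satellite arrays) or from LINE segments; both reduce to intervals with
    strands. Coverage at an offset counts the flanks whose read extends that
    far; proportions are over coverage, so they sum to at most 1 at every
    offset (the remainder is unannotated sequence).
    """
    reads = {ar.read_id: ar for ar in annotated_reads}
    if not features:
        warnings.warn("flank_profile: no focal features", stacklevel=2)
        return FlankProfile(focal_type, window,
                            np.concatenate([np.arange(-window, 0),
                                            np.arange(1, window + 1)]),
                            {}, np.zeros(2 * window, dtype=np.int64), 0)

    # per-read cache of (label_code per base, code table)
    label_codes: dict[tuple[str, str], int] = {}
    per_read: dict[str, np.ndarray] = {}

    def read_labels(ar: AnnotatedRead) -> np.ndarray:
        arr = per_read.get(ar.read_id)
        if arr is None:
            arr = np.zeros(ar.length, dtype=np.int32)
            for seg in ar.segments:
                key = (_segment_label(seg), seg.strand)
                code = label_codes.setdefault(key, len(label_codes) + 1)
                arr[seg.start:seg.end] = code
            per_read[ar.read_id] = arr
        return arr

    n_off = 2 * window
    coverage = np.zeros(n_off, dtype=np.int64)
    # counts[code, offset_index]; code 0 = unannotated
    counts: dict[int, np.ndarray] = {}
    code_orientations: dict[int, tuple[str, str]] = {}

    for feat in features:
        ar = reads.get(feat.read_id)
        if ar is None:
            raise KeyError(f"feature on unknown read {feat.read_id!r}")
        labels = read_labels(ar)
        n = ar.length
        up = labels[max(0, feat.start - window):feat.start]
        down = labels[feat.end:min(n, feat.end + window)]
        # pad to window length with -1 (= beyond read end, excluded)
        if up.size < window:
            up = np.concatenate([np.full(window - up.size, -1, np.int32), up])
        if down.size < window:
            down = np.concatenate([down,
                                   np.full(window - down.size, -1, np.int32)])
        if feat.strand == "-":
            up, down = down[::-1], up[::-1]
        flank = np.concatenate([up, down])
        valid = flank >= 0
        coverage += valid
        for code in np.unique(flank[valid]):
            if code == 0:
                continue
            c = counts.setdefault(int(code), np.zeros(n_off, dtype=np.int64))
            c += (flank == code)

    # translate codes to (label, relative orientation) pooled over focal strand
    by_code = {v: k for k, v in label_codes.items()}
    pooled: dict[tuple[str, str], np.ndarray] = {}
    # re-accumulate per focal strand: strand-dependent orientation means one
    # absolute code maps to different relative labels per feature; handle by
    # a second pass only when both strands occur among features
    strands = {f.strand for f in features}
    if len(strands) == 1:
        focal_strand = next(iter(strands))
        for code, c in counts.items():
            label, seg_strand = by_code[code]
            key = (label, _relative(seg_strand, focal_strand))
            pooled[key] = pooled.get(key, 0) + c
    else:
        # slower exact path: accumulate per feature with relative orientation
        return _flank_profile_exact(reads, features, window, focal_type,
                                    read_labels, label_codes)

    with np.errstate(invalid="ignore", divide="ignore"):
        proportions = {k: np.where(coverage > 0, v / np.maximum(coverage, 1), 0.0)
                       for k, v in pooled.items()}
    offsets = np.concatenate([np.arange(-window, 0), np.arange(1, window + 1)])
    return FlankProfile(focal_type, window, offsets, proportions, coverage,
                        len(features))


def _flank_profile_exact(reads, features, window, focal_type,
                         read_labels, label_codes) -> FlankProfile:
    """Per-feature accumulation with strand-relative label orientation."""
    n_off = 2 * window
    coverage = np.zeros(n_off, dtype=np.int64)
    pooled: dict[tuple[str, str], np.ndarray] = {}
    for feat in features:
        ar = reads[feat.read_id]
        labels = read_labels(ar)
        n = ar.length
        up = labels[max(0, feat.start - window):feat.start]
        down = labels[feat.end:min(n, feat.end + window)]
        if up.size < window:
            up = np.concatenate([np.full(window - up.size, -1, np.int32), up])
        if down.size < window:
            down = np.concatenate([down,
                                   np.full(window - down.size, -1, np.int32)])
        if feat.strand == "-":
            up, down = down[::-1], up[::-1]
        flank = np.concatenate([up, down])
        valid = flank >= 0
        coverage += valid
        by_code = {v: k for k, v in label_codes.items()}
        for code in np.unique(flank[valid]):
            if code == 0:
                continue
            label, seg_strand = by_code[int(code)]
            key = (label, _relative(seg_strand, feat.strand))
            c = pooled.setdefault(key, np.zeros(n_off, dtype=np.int64))
            c += (flank == code)
    with np.errstate(invalid="ignore", divide="ignore"):
        proportions = {k: np.where(coverage > 0, v / np.maximum(coverage, 1), 0.0)
                       for k, v in pooled.items()}
    offsets = np.concatenate([np.arange(-window, 0), np.arange(1, window + 1)])
    return FlankProfile(focal_type, window, offsets, proportions, coverage,
                        len(features))


def arrays_as_features(arrays: Iterable[SatelliteArray]) -> list[Feature]:
    return [Feature(a.read_id, a.start, a.end, a.strand) for a in arrays]


def adjacency_summary(annotated_reads: Iterable[AnnotatedRead],
                      focal_family: str,
                      adjacency_gap: int = 50,
                      split_gap: int = 100,
                      edge_tol: int = 10) -> AdjacencySummary:
    """Tally the nearest annotated neighbor of each array side.

    For each side of each focal-family array that is not at a read end, the
    nearest annotated segment with gap <= ``adjacency_gap`` is tallied by
    (label, orientation relative to the array); sides with no such neighbor
    count as unterminated. Fractions are over all scored sides.
    """
    tallies: dict[tuple[str, str], int] = {}
    n_scored = 0
    n_none = 0
    for ar in annotated_reads:
        arrays = detect_arrays(ar, focal_family, split_gap=split_gap,
                               edge_tol=edge_tol)
        segs = ar.segments
        n = ar.length
        for arr in arrays:
            for side in ("left", "right"):
                boundary = arr.start if side == "left" else arr.end
                if boundary <= edge_tol or boundary >= n - edge_tol:
                    continue  # read-truncated side: excluded
                n_scored += 1
                best = None
                best_gap = None
                for seg in segs:
                    if side == "right" and seg.start >= arr.end:
                        gap = seg.start - arr.end
                    elif side == "left" and seg.end <= arr.start:
                        gap = arr.start - seg.end
                    else:
                        continue
                    if gap <= adjacency_gap and (best_gap is None
                                                 or gap < best_gap):
                        best, best_gap = seg, gap
                if best is None:
                    n_none += 1
                else:
                    key = (_segment_label(best),
                           _relative(best.strand, arr.strand))
                    tallies[key] = tallies.get(key, 0) + 1
    denom = max(n_scored, 1)
    return AdjacencySummary(
        focal_family=focal_family, n_sides_scored=n_scored,
        fractions={k: v / denom for k, v in tallies.items()},
        none_fraction=n_none / denom)
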