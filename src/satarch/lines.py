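"""LINE lineage assignment, satellite association and insertion-site mapping.

LINE segments found during annotation are (re-)assigned to phylogenetic
lineages by the single best bitscore hit against full-length reference
elements. Each segment is classified as associated with a satellite family
when the nearest array on the same read lies within an association distance
(10 kb by default); per-lineage associated fractions are reported as a
summary table.

Full-length elements (5–7 kb) additionally have their insertion sites
mapped onto the satellite monomer: a 200 bp flank window is taken on each
side of the element (in element orientation), windows shorter than 190 bp
or with fewer than 190 bp annotated as the satellite family are discarded,
and each surviving window is aligned to a head-to-tail monomer *dimer* so
alignments spanning the monomer origin stay contiguous. The monomer
coordinate of the window base abutting the element, folded modulo the
monomer length, feeds the 5′- or 3′-end profile. Because target-primed
insertion duplicates the target site, the two profiles are shifted by the
TSD length, recovered by circular cross-correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import revcomp
from .annotation import AnnotatedRead, AnnotatedSegment, ReferenceRepeat
from .arrays import SatelliteArray
from .engine import best_infix_alignment, hit_score

logger = logging.getLogger(__name__)


@dataclass
class LineInsertion:
    """A LINE segment with lineage, association and mapped insertion sites."""

    read_id: str
    start: int
    end: int
    strand: str
    lineage: str | None
    best_score: float
    full_length: bool
    associated: bool | None = None
    site5: int | None = None
    site3: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class InsertionProfile:
    """Frequencies of mapped LINE 5′ and 3′ ends per monomer position."""

    monomer_length: int
    freq5: np.ndarray
    freq3: np.ndarray
    n_windows_scored: int
    n_windows_discarded: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "position": np.arange(self.monomer_length),
            "freq5": self.freq5.astype(int),
            "freq3": self.freq3.astype(int)})


class FlatProfileError(ValueError):
    """Both end-profiles are empty/flat; no TSD shift is defined."""


# ---------------------------------------------------------------------------
# Lineage assignment
# ---------------------------------------------------------------------------

def assign_lineage(segments: Sequence[AnnotatedSegment],
                   reads: Mapping[str, str],
                   references: Sequence[ReferenceRepeat],
                   min_score: float = 0.0,
                   ) -> list[tuple[AnnotatedSegment, str | None, float]]:
    """Assign each LINE segment to the lineage of its best-scoring reference.

    Each segment's sequence is aligned (both orientations, semi-global) to
    every full-length reference; the lineage of the single highest-scoring
    hit wins, exact ties resolving to the earlier reference in database
    order. Segments with no hit scoring above ``min_score`` stay unassigned.
    Returns (segment, lineage, best_score) triples.
    """
    line_refs = [r for r in references if r.repeat_class == "LINE"]
    if not line_refs:
        raise ValueError("no LINE references in database")
    out = []
    for seg in segments:
        read_seq = reads[seg.read_id]
        qseq = read_seq[seg.start:seg.end]
        best_lineage, best = None, min_score
        for ref in line_refs:
            for seq in (qseq, revcomp(qseq)):
                aln = best_infix_alignment(seq, ref.consensus)
                if aln is None:
                    continue
                _, _, dist = aln
                matches = max(len(seq) - dist, 0)
                score = hit_score(matches, 0, dist)
                if score > best:
                    best = score
                    best_lineage = ref.lineage or ref.name
        out.append((seg, best_lineage, best if best_lineage else 0.0))
    return out


# ---------------------------------------------------------------------------
# Association with satellite arrays
# ---------------------------------------------------------------------------

def classify_association(line_segments: Sequence[AnnotatedSegment | LineInsertion],
                         satellite_arrays: Sequence[SatelliteArray],
                         assoc_dist: int = 10_000) -> pd.DataFrame:
    """Classify LINE segments as satellite-associated and summarize by lineage.

    A segment is associated when the gap to the nearest array on the same
    read is at most ``assoc_dist`` bp (0 for overlapping or directly
    adjacent intervals). Returns a per-lineage table with associated /
    not-associated fractions and the number of elements scored; the
    classification is recorded on the segments when they carry an
    ``associated`` attribute.
    """
    arrays_by_read: dict[str, list[SatelliteArray]] = {}
    for arr in satellite_arrays:
        arrays_by_read.setdefault(arr.read_id, []).append(arr)

    rows = []
    for seg in line_segments:
        gap = None
        for arr in arrays_by_read.get(seg.read_id, ()):
            g = max(arr.start - seg.end, seg.start - arr.end, 0)
            gap = g if gap is None else min(gap, g)
        associated = gap is not None and gap <= assoc_dist
        if hasattr(seg, "associated"):
            seg.associated = associated
        lineage = getattr(seg, "lineage", None) or "unassigned"
        rows.append((lineage, associated))

    frame = pd.DataFrame(rows, columns=["lineage", "associated"])
    if frame.empty:
        return pd.DataFrame(columns=["lineage", "yes_fraction", "no_fraction",
                                     "elements_scored"])
    summary = (frame.groupby("lineage")["associated"]
               .agg(yes_fraction="mean", elements_scored="size")
               .reset_index())
    summary["no_fraction"] = 1.0 - summary["yes_fraction"]
    return summary[["lineage", "yes_fraction", "no_fraction",
                    "elements_scored"]]


# ---------------------------------------------------------------------------
# Insertion-site mapping
# ---------------------------------------------------------------------------

def _satellite_mask(ar: AnnotatedRead, family: str) -> np.ndarray:
    mask = np.zeros(ar.length, dtype=bool)
    for seg in ar.segments:
        if seg.family == family:
            mask[seg.start:seg.end] = True
    return mask


def _map_window(window: str, dimer: str, monomer_length: int,
                abutting: str, max_identity_dist_frac: float = 0.35
                ) -> int | None:
    """Monomer coordinate of the element junction for one flank window.

    ``abutting`` names which window end touches the element ("right" for
    the 5′ upstream window, "left" for the 3′ downstream one). The site is
    the half-open junction coordinate: the dimer position just past the
    last flank base for a right-abutting window, the first flank base for
    a left-abutting one, folded modulo the monomer length. With a TSD of
    d bp the 5′ and 3′ sites then differ by exactly d.

    The window is aligned in both orientations; the better (then lower
    dimer start) wins. Reverse-orientation alignment swaps which alignment
    end abuts the element.
    """
    best = None
    for orient, seq in (("+", window), ("-", revcomp(window))):
        aln = best_infix_alignment(seq, dimer)
        if aln is None:
            continue
        start, end, dist = aln
        key = (dist, start)
        if best is None or key < best[0]:
            best = (key, start, end, orient)
    if best is None:
        return None
    (dist, _), start, end, orient = best
    if dist > max_identity_dist_frac * len(window):
        return None
    side = abutting if orient == "+" else ("left" if abutting == "right"
                                           else "right")
    pos = end if side == "right" else start
    return pos % monomer_length


def insertion_site_profile(full_length_lines: Sequence[LineInsertion],
                           annotated_reads: Iterable[AnnotatedRead],
                           monomer_consensus: str,
                           family: str = "CUS-TR24",
                           win: int = 200, min_win: int = 190
                           ) -> InsertionProfile:
    """Map full-length LINE 5′/3′ ends onto the satellite monomer.

    See the module docstring for the window extraction, filtering and
    dimer-folding rules. Elements on the minus strand have their windows
    swapped and reverse-complemented first, so both profiles are in element
    orientation.
    """
    if not monomer_consensus:
        raise ValueError("monomer consensus is required for insertion mapping")
    monomer = monomer_consensus.upper()
    L = len(monomer)
    dimer = monomer * 2
    reads = {ar.read_id: ar for ar in annotated_reads}

    freq5 = np.zeros(L, dtype=np.int64)
    freq3 = np.zeros(L, dtype=np.int64)
    n_scored = n_discarded = 0

    for el in full_length_lines:
        ar = reads.get(el.read_id)
        if ar is None:
            raise KeyError(f"LINE on unknown read {el.read_id!r}")
        seq = ar.read.sequence
        mask = _satellite_mask(ar, family)
        left = seq[max(0, el.start - win):el.start]
        left_sat = int(mask[max(0, el.start - win):el.start].sum())
        right = seq[el.end:el.end + win]
        right_sat = int(mask[el.end:el.end + win].sum())

        if el.strand == "-":
            # element orientation: upstream(5') window is the read-right one
            w5, w5_sat = revcomp(right), right_sat
            w3, w3_sat = revcomp(left), left_sat
        else:
            w5, w5_sat = left, left_sat
            w3, w3_sat = right, right_sat

        for which, window, sat in (("5", w5, w5_sat), ("3", w3, w3_sat)):
            if len(window) < min_win or sat < min_win:
                n_discarded += 1
                continue
            abutting = "right" if which == "5" else "left"
            pos = _map_window(window, dimer, L, abutting)
            if pos is None:
                n_discarded += 1
                continue
            (freq5 if which == "5" else freq3)[pos] += 1
            n_scored += 1

    return InsertionProfile(L, freq5, freq3, n_scored, n_discarded)


# ---------------------------------------------------------------------------
# Target motifs and TSD shift
# ---------------------------------------------------------------------------

def target_motif_consensus(profile: InsertionProfile, monomer_consensus: str,
                           enrich_fold: float = 5.0, context: int = 5,
                           cluster_gap: int = 3
                           ) -> list[tuple[int, str]]:
    """Enriched insertion positions and their monomer sequence context.

    A position is a peak when its pooled 5′+3′ frequency reaches
    ``enrich_fold`` times the uniform expectation; peaks within
    ``cluster_gap`` bp cluster, and each cluster reports the monomer
    subsequence spanning it ± ``context`` bp (circularly).
    """
    monomer = monomer_consensus.upper()
    L = profile.monomer_length
    pooled = profile.freq5 + profile.freq3
    total = pooled.sum()
    if total == 0:
        return []
    threshold = enrich_fold * total / L
    peaks = np.flatnonzero(pooled >= threshold)
    if peaks.size == 0:
        return []
    clusters: list[list[int]] = [[int(peaks[0])]]
    for p in peaks[1:]:
        if p - clusters[-1][-1] <= cluster_gap:
            clusters[-1].append(int(p))
        else:
            clusters.append([int(p)])
    out = []
    dimer = monomer * 2
    for cl in clusters:
        lo = cl[0] - context
        hi = cl[-1] + context + 1
        seq = dimer[lo % L: lo % L + (hi - lo)]
        out.append((cl[0], seq))
    return out


def tsd_estimate(profile: InsertionProfile) -> tuple[int, float]:
    """Target-site-duplication length from the 5′/3′ end-profile shift.

    Finds the circular cross-correlation lag (over the monomer length)
    maximizing the overlap of the two end profiles and reports its circular
    magnitude ``min(lag, L - lag)`` — the duplicated target shifts one
    profile relative to the other by the TSD length, in a direction set by
    the element orientation — together with the normalized correlation at
    the optimum. Identical profiles give shift 0.
    """
    p5 = profile.freq5.astype(np.float64)
    p3 = profile.freq3.astype(np.float64)
    if p5.sum() == 0 or p3.sum() == 0:
        raise FlatProfileError("cannot estimate a TSD shift from flat profiles")
    L = profile.monomer_length
    corr = np.empty(L, dtype=np.float64)
    for lag in range(L):
        corr[lag] = float(np.dot(np.roll(p3, lag), p5))
    lag = int(np.argmax(corr))
    norm = float(corr[lag] / (np.linalg.norm(p5) * np.linalg.norm(p3)))
    return min(lag, L - lag), norm


# ---------------------------------------------------------------------------
# Assembly of the per-element table
# ---------------------------------------------------------------------------

def collect_line_insertions(annotated_reads: Iterable[AnnotatedRead],
                            references: Sequence[ReferenceRepeat],
                            fl_min: int = 5_000, fl_max: int = 7_000,
                            reassign: bool = False,
                            ) -> list[LineInsertion]:
    """Gather LINE segments into :class:`LineInsertion` records.

    Lineage comes from the winning annotation hit's reference; with
    ``reassign=True`` every segment is re-scored against all full-length
    LINE references (the best-bitscore rule) instead.
    """
    annotated_reads = list(annotated_reads)
    segs = [(ar, seg) for ar in annotated_reads for seg in ar.segments
            if seg.repeat_class == "LINE"]
    if reassign:
        reads = {ar.read_id: ar.read.sequence for ar in annotated_reads}
        triples = assign_lineage([s for _, s in segs], reads, references)
        lineages = {id(s): (lin, sc) for (s, lin, sc) in triples}
    out = []
    for ar, seg in segs:
        if reassign:
            lineage, score = lineages[id(seg)]
        else:
            lineage, score = seg.lineage, seg.support_score
        out.append(LineInsertion(
            read_id=seg.read_id, start=seg.start, end=seg.end,
            strand=seg.strand, lineage=lineage, best_score=score,
            full_length=fl_min <= seg.length <= fl_max))
    return out


def insertions_to_frame(insertions: Sequence[LineInsertion]) -> pd.DataFrame:
    return pd.DataFrame([{
        "read_id": i.read_id, "start": i.start, "end": i.end,
        "strand": i.strand, "lineage": i.lineage, "score": i.best_score,
        "full_length": i.full_length, "associated": i.associated,
        "site5": i.site5, "site3": i.site3} for i in insertions])
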