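"""Read-level repeat annotation against a consensus reference database.

A reference database is a FASTA whose headers follow ``name#class/lineage``
(lineage optional), e.g. ``CUS-TR24#satellite`` or ``cl3#LINE/L1-CS``. All
members of one tandem/LINE family share a single orientation convention so
that strand reported on a hit is meaningful across reads.

Local similarity hits (from the built-in engine, an external ``lastz``
invocation, or an imported hit table) are resolved into non-overlapping,
strand-aware annotated segments: where hits overlap, each base takes the
label of the highest-scoring hit; adjacent same-label segments separated by
a small unannotated gap are merged; short leftovers are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._util import revcomp, rotations
from .io import SequencingRead

logger = logging.getLogger(__name__)

REPEAT_CLASSES = ("satellite", "SSR", "LINE", "rDNA", "other_mobile", "other")

#: LASTZ-style general-format column set for hit import/export
HIT_COLUMNS = ["name1", "size1", "start1", "length1", "strand1",
               "name2", "size2", "start2", "length2", "strand2",
               "identity", "score"]


class ReferenceDBError(ValueError):
    """Malformed reference database (bad header grammar, duplicate names)."""


@dataclass(frozen=True)
class ReferenceRepeat:
    """One reference consensus: family name, repeat class, optional lineage."""

    name: str
    repeat_class: str
    consensus: str
    lineage: str | None = None

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ReferenceDBError(f"reference {self.name!r} has empty sequence")
        if self.repeat_class not in REPEAT_CLASSES:
            raise ReferenceDBError(
                f"reference {self.name!r}: unknown class {self.repeat_class!r}")

    @property
    def length(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class SimilarityHit:
    """A local alignment between a read interval and a reference interval.

    Coordinates are 0-based half-open on the read's forward strand; ``strand``
    gives the reference orientation relative to the read; ``score`` is a
    bitscore-like quantity (higher is better).
    """

    read_id: str
    read_start: int
    read_end: int
    strand: str
    ref_name: str
    ref_start: int
    ref_end: int
    identity: float
    score: float

    def __post_init__(self) -> None:
        if not (0 <= self.read_start < self.read_end):
            raise ValueError(f"bad read interval on {self.read_id}: "
                             f"[{self.read_start},{self.read_end})")
        if not (0 <= self.ref_start < self.ref_end):
            raise ValueError(f"bad reference interval on {self.ref_name}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.score < 0:
            raise ValueError("negative score")


@dataclass
class AnnotatedSegment:
    """A resolved, non-overlapping repeat segment on a read."""

    read_id: str
    start: int
    end: int
    repeat_class: str
    family: str
    strand: str
    support_score: float
    lineage: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedRead:
    """A read together with its ordered, non-overlapping repeat segments."""

    read: SequencingRead
    segments: list[AnnotatedSegment] = field(default_factory=list)

    @property
    def read_id(self) -> str:
        return self.read.read_id

    @property
    def length(self) -> int:
        return self.read.length

    def label_array(self, labels: Mapping[tuple[str, str], int] | None = None
                    ) -> np.ndarray:
        """Per-base integer label codes (0 = unannotated); helper for profiling."""
        arr = np.zeros(self.length, dtype=np.int32)
        if labels is None:
            return arr
        for seg in self.segments:
            code = labels.get((seg.family, seg.strand))
            if code is not None:
                arr[seg.start:seg.end] = code
        return arr


# ---------------------------------------------------------------------------
# Reference database
# ---------------------------------------------------------------------------

def parse_reference_header(header: str) -> tuple[str, str, str | None]:
    """Split a ``name#class/lineage`` FASTA header (lineage optional)."""
    if "#" not in header:
        raise ReferenceDBError(
            f"reference header {header!r} lacks a '#class' tag")
    name, _, tail = header.partition("#")
    cls, _, lineage = tail.partition("/")
    if not name or not cls:
        raise ReferenceDBError(f"malformed reference header {header!r}")
    return name, cls, (lineage or None)


def load_reference_db(path: str | Path) -> list[ReferenceRepeat]:
    """Load a reference repeat database from FASTA with tagged headers.

    Database order is preserved: it is the deterministic tie-break order used
    during hit resolution and lineage assignment.
    """
    refs: list[ReferenceRepeat] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name, cls, lineage = parse_reference_header(rec.id)
        if name in seen:
            raise ReferenceDBError(f"duplicate reference name {name!r}")
        seen.add(name)
        refs.append(ReferenceRepeat(name, cls, str(rec.seq).upper(), lineage))
    return refs


def write_reference_db(refs: Iterable[ReferenceRepeat], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ref in refs:
            tag = f"{ref.name}#{ref.repeat_class}"
            if ref.lineage:
                tag += f"/{ref.lineage}"
            fh.write(f">{tag}\n{ref.consensus}\n")


# ---------------------------------------------------------------------------
# Similarity search
# ---------------------------------------------------------------------------

def similarity_search(reads: Iterable[SequencingRead],
                      refdb: Sequence[ReferenceRepeat],
                      engine: str = "builtin",
                      **params) -> list[SimilarityHit]:
    """Report local similarities between reads and references on both strands.

    ``engine`` selects the implementation: ``"builtin"`` (seeded tandem-tiling
    aligner, no external binary) or ``"external"`` (a LASTZ invocation; raises :class:`EngineNotFoundError` if the binary is
    absent). Both emit the same :class:`SimilarityHit` schema.
    """
    refs = list(refdb)
    reads = list(reads)
    if not reads or not refs:
        raise ValueError("similarity_search requires non-empty reads and refdb")
    if engine == "builtin":
        from .engine import builtin_search
        return builtin_search(reads, refs, **params)
    if engine == "external":
        from .engine import external_search
        return external_search(reads, refs, **params)
    raise ValueError(f"unknown engine {engine!r}")


def hits_to_frame(hits: Iterable[SimilarityHit],
                  read_lengths: Mapping[str, int],
                  ref_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Export hits in the LASTZ general-format column set (bit-exact re-import)."""
    rows = []
    for h in hits:
        rows.append({
            "name1": h.ref_name, "size1": ref_lengths[h.ref_name],
            "start1": h.ref_start, "length1": h.ref_end - h.ref_start,
            "strand1": "+",
            "name2": h.read_id, "size2": read_lengths[h.read_id],
            "start2": h.read_start, "length2": h.read_end - h.read_start,
            "strand2": h.strand,
            "identity": round(h.identity, 6), "score": h.score,
        })
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def frame_to_hits(frame: pd.DataFrame) -> list[SimilarityHit]:
    """Import hits from a LASTZ general-format table (columns as HIT_COLUMNS)."""
    missing = [c for c in HIT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"hit table lacks columns {missing}")
    hits = []
    for row in frame.itertuples(index=False):
        hits.append(SimilarityHit(
            read_id=str(row.name2), read_start=int(row.start2),
            read_end=int(row.start2) + int(row.length2),
            strand=str(row.strand2), ref_name=str(row.name1),
            ref_start=int(row.start1), ref_end=int(row.start1) + int(row.length1),
            identity=float(row.identity), score=float(row.score)))
    return hits


# ---------------------------------------------------------------------------
# SSR scanner
# ---------------------------------------------------------------------------

def annotate_ssr(read: SequencingRead, motifs: Sequence[str] = ("TAA", "TGA"),
                 min_array: int = 60, max_mismatch_frac: float = 0.2,
                 max_gap: int = 6) -> list[AnnotatedSegment]:
    """Detect simple-sequence-repeat arrays as maximal tandem runs of a motif.

    A position supports motif ``m`` if the k-mer starting there is a cyclic
    rotation of ``m`` (forward strand) or of its reverse complement (minus
    strand). Perfect runs separated by at most ``max_gap`` non-supporting
    bases merge while the merged run's mismatch fraction stays below
    ``max_mismatch_frac``; runs of total length >= ``min_array`` are reported.
    """
    segments: list[AnnotatedSegment] = []
    seq = read.sequence
    for motif in motifs:
        if not 1 <= len(motif) <= 6:
            raise ValueError(f"SSR motif {motif!r} must be 1-6 bp")
        for strand, variant in (("+", motif), ("-", revcomp(motif))):
            for start, end, mism in _motif_runs(seq, variant, max_gap,
                                                max_mismatch_frac):
                if end - start >= min_array:
                    length = end - start
                    segments.append(AnnotatedSegment(
                        read_id=read.read_id, start=start, end=end,
                        repeat_class="SSR", family=f"SSR_{motif}",
                        strand=strand,
                        support_score=2.0 * (length - mism) - 3.0 * mism))
    segments.sort(key=lambda s: (s.start, s.end))
    return segments


def _motif_runs(seq: str, motif: str, max_gap: int, max_mm_frac: float):
    """Yield (start, end, mismatch_count) maximal runs of tandem motif copies."""
    k = len(motif)
    n = len(seq)
    if n < k:
        return
    rot = rotations(motif)
    good = np.zeros(n - k + 1, dtype=bool)
    for r in rot:
        # mark every position whose k-mer equals a rotation
        idx = 0
        while True:
            idx = seq.find(r, idx)
            if idx == -1:
                break
            good[idx] = True
            idx += 1
    # maximal perfect stretches of consecutive supporting positions
    runs = []
    i = 0
    m = len(good)
    while i < m:
        if good[i]:
            j = i
            while j < m and good[j]:
                j += 1
            runs.append([i, j - 1 + k])  # [start, end) covered bases
            i = j
        else:
            i += 1
    if not runs:
        return
    # merge runs across small gaps while mismatch fraction stays acceptable
    merged = [runs[0] + [0]]  # start, end, mismatches
    for start, end in runs[1:]:
        prev = merged[-1]
        gap = start - prev[1]
        new_mm = prev[2] + max(gap, 0)
        if gap <= max_gap and new_mm / (end - prev[0]) <= max_mm_frac:
            prev[1] = end
            prev[2] = new_mm
        else:
            merged.append([start, end, 0])
    for start, end, mm in merged:
        yield start, end, mm


# ---------------------------------------------------------------------------
# Resolution
# ---------------------------------------------------------------------------

def resolve_annotation(read: SequencingRead,
                       hits: Iterable[SimilarityHit],
                       refdb: Sequence[ReferenceRepeat],
                       min_segment_length: int = 100,
                       merge_gap: int = 50,
                       extra_segments: Iterable[AnnotatedSegment] = (),
                       ) -> AnnotatedRead:
    """Resolve overlapping hits into non-overlapping annotated segments.

    Every base takes the (family, strand) of the highest-scoring covering hit;
    exact score ties break toward the earlier reference in database order,
    then the lower read start. Adjacent same-label segments separated by at
    most ``merge_gap`` unannotated bases merge; segments shorter than
    ``min_segment_length`` are dropped. ``extra_segments`` (e.g. SSR-scanner
    output) compete in the same resolution with their ``support_score``.

    The result is order-invariant in the hit input.
    """
    ref_by_name = {r.name: r for r in refdb}
    ref_order = {r.name: i for i, r in enumerate(refdb)}
    n = read.length

    candidates = []  # (start, end, score, order_key, family, strand, class, lineage)
    for h in hits:
        if h.read_id != read.read_id:
            continue
        if h.read_end > n:
            raise ValueError(
                f"hit [{h.read_start},{h.read_end}) exceeds read "
                f"{read.read_id!r} length {n}")
        ref = ref_by_name.get(h.ref_name)
        if ref is None:
            raise ValueError(f"hit references unknown family {h.ref_name!r}")
        candidates.append((h.read_start, h.read_end, h.score,
                           (ref_order[h.ref_name], h.read_start),
                           ref.name, h.strand, ref.repeat_class, ref.lineage))
    for seg in extra_segments:
        if seg.read_id != read.read_id:
            continue
        if seg.end > n:
            raise ValueError("extra segment exceeds read length")
        candidates.append((seg.start, seg.end, seg.support_score,
                           (len(refdb), seg.start),
                           seg.family, seg.strand, seg.repeat_class, seg.lineage))

    if not candidates:
        return AnnotatedRead(read, [])

    # deterministic processing order regardless of input order
    candidates.sort(key=lambda c: (c[0], c[1], -c[2], c[3], c[4], c[5]))

    bounds = sorted({c[0] for c in candidates} | {c[1] for c in candidates})
    # elementary intervals between consecutive boundaries; pick winner per interval
    winner: list[tuple[int, int, tuple]] = []  # (start, end, candidate)
    for a, b in zip(bounds[:-1], bounds[1:]):
        best = None
        for c in candidates:
            if c[0] > a:
                break  # sorted by start; nothing later can cover [a, b)
            if c[1] >= b and (best is None or c[2] > best[2]
                              or (c[2] == best[2] and c[3] < best[3])):
                best = c
        if best is not None:
            winner.append((a, b, best))

    # merge consecutive elementary intervals with identical labels
    segments: list[AnnotatedSegment] = []
    for a, b, c in winner:
        label = (c[4], c[5], c[6], c[7])
        if segments and segments[-1].end == a and \
                (segments[-1].family, segments[-1].strand,
                 segments[-1].repeat_class, segments[-1].lineage) == label:
            segments[-1].end = b
            segments[-1].support_score = max(segments[-1].support_score, c[2])
        else:
            segments.append(AnnotatedSegment(
                read_id=read.read_id, start=a, end=b, repeat_class=c[6],
                family=c[4], strand=c[5], support_score=c[2], lineage=c[7]))

    # merge same-label segments across small unannotated gaps
    merged: list[AnnotatedSegment] = []
    for seg in segments:
        if merged:
            prev = merged[-1]
            gap = seg.start - prev.end
            if (0 <= gap <= merge_gap and prev.family == seg.family
                    and prev.strand == seg.strand
                    and prev.repeat_class == seg.repeat_class):
                prev.end = seg.end
                prev.support_score = max(prev.support_score, seg.support_score)
                continue
        merged.append(seg)

    merged = [s for s in merged if s.length >= min_segment_length]
    return AnnotatedRead(read, merged)


def annotate_reads(reads: Iterable[SequencingRead],
                   refdb: Sequence[ReferenceRepeat],
                   engine: str = "builtin",
                   ssr_motifs: Sequence[str] = ("TAA", "TGA"),
                   min_ssr_array: int = 60,
                   min_segment_length: int = 100,
                   merge_gap: int = 50,
                   hits: Iterable[SimilarityHit] | None = None,
                   **search_params,
                   ) -> tuple[list[AnnotatedRead], list[SimilarityHit]]:
    """Full annotation of a read set: search (or imported hits) + SSR scan + resolve.

    Returns the annotated reads and the raw hits (needed downstream for
    junction-level monomer coordinates).
    """
    reads = list(reads)
    if hits is None:
        hits = similarity_search(reads, refdb, engine=engine, **search_params)
    else:
        hits = list(hits)
    by_read: dict[str, list[SimilarityHit]] = {}
    for h in hits:
        by_read.setdefault(h.read_id, []).append(h)
    annotated = []
    for read in reads:
        ssr_segments = annotate_ssr(read, motifs=ssr_motifs,
                                    min_array=min_ssr_array)
        annotated.append(resolve_annotation(
            read, by_read.get(read.read_id, ()), refdb,
            min_segment_length=min_segment_length, merge_gap=merge_gap,
            extra_segments=ssr_segments))
    return annotated, hits


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def segments_to_bed(annotated: Iterable[AnnotatedRead]) -> pd.DataFrame:
    """BED6 table of resolved segments (name = class/family[/lineage])."""
    rows = []
    for ar in annotated:
        for seg in ar.segments:
            name = f"{seg.repeat_class}/{seg.family}"
            if seg.lineage:
                name += f"/{seg.lineage}"
            rows.append((ar.read_id, seg.start, seg.end, name,
                         int(round(seg.support_score)), seg.strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "name", "score", "strand"])


def segments_to_gff3(annotated: Iterable[AnnotatedRead]) -> str:
    lines = ["##gff-version 3"]
    for ar in annotated:
        for i, seg in enumerate(ar.segments):
            attrs = f"ID={ar.read_id}.{i};family={seg.family}"
            if seg.lineage:
                attrs += f";lineage={seg.lineage}"
            lines.append("\t".join([
                ar.read_id, "satarch", seg.repeat_class,
                str(seg.start + 1), str(seg.end), f"{seg.support_score:.1f}",
                seg.strand, ".", attrs]))
    return "\n".join(lines) + "\n"
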