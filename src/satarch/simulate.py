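"""Synthetic satellite-locus generator with base-exact ground truth.

The generator emulates the evolutionary model inferred for CUS-TR24-type
heterochromatic loci: ancestral tandem arrays of a ~389 bp monomer occur in
short runs (1–10+ units), frequently terminated by a partial monomer
(~120 bp retained); simple-sequence repeats expand at (TAA)/(TGA) hotspot
motifs between arrays; LINE elements of a dominant lineage insert at a
conserved target motif inside the monomer, producing a 13–16 bp target
site duplication; and whole arrays occasionally invert or duplicate.
Nanopore-like reads are sampled from the loci with i.i.d. substitution /
insertion / deletion errors, and every feature is lifted through strand
flips and indels into read coordinates, so each pipeline stage can be
scored against exact truth without any external data.

All randomness flows from a single integer seed through independent
derived streams; repeated runs are bit-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import revcomp, rng_for
from .annotation import AnnotatedRead, AnnotatedSegment, ReferenceRepeat
from .io import SequencingRead

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

SATELLITE_FAMILY = "CUS-TR24"


# ---------------------------------------------------------------------------
# Parameters and truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimulationParams:
    """Knobs of the locus-evolution and read-error model.

    Defaults describe the genomic conditions the simulator emulates: 389 bp
    monomer, arrays of 1–10 units, ~120 bp terminal partial monomers,
    (TAA)/(TGA) SSR expansions, a dominant satellite-targeting LINE lineage
    with 13–16 bp TSDs, occasional inversions/duplications, ultra-long
    (30–100 kb) reads at ~5% total error.
    """

    seed: int = 42
    monomer: str | None = None          # generated if None
    monomer_length: int = 389
    n_loci: int = 8
    blocks_per_locus: int = 12          # satellite array blocks per locus
    unit_count_range: tuple[int, int] = (1, 10)
    truncation_offset: int = 120        # bp of terminal partial monomer
    truncation_prob: float = 0.5
    ssr_motifs: tuple[str, ...] = ("TAA", "TGA")
    ssr_prob: float = 0.4               # SSR expansion at an array junction
    ssr_copy_range: tuple[int, int] = (25, 100)
    spacer_prob: float = 0.3
    spacer_range: tuple[int, int] = (2_000, 8_000)
    line_lengths: Mapping[str, int] = field(default_factory=lambda: {
        "L1-CS": 6_000, "L1-Llb": 5_800, "RTE": 5_200})
    line_weights: Mapping[str, float] = field(default_factory=lambda: {
        "L1-CS": 0.7, "L1-Llb": 0.1, "RTE": 0.2})
    assoc_fraction: Mapping[str, float] = field(default_factory=lambda: {
        "L1-CS": 0.9, "L1-Llb": 0.3, "RTE": 0.15})
    lines_per_locus: int = 5
    full_length_fraction: float = 0.5
    fragment_range: tuple[int, int] = (500, 4_000)
    tsd_range: tuple[int, int] = (13, 16)
    # orientation of inserted elements relative to the monomer-forward array;
    # target-primed insertion at a fixed motif fixes this (observed: reverse)
    line_orientation: str = "-"
    inversion_rate: float = 0.05
    duplication_rate: float = 0.05
    n_reads: int = 200
    read_length_range: tuple[int, int] = (30_000, 100_000)
    sub_rate: float = 0.03
    ins_rate: float = 0.01
    del_rate: float = 0.01

    def error_free(self) -> "SimulationParams":
        return replace(self, sub_rate=0.0, ins_rate=0.0, del_rate=0.0)


@dataclass
class TruthFeature:
    """One ground-truth feature, in locus or read coordinates."""

    ftype: str                   # array | SSR | LINE | spacer
    start: int
    end: int
    strand: str = "+"
    family: str | None = None
    lineage: str | None = None
    unit_count: int | None = None
    partial_monomer: int | None = None   # terminal truncation offset, bp
    tsd: int | None = None
    insert_site: int | None = None       # monomer cleavage coordinate
    full_length: bool | None = None
    associated: bool | None = None       # generator intent for LINEs

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LocusTruth:
    locus_id: str
    length: int
    features: list[TruthFeature]


@dataclass
class ReadTruth:
    read_id: str
    locus_id: str
    locus_start: int
    locus_end: int
    strand: str
    features: list[TruthFeature]


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def make_monomer(length: int = 389, seed: int = 1,
                 target_motif: str = "TTCTA",
                 ssr_motif: str = "TAA") -> tuple[str, dict]:
    """Generate a satellite monomer with planted hotspot and target motifs.

    The sequence carries >= 3 occurrences of the SSR hotspot motif (as short
    ``(TAA)2`` islands, kept well below SSR-detection length) and one LINE
    target motif at a recorded position near mid-monomer. Deterministic per
    seed. Returns (sequence, info) with ``info['target_pos']`` the motif
    start, ``info['cleavage_pos']`` the insertion coordinate used by the
    simulator, and ``info['ssr_hotspots']`` the hotspot positions.
    """
    if length < 50:
        raise ValueError("monomer length must be >= 50")
    rng = rng_for(seed, 101)
    seq = np.frombuffer(_random_seq(rng, length).encode(), np.uint8).copy()

    island = (ssr_motif * 2).encode()          # 6 bp: below scanner/seed scale
    # hotspot fractions avoid the ~0.31 truncation point (120/389): an island
    # abutting the terminal cut would let SSR expansions chain into the
    # partial monomer and erode array boundaries
    hotspots = [int(length * f) for f in (0.10, 0.22, 0.70, 0.90)]
    hotspots = [min(h, length - len(island)) for h in hotspots]
    for h in hotspots:
        seq[h:h + len(island)] = np.frombuffer(island, np.uint8)

    # keep the target site away from half-monomer positions: array pieces
    # produced by element insertion would otherwise end near L/2 and lend
    # spurious support to half-period aliases in the length lattice
    target_pos = int(length * 0.58)
    tm = target_motif.encode()
    seq[target_pos:target_pos + len(tm)] = np.frombuffer(tm, np.uint8)

    info = {"target_pos": target_pos,
            "cleavage_pos": target_pos + len(target_motif),
            "ssr_hotspots": hotspots,
            "target_motif": target_motif}
    return seq.tobytes().decode(), info


def make_line_references(params: SimulationParams) -> list[ReferenceRepeat]:
    """Generate one full-length reference consensus per LINE lineage."""
    rng = rng_for(params.seed, 202)
    refs = []
    for i, (lineage, length) in enumerate(sorted(params.line_lengths.items())):
        seq = _random_seq(rng, length)
        refs.append(ReferenceRepeat(
            name=f"LINE_{lineage}", repeat_class="LINE",
            consensus=seq, lineage=lineage))
    return refs


# ---------------------------------------------------------------------------
# Locus simulation
# ---------------------------------------------------------------------------

def _invert_block(seq: str, feats: list[TruthFeature]) -> tuple[str, list[TruthFeature]]:
    n = len(seq)
    out = []
    for f in reversed(feats):
        out.append(replace(f, start=n - f.end, end=n - f.start,
                           strand="-" if f.strand == "+" else "+"))
    return revcomp(seq), out


def _array_block(rng: np.random.Generator, monomer: str, info: dict,
                 params: SimulationParams,
                 line_queue: list[tuple[str, bool]],
                 line_refs: dict[str, str],
                 ) -> tuple[str, list[TruthFeature]]:
    """One satellite array block, possibly carrying a LINE insertion,
    a terminal partial monomer, an inversion or a duplication."""
    L = len(monomer)
    lo, hi = params.unit_count_range
    n_units = int(rng.integers(lo, hi + 1))
    seq = monomer * n_units
    partial = None
    if rng.random() < params.truncation_prob:
        partial = int(params.truncation_offset)
        seq = seq + monomer[:partial]
    feats = [TruthFeature("array", 0, len(seq), "+", SATELLITE_FAMILY,
                          unit_count=n_units, partial_monomer=partial)]

    if line_queue and rng.random() < 0.9:
        lineage, full_length = line_queue.pop(0)
        ref = line_refs[lineage]
        if full_length:
            el = ref
        else:
            flo, fhi = params.fragment_range
            flen = int(rng.integers(flo, min(fhi, len(ref)) + 1))
            el = ref[-flen:]          # 5'-truncated fragment, as in TPRT
        el_strand = params.line_orientation
        el_seq = el if el_strand == "+" else revcomp(el)
        d = int(rng.integers(params.tsd_range[0], params.tsd_range[1] + 1))
        # keep the duplicated tract inside one monomer copy
        p = min(info["cleavage_pos"], L - params.tsd_range[1] - 1)
        unit = int(rng.integers(0, n_units))
        cut = unit * L + p
        # target-primed insertion: duplicate monomer[p : p+d] around the element
        left = seq[:cut + d]
        right = seq[cut:]
        seq = left + el_seq + right
        feats = [
            TruthFeature("array", 0, len(left), "+", SATELLITE_FAMILY,
                         unit_count=unit, partial_monomer=(p + d) % L),
            TruthFeature("LINE", len(left), len(left) + len(el_seq), el_strand,
                         lineage=lineage, tsd=d, insert_site=p,
                         full_length=full_length, associated=True),
            TruthFeature("array", len(left) + len(el_seq), len(seq), "+",
                         SATELLITE_FAMILY, unit_count=n_units - unit,
                         partial_monomer=partial),
        ]

    if rng.random() < params.inversion_rate:
        seq, feats = _invert_block(seq, feats)
    if rng.random() < params.duplication_rate:
        shifted = [replace(f, start=f.start + len(seq), end=f.end + len(seq))
                   for f in feats]
        seq, feats = seq + seq, feats + shifted
    return seq, feats


def _ssr_block(rng: np.random.Generator, params: SimulationParams
               ) -> tuple[str, list[TruthFeature]]:
    motif = str(rng.choice(list(params.ssr_motifs)))
    lo, hi = params.ssr_copy_range
    copies = int(rng.integers(lo, hi + 1))
    strand = "+" if rng.random() < 0.5 else "-"
    seq = motif * copies if strand == "+" else revcomp(motif * copies)
    return seq, [TruthFeature("SSR", 0, len(seq), strand,
                              family=f"SSR_{motif}")]


def simulate_locus(params: SimulationParams, locus_index: int = 0,
                   monomer: str | None = None, monomer_info: dict | None = None,
                   line_refs: Mapping[str, str] | None = None,
                   ) -> tuple[str, LocusTruth]:
    """Build one locus sequence and its tiling ground truth.

    The locus alternates satellite array blocks with SSR expansions and
    spacers; generator-associated LINEs sit inside arrays (with exact
    TSDs), non-associated ones inside long distal spacers guaranteeing
    >10 kb distance from any satellite sequence.
    """
    rng = rng_for(params.seed, 303, locus_index)
    if monomer is None:
        if params.monomer is not None:
            monomer = params.monomer.upper()
            monomer_info = monomer_info or _locate_motifs(monomer)
        else:
            monomer, monomer_info = make_monomer(params.monomer_length,
                                                 params.seed)
    if monomer_info is None:
        monomer_info = _locate_motifs(monomer)
    if line_refs is None:
        line_refs = {r.lineage: r.consensus
                     for r in make_line_references(params)}

    # decide this locus' LINE complement up front
    lineages = sorted(params.line_weights)
    weights = np.array([params.line_weights[l] for l in lineages], float)
    weights /= weights.sum()
    assoc_queue: list[tuple[str, bool]] = []
    distal: list[tuple[str, bool]] = []
    for _ in range(params.lines_per_locus):
        lineage = lineages[int(rng.choice(len(lineages), p=weights))]
        full = bool(rng.random() < params.full_length_fraction)
        if rng.random() < params.assoc_fraction.get(lineage, 0.0):
            assoc_queue.append((lineage, full))
        else:
            distal.append((lineage, full))

    pieces: list[str] = []
    feats: list[TruthFeature] = []
    pos = 0

    def add(seq: str, block_feats: list[TruthFeature]) -> None:
        nonlocal pos
        pieces.append(seq)
        for f in block_feats:
            feats.append(replace(f, start=f.start + pos, end=f.end + pos))
        pos += len(seq)

    def add_spacer(length: int) -> None:
        add(_random_seq(rng, length), [TruthFeature("spacer", 0, length)])

    add_spacer(int(rng.integers(*params.spacer_range)))
    n_blocks = params.blocks_per_locus + max(
        0, len(assoc_queue) - params.blocks_per_locus)
    blocks_done = 0
    while blocks_done < n_blocks or (assoc_queue and blocks_done < n_blocks + 60):
        add(*_array_block(rng, monomer, monomer_info, params,
                          assoc_queue, line_refs))
        blocks_done += 1
        if rng.random() < params.ssr_prob:
            add(*_ssr_block(rng, params))
        if rng.random() < params.spacer_prob:
            add_spacer(int(rng.integers(*params.spacer_range)))
    # distal, non-associated elements: buried in long spacers
    margin = 12_000
    for lineage, full in distal:
        add_spacer(margin)
        ref = line_refs[lineage]
        if full:
            el = ref
        else:
            flo, fhi = params.fragment_range
            el = ref[-int(rng.integers(flo, min(fhi, len(ref)) + 1)):]
        strand = "+" if rng.random() < 0.5 else "-"
        add(el if strand == "+" else revcomp(el),
            [TruthFeature("LINE", 0, len(el), strand, lineage=lineage,
                          full_length=full, associated=False)])
        add_spacer(margin)
    add_spacer(int(rng.integers(*params.spacer_range)))

    sequence = "".join(pieces)
    truth = LocusTruth(f"locus{locus_index}", len(sequence), feats)
    assert sum(f.length for f in feats) == len(sequence)
    return sequence, truth


def _locate_motifs(monomer: str) -> dict:
    """Best-effort motif localization for a user-supplied monomer."""
    for motif in ("TTCTA", "TTTCAA", "TTTTAA"):
        idx = monomer.find(motif)
        if idx >= 0:
            return {"target_pos": idx, "cleavage_pos": idx + len(motif),
                    "ssr_hotspots": [], "target_motif": motif}
    mid = len(monomer) // 2
    return {"target_pos": mid, "cleavage_pos": mid, "ssr_hotspots": [],
            "target_motif": monomer[mid:mid + 5]}


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _apply_errors(seq: str, rng: np.random.Generator, sub: float,
                  ins: float, dele: float) -> tuple[str, np.ndarray]:
    """Introduce i.i.d. errors; return (read, map) with ``map[t]`` the read
    coordinate of template position t (length len(seq)+1, monotone)."""
    n = len(seq)
    arr = np.frombuffer(seq.encode(), np.uint8).copy()
    if sub + ins + dele == 0:
        return seq, np.arange(n + 1, dtype=np.int64)
    keep = rng.random(n) >= dele
    subs = (rng.random(n) < sub) & keep
    insm = rng.random(n) < ins
    # substitute with a strictly different base
    if subs.any():
        idx = np.flatnonzero(subs)
        cur = np.searchsorted(_BASES, arr[idx])
        cur = np.where(cur > 3, 0, cur)  # non-ACGT treated as A
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(cur + shift) % 4]
    contrib = keep.astype(np.int64) + insm.astype(np.int64)
    cmap = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(contrib, out=cmap[1:])
    out = np.zeros(int(cmap[-1]), dtype=np.uint8)
    out[cmap[:-1][keep]] = arr[keep]
    ins_pos = cmap[:-1][insm] + keep[insm]
    out[ins_pos] = _BASES[rng.integers(0, 4, size=int(insm.sum()))]
    return out.tobytes().decode(), cmap


def simulate_reads(loci: Sequence[tuple[str, LocusTruth]],
                   params: SimulationParams
                   ) -> tuple[list[SequencingRead], list[ReadTruth]]:
    """Sample error-injected reads from loci, lifting truth to read coords.

    Reads come from both strands; minus-strand reads have coordinates
    mirrored and feature strands flipped. Qualities are synthesized from
    the total error rate (with small per-base jitter).
    """
    rng = rng_for(params.seed, 404)
    err_total = params.sub_rate + params.ins_rate + params.del_rate
    q_mean = 40 if err_total == 0 else max(
        2, int(round(-10 * math.log10(err_total))))
    reads: list[SequencingRead] = []
    truths: list[ReadTruth] = []
    lo, hi = params.read_length_range
    for i in range(params.n_reads):
        li = int(rng.integers(0, len(loci)))
        seq, locus = loci[li]
        tlen = int(rng.integers(lo, hi + 1))
        if tlen >= len(seq):
            start, tlen = 0, len(seq)
        else:
            start = int(rng.integers(0, len(seq) - tlen + 1))
        template = seq[start:start + tlen]
        read_seq, cmap = _apply_errors(template, rng, params.sub_rate,
                                       params.ins_rate, params.del_rate)
        n_read = len(read_seq)
        feats = []
        for f in locus.features:
            a = max(f.start, start) - start
            b = min(f.end, start + tlen) - start
            if b <= a:
                continue
            clipped = (a > f.start - start) or (b < f.end - start)
            feats.append(replace(
                f, start=int(cmap[a]), end=int(cmap[b]),
                unit_count=None if clipped else f.unit_count))
        strand = "+"
        if rng.random() < 0.5:
            strand = "-"
            read_seq = revcomp(read_seq)
            feats = [replace(f, start=n_read - f.end, end=n_read - f.start,
                             strand="-" if f.strand == "+" else "+")
                     for f in reversed(feats)]
        quals = np.clip(q_mean + rng.integers(-2, 3, size=n_read), 2, 60)
        read_id = f"sim_{locus.locus_id}_{i:05d}"
        reads.append(SequencingRead(read_id, read_seq, [int(q) for q in quals]))
        truths.append(ReadTruth(read_id, locus.locus_id, start, start + tlen,
                                strand, [f for f in feats if f.length > 0]))
    return reads, truths


def simulate(params: SimulationParams
             ) -> tuple[list[tuple[str, LocusTruth]],
                        list[SequencingRead], list[ReadTruth],
                        list[ReferenceRepeat], dict]:
    """Full simulation: loci, reads, truth, matching reference DB, monomer info."""
    if params.monomer is not None:
        monomer = params.monomer.upper()
        info = _locate_motifs(monomer)
    else:
        monomer, info = make_monomer(params.monomer_length, params.seed)
    line_refs = make_line_references(params)
    lr = {r.lineage: r.consensus for r in line_refs}
    loci = [simulate_locus(params, i, monomer, info, lr)
            for i in range(params.n_loci)]
    reads, truths = simulate_reads(loci, params)
    refdb = [ReferenceRepeat(SATELLITE_FAMILY, "satellite", monomer)] + line_refs
    return loci, reads, truths, refdb, info


# ---------------------------------------------------------------------------
# Truth-derived annotation and evaluation
# ---------------------------------------------------------------------------

def loci_as_reads(loci: Sequence[tuple[str, LocusTruth]]
                  ) -> tuple[list[SequencingRead], list[ReadTruth]]:
    """Expose each locus as one error-free read (element-level scoring:
    every simulated feature appears exactly once)."""
    reads, truths = [], []
    for seq, lt in loci:
        rid = f"locusread_{lt.locus_id}"
        reads.append(SequencingRead(rid, seq))
        truths.append(ReadTruth(rid, lt.locus_id, 0, len(seq), "+",
                                [replace(f) for f in lt.features]))
    return reads, truths


def truth_annotation(read: SequencingRead, truth: ReadTruth) -> AnnotatedRead:
    """AnnotatedRead built directly from ground truth (no alignment)."""
    if read.read_id != truth.read_id:
        raise ValueError("read/truth id mismatch")
    segs = []
    for f in truth.features:
        if f.ftype == "spacer":
            continue
        cls = {"array": "satellite", "SSR": "SSR", "LINE": "LINE"}[f.ftype]
        segs.append(AnnotatedSegment(
            read_id=read.read_id, start=f.start, end=f.end,
            repeat_class=cls,
            family=f.family or (f"LINE_{f.lineage}" if f.lineage else f.ftype),
            strand=f.strand, support_score=2.0 * f.length, lineage=f.lineage))
    segs.sort(key=lambda s: (s.start, s.end))
    return AnnotatedRead(read, segs)


def evaluate_against_truth(annotated_reads: Sequence[AnnotatedRead],
                           truths: Sequence[ReadTruth],
                           family: str = SATELLITE_FAMILY,
                           boundary_tol: int = 50) -> dict:
    """Score pipeline annotation against simulator ground truth.

    Returns base-level F1 per repeat class, mean array boundary error (bp,
    over truth arrays matched by maximal overlap), and LINE lineage
    accuracy over truth elements overlapped by a predicted LINE segment.
    """
    truth_by_id = {t.read_id: t for t in truths}
    classes = ("satellite", "SSR", "LINE")
    tp = {c: 0 for c in classes}
    fp = {c: 0 for c in classes}
    fn = {c: 0 for c in classes}
    boundary_errors: list[int] = []
    lineage_total = lineage_correct = 0

    for ar in annotated_reads:
        truth = truth_by_id.get(ar.read_id)
        if truth is None:
            raise KeyError(f"no truth for read {ar.read_id!r}")
        n = ar.length
        t_mask = {c: np.zeros(n, dtype=bool) for c in classes}
        p_mask = {c: np.zeros(n, dtype=bool) for c in classes}
        for f in truth.features:
            cls = {"array": "satellite", "SSR": "SSR", "LINE": "LINE",
                   "spacer": None}[f.ftype]
            if cls:
                t_mask[cls][f.start:min(f.end, n)] = True
        for seg in ar.segments:
            if seg.repeat_class in p_mask:
                p_mask[seg.repeat_class][seg.start:seg.end] = True
        for c in classes:
            tp[c] += int((t_mask[c] & p_mask[c]).sum())
            fp[c] += int((~t_mask[c] & p_mask[c]).sum())
            fn[c] += int((t_mask[c] & ~p_mask[c]).sum())

        # array boundaries: coalesce touching truth array features (an
        # inserted duplication leaves two abutting records) before matching
        pred_arrays = [(s.start, s.end) for s in ar.segments
                       if s.family == family]
        truth_arrays: list[list[int]] = []
        for f in truth.features:
            if f.ftype != "array":
                continue
            if truth_arrays and truth_arrays[-1][1] == f.start:
                truth_arrays[-1][1] = f.end
            else:
                truth_arrays.append([f.start, f.end])
        for ta, tb in truth_arrays:
            best = None
            for (a, b) in pred_arrays:
                ov = min(b, tb) - max(a, ta)
                if ov > 0 and (best is None or ov > best[0]):
                    best = (ov, a, b)
            if best is not None:
                boundary_errors.append(abs(best[1] - ta) + abs(best[2] - tb))

        pred_lines = [s for s in ar.segments if s.repeat_class == "LINE"]
        for f in truth.features:
            if f.ftype != "LINE":
                continue
            best = None
            for s in pred_lines:
                ov = min(s.end, f.end) - max(s.start, f.start)
                if ov > 0 and (best is None or ov > best[0]):
                    best = (ov, s)
            if best is not None:
                lineage_total += 1
                if best[1].lineage == f.lineage:
                    lineage_correct += 1

    def f1(c: str) -> float:
        denom = 2 * tp[c] + fp[c] + fn[c]
        return 1.0 if denom == 0 else 2 * tp[c] / denom

    return {
        "base_f1": {c: f1(c) for c in classes},
        "mean_boundary_error": (float(np.mean(boundary_errors))
                                if boundary_errors else float("nan")),
        "lineage_accuracy": (lineage_correct / lineage_total
                             if lineage_total else float("nan")),
        "n_boundary_matched": len(boundary_errors),
        "n_lineage_scored": lineage_total,
    }


def truth_to_frame(truths: Iterable[ReadTruth]) -> pd.DataFrame:
    """BED-like truth table (one row per feature, read coordinates)."""
    rows = []
    for t in truths:
        for f in t.features:
            rows.append({
                "read_id": t.read_id, "start": f.start, "end": f.end,
                "ftype": f.ftype, "family": f.family, "strand": f.strand,
                "lineage": f.lineage, "unit_count": f.unit_count,
                "partial_monomer": f.partial_monomer, "tsd": f.tsd,
                "insert_site": f.insert_site, "full_length": f.full_length,
                "associated": f.associated})
    return pd.DataFrame(rows)
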