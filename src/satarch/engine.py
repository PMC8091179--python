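"""Built-in local-similarity engine (seeded tandem-tiling alignment).

The engine finds, per (read, reference, strand), candidate read regions by
exact k-mer seeding and then aligns each region against a head-to-tail tiling
of the reference with edlib (bit-parallel edit distance, semi-global so the
region may land anywhere inside the tiling). Tiling makes tandem arrays —
including truncated terminal monomers — align contiguously; the alignment
path is then cut at reference-copy boundaries and at long indels, so each
emitted :class:`SimilarityHit` spans at most one reference copy with its own
identity and score. Reference coordinates are folded back to the single
consensus and always reported on its forward orientation.

Scores are bitscore-like: ``2·matches − 3·mismatches − 4·gap_bases``
(floored at 0 on emission), comparable across references and with the SSR
scanner's perfect-run scoring.

An ``external`` engine hook shells out to LASTZ when the binary is
available.
"""

from __future__ import annotations

import logging
import re
import shutil
import subprocess
import tempfile
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np

from ._util import revcomp
from .annotation import ReferenceRepeat, SimilarityHit
from .io import SequencingRead

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")

MATCH_SCORE = 2.0
MISMATCH_PENALTY = 3.0
GAP_PENALTY = 4.0


class EngineNotFoundError(RuntimeError):
    """The selected external alignment engine is not on PATH."""


def hit_score(matches: int, mismatches: int, gaps: int) -> float:
    return MATCH_SCORE * matches - MISMATCH_PENALTY * mismatches \
        - GAP_PENALTY * gaps


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def seed_regions(read_seq: str, ref_seq: str, k: int = 12,
                 max_seed_gap: int = 100, min_region: int = 30
                 ) -> list[tuple[int, int]]:
    """Candidate read intervals sharing exact k-mers with the reference.

    Seed positions separated by more than ``max_seed_gap`` bases split the
    region, so insertions of foreign sequence (SSR expansions, mobile
    elements) inside an array break it into separate candidates.
    """
    kmers = _kmer_set(ref_seq, k)
    n = len(read_seq)
    positions = [i for i in range(n - k + 1) if read_seq[i:i + k] in kmers]
    regions: list[tuple[int, int]] = []
    for pos in positions:
        if regions and pos - (regions[-1][1] - k) <= max_seed_gap:
            regions[-1] = (regions[-1][0], pos + k)
        else:
            regions.append((pos, pos + k))
    return [(s, e) for s, e in regions if e - s >= min_region]


# ---------------------------------------------------------------------------
# Tiled alignment and path splitting
# ---------------------------------------------------------------------------

def _align_region(region_seq: str, ref: ReferenceRepeat,
                  min_identity: float, min_hit: int, split_indel: int,
                  ) -> list[tuple[int, int, int, int, int, int, int]]:
    """Align one read region against a tiling of the reference.

    Returns raw sub-hits ``(q_start, q_end, t_start, t_end, matches,
    mismatches, gap_bases)`` with q on the region, t on the tiling.
    """
    L = ref.length
    n_copies = max(1, -(-len(region_seq) // L) + 1)
    target = ref.consensus * n_copies
    res = edlib.align(region_seq, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return []
    # quick reject: region must be broadly similar overall
    if 1.0 - res["editDistance"] / max(len(region_seq), 1) < min_identity - 0.15:
        return []
    t0 = res["locations"][0][0]
    return _split_path(res["cigar"], t0, L, split_indel)


def _split_path(cigar: str, t_start: int, period: int, split_indel: int
                ) -> list[tuple[int, int, int, int, int, int, int]]:
    """Walk an extended CIGAR, cutting at reference-copy boundaries and
    at indels of length >= split_indel."""
    subs: list[tuple[int, int, int, int, int, int, int]] = []
    q = 0
    t = t_start
    cur = [0, 0, t, t, 0, 0, 0]  # qs, qe, ts, te, m, mm, gaps

    def flush() -> None:
        if cur[1] > cur[0] or cur[3] > cur[2]:
            subs.append(tuple(cur))

    for num, op in _CIGAR_RE.findall(cigar):
        num = int(num)
        if op in ("=", "X", "M"):
            while num > 0:
                # distance to next reference-copy boundary
                room = period - (t % period)
                step = min(num, room)
                cur[1] = q + step
                cur[3] = t + step
                if op == "=":
                    cur[4] += step
                else:
                    cur[5] += step
                q += step
                t += step
                num -= step
                if t % period == 0:  # crossed a copy boundary
                    flush()
                    cur = [q, q, t, t, 0, 0, 0]
        elif op == "I":  # bases present in region, absent in reference
            if num >= split_indel:
                flush()
                q += num
                cur = [q, q, t, t, 0, 0, 0]
            else:
                cur[6] += num
                q += num
                cur[1] = q
        elif op == "D":  # bases present in reference, absent in region
            if num >= split_indel or (t % period) + num >= period:
                flush()
                t += num
                cur = [q, q, t, t, 0, 0, 0]
            else:
                cur[6] += num
                t += num
                cur[3] = t
    flush()
    return subs


def _extend_alignment(a: str, b: str, gap: float = GAP_PENALTY
                      ) -> tuple[int, int, float]:
    """Anchored free-end extension: best-scoring partial alignment of ``a``
    against ``b`` starting at their common origin. Returns (consumed_a,
    consumed_b, score_gain); (0, 0, 0.0) when no extension scores > 0."""
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0, 0, 0.0
    S = np.full((n + 1, m + 1), -1e9)
    S[0, 0] = 0.0
    S[1:, 0] = -gap * np.arange(1, n + 1)
    S[0, 1:] = -gap * np.arange(1, m + 1)
    aa = np.frombuffer(a.encode(), np.uint8)
    bb = np.frombuffer(b.encode(), np.uint8)
    for i in range(1, n + 1):
        diag = S[i - 1, :-1] + np.where(aa[i - 1] == bb, MATCH_SCORE,
                                        -MISMATCH_PENALTY)
        up = S[i - 1, 1:] - gap
        cand = np.maximum(diag, up)
        prev = S[i, 0]
        row = S[i]
        for j in range(1, m + 1):  # left moves are a running recurrence
            v = cand[j - 1]
            left = prev - gap
            if left > v:
                v = left
            row[j] = v
            prev = v
    i, j = np.unravel_index(int(np.argmax(S)), S.shape)
    gain = float(S[i, j])
    if gain <= 0:
        return 0, 0, 0.0
    return int(i), int(j), gain


def _extend_terminal_hits(subs: list, seq: str, rs: int, re_: int,
                          ref: ReferenceRepeat, extend_bp: int,
                          min_gain: float = 8.0) -> list:
    """Recover bases lost at seed-region edges.

    Seed regions end at the last exact k-mer, so under sequencing error the
    terminal bases of an array (or element) fall outside the aligned
    region. Anchored free-end extension past each region edge pulls the
    boundary back out; a minimum score gain keeps error-free boundaries
    exact (chance matches into flanking sequence rarely reach it).
    """
    if not subs or extend_bp <= 0:
        return subs
    L = ref.length
    tiled2 = ref.consensus + ref.consensus
    out = list(subs)

    # rightmost sub-hit touching the region end
    last = max(range(len(out)), key=lambda i: out[i][1])
    qs, qe, ts, te, m, mm, gaps = out[last]
    if qe >= re_ - rs - 1:
        a = seq[rs + qe: rs + qe + extend_bp]
        start = te % L
        b = (tiled2 + ref.consensus)[start:start + extend_bp]
        di, dj, gain = _extend_alignment(a, b)
        if gain >= min_gain:
            add_m = int(gain // MATCH_SCORE)
            out[last] = (qs, qe + di, ts, te + dj, m + add_m, mm, gaps)

    first = min(range(len(out)), key=lambda i: out[i][0])
    qs, qe, ts, te, m, mm, gaps = out[first]
    if qs <= 1:
        lo = max(0, rs + qs - extend_bp)
        a = seq[lo: rs + qs][::-1]
        start = ts % L
        b = tiled2[start + L - extend_bp: start + L][::-1]
        di, dj, gain = _extend_alignment(a, b)
        if gain >= min_gain:
            add_m = int(gain // MATCH_SCORE)
            out[first] = (qs - di, qe, ts - dj, te, m + add_m, mm, gaps)
    return out


def builtin_search(reads: Sequence[SequencingRead],
                   refs: Sequence[ReferenceRepeat],
                   k: int = 12,
                   max_seed_gap: int = 100,
                   min_identity: float = 0.65,
                   min_hit: int = 30,
                   split_indel: int = 20,
                   extend_bp: int = 40,
                   **_ignored) -> list[SimilarityHit]:
    """Seeded tandem-tiling search over both strands of every reference."""
    hits: list[SimilarityHit] = []
    for read in reads:
        for ref in refs:
            for strand in "+-":
                seq = read.sequence if strand == "+" \
                    else revcomp(read.sequence)
                for rs, re_ in seed_regions(seq, ref.consensus, k=k,
                                            max_seed_gap=max_seed_gap,
                                            min_region=min_hit):
                    region = seq[rs:re_]
                    subs = _align_region(region, ref, min_identity,
                                         min_hit, split_indel)
                    subs = _extend_terminal_hits(subs, seq, rs, re_, ref,
                                                 extend_bp)
                    for qs, qe, ts, te, m, mm, gaps in subs:
                        qlen = qe - qs
                        if qlen < min_hit and te - ts < min_hit:
                            continue
                        aln_len = m + mm + gaps
                        if aln_len == 0:
                            continue
                        identity = m / aln_len
                        if identity < min_identity:
                            continue
                        score = hit_score(m, mm, gaps)
                        if score <= 0:
                            continue
                        # fold tiling coordinates onto the consensus
                        L = ref.length
                        fs = ts % L
                        fe = fs + (te - ts)
                        if fe > L:  # numerical guard; splitting bounds te-ts<=L
                            fe = L
                        if fe <= fs:
                            continue
                        # map region coords back to the read's forward strand
                        a = rs + qs
                        b = rs + qe
                        if strand == "-":
                            a, b = read.length - b, read.length - a
                        hits.append(SimilarityHit(
                            read_id=read.read_id, read_start=a, read_end=b,
                            strand=strand, ref_name=ref.name,
                            ref_start=fs, ref_end=fe,
                            identity=round(identity, 6), score=score))
    hits.sort(key=lambda h: (h.read_id, h.read_start, h.read_end,
                             h.ref_name, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Window-level alignment helper (shared with insertion-site mapping)
# ---------------------------------------------------------------------------

def best_infix_alignment(query: str, target: str
                         ) -> tuple[int, int, int] | None:
    """Best semi-global alignment of ``query`` inside ``target``.

    Returns ``(t_start, t_end, edit_distance)`` (half-open target interval)
    for the lowest-distance location, ties toward the lowest start; None if
    alignment is impossible.
    """
    if not query or not target:
        return None
    res = edlib.align(query, target, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    start, end = min(res["locations"], key=lambda loc: (loc[0], loc[1]))
    return start, end + 1, res["editDistance"]


# ---------------------------------------------------------------------------
# External engine (LASTZ)
# ---------------------------------------------------------------------------

def external_search(reads: Sequence[SequencingRead],
                    refs: Sequence[ReferenceRepeat],
                    xdrop: int = 10, hspthresh: int = 1000,
                    binary: str = "lastz", **_ignored) -> list[SimilarityHit]:
    """Run LASTZ with the standard search parameters and parse its hits.

    Raises :class:`EngineNotFoundError` when the binary is not on PATH.
    """
    if shutil.which(binary) is None:
        raise EngineNotFoundError(
            f"external alignment engine {binary!r} not found on PATH; "
            "use engine='builtin' or import pre-computed hits")
    fields = ("name1,size1,start1,length1,strand1,"
              "name2,size2,start2,length2,strand2,identity,score")
    hits: list[SimilarityHit] = []
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        qpath = tmp / "reads.fa"
        with open(qpath, "w") as fh:
            for r in reads:
                fh.write(f">{r.read_id}\n{r.sequence}\n")
        tpath = tmp / "refs.fa"
        with open(tpath, "w") as fh:
            for ref in refs:
                fh.write(f">{ref.name}\n{ref.consensus}\n")
        cmd = [binary, f"{qpath}[multiple,unmask]", str(tpath),
               f"--format=general:{fields}",
               "--ambiguous=iupac", f"--xdrop={xdrop}",
               f"--hspthresh={hspthresh}"]
        out = subprocess.run(cmd, capture_output=True, text=True, check=True)
        for line in out.stdout.splitlines():
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            # name1=read (query file), name2=reference here
            read_id, rsize, rstart, rlen, rstrand = f[0], f[1], f[2], f[3], f[4]
            ref_name, _, tstart, tlen, tstrand = f[5], f[6], f[7], f[8], f[9]
            ident = float(f[10].rstrip("%")) / 100 if "%" in f[10] else float(f[10])
            hits.append(SimilarityHit(
                read_id=read_id, read_start=int(rstart),
                read_end=int(rstart) + int(rlen),
                strand="+" if rstrand == tstrand else "-",
                ref_name=ref_name, ref_start=int(tstart),
                ref_end=int(tstart) + int(tlen),
                identity=ident, score=float(f[11])))
    return hits
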