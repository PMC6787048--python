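"""Seed-and-extend alignment of short probes against a genome.

The search strategy is the classic one for oligo specificity screens: exact
seed words (default 12 nt) anchor candidate loci on either strand, and each
candidate is then verified by a banded edit-distance alignment (edlib, infix
mode) of the full probe against a small target window.  Identity is defined
as matched columns / total alignment columns, so gaps count against it.

Variant events are reported in probe coordinates (1-based): a ``mismatch``
per substituted base, one ``deletion`` per run of probe bases absent from
the target, one ``insertion`` per run of target bases absent from the probe.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import edlib
import numpy as np

from ._seq import encode, kmer_codes, revcomp

_CIGAR_RE = re.compile(r"(\d+)([=XID])")


@dataclass(frozen=True)
class Variant:
    """One alignment difference, in 1-based probe coordinates.

    ``offset`` is the leftmost probe base involved; for an ``insertion``
    (target-only bases) it is the probe base immediately to the left of the
    inserted material.  ``ref`` holds the probe's bases, ``alt`` the
    target's.
    """

    offset: int
    vtype: str  # mismatch | insertion | deletion
    ref: str
    alt: str

    def occupied_range(self) -> tuple[int, int]:
        """1-based inclusive probe positions touched by this event."""
        if self.vtype == "deletion":
            return self.offset, self.offset + len(self.ref) - 1
        if self.vtype == "insertion":
            return self.offset, self.offset + 1
        return self.offset, self.offset


@dataclass
class Match:
    """A candidate locus for a probe on a target genome."""

    chrom: str
    start: int  # 0-based, target forward strand
    end: int  # half-open
    strand: str  # '+' or '-'
    identity: float
    n_matches: int
    n_columns: int
    variants: list[Variant] = field(default_factory=list)
    cigar: str = ""

    @property
    def n_variant_events(self) -> int:
        return len(self.variants)


class SeedIndex:
    """Positions of every exact seed word (default 12-mer) in a genome.

    Built once per genome; lookups are vectorized searchsorted calls against
    the sorted code array.
    """

    def __init__(self, genome: Mapping[str, str], seed_len: int = 12):
        self.seed_len = int(seed_len)
        self.chrom_names: list[str] = list(genome)
        self.genome = dict(genome)
        codes_all, pos_all, cid_all = [], [], []
        for cid, name in enumerate(self.chrom_names):
            codes, valid = kmer_codes(encode(genome[name]), self.seed_len)
            idx = np.nonzero(valid)[0]
            codes_all.append(codes[idx])
            pos_all.append(idx.astype(np.int64))
            cid_all.append(np.full(idx.size, cid, dtype=np.int32))
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, np.uint64)
        pos = np.concatenate(pos_all) if pos_all else np.empty(0, np.int64)
        cid = np.concatenate(cid_all) if cid_all else np.empty(0, np.int32)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = pos[order]
        self._cid = cid[order]

    def occurrences(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) slice bounds into the sorted arrays for each query code."""
        lo = np.searchsorted(self._codes, codes, side="left")
        hi = np.searchsorted(self._codes, codes, side="right")
        return lo, hi

    def hits(self, lo: int, hi: int) -> tuple[np.ndarray, np.ndarray]:
        """Chromosome ids and positions for one occurrence slice."""
        return self._cid[lo:hi], self._pos[lo:hi]


def _parse_cigar(cigar: str, qseq: str, tseq: str, t0: int) -> tuple[int, int, list[Variant]]:
    """Walk an extended cigar; return (matches, columns, variants).

    ``tseq`` is the aligned window, ``t0`` the offset of the alignment start
    within it.
    """
    qpos = 0
    tpos = t0
    matches = 0
    columns = 0
    variants: list[Variant] = []
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        columns += n
        if op == "=":
            matches += n
            qpos += n
            tpos += n
        elif op == "X":
            for j in range(n):  # each substituted base is its own event
                variants.append(
                    Variant(qpos + j + 1, "mismatch", qseq[qpos + j], tseq[tpos + j])
                )
            qpos += n
            tpos += n
        elif op == "I":  # probe-only bases: a deletion in the target
            variants.append(Variant(qpos + 1, "deletion", qseq[qpos : qpos + n], ""))
            qpos += n
        elif op == "D":  # target-only bases: an insertion relative to the probe
            variants.append(
                Variant(max(qpos, 1), "insertion", "", tseq[tpos : tpos + n])
            )
            tpos += n
    return matches, columns, variants


def _flip_variants(variants: list[Variant], qlen: int) -> list[Variant]:
    """Map variants found against the reverse-complemented probe back to
    forward-probe coordinates."""
    out = []
    for v in variants:
        if v.vtype == "mismatch":
            off = qlen - v.offset + 1
        elif v.vtype == "deletion":
            off = qlen - (v.offset + len(v.ref) - 1) + 1
        else:  # insertion sits between off and off+1 on the rc probe
            off = max(qlen - v.offset, 1)
        out.append(Variant(off, v.vtype, revcomp(v.ref), revcomp(v.alt)))
    return sorted(out, key=lambda v: v.offset)


def _overlaps(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> bool:
    return a_lo < b_hi and b_lo < a_hi


def max_edits(qlen: int, min_identity: float) -> int:
    """Edit-distance budget implied by an identity threshold.

    A counterpart alignment must satisfy both identity >= threshold and
    edit distance <= floor((1 - threshold) * len); without the cap, long
    gapped alignments can reach the identity threshold against random
    sequence (identity is matches/columns and columns grow with gaps)."""
    return int((1.0 - min_identity) * qlen)


def extend_alignment(
    query: str, target: str, t0: int, pad: int = 16, max_rounds: int = 3
) -> tuple[int, int, int, int, list[Variant], str] | None:
    """Canonical alignment of ``query`` around anchor ``t0`` on ``target``.

    The probe is infix-aligned in the window ``[t0 - pad, t0 + len + pad]``
    and re-anchored until the alignment start is the anchor itself, so the
    reported path depends only on the local sequence content, never on how
    the anchor was first found (equal-cost paths would otherwise tie-break
    differently for different window extents).  Returns
    ``(start, end, matches, columns, variants, cigar)`` or None.
    """
    qlen = len(query)
    for _ in range(max_rounds):
        w_lo = max(0, t0 - pad)
        w_hi = min(len(target), t0 + qlen + pad)
        if w_hi - w_lo < qlen // 2:
            return None
        window = target[w_lo:w_hi]
        aln = edlib.align(query, window, mode="HW", task="path")
        if aln["editDistance"] < 0 or not aln["locations"]:
            return None
        t_beg, t_end = aln["locations"][0]
        start = w_lo + t_beg
        if start == t0:
            break
        t0 = start
    matches, columns, variants = _parse_cigar(aln["cigar"], query, window, t_beg)
    return start, w_lo + t_end + 1, matches, columns, variants, aln["cigar"]


def find_matches(
    query: str,
    index: SeedIndex,
    min_identity: float = 0.75,
    exclude: tuple[str, int, int] | None = None,
    max_seed_occ: int = 64,
    max_candidates: int = 16,
    pad: int = 20,
    stop_at_first: bool = False,
) -> list[Match]:
    """All loci where ``query`` aligns at >= ``min_identity``.

    ``exclude`` masks the probe's own locus (chrom, start, end; 0-based
    half-open).  Candidate loci are found on both strands; results are
    deduplicated by target interval and sorted by descending identity.
    """
    qlen = len(query)
    results: list[Match] = []
    for strand in ("+", "-"):
        qseq = query if strand == "+" else revcomp(query)
        codes, valid = kmer_codes(encode(qseq), index.seed_len)
        if codes.size == 0:
            continue
        lo, hi = index.occurrences(codes)
        # gather candidate (chrom, diagonal-start) pairs with vote counts
        votes: dict[tuple[int, int], int] = {}
        for off in np.nonzero(valid & (hi - lo <= max_seed_occ) & (hi > lo))[0]:
            cids, poss = index.hits(lo[off], hi[off])
            for c, p in zip(cids.tolist(), poss.tolist()):
                key = (c, p - int(off))
                votes[key] = votes.get(key, 0) + 1
        # cluster nearby diagonals (indels shift the start by a few bp)
        clustered: dict[tuple[int, int], int] = {}
        for (c, s), n in sorted(votes.items()):
            merged = False
            for (cc, ss) in list(clustered):
                if cc == c and abs(ss - s) <= pad:
                    if n > votes.get((cc, ss), 0):
                        clustered[(c, s)] = clustered.pop((cc, ss)) + n
                    else:
                        clustered[(cc, ss)] += n
                    merged = True
                    break
            if not merged:
                clustered[(c, s)] = n
        candidates = sorted(clustered.items(), key=lambda kv: -kv[1])[:max_candidates]
        for (cid, s0), _n in candidates:
            chrom = index.chrom_names[cid]
            target = index.genome[chrom]
            ext = extend_alignment(qseq, target, s0)
            if ext is None:
                continue
            start, end, matches, columns, variants, cigar = ext
            identity = matches / columns if columns else 0.0
            if exclude is not None and chrom == exclude[0] and _overlaps(
                start, end, exclude[1], exclude[2]
            ):
                continue
            if identity < min_identity or columns - matches > max_edits(qlen, min_identity):
                continue
            if strand == "-":
                variants = _flip_variants(variants, qlen)
            m = Match(chrom, start, end, strand, identity, matches, columns, variants, cigar)
            # dedupe against an overlapping locus already found
            kept = False
            for i, prev in enumerate(results):
                if prev.chrom == m.chrom and _overlaps(prev.start, prev.end, m.start, m.end):
                    if m.identity > prev.identity:
                        results[i] = m
                    kept = True
                    break
            if not kept:
                results.append(m)
                if stop_at_first:
                    return sorted(results, key=lambda r: -r.identity)
    return sorted(results, key=lambda r: -r.identity)


def _exhaustive_matches(query: str, index: SeedIndex, min_identity: float,
                        pad: int = 20) -> list[Match]:
    """Whole-genome edit-distance scan (both strands) for probes whose
    counterpart carries no exact seed word (e.g. mismatches spaced closer
    than the seed length).  Takes the best-edit-distance locus per strand
    and chromosome and re-aligns a local window for the identity/cigar."""
    qlen = len(query)
    out: list[Match] = []
    max_ed = max_edits(qlen, min_identity)
    for strand in ("+", "-"):
        qseq = query if strand == "+" else revcomp(query)
        for chrom in index.chrom_names:
            target = index.genome[chrom]
            scan = edlib.align(qseq, target, mode="HW", task="locations", k=max_ed)
            if scan["editDistance"] < 0:
                continue
            for t_beg, t_end in scan["locations"][:4]:
                anchor = t_beg if t_beg is not None else t_end - qlen + 1
                ext = extend_alignment(qseq, target, anchor)
                if ext is None:
                    continue
                start, end, matches, columns, variants, cigar = ext
                identity = matches / columns if columns else 0.0
                if identity < min_identity or columns - matches > max_ed:
                    continue
                if strand == "-":
                    variants = _flip_variants(variants, qlen)
                m = Match(chrom, start, end, strand, identity,
                          matches, columns, variants, cigar)
                if not any(
                    p.chrom == m.chrom and _overlaps(p.start, p.end, m.start, m.end)
                    for p in out
                ):
                    out.append(m)
    return sorted(out, key=lambda r: -r.identity)


def best_match(
    query: str,
    index: SeedIndex,
    min_identity: float = 0.75,
    exclude: tuple[str, int, int] | None = None,
    exhaustive: bool = False,
    **kw,
) -> tuple[Match | None, str]:
    """Best locus and a status: ``unique``, ``absent`` or ``multi``.

    ``multi`` means two distinct loci tie at the top identity (the probe is
    treated as multi-mapping and rejected downstream).  With ``exhaustive``,
    an empty seed-based search falls back to a whole-genome edit-distance
    scan before declaring the probe absent, so an "absent" verdict really
    means no locus anywhere reaches ``min_identity``.
    """
    ms = find_matches(query, index, min_identity=min_identity, exclude=exclude, **kw)
    if not ms and exhaustive and exclude is None:
        ms = _exhaustive_matches(query, index, min_identity)
    if not ms:
        return None, "absent"
    if len(ms) > 1 and abs(ms[0].identity - ms[1].identity) < 1e-9:
        return None, "multi"
    return ms[0], "unique"
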