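"""Single-copy oligo selection.

Candidate 45-nt oligos are tiled every 5 bp along a chromosome and filtered
in two passes, mirroring standard oligo-painting probe selection:

1. **k-mer repetitiveness** - any 17-mer whose genome-wide frequency exceeds
   100 is "repetitive"; an oligo containing 2 or more repetitive 17-mers is
   discarded.  Frequencies come from an assembly by default (canonical
   k-mers) or from a read set, in which case the threshold should be scaled
   to the read coverage.
2. **homology** - an oligo with a second locus anywhere in the genome (either
   strand) at >= 75% identity is discarded.

The homology pass short-circuits: an oligo none of whose 12-nt seed words
occurs anywhere but its own locus cannot have a candidate second locus and
passes without alignment, which makes whole-chromosome screens cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from ._seq import canonical_kmer_codes, encode, is_acgt, kmer_codes, rc_kmer_codes
from ._seq import revcomp as rc_seq
from .align import SeedIndex, find_matches


@dataclass(frozen=True)
class Oligo:
    """A candidate probe: a fixed-length window on one haplotype's forward
    strand."""

    haplotype_id: str
    chrom: str
    start: int  # 0-based
    seq: str
    strand: str = "+"

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def end(self) -> int:
        return self.start + len(self.seq)

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class ScreenConfig:
    """Parameters of the single-copy screen (defaults are the published
    painting-probe settings)."""

    oligo_len: int = 45
    step: int = 5
    k: int = 17
    repeat_freq_threshold: int = 100
    max_repetitive_kmers_allowed: int = 1
    homology_identity: float = 0.75
    seed_len: int = 12

    def __post_init__(self):
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.k >= self.oligo_len:
            raise ValueError("k must be smaller than the oligo length")
        if self.repeat_freq_threshold <= 0 or self.homology_identity <= 0:
            raise ValueError("thresholds must be positive")


class KmerIndex:
    """Genome-wide k-mer frequency table backed by sorted numpy code arrays.

    ``canonical=True`` merges each k-mer with its reverse complement, which
    is what a read-based count effectively sees.
    """

    def __init__(self, codes: np.ndarray, counts: np.ndarray, k: int,
                 canonical: bool, source: str = "assembly"):
        self.k = k
        self.canonical = canonical
        self.source = source
        self._codes = codes
        self._counts = counts

    @classmethod
    def build(cls, sequences: Iterable[str], k: int = 17, canonical: bool = True,
              source: str = "assembly") -> "KmerIndex":
        if k < 1:
            raise ValueError("k must be >= 1")
        parts = []
        for seq in sequences:
            codes, valid = kmer_codes(encode(seq), k)
            codes = codes[valid]
            if canonical and codes.size:
                codes = canonical_kmer_codes(codes, k)
            parts.append(codes)
        allc = np.concatenate(parts) if parts else np.empty(0, np.uint64)
        codes, counts = np.unique(allc, return_counts=True)
        return cls(codes, counts, k, canonical, source)

    def __len__(self) -> int:
        return int(self._codes.size)

    def counts_for_codes(self, codes: np.ndarray) -> np.ndarray:
        """Frequencies for raw (non-canonical) k-mer codes; absent -> 0."""
        out = np.zeros(codes.size, dtype=np.int64)
        if self._codes.size == 0:
            return out
        if self.canonical:
            codes = canonical_kmer_codes(codes.astype(np.uint64), self.k)
        idx = np.searchsorted(self._codes, codes)
        idx = np.minimum(idx, self._codes.size - 1)
        hit = self._codes[idx] == codes
        out[hit] = self._counts[idx[hit]]
        return out

    def get(self, kmer: str) -> int:
        """Frequency of one k-mer string (0 if absent or non-ACGT)."""
        if len(kmer) != self.k or not is_acgt(kmer):
            return 0
        codes, valid = kmer_codes(encode(kmer), self.k)
        if not valid[0]:
            return 0
        return int(self.counts_for_codes(codes)[0])


def tile_oligos(seq: str, cfg: ScreenConfig | None = None,
                haplotype_id: str = "hap", chrom: str = "chr1") -> list[Oligo]:
    """Tile candidate oligos at starts 0, step, 2*step, ...

    Oligos containing non-ACGT characters are dropped.  A sequence shorter
    than the oligo length yields an empty list with a warning.
    """
    cfg = cfg or ScreenConfig()
    L = len(seq)
    if L < cfg.oligo_len:
        warnings.warn(
            f"sequence ({L} bp) shorter than oligo length ({cfg.oligo_len} nt); no oligos",
            stacklevel=2,
        )
        return []
    out = []
    for start in range(0, L - cfg.oligo_len + 1, cfg.step):
        s = seq[start : start + cfg.oligo_len]
        if is_acgt(s):
            out.append(Oligo(haplotype_id, chrom, start, s))
    return out


def count_repetitive_kmers(oligo: Oligo, index: KmerIndex,
                           freq_threshold: int = 100) -> int:
    """Number of the oligo's constituent k-mers with genome frequency
    strictly above ``freq_threshold``."""
    codes, valid = kmer_codes(encode(oligo.seq), index.k)
    counts = index.counts_for_codes(codes[valid])
    return int((counts > freq_threshold).sum())


def homology_screen(
    oligo: Oligo,
    genome: Mapping[str, str] | SeedIndex,
    min_identity: float = 0.75,
    self_window: tuple[str, int, int] | None = None,
) -> bool:
    """True (pass) iff no second locus aligns to the oligo at
    >= ``min_identity`` outside its own window, on either strand."""
    index = genome if isinstance(genome, SeedIndex) else SeedIndex(genome)
    if self_window is None:
        self_window = (oligo.chrom, oligo.start, oligo.end)
    hits = find_matches(
        oligo.seq, index, min_identity=min_identity, exclude=self_window,
        stop_at_first=True,
    )
    return not hits


def select_single_copy(
    seq: str,
    genome: Mapping[str, str] | None = None,
    index: KmerIndex | None = None,
    cfg: ScreenConfig | None = None,
    haplotype_id: str = "hap",
    chrom: str = "chr1",
    seed_index: SeedIndex | None = None,
) -> list[Oligo]:
    """Tile, k-mer-filter and homology-filter one chromosome.

    ``genome`` defaults to ``{chrom: seq}``; ``index`` defaults to canonical
    k-mer counts of that genome.  Output is sorted by start.
    """
    cfg = cfg or ScreenConfig()
    if genome is None:
        genome = {chrom: seq}
    if index is None:
        index = KmerIndex.build(genome.values(), k=cfg.k, canonical=True)
    oligos = tile_oligos(seq, cfg, haplotype_id=haplotype_id, chrom=chrom)
    if not oligos:
        return []

    # --- vectorized k-mer pass over the whole chromosome ---
    codes17, valid17 = kmer_codes(encode(seq), cfg.k)
    counts = index.counts_for_codes(codes17)
    rep = ((counts > cfg.repeat_freq_threshold) & valid17).astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(rep)))
    per_k = cfg.oligo_len - cfg.k + 1  # k-mers per oligo
    starts = np.array([o.start for o in oligos], dtype=np.int64)
    n_rep = cs[starts + per_k] - cs[starts]
    oligos = [o for o, n in zip(oligos, n_rep.tolist()) if n <= cfg.max_repetitive_kmers_allowed]
    if not oligos:
        return []

    # --- homology pass ---
    # A random genome of megabase scale duplicates many 12-mers by chance,
    # so "some seed occurs twice" alone would send nearly every oligo to a
    # full alignment.  Instead each duplicate seed's diagonal is checked by
    # a direct ungapped comparison; only candidates whose ungapped identity
    # approaches the threshold, or whose seeds scatter over nearby distinct
    # diagonals (the indel signature), escalate to the full screen.
    if seed_index is None:
        seed_index = SeedIndex(genome, seed_len=cfg.seed_len)
    codes12, valid12 = kmer_codes(encode(seq), cfg.seed_len)
    lo, hi = seed_index.occurrences(codes12)
    fwd_extra = ((hi - lo) > 1) & valid12  # any occurrence beyond the oligo's own
    rc12 = rc_kmer_codes(codes12, cfg.seed_len)
    lo_r, hi_r = seed_index.occurrences(rc12)
    rc_any = ((hi_r - lo_r) > 0) & valid12
    flagged_pos = np.nonzero(fwd_extra | rc_any)[0]
    per_s = cfg.oligo_len - cfg.seed_len + 1
    starts = np.array([o.start for o in oligos], dtype=np.int64)
    f_lo = np.searchsorted(flagged_pos, starts)
    f_hi = np.searchsorted(flagged_pos, starts + per_s)
    try:
        self_cid = seed_index.chrom_names.index(chrom)
    except ValueError:
        self_cid = -1
    escalate_margin = 0.10
    max_occ = 32
    kept: list[Oligo] = []
    for o, i0, i1 in zip(oligos, f_lo.tolist(), f_hi.tolist()):
        if i0 == i1:
            kept.append(o)  # no non-self seed anywhere: trivially single-copy
            continue
        suspicious = False
        diags: list[tuple[int, str, int]] = []
        for q in flagged_pos[i0:i1].tolist():
            off = q - o.start
            if fwd_extra[q]:
                if hi[q] - lo[q] > max_occ:
                    suspicious = True
                    break
                cids, poss = seed_index.hits(int(lo[q]), int(hi[q]))
                for c, p in zip(cids.tolist(), poss.tolist()):
                    if c == self_cid and p == q:
                        continue
                    diags.append((c, "+", p - off))
            if rc_any[q]:
                if hi_r[q] - lo_r[q] > max_occ:
                    suspicious = True
                    break
                cids, poss = seed_index.hits(int(lo_r[q]), int(hi_r[q]))
                for c, p in zip(cids.tolist(), poss.tolist()):
                    # seed offset within the reverse-complemented oligo
                    j = per_s - 1 - off
                    diags.append((c, "-", p - j))
        if not suspicious and diags:
            diags.sort()
            for k, (c, strand, d) in enumerate(diags):
                if k + 1 < len(diags):
                    c2, s2, d2 = diags[k + 1]
                    if c2 == c and s2 == strand and d2 != d and d2 - d <= 12:
                        suspicious = True  # split diagonals: possible indel copy
                        break
                tname = seed_index.chrom_names[c]
                tseq = seed_index.genome[tname]
                if d < 0 or d + o.length > len(tseq):
                    suspicious = True
                    break
                if tname == chrom and d < o.end and o.start < d + o.length:
                    continue  # overlaps the oligo's own locus
                cand = tseq[d : d + o.length]
                qseq = o.seq if strand == "+" else rc_seq(o.seq)
                mism = sum(a != b for a, b in zip(qseq, cand))
                if (o.length - mism) / o.length >= cfg.homology_identity - escalate_margin:
                    suspicious = True
                    break
        if not suspicious:
            kept.append(o)
        elif homology_screen(o, seed_index, cfg.homology_identity):
            kept.append(o)
    return sorted(kept, key=lambda o: o.start)
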