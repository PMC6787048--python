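"""Synthetic diploid genomes for probe-design and crossover-mapping runs.

This module generates the three layers of data the pipeline consumes, with
the statistical structure of a real maize-style experiment:

1. a repeat-containing reference chromosome (haplotype A);
2. a second haplotype differing by SNPs, short indels and large
   presence-absence (PAV) segments, with an exact variant truth list and a
   monotone coordinate map between the two haplotypes;
3. F2 recombinant chromosome pairs (0-2 crossovers per copy) and
   low-coverage per-site allele observations with sequencing-like noise.

Default rates are chosen to mimic an intercross of two diverged inbreds
sequenced at ~2.4x: ~1 SNP per 100 bp outside PAV segments, short indels an
order of magnitude rarer, and PAV segments of at least 200 bp so that a
45-nt oligo can sit entirely inside one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import decode, encode

#: study-condition defaults used by the end-to-end tests and the CLI
DEFAULT_SNP_RATE = 0.01
DEFAULT_INDEL_RATE = 1e-3
DEFAULT_MEAN_DEPTH = 2.41
DEFAULT_ERROR_RATE = 0.01
#: per chromosome copy; >=3 crossovers per copy are never drawn
DEFAULT_CO_DIST = {0: 0.36, 1: 0.54, 2: 0.10}
MIN_PAV_LEN = 200

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class VariantTruth:
    """A planted difference between haplotype A and haplotype B.

    ``position`` is a 0-based offset on haplotype A.  For insertions the
    alternate bases are inserted *before* ``position``; for deletions
    ``ref_allele`` is the deleted A-sequence starting at ``position``.
    """

    position: int
    vtype: str  # snp | insertion | deletion | pav_insertion | pav_deletion
    ref_allele: str
    alt_allele: str

    @property
    def ref_span(self) -> int:
        return len(self.ref_allele)


@dataclass
class HaplotypePair:
    """Two homologous chromosome sequences plus their exact variant truth."""

    seq_a: str
    seq_b: str
    truth: list[VariantTruth]
    #: b_of_a[i] = B-coordinate of A-position i (deleted A-positions map,
    #: non-decreasingly, to the B-coordinate where the deletion closed)
    b_of_a: np.ndarray
    #: True where the A-position survives in B
    a_present: np.ndarray

    def snp_positions(self) -> np.ndarray:
        return np.array([v.position for v in self.truth if v.vtype == "snp"], dtype=np.int64)

    def snp_alleles(self) -> dict[int, tuple[str, str]]:
        return {v.position: (v.ref_allele, v.alt_allele) for v in self.truth if v.vtype == "snp"}


@dataclass
class RecombinantTruth:
    """One F2 chromosome copy: crossover breakpoints in A-coordinates and the
    alternating parental origin of the tiled segments."""

    breakpoints: list[int]
    origin_segments: list[str]  # alternating 'A'/'B', one per segment
    length: int

    def origin_at(self, pos: int) -> str:
        i = int(np.searchsorted(np.asarray(self.breakpoints), pos, side="right"))
        return self.origin_segments[i]


def generate_reference(
    length_bp: int,
    repeat_specs: Sequence[tuple[int, int]] = (),
    seed: int = 0,
) -> str:
    """Random ACGT reference with planted tandem-free repeat families.

    Each ``(monomer_len, copy_number)`` spec creates one random monomer that
    is written over ``copy_number`` random non-overlapping positions, so its
    internal k-mers reach genome-wide frequency >= copy_number.
    """
    if length_bp < 1000:
        raise ValueError(f"length_bp must be >= 1000, got {length_bp}")
    total_repeat = sum(m * c for m, c in repeat_specs)
    if total_repeat > length_bp:
        raise ValueError(
            f"repeat content ({total_repeat} bp) exceeds genome length ({length_bp} bp)"
        )
    rng = np.random.default_rng(seed)
    bases = rng.integers(0, 4, size=length_bp, dtype=np.uint8)
    # lay repeat copies into random gaps: draw gap sizes around the blocks
    blocks: list[np.ndarray] = []
    for monomer_len, copies in repeat_specs:
        monomer = rng.integers(0, 4, size=monomer_len, dtype=np.uint8)
        blocks.extend([monomer] * copies)
    if blocks:
        order = rng.permutation(len(blocks))
        blocks = [blocks[i] for i in order]
        free = length_bp - sum(b.size for b in blocks)
        cuts = np.sort(rng.integers(0, free + 1, size=len(blocks)))
        pos = 0
        prev_cut = 0
        for b, cut in zip(blocks, cuts):
            pos += int(cut - prev_cut)
            bases[pos : pos + b.size] = b
            pos += b.size
            prev_cut = cut
    return decode(bases)


def _place_intervals(
    rng: np.random.Generator,
    n_sites: Iterable[tuple[int, int]],
    length: int,
    occupied: list[tuple[int, int]],
) -> list[int]:
    """Random non-overlapping start positions for intervals of given widths
    (width, margin) avoiding ``occupied``; appends to ``occupied``."""
    starts = []
    for width, margin in n_sites:
        for _ in range(1000):
            s = int(rng.integers(margin, max(length - width - margin, margin + 1)))
            if all(s + width <= lo or s >= hi for lo, hi in occupied):
                occupied.append((s, s + width))
                starts.append(s)
                break
        else:
            raise ValueError("could not place non-overlapping segment; genome too crowded")
    return starts


def derive_haplotype(
    ref: str,
    snp_rate: float = DEFAULT_SNP_RATE,
    indel_rate: float = DEFAULT_INDEL_RATE,
    pav_specs: Sequence[tuple] = (),
    seed: int = 0,
    min_pav_len: int = MIN_PAV_LEN,
    max_indel_len: int = 10,
) -> HaplotypePair:
    """Mutate ``ref`` (haplotype A) into haplotype B.

    ``pav_specs`` entries are ``(length, kind)`` with kind in
    ``{"pav_insertion", "pav_deletion"}``, optionally ``(length, kind, position)``
    to pin the segment.  PAV segments must be at least ``min_pav_len`` and may
    not overlap each other.
    """
    for rate, name in ((snp_rate, "snp_rate"), (indel_rate, "indel_rate")):
        if not 0 <= rate <= 0.05:
            raise ValueError(f"{name} must be in [0, 0.05], got {rate}")
    L = len(ref)
    rng = np.random.default_rng(seed)
    occupied: list[tuple[int, int]] = []
    variants: list[VariantTruth] = []

    # PAV segments first (largest constraints)
    pinned, floating = [], []
    for spec in pav_specs:
        length, kind = spec[0], spec[1]
        if kind not in ("pav_insertion", "pav_deletion"):
            raise ValueError(f"unknown PAV kind {kind!r}")
        if length < min_pav_len:
            raise ValueError(
                f"PAV segment of {length} bp is shorter than the minimum {min_pav_len} bp"
            )
        (pinned if len(spec) > 2 else floating).append(spec)
    for length, kind, pos in pinned:
        width = length if kind == "pav_deletion" else 0
        for lo, hi in occupied:
            if pos < hi and lo < pos + max(width, 1):
                raise ValueError(f"overlapping PAV specs at position {pos}")
        occupied.append((pos, pos + max(width, 1)))
        alt = decode(rng.integers(0, 4, size=length, dtype=np.uint8)) if kind == "pav_insertion" else ""
        refa = ref[pos : pos + length] if kind == "pav_deletion" else ""
        variants.append(VariantTruth(pos, kind, refa, alt))
    for length, kind in floating:
        width = length if kind == "pav_deletion" else 1
        (pos,) = _place_intervals(rng, [(width, 50)], L, occupied)
        alt = decode(rng.integers(0, 4, size=length, dtype=np.uint8)) if kind == "pav_insertion" else ""
        refa = ref[pos : pos + length] if kind == "pav_deletion" else ""
        variants.append(VariantTruth(pos, kind, refa, alt))

    # short indels
    n_indels = rng.binomial(L, indel_rate)
    for _ in range(n_indels):
        ilen = int(rng.integers(1, max_indel_len + 1))
        kind = "deletion" if rng.random() < 0.5 else "insertion"
        width = ilen if kind == "deletion" else 1
        try:
            (pos,) = _place_intervals(rng, [(width, 1)], L, occupied)
        except ValueError:
            continue  # crowded toy genome: drop the event
        if kind == "deletion":
            variants.append(VariantTruth(pos, "deletion", ref[pos : pos + ilen], ""))
        else:
            alt = decode(rng.integers(0, 4, size=ilen, dtype=np.uint8))
            variants.append(VariantTruth(pos, "insertion", "", alt))

    # SNPs everywhere not already occupied
    snp_pos = np.nonzero(rng.random(L) < snp_rate)[0]
    if occupied and snp_pos.size:
        occ = np.array(sorted(occupied))
        idx = np.searchsorted(occ[:, 0], snp_pos, side="right") - 1
        inside = (idx >= 0) & (snp_pos < occ[np.maximum(idx, 0), 1])
        snp_pos = snp_pos[~inside]
    ref_codes = encode(ref)
    for pos in snp_pos.tolist():
        old = ref_codes[pos]
        new = (old + rng.integers(1, 4)) % 4
        variants.append(VariantTruth(int(pos), "snp", "ACGT"[old], "ACGT"[new]))

    variants.sort(key=lambda v: v.position)
    return apply_truth(ref, variants)


def apply_truth(seq_a: str, truth: Sequence[VariantTruth]) -> HaplotypePair:
    """Apply a sorted variant list to haplotype A, producing haplotype B and
    the A->B coordinate map."""
    L = len(seq_a)
    parts: list[str] = []
    b_of_a = np.empty(L + 1, dtype=np.int64)
    a_present = np.ones(L, dtype=bool)
    a_cursor = 0
    b_cursor = 0
    last_end = -1
    for v in truth:
        if v.position <= last_end and not (v.ref_span == 0 and v.position == last_end + 1):
            raise ValueError(f"overlapping or unsorted variants near position {v.position}")
        # copy invariant block
        block = seq_a[a_cursor : v.position]
        parts.append(block)
        b_of_a[a_cursor : v.position] = b_cursor + np.arange(len(block))
        b_cursor += len(block)
        a_cursor = v.position
        if v.vtype == "snp":
            if seq_a[v.position] != v.ref_allele:
                raise ValueError(f"truth/ref mismatch at {v.position}")
            parts.append(v.alt_allele)
            b_of_a[a_cursor] = b_cursor
            a_cursor += 1
            b_cursor += 1
        elif v.vtype in ("deletion", "pav_deletion"):
            span = v.ref_span
            if seq_a[v.position : v.position + span] != v.ref_allele:
                raise ValueError(f"truth/ref mismatch at {v.position}")
            b_of_a[a_cursor : a_cursor + span] = b_cursor
            a_present[a_cursor : a_cursor + span] = False
            a_cursor += span
        else:  # insertion / pav_insertion
            parts.append(v.alt_allele)
            b_cursor += len(v.alt_allele)
        last_end = v.position + max(v.ref_span, 1) - 1
    parts.append(seq_a[a_cursor:])
    b_of_a[a_cursor:L] = b_cursor + np.arange(L - a_cursor)
    b_of_a[L] = b_cursor + (L - a_cursor)
    seq_b = "".join(parts)
    return HaplotypePair(seq_a, seq_b, list(truth), b_of_a, a_present)


def simulate_f2_plant(
    pair: HaplotypePair,
    co_count_dist: Mapping[int, float] | None = None,
    seed: int = 0,
    position_profile: str = "uniform",
) -> tuple[RecombinantTruth, RecombinantTruth]:
    """Draw the two chromosome copies of one F2 plant.

    Each copy gets 0-2 crossover breakpoints (counts from ``co_count_dist``)
    at positions drawn either uniformly or, with ``position_profile=
    "distal"``, from an arcsine profile concentrated near the telomeres.
    """
    dist = dict(co_count_dist or DEFAULT_CO_DIST)
    if abs(sum(dist.values()) - 1.0) > 1e-9:
        raise ValueError("co_count_dist probabilities must sum to 1")
    if any(k < 0 or k > 2 for k in dist):
        raise ValueError("crossover counts per copy must be in {0, 1, 2}")
    rng = np.random.default_rng(seed)
    L = len(pair.seq_a)
    counts = list(dist.keys())
    probs = np.array([dist[k] for k in counts], dtype=float)

    def one_copy() -> RecombinantTruth:
        k = int(rng.choice(counts, p=probs))
        if position_profile == "distal":
            u = rng.random(k)
            raw = (1 - np.cos(np.pi * u)) / 2 * L
        elif position_profile == "uniform":
            raw = rng.random(k) * L
        else:
            raise ValueError(f"unknown position profile {position_profile!r}")
        bps = sorted({int(np.clip(p, 1, L - 1)) for p in raw})
        start = "A" if rng.random() < 0.5 else "B"
        segs = [start]
        for _ in bps:
            segs.append("B" if segs[-1] == "A" else "A")
        return RecombinantTruth(bps, segs, L)

    return one_copy(), one_copy()


def sample_allele_observations(
    plant: tuple[RecombinantTruth, RecombinantTruth],
    pair: HaplotypePair,
    mean_depth: float = DEFAULT_MEAN_DEPTH,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int = 0,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Site-level allele observations at the truth SNP sites.

    Depth is Poisson(``mean_depth``); sites with depth 0 are dropped.  Each
    read samples one of the two chromosome copies uniformly and reports that
    copy's parental allele (P1 = haplotype A, P2 = haplotype B), flipped with
    probability ``error_rate``; the row's reported allele is that of a random
    read.  qual/mapq columns carry plausible variant-caller scores so the
    input filters have something to act on.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not 0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be in [0, 0.1]")
    rng = np.random.default_rng(seed)
    sites = pair.snp_positions()
    n = sites.size
    depth = rng.poisson(mean_depth, size=n)
    keep = depth >= 1
    sites = sites[keep]
    depth = depth[keep]
    n = sites.size
    copy1, copy2 = plant
    orig1 = np.array([1 if copy1.origin_at(p) == "B" else 0 for p in sites.tolist()])
    orig2 = np.array([1 if copy2.origin_at(p) == "B" else 0 for p in sites.tolist()])
    which = rng.integers(0, 2, size=n)  # which copy the reported read came from
    allele_is_p2 = np.where(which == 0, orig1, orig2).astype(bool)
    flip = rng.random(n) < error_rate
    allele_is_p2 ^= flip
    # caller-style scores: confident biallelic sites score ~20 + 10-25 per
    # supporting read, so most true sites survive the published filters
    qual = 20.0 + depth * rng.uniform(10.0, 25.0, size=n) + rng.uniform(0.0, 5.0, size=n)
    mapq = np.where(rng.random(n) < 0.95, 60, 30)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": sites + 1,  # 1-based, matching variant-caller output
            "allele": np.where(allele_is_p2, "P2", "P1"),
            "depth": depth,
            "qual": np.round(qual, 2),
            "mapq": mapq,
        }
    )
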