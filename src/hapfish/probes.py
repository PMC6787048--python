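"""Haplotype-specific probe construction.

Single-copy oligos from one haplotype are mapped onto the other haplotype's
assembly.  An oligo with no counterpart locus at >= 75% identity is a **PAV
oligo** (its sequence is simply absent from the other haplotype); an oligo
whose counterpart differs by mismatches and/or indels becomes half of a
**SNP oligo pair**: the partner member is the other haplotype's sequence
over the same locus, so the two members differ exactly at the variant
positions.  Variants too close to the oligo ends (outside positions 10-35 of
the 45-mer) discriminate poorly and those oligos are rejected, as are oligos
identical between haplotypes.

Pairs are binned by variant-event count (1, 2, 3-4, >= 5), ΔTm-filtered, and
assembled with the PAV oligos into the two painting probe sets (classically
"hapB"/"hapM" for a B73 x Mo17 design).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import is_acgt, revcomp
from .align import Match, SeedIndex, Variant, best_match
from .screen import KmerIndex, Oligo, ScreenConfig, select_single_copy
from .thermo import DEFAULT_CONDITIONS, ThermoConditions, delta_tm

CLASS_LABELS = ("1", "2", "3-4", "5+")
DEFAULT_VARIANT_WINDOW = (10, 35)
DEFAULT_INCLUDE = frozenset({"PAV", "3-4", "5+"})
DEFAULT_DTM_CUTOFF = 5.0


@dataclass
class CrossMatch:
    """Best counterpart locus of an oligo on the other haplotype."""

    target_chrom: str
    target_start: int
    target_end: int
    strand: str
    identity: float
    variants: list[Variant]

    @classmethod
    def from_match(cls, m: Match) -> "CrossMatch":
        return cls(m.chrom, m.start, m.end, m.strand, m.identity, list(m.variants))


@dataclass
class OligoPair:
    """Matched probe variants: ``member_a`` from the scanned haplotype,
    ``member_b`` the substituted counterpart from the other haplotype."""

    member_a: Oligo
    member_b: Oligo
    n_variants: int
    delta_tm: float = float("nan")
    snp_class: str = ""

    def __post_init__(self):
        if not self.snp_class:
            self.snp_class = variant_class(self.n_variants)


@dataclass
class ProbeSet:
    """A named haplotype-specific probe collection with its class
    composition (counts per PAV / SNP class)."""

    name: str
    haplotype: str
    members: list[Oligo]
    composition: dict[str, int]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class DensityTrack:
    """Per-window oligo counts along a chromosome."""

    window_bp: int
    counts: np.ndarray
    chrom_len: int


def variant_class(n: int) -> str:
    """Class label for a pair with ``n`` variant events."""
    if n < 1:
        raise ValueError("a pair must have at least one variant event")
    if n == 1:
        return "1"
    if n == 2:
        return "2"
    if n <= 4:
        return "3-4"
    return "5+"


def cross_map(
    oligo: Oligo,
    other_genome: Mapping[str, str] | SeedIndex,
    min_identity: float = 0.75,
) -> CrossMatch | None:
    """Best-scoring locus of ``oligo`` on the other haplotype, or None.

    None means either no locus reaches ``min_identity`` (a PAV candidate) or
    two distinct loci tie at the top identity (multi-mapping; such oligos
    are rejected, not treated as PAV -- use :func:`cross_map_status` to tell
    the cases apart).
    """
    m, _status = cross_map_status(oligo, other_genome, min_identity)
    return m


def cross_map_status(
    oligo: Oligo,
    other_genome: Mapping[str, str] | SeedIndex,
    min_identity: float = 0.75,
) -> tuple[CrossMatch | None, str]:
    index = other_genome if isinstance(other_genome, SeedIndex) else SeedIndex(other_genome)
    m, status = best_match(oligo.seq, index, min_identity=min_identity, exhaustive=True)
    return (CrossMatch.from_match(m) if m else None), status


def classify_oligo(
    match: CrossMatch | None,
    variant_window: tuple[int, int] = DEFAULT_VARIANT_WINDOW,
) -> str:
    """PAV / snp_candidate / rejected_identical / rejected_edge_variant.

    An oligo is a SNP candidate only if every variant event lies entirely
    within the (1-based, inclusive) ``variant_window`` of the oligo.
    """
    if match is None:
        return "PAV"
    if not match.variants:
        return "rejected_identical"
    lo, hi = variant_window
    for v in match.variants:
        v_lo, v_hi = v.occupied_range()
        if v_lo < lo or v_hi > hi:
            return "rejected_edge_variant"
    return "snp_candidate"


def make_pair(
    oligo: Oligo,
    match: CrossMatch,
    other_genome: Mapping[str, str],
    other_haplotype_id: str = "other",
    oligo_len: int | None = None,
) -> OligoPair:
    """Build the substituted counterpart oligo from the target genome.

    The counterpart is re-anchored to exactly the oligo length from the
    target genome at the alignment start, so indel-bearing pairs still yield
    two synthesis-length sequences; by construction it equals the oligo with
    each variant's bases replaced by the other haplotype's bases.
    """
    L = oligo_len or oligo.length
    tseq = other_genome[match.target_chrom]
    if match.strand == "+":
        start = match.target_start
        seq_b = tseq[start : start + L]
    else:
        end = match.target_end
        start = max(end - L, 0)
        seq_b = revcomp(tseq[start:end])
    if len(seq_b) < L or not is_acgt(seq_b):
        raise ValueError(
            f"substituted counterpart of {oligo.name} is truncated or non-ACGT"
        )
    member_b = Oligo(other_haplotype_id, match.target_chrom, start, seq_b, match.strand)
    return OligoPair(oligo, member_b, n_variants=len(match.variants))


def filter_delta_tm(
    pairs: Sequence[OligoPair],
    cutoff: float = DEFAULT_DTM_CUTOFF,
    cond: ThermoConditions = DEFAULT_CONDITIONS,
) -> list[OligoPair]:
    """Drop pairs whose members' predicted Tm differs by more than
    ``cutoff`` °C; order preserved.  Fills ``delta_tm`` where missing."""
    out = []
    for p in pairs:
        if p.delta_tm != p.delta_tm:  # NaN: not yet computed
            p.delta_tm = delta_tm(p.member_a.seq, p.member_b.seq, cond)
        if p.delta_tm <= cutoff:
            out.append(p)
    return out


def bin_by_variant_count(pairs: Iterable[OligoPair]) -> dict[str, list[OligoPair]]:
    """Partition pairs into the four variant-count classes."""
    classes: dict[str, list[OligoPair]] = {c: [] for c in CLASS_LABELS}
    for p in pairs:
        classes[variant_class(p.n_variants)].append(p)
    return classes


def probe_set_size(composition: Mapping[str, int],
                   include: Iterable[str] = DEFAULT_INCLUDE) -> int:
    """Probe-set size from per-class counts (PAV plus included SNP classes)."""
    return sum(int(composition.get(c, 0)) for c in set(include))


def assemble_probe_sets(
    pav_a: Sequence[Oligo],
    pav_b: Sequence[Oligo],
    classes: Mapping[str, Sequence[OligoPair]],
    include: Iterable[str] = DEFAULT_INCLUDE,
    names: tuple[str, str] = ("hapA", "hapB"),
    haplotypes: tuple[str, str] = ("A", "B"),
) -> tuple[ProbeSet, ProbeSet]:
    """Combine PAV oligos and the included SNP classes into the two
    haplotype-specific probe sets."""
    include = set(include)
    comp_a: dict[str, int] = {"PAV": len(pav_a)} if "PAV" in include else {"PAV": 0}
    comp_b: dict[str, int] = dict(comp_a)
    members_a = list(pav_a) if "PAV" in include else []
    members_b = list(pav_b) if "PAV" in include else []
    for label in CLASS_LABELS:
        if label not in include:
            continue
        pairs = classes.get(label, [])
        comp_a[label] = len(pairs)
        comp_b[label] = len(pairs)
        members_a.extend(p.member_a for p in pairs)
        members_b.extend(p.member_b for p in pairs)
    for name, members in ((names[0], members_a), (names[1], members_b)):
        loci = {(m.chrom, m.start) for m in members}
        if len(loci) != len(members):
            raise ValueError(f"duplicate loci in probe set {name}")
    set_a = ProbeSet(names[0], haplotypes[0], members_a, comp_a)
    set_b = ProbeSet(names[1], haplotypes[1], members_b, comp_b)
    return set_a, set_b


def density_track(pset: ProbeSet, chrom_len: int, window_bp: int = 500_000) -> DensityTrack:
    """Per-window member counts (an oligo belongs to the window holding its
    start coordinate)."""
    n_win = max((chrom_len + window_bp - 1) // window_bp, 1)
    counts = np.zeros(n_win, dtype=np.int64)
    for m in pset.members:
        if m.start >= chrom_len:
            raise ValueError(f"oligo {m.name} beyond chromosome end {chrom_len}")
        counts[m.start // window_bp] += 1
    return DensityTrack(window_bp, counts, chrom_len)


def off_target_screen(
    pset: ProbeSet,
    genomes: Mapping[str, Mapping[str, str] | SeedIndex],
    min_identity: float = 0.75,
) -> list[tuple[Oligo, str, Match]]:
    """Flag probe-set members with a locus other than their design locus.

    ``genomes`` maps a genome label to its sequences (or a prebuilt
    SeedIndex).  The design locus is excluded only within the member's own
    haplotype genome (identified by matching genome label to the member's
    ``haplotype_id``).  Catches diverged off-targets (e.g. rDNA-like
    families) that evade exact k-mer screens.
    """
    from .align import find_matches

    flags: list[tuple[Oligo, str, Match]] = []
    indexes = {
        label: (g if isinstance(g, SeedIndex) else SeedIndex(g))
        for label, g in genomes.items()
    }
    for member in pset.members:
        for label, index in indexes.items():
            exclude = None
            if label == member.haplotype_id:
                exclude = (member.chrom, member.start, member.end)
            hits = find_matches(
                member.seq, index, min_identity=min_identity, exclude=exclude,
                stop_at_first=True,
            )
            for h in hits:
                flags.append((member, label, h))
    return flags


# ---------------------------------------------------------------------------
# end-to-end design pipeline
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeScan:
    """Classification of one haplotype's single-copy oligos against the
    other haplotype."""

    screened: list[Oligo]
    pav: list[Oligo]
    pairs: list[OligoPair]  # snp candidates, pre-ΔTm
    rejected_identical: int = 0
    rejected_edge: int = 0
    rejected_multi: int = 0


@dataclass
class DesignResult:
    """Full output of a two-haplotype probe design run."""

    scan_a: HaplotypeScan
    scan_b: HaplotypeScan
    pairs: list[OligoPair]  # merged, pre-ΔTm
    pairs_post_dtm: list[OligoPair]
    classes_pre: dict[str, list[OligoPair]]
    classes: dict[str, list[OligoPair]]  # post-ΔTm
    probe_set_a: ProbeSet
    probe_set_b: ProbeSet


def _fast_cross_matches(
    oligos: Sequence[Oligo],
    other_index: SeedIndex,
    source_genome: Mapping[str, str],
    min_identity: float,
) -> dict[int, CrossMatch]:
    """Resolve the easy cross-mapping cases without full alignment.

    When an oligo's first and last seed words each occur exactly once on the
    other haplotype and agree on the diagonal, the counterpart locus is that
    ungapped window.  Identical and single-mismatch counterparts (the bulk
    of a between-haplotype scan) are resolved by direct base comparison --
    a gapped path can never beat them.  Counterparts with two or more
    ungapped mismatches are re-aligned canonically at that anchor, since an
    equal-cost gapped path may score a higher identity.  Anything else
    (no/ambiguous seeds, disagreeing diagonals, sub-threshold identity)
    falls through to the full seed-and-extend search.
    """
    from ._seq import encode as _encode
    from ._seq import kmer_codes as _kmer_codes
    from .align import extend_alignment, max_edits

    resolved: dict[int, CrossMatch] = {}
    by_chrom: dict[str, list[int]] = {}
    for i, o in enumerate(oligos):
        by_chrom.setdefault(o.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        codes, valid = _kmer_codes(_encode(source_genome[chrom]), other_index.seed_len)
        starts = np.array([oligos[i].start for i in idxs], dtype=np.int64)
        last = oligos[idxs[0]].length - other_index.seed_len
        ok = (starts + last < codes.size) & valid[starts] & valid[
            np.minimum(starts + last, codes.size - 1)
        ]
        lo0, hi0 = other_index.occurrences(codes[starts])
        lo1, hi1 = other_index.occurrences(codes[np.minimum(starts + last, codes.size - 1)])
        single = ok & (hi0 - lo0 == 1) & (hi1 - lo1 == 1)
        for j in np.nonzero(single)[0].tolist():
            i = idxs[j]
            o = oligos[i]
            c0, p0 = other_index.hits(int(lo0[j]), int(hi0[j]))
            c1, p1 = other_index.hits(int(lo1[j]), int(hi1[j]))
            if c0[0] != c1[0] or p1[0] - p0[0] != last:
                continue  # disagreeing diagonals: likely an indel
            tchrom = other_index.chrom_names[int(c0[0])]
            d = int(p0[0])
            tseq = other_index.genome[tchrom]
            if d + o.length > len(tseq):
                continue
            window = tseq[d : d + o.length]
            variants = [
                Variant(k + 1, "mismatch", a, b)
                for k, (a, b) in enumerate(zip(o.seq, window))
                if a != b
            ]
            if len(variants) >= 2:
                ext = extend_alignment(o.seq, tseq, d)
                if ext is None:
                    continue
                start, end, matches, columns, variants, _cigar = ext
                identity = matches / columns if columns else 0.0
                if identity < min_identity or columns - matches > max_edits(
                    o.length, min_identity
                ):
                    continue  # too diverged for a local call; escalate
                resolved[i] = CrossMatch(tchrom, start, end, "+", identity, variants)
                continue
            identity = (o.length - len(variants)) / o.length
            resolved[i] = CrossMatch(tchrom, d, d + o.length, "+", identity, variants)
    return resolved


def scan_haplotype(
    oligos: Sequence[Oligo],
    other_index: SeedIndex,
    other_genome: Mapping[str, str],
    other_haplotype_id: str,
    min_identity: float = 0.75,
    variant_window: tuple[int, int] = DEFAULT_VARIANT_WINDOW,
    source_genome: Mapping[str, str] | None = None,
) -> HaplotypeScan:
    """Cross-map and classify screened oligos from one haplotype.

    ``source_genome`` (the haplotype the oligos were tiled from) enables the
    fast ungapped path of :func:`_fast_cross_matches`.
    """
    scan = HaplotypeScan(screened=list(oligos), pav=[], pairs=[])
    fast: dict[int, CrossMatch] = {}
    if source_genome is not None and oligos:
        fast = _fast_cross_matches(oligos, other_index, source_genome, min_identity)
    for i, o in enumerate(oligos):
        if i in fast:
            cm = fast[i]
        else:
            m, status = best_match(o.seq, other_index, min_identity=min_identity,
                                   exhaustive=True)
            if status == "multi":
                scan.rejected_multi += 1
                continue
            cm = CrossMatch.from_match(m) if m else None
        cls = classify_oligo(cm, variant_window)
        if cls == "PAV":
            scan.pav.append(o)
        elif cls == "rejected_identical":
            scan.rejected_identical += 1
        elif cls == "rejected_edge_variant":
            scan.rejected_edge += 1
        else:
            scan.pairs.append(make_pair(o, cm, other_genome, other_haplotype_id))
    return scan


def design_probes(
    genome_a: Mapping[str, str],
    genome_b: Mapping[str, str],
    cfg: ScreenConfig | None = None,
    cond: ThermoConditions = DEFAULT_CONDITIONS,
    dtm_cutoff: float = DEFAULT_DTM_CUTOFF,
    include: Iterable[str] = DEFAULT_INCLUDE,
    min_identity: float | None = None,
    variant_window: tuple[int, int] = DEFAULT_VARIANT_WINDOW,
    names: tuple[str, str] = ("hapA", "hapB"),
    haplotype_ids: tuple[str, str] = ("A", "B"),
    kmer_indexes: tuple[KmerIndex, KmerIndex] | None = None,
) -> DesignResult:
    """Run the whole design: screen both haplotypes, classify both ways,
    merge pairs (deduplicated by the A-side anchor locus), ΔTm-filter, bin
    into classes and assemble the two probe sets.

    SNP pairs are primarily generated from the A-side scan; the mirrored
    B-side scan contributes the B-specific PAV oligos and any pair whose
    A-locus the A-side scan did not produce.
    """
    cfg = cfg or ScreenConfig()
    if min_identity is None:
        min_identity = cfg.homology_identity
    idx_a = SeedIndex(genome_a, seed_len=cfg.seed_len)
    idx_b = SeedIndex(genome_b, seed_len=cfg.seed_len)
    kidx_a, kidx_b = kmer_indexes or (
        KmerIndex.build(genome_a.values(), k=cfg.k),
        KmerIndex.build(genome_b.values(), k=cfg.k),
    )
    screened_a: list[Oligo] = []
    for chrom, seq in genome_a.items():
        screened_a.extend(
            select_single_copy(seq, genome_a, kidx_a, cfg,
                               haplotype_id=haplotype_ids[0], chrom=chrom,
                               seed_index=idx_a)
        )
    screened_b: list[Oligo] = []
    for chrom, seq in genome_b.items():
        screened_b.extend(
            select_single_copy(seq, genome_b, kidx_b, cfg,
                               haplotype_id=haplotype_ids[1], chrom=chrom,
                               seed_index=idx_b)
        )
    scan_a = scan_haplotype(screened_a, idx_b, genome_b, haplotype_ids[1],
                            min_identity, variant_window, source_genome=genome_a)
    scan_b = scan_haplotype(screened_b, idx_a, genome_a, haplotype_ids[0],
                            min_identity, variant_window, source_genome=genome_b)

    # merge: A-side pairs win; B-side pairs are mirrored and deduplicated by
    # their locus on haplotype A
    seen_a_loci = {(p.member_a.chrom, p.member_a.start) for p in scan_a.pairs}
    seen_b_loci = {(p.member_b.chrom, p.member_b.start) for p in scan_a.pairs}
    merged = list(scan_a.pairs)
    for p in scan_b.pairs:
        # p.member_a is a B-oligo, p.member_b sits on haplotype A
        key = (p.member_b.chrom, p.member_b.start)
        key_b = (p.member_a.chrom, p.member_a.start)
        if key in seen_a_loci or key_b in seen_b_loci:
            continue
        seen_a_loci.add(key)
        seen_b_loci.add(key_b)
        mirrored = OligoPair(p.member_b, p.member_a, p.n_variants)
        merged.append(mirrored)
    post = filter_delta_tm(merged, cutoff=dtm_cutoff, cond=cond)
    classes_pre = bin_by_variant_count(merged)
    classes = bin_by_variant_count(post)
    set_a, set_b = assemble_probe_sets(
        scan_a.pav, scan_b.pav, classes, include=include,
        names=names, haplotypes=haplotype_ids,
    )
    return DesignResult(scan_a, scan_b, merged, post, classes_pre, classes, set_a, set_b)
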