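"""Cross-haplotype classification, pair construction and probe-set
assembly."""

import numpy as np
import pytest

import hapfish as hf
from hapfish.probes import CLASS_LABELS
from hapfish.screen import Oligo
from hapfish.synthetic import VariantTruth
from tests.test_screen import plant_copy
from tests.test_thermo import tm_oracle


@pytest.fixture(scope="module")
def snp_pair(ref8k):
    """Haplotypes differing by a single planted SNP at offset 20 of the
    oligo starting at 1000 (0-based position 1019)."""
    ref = ref8k
    alt = "T" if ref[1019] != "T" else "C"
    truth = [VariantTruth(1019, "snp", ref[1019], alt)]
    return hf.apply_truth(ref, truth)


class TestCrossMap:
    def test_variant_free_region_maps_identically(self, snp_pair):
        o = Oligo("A", "chr1", 3000, snp_pair.seq_a[3000:3045])
        m = hf.cross_map(o, {"chr1": snp_pair.seq_b})
        assert m is not None
        assert m.identity == 1.0 and m.variants == [] and m.target_start == 3000

    def test_planted_snp_reported_at_oligo_offset(self, snp_pair):
        o = Oligo("A", "chr1", 1000, snp_pair.seq_a[1000:1045])
        m = hf.cross_map(o, {"chr1": snp_pair.seq_b})
        assert len(m.variants) == 1
        v = m.variants[0]
        assert (v.offset, v.vtype) == (20, "mismatch")
        assert v.ref == snp_pair.seq_a[1019] and v.alt == snp_pair.seq_b[1019]

    def test_oligo_inside_pav_deletion_is_absent(self, ref8k):
        ref = hf.generate_reference(20_000, seed=51)
        pair = hf.derive_haplotype(ref, 0, 0, [(5000, "pav_deletion", 6000)], seed=0)
        o = Oligo("A", "chr1", 8000, pair.seq_a[8000:8045])
        assert hf.cross_map(o, {"chr1": pair.seq_b}) is None


class TestClassifyOligo:
    def test_absent_is_pav(self):
        assert hf.classify_oligo(None) == "PAV"

    def test_variant_window_boundaries(self, snp_pair):
        def match_with_offset(off):
            return hf.CrossMatch("chr1", 0, 45, "+", 44 / 45,
                                 [hf.Variant(off, "mismatch", "A", "C")])

        assert hf.classify_oligo(match_with_offset(5)) == "rejected_edge_variant"
        assert hf.classify_oligo(match_with_offset(9)) == "rejected_edge_variant"
        assert hf.classify_oligo(match_with_offset(10)) == "snp_candidate"
        assert hf.classify_oligo(match_with_offset(35)) == "snp_candidate"
        assert hf.classify_oligo(match_with_offset(36)) == "rejected_edge_variant"

    def test_zero_variants_rejected_identical(self):
        m = hf.CrossMatch("chr1", 0, 45, "+", 1.0, [])
        assert hf.classify_oligo(m) == "rejected_identical"


class TestMakePair:
    def test_single_snp_substitution(self, snp_pair):
        o = Oligo("A", "chr1", 1000, snp_pair.seq_a[1000:1045])
        m = hf.cross_map(o, {"chr1": snp_pair.seq_b})
        p = hf.make_pair(o, m, {"chr1": snp_pair.seq_b}, "B")
        diffs = [i for i, (a, b) in enumerate(zip(p.member_a.seq, p.member_b.seq))
                 if a != b]
        assert diffs == [19]  # 0-based position of the 1-based offset 20
        assert p.member_b.seq == snp_pair.seq_b[m.target_start : m.target_start + 45]
        assert p.n_variants == 1 and p.snp_class == "1"

    def test_bidirectional_runs_mirror(self):
        ref = hf.generate_reference(10_000, seed=61)
        pair = hf.derive_haplotype(ref, snp_rate=0.005, indel_rate=0, seed=62)
        res = hf.design_probes({"chr1": pair.seq_a}, {"chr1": pair.seq_b})
        # SNP-only pair: every B-side pair mirrors an A-side pair, so the
        # merged set is exactly the A-side scan
        assert len(res.pairs) == len(res.scan_a.pairs)
        a_loci = {p.member_a.start for p in res.scan_a.pairs}
        b_anchors = {p.member_b.start for p in res.scan_b.pairs}
        assert b_anchors == a_loci


class TestDeltaTmFilter:
    def test_zero_delta_retained_and_cutoff_default(self, snp_pair):
        o = Oligo("A", "chr1", 3000, snp_pair.seq_a[3000:3045])
        p = hf.OligoPair(o, o, 1)
        assert hf.filter_delta_tm([p]) == [p]
        assert p.delta_tm == 0.0
        from hapfish.probes import DEFAULT_DTM_CUTOFF

        assert DEFAULT_DTM_CUTOFF == 5.0

    def test_engineered_at_to_gc_pair_discarded(self):
        # swapping 5 A:T pairs for G:C in an AT-rich probe shifts Tm far
        # beyond the cutoff; verified against the independent NN oracle
        a = "AT" * 22 + "A"
        b = list(a)
        for i in (14, 18, 22, 26, 30):
            b[i] = "G"
        b = "".join(b)
        assert abs(tm_oracle(a) - tm_oracle(b)) > 5.0
        o1 = Oligo("A", "chr1", 0, a)
        o2 = Oligo("B", "chr1", 0, b)
        assert hf.filter_delta_tm([hf.OligoPair(o1, o2, 5)]) == []

    def test_raising_cutoff_never_shrinks(self, rng):
        pairs = []
        for i in range(10):
            s = "".join(rng.choice(list("ACGT"), 45))
            t = "".join(rng.choice(list("ACGT"), 45))
            pairs.append(hf.OligoPair(Oligo("A", "c", i, s), Oligo("B", "c", i, t), 1))
        kept = [len(hf.filter_delta_tm(list(pairs), cutoff=c)) for c in (0.5, 2, 5, 10, 30)]
        assert kept == sorted(kept)


class TestClassBinning:
    @pytest.mark.parametrize("n,label", [(1, "1"), (2, "2"), (3, "3-4"),
                                         (4, "3-4"), (5, "5+"), (7, "5+")])
    def test_label_mapping(self, n, label):
        assert hf.variant_class(n) == label

    def test_partition_property(self, rng):
        o = Oligo("A", "c", 0, "A" * 45)
        pairs = [hf.OligoPair(o, o, int(n), delta_tm=0.0)
                 for n in rng.integers(1, 9, size=50)]
        classes = hf.bin_by_variant_count(pairs)
        assert set(classes) == set(CLASS_LABELS)
        assert sum(len(v) for v in classes.values()) == len(pairs)
        seen = [id(p) for v in classes.values() for p in v]
        assert len(seen) == len(set(seen))


class TestProbeSets:
    def test_single_class_include(self):
        pav = [Oligo("A", "c", i * 50, "A" * 45) for i in range(4)]
        sa, sb = hf.assemble_probe_sets(pav, pav[:2], {}, include={"PAV"})
        assert sa.size == 4 and sb.size == 2
        assert sa.composition["PAV"] == 4

    def test_published_composition_sizes(self):
        b73 = {"PAV": 6251, "3-4": 3894, "5+": 4353}
        mo17 = {"PAV": 5506, "3-4": 3894, "5+": 4353}
        assert hf.probe_set_size(b73) == 14_498
        assert hf.probe_set_size(mo17) == 13_753

    def test_duplicate_loci_rejected(self):
        dup = [Oligo("A", "c", 0, "A" * 45), Oligo("A", "c", 0, "C" * 45)]
        with pytest.raises(ValueError, match="duplicate"):
            hf.assemble_probe_sets(dup, [], {}, include={"PAV"})


class TestDensityTrack:
    def test_point_mass_and_conservation(self):
        members = [Oligo("A", "c", 100 + 5 * i, "A" * 45) for i in range(20)]
        pset = hf.ProbeSet("s", "A", members, {"PAV": 20})
        track = hf.density_track(pset, chrom_len=2_000_000)
        assert track.counts.sum() == 20
        assert track.counts[0] == 20 and (track.counts[1:] == 0).all()

    def test_counts_match_direct_tally(self, rng):
        starts = rng.integers(0, 3_000_000, size=200)
        members = [Oligo("A", "c", int(s), "A" * 45) for s in starts]
        pset = hf.ProbeSet("s", "A", members, {})
        track = hf.density_track(pset, chrom_len=3_000_000, window_bp=500_000)
        oracle = np.bincount(starts // 500_000, minlength=6)
        assert (track.counts == oracle).all()


class TestOffTargetScreen:
    def test_clean_set_unflagged(self, ref8k):
        o = Oligo("A", "chr1", 1000, ref8k[1000:1045])
        pset = hf.ProbeSet("s", "A", [o], {})
        assert hf.off_target_screen(pset, {"A": {"chr1": ref8k}}) == []

    def test_planted_85pct_copy_flagged_despite_kmer_screen(self, ref8k):
        # 4 mismatches spaced 13 apart break every 17-mer (so the k-mer
        # screen is blind to the duplication) but leave 12-nt seeds intact
        genome = plant_copy(ref8k, (1000, 1045), 5000, mismatch_at=(0, 13, 26, 39))
        o = Oligo("A", "chr1", 1000, genome[1000:1045])
        idx = hf.KmerIndex.build([genome], k=17)
        assert hf.count_repetitive_kmers(o, idx, 1) == 0  # even at threshold 1
        pset = hf.ProbeSet("s", "A", [o, Oligo("A", "chr1", 3000, genome[3000:3045])], {})
        flags = hf.off_target_screen(pset, {"A": {"chr1": genome}}, min_identity=0.75)
        assert len(flags) == 1
        member, label, match = flags[0]
        assert member.start == 1000
        assert abs(match.start - 5000) <= 2  # equal-cost paths may shift 1-2 bp
        assert match.identity > 0.85


@pytest.fixture(scope="module")
def design20k(pair20k):
    return hf.design_probes({"chr1": pair20k.seq_a}, {"chr1": pair20k.seq_b})


class TestEndToEndInvariants:
    def test_classification_partitions_screened_oligos(self, design20k):
        res = design20k
        for scan in (res.scan_a, res.scan_b):
            total = (len(scan.pav) + len(scan.pairs) + scan.rejected_identical
                     + scan.rejected_edge + scan.rejected_multi)
            assert total == len(scan.screened)

    def test_pair_members_hamming_equals_n_variants_without_indels(self):
        ref = hf.generate_reference(10_000, seed=71)
        pair = hf.derive_haplotype(ref, snp_rate=0.01, indel_rate=0, seed=72)
        res = hf.design_probes({"chr1": pair.seq_a}, {"chr1": pair.seq_b})
        assert res.pairs
        for p in res.pairs:
            ham = sum(a != b for a, b in zip(p.member_a.seq, p.member_b.seq))
            assert ham == p.n_variants

    def test_pav_oligos_localize_to_planted_pav_structure(self, pair20k, design20k):
        res = design20k
        deletions = [(v.position, v.position + len(v.ref_allele))
                     for v in pair20k.truth if v.vtype == "pav_deletion"]
        insert_points = [v.position for v in pair20k.truth
                         if v.vtype == "pav_insertion"]
        def truth_edit_load(o):
            # edits the counterpart alignment must spend inside the oligo
            total = 0
            for v in pair20k.truth:
                lo, hi = v.position, v.position + max(len(v.ref_allele), 1)
                if o.start < hi and lo < o.end:
                    if v.vtype == "snp":
                        total += 1
                    elif "insertion" in v.vtype:
                        total += len(v.alt_allele)
                    else:
                        total += min(hi, o.end) - max(lo, o.start)
            return total

        assert res.scan_a.pav
        for o in res.scan_a.pav:
            in_deletion = any(o.start < hi and lo < o.end for lo, hi in deletions)
            # an oligo split by a large inserted segment on the other
            # haplotype also loses its counterpart, as does one whose local
            # indel load exceeds the edit budget of the identity threshold
            spans_insertion = any(o.start < p < o.end for p in insert_points)
            assert in_deletion or spans_insertion or truth_edit_load(o) > 11
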