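# Methods

`hapfish` implements the computational side of a haplotype-specific
chromosome-painting experiment: designing oligo-FISH probe sets that
distinguish two haplotype-resolved assemblies of the same chromosome, and
mapping meiotic crossovers in the progeny of a cross between the two
haplotypes, both from low-coverage sequencing (bin-map genotyping) and from
cytological measurements (fractional arm positions). This note records the
models, parameter choices and numerical conventions; everything quantitative
stated here is computed by the test suite or by `scripts/acceptance.py`.

## Probe design

### Single-copy screen

Candidate probes are 45-nt windows tiled every 5 bp along the chromosome
(forward strand only; reverse-complement identity is handled inside the
screens). Two filters remove non-specific probes:

1. **17-mer repetitiveness.** A 17-mer with genome-wide frequency above 100
   is *repetitive*; an oligo containing two or more repetitive 17-mers is
   discarded. Frequencies default to canonical (strand-merged) counts of the
   assembly itself. A read-set source is supported (`--kmer-source`), in
   which case the frequency threshold is coverage-dependent and must be
   scaled by the user — the default 100 presumes roughly assembly-scale
   counts times the sequencing depth of the original read sets.
2. **Homology.** An oligo with a second locus anywhere in the genome, on
   either strand, matching at ≥ 75% identity is discarded. Loci are found
   by exact 12-nt seed words followed by a banded edit-distance alignment
   (edlib, infix mode) of the whole oligo against a small window; identity
   is matched columns / alignment columns, so gaps count against it. A
   probe with no non-self seed word anywhere trivially passes, which is
   what makes whole-chromosome screens fast; duplicate seeds are first
   checked by a direct ungapped comparison and only near-threshold or
   indel-suspect candidates (seed hits scattered over nearby distinct
   diagonals) escalate to the full alignment.

The seed-based search cannot see a second locus whose differences are
spaced closer than 12 nt apart everywhere; this mirrors the behaviour of
k-mer/seed-based screening tools generally and is the reason an additional
off-target screen exists for assembled probe sets (below).

### The counterpart-match definition

Cross-haplotype classification asks whether a screened oligo has a
*counterpart locus* on the other assembly. A locus is a valid counterpart
iff the alignment satisfies **both**

- identity ≥ 0.75 (matched columns / total columns), and
- edit distance ≤ ⌊(1 − 0.75) × 45⌋ = 11.

The edit cap is not redundant: identity alone can be reached against random
megabase-scale sequence by long gapped alignments (gaps add columns faster
than they destroy matches), which would silently misclassify genuine
presence–absence (PAV) oligos. Both conditions scale with the configured
identity threshold.

Reported alignments are *canonicalized*: re-aligned in a fixed window of
±16 bp around their own start and re-anchored until the start is the
window anchor. Optimal alignments with equal edit cost are not unique
(e.g. two adjacent mismatches versus an insertion/deletion pair), and
edlib's tie-break depends on window extent; canonicalization makes the
reported variant list a function of the local sequence only, regardless of
how the locus was discovered. This matters because the end-to-end tests
compare the pipeline's classification counts *exactly* against an
independently-searched oracle.

When the seed search finds nothing above threshold, cross-mapping falls
back to a whole-genome edit-distance scan (edlib with `k` = the edit cap)
before declaring the oligo absent, so a PAV verdict means "no valid
counterpart anywhere", including counterparts with tightly spaced
mismatches that carry no exact seed.

### Classification and pairs

- no counterpart → **PAV oligo** (used as-is; it has nothing to pair with);
- counterpart identical → rejected (non-discriminating);
- any variant event outside positions 10–35 (1-based, inclusive) of the
  45-mer → rejected (a variant too close to an end barely affects duplex
  stability, so the pair would not discriminate);
- otherwise → **SNP oligo pair**: the partner member is the other
  assembly's sequence over the counterpart footprint, re-anchored to
  exactly 45 nt, so the two members differ precisely at the variant
  positions. Variant *events* are counted (each mismatch = 1, each
  contiguous indel = 1); pairs are binned into the classes 1, 2, 3–4 and
  ≥5 events. Counting indels as events is configurable in spirit but the
  default treats them like SNPs, since an indel discriminates at least as
  strongly as a substitution.

Pairs are generated from the A-side scan; the mirrored B-side scan
contributes B-specific PAV oligos and any pair the A-side tiling missed,
deduplicated by anchor locus. Cross-mapping ties (two distinct loci at
equal best identity) reject the oligo as multi-mapping rather than risking
an off-target pair.

### ΔTm filter

Melting temperatures use the unified nearest-neighbor model
(SantaLucia-1998-style parameter set) with the entropy salt correction at
50 mM monovalent cation, 0 mM Mg²⁺, 50 nM oligo. These conditions are the
package's defaults (they are the common defaults of primer-design tools)
and are recorded in output metadata; all are configurable. Pairs whose
members' predicted Tm differ by more than 5 °C are discarded — the
lower-Tm member would be out-competed during hybridization and the pair
would fluoresce asymmetrically. ΔTm for unequal-length members (indel
cases do not arise with re-anchoring, but the API allows it) is computed on
the as-given sequences without length normalization.

### Probe sets, density, off-targets

The two painting probe sets combine all PAV oligos with the 3–4 and ≥5
variant classes (the published best-contrast combination); class
composition is recorded, and the assembly errors on duplicate loci.
Density tracks count probe starts in 500-kb windows. The off-target screen
re-aligns every assembled probe against any provided genome at the homology
threshold, excluding only its design locus — this catches moderately
diverged multi-copy families (the classic failure mode is rDNA-like
repeats at ~80–90% identity) that pass the exact 17-mer screen.

## Synthetic genomes

The generator produces the statistical structure the pipeline assumes,
with defaults chosen once to mimic a maize-inbred-style intercross:

| parameter | default | rationale |
| --- | --- | --- |
| SNP rate | 0.01 /bp | diverged-inbred scale; gives a 300-SNP window ~30 kb, so a 1-Mb toy holds ~30 windows |
| short indel rate | 10⁻³ /bp | an order of magnitude rarer than SNPs, lengths 1–10 bp |
| PAV segment minimum | 200 bp | well above the 45-nt oligo, so PAV oligos genuinely lack a counterpart |
| mean sequencing depth | 2.41× | skim-sequencing scale of an F2 validation experiment |
| allele-call error | 1% | mapping/calling error at low coverage |
| crossovers per chromosome copy | {0: 0.36, 1: 0.54, 2: 0.10} | ~36% of copies non-recombinant; three or more COs per copy never drawn |

Reference sequences are uniform random ACGT with optional repeat families
(one random monomer written over N non-overlapping positions). Haplotype B
is derived from A by placing PAV segments, then short indels, then SNPs,
all non-overlapping; the exact variant list and a monotone A→B coordinate
map are returned and round-trip tested. Crossover positions are uniform by
default; an arcsine (`distal`) profile is available to mimic the
telomere-proximal concentration of real exchange positions, but the
defaults stay uniform since no positional distribution is being estimated.

Allele observations are site-level, not read-level: at each truth SNP site
the depth is Poisson(2.41) (zero-depth sites emit no row), each read
samples one of the two chromosome copies uniformly, and the reported
allele is that of a random read, flipped with the error probability.
qual/mapq columns carry plausible caller-style scores (≈20 + 10–25 per
supporting read; 5% of sites at mapq 30) so the input filters act on
something, without modelling caller internals. What passing tests on these
data do **not** show: robustness to reference bias, segmental duplication
mismapping, structurally mis-assembled regions, or allele-specific
coverage — real inputs bring all of these.

## Bin-map genotyping

Raw per-site calls are filtered by retention conditions mapq > 50,
QUAL ≥ 30, DP < 40 (strict: at ~2.4× coverage, high depth marks collapsed
repeats) and QUAL/DP > 10 (strict). Retained SNPs are scanned in
non-overlapping 300-SNP windows (the step is configurable; overlapping
windows change only smoothing, not the calls' information content). A
window is homozygous-P1 if the P1-allele fraction exceeds 0.8,
homozygous-P2 below 0.2, heterozygous on the closed interval [0.2, 0.8]
("more than 80%" read strictly, so exactly 0.8 is heterozygous). A
trailing partial window is kept iff it holds at least half a window of
SNPs. Runs of equal calls become bin segments; single-window segments are
flagged low-confidence.

### Breakpoint refinement

Window-level segmentation localizes a transition only to ~one window, and
the literal window-boundary SNPs bracket a gap of two adjacent SNPs that
essentially never contains the true breakpoint. Two SNP-level steps
sharpen this, both driven by a three-state emission model
P(P1-allele | homP1, het, homP2) = (1−e, ½, e) with e the allele error
rate (default 0.01, floored at 10⁻⁴):

1. **Changepoint refinement.** For each transition, the maximum-likelihood
   changepoint over the flanking sites (up to two windows each side) is
   found, and the reported `[left_bound, right_bound]` interval is the
   *likelihood support interval*: all changepoints within `support_delta`
   log-units of the optimum. The default `support_delta = 5` is calibrated
   to the emission model: one mis-called site costs |log(e/½)| ≈ 3.9, so
   the interval can absorb a single error adjacent to the breakpoint; at
   e = 0 support decays at log 2 ≈ 0.69 per site, giving ~7-site intervals.
   `refine=False` reproduces the raw window-boundary bounds.
2. **Hidden-tract scan.** A genotype tract shorter than ~½ window (a
   double crossover on one homolog, or a breakpoint so near the chromosome
   end that no flanking window exists) never dominates any window and is
   invisible to window calls, yet leaves decisive SNP-level signal. Each
   segment is scanned, per alternative state, for the maximum-sum run of
   per-site log-likelihood differences (Kadane's algorithm, O(n)); a run
   with total gain above `split_threshold = 15` is split out as its own
   segment. On an error-free uniform segment every per-site difference is
   negative, so no split is possible — which is exactly the "zero false
   exchange points on noiseless parental copies" property the tests
   assert. A true 100-SNP tract scores ≈ 100 × log 2 ≈ 69, far above
   threshold; a spurious split inside a heterozygous segment needs ~22
   consecutive same-allele draws (probability ≈ 2⁻²² per site).

A heterozygous segment flanked by the same homozygous call on both sides
is reported as two exchange points flagged *ambiguous double crossover* —
the diploid data cannot distinguish one double CO on a single homolog from
two single COs on the two homologs, and the package reports the ambiguity
rather than resolving it.

At the defaults (1-Mb toy, ~9,000 retained SNPs, 2.41×), 50-plant
simulations recover ≥ 90% of truth breakpoints inside the reported
interval; the residual misses are breakpoints within a handful of SNPs of
a chromosome end, where no method has data. Population summaries report
the percent of copies with ≥ 1 exchange, the percent of
sequencing-checked copies confirmed non-recombinant, and the corrected
population non-CO estimate (confirmed/checked × exchange-negative/total),
all rounded to integer percent, the resolution such counts support.

## Cytology

FLA (fractional length of the arm) = 100 × (EP-to-telomere distance) /
(arm length), on a 0 (telomere) to 100 (centromere) scale; it is invariant
under magnification and strictly monotone in the distance. Interval binning
is floor(FLA / width) with FLA = 100 assigned to the last bin so
centromere-adjacent exchanges stay countable; width 5 gives the standard
20-interval arm histogram, width 1 the 100-interval scheme. Chromosome
copies are classified by centromere origin (B/M) and per-arm exchange
counts: digit 1 = parental, 2 = one exchange on the short arm, 3 = one on
the long arm, 4 = one on each arm; the short/long assignment of digits
2/3 is a convention (`short_arm_digit`) and can be swapped. Two or more
exchanges on a single arm fall outside the eight types and are reported as
`other` with a double-CO annotation. No image analysis is performed;
measurements are consumed from TSV.

## Problem sizes

The end-to-end checks run on a 1-Mb haplotype pair (≈200,000 candidate
oligos per haplotype, ~10,800 planted variants including three PAV
segments of 3–5 kb) and 50 simulated F2 plants; these sizes exercise every
code path at full parameter realism while a complete run (pipeline, both
oracles, simulations) finishes in a few minutes on one CPU. Real
chromosome-scale inputs differ only in length.

## Known limitations

- The homology screen's seed-based sensitivity bound (no exact 12-mer ⇒
  invisible) is intrinsic to seed-and-extend screening; the off-target
  screen on the much smaller assembled probe set is the backstop.
- Identity is edit-distance-based; no thermodynamic model of mismatch
  position within the duplex is applied beyond the 10–35 variant window
  rule.
- The bin map assumes a diploid F2 with exactly two copies per chromosome
  and biallelic, pre-assigned parental alleles; no imputation or phasing.
- Whether published class counts were tallied before or after the ΔTm
  filter is not derivable from the source material; the pipeline reports
  both pre- and post-filter counts.
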