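# Methods

## Problem and model

Tumor–normal somatic variant callers disagree substantially on the same
sequencing data, and no single caller dominates across datasets. The
ensemble implemented here treats each caller as a binary detector per
candidate variant and combines detections with fixed decision rules rather
than a trained model: fixed rules need no training data, transfer across
cohorts, and are auditable.

A variant's identity is its normalized VCF key `(contig, pos, ref, alt)`.
Two voting schemes decide each variant:

* **Majority**: PASS iff the number of supporting callers reaches
  `ceil(cutoff * n_callers)` (fraction mode, default cutoff 0.5) or an
  absolute minimum count. The ceiling convention means "at least 50% of 7"
  is 4, matching the usual strict-majority reading.
* **VAF-adaptive** (SNVs only): three PASS conditions tested in order —
  (1) both anchors (Strelka, MuTect2) support the call and the tumor VAF is
  in `[low_vaf, mid_vaf]`; (2) the VAF is below `low_vaf` and MuTect2
  supports it; (3) plain majority. The first satisfied rule is recorded in
  the output (`INFO/VOTE_RULE`). The premise is empirical: a small number
  of callers retain high precision at low allele fractions, so a variant in
  that regime should not need a full majority.

Indels always use majority voting: the low-VAF rescue conditions are
defined for SNVs, and indel false positives are the dominant error mode, so
extending the relaxation to indels would be unsafe. Equal-length multi-base
substitutions (MNVs) are likewise grouped with indels for scheme selection
— a conservative choice, since the adaptive rule names SNVs only.

Confidence is tagged in FILTER: `PASS` when the majority rule holds,
`LowVAF` when only the adaptive rescue rules hold, `Rejected` otherwise.
This keeps the merged VCF a superset of all inputs while remaining easy to
threshold downstream.

## Tumor VAF per variant

Each caller encodes the tumor allele fraction differently; the dialect
table is a documented convention of this package (the field has no
standard): Strelka SNVs use tier-1 base counts `xU` (alt tier-1 over the
sum of the four bases), Strelka indels `TIR/(TIR+TAR)` tier 1; VarScan
parses the `FREQ` percent string; MuTect uses FORMAT `FA`; MuTect2 and
VarDict FORMAT `AF` (allelic-depth ratio as fallback); MuSE and any
unrecognized dialect fall back to the `AD` ratio `alt/(ref+alt)`; LoFreq,
whose somatic VCFs carry no sample columns, uses `INFO/AF`. A VAF that
cannot be extracted is *missing*, never fabricated; missing VAFs disable
the two VAF-dependent adaptive rules but not the majority rule.

The single VAF reported per merged variant (`INFO/TVAF`) — and the one the
adaptive rules test — is that of the highest-priority supporting caller
that produced one. The default priority (MuTect2, Strelka, LoFreq, MuSE,
MuTect, VarDict, VarScan) puts the anchors first so the thresholds see the
anchor's own estimate. The tumor sample column is resolved as: explicit
name > a sample literally called `TUMOR` > a `##tumor_sample=` header
line > the last sample column (logged).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `cutoff` | 0.5 | fraction of configured callers required (ceiling applied) |
| `min_callers` | unset | absolute support count, overrides `cutoff` |
| `anchor_callers` | Strelka, MuTect2 | rule-1 pair; configurable because the choice is empirical |
| `low_vaf` | 0.03 | rule-1 lower / rule-2 upper VAF bound (fraction) |
| `mid_vaf` | 0.1 | rule-1 upper VAF bound (fraction) |
| `min_tumor_vaf` | unset | post-voting demotion threshold (fraction) |
| `priority` | MuTect2 first | caller order for the reported VAF |

Boundary inclusivity follows the rule statements exactly: rule 1 is
`low_vaf <= v <= mid_vaf`, rule 2 is `v < low_vaf`. The optional
`min_tumor_vaf` filter is applied *after* voting as a demotion to
`Rejected` (the vote and its rule stay recorded); variants with a missing
VAF are not demoted, since the threshold cannot be evaluated. VarDict
records are pre-filtered with the published hard-filter expression when all
five metrics (AF, DP, MQ, NM, QUAL) are present; otherwise the record is
kept and a warning logged.

## Normalization

Indel representations are left-aligned and trimmed (the standard
parsimony algorithm: drop shared trailing bases, left-extending with the
reference base when an allele would empty; then drop shared leading bases
while both alleles exceed one base). Normalization is applied both before
merging and before comparison — merging unnormalized representations would
silently fragment support across equivalent keys, which is worse than the
alternative of normalizing only at comparison time. Without a reference
FASTA only the trims are applied (no left shift) and a diagnostic is
logged; SNVs are fixed points. A REF allele that contradicts the reference
is a rejected record, not a crash. At the contig start, shifting stops and
the current representation is returned.

The test suite checks the implementation against an exhaustive oracle that
enumerates every equivalent `(pos, ref, alt)` over the context and selects
the left-most minimal parsimonious one, on 1,000+ randomized indel
representations over repeat-rich 50-bp contexts.

## Evaluation

Matching is exact on the normalized key for SNVs and indels alike — a
single well-defined rule rather than haplotype-aware realignment
(rtg-vcfeval-style comparison is out of scope). Comparison regions are
BED (0-based half-open) intersected by a sorted sweep; a 1-based variant
position `p` is inside `[start, end)` iff `start < p <= end`. Truth
records with non-PASS FILTER are excluded by default. Zero-denominator
conventions: precision is 0 when there are no calls; recall (and FNR and
F1) are undefined when the truth set is empty and reported as missing
(`NA`/`null`) with the counts still shown; F1 is 0 when precision and
recall are both 0.

## What the simulator emulates — and what it does not

The generator reproduces the *structure* of a dilution-series benchmark:
truth VAF strata default to the expected heterozygous VAFs of 1–50%
two-sample mixtures (0.005, 0.01, 0.025, 0.05, 0.1, 0.25, equal
proportions, exact largest-remainder allocation), a ~1,600× mean depth
typical of deep targeted panels, and per-caller logistic sensitivity
curves whose defaults encode the qualitative behavior seen in deep
sequencing: MuTect2 sensitive at ultra-low VAF (midpoint 0.008), Strelka
precise with the lowest false-positive rate, VarDict sensitive but noisy
(12 FP/Mb), VarScan losing sensitivity below ~10% VAF (midpoint 0.08).
Reported VAFs get Gaussian noise (sd ≈ 0.3–0.6% VAF); false positives are
Poisson-placed SNVs at unused positions.

Deliberate simplifications: caller detections are independent given the
truth (real callers are correlated through the same reads and artifacts,
so real consensus gains are smaller than the binomial ideal); false
positives are uncorrelated across callers (real artifacts recur at the
same sites); no read-level simulation, mapping bias, or error motifs;
per-caller native metrics are benign constants. Consequently, passing
tests demonstrate the *mechanics* of merging, voting and scoring — and the
directional low-VAF advantage of the adaptive scheme — not the absolute
performance to expect on real tumors.

Dialect fidelity is taken seriously: each simulated VCF uses its caller's
real encoding (tier-count pairs, percent strings, sample-free LoFreq,
tumor-first vs tumor-last sample columns, `##tumor_sample` header lines),
and the generator records the VAF each record *actually encodes* after
quantization (count ratios, rounded percents) so readers can be checked to
1e-6 without pretending integer counts carry float precision.

## Numerical and design choices

* Fraction cutoffs use `ceil(cutoff * n - 1e-9)`; the epsilon guards
  against binary-float artifacts like `0.3 * 10 = 2.9999…`.
* Iteration and output order is always `(contig natural-sorted, pos, ref,
  alt)`; merged output is byte-deterministic for fixed inputs and config.
* Duplicate keys within one caller's VCF: first record wins, logged.
* Symbolic ALTs (`<DEL>`, breakends, `*`) are dropped with a diagnostic;
  structural variants and genotype semantics are out of scope.
* All simulator randomness flows from one integer seed through
  `numpy.random.SeedSequence` children (one per caller), so adding or
  reordering callers does not perturb other callers' draws.
* Test problem sizes (50–200 kb contigs, 10²–10³ variants) were chosen so
  every statistical check has enough events for a three-standard-error
  band while the whole suite stays interactive.

## Known limitations

* Exact-key matching undercounts agreement for complex indels that
  normalization cannot reconcile (different but overlapping events).
* The adaptive scheme inherits its anchors' false positives below 3% VAF;
  on data where MuTect2 is noisy at low VAF, rule 2 should be retuned or
  the `wgs` preset used.
* The merged VCF is INFO-annotated only (no FORMAT/sample columns); tools
  expecting genotypes must consult the original caller VCFs, whose key
  metrics are carried through as `<CALLER>_<KEY>` INFO fields.
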