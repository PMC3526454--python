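# Methods

This note records the models, defaults, numerical choices and known
limitations behind probelint, in the order the pipeline runs.

## Probe-to-genome mapping

Probes are remapped with a deterministic seed-and-extend **ungapped**
scanner: every exact k-mer seed (default `seed_len = 12`) anchors a
fixed-offset comparison of the full probe window against the genome, on both
strands, and a placement is reported when it reaches `min_report_matches`
identical bases (default 50). The scanner is provably complete for any
placement whose longest exact run is at least `seed_len`; since the
cross-hybridization run criterion is 15 nt, the default seed of 12 cannot
miss a run-qualifying locus. Coordinates are 0-based half-open everywhere;
BED is read as-is, GFF3 and 1-based alignment tables are converted on read.

An ingestion path accepts 12-column tabular alignments from an external
aligner instead. Such tables do not carry the longest contiguous run, so it
is reconstructed as the pigeonhole lower bound `ceil(matches/(mismatches+1))`
(exact when mismatches are evenly spread, conservative otherwise): the
run-based cross-hybridization arm may under-flag on ingested tables, which
is the price of not having the alignment itself. Gapped alignments are
representable (the hit type allows indel slack) but never produced
internally.

Hits are classified against exon annotations by containment: fully inside
one exon (`exonic_single`), overlapping an exon without containment
(`exon_junction`), inside a gene's exon span but no exon (`intronic`), else
`intergenic`. Expression status is a one-base overlap with the
expressed-region intervals.

## Sequence-property filters

* **Cross-hybridization.** The specificity rule for long oligos has two
  independent physical mechanisms and is implemented disjunctively:
  (matches ≥ 50 **and** identity ≥ 85 %) **or** a contiguous exact run
  ≥ 15 nt. The two count thresholds are kept as one conjunctive arm because
  50/60 = 83.3 % would otherwise contradict the 85 % identity requirement;
  all three values are configurable. A secondary locus only flags the probe
  if it also lies in an expressed region *and* its probe–target heteroduplex
  is stable enough to yield signal (ΔG ≤ −15 kcal/mol by default; the
  combination rule is stated in the source method without a numeric duplex
  cutoff, so the default here is a package choice, configurable).
* **Intended-target resolution.** The hit overlapping the probe's declared
  design locus is "intended"; without a declared locus the best-scoring
  single-exon hit is taken. With no intended hit at all the probe is handled
  by the loss-of-target filter, not the cross-hybridization filter.
* **Loss of target.** Flagged when no intended hit exists or the intended
  hit is not `exonic_single` (junction-spanning probes violate the
  single-exon design contract; they are listed and can be added back when
  the isoform is known to be present).
* **SNP load.** Variant sites strictly inside the intended hit's interval
  are counted (multi-allelic sites once, indels as one site each); the flag
  fires at ≥ 4 sites. Probes with 1–3 sites are kept but emitted to a
  low-SNP annotation report so users can tighten the rule.
* **Poly-G.** Any run of ≥ 4 consecutive guanines flags the probe,
  regardless of its intensity behavior; intensity diagnostics are
  informational only.
* **Repeats.** A probe is flagged when it shares an exact substring of
  ≥ `repeat_min_match` (default 15, matching the run criterion) with any
  repeat-library entry, on either strand; decided by k-mer membership,
  which is equivalent to the substring test.

Filter outcomes merge into a per-probe verdict ledger. Flags form a set, so
re-running any filter or permuting filter order cannot change the ledger;
`allowed` is true iff every raised flag has been explicitly cleared by an
`add_back(flag, reason)` with provenance retained.

## Nearest-neighbor thermodynamics

Monomer folding and heteroduplex stability use the unified DNA
nearest-neighbor ΔH/ΔS stack table (shipped as packaged TSV), with
ΔG(T) = ΔH − T·(ΔS + 0.368·ln[Na⁺]) per stack (the salt term vanishes at
the 1 M reference) and loop penalties tabulated at 37 °C, treated as
entropic (scaled by T/310.15) with Jacobson–Stockmayer extrapolation beyond
size 30. Default conditions: 60 °C (the middle of the validated 55–62 °C
window — the single temperature behind the −5.2 kcal/mol cutoff is not
published, so 60 °C is this package's documented choice), 1.0 M Na⁺,
0.0 M Mg²⁺ (no magnesium model).

The monomer structure space is a single hairpin: one terminal loop (≥ 3 nt)
closed by a nested Watson–Crick helix with interior loops and bulges capped
at 30 unpaired bases; no multiloops, pseudoknots, wobble pairs, dangling
ends, or terminal-AT penalties. The MFE is computed by an exact dynamic
program over that space and is verified in the tests against complete
structure enumeration for sequences up to length 20. Equivalence with any
external folding program is *not* claimed; the testable contract is
enumeration-exactness plus correct threshold behavior. Duplexes are ungapped
best-offset stack sums in which a mismatch simply interrupts stacking, so
added mismatches can only destabilize.

Cutoffs (both strict `<`): −5.2 kcal/mol removes self-folding probes;
−10 kcal/mol defines the "very stable" folders used as background sensors.

## Background, measurement filter, outliers

Background candidates must pass the *uniqueness* filters
(cross-hybridization, loss of target, SNP, repeat — the ΔG and poly-G flags
do not disqualify, since stable folders are precisely the sensors wanted),
fold below −10 kcal/mol, and map to genes on the caller-supplied
unexpressed list. The per-class cutoff is the mean (default), median, or a
Lowess floor (local-linear smooth of per-probe mean intensity against
monomer ΔG, averaged over the candidate probes) of candidate measurements
across the class's arrays.

A probe enters testing only with a strictly-above-cutoff measurement in
every array of both classes (configurable to either-class retention; the
source method is ambiguous on this point and both readings are supported).
Missing measurements (negative raw spot intensities are dropped at parse
time and carried as NaN) never count as valid.

Sample outliers: per class, each sample's mean signal over probes and its
count of above-cutoff probes are compared to the class mean; a sample
straying strictly more than k = 2 population SDs on either criterion is
flagged. **The class statistics exclude the candidate sample by default**
(leave-one-out). This is a deliberate deviation from the simplest
include-self reading: with inclusion, the largest attainable deviation in a
class of n samples is (n−1)/√n SDs (≈ 2.47 at n = 8), so a genuinely gross
outlier inflates the SD enough to mask itself and can *never* sit 3 SDs
out. Leave-one-out removes the masking and makes detection of a 3-SD
displacement deterministic. The cost is sensitivity at small n: the
leave-one-out z at k = 2 corresponds to a t₆-like threshold of ≈ 1.73 in a
class of 8, so ~14 % of perfectly ordinary samples exceed it by chance.
The flag is therefore a review trigger, not an automatic drop — the
diagnostics table reports both z-scores for every sample — and the
conservative include-self variant remains available
(`leave_one_out=False`).

Distribution diagnostics: two-sided F test on sample variances,
Shapiro–Wilk per group (reported as undefined for constant groups), and QQ
pairs (theoretical normal quantile vs ordered sample) ready for plotting.

## Differential expression and baselines

Each retained probe is tested separately (arrays of this design carry 1–2
probes per gene; no probe-to-gene summarization) with the Wilcoxon rank-sum
test: exact two-sided p by enumeration of the null rank-sum distribution
(a cached subset-sum dynamic program) when n ≤ 25 without ties, else the
tie-corrected normal approximation with continuity correction (the
continuity correction is switchable; default on, matching common R
behavior). Direction is the sign of the disease-minus-control median
difference. Adjustment is BH step-up (default) or Bonferroni; results sort
by raw p with gene-id tie-breaks.

Expected operating characteristics under the synthetic study conditions
(1000 genes, 10 planted 3-SD shifts, 11 vs 11): the exact-test tail needs a
rank sum of ≥ 176/187 to clear the BH threshold at rank 10, which a 3-SD
shift misses for ~2 % of genes, so mean sensitivity sits near 0.98 (not
exactly 1) with false discovery proportion well under 0.10 — the acceptance
checks assert exactly this averaged behavior.

DE-list comparison reports the set decomposition of two gene lists and, for
each discordant gene, the verdict-ledger flag that explains its absence
from the other pipeline. Cross-study baseline validation takes per-gene
mean control intensities in two studies, reports the squared Pearson
correlation (by construction r² equals ρ² ≈ 0.81 when baselines correlate
at ρ = 0.9), and a Lowess trend (tricube local linear, span 0.3, 3
robustness iterations — the smoother's parameters are package choices).

## qPCR quantification

Standard curves use six 10-fold dilutions in triplicate; replicates further
than 0.5 cycles from their triplicate median are discarded before averaging
(an outlier guard the wet-lab protocol leaves unstated). Mean Cq must
increase strictly with dilution or the fit aborts naming the offending
level. E = 10^(−1/slope); efficiencies outside [1.6, 2.2] are fitted but
marked implausible. The Pfaffl ratio uses ΔCq = Cq(control) − Cq(treated),
so disease over-expression gives ratios > 1; with equal efficiencies it
reduces to the ΔΔCq identity E^(ΔCq_t − ΔCq_r).

## Synthetic universes

The generator emulates the real inputs the pipeline was built for — an
array design file, a reference genome with exon/expressed annotations, a
variant catalog, a repeat library, class-structured log₁₀ intensity
matrices from a two-color pooled-reference design, and Cq titrations — at
desk scale. Defaults: 60-mer probes, one 180-bp exon per gene on a random
genome with 120-bp gaps, all exons expressed except those of designated
background genes; intensities normal on the log₁₀ scale with per-probe
baselines U(3.2, 4.4), noise SD 0.25, a noise floor at
log₁₀ = 2.5 (SD 0.1), DE shifts expressed in noise-SD units; Cq noise SD
0.1 cycles. Defects are planted surgically so that truth is unambiguous
(verbatim copies for cross-hybridizers, constructed stem-loops for folding
defects, exactly four variant records for SNP probes, junction-spanning or
absent targets for loss probes), clean probes are rejection-sampled until
they trip no filter, and a global rescan regenerates any probe that
acquires an accidental near-identical second locus. Planted outlier samples
are displaced to sit exactly the requested number of leave-one-out SDs from
their class.

What the generator does **not** model — dye bias, spatial artifacts,
heavy-tailed intensity noise (available as an option only through the
statistics tests), probe GC composition bias, population allele
frequencies — bounds what passing tests show: they certify the pipeline's
logic and calibration on idealized data, not performance on any real
array.

## Problem sizes and determinism

The shipped checks use: 200 probe/genome pairs (10 kb genomes) for the
alignment oracle; a 90-probe universe on a 32-kb genome with ten planted
defects per filter; 100 sequences of length ≤ 20 for the thermodynamic
enumeration; 500 probes × 12 arrays for background recovery; 20 seeded
replicates for outlier, DE and qPCR recovery; 50 for the null-matrix FDR
check; and a 23-probe universe for byte-level determinism of the chained
pipeline. All generators are pure functions of (configuration, seed);
primary outputs contain no timestamps, so repeated runs are byte-identical.
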