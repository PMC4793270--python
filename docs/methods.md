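# Methods

## Coordinates and conventions

All internal coordinates are 0-based half-open. A cut site is the 0-based
start of the recognition motif (`GAATTC`); fragments are delimited at
recognition-site starts, which is sufficient because every rule in the
pipeline measures "distance to the nearest EcoRI site" with one consistent
anchor. Human-facing report tables use 1-based inclusive positions; BED and
BEDPE files keep the 0-based half-open standard. Lowercase (soft-masked)
sequence matches the motif — capture arrays target masked regions too, and
repeat handling belongs to the downstream probe filter; `N` never matches.

## Bait design and naming

Within each target locus, every cut site contributes two probe regions: the
upstream flank `[site − 250, site)` (named `…U`) and the downstream flank
`[site, site + 250)` (`…D`), truncated at chromosome ends. Sites are
numbered 1..n per locus in coordinate order, and locus prefixes follow the
first-on-chromosome = A, second = B convention, with the prefix left empty
when a chromosome carries a single locus. Because bait names key the contact
table, `design_baits` rejects designs whose names collide across loci; the
simulator therefore assigns globally unique prefixes.

## Pair classification

A pair is informative (on-target) when at least one fully mapped end lies
inside a probe flank — i.e. inside the half-open window
`[site − flank, site + flank)` of an in-locus cut site, which both bounds
the distance to the site by `flank` and makes the anchoring flank region
(U or D; a read exactly on the site anchors to D) always well defined. Cis
means both ends on one chromosome, trans otherwise; pairs with any unmapped
end are tallied as unmapped and not classified further, since interaction
counting needs both coordinates. Ends are stored in canonical order so
order-swapped PCR copies compare equal; duplicates are coordinate+strand
tuples already seen, are excluded from every category tally, and the first
occurrence keeps its category. A pair whose both ends fall in probe flanks
credits one count to each bait's profile — this symmetric counting is what
produces the bait × bait block visible in capture heat maps. The counted
fragment is always the partner end's fragment.

## Normalization and masking

Capture efficiency is proxied by the raw on-target total per probe — the
only observable the data offer. The probe filter removes the
`floor(0.22 · P)` lowest-total probes (nearest-rank, floor — the
conservative reading of "lower 22 percentile"), ties broken by name so the
operation is deterministic, plus any probe overlapping an optional repeat
track. The filter is applied per library; a pooled mode across libraries
would simply concatenate totals first. Scaling factors are
`median(retained totals) / total_p` with the median recomputed on retained
probes (removed probes are declared unusable and should not set the scale);
after scaling, every retained probe's total equals that median exactly,
which the tests assert to 1e-9. Fragments overlapping the probe interval
expanded by ±25 kb are masked per bait — flagged, never deleted — because
self- and near-ligation dominates there. Anchoring the window on the probe
interval rather than the bare cut site means an exclusion of 0 masks exactly
the bait's own fragment for both U and D probes.

## Significance calling

The permutation null redistributes the bait's `N` mappable-fragment reads
uniformly over the `M` unmasked fragments of its chromosome (trans
fragments are excluded; the method calls cis interactions only). The test
statistic is the count in windows of `window` consecutive mappable
fragments (default 1). Calling uses a pooled-permutation candidate
threshold `T0` (smallest count with pooled exceedance fraction ≤
`top_pct`/100, default 5%), then the smallest `T ≥ T0` whose empirical FDR

    FDR(c) = (pooled exceedances / n_perm) / max(1, observed exceedances)

is ≤ 0.01; no such `T` means no calls, so the achieved FDR is ≤ the target
whenever anything is called. Per-window p-values use the add-one pooled
estimator `(1 + #{pooled ≥ c}) / (n_perm·W + 1)`. Significance runs on raw
integer counts — the multinomial null conserves integer read totals, and
probe normalization only affects cross-bait comparison. Permutations are
drawn one at a time from a single seeded generator, baits in sorted-name
order, so every run is reproducible from (config, seed). The null is
deliberately uniform (no distance-decay model): that is the stated shuffling
scheme, and its consequence — near-bait background passes the threshold
easily — is contained by the ±25 kb mask, not removed. Calls adjacent to
the mask should therefore be read with the decay background in mind.

## Downstream quantifications

* **Replicate correlation** — Pearson r over fragments with count ≥
  min_count in *both* replicates (joint filter); fewer than 3 survivors or a
  constant vector is an error, not a number.
* **3C-qPCR** — `ratio(m) = E^−(mean Ct_3C − mean Ct_control)` with
  `E = 2` (perfect doubling, configurable; no efficiency correction is
  applied); the contact frequency is `ratio(test)/ratio(adjacent)`, and the
  replicate SD propagates through the exponent by the delta method.
* **eQTL** — ordinary least squares of RPKM on additive dosage (0/1/2), no
  covariates; t on n−2 df, two-sided. A constant expression vector returns
  slope 0, p 1; a perfect fit saturates at the smallest positive double
  (documented, asserted). Scans report raw p plus a labeled
  Benjamini–Hochberg column as an extra, never a replacement.
* **PWM allele scoring** — log2 odds against a uniform background, both
  strands, every window covering the SNP, per-allele maximum
  (maximum-affinity disruption convention); delta is antisymmetric in the
  alleles by construction. JASPAR count matrices are smoothed with a
  pseudocount before use.
* **Overlap annotation** — any-overlap (≥ 1 bp), half-open semantics,
  feature order preserved.

## The synthetic generator

The generator is the test bed standing in for the study's unreleased
libraries. Defaults are the study-scale composition: 17.7% of pairs
unmapped, 76.6% of mapped pairs off-target (so ~23.4% on-target), 10% of
on-target pairs trans, 5% PCR-duplicate copies, log-normal per-probe
capture efficiency with σ = 0.5, EcoRI-like cut-site spacing (exponential,
mean 4096 bp) and loci of ≥ 10 cut sites — the smallest captured locus size.
Desk-scale geometry is 3 × 1 Mb chromosomes with 4 loci and 10⁵ base pairs
per library.

Cis partners land in a fragment drawn with probability ∝ fragment length ×
`(d + d0)^−α` (α = 1, d0 = 1 kb — canonical polymer-ligation decay), with
planted (bait, fragment) interactions up-weighted multiplicatively.
Anchor ends are uniform inside a probe flank chosen ∝ efficiency; partner
ends are uniform *within* their fragment, because these libraries are
sonicated after ligation so only the captured end is junction-proximal —
this also keeps probe totals an honest readout of efficiency (Spearman ρ >
0.8 against the planted factors at default depth). Off-target ends are
uniform on the genome with bait-proximal windows rejection-sampled away, so
the generator's category labels coincide exactly with the pipeline's
classification. Duplicates are exact coordinate copies; the truth records
the duplicate count by the same canonical-coordinate rule the pipeline
uses, so the two agree exactly even when two independently drawn pairs
collide by chance. What the generator does *not* model: read-level
sequences and sequencing error, TAD-structured contact blocks, chromatin-
state-dependent background, and mappability variation — so passing tests
demonstrate the pipeline's statistical behavior, not robustness to those
real-data features.

The replicate-count generator models a shared log-normal contact profile
(Poisson-sampled per replicate) plus two replicate-independent artifacts: a
uniform spurious-ligation background and sparse one-sided spikes
(probability 0.08, mean 18) mimicking localized ligation/PCR artifacts that
do not reproduce between libraries. The spikes are the feature that makes a
joint minimum-count filter informative — a spiked fragment is high in one
replicate and near background in the other, so raising the joint threshold
from 1 to 3 removes precisely the discordant points and raises r (0.86 →
0.89 at defaults, matching the direction of the 0.90 → 0.93 observation
between the study's duplicate libraries).

## Calibration experiments and problem sizes

* FDR control: 20 null baits at N = 50,000 reads over M = 500 fragments,
  1000 permutations — the mean called fraction must stay ≤ 2× the nominal
  0.01.
* Planted recovery: 50 single-locus simulations (400 kb chromosome, 8 kb
  spacing, 10-site locus, 260,000 informative pairs, equal probe
  efficiencies so the stated ≥ 100 reads/fragment depth condition holds for
  the planted bait), an 8-fold peak planted 60 kb from the bait; recovery =
  the planted fragment is called significant, required in ≥ 90% of seeds.
  The caller is run on the bait's raw profile directly: probe QC gates which
  baits are *reported*, not what the permutation test sees. The companion
  top-count property plants the peak in the first unmasked fragment of at
  least average length, so it measures enrichment rather than the
  fragment-size lottery (a tiny fragment can lose the raw-count race to a
  long near-mask neighbor even at 8-fold).
* Decay-slope fidelity: |slope − (−α)| ≤ 0.3 measured on informative cis
  pairs of a 10⁵-pair library over the 20–400 kb range.

## Known limitations

The uniform permutation null concentrates calls near the mask edge whenever
depth is high; a decay-aware background (as in r3Cseq or CHiCAGO) would be
strictly more specific but is a different method. The probe filter's
percentile cut is count-based and per-library; with very few probes
(P < 5) it removes nothing. Multi-enzyme digests, ICE-style matrix
balancing, trans-interaction calling and read alignment itself are out of
scope.
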