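# Methods

## Problem setting

A cryo-EM density map of an amyloid filament extracted from tissue can be
resolved to near-atomic detail before anyone knows which protein the
filament is made of. The map nevertheless constrains the sequence: large
branched densities on the outside of the fold mark N-glycosylated
asparagines, which in turn sit in N-x-[ST] sequons; a dumbbell of density
between two rungs marks a disulfide cysteine pair; and because the rungs
of a cross-β stack are single residues, the spacing between two such
features is an exact residue count. `filamentid` formalizes the resulting
identification step: observations → gapped pattern(s) → exact proteome
scan → specificity statistics.

## Pattern dialect and canonical form

Patterns are dash-separated elements: a residue class (`N`, `[ST]`) or a
wildcard run (`x`, `x(n)`). The dialect deliberately excludes
variable-length runs `x(n,m)`: spacer uncertainty is handled upstream by
enumerating candidate patterns with integer offsets, which keeps the
scanner exact and the expected-hit arithmetic a simple product. It also
excludes negated classes and ambiguity codes. Canonicalization merges
adjacent wildcard runs, sorts class letters, and writes singleton classes
as bare letters, so equal patterns have equal strings; parse/serialize
round-trips through this form.

Anchors — the elements corresponding to map features — default to the
singleton residue classes (the sequon asparagines, the cysteines). The
`[ST]` of a sequon is a constraint position but not an anchor.

## Scanning semantics

Every window is tested; overlapping matches are all reported, because the
uniqueness claim that matters ("only one protein in the proteome
matches") is at sequence level and is exposed as `ScanReport.unique_hit`.
Coordinates are 1-based and inclusive throughout, matching residue
numbering conventions (the first anchor of the TMEM106B match is residue
145, not offset 144).

An `X` in a sequence satisfies wildcard positions but never a residue
class. This is the conservative choice: a low-quality proteome entry full
of `X` can suppress a match but can never manufacture one, so a reported
unique hit cannot rest on unknown residues. Rare non-canonical letters in
input FASTA (B, Z, J, U, O) are mapped to `X` on read under the same
conservative semantics.

Internally the scanner compiles a pattern to a regular expression with a
look-ahead capture (for overlap) and runs it once per sequence; the
dialect (no back-references, fixed-length elements) makes this an exact
linear scan. The test suite holds the scanner equal to an independent
position-by-position window oracle over thousands of randomized
instances, so the compilation step is not trusted, it is checked.

## From density features to patterns

A feature list is ordered by rung offset, with the first feature at
offset 0 — a map yields relative, not absolute, positions. A
glycosylated-Asn feature contributes `N-x-[ST]` (footprint 3); a
disulfide-Cys or generic feature contributes a single class (footprint
1). The spacer between consecutive features is `next_offset −
current_offset − footprint`; negative spacers mark an infeasible offset
combination, which is dropped. Each feature may carry a symmetric integer
uncertainty ±u; enumeration over all combinations is capped at 10,000
patterns (desk scale) and deduplicated by canonical string.

The sequon is encoded exactly as `N-x-[ST]`, without forbidding proline
at the middle position, to reproduce the printed fingerprint literally.
The biologically stricter sequon (no proline at x) is available as
`strict_sequon=True`, encoded as the 19-letter class, and is off by
default.

Candidate ranking is lexicographic: ascending expected background hits,
then ascending observed hits, then descending information content, then
the canonical string. Expected hits dominate because the identification
logic is "as few chance matches as possible"; observed hits discriminate
among patterns with equal background behaviour; information content is a
tiebreak that prefers more constrained patterns when both counts tie.

## Match statistics

Under an order-0 (i.i.d.) background with residue frequencies `f`, the
per-window match probability is `p = Π_classes Σ_{r∈class} f(r)`;
wildcards contribute 1. For a proteome with window count
`W = Σ max(0, L_i − span + 1)`, the expected hit count is `λ = pW`
(exact under the model, by linearity of expectation), and the
significance of an observed count k is the Poisson tail `P[K ≥ k]`.

Two approximations are documented rather than corrected: the background
is order-0 (no dipeptide structure — the uniqueness argument only needs
order-of-magnitude specificity), and overlapping-window dependence is
ignored in the Poisson tail (for sparse, high-information patterns the
clumping correction is negligible). Background estimation from a proteome
uses add-one smoothing over the 20 canonical residues, excluding `X`, so
small fixtures never yield zero class probabilities.

Information content is `Σ_classes log2(1/p_class)`; the four-sequon
fingerprint is worth `4·log2(20) + 4·log2(10) ≈ 30.6` bits under a
uniform background, with per-window probability `0.05⁴ × 0.10⁴ =
6.25×10⁻¹⁰`.

## Helical seeding arithmetic

In projection a twisted filament repeats its appearance every half turn,
the crossover distance. With rise δ per rung, `|twist| = 180°·δ/C`
degrees per rung; the default rise is 4.75 Å (cross-β stacking) and the
default handedness is left (negative twist), the convention for amyloid
filaments — a documented default rather than a silent sign. A crossover
shorter than the rise is rejected as unphysical. Two-protofilament C2
filaments share the per-rung twist; no symmetry expansion is done here.

## Case-table analysis

The packaged table transcribes the 25 donors (22 with abundant amyloid
deposits, 3 neurologically normal controls), their age, T185S (rs3173615)
genotype and observed filament types. Filament-type labels carry the fold
(I, IIa, IIb, III) and `-s`/`-d` for one or two protofilaments; folds IIa
and IIb collapse to II for association tests (toggleable), and a case
counts once per fold regardless of how many filament types of that fold
it shows, matching per-individual statements. Percentages reflect picked
cryo-EM segments, not brain content, and are carried as annotation only;
sub-percent entries (`<1`) are stored with the raw token preserved and a
numeric stand-in of 0.5 for range validation.

Fisher's exact test is implemented as a full hypergeometric enumeration
in integer arithmetic (binomial coefficients via `math.comb`), so the
two-sided rule — sum the probability of every table whose point
probability does not exceed the observed one — involves no floating-point
tie tolerance at all. The test suite checks it against an independent
implementation on every 2×2 table with total ≤ 30.

## Synthetic decoys: what they do and do not establish

Decoy proteomes are i.i.d. draws from a configurable background
(uniform by default) with fixed or truncated log-normal lengths
(defaults: 2,000 sequences × 300 aa, the scale at which calibration runs
are affordable; log-normal μ=5.8, σ=0.6 truncated to [50, 5000] roughly
matches real protein length spread). Implanted motif instances are placed
uniformly over feasible windows, never overlapping (rejection sampling,
capped at 1,000 attempts), so implant accounting stays exact; partial
implants degrade named elements by substituting a residue outside the
class. Generation is deterministic per seed, with the RNG algorithm
(NumPy PCG64) and seed recorded in every FASTA header.

Decoys emulate composition only. A green calibration test establishes
that the scanner and the closed-form expected-hit arithmetic agree under
the i.i.d. model; it does not establish uniqueness of any pattern in a
real proteome, which has homology, repeats and biased local composition.
The real-proteome claim is therefore exposed as an optional user-supplied
run, not asserted by the test suite.

The packaged TMEM106B reference sequence (274 residues) carries its
structure-derived annotations — ordered core S120–G254, glycosylated
asparagines N145/N151/N164/N183/N256, disulfide C214–C253, variant
position 185 — and every annotation is asserted against the sequence at
load time, so a transcription error would fail loudly rather than skew
results.

## Numerical and design choices

- All randomness flows through explicit integer seeds; equal seeds give
  byte-identical FASTA output.
- Background frequencies must sum to 1 within 1e-9; they are renormalized
  only at the RNG boundary (where NumPy requires exact normalization).
- Expected-hit calibration tests compare the empirical mean over seeded
  decoy proteomes with λ using the Poisson-scale standard error
  √(λ/n_proteomes); overlapping sequon windows are negatively correlated,
  so this SE is mildly conservative.
- Scan of a pattern longer than a sequence returns an empty list, not an
  error; a CLI run with zero hits exits 0 — pipelines must distinguish
  "no match" from "failure".

## Known limitations

- No variable-length spacers in a single pattern; enumerate instead.
- No mismatch tolerance; a single wrong anchor kills a match by design.
- The statistics module models hit counts, not hit positions; no
  per-sequence length-bias or clump-size modelling.
- Feature extraction from maps (MRC volumes) is out of scope; features
  are operator-supplied annotations, as they are in practice.
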