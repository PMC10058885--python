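# Methods

## Data model

Both assays are dominant-marker systems: a band is scored present (1) or
absent (0), with no allele dosage. The `BandMatrix` container crosses
named bands — identified by `(primer, band_id)`, with fragment size
carried as metadata only — with samples (one control at dose 0 plus
treated groups) and lane kinds `X` (undigested), `H` (HpaII) and `M`
(MspI). RAPD matrices hold `X` lanes only; CRED-RA matrices hold all
three for every sample. One TSV dialect serves both assays: sample doses
and the control flag live in `# sample=` header comments, one row per
band, strictly binary cells. Band identity across samples is positional
(by id) exactly as bands are matched within one gel; the package does not
do image densitometry or ladder regression — scoring is the caller's
boundary.

## Genotoxicity (GTS)

For a treated sample, bands are compared one-by-one with the control's
X-lane profile: `appeared` (present in treated, absent in control),
`disappeared` (the converse), `a = appeared + disappeared`, and `n` = the
number of bands the control shows in the same primer scope. Then
`polymorphism % = (a/n)·100` and `GTS % = (1 − a/n)·100`. Comparison uses
X lanes even in CRED-RA matrices, since polymorphism is defined on
undigested profiles.

Choices worth stating:

- **Aggregation across primers.** A per-dose figure can pool counts
  (`Σa / Σn`, default) or average per-primer percentages with equal
  weights (`aggregate="mean"`). Pooling is the count-consistent reading of
  the formula's definition of `a` and `n`; both are exposed.
- **`a > n` is allowed.** Many new bands can push GTS negative; the value
  is returned as computed with a `RuntimeWarning`, never clamped, so
  pathological simulations stay visible.
- **Exact complementarity.** GTS is computed as
  `100 − polymorphism%` (algebraically identical to the defining formula)
  so that the pair sums to exactly 100 in floating point for every
  `(a, n)` — an invariant the test suite asserts as `==`, not approx.
- `n = 0` (control with no bands in scope) is a domain error, not a 0 or
  NaN.

## Methylation typing

`classify_band` is the four-row truth table above, total on all 8 binary
triplets: the four `x=0` triplets return *unclassifiable* — a band that
never amplified from undigested template carries no methylation
information — and unclassifiable bands are excluded from every
percentage denominator.

Note on Type II: this classification takes HpaII as cutting and MspI as
blocked for the hemi-methylated external-cytosine configuration. Parts of
the MSAP literature use the opposite (y,z) reading for semi-methylation;
this package implements the convention stated above verbatim, and the
simulator's enzyme rules are its exact inverse, so the round-trip tests
pin the convention rather than hide it.

Two ratio pathways exist deliberately:

1. **Count-based** (`pattern_ratios_from_counts`) — the footnote formulas
   applied to integer tallies; used by the pipeline.
2. **Percent-vector** (`pattern_ratios_from_percent_vector`) — takes
   already-published per-type percentages, treats the denominator as 100
   and returns the linear sums. Published tables of this assay print type
   columns that do not always sum to 100 (rounding or unscored bands;
   typically 97.7–100.2), yet their printed ratio rows equal the linear
   sums of the printed type rows. The percent-vector path reproduces such
   tables exactly; the discrepancy is documented here rather than silently
   renormalized.

Per-sample tables support two modes mirroring the genotoxicity choice:
`average` (per-primer percentages, equal primer weights — the "average
rates" presentation) and `pooled` (counts pooled over primers).

### Numerical closure

`type_percentages` must sum to exactly 100 (a conservation invariant the
acceptance checks use). Four independently rounded `100·c/d` terms miss
100 by one ulp in ~12 % of random count vectors, so the share of the last
nonzero type is computed as the complement of the left-to-right running
sum. This makes the in-order sum exactly 100.0 for any realistic count
vector and never produces a negative share (the correction is ≤ a few
ulp, the closed share ≥ 100/d). The same complement trick makes
`non + total = 100` exact in the count-based ratio path.

## The simulator

The generator emulates the full experiment at the sequence level:

1. **Amplicons.** For each (primer, band) a random A/C/G/T sequence of
   length uniform on [100, 1000] bp is built containing exactly
   `sites_per_amplicon` CCGG motifs and no accidental extras: the
   background is scrubbed (rewriting one G of any chance CCGG to A, which
   cannot seed a new motif) and sites are then overwritten at
   non-overlapping offsets. Primer names follow the standard decamer
   panel (OPC/OPA series); the primer sequences are carried as metadata
   but not embedded in the amplicons — simulating priming thermodynamics
   is out of scope.
2. **States.** Every CCGG site in every sample draws independently from
   its dose's probability vector over `U` (unmethylated), `HE`
   (hemi-methylated external C), `IF` (internal C methylated on both
   strands), `FF` (fully methylated). No spatial correlation between
   sites is modelled; correlation would be a config extension, not a
   default.
3. **Digestion.** HpaII is blocked by `{IF, FF}`, MspI by `{HE, FF}` —
   the exact inverse of the classifier, so with one site and no mutations
   the state→type map `U→I, HE→II, IF→III, FF→IV` is a bijection. A band
   survives a digestion lane only if *every* site blocks the enzyme: a
   single cut destroys the full-length template ("any cleavable site
   kills the band").
4. **Mutations.** Per treated sample, each band is lost with probability
   `band_loss_prob[dose]` (dark in all lanes) and each primer gains
   `Poisson(band_gain_rate[dose])` fresh bands, present only in that
   sample, with their own amplicons and state draws. Expected
   polymorphism fraction is therefore `q + g·n_primers/n`.

All draws come from one seeded `numpy` generator in a fixed order —
amplicons, then states, then mutations — so identical seeds give
bit-identical output files (asserted by test).

### Default calibration

The defaults are pinned to the published summary statistics of a Cu
dose-ladder experiment on safflower roots (doses 0, 20, 40, 80, 160, 320,
640, 1280 mg/L CuSO₄·5H₂O), the only numbers available — raw band counts
were not published:

- `state_probs[dose]` = the reported average type percentages per dose,
  normalized to sum to 1 (e.g. control ≈ (0.027, 0.035, 0.052, 0.886));
- `band_loss_prob` and `band_gain_rate` are set so the expected
  polymorphic fraction equals `1 − GTS/100` from the reported per-dose
  GTS (82.25–88.90 %), split 2/3 into band loss and 1/3 into band gain —
  band loss dominates observed metal-stress RAPD changes, but both
  channels must be exercised for the recovery tests;
- the control uses zero mutation rates (it is its own reference);
- `n_primers=10` (the decamer panel size), `bands_per_primer=10`
  (≈100 scorable bands per profile set, a realistic gel yield),
  `sites_per_amplicon=1`.

These defaults reproduce the *distributional* behaviour (GTS in the low
80s–high 80s, Type IV dominance, total methylation ≈ 92–95 %), not any
specific gel. What passing tests show is that the scoring pipeline
inverts the generative model; they cannot show that real gels are scored
correctly upstream, that methylation states are spatially independent in
real genomes, or that band identity across lanes is error-free.

## Problem sizes

Unit and property tests run on matrices of ≤ a few dozen bands. The
larger consistency checks use 500 bands per dose for the exact
simulator→classifier round trip and 5,000 bands per dose for stochastic
parameter recovery, judged against 3× binomial standard errors — sizes at
which those intervals are tight (≈ ±0.7 percentage points for a 2.6 %
share) while the whole suite stays fast.

## Reports

The JSON summary is the canonical output (tool version, seed, input
checksums, every percentage unrounded and rounded); TSV tables and the
two figures (type shares by dose, pattern ratios by dose) are views.
Rounding — half-up to 2 decimals — happens only at the view layer; all
internal arithmetic is unrounded.

## Known limitations

- No gel-image processing, band calling, or faint-band thresholding; the
  binary matrix is the trust boundary.
- No significance testing between dose groups (none is defined for these
  indices here).
- The simulator does not model PCR kinetics, gel migration, primer
  thermodynamics, or realistic genome composition.
- Bisulfite-resolution methylation and non-CCGG loci are out of scope.
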