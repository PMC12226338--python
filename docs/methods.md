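# Methods

`tripletrep` implements the quantitative analyses around ribozyme-catalysed
RNA replication with trinucleotide (triplet) substrates under pH/freeze–thaw
cycling: reannealing kinetics, cycle bookkeeping, emergent-pool
classification, and reduced-genetic-code statistics, together with a
synthetic-data generator that emulates the statistical structure of the raw
gel and sequencing data.

## Reannealing kinetics (`tripletrep.kinetics`)

Dissociated complementary strands re-associate by irreversible second-order
kinetics: duplex dissociation is negligible at working temperatures, so for
equal strand concentrations S0 (µM) the free fraction is

    f(t) = 1 / (1 + k·S0·t),

the solution of ds/dt = −k·s². Unequal concentrations use the standard
two-species closed form for the limiting strand. The rate constant k has
units µM⁻¹·min⁻¹; the quantity printed as a "t½" in this field carries the
same units and is treated here as k (both readings give the same closed
form up to a constant, and k is a free fit parameter in any case).

`fit_k` is unweighted least squares of the closed form on (delay, free
fraction) data, with k bounded below at 0. Fractions of exactly 0 are
retained (no log transform), so fully-annealed points cannot produce
singularities. A series pinned at 1 (no annealing observed) returns k = 0
with a boundary flag instead of a spurious estimate. R² is 1 − SS_res/SS_tot,
defined as 1 for an exact fit of a constant series.

**Triplet-coating attenuation** is this package's explicit mechanistic
model; the experiments report only the phenomenology (a ~200-fold slowdown
when one strand's triplets are present, effectively complete arrest when
both are). The template is partitioned into contiguous 3-nt sites from the
5′ end; each site is independently occupied by a bound triplet with
probability θ; duplex nucleation requires a run of at least `w_sites`
contiguous *free* sites. The effective rate is

    k_eff = k · P(free window | plus strand) · P(free window | minus strand),

with an uncoated strand contributing factor 1, so attenuation multiplies
across strands and k_eff ≤ k always. P(free window) is computed by exact
dynamic programming over trailing free-run lengths (verified against
enumeration of all 2ⁿ configurations up to n = 12). `calibrate_occupancy`
inverts the model by bracketed root-finding: the θ at which one coated
strand gives a 1/200 free-window probability reproduces the observed
200-fold slowdown, and the same θ on both strands predicts a 40,000-fold
slowdown — the model's explanation of why double coating effectively stops
reannealing. All mechanism parameters (θ, n_sites, w_sites) are exposed;
none is hard-coded.

## Cycle bookkeeping (`tripletrep.cycling`)

Each pH cycle neutralises an HCl spike with KOH, depositing
(v_acid·m_acid)/v_reaction of KCl — +0.6 mM per cycle for 0.75 µl of 0.1 M
HCl in 125 µl. Increments use the nominal reaction volume, ignoring the
1.5 µl/cycle volume growth; this reproduces the protocol's stated +0.6 mM
exactly and errs by <1.2% over four cycles. The serial diluent carries no
KCl or template, so a dilution event divides KCl by the dilution fold.
Dilutions are applied after the sampling point at each interval;
consequently `cumulative_dilution(from, to)` counts interval multiples m
with from ≤ m < to (a 3-fold/5-cycle schedule gives 3⁷ = 2187 between the
cycle-5 and cycle-40 samples).

The eutectic freeze-concentration factor is the product of the calibration
series' pre-concentration fold and the fold at which no ice phase remains
(50 × 8.8 = 440 for replication buffer), applied linearly to bulk
concentrations — the assumption being uniform freezing-point depression, so
eutectic-phase composition is independent of starting volume.

Amplification accounting multiplies band-intensity fold-change by the
cumulative dilution between the same two sampling points; the apparent
per-cycle amplification is the n-th root of the total. `fit_growth` is OLS
of ln(copies) on cycle over a pre-plateau window. The auto-window is the
longest initial run of cycles whose log-increments are positive and exceed
10% of the first increment; if that run is shorter than 3 points (e.g. a
flat trajectory) all points are used, which makes a constant trajectory fit
b = 0 rather than erroring. `fold_per_cycle` is derived as exp(b) in the
result object, so the two representations cannot drift apart. Gel yields
treat intercalating-dye fluorescence as proportional to RNA length, so
molar amount scales as intensity-per-nucleotide against a reference band.
Triplet consumption counts floor(L/3) triplets per product (lengths off the
triplet register arise from a 5-nt terminal substrate).

## Pool classification (`tripletrep.pools`)

Matching is exact longest-common-substring (LCS), computed by row-vectorised
common-suffix dynamic programming and checked in tests against an
independent quadratic oracle (exhaustively for all 4⁵ pentamers against a
30-nt reference). Exact matching was chosen over mismatch-tolerant
alignment because the classification criterion is complementarity of
replication products, an exact oracle stays trivial, and at the default
threshold the random-match rate is negligible; tolerant matching is out of
scope.

A record with an LCS ≥ `min_match` against a subunit's (+) strand is
`plus_homologous`; against its reverse complement, `minus_homologous`; both,
`ambiguous`; neither, `no_homology`. `min_match` defaults to 12 nt and is a
prominent parameter, not a constant: for random 9–27-mers against a ~270-nt
two-subunit reference the expected chance-match rate is bounded by
≈ 4·(2·270)·4⁻¹² ≈ 10⁻⁴ per query, verified by simulation. (−)-strand match
intervals are reported as their footprint in (+)-strand coordinates
(0-based, half-open), so both strands of a subunit share one positional
axis. Multi-mapping records are assigned to exactly one of their
best-length intervals, drawn uniformly with a required seed; total
footprint mass (weight × lane intensity × interval length) is conserved
across seeds. Class proportions are weight-normalised per cycle within a
configurable length band (default 9–27 nt). Composition statistics weight
nucleotide counts by record weight; zero-denominator ratios return NaN
rather than raising.

## Reduced-code statistics (`tripletrep.codons`)

The family-box set is *derived* from the standard genetic code (via
Biopython's table): a box qualifies when its four codons translate
identically and contain no stop (stops break third-position invariance for
their box). This yields exactly the 8 canonical family boxes / 32 codons;
the test suite re-derives the set from an independently hard-coded codon
table. Sequences are read in frame 0 from the 5′ end — products are
synthesised in triplet register — and trailing 1–2 nt are truncated;
no multi-frame scan is performed. The null model draws codons i.i.d.
uniformly over all 64 (the codon-level statement implemented literally;
for full-length multiples of 3 it coincides with uniform nucleotides),
matched to the observed length list, with uniform trailing bases for
off-register lengths. Enrichment is summarised by per-length frequency
tables, the observed-minus-null mean stretch, and an empirical exceedance
probability from resampling the null — no parametric test, since the
comparison of interest is distributional.

## Synthetic data (`tripletrep.simulate`)

The generator emulates three data types. **Emergent pools** mix four
classes: `minus_homologous` (reverse complements of contiguous reference
substrings), `plus_homologous` (contiguous substrings), `de_novo`, and
`junk` (uniform i.i.d. nucleotides — the classifier's specificity null).
Fragment endpoints are snapped to triplet boundaries of the reference 5′
end, matching triplet-register synthesis. De novo sequences are built from
complementary triplet pairs, sampled with per-base GC probability
`gc_target` and shuffled: this enforces G≈C and A≈U (Chargaff balance) in
expectation at the pool level — which is what the sequencing shows —
without imposing per-sequence self-complementarity. Generated lengths are
multiples of 3 in a configurable range within [9, 60]; the length
distribution is deliberately a parameter (uniform over register lengths by
default) because only the attained range and its growth over cycles are
characterised experimentally. **Delay series** add Gaussian noise (sd as a
fraction, clipped to [0, 1]) to the closed-form free fraction — additive
noise keeps the support valid for a bounded fraction. **Amplification
trajectories** follow min(c0·rˣ, plateau) with multiplicative lognormal
noise, which keeps copy numbers positive. All generators are
bit-reproducible from their seed.

What passing round-trip tests shows, and what it does not: the classifier
recovers generator truth essentially perfectly because generated homologous
fragments are exact substrings at least `min_match` long. Real pools
contain recombination chimeras, partial-homology products and sequencing
errors that exact matching will call `no_homology` or assign shorter
matches; round-trip accuracy on synthetic pools is therefore a correctness
check of the machinery, not an accuracy estimate for real data.

## Pipeline and reproducibility

The demo pipeline (simulate → classify → map_sites → proportions →
composition → codon_stats → cycle_report) derives one child seed per stage
from the single config seed via `numpy` SeedSequence spawning (all child
seeds < 2³¹), records them in a JSON manifest with all parameter values and
the package version, and is byte-identical on re-run. Default problem sizes
(400 sequences per pool snapshot at four cycles, 10-delay kinetic series,
8-cycle growth trajectory, 50 null replicates) complete in a few seconds on
one CPU; the default drift schedule moves weight from junk toward
(−)-strand then (+)-strand homologous classes across cycles, mirroring the
observed order of emergence ((−)-strand products template later (+)-strand
synthesis).

## Numerical choices and limitations

- `curve_fit` initialises k from the median of the closed form inverted at
  interior points; brentq tolerances are 1e-13 on θ.
- Ties in LCS matching retain *all* maximal intervals; assignment among
  them is the only stochastic step in classification.
- The classifier handles only exact contiguous homology; chimeric or
  indel-containing homology is coarsened into shorter matches.
- Eutectic scaling is linear by assumption; saturation effects near the
  eutectic composition are not modelled.
- The occupancy model treats sites independently; cooperative
  triplet–triplet stacking would correlate occupancy and is not modelled.
- `register_class` refuses offset sets that collide mod 3 and leaves
  lengths shorter than their congruent offset unassigned.
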