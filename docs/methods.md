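# Methods

This note documents the models, estimators, numerical choices and known
limitations behind each module, and what the synthetic generators do and do
not emulate.

## Repeat detection

`repeats.find_repeats` compares a circular genome against itself on both
strands by seed-and-extend: exact word seeds (default word size 7; seeds of
at least max(word, 12) bp trigger extension), diagonal clustering, and
ungapped X-drop extension with +1/−2 match/mismatch scores (X-drop 30).
Significance uses the ungapped Karlin–Altschul e-value
E = K·m·n·exp(−λS) with λ solved from the score distribution under uniform
base composition and K ≈ 0.333; at the default e ≤ 1e-6 on a 50-kb genome
this corresponds to a ~26-bp near-exact match, far above what random
sequence produces. Hits crossing the circular origin are recovered by
rescanning a half-length rotation; fragments that the rotation cut splits
are removed by a circular containment filter, self-hits and mirror
duplicates are collapsed to a canonical (locusA.start < locusB.start) form.

Extension is deliberately ungapped: the repeats this caller targets are
near-identical organelle duplications, and the synthetic truth sets used
for validation are indel-free, so ungapped extension keeps hit boundaries
exact. The practical sensitivity floor is a repeat containing an exact run
of ≥ 12 bp — comfortably met by anything at ≥ 98% identity and ≥ 50 bp.
Boundaries of diverged, indel-containing repeats would be conservative;
that regime is outside the validated envelope.

Length classes use closed integer bins as printed in the field's
convention: <100; [100, 500]; [501, 1000]; >1000 bp. Total repeat length
counts each pair once by default (`per_copy=True` doubles it); the choice
is exposed because conventions differ between publications.

## PGLS

`repeats.pgls_fit` regresses a repeat metric on genome size under a
Brownian-motion trait covariance: V_ij is the shared root-to-tip path
length of tips i and j, computed from the dated tree. The fit itself is
generalized least squares (statsmodels `GLS` with sigma = V), reporting the
slope, adjusted R² and the F-test p-value. On a star tree with equal branch
lengths V is proportional to the identity, so PGLS reduces to OLS exactly —
the suite asserts agreement to 1e-10. Branch lengths must be positive;
mismatched tip sets raise an error naming the offenders.

## Recombination assay

For a repeat pair with copies b (locus A, forward strand) and e (locus B,
read on the strand that aligns with b), 200-bp flanks a,c and d,f define
reference forms a-b-c and d-e-f, and recombinant forms
{a,d}×{b,e}×{c,f} minus the references — six forms, collapsing to
{a-b-f, d-b-c} when b = e exactly. A read supports a form when the form's
best edit-distance alignment into the read (either strand; edlib, infix
mode) exceeds 99% identity over the full form. Aligning the *full* form
enforces the both-flanks requirement: a missing 200-bp flank alone costs
far more than the ~1% edit budget. Reads supporting no form are
uninformative; ties between best forms are counted uninformative rather
than fractionally assigned (conservative, and consistent with the strict
flank requirement). The edit-distance search is capped at the identity
budget, which is exact — forms beyond the budget cannot be supporting —
and fast. Frequency = 100·n_recomb/(n_ref+n_recomb), NA when no
informative reads; uninformative reads are excluded from the denominator,
matching a "proportion of reads mapping to expected recombination
products" definition. A pair is "active" at ≥1 recombinant-supporting read
(`min_support` configurable; published analyses rarely state a minimum).

Read filtering (`build_mito_read_set`) keeps reads carrying a near-exact
anchor whose Karlin–Altschul e-value against the mitogenome clears 1e-100
(a ~200-bp near-exact match is orders of magnitude below that), and drops
reads whose chunked alignment coverage against the plastid genome exceeds
85% of the read — so mito/plastid chimeras survive but pure plastid reads
do not.

## Inversion distance

Block orders are circular signed permutations. The circular problem reduces
to linear: rotate (and, if block 1 is negative, reflect — reverse the order
and flip all signs) so the order starts with +1, drop that block and
relabel; the linear reversal distance of the remainder is the circular
inversion distance. The linear distance is exact Hannenhalli–Pevzner:
d = (n+1) − c + h + f, with c the breakpoint-graph cycle count, h the
number of hurdles and f the fortress indicator. Hurdles are found by
scanning positions of unoriented components around the circle of
positions, collapsing runs: a component forming exactly one circular run
is a hurdle; a hurdle whose removal would merge the two runs of another
component into one "protects" it and is a superhurdle; a fortress is an
odd number of hurdles, all superhurdles. The implementation is O(n²),
ample for organelle block counts, and is verified exhaustively against
breadth-first search over the inversion move set for every circular signed
permutation with n ≤ 6 (3840 states) and every linear one with n ≤ 6
(46080 states) during development; the shipped suite re-runs the circular
check.

Blocks are built from unique 21-mers shared by two genomes (either strand),
chained along genome A into consistently stranded, collinear runs
(diagonal tolerance 20 bp, gap ≤ 2 kb) of at least 500 bp. This is a
deliberate simplification of whole-genome collinear-block alignment,
adequate for genomes sharing long exactly conserved tracts (the synthetic
regime); diverged real genomes would need a true aligner upstream, and the
block orders can be supplied as TSV in that case.

Rates: branch mode divides events by the branch's absolute time;
pairwise mode divides by twice the divergence time (each lineage
accumulates events for T). Published per-branch figures (e.g., six events
at 0.05 Mya → 120 events/Mya) follow the branch convention. Rates are
point estimates; divergence-time uncertainty is not propagated.

## Population scans

Variant matrices are haploid (organelle inheritance), phased by
construction. Filtering drops sites with minor-allele frequency ≤ 0.01
(over non-missing calls) or missing fraction ≥ 0.1. Per-site diversity is
the unbiased haploid estimator π = n/(n−1)·(1 − Σ p_a²); a window's π is
the sum over its sites divided by the window length (1000 bp, 500-bp
steps; windows wrap the circular origin). F_ST is Weir–Cockerham
specialized to haploid calls: per site and allele,
MSP = Σ n_i(p_i−p̄)²/(r−1), MSG = Σ n_i p_i(1−p_i)/Σ(n_i−1),
n_c = (N − Σn_i²/N)/(r−1); a window's weighted estimate is
Σ(MSP−MSG)/Σ(MSP+(n_c−1)·MSG), with negative estimates reported as
computed. A window is a sweep candidate when F_ST > 0.1 and
π_wild/π_cul > 2 (plain thresholds; an optional top-quantile mode exists
but is off by default). π_cul = 0 gives an undefined ratio and no flag
unless `allow_infinite_ratio` is set. Adjacent flagged windows merge;
regions wrapping the origin are joined when the reference length is known.

## Deletion genotyping

Idep is the mean per-base depth over the candidate region (median by
flag — publications rarely say which; mean is the default here), Wdep the
whole-genome mean, and the call uses the ratio. The default single
threshold of 2.0 sits in the empirical gap between the observed low
(0.24–0.72) and high (6.94–142.98) bands, near their geometric midpoint on
the log scale; a two-band mode preserves the gap explicitly and returns
"ambiguous" for ratios strictly inside it. Chi-square tests are Pearson
without continuity correction (Yates by flag). Homology totals keep hits
strictly longer than 100 bp and union the rest. The ORF scan reports every
ATG-to-stop frame of ≥150 bp (stop included) on both strands, nested
starts included, with coordinates mapped to the forward strand; frames
without an in-frame stop are not reported.

## Synthetic generators

All generators are pure functions of `SimulationConfig.seed` (seeds are
fanned out through independent streams per generator, so outputs are
reproducible individually and jointly).

*Genomes.* Background is i.i.d. uniform ACGT; planted repeat pairs of
configured length/identity/orientation are laid out with ≥500 bp of unique
separation, and the 16 bases flanking copy B are forced to mismatch the
aligned bases flanking copy A so each planted repeat is a *maximal* exact
match — truth coordinates are exact, which is what makes precision/recall
= 1.0 a meaningful assertion. A rejection check re-samples if any exact
50-mer recurs outside the planted copies (essentially never at these
sizes). The default genome is 50 kb — real Rosaceae mitogenomes run
278–536 kb, and everything here scales linearly; desk scale keeps the
property suites fast while leaving the per-bp regime (repeat density,
window occupancy) comparable.

*Reads.* The recombinant conformation of a direct pair splits the circle
into two subcircles (crossover at the repeat midpoint); an inverted pair
inverts the intervening segment. A binomial share f of reads comes from
the recombinant conformation, the rest from the reference circle; starts
are uniform on the source circle (wrap-around allowed), lengths lognormal
truncated to [500, 4·mean], strands random, substitution errors i.i.d.
Because reference and recombinant conformations have equal total length
and equally many junctions, the recombinant share among junction-spanning
reads is Binomial(n_informative, f) — the exact oracle the suite tests
against. The default error rate is 0.5% substitutions, modelling
*error-corrected* long reads: the assay's 99%-identity filter presumes
correction (raw ~5%-error reads would all be discarded), matching how such
read sets are prepared in practice. No indel errors and no
instrument-specific error profiles are simulated; diploid genotypes are
out of scope (organelles are effectively haploid).

*Populations.* Neutral sites share one allele frequency
(Beta(0.5, 0.5) clipped to [0.05, 0.95]) across populations; inside a
sweep window the cultivated frequency is pushed toward the nearest
fixation point by reduction×boost, which reduces π_cul by about the
reduction factor and raises F_ST. SNP density defaults to 0.02/bp so that
1-kb windows carry ~20 sites — enough for stable window estimates at desk
scale (real organelle SNP matrices are sparser; the scan itself is
agnostic). Default population sizes (33, 52) mirror a wild/cultivated
accession split of realistic size. Missingness is i.i.d. (2%).

*Depth ratios.* True ratios are drawn uniformly from the configured band
(present → high, absent → low), Wdep uniform in [20, 60]; observed Idep
and Wdep are Poisson around their means. At these depths the bands are
separated by many standard deviations, so 100% recovery by the classifier
is the expected behaviour, and the suite asserts it.

What passing these suites shows — and does not. They show the estimators
are correct on data that satisfies their assumptions exactly (indel-free
repeats, corrected reads, i.i.d. missingness, clean depth bands). They do
not show robustness to assembly errors, mapping bias, chimeric reads
beyond the simulated kind, or population structure within groups.

## Pipeline

`run_pipeline` executes stages in dependency order from one validated
config (unknown keys rejected). Every file read or written is recorded in
`manifest.json` with its SHA-256; a stage refuses an upstream input whose
checksum no longer matches what its producer recorded, and a missing
upstream output raises an error naming the stage. Re-running an identical
config is byte-identical. The `mitostructkit` CLI exposes one subcommand
per stage plus `all`.

## Problem sizes used by the shipped checks

Acceptance-style runs use 20-kb genomes for the read assay (one 2-kb exact
pair, coverage 60, read length 3000±800 — chosen so both recombinant
subcircles dwarf the read length and truncation cannot bias junction
exposure), 50-kb genomes for the repeat census and population scans,
50 seeds × three mixture fractions for the binomial-recovery suite,
20 seeds for sweep recovery and for neutral false positives, 200
band-generated samples for deletion recovery, 200 Brownian replicates on a
20-tip ultrametric caterpillar (whose covariance has a closed form,
keeping the simulation independent of the estimator), and all 3840
circular signed permutations of six blocks for the exhaustive
inversion-distance check.
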