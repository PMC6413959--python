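# Methods

This note documents the models implemented in `pedsel`, the defaults chosen
where the design was genuinely open, and what the synthetic-data experiments
do and do not demonstrate.

## Pedigree model and selfing augmentation

A pedigree is a directed acyclic graph of entries with up to two known
parents. Entries with a single known parent are legal; the unknown slot is
treated throughout as a unique, unrelated, fully inbred founder. Cycles are
rejected at validation and never silently broken.

Inbred varieties are not the F1 of their recorded cross: they are derived by
repeated self-fertilisation (or doubled-haploid production, which the model
approximates as complete selfing). `augment_selfing` therefore inserts
`generations` intermediate entries below every cross — the F1 and a chain in
which each entry has the previous one as both parents — with the named
variety as the final generation. The default of **7 generations** reflects
typical variety-development practice; the named line's expected self-kinship
becomes 1 − 2⁻⁸ ≈ 0.996, i.e. nearly fully inbred. Inserted ids are
`<id>__S<k>` so the original ids remain valid references. The augmentation is
applied identically to entries with one known parent (chain below the
half-known cross); this was an open choice, made so that single-parent
entries receive the same inbreeding treatment as fully documented ones.

## Kinship

**Pedigree kinship** is computed by the tabular recursion in topological
order. The crop-specific convention is that founders are fully inbred
(F = 1, Φ(f, f) = 1): pedigree founders are varieties or landrace
selections, not outbred individuals, and this convention is what makes two
fully inbred sibling lines of inbred parents come out at Φ = 0.5 and any
fully inbred line at self-kinship 1. An unknown parent contributes 0 to both
the off-diagonal and the self-kinship formulas. The recursion is computed
over the ancestor closure of the requested targets; memory is quadratic in
that closure, which is adequate for pedigrees up to a few thousand relevant
entries.

**Marker kinship** is identity-by-state sharing: per marker
1 − |dosage difference|/2, averaged over markers jointly observed in both
lines, diagonal 1 by convention. IBS was chosen over an allele-frequency
weighted genomic relationship because frequency estimation is ill-posed in a
structured collection of inbred lines. Heterozygous calls contribute
fractional sharing rather than being discarded, since real inbred lines
retain residual heterozygosity. Pairs with fewer than `min_overlap`
(default 100) jointly observed markers are reported as unreliable; pairs
with none are missing.

**Marker thinning** is a greedy keep-first pass in map order (input order
without a map): a marker is dropped when its absolute Pearson correlation
with any already-kept marker exceeds 0.75. Keep-first was fixed for
determinism; monomorphic markers have undefined correlation and are retained
but never compared. An option additionally drops markers mapping to the
exact position of a kept marker (used ahead of the diversity scan); thinning
is applied within the founder set in that workflow.

**Comparison and error flagging.** The two matrices are compared over
off-diagonal pairs present in both; pairs with pedigree kinship exactly 0
are excluded by default because the pedigree is uninformative there (raw
Pearson correlation on the remaining pairs; no transformation is applied to
the weakly curvilinear cloud). Residuals from the least-squares line are
standardised by a robust scale (1.4826 × MAD) so that the gross outliers the
flagging step looks for cannot mask themselves by inflating the scale. A
line is flagged when more than 25% of its pairs have |standardised residual|
above 4; both numbers are heuristics for manual review, tunable, and
annotated with the line's parents and children to guide inspection. They are
not significance tests.

## Gene dropping

Gametes are formed chromosome by chromosome. The strand indicator is the
running parity of per-marker switch events: probability 0.5 at the first
marker of each chromosome (uniform starting strand, independent
chromosomes), and the **Haldane** recombination fraction
r = ½(1 − e^(−2d/100)) of the inter-marker distance d (cM) elsewhere.
Haldane (no interference) was chosen because nothing in the analysis depends
on interference and it has a clean closed form for verification; the mapping
function is isolated in `GeneticMap.switch_probs` so Kosambi could be
substituted. Markers at identical positions never recombine.

Each non-founder receives one gamete from each parent and is taken through
`selfing_generations` (default 7) of single-seed descent; pass 0 when the
pedigree already contains explicit selfing entries. Heterozygous founder
calls are resolved to a random homozygote per replicate (founders are
near-inbred; a residual het call is ambiguous about which allele the seed
stock fixed). Missing founder alleles propagate as unknown: a locus stays
missing until, under selfing, the known allele happens to fix. Ensembles use
seed `base_seed + i` for replicate i, so any replicate is reproducible in
isolation.

## Within-cross selection test

For a genotyped trio, sharing with each parent is the mean over jointly
observed markers of 1 − |dosage difference|/2. By default **all** markers
enter the proportions, including those where the parents carry the same
allele (a genome-proportion reading); a `polymorphic_only` mode restricts to
markers polymorphic between the parents. The null simulates two fully
inbred, fully opposite parents — so the F1 is heterozygous everywhere — and
takes the F1 through the selfing chain with map-based recombination,
recording the max-parent sharing per replicate (1,000 by default). Because
observed trios are scored on all markers while the null parents are fully
polymorphic, observed proportions are conservative relative to the null.
Thresholds are empirical (1 − p) quantiles at p = 0.01 and 0.001; the
reported median is the 0.5 quantile with linear interpolation. With L
unlinked loci and complete homozygosity the max-parent sharing tends to
0.5 + |N(0, √(0.25/L))|, which the calibration tests use as a closed-form
oracle.

## Cross-pedigree diversity scan

Founders are the genotyped entries released before the cutoff year (default
2000); eligible descendants are entries whose every ancestor path terminates
inside the founder set; targets are eligible, genotyped, post-cutoff
entries. Per marker, observed allelic diversity D = 1 − Σpᵢ² = 2p(1 − p)
among the targets (frequencies from dosages over non-missing calls,
heterozygotes counting once for each allele) is compared with its
distribution over a gene-dropped ensemble (default 100 replicates):
z = (D_obs − mean_sim)/sd_sim, flags at z ≤ −5 ("loss") and z ≥ +5
("gain"). With ~2,000 markers the ±5 SD rule approximates a Bonferroni
p = 0.001 only asymptotically, and with 100 replicates the SD estimate is
noisy — occasional isolated false flags are expected and the ensemble size
is configurable. Markers with zero simulated SD (e.g. monomorphic in the
founders) are reported separately rather than given a z-score.

## LD analysis

R² is the squared Pearson correlation of dosage vectors over jointly
observed lines (pairs with fewer than 3 joint observations are missing), so
it is invariant to allele relabelling. Markers are first filtered to minor
allele frequency strictly above 0.2. Decay per chromosome is a loess fit of
R² on distance: locally linear, tricube weights, span 0.75 as the fraction
of points, no robustness iterations, evaluated on a 1-cM grid — all fixed
for determinism. The "distance at R² = 0.15" is the first downward crossing
of the fitted curve, linearly interpolated, reported as not-reached when the
curve stays above the level. Simulated LD is computed per replicate and then
averaged across replicates (stabler than pooling genotypes). The difference
profile bins intra-chromosomal pairs by distance (default 5-cM bins) and
reports mean(R²_obs) − mean(R²_sim) per bin plus the inter-chromosomal
baseline; a square matrix export (observed above the diagonal, simulated
below) supports heat-map rendering by external tools.

## Synthetic data

The generator emulates the three inputs of the real analysis: a
21-chromosome map (default lengths spread over 150–330 cM, uniform random
marker placement), fully homozygous founders with per-marker reference
frequencies (default Uniform(0.1, 0.9)), and a multi-generation crossing
pedigree with release years increasing by generation (so cutoff-year
subsetting is exercised) and cycling country labels. Selection is modelled
as **best-of-k truncation on an additive QTL score** within each cross: k
independent selfed progeny are simulated and the top scorer becomes the
entry. This is the simplest mechanism that generates all three observed
signatures — distorted parental sharing, localized diversity loss, and
conserved short-range LD — and is a deliberate stand-in for real breeder
practice, not a model of it. k = 1 reduces exactly to neutral gene dropping
(same seed, identical output).

What passing the synthetic experiments shows — and what it does not: the
generator produces clean biallelic data with no genotyping error, no
population structure beyond the pedigree itself, no introgressions or
segregation-distorting regions, and pedigrees that are complete and correct
by construction. Detection power and calibration on real data, where all of
those are violated to some degree, will differ; the experiments establish
that each statistic responds to its intended signal and is calibrated under
its own null.

## Verification scales

The behavioural checks run at deliberately compact sizes chosen to give
tight Monte-Carlo error while keeping the suite fast: 10⁵ single-locus drops
for the kinship oracle, 10⁵ marker-pair transmissions per distance for the
Haldane check, 10⁴ selfing chains for residual heterozygosity, 1,000-
simulation nulls at 4,009 unlinked loci for the binomial calibration, and 20
independent replicate runs for each selection-recovery experiment (within-
cross: 5 chromosomes × 10 markers, best-of-8; diversity: 21 chromosomes × 6
markers, best-of-20, 100-replicate ensembles; LD: 4 chromosomes × 50
markers, six generations of best-of-30 polygenic selection). The deep
polygenic design for the LD experiment reflects that conserved linkage
blocks emerge from cumulative selection on many loci over multiple
generations, not from one round on a single major gene.

## Known limitations

* Doubled-haploid derivation is approximated by the selfing chain.
* The kinship comparison reports raw Pearson r; no curvature correction.
* Error flagging is a screening heuristic; confirmed errors require manual
  review of the flagged lines and their relatives.
* The tabular kinship recursion stores a dense matrix over the ancestor
  closure; very large augmented pedigrees (tens of thousands of relevant
  entries) need substantial memory.
* Haldane's function ignores crossover interference; map distances are taken
  at face value even where real maps inflate them.
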