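# Methods

## Scope and model

`msynet` implements the downstream half of a short-read Y-chromosome
population analysis. Read mapping, duplicate removal and variant calling
are assumed done by standard external tools; the package takes per-window
depth tables, a VCF and region files, and produces classified Y regions, a
cleaned haploid genotype matrix, a median-joining haplotype network,
diversity estimates and rho-based node dates. The male-specific region
(MSY) is haploid and non-recombining, so a sample's variant alleles form a
single haplotype and the genealogy of haplotypes is a tree unless
recurrent mutation introduces homoplasy.

## Window classification

Windows of fixed width w (default 50 bp) are scored with a Poisson model
on depth. Depths are first normalized per sample to genome-wide mean 1
(the normalizer is the sample's mean window depth; the individual the
assembly derives from should be excluded, since its reads match the
reference perfectly). For scoring, normalized depths are rescaled by one
common reference depth D (default: the mean of the per-sample
normalizers) and the per-class log-likelihood Σ_s [x_s·log λ_s − λ_s] is
summed over samples, with expected ratios (♂, ♀) of (1, 1) for nonMSY,
(0.5, ε) for scY and (0.5k, ε) for mcY, maximizing over integer k in
[2, 20]. Because a common rescale multiplies every between-class
log-likelihood difference by a positive constant, assignments are exactly
invariant to rescaling any sample's raw depths — sequencing depth
differences between individuals cannot change calls.

Parameters that matter:

* ε (default 0.02) — the female mismapping leak on true Y windows. It
  keeps the female likelihood finite and matches the generator's default
  leak. Setting ε too high blurs scY against nonMSY for females; too low
  makes single stray female reads veto scY.
* k cap (default 20) — bounded copy-number search; hitting the cap is
  logged implicitly by the assigned copy number.
* All-zero windows get a `nocall` sentinel and count as non-Y in contig
  content fractions (conservative toward Y specificity).

Contig cleanup keeps a contig iff length ≥ 200 bp **and** Y-specific
window fraction ≥ 50%; the discard sentence this rule derives from is
grammatically ambiguous, and the conjunctive keep-rule is the one that
yields a clean Y reference. Both thresholds are configurable. Assembly
summary statistics use the descending-cumulative definition of N50 (the
length at which the sorted cumulative sum first reaches half the total).

## Variant filtering

Rules apply in a fixed order, and each dropped site records the first rule
it violated: (1) inside scY regions; (2) SNV; (3) exactly one ALT; (4) no
heterozygous genotype; (5) no phased genotype (phase is read only for
ploidy ≥ 2 — htslib marks haploid calls "phased", which is meaningless);
(6) not a reference error; (7) not all-missing; (8) at least one sample
with DP ≥ 3 and GQ > 9 (strict), with failing cells demoted to missing
rather than dropping the site. The depth rule is read as "≥ 3 in at least
one individual" — site-level rescue — because haploid calls from a single
deep sample are informative and the cascade retains maximal haplotype
information.

"Reference error" is operationalized as: every called ingroup sample
carries ALT, with at least two called samples (a single call cannot
establish that the reference base — one individual's consensus — is
wrong). Optionally the reference individual itself can be required to
carry ALT.

Imputation fills each missing cell from the sample's nearest neighbour by
Hamming distance on complete sites; ties go to the tied donors' shared
allele if unanimous, else to the majority allele within the recipient's
cluster (the two sides of the unique longest minimum-spanning-tree edge),
else to REF. Every imputation is logged with donor and distance. This is a
deterministic, algorithmic version of assigning missing calls "according
to the clustering"; it recovers ≥ 98% of masked truth at 10% missingness
when clusters are ≥ 20 mutations apart, and it degrades when missingness
concentrates on the sites that separate close haplotypes.

## Median-joining network

Haplotypes are binary vectors over the segregating sites (constant columns
are dropped at collapse and counted, so diversity denominators stay the
full sequence length). The construction iterates: build the ε-relaxed
minimum-spanning network (union of minimum spanning trees for ε = 0) over
the current vectors; among the per-site majority (median) vectors of
connected triples, insert the single candidate that most reduces the
minimum-spanning length (lexicographic tie-break); repeat to a fixed
point, then prune median vectors whose removal leaves the spanning length
unchanged. ε defaults to 0, standard for SNP data. The maximum-parsimony
post-processing step of the original program is omitted: on
homoplasy-free data it is a no-op, and the networks this package targets
are tree-like. On infinite-sites input the output is the perfect
phylogeny: path lengths equal Hamming distances exactly, and an exhaustive
Steiner oracle (subset enumeration over the median closure, test-only,
≤ 12 haplotypes / ≤ 64 sites) confirms minimality on every tree-like
instance tested.

Haplogroup assignment cuts the single longest edge on the paths between
differently-labeled seed nodes and propagates labels through the resulting
components; ties among longest edges are reported as an error listing the
candidates rather than resolved silently.

## Diversity

θ = S/(a_n·L) with a_n = Σ_{i<n} 1/i, and π = mean pairwise Hamming
distance / L, with no small-sample correction — the plain pairwise mean is
what reproduces the published domestic values, and for a three-sample star
it makes π = θ an identity. L defaults to 2,390,000 bp, the single-copy
length of the assembly the defaults are tuned to; it is a free parameter
because the callable length, not the variant count, is the denominator.

## Dating

ρ is the multiplicity-weighted mean path length from tips to the dated
node; σ² = Σ_edges (tips through the edge)²·length / n² over the spanning
subtree; T = ρ/(μL)·g years with defaults μ = 1.68 × 10⁻⁸ (a horse Y
pedigree rate, borrowed for camels where no pedigree rate exists),
L = 2.39 Mbp and g = 6 years/generation. The dated node is specified by
id; for a two-haplogroup split both endpoints of the split edge are
reasonable choices and the pipeline reports both. ρ requires unique
geodesics; a reticulation on any tip path raises an error rather than
averaging over paths.

## Synthetic data

The generator emulates the study conditions end to end. Depth profiles:
Poisson per window with mean = autosomal depth × factor (males 0.5 × copy
number on Y windows, females a leak of 0.02 × autosomal, both 1.0
elsewhere); the default cohort has eight sequenced males (10–22×) and six
females, matching the sexed-cohort design the classifier needs. Windows
straddling segment boundaries take the majority class (ties to the
earlier segment) — deterministic under the fixed 50-bp tiling.

Haplotypes evolve under infinite sites on a known rooted tree; each edge
toggles a fresh block of sites. The bundled reference genealogy has three
domestic lineages of 13/14/15 mutations and one wild-sampled lineage of 12
on the domestic side, a 536-mutation inter-haplogroup edge, and wild
lineages of 0/2/4 mutations with a father-sharing sample pair on the
2-branch: 596 variants, eight samples, seven haplotypes. These lengths
were chosen so that the network totals, the domestic θ = π = 1.17 × 10⁻⁵,
and both wild θ values (1.37 × 10⁻⁶ and 1.11 × 10⁻⁴ over L = 2.39 Mbp)
are all mutually consistent; the wild basal node carrying a sampled
haplotype directly is an assumption, as the wild-clade internal topology
is otherwise underdetermined. Variant sites are placed uniformly at random
within scY segments of contigs that survive cleanup, mirroring calling
against a cleaned assembly.

What the generator does **not** model: mappability structure and repeat
mismapping beyond the flat female leak, depth autocorrelation along
contigs, base-calling error and genotype-likelihood noise (DP and GQ are
configurable dials, not error models), homoplasy, and indels or
multiallelic sites except as explicit test constructions. Passing recovery
tests therefore demonstrates correctness of the inference machinery under
the stated model, not robustness to every artifact of real short-read
data.

## Numerical and reproducibility choices

All randomness flows from one integer seed through named substreams
(crc32-keyed `SeedSequence` spawn keys), so fixture files are
byte-identical under a fixed seed and no stage's draws depend on another
stage's consumption order. Simulation sizes used by the test and
acceptance runs — ~4,500 classified windows, 100 oracle instances, 200
dating replicates of 8 tips at ~180 mutations per branch — keep the whole
suite under a minute while leaving Monte-Carlo error far inside the
asserted tolerances (the mean of 200 star replicates has a relative
standard error of ~0.2%). Degenerate inputs are errors, not silent
defaults: zero-depth samples, windows on unknown contigs, fully-missing
samples, ambiguous haplogroup cuts and ambiguous geodesics all raise with
context.

## Known limitations

* The classifier is per-window with no spatial smoothing; isolated
  boundary windows are the dominant error mode (and the reason an
  end-to-end run may lose a handful of true scY variants).
* The exhaustive network oracle scales exponentially and is capped; it is
  a test instrument, not an analysis path.
* Published wild-subset π values are not reproducible from branch lengths
  under any single (formula, L) combination and are treated as outside the
  package's reach; the wild θ values are reproduced.
* Dating inherits the borrowed mutation rate and the assumption that the
  dated node's subtree is clock-like; σ captures mutational noise only,
  not rate uncertainty.
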