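# Methods

`salhap` implements the computational chain used to map salmonid genomes
from fixed-length RAD loci: a meiosis simulator, construction of a
duplicate-aware reference locus database, genotype calling, two-point
linkage mapping, half-tetrad centromere analysis, and characterisation of
homeologous-arm divergence after whole genome duplication.  This note
documents the models, the defaults and why they were chosen, and what the
simulator does and does not emulate.

## The meiosis model

A tetrad is the four-chromatid bundle of one female meiosis.  Chromatids
0 and 1 are sisters carrying the haplotype-0 centromere; 2 and 3 carry
haplotype 1.  Crossovers are placed per arm, independently across arms and
meioses:

* **complete** interference — exactly one crossover per arm, uniformly
  positioned.  This is the salmonid-like regime of one obligate chiasma per
  arm; it makes the realized genetic length of every arm 50 cM regardless
  of its nominal coordinate span.
* **none** — a Poisson count with mean equal to the arm length in Morgans,
  positions uniform.
* **gamma(nu)** — a renewal process anchored at the centromere with
  Gamma(nu)-distributed inter-crossover distances of mean 1 Morgan; nu = 1
  reduces to the Poisson model.  This is a simple origin-anchored renewal,
  not a stationary one; it is provided to bracket intermediate interference
  regimes, not calibrated to data.

Each crossover exchanges the segments distal to its position between one
chromatid of each homolog, chosen uniformly among the four non-sister pairs
(**no chromatid interference**).  That assumption is what produces the
half-tetrad closed form

    y_k = (2/3) (1 - (-1/2)^k)

for the probability that a gynogenetic diploid is heterozygous at a locus
separated from its centromere by k crossovers: y_0 = 0, y_1 = 1, and
y_k -> 2/3 as k grows.  Hence the two diagnostic plateaus for the maximum
proportion of heterozygotes (MPH) at distal loci: 1.00 under complete
interference and 0.67 under none.  The package verifies the closed form
against exhaustive enumeration of chromatid choices for k <= 3.

One convention deserves emphasis: crossover counts are parameterised **per
tetrad** (mean = arm length in Morgans under the Poisson model).  Each
gamete receives a given crossover with probability 1/2, so the realized
per-gamete map length of an interval is half its tetrad-level expectation;
the Poisson-model recombination fraction between markers d cM apart is
(1 - e^(-d/100))/2.  Tests and distance checks use this realized scale.

Cross types: *haploid* offspring receive one random chromatid per tetrad
(eggs activated with genetically inactivated sperm); *gynogenetic diploids*
receive both meiosis-II products of one randomly chosen meiosis-I pole
(second polar body retention), making them homozygous at any locus not
separated from its centromere by an exchange; *diploids* receive one
chromatid from each parent.  Male meiosis uses the same crossover model —
pseudolinkage through homeologous pairing in males is not modelled, and only
female-informative markers are mapped.

## The locus model and what the simulator emulates

A locus is a 74-nt haplotype; alleles are substitution variants of a base
haplotype.  Unique loci carry one segregating SNP.  A duplicated locus is a
pair of paralogs on two homeologous arms whose haplotypes differ at 1-3 of
the 74 positions, so read clustering at the 3-mismatch radius collapses the
pair into a single observed locus.  The dam's genotype at the two paralogs
determines the composite segregation class (aa/bb, ab/ab, aa/ab, aa/bc,
ab/ac, ab/cd); the allele letters name shared haplotypes, so classes with a
shared allele model recently diverged paralogs whose "diverged" sites still
segregate.  Paralog pairs default to divergence 2: with depth-weighted
majority consensus every paralog haplotype then stays within the 3-mismatch
alignment radius of the merged cluster consensus.  At divergence 3 an
unlucky consensus tie-break can push one haplotype to 4 mismatches and its
reads drop out of alignment — real pipelines show the same edge behaviour
at their alignment limits, so it is left as is.

Read depths are negative binomial (default mean 40, dispersion 5 — typical
RAD coverage with moderate over-dispersion; variance = mean + mean²/5).
Reads split binomially between a heterozygote's alleles.  Sequencing error
re-assigns reads at `error_rate` (default 0.005 per read) to a designated
error haplotype one substitution from the locus consensus; making the error
a *third* allele keeps error-driven haploid "heterozygotes" distinguishable
from true duplicated loci, and an optional parental-allele error mode
stress-tests the duplicate-detection rule.  The simulator does not emulate
base-level qualities, barcodes, restriction-site dropout, allele-specific
amplification bias, missing-data structure correlated across loci, or
population structure in the database panel — passing tests demonstrate the
analysis chain is correct under its stated genetic model, not that it is
robust to every artefact of real libraries.

## Reference database construction

Fixed order: cluster -> coverage -> self-alignment -> low-complexity ->
duplicate identification.

1. **Clustering**: distinct read sequences, pooled over individuals, are
   visited in decreasing-depth order; a sequence joins the single cluster
   whose consensus is within 3 mismatches, seeds a new cluster if none is,
   and is flagged ambiguous if several are.  Consensus = depth-weighted
   majority base per position, ties broken in ACGT order (deterministic).
2. **Coverage**: retain loci with depth > 5 in more than 85% of panel
   individuals (both inequalities strict, as stated).
3. **Self-alignment screen**: a locus matching more than one retained locus
   (itself included) within 3 mismatches is a likely repeat; all members of
   the matching set are excluded.  Symmetric by construction.
4. **Low-complexity screen**: a DUST-style triplet statistic
   (sum c(c-1)/2 over the 72 overlapping triplets, normalised by 71)
   replaces an alignment-based low-complexity filter.  The threshold 1.0
   was calibrated on uniform-random 74-mers (mean 0.56, 99th percentile
   0.89), masking well under 1% of random sequences while dinucleotide
   repeats score ~18 and mononucleotide runs 36.
5. **Duplicate identification**: a locus heterozygous in at least two
   haploid offspring within one family is duplicated; a single heterozygote
   is attributed to sequencing error.  Evidence is deliberately not
   weighted by family size.

## Genotyping

Reads are assigned to the unique database locus within 3 mismatches;
multi-locus matches are dropped.  Calls: total depth < 10 is missing; a
heterozygote requires two *verified* alleles with depth > 2 and total
depth >= 10; otherwise the majority allele is called homozygous.  An
allele is verified when a one-sided binomial test rejects a sequencing-error
origin (assumed per-read error 0.01, alpha 0.01) — a conservative
implementation of allele verification around the stated depth rules.
Three or more verified alleles indicate collapse beyond the two-paralog
model and the call is set missing.  At total depth >= 10 with a minor
allele at depth <= 2 the call is homozygous (the low-depth allele is
unverified by definition).

Composite genotypes of duplicated loci are classified by gamete
enumeration; classes with one polymorphic paralog (OPP) map one paralog,
classes with both polymorphic and distinct allele pairs (BPP) map both, and
ab x ab is unmappable because heterozygous offspring are uninformative.
The dam's paralog genotypes are reconstructed from the observed composite
genotype set (genotypes seen in >= 2 offspring), which identifies the class
up to the paralog labelling — and the labelling is resolved by the map
itself.  A chi-square goodness-of-fit against the class expectation is
provided; observations in classes with zero expectation fail outright.

## Linkage mapping

Two-point analysis on haploid calls: rf = R/n over jointly scored
offspring and LOD = R log10(2 rf) + (n - R) log10(2(1 - rf)).  Haploid
allele coding is arbitrary, so the folded estimate min(R, n-R)/n is used
for grouping and ordering, while the phase-dependent raw fraction is also
reported.  Pairs with fewer than 10 joint observations never link.

Grouping is single-linkage transitive closure over pairs with rf <= 0.25
and LOD >= a threshold escalated from 3.0 in steps of 1.0 until the group
count reaches the chromosome number — with a small number of markers and
46-72 offspring the starting threshold often leaves chance linkage between
chromosomes, and the escalation protocol is what removes it.  The tiny test
fixture (20 offspring) uses a LOD-2 start suited to its lower information
content.

Ordering minimises the total adjacent recombinant count: co-segregating
markers are binned (representative = smallest marker id); up to 8 bins are
ordered exhaustively (provably optimal), larger groups by nearest-neighbour
construction refined with 2-opt.  Adjacent distances use the Kosambi map
function by default (Haldane and Morgan selectable); under the
dense-marker, complete-interference regime all three approach 100 rf and
per-arm map length converges to the realized 50 cM.  Distances are summed
two-point estimates; no multipoint re-estimation is attempted.

Family maps merge through a directed precedence graph: each family
contributes all ordered pairs of its markers (after orientation alignment
by rank concordance on shared markers), majority direction wins, tied
conflicts drop the less-supported marker into a conflict report, and any
remaining cycles are broken the same way.  Consensus positions are family
positions rescaled to the mean group length, averaged, and made monotone
along the topological order.  This replaces linear-programming consensus
tools with a simpler deterministic merge adequate at this scale.

Groups are anchored to chromosomes by majority vote over anchor markers
(emulating previously mapped markers with known chromosome, arm and
position); orientation uses rank concordance with anchor positions when
available, else mean p- vs q-anchor position.

## Centromere analysis

The heterozygote fraction y of gynogenetic diploids is profiled per mapped
locus (duplicated loci are excluded — they cannot be reliably genotyped in
gynogenetic diploids).  The centromere interval of a group is the longest
run of consecutive loci with y <= 2/n (tolerating one miscalled offspring;
the "about zero" rule is our convention).  A group is metacentric when
loci above the floor flank the interval on both sides, acrocentric when on
one side; a flat profile is unresolved.  Gene-centromere distance is
y/2 x 100 cM, exact under complete interference and biased distally under
weaker interference (documented, not corrected).  MPH is the maximum y per
arm, with arms assigned by side of the centromere interval; arms whose
distal regions carry only duplicated (excluded) loci show depressed MPH as
a coverage artefact, which the tests reproduce.  Crossovers per progeny per
arm are counted as maternal-phase switches along the ordered markers,
phased greedily marker-to-marker (switch counts are invariant to the global
phase flip).

## Duplication analysis

The proportion of duplicated markers along each group is smoothed with a
Gaussian kernel (bandwidth 2 cM, grid step 0.5 cM) because mapped positions
are not uniform.  Homeologies are inferred from BPP loci — the only class
where both paralogs map — by tallying unordered arm pairs; same-arm pairs
are anomalous and reported separately, and a support threshold (default 1)
is exposed.  Cross-database alignment keeps a locus pair only when each
locus matches exactly one locus of the other database within 3 mismatches
(reciprocal uniqueness, the strict reading of "aligned uniquely").

## Pipeline and reproducibility

`salhap run` executes simulate -> build-refdb -> genotype -> map ->
centromere -> duplication from one YAML config, recording each stage's
outputs in a manifest (with a config digest) before the next stage starts.
One global seed fans out to fixed per-stage child seeds, so identical
config + seed reproduce byte-identical tables and stages can be rerun
independently.  Two ready-made configurations exist: `tiny` (two
chromosomes, 40 loci, 20-offspring families — seconds, used by the test
suite) and `demo` (the full 34-chromosome karyotype with three haploid
families of 46/48/72, three gynogenetic families of 84/90/93, a
44-offspring diploid cross and a 159-individual database panel — a few
minutes).

Problem sizes used by `scripts/acceptance.py`: the half-tetrad plateaus use
10,000 gynogenetic offspring with the distal marker 500 cM from the
centromere, far enough that the Poisson-model heterozygote fraction
(2/3)(1 - e^(-1.5 lambda)) is within 0.001 of its 2/3 asymptote; the
karyotype-recovery run uses one 46-offspring haploid family with 21 evenly
spaced markers per chromosome, a density at which single-linkage chains
bridge the centromere and survive the LOD escalation.  The segregation
ratios are analytic (gamete enumeration) and involve no sampling.

## Known limitations

* Complete interference is modelled as exactly one crossover per arm;
  real salmonid arms show rare double crossovers that this regime cannot
  produce (the gamma model can).
* Crossover positions along an arm are uniform; the empirical positional
  distribution is unknown and unmodelled, so marker spacing in map units
  is uniform in expectation rather than telomere-compressed.
* The y/2 distance estimator and the "metacentric vs acrocentric" call
  depend on marker coverage around the centromere; sparse maps widen the
  interval and can misclassify a poorly covered metacentric.
* The greedy clustering does not reassign sequences after consensus
  updates, and paralog pairs at divergence 3 can lose one haplotype from
  alignment (see above).
* Map lengths are two-point sums; genotyping error inflates them exactly
  as it does in practice.
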