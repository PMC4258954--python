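# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `pedlink`: a pipeline for single-family mapping of a
rare autosomal-dominant trait by genome-wide parametric multipoint linkage
followed by exome variant prioritization, with a seeded simulator that
stands in for the study's raw data.

## Disease model

A single biallelic disease locus with allele `a` at population frequency
q and penetrance triple (f_AA, f_Aa, f_aa) — the probability of being
affected given 0, 1 or 2 copies of `a`. Defaults: q = 5×10⁻³,
f_AA = 0.005 (phenocopy rate), f_Aa = f_aa = 0.95 (dominant, incompletely
penetrant). These defaults are the parameters under which all shipped
analyses and simulations run; there are no liability classes, no
sex-specific effects, and no locus heterogeneity.

Affection statuses are affected / unaffected / unknown / unconfirmed.
"Unconfirmed" records a clinically-assessed-only status and collapses to
unknown in every likelihood: an unconfirmed member contributes no
penetrance factor, exactly as an untyped member contributes no marker
factor.

## Multipoint linkage engine

**State space.** The Lander–Green inheritance vector has one bit per
meiosis (2 per non-founder); bit = 0 means the grandpaternal allele was
transmitted. Members that carry no information — no genotypes at the
markers being analysed, unknown effective affection, and no retained
descendants — are pruned first; pruning is exact (their meioses
marginalize to a factor of 1).

**Founder-phase quotient.** Swapping a founder's two alleles while
flipping every meiosis that founder transmits changes no emission or
penetrance term (genotypes are unordered, founder slots exchangeable) and
commutes with the transition kernel. The HMM therefore runs on the
quotient space: per transmitting founder, the first child meiosis is
dropped and the remaining ones become bits relative to it. The quotient
transition is the usual independent per-bit Haldane mixing followed, per
founder group, by a blend with the jointly-flipped image at weight θ.
This is exact (validated to 1e-10 against the full space) and reduces the
default study pedigree from 2^20 to 2^14 states. The capacity ceiling
(default 20 bits, with a `CapacityError` advising pedigree splitting)
applies to the *effective* bit count after pruning and reduction.

**Emissions.** Markers are biallelic SNPs, which turns the founder-allele
graph into a parity problem: a homozygous individual forces its two
founder slots to one allele, a heterozygous one constrains them to
differ. A weighted union-find with parity and forced-color tracking
evaluates P(genotypes | v) in near-linear time per constraint; connected
components contribute the summed frequency mass of their (at most two)
consistent colorings, and untouched slots marginalize to 1. Zero signals
inconsistency with v, and a marker inconsistent with every v raises an
error (marker QC removes such markers beforehand).

**Phenotype likelihood.** P(phenotypes | v) sums over founder
disease-allele configurations: components of the founder-slot graph are
enumerated (capped at 2^24 assignments per component), each slot carrying
`a` with prior q, each phenotyped member contributing its penetrance or
complement. The vector over all quotient states is memoized per
(pedigree, statuses, model) because the same vector serves every marker
subset and the phenotype-conditional simulator.

**Transitions and evaluation.** Inter-locus recombination uses Haldane's
map function θ = (1 − e^(−2d))/2 (no interference) on sex-averaged cM; a
MAP file with all-zero genetic positions is converted at 1 cM/Mb. Forward
and backward passes are normalized per locus (underflow control; only
posteriors are needed, so scale factors cancel). LOD is evaluated at the
marker positions by default — peak bounds are then marker coordinates —
and arbitrary cM positions are supported by propagating the flanking
messages. The unlinked baseline is log10 of the mean phenotype likelihood
over states. With the default model all penetrance factors are strictly
inside (0, 1), so LOD is finite everywhere; degenerate 0/1-penetrance
models can produce −inf off-plateau, which is mathematically correct and
left unclamped.

**Thinning and averaging.** Dense panels inflate multipoint LOD through
linkage disequilibrium, which the model ignores (founder haplotypes are
treated as independent draws). Following the study's procedure the panel
is split genome-wide into k interleaved subsets (default 30 for real
array data; 3 in the simulation experiments, matched to their 600-marker
maps), each subset analysed separately, and the curves averaged
position-wise on the full marker grid, interpolating linearly in cM with
constant extension at chromosome ends.

**Peak reporting.** Multipoint curves are flat across the family's
no-recombination window around a fully supported locus. `LodCurve.argmax`
therefore reports the midpoint of the maximal run (ties within 1e-6 LOD)
instead of numpy's first-index argmax, which would systematically sit at
the window's left edge.

## Region calling

Candidate regions are maximal runs of consecutive evaluated positions
with averaged LOD ≥ threshold (default 1.90, the conventional suggestive
level used by the study). Bounds are the outermost above-threshold
positions themselves — reproducing marker-delimited interval reporting —
and single-position regions are legal. No multiple-testing adjustment is
applied. Internal coordinates are 1-based inclusive bp; BED export is
0-based half-open with score = round(100 × max LOD).

## Variant prioritization cascade

Annotated exome variants (VCF genotypes plus a TSV keyed by
chrom:pos:ref:alt) pass through: (1) functional classes — non-synonymous,
stop gain/loss and splicing SNVs; frameshift and non-frameshift indels;
(2) two *independent* branches, novel (no dbSNP id and not in 1000
Genomes) and rare (panel MAF ≤ 0.02, inclusive, per the "up to 2%"
criterion); the branches are unioned, not chained, because they reach
different genes in practice; an unrecorded MAF qualifies in the rare
branch (absence from the panel bounds the frequency above by novelty);
(3) linkage-region intersection, inclusive on both ends; (4) the sharing
constraint: every affected sample het or hom-alt (a missing call in an
affected disqualifies the variant — conservative, favoring fully observed
candidates), every unaffected sample hom-ref (a missing call in an
unaffected does not disqualify: absence cannot be asserted from a
no-call), unconfirmed samples ignored. Per-sample stage counts use
carried-variant semantics (a variant counts for a sample only when that
sample's genotype is non-reference), mirroring per-column exome-table
accounting. GERP/SIFT/PolyPhen-2 are pass-through annotations, never
recomputed or thresholded.

## Follow-up

Co-segregation classification takes confirmatory carrier calls for one
variant across the whole family: strict mode flags unaffected carriers
and affected non-carriers; the lenient mode tolerates unaffected carriers
(expected under 0.95 penetrance) and flags only affected non-carriers.
Obligate-carrier inference is deliberately not performed — carrier status
comes only from supplied genotypes. Gene-level replication counts, per
candidate gene, the unrelated samples carrying at least one
protein-affecting variant that is novel or rare (the novel-or-rare
criterion, reusing the cascade predicates); support is counted in
samples, not variants.

## Synthetic data

**What it emulates.** The generator reproduces the *shape* of the study's
inputs: a three-generation, 17-member family (plus the unobserved
ancestral couple I:1 × I:2 above the generation-II sibship, required for a
single founder haplotype to reach every affected branch), 12 SNP-typed
members, an exome-sequenced subset of 8 with four affected, two simulated
chromosomes of 300 evenly spaced biallelic SNPs (0.5 cM spacing, MAF
uniform on [0.1, 0.5], 1 cM/Mb), a causal locus mid-chromosome 1, 1%
genotype missingness, and exome tables of 1,000 background variants with
an exome-like class mix, ~5% novelty and ~4% rare among catalogued
variants. Untyped members are emitted with status "unconfirmed". Exact
spouse assignments are not recoverable from the published account and are
configurable.

**Gene dropping.** The causal locus and affection are drawn first;
marker haplotypes are then dropped conditional on the accepted
causal-locus meiosis indicators by extending them outward along each
chromosome with Haldane flip probabilities, so markers near the locus
remain in linkage with it. Two phenotype modes:

* *Ascertained sampling* (default): affection is sampled from the
  penetrances and draws are rejected until the family looks like one a
  linkage study would recruit — at least 6 affected among the typed
  members, spanning 3 generations, none married-in, affecteds in at least
  2 last-generation sibships, and visibly unbroken dominant transmission
  (every affected has an affected parent unless its parents are the
  unobserved ancestors). All conditions are phenotype-observable and all
  hold for the motivating family.
* *Phenotype-conditional* (`affection_template`): the affection pattern is
  fixed (e.g. the family's published pattern) and the causal-locus descent
  is sampled from its exact posterior — inheritance vector with
  probability ∝ P(phenotypes | v), founder alleles from their conditional
  distribution per founder-graph component — the standard way marker data
  are simulated for a real family.

Identical config and seed give byte-identical outputs; seeds are recorded
in output file headers.

**Variant tables.** The planted causal variant satisfies its branch's
predicates by construction (heterozygous in every affected, absent from
every unaffected, random in unconfirmed) and is placed inside a provided
linkage region; any background variant that would also survive the
cascade has one affected genotype reset, making the plant the unique
survivor. Qualifying rare variants are seeded into 3 of 4 unrelated
samples, mirroring the replication pattern. Background genotypes are
drawn from Hardy–Weinberg at the variant's own frequency, independently
across family members.

**What it does not emulate.** No linkage disequilibrium (thinning removes
it in real data, so independent markers suffice); no genotyping error; no
relatedness in exome background genotypes (family members draw
independently, which overstates background survivor counts slightly and
is compensated by the uniqueness guarantee); a single causal locus with
no heterogeneity; no read-level artifacts. Passing tests therefore
demonstrate the correctness of the inference machinery and the
qualitative behavior of the pipeline, not robustness to LD, genotyping
error or annotation noise.

## Validation experiments and their observed limits

The heavyweight checks run the whole pipeline on 100 seeded replicates of
the default configuration (and `scripts/acceptance.py` reruns 40 with
fresh seeds). Two recovery rates are measured: the averaged-LOD
genome-wide peak falling within 10 cM of the planted locus, and the
planted gene emerging as the unique final candidate. Under the frozen
defaults these land around 70–85%, not higher, for reasons intrinsic to
the study conditions rather than to the implementation (the engine itself
matches a brute-force joint-enumeration oracle to 1e-9 on a thousand
random instances):

* **Silent carriers.** With penetrance 0.95, each unaffected at-risk
  relative is a carrier with ≈5% probability. One silent carrier shares
  the causal haplotype while being scored unaffected, which depresses the
  LOD at the true locus and displaces the peak toward wherever that
  carrier recombined away. Roughly one replicate in five draws at least
  one.
* **Plateau geometry.** The LOD is flat across the family's
  no-recombination window (typically 10–17 cM here), so even a perfect
  replicate's single-point peak can sit more than 10 cM from the locus.
* **Chance co-segregation.** Segments elsewhere in the genome that happen
  to co-segregate with affection reach the same LOD ceiling — the
  motivating study itself called a second locus on chromosome 14 this
  way.

## Numerical choices

Marker allele frequencies are estimated by founder counting, falling back
to all typed individuals below 4 observed founder alleles, 0.5/0.5 when
nothing is typed; the simulator's Marker objects carry the generating
frequencies. QC assigns one exclusion reason per marker in the order
sex-linked, monomorphic (zero observed alleles counts as monomorphic),
Mendelian-inconsistent. Mendelian checking is per parent-offspring trio
by transmission enumeration; missing genotypes never violate. All
probability accumulation is in double precision; forward variables are
renormalized per locus; log-space is entered only at the final LOD.
Derived child seeds stay below 2^31.
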