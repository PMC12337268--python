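# Methods

`pavcoex` analyzes dual host–symbiont RNA-seq from legume root nodules to
link rhizobial gene content (presence–absence variation, PAV), coexpression
structure, and symbiotic partner quality (strain-mean host shoot biomass).
Because the analysis is validated on synthetic data with planted ground
truth, this note describes both the generator's model and the numerical
choices of every analysis stage.

## The synthetic study

The generator emulates a common-garden design: one host genotype inoculated
with each of *n* = 20 rhizobial strains, 4 nodule RNA-seq replicates per
strain, ~6,000 symbiont genes distributed over a multipartite genome
(chromosome, megaplasmids pSymA and pSymB, plus a small accessory plasmid
carried by 8 of 20 strains) and ~5,200 host genes.

**Gene frequency classes.** Each background gene group draws a class from a
per-replicon multinomial — core / shell / cloud with default probabilities
(0.561, 0.329, 0.110) on the chromosome, (0.199, 0.601, 0.200) on pSymA and
(0.679, 0.241, 0.080) on pSymB; the core values reproduce the study system's
per-replicon pangenome partition, the shell/cloud split of the remainder is a
package choice. Core genes are present in all strains; shell genes draw a
carrier frequency *f* ~ U(0.15, 0.95) and cloud genes *f* ~ U(1/n, 0.15);
carriers are a uniformly random subset of size round(*f·n*) (at least 1), so
realized class fractions match the profile up to multinomial noise.

**The latent quality axis.** A standardized strain score *Q* ties the planted
signal together: trait-linked clusters are carried by the top (positive
effect) or bottom (negative effect) round(*f·n*) strains by *Q*, and a
trait-coupled module's strain factor is
*f_m* = λ*Q* + √(1−λ²)·η, η ~ N(0,1), with λ = `quality_cor` (default 0.95
for the coupled modules). This is deliberate: at *n* = 20 strains,
independent cluster and module contributions to biomass cannot jointly
produce gene-trait |r| > 0.5, module-trait |r| > 0.6 and cross-kingdom
|r| > 0.7 — the implied R² terms would sum past 1 — whereas real systems
show exactly this coupling (trait-linked clusters sit inside
biomass-correlated modules). The default plant includes a 4-gene
positive-effect cluster and a 10-gene negative-effect cluster on pSymA
(complementary carrier sets, echoing clusters found in high- vs low-quality
strains), two neutral clusters, six symbiont modules (600…60 genes, one
trait-coupled) and five host modules (800…120 genes, one trait-coupled).
Module members are drawn from genes present in every strain: modules model
regulatory programs over the common genome, while accessory genes'
expression variance is dominated by their own presence/absence — the signal
the PAV branch models, which would otherwise corrupt within-module
correlation by construction.

**Counts.** count ~ NegativeBinomial with mean
lib·10⁻⁶·μ_g·exp(loading_g·f_m(g),s)·presence and shape (size) parameter
`nb_dispersion` = 15. Baseline expression log₂ μ_g ~ N(7, 1.2) CPM (cluster
members floored at 40 CPM so planted clusters are clearly expressed when
present, as observed for real PAV clusters); per-gene loadings are the module
loading (0.3) scaled by U(0.7, 1.3); library sizes U(2, 5)·10⁶. A
contamination rate δ (CPM leaked into truly absent genes, default 0) is
available to stress the absence caller. Truly absent genes therefore have
hard-zero counts at the default.

**Phenotype.** With U_s = Σ_c effect_c·presence_cs + Σ_m γ_m·f_ms (effects in
units of the among-strain biomass SD, γ = `trait_coupling`), biomass is
μ₀·(1 + CV·(√(1−v)·Ũ_s + √v·ε_s)) where Ũ is U standardized across strains,
ε ~ N(0,1), v = `resid_frac` = 0.15, μ₀ = 0.26 g and CV target 0.60 (these
reproduce the study's σ² = 0.024 and CV = 0.60; if the planted predictor is
degenerate, v is set to 1 so the CV target still holds). Values below
0.05·μ₀ are clipped with a warning. Replicate-level biomass adds N(0,
(0.5·CV·μ₀)²) noise over 10 replicates; five companion traits (root biomass,
chlorophyll, leaf number, height, nodule number) are correlated copies of
the biomass z-score (nodule number negatively).

**Assemblies.** Each gene gets an i.i.d. random nucleotide reference sequence
with length ~ LogNormal(log 900, 0.3) bp. A strain's replicon concatenates
the reference spacers with the genes truly present, each copy mutated by
per-site substitutions at `substitution_rate` = 0.005 and reverse-complement
inserted with probability 0.3; absent genes leave no copy. Spacer layout:
U(50, 500) bp inside planted clusters, U(4000, 8000) bp flanking them, and
U(3050, 4500) bp around shell genes — every gap adjacent to a *potential
candidate* gene strictly exceeds the 3-kb chaining rule, so background genes
cannot form spurious clusters, while core/cloud neighbors use realistic
U(50, 400) bp spacing (core genes are never on/off and cloud genes fail the
≥3-strain filter, so they can never enter the candidate set). The resulting
~18 Mb genomes are larger than the real organism but keep generation and
search desk-tractable.

**Determinism and consistency.** All randomness flows from one
`numpy.random.default_rng(seed)`; identical parameters + seed give
byte-identical outputs. Every generated dataset asserts that expression
truth, sequence truth and recorded ground truth agree.

## Analysis stages

**Presence calling.** Per strain, the CPM cutoff equals `cpm_floor` (10)
counts at the median library size of that strain's replicates
(filterByExpr-style); a gene is absent when its CPM is below the cutoff in at
least ceil(0.75·n_reps) replicates ("three out of four"). On/off genes are
those present in 3 … n−3 strains.

**Gene–trait association.** Point-biserial (Pearson on the 0/1 indicator)
correlation with strain-mean biomass; p from t = r√(n−2)/√(1−r²), df = n−2,
two-sided; Benjamini–Hochberg FDR over all tested on/off genes (constant
genes are flagged and excluded); significance at |r| > 0.5 and fdr < 0.15. A
config switch substitutes strain-mean logCPM for the binary indicator.

**Sequence confirmation.** Nucleotide containment of the candidate gene in
each strain assembly. Exact 31-mer seeds taken at 6 evenly spaced query
offsets (both strands) locate candidate windows; the query is aligned to the
padded window by exact bit-parallel edit-distance alignment (edlib, infix
mode). identity = matching columns / alignment columns; coverage = query
bases aligned to a target base / query length; present iff identity ≥ 0.98
and coverage ≥ 0.98. The scan stops at the first accepting hit; if *no* seed
hits anywhere, a denser rescan (k = 15, 24 offsets) runs before the gene is
called absent, which keeps copies up to ~10% diverged alignable while truly
absent genes cost one bounded extra pass. Ambiguous IUPAC bases count as
mismatches. Genes are confirmed only with 100% per-strain agreement between
expression and sequence calls.

**Syntenic clustering.** Candidates are sorted by start within each replicon
and chained while the inter-feature gap (next.start − current.end − 1,
strand ignored) is ≤ 3000 bp inclusive; chains of ≥ 2 genes are clusters.
Cluster presence per strain requires all members by default (fraction rule
configurable); cluster–trait tests are two-sided pooled-variance Student's t
on strain-mean biomass between carrier groups (Welch optional; groups < 2
flagged undefined).

**Pangenome partition.** f = carriers / n_strains; core iff f > 0.99, cloud
iff f < 0.15, shell otherwise — the (0.95, 0.99] bin the printed thresholds
leave undefined is assigned shell, the conservative choice that avoids
inflating core.

**Coexpression networks.** Built per organism on strain means of logCPM
(log₂((count+0.5)/(lib+1)·10⁶), averaged over replicates; log first, then
average), after dropping genes with median raw count < 10; the host network
uses its 5,000 most variable genes. Unsigned adjacency |cor|^β with β chosen
from the grid 4–10 as the smallest power whose scale-free fit R² (log–log
regression of binned connectivity frequency, 10 bins) reaches 0.8, skipping
powers with mean connectivity > 100 (the standard guidance that very dense
networks defeat soft thresholding), falling back to the argmax R². TOM_ij =
(l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij). Modules: average-linkage clustering
of 1 − TOM cut at the fixed height 0.85 (module cores of ≥ 10 genes), then a
kME rescue that assigns each leftover gene to the core whose eigengene it
correlates with at |r| ≥ 0.7, then iterative merging of modules whose
eigengenes correlate above 0.75. A quantile-of-merge-heights cut was tried
first and discarded: with thousands of unstructured genes the height
distribution is dominated by the background band, so any high quantile cuts
above background coalescence and absorbs every module into one cluster. The
static-height-plus-kME scheme is the deterministic analog of common WGCNA
practice (cutreeStatic + assignment by kME) and recovers planted modules
with ARI 0.79–0.97 at within-module correlations ~0.8. Eigengenes are the
first left singular vector of the z-scored module matrix (unit norm over
strains, oriented to correlate positively with members on average); module
counts at this scale (5–7) are a consequence of the planted structure, not a
target.

**Associations and report.** Module–trait: Pearson r with the t-transform,
flagged at |r| > 0.6 and raw P < 0.05 (BH across modules available but off
by default — the convention is raw P with an |r| cut). Cross-kingdom edges:
all host × symbiont eigengene pairs, |r| > 0.7, with a hard error on strain
order mismatch. Phenotype summary: CV of strain means, one-way ANOVA over
replicate-level biomass, among-strain variance component by the method of
moments ((MS_strain − MS_error)/n̄_reps, floored at 0 — closed-form and
hand-checkable, unlike REML). Enrichment: hypergeometric upper tail per
(module, category) with BH FDR; the universe is the set of genes that
entered the network; in the simulated analyses the categories are replicons.

## What the generator does not emulate

Strain relatedness (presence patterns are exchangeable; no phylogeny and no
tree-incongruence signal), read-level artifacts (alignment, rRNA, GC bias —
counts are drawn directly), host–symbiont cross-mapping (host and symbiont
counts are independent given the strain factors), copy-number variation
(genes are single-copy), structural rearrangement, and real regulatory
network topology (modules are disjoint blocks driven by single factors).
Passing the recovery tests therefore demonstrates that the statistical
machinery is correct and well calibrated at the study's design size — not
that it would be robust to mapping artifacts or confounded designs.

## Problem sizes

Tests run the full default simulation once (20 strains × 4 replicates,
6,060 symbiont and 5,200 host genes, 20 assemblies) plus down-scaled
variants (~400 genes) for per-operation checks; seed-averaged calibrations
use 10 seeds (pangenome fractions, biomass CV) or 50 seeds (module–trait
flagging, via eigengenes of the planted memberships). The acceptance script
averages 10 seeds derived from `--seed`.

## Known limitations

The static cut height (0.85 on the 1 − TOM scale) is appropriate for the β
range 4–10; strongly different β or signed networks may need a different
height. The seed-and-extend aligner targets high-identity containment
(≥ ~90%); it is not a general homology search. The on/off trait correlation
treats strains as independent; with related strains the point-biserial
p-values would be anticonservative.
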