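# Methods

## The conservation statistic

**Expression distance.** For two whole-embryo transcriptome vectors $x, y$
over the same ordered set of ortholog groups, the dissimilarity is

$$\mathrm{expdist}(x, y) = 1 - \rho_s(x, y),$$

where $\rho_s$ is the Spearman correlation computed as Pearson on average
ranks (ties averaged).  The value lies in $[0, 2]$; a constant vector makes
the correlation undefined and raises an error rather than returning 0.
Because the statistic is rank-based, no expression prefilter or log
transform is applied — both would leave it unchanged.

**Stage combinations on the tree.** A stage combination assigns one
developmental stage to every species of the taxon set under analysis.  The
rooted binary species tree is traversed post-order; at each internal node
the expdist between the two child expression profiles is accumulated and
the node then exposes the arithmetic mean of the child profiles (on TPM
scale) to its parent.  The combination's score is the sum over internal
nodes.  This progressive-averaging rule avoids the double-counting bias of
all-pairs comparisons between unevenly related species, and reduces exactly
to the pairwise expdist for two species.  Branch lengths are parsed but not
used by the scorer (topology only).  A combination whose profile is
constant at any node is excluded and logged, never scored as 0.

**Ptop.** All $\prod_i S_i$ combinations are scored exhaustively
(enumerated in lexicographic stage-index order over the tree's leaf order;
a cap of $10^7$ combinations guards against accidental blow-ups).  With
$N$ valid combinations and top fraction $q$ (default 0.01), the top set is
the $n_{top} = \max(1, \mathrm{round}(qN))$ smallest scores, distance ties
broken by enumeration order so results are exactly reproducible.  For each
species and stage,

$$P_{top}(\text{sp}, s) = 100 \cdot \frac{\#\{\text{top combinations containing } s\}}{n_{top}}.$$

Since every combination contributes exactly one stage per species, Ptop
sums to 100 within each species — a conservation law asserted in the tests.

**BRI resampling.** Each of $B$ (default 100) "biological replicate
included" tables picks one replicate uniformly at random per
(species, stage), independently across stages, species and tables (the same
replicate may recur).  Ptop is computed independently inside each BRI table;
the mean and sample SD (ddof = 1) over the $B$ tables are reported, and the
$B \times \text{stages}$ matrix is retained.

**Friedman test.** Per species, blocks = BRI tables and treatments =
stages:

$$\chi^2_F = \frac{12}{Bk(k+1)} \sum_j R_j^2 - 3B(k+1),$$

divided by the standard tie-correction factor
$1 - \sum (t^3 - t) / (Bk(k^2-1))$, with $k-1$ degrees of freedom.  The
implementation is checked against `scipy.stats.friedmanchisquare` in the
tests.  If every block is entirely tied the statistic is reported as 0 with
a warning.

### What the Friedman-over-BRI design does and does not test

BRI tables resample *replicates only*: every block shares the single
realized pattern of evolutionary divergence in the dataset.  The test
therefore asks whether Ptop differences among stages are robust to
replicate choice — not whether they exceed what a stage-exchangeable
data-generating process would produce.  On synthetic data with a flat
divergence profile, each dataset still carries chance stage asymmetries
(one realization of the per-group divergence curves), and with $B = 100$
high-precision blocks the test detects them essentially always.  The
package's null-calibration experiment documents this: the rejection rate
under a flat profile is far above the nominal 5%, which is a property of
the statistic's design, not an implementation artifact.  Interpreting a
significant Friedman p-value as "stage effects beyond replicate noise" is
correct; interpreting it as evidence against a stage-exchangeable null is
not.

## Synthetic expression data

Each ortholog group receives a smooth ancestral log-expression trajectory
on a 100-point pseudo-time grid: a group-level baseline
$\sim \mathcal{N}(1, 1.5^2)$ plus a cubic spline through 10 standard
Gaussian knots.  Along every tree branch the trajectory is perturbed by an
independent smooth Gaussian curve (same spline construction) scaled
pointwise by $\sigma(t) \times \ell$, where $\sigma$ is the divergence
profile and $\ell$ the branch length.  Species stage $i$ of $S$ maps to
pseudo-time $i/(S-1)$ (simple alignment of heterochronic stage grids);
replicates multiply by lognormal noise with log-sd `noise_sd`; each
stage:replicate column is rescaled to a total of $10^6$ (TPM semantics);
optional dropout removes a group from a species entirely (never a blank
cell).

Defaults are fixed at study-like conditions: tree `(Anj,(Apj,(Sp,Lv)))`
with unit branch lengths; 15/14/17/16 stages for Anj/Apj/Sp/Lv; 2
replicates; 2000 groups; `noise_sd` 0.25; dropout 0.05.  The hourglass
profile is $\sigma(f) = 0.1 + 0.9\,(2f-1)^2$ (strong divergence at the
extremes, minimum at mid-development); the flat profile is
$\sigma \equiv 0.5$.  The **designated conserved window** of a species is
the set of stages whose $\sigma$ at the stage fraction lies within 25% of
the profile's range above its minimum — for 10 stages under the hourglass
profile, the four mid stages (fractions 1/3 to 2/3); for a flat profile,
all stages.

One root seed drives everything; per-generator streams are derived as
`default_rng([seed, component])` so each generator is reproducible in
isolation.

What the generator does *not* emulate: read-level quantification noise,
paralog expression divergence, alternative splicing, mean–variance
relationships of count data, or batch effects.  Passing recovery tests
therefore show that the statistic behaves as designed when its model
assumptions hold, not that real RNA-seq pipelines upstream are validated.

## Synthetic proteomes, reads, and the companion analyses

**Proteomes.** Random 150–450 aa sequences per group are mutated along the
tree at `mutation_rate` substitutions/site per unit branch length.
All-vs-all hit tables in the standard 12-column layout are emitted with
bitscore $= 2 \cdot \text{identity} \cdot \text{length}$ and e-value
$10^{-\text{bitscore}/4}$ so that within-group hits dominate; ~10% of genes
also receive a low-identity cross-group background hit, and decoy paralogs
(extra-mutated copies) exercise the best-hit tie-breaking.  RBBH keeps, per
query, the max-bitscore hit among those with e-value $\le 10^{-5}$ (ties:
min e-value, then smallest subject id; multiple HSPs collapsed to the best
row), intersects the two directions, and anchors 1:1 sets on a reference
species, emitting a set only when the reference gene has a partner in
every species.

**Relative rates.** The count-based Tajima form at the residue level:
sites containing gaps/ambiguity in any of the three sequences are skipped;
$m_A$ counts sites where only lineage A differs from the outgroup, $m_B$
likewise for B; $\chi^2 = (m_A - m_B)^2/(m_A + m_B)$ with df = 1, no
continuity or multiple-hit correction.  With $m_A + m_B = 0$ the test is
flagged undefined rather than given a p-value.

**Loss screen.** Presence of an anchor gene in a species requires a hit
with identity strictly above 50% and alignment ratio (aligned
columns/query length) strictly above 30%; a gene is called lost when
present in at least one comparison-clade species and absent in every
ingroup species.  The alignment-ratio denominator is the query (anchor)
length — the convention for detecting partial homology of the anchor.

**Genome size.** Canonical k-mers (default k = 17) are counted in memory
with a vectorized 2-bit encoding (intended scale: tens of Mb of read data).
The valley is the first depth at which the histogram stops falling; the
coverage peak is the argmax beyond it (ties to the smaller depth).  The
error mass at or below the valley is excluded before applying
size = k-mer number / peak depth — without that exclusion the estimate is
biased upward by error k-mers on noisy data.

## Problem sizes in tests and the acceptance script

The hourglass-recovery experiment uses 20 datasets of 1000 groups, 10
stages/species, 2 replicates, B = 100, q = 0.01 ($10^4$ combinations per
BRI table).  The null-calibration experiment uses 100 flat-profile datasets
of 300 groups (both the chance stage asymmetries and the block noise of the
rank correlation scale as $G^{-1/2}$, so the rejection rate is essentially
independent of the group count; 300 keeps the 100-dataset study quick).
Genome-size recovery uses a 100 kb genome at 40x with 0.5% substitution
errors, and error-free.  Oracle-equivalence checks run the 3-species,
4-stage (64 combinations) case against an independent pure-Python
re-implementation.

## Known limitations

* The tree-aware distance is a declared design choice (progressive profile
  averaging); other tree-aware formulations exist and would give different
  absolute scores, though the same qualitative Ptop profiles in the regimes
  tested.
* Ptop's top-set rule (`max(1, round(qN))`, ties by enumeration order)
  privileges reproducibility over statistical treatment of ties.
* The Friedman-over-BRI test has no type-I control against chance realized
  divergence asymmetries (see above).
* The k-mer counter holds all k-mer codes in memory; it is not a
  replacement for external counters on real sequencing volumes.
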