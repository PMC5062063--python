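# Methods

`genelossclock` re-implements, as one tested pipeline, the standard
pangenome-based analysis of intra-species bacterial gene loss: cluster
orthologous CDS into pangenes, classify them by frequency, place the
absences of near-core pangenes on a rooted species tree by Dollo
parsimony, and ask (i) whether lost genes were already less conserved,
less constrained and less codon-biased than never-lost genes, and (ii)
whether losses accumulate clocklike along branches. Because the original
analyses rest on bulk public genome collections, validation here is
simulation-based: a forward generator with known ground truth stands in
for the empirical data, and every stage is scored against that truth.

## The simulator (study conditions)

A pure-birth (Yule) topology is grown to `n_strains` leaves; every branch
receives an i.i.d. exponential length, rescaled so the mean root-to-tip
depth equals `tree_depth` (default 0.05, the scale of typical
intra-species AND distances). One outgroup leaf is attached above the
ingroup root on a 3x-depth branch; it evolves sequences but never loses
or gains genes, so rooting is clean and the outgroup is used only for
rooting, mirroring its role in the analysis.

The ancestral genome carries three constraint classes, chosen so that
class membership ties loss propensity to constraint and codon bias the
way the biological argument requires (genes that are lost were *already*
under weaker selection):

| class       | genes | loss rate λ (events/gene/unit) | target ω | codon-bias weight | reference-species presence |
|-------------|------:|-------------------------------:|---------:|------------------:|---------------------------:|
| constrained |  150  | 0.3                            | 0.05     | 0.7               | 0.70 |
| relaxed     |   90  | 2.0                            | 0.30     | 0.4               | 0.30 |
| volatile    |   60  | 6.0                            | 0.80     | 0.1               | 0.10 |

Mechanics, per branch of length ℓ:

- **Loss** — each surviving gene is lost with probability `1 − exp(−λ_c·ℓ)`
  (clocklike by construction); loss is irreversible in the ingroup (the
  Dollo assumption the inference also makes). An optional branch
  whitelist confines loss to named branches, giving the non-clocklike
  negative control.
- **Gain** — horizontally acquired genes arrive at rate `hgt_rate·ℓ`
  (default 100/unit) as brand-new random sequences, so they cluster as
  novel pangenes and populate the rare arm of the U-shaped frequency
  spectrum. Gained genes are not lost again; they exist to shape the
  accessory class, which is never run through loss mapping.
- **Substitution** — each codon receives `Poisson(μ·ℓ)` proposed single
  nucleotide changes (μ = 0.5 proposals/codon/unit, so μ·depth = 0.025
  and ortholog identities stay near 95%, comfortably above the 80%
  clustering threshold). Synonymous proposals are always accepted,
  stop-creating ones rejected, nonsynonymous ones accepted with
  probability ω_c — so the realized NG86 dN/dS of a class estimates ω_c.
- **Codon bias** — ancestral codons are drawn per amino acid as a mixture:
  with probability equal to the class bias weight the family's preferred
  codon, otherwise uniform over the family. Higher weight ⇒ lower ENC′.

Gene lengths are uniform over 300–900 codons (≥ 100 always, so the ENC′
length filter cannot silently empty a test set). The synthetic
cross-species protein database plants each ancestral gene into a
class-dependent number of pseudo-species (40 available) at 15–55% random
protein divergence, so conservation counts order the classes; the
synthetic functional-label database assigns "housekeeping"-type
categories predominantly to the constrained class.

What the generator does *not* model: recombination, indels and
frameshifts, paralogy within a strain, pseudogenization by partial decay,
rate variation among sites, and any demographic structure. Passing tests
therefore demonstrate that the pipeline's inferences are correct when its
own model assumptions hold — not that the statistics are robust to, e.g.,
recombination or assembly artifacts in real data.

## Pipeline stages and their thresholds

All thresholds default to the printed values of the analysis the package
reproduces: 80% nucleotide identity for clustering (validated by the
95%-at-80% ortholog-identity check with a relaxed 30% search floor), the
2/3-length member correction, ≥ 70% coverage of the shorter gene, the
75% near-core frequency boundary (inclusive), AND = 100 − ANI over core
non-recombining genes with POGO-style 30%/70% ortholog thresholds, NI =
I·AL/QL with a 40% presence threshold (inclusive, capped at 100), dN/dS
kept when 0.0001 < ω ≤ 2 and the synonymous tree length ≥ 0.001, ENC′
pangenes dropped when the member CV exceeds 10% (sample SD, ddof = 1) or
any member is under 100 codons, and COG-style labels at ≥ 70% identity
over ≥ 2/3 of the query.

Notable implementation choices where the method was genuinely open:

- **Alignment engines.** The reference pairwise aligner is an affine
  overlap alignment (match +5, mismatch −4, gap 12 + 4·(L−1), terminal
  gaps free); identity counts matches over aligned columns, internal gaps
  in the denominator. Bulk clustering uses a fast unit-cost path (column
  comparison for equal lengths, infix edit-distance alignment otherwise)
  that agrees with the affine engine at the identities where clustering
  decisions happen. Candidate pairs come from a content-sampled k-mer
  index (phase-invariant, k = 14 for DNA sampled 1-in-8); retrieval is
  reliable down to roughly 70% identity (a denser k = 10 index is used
  automatically for relaxed search floors), which bounds the sensitivity
  of the 30% ANI floor in practice. All-vs-all alignment is available by
  constructing denser indexes where exactness matters.
- **dN/dS.** Maximum-likelihood codon models are replaced by NG86
  counting: per-pair synonymous/nonsynonymous sites averaged over the
  pair, pathway-averaged difference counts (paths through stop codons
  discarded; mutations to stops ignored in site counting), Jukes–Cantor
  correction; a pangene's single ω is mean pairwise dN over mean pairwise
  dS, and its synonymous tree length is a non-negative least-squares fit
  of pairwise dS onto the (trimmed) tree's branches, falling back to the
  mean pairwise dS for degenerate fits. This keeps the single-ω contract
  and all filters but makes no claim of numerical CodeML equality; an
  independent NG86 implementation (Biopython's) is used as a cross-check
  with tolerance for its different stop-codon conventions.
- **Per-branch dS.** Branch-free ML is replaced by Fitch parsimony
  ancestral codon states (ties resolved toward the parent state for
  determinism) over gap-free columns; a branch's per-gene dS is the
  pathway-averaged synonymous difference count between its endpoint
  states divided by the NG86 synonymous sites of the parent sequence
  (no multiple-hit correction at these short branches). Genes with
  dS = 0 or dN/dS > 2 on a branch are excluded from that branch's adS.
- **Codon alignment.** Translate → protein alignment → back-translate,
  genetic code 11. Equal-length protein sets (the only case the
  indel-free simulator produces) align trivially; unequal lengths run
  through mafft. Sequences with internal stops are rejected per sequence.
- **ENC′.** Composition-adjusted homozygosity per synonymous family,
  F′ = (χ² + n − k)/(k(n − 1)) with expected codon proportions from the
  background nucleotide composition (the strain's own concatenated CDS
  in the pipeline), combined by Wright's formula
  Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ for the code-11 family structure,
  capped at 61. A missing 3-fold class is imputed as (F̄₂+F̄₄)/2; any
  other missing class falls back to the mean of observed classes.
- **Recombination screen.** The four-gamete test on biallelic site pairs
  stands in for the unpublished original filter. It is deterministic and
  conservative: recurrent mutation occasionally produces a violation
  without recombination, so a small fraction of genuinely clonal genes
  is discarded.
- **Neighbor joining.** Canonical Saitou–Nei with lexicographic
  tie-breaking on cluster labels and negative branch estimates clamped
  to zero; the root is placed at the outgroup's attachment node and the
  outgroup pruned. On additive matrices the recovered clades and path
  lengths are exact, which is tested directly.
- **Dollo placement.** A gene present in ≥ 75% of strains is assumed
  present at the ingroup root and never regained; loss branches are the
  maximal all-absent clades. Under this model the returned set is the
  unique minimum, verified against exhaustive clade-cover search. When
  absences span both root children the strict no-regain rule yields two
  child-branch losses rather than a root-adjacent event.
- **Statistics.** Group comparisons use the non-paired one-sided
  Mann-Whitney U (exact enumeration when n ≤ 12 without ties, otherwise
  normal approximation with tie and continuity corrections); the
  "paired Mann-Whitney" of the functional analysis is implemented as the
  Wilcoxon signed-rank test, the standard paired rank analogue, recorded
  as such in the output; the clock test is a one-sided Spearman
  correlation of per-branch loss counts against adS (exact permutation
  null for ≤ 8 branches). No multiple-testing correction is applied by
  default, matching the per-comparison reporting convention;
  Benjamini-Hochberg is available from `scipy` downstream of the TSVs.

## Validation studies and problem sizes

The test suite runs the following study sizes, chosen as the smallest
that make the pass criteria statistically meaningful:

- Dollo vs exhaustive search: 200 random trees of ≤ 8 leaves, every
  informative pattern (unit suite: 6 trees; acceptance script: 60).
- NJ exactness: 100 additive matrices of ≤ 12 leaves, clades and path
  lengths to 1e-9.
- End-to-end loss recovery: 20 strains × 300 genes, μ·depth 0.025,
  12 seeds; ≥ 90% of true events recovered on the correct branch and
  ≤ 5% single-vs-multiple misclassification.
- Directional metric orderings: 30 strains × 600 genes, 10 seeds; all
  six one-sided comparisons significant at p ≤ 0.05 in ≥ 90% of seeds.
- Clock power / negative control: 30 strains × 500 genes, 15 seeds each;
  uniform-rate fixtures significant in ≥ 90%, single-branch-concentrated
  loss in ≤ 20%.
- Calibration: 10,000 Mann-Whitney null replicates (rejection rate in
  [4%, 6%] at α = 0.05) and 1,000 Spearman null profiles (≤ 6%).

`scripts/acceptance.py` recomputes the same quantities at slightly
smaller replicate counts (stated in its functions) so a full from-scratch
run stays in the minutes range on one CPU.

## Known limitations

- Clustering candidate retrieval is heuristic below ~70% identity; truly
  diverged orthologs (legal under the 30% ANI floor) can be missed. The
  simulated regime never approaches that floor.
- The NG86 estimator is a counting approximation: unbiased in the
  simulator's uniform-mutation regime, but it ignores
  transition/transversion bias and codon-frequency effects that a
  likelihood model would absorb.
- adS from parsimony reconstruction underestimates synonymous divergence
  on long branches (no correction for multiple hits along a branch); the
  clock test only uses ranks, which this does not disturb.
- The four-gamete screen cannot detect gene conversion between identical
  sites and false-positives on homoplasy; it is a stand-in, and its
  output is not claimed to match any particular published gene subset.
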