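# Methods

`mamoscan` re-implements, as a tested library, the computational chain
used to characterize the silkworm BTB-ZF transcription factor Bm-mamo:
predicting its DNA-binding motif from the zinc-finger recognition
residues, scanning gene flanks genome-wide for candidate binding sites,
intersecting those sites with differential expression to nominate direct
targets, and scanning two-population resequencing data for nucleotide
diversity (π) and fixation-index (F_ST) signatures of selection.  A
synthetic-data module generates ground-truthed inputs for every stage so
the whole chain is verifiable without external downloads.

## Zinc-finger detection and binding-site prediction (`zfrec`)

C2H2 fingers are detected with the classical Cys2His2 spacing pattern
`C-x(1,4)-C-x(12)-H-x(3,5)-H`.  Helix position 1 is the first residue of
the recognition α-helix, six residues N-terminal of the first
coordinating histidine; position −1 is the residue immediately before
it.  For the classic Zif268 finger-2 anchor (`FQCRICMRNFSRSDHLTTHIRTH`)
this numbering reads −1=R, 1=S, 2=D, 3=H, 4=L, 5=T, 6=T, matching the
standard structural assignment.

The motif is assembled under the canonical binding model: fingers array
antiparallel to the DNA, so the C-terminal finger's 3-bp subsite forms
the 5′ end of the motif, and within a finger residue 6 contacts base 1,
residue 3 base 2, and residue −1 base 3 of the sense-strand triplet.
Residue 2 contacts the complementary strand of the base 3′-adjacent to
the triplet; it can contribute an optional fourth column per finger
(`cross_strand_pos2`, default off — a 3-finger protein then yields the
9-bp motif width observed for Bm-mamo-S).

Residue→base preferences come from a plain-text recognition-code table.
The packaged default is a coarse qualitative canonical code (arginine→G,
asparagine/glutamine→A, glutamate/aspartate→C, and weaker preferences
for the small/hydrophobic residues, identical across contact positions);
it is deliberately simple, fully user-replaceable, and is *not* a
re-implementation of any published regression model.  Because the
numeric PWM behind the published Bm-mamo-S logo is not recoverable from
text, the package also ships `BmMamoS_printed`: a width-9 PWM built from
the printed consensus GTGCGTGGC with per-base match probability 0.97.
Downstream stages anchor on this fixture, independent of the code table.
Finger `confidence` is an internal heuristic (pattern match plus
hydrophobic-core hallmarks, range 1–2) and is not comparable to external
prediction-server scores; the default threshold accepts all pattern
matches.

## PWM scanning with exact p-values (`pwmscan`)

Scanning is FIMO-like: log₂-odds scores of the pseudocount-regularized
PWM against a 0-order background, both strands, windows containing N
skipped, hits reported at p ≤ threshold (default 1e−4) on
forward-strand coordinates.  The regularization mixes
`pseudocount × background` into each column and renormalizes
(default pseudocount 0.25).  When no background is given, a
strand-symmetrized 0-order model is estimated from the scanned
sequences, with a uniform fallback.

P-values are survival probabilities of the null score distribution.
For motifs up to width 10 the null is built by full enumeration of all
4^W words — exact to float precision.  For wider motifs, per-column
scores are discretized onto a shared integer grid (default 1000 bins
over the widest column range) and the total-score pmf is built by
dynamic-programming convolution; the same integer lookup scores the
windows, so scan p-values and the null are always mutually consistent.
Boundary queries use a 1e−9 score tolerance to absorb float
summation-order noise.  Minus-strand windows are scored with the
complemented/reversed lookup table, which is identical to scoring the
reverse-complemented window with the motif itself, so a single null
serves both strands.

Multiple testing uses Benjamini–Hochberg step-up q-values
(`scipy.stats.false_discovery_control`); no π₀ estimation.

One practical consequence of exact nulls: a pure-consensus PWM has only
~W discrete score levels, so the largest achievable p-value below a
threshold can sit well under it.  Calibration claims of the form
"false-positive count ≈ 2·L·p" therefore hold for dense-scored motifs
and are tested with one; for the consensus fixture, realized rates are
conservative.

## Flanks and ORFs (`genomeprep`)

Flanks are 2 kb (configurable) windows on either side of the annotated
gene span — not per-transcript TSSs, since the analysis operates on
predicted gene loci.  Minus-strand flanks are mirrored and
reverse-complemented so every flank reads 5′→3′ relative to its gene.
Flanks are clipped (flagged `truncated`) at contig edges and are not
trimmed when they overlap neighboring genes, matching per-gene
site-presence reporting.  GFF3 `gene` records are converted to 0-based
half-open coordinates; malformed records are skipped with a logged
warning naming the line.

`longest_orf` searches the three forward frames for the longest
ATG-initiated, stop-terminated reading frame (length includes the stop;
ties to the smallest start).  The deposited transcripts of the two mamo
isoforms carry ORFs of 2397 and 1824 nt; because verifying against the
deposited records requires a network fetch, the test suite runs fully
offline and exercises the caller on deterministic synthetic stand-in
transcripts constructed to those lengths (they share no sequence with
the real records and are labeled synthetic), plus an
exhaustive-enumeration oracle on random sequences.
`fixtures.fetch_genbank_fasta` runs the same check on the real records
when a network is available.

## Target nomination (`targets`)

A gene is nominated as a candidate direct target iff it has ≥ 1 motif
hit in its flanks AND it is a significant DEG.  DEG calling itself is
upstream of this package; the consumed table carries (gene_id, log2fc,
pvalue, fdr), with significance defined as |log2FC| ≥ 1 and FDR ≤ 0.05
by default (both configurable; the thresholds behind the original
191-gene table are defined in the prior transcriptome study, not here).
Genes absent from the DEG table are carried un-nominated.  Raising the
fold-change threshold or lowering the FDR threshold can only shrink the
nominated set.

## Selection scan (`popgen`)

Within-population diversity per window:
π = Σ_sites 2p̂q̂·n/(n−1) / window_length — the unbiased mean pairwise
difference per bp, with missing calls excluded per site (per-site n).
Between populations, Hudson's F_ST as a ratio of averages across sites:
F_ST = 1 − mean(H_w)/mean(H_b), H_w the average unbiased
within-population heterozygosity, H_b = p_A q_B + p_B q_A, excluding
sites monomorphic across both populations.  Hudson's estimator was
chosen over Weir–Cockerham for robustness to the very unequal panel
sizes of the motivating data (51 wild vs 171 domesticated strains); the
estimator is a parameter of the module in name only — no other is
currently shipped.  Small negative estimates are expected under zero
differentiation (order 1/(n−1)) and are not clamped.

Windows default to 5 kb with 1 kb steps (the motivating signal is a
~1 kb region, so step ≤ 1 kb; the original tool's settings are not
published).  Windows with no variant sites report `n_sites = 0` with
absent statistics — distinct from a window with sites but no variation
(π = 0).  Outliers are windows at or above the empirical top quantile
(default q = 0.95, linear interpolation), mirroring a top-5% dashed
line.  VCF input (biallelic SNPs, GT field) is read with cyvcf2;
diploid genotypes are split into haplotype rows (no phasing is needed
for π/F_ST); a 0/1 matrix TSV is accepted as an alternative.

## qPCR (`qpcr`)

Classical relative quantification: technical replicates are averaged
per (sample, gene); ΔCt = Ct_target − Ct_reference per sample
(reference RpL3 in the motivating design); ΔΔCt subtracts the
calibrator-group mean; R = 2^−ΔΔCt per sample, reported as mean ± SD
per group.  Significance is tested on ΔCt (approximately normal), not
on fold changes: equal-variance Student's t by default, Welch and
paired variants available.  Groups with < 2 samples get no p-value.  No
amplification-efficiency correction is applied.

## Phylogeny (`njtree`)

Distances from an existing protein alignment: pairwise-deletion
mismatch proportions, optionally Poisson-corrected (−ln(1−p)).  The
motivating analysis names a "Pearson model", which has no meaning in
the MEGA7 distance menu; it is read here as a likely typo for the
Poisson amino-acid correction, which is the default (raw p-distances
available).  Pairwise deletion retains more signal than complete
deletion and is the default for the same reason.

Neighbor joining is the classical Saitou–Nei algorithm: Q-matrix
selection with ties broken by the smallest (i, j) index pair, standard
limb-length formulas, negative limbs clamped to zero with the deficit
moved to the sibling edge, and a trifurcating root for the unrooted
result.  On additive matrices the output reproduces the generating
topology and all path lengths.  Bootstrap support resamples alignment
columns with replacement; replicate r draws from the deterministic
substream `default_rng([seed, r])`, so supports are bit-reproducible
for a fixed seed and invariant to execution order.  Support is the
percentage of replicate trees containing each internal split of the
full-data tree, written as integer labels in Newick output.  The
motivating study used 2000 replicates; that is the default, while tests
use far fewer.

## Synthetic data (`simdata`)

All generators are pure functions of parameters + seed and emit their
ground truth:

- `simulate_genome` — one contig (default 200 kb, uniform base
  composition, GC configurable) with n_genes (default 20) evenly spaced
  1-kb genes on random strands; n_true_targets (default 7) genes
  receive one site sampled from the motif at the given strength
  (strength 1.0 plants the exact consensus) at a uniform offset inside
  a random flank, random strand, avoiding the outer 10 bp so clipping
  can never cut a site.  The scale emulates a 14,623-gene genome scan
  at desk size.
- `simulate_deg_table` — per-gene t-tests over n_reps (default 3)
  log2-scale replicates with noise SD 0.2; true targets get the planted
  effect (default 3 log2 units), BH FDR appended.  Emulates the
  knockout-vs-control DEG table.
- `simulate_haplotypes` — 51 + 171 haplotypes (the wild/domesticated
  panel sizes) over a 50-kb region, shared Uniform(0.05, 0.95) allele
  frequencies, and one planted window where frequencies are separated
  by exactly the divergence level (1.0 ⇒ fixed differences, F_ST = 1).
- `simulate_ct_table` — constant-reference qPCR plates with known fold
  changes, Gaussian cycle noise, 3 technical replicates per sample.

What the generators do *not* emulate: linkage/recombination and
demography (divergence is planted, not evolved), realistic genome
composition and repeat structure, overdispersed expression counts, and
amplification-efficiency variation.  Passing tests therefore
demonstrate algorithmic correctness and calibration under the stated
models, not performance on real silkworm data.

## Desk-scale limits

The genome-wide numbers of the motivating study — 14,623 predicted
genes scanned, 10,622 genes with recognition sites within the 2-kb
flanks, the 191-gene DEG table, the 18 cuticular-protein genes with
binding sites, and the chromosome-9 π/F_ST curves — depend on the full
silkworm genome assembly and annotation, the prior transcriptome, 222
resequenced strains, and unpublished tool settings (FIMO version and
threshold, window/step, DEG thresholds).  They are documented here as
context and are deliberately not test targets; the property suite
(planted-truth recovery, oracle equivalence, null calibration) covers
the same code paths at toy scale.

## Numerical choices

- PWM columns and backgrounds validated to sum to 1 ± 1e−9.
- Score-boundary queries use a 1e−9 tolerance; oracle-equivalence tests
  assert 1e−12 agreement against enumeration.
- Consensus ties break alphabetically (A < C < G < T).
- Quantile thresholds use linear interpolation (`numpy.quantile`).
- ORF ties break to the smallest start; an unterminated ATG run is not
  an ORF.
- BED hit scores map −100·log10(p), capped at 1000.
- All RNG flows through `numpy.random.default_rng`; multi-replicate
  procedures use `default_rng([seed, replicate])` substreams.
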