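# Methods

`splicedesign` implements a tissue-specific splicing code — a model
that predicts cassette-exon inclusion (Ψ) and differential inclusion
(ΔΨ) from genomic sequence and cellular condition — together with a
sequence-design engine that inverts that code: given a predictor and a
target splicing outcome, find a small set of edits that achieves it.
Everything is testable at desk scale against a synthetic oracle whose
ground truth is known exactly.

## The prediction model

### Inputs and windows

A cassette event `e` is represented by four fixed-width sequence
windows `S_e^1..S_e^4`, one per splice site in transcription order:
upstream-exon donor, alternative-exon acceptor, alternative-exon
donor, downstream-exon acceptor.  Windows are read 5'→3' on the
transcribed strand with the junction at the center; the anchor base at
index `W//2` is the first base 3' of the junction (the first intronic
base for donors, the first exonic base for acceptors).  This one
uniform anchoring rule is a package convention — "splice site in the
center" admits several off-by-one interpretations, and a single
testable rule beats guessing among them.  Default width is 400 nt
(desk-scale configurations use 100 nt); sites closer than `W/2` to a
contig end are an error, never silently padded, because padding would
corrupt the positional code the model relies on.

Sequences are tokenized as overlapping 6-mers (stride 1), vocabulary
4096 k-mers + {CLS, SEP, MASK, PAD, UNK}; any k-mer covering an
ambiguous base maps to UNK.

### Auxiliary features

The feature bundle `F_e` covers properties local sequence cannot
express:

- **Lengths** of the five segments (three exons, two introns), binned
  on log2 edges 64…262144 (configurable).  Log spacing reflects the
  orders-of-magnitude spread of intron lengths.
- **Conservation**, discretized per k-mer into 10 equal bins on
  [0, 1].  Exonic k-mers all receive the bin of the training-set
  intronic mean — exonic conservation mostly reflects coding
  constraint, which would otherwise swamp the regulatory signal —
  while intronic k-mers keep the bin of their own mean.  Missing
  scores get a dedicated token.  A k-mer counts as exonic when the
  majority of its bases are.
- **Coding flags**: five binary digits (fully coding / non-coding /
  overlaps CDS start / overlaps CDS end / multiple categories), a
  frame-shift indicator (alt-exon length mod 3 ≠ 0 when coding) and a
  de-novo flag.

### Condition representation

Two interchangeable modes fill the same conditioning slot:

- **token** — a learned embedding per training condition; cannot be
  queried for unseen conditions (by design, the API raises).
- **pca** — a linear projection of the condition's expression
  embedding: per-gene min–max scaling over an RNA-binding-protein
  gene list fitted on training conditions (degenerate genes map to 0;
  unseen-condition values are clipped into the fitted range so the
  embedding stays bounded), followed by PCA (up to 50 components,
  truncated to what the table's rank supports).  Because the
  projection is computed from expression rather than learned per
  condition, the model can be queried for conditions never seen in
  training.

### Architecture

Each window feeds its own transformer encoder (defaults: 6 layers, 12
heads, hidden 768; weights not shared across the four encoders —
sharing is available as a flag but measurably hurts held-out accuracy
on synthetic data, so the default stands).  Per-k-mer conservation
tokens enter as a parallel embedding summed into the token + position
embeddings, which keeps the feature aligned with the sequence it
annotates.  The four CLS vectors are concatenated with the length
embeddings, the seven binary flags and two condition embeddings
(for conditions c and c'), then fused by a two-layer GELU MLP
(widths 3080, 768 at full scale) with three output heads.

### Supervision

The three heads pass through a logistic link and are trained on
targets

    Ψ_{e,c},   ΔΨ+ = |max(ε, ΔΨ)|,   ΔΨ− = |min(−ε, ΔΨ)|

with ΔΨ = Ψ_{e,c} − Ψ_{e,c'} and ε resampled per example per epoch
from Uniform(0.001, 0.002).  The ε floor keeps gradients alive for the
large majority of non-changing pairs; note the minus-side clip is at
−ε (a clip at +ε would return 0 at ΔΨ = 0 and defeat the floor).  The
loss is soft-label binary cross-entropy summed over the three heads
and averaged over the batch; the logistic link makes this
well-defined for fractional targets.  The derived differential
prediction is ΔΨ̂ = ΔΨ̂+ − ΔΨ̂−.

### Training

Masked-LM pre-training of a splice-site encoder follows the BERT
recipe adapted to overlapping k-mers: 15% of token positions are
anchors, each anchor plus three tokens either side is masked (an
unmasked overlapping neighbor would leak the anchor), and the loss is
computed at the anchors only.  Full-scale defaults: 110k steps, batch
40, AdamW, lr 4e-4 with 10k-step linear warmup then linear decay.

Fine-tuning optimizes the supervision loss over (event, ordered
condition pair) examples; full-scale defaults are lr 2e-5, batch 32,
10 epochs.  The desk-scale recipe (`FinetuneConfig.tiny`) trains from
scratch, so it uses lr 1e-3 with warmup/linear decay and subsamples
condition pairs per event per epoch with sampling probability
proportional to 0.15 + |ΔΨ| (`pair_weighting="dpsi"`): changing pairs
are rare but carry the entire differential signal, and uniform
subsampling starves the ΔΨ heads.  Initializing the four encoders
from a short masked-LM pre-training run on the training windows
improves held-out correlation substantially (~+0.04 r at desk scale)
— consistent with pre-training being the single most valuable
ingredient in ablations of this model family — whereas several
alternative regularizers evaluated during development (full encoder
weight sharing, a shared k-mer embedding table, train-time token
corruption, base-composition embedding initialization, wider
feed-forward blocks) either did not help or hurt held-out accuracy;
they remain available as configuration flags.  Validation is split by
event (pairs of one event share windows, so an example-level split
would leak), and the best-validation epoch is restored.

Determinism: all randomness flows through seeded NumPy generators;
single-threaded CPU runs are reproducible bit-for-bit.

## Data curation

- **Labels**: an event is *changing* when any condition pair shows
  |ΔΨ| ≥ 0.15, *non-changing* when all pairs show |ΔΨ| < 0.08 with
  quantification confidence > 0.7 (read from the table; when absent a
  confidence of 1.0 is assumed, with a warning in the docs rather than
  silently), otherwise unlabeled.  Events quantified in fewer than two
  conditions are dropped.
- **Negative augmentation**: 'fake' skip junctions attached to
  constitutive exon triplets with skip PSI drawn from Uniform(0, 0.02).
- **Similarity filtering** (paralogs and overlapping event
  definitions): alternative exons are compared by global alignment
  (match +1 / mismatch −1 / gap −2) with identity = matched columns /
  max(length) and a Karlin–Altschul-style significance surrogate
  (λ = ln 3 in closed form for ±1 scoring on uniform DNA, K = 0.1).  A
  pair is similar when identity ≥ 95%, length difference ≤ 5 and
  p ≤ 1e-4 — thresholds mapped from the standard BLAT-based settings;
  the aligner backend is pluggable.  Of each similar pair the
  lexicographically later event id is dropped, making the kept set
  order-independent.  A shared-12-mer prescreen skips alignment for
  pairs that cannot reach 95% identity (≤5% mismatches over these exon
  lengths force an exact run ≥ 12).
- **Splits** are by chromosome; test events similar to any training
  event are additionally purged, and the leakage audit (re-running the
  similarity scan across the split) must come back empty.
- **Classification sets** per ordered tissue pair use ΔΨ ≥ 0.15
  positives and ΔΨ < 0.05 negatives (signed for the
  inclusion/exclusion tasks, absolute for change vs no-change).

## Splice-site scoring

A first-order position weight matrix over the canonical windows
(donor 9-mer: 3 exonic + 6 intronic; acceptor 23-mer: 20 intronic + 3
exonic), scored as summed log2-odds against a uniform background.
This is an interface-compatible stand-in for higher-order models such
as maximum-entropy scorers, which the analyses only use for ranking
and thresholding; externally computed scores can be substituted
wherever a scorer is consumed.  Strong/weak classification takes the
top/bottom 15% by empirical order statistics with inclusive
tie-breaks.  Swap and disruption operators edit only the scored
window of the targeted site.

## The synthetic oracle

The oracle is a rule-based map (windows, tissue) → Ψ with a logistic
link over additive effects:

    z = b0 + w_acc·acc̃ + w_don·doñ + w_flank·(flank scores)
        + Σ_occurrences β_{m,c} · sign_side · pos_weight(d)

where acc̃/doñ are PWM scores of the alternative exon's sites,
standardized against the generative site distribution (sites are
planted at PWM temperatures 0.55–2.8; the standardization moments are
computed in closed form over that temperature mixture), and motif
occurrences contribute only when fully intronic and within an
effective range (default ±45 nt at desk window width; a quadratic bump
`1 − (d/range)²` decays with distance from the exon).  Effects may
flip sign downstream vs upstream.  Tissue specificity is linear by
construction: β_{m,c} = slope_m × scaled TPM of motif m's synthetic
regulator in tissue c.  Tissue expression profiles are mixtures of
two archetype profiles, so conditions lie on a low-dimensional
manifold — the property the PCA conditioning exploits.  The default
motif set contains a FOX-like element (TGCATG; enhancing downstream,
repressive upstream), a tissue-specific QKI-like silencer (ACTAAC;
regulator expressed in one tissue only — the planted handle for
tissue-specific design tasks) and random broad motifs.

Observation noise is Beta(pκ, (1−p)κ) around the deterministic value
(κ = 50 by default; κ = 0 disables noise).  Site weights
(w_acc = w_don = 2.2) and motif presence (0.12 per motif per side)
were calibrated once so the generator reproduces the regimes
cross-tissue splicing data shows: inclusion concentrated near the
extremes, and a sparse changing fraction (~16% of events with maximal
pairwise |ΔΨ| ≥ 0.15).

The generator emits the full input bundle — genome FASTA with planted
events on both strands, GTF-lite annotation with CDS intervals,
bedGraph conservation (elevated over exons and planted motifs, so the
conservation feature is informative), RBP TPM table, quantification
TSV — and the per-event ground-truth decomposition.  What it does not
emulate: read-level quantification noise structure (beta noise is a
convenient stand-in for posterior uncertainty), overlapping/nested
events, alternative 3'/5' events, correlated motif grammars, or
realistic genome composition; passing tests therefore demonstrate
method correctness and recoverability under the model's assumptions,
not performance on real tissue data.

## Sequence design (BOS)

The design representation is the concatenation of the four windows;
the edit budget τ is a hard Levenshtein constraint against the start
sequence (computed with edlib), rejected rather than penalized.
Constraints — every non-target condition's Ψ must stay above a floor
(default 0.05) and optionally within a band of its start value; an
optional floor on the target condition for reduction tasks — are
evaluated on decoded sequences, never in latent space.

**VAE.**  A transformer encoder/decoder VAE over fixed-length
sequences: non-overlapping 4-base patches as input tokens (quadratic
attention cost at base resolution is the binding numerical
constraint; patching preserves base-level outputs through a
factorized 4×patch head); a position-resolved latent interface (all
final encoder states project jointly to the diagonal-Gaussian latent,
and the latent projects back to a full per-position state grid —
a pooled bottleneck loses too much positional identity for faithful
reconstruction); a non-autoregressive decoder.  Two initialization /
objective details matter in practice and are defaults:

- the log-variance head's bias starts at −6; with the conventional
  near-zero initialization the reparameterization noise (σ ≈ 1)
  drowns the small initial means and the decoder permanently learns
  to ignore the latent (posterior collapse);
- when the training corpus is the substitution neighborhood of a
  reference sequence (the design-task corpus: up to τ random edits of
  the start), reconstruction loss upweights positions that differ
  from the reference (default ×25).  Without this the decoder earns
  ~96% accuracy by emitting the consensus and encodes no edits at
  all; with it the latent demonstrably carries the edit pattern
  (~96% of a held member's edits survive encode→decode).

The KL term anneals linearly from zero to a small final weight
(1e-3): latent-space optimization needs a latent code that faithfully
identifies sequences, so reconstruction dominates by design.
Training clips gradients at global norm 5; learning rates above 1e-3
destabilize the float32 training loop.  On weakly structured corpora
the optimization has a deep saddle at the position-marginal solution
(predict per-position base frequencies, ignore the latent); whether a
run escapes it is initialization luck.  Two mechanisms make training
reliable: a curriculum warm-up (the first 10 epochs train on 96
sequences, whose strong per-sequence gradients open the
encoder–latent–decoder channel before the full corpus is seen — in
practice this alone lifts every tested seed) and, as a safety net, a
restart-on-stall rule that reinitializes a run whose token accuracy
has not left the marginal plateau after 15 epochs.

**Optimization loop.**  Exact GP surrogates (Matérn-5/2 with a
white-noise term, fitted by scikit-learn; ARD lengthscales by
default, isotropic in the desk-scale configuration where ARD's
extra hyperparameters fit no better and cost ~40× the wall time)
model the objective and the aggregate constraint violation over
observed (z, y) pairs; hyperparameters are re-optimized every 120
evaluations and the posterior is re-conditioned every batch.
Candidates are generated on spheres around the incumbent: because the
argmax decoder is locally constant and the decoded edit count rises
cliff-like with step norm, the radius producing a target edit count
(default 8) is calibrated once by bisection using decoder calls only,
and the trust-region length scales that radius (init 0.8, doubled
after 3 consecutive improving batches, halved after 4 failing ones;
on collapse below the minimum the region restarts at its initial
length, TuRBO-style).  Thompson samples of objective and violation
rank the candidates feasibility-first (sampled violation ≤ 0.02);
the batch is filled by walking the ranking and keeping only
candidates that decode to sequences not yet evaluated — near the
flip boundary many latent points decode identically, and deduplication
converts small-trust-region batches into a surrogate-guided
single-edit local search.  Initialization encodes the start sequence
plus 19 sphere perturbations.  Malformed decoder output marks the
candidate infeasible instead of crashing the loop.  Joint VAE–GP
fine-tuning during the search is not performed (no schedule for it is
established; the static-VAE loop already solves the desk-scale
tasks).

**Baselines** share the exact oracle-call budget: random k-mer
substitution (k ∈ {3, 6, 15, 30}) and a generational GA (tournament
k = 2, crossover 0.7, per-base mutation 1/L, 10% elitism; offspring
beyond τ are replaced by fresh mutants of the start).  Budget
accounting is part of the result audit: every method's candidate list
length equals its budget.

## Evaluation and in-silico mutagenesis

- `metric_a`: fraction of predictions strictly within 0.2 of the
  observation (the boundary is exclusive, documented).
- AUROC/AUPRC via scikit-learn; the test suite pins both against
  O(n²) pair counting (ties at half credit) and step-wise
  precision-integration oracles.
- Motif insertion scans substitute the motif at each position and
  subtract the mean effect of 10 random insertions matched in length
  and local base composition (composition matching isolates motif
  identity from generic disruption).
- Knockdown mimicry scrambles annotated motif occurrences and calls
  increase/decrease only beyond the 95th percentile of a
  random-mutation null built at the same relative offsets from the
  splice sites; thresholds are always recomputed from the null rather
  than using frozen literature values, which are dataset-specific.
- The 6-bp sliding-window scan mutates each span five times
  (averaging avoids accidentally creating a new motif) and skips
  spans crossing window boundaries (not contiguous genomic regions).
- Marginal per-position effects divide a multi-position record's
  |ΔΨ| equally among its positions by default (`full` credit is a
  flag); positions never mutated are reported missing, not zero.
  Position-selection enrichment compares hits in the top vs bottom
  effect deciles with an exact binomial test.

## Desk-scale problem sizes

The test suite and the acceptance script train a 2-layer, 2-head,
hidden-64 model with 100-nt windows on 2000 synthetic events across 3
tissues (noise κ = 50), hold out two chromosomes, and run the design
comparison at τ = 30 with a 300-call oracle budget; the VAE fidelity
check uses 1000 random 120-nt sequences.  These sizes are the
package's reference configuration for verifying the method end to end
on one CPU; all of them are plain configuration values and scale up
unchanged.

## Known limitations

- No GPU path; the autodiff core is NumPy-only and single-threaded.
- The PWM site scorer ignores positional dependencies that
  maximum-entropy models capture; scores are comparable only within
  one scorer.
- The VAE decoder is non-autoregressive and fixed-length; designs are
  substitution-only in practice (the Levenshtein check still guards
  against decoder drift).
- The oracle's linearity of tissue effects in regulator expression is
  an idealization; real splicing codes are not linear in TPM.
- Condition embeddings average expression per condition; replicate
  structure is not modeled.
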