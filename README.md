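# splicedesign

Tissue-specific splicing-code modelling and RNA sequence design.

Alternative splicing of cassette exons — whether an exon is included
in the mature transcript — is quantified as PSI (Ψ ∈ [0, 1], percent
spliced in), and its change between two cellular conditions as
dPSI (ΔΨ = Ψ_{e,c} − Ψ_{e,c'}).  `splicedesign` addresses two linked
problems for researchers studying splicing regulation:

1. **Prediction** — a multi-window transformer model of the splicing
   code.  Four transformer encoders, one per splice site of a cassette
   event (upstream donor, alternative-exon acceptor, alternative-exon
   donor, downstream acceptor), read 6-mer-tokenized sequence windows
   centered on their splice sites, plus discretized conservation,
   exon/intron length bins, coding-frame flags, and a condition
   representation (learned tissue tokens, or a PCA embedding of
   RNA-binding-protein expression that generalizes to conditions never
   seen in training).  Three logistic output heads predict
   Ψ̂_{e,c}, ΔΨ̂+_{e,c,c'} and ΔΨ̂−_{e,c,c'} (clipped positive and
   negative parts of ΔΨ, with an ε ∈ [0.001, 0.002] floor), trained
   with soft-label cross-entropy.

2. **Design** — BOS, latent-space Bayesian optimization for splicing
   outcomes.  A transformer VAE embeds sequences in a continuous
   latent space; a Gaussian-process surrogate with a trust region and
   constrained Thompson sampling searches for edits (within a
   Levenshtein budget τ) that achieve a target outcome, e.g. raise
   inclusion in one tissue while leaving other tissues unchanged:

       argmax_S̃  Ψ_c(S̃)   s.t.  lev(S̃, S) ≤ τ,  Ψ_{c'}(S̃) ≥ 0.05 ∀c'≠c

   Random-mutation and genetic-algorithm baselines run under the same
   oracle-call budget for fair comparison.

Because full-scale training data (consortium RNA-seq) is not
shippable, the package includes a first-class **synthetic splicing
oracle**: a rule-based map (sequence, tissue) → Ψ with planted splice
sites of known strength and tissue-specific regulatory motifs with
positional effects, which generates complete input bundles (FASTA
genome, annotation, conservation bedGraph, expression table,
quantification TSV) and exact ground truth.  Every claim in the test
suite is verified against this oracle.  See `docs/methods.md` for the
model and generator details.

## Worked example

Simulate a dataset, train the desk-scale model (masked-LM pre-training
of the splice-site encoder, then supervised fine-tuning), and predict
on held-out chromosomes:

```python
import numpy as np
from splicedesign.oracle import sample_oracle, generate_dataset
from splicedesign.events import chromosome_split
from splicedesign.model import (SpliceCodeConfig, SpliceCodeModel,
                                FinetuneConfig, PretrainConfig,
                                finetune, init_encoders_from, pretrain)
from splicedesign.evaluate import pearson_r

spec = sample_oracle(seed=11, n_tissues=3)           # the ground truth
ds = generate_dataset(spec, n_events=2000, seed=12)  # full input bundle
train, test = chromosome_split(ds.events, {"chr1", "chr3"})

cfg = SpliceCodeConfig.tiny(cond_mode="token", n_conditions=3)
mlm = pretrain([w.sequence for e in train for w in e.windows], cfg,
               PretrainConfig.tiny(steps=1000, batch_size=24,
                                   lr=2e-3, warmup=100))
model = SpliceCodeModel(cfg, seed=0, condition_names=spec.tissues)
init_encoders_from(model, mlm)
finetune(model, train, ds.records, FinetuneConfig.tiny(seed=0))

out = model.predict(test[:4], "tissueA", "tissueB")
psis = {r.event_id: r.psi for r in ds.records if r.condition == "tissueA"}
obs = np.array([psis[e.event_id] for e in test[:4]])
print("predicted PSI:", np.round(out["psi"], 2))
print("observed  PSI:", np.round(obs, 2))
allp = model.predict(test, "tissueA", "tissueB")["psi"]
allo = [psis[e.event_id] for e in test]
print(f"held-out Pearson r (tissueA, {len(test)} events):",
      round(pearson_r(allp, allo), 3))
```

```
predicted PSI: [0.51 0.51 0.25 0.66]
observed  PSI: [0.32 0.69 0.8  0.35]
held-out Pearson r (tissueA, 500 events): 0.77
```

Individual mid-range events can be off by a lot — exact inclusion
levels are noisy and hard — but across the full held-out chromosomes
the single-tissue readout correlates at r ≈ 0.77, and the pooled
three-tissue measure the test suite evaluates (predictions averaged
over condition pairings) reaches r ≥ 0.8.  The run takes about ten
minutes on one CPU.

The command-line interface exposes the same workflows
(`splicedesign simulate`, `label-events`, `score-sites`, `train`,
`predict`, `design`); run `splicedesign --help`.

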