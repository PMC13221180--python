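"""The multi-window splicing-code model.

Four transformer encoders, one per splice-site window of a cassette
event (upstream-exon donor, alternative-exon acceptor, alternative-exon
donor, downstream-exon acceptor), each consuming overlapping 6-mer
tokens with per-k-mer conservation tokens summed into the embeddings.
The four CLS representations are concatenated with the scalar/flag event
features and two condition embeddings, then fused by an MLP that emits
three outputs through a logistic link: predicted inclusion PSI_{e,c} and
the two clipped differential targets dPSI+ and dPSI- between conditions
(c, c').  Training minimizes soft-label binary cross-entropy summed over
the three heads.

Conditions are represented either as learned per-tissue tokens or as a
linear projection of the PCA expression embedding; the latter is what
allows querying conditions never seen in training.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import nn
from .events import CassetteEvent
from .features import MISSING_CONS_TOKEN, n_length_bins
from .genomic_io import QuantRecord
from .tokenizer import TokenizerSpec, mask_for_mlm, tokenize


@dataclass(frozen=True)
class SpliceCodeConfig:
    n_layers: int = 6
    n_heads: int = 12
    hidden: int = 768
    ff_mult: int = 4
    mlp_widths: tuple[int, int] = (3080, 768)
    window_width: int = 400
    k: int = 6
    n_cons_bins: int = 10
    n_len_bins: int = n_length_bins()
    len_embed_dim: int = 8
    cond_mode: str = "token"          # "token" | "pca"
    cond_dim: int = 16
    n_conditions: int = 0             # token mode
    pca_dim: int = 0                  # pca mode
    share_encoders: bool = False
    share_token_embeddings: bool = False  # one k-mer table, 4 encoders
    kmer_composition_init: bool = False   # base-identity embedding prior

    @property
    def tokens_per_window(self) -> int:
        return self.window_width - self.k + 1 + 2  # k-mers + CLS + SEP

    @classmethod
    def tiny(cls, **overrides) -> "SpliceCodeConfig":
        """Desk-scale configuration used throughout the test suite."""
        base = dict(n_layers=2, n_heads=2, hidden=64, ff_mult=2,
                    mlp_widths=(128, 64), window_width=100)
        base.update(overrides)
        return cls(**base)


def count_parameters(cfg: SpliceCodeConfig) -> int:
    """Analytic parameter count for a configuration.

    Strictly increasing in depth/width; used to report model size
    without instantiating the weights.
    """
    spec = TokenizerSpec(cfg.k)
    d, f = cfg.hidden, cfg.ff_mult * cfg.hidden
    per_layer = (2 * d                      # ln1
                 + 4 * (d * d + d)          # attention projections
                 + 2 * d                    # ln2
                 + d * f + f + f * d + d)   # feed-forward
    n_aux = cfg.n_cons_bins + 2
    encoder = (spec.vocab_size * d + cfg.tokens_per_window * d + n_aux * d
               + cfg.n_layers * per_layer + 2 * d)
    n_enc = 1 if cfg.share_encoders else 4
    encoders = n_enc * encoder
    if cfg.share_token_embeddings and not cfg.share_encoders:
        encoders -= 3 * spec.vocab_size * d  # one shared table, not 4
    feat = 5 * cfg.len_embed_dim + 7
    fusion_in = 4 * d + feat + 2 * cfg.cond_dim
    w1, w2 = cfg.mlp_widths
    mlp = fusion_in * w1 + w1 + w1 * w2 + w2 + w2 * 3 + 3
    lengths = cfg.n_len_bins * cfg.len_embed_dim
    if cfg.cond_mode == "token":
        cond = cfg.n_conditions * cfg.cond_dim
    else:
        cond = cfg.pca_dim * cfg.cond_dim + cfg.cond_dim
    return encoders + mlp + lengths + cond


# ------------------------------------------------------------- targets
def make_targets(psi_c: float, psi_cprime: float,
                 rng: np.random.Generator) -> tuple[float, float, float]:
    """Supervision targets (PSI, dPSI+, dPSI-) for one condition pair.

    dPSI+ = |max(eps, dPSI)| and dPSI- = |min(-eps, dPSI)| with eps
    drawn uniformly from [0.001, 0.002]; the eps floor keeps gradients
    alive for non-changing events while dPSI+ - dPSI- reconstructs dPSI
    to within eps whenever |dPSI| >= eps.  (Clipping the minus side at
    -eps rather than +eps is what actually enforces the floor at
    dPSI = 0.)
    """
    dpsi = psi_c - psi_cprime
    eps = float(rng.uniform(0.001, 0.002))
    return (float(psi_c), abs(max(eps, dpsi)), abs(min(-eps, dpsi)))


def supervision_loss(logits: nn.Tensor, targets: np.ndarray) -> nn.Tensor:
    """Soft-label BCE summed over the three heads, averaged over batch."""
    return nn.bce_with_logits(logits, targets) * 3.0


def kmer_composition_init(embedding: nn.Embedding, spec: TokenizerSpec,
                          scale: float = 0.1) -> None:
    """Seed k-mer embeddings with a one-hot encoding of their bases.

    The first 4k dimensions of each k-mer's vector encode base identity
    per position, so position-weight-style scoring is a linear readout
    from the first gradient step instead of something the model must
    reconstruct token by token — an inductive bias that measurably
    improves generalization to unseen sequence.  Special tokens are
    left at their random initialization.
    """
    d = embedding.w.data.shape[1]
    k = spec.k
    if 4 * k > d:
        return  # hidden size too small for the structured block
    ids = np.arange(spec.n_kmers)
    for pos in range(k):
        base = (ids // (4 ** (k - 1 - pos))) % 4
        embedding.w.data[ids, 4 * pos + base] += np.float32(scale)


def _pad_rows(g: np.ndarray, start: int, total: int) -> np.ndarray:
    out = np.zeros((total,) + g.shape[1:], dtype=g.dtype)
    out[start:start + g.shape[0]] = g
    return out


# ------------------------------------------------------------ the model
class SpliceCodeModel(nn.Module):
    def __init__(self, cfg: SpliceCodeConfig, seed: int = 0,
                 condition_names: Sequence[str] | None = None):
        self.cfg = cfg
        self.tok_spec = TokenizerSpec(cfg.k)
        rng = np.random.default_rng(seed)
        n_aux = cfg.n_cons_bins + 2  # bins + MISSING + none(CLS/SEP)

        def make_encoder():
            return nn.TransformerEncoder(
                n_vocab=self.tok_spec.vocab_size,
                max_pos=cfg.tokens_per_window,
                dim=cfg.hidden, n_layers=cfg.n_layers,
                n_heads=cfg.n_heads, rng=rng, ff_mult=cfg.ff_mult,
                n_aux_vocab=n_aux)

        if cfg.share_encoders:
            enc = make_encoder()
            self.encoders = [enc] * 4
        else:
            self.encoders = [make_encoder() for _ in range(4)]
            if cfg.share_token_embeddings:
                # k-mer identity is window-independent; sharing the
                # vocabulary table keeps window-specific layers while
                # removing the largest memorization surface
                for enc in self.encoders[1:]:
                    enc.tok = self.encoders[0].tok
        if cfg.kmer_composition_init:
            seen = set()
            for enc in self.encoders:
                if id(enc.tok) not in seen:
                    seen.add(id(enc.tok))
                    kmer_composition_init(enc.tok, self.tok_spec)

        self.len_embed = nn.Embedding(cfg.n_len_bins, cfg.len_embed_dim, rng)
        if cfg.cond_mode == "token":
            if not condition_names:
                raise ValueError("token conditioning requires the list of "
                                 "training condition names")
            self.condition_index = {c: i for i, c
                                    in enumerate(condition_names)}
            self.cond_embed = nn.Embedding(len(condition_names),
                                           cfg.cond_dim, rng)
        elif cfg.cond_mode == "pca":
            if cfg.pca_dim <= 0:
                raise ValueError("pca conditioning requires pca_dim > 0")
            self.condition_index = None
            self.cond_proj = nn.Linear(cfg.pca_dim, cfg.cond_dim, rng)
        else:
            raise ValueError(f"unknown cond_mode {cfg.cond_mode!r}")

        feat_dim = 5 * cfg.len_embed_dim + 7
        fusion_in = 4 * cfg.hidden + feat_dim + 2 * cfg.cond_dim
        w1, w2 = cfg.mlp_widths
        self.mlp1 = nn.Linear(fusion_in, w1, rng)
        self.mlp2 = nn.Linear(w1, w2, rng)
        self.head = nn.Linear(w2, 3, rng)

    # ------------------------------------------------------------------
    def encode_event(self, event: CassetteEvent
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                np.ndarray]:
        """Precompute (tokens[4,T], aux[4,T], length_tokens[5], flags[7])."""
        cfg = self.cfg
        toks, auxs = [], []
        for i, win in enumerate(event.windows):
            if len(win.sequence) != cfg.window_width:
                raise ValueError("window width does not match model config")
            ids = tokenize(win.sequence, self.tok_spec)
            aux = np.full(ids.size, cfg.n_cons_bins + 1, dtype=np.int64)
            if event.features is not None:
                cons = event.features.conservation_tokens[i]
                mapped = np.where(cons == MISSING_CONS_TOKEN,
                                  cfg.n_cons_bins, cons)
                aux[1:-1] = mapped
            toks.append(ids)
            auxs.append(aux)
        if event.features is not None:
            lens = np.asarray(event.features.length_tokens, dtype=np.int64)
            flags = np.concatenate([
                event.features.coding_flags,
                [event.features.frame_shift, event.features.de_novo]])
        else:
            lens = np.zeros(5, dtype=np.int64)
            flags = np.zeros(7)
        return (np.stack(toks), np.stack(auxs), lens,
                flags.astype(np.float32))

    def condition_input(self, cond) -> np.ndarray | int:
        if self.cfg.cond_mode == "token":
            if cond not in self.condition_index:
                raise KeyError(
                    f"condition {cond!r} was not seen in training; the "
                    "token-conditioned model cannot be queried for it")
            return self.condition_index[cond]
        return np.asarray(cond, dtype=np.float32)

    def forward(self, tokens: np.ndarray, aux: np.ndarray,
                lens: np.ndarray, flags: np.ndarray,
                cond_c, cond_cp) -> nn.Tensor:
        """Logits (batch, 3) for a batch.

        tokens/aux: (4, B, T); lens: (B, 5); flags: (B, 7);
        cond_c/cond_cp: int ids (B,) for token mode or vectors (B, P).
        """
        b = tokens.shape[1]
        if self.cfg.share_encoders:
            t = tokens.shape[2]
            hidden = self.encoders[0](tokens.reshape(4 * b, t),
                                      aux.reshape(4 * b, t))
            cls_all = nn.cls_vector(hidden)  # (4B, d)
            cls_vecs = [
                nn.Tensor(cls_all.data[i * b:(i + 1) * b],
                          _parents=(cls_all,),
                          _backward=(lambda g, i=i: cls_all._acc(
                              _pad_rows(g, i * b, 4 * b))))
                for i in range(4)]
        else:
            cls_vecs = []
            for i in range(4):
                hidden = self.encoders[i](tokens[i], aux[i])
                cls_vecs.append(nn.cls_vector(hidden))
        len_vec = self.len_embed(lens).reshape(b, -1)
        flag_vec = nn.Tensor(flags)
        if self.cfg.cond_mode == "token":
            cc = self.cond_embed(np.asarray(cond_c))
            cp = self.cond_embed(np.asarray(cond_cp))
        else:
            cc = self.cond_proj(nn.Tensor(np.asarray(cond_c)))
            cp = self.cond_proj(nn.Tensor(np.asarray(cond_cp)))
        x = nn.concat(cls_vecs + [len_vec, flag_vec, cc, cp], axis=-1)
        x = self.mlp1(x).gelu()
        x = self.mlp2(x).gelu()
        return self.head(x)

    # ------------------------------------------------------------------
    def predict(self, events: CassetteEvent | Sequence[CassetteEvent],
                condition, condition_vs,
                batch_size: int = 64) -> dict[str, np.ndarray]:
        """Predicted (psi, dpsi_plus, dpsi_minus, dpsi) for (c, c').

        ``condition``/``condition_vs`` are names (token mode, or pca mode
        with per-name vectors registered at training) or raw embedding
        vectors (pca mode).  Accepts one event or a sequence.
        """
        single = isinstance(events, CassetteEvent)
        evs = [events] if single else list(events)
        enc = [self.encode_event(e) for e in evs]
        cc = self._resolve_condition(condition)
        cp = self._resolve_condition(condition_vs)
        outs = []
        for lo in range(0, len(evs), batch_size):
            chunk = enc[lo:lo + batch_size]
            tokens = np.stack([c[0] for c in chunk], axis=1)
            aux = np.stack([c[1] for c in chunk], axis=1)
            lens = np.stack([c[2] for c in chunk])
            flags = np.stack([c[3] for c in chunk])
            n = len(chunk)
            ccb = (np.repeat(cc, n) if np.isscalar(cc)
                   else np.tile(cc, (n, 1)))
            cpb = (np.repeat(cp, n) if np.isscalar(cp)
                   else np.tile(cp, (n, 1)))
            logits = self.forward(tokens, aux, lens, flags, ccb, cpb)
            outs.append(1.0 / (1.0 + np.exp(-logits.data)))
        probs = np.concatenate(outs, axis=0)
        result = {"psi": probs[:, 0], "dpsi_plus": probs[:, 1],
                  "dpsi_minus": probs[:, 2],
                  "dpsi": probs[:, 1] - probs[:, 2]}
        if single:
            result = {k: float(v[0]) for k, v in result.items()}
        return result

    def _resolve_condition(self, cond):
        if self.cfg.cond_mode == "token":
            return self.condition_input(cond)
        if isinstance(cond, str):
            vecs = getattr(self, "condition_vectors", None)
            if vecs is None or cond not in vecs:
                raise KeyError(f"no registered embedding vector for "
                               f"condition {cond!r}")
            return np.asarray(vecs[cond], dtype=np.float32)
        return np.asarray(cond, dtype=np.float32)


def swap_windows(event: CassetteEvent,
                 permutation: Sequence[int]) -> CassetteEvent:
    """Reorder the four windows (a test-time perturbation experiment).

    ``permutation[i]`` gives the source slot feeding encoder i.  Sites
    and features are left untouched; only the sequence windows move.
    """
    if sorted(permutation) != [0, 1, 2, 3]:
        raise ValueError("permutation must rearrange the four slots")
    ev = copy.copy(event)
    ev.windows = [event.windows[j] for j in permutation]
    if event.features is not None:
        feats = copy.copy(event.features)
        feats.conservation_tokens = [
            event.features.conservation_tokens[j] for j in permutation]
        ev.features = feats
    return ev


# ---------------------------------------------------------- pre-training
@dataclass
class PretrainConfig:
    steps: int = 110_000
    batch_size: int = 40
    lr: float = 4e-4
    warmup: int = 10_000
    seed: int = 0

    @classmethod
    def tiny(cls, **overrides) -> "PretrainConfig":
        base = dict(steps=300, batch_size=16, lr=1e-3, warmup=30)
        base.update(overrides)
        return cls(**base)


@dataclass
class MlmEncoder(nn.Module):
    encoder: nn.TransformerEncoder
    head: nn.Linear
    cfg: SpliceCodeConfig
    history: list[float] = field(default_factory=list)

    def masked_accuracy(self, sequences: Sequence[str], rate: float,
                        seed: int) -> float:
        """Fraction of masked anchors recovered exactly."""
        spec = TokenizerSpec(self.cfg.k)
        rng = np.random.default_rng(seed)
        correct = total = 0
        for seq in sequences:
            ids = tokenize(seq, spec)
            masked, anchors = mask_for_mlm(ids, rate, rng=rng, spec=spec)
            if anchors.size == 0:
                continue
            hidden = self.encoder(masked[None, :])
            logits = self.head(hidden).data[0]
            pred = logits[anchors].argmax(axis=-1)
            correct += int((pred == ids[anchors]).sum())
            total += anchors.size
        return correct / max(total, 1)


def pretrain(window_sequences: Sequence[str], model_cfg: SpliceCodeConfig,
             train_cfg: PretrainConfig, mask_rate: float = 0.15
             ) -> MlmEncoder:
    """Masked-LM pre-training of one splice-site encoder.

    15% of k-mer tokens are chosen as anchors per sequence; each anchor
    and its six surrounding tokens are replaced by MASK (overlapping
    6-mers leak the anchor otherwise) but the loss covers the anchors
    only.  AdamW with linear warmup/decay.
    """
    spec = TokenizerSpec(model_cfg.k)
    rng = np.random.default_rng(train_cfg.seed)
    enc_rng = np.random.default_rng(train_cfg.seed + 1)
    encoder = nn.TransformerEncoder(
        n_vocab=spec.vocab_size,
        max_pos=max(len(s) for s in window_sequences) - model_cfg.k + 3,
        dim=model_cfg.hidden, n_layers=model_cfg.n_layers,
        n_heads=model_cfg.n_heads, rng=enc_rng,
        ff_mult=model_cfg.ff_mult,
        n_aux_vocab=model_cfg.n_cons_bins + 2)
    head = nn.Linear(model_cfg.hidden, spec.vocab_size, enc_rng)
    mlm = MlmEncoder(encoder=encoder, head=head, cfg=model_cfg)

    token_cache = [tokenize(s, spec) for s in window_sequences]
    params = encoder.parameters() + head.parameters()
    opt = nn.AdamW(params, lr=train_cfg.lr, weight_decay=0.01)

    for step in range(train_cfg.steps):
        opt.lr = nn.linear_warmup_decay(step, train_cfg.steps,
                                        train_cfg.warmup, train_cfg.lr)
        idx = rng.integers(len(token_cache), size=train_cfg.batch_size)
        batch, rows, cols, labels = [], [], [], []
        for r, i in enumerate(idx):
            masked, anchors = mask_for_mlm(token_cache[i], mask_rate,
                                           rng=rng, spec=spec)
            batch.append(masked)
            rows.extend([r] * anchors.size)
            cols.extend(anchors.tolist())
            labels.extend(token_cache[i][anchors].tolist())
        if not rows:
            continue
        hidden = encoder(np.stack(batch))
        logits = head(hidden)
        b, t, v = logits.shape
        flat = logits.reshape(b * t, v)
        sel_idx = np.asarray(rows) * t + np.asarray(cols)
        sel = nn.Tensor(flat.data[sel_idx], _parents=(flat,))

        def bw(g, flat=flat, sel_idx=sel_idx):
            full = np.zeros_like(flat.data)
            np.add.at(full, sel_idx, g)
            flat._acc(full)
        sel._backward = bw
        loss = nn.cross_entropy_logits(sel, np.asarray(labels))
        if not np.isfinite(loss.item()):
            raise RuntimeError(
                f"masked-LM loss diverged at step {step}: {loss.item()}; "
                f"lr={opt.lr:g}, batch={train_cfg.batch_size}")
        mlm.history.append(loss.item())
        for p in params:
            p.grad = None
        loss.backward()
        opt.step()
    return mlm


# ------------------------------------------------------------ fine-tuning
@dataclass
class FinetuneConfig:
    lr: float = 2e-5
    batch_size: int = 32
    epochs: int = 10
    pairs_per_event: int | None = None  # None = all ordered pairs / epoch
    weight_decay: float = 0.01
    seed: int = 0
    val_fraction: float = 0.1
    schedule: str = "constant"          # "constant" | "linear"
    warmup_frac: float = 0.05
    token_dropout: float = 0.0          # train-time UNK corruption rate
    pair_weighting: str = "uniform"     # "uniform" | "dpsi"

    @classmethod
    def tiny(cls, **overrides) -> "FinetuneConfig":
        """Desk-scale recipe: training (near) from scratch on small
        synthetic sets wants a larger, decaying learning rate than
        fine-tuning a full-size pre-trained model, and benefits from
        sampling informative (changing) condition pairs preferentially."""
        base = dict(lr=1e-3, batch_size=32, epochs=12,
                    pairs_per_event=2, schedule="linear",
                    pair_weighting="dpsi")
        base.update(overrides)
        return cls(**base)


def finetune(model: SpliceCodeModel, events: Sequence[CassetteEvent],
             records: Iterable[QuantRecord], cfg: FinetuneConfig,
             condition_vectors: dict[str, np.ndarray] | None = None
             ) -> dict:
    """Train the fusion model on quantified events.

    Each training example is an (event, ordered condition pair) with
    targets from `make_targets`; epsilon is resampled each epoch.  The
    best-validation-loss parameters are restored at the end.  Returns a
    history dict with per-epoch train/val loss.
    """
    rng = np.random.default_rng(cfg.seed)
    if condition_vectors is not None:
        model.condition_vectors = {
            k: np.asarray(v, dtype=np.float32)
            for k, v in condition_vectors.items()}

    psis: dict[str, dict[str, float]] = {}
    for rec in records:
        psis.setdefault(rec.event_id, {})[rec.condition] = rec.psi
    enc_cache, examples = {}, []
    for ei, ev in enumerate(events):
        by_cond = psis.get(ev.event_id)
        if not by_cond or len(by_cond) < 2:
            continue
        enc_cache[ei] = model.encode_event(ev)
        conds = sorted(by_cond)
        for c in conds:
            for cp in conds:
                if c != cp:
                    examples.append((ei, c, cp, by_cond[c], by_cond[cp]))
    if not examples:
        raise ValueError("no trainable (event, condition-pair) examples")

    # validation split is by event, not by example: pairs of one event
    # share windows, so an example-level split would leak
    event_ids = sorted({ex[0] for ex in examples})
    n_val_ev = max(1, int(len(event_ids) * cfg.val_fraction))
    val_events = set(np.array(event_ids)[
        rng.permutation(len(event_ids))[:n_val_ev]])
    val_ex = [ex for ex in examples if ex[0] in val_events]
    train_ex = [ex for ex in examples if ex[0] not in val_events]

    def resolve(c):
        if model.cfg.cond_mode == "token":
            return model.condition_input(c)
        return model.condition_vectors[c]

    unk = model.tok_spec.unk_id

    def batch_forward(batch, train_rng, corrupt=0.0):
        tokens = np.stack([enc_cache[b[0]][0] for b in batch], axis=1)
        aux = np.stack([enc_cache[b[0]][1] for b in batch], axis=1)
        if corrupt > 0:
            # sequence-augmentation regularizer: hide a random subset
            # of k-mer tokens so the model cannot key on exact
            # token-position combinations of the training windows
            drop = train_rng.random(tokens.shape) < corrupt
            drop[..., 0] = drop[..., -1] = False  # keep CLS/SEP
            tokens = np.where(drop, unk, tokens)
        lens = np.stack([enc_cache[b[0]][2] for b in batch])
        flags = np.stack([enc_cache[b[0]][3] for b in batch])
        if model.cfg.cond_mode == "token":
            cc = np.array([resolve(b[1]) for b in batch])
            cp = np.array([resolve(b[2]) for b in batch])
        else:
            cc = np.stack([resolve(b[1]) for b in batch])
            cp = np.stack([resolve(b[2]) for b in batch])
        targets = np.array([make_targets(b[3], b[4], train_rng)
                            for b in batch], dtype=np.float32)
        logits = model.forward(tokens, aux, lens, flags, cc, cp)
        return supervision_loss(logits, targets)

    params = model.parameters()
    opt = nn.AdamW(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, None)
    if cfg.epochs == 0:
        return history
    steps_per_epoch = max(1, int(np.ceil(
        (len(train_ex) if cfg.pairs_per_event is None else
         len({e[0] for e in train_ex}) * cfg.pairs_per_event)
        / cfg.batch_size)))
    total_steps = steps_per_epoch * cfg.epochs
    warmup = int(cfg.warmup_frac * total_steps)
    global_step = 0

    for epoch in range(cfg.epochs):
        if cfg.pairs_per_event is not None:
            by_event: dict[int, list] = {}
            for ex in train_ex:
                by_event.setdefault(ex[0], []).append(ex)
            epoch_ex = []
            for exs in by_event.values():
                take = min(cfg.pairs_per_event, len(exs))
                if cfg.pair_weighting == "dpsi":
                    # changing pairs are rare but carry the entire
                    # differential signal; sample them preferentially
                    w = np.array([0.15 + abs(e[3] - e[4]) for e in exs])
                    p = w / w.sum()
                else:
                    p = None
                for i in rng.choice(len(exs), size=take, replace=False,
                                    p=p):
                    epoch_ex.append(exs[i])
        else:
            epoch_ex = list(train_ex)
        order = rng.permutation(len(epoch_ex))
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            if cfg.schedule == "linear":
                opt.lr = nn.linear_warmup_decay(global_step, total_steps,
                                                warmup, cfg.lr)
            global_step += 1
            batch = [epoch_ex[i] for i in order[lo:lo + cfg.batch_size]]
            loss = batch_forward(batch, rng, corrupt=cfg.token_dropout)
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"fine-tuning loss diverged in epoch "
                                   f"{epoch}")
            losses.append(loss.item())
            for p in params:
                p.grad = None
            loss.backward()
            opt.step()
        val_rng = np.random.default_rng(cfg.seed + 999)
        val_losses = []
        for lo in range(0, len(val_ex), cfg.batch_size):
            val_losses.append(
                batch_forward(val_ex[lo:lo + cfg.batch_size],
                              val_rng).item())
        tr, vl = float(np.mean(losses)), float(np.mean(val_losses))
        history["train_loss"].append(tr)
        history["val_loss"].append(vl)
        if vl < best[0]:
            best = (vl, model.state_dict())
    if best[1] is not None:
        model.load_state_dict(best[1])
    return history


def init_encoders_from(model: SpliceCodeModel, mlm: MlmEncoder) -> None:
    """Copy pre-trained encoder weights into all four window encoders."""
    state = mlm.encoder.state_dict()
    for enc in model.encoders:
        enc.load_state_dict(state)


# ---------------------------------------------------------- checkpoints
def save_checkpoint(model: SpliceCodeModel, path) -> None:
    """Write weights (.npz) plus a JSON sidecar with the configuration,
    condition vocabulary and tokenizer vocabulary size."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"),
             *[p.data for p in model.parameters()])
    meta = {
        "config": dataclasses.asdict(model.cfg),
        "condition_names": (None if model.condition_index is None
                            else sorted(model.condition_index,
                                        key=model.condition_index.get)),
        "condition_vectors": {
            k: np.asarray(v).tolist()
            for k, v in getattr(model, "condition_vectors", {}).items()},
        "vocab_size": model.tok_spec.vocab_size,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> SpliceCodeModel:
    import json
    from pathlib import Path

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = SpliceCodeConfig(**{k: tuple(v) if isinstance(v, list) else v
                              for k, v in meta["config"].items()})
    model = SpliceCodeModel(cfg, seed=0,
                            condition_names=meta["condition_names"])
    with np.load(path.with_suffix(".npz")) as npz:
        model.load_state_dict([npz[k] for k in npz.files])
    if meta.get("condition_vectors"):
        model.condition_vectors = {
            k: np.asarray(v, dtype=np.float32)
            for k, v in meta["condition_vectors"].items()}
    return model
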