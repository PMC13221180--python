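"""Overlapping k-mer tokenization and masked-LM masking.

Sequences are converted to overlapping (stride-1) k-mer tokens, the
representation used both for masked-LM pre-training of the splice-site
encoders and for the downstream inclusion model.  Any k-mer touching an
ambiguous base maps to UNK.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

SPECIALS = ("CLS", "SEP", "MASK", "PAD", "UNK")


@dataclass(frozen=True)
class TokenizerSpec:
    k: int = 6

    @property
    def n_kmers(self) -> int:
        return 4 ** self.k

    @property
    def vocab_size(self) -> int:
        return self.n_kmers + len(SPECIALS)

    # special token ids sit after the 4^k k-mers
    @property
    def cls_id(self) -> int:
        return self.n_kmers + 0

    @property
    def sep_id(self) -> int:
        return self.n_kmers + 1

    @property
    def mask_id(self) -> int:
        return self.n_kmers + 2

    @property
    def pad_id(self) -> int:
        return self.n_kmers + 3

    @property
    def unk_id(self) -> int:
        return self.n_kmers + 4

    def vocabulary(self) -> list[str]:
        kmers = ["".join(p) for p in product("ACGT", repeat=self.k)]
        return kmers + list(SPECIALS)


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def tokenize(sequence: str, spec: TokenizerSpec = TokenizerSpec()
             ) -> np.ndarray:
    """CLS + overlapping k-mer ids + SEP for one sequence."""
    seq = sequence.upper()
    n, k = len(seq), spec.k
    if n < k:
        raise ValueError(f"sequence shorter than k={k}")
    codes = np.array([_BASE_CODE.get(b, -1) for b in seq], dtype=np.int64)
    # rolling base-4 encoding; any -1 (non-ACGT) poisons covering k-mers
    ids = np.zeros(n - k + 1, dtype=np.int64)
    valid = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        window = codes[j:j + n - k + 1]
        ids = ids * 4 + np.where(window < 0, 0, window)
        valid &= window >= 0
    ids[~valid] = spec.unk_id
    return np.concatenate(([spec.cls_id], ids, [spec.sep_id]))


def detokenize_kmers(ids: np.ndarray, spec: TokenizerSpec = TokenizerSpec()
                     ) -> list[str]:
    vocab = spec.vocabulary()
    return [vocab[i] for i in ids]


def mask_for_mlm(tokens: np.ndarray, rate: float = 0.15,
                 neighbor_span: int = 6, *,
                 rng: np.random.Generator,
                 spec: TokenizerSpec = TokenizerSpec()
                 ) -> tuple[np.ndarray, np.ndarray]:
    """BERT-style masking adapted to overlapping k-mers.

    Anchor positions are sampled at ``rate`` among the k-mer positions
    (CLS/SEP are never masked).  Because stride-1 k-mers overlap, each
    anchor additionally masks its ``neighbor_span`` surrounding tokens
    (span // 2 either side), but the loss labels are the anchors only.

    Returns (masked token array, sorted anchor positions).
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    tokens = np.asarray(tokens)
    n = tokens.size
    inner = np.arange(1, n - 1)  # k-mer positions between CLS and SEP
    if rate == 0.0 or inner.size == 0:
        return tokens.copy(), np.array([], dtype=int)
    anchors = inner[rng.random(inner.size) < rate]
    masked = tokens.copy()
    half = neighbor_span // 2
    for a in anchors:
        lo = max(1, a - half)
        hi = min(n - 1, a + half + 1)
        masked[lo:hi] = spec.mask_id
    return masked, np.sort(anchors)
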