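"""Auxiliary event features and the PCA condition embedding.

The feature bundle ``F_e`` complements the four sequence windows with
properties the local sequence cannot convey: exon/intron lengths
(log2-binned tokens), per-k-mer discretized conservation, coding-region
flags, a frame-shift indicator and a de-novo flag.  Conditions (tissues,
cell lines) are represented either as learned tokens or as a PCA
projection of RNA-binding-protein expression, which is what lets the
model generalize to conditions never seen during training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

# token value reserved for k-mers whose conservation is unknown
MISSING_CONS_TOKEN = -1

DEFAULT_LENGTH_EDGES = tuple(2 ** e for e in range(6, 19))  # 64 .. 262144


@dataclass
class FeatureBundle:
    """Scalar/flag features of one cassette event.

    ``length_tokens`` holds five bins: upstream exon, upstream intron,
    alternative exon, downstream intron, downstream exon.
    ``conservation_tokens`` holds one int array per window (per k-mer).
    """

    length_tokens: np.ndarray
    conservation_tokens: list[np.ndarray]
    coding_flags: np.ndarray  # 5 binary digits
    frame_shift: int
    de_novo: int

    def __post_init__(self):
        if len(self.coding_flags) != 5:
            raise ValueError("exactly 5 coding-region digits required")


def discretize_conservation(conservation: np.ndarray,
                            exonic: np.ndarray,
                            intron_mean: float,
                            n_bins: int = 10,
                            k: int = 6) -> np.ndarray:
    """Per-k-mer conservation tokens for one window.

    Exonic conservation mostly reflects coding constraint, so every
    exonic k-mer receives the bin of the training-set intronic mean;
    intronic k-mers receive the bin of their own mean per-base score.
    A k-mer counts as exonic when the majority of its bases are exonic.
    Any NaN in a k-mer's span yields the MISSING token.
    """
    conservation = np.asarray(conservation, dtype=float)
    exonic = np.asarray(exonic, dtype=bool)
    if conservation.shape != exonic.shape:
        raise ValueError("conservation and exonic mask length mismatch")
    w = conservation.size
    if w < k:
        raise ValueError("window shorter than k")

    def to_bin(v: float) -> int:
        return int(min(n_bins - 1, np.floor(v * n_bins)))

    tokens = np.empty(w - k + 1, dtype=int)
    exon_bin = to_bin(float(intron_mean))
    for i in range(w - k + 1):
        span = conservation[i:i + k]
        if np.isnan(span).any():
            tokens[i] = MISSING_CONS_TOKEN
        elif exonic[i:i + k].sum() * 2 > k:
            tokens[i] = exon_bin
        else:
            tokens[i] = to_bin(float(span.mean()))
    return tokens


def length_tokens(lengths, bin_edges=DEFAULT_LENGTH_EDGES) -> np.ndarray:
    """Map segment lengths to log2-spaced bins.

    Bin b covers (edges[b-1], edges[b]]; values <= edges[0] share bin 0
    and values > edges[-1] share the final overflow bin.
    """
    lengths = np.asarray(lengths, dtype=float)
    if (lengths < 0).any():
        raise ValueError("negative segment length")
    edges = np.asarray(bin_edges, dtype=float)
    return np.searchsorted(edges, lengths, side="left").astype(int)


def n_length_bins(bin_edges=DEFAULT_LENGTH_EDGES) -> int:
    return len(bin_edges) + 1


def coding_flags(exon_start: int, exon_end: int,
                 cds_intervals: list[tuple[int, int]]
                 ) -> tuple[np.ndarray, int]:
    """Five-digit coding category flags plus the frame-shift indicator.

    Categories: fully coding, non-coding, overlapping a CDS start,
    overlapping a CDS end, or several of these at once (the fifth digit).
    Frame shift = exon length not divisible by 3, only meaningful when
    the exon touches coding sequence.
    """
    if exon_start >= exon_end:
        raise ValueError("empty exon")
    cats: set[str] = set()
    for cs, ce in cds_intervals:
        if ce <= exon_start or cs >= exon_end:
            continue
        starts_inside = exon_start < cs
        ends_inside = ce < exon_end
        if not starts_inside and not ends_inside:
            cats.add("coding")
        if starts_inside:
            cats.add("start")
        if ends_inside:
            cats.add("end")
    flags = np.zeros(5, dtype=int)
    if not cats:
        flags[1] = 1  # non-coding
        return flags, 0
    if len(cats) > 1:
        flags[4] = 1  # multiple categories
    else:
        cat = cats.pop()
        flags[{"coding": 0, "start": 2, "end": 3}[cat]] = 1
    frame_shift = int((exon_end - exon_start) % 3 != 0)
    return flags, frame_shift


@dataclass
class TissueEmbedding:
    """Min-max ranges + PCA components fitted on training conditions."""

    genes: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    components: np.ndarray          # (n_components, n_genes)
    mean: np.ndarray                # scaled-space mean
    scores: pd.DataFrame            # per training condition
    explained_variance_ratio: np.ndarray = field(
        default_factory=lambda: np.array([]))

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def to_json_dict(self) -> dict:
        return {
            "genes": self.genes,
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "components": self.components.tolist(),
            "mean": self.mean.tolist(),
            "scores": {c: self.scores.loc[c].tolist()
                       for c in self.scores.index},
        }


def _minmax_scale(values: np.ndarray, mins: np.ndarray,
                  maxs: np.ndarray) -> np.ndarray:
    span = maxs - mins
    out = np.zeros_like(values, dtype=float)
    ok = span > 0
    out[..., ok] = (values[..., ok] - mins[ok]) / span[ok]
    return np.clip(out, 0.0, 1.0)


def tissue_pca_fit(tpm: pd.DataFrame, rbp_genes: list[str] | None = None,
                   n_components: int = 50) -> TissueEmbedding:
    """Fit the condition embedding on a genes x conditions TPM table.

    Each gene is min-max scaled across training conditions (degenerate
    genes with min == max map to 0), then PCA extracts up to
    ``n_components`` directions.  The component count is truncated to
    min(n_genes, n_conditions - 1) when the table is too small.
    """
    if rbp_genes is not None:
        missing = set(rbp_genes) - set(tpm.index)
        if missing:
            raise KeyError(f"RBP genes missing from TPM table: "
                           f"{sorted(missing)[:5]}...")
        tpm = tpm.loc[list(rbp_genes)]
    conditions = list(tpm.columns)
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions to fit the embedding")
    x = tpm.to_numpy(dtype=float).T  # conditions x genes
    mins = x.min(axis=0)
    maxs = x.max(axis=0)
    xs = _minmax_scale(x, mins, maxs)
    k = min(n_components, xs.shape[1], xs.shape[0] - 1)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(xs)
    return TissueEmbedding(
        genes=list(tpm.index),
        mins=mins, maxs=maxs,
        components=pca.components_,
        mean=pca.mean_,
        scores=pd.DataFrame(scores, index=conditions,
                            columns=[f"pc{i + 1}" for i in range(k)]),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def tissue_pca_transform(embedding: TissueEmbedding,
                         tpm_vector: pd.Series | np.ndarray) -> np.ndarray:
    """Project a (possibly unseen) condition onto the fitted components.

    Values are clipped into the fitted per-gene range before projection
    so the embedding stays bounded for out-of-range conditions.
    """
    if isinstance(tpm_vector, pd.Series):
        tpm_vector = tpm_vector.reindex(embedding.genes).to_numpy(dtype=float)
    v = np.asarray(tpm_vector, dtype=float)
    if v.shape != (len(embedding.genes),):
        raise ValueError("TPM vector does not match the fitted gene list")
    xs = _minmax_scale(v, embedding.mins, embedding.maxs)
    return (xs - embedding.mean) @ embedding.components.T
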