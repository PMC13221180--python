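"""Position-weight-matrix splice-site strength scoring and the
swap / disruption operators used in site-strength experiments.

The canonical windows are the donor 9-mer (3 exonic + 6 intronic bases)
and the acceptor 23-mer (20 intronic + 3 exonic bases).  Scores are
log2-odds against a uniform background, summed over positions — an
interface-compatible stand-in for higher-order models such as MaxEnt;
externally computed scores can be supplied wherever a scorer is used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .genomic_io import Window

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

# (exonic bases, intronic bases) of the scoring window
DONOR_EXTENT = (3, 6)
ACCEPTOR_EXTENT = (20, 3)  # intronic, exonic — see window_bounds()


@dataclass
class SiteModel:
    kind: Literal["donor", "acceptor"]
    log_odds: np.ndarray      # (width, 4), bits
    pseudocount: float = 1.0

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    def window_bounds(self) -> tuple[int, int]:
        """Offsets (start, end) of the scored bases relative to the
        splice-site anchor (the first intronic base), on the transcribed
        strand.  Donor: [-3, +6); acceptor: [-20, +3) where the exon
        starts at offset 0 ... i.e. intronic bases come first."""
        if self.kind == "donor":
            return (-DONOR_EXTENT[0], DONOR_EXTENT[1])
        return (-ACCEPTOR_EXTENT[0], ACCEPTOR_EXTENT[1])

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=1))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "kind": self.kind, "pseudocount": self.pseudocount,
            "log_odds": self.log_odds.tolist()}))

    @classmethod
    def from_json(cls, path: str | Path) -> "SiteModel":
        d = json.loads(Path(path).read_text())
        return cls(kind=d["kind"], log_odds=np.array(d["log_odds"]),
                   pseudocount=d["pseudocount"])

    @classmethod
    def from_probs(cls, kind: str, probs: np.ndarray,
                   pseudocount: float = 1.0) -> "SiteModel":
        probs = np.asarray(probs, dtype=float)
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("position probabilities must sum to 1")
        return cls(kind=kind, log_odds=np.log2(probs / 0.25),
                   pseudocount=pseudocount)


def fit_site_model(sequences: Sequence[str], kind: str,
                   pseudocount: float = 1.0) -> SiteModel:
    """Fit a first-order PWM from aligned site sequences."""
    if not sequences:
        raise ValueError("no sequences to fit")
    width = len(sequences[0])
    expected = sum(DONOR_EXTENT if kind == "donor" else ACCEPTOR_EXTENT)
    if width != expected:
        raise ValueError(f"{kind} sites must be {expected} bases, "
                         f"got {width}")
    counts = np.full((width, 4), float(pseudocount))
    for seq in sequences:
        if len(seq) != width:
            raise ValueError("ragged site sequences")
        for i, b in enumerate(seq.upper()):
            if b not in _BASE_IDX:
                raise ValueError(f"non-ACGT base {b!r} in site sequence")
            counts[i, _BASE_IDX[b]] += 1.0
    probs = counts / counts.sum(axis=1, keepdims=True)
    return SiteModel(kind=kind, log_odds=np.log2(probs / 0.25),
                     pseudocount=pseudocount)


def score_site(model: SiteModel, sequence: str) -> float:
    """Sum of per-position log2-odds (bits); additive over positions."""
    seq = sequence.upper()
    if len(seq) != model.width:
        raise ValueError(f"sequence length {len(seq)} != model width "
                         f"{model.width}")
    total = 0.0
    for i, b in enumerate(seq):
        if b not in _BASE_IDX:
            return float(model.log_odds.min(axis=1)[i])  # worst case for N
        total += model.log_odds[i, _BASE_IDX[b]]
    return float(total)


def site_sequence_from_window(window: Window, model: SiteModel) -> str:
    """Slice the model-scored bases out of a splice-site window."""
    lo, hi = model.window_bounds()
    a = window.offset_of_site
    if a + lo < 0 or a + hi > len(window.sequence):
        raise ValueError("window too narrow for the site model extent")
    return window.sequence[a + lo:a + hi]


def score_window(model: SiteModel, window: Window) -> float:
    return score_site(model, site_sequence_from_window(window, model))


def classify_strength(scores: dict[str, float] | Sequence[float],
                      top_frac: float = 0.15, bottom_frac: float = 0.15
                      ) -> tuple[dict[str, str] | list[str], float, float]:
    """Label each site strong / weak / mid by empirical percentiles.

    Thresholds are order statistics of the score multiset: the strong
    threshold is the ceil((1-top_frac)*n)-th smallest score and
    classification is inclusive at both thresholds (ties at a threshold
    are labeled strong/weak).  Returns (labels, weak_thr, strong_thr).
    """
    if isinstance(scores, dict):
        keys, values = list(scores), np.array(list(scores.values()))
    else:
        keys, values = None, np.asarray(scores, dtype=float)
    n = values.size
    if n == 0:
        raise ValueError("empty score set")
    srt = np.sort(values)
    k_top = int(np.floor(top_frac * n))
    k_bot = int(np.floor(bottom_frac * n))
    strong_thr = srt[n - k_top] if k_top > 0 else np.inf
    weak_thr = srt[k_bot - 1] if k_bot > 0 else -np.inf
    labels = ["strong" if v >= strong_thr
              else "weak" if v <= weak_thr else "mid" for v in values]
    if keys is not None:
        return dict(zip(keys, labels)), float(weak_thr), float(strong_thr)
    return labels, float(weak_thr), float(strong_thr)


def _replace_span(sequence: str, start: int, replacement: str) -> str:
    return sequence[:start] + replacement + sequence[start + len(replacement):]


def swap_splice_site(window: Window, model: SiteModel,
                     replacement: str) -> Window:
    """Substitute the model-window bases of a site; nothing else changes."""
    if len(replacement) != model.width:
        raise ValueError("replacement length must equal the site width")
    lo, _hi = model.window_bounds()
    start = window.offset_of_site + lo
    new_seq = _replace_span(window.sequence, start, replacement.upper())
    return Window(sequence=new_seq, offset_of_site=window.offset_of_site,
                  conservation=window.conservation)


def disrupt_splice_site(window: Window, model: SiteModel,
                        n_positions: int, seed: int) -> Window:
    """Randomly mutate ``n_positions`` bases inside the site window only."""
    if n_positions < 0 or n_positions > model.width:
        raise ValueError("n_positions outside [0, site width]")
    if n_positions == 0:
        return Window(window.sequence, window.offset_of_site,
                      window.conservation)
    rng = np.random.default_rng(seed)
    lo, _ = model.window_bounds()
    start = window.offset_of_site + lo
    site = list(window.sequence[start:start + model.width])
    for pos in rng.choice(model.width, size=n_positions, replace=False):
        alts = [b for b in BASES if b != site[pos]]
        site[pos] = alts[rng.integers(len(alts))]
    new_seq = _replace_span(window.sequence, start, "".join(site))
    return Window(sequence=new_seq, offset_of_site=window.offset_of_site,
                  conservation=window.conservation)


def sample_site(model_probs: np.ndarray, rng: np.random.Generator,
                temperature: float = 1.0) -> str:
    """Sample a site sequence from position probabilities.

    ``temperature`` > 1 flattens the profile (weaker sites), < 1
    sharpens it toward the consensus (stronger sites).
    """
    p = np.asarray(model_probs, dtype=float) ** (1.0 / temperature)
    p /= p.sum(axis=1, keepdims=True)
    return "".join(BASES[rng.choice(4, p=row)] for row in p)
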