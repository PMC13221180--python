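"""Evaluation statistics and in-silico mutagenesis procedures.

Scan operations take a *model function* mapping the four window
sequences to a predicted inclusion value for the condition of interest
— any oracle works: a trained splicing-code model, the synthetic
rule-based oracle, or a constant control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .events import CassetteEvent

BASES = "ACGT"

ModelFn = Callable[[list[str]], float]  # four windows -> predicted PSI


# ----------------------------------------------------------- statistics
def metric_a(pred, obs, delta: float = 0.2) -> float:
    """Fraction of predictions strictly within ``delta`` of observation."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("shape mismatch")
    if pred.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(pred - obs) < delta))


def pearson_r(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two same-length vectors of size >= 2")
    return float(stats.pearsonr(x, y)[0])


def classification_metrics(scores, labels) -> dict[str, float]:
    """AUROC and AUPRC (average precision) for a binary task."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("need both classes present")
    return {"auroc": float(roc_auc_score(labels, scores)),
            "auprc": float(average_precision_score(labels, scores))}


# -------------------------------------------------------- mutation types
@dataclass
class MutationRecord:
    event_id: str
    positions: list[tuple[int, str, str]]  # (position, ref, alt)
    dpsi: float


@dataclass
class NullDistribution:
    """Effects of random mutations, with the 95th-percentile threshold."""

    values: np.ndarray
    percentile: float = 95.0

    @property
    def threshold(self) -> float:
        return float(np.percentile(np.abs(self.values), self.percentile))


# ----------------------------------------------------------------- scans
def _mutate_windows(windows: list[str], window_idx: int, start: int,
                    replacement: str) -> list[str]:
    w = list(windows)
    seq = w[window_idx]
    if start < 0 or start + len(replacement) > len(seq):
        raise ValueError("edit outside the window")
    w[window_idx] = (seq[:start] + replacement
                     + seq[start + len(replacement):])
    return w


def _composition_sampler(seq: str, rng: np.random.Generator):
    counts = np.array([seq.count(b) for b in BASES], dtype=float)
    if counts.sum() == 0:
        counts[:] = 1.0
    p = counts / counts.sum()

    def draw(n: int) -> str:
        return "".join(rng.choice(list(BASES), size=n, p=p))
    return draw


def motif_insertion_scan(model_fn: ModelFn, event: CassetteEvent,
                         motif: str,
                         positions: Sequence[tuple[int, int]],
                         n_background: int = 10,
                         seed: int = 0) -> np.ndarray:
    """Background-corrected effect of inserting a motif at each position.

    ``positions`` are (window index, offset) pairs.  The insertion is a
    same-length substitution; the background subtracts the mean effect
    of ``n_background`` random insertions matched in length and in base
    composition to the local window, so the profile isolates the motif's
    sequence identity from generic disruption.
    """
    rng = np.random.default_rng(seed)
    windows = [w.sequence for w in event.windows]
    base = model_fn(windows)
    effects = np.empty(len(positions))
    for i, (wi, off) in enumerate(positions):
        motif_effect = model_fn(
            _mutate_windows(windows, wi, off, motif)) - base
        draw = _composition_sampler(windows[wi], rng)
        bg = [model_fn(_mutate_windows(windows, wi, off,
                                       draw(len(motif)))) - base
              for _ in range(n_background)]
        effects[i] = motif_effect - float(np.mean(bg))
    return effects


def build_null_distribution(model_fn: ModelFn,
                            events: Sequence[CassetteEvent],
                            offsets: Sequence[tuple[int, int]],
                            length: int = 6, reps: int = 5,
                            seed: int = 0,
                            percentile: float = 95.0) -> NullDistribution:
    """Random-mutation null matched by position offset.

    For each event and each (window, offset) — the same relative
    distances to the splice sites as the real motif set — apply ``reps``
    random same-length substitutions and record the effect.
    """
    rng = np.random.default_rng(seed)
    values = []
    for ev in events:
        windows = [w.sequence for w in ev.windows]
        base = model_fn(windows)
        for wi, off in offsets:
            draw = _composition_sampler(windows[wi], rng)
            for _ in range(reps):
                eff = model_fn(_mutate_windows(windows, wi, off,
                                               draw(length))) - base
                values.append(eff)
    return NullDistribution(values=np.array(values), percentile=percentile)


def kd_mimicry(model_fn: ModelFn, event: CassetteEvent,
               occurrences: Sequence[tuple[int, int, int]],
               null: NullDistribution, seed: int = 0) -> tuple[str, float]:
    """Mimic a regulator knockdown by scrambling its binding motifs.

    ``occurrences`` are (window index, start, length) of annotated
    motif instances.  Returns (call, dpsi) where call is 'increase',
    'decrease' or 'no-change' using the null's 95th-percentile
    threshold.
    """
    rng = np.random.default_rng(seed)
    windows = [w.sequence for w in event.windows]
    base = model_fn(windows)
    mutated = windows
    for wi, start, length in occurrences:
        draw = _composition_sampler(windows[wi], rng)
        mutated = _mutate_windows(mutated, wi, start, draw(length))
    dpsi = model_fn(mutated) - base
    if abs(dpsi) <= null.threshold:
        return "no-change", dpsi
    return ("increase" if dpsi > 0 else "decrease"), dpsi


def sliding_window_scan(model_fn: ModelFn, event: CassetteEvent,
                        window: int = 6, reps: int = 5,
                        seed: int = 0) -> np.ndarray:
    """Mean |effect| of mutating each ``window``-bp span, ``reps`` times.

    Operates over the concatenated four-window sequence; output length
    is (total length - window + 1).  Each span is substituted ``reps``
    times with random composition-matched bases (multiple draws avoid
    accidentally creating a new motif) and the average dPSI is recorded.
    """
    rng = np.random.default_rng(seed)
    windows = [w.sequence for w in event.windows]
    widths = [len(w) for w in windows]
    total = sum(widths)
    base = model_fn(windows)
    bounds = np.cumsum([0] + widths)
    out = np.full(total - window + 1, np.nan)
    for pos in range(total - window + 1):
        wi = int(np.searchsorted(bounds, pos, side="right") - 1)
        off = pos - bounds[wi]
        if off + window > widths[wi]:
            continue  # span crosses a window boundary: not a contiguous
            # genomic region, skip (kept NaN)
        draw = _composition_sampler(windows[wi], rng)
        effs = [model_fn(_mutate_windows(windows, wi, off, draw(window)))
                - base for _ in range(reps)]
        out[pos] = float(np.mean(effs))
    return out


# -------------------------------------------------- marginal attribution
def marginal_position_effects(records: Sequence[MutationRecord],
                              attribution: str = "split") -> pd.DataFrame:
    """Per-position mean |dPSI| from mutation records.

    Records mutating several positions attribute |dPSI| either divided
    equally among them (``split``, default) or in full to each
    (``full``).  Positions never mutated are simply absent (missing,
    not zero).
    """
    if attribution not in ("split", "full"):
        raise ValueError("attribution must be 'split' or 'full'")
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for rec in records:
        if not rec.positions:
            continue
        share = (abs(rec.dpsi) / len(rec.positions)
                 if attribution == "split" else abs(rec.dpsi))
        for pos, _ref, _alt in rec.positions:
            sums[pos] = sums.get(pos, 0.0) + share
            counts[pos] = counts.get(pos, 0) + 1
    rows = [{"position": p, "mean_abs_dpsi": sums[p] / counts[p],
             "n_mutations": counts[p]} for p in sorted(sums)]
    return pd.DataFrame(rows, columns=["position", "mean_abs_dpsi",
                                       "n_mutations"])


def position_enrichment(selected_positions: Sequence[int],
                        marginal: pd.DataFrame,
                        top_frac: float = 0.1,
                        bottom_frac: float = 0.1) -> dict:
    """Are the selected positions enriched among high-effect positions?

    Splits the marginal table into top/bottom deciles by mean |dPSI|,
    counts selections landing in each, and tests the top-vs-bottom split
    against the null that a selection is equally likely to hit either
    decile (exact binomial, two-sided adjusted for decile sizes).
    """
    m = marginal.sort_values("mean_abs_dpsi")
    n = len(m)
    if n == 0:
        raise ValueError("empty marginal table")
    k_top = max(1, int(np.floor(top_frac * n)))
    k_bot = max(1, int(np.floor(bottom_frac * n)))
    top = set(m["position"].iloc[n - k_top:])
    bot = set(m["position"].iloc[:k_bot])
    hits_top = sum(p in top for p in selected_positions)
    hits_bot = sum(p in bot for p in selected_positions)
    trials = hits_top + hits_bot
    p_null = k_top / (k_top + k_bot)
    if trials == 0:
        pvalue = 1.0
    else:
        pvalue = stats.binomtest(hits_top, trials, p_null,
                                 alternative="greater").pvalue
    return {"hits_top": hits_top, "hits_bottom": hits_bot,
            "n_top_positions": k_top, "n_bottom_positions": k_bot,
            "pvalue": float(pvalue)}
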