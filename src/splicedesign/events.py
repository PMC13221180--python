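"""Building labeled cassette-event sets: changing/non-changing labels,
fake skip-junction negatives, similarity (paralog/overlap) filtering and
leakage-free chromosome splits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .features import FeatureBundle
from .genomic_io import QuantRecord, SpliceSiteCoord, Window

Label = Literal["changing", "non-changing", "unlabeled"]

# window slots, in transcription order
SLOTS = ("c1_donor", "alt_acceptor", "alt_donor", "c2_acceptor")


@dataclass
class CassetteEvent:
    event_id: str
    gene_id: str
    sites: tuple[SpliceSiteCoord, SpliceSiteCoord,
                 SpliceSiteCoord, SpliceSiteCoord]
    windows: list[Window]
    features: FeatureBundle | None = None
    alt_exon_sequence: str | None = None
    de_novo: bool = False
    label: Label = "unlabeled"

    def __post_init__(self):
        if len(self.windows) != 4 or len(self.sites) != 4:
            raise ValueError("a cassette event has exactly four splice sites")
        kinds = tuple(s.kind for s in self.sites)
        if kinds != ("donor", "acceptor", "donor", "acceptor"):
            raise ValueError(f"site kinds out of order: {kinds}")
        strand = self.sites[0].strand
        acc, don = self.sites[1].position, self.sites[2].position
        if (strand == "+" and acc >= don) or (strand == "-" and acc <= don):
            raise ValueError(
                "alternative-exon acceptor must precede its donor on the "
                "transcribed strand")

    @property
    def contig(self) -> str:
        return self.sites[0].contig

    @property
    def strand(self) -> str:
        return self.sites[0].strand


@dataclass
class SplitSpec:
    held_out_contigs: set[str]
    purge_similarity: bool = True


# --------------------------------------------------------------- labeling
def label_events(records: Iterable[QuantRecord],
                 changing_min_dpsi: float = 0.15,
                 nonchanging_max_dpsi: float = 0.08,
                 nonchanging_min_conf: float = 0.7) -> dict[str, Label]:
    """Assign changing / non-changing / unlabeled per event.

    An event is *changing* when any condition pair shows
    |dPSI| >= ``changing_min_dpsi`` and *non-changing* when every pair
    shows |dPSI| < ``nonchanging_max_dpsi`` with quantification
    confidence above ``nonchanging_min_conf``.  Events quantified in
    fewer than two conditions are dropped.
    """
    by_event: dict[str, list[QuantRecord]] = {}
    for rec in records:
        by_event.setdefault(rec.event_id, []).append(rec)
    labels: dict[str, Label] = {}
    for event_id, recs in by_event.items():
        psis = {}
        for r in recs:
            psis[r.condition] = r.psi
        if len(psis) < 2:
            continue
        values = list(psis.values())
        max_dpsi = max(abs(a - b) for i, a in enumerate(values)
                       for b in values[i + 1:])
        conf = min(r.confidence for r in recs)
        if max_dpsi >= changing_min_dpsi:
            labels[event_id] = "changing"
        elif max_dpsi < nonchanging_max_dpsi and conf > nonchanging_min_conf:
            labels[event_id] = "non-changing"
        else:
            labels[event_id] = "unlabeled"
    return labels


def add_fake_skip_events(constitutive_triplets: Sequence[CassetteEvent],
                         conditions: Sequence[str],
                         seed: int,
                         psi_low: Callable[[np.random.Generator], float]
                         | None = None
                         ) -> tuple[list[CassetteEvent], list[QuantRecord]]:
    """Negative examples from constitutive exon triplets.

    A 'fake' skip junction is attached to each constitutive triplet and a
    small random skip PSI (default Uniform(0, 0.02)) is assigned, i.e.
    inclusion PSI = 1 - skip in every condition.
    """
    rng = np.random.default_rng(seed)
    if psi_low is None:
        def psi_low(r):
            return float(r.uniform(0.0, 0.02))
    events: list[CassetteEvent] = []
    records: list[QuantRecord] = []
    for trip in constitutive_triplets:
        ev = CassetteEvent(
            event_id=f"{trip.event_id}_fakeskip",
            gene_id=trip.gene_id, sites=trip.sites,
            windows=trip.windows,
            alt_exon_sequence=trip.alt_exon_sequence,
            de_novo=False, label="non-changing")
        events.append(ev)
        for cond in conditions:
            skip = psi_low(rng)
            records.append(QuantRecord(event_id=ev.event_id, condition=cond,
                                       psi=1.0 - skip))
    return events, records


# ------------------------------------------------------- similarity filter
# Karlin-Altschul lambda for +1/-1 scoring on uniform DNA:
# 0.25 e^lam + 0.75 e^-lam = 1  =>  e^lam = 3
_KA_LAMBDA = math.log(3.0)
_KA_K = 0.1


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def builtin_similarity_backend(seq_a: str, seq_b: str
                               ) -> tuple[float, float]:
    """Alignment identity (%) and a Karlin-Altschul style p-value.

    Global alignment with match +1 / mismatch -1 / gap -2; identity is
    matched columns over the longer sequence, which keeps unrelated
    random sequences near the 25% background identity.
    """
    aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    identity = 100.0 * counts.identities / max(len(seq_a), len(seq_b))
    e_value = (_KA_K * len(seq_a) * len(seq_b)
               * math.exp(-_KA_LAMBDA * max(aln.score, 0.0)))
    pval = -math.expm1(-e_value)
    return identity, pval


_PRESCREEN_WORD = 12


def _word_set(seq: str, w: int = _PRESCREEN_WORD) -> frozenset:
    if len(seq) < w:
        return frozenset()
    return frozenset(seq[i:i + w] for i in range(len(seq) - w + 1))


def _shares_long_word(words_a: frozenset, words_b: frozenset) -> bool:
    """Fast prescreen: >=95% identity over these exon lengths forces a
    shared exact run of at least 12 bases (<=5% mismatches leave runs
    averaging ~17 nt)."""
    if not words_a or not words_b:
        return True  # too short to screen; fall through to alignment
    return not words_a.isdisjoint(words_b)


def similar_pairs(events: Sequence[CassetteEvent],
                  others: Sequence[CassetteEvent] | None = None,
                  max_len_diff: int = 5, min_identity: float = 95.0,
                  min_pval: float = 1e-4,
                  backend: Callable[[str, str], tuple[float, float]]
                  | None = None) -> list[tuple[str, str]]:
    """All (id_a, id_b) pairs whose alternative exons are similar.

    With ``others`` given, compares events x others; otherwise all pairs
    within ``events``.
    """
    backend = backend or builtin_similarity_backend
    for ev in list(events) + list(others or []):
        if ev.alt_exon_sequence is None:
            raise ValueError(f"event {ev.event_id} lacks its alt-exon "
                             "sequence; similarity filter needs it")
    pairs = []
    if others is None:
        candidates = [(a, b) for i, a in enumerate(events)
                      for b in events[i + 1:]]
    else:
        candidates = [(a, b) for a in events for b in others]
    words: dict[str, frozenset] = {}
    if backend is builtin_similarity_backend:
        for ev in list(events) + list(others or []):
            words[ev.event_id] = _word_set(ev.alt_exon_sequence)
    for a, b in candidates:
        sa, sb = a.alt_exon_sequence, b.alt_exon_sequence
        if abs(len(sa) - len(sb)) > max_len_diff:
            continue
        if words and not _shares_long_word(words[a.event_id],
                                           words[b.event_id]):
            continue
        identity, pval = backend(sa, sb)
        if identity >= min_identity and pval <= min_pval:
            pairs.append((a.event_id, b.event_id))
    return pairs


def similarity_filter(events: Sequence[CassetteEvent],
                      max_len_diff: int = 5, min_identity: float = 95.0,
                      min_pval: float = 1e-4,
                      backend: Callable[[str, str], tuple[float, float]]
                      | None = None
                      ) -> tuple[list[CassetteEvent], list[tuple[str, str]]]:
    """Drop one member of every similar pair (the later-sorted id).

    Returns (kept events, removed pairs report).  The keep rule is
    canonical, so the result does not depend on input order.
    """
    pairs = similar_pairs(events, None, max_len_diff, min_identity,
                          min_pval, backend)
    removed = {max(a, b) for a, b in pairs}
    kept = [ev for ev in events if ev.event_id not in removed]
    return kept, pairs


def chromosome_split(events: Sequence[CassetteEvent],
                     held_out: set[str],
                     purge_similarity: bool = True,
                     **similarity_kwargs
                     ) -> tuple[list[CassetteEvent], list[CassetteEvent]]:
    """Partition events by contig; purge test events similar to training.

    ``held_out`` contigs form the test set.  With purging on, any test
    event whose alternative exon is similar to a training event (same
    thresholds as `similarity_filter`) is dropped from the test set.
    """
    train = [ev for ev in events if ev.contig not in held_out]
    test = [ev for ev in events if ev.contig in held_out]
    if not train:
        raise ValueError("held-out contigs cover every event: empty train")
    if purge_similarity and test:
        pairs = similar_pairs(test, train, **similarity_kwargs)
        leaky = {a for a, _ in pairs}
        test = [ev for ev in test if ev.event_id not in leaky]
    return train, test


# ------------------------------------------------- classification labels
def build_classification_sets(records: Iterable[QuantRecord],
                              pos_min: float = 0.15,
                              neg_max: float = 0.05) -> pd.DataFrame:
    """Per-tissue-pair labels for the inclusion/exclusion/change tasks.

    For each event measured in an ordered condition pair (c, c') with
    dPSI = PSI_c - PSI_c': 'included' positives have dPSI >= pos_min,
    'excluded' positives have dPSI <= -pos_min, 'change' positives have
    |dPSI| >= pos_min; negatives require (signed or absolute) dPSI below
    ``neg_max``; everything between the thresholds is left out.

    Returns a tidy frame: event_id, condition, condition_vs, dpsi,
    task, label.
    """
    psis: dict[str, dict[str, float]] = {}
    for rec in records:
        psis.setdefault(rec.event_id, {})[rec.condition] = rec.psi
    rows = []
    for event_id, by_cond in psis.items():
        conds = sorted(by_cond)
        for c in conds:
            for cp in conds:
                if c == cp:
                    continue
                dpsi = by_cond[c] - by_cond[cp]
                tasks = {
                    "included": (1 if dpsi >= pos_min
                                 else 0 if dpsi < neg_max else None),
                    "excluded": (1 if -dpsi >= pos_min
                                 else 0 if -dpsi < neg_max else None),
                    "change": (1 if abs(dpsi) >= pos_min
                               else 0 if abs(dpsi) < neg_max else None),
                }
                for task, label in tasks.items():
                    if label is not None:
                        rows.append({"event_id": event_id, "condition": c,
                                     "condition_vs": cp, "dpsi": dpsi,
                                     "task": task, "label": label})
    return pd.DataFrame(
        rows, columns=["event_id", "condition", "condition_vs",
                       "dpsi", "task", "label"])
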