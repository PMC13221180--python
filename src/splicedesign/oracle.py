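"""Synthetic splicing oracle and dataset generator.

A rule-based, fully known map (sequence windows, tissue) -> PSI with
planted splice-site strengths and tissue-specific positional motif
effects.  The oracle emulates the statistical regimes a splicing-code
model assumes: inclusion dominated by core splice-site strength,
modulated by intronic regulatory motifs whose effect depends on binding
position (strongest within ~tens of bases of the alternative exon,
with sign allowed to differ upstream vs downstream) and whose
tissue-specificity is *linear in the expression of a synthetic
regulator* across tissues.  Observation noise is beta-distributed
around the deterministic oracle value.

Window-coordinate convention (matches `genomic_io.extract_window`):
the anchor base at index W//2 is the first base 3' of the junction on
the transcribed strand — the first intronic base for donors, the first
exonic base for acceptors.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import genomic_io as gio
from .events import CassetteEvent
from .features import (FeatureBundle, coding_flags, discretize_conservation,
                       length_tokens)
from .genomic_io import (GenomeIndex, QuantRecord, SpliceSiteCoord, Window,
                         revcomp)
from .site_scorer import (ACCEPTOR_EXTENT, DONOR_EXTENT, SiteModel,
                          sample_site, score_site)

BASES = "ACGT"

DONOR_CONSENSUS = "CAGGTAAGT"
ACCEPTOR_CONSENSUS = "TTTTTCTTTTTCCTTTTTAGGTG"


def _consensus_probs(consensus: str, strength: float = 0.85) -> np.ndarray:
    """Position probabilities: consensus base gets ``strength``."""
    p = np.full((len(consensus), 4), (1.0 - 0.85) / 3)
    p[:] = (1.0 - strength) / 3
    for i, b in enumerate(consensus):
        p[i, BASES.index(b)] = strength
    return p


@dataclass
class Motif:
    name: str
    sequence: str
    regulator: str                     # synthetic RBP gene id
    slope: float                       # effect per unit scaled TPM
    sign_downstream: float = 1.0       # flips effect sign downstream
    max_distance: int = 45             # effective positional range (nt)

    def beta(self, scaled_tpm: float) -> float:
        return self.slope * scaled_tpm

    def pos_weight(self, distance: int) -> float:
        """Quadratic bump in distance from the alternative exon."""
        if distance < 0 or distance > self.max_distance:
            return 0.0
        return 1.0 - (distance / self.max_distance) ** 2


@dataclass
class OracleSpec:
    donor_probs: np.ndarray
    acceptor_probs: np.ndarray
    motifs: list[Motif]
    tissues: list[str]
    rbp_tpm: pd.DataFrame              # genes x tissues
    intercept: float = 0.0
    w_donor: float = 2.2
    w_acceptor: float = 2.2
    w_flank: float = 0.25
    noise_concentration: float = 50.0
    window_width: int = 100
    site_temp_range: tuple[float, float] = (0.55, 2.8)

    # analytic standardization of PWM scores (set in __post_init__)
    _don_norm: tuple[float, float] = field(default=(0.0, 1.0))
    _acc_norm: tuple[float, float] = field(default=(0.0, 1.0))

    def __post_init__(self):
        self.donor_model = SiteModel.from_probs("donor", self.donor_probs)
        self.acceptor_model = SiteModel.from_probs(
            "acceptor", self.acceptor_probs)
        lo, hi = self.site_temp_range
        self._don_norm = _score_moments(self.donor_probs,
                                        self.donor_model.log_odds, lo, hi)
        self._acc_norm = _score_moments(self.acceptor_probs,
                                        self.acceptor_model.log_odds,
                                        lo, hi)

    @property
    def tpm_scale(self) -> float:
        return float(self.rbp_tpm.to_numpy().max())

    def scaled_tpm(self, gene: str, tissue: str) -> float:
        return float(self.rbp_tpm.loc[gene, tissue]) / self.tpm_scale

    def motif_beta(self, motif: Motif, tissue: str) -> float:
        return motif.beta(self.scaled_tpm(motif.regulator, tissue))

    def spec_hash(self) -> str:
        payload = json.dumps({
            "donor": self.donor_probs.round(6).tolist(),
            "acceptor": self.acceptor_probs.round(6).tolist(),
            "motifs": [(m.name, m.sequence, m.regulator, m.slope,
                        m.sign_downstream, m.max_distance)
                       for m in self.motifs],
            "tissues": self.tissues,
            "tpm": self.rbp_tpm.round(4).to_dict(),
            "weights": [self.intercept, self.w_donor, self.w_acceptor,
                        self.w_flank, self.noise_concentration],
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _score_moments(probs: np.ndarray, log_odds: np.ndarray,
                   t_lo: float = 1.0, t_hi: float = 1.0,
                   n_grid: int = 15) -> tuple[float, float]:
    """Mean and sd of the PWM score under the generative site
    distribution: sites are sampled from the PWM sharpened/flattened by
    a temperature drawn uniformly from [t_lo, t_hi] (positions
    independent).  Mixture moments are exact given the temperature
    grid; used to standardize scores."""
    means, second = [], []
    for t in np.linspace(t_lo, t_hi, n_grid):
        p_t = probs ** (1.0 / t)
        p_t /= p_t.sum(axis=1, keepdims=True)
        m_pos = (p_t * log_odds).sum(axis=1)
        v_pos = (p_t * log_odds ** 2).sum(axis=1) - m_pos ** 2
        m = float(m_pos.sum())
        means.append(m)
        second.append(float(v_pos.sum()) + m ** 2)
    mean = float(np.mean(means))
    var = float(np.mean(second)) - mean ** 2
    return mean, np.sqrt(max(var, 1e-12))


def sample_oracle(seed: int, n_tissues: int = 3, n_motifs: int = 4,
                  window_width: int = 100,
                  noise_concentration: float = 50.0,
                  n_decoy_rbps: int = 20,
                  motif_max_distance: int = 45) -> OracleSpec:
    """Draw an oracle specification.

    The first motif is a FOX-like element (enhances inclusion downstream
    of the exon, represses upstream); the second is a QKI-like silencer
    whose regulator is expressed almost exclusively in the first tissue,
    giving the dataset a planted tissue-specific handle.  Remaining
    motifs get random sequences and broad regulators.

    Tissue expression profiles are mixtures of two archetype profiles,
    so every tissue lies on a low-dimensional expression manifold and
    the motif effects are linear in regulator TPM by construction.
    """
    rng = np.random.default_rng(seed)
    tissues = [f"tissue{chr(65 + i)}" for i in range(n_tissues)]

    motif_seqs = ["TGCATG", "ACTAAC"]
    while len(motif_seqs) < n_motifs:
        cand = "".join(rng.choice(list(BASES), size=7))
        if cand not in motif_seqs:
            motif_seqs.append(cand)
    motif_seqs = motif_seqs[:n_motifs]

    # archetype mixture coefficients per tissue, spread over [0.1, 0.9]
    alphas = np.linspace(0.15, 0.85, n_tissues)
    genes, rows = [], []
    motifs: list[Motif] = []
    for i, seq in enumerate(motif_seqs):
        gene = f"RBP_{i}"
        genes.append(gene)
        if i == 1:
            # tissue-specific regulator: expressed in the first tissue only
            tpm = np.full(n_tissues, 2.0)
            tpm[0] = 90.0
        else:
            hi, lo = rng.uniform(60, 100), rng.uniform(5, 30)
            tpm = alphas * hi + (1 - alphas) * lo + rng.normal(
                0, 2.0, n_tissues)
        rows.append(np.clip(tpm, 0.0, None))
        if i == 0:
            motifs.append(Motif(name="FOX-like", sequence=seq,
                                regulator=gene, slope=-2.2,
                                sign_downstream=-1.0,
                                max_distance=motif_max_distance))
        elif i == 1:
            motifs.append(Motif(name="QKI-like-silencer", sequence=seq,
                                regulator=gene, slope=-3.0,
                                sign_downstream=1.0,
                                max_distance=motif_max_distance))
        else:
            motifs.append(Motif(
                name=f"motif{i}", sequence=seq, regulator=gene,
                slope=float(rng.uniform(1.5, 2.5) * rng.choice([-1, 1])),
                sign_downstream=float(rng.choice([-1.0, 1.0])),
                max_distance=motif_max_distance))
    for j in range(n_decoy_rbps):
        genes.append(f"DECOY_{j}")
        hi, lo = rng.uniform(20, 100), rng.uniform(0, 20)
        rows.append(np.clip(alphas * hi + (1 - alphas) * lo
                            + rng.normal(0, 5.0, n_tissues), 0.0, None))
    tpm = pd.DataFrame(np.array(rows), index=genes, columns=tissues)

    return OracleSpec(
        donor_probs=_consensus_probs(DONOR_CONSENSUS, 0.85),
        acceptor_probs=_consensus_probs(ACCEPTOR_CONSENSUS, 0.80),
        motifs=motifs, tissues=tissues, rbp_tpm=tpm,
        noise_concentration=noise_concentration,
        window_width=window_width)


# ------------------------------------------------------------------ scoring
def _site_scores(spec: OracleSpec, windows: list[str]) -> dict[str, float]:
    w = spec.window_width
    a = w // 2
    dx_lo, dx_hi = -DONOR_EXTENT[0], DONOR_EXTENT[1]
    ax_lo, ax_hi = -ACCEPTOR_EXTENT[0], ACCEPTOR_EXTENT[1]
    don1 = score_site(spec.donor_model, windows[0][a + dx_lo:a + dx_hi])
    acc2 = score_site(spec.acceptor_model, windows[1][a + ax_lo:a + ax_hi])
    don3 = score_site(spec.donor_model, windows[2][a + dx_lo:a + dx_hi])
    acc4 = score_site(spec.acceptor_model, windows[3][a + ax_lo:a + ax_hi])
    return {"c1_donor": don1, "alt_acceptor": acc2,
            "alt_donor": don3, "c2_acceptor": acc4}


def _motif_terms(spec: OracleSpec, windows: list[str], tissue: str
                 ) -> float:
    """Sum of positional motif effects from the two alt-exon windows.

    Only fully intronic occurrences count; exonic conservation pressure
    is assumed to mask motif readout inside the exon.
    """
    a = spec.window_width // 2
    total = 0.0
    up, down = windows[1], windows[2]
    for m in spec.motifs:
        beta = spec.motif_beta(m, tissue)
        L = len(m.sequence)
        start = 0
        while True:
            s = up.find(m.sequence, start)
            if s < 0:
                break
            if s + L <= a:  # fully intronic, upstream of the exon
                total += beta * m.pos_weight(a - (s + L))
            start = s + 1
        start = 0
        while True:
            s = down.find(m.sequence, start)
            if s < 0:
                break
            if s >= a:  # fully intronic, downstream of the exon
                total += beta * m.sign_downstream * m.pos_weight(s - a)
            start = s + 1
    return total


def oracle_logit(spec: OracleSpec, windows: list[str], tissue: str) -> float:
    scores = _site_scores(spec, windows)
    dm, ds = spec._don_norm
    am, asd = spec._acc_norm
    z = spec.intercept
    z += spec.w_acceptor * (scores["alt_acceptor"] - am) / asd
    z += spec.w_donor * (scores["alt_donor"] - dm) / ds
    z += spec.w_flank * ((scores["c1_donor"] - dm) / ds
                         + (scores["c2_acceptor"] - am) / asd)
    z += _motif_terms(spec, windows, tissue)
    return z


def oracle_psi(spec: OracleSpec, windows: list[str] | list[Window],
               tissue: str) -> float:
    """Deterministic ground-truth inclusion level in [0, 1]."""
    if tissue not in spec.tissues:
        raise KeyError(f"unknown tissue {tissue!r}")
    seqs = [w.sequence if isinstance(w, Window) else w for w in windows]
    for s in seqs:
        if len(s) != spec.window_width:
            raise ValueError("window width does not match oracle spec")
    z = oracle_logit(spec, seqs, tissue)
    return float(1.0 / (1.0 + np.exp(-z)))


def positional_effect_profile(spec: OracleSpec, motif: Motif, tissue: str,
                              side: str = "upstream",
                              distances: np.ndarray | None = None
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth logit effect of one motif occurrence vs distance.

    ``side`` is 'upstream' or 'downstream' of the alternative exon;
    distance is measured from the exon boundary to the nearest motif
    base.  Returns (distances, effects)."""
    if distances is None:
        distances = np.arange(0, spec.window_width // 2)
    beta = spec.motif_beta(motif, tissue)
    sign = 1.0 if side == "upstream" else motif.sign_downstream
    effects = np.array([beta * sign * m if (m := motif.pos_weight(int(d)))
                        else 0.0 for d in distances])
    return np.asarray(distances), effects


# ------------------------------------------------------------- generation
@dataclass
class EventTruth:
    logits: dict[str, float]
    psi_true: dict[str, float]
    site_scores: dict[str, float]
    motif_plants: list[tuple[str, str, int]]  # (motif name, side, distance)


@dataclass
class SyntheticDataset:
    genome: GenomeIndex
    annotation: pd.DataFrame
    conservation: dict[str, np.ndarray]
    rbp_tpm: pd.DataFrame
    events: list[CassetteEvent]
    records: list[QuantRecord]
    truth: dict[str, EventTruth]
    spec: OracleSpec
    manifest: dict

    def event_table(self) -> pd.DataFrame:
        rows = []
        for ev in self.events:
            rows.append({
                "event_id": ev.event_id, "contig": ev.contig,
                "strand": ev.strand, "c1_5ss": ev.sites[0].position,
                "alt_3ss": ev.sites[1].position,
                "alt_5ss": ev.sites[2].position,
                "c2_3ss": ev.sites[3].position})
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        """Emit the full input bundle as plain-text files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gio.write_genome(self.genome, outdir / "genome.fa")
        gio.write_annotation(self.annotation, outdir / "annotation.tsv")
        gio.write_conservation(self.conservation,
                               outdir / "conservation.bedgraph")
        self.rbp_tpm.to_csv(outdir / "rbp_tpm.tsv", sep="\t",
                            index_label="gene_id")
        gio.write_quant_table(self.records, self.event_table(),
                              outdir / "quant.tsv")
        (outdir / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2))


def _plant(region: list[str], start: int, seq: str) -> None:
    region[start:start + len(seq)] = list(seq)


def generate_dataset(spec: OracleSpec, n_events: int, seed: int,
                     noise: float | None = None,
                     n_contigs: int = 8,
                     motif_presence: float = 0.12,
                     coding_fraction: float = 0.5) -> SyntheticDataset:
    """Generate a toy genome with planted cassette exons plus all the
    companion inputs (annotation, conservation, RBP TPM, quantification).

    ``noise`` overrides the spec's beta observation-noise concentration
    (None keeps the spec value; 0 means noiseless).  Motif presence and
    effect sizes are calibrated so that with the default three-tissue
    spec roughly 10–20% of events change (max pairwise |dPSI| >= 0.15),
    the sparse-changing regime typical of cross-tissue splicing data.
    """
    rng = np.random.default_rng(seed)
    W = spec.window_width
    half = W // 2
    kappa = spec.noise_concentration if noise is None else noise

    contig_names = [f"chr{i + 1}" for i in range(n_contigs)]
    contig_parts: dict[str, list[str]] = {c: [] for c in contig_names}
    contig_len: dict[str, int] = {c: 0 for c in contig_names}

    events: list[CassetteEvent] = []
    records: list[QuantRecord] = []
    truth: dict[str, EventTruth] = {}
    ann_rows = []
    cons_parts: dict[str, list[np.ndarray]] = {c: [] for c in contig_names}

    don_lo, don_hi = -DONOR_EXTENT[0], DONOR_EXTENT[1]
    acc_lo, acc_hi = -ACCEPTOR_EXTENT[0], ACCEPTOR_EXTENT[1]

    for idx in range(n_events):
        contig = contig_names[idx % n_contigs]
        strand = "+" if rng.random() < 0.5 else "-"

        e1 = int(rng.integers(70, 130))
        i1 = int(rng.integers(W + 20, W + 120))
        ea = int(rng.integers(W, W + 60))
        i2 = int(rng.integers(W + 20, W + 120))
        e2 = int(rng.integers(70, 130))
        margin = W
        L = margin + e1 + i1 + ea + i2 + e2 + margin

        region = list(rng.choice(list(BASES), size=L))
        cons = rng.uniform(0.05, 0.35, size=L)

        # transcribed-strand anchors
        t1 = margin + e1              # c1 donor: first intronic base
        t2 = t1 + i1                  # alt acceptor: first exonic base
        t3 = t2 + ea                  # alt donor: first intronic base
        t4 = t3 + i2                  # c2 acceptor: first exonic base

        temps = rng.uniform(*spec.site_temp_range, size=4)
        _plant(region, t1 + don_lo,
               sample_site(spec.donor_probs, rng, temps[0]))
        _plant(region, t2 + acc_lo,
               sample_site(spec.acceptor_probs, rng, temps[1]))
        _plant(region, t3 + don_lo,
               sample_site(spec.donor_probs, rng, temps[2]))
        _plant(region, t4 + acc_lo,
               sample_site(spec.acceptor_probs, rng, temps[3]))

        plants: list[tuple[str, str, int]] = []
        for m in spec.motifs:
            Lm = len(m.sequence)
            if rng.random() < motif_presence:
                dist = int(rng.integers(acc_hi + 21, half - Lm - 2))
                _plant(region, t2 - dist - Lm, m.sequence)
                cons[t2 - dist - Lm:t2 - dist] = rng.uniform(0.9, 1.0, Lm)
                plants.append((m.name, "upstream", dist))
            if rng.random() < motif_presence:
                dist = int(rng.integers(don_hi + 2, half - Lm - 2))
                _plant(region, t3 + dist, m.sequence)
                cons[t3 + dist:t3 + dist + Lm] = rng.uniform(0.9, 1.0, Lm)
                plants.append((m.name, "downstream", dist))

        # exons are conserved
        for lo, hi in ((margin, t1), (t2, t3), (t4, t4 + e2)):
            cons[lo:hi] = rng.uniform(0.6, 0.95, hi - lo)

        offset = contig_len[contig]
        seq = "".join(region)
        if strand == "+":
            contig_parts[contig].append(seq)
            cons_parts[contig].append(cons)

            def g(t):
                return offset + t
        else:
            contig_parts[contig].append(revcomp(seq))
            cons_parts[contig].append(cons[::-1].copy())

            def g(t):
                return offset + L - 1 - t
        contig_len[contig] += L

        event_id = f"ev{idx:05d}"
        gene_id = f"gene{idx:05d}"
        sites = (
            SpliceSiteCoord(contig, g(t1), "donor", strand),
            SpliceSiteCoord(contig, g(t2), "acceptor", strand),
            SpliceSiteCoord(contig, g(t3), "donor", strand),
            SpliceSiteCoord(contig, g(t4), "acceptor", strand),
        )
        win_seqs = [seq[t1 - half:t1 + W - half],
                    seq[t2 - half:t2 + W - half],
                    seq[t3 - half:t3 + W - half],
                    seq[t4 - half:t4 + W - half]]
        win_cons = [cons[t1 - half:t1 + W - half],
                    cons[t2 - half:t2 + W - half],
                    cons[t3 - half:t3 + W - half],
                    cons[t4 - half:t4 + W - half]]
        windows = [Window(s, half, c.copy())
                   for s, c in zip(win_seqs, win_cons)]

        # annotation rows (1 transcript, 3 exons, optional CDS)
        is_coding = rng.random() < coding_fraction
        exon_bounds_t = [(margin, t1), (t2, t3), (t4, t4 + e2)]
        for lo, hi in exon_bounds_t:
            glo, ghi = sorted((g(lo), g(hi - 1)))
            ann_rows.append({"seqname": contig, "feature": "exon",
                             "start": glo, "end": ghi + 1,
                             "strand": strand, "transcript_id": gene_id})
        cds_intervals_t = []
        if is_coding:
            cds_intervals_t = [(margin + 10, t1), (t2, t3),
                               (t4, t4 + e2 - 10)]
            for lo, hi in cds_intervals_t:
                glo, ghi = sorted((g(lo), g(hi - 1)))
                ann_rows.append({"seqname": contig, "feature": "CDS",
                                 "start": glo, "end": ghi + 1,
                                 "strand": strand,
                                 "transcript_id": gene_id})

        flags, fs = coding_flags(t2, t3, cds_intervals_t)
        # exonic masks on the transcribed strand (anchor = W//2)
        exonic = [np.arange(W) < half, np.arange(W) >= half,
                  np.arange(W) < half, np.arange(W) >= half]
        intron_mean = 0.2  # expectation of the intronic background
        cons_tokens = [discretize_conservation(c, ex, intron_mean)
                       for c, ex in zip(win_cons, exonic)]
        bundle = FeatureBundle(
            length_tokens=length_tokens([e1, i1, ea, i2, e2]),
            conservation_tokens=cons_tokens,
            coding_flags=flags, frame_shift=fs, de_novo=0)

        ev = CassetteEvent(event_id=event_id, gene_id=gene_id,
                           sites=sites, windows=windows,
                           features=bundle,
                           alt_exon_sequence=seq[t2:t3])
        events.append(ev)

        logits, psis = {}, {}
        for tissue in spec.tissues:
            z = oracle_logit(spec, win_seqs, tissue)
            p = 1.0 / (1.0 + np.exp(-z))
            logits[tissue] = float(z)
            psis[tissue] = float(p)
            if kappa and kappa > 0:
                a = max(p * kappa, 1e-3)
                b = max((1.0 - p) * kappa, 1e-3)
                obs = float(np.clip(rng.beta(a, b), 0.0, 1.0))
            else:
                obs = float(p)
            records.append(QuantRecord(event_id=event_id, condition=tissue,
                                       psi=obs))
        truth[event_id] = EventTruth(
            logits=logits, psi_true=psis,
            site_scores=_site_scores(spec, win_seqs),
            motif_plants=plants)

    genome = GenomeIndex({c: "".join(parts)
                          for c, parts in contig_parts.items() if parts})
    conservation = {c: np.concatenate(parts)
                    for c, parts in cons_parts.items() if parts}
    annotation = pd.DataFrame(ann_rows, columns=gio.GTF_COLUMNS)
    manifest = {"seed": seed, "n_events": n_events,
                "noise_concentration": kappa,
                "spec_hash": spec.spec_hash()}
    return SyntheticDataset(genome=genome, annotation=annotation,
                            conservation=conservation,
                            rbp_tpm=spec.rbp_tpm, events=events,
                            records=records, truth=truth, spec=spec,
                            manifest=manifest)


def make_design_event(spec: OracleSpec, seed: int,
                      silencer_distance: int = 25,
                      plant_silencer: bool = True) -> CassetteEvent:
    """A single start event for design tasks: mid-strength splice sites
    and one planted occurrence of the tissue-specific silencer upstream
    of the alternative exon (clear of the acceptor score window).

    Start events are drawn until inclusion is low in the silencer's
    tissue, moderate in the others, and scrambling the silencer rescues
    it — mirroring how design experiments start from lowly included
    exons that a regulatory element demonstrably controls.
    """
    W = spec.window_width
    half = W // 2
    don_lo = -DONOR_EXTENT[0]
    acc_lo = -ACCEPTOR_EXTENT[0]
    silencer = spec.motifs[1]
    Lm = len(silencer.sequence)
    t_sil = spec.tissues[0]
    t_others = spec.tissues[1:]
    for attempt in range(200):
        rng = np.random.default_rng((seed * 1000 + attempt) % (2 ** 31))
        windows = []
        for i in range(4):
            region = list(rng.choice(list(BASES), size=W))
            # keep accidental motif hits out of the start sequence
            for m in spec.motifs:
                s = "".join(region)
                while m.sequence in s:
                    pos = s.find(m.sequence)
                    region[pos] = BASES[(BASES.index(region[pos]) + 1) % 4]
                    s = "".join(region)
            temp = rng.uniform(1.2, 2.0)
            if i in (0, 2):
                _plant(region, half + don_lo,
                       sample_site(spec.donor_probs, rng, temp))
            else:
                _plant(region, half + acc_lo,
                       sample_site(spec.acceptor_probs, rng, temp))
            windows.append(region)
        if plant_silencer:
            _plant(windows[1], half - silencer_distance - Lm,
                   silencer.sequence)
        seqs = ["".join(r) for r in windows]
        psi_a = oracle_psi(spec, seqs, t_sil)
        psi_oth = [oracle_psi(spec, seqs, t) for t in t_others]
        if not plant_silencer:
            ok = 0.25 <= psi_a <= 0.75
        else:
            scrambled = list(seqs)
            s = half - silencer_distance - Lm
            scrambled[1] = (scrambled[1][:s] + "A" * Lm
                            + scrambled[1][s + Lm:])
            if silencer.sequence in scrambled[1]:
                continue
            rescued = oracle_psi(spec, scrambled, t_sil)
            ok = (psi_a <= 0.35 and rescued >= psi_a + 0.3
                  and all(0.35 <= p <= 0.85 for p in psi_oth))
        if ok:
            win_objs = [Window(q, half) for q in seqs]
            sites = (SpliceSiteCoord("design", 1000, "donor", "+"),
                     SpliceSiteCoord("design", 2000, "acceptor", "+"),
                     SpliceSiteCoord("design", 2000 + max(W, 120),
                                     "donor", "+"),
                     SpliceSiteCoord("design", 4000, "acceptor", "+"))
            return CassetteEvent(event_id=f"design_seed{seed}",
                                 gene_id="design", sites=sites,
                                 windows=win_objs,
                                 alt_exon_sequence=None)
    raise RuntimeError("could not draw a qualifying design start event")
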