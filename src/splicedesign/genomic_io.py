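"""Reading the standard inputs and extracting strand-aware splice-site windows.

Coordinate conventions used throughout the package:

* all internal coordinates are 0-based, half-open;
* a splice-site coordinate is the index of the first intronic base of the
  junction on the reference strand;
* a window of width ``W`` places that anchor base at index ``W // 2`` of
  the sequence read 5'->3' on the transcribed strand.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

QUANT_COLUMNS = ["event_id", "contig", "strand", "c1_5ss", "alt_3ss",
                 "alt_5ss", "c2_3ss", "condition", "psi", "dpsi_vs",
                 "dpsi", "confidence"]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeIndex:
    """In-memory genome: contig name -> uppercase sequence over {A,C,G,T,N}."""

    contigs: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.contigs.items()}

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self.contigs.get(contig)
        if seq is None:
            raise KeyError(f"unknown contig {contig!r}")
        if start < 0 or end > len(seq) or start >= end:
            raise ValueError(
                f"range [{start},{end}) out of bounds for {contig} "
                f"(length {len(seq)})")
        return seq[start:end]


@dataclass(frozen=True)
class SpliceSiteCoord:
    contig: str
    position: int  # first intronic base of the junction (0-based)
    kind: Literal["donor", "acceptor"]
    strand: Literal["+", "-"]

    def __post_init__(self):
        if self.kind not in ("donor", "acceptor"):
            raise ValueError(f"bad site kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class Window:
    """Fixed-width sequence window on the transcribed strand.

    ``offset_of_site`` is the index of the splice-site anchor base;
    ``conservation`` (optional) is per-base, aligned to ``sequence``,
    with NaN marking missing scores.
    """

    sequence: str
    offset_of_site: int
    conservation: np.ndarray | None = None

    def __post_init__(self):
        if self.conservation is not None and \
                len(self.conservation) != len(self.sequence):
            raise ValueError("conservation length != window length")


@dataclass
class QuantRecord:
    event_id: str
    condition: str
    psi: float
    dpsi_vs: str | None = None
    dpsi: float | None = None
    confidence: float = 1.0
    read_support: bool = True

    def __post_init__(self):
        if not (0.0 <= self.psi <= 1.0):
            raise ValueError(f"psi {self.psi} outside [0,1] "
                             f"for {self.event_id}/{self.condition}")
        if self.dpsi is not None and abs(self.dpsi) > 1.0:
            raise ValueError(f"|dpsi| > 1 for {self.event_id}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence outside [0,1]")


def read_genome(path: str | Path) -> GenomeIndex:
    """Read a FASTA genome; duplicate headers and empty files are errors."""
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate FASTA header {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for contig {rec.id!r}")
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"contig {rec.id!r} contains non-ACGTN characters {bad}")
        contigs[rec.id] = seq
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeIndex(contigs)


def write_genome(genome: GenomeIndex, path: str | Path,
                 line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")


def extract_window(genome: GenomeIndex, site: SpliceSiteCoord,
                   width: int = 400,
                   conservation: dict[str, np.ndarray] | None = None
                   ) -> Window:
    """Extract the fixed-width window around a splice site.

    The window is read 5'->3' on the transcribed strand (reverse
    complemented for '-' sites) with the anchor base at index
    ``width // 2``.  Sites too close to a contig end are an error: no
    silent padding.
    """
    if width < 2:
        raise ValueError("width must be >= 2")
    half = width // 2
    if site.strand == "+":
        start, end = site.position - half, site.position + (width - half)
    else:
        start = site.position - (width - half) + 1
        end = site.position + half + 1
    contig_len = genome.lengths.get(site.contig)
    if contig_len is None:
        raise KeyError(f"unknown contig {site.contig!r}")
    if start < 0 or end > contig_len:
        raise ValueError(
            f"window [{start},{end}) for site at {site.contig}:"
            f"{site.position} extends past contig bounds; not padding")
    seq = genome.fetch(site.contig, start, end)
    cons = None
    if conservation is not None:
        track = conservation.get(site.contig)
        if track is not None:
            cons = np.array(track[start:end], dtype=float)
    if site.strand == "-":
        seq = revcomp(seq)
        if cons is not None:
            cons = cons[::-1].copy()
    return Window(sequence=seq, offset_of_site=half, conservation=cons)


def read_quant_table(path: str | Path | io.StringIO) -> list[QuantRecord]:
    """Read the event quantification TSV (one row per event x condition)."""
    df = pd.read_csv(path, sep="\t", dtype={"event_id": str,
                                            "condition": str,
                                            "dpsi_vs": str})
    missing = set(QUANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"quantification table missing columns {missing}")
    records = []
    psis: dict[tuple[str, str], float] = {}
    for row in df.itertuples(index=False):
        rec = QuantRecord(
            event_id=row.event_id,
            condition=row.condition,
            psi=float(row.psi),
            dpsi_vs=None if pd.isna(row.dpsi_vs) else str(row.dpsi_vs),
            dpsi=None if pd.isna(row.dpsi) else float(row.dpsi),
            confidence=1.0 if pd.isna(row.confidence)
            else float(row.confidence),
        )
        records.append(rec)
        psis[(rec.event_id, rec.condition)] = rec.psi
    # consistency: dpsi must equal psi_c - psi_c' when both psis present
    for rec in records:
        if rec.dpsi is None or rec.dpsi_vs is None:
            continue
        other = psis.get((rec.event_id, rec.dpsi_vs))
        if other is not None and abs(rec.dpsi - (rec.psi - other)) > 1e-6:
            raise ValueError(
                f"dpsi inconsistent with psi values for event "
                f"{rec.event_id} ({rec.condition} vs {rec.dpsi_vs})")
    return records


def write_quant_table(records: list[QuantRecord], events: pd.DataFrame,
                      path: str | Path) -> None:
    """Write records joined with per-event coordinates.

    ``events`` must carry columns event_id, contig, strand, c1_5ss,
    alt_3ss, alt_5ss, c2_3ss (one row per event).
    """
    ev = events.set_index("event_id")
    rows = []
    for rec in records:
        coords = ev.loc[rec.event_id]
        rows.append({
            "event_id": rec.event_id, "contig": coords["contig"],
            "strand": coords["strand"], "c1_5ss": coords["c1_5ss"],
            "alt_3ss": coords["alt_3ss"], "alt_5ss": coords["alt_5ss"],
            "c2_3ss": coords["c2_3ss"], "condition": rec.condition,
            "psi": rec.psi, "dpsi_vs": rec.dpsi_vs, "dpsi": rec.dpsi,
            "confidence": rec.confidence,
        })
    pd.DataFrame(rows, columns=QUANT_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_conservation(path: str | Path,
                      contig_lengths: dict[str, int]
                      ) -> dict[str, np.ndarray]:
    """Read a bedGraph conservation track into per-contig base arrays.

    Intervals must be sorted and non-overlapping per contig; bases not
    covered by any interval are NaN (missing).
    """
    arrays = {name: np.full(n, np.nan) for name, n in contig_lengths.items()}
    last_end: dict[str, int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"bad bedGraph line {line_no}: {line!r}")
            contig, start, end, value = (parts[0], int(parts[1]),
                                         int(parts[2]), float(parts[3]))
            if contig not in arrays:
                raise KeyError(f"bedGraph contig {contig!r} not in genome")
            if start < last_end.get(contig, 0):
                raise ValueError(
                    f"overlapping/unsorted bedGraph intervals on {contig} "
                    f"at line {line_no}")
            if end > contig_lengths[contig]:
                raise ValueError(f"interval past contig end at line {line_no}")
            arrays[contig][start:end] = value
            last_end[contig] = end
    return arrays


def write_conservation(tracks: dict[str, np.ndarray],
                       path: str | Path) -> None:
    """Write per-base arrays as a run-length-merged bedGraph."""
    with open(path, "w") as fh:
        for contig, arr in tracks.items():
            i, n = 0, len(arr)
            while i < n:
                if np.isnan(arr[i]):
                    i += 1
                    continue
                j = i + 1
                while j < n and not np.isnan(arr[j]) and arr[j] == arr[i]:
                    j += 1
                fh.write(f"{contig}\t{i}\t{j}\t{arr[i]:g}\n")
                i = j


GTF_COLUMNS = ["seqname", "feature", "start", "end", "strand",
               "transcript_id"]


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the simplified (GTF-lite) annotation.

    Columns: seqname, feature, start, end, strand, transcript_id with
    1-based inclusive GTF coordinates, converted on read to 0-based
    half-open.
    """
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=GTF_COLUMNS, header=0)
    missing = set(GTF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation missing columns {missing}")
    df = df.copy()
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ValueError("invalid annotation intervals")
    return df


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["start"] = out["start"].astype(int) + 1
    out[GTF_COLUMNS].to_csv(path, sep="\t", index=False)
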