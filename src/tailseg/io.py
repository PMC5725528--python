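"""Readers/writers for the formats the pipeline touches, plus the coordinate frame.

Internal convention, used everywhere in the package: coordinates are 0-based,
half-open.  Conversion to/from other conventions (GTF is 1-based inclusive,
BED is already 0-based half-open) happens only at file boundaries.

Transcript coordinates run 5'->3' in transcript orientation: position 0 of a
minus-strand transcript maps to the *highest* genomic position covered by its
exons.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("tailseg")

GTF_DIALECT = {
    "leading semicolon": False,
    "trailing semicolon": True,
    "quoted GFF2 values": True,
    "field separator": "; ",
    "keyval separator": " ",
    "multival separator": ",",
    "fmt": "gtf",
    "repeated keys": False,
    "order": ["gene_id", "transcript_id"],
}


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of one transcript in genomic and transcript coordinates.

    ``cds_end_tx`` is the transcript-coordinate offset one past the last coding
    base (i.e. the first 3'-UTR base); 0 means no annotated CDS, in which case
    the whole transcript is treated as 3'-UTR for window labelling.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_end_tx: int = 0

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if start >= end:
                raise ValueError(
                    f"{self.transcript_id}: empty/inverted exon ({start},{end})")
            if start < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons unsorted or overlapping")
            prev_end = end
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        if not 0 <= self.cds_end_tx <= self.length_tx:
            raise ValueError(
                f"{self.transcript_id}: cds_end_tx {self.cds_end_tx} outside "
                f"[0, {self.length_tx}]")

    @property
    def length_tx(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) of the whole transcript footprint."""
        return self.exons[0][0], self.exons[-1][1]

    def genomic_positions(self) -> np.ndarray:
        """Genomic coordinate of every transcript base, in 5'->3' order."""
        parts = [np.arange(s, e) for s, e in self.exons]
        pos = np.concatenate(parts)
        if self.strand == "-":
            pos = pos[::-1]
        return pos

    def tx_to_genomic(self, pos: int) -> int:
        """Map a transcript coordinate to its genomic coordinate."""
        if not 0 <= pos < self.length_tx:
            raise ValueError(f"transcript position {pos} out of range")
        if self.strand == "+":
            remaining = pos
            for s, e in self.exons:
                if remaining < e - s:
                    return s + remaining
                remaining -= e - s
        else:
            remaining = pos
            for s, e in reversed(self.exons):
                if remaining < e - s:
                    return e - 1 - remaining
                remaining -= e - s
        raise AssertionError("unreachable")

    def genomic_to_tx(self, gpos: int) -> int:
        """Map an exonic genomic coordinate to its transcript coordinate."""
        offset = 0
        if self.strand == "+":
            for s, e in self.exons:
                if s <= gpos < e:
                    return offset + (gpos - s)
                offset += e - s
        else:
            for s, e in reversed(self.exons):
                if s <= gpos < e:
                    return offset + (e - 1 - gpos)
                offset += e - s
        raise ValueError(f"genomic position {gpos} not exonic in "
                         f"{self.transcript_id}")

    def tx_interval_to_genomic(self, t0: int, t1: int) -> list[tuple[int, int]]:
        """Genomic intervals (0-based half-open, genomically sorted) covered by
        transcript interval [t0, t1)."""
        if not 0 <= t0 < t1 <= self.length_tx:
            raise ValueError(f"bad transcript interval [{t0},{t1})")
        pos = self.genomic_positions()[t0:t1]
        pos = np.sort(pos)
        breaks = np.where(np.diff(pos) != 1)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        return [(int(pos[s]), int(pos[e]) + 1) for s, e in zip(starts, ends)]


class GenomeCoverage:
    """Per-base coverage over an implicitly declared genome.

    Positions never written read back as 0.  Backed by one dense array per
    chromosome (adequate for the compact synthetic genomes and the per-locus
    slices this package works with).
    """

    def __init__(self, arrays: dict[str, np.ndarray] | None = None,
                 stranded: bool = False):
        self.arrays: dict[str, np.ndarray] = {}
        self.stranded = stranded
        if arrays:
            for chrom, arr in arrays.items():
                arr = np.asarray(arr, dtype=float)
                if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                    raise ValueError(f"{chrom}: coverage must be finite and >= 0")
                self.arrays[chrom] = arr

    def chroms(self) -> list[str]:
        return sorted(self.arrays)

    def add(self, chrom: str, start: int, values: np.ndarray) -> None:
        """Add ``values`` onto [start, start+len(values)) of ``chrom``."""
        values = np.asarray(values, dtype=float)
        end = start + len(values)
        cur = self.arrays.get(chrom)
        if cur is None or len(cur) < end:
            grown = np.zeros(end, dtype=float)
            if cur is not None:
                grown[: len(cur)] = cur
            self.arrays[chrom] = grown
        self.arrays[chrom][start:end] += values

    def get(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Coverage over [start, end); zeros where nothing was declared."""
        out = np.zeros(end - start, dtype=float)
        arr = self.arrays.get(chrom)
        if arr is None:
            return out
        lo, hi = max(start, 0), min(end, len(arr))
        if hi > lo:
            out[lo - start: hi - start] = arr[lo:hi]
        return out

    def to_bedgraph(self, path: str | os.PathLike) -> None:
        """Write non-zero runs as 4-column bedGraph (0-based half-open)."""
        with open(path, "w") as fh:
            for chrom in self.chroms():
                arr = self.arrays[chrom]
                if len(arr) == 0:
                    continue
                breaks = np.where(np.diff(arr) != 0)[0]
                starts = np.concatenate([[0], breaks + 1])
                ends = np.concatenate([breaks + 1, [len(arr)]])
                for s, e in zip(starts, ends):
                    v = arr[s]
                    if v != 0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")


def read_bedgraph(path: str | os.PathLike) -> GenomeCoverage:
    """Read a 4-column bedGraph into :class:`GenomeCoverage`.

    Overlapping records are summed; negative values are rejected.
    """
    cov = GenomeCoverage()
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    if (df["value"] < 0).any():
        raise ValueError(f"{path}: negative coverage values")
    for chrom, sub in df.groupby("chrom", sort=False):
        end = int(sub["end"].max())
        arr = np.zeros(end, dtype=float)
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            arr[int(s):int(e)] += v
        cov.add(chrom, 0, arr)
    return cov


def _cds_end_tx_from_intervals(strand: str, exons, cds_intervals,
                               tx: TranscriptModel) -> int:
    if not cds_intervals:
        return 0
    if strand == "+":
        last_base = max(e for _, e in cds_intervals) - 1
    else:
        last_base = min(s for s, _ in cds_intervals)
    return tx.genomic_to_tx(last_base) + 1


def _read_gtf(path) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, disable_infer_genes=True,
                            disable_infer_transcripts=True)
    exons: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as err:
            raise ValueError(f"{path}: feature missing {err} attribute")
        rec = exons.setdefault(tid, {"gene_id": gid, "chrom": feat.seqid,
                                     "strand": feat.strand, "exons": [],
                                     "cds": []})
        iv = (feat.start - 1, feat.end)  # GTF 1-based inclusive -> half-open
        rec["exons" if feat.featuretype == "exon" else "cds"].append(iv)
    models = []
    for tid, rec in exons.items():
        ivs = sorted(rec["exons"])
        try:
            tx = TranscriptModel(tid, rec["gene_id"], rec["chrom"],
                                 rec["strand"], tuple(ivs))
            cds_end = _cds_end_tx_from_intervals(rec["strand"], ivs,
                                                 rec["cds"], tx)
            if cds_end:
                tx = TranscriptModel(tid, rec["gene_id"], rec["chrom"],
                                     rec["strand"], tuple(ivs), cds_end)
        except ValueError as err:
            logger.warning("rejecting transcript %s: %s", tid, err)
            continue
        models.append(tx)
    return models


def _read_bed12(path) -> list[TranscriptModel]:
    cols = ["chrom", "start", "end", "name", "score", "strand", "thickStart",
            "thickEnd", "rgb", "blockCount", "blockSizes", "blockStarts"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols,
                     dtype={"chrom": str, "name": str})
    models = []
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        ivs = tuple((row.start + o, row.start + o + s)
                    for o, s in zip(offsets, sizes))
        name = row.name
        if not name or name == "nan":
            raise ValueError(f"{path}: BED12 record without a name")
        gene = name.rsplit("|", 1)[-1] if "|" in name else name
        tid = name.split("|", 1)[0]
        try:
            tx = TranscriptModel(tid, gene, row.chrom, row.strand, ivs)
            if row.thickEnd > row.thickStart:
                cds_end = _cds_end_tx_from_intervals(
                    row.strand, ivs, [(row.thickStart, row.thickEnd)], tx)
                tx = TranscriptModel(tid, gene, row.chrom, row.strand, ivs,
                                     cds_end)
        except ValueError as err:
            logger.warning("rejecting transcript %s: %s", name, err)
            continue
        models.append(tx)
    return models


def read_transcripts(path: str | os.PathLike) -> list[TranscriptModel]:
    """Read transcript models from a GTF (exon/CDS features) or BED12 file.

    Format is chosen by extension (.bed -> BED12, otherwise GTF).  Transcripts
    with unsorted or overlapping exons are rejected with a logged warning;
    missing identifiers raise.
    """
    if str(path).endswith(".bed"):
        return _read_bed12(path)
    return _read_gtf(path)


def write_transcripts_gtf(models: list[TranscriptModel],
                          path: str | os.PathLike) -> None:
    """Write transcript/exon/CDS features as GTF (1-based inclusive)."""
    with open(path, "w") as fh:
        for tx in models:
            attrs = (f'gene_id "{tx.gene_id}"; '
                     f'transcript_id "{tx.transcript_id}";')
            span = tx.span
            fh.write(f"{tx.chrom}\ttailseg\ttranscript\t{span[0] + 1}\t"
                     f"{span[1]}\t.\t{tx.strand}\t.\t{attrs}\n")
            for s, e in tx.exons:
                fh.write(f"{tx.chrom}\ttailseg\texon\t{s + 1}\t{e}\t.\t"
                         f"{tx.strand}\t.\t{attrs}\n")
            if tx.cds_end_tx > 0:
                for s, e in tx.tx_interval_to_genomic(0, tx.cds_end_tx):
                    fh.write(f"{tx.chrom}\ttailseg\tCDS\t{s + 1}\t{e}\t.\t"
                             f"{tx.strand}\t.\t{attrs}\n")


CALL_COLUMNS = [
    "transcript_id", "gene_id", "treatment", "k", "n_windows",
    "cleavage_tx", "cleavage_genomic", "loglik", "loglik_no_transition",
    "ks_D", "pvalue", "qvalue", "body_mean_dev", "tail_mean_dev",
]


def write_calls(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a cleavage-call table as TSV with fixed float precision.

    Floats are written with 12 significant digits so that a round trip
    preserves p-values.
    """
    table.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_calls(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"transcript_id": str,
                                              "gene_id": str})


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
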