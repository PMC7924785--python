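"""Readers and writers for the standard formats the pipeline touches.

GTF is the Ensembl dialect (exon / CDS / five_prime_utr / three_prime_utr
features, 1-based inclusive coordinates, ``gene_id``/``transcript_id``
attributes); annotation is normalized into transcript-coordinate
:class:`~decaylens.models.GeneModelSet` objects on read. bedGraph and BED
are 0-based half-open with chromosome names equal to transcript ids
(transcriptome coordinates).
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from decaylens.models import (
    CoverageTrack,
    CodonUsageTable,
    GeneModel,
    GeneModelSet,
    RegionMap,
    ValidationError,
)

__all__ = [
    "ParseError",
    "parse_gtf",
    "write_gtf",
    "select_longest_isoform",
    "load_codon_usage",
    "load_coverage",
    "load_reads_bed",
    "write_bed",
    "write_bedgraph",
    "read_cds_fasta",
    "write_fasta",
]


class ParseError(ValueError):
    """A file could not be parsed; carries the offending line number."""


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

_REGION_FEATURES = {
    "five_prime_utr": "utr5",
    "CDS": "cds",
    "three_prime_utr": "utr3",
}


def _parse_attributes(s: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(s))


def parse_gtf(path: str | Path) -> GeneModelSet:
    """Parse an Ensembl-style GTF into transcript-coordinate gene models.

    Per transcript, region lengths are the summed lengths of its
    five_prime_utr / CDS / three_prime_utr features; transcript coordinate 0
    is the biological 5' end on either strand (the feature types already
    name the biological region, so no strand flip is needed beyond
    validation). GTF coordinates are 1-based inclusive: a feature
    ``start=1 end=10`` spans internal interval [0, 10).

    Raises
    ------
    ParseError
        On a malformed line (with its line number).
    ValidationError
        If a transcript's region features overlap genomically, exon lengths
        disagree with region lengths, or a CDS length is not divisible by 3.
    """
    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = (
                fields
            )
            if feature not in _REGION_FEATURES and feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates {start!r}/{end!r}"
                ) from None
            if start_i < 1 or end_i < start_i:
                raise ParseError(
                    f"{path}:{lineno}: invalid coordinate range {start}-{end}"
                )
            attr = _parse_attributes(attrs)
            if "transcript_id" not in attr or "gene_id" not in attr:
                raise ParseError(
                    f"{path}:{lineno}: missing gene_id/transcript_id attribute"
                )
            rec = per_tx.setdefault(
                attr["transcript_id"],
                {
                    "gene_id": attr["gene_id"],
                    "chrom": chrom,
                    "strand": strand,
                    "exon": [],
                    "utr5": [],
                    "cds": [],
                    "utr3": [],
                    "start": start_i,
                },
            )
            if rec["strand"] != strand or rec["chrom"] != chrom:
                raise ValidationError(
                    f"transcript {attr['transcript_id']} mixes strands/chroms"
                )
            rec["start"] = min(rec["start"], start_i)
            # GTF [start, end] 1-based inclusive -> [start-1, end) half-open
            iv = (start_i - 1, end_i)
            key = _REGION_FEATURES.get(feature, "exon")
            rec[key].append(iv)

    entries = []
    for tx_id, rec in per_tx.items():
        region_ivs = sorted(rec["utr5"] + rec["cds"] + rec["utr3"])
        for (s1, e1), (s2, _e2) in zip(region_ivs, region_ivs[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"transcript {tx_id}: overlapping region features "
                    f"{(s1, e1)} and {(s2, _e2)}"
                )
        lengths = {
            k: sum(e - s for s, e in rec[k]) for k in ("utr5", "cds", "utr3")
        }
        exon_len = sum(e - s for s, e in rec["exon"])
        region_len = sum(lengths.values())
        if rec["exon"] and region_len and exon_len != region_len:
            raise ValidationError(
                f"transcript {tx_id}: exon length {exon_len} != "
                f"summed region length {region_len}"
            )
        if rec["exon"] and not region_len:
            # exon-only transcript (no annotated CDS/UTRs): length is kept
            # (metagene/full-length analyses still use it); has_cds stays
            # False so region/CAI analyses skip it
            lengths = {"utr5": exon_len, "cds": 0, "utr3": 0}
        entries.append(
            GeneModel(
                gene_id=rec["gene_id"],
                transcript_id=tx_id,
                regions=RegionMap.from_lengths(
                    lengths["utr5"], lengths["cds"], lengths["utr3"]
                ),
                strand=rec["strand"],
                chrom=rec["chrom"],
                genomic_start=rec["start"] - 1,
            )
        )
    entries.sort(key=lambda m: (m.gene_id, m.transcript_id))
    return GeneModelSet(entries)


def write_gtf(models: GeneModelSet, path: str | Path) -> None:
    """Write gene models as Ensembl-style GTF (1-based inclusive).

    Genomic placement: each transcript occupies ``[genomic_start,
    genomic_start + length)`` on its chromosome (defaults: chrom =
    transcript id, start 0). On the minus strand the 5'UTR sits at the high
    end of the genomic span, so a round-trip through :func:`parse_gtf`
    preserves region lengths and strand.
    """
    with open(path, "w") as fh:
        for m in models:
            chrom = m.chrom or m.transcript_id
            g0 = m.genomic_start or 0
            L = m.length
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            )

            def row(feature: str, s: int, e: int) -> str:
                # s, e are 0-based half-open genomic
                return (
                    f"{chrom}\tdecaylens\t{feature}\t{s + 1}\t{e}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )

            fh.write(row("exon", g0, g0 + L))
            if not m.has_cds:
                continue  # unpartitioned transcript: exon feature only
            for name, feature in (
                ("utr5", "five_prime_utr"),
                ("cds", "CDS"),
                ("utr3", "three_prime_utr"),
            ):
                ts, te = getattr(m.regions, name)
                if te == ts:
                    continue
                if m.strand == "+":
                    gs, ge = g0 + ts, g0 + te
                else:
                    gs, ge = g0 + L - te, g0 + L - ts
                fh.write(row(feature, gs, ge))


def select_longest_isoform(models: GeneModelSet) -> GeneModelSet:
    """Keep one transcript per gene: the longest; length ties broken by
    lexicographically smallest transcript id for determinism."""
    best: dict[str, GeneModel] = {}
    for m in models:
        cur = best.get(m.gene_id)
        if (
            cur is None
            or m.length > cur.length
            or (m.length == cur.length and m.transcript_id < cur.transcript_id)
        ):
            best[m.gene_id] = m
    kept = sorted(best.values(), key=lambda m: (m.gene_id, m.transcript_id))
    return GeneModelSet(kept)


def load_codon_usage(path: str | Path) -> CodonUsageTable:
    """Load a two-column codon/frequency TSV (Kazusa-style export).

    Accepts RNA (U) or DNA (T) codons, counts or per-thousand values
    (normalized internally), comment lines starting with '#', and an
    optional non-codon header line.
    """
    freq: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected codon and value")
            codon = parts[0].upper().replace("U", "T")
            if lineno == 1 and not re.fullmatch(r"[ACGT]{3}", codon):
                continue  # header
            if not re.fullmatch(r"[ACGT]{3}", codon):
                raise ParseError(f"{path}:{lineno}: invalid codon {parts[0]!r}")
            try:
                value = float(parts[1])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric frequency {parts[1]!r}"
                ) from None
            freq[codon] = value
    return CodonUsageTable(freq)


def write_codon_usage(table: CodonUsageTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("codon\tper_thousand\n")
        for codon, value in table.freq.items():
            fh.write(f"{codon}\t{value:.6f}\n")


def load_coverage(
    path: str | Path, models: GeneModelSet
) -> list[CoverageTrack]:
    """Read a transcriptome-coordinate bedGraph into dense depth arrays.

    Every model receives a track; positions not listed in the file have
    depth 0. A record reaching beyond its transcript's length is an error.
    """
    depth = {m.transcript_id: np.zeros(m.length) for m in models}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 bedGraph fields"
                )
            tx, start, end, value = (
                parts[0],
                int(parts[1]),
                int(parts[2]),
                float(parts[3]),
            )
            if tx not in depth:
                raise ValidationError(
                    f"{path}:{lineno}: unknown transcript {tx!r}"
                )
            if start < 0 or end > len(depth[tx]) or end <= start:
                raise ValidationError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside "
                    f"transcript {tx} (length {len(depth[tx])})"
                )
            depth[tx][start:end] += value
    return [CoverageTrack(m.transcript_id, depth[m.transcript_id]) for m in models]


def load_reads_bed(
    path: str | Path, models: GeneModelSet
) -> list[CoverageTrack]:
    """Read BED read intervals (transcriptome coordinates) into coverage
    tracks carrying both depth and the raw intervals."""
    reads: dict[str, list[tuple[int, int]]] = {
        m.transcript_id: [] for m in models
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED fields")
            tx, start, end = parts[0], int(parts[1]), int(parts[2])
            if tx not in reads:
                raise ValidationError(
                    f"{path}:{lineno}: unknown transcript {tx!r}"
                )
            length = models.get(tx).length
            if start < 0 or end > length or end <= start:
                raise ValidationError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside "
                    f"transcript {tx} (length {length})"
                )
            reads[tx].append((start, end))
    return [
        CoverageTrack.from_reads(m.transcript_id, m.length, reads[m.transcript_id])
        for m in models
    ]


def write_bed(
    reads_by_tx: Mapping[str, Sequence[tuple[int, int]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for tx, intervals in reads_by_tx.items():
            for i, (s, e) in enumerate(intervals):
                fh.write(f"{tx}\t{s}\t{e}\tread{i}\t0\t+\n")


def write_bedgraph(tracks: Iterable[CoverageTrack], path: str | Path) -> None:
    """Write tracks as bedGraph, run-length collapsing constant stretches
    and omitting zero-depth runs."""
    with open(path, "w") as fh:
        for t in tracks:
            d = t.depth
            if len(d) == 0:
                continue
            change = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(d)]))
            for s, e in zip(starts, ends):
                v = d[s]
                if v != 0:
                    fh.write(f"{t.transcript_id}\t{s}\t{e}\t{v:g}\n")


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    """CDS sequences keyed by transcript id (first word of the header)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")
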