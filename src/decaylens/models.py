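"""Core in-memory containers: gene models in transcript coordinates,
codon usage tables, and per-transcript coverage tracks.

All internal coordinates are 0-based half-open; conversion to/from the
1-based inclusive GTF convention happens only at format boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from Bio.Data.CodonTable import unambiguous_dna_by_id

_BASES = "ACGT"
ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
)

_STANDARD_TABLE = unambiguous_dna_by_id[1]
#: codon -> amino acid for the standard genetic code (id 1); stops map to "*".
STANDARD_GENETIC_CODE: dict[str, str] = {
    **{c: aa for c, aa in _STANDARD_TABLE.forward_table.items()},
    **{c: "*" for c in _STANDARD_TABLE.stop_codons},
}
STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)


class ValidationError(ValueError):
    """An input violated a structural invariant."""


@dataclass(frozen=True)
class RegionMap:
    """5'UTR / CDS / 3'UTR intervals of one transcript, in transcript
    coordinates (0-based half-open, 5' end at position 0).

    The three intervals are contiguous, ordered 5'UTR < CDS < 3'UTR, and
    together cover ``[0, transcript_length)``. A region may be empty
    (zero-length interval).
    """

    utr5: tuple[int, int]
    cds: tuple[int, int]
    utr3: tuple[int, int]

    def __post_init__(self) -> None:
        u5, cds, u3 = self.utr5, self.cds, self.utr3
        for name, (s, e) in (("utr5", u5), ("cds", cds), ("utr3", u3)):
            if s < 0 or e < s:
                raise ValidationError(f"{name} interval {s, e} is invalid")
        if not (u5[0] == 0 and u5[1] == cds[0] and cds[1] == u3[0]):
            raise ValidationError(
                f"regions not contiguous/ordered: {u5}, {cds}, {u3}"
            )
        cds_len = cds[1] - cds[0]
        if cds_len and cds_len % 3:
            raise ValidationError(f"CDS length {cds_len} not divisible by 3")

    @classmethod
    def from_lengths(cls, utr5: int, cds: int, utr3: int) -> "RegionMap":
        return cls((0, utr5), (utr5, utr5 + cds), (utr5 + cds, utr5 + cds + utr3))

    @property
    def transcript_length(self) -> int:
        return self.utr3[1]

    def length(self, region: str) -> int:
        s, e = getattr(self, region)
        return e - s

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {"utr5": self.utr5, "cds": self.cds, "utr3": self.utr3}


@dataclass(frozen=True)
class GeneModel:
    """One transcript of one gene, reduced to transcript coordinates."""

    gene_id: str
    transcript_id: str
    regions: RegionMap
    strand: str = "+"
    chrom: str | None = None
    genomic_start: int | None = None  # 0-based genomic start of the span

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.regions.transcript_length

    @property
    def has_cds(self) -> bool:
        return self.regions.length("cds") > 0


class GeneModelSet:
    """An ordered collection of gene models indexed by transcript id."""

    def __init__(self, entries: Sequence[GeneModel]):
        self.entries: list[GeneModel] = list(entries)
        self._by_tx: dict[str, GeneModel] = {}
        for m in self.entries:
            if m.transcript_id in self._by_tx:
                raise ValidationError(
                    f"duplicate transcript_id {m.transcript_id!r}"
                )
            self._by_tx[m.transcript_id] = m

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.entries)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_tx

    def get(self, transcript_id: str) -> GeneModel:
        return self._by_tx[transcript_id]

    def gene_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.entries:
            seen.setdefault(m.gene_id, None)
        return list(seen)

    def by_gene(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for m in self.entries:
            out.setdefault(m.gene_id, []).append(m)
        return out

    def transcript_of_gene(self) -> dict[str, str]:
        """gene_id -> transcript_id; requires one transcript per gene."""
        by_gene = self.by_gene()
        multi = [g for g, ms in by_gene.items() if len(ms) > 1]
        if multi:
            raise ValidationError(
                f"{len(multi)} genes have multiple isoforms; "
                "run select_longest_isoform first"
            )
        return {g: ms[0].transcript_id for g, ms in by_gene.items()}


class CodonUsageTable:
    """Per-codon usage frequencies plus the genetic code, supporting the
    relative-adaptiveness weights w(codon) = freq / max frequency within the
    codon's synonymous family.

    Frequencies may arrive as raw counts or per-thousand values; they are
    normalized internally to per-thousand, which leaves every w unchanged.
    """

    def __init__(
        self,
        freq: Mapping[str, float],
        genetic_code: Mapping[str, str] | None = None,
    ):
        code = dict(genetic_code) if genetic_code is not None else dict(
            STANDARD_GENETIC_CODE
        )
        freq = {k.upper().replace("U", "T"): float(v) for k, v in freq.items()}
        missing = [c for c in ALL_CODONS if c not in freq]
        if missing:
            raise ValidationError(
                f"codon usage table missing {len(missing)} codons "
                f"(first: {missing[0]})"
            )
        negative = [c for c, v in freq.items() if v < 0]
        if negative:
            raise ValidationError(f"negative frequency for codon {negative[0]}")
        total = sum(freq[c] for c in ALL_CODONS)
        if total <= 0:
            raise ValidationError("codon usage table sums to zero")
        self.freq: dict[str, float] = {
            c: 1000.0 * freq[c] / total for c in ALL_CODONS
        }
        self.genetic_code: dict[str, str] = code

    def families(self) -> dict[str, list[str]]:
        """Amino acid (or '*') -> list of synonymous codons."""
        fam: dict[str, list[str]] = {}
        for c in ALL_CODONS:
            fam.setdefault(self.genetic_code[c], []).append(c)
        return fam

    def family_max(self) -> dict[str, float]:
        return {
            aa: max(self.freq[c] for c in codons)
            for aa, codons in self.families().items()
        }

    def weights(self) -> dict[str, float]:
        """Relative adaptiveness w for every codon (0 for codons whose whole
        family is unused)."""
        fmax = self.family_max()
        return {
            c: (self.freq[c] / fmax[self.genetic_code[c]])
            if fmax[self.genetic_code[c]] > 0
            else 0.0
            for c in ALL_CODONS
        }


@dataclass
class CoverageTrack:
    """Positional read depth over one transcript, optionally backed by the
    read intervals that produced it."""

    transcript_id: str
    depth: np.ndarray
    reads: list[tuple[int, int]] | None = field(default=None)

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValidationError("depth must be 1-dimensional")
        if np.any(self.depth < 0):
            raise ValidationError(
                f"negative depth on transcript {self.transcript_id}"
            )
        if self.reads is not None:
            recomputed = self.__class__.depth_from_reads(
                len(self.depth), self.reads
            )
            if not np.allclose(self.depth, recomputed):
                raise ValidationError(
                    f"depth does not match read intervals on "
                    f"{self.transcript_id}"
                )

    @staticmethod
    def depth_from_reads(
        length: int, reads: Sequence[tuple[int, int]]
    ) -> np.ndarray:
        depth = np.zeros(length + 1)
        for s, e in reads:
            if s < 0 or e > length or e <= s:
                raise ValidationError(
                    f"read interval {(s, e)} outside [0, {length})"
                )
            depth[s] += 1
            depth[e] -= 1
        return np.cumsum(depth)[:length]

    @classmethod
    def from_reads(
        cls, transcript_id: str, length: int, reads: Sequence[tuple[int, int]]
    ) -> "CoverageTrack":
        reads = [tuple(r) for r in reads]
        return cls(transcript_id, cls.depth_from_reads(length, reads), reads)

    @property
    def length(self) -> int:
        return len(self.depth)

    @property
    def total(self) -> float:
        return float(self.depth.sum())
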