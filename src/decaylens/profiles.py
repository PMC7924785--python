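"""Metagene coverage profiles and gene-body region read densities.

Each transcript's coverage is rescaled onto 100 bins (fractional positions
weighted by proportional overlap) and normalized by its own mean depth, so
the metagene average is not dominated by highly expressed genes. Region
read densities are reads per nucleotide of 5'UTR / CDS / 3'UTR, with a
read that spans a region boundary counted once for every region it
overlaps; the mutant/WT density ratio per region is the 3'-bias statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from decaylens.models import (
    CoverageTrack,
    GeneModelSet,
    RegionMap,
    ValidationError,
)

__all__ = [
    "TrackSkipped",
    "MetageneProfile",
    "bin_profile",
    "average_tracks",
    "metagene",
    "count_reads_by_region",
    "region_density",
    "region_density_ratio",
    "compare_region_densities",
]

REGIONS = ("utr5", "cds", "utr3")


class TrackSkipped(ValueError):
    """A track is unusable for profiling (too short or zero coverage)."""


@dataclass
class MetageneProfile:
    set_id: str
    genotype: str
    values: np.ndarray
    n_genes: int
    n_skipped: int
    normalization: str = "per-transcript mean depth; unweighted gene mean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def bin_profile(
    track: CoverageTrack,
    n_bins: int = 100,
    min_length: int = 100,
    normalize: bool = True,
) -> np.ndarray:
    """Rescale one transcript's depth onto ``n_bins`` equal-width bins.

    Bin boundaries fall at fractional positions; a position overlapping two
    bins contributes to each in proportion to the overlap, so
    sum(bins) * (L / n_bins) conserves the total coverage exactly. With
    ``normalize`` the track is first divided by its mean depth (a flat
    track maps to all ones).

    Raises :class:`TrackSkipped` for transcripts shorter than
    ``min_length`` or with zero total coverage (excluded, never
    zero-filled).
    """
    length = track.length
    if length < min_length:
        raise TrackSkipped(
            f"{track.transcript_id}: length {length} < {min_length}"
        )
    depth = track.depth
    mean = depth.mean()
    if normalize:
        if mean == 0:
            raise TrackSkipped(f"{track.transcript_id}: zero coverage")
        depth = depth / mean
    # integral of piecewise-constant depth via its cumulative sum,
    # evaluated at fractional bin edges
    cum = np.concatenate(([0.0], np.cumsum(depth)))
    edges = np.linspace(0.0, length, n_bins + 1)
    integrals = np.diff(np.interp(edges, np.arange(length + 1), cum))
    return integrals / (length / n_bins)


def average_tracks(replicates: Sequence[CoverageTrack]) -> CoverageTrack:
    """Average replicate coverage of one transcript position-wise."""
    if not replicates:
        raise ValidationError("no replicate tracks given")
    tx = {t.transcript_id for t in replicates}
    lengths = {t.length for t in replicates}
    if len(tx) > 1 or len(lengths) > 1:
        raise ValidationError("replicate tracks disagree in id or length")
    depth = np.mean([t.depth for t in replicates], axis=0)
    return CoverageTrack(replicates[0].transcript_id, depth)


def metagene(
    gene_set: Sequence[str],
    tracks_by_genotype: Mapping[str, Sequence[Mapping[str, CoverageTrack]]],
    n_bins: int = 100,
    min_length: int = 100,
    set_id: str = "genes",
) -> dict[str, MetageneProfile]:
    """Metagene profile of a gene (transcript-id) set per genotype.

    ``tracks_by_genotype`` maps genotype -> list of replicate track dicts
    (transcript id -> CoverageTrack). Replicates are averaged at the
    coverage level, each usable transcript is binned and mean-normalized,
    and the per-gene bin vectors are averaged unweighted.
    """
    out: dict[str, MetageneProfile] = {}
    for genotype, replicate_maps in tracks_by_genotype.items():
        profiles = []
        skipped = 0
        for tx in gene_set:
            reps = [m[tx] for m in replicate_maps if tx in m]
            if not reps:
                skipped += 1
                continue
            track = average_tracks(reps)
            try:
                profiles.append(
                    bin_profile(track, n_bins=n_bins, min_length=min_length)
                )
            except TrackSkipped:
                skipped += 1
        if not profiles:
            raise ValidationError(
                f"no usable transcripts for genotype {genotype!r}"
            )
        out[genotype] = MetageneProfile(
            set_id=set_id,
            genotype=genotype,
            values=np.mean(profiles, axis=0),
            n_genes=len(profiles),
            n_skipped=skipped,
        )
    return out


def count_reads_by_region(
    reads: Sequence[tuple[int, int]], regions: RegionMap
) -> dict[str, int]:
    """Count reads per gene-body region; a read overlapping two regions by
    at least one nucleotide is counted for both of them."""
    counts = dict.fromkeys(REGIONS, 0)
    for s, e in reads:
        for name in REGIONS:
            rs, re_ = getattr(regions, name)
            if max(s, rs) < min(e, re_):
                counts[name] += 1
    return counts


def region_density(
    tracks: Mapping[str, CoverageTrack],
    models: GeneModelSet,
) -> pd.DataFrame:
    """Per-gene read counts and densities (reads/length) for each region.

    Uses the read intervals attached to each track; transcripts without an
    annotated CDS are skipped, zero-length regions yield NaN density.
    Returns a frame indexed by gene id with columns reads_<region> and
    density_<region>.
    """
    tx_of_gene = models.transcript_of_gene()
    rows = {}
    for gene, tx in tx_of_gene.items():
        model = models.get(tx)
        if not model.has_cds or tx not in tracks:
            continue
        track = tracks[tx]
        if track.reads is None:
            raise ValidationError(
                f"track {tx} carries no read intervals; densities need reads"
            )
        counts = count_reads_by_region(track.reads, model.regions)
        row = {}
        for name in REGIONS:
            length = model.regions.length(name)
            row[f"reads_{name}"] = counts[name]
            row[f"density_{name}"] = (
                counts[name] / length if length > 0 else np.nan
            )
        rows[gene] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def region_density_ratio(
    table_wt: pd.DataFrame, table_mut: pd.DataFrame
) -> pd.DataFrame:
    """Mutant/WT density ratio per gene per region.

    Exclusion rules: if both densities are zero the ratio is not considered;
    if only the WT density is zero the ratio is undefined and excluded as
    well, but tallied separately (``exclusion`` column distinguishes
    'both_zero' from 'wt_zero'). Zero-length regions (NaN density) are
    skipped.
    """
    genes = table_wt.index.intersection(table_mut.index)
    records = []
    for gene in genes:
        for name in REGIONS:
            dw = table_wt.at[gene, f"density_{name}"]
            dm = table_mut.at[gene, f"density_{name}"]
            if np.isnan(dw) or np.isnan(dm):
                continue
            if dw == 0 and dm == 0:
                records.append((gene, name, dw, dm, np.nan, "both_zero"))
            elif dw == 0:
                records.append((gene, name, dw, dm, np.nan, "wt_zero"))
            else:
                records.append((gene, name, dw, dm, dm / dw, ""))
    return pd.DataFrame(
        records,
        columns=["gene", "region", "density_wt", "density_mut", "ratio", "exclusion"],
    )


def compare_region_densities(
    densities_wt: np.ndarray,
    densities_mut: np.ndarray,
    min_genes: int = 3,
) -> tuple[float, float]:
    """Two-sided unpaired Wilcoxon rank-sum test of per-gene region
    densities, mutant vs. WT. Returns (U statistic, p); (nan, nan) when
    fewer than ``min_genes`` defined values are available in either group."""
    x = np.asarray(densities_wt, dtype=float)
    y = np.asarray(densities_mut, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < min_genes or len(y) < min_genes:
        return float("nan"), float("nan")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # degenerate: every value tied
        return float(len(x) * len(y) / 2), 1.0
    res = stats.mannwhitneyu(
        y, x, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))
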