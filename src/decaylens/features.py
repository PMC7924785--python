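"""Transcript-feature analyses: region lengths, codon adaptation index
(CAI) with a random-sequence background, and expression-level comparison
of DEG classes.

CAI follows the classical Sharp & Li definition: the geometric mean (in
log space) of the relative adaptiveness w = freq / max synonymous-family
frequency over the scored codons of a CDS. Stop codons and the
single-codon families (ATG/Met, TGG/Trp) are excluded from scoring by
default, as are codons containing ambiguous bases; exclusions are
configurable and reported per gene.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from decaylens.models import (
    CodonUsageTable,
    GeneModelSet,
    STOP_CODONS,
    ValidationError,
)

__all__ = [
    "CAIResult",
    "region_lengths",
    "ks_compare",
    "cai",
    "cai_table",
    "cai_background",
    "expression_level_compare",
]

#: codons excluded from CAI scoring by default: stops plus the two
#: single-codon families, whose w is 1 by construction.
DEFAULT_CAI_EXCLUSIONS: frozenset[str] = STOP_CODONS | {"ATG", "TGG"}


@dataclass
class CAIResult:
    cai: float
    n_scored: int
    n_excluded: int
    n_floored: int = 0  # scored codons whose zero w was floored


def region_lengths(models: GeneModelSet) -> pd.DataFrame:
    """Per-gene lengths of the full transcript and each region, from
    longest-isoform models. Genes missing a UTR or CDS annotation carry a
    zero length there and are flagged ``incomplete``."""
    tx_of_gene = models.transcript_of_gene()
    rows = {}
    for gene, tx in tx_of_gene.items():
        r = models.get(tx).regions
        u5, cds, u3 = (r.length(n) for n in ("utr5", "cds", "utr3"))
        rows[gene] = {
            "transcript": tx,
            "full": u5 + cds + u3,
            "utr5": u5,
            "cds": cds,
            "utr3": u3,
            "incomplete": (u5 == 0) or (cds == 0) or (u3 == 0),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def ks_compare(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test; returns (D, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValidationError("KS comparison needs >= 3 values per sample")
    res = stats.ks_2samp(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def cai(
    cds_sequence: str,
    usage: CodonUsageTable,
    exclusions: frozenset[str] = DEFAULT_CAI_EXCLUSIONS,
    zero_weight_floor: float | None = None,
) -> CAIResult:
    """Codon adaptation index of one CDS.

    Codons in ``exclusions`` or containing non-ACGT characters are excluded
    from scoring (and counted). A scored codon with zero usage frequency
    would make ln w infinite; its w is floored at ``zero_weight_floor``
    (default: the w of a half-count, 0.5 / family maximum frequency) and
    tallied in ``n_floored``.
    """
    seq = cds_sequence.upper().replace("U", "T")
    if len(seq) % 3:
        raise ValidationError(
            f"CDS length {len(seq)} not divisible by 3"
        )
    weights = usage.weights()
    fmax = usage.family_max()
    code = usage.genetic_code
    log_sum = 0.0
    n_scored = 0
    n_excluded = 0
    n_floored = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon not in weights or codon in exclusions:
            n_excluded += 1
            continue
        w = weights[codon]
        if w == 0:
            floor = (
                zero_weight_floor
                if zero_weight_floor is not None
                else 0.5 / fmax[code[codon]]
                if fmax[code[codon]] > 0
                else None
            )
            if floor is None:
                n_excluded += 1
                continue
            w = floor
            n_floored += 1
        log_sum += math.log(w)
        n_scored += 1
    if n_scored == 0:
        raise ValidationError("no scorable codons in sequence")
    return CAIResult(
        cai=math.exp(log_sum / n_scored),
        n_scored=n_scored,
        n_excluded=n_excluded,
        n_floored=n_floored,
    )


def cai_table(
    seqs: Mapping[str, str],
    usage: CodonUsageTable,
    **kwargs,
) -> pd.DataFrame:
    """CAI for every sequence; indexed by sequence id."""
    rows = {}
    for name, seq in seqs.items():
        res = cai(seq, usage, **kwargs)
        rows[name] = {
            "cai": res.cai,
            "n_scored": res.n_scored,
            "n_excluded": res.n_excluded,
            "n_floored": res.n_floored,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def cai_background(
    usage: CodonUsageTable,
    group_size: int,
    mean_cds_codons: int,
    seed: int | np.random.Generator | None = None,
    large_group_n: int = 500,
    large_group_threshold: int = 1000,
) -> np.ndarray:
    """CAI distribution of random coding sequences drawn from the usage
    table, the control the study computes per compared group.

    The number of random sequences equals the group size, or
    ``large_group_n`` (500) if the group exceeds ``large_group_threshold``
    (1000); each sequence has ``mean_cds_codons`` codons drawn with
    probability proportional to usage frequency, stop codons excluded so
    the scored length is exact.
    """
    if group_size < 1 or mean_cds_codons < 1:
        raise ValidationError("group size and codon count must be positive")
    n = group_size if group_size <= large_group_threshold else large_group_n
    rng = np.random.default_rng(seed)
    sense = [c for c in usage.freq if c not in STOP_CODONS]
    p = np.array([usage.freq[c] for c in sense])
    p = p / p.sum()
    out = np.empty(n)
    for i in range(n):
        codons = rng.choice(len(sense), size=mean_cds_codons, p=p)
        seq = "".join(sense[j] for j in codons)
        out[i] = cai(seq, usage).cai
    return out


def expression_level_compare(
    tpm_wt: pd.Series,
    classes: pd.Series,
    stage: str | None = None,
    min_group: int = 2,
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of wild-type expression (TPM) of the
    up- and down-regulated classes against unchanged genes.

    ``classes`` maps gene -> class at one stage. Returns one row per
    comparison with medians, group sizes, U and p; classes smaller than
    ``min_group`` are skipped with a note.
    """
    rows = []
    unchanged = tpm_wt.reindex(
        classes.index[classes == "unchanged"]
    ).dropna()
    for direction in ("up", "down"):
        group = tpm_wt.reindex(classes.index[classes == direction]).dropna()
        note = ""
        if len(group) < min_group or len(unchanged) < min_group:
            statistic, pvalue = np.nan, np.nan
            note = "group too small; comparison skipped"
        else:
            res = stats.mannwhitneyu(
                group.to_numpy(), unchanged.to_numpy(), alternative="two-sided"
            )
            statistic, pvalue = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "stage": stage,
                "comparison": f"{direction}_vs_unchanged",
                "n_group": len(group),
                "n_unchanged": len(unchanged),
                "median_group": float(group.median()) if len(group) else np.nan,
                "median_unchanged": (
                    float(unchanged.median()) if len(unchanged) else np.nan
                ),
                "statistic": statistic,
                "pvalue": pvalue,
                "note": note,
            }
        )
    return pd.DataFrame(rows)
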