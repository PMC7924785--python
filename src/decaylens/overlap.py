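"""DEG-set overlap analysis against expression-matched resampled nulls.

The question answered here: do the DEG sets of two stages (or periods)
share more genes than expected for gene sets with the same wild-type
expression profile? Controls are drawn from unchanged genes, matched to
the DEG set's WT-expression distribution by quantile binning, and the
observed intersection is compared to the resampled intersections both by
a Yates-corrected chi-squared test on proportions (the study's construction)
and by an empirical resampling quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from decaylens.models import ValidationError

__all__ = [
    "MatchedControlSet",
    "OverlapResult",
    "shared_degs",
    "shared_period_degs",
    "sample_expression_matched",
    "overlap_chisq",
    "overlap_significance",
    "expression_breadth",
    "cross_period_status",
]


@dataclass
class MatchedControlSet:
    """One resampled control set matched to a DEG set's expression bins."""

    source_id: str
    control_genes: list[str]
    bin_of_gene: dict[str, int]
    fallback_moves: int = 0


@dataclass
class OverlapResult:
    set_a: str
    set_b: str
    observed_shared: int
    observed_fraction: float
    control_shared: np.ndarray
    chisq: float
    pvalue: float
    quantile: float
    quantile_randomized: float
    n_resamples: int
    seed: int | None = None
    notes: list[str] = field(default_factory=list)


def shared_degs(
    sets: Mapping[str, set], max_order: int | None = None
) -> dict[tuple[str, ...], int]:
    """Exact intersection cardinalities for every combination of >= 2 of
    the given gene sets (up to ``max_order``-way if given)."""
    names = list(sets)
    if len(names) < 2:
        raise ValidationError("need at least 2 sets")
    top = max_order or len(names)
    out: dict[tuple[str, ...], int] = {}
    for k in range(2, top + 1):
        for combo in combinations(names, k):
            inter = set(sets[combo[0]])
            for name in combo[1:]:
                inter &= set(sets[name])
            out[combo] = len(inter)
    return out


def shared_period_degs(
    deg: pd.DataFrame, period: str, direction: str
) -> set[str]:
    """Genes classified ``direction`` ('up' or 'down') at every stage of the
    period — the study's 'shared period DEGs', its most confident target set."""
    sub = deg[deg["period"] == period]
    stages = list(dict.fromkeys(sub["stage"]))
    if not stages:
        raise ValidationError(f"no stages found for period {period!r}")
    per_stage = [
        set(sub.loc[(sub["stage"] == s) & (sub["cls"] == direction), "gene"])
        for s in stages
    ]
    shared = per_stage[0]
    for s in per_stage[1:]:
        shared &= s
    return shared


def sample_expression_matched(
    deg_set: set[str] | Sequence[str],
    pool: set[str] | Sequence[str],
    expr: pd.Series,
    n_bins: int = 20,
    rng: np.random.Generator | int | None = None,
    source_id: str = "deg",
) -> MatchedControlSet:
    """Sample one control gene per DEG from ``pool`` (unchanged genes),
    matching the DEG set's expression distribution.

    Genes are binned by quantiles of ``expr`` (WT expression) computed over
    ``deg_set | pool``; for each DEG one control is drawn uniformly without
    replacement from the same bin. An exhausted bin falls back to the
    nearest bin with remaining pool genes; each such move is recorded.
    """
    deg_list = sorted(set(deg_set))
    pool_list = sorted(set(pool))
    if set(deg_list) & set(pool_list):
        raise ValidationError("control pool overlaps the DEG set")
    if len(pool_list) < len(deg_list):
        raise ValidationError(
            f"pool ({len(pool_list)}) smaller than DEG set ({len(deg_list)})"
        )
    rng = np.random.default_rng(rng)
    all_genes = deg_list + pool_list
    values = expr.reindex(all_genes)
    if values.isna().any():
        raise ValidationError("expression missing for some genes")
    edges = np.quantile(
        values.to_numpy(), np.linspace(0, 1, n_bins + 1)[1:-1]
    )
    bins = np.searchsorted(edges, values.to_numpy(), side="right")
    bin_of = dict(zip(all_genes, bins.tolist()))

    remaining: dict[int, list[str]] = {}
    for g in pool_list:
        remaining.setdefault(bin_of[g], []).append(g)
    for b in remaining:
        rng.shuffle(remaining[b])

    controls: list[str] = []
    moves = 0
    for g in deg_list:
        b = bin_of[g]
        if not remaining.get(b):
            nonempty = [bb for bb, lst in remaining.items() if lst]
            b_new = min(nonempty, key=lambda bb: (abs(bb - b), bb))
            moves += 1
            b = b_new
        controls.append(remaining[b].pop())
    return MatchedControlSet(
        source_id=source_id,
        control_genes=controls,
        bin_of_gene=bin_of,
        fallback_moves=moves,
    )


def overlap_chisq(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson chi-squared with Yates continuity correction on a 2x2 table.

    chi2 = N (max(0, |ad - bc| - N/2))^2 / ((a+b)(c+d)(a+c)(b+d)), compared
    to the chi-squared distribution with 1 df.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValidationError("table must hold non-negative integers")
    (a, b), (c, d) = t
    n = t.sum()
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValidationError("chi-squared undefined: zero margin")
    num = n * max(0.0, abs(a * d - b * c) - n / 2) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    chisq = num / den
    return float(chisq), float(stats.chi2.sf(chisq, df=1))


def overlap_significance(
    deg_set_a: set[str] | Sequence[str],
    deg_set_b: set[str] | Sequence[str],
    pool: set[str] | Sequence[str],
    expr: pd.Series,
    n_resamples: int = 100,
    seed: int | None = None,
    n_bins: int = 20,
    set_a_id: str = "A",
    set_b_id: str = "B",
) -> OverlapResult:
    """Test whether |A intersect B| exceeds the sharing of expression-matched
    control sets drawn in place of A.

    For each resample, a matched control set A' is drawn from ``pool`` and
    |A' intersect B| recorded. The chi-squared test compares the observed
    shared proportion against the mean control proportion (rounded); the
    empirical quantile of the observed count among the control counts is
    reported both as a deterministic mid-quantile and as a randomized PIT
    quantile (exactly uniform under exchangeability), which is the one to
    use for calibration checks. If both the observed and mean control
    counts are zero the chi-squared test is undefined and reported as
    (0, 1) with a note.
    """
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")
    a = set(deg_set_a)
    b = set(deg_set_b)
    rng = np.random.default_rng(seed)
    observed = len(a & b)
    control_shared = np.empty(n_resamples, dtype=int)
    for i in range(n_resamples):
        ctrl = sample_expression_matched(
            a, pool, expr, n_bins=n_bins, rng=rng, source_id=set_a_id
        )
        control_shared[i] = len(set(ctrl.control_genes) & b)

    notes: list[str] = []
    mean_ctrl = int(round(control_shared.mean()))
    table = [
        [observed, len(a) - observed],
        [mean_ctrl, len(a) - mean_ctrl],
    ]
    try:
        chisq, pvalue = overlap_chisq(table)
    except ValidationError as err:
        chisq, pvalue = 0.0, 1.0
        notes.append(str(err))

    less = int((control_shared < observed).sum())
    equal = int((control_shared == observed).sum())
    quantile = (less + 0.5 * equal) / n_resamples
    quantile_randomized = (less + rng.uniform() * (equal + 1)) / (
        n_resamples + 1
    )
    return OverlapResult(
        set_a=set_a_id,
        set_b=set_b_id,
        observed_shared=observed,
        observed_fraction=observed / len(a) if a else 0.0,
        control_shared=control_shared,
        chisq=chisq,
        pvalue=pvalue,
        quantile=quantile,
        quantile_randomized=quantile_randomized,
        n_resamples=n_resamples,
        seed=seed,
        notes=notes,
    )


def expression_breadth(
    gene: str, expressed_sets: Mapping[str, set[str]]
) -> tuple[int, list[str]]:
    """Number (and list) of periods in which the gene passes the expression
    filter. Breadth 0 flags a gene never identified as expressed."""
    periods = [p for p, s in expressed_sets.items() if gene in s]
    return len(periods), periods


def cross_period_status(
    deg: pd.DataFrame, gene: str, home_period: str, other_period: str
) -> str:
    """Class of a ``home_period`` DEG when looked up in ``other_period``.

    Precedence across the other period's stages: DEG (up/down) at any stage
    beats unchanged at any stage beats other; a gene filtered at every
    stage is 'untested'. Conservative toward calling regulation.
    """
    home = deg[(deg["period"] == home_period) & (deg["gene"] == gene)]
    if not (home["cls"].isin(["up", "down"])).any():
        raise ValidationError(
            f"{gene} is not a DEG in period {home_period!r}"
        )
    rows = deg[(deg["period"] == other_period) & (deg["gene"] == gene)]
    if rows.empty:
        return "untested"
    classes = set(rows["cls"])
    if classes & {"up", "down"}:
        return "DEG"
    if "unchanged" in classes:
        return "unchanged"
    if classes == {"filtered"}:
        return "untested"
    return "other"
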