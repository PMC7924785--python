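"""Differential expression calling and classification.

Raw counts from a genotype (WT vs. mutant) x period x stage x replicate
design are library-size normalized, filtered on expression (>= 10 cpm in
>= 3 libraries of a period), tested per stage with a simplified
negative-binomial exact test (the d -> 0 limit is the conditional binomial
test), BH-adjusted, and classified into the study's categories:

* ``up``       FDR < 0.05 and fold change (mutant/WT) > 1
* ``down``     FDR < 0.05 and fold change < 1
* ``unchanged``  FDR > 0.05 and 0.8 < fold change < 1.2
* ``other``    tested but in neither category
* ``filtered`` failed the expression filter

Periods are analyzed separately; each stage contributes one WT-vs-mutant
contrast. PCA of log2(cpm+1)-transformed samples on the 1000 most variable
genes provides the sample-level embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from decaylens.models import ValidationError

__all__ = [
    "CountMatrix",
    "cpm",
    "tpm",
    "filter_expressed",
    "estimate_common_dispersion",
    "nb_test",
    "bh_adjust",
    "classify_genes",
    "de_analysis",
    "pca_embed",
    "load_de_table",
    "write_de_table",
]

DESIGN_COLUMNS = ("genotype", "period", "stage", "replicate")

DEG_CLASSES = ("up", "down", "unchanged", "other", "filtered")


@dataclass
class CountMatrix:
    """Genes x samples integer counts plus the sample design.

    ``design`` is indexed by sample id with columns genotype / period /
    stage / replicate; its index must match the count columns exactly.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.design.index):
            raise ValidationError("count columns and design index differ")
        missing = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing:
            raise ValidationError(f"design lacks columns {missing}")
        if self.design[list(DESIGN_COLUMNS)].isna().any().any():
            raise ValidationError("design contains missing factor levels")
        values = self.counts.to_numpy()
        if (values < 0).any():
            raise ValidationError("negative counts")
        if not np.allclose(values, np.round(values)):
            raise ValidationError("non-integer counts")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_of(self, **factors) -> list[str]:
        mask = pd.Series(True, index=self.design.index)
        for key, value in factors.items():
            mask &= self.design[key] == value
        return list(self.design.index[mask])

    def periods(self) -> list[str]:
        return list(dict.fromkeys(self.design["period"]))

    def stages_of(self, period: str) -> list[str]:
        sub = self.design[self.design["period"] == period]
        return list(dict.fromkeys(sub["stage"]))


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: scale each column to sum 10^6."""
    lib = counts.sum(axis=0)
    zero = lib.index[lib == 0]
    if len(zero):
        raise ValidationError(f"zero library size for sample {zero[0]!r}")
    return counts.div(lib, axis=1) * 1e6


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates rescaled so each
    column sums to 10^6. Genes without a length are dropped with a warning."""
    missing = counts.index.difference(lengths.index)
    if len(missing):
        warnings.warn(
            f"dropping {len(missing)} genes without a length "
            f"(first: {missing[0]})"
        )
        counts = counts.drop(index=missing)
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValidationError("non-positive transcript length")
    rate = counts.div(lengths, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def filter_expressed(
    cm: CountMatrix,
    period: str,
    min_cpm: float = 10.0,
    min_libraries: int = 3,
) -> pd.Index:
    """Genes with >= ``min_cpm`` in >= ``min_libraries`` of the period's
    libraries (pooled across genotypes and stages of that period)."""
    samples = cm.samples_of(period=period)
    if len(samples) < min_libraries:
        raise ValidationError(
            f"period {period!r} has {len(samples)} libraries, "
            f"need >= {min_libraries}"
        )
    period_cpm = cpm(cm.counts)[samples]
    passing = (period_cpm >= min_cpm).sum(axis=1) >= min_libraries
    return cm.genes[passing]


def estimate_common_dispersion(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    lib_a: np.ndarray,
    lib_b: np.ndarray,
    min_mean: float = 1.0,
) -> float:
    """Method-of-moments common NB dispersion across genes.

    Counts are scaled to a common effective library size; with
    Var = mu + d mu^2, d is estimated as sum_g (v_g - m_g) / sum_g m_g^2
    over within-group moments (ratio of sums, for stability at n = 3),
    floored at 0.
    """
    common = float(np.exp(np.mean(np.log(np.concatenate([lib_a, lib_b])))))
    num = 0.0
    den = 0.0
    for counts, lib in ((counts_a, lib_a), (counts_b, lib_b)):
        if counts.shape[1] < 2:
            continue
        z = counts * (common / lib)[None, :]
        m = z.mean(axis=1)
        v = z.var(axis=1, ddof=1)
        use = m >= min_mean
        num += float((v[use] - m[use]).sum())
        den += float((m[use] ** 2).sum())
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def _conditional_pmf(
    total: int, n_a: int, n_b: int, dispersion: float
) -> np.ndarray:
    """pmf of the group-A normalized sum conditioned on the total under the
    null of a common per-replicate mean."""
    k = np.arange(total + 1)
    if dispersion <= 1e-10:
        # Poisson limit: conditional distribution is binomial
        return stats.binom.pmf(k, total, n_a / (n_a + n_b))
    mu = total / (n_a + n_b)
    r_a, r_b = n_a / dispersion, n_b / dispersion
    m_a, m_b = n_a * mu, n_b * mu
    p_a = r_a / (r_a + m_a)
    p_b = r_b / (r_b + m_b)
    logf = stats.nbinom.logpmf(k, r_a, p_a) + stats.nbinom.logpmf(
        total - k, r_b, p_b
    )
    return np.exp(logf - logsumexp(logf))


def nb_test(
    counts_wt: np.ndarray,
    counts_mut: np.ndarray,
    lib_wt: np.ndarray,
    lib_mut: np.ndarray,
    dispersion: float = 0.0,
    pseudocount: float = 0.5,
) -> tuple[float, float]:
    """Simplified NB exact test of mutant vs. WT replicate counts.

    Counts are scaled to a common effective library size (geometric mean),
    summed per group, and the WT sum is tested against its conditional null
    distribution given the total (NB with per-group dispersion d/n; the
    d = 0 limit is binomial). Two-sided p sums all outcomes with
    probability mass <= that of the observation (minimum-likelihood rule).

    Returns ``(log2FC, p)`` with FC = mutant/WT computed from per-replicate
    normalized group means with a pseudocount of 0.5 on each mean.
    """
    counts_wt = np.asarray(counts_wt, dtype=float)
    counts_mut = np.asarray(counts_mut, dtype=float)
    lib_wt = np.asarray(lib_wt, dtype=float)
    lib_mut = np.asarray(lib_mut, dtype=float)
    if counts_wt.size < 1 or counts_mut.size < 1:
        raise ValidationError("each group needs at least one replicate")
    common = float(np.exp(np.mean(np.log(np.concatenate([lib_wt, lib_mut])))))
    z_wt = counts_wt * (common / lib_wt)
    z_mut = counts_mut * (common / lib_mut)
    n_wt, n_mut = counts_wt.size, counts_mut.size
    mean_wt = z_wt.sum() / n_wt
    mean_mut = z_mut.sum() / n_mut
    log2fc = float(
        np.log2((mean_mut + pseudocount) / (mean_wt + pseudocount))
    )

    sum_wt = int(round(z_wt.sum()))
    sum_mut = int(round(z_mut.sum()))
    total = sum_wt + sum_mut
    if total == 0:
        return 0.0, 1.0
    f = _conditional_pmf(total, n_wt, n_mut, dispersion)
    f_obs = f[sum_wt]
    p = float(f[f <= f_obs * (1 + 1e-12)].sum())
    return log2fc, min(p, 1.0)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR with enforced monotonicity."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def classify_genes(
    fdr: np.ndarray,
    fc: np.ndarray,
    fdr_threshold: float = 0.05,
    unchanged_window: tuple[float, float] = (0.8, 1.2),
) -> np.ndarray:
    """Assign the study's class labels from FDR and linear fold change
    (mutant/WT). Every tested gene lands in exactly one class."""
    fdr = np.asarray(fdr, dtype=float)
    fc = np.asarray(fc, dtype=float)
    lo, hi = unchanged_window
    labels = np.full(fdr.shape, "other", dtype=object)
    labels[(fdr < fdr_threshold) & (fc > 1)] = "up"
    labels[(fdr < fdr_threshold) & (fc < 1)] = "down"
    labels[(fdr > fdr_threshold) & (fc > lo) & (fc < hi)] = "unchanged"
    return labels


def de_analysis(
    cm: CountMatrix,
    period: str,
    wt_label: str = "WT",
    mut_label: str = "mut",
    fdr_threshold: float = 0.05,
    unchanged_window: tuple[float, float] = (0.8, 1.2),
    min_cpm: float = 10.0,
    min_libraries: int = 3,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Full per-period DE analysis: filter, per-stage exact tests, per-stage
    BH adjustment, classification.

    Returns a tidy table with one row per gene per stage (columns gene,
    period, stage, log2fc, fc, pvalue, fdr, cls); genes failing the
    expression filter appear once per stage with cls = 'filtered'.
    """
    expressed = filter_expressed(cm, period, min_cpm, min_libraries)
    lib = cm.library_sizes()
    rows = []
    for stage in cm.stages_of(period):
        wt_samples = cm.samples_of(period=period, stage=stage, genotype=wt_label)
        mut_samples = cm.samples_of(
            period=period, stage=stage, genotype=mut_label
        )
        if not wt_samples or not mut_samples:
            raise ValidationError(
                f"stage {stage!r} lacks samples for one genotype"
            )
        counts_wt = cm.counts.loc[expressed, wt_samples].to_numpy()
        counts_mut = cm.counts.loc[expressed, mut_samples].to_numpy()
        lib_wt = lib[wt_samples].to_numpy(dtype=float)
        lib_mut = lib[mut_samples].to_numpy(dtype=float)
        d = (
            dispersion
            if dispersion is not None
            else estimate_common_dispersion(counts_wt, counts_mut, lib_wt, lib_mut)
        )
        log2fc = np.empty(len(expressed))
        pval = np.empty(len(expressed))
        for i in range(len(expressed)):
            log2fc[i], pval[i] = nb_test(
                counts_wt[i], counts_mut[i], lib_wt, lib_mut, d
            )
        fdr = bh_adjust(pval)
        fc = 2.0 ** log2fc
        cls = classify_genes(fdr, fc, fdr_threshold, unchanged_window)
        rows.append(
            pd.DataFrame(
                {
                    "gene": expressed,
                    "period": period,
                    "stage": stage,
                    "log2fc": log2fc,
                    "fc": fc,
                    "pvalue": pval,
                    "fdr": fdr,
                    "cls": cls,
                }
            )
        )
        unexpressed = cm.genes.difference(expressed)
        if len(unexpressed):
            rows.append(
                pd.DataFrame(
                    {
                        "gene": unexpressed,
                        "period": period,
                        "stage": stage,
                        "log2fc": np.nan,
                        "fc": np.nan,
                        "pvalue": np.nan,
                        "fdr": np.nan,
                        "cls": "filtered",
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def pca_embed(
    cm: CountMatrix, n_top: int = 1000, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on log2(cpm+1)-transformed counts of the ``n_top``
    most variable genes.

    Returns (coordinates indexed by sample with PC columns, fraction of
    variance explained per component). Sign convention: within each
    component the gene with the largest |loading| has a positive loading.
    """
    if cm.counts.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    x = np.log2(cpm(cm.counts) + 1.0)
    gene_var = x.var(axis=1)
    if len(gene_var) < n_top:
        warnings.warn(
            f"only {len(gene_var)} genes available, fewer than the "
            f"{n_top} requested"
        )
        n_top = len(gene_var)
    top = gene_var.sort_values(ascending=False, kind="mergesort").index[:n_top]
    mat = x.loc[top].to_numpy().T  # samples x genes
    mat = mat - mat.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(mat, full_matrices=False)
    k = min(n_components, len(s))
    total_var = float((s**2).sum())
    var_explained = (
        (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    )
    coords = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            coords[:, j] *= -1
            vt[j] *= -1
    frame = pd.DataFrame(
        coords,
        index=cm.samples,
        columns=[f"PC{j + 1}" for j in range(k)],
    )
    return frame, var_explained


def write_de_table(deg: pd.DataFrame, path) -> None:
    deg.to_csv(path, sep="\t", index=False)


def load_de_table(path) -> pd.DataFrame:
    """Import an externally produced DE result table (e.g. from edgeR).

    Requires columns gene, stage, log2fc (or logFC), pvalue (or PValue),
    fdr (or FDR); period and cls are derived if absent.
    """
    table = pd.read_csv(path, sep="\t")
    renames = {"logFC": "log2fc", "PValue": "pvalue", "FDR": "fdr"}
    table = table.rename(columns=renames)
    required = {"gene", "stage", "log2fc", "pvalue", "fdr"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"DE table missing columns {sorted(missing)}")
    if "fc" not in table.columns:
        table["fc"] = 2.0 ** table["log2fc"]
    if "cls" not in table.columns:
        table["cls"] = classify_genes(
            table["fdr"].to_numpy(), table["fc"].to_numpy()
        )
    return table
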