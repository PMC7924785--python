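"""Synthetic-data generator emulating the study design.

The generator produces, from one global seed, a mutually consistent set of
inputs for the whole pipeline: single-isoform gene models with log-normal
region lengths, CDS sequences drawn from a codon usage table, NB-distributed
counts for a 2-genotype x 3-period (oogenesis O1-O4; mature eggs
UNA/ACT/FER; embryogenesis E1-E4) x 3-replicate design, and per-transcript
read coverage.

Three effects the analysis must recover are injected:

* a "stabilized" gene subset, chosen with probability proportional to
  exp(-weight x expression rank) so it concentrates at low wild-type
  expression, whose mutant means are multiplied by ``stabilized_fc`` in
  each gene's designated period;
* mutant coverage of stabilized genes redistributed toward the 3' end
  (read-start density proportional to exp(bias3 x/L));
* rare-codon enrichment of the stabilized subset (synonymous-codon choice
  mixed toward an inverted-frequency table by ``codon_bias``), leaving the
  amino-acid composition untouched.

Truth labels are returned separately and never leak into pipeline inputs.
The global seed is split into fixed per-component, per-stage substreams so
outputs are byte-reproducible and draws for one stage do not perturb
another.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from decaylens.deg import CountMatrix
from decaylens.io import (
    write_bed,
    write_bedgraph,
    write_codon_usage,
    write_fasta,
    write_gtf,
)
from decaylens.models import (
    ALL_CODONS,
    CodonUsageTable,
    CoverageTrack,
    GeneModel,
    GeneModelSet,
    RegionMap,
    STOP_CODONS,
    ValidationError,
)

__all__ = [
    "SimulationParams",
    "default_codon_usage",
    "gene_labels",
    "simulate_annotation",
    "simulate_counts",
    "simulate_coverage",
    "write_dataset",
]

_STREAM = {"labels": 1, "annotation": 2, "counts": 3, "coverage": 4}

DEFAULT_PERIODS: dict[str, tuple[str, ...]] = {
    "O": ("O1", "O2", "O3", "O4"),
    "M": ("UNA", "ACT", "FER"),
    "E": ("E1", "E2", "E3", "E4"),
}


@dataclass
class SimulationParams:
    """Generator settings; defaults are the study conditions the pipeline
    is exercised under (sample design, effect and noise magnitudes)."""

    n_genes: int = 2000
    # log-normal region-length parameters (log-scale mean, sigma)
    utr5_loc: float = math.log(150.0)
    utr5_sigma: float = 0.6
    cds_loc: float = math.log(900.0)
    cds_sigma: float = 0.45
    utr3_loc: float = math.log(500.0)
    utr3_sigma: float = 0.6
    periods: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PERIODS)
    )
    genotypes: tuple[str, str] = ("WT", "mut")
    n_replicates: int = 3
    baseline_sigma: float = 1.2  # log-normal sd of relative abundance
    library_size_loc: float = math.log(1e6)
    library_size_sigma: float = 0.15
    dispersion: float = 0.05  # NB: Var = mu + mu^2 d
    stabilized_fraction: float = 0.10
    stabilized_low_expression_weight: float = 4.0
    stabilized_fc: float = 4.0
    bias3: float = 4.0
    codon_bias: float = 0.5
    read_length: int = 50
    coverage_reads: int = 200_000  # reads per genotype coverage track set
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be >= 1")
        if not 0 <= self.stabilized_fraction <= 1:
            raise ValidationError("stabilized_fraction must be in [0, 1]")
        if not 0 <= self.codon_bias <= 1:
            raise ValidationError("codon_bias must be in [0, 1]")
        if self.stabilized_fc < 1:
            raise ValidationError("stabilized_fc must be >= 1")
        for name in ("dispersion", "bias3", "stabilized_low_expression_weight"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_replicates < 1 or any(
            len(stages) < 1 for stages in self.periods.values()
        ):
            raise ValidationError("need >= 1 replicate and >= 1 stage per period")

    def stages(self) -> list[tuple[str, str]]:
        """(period, stage) pairs in design order."""
        return [(p, s) for p, ss in self.periods.items() for s in ss]

    def rng(self, component: str, *key: int) -> np.random.Generator:
        return np.random.default_rng(
            [self.seed, _STREAM[component], *key]
        )

    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]

    def transcript_ids(self) -> list[str]:
        return [f"t{i:05d}" for i in range(self.n_genes)]


def default_codon_usage() -> CodonUsageTable:
    """A synthetic codon usage table with graded synonymous preferences.

    Within each synonymous family, frequencies fall geometrically
    (1, 0.55, 0.3, ...) in codon-alphabetical order, giving every
    multi-codon family a unique most-frequent codon. Synthetic stand-in for
    a species usage table; any Kazusa-style table can be supplied instead.
    """
    table = CodonUsageTable({c: 1.0 for c in ALL_CODONS})
    freq = {}
    for _aa, codons in table.families().items():
        for i, codon in enumerate(sorted(codons)):
            freq[codon] = 16.0 * (0.55**i)
    return CodonUsageTable(freq)


def gene_labels(params: SimulationParams) -> pd.DataFrame:
    """Ground-truth labels per gene (test oracle; not a pipeline input).

    Columns: abundance (relative), stabilized, stabilized_period,
    rare_codon_member, and fc_<period> (the true mutant/WT fold change in
    each period). Deterministic given the params seed; both the annotation
    and count generators derive from this same table.
    """
    rng = params.rng("labels")
    n = params.n_genes
    abundance = rng.lognormal(0.0, params.baseline_sigma, size=n)
    order = np.argsort(abundance, kind="mergesort")
    rank = np.empty(n, dtype=float)
    rank[order] = np.arange(n)
    weight = params.stabilized_low_expression_weight
    w = np.exp(-weight * rank / max(n - 1, 1))
    n_stab = int(round(params.stabilized_fraction * n))
    stabilized = np.zeros(n, dtype=bool)
    if n_stab:
        chosen = rng.choice(n, size=n_stab, replace=False, p=w / w.sum())
        stabilized[chosen] = True
    period_names = list(params.periods)
    stab_period = np.array([""] * n, dtype=object)
    stab_period[stabilized] = rng.choice(
        period_names, size=int(stabilized.sum())
    )
    frame = pd.DataFrame(
        {
            "abundance": abundance,
            "stabilized": stabilized,
            "stabilized_period": stab_period,
            "rare_codon_member": stabilized.copy(),
        },
        index=pd.Index(params.gene_ids(), name="gene"),
    )
    for period in period_names:
        fc = np.where(
            stabilized & (stab_period == period), params.stabilized_fc, 1.0
        )
        frame[f"fc_{period}"] = fc
    return frame


def _codon_sampler(
    usage: CodonUsageTable, codon_bias: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sense-codon arrays and sampling probabilities for the plain and
    rare-codon-shifted distributions (family totals preserved)."""
    sense = np.array([c for c in ALL_CODONS if c not in STOP_CODONS])
    freq = np.array([usage.freq[c] for c in sense])
    p_plain = freq / freq.sum()
    p_rare = np.zeros_like(p_plain)
    families = usage.families()
    for aa, codons in families.items():
        if aa == "*":
            continue
        idx = np.array([np.flatnonzero(sense == c)[0] for c in codons])
        f = freq[idx]
        fam_total = f.sum()
        if fam_total == 0:
            continue
        cond = f / fam_total
        inv = 1.0 / np.maximum(f, 1e-6)
        inv = inv / inv.sum()
        mixed = (1 - codon_bias) * cond + codon_bias * inv
        p_rare[idx] = (fam_total / freq.sum()) * mixed
    p_rare = p_rare / p_rare.sum()
    stops = np.array(sorted(STOP_CODONS))
    p_stop = np.array([usage.freq[c] for c in stops])
    p_stop = (
        p_stop / p_stop.sum()
        if p_stop.sum() > 0
        else np.full(len(stops), 1 / len(stops))
    )
    return sense, p_plain, p_rare, (stops, p_stop)


def simulate_annotation(
    params: SimulationParams, usage: CodonUsageTable | None = None
) -> tuple[GeneModelSet, dict[str, str]]:
    """Generate single-isoform gene models and their CDS sequences.

    Every CDS starts with ATG, ends with a stop codon, and has length
    divisible by 3; internal codons are drawn from the usage table, with
    the rare-codon subset (see :func:`gene_labels`) drawn from the
    codon_bias-mixed distribution. Deterministic (byte-identical outputs)
    for a fixed seed.
    """
    usage = usage or default_codon_usage()
    labels = gene_labels(params)
    rng = params.rng("annotation")
    sense, p_plain, p_rare, (stops, p_stop) = _codon_sampler(
        usage, params.codon_bias
    )
    entries = []
    seqs: dict[str, str] = {}
    gene_ids = params.gene_ids()
    tx_ids = params.transcript_ids()
    for i in range(params.n_genes):
        utr5 = max(10, int(round(rng.lognormal(params.utr5_loc, params.utr5_sigma))))
        utr3 = max(20, int(round(rng.lognormal(params.utr3_loc, params.utr3_sigma))))
        n_codons = max(
            12, int(round(rng.lognormal(params.cds_loc, params.cds_sigma) / 3))
        )
        p = p_rare if labels["rare_codon_member"].iloc[i] else p_plain
        internal = rng.choice(len(sense), size=n_codons - 2, p=p)
        stop = stops[rng.choice(len(stops), p=p_stop)]
        seq = "ATG" + "".join(sense[internal]) + stop
        entries.append(
            GeneModel(
                gene_id=gene_ids[i],
                transcript_id=tx_ids[i],
                regions=RegionMap.from_lengths(utr5, 3 * n_codons, utr3),
                strand="+",
            )
        )
        seqs[tx_ids[i]] = seq
    return GeneModelSet(entries), seqs


def simulate_counts(
    models: GeneModelSet, params: SimulationParams
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate NB counts for the full design; returns (CountMatrix,
    truth labels).

    Per sample, gene g's mean is library_size x a_g fc_g / sum(a), with
    fc_g = stabilized_fc for stabilized genes of that period in the mutant
    and 1 otherwise; counts ~ NB(mean, dispersion) with
    Var = mu + mu^2 d (Poisson at d = 0). Each stage draws from its own
    seed substream.
    """
    labels = gene_labels(params)
    gene_ids = params.gene_ids()
    if sorted(models.gene_ids()) != sorted(gene_ids):
        raise ValidationError("models do not match the params gene set")
    abundance = labels["abundance"].to_numpy()
    total_abundance = abundance.sum()
    columns: dict[str, np.ndarray] = {}
    design_rows = []
    d = params.dispersion
    for stage_index, (period, stage) in enumerate(params.stages()):
        rng = params.rng("counts", stage_index)
        fc = labels[f"fc_{period}"].to_numpy()
        for genotype in params.genotypes:
            rel = abundance * (fc if genotype == params.genotypes[1] else 1.0)
            for rep in range(1, params.n_replicates + 1):
                lib = rng.lognormal(
                    params.library_size_loc, params.library_size_sigma
                )
                mean = lib * rel / total_abundance
                if d > 0:
                    counts = rng.negative_binomial(1.0 / d, 1.0 / (1.0 + mean * d))
                else:
                    counts = rng.poisson(mean)
                name = f"{genotype}_{stage}_r{rep}"
                columns[name] = counts
                design_rows.append(
                    {
                        "sample": name,
                        "genotype": genotype,
                        "period": period,
                        "stage": stage,
                        "replicate": rep,
                    }
                )
    counts = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene"))
    design = pd.DataFrame(design_rows).set_index("sample")
    return CountMatrix(counts, design), labels


def simulate_coverage(
    models: GeneModelSet,
    labels: pd.DataFrame,
    params: SimulationParams,
    period: str | None = None,
) -> dict[str, dict[str, CoverageTrack]]:
    """Simulate read coverage per genotype for one period.

    ``coverage_reads`` reads of fixed length are apportioned to genes in
    proportion to expression (abundance x the period's true fold change for
    the mutant). Read starts are uniform, except for mutant stabilized
    genes of this period whose start density is proportional to
    exp(bias3 x/L), shifting coverage toward the 3' end. Transcripts
    shorter than the read length are skipped with a warning. Returns
    {genotype: {transcript_id: CoverageTrack}} with read intervals attached.
    """
    period = period or next(iter(params.periods))
    period_index = list(params.periods).index(period)
    tx_of_gene = models.transcript_of_gene()
    gene_ids = [g for g in params.gene_ids() if g in tx_of_gene]
    out: dict[str, dict[str, CoverageTrack]] = {}
    for geno_index, genotype in enumerate(params.genotypes):
        rng = params.rng("coverage", period_index, geno_index)
        is_mut = genotype == params.genotypes[1]
        fc = labels[f"fc_{period}"].reindex(gene_ids).to_numpy()
        rel = labels["abundance"].reindex(gene_ids).to_numpy() * (
            fc if is_mut else 1.0
        )
        usable = []
        for g in gene_ids:
            ok = models.get(tx_of_gene[g]).length >= params.read_length
            if not ok:
                warnings.warn(
                    f"transcript {tx_of_gene[g]} shorter than the read "
                    "length; skipped"
                )
            usable.append(ok)
        usable = np.array(usable)
        p = np.where(usable, rel, 0.0)
        tracks: dict[str, CoverageTrack] = {}
        if p.sum() == 0:
            n_reads = np.zeros(len(gene_ids), dtype=int)
        else:
            n_reads = rng.multinomial(params.coverage_reads, p / p.sum())
        for i, g in enumerate(gene_ids):
            tx = tx_of_gene[g]
            length = models.get(tx).length
            if not usable[i]:
                continue
            n = int(n_reads[i])
            if n == 0:
                tracks[tx] = CoverageTrack.from_reads(tx, length, [])
                continue
            span = length - params.read_length + 1
            stab_here = bool(
                labels.at[g, "stabilized"]
                and labels.at[g, "stabilized_period"] == period
            )
            if is_mut and stab_here and params.bias3 > 0:
                x = np.arange(span)
                w = np.exp(params.bias3 * x / length)
                starts = rng.choice(span, size=n, p=w / w.sum())
            else:
                starts = rng.integers(0, span, size=n)
            starts = np.sort(starts)
            reads = [(int(s), int(s) + params.read_length) for s in starts]
            tracks[tx] = CoverageTrack.from_reads(tx, length, reads)
        out[genotype] = tracks
    return out


def write_dataset(
    outdir: str | Path,
    params: SimulationParams,
    usage: CodonUsageTable | None = None,
    coverage_periods: list[str] | None = None,
) -> dict[str, Path]:
    """Run the full generator and write every pipeline input (plus the
    test-only truth labels) as plain-text files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    usage = usage or default_codon_usage()
    models, seqs = simulate_annotation(params, usage)
    cm, labels = simulate_counts(models, params)
    paths = {
        "gtf": outdir / "annotation.gtf",
        "fasta": outdir / "cds.fasta",
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "truth": outdir / "truth_labels.tsv",
        "usage": outdir / "codon_usage.tsv",
    }
    write_gtf(models, paths["gtf"])
    write_fasta(seqs, paths["fasta"])
    cm.counts.to_csv(paths["counts"], sep="\t")
    cm.design.to_csv(paths["design"], sep="\t")
    labels.to_csv(paths["truth"], sep="\t")
    write_codon_usage(usage, paths["usage"])
    for period in coverage_periods or list(params.periods):
        tracks = simulate_coverage(models, labels, params, period)
        for genotype, by_tx in tracks.items():
            stem = f"coverage_{period}_{genotype}"
            bed = outdir / f"{stem}.bed"
            bedgraph = outdir / f"{stem}.bedGraph"
            write_bed(
                {tx: t.reads or [] for tx, t in by_tx.items()}, bed
            )
            write_bedgraph(by_tx.values(), bedgraph)
            paths[stem] = bed
    return paths
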