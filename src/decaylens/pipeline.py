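"""End-to-end pipeline: simulate (or load) -> filter -> DE -> classify ->
overlap -> coverage profiles -> transcript features, as one configured,
seeded, reproducible run writing TSV outputs and a JSON report.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from decaylens import __version__
from decaylens import deg as deg_mod
from decaylens import features as feat_mod
from decaylens import overlap as overlap_mod
from decaylens import profiles as prof_mod
from decaylens.deg import CountMatrix
from decaylens.io import select_longest_isoform
from decaylens.models import GeneModelSet, ValidationError
from decaylens.simulate import (
    SimulationParams,
    default_codon_usage,
    simulate_annotation,
    simulate_counts,
    simulate_coverage,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Thresholds and inputs of one pipeline run.

    Every threshold defaults to the study's printed value (FDR 0.05,
    10 cpm in 3 libraries, unchanged fold-change window 0.8-1.2, 100 nt
    minimum transcript length, 100 bins); all are overridable.
    """

    outdir: str = "decaylens_run"
    seed: int = 0
    fdr_threshold: float = 0.05
    min_cpm: float = 10.0
    min_libraries: int = 3
    unchanged_window: tuple[float, float] = (0.8, 1.2)
    min_transcript_length: int = 100
    n_bins: int = 100
    n_resamples: int = 100
    n_matching_bins: int = 20
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.unchanged_window
        checks = [
            (0 < self.fdr_threshold <= 1, "fdr_threshold must be in (0, 1]"),
            (self.min_cpm >= 0, "min_cpm must be >= 0"),
            (self.min_libraries >= 1, "min_libraries must be >= 1"),
            (0 < lo < 1 < hi, "unchanged_window must bracket 1"),
            (self.n_bins >= 1, "n_bins must be >= 1"),
            (self.n_resamples >= 1, "n_resamples must be >= 1"),
            (self.n_matching_bins >= 1, "n_matching_bins must be >= 1"),
            (
                self.min_transcript_length >= self.n_bins,
                "min_transcript_length must be >= n_bins",
            ),
        ]
        for ok, message in checks:
            if not ok:
                raise ValidationError(message)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "unchanged_window" in data:
            data["unchanged_window"] = tuple(data["unchanged_window"])
        return cls(**data)

    def simulation_params(self) -> SimulationParams:
        kwargs = dict(self.simulation)
        kwargs.setdefault("seed", self.seed)
        return SimulationParams(**kwargs)

    def fingerprint(self) -> dict:
        data = asdict(self)
        data["unchanged_window"] = list(self.unchanged_window)
        data["version"] = __version__
        return data


def _wt_mean_tpm(
    cm: CountMatrix, lengths: pd.Series, stage: str, wt_label: str = "WT"
) -> pd.Series:
    samples = cm.samples_of(stage=stage, genotype=wt_label)
    tpm = deg_mod.tpm(cm.counts[samples], lengths)
    return tpm.mean(axis=1)


def run_pipeline(
    config: RunConfig,
    cm: CountMatrix | None = None,
    models: GeneModelSet | None = None,
    cds_seqs: dict[str, str] | None = None,
    usage=None,
) -> dict:
    """Execute every stage on the given inputs (or a fresh simulation when
    none are supplied) and write all outputs under ``config.outdir``.

    Returns the run report (also written as ``report.json``): per-stage DEG
    class counts, overlap results, metagene and region-density summaries,
    and feature comparisons, all stamped with the config fingerprint.
    Deterministic for a fixed config and seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.fingerprint(), "stages": {}}
    t0 = time.time()

    # --- inputs -----------------------------------------------------------
    simulated = cm is None
    labels = None
    params = config.simulation_params()
    usage = usage or default_codon_usage()
    if simulated:
        models, cds_seqs = simulate_annotation(params, usage)
        cm, labels = simulate_counts(models, params)
    if models is None:
        raise ValidationError("gene models are required")
    models = select_longest_isoform(models)
    lengths_table = feat_mod.region_lengths(models)
    gene_lengths = lengths_table["full"]

    # --- differential expression -----------------------------------------
    deg_tables = []
    for period in cm.periods():
        deg_tables.append(
            deg_mod.de_analysis(
                cm,
                period,
                fdr_threshold=config.fdr_threshold,
                unchanged_window=config.unchanged_window,
                min_cpm=config.min_cpm,
                min_libraries=config.min_libraries,
            )
        )
    deg = pd.concat(deg_tables, ignore_index=True)
    deg.to_csv(outdir / "de_results.tsv", sep="\t", index=False)
    class_counts = (
        deg.groupby(["period", "stage", "cls"]).size().unstack(fill_value=0)
    )
    class_counts.to_csv(outdir / "deg_class_counts.tsv", sep="\t")
    report["stages"]["de"] = {
        "n_genes": int(len(cm.genes)),
        "class_counts": {
            f"{p}/{s}": row.to_dict()
            for (p, s), row in class_counts.iterrows()
        },
    }

    coords, var_explained = deg_mod.pca_embed(cm)
    coords.to_csv(outdir / "pca.tsv", sep="\t")
    report["stages"]["pca"] = {
        "variance_explained": [float(v) for v in var_explained]
    }

    # --- shared-period DEG sets and overlap -------------------------------
    shared_sets: dict[str, dict[str, set]] = {}
    for period in cm.periods():
        shared_sets[period] = {
            d: overlap_mod.shared_period_degs(deg, period, d)
            for d in ("up", "down")
        }
    overlap_rows = []
    for period in cm.periods():
        stages = cm.stages_of(period)
        for direction in ("up", "down"):
            for i, s1 in enumerate(stages):
                for s2 in stages[i + 1 :]:
                    sub1 = deg[(deg["stage"] == s1)]
                    sub2 = deg[(deg["stage"] == s2)]
                    set_a = set(
                        sub1.loc[sub1["cls"] == direction, "gene"]
                    )
                    set_b = set(
                        sub2.loc[sub2["cls"] == direction, "gene"]
                    )
                    pool = set(
                        sub1.loc[sub1["cls"] == "unchanged", "gene"]
                    ) - set_a
                    if not set_a or not set_b or len(pool) < len(set_a):
                        continue
                    expr = _wt_mean_tpm(cm, gene_lengths, s1)
                    res = overlap_mod.overlap_significance(
                        set_a,
                        set_b,
                        pool,
                        expr,
                        n_resamples=config.n_resamples,
                        seed=config.seed,
                        n_bins=config.n_matching_bins,
                        set_a_id=f"{direction}:{s1}",
                        set_b_id=f"{direction}:{s2}",
                    )
                    overlap_rows.append(
                        {
                            "period": period,
                            "direction": direction,
                            "set_a": res.set_a,
                            "set_b": res.set_b,
                            "observed_shared": res.observed_shared,
                            "observed_fraction": res.observed_fraction,
                            "mean_control_shared": float(
                                res.control_shared.mean()
                            ),
                            "chisq": res.chisq,
                            "pvalue": res.pvalue,
                            "quantile": res.quantile,
                        }
                    )
    overlap_table = pd.DataFrame(overlap_rows)
    overlap_table.to_csv(outdir / "overlap.tsv", sep="\t", index=False)
    report["stages"]["overlap"] = {
        "n_pairs": int(len(overlap_table)),
        "median_observed_fraction": (
            float(overlap_table["observed_fraction"].median())
            if len(overlap_table)
            else None
        ),
        "shared_period_counts": {
            p: {d: len(s) for d, s in ds.items()}
            for p, ds in shared_sets.items()
        },
    }

    # --- coverage profiles and region densities ---------------------------
    tx_of_gene = models.transcript_of_gene()
    profile_rows = []
    density_tests = []
    ratio_summaries = {}
    if simulated:
        for period in cm.periods():
            tracks = simulate_coverage(models, labels, params, period)
            first_stage = cm.stages_of(period)[0]
            stage_classes = deg[
                (deg["period"] == period) & (deg["stage"] == first_stage)
            ].set_index("gene")["cls"]
            class_sets = {
                "up": shared_sets[period]["up"],
                "down": shared_sets[period]["down"],
                "unchanged": set(
                    stage_classes.index[stage_classes == "unchanged"]
                ),
            }
            genotype_maps = {g: [t] for g, t in tracks.items()}
            for cls_name, genes in class_sets.items():
                tx_set = [tx_of_gene[g] for g in genes if g in tx_of_gene]
                if not tx_set:
                    continue
                profs = prof_mod.metagene(
                    tx_set,
                    genotype_maps,
                    n_bins=config.n_bins,
                    min_length=config.min_transcript_length,
                    set_id=f"{period}:{cls_name}",
                )
                for genotype, prof in profs.items():
                    profile_rows.append(
                        {
                            "period": period,
                            "cls": cls_name,
                            "genotype": genotype,
                            "n_genes": prof.n_genes,
                            **{
                                f"bin{i + 1}": v
                                for i, v in enumerate(prof.values)
                            },
                        }
                    )
            density = {
                genotype: prof_mod.region_density(by_tx, models)
                for genotype, by_tx in tracks.items()
            }
            wt_label, mut_label = params.genotypes
            ratios = prof_mod.region_density_ratio(
                density[wt_label], density[mut_label]
            )
            ratios.to_csv(
                outdir / f"region_density_ratio_{period}.tsv",
                sep="\t",
                index=False,
            )
            up_genes = shared_sets[period]["up"]
            up_ratios = ratios[ratios["gene"].isin(up_genes)]
            ratio_summaries[period] = {
                region: (
                    float(
                        up_ratios.loc[
                            up_ratios["region"] == region, "ratio"
                        ].median()
                    )
                    if (up_ratios["region"] == region).any()
                    else None
                )
                for region in prof_mod.REGIONS
            }
            for region in prof_mod.REGIONS:
                for cls_name, genes in class_sets.items():
                    sub_genes = [g for g in genes if g in density[wt_label].index]
                    if len(sub_genes) < 3:
                        continue
                    stat, pvalue = prof_mod.compare_region_densities(
                        density[wt_label].loc[sub_genes, f"density_{region}"],
                        density[mut_label].loc[sub_genes, f"density_{region}"],
                    )
                    density_tests.append(
                        {
                            "period": period,
                            "cls": cls_name,
                            "region": region,
                            "n_genes": len(sub_genes),
                            "statistic": stat,
                            "pvalue": pvalue,
                        }
                    )
    if profile_rows:
        pd.DataFrame(profile_rows).to_csv(
            outdir / "metagene_profiles.tsv", sep="\t", index=False
        )
    if density_tests:
        pd.DataFrame(density_tests).to_csv(
            outdir / "region_density_tests.tsv", sep="\t", index=False
        )
    report["stages"]["profiles"] = {
        "median_up_ratio_by_region": ratio_summaries,
    }

    # --- transcript features ----------------------------------------------
    lengths_table.to_csv(outdir / "region_lengths.tsv", sep="\t")
    feature_rows = []
    cai_by_gene = None
    if cds_seqs is not None:
        seq_of_gene = {
            g: cds_seqs[tx] for g, tx in tx_of_gene.items() if tx in cds_seqs
        }
        cai_frame = feat_mod.cai_table(seq_of_gene, usage)
        cai_frame.to_csv(outdir / "cai.tsv", sep="\t")
        cai_by_gene = cai_frame["cai"]
    for period in cm.periods():
        first_stage = cm.stages_of(period)[0]
        stage_rows = deg[
            (deg["period"] == period) & (deg["stage"] == first_stage)
        ].set_index("gene")
        unchanged = list(stage_rows.index[stage_rows["cls"] == "unchanged"])
        for direction in ("up", "down"):
            genes = sorted(shared_sets[period][direction])
            if len(genes) < 3 or len(unchanged) < 3:
                continue
            for feature in ("full", "utr5", "cds", "utr3"):
                d_stat, pvalue = feat_mod.ks_compare(
                    lengths_table.loc[
                        lengths_table.index.isin(genes), feature
                    ],
                    lengths_table.loc[
                        lengths_table.index.isin(unchanged), feature
                    ],
                )
                feature_rows.append(
                    {
                        "period": period,
                        "comparison": f"{direction}_vs_unchanged",
                        "feature": f"length_{feature}",
                        "statistic": d_stat,
                        "pvalue": pvalue,
                        "n_group": len(genes),
                        "n_unchanged": len(unchanged),
                    }
                )
            if cai_by_gene is not None:
                group_cai = cai_by_gene.reindex(genes).dropna()
                unchanged_cai = cai_by_gene.reindex(unchanged).dropna()
                if len(group_cai) >= 3 and len(unchanged_cai) >= 3:
                    d_stat, pvalue = feat_mod.ks_compare(
                        group_cai, unchanged_cai
                    )
                    feature_rows.append(
                        {
                            "period": period,
                            "comparison": f"{direction}_vs_unchanged",
                            "feature": "cai",
                            "statistic": d_stat,
                            "pvalue": pvalue,
                            "n_group": len(group_cai),
                            "n_unchanged": len(unchanged_cai),
                        }
                    )
    expr_rows = []
    for period in cm.periods():
        for stage in cm.stages_of(period):
            stage_cls = deg[
                (deg["period"] == period) & (deg["stage"] == stage)
            ].set_index("gene")["cls"]
            tpm_wt = _wt_mean_tpm(cm, gene_lengths, stage)
            expr_rows.append(
                feat_mod.expression_level_compare(tpm_wt, stage_cls, stage)
            )
    expression_compare = pd.concat(expr_rows, ignore_index=True)
    expression_compare.to_csv(
        outdir / "expression_compare.tsv", sep="\t", index=False
    )
    feature_table = pd.DataFrame(feature_rows)
    feature_table.to_csv(
        outdir / "feature_compare.tsv", sep="\t", index=False
    )
    report["stages"]["features"] = {
        "n_feature_comparisons": int(len(feature_table)),
        "n_expression_comparisons": int(len(expression_compare)),
    }

    # report.json stays deterministic for a fixed config+seed; timing goes
    # to a side log instead
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(outdir / "run.log", "a") as fh:
        fh.write(f"run completed in {time.time() - t0:.2f} s\n")
    return report
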