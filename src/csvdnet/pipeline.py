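"""End-to-end orchestration: matrices -> metrics -> null models -> AUC -> stats.

Each stage is a plain function over DataFrames so it can be driven from
the CLI, from tests, or interactively.  ``run_pipeline`` sequences them,
writes every table as CSV and records a manifest (config echo, seed,
versions, per-stage row counts) sufficient to reproduce the run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate, io, metrics, netbuild, nullnorm, stats
from .errors import ParameterError
from .synthgen import COGNITIVE_TESTS, GROUPS

GLOBAL_METRICS = ("Cp", "Lp", "Eglob", "Eloc")


@dataclass
class PipelineConfig:
    matrix_dir: str | None = None
    metadata_csv: str | None = None
    output_dir: str = "results"
    s_min: float = netbuild.DEFAULT_SMIN
    s_max: float = netbuild.DEFAULT_SMAX
    step: float = netbuild.DEFAULT_STEP
    n_random: int = nullnorm.DEFAULT_N_RANDOM
    seed: int = 0
    q_threshold: float = 0.05
    corr_mode: str = "pearson"
    fdr_scope: str = "group"
    run_metrics: bool = True
    run_smallworld: bool = True
    run_auc: bool = True
    run_hubs: bool = True
    run_stats: bool = True
    stage_rows: dict = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# stages

def compute_metric_tables(matrices, subject_ids, grid, node_labels=None):
    """Per-(subject, sparsity) global metrics and nodal efficiencies."""
    grows, nrows = [], []
    labels = None
    for sid, mat in zip(subject_ids, matrices):
        if labels is None:
            n = mat.weights.shape[0] if hasattr(mat, "weights") else np.asarray(mat).shape[0]
            labels = list(node_labels) if node_labels else [f"n{i + 1:03d}" for i in range(n)]
        cache = {}  # saturated sweep levels yield identical networks; compute once
        for tn in netbuild.threshold_sweep(mat, *grid):
            if tn.retained_edges not in cache:
                rec = metrics.compute_global_metrics(tn, subject_id=sid)
                e = metrics.nodal_efficiency(metrics.shortest_paths(tn)).e
                cache[tn.retained_edges] = (rec, e)
            rec, e = cache[tn.retained_edges]
            grows.append({
                "subject_id": sid, "sparsity": tn.sparsity, "Cp": rec.Cp, "Lp": rec.Lp,
                "Eglob": rec.Eglob, "Eloc": rec.Eloc, "disconnected": rec.disconnected,
            })
            nrows.append({"subject_id": sid, "sparsity": tn.sparsity,
                          **dict(zip(labels, e))})
    return pd.DataFrame(grows), pd.DataFrame(nrows)


def compute_eloc_curves(matrices, grid) -> np.ndarray:
    """Local-efficiency curve per subject over the sparsity grid (fast path).

    Returns an array of shape (n_subjects, n_thresholds); used by power /
    calibration studies that only need the Eloc AUC.
    """
    curves = []
    for mat in matrices:
        cache = {}
        row = []
        for tn in netbuild.threshold_sweep(mat, *grid):
            if tn.retained_edges not in cache:
                cache[tn.retained_edges] = metrics.local_efficiency(tn)
            row.append(cache[tn.retained_edges])
        curves.append(row)
    return np.asarray(curves)


def compute_eloc_auc(matrices, grid) -> np.ndarray:
    """Per-subject AUC of the local-efficiency curve over the sparsity grid."""
    thresholds = netbuild.sparsity_grid(*grid)
    curves = compute_eloc_curves(matrices, grid)
    return np.trapezoid(curves, thresholds, axis=1)


def compute_smallworld_table(matrices, subject_ids, grid, n_random, seed, swap_factor=None):
    """gamma / lambda / sigma per (subject, sparsity); one RNG stream per subject."""
    kw = {} if swap_factor is None else {"swap_factor": swap_factor}
    children = np.random.SeedSequence(seed).spawn(len(list(subject_ids)))
    rows = []
    for child, sid, mat in zip(children, subject_ids, matrices):
        rng = np.random.default_rng(child)
        cache = {}  # identical saturated networks share one ensemble
        for tn in netbuild.threshold_sweep(mat, *grid):
            if tn.retained_edges not in cache:
                cache[tn.retained_edges] = nullnorm.normalized_small_world(
                    tn, n_random, rng, subject_id=sid, **kw
                )
            sw = cache[tn.retained_edges]
            rows.append({"subject_id": sid, "sparsity": tn.sparsity,
                         "gamma": sw.gamma, "lambda": sw.lam, "sigma": sw.sigma})
    return pd.DataFrame(rows)


def compute_auc_tables(global_df, nodal_df, smallworld_df=None):
    """Collapse every per-threshold curve to its trapezoidal AUC."""
    def auc_wide(df, value_cols):
        out = []
        for sid, sub in df.groupby("subject_id", sort=False):
            sub = sub.sort_values("sparsity")
            row = {"subject_id": sid}
            for c in value_cols:
                row[c] = aggregate.compute_auc(
                    thresholds=sub["sparsity"].to_numpy(), values=sub[c].to_numpy()
                )
            out.append(row)
        return pd.DataFrame(out)

    gcols = list(GLOBAL_METRICS)
    gdf = global_df
    if smallworld_df is not None and len(smallworld_df):
        gdf = global_df.merge(smallworld_df, on=["subject_id", "sparsity"])
        gcols += ["gamma", "lambda", "sigma"]
    node_cols = [c for c in nodal_df.columns if c not in ("subject_id", "sparsity")]
    return auc_wide(gdf, gcols), auc_wide(nodal_df, node_cols)


def compute_hubs(auc_nodal, table, ddof=1):
    """Per-group hub sets from group-mean nodal-efficiency AUC vectors."""
    merged = auc_nodal.merge(table[["subject_id", "group"]], on="subject_id")
    node_cols = [c for c in auc_nodal.columns if c != "subject_id"]
    rows = []
    for grp in [g for g in GROUPS if g in set(merged["group"])] or sorted(set(merged["group"])):
        mean_vec = merged.loc[merged["group"] == grp, node_cols].mean(axis=0).to_numpy()
        hubset = aggregate.identify_hubs(mean_vec, node_cols, group_label=grp, ddof=ddof)
        for lab, val in zip(node_cols, mean_vec):
            if lab in hubset.hubs:
                rows.append({"group": grp, "region": lab, "enodal_auc": val,
                             "cutoff": hubset.cutoff})
    return pd.DataFrame(rows, columns=["group", "region", "enodal_auc", "cutoff"])


def _mean_sd_string(x):
    return f"{np.mean(x):.2f} ± {np.std(x, ddof=1):.2f}"


def compute_demographics_table(table):
    """ANOVA (chi-square for sex) across groups on demographics and scores."""
    groups_present = [g for g in GROUPS if g in set(table["group"])]
    rows = []
    sex_counts = [
        [int(((table["group"] == g) & (table["sex"] == s)).sum()) for s in ("M", "F")]
        for g in groups_present
    ]
    chi2, p = stats.chi_square(sex_counts)
    rows.append({"characteristic": "sex", "test": "chi-square",
                 **{g: f"{c[0]} M / {c[1]} F" for g, c in zip(groups_present, sex_counts)},
                 "statistic": chi2, "p": p})
    for col in ["age", "education", *COGNITIVE_TESTS]:
        F, p = stats.oneway_anova(table[col], table["group"])
        rows.append({"characteristic": col, "test": "ANOVA",
                     **{g: _mean_sd_string(table.loc[table["group"] == g, col])
                        for g in groups_present},
                     "statistic": F, "p": p})
    return pd.DataFrame(rows)


def compute_group_stats(auc_global, table, covariate_cols=("age", "sex", "education")):
    """ANCOVA with LSD post hoc on each global-metric AUC (published-table layout)."""
    merged = auc_global.merge(table, on="subject_id")
    cov = merged[list(covariate_cols)] if covariate_cols else None
    groups_present = [g for g in GROUPS if g in set(merged["group"])]
    rows = []
    for metric in [c for c in auc_global.columns if c != "subject_id"]:
        res = stats.ancova_f_test(merged[metric], merged["group"], covariates=cov)
        row = {"metric": metric}
        for g in groups_present:
            row[g] = _mean_sd_string(merged.loc[merged["group"] == g, metric])
        row.update({"F": res.omnibus_F, "p": res.omnibus_p})
        for (g1, g2), pv in res.posthoc.items():
            row[f"p[{g1} vs {g2}]"] = pv
        rows.append(row)
    return pd.DataFrame(rows)


def compute_nodal_stats(auc_nodal, table, covariate_cols=("age", "sex", "education")):
    """Per-node ANCOVA on nodal-efficiency AUC, BH-FDR across nodes."""
    merged = auc_nodal.merge(table, on="subject_id")
    cov = merged[list(covariate_cols)] if covariate_cols else None
    node_cols = [c for c in auc_nodal.columns if c != "subject_id"]
    rows = []
    for node in node_cols:
        res = stats.ancova_f_test(merged[node], merged["group"], covariates=cov)
        rows.append({"region": node, "F": res.omnibus_F, "p": res.omnibus_p,
                     **{f"p[{g1} vs {g2}]": pv for (g1, g2), pv in res.posthoc.items()}})
    df = pd.DataFrame(rows)
    df["q"] = stats.bh_fdr(df["p"].to_numpy())
    return df


def compute_correlations(auc_nodal, table, significant_regions,
                         mode="pearson", fdr_scope="group"):
    """Brain-behavior correlations for regions with group differences."""
    if not significant_regions:
        return pd.DataFrame(columns=["group", "region", "test", "r", "p", "q", "n"])
    merged = auc_nodal.merge(table, on="subject_id")
    cov = merged[["age", "sex", "education"]] if mode == "partial" else None
    res = stats.pearson_correlations(
        merged[list(significant_regions)], merged[list(COGNITIVE_TESTS)],
        merged["group"], mode=mode, covariates=cov, fdr_scope=fdr_scope,
    )
    return pd.DataFrame([{
        "group": r.group, "region": r.feature, "test": r.test,
        "r": r.r, "p": r.p, "q": r.q, "n": r.n,
    } for r in res])


# ---------------------------------------------------------------------------
# orchestration

def run_pipeline(config: PipelineConfig, matrices=None, table=None) -> dict:
    """Run the configured stages and write all artifacts under output_dir.

    ``matrices`` / ``table`` may be passed in memory (e.g. straight from the
    generator); otherwise they are read from ``matrix_dir`` / ``metadata_csv``.
    Deterministic given identical inputs and seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if matrices is None or table is None:
        if not (config.matrix_dir and config.metadata_csv):
            raise ParameterError("need matrix_dir and metadata_csv (or in-memory cohort)")
        matrices, table = io.read_cohort(config.matrix_dir, config.metadata_csv)
    ids = table["subject_id"].tolist()
    grid = (config.s_min, config.s_max, config.step)
    labels = getattr(matrices[0], "node_labels", None)
    results: dict = {"table": table}
    counts = {}

    if config.run_metrics:
        gdf, ndf = compute_metric_tables(matrices, ids, grid, node_labels=labels)
        gdf.to_csv(out / "global_metrics.csv", index=False)
        ndf.to_csv(out / "nodal_efficiency.csv", index=False)
        results["global_metrics"], results["nodal_efficiency"] = gdf, ndf
        counts["global_metrics"], counts["nodal_efficiency"] = len(gdf), len(ndf)

    if config.run_smallworld:
        sw = compute_smallworld_table(matrices, ids, grid, config.n_random, config.seed)
        sw.to_csv(out / "small_world.csv", index=False)
        results["small_world"] = sw
        counts["small_world"] = len(sw)

    if config.run_auc and config.run_metrics:
        auc_g, auc_n = compute_auc_tables(
            results["global_metrics"], results["nodal_efficiency"],
            results.get("small_world"),
        )
        auc_g.to_csv(out / "auc_global.csv", index=False)
        auc_n.to_csv(out / "auc_nodal.csv", index=False)
        results["auc_global"], results["auc_nodal"] = auc_g, auc_n
        counts["auc_global"], counts["auc_nodal"] = len(auc_g), len(auc_n)

    if config.run_hubs and "auc_nodal" in results:
        hubs = compute_hubs(results["auc_nodal"], table)
        hubs.to_csv(out / "hubs.csv", index=False)
        results["hubs"] = hubs
        counts["hubs"] = len(hubs)

    if config.run_stats and "auc_global" in results:
        demo = compute_demographics_table(table)
        gstats = compute_group_stats(results["auc_global"], table)
        nstats = compute_nodal_stats(results["auc_nodal"], table)
        sig = nstats.loc[nstats["p"] < config.q_threshold, "region"].tolist()
        corr = compute_correlations(
            results["auc_nodal"], table, sig,
            mode=config.corr_mode, fdr_scope=config.fdr_scope,
        )
        demo.to_csv(out / "demographics.csv", index=False)
        gstats.to_csv(out / "stats_global.csv", index=False)
        nstats.to_csv(out / "stats_nodal.csv", index=False)
        corr.to_csv(out / "correlations.csv", index=False)
        results.update(demographics=demo, stats_global=gstats,
                       stats_nodal=nstats, correlations=corr)
        counts.update(demographics=len(demo), stats_global=len(gstats),
                      stats_nodal=len(nstats), correlations=len(corr))

    import numpy, scipy  # versions for the manifest

    cfg_echo = asdict(config)
    cfg_echo.pop("stage_rows", None)
    manifest = {
        "config": cfg_echo,
        "seed": config.seed,
        "n_subjects": len(ids),
        "versions": {"numpy": numpy.__version__, "scipy": scipy.__version__},
        "stage_rows": counts,
    }
    io.write_json(manifest, out / "manifest.json")
    results["manifest"] = manifest
    return results
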