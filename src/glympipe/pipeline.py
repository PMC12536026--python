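"""End-to-end pipeline tying the stages together.

``run_pipeline`` executes simulate -> preprocess -> coupling -> markers ->
statistics -> diagnostics, writing every artifact (CSV/TSV/JSON) under an
output directory together with a metadata echo of the configuration and
all stage seeds.  Each stage is also callable on its own, which is how
the CLI subcommands and the analysis scripts use them.

All randomness flows from ``RunConfig.seed`` through named child seeds
(one per stage), so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling as cpl
from . import diagnostics as dgn
from . import fileio
from . import markers as mk
from . import stats as st
from .cohort import (CohortConfig, SignalConfig, generate_diffusivity_table,
                     generate_marker_table, generate_retest,
                     generate_signal_pair)
from .config import RunConfig
from .preprocess import preprocess

MARKER_COLUMNS = ("coupling_index", "alps_index", "cpv_fraction_pct")


def _stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    names = ("cohort", "signals", "permutation", "bootstrap", "retest")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return dict(zip(names, children))


def stage_simulate(config: RunConfig, outdir: Path,
                   cohort_config: CohortConfig | None = None) -> dict:
    """Generate the synthetic cohort: marker table, diffusivity table,
    retest table, and per-subject coupled signal pairs with a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    if cohort_config is None:
        cohort_config = CohortConfig(seed=config.seed)

    rng_cohort = np.random.default_rng(seeds["cohort"])
    table = generate_marker_table(cohort_config, rng=rng_cohort)
    fileio.write_subject_table(outdir / "subject_table.csv", table)

    diffusivity = generate_diffusivity_table(table, rng=rng_cohort)
    diffusivity.to_csv(outdir / "diffusivity_table.csv", index=False,
                       float_format="%.10g")

    retest = generate_retest(table, "coupling_index",
                             cohort_config.retest_noise_frac,
                             rng=np.random.default_rng(seeds["retest"]))
    retest.to_csv(outdir / "coupling_retest.csv", index=False,
                  float_format="%.10g")

    signal_dir = outdir / "signals"
    signal_dir.mkdir(exist_ok=True)
    sig_children = seeds["signals"].spawn(len(table))
    manifest_rows = []
    for (_, rec), child in zip(table.iterrows(), sig_children):
        sig_cfg = SignalConfig(
            n_volumes=config.n_volumes, tr=config.tr,
            passband=config.passband,
            coupling_strength=config.signal_coupling_strength,
        )
        gbold, csf = generate_signal_pair(sig_cfg, rng=np.random.default_rng(child))
        path = signal_dir / f"{rec['subject_id']}.tsv"
        fileio.write_signal_tsv(path, gbold, csf)
        manifest_rows.append({"subject_id": rec["subject_id"],
                              "signal_path": f"signals/{path.name}"})
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)

    fileio.write_json(outdir / "simulate_metadata.json", {
        "run_config": config.to_dict(),
        "cohort_config": table.attrs["config"],
        "n_subjects": len(table),
    })
    return {"table": table, "diffusivity": diffusivity, "retest": retest,
            "manifest": outdir / "manifest.csv"}


def stage_coupling(manifest_path, config: RunConfig, outdir: Path) -> dict:
    """Preprocess every subject's signals and compute the coupling
    statistics: per-subject correlogram/index, group-mean correlogram,
    and the subject-pair permutation null."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    perm_seed = int(seeds["permutation"].generate_state(1)[0] & 0x7FFFFFFF)

    manifest = fileio.read_manifest(manifest_path)
    pairs, correlograms, rows = [], [], []
    low, high = config.passband
    for _, rec in manifest.iterrows():
        gbold_raw, csf_raw = fileio.read_signal_tsv(rec["signal_path"])
        gbold = preprocess(gbold_raw, config.n_discard, low, high)
        csf = preprocess(csf_raw, config.n_discard, low, high)
        cc = cpl.cross_correlate(gbold, csf, config.max_lag)
        pairs.append((gbold, csf))
        correlograms.append(cc)
        rows.append({
            "subject_id": rec["subject_id"],
            "n_timepoints": len(gbold),
            "coupling_index_signal": cpl.coupling_index(cc, config.index_lag),
            "derivative_r0": cpl.derivative_coupling(gbold, csf),
        })
    subject_results = pd.DataFrame(rows)
    subject_results.to_csv(outdir / "coupling_subjects.csv", index=False,
                           float_format="%.10g")

    mean_cc = cpl.group_mean_correlogram(correlograms)
    null = cpl.permutation_test(pairs, config.max_lag, config.n_perm,
                                seed=perm_seed)
    group = {
        "lags_s": mean_cc.lags,
        "mean_r": mean_cc.r,
        "p_per_lag": null.p_per_lag,
        "band95_low": null.band95[0],
        "band95_high": null.band95[1],
        "n_perm": null.n_perm,
        "permutation_seed": null.seed,
        "n_subjects": len(pairs),
        "index_lag_s": config.index_lag,
        "p_at_index_lag": float(
            null.p_per_lag[np.isclose(null.lags, config.index_lag)][0]
        ),
        "run_config": config.to_dict(),
    }
    fileio.write_json(outdir / "coupling_group.json", group)
    return {"subjects": subject_results, "group_correlogram": mean_cc,
            "permutation": null}


def stage_markers(table: pd.DataFrame, diffusivity: pd.DataFrame,
                  outdir: Path) -> pd.DataFrame:
    """Recompute derived markers from their source tables and merge.

    The ALPS index is recomputed from the per-hemisphere diffusivity
    table, the CPV fraction from the volumes, and the progression rate
    from the clinical fields; recomputed values replace the incoming
    columns so downstream stages always see values consistent with their
    defining formulas.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    merged = table.copy()

    alps = mk.alps_from_table(diffusivity)
    merged["alps_index"] = merged["subject_id"].map(alps)
    merged["cpv_fraction_pct"] = [
        mk.cpv_fraction(c, t) for c, t in zip(merged["cpv_ml"], merged["tiv_ml"])
    ]
    als_mask = merged["group"] == "ALS"
    merged.loc[als_mask, "progression_rate"] = [
        mk.progression_rate(a, d)
        for a, d in zip(merged.loc[als_mask, "alsfrs_r"],
                        merged.loc[als_mask, "duration_months"])
    ]
    fileio.write_subject_table(outdir / "subject_table_markers.csv", merged)
    return merged


def stage_stats(table: pd.DataFrame, config: RunConfig, outdir: Path,
                retest: pd.DataFrame | None = None) -> dict:
    """Group comparisons, the ALS-group correlation family with FDR,
    the duration-adjusted partial correlation, and (optionally) ICC."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    als = table[table["group"] == "ALS"]
    hc = table[table["group"] == "HC"]

    comparisons = []
    for col in ("alps_index", "coupling_index", "cpv_ml", "tiv_ml",
                "cpv_fraction_pct"):
        comparisons.append(st.compare_groups(
            als[col], hc[col], config.normality_alpha, variable=col))
    comp_df = pd.DataFrame([{
        "variable": c.variable, "test_used": c.test_used,
        "statistic": c.statistic, "p": c.p,
        "als_summary": c.summary_a, "hc_summary": c.summary_b,
        "normality_p_als": c.normality_p[0], "normality_p_hc": c.normality_p[1],
    } for c in comparisons])
    comp_df.to_csv(outdir / "group_comparisons.csv", index=False,
                   float_format="%.6g")

    entries = st.correlation_matrix(als, list(config.correlation_family))
    corr_df = pd.DataFrame([{
        "var_x": e.var_x, "var_y": e.var_y, "r": e.r, "p": e.p, "q": e.q,
        "n": e.n,
    } for e in entries])
    corr_df.to_csv(outdir / "als_correlations.csv", index=False,
                   float_format="%.6g")

    partial = st.partial_correlation(
        als["alps_index"], als["cpv_fraction_pct"], als["duration_months"],
        var_x="alps_index", var_y="cpv_fraction_pct",
        covariate_name="duration_months")

    result = {"comparisons": comparisons, "correlations": entries,
              "partial_alps_cpv": partial}
    payload = {
        "partial_correlation": {
            "x": partial.var_x, "y": partial.var_y,
            "covariate": partial.covariate, "r": partial.r, "p": partial.p,
            "n": partial.n,
        }
    }
    if retest is not None:
        icc = st.icc_reproducibility(
            retest[["measurement_1", "measurement_2"]].to_numpy(float))
        payload["icc_coupling_retest"] = icc
        result["icc"] = icc
    fileio.write_json(outdir / "stats_summary.json", payload)
    return result


def stage_diagnostics(table: pd.DataFrame, config: RunConfig,
                      outdir: Path) -> dict:
    """Per-marker ROC, the combined three-marker logistic nomogram,
    optimism-corrected calibration, and decision-curve analysis."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    boot_seed = int(seeds["bootstrap"].generate_state(1)[0] & 0x7FFFFFFF)

    labels = (table["group"] == "ALS").to_numpy()
    roc_summary = {}
    for col in MARKER_COLUMNS:
        roc = dgn.roc_analysis(table[col].to_numpy(float), labels)
        pd.DataFrame({
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
        }).to_csv(outdir / f"roc_{col}.csv", index=False, float_format="%.6g")
        roc_summary[col] = {
            "auc": roc.auc, "ci95": list(roc.ci95), "cutoff": roc.cutoff,
            "sensitivity": roc.sens_at_cutoff,
            "specificity": roc.spec_at_cutoff, "direction": roc.direction,
        }

    features = table[list(MARKER_COLUMNS)]
    model = dgn.fit_logistic(features, labels)
    combined_roc = dgn.roc_analysis(model.fitted_probabilities, labels,
                                    direction="greater")
    roc_summary["combined_model"] = {
        "auc": combined_roc.auc, "ci95": list(combined_roc.ci95),
        "cutoff": combined_roc.cutoff,
        "sensitivity": combined_roc.sens_at_cutoff,
        "specificity": combined_roc.spec_at_cutoff, "direction": "greater",
    }
    fileio.write_json(outdir / "roc_summary.json", roc_summary)

    ranges = {c: (float(table[c].min()), float(table[c].max()))
              for c in MARKER_COLUMNS}
    nomogram = dgn.build_nomogram(model, ranges)
    fileio.write_json(outdir / "model.json", {
        "features": list(model.feature_names),
        "intercept": model.intercept,
        "coefficients": model.coef,
        "feature_ranges": {k: list(v) for k, v in ranges.items()},
        "nomogram": {
            "anchors": nomogram.anchors,
            "points_per_unit": nomogram.point_slopes,
            "max_points": nomogram.max_points,
            "base_linear_predictor": nomogram.base_lp,
            "lp_per_point": nomogram.points_to_lp,
        },
        "total_points_to_probability": nomogram.table().to_dict("list"),
    })

    calibration = dgn.calibration_bootstrap(model, features, labels,
                                            n_boot=config.n_boot,
                                            seed=boot_seed)
    calibration.to_csv(outdir / "calibration.csv", index=False,
                       float_format="%.6g")

    dca = dgn.decision_curve(model.fitted_probabilities, labels,
                             np.arange(0.01, 1.0, 0.01))
    dca.to_csv(outdir / "dca.csv", index=False, float_format="%.6g")

    return {"roc": roc_summary, "model": model, "nomogram": nomogram,
            "calibration": calibration, "dca": dca}


def run_pipeline(config: RunConfig, outdir,
                 cohort_config: CohortConfig | None = None,
                 manifest_path=None, subject_table_path=None) -> dict:
    """Run every stage, simulating inputs unless real tables are given.

    When ``manifest_path``/``subject_table_path`` are provided they
    replace the simulated signals/markers; otherwise the synthetic
    generator supplies both (the usual mode for this package, since the
    study's raw data are not deposited).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if manifest_path is None or subject_table_path is None:
        sim = stage_simulate(config, outdir, cohort_config)
        table, diffusivity, retest = sim["table"], sim["diffusivity"], sim["retest"]
        manifest_path = manifest_path or sim["manifest"]
    else:
        table = fileio.read_subject_table(subject_table_path)
        diffusivity = None
        retest = None

    coupling_res = stage_coupling(manifest_path, config, outdir)
    if diffusivity is not None:
        table = stage_markers(table, diffusivity, outdir)
    stats_res = stage_stats(table, config, outdir, retest=retest)
    diag_res = stage_diagnostics(table, config, outdir)

    fileio.write_json(outdir / "run_metadata.json", {
        "run_config": config.to_dict(),
        "stage_outputs": sorted(p.name for p in outdir.glob("*.csv"))
        + sorted(p.name for p in outdir.glob("*.json")),
    })
    return {"table": table, "coupling": coupling_res, "stats": stats_res,
            "diagnostics": diag_res, "outdir": outdir}
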