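"""End-to-end pipeline: configuration, orchestration, deterministic outputs.

``run_all`` validates and filters a panel, runs every one-level analysis on
z-scored subject means, every multilevel analysis on z-scored daily rows, the
cross-model component comparison, and writes each result as a CSV table plus
a JSON manifest.  All writers are deterministic (fixed column order, 12-digit
float repr, no timestamps) so reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .domain_models import jive_fit, jive_rank_select, pls_fit, variance_table
from .errors import MMJiveError
from .feature_models import lasso_panel, pcr_fit, pearson_matrix
from .multilevel import (
    ScoreSet,
    anova_decompose,
    compare_components,
    ml_jive,
    ml_pls,
    score_feature_correlations,
)
from .panel import (
    WEAR_COL,
    FLOAT_FMT,
    FeaturePanel,
    filter_valid_days,
    read_domain_map,
    read_panel,
    scale_panel,
    subject_means,
)

logger = logging.getLogger(__name__)

#: every CSV table a full run must emit
OUTPUT_TABLES = [
    "correlations.csv",
    "correlation_pvalues.csv",
    "lasso_coefficients.csv",
    "pca_loadings.csv",
    "pcr_coefficients.csv",
    "pls_weights.csv",
    "pls_correlation_circle.csv",
    "jive_variance_table.csv",
    "mlpls_loadings_between.csv",
    "mlpls_loadings_within.csv",
    "mljive_level_table.csv",
    "mljive_score_correlations_between.csv",
    "mljive_score_correlations_within.csv",
    "component_comparison.csv",
]


@dataclass
class RunConfig:
    """Settings for a full pipeline run; defaults are echoed in the manifest."""

    input_path: str | None = None
    domains_path: str | None = None
    out_dir: str = "mmjive_out"
    seed: int = 0
    min_wear_hours: float | None = 10.0
    alpha_corr: float = 0.1
    alpha_pcr: float = 0.05
    alpha_scores: float = 0.05
    lasso_folds: int = 5
    pcr_k: int | str = "auto"
    pls_components: int = 2
    jive_ranks: tuple[int, int, int] | str = "auto"
    ml_ranks_between: tuple[int, int, int] | str = "auto"
    ml_ranks_within: tuple[int, int, int] | str = "auto"
    n_perm: int = 100
    mpca_retained: float = 0.9
    mpca_method: str = "moments"

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise MMJiveError(f"unknown config keys: {sorted(unknown)}")
        for key in ("jive_ranks", "ml_ranks_between", "ml_ranks_within"):
            if key in raw and not isinstance(raw[key], str):
                raw[key] = tuple(int(v) for v in raw[key])
        return cls(**raw)


def _write_table(df: pd.DataFrame, path: Path, seed: int, index: bool = True) -> None:
    """CSV with a seed-bearing comment header and 12-digit deterministic floats."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"# mmjive v{__version__} seed={seed}\n")
        df.to_csv(fh, float_format=FLOAT_FMT, na_rep="", index=index)


def run_all(config: RunConfig, panel: FeaturePanel | None = None) -> dict:
    """Execute the full framework on a panel and write the report bundle.

    Returns the manifest dict.  Any stage failure aborts with the stage name
    after writing a partial manifest listing completed stages.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "stages_completed": [],
        "tables": [],
    }
    stage = "load"
    try:
        if panel is None:
            if config.input_path is None or config.domains_path is None:
                raise MMJiveError("config must provide input_path and domains_path")
            domain_map = read_domain_map(config.domains_path)
            panel = read_panel(config.input_path, domain_map)
        manifest["n_subjects_raw"] = panel.n_subjects
        manifest["n_rows_raw"] = panel.n_rows

        stage = "filter"
        if config.min_wear_hours is not None and WEAR_COL in panel.data.columns:
            panel, filt = filter_valid_days(panel, config.min_wear_hours)
            manifest["filter"] = {
                "rows_removed": filt.n_rows_removed,
                "subjects_dropped": [str(s) for s in filt.dropped_subjects],
            }
        manifest["n_subjects"] = panel.n_subjects
        manifest["n_rows"] = panel.n_rows
        manifest["P"] = panel.P
        manifest["Q"] = panel.Q
        manifest["stages_completed"].append("load")

        def emit(name: str, df: pd.DataFrame, index: bool = True) -> None:
            _write_table(df, out / name, seed, index=index)
            manifest["tables"].append(name)

        # ---- one-level analyses on exactly z-scored subject means --------
        stage = "scale"
        means_z = subject_means(scale_panel(panel, scope="subject_means").panel)
        manifest["stages_completed"].append("scale")

        stage = "correlate"
        corr = pearson_matrix(means_z, alpha=config.alpha_corr)
        emit("correlations.csv", corr.full_r)
        emit("correlation_pvalues.csv", corr.full_p)
        manifest["stages_completed"].append("correlate")

        stage = "lasso"
        tables = []
        for direction in ("gait_on_PA", "PA_on_gait"):
            tab, _ = lasso_panel(
                means_z, direction, n_folds=config.lasso_folds, seed=seed
            )
            tab.insert(0, "direction", direction)
            tab.index.name = "response"
            tables.append(tab)
        lasso_table = pd.concat(tables)
        emit("lasso_coefficients.csv", lasso_table)
        manifest["stages_completed"].append("lasso")

        stage = "pcr"
        pcr = pcr_fit(means_z, k=config.pcr_k, p_alpha=config.alpha_pcr)
        loadings = pcr.pc_loadings.copy()
        loadings.loc["explained_fraction"] = pcr.pc_explained[: pcr.k]
        emit("pca_loadings.csv", loadings)
        masked = pcr.coefficients.where(pcr.mask)
        emit("pcr_coefficients.csv", masked)
        manifest["pcr"] = {"k": pcr.k, "k_elbow": pcr.k_elbow}
        manifest["stages_completed"].append("pcr")

        stage = "pls"
        pls = pls_fit(
            means_z.x() - means_z.x().mean(axis=0),
            means_z.y() - means_z.y().mean(axis=0),
            n_components=config.pls_components,
            x_names=means_z.pa_features,
            y_names=means_z.gait_features,
        )
        emit("pls_weights.csv", _weights_frame(pls))
        emit("pls_correlation_circle.csv", pls.correlation_circle(), index=False)
        manifest["stages_completed"].append("pls")

        stage = "jive"
        Xt, Yt = means_z.x().T, means_z.y().T
        if config.jive_ranks == "auto":
            ranks = jive_rank_select(Xt, Yt, n_perm=config.n_perm, seed=seed)
        else:
            ranks = tuple(config.jive_ranks)
        jive = jive_fit(Xt, Yt, *ranks)
        manifest["jive_ranks"] = list(ranks)
        emit("jive_variance_table.csv", variance_table(jive))
        feats = {"PA": means_z.pa_features, "gait": means_z.gait_features}
        for label, block in (
            ("joint_PA", jive.J1), ("joint_gait", jive.J2),
            ("individual_PA", jive.A1), ("individual_gait", jive.A2),
        ):
            names = feats["PA"] if label.endswith("PA") else feats["gait"]
            emit(
                f"jive_structures/{label}.csv",
                pd.DataFrame(block, index=names, columns=means_z.subject_ids),
            )
        manifest["stages_completed"].append("jive")

        # ---- multilevel analyses on z-scored daily rows -------------------
        stage = "decompose"
        daily_z = scale_panel(panel, scope="daily_rows")
        decomp = anova_decompose(daily_z)
        manifest["stages_completed"].append("decompose")

        stage = "ml-pls"
        pls_b, pls_w = ml_pls(decomp, n_components=config.pls_components)
        emit("mlpls_loadings_between.csv", _weights_frame(pls_b))
        if pls_w is not None:
            emit("mlpls_loadings_within.csv", _weights_frame(pls_w))
        manifest["stages_completed"].append("ml-pls")

        stage = "ml-jive"
        mlj = ml_jive(
            decomp,
            retained_fraction=config.mpca_retained,
            ranks_between=config.ml_ranks_between,
            ranks_within=config.ml_ranks_within,
            n_perm=config.n_perm,
            seed=seed,
            mpca_method=config.mpca_method,
        )
        manifest["ml_jive_ranks"] = {k: list(v) for k, v in mlj.ranks.items()}
        emit("mljive_level_table.csv", mlj.level_table)
        score_corrs = score_feature_correlations(mlj, decomp, alpha=config.alpha_scores)
        for level in ("between", "within"):
            lc = score_corrs[level]
            starred = lc.r.round(12).astype(object)
            starred = starred.where(~lc.mask, starred.astype(str) + "*")
            emit(f"mljive_score_correlations_{level}.csv", starred)
        manifest["stages_completed"].append("ml-jive")

        stage = "compare"
        sets = _standard_score_sets(means_z, pls, jive, decomp, pls_b, pls_w, mlj)
        comparison = compare_components(sets, n_components=2)
        emit("component_comparison.csv", comparison)
        manifest["stages_completed"].append("compare")

    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest(manifest, out)
        raise

    _write_manifest(manifest, out)
    return manifest


def _weights_frame(pls) -> pd.DataFrame:
    """Stacked per-feature weight table for both blocks of a PLS model."""
    k = pls.n_components
    cols = [f"comp{j + 1}" for j in range(k)]
    xw = pd.DataFrame(pls.x_weights, index=pls.x_names, columns=cols)
    xw.insert(0, "domain", "PA")
    yw = pd.DataFrame(pls.y_weights, index=pls.y_names, columns=cols)
    yw.insert(0, "domain", "gait")
    frame = pd.concat([xw, yw])
    frame.index.name = "feature"
    return frame


def _standard_score_sets(means_z, pls, jive, decomp, pls_b, pls_w, mlj) -> list[ScoreSet]:
    subjects = means_z.subject_ids
    obs_subjects = [decomp.subjects[i] for i in decomp.subject_index]
    sets = [
        ScoreSet("PLS", pls.x_scores, "subject", subjects),
        ScoreSet("PLS.B", pls_b.x_scores, "subject", decomp.subjects),
    ]
    if pls_w is not None:
        sets.append(ScoreSet("PLS.W", pls_w.x_scores, "observation", obs_subjects))
    if jive.r > 0:
        sets.append(ScoreSet("JIVE.JT", jive.joint_scores.T, "subject", subjects))
    if mlj.between_jive.r > 0:
        sets.append(
            ScoreSet("JIVE.B.JT", mlj.between_jive.joint_scores.T, "subject", decomp.subjects)
        )
    if mlj.within_jive.r > 0:
        sets.append(
            ScoreSet("JIVE.W.JT", mlj.within_jive.joint_scores.T, "observation", obs_subjects)
        )
    return sets


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
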