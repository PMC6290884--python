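"""Readers, writers, configuration and the end-to-end pipeline.

The pipeline runs the stages in their natural order: map metabolite names to
HMDB accessions, transform to pathway deregulation scores (curves fitted on
the training split only), select phenotype-relevant pathways on the training
scores, train and evaluate the classifiers on the hold-out split, and
optionally calibrate against clinical covariates.

Every output file carries a ``#``-prefixed metadata header (tool version,
database snapshot versions, master seed). Outputs deliberately contain no
timestamps: a rerun with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import (
    ALGORITHM_ORDER,
    CVConfig,
    SplitSpec,
    build_combined_models,
    correlation_matrix,
    encode_clinical,
    encode_labels,
    min_max_scale,
    run_all_algorithms,
    split_train_test,
)
from .db import load_metabolite_db, load_pathway_db
from .errors import ConfigError, ProfileFormatError
from .mapping import DEFAULT_MAX_NORM_DIST, map_features
from .pds import MetaboliteProfile, PdsConfig, cluster_for_heatmap, fit_pds, score_new_samples
from .select import select_features

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# file I/O

def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_profile(path, control_label: str, transpose: bool = False) -> MetaboliteProfile:
    """Read an intensity table: rows = samples, column 1 sample id, column 2
    phenotype label, remaining columns metabolite names/IDs (``transpose``
    accepts metabolite-as-rows tables). Duplicate metabolite columns are
    collapsed by their mean with a warning.

    The header is handled manually so genuinely duplicated metabolite names
    are seen as duplicates instead of being silently renamed.
    """
    from io import StringIO

    with open(path, "rt", encoding="utf-8") as fh:
        text = "".join(ln for ln in fh if not ln.startswith("#"))
    raw = pd.read_csv(StringIO(text), sep=_sep_for(path), header=None, dtype=str)
    if transpose:
        raw = raw.T.reset_index(drop=True)
    header = [str(h) for h in raw.iloc[0].tolist()]
    if len(header) < 3:
        raise ProfileFormatError(f"{path}: need a phenotype column plus at least one metabolite")
    sample_ids = [str(s) for s in raw.iloc[1:, 0].tolist()]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ProfileFormatError(f"{path}: duplicate sample ids {dupes}")
    labels = pd.Series([str(v) for v in raw.iloc[1:, 1].tolist()], index=sample_ids)
    if labels.nunique() < 2:
        raise ProfileFormatError(f"{path}: phenotype column has fewer than 2 levels")
    values = raw.iloc[1:, 2:].copy()
    values.index = sample_ids
    values.columns = header[2:]
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.any().any():
        row = bad.any(axis=1).idxmax()
        col = bad.columns[bad.loc[row].argmax()]
        raise ProfileFormatError(f"{path}: non-numeric intensity at sample {row!r}, metabolite {col!r}")
    if numeric.columns.duplicated().any():
        dupes = sorted(numeric.columns[numeric.columns.duplicated()].unique())
        logger.warning("collapsing duplicate metabolite columns by mean: %s", dupes)
        numeric = numeric.T.groupby(level=0, sort=False).mean().T
    return MetaboliteProfile(
        intensities=numeric.T,
        phenotype=labels,
        control_label=control_label,
    )


def write_profile(profile: MetaboliteProfile, path, label_column: str = "phenotype") -> None:
    out = profile.intensities.T
    out.insert(0, label_column, profile.phenotype)
    out.to_csv(path, sep=_sep_for(path), index_label="sample_id")


def metadata_header(seed: int | None = None, **extra: str) -> list[str]:
    fields = {"tool": f"pdskit {__version__}"}
    if seed is not None:
        fields["seed"] = str(seed)
    fields.update({k: str(v) for k, v in extra.items()})
    return [f"# {k}: {v}" for k, v in fields.items()]


def write_table(frame: pd.DataFrame, path, seed: int | None = None, index: bool = True, **meta) -> None:
    path = Path(path)
    with open(path, "wt", encoding="utf-8") as fh:
        for line in metadata_header(seed=seed, **meta):
            fh.write(line + "\n")
        frame.to_csv(fh, sep=_sep_for(path), index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path), comment="#", index_col=index_col)


# --------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    profile: str | None = None
    metabolite_db: str | None = None
    pathway_db: str | None = None
    clinical: str | None = None
    outdir: str = "pdskit_out"
    control_label: str = "control"
    transpose: bool = False
    max_norm_dist: float = DEFAULT_MAX_NORM_DIST
    fit_on: str = "train"          # train | all
    pds: PdsConfig = field(default_factory=PdsConfig)
    selection_method: str = "infogain"
    top_k: int = 20
    algorithms: list[str] = field(default_factory=lambda: list(ALGORITHM_ORDER))
    train_fraction: float = 0.8
    n_folds: int = 10
    importance_repeats: int = 20
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        pds_raw = raw.pop("pds", {})
        cfg = cls(**raw)
        cfg.pds = PdsConfig(**pds_raw)
        return cfg

    def validate(self) -> None:
        for name in ("profile", "metabolite_db", "pathway_db"):
            value = getattr(self, name)
            if value is None:
                raise ConfigError(f"config missing required path: {name}")
            if not Path(value).exists():
                raise ConfigError(f"{name} path does not exist: {value}")
        if self.clinical is not None and not Path(self.clinical).exists():
            raise ConfigError(f"clinical path does not exist: {self.clinical}")
        if self.fit_on not in ("train", "all"):
            raise ConfigError(f"fit_on must be 'train' or 'all', got {self.fit_on!r}")
        unknown = set(self.algorithms) - set(ALGORITHM_ORDER)
        if unknown:
            raise ConfigError(f"unknown algorithms: {sorted(unknown)}")


# --------------------------------------------------------------------------
# the end-to-end pipeline

def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute map → pds → select → train/evaluate → (optional) calibrate.

    Writes every intermediate artifact plus a machine-readable run manifest
    into ``config.outdir`` and returns that directory.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    manifest: dict = {
        "tool": f"pdskit {__version__}",
        "seed": seed,
        "config": {
            "control_label": config.control_label,
            "max_norm_dist": config.max_norm_dist,
            "fit_on": config.fit_on,
            "selection_method": config.selection_method,
            "top_k": config.top_k,
            "algorithms": config.algorithms,
            "train_fraction": config.train_fraction,
            "n_folds": config.n_folds,
            "min_pathway_size": config.pds.min_pathway_size,
            "var_explained": config.pds.var_explained,
        },
        "stages": {},
    }

    t0 = _stage("load")
    met_db = load_metabolite_db(config.metabolite_db)
    path_db = load_pathway_db(config.pathway_db)
    profile = read_profile(config.profile, control_label=config.control_label, transpose=config.transpose)
    manifest["db_versions"] = {"metabolite_db": met_db.version, "pathway_db": path_db.version}
    logger.info("load done in %.2fs", time.perf_counter() - t0)

    t0 = _stage("map")
    table = map_features(list(profile.intensities.index), met_db, max_norm_dist=config.max_norm_dist)
    rows = [
        {
            "input_name": r.input_name,
            "hmdb_id": r.hmdb_id or "",
            "tier": r.tier,
            "edit_distance": "" if r.edit_distance is None else r.edit_distance,
            "matched_string": r.matched_string or "",
        }
        for r in table.results
    ]
    write_table(pd.DataFrame(rows), outdir / "mapping.tsv", seed=seed, db=met_db.version, index=False)
    mapped = table.mapped_ids()
    intens = profile.intensities.loc[[n for n in profile.intensities.index if n in mapped]]
    intens.index = [mapped[n] for n in intens.index]
    if intens.index.duplicated().any():
        logger.warning("multiple input names map to the same accession; collapsing by mean")
        intens = intens.groupby(level=0, sort=True).mean()
    profile = MetaboliteProfile(intens, profile.phenotype, config.control_label)
    manifest["stages"]["map"] = {"n_input": table.n_input, "n_mapped": table.n_mapped}
    logger.info("map done in %.2fs: %d of %d mapped", time.perf_counter() - t0, table.n_mapped, table.n_input)

    t0 = _stage("split")
    train_ids, test_ids = split_train_test(
        profile.sample_ids, profile.phenotype.to_numpy(), SplitSpec(config.train_fraction, True, seed)
    )
    split_frame = pd.DataFrame(
        {"sample_id": train_ids + test_ids, "partition": ["train"] * len(train_ids) + ["test"] * len(test_ids)}
    )
    write_table(split_frame, outdir / "split_manifest.csv", seed=seed, index=False)
    manifest["stages"]["split"] = {"n_train": len(train_ids), "n_test": len(test_ids)}

    t0 = _stage("pds")
    fit_profile = profile if config.fit_on == "all" else profile.subset_samples(train_ids)
    pds_fit, model = fit_pds(fit_profile, path_db, config.pds)
    pds_train = pds_fit.scores[train_ids] if config.fit_on == "all" else pds_fit.scores
    pds_test = score_new_samples(model, profile.subset_samples(test_ids)).scores
    write_table(pds_train, outdir / "pds_train.csv", seed=seed, db=path_db.version, fit_on=config.fit_on)
    write_table(pds_test, outdir / "pds_test.csv", seed=seed, db=path_db.version, fit_on=config.fit_on)
    if pds_fit.skipped_pathways:
        skipped = pd.DataFrame(pds_fit.skipped_pathways, columns=["pathway_id", "reason"])
        write_table(skipped, outdir / "skipped_pathways.tsv", seed=seed, index=False)
    row_order, col_order = cluster_for_heatmap(pds_fit)
    write_table(
        pd.DataFrame({"axis": ["row"] * len(row_order) + ["column"] * len(col_order), "id": row_order + col_order}),
        outdir / "heatmap_order.csv",
        seed=seed,
        index=False,
    )
    manifest["stages"]["pds"] = {
        "n_pathways": int(pds_train.shape[0]),
        "n_skipped": len(pds_fit.skipped_pathways),
    }
    logger.info("pds done in %.2fs: %d pathways", time.perf_counter() - t0, pds_train.shape[0])

    t0 = _stage("select")
    y_train = encode_labels(profile.phenotype.loc[train_ids].to_numpy(), config.control_label)
    y_test = encode_labels(profile.phenotype.loc[test_ids].to_numpy(), config.control_label)
    ranking = select_features(pds_train, y_train, method=config.selection_method, top_k=config.top_k)
    write_table(ranking.to_frame(), outdir / "feature_ranking.tsv", seed=seed, index=False)
    selected = ranking.selected_ids
    if not selected:
        selected = [e.pathway_id for e in ranking.entries[: min(5, len(ranking.entries))]]
        logger.warning("no feature scored > 0; falling back to the top %d ranked pathways", len(selected))
    manifest["stages"]["select"] = {"n_selected": len(selected), "selected": selected}
    logger.info("select done in %.2fs: %d features", time.perf_counter() - t0, len(selected))

    t0 = _stage("train")
    X_train = pds_train.loc[selected].T
    X_test = pds_test.loc[selected].T
    cv = CVConfig(n_folds=config.n_folds, stratified=True, seed=seed)
    report = run_all_algorithms(
        X_train, y_train, X_test, y_test, cv,
        algorithms=config.algorithms, importance_repeats=config.importance_repeats,
    )
    metric_rows = []
    for alg in config.algorithms:
        for split_name, metrics in (("train_cv", report.cv_metrics[alg]), ("test", report.test_metrics[alg])):
            for metric, value in sorted(metrics.items()):
                metric_rows.append({"algorithm": alg, "split": split_name, "metric": metric, "value": round(value, 10)})
        write_table(report.roc_points[alg].round(10), outdir / f"roc_{alg}.csv", seed=seed, index=False)
    write_table(pd.DataFrame(metric_rows), outdir / "metrics.csv", seed=seed, index=False)
    importance = pd.DataFrame({alg: report.importance[alg] for alg in config.algorithms}).round(10)
    importance.index.name = "pathway_id"
    write_table(importance, outdir / "importance.csv", seed=seed)
    best = report.best_algorithm("auc")
    with open(outdir / "best_model.json", "wt") as fh:
        json.dump(
            {"algorithm": best, "metric": "auc", "value": round(report.test_metrics[best]["auc"], 10),
             "selected_params": report.selected_params[best]},
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    manifest["stages"]["train"] = {
        "best_algorithm": best,
        "best_test_auc": round(report.test_metrics[best]["auc"], 10),
    }
    logger.info("train done in %.2fs: best %s", time.perf_counter() - t0, best)

    if config.clinical is not None:
        t0 = _stage("calibrate")
        clinical = read_table(config.clinical)
        y_all = encode_labels(profile.phenotype.to_numpy(), config.control_label)
        calib = build_combined_models(
            pd.concat([X_train, X_test]).loc[train_ids + test_ids],
            clinical,
            pd.Series(y_all, index=profile.sample_ids).loc[train_ids + test_ids].to_numpy(),
            train_ids,
            test_ids,
            cv,
            algorithm=best,
        )
        rows = []
        for name, (_, ev) in calib.reports.items():
            for metric, value in sorted(ev.metrics.items()):
                rows.append({"model": name, "metric": metric, "value": round(value, 10)})
            write_table(ev.roc_points.round(10), outdir / f"roc_calibration_{name}.csv", seed=seed, index=False)
        write_table(pd.DataFrame(rows), outdir / "calibration_metrics.csv", seed=seed, index=False)
        clin_train_scaled, _ = min_max_scale(encode_clinical(clinical.loc[train_ids]))
        corr, flagged = correlation_matrix(clin_train_scaled, X_train)
        write_table(corr.round(10), outdir / "correlation_matrix.csv", seed=seed)
        manifest["stages"]["calibrate"] = {"aucs": {k: round(v, 10) for k, v in calib.aucs().items()},
                                           "zero_variance_flagged": flagged}
        logger.info("calibrate done in %.2fs", time.perf_counter() - t0)

    with open(outdir / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
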