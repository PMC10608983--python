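"""End-to-end study workflow.

``run_study`` chains the full analysis: load or simulate a bucket
table, PCA overview, class-weighted surrogate forest with OOB report,
SMD and Boruta variable selection with their overlap, mean adjusted
agreement relations on the union of the selections, same-signal
reduction, Ward clustering of the relation matrix, superimposed-bucket
disambiguation when annotations are available, and per-cluster boxplot
data — everything written as CSV/JSON artifacts plus a deterministic
run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import __version__
from .boruta import boruta_select, selection_overlap
from .buckets import (
    AnnotationMap,
    BucketTable,
    read_annotation_map,
    read_bucket_table,
    write_annotation_map,
    write_bucket_table,
)
from .forest import SurrogateForest, default_params
from .relations import (
    adjacency_signal_groups,
    cluster_boxplot_data,
    cluster_relations,
    correlation_matrix,
    disambiguate_bucket,
    mean_adjusted_agreement,
    reduce_same_signal,
)
from .simulate import truffle_like_scenario
from .smd import select_variables_smd

__all__ = ["PCAScores", "pca_scores", "RunConfig", "run_study", "StageError"]

log = logging.getLogger("nmrforest")


@dataclass
class PCAScores:
    """Scores on the first principal components of the centred matrix."""

    scores: pd.DataFrame  # samples x components, PC1, PC2, ...
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # buckets x components


def pca_scores(table: BucketTable, n_components: int = 2) -> PCAScores:
    """PCA of the mean-centred (unscaled) bucket matrix.

    Sign convention: the largest-magnitude loading of each component is
    made positive, so scores are reproducible across runs and row
    orders.
    """
    n, p = table.intensities.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(
            f"n_components must be within 1..{min(n - 1, p)}, got {n_components}"
        )
    X = table.intensities - table.intensities.mean(axis=0)
    if not np.any(X):
        scores = np.zeros((n, n_components))
        load = np.zeros((p, n_components))
        ratio = np.zeros(n_components)
    else:
        pca = PCA(n_components=n_components, svd_solver="full")
        scores = pca.fit_transform(X)
        load = pca.components_.T
        for j in range(n_components):
            i = int(np.argmax(np.abs(load[:, j])))
            if load[i, j] < 0:
                load[:, j] = -load[:, j]
                scores[:, j] = -scores[:, j]
        ratio = pca.explained_variance_ratio_
    cols = [f"PC{i + 1}" for i in range(n_components)]
    sdf = pd.DataFrame(scores, index=pd.Index(table.sample_ids, name="sample_id"), columns=cols)
    sdf.insert(0, "class", table.class_labels)
    return PCAScores(
        scores=sdf,
        explained_variance_ratio=np.asarray(ratio),
        loadings=pd.DataFrame(load, index=pd.Index(table.labels, name="bucket"), columns=cols),
    )


@dataclass
class RunConfig:
    """Configuration of a full study run.

    ``input_path`` loads a bucket table; with ``input_path=None`` the
    packaged truffle-like scenario is simulated instead.  Forest
    parameters default to the study conventions for the table at hand;
    ``ntree`` here is the desk-scale default, not the ntree=10000 of a
    full-size production run.
    """

    outdir: str | Path = "nmrforest_run"
    input_path: str | Path | None = None
    label_column: str = "class"
    annotations_path: str | Path | None = None
    scenario: str = "truffle_like"
    seed: int = 0
    ntree: int = 500
    mtry: int | None = None
    s: int | None = None
    min_node_size: int = 1
    n_shadow: int | None = None
    smd_quantile: float = 0.01
    boruta_confidence: float = 0.01
    boruta_max_runs: int = 25
    importance_mode: str = "corrected"
    relation_on: str = "union"  # or "intersection"
    n_clusters: int = 4
    pca_components: int = 2
    verbosity: int = 1

    def validate(self) -> None:
        if self.ntree < 1:
            raise ValueError(f"ntree must be >= 1, got {self.ntree}")
        if self.relation_on not in ("union", "intersection"):
            raise ValueError("relation_on must be 'union' or 'intersection'")
        if self.scenario not in ("truffle_like",):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(d["outdir"])
        if d["input_path"] is not None:
            d["input_path"] = str(d["input_path"])
        if d["annotations_path"] is not None:
            d["annotations_path"] = str(d["annotations_path"])
        return d


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _write_json(path: Path, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_study(config: RunConfig) -> Path:
    """Execute the full workflow; returns the output directory.

    Any stage error aborts the run with a :class:`StageError`; partial
    outputs are retained next to a ``FAILED`` marker naming the stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    level = logging.DEBUG if config.verbosity > 1 else (logging.INFO if config.verbosity else logging.WARNING)
    logging.basicConfig(level=level, format="%(message)s")
    timings: dict[str, float] = {}
    manifest: dict = {"config": config.to_dict(), "version": __version__, "stages": []}

    def stage(name: str):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log.info("[%s]", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    (outdir / "FAILED").write_text(f"{name}: {exc}\n", encoding="utf-8")
                    raise StageError(name, exc) from exc
                timings[name] = time.perf_counter() - self_inner.t0
                manifest["stages"].append(name)
                return False

        return _Ctx()

    annotations: AnnotationMap | None = None
    truth = None
    with stage("load"):
        if config.input_path is not None:
            table = read_bucket_table(config.input_path, label_column=config.label_column)
        else:
            table, truth = truffle_like_scenario(seed=config.seed)
            write_bucket_table(table, outdir / "table.csv")
            write_annotation_map(truth.to_annotation_map(), outdir / "annotations.csv")
            truth.concentrations.rename_axis("sample_id").to_csv(outdir / "concentrations.csv")
        if config.annotations_path is not None:
            annotations = read_annotation_map(config.annotations_path)
            annotations.validate_against(table)
        elif truth is not None:
            annotations = truth.to_annotation_map()
        manifest["n_samples"] = table.n_samples
        manifest["n_buckets"] = table.n_buckets
        manifest["classes"] = table.class_counts()

    with stage("pca"):
        pca = pca_scores(table, n_components=config.pca_components)
        pca.scores.to_csv(outdir / "pca_scores.csv")
        manifest["pca_explained_variance_ratio"] = [
            round(float(v), 6) for v in pca.explained_variance_ratio
        ]

    with stage("forest"):
        params = default_params(
            table.n_buckets, table.class_counts(), ntree=config.ntree,
            min_node_size=config.min_node_size, seed=config.seed,
        )
        if config.mtry is not None:
            params.mtry = config.mtry
        if config.s is not None:
            params.s = config.s
        results = SurrogateForest.from_bucket_table(table, params).fit(seed=config.seed)
        manifest["forest"] = {
            "ntree": params.ntree, "mtry": params.mtry, "s": params.s,
            "min_node_size": params.min_node_size, "seed": config.seed,
        }

    with stage("oob_report"):
        report = results.oob_report()
        report.confusion.rename_axis("true").to_csv(outdir / "oob_confusion.csv")
        _write_json(
            outdir / "classification_report.json",
            {
                "accuracy": report.accuracy,
                "oob_error": report.oob_error,
                "sensitivity": {k: float(v) for k, v in report.sensitivity.items()},
                "specificity": {k: float(v) for k, v in report.specificity.items()},
                "n_excluded": report.n_excluded,
            },
        )
        manifest["oob_accuracy"] = report.accuracy

    with stage("smd_selection"):
        smd_res = select_variables_smd(
            results=results,
            n_shadow=config.n_shadow,
            quantile=config.smd_quantile,
            seed=config.seed,
        )
        smd_res.to_csv(outdir / "smd_scores.csv")
        manifest["n_selected_smd"] = len(smd_res.selected)

    with stage("boruta_selection"):
        boruta_res = boruta_select(
            table,
            params,
            importance_mode=config.importance_mode,
            confidence=config.boruta_confidence,
            max_runs=config.boruta_max_runs,
            seed=config.seed,
        )
        boruta_res.to_csv(outdir / "boruta_decisions.csv")
        manifest["n_confirmed_boruta"] = len(boruta_res.confirmed)

    with stage("selection_overlap"):
        ov = selection_overlap(smd_res.selected, boruta_res.confirmed)
        _write_json(
            outdir / "selection_overlap.json",
            {"common": ov.n_common, "smd_only": ov.n_only_a, "boruta_only": ov.n_only_b},
        )

    with stage("relations"):
        if config.relation_on == "union":
            chosen = sorted(set(smd_res.selected) | set(boruta_res.confirmed))
        else:
            chosen = sorted(set(smd_res.selected) & set(boruta_res.confirmed))
        if len(chosen) < 2:
            raise ValueError("fewer than 2 selected variables; nothing to relate")
        matrix = mean_adjusted_agreement(results, variables=chosen)
        matrix.values.rename_axis("bucket").to_csv(outdir / "relations.csv")
        matrix.directed.rename_axis("bucket").to_csv(outdir / "relations_directed.csv")
        correlation_matrix(table, chosen).rename_axis("bucket").to_csv(
            outdir / "correlations.csv"
        )
        manifest["relation_variables"] = chosen

    with stage("reduce_same_signal"):
        if annotations is not None:
            groups = annotations.signal_groups()
        else:
            groups = adjacency_signal_groups(chosen, matrix)
        reps = reduce_same_signal(chosen, smd_res.smd, groups)
        pd.Series(reps, name="bucket").to_csv(outdir / "representatives.csv", index=False)
        manifest["n_representatives"] = len(reps)

    with stage("cluster_relations"):
        k = min(config.n_clusters, len(reps))
        if len(reps) >= 2:
            sub = mean_adjusted_agreement(results, variables=reps)
            clustering = cluster_relations(sub, k=k)
            clustering.to_frame().to_csv(outdir / "clusters.csv")
            (outdir / "dendrogram.txt").write_text(
                clustering.dendrogram_text() + "\n", encoding="utf-8"
            )
            cluster_boxplot_data(table, clustering.members).to_csv(
                outdir / "cluster_boxplot_data.csv", index=False
            )
            manifest["n_clusters"] = clustering.n_clusters
        else:
            manifest["n_clusters"] = len(reps)

    with stage("disambiguate"):
        rows = []
        if annotations is not None:
            met_buckets = annotations.metabolite_buckets()
            for label in sorted(set(chosen) & set(annotations.entries)):
                mets = sorted(annotations.metabolites(label))
                if len(mets) < 2:
                    continue
                cands = {m: [b for b in met_buckets[m] if b != label] for m in mets}
                for met, verdict in disambiguate_bucket(label, cands, matrix).items():
                    rows.append((label, met, verdict.status, verdict.max_relation, verdict.reason))
        pd.DataFrame(
            rows, columns=["bucket", "metabolite", "verdict", "max_relation", "reason"]
        ).to_csv(outdir / "disambiguation.csv", index=False)

    _write_json(outdir / "manifest.json", manifest)
    with open(outdir / "run.log", "w", encoding="utf-8") as fh:
        for name, dt in timings.items():
            fh.write(f"{name}: {dt:.2f} s\n")
        fh.write(f"total: {sum(timings.values()):.2f} s\n")
    log.info("run complete: %s", outdir)
    return outdir
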