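"""Matrix/label I/O and the end-to-end pipeline.

Expression matrices travel as dense TSV/CSV, features in rows and
samples in columns, sample IDs in the header row and feature IDs in the
first column (delimiter auto-detected). The pipeline is
normalization -> kNN graph -> sgLRR solve -> affinity -> Ncuts, with
repeated clustering and metric averaging when ground-truth labels are
supplied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .affinity import build_affinity
from .graph import ExpressionMatrix, build_knn_graph
from .ncuts import ClusteringResult, ncut_cluster, repeated_cluster_metrics
from .solver import SgLRRParams, SgLRRSolution, solve_sglrr

__all__ = [
    "RunConfig",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_labels_csv",
    "write_labels_csv",
    "run_pipeline",
]

logger = logging.getLogger("sglrr.pipeline")

NORMALIZATIONS = ("none", "per_sample_l2", "log2p1")


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    input_path: str | Path
    n_clusters: int
    labels_path: str | Path | None = None
    params: SgLRRParams = field(default_factory=SgLRRParams)
    repeats: int = 50
    seed: int = 0
    kmeans_restarts: int = 20
    normalization: str = "none"
    transpose: bool = False
    output_dir: str | Path | None = None
    write_affinity: bool = False

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(
                f"normalization must be one of {NORMALIZATIONS}, got {self.normalization!r}"
            )
        if not Path(self.input_path).exists():
            raise FileNotFoundError(self.input_path)
        if self.labels_path is not None and not Path(self.labels_path).exists():
            raise FileNotFoundError(self.labels_path)


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a features-x-samples matrix from TSV/CSV.

    First row holds sample IDs, first column feature IDs. Non-numeric
    cells and ragged rows raise ``ValueError`` naming the location;
    duplicate IDs are rejected.
    """
    path = Path(path)
    sep = _detect_sep(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        raise ValueError(f"duplicate sample IDs in {path}")
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, header=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"malformed table in {path}: {exc}") from exc
    if df.index.has_duplicates:
        raise ValueError(f"duplicate feature IDs in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        i, j = np.argwhere(bad.values)[0]
        raise ValueError(
            f"non-numeric cell at feature {df.index[i]!r}, sample {df.columns[j]!r} "
            f"in {path}: {df.iat[i, j]!r}"
        )
    if numeric.isna().any().any():
        i, j = np.argwhere(numeric.isna().values)[0]
        raise ValueError(f"missing value at feature {df.index[i]!r}, sample {df.columns[j]!r}")
    return ExpressionMatrix(
        # numpy's string conversion is correctly rounded, unlike the fast
        # pandas to_numeric path, so full-precision roundtrips hold
        values=df.values.astype(np.float64),
        feature_ids=[str(x) for x in df.index],
        sample_ids=[str(x) for x in df.columns],
    )


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.feature_ids, columns=matrix.sample_ids)
    # float repr is shortest-roundtrip, so values survive exactly
    df.to_csv(path, sep="\t", float_format=lambda x: repr(float(x)))


def read_labels_csv(path: str | Path, sample_ids: list[str]) -> np.ndarray:
    """Read a two-column (sample_id, label) file and align to sample order."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path), header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"labels file {path} needs two columns (sample_id, label)")
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ValueError(f"labels file {path} missing samples: {missing[:5]}")
    return np.asarray([mapping[s] for s in sample_ids])


def write_labels_csv(sample_ids, labels, path: str | Path) -> None:
    pd.DataFrame({"sample_id": list(sample_ids), "label": list(labels)}).to_csv(
        path, index=False
    )


def normalize(values: np.ndarray, method: str) -> np.ndarray:
    """Optional preprocessing of the features-x-samples matrix."""
    if method == "none":
        return values
    if method == "per_sample_l2":
        norms = np.linalg.norm(values, axis=0)
        norms[norms == 0] = 1.0
        return values / norms[None, :]
    if method == "log2p1":
        if np.any(values < 0):
            raise ValueError("log2p1 normalization requires nonnegative values")
        return np.log2(values + 1.0)
    raise ValueError(f"unknown normalization {method!r}")


def run_pipeline(config: RunConfig) -> tuple[ClusteringResult, dict | None, SgLRRSolution]:
    """Run the full clustering pipeline described by ``config``.

    Returns the clustering result, the metrics summary (None when no
    ground-truth labels were given) and the solver solution. When
    ``config.output_dir`` is set, writes labels CSV, metrics JSON, the
    residual history CSV and optionally the affinity matrix TSV.
    """
    matrix = read_expression_tsv(config.input_path)
    if config.transpose:
        matrix = ExpressionMatrix(
            values=matrix.values.T,
            feature_ids=matrix.sample_ids,
            sample_ids=matrix.feature_ids,
        )
    n = matrix.n_samples
    if config.n_clusters > n:
        raise ValueError(f"n_clusters={config.n_clusters} exceeds n={n} samples")

    true_labels = None
    if config.labels_path is not None:
        true_labels = read_labels_csv(config.labels_path, matrix.sample_ids)

    values = normalize(matrix.values, config.normalization)
    matrix = ExpressionMatrix(values, matrix.feature_ids, matrix.sample_ids)

    graph = build_knn_graph(matrix, k=config.params.k_neighbors)
    solution = solve_sglrr(matrix, graph, config.params)
    if not solution.converged:
        logger.warning("solver did not converge; clustering the last iterate")
    aff = build_affinity(solution.Z)

    metrics_summary: dict | None = None
    if true_labels is not None:
        metrics_summary = repeated_cluster_metrics(
            aff,
            config.n_clusters,
            true_labels,
            n_repeats=config.repeats,
            seed=config.seed,
            n_init=config.kmeans_restarts,
        )
        labels = metrics_summary["repeat_results"][0]
        result = ClusteringResult(
            labels=labels,
            n_clusters=config.n_clusters,
            repeat_results=metrics_summary["repeat_results"],
        )
    else:
        result = ncut_cluster(
            aff, config.n_clusters, seed=config.seed, n_init=config.kmeans_restarts
        )

    if config.output_dir is not None:
        _write_outputs(config, matrix, solution, aff, result, metrics_summary)
    return result, metrics_summary, solution


def _write_outputs(config, matrix, solution, aff, result, metrics_summary) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_labels_csv(matrix.sample_ids, result.labels, out / "labels.csv")
    pd.DataFrame(
        solution.residual_history, columns=["primal_residual", "z_gap"]
    ).to_csv(out / "residuals.csv", index_label="iteration")
    meta = {
        "converged": solution.converged,
        "n_iter": solution.n_iter,
        "n_samples": matrix.n_samples,
        "n_features": matrix.n_features,
        "affinity_rank": aff.rank_used,
    }
    if metrics_summary is not None:
        # percentage convention for display, matching the field's tables
        meta["metrics"] = {
            name: {
                "mean": 100.0 * metrics_summary[name]["mean"],
                "std": 100.0 * metrics_summary[name]["std"],
            }
            for name in ("acc", "mcc", "ri", "nmi")
        }
        meta["n_repeats"] = metrics_summary["n_repeats"]
    with open(out / "metrics.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    if config.write_affinity:
        pd.DataFrame(aff.H, index=matrix.sample_ids, columns=matrix.sample_ids).to_csv(
            out / "affinity.tsv", sep="\t"
        )
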