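"""Clustered binary grey wolf feature selection: model and results.

The selector orchestrates the full procedure on an encoded dataset:

1. split off a stratified held-out fraction (selection sees only the
   training rows, evaluation only the held-out rows);
2. discretise the training block, screen out all-zero columns, and
   compute the pairwise feature MI matrix plus each feature's MI with
   the class label;
3. optionally pre-filter to the most label-relevant fraction;
4. cluster the retained features on their MI-profile rows with k-means;
5. run an independent binary grey wolf search inside every cluster
   (single-feature clusters skip the search and are kept iff the
   singleton beats the empty-set baseline);
6. aggregate the per-cluster selections into one sorted feature set.

The public surface follows the model/results idiom: build a
:class:`ClusteredBGWOSelector` from data, call :meth:`fit`, and read
estimates and diagnostics off the returned :class:`SelectionResults`
(``summary()``, ``rank_selected()``, ``evaluate()``).

Every stage seed is derived from one master seed through a fixed
spawn-key scheme, so stages are individually reproducible and the whole
fit is a pure function of (data, config).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import bgwo, clustering, mi
from .encoding import FeatureMatrix, encode_dataset, index_to_tripeptide
from .evaluation import DEFAULT_CLASSIFIERS, evaluate_classifiers
from .sequence_io import (attach_labels, preprocess, read_fasta,
                          read_label_table)

_STAGE_IDS = {"split": 1, "kmeans": 2, "bgwo": 3, "fitness": 4, "eval": 5}


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Derive a stage seed (< 2^31) from the master seed.

    The derivation uses a seed sequence keyed by (stage id, index), so
    e.g. every cluster's optimizer gets an independent, reproducible
    stream.
    """
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(_STAGE_IDS[stage], index))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """All tunable settings of the selector, with reproducible defaults.

    ``n_clusters=None`` uses max(2, round(sqrt(d_retained))).
    ``prefilter_top_fraction=1.0`` disables the label-relevance
    pre-filter (relevance is then reporting-only).
    """

    n_bins: int = 5
    n_clusters: int | None = None
    kmeans_restarts: int = 10
    kmeans_max_iter: int = 300
    kmeans_tol: float = 1e-6
    pop_size: int = 10
    n_iterations: int = 30
    lambda_weight: float = 0.99
    cv_folds: int = 3
    inner_classifier: str = "centroid"
    prefilter_top_fraction: float = 1.0
    test_fraction: float = 0.3
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prefilter_top_fraction <= 1.0:
            raise ValueError("prefilter_top_fraction must be in (0, 1]")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        # validate the shared fitness fields early
        bgwo.FitnessConfig(lambda_weight=self.lambda_weight,
                           cv_folds=self.cv_folds,
                           inner_classifier=self.inner_classifier)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def aggregate(per_cluster: dict, index_maps: dict) -> list[int]:
    """Union the per-cluster selections in original 1-based coordinates.

    ``index_maps[c]`` holds the original feature indices of cluster c's
    bit positions.  The maps must partition the feature set; overlap is
    an error.  Returns a sorted index list (empty selections everywhere
    produce an empty list with a warning).
    """
    seen: set[int] = set()
    for c, idx in index_maps.items():
        idx = set(int(i) for i in idx)
        if seen & idx:
            raise ValueError(f"cluster {c}: overlapping index maps "
                             "(partition violated)")
        seen |= idx
    selected: set[int] = set()
    for c, solution in per_cluster.items():
        idx = np.asarray(index_maps[c])
        selected |= set(int(i) for i in idx[np.asarray(solution.bits)])
    if not selected:
        warnings.warn("no feature selected in any cluster", stacklevel=2)
    return sorted(selected)


@dataclass
class SelectionResults:
    """Fitted selection: the feature set, provenance and diagnostics."""

    selected_features: list[int]
    per_cluster: dict
    cluster_assignment: clustering.ClusterAssignment
    relevance: pd.Series
    mi_matrix: mi.MIMatrix
    config: PipelineConfig
    train_index: np.ndarray
    test_index: np.ndarray
    matrix: FeatureMatrix = field(repr=False)
    traces: dict = field(default_factory=dict, repr=False)

    @property
    def n_retained(self) -> int:
        return len(self.cluster_assignment.feature_indices)

    @property
    def selected_fraction(self) -> float:
        return len(self.selected_features) / self.matrix.values.shape[1]

    @property
    def selected_tripeptides(self) -> list[str]:
        return [index_to_tripeptide(i) for i in self.selected_features]

    def rank_selected(self, top_n: int | None = None) -> pd.DataFrame:
        """Selected features ordered by label-relevance MI (descending).

        Ties are broken by ascending feature index.
        """
        idx = np.array(self.selected_features, dtype=int)
        rel = self.relevance.reindex(idx).fillna(0.0).to_numpy()
        order = np.lexsort((idx, -rel))
        frame = pd.DataFrame({
            "feature_index": idx[order],
            "tripeptide": [index_to_tripeptide(int(i)) for i in idx[order]],
            "relevance_bits": rel[order],
        })
        cluster_of = dict(zip(self.cluster_assignment.feature_indices,
                              self.cluster_assignment.cluster_ids))
        frame["cluster_id"] = [cluster_of.get(int(i), -1)
                               for i in frame["feature_index"]]
        return frame.head(top_n) if top_n else frame

    def evaluate(self, classifiers=DEFAULT_CLASSIFIERS,
                 averaging: str = "macro"):
        """Train/score the configured classifiers on the selected columns.

        Training uses the selection split's training rows, scoring its
        held-out rows, so no selection leakage enters the estimate.
        """
        cols = np.array(self.selected_features, dtype=int) - 1
        X = self.matrix.values
        y = self.matrix.labels
        return evaluate_classifiers(
            X[np.ix_(self.train_index, cols)], y[self.train_index],
            X[np.ix_(self.test_index, cols)], y[self.test_index],
            classifiers=classifiers,
            seed=stage_seed(self.config.master_seed, "eval"),
            averaging=averaging)

    def summary(self) -> str:
        lines = [
            "Clustered binary grey wolf feature selection",
            "=" * 52,
            f"samples (train/test):   {len(self.train_index)}/"
            f"{len(self.test_index)}",
            f"features total:         {self.matrix.values.shape[1]}",
            f"features retained:      {self.n_retained}",
            f"clusters (K):           {self.cluster_assignment.n_clusters}",
            f"selected features:      {len(self.selected_features)}",
            f"selected fraction:      {self.selected_fraction:.4f}",
            f"master seed:            {self.config.master_seed}",
            "",
            "top features by label relevance (bits):",
        ]
        top = self.rank_selected(10)
        for _, row in top.iterrows():
            lines.append(f"  {row.tripeptide}  (index {row.feature_index}, "
                         f"cluster {row.cluster_id}): "
                         f"{row.relevance_bits:.4f}")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.rank_selected().to_csv(outdir / "selected_features.tsv",
                                    sep="\t", index=False)
        self.config.to_json(outdir / "config.json")
        report = {
            "n_selected": len(self.selected_features),
            "selected_fraction": self.selected_fraction,
            "n_retained": self.n_retained,
            "n_clusters": int(self.cluster_assignment.n_clusters),
            "per_cluster": {
                str(c): {"fitness": sol.fitness,
                         "n_selected": sol.n_selected}
                for c, sol in self.per_cluster.items()},
            "seeds": {stage: stage_seed(self.config.master_seed, stage)
                      for stage in ("split", "kmeans", "eval")},
        }
        (outdir / "selection_report.json").write_text(
            json.dumps(report, indent=2))
        trace_dir = outdir / "trace"
        trace_dir.mkdir(exist_ok=True)
        for c, trace in self.traces.items():
            trace.to_frame().to_csv(trace_dir / f"cluster_{c}.csv",
                                    index=False)


class ClusteredBGWOSelector:
    """Wrapper feature selector over tripeptide-composition data.

    Parameters
    ----------
    matrix : FeatureMatrix
        Encoded, preprocessed dataset (rows = sequences, 8000 columns).
    config : PipelineConfig, optional
        Settings; defaults are reproducible out of the box.
    """

    def __init__(self, matrix: FeatureMatrix,
                 config: PipelineConfig | None = None):
        labels = np.unique(matrix.labels)
        if labels.size < 2:
            raise ValueError("need at least 2 classes to select features")
        self.matrix = matrix
        self.config = config or PipelineConfig()

    @classmethod
    def from_records(cls, records, config: PipelineConfig | None = None,
                     min_length: int = 20, alphabet_policy: str = "strict"):
        clean, _ = preprocess(records, min_length=min_length,
                              alphabet_policy=alphabet_policy)
        return cls(encode_dataset(clean, alphabet_policy), config)

    @classmethod
    def from_fasta(cls, fasta_path, labels_path,
                   config: PipelineConfig | None = None, **kwargs):
        records = read_fasta(fasta_path)
        labelled, _ = attach_labels(records, read_label_table(labels_path))
        return cls.from_records(labelled, config, **kwargs)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame,
                       config: PipelineConfig | None = None):
        """Build from a DataFrame with id/label columns + 8000 features."""
        from .encoding import TRIPEPTIDES
        matrix = FeatureMatrix(
            values=frame[list(TRIPEPTIDES)].to_numpy(dtype=np.float64),
            labels=frame["label"].to_numpy(),
            ids=frame["id"].astype(str).tolist())
        return cls(matrix, config)

    def _split(self) -> tuple[np.ndarray, np.ndarray]:
        idx = np.arange(self.matrix.n_samples)
        train, test = train_test_split(
            idx, test_size=self.config.test_fraction,
            stratify=self.matrix.labels,
            random_state=stage_seed(self.config.master_seed, "split"))
        return np.sort(train), np.sort(test)

    def fit(self) -> SelectionResults:
        """Run the full selection and return the results object."""
        cfg = self.config
        train_index, test_index = self._split()
        train = FeatureMatrix(values=self.matrix.values[train_index],
                              labels=self.matrix.labels[train_index],
                              ids=[self.matrix.ids[i] for i in train_index])

        mim = mi.pairwise_mi_matrix(train, n_bins=cfg.n_bins)
        relevance = mi.relevance_to_label(
            train, codes=mim.codes, feature_indices=mim.feature_indices,
            n_bins=cfg.n_bins)

        if cfg.prefilter_top_fraction < 1.0:
            d_keep = max(1, int(np.ceil(cfg.prefilter_top_fraction
                                        * mim.n_features)))
            rel = relevance.to_numpy()
            order = np.lexsort((mim.feature_indices, -rel))[:d_keep]
            keep = np.sort(order)
            mim = mi.MIMatrix(values=mim.values[np.ix_(keep, keep)],
                              feature_indices=mim.feature_indices[keep],
                              n_bins=mim.n_bins,
                              codes=mim.codes[:, keep])

        K = cfg.n_clusters or clustering.default_n_clusters(mim.n_features)
        assignment = clustering.cluster_features(
            mim, K, n_restarts=cfg.kmeans_restarts,
            max_iter=cfg.kmeans_max_iter, tol=cfg.kmeans_tol,
            seed=stage_seed(cfg.master_seed, "kmeans"))

        X_train = train.values[:, mim.feature_indices - 1]
        y_train = train.labels
        per_cluster: dict = {}
        index_maps: dict = {}
        traces: dict = {}
        for c in range(assignment.n_clusters):
            members = assignment.members(c)
            index_maps[c] = assignment.feature_indices[members]
            Xc = X_train[:, members]
            fit_cfg = bgwo.FitnessConfig(
                lambda_weight=cfg.lambda_weight, cv_folds=cfg.cv_folds,
                inner_classifier=cfg.inner_classifier,
                seed=stage_seed(cfg.master_seed, "fitness", c))
            objective = bgwo.WrapperFitness(Xc, y_train, fit_cfg)
            if len(members) == 1:
                # keep a singleton iff it beats the empty-set baseline
                f1 = objective(np.array([True]))
                keep_it = f1 < cfg.lambda_weight
                per_cluster[c] = bgwo.BinarySolution(
                    bits=np.array([keep_it]),
                    fitness=f1 if keep_it else cfg.lambda_weight)
                continue
            solution, trace = bgwo.optimize(
                d=len(members), fitness_fn=objective,
                pop_size=cfg.pop_size, n_iterations=cfg.n_iterations,
                seed=stage_seed(cfg.master_seed, "bgwo", c))
            per_cluster[c] = solution
            traces[c] = trace

        selected = aggregate(per_cluster, index_maps)
        return SelectionResults(
            selected_features=selected, per_cluster=per_cluster,
            cluster_assignment=assignment, relevance=relevance,
            mi_matrix=mim, config=cfg, train_index=train_index,
            test_index=test_index, matrix=self.matrix, traces=traces)


def run(matrix: FeatureMatrix,
        config: PipelineConfig | None = None) -> SelectionResults:
    """Functional entry point: fit the selector on an encoded matrix."""
    return ClusteredBGWOSelector(matrix, config).fit()
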