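"""Radiomic phenotype discovery: 2+1 k-means clustering in z-space.

The cohort is first split into two clusters; the branch with the most
aggressive characteristics is then re-split, giving clusters 1, 2a and 2b
(the 2+1 scheme is preferred over a direct k=3 fit for reproducibility of
the non-convex optimization).  Unseen cases are assigned to the nearest
centroid; feature importance is ranked by pairwise inter-centroid
distances; a mask-perturbation protocol quantifies robustness of the
cluster assignment to segmentation errors.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

CLUSTER_ORDER = ("1", "2a", "2b")


class ClusterDegeneracyError(RuntimeError):
    """A k-means split persistently produced an empty/singleton cluster."""


def _kmeans_two(X: np.ndarray, seed: int, n_restarts: int, max_attempts: int = 5) -> np.ndarray:
    """k=2 k-means (squared Euclidean) with multiple restarts, keeping the
    best-inertia solution; retries with a shifted seed if a split yields a
    singleton cluster."""
    for attempt in range(max_attempts):
        km = KMeans(n_clusters=2, n_init=n_restarts, random_state=seed + attempt)
        lab = km.fit_predict(X)
        sizes = np.bincount(lab, minlength=2)
        if sizes.min() >= 2:
            return lab
    raise ClusterDegeneracyError("k-means split persistently degenerate")


def _kmedoids_two(X: np.ndarray, seed: int, n_restarts: int = 10) -> np.ndarray:
    """k=2 PAM on Euclidean distances: BUILD initialization followed by the
    full SWAP phase (every medoid/non-medoid exchange considered each
    iteration).  Deterministic; ``seed``/``n_restarts`` kept for interface
    parity with the k-means variant."""
    del seed, n_restarts
    n = X.shape[0]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    # BUILD: first medoid minimizes total distance; second maximizes the
    # additional cost reduction
    m0 = int(np.argmin(D.sum(axis=0)))
    gain = np.maximum(D[:, m0][None, :] - D, 0.0).sum(axis=1)
    gain[m0] = -np.inf
    medoids = [m0, int(np.argmax(gain))]

    def cost_of(meds):
        return float(np.minimum(D[:, meds[0]], D[:, meds[1]]).sum())

    cost = cost_of(medoids)
    improved = True
    while improved:
        improved = False
        best = (0.0, None)
        for mi in range(2):
            other = medoids[1 - mi]
            for h in range(n):
                if h in medoids:
                    continue
                t_cost = float(np.minimum(D[:, other], D[:, h]).sum())
                if cost - t_cost > best[0] + 1e-12:
                    best = (cost - t_cost, (mi, h))
        if best[1] is not None:
            mi, h = best[1]
            medoids[mi] = h
            cost = cost_of(medoids)
            improved = True
    return np.argmin(D[:, medoids], axis=1)


@dataclasses.dataclass
class ClusterConfig:
    seed: int = 0
    n_restarts: int = 50
    algorithm: str = "kmeans"  # or "kmedoids"
    branch_rule: str = "auto"  # "auto" | "labels" | "volume"
    volume_feature: str = "vol"


class RadiomicPhenotypeModel:
    """2+1 clustering model over a z-scored feature matrix.

    Parameters
    ----------
    Z : DataFrame
        Cases x features, z-scored with the training normalization.
    aggressive_flags : optional boolean Series aligned with Z
        External per-case truth of aggressive disease; when given, the
        branch to re-split is chosen by majority vote of these flags,
        otherwise by the larger-centroid-volume heuristic.
    """

    def __init__(self, Z: pd.DataFrame, aggressive_flags: pd.Series | None = None,
                 config: ClusterConfig | None = None) -> None:
        self.Z = pd.DataFrame(Z)
        if len(self.Z) < 6:
            raise ValueError("need at least 6 cases for a 2+1 clustering")
        self.aggressive_flags = aggressive_flags
        self.config = config or ClusterConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, feature_columns: Sequence[str],
                       aggressive_column: str | None = None,
                       config: ClusterConfig | None = None) -> "RadiomicPhenotypeModel":
        flags = df[aggressive_column].astype(bool) if aggressive_column else None
        return cls(df[list(feature_columns)], aggressive_flags=flags, config=config)

    def fit(self) -> "RadiomicPhenotypeResults":
        cfg = self.config
        X = self.Z.to_numpy(dtype=float)
        split = (_kmeans_two(X, cfg.seed, cfg.n_restarts) if cfg.algorithm == "kmeans"
                 else _kmedoids_two(X, cfg.seed, cfg.n_restarts))
        branch, rule_used = self._select_aggressive_branch(split)
        agg_idx = np.flatnonzero(split == branch)
        if agg_idx.size < 4:
            raise ClusterDegeneracyError("aggressive branch too small to re-split")
        sub = (_kmeans_two(X[agg_idx], cfg.seed, cfg.n_restarts) if cfg.algorithm == "kmeans"
               else _kmedoids_two(X[agg_idx], cfg.seed, cfg.n_restarts))
        # sub-branches named by descending membership: 2a >= 2b; equal sizes
        # are broken by the volume-like feature (2b = larger tumors) so the
        # naming stays deterministic
        sizes = np.bincount(sub, minlength=2)
        if sizes[0] != sizes[1]:
            a_id = int(np.argmax(sizes))
        elif cfg.volume_feature in self.Z.columns:
            vol = self.Z[cfg.volume_feature].to_numpy(dtype=float)
            a_id = int(np.argmin([vol[agg_idx[sub == i]].mean() for i in (0, 1)]))
        else:
            a_id = 0
        labels = np.where(split == branch, "", "1").astype(object)
        labels[agg_idx[sub == a_id]] = "2a"
        labels[agg_idx[sub != a_id]] = "2b"
        labels = pd.Series(labels.astype(str), index=self.Z.index, name="cluster")
        if cfg.algorithm == "kmeans":
            centroids = pd.DataFrame(
                [X[labels.to_numpy() == c].mean(axis=0) for c in CLUSTER_ORDER],
                index=list(CLUSTER_ORDER), columns=self.Z.columns)
        else:
            # medoid = member minimizing total within-cluster distance
            rows = []
            for c in CLUSTER_ORDER:
                members = X[labels.to_numpy() == c]
                D = np.sqrt(((members[:, None] - members[None]) ** 2).sum(-1))
                rows.append(members[int(np.argmin(D.sum(axis=0)))])
            centroids = pd.DataFrame(rows, index=list(CLUSTER_ORDER), columns=self.Z.columns)
        return RadiomicPhenotypeResults(self, centroids, labels, rule_used)

    def _select_aggressive_branch(self, split: np.ndarray) -> tuple[int, str]:
        cfg = self.config
        use_labels = (cfg.branch_rule == "labels"
                      or (cfg.branch_rule == "auto" and self.aggressive_flags is not None))
        if use_labels:
            if self.aggressive_flags is None:
                raise ValueError("branch_rule 'labels' requires aggressive_flags")
            flags = np.asarray(self.aggressive_flags, dtype=bool)
            props = [flags[split == b].mean() for b in (0, 1)]
            if props[0] == props[1]:
                warnings.warn("aggressive-branch vote tied: branch 0 selected", UserWarning)
                return 0, "labels(tie)"
            return int(np.argmax(props)), "labels"
        if cfg.volume_feature not in self.Z.columns:
            raise ValueError(
                f"volume heuristic needs feature {cfg.volume_feature!r}; "
                "provide aggressive_flags or set volume_feature")
        vol = self.Z[cfg.volume_feature].to_numpy(dtype=float)
        means = [vol[split == b].mean() for b in (0, 1)]
        if means[0] == means[1]:
            warnings.warn("volume heuristic tied: branch 0 selected", UserWarning)
            return 0, "volume(tie)"
        return int(np.argmax(means)), "volume"


class RadiomicPhenotypeResults:
    """Fitted 2+1 cluster model: centroids in z-space, training labels,
    feature-importance ranking, assignment of new cases."""

    def __init__(self, model: RadiomicPhenotypeModel, centroids: pd.DataFrame,
                 labels: pd.Series, branch_rule_used: str) -> None:
        self.model = model
        self.centroids = centroids
        self.labels = labels
        self.branch_rule_used = branch_rule_used
        self.algorithm = model.config.algorithm

    @property
    def cluster_sizes(self) -> pd.Series:
        return self.labels.value_counts().reindex(list(CLUSTER_ORDER)).fillna(0).astype(int)

    def assign(self, Z: pd.DataFrame | np.ndarray) -> pd.Series:
        """Assign cases to the nearest centroid (Euclidean); ties go to the
        lowest cluster id in the order 1, 2a, 2b."""
        Zdf = pd.DataFrame(Z)
        if list(Zdf.columns) != list(self.centroids.columns):
            if Zdf.shape[1] != self.centroids.shape[1]:
                raise ValueError("feature dimension mismatch with the fitted model")
            Zdf.columns = self.centroids.columns
        X = Zdf.to_numpy(dtype=float)
        C = self.centroids.to_numpy(dtype=float)
        d = np.sqrt(((X[:, None, :] - C[None, :, :]) ** 2).sum(-1))
        idx = np.argmin(d, axis=1)  # argmin takes the first (lowest id) on ties
        return pd.Series([CLUSTER_ORDER[i] for i in idx], index=Zdf.index, name="cluster")

    def feature_importance(self) -> pd.DataFrame:
        """Per-feature absolute inter-centroid distances for the pairs
        (1,2a), (1,2b), (2a,2b), their sum, and the descending rank."""
        c1 = self.centroids.loc["1"]
        c2a = self.centroids.loc["2a"]
        c2b = self.centroids.loc["2b"]
        df = pd.DataFrame({
            "d_1_2a": (c1 - c2a).abs(),
            "d_1_2b": (c1 - c2b).abs(),
            "d_2a_2b": (c2a - c2b).abs(),
        })
        df["aggregate"] = df.sum(axis=1)
        df = df.sort_values("aggregate", ascending=False)
        df["rank"] = np.arange(1, len(df) + 1)
        return df

    def summary(self) -> str:
        imp = self.feature_importance()
        lines = [
            "Radiomic phenotype clustering (2+1)",
            "=" * 40,
            f"algorithm:        {self.algorithm}",
            f"branch rule:      {self.branch_rule_used}",
            f"cases:            {len(self.labels)}",
            "cluster sizes:    " + ", ".join(f"{c}={n}" for c, n in self.cluster_sizes.items()),
            "",
            "Top features by centroid inter-distance:",
        ]
        for name, row in imp.head(10).iterrows():
            lines.append(f"  {int(row['rank']):2d}. {name:28s} aggregate={row['aggregate']:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "branch_rule_used": self.branch_rule_used,
            "feature_names": list(self.centroids.columns),
            "centroids": {c: self.centroids.loc[c].tolist() for c in CLUSTER_ORDER},
            "labels": {str(k): v for k, v in self.labels.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RadiomicPhenotypeResults":
        centroids = pd.DataFrame(
            [d["centroids"][c] for c in CLUSTER_ORDER],
            index=list(CLUSTER_ORDER), columns=d["feature_names"])
        labels = pd.Series(d["labels"], name="cluster")
        obj = cls.__new__(cls)
        obj.model = None
        obj.centroids = centroids
        obj.labels = labels
        obj.branch_rule_used = d["branch_rule_used"]
        obj.algorithm = d["algorithm"]
        return obj


# ---------------------------------------------------------------------------
# Mask-perturbation robustness protocol
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PerturbationReport:
    baseline_labels: pd.Series
    perturbed_labels: Mapping[str, pd.Series]  # op -> labels
    change_rates: Mapping[str, float]          # op -> fraction changed
    excluded: Mapping[str, list[str]]          # op -> case ids emptied by the op


def perturbation_protocol(cases, results: RadiomicPhenotypeResults, ztransform,
                          radiomics_config=None,
                          operations: Sequence[str] = ("dilate", "erode")) -> PerturbationReport:
    """Re-extract features on morphologically perturbed masks, re-normalize
    with the *training* parameters, re-assign, and report the fraction of
    cases that change cluster per operation.  Cases whose eroded mask is
    empty are excluded from the rate and reported separately.
    """
    from . import image as img
    from .features import DEFAULT_CONFIG, FEATURE_NAMES, extract_radiomics

    cfg = radiomics_config or DEFAULT_CONFIG
    ops = {"dilate": img.dilate_mask, "erode": img.erode_mask,
           "identity": lambda m: m}

    def _features(case_list):
        rows = {c.case_id: extract_radiomics(c, cfg) for c in case_list}
        df = pd.DataFrame.from_dict(rows, orient="index")[list(FEATURE_NAMES)]
        fs = pd.Series({c.case_id: c.field_strength for c in case_list})
        return df, fs.loc[df.index]

    base_df, base_fs = _features(cases)
    baseline = results.assign(ztransform.transform(base_df, base_fs))

    perturbed_labels: dict[str, pd.Series] = {}
    change_rates: dict[str, float] = {}
    excluded: dict[str, list[str]] = {}
    for op in operations:
        fn = ops[op]
        kept, dropped = [], []
        for case in cases:
            new_mask = fn(case.mask)
            if new_mask.n_voxels == 0:
                dropped.append(case.case_id)
                continue
            kept.append(img.StudyCase(case.case_id, case.channels, new_mask,
                                      clinical=case.clinical, group_truth=case.group_truth))
        if not kept:
            raise ValueError(f"perturbation {op!r} emptied every mask")
        df, fs = _features(kept)
        lab = results.assign(ztransform.transform(df, fs))
        common = lab.index
        change_rates[op] = float((lab.loc[common] != baseline.loc[common]).mean())
        perturbed_labels[op] = lab
        excluded[op] = dropped
    return PerturbationReport(baseline, perturbed_labels, change_rates, excluded)
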