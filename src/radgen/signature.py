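"""SAM differential expression and the up-minus-down gene signature score.

SAM (significance analysis of microarrays) moderates the per-gene group
difference by a fudge factor s0 added to the gene-wise standard error and
estimates the false discovery rate of a calling threshold delta from label
permutations.  A signature is built from the genes called in both a
two-class run (cluster 1 vs the most aggressive cluster) and a multiclass
run (all three clusters); the per-sample signature score is the sum of
z-normalized expression over up-genes minus down-genes, dichotomized at
the cohort-mean score.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

S0_PERCENTILES = tuple(range(0, 101, 5))


def _fudge_factor(d_raw: np.ndarray, s: np.ndarray,
                  percentiles: Sequence[int] = S0_PERCENTILES) -> float:
    """Tusher/Chu s0: the percentile of the gene-wise scatter {s_i} that
    minimizes the coefficient of variation of the moderated statistic's
    spread across s-windows."""
    order = np.argsort(s, kind="stable")
    s_sorted, r_sorted = s[order], d_raw[order]
    n = s.size
    edges = np.linspace(0, n, 101).astype(int)  # 100 quantile windows
    candidates = np.percentile(s, percentiles)
    best_cv, best_s0 = np.inf, float(candidates[0])
    for s0 in candidates:
        d = r_sorted / (s_sorted + s0)
        spreads = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            if hi - lo >= 2:
                w = d[lo:hi]
                spreads.append(np.median(np.abs(w - np.median(w))) / 0.64)
        spreads = np.asarray(spreads)
        mean = spreads.mean()
        if mean <= 0:
            continue
        cv = spreads.std() / mean
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def _two_class_stats(X: np.ndarray, g1: np.ndarray, g2: np.ndarray):
    """Raw difference r_i = mean(group2) - mean(group1) and pooled scatter
    s_i = sqrt((1/n1 + 1/n2) * pooled variance)."""
    x1, x2 = X[:, g1], X[:, g2]
    n1, n2 = x1.shape[1], x2.shape[1]
    r = x2.mean(axis=1) - x1.mean(axis=1)
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return r, s


def _multiclass_stats(X: np.ndarray, group_idx: list[np.ndarray]):
    """F-like raw statistic: sqrt(between-group SS / (K-1)); scatter =
    pooled within-group SD."""
    K = len(group_idx)
    n = X.shape[1]
    grand = X.mean(axis=1)
    between = np.zeros(X.shape[0])
    within = np.zeros(X.shape[0])
    for idx in group_idx:
        xk = X[:, idx]
        mk = xk.mean(axis=1)
        between += idx.size * (mk - grand) ** 2
        within += ((xk - mk[:, None]) ** 2).sum(axis=1)
    r = np.sqrt(between / (K - 1))
    s = np.sqrt(within / (n - K))
    return r, s


@dataclasses.dataclass
class SAMResults:
    """Fitted SAM: per-gene statistic, fudge factor, permutation null."""

    gene_ids: list[str]
    d: np.ndarray                 # observed moderated statistics
    s: np.ndarray                 # gene-wise scatter
    s0: float
    perm_sorted: np.ndarray       # (B, G) sorted permuted statistics
    two_sided: bool               # True for two-class (signed d)
    groups: tuple

    def __post_init__(self) -> None:
        self._d_sorted = np.sort(self.d)
        self._d_expected = self.perm_sorted.mean(axis=0)

    @property
    def d_expected(self) -> np.ndarray:
        """Expected order statistics of d under the permutation null."""
        return self._d_expected

    @property
    def d_sorted(self) -> np.ndarray:
        return self._d_sorted

    def call_genes(self, delta: float) -> dict:
        """Call genes at threshold delta via the observed-vs-expected
        order-statistic rule; FDR = median permuted call count / observed
        call count."""
        d_sorted = self.d_sorted
        dbar = self.d_expected
        diff = d_sorted - dbar
        G = len(d_sorted)
        cut_up = np.inf
        up_region = np.flatnonzero(diff >= delta)
        if self.two_sided:
            up_region = up_region[dbar[up_region] >= 0]
        if up_region.size:
            cut_up = d_sorted[up_region[0]]
        cut_low = -np.inf
        if self.two_sided:
            low_region = np.flatnonzero(diff <= -delta)
            low_region = low_region[dbar[low_region] <= 0]
            if low_region.size:
                cut_low = d_sorted[low_region[-1]]
        called_up = self.d >= cut_up
        called_down = self.d <= cut_low
        n_called = int(called_up.sum() + called_down.sum())
        perm_counts = ((self.perm_sorted >= cut_up).sum(axis=1)
                       + (self.perm_sorted <= cut_low).sum(axis=1))
        median_false = float(np.median(perm_counts))
        fdr = min(1.0, median_false / n_called) if n_called else 0.0
        genes = np.asarray(self.gene_ids, dtype=object)
        return {
            "delta": float(delta),
            "cut_up": float(cut_up),
            "cut_low": float(cut_low),
            "n_called": n_called,
            "fdr": fdr,
            "up": list(genes[called_up]),
            "down": list(genes[called_down]),
            "called": dict(zip(genes[called_up | called_down],
                               np.where(self.d[called_up | called_down] > 0, "up", "down"))),
        }

    def select_delta(self, fdr_target: float = 0.05, grid_size: int = 128) -> dict:
        """Smallest delta (on a quantile grid of the observed-vs-expected
        deviations) achieving the FDR target with a non-empty call set;
        falls back to an empty call when no delta qualifies."""
        diff = np.abs(self.d_sorted - self.d_expected)
        positive = np.unique(diff[diff > 0])
        if positive.size > grid_size:
            # quantiles track the bulk; the linear grid covers the sparse
            # tail between the null bulk and strong effects
            positive = np.unique(np.concatenate([
                np.quantile(positive, np.linspace(0, 1, grid_size)),
                np.linspace(positive.min(), positive.max(), grid_size),
            ]))
        results = [self.call_genes(float(delta)) for delta in positive]
        # The raw median-based FDR estimate is not monotone in delta: when a
        # cutoff lands exactly on the most extreme null gene, that gene defines
        # its own threshold and the median permuted count can dip to zero even
        # though slightly larger deltas estimate a higher FDR.  Regularize with
        # the non-increasing envelope from above (as in the monotone delta
        # tables of canonical SAM software) before thresholding.
        envelope = np.maximum.accumulate([r["fdr"] for r in results][::-1])[::-1]
        best = None
        for res, fdr in zip(results, envelope):
            if res["n_called"] > 0 and fdr <= fdr_target:
                best = res
                break  # ascending grid: first qualifying delta is smallest
        if best is None:
            return self.call_genes(float(diff.max()) + 1.0 if diff.size else 1.0)
        return best

    def summary(self, fdr_target: float = 0.05) -> str:
        res = self.select_delta(fdr_target)
        kind = "two-class" if self.two_sided else "multiclass"
        return "\n".join([
            f"SAM ({kind}) over {len(self.gene_ids)} genes, groups {self.groups}",
            f"  s0 = {self.s0:.4g}",
            f"  delta = {res['delta']:.4g} (FDR target {fdr_target})",
            f"  called: {res['n_called']} genes "
            f"({len(res['up'])} up, {len(res['down'])} down), est. FDR = {res['fdr']:.3f}",
        ])


class SAM:
    """SAM model: expression matrix (genes x samples) + sample labels.

    Two groups give the signed two-class statistic d = (mean2 - mean1) /
    (s + s0), positive when expression is higher in ``groups[1]``; three or
    more give a positive F-like statistic with the same s0 construction.
    """

    def __init__(self, matrix: pd.DataFrame, labels: Sequence[str],
                 groups: Sequence[str] | None = None) -> None:
        self.matrix = pd.DataFrame(matrix)
        labels = np.asarray(list(labels))
        if labels.size != self.matrix.shape[1]:
            raise ValueError("one label per sample (column) required")
        if self.matrix.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        if self.matrix.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.labels = labels
        self.groups = tuple(groups) if groups is not None else tuple(np.unique(labels))
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        for g in self.groups:
            if (labels == g).sum() < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")

    def fit(self, n_permutations: int = 200, seed: int = 0) -> SAMResults:
        X = self.matrix.to_numpy(dtype=float)
        idx = [np.flatnonzero(self.labels == g) for g in self.groups]
        used = np.concatenate(idx)
        Xu = X[:, used]
        sizes = [i.size for i in idx]
        bounds = np.cumsum([0] + sizes)
        groups_u = [np.arange(bounds[k], bounds[k + 1]) for k in range(len(sizes))]
        two_sided = len(self.groups) == 2

        if two_sided:
            r, s = _two_class_stats(Xu, groups_u[0], groups_u[1])
        else:
            r, s = _multiclass_stats(Xu, groups_u)
        s0 = _fudge_factor(r, s)
        d = r / (s + s0)

        rng = np.random.default_rng(seed)
        n = Xu.shape[1]
        perm_sorted = np.empty((n_permutations, X.shape[0]))
        for b in range(n_permutations):
            perm = rng.permutation(n)
            gperm = [perm[bounds[k]:bounds[k + 1]] for k in range(len(sizes))]
            if two_sided:
                rb, sb = _two_class_stats(Xu, gperm[0], gperm[1])
            else:
                rb, sb = _multiclass_stats(Xu, gperm)
            perm_sorted[b] = np.sort(rb / (sb + s0))
        return SAMResults(list(self.matrix.index), d, s, s0, perm_sorted,
                          two_sided, self.groups)


# ---------------------------------------------------------------------------
# Signature construction and scoring
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class GeneSignature:
    """Ordered up- and down-regulated gene sets (directions relative to the
    most aggressive cluster) with the provenance of the two SAM runs."""

    up: list[str]
    down: list[str]
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise ValueError("up and down gene sets must be disjoint")

    @property
    def empty(self) -> bool:
        return not (self.up or self.down)

    @property
    def genes(self) -> list[str]:
        return list(self.up) + list(self.down)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.genes,
            "direction": ["up"] * len(self.up) + ["down"] * len(self.down),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneSignature":
        up = df.loc[df["direction"] == "up", "gene"].tolist()
        down = df.loc[df["direction"] == "down", "gene"].tolist()
        return cls(up, down)


def build_signature(result_two_class: SAMResults, result_multiclass: SAMResults,
                    fdr_target: float = 0.05) -> GeneSignature:
    """Overlap rule: genes called in BOTH the two-class and the multiclass
    SAM runs, with direction taken from the two-class comparison (up =
    higher in the aggressive cluster), ordered by decreasing |d|.

    An empty intersection yields an (empty) signature, not an exception.
    """
    if list(result_two_class.gene_ids) != list(result_multiclass.gene_ids):
        raise ValueError("the two SAM runs must share one gene universe")
    call2 = result_two_class.select_delta(fdr_target)
    call3 = result_multiclass.select_delta(fdr_target)
    overlap = set(call2["called"]) & set(call3["called"])
    d = pd.Series(result_two_class.d, index=result_two_class.gene_ids)
    ordered = sorted(overlap, key=lambda g: -abs(d[g]))
    up = [g for g in ordered if d[g] > 0]
    down = [g for g in ordered if d[g] <= 0]
    if not overlap:
        warnings.warn("no overlapping SAM calls: empty signature", UserWarning)
    return GeneSignature(up, down, provenance={
        "two_class": {k: call2[k] for k in ("delta", "fdr", "n_called")},
        "multiclass": {k: call3[k] for k in ("delta", "fdr", "n_called")},
        "fdr_target": fdr_target,
    })


@dataclasses.dataclass
class SignatureScores:
    scores: pd.Series           # per-sample score
    classes: pd.Series          # "high" / "low"
    cutoff: float               # cohort-mean score
    dropped_genes: list[str]


def score_signature(matrix: pd.DataFrame, signature: GeneSignature) -> SignatureScores:
    """Per-sample score = sum of z-normalized expression over up-genes
    minus down-genes; z per gene across the scored cohort (population SD).
    Class = high iff score > cohort-mean cutoff.  Signature genes absent
    from the matrix are dropped with a warning; all absent is an error.
    """
    if signature.empty:
        raise ValueError("cannot score an empty signature")
    present_up = [g for g in signature.up if g in matrix.index]
    present_down = [g for g in signature.down if g in matrix.index]
    dropped = [g for g in signature.genes if g not in matrix.index]
    if not (present_up or present_down):
        raise ValueError("no signature gene present in the expression matrix")
    if dropped:
        warnings.warn(f"signature genes missing from matrix, dropped: {dropped}",
                      UserWarning)
    sub = matrix.loc[present_up + present_down].astype(float)
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0).replace(0.0, 1.0)
    z = sub.sub(mu, axis=0).div(sd, axis=0)
    scores = z.loc[present_up].sum(axis=0) - z.loc[present_down].sum(axis=0)
    cutoff = float(scores.mean())
    classes = pd.Series(np.where(scores > cutoff, "high", "low"),
                        index=scores.index, name="signature_class")
    return SignatureScores(scores.rename("score"), classes, cutoff, dropped)


def printed_percent(numerator: int, denominator: int) -> int:
    """Percentage rounded to the nearest integer (half away from zero), the
    convention of the cohort tables."""
    if denominator == 0:
        raise ValueError("zero denominator")
    x = 100.0 * numerator / denominator
    return int(np.floor(x + 0.5))


def crosstab_signature_vs_cluster(classes: pd.Series, clusters: pd.Series) -> dict:
    """2x2 table of low/high signature class against cluster 1 vs cluster
    2a/2b, with printed-style percentage of low-score cases per cluster."""
    common = classes.index.intersection(clusters.index)
    missing = classes.index.symmetric_difference(clusters.index)
    if len(common) == 0:
        raise ValueError(f"no matched sample ids; unmatched: {list(missing)[:10]}")
    if len(missing) > 0:
        raise ValueError(f"unmatched sample ids: {sorted(map(str, missing))}")
    cls = classes.loc[common]
    grp = clusters.loc[common].map(lambda c: "1" if str(c) == "1" else "2a/b")
    table = pd.crosstab(cls, grp).reindex(index=["low", "high"],
                                          columns=["1", "2a/b"]).fillna(0).astype(int)
    n1 = int(table["1"].sum())
    n2 = int(table["2a/b"].sum())
    return {
        "table": table,
        "cluster1_low_pct": printed_percent(int(table.loc["low", "1"]), n1) if n1 else None,
        "cluster2_low_pct": printed_percent(int(table.loc["low", "2a/b"]), n2) if n2 else None,
    }
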