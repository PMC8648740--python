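"""End-to-end orchestration: discovery (features -> z-transform -> 2+1
clustering -> SAM -> signature -> survival) and validation (assign held-out
cases with training normalization -> score -> survival)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cluster import ClusterConfig, RadiomicPhenotypeModel, RadiomicPhenotypeResults
from .features import DEFAULT_CONFIG, FEATURE_NAMES, RadiomicsConfig, ZTransform, extract_radiomics
from .image import EmptyMaskError, StudyCase, read_case
from .signature import (SAM, GeneSignature, SignatureScores, build_signature,
                        crosstab_signature_vs_cluster, score_signature)
from .stats import LogrankResult, logrank_test, select_test


@dataclasses.dataclass
class RunConfig:
    radiomics: RadiomicsConfig = dataclasses.field(default_factory=RadiomicsConfig)
    clustering: ClusterConfig = dataclasses.field(default_factory=ClusterConfig)
    sam_permutations: int = 200
    sam_fdr_target: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "radiomics": self.radiomics.to_dict(),
            "clustering": dataclasses.asdict(self.clustering),
            "sam_permutations": self.sam_permutations,
            "sam_fdr_target": self.sam_fdr_target,
            "seed": self.seed,
        }

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def provenance(config: RunConfig) -> dict:
    return {"config_hash": config.config_hash, "seed": config.seed,
            "version": __version__}


def extract_feature_matrix(cases: Sequence[StudyCase],
                           config: RadiomicsConfig = DEFAULT_CONFIG
                           ) -> tuple[pd.DataFrame, pd.Series]:
    """53-feature matrix (canonical column order) + field-strength series."""
    rows = {c.case_id: extract_radiomics(c, config) for c in cases}
    df = pd.DataFrame.from_dict(rows, orient="index")[list(FEATURE_NAMES)]
    fs = pd.Series({c.case_id: c.field_strength for c in cases}).loc[df.index]
    return df, fs


def load_cases_from_manifest(manifest_path: str | Path):
    """Read cases listed in a cohort manifest CSV (columns path_<channel>,
    path_mask, field_strength, ...).  Cases with empty masks are excluded
    and returned separately, never silently dropped."""
    from .image import CHANNELS

    manifest = pd.read_csv(manifest_path)
    cases, excluded = [], []
    for _, row in manifest.iterrows():
        cid = str(row["case_id"])
        try:
            case = read_case(
                cid,
                {tag: row[f"path_{tag}"] for tag in CHANNELS},
                row["path_mask"],
                field_strength=str(row.get("field_strength", "1.5T")),
            )
        except EmptyMaskError:
            excluded.append(cid)
            continue
        case.group_truth = str(row["group"]) if "group" in row and pd.notna(row["group"]) else None
        cases.append(case)
    return cases, manifest, excluded


@dataclasses.dataclass
class DiscoveryResult:
    features: pd.DataFrame
    ztransform: ZTransform
    cluster_results: RadiomicPhenotypeResults
    signature: GeneSignature | None
    scores: SignatureScores | None
    crosstab: dict | None
    logrank_two: LogrankResult | None
    logrank_three: LogrankResult | None
    provenance: dict
    log: list[str]

    def summary(self) -> str:
        lines = [self.cluster_results.summary(), ""]
        if self.logrank_two is not None:
            lines.append(f"log-rank 1 vs 2a/b: chi2 = {self.logrank_two.statistic:.2f}, "
                         f"p = {self.logrank_two.p_value:.2e}")
            lines.append(f"log-rank 1/2a/2b:   chi2 = {self.logrank_three.statistic:.2f}, "
                         f"p = {self.logrank_three.p_value:.2e}")
        if self.signature is not None:
            lines.append(f"signature: {len(self.signature.up)} up, "
                         f"{len(self.signature.down)} down genes")
        if self.crosstab is not None:
            lines.append(f"cluster-1 low-score proportion: {self.crosstab['cluster1_low_pct']}%")
            lines.append(f"cluster-2 low-score proportion: {self.crosstab['cluster2_low_pct']}%")
        lines.extend(self.log)
        lines.append(f"[config {self.provenance['config_hash']} seed "
                     f"{self.provenance['seed']} v{self.provenance['version']}]")
        return "\n".join(lines)


def run_discovery(cases: Sequence[StudyCase],
                  survival: pd.DataFrame | None = None,
                  expression: pd.DataFrame | None = None,
                  config: RunConfig | None = None) -> DiscoveryResult:
    """Discovery pipeline on a training cohort.

    ``survival`` (optional): DataFrame indexed by case id with columns
    time_months, event.  ``expression`` (optional): genes x samples with
    sample ids matching case ids; when absent the signature stages are
    skipped and logged.
    """
    config = config or RunConfig()
    log: list[str] = []
    features, fs = extract_feature_matrix(cases, config.radiomics)
    zt = ZTransform()
    Z = zt.fit_transform(features, fs)

    truth = pd.Series({c.case_id: c.group_truth for c in cases}).loc[Z.index]
    flags = truth.isin(["2a", "2b"]) if truth.notna().all() else None
    model = RadiomicPhenotypeModel(Z, aggressive_flags=flags, config=config.clustering)
    results = model.fit()

    signature = scores = crosstab = None
    if expression is not None:
        common = results.labels.index.intersection(expression.columns)
        if len(common) < 6:
            raise ValueError("too few cases with both imaging and expression data")
        labels = results.labels.loc[common]
        mat = expression[common]
        seed = config.seed
        res2 = SAM(mat.loc[:, labels.isin(["1", "2b"])],
                   labels[labels.isin(["1", "2b"])], groups=("1", "2b")).fit(
            config.sam_permutations, seed=seed)
        res3 = SAM(mat, labels).fit(config.sam_permutations, seed=seed + 1)
        signature = build_signature(res2, res3, config.sam_fdr_target)
        if signature.empty:
            log.append("signature empty: no overlapping SAM calls")
        else:
            scores = score_signature(mat, signature)
            crosstab = crosstab_signature_vs_cluster(scores.classes, labels)
    else:
        log.append("no expression input: signature stages skipped")

    lr2 = lr3 = None
    if survival is not None:
        surv = survival.loc[results.labels.index]
        two = results.labels.map(lambda c: "1" if c == "1" else "2a/b")
        lr2 = logrank_test(surv["time_months"], surv["event"], two)
        lr3 = logrank_test(surv["time_months"], surv["event"], results.labels)
    return DiscoveryResult(features, zt, results, signature, scores, crosstab,
                           lr2, lr3, provenance(config), log)


@dataclasses.dataclass
class ValidationResult:
    labels: pd.Series
    scores: SignatureScores | None
    crosstab: dict | None
    logrank_two: LogrankResult | None
    logrank_three: LogrankResult | None
    excluded: list[str]
    provenance: dict

    def summary(self) -> str:
        lines = [
            "Validation run",
            "=" * 40,
            "assigned sizes:   " + ", ".join(
                f"{c}={n}" for c, n in self.labels.value_counts().sort_index().items()),
            f"excluded (empty mask): {len(self.excluded)}",
        ]
        if self.logrank_two is not None:
            lines.append(f"log-rank 1 vs 2a/b: p = {self.logrank_two.p_value:.2e}")
            lines.append(f"log-rank 1/2a/2b:   p = {self.logrank_three.p_value:.2e}")
        lines.append(f"[config {self.provenance['config_hash']} seed "
                     f"{self.provenance['seed']} v{self.provenance['version']}]")
        return "\n".join(lines)


def run_validation(cases: Sequence[StudyCase],
                   cluster_results: RadiomicPhenotypeResults,
                   ztransform: ZTransform,
                   survival: pd.DataFrame | None = None,
                   expression: pd.DataFrame | None = None,
                   signature: GeneSignature | None = None,
                   excluded: Sequence[str] = (),
                   config: RunConfig | None = None) -> ValidationResult:
    """Validation pipeline: normalize held-out cases with the *training*
    parameters, assign to the trained centroids, optionally score the
    signature, and compare survival across assigned clusters."""
    config = config or RunConfig()
    features, fs = extract_feature_matrix(cases, config.radiomics)
    Z = ztransform.transform(features, fs)
    labels = cluster_results.assign(Z)

    scores = crosstab = None
    if expression is not None and signature is not None and not signature.empty:
        common = labels.index.intersection(expression.columns)
        scores = score_signature(expression[common], signature)
        crosstab = crosstab_signature_vs_cluster(scores.classes, labels.loc[common])

    lr2 = lr3 = None
    if survival is not None:
        surv = survival.loc[labels.index]
        two = labels.map(lambda c: "1" if c == "1" else "2a/b")
        lr2 = logrank_test(surv["time_months"], surv["event"], two)
        lr3 = logrank_test(surv["time_months"], surv["event"], labels)
    return ValidationResult(labels, scores, crosstab, lr2, lr3, list(excluded),
                            provenance(config))


def crosstab_variable_vs_cluster(variable: pd.Series, labels: pd.Series):
    """Contingency table of a categorical clinical variable against cluster
    1 vs 2a/2b, tested with chi-square or Fisher as appropriate."""
    common = variable.dropna().index.intersection(labels.index)
    two = labels.loc[common].map(lambda c: "1" if str(c) == "1" else "2a/b")
    table = pd.crosstab(variable.loc[common], two)
    return table, select_test(table.to_numpy())
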