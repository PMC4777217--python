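"""Cluster-based in vivo toxicity prediction and its evaluation.

For each endpoint the compounds with calls are split at random into equal
training and test halves.  Every cluster containing training compounds
receives a signed toxicity score: the one-sided Fisher exact P of toxic
enrichment in the cluster (over the training set), reported as -log10 P
when the cluster's toxic fraction exceeds the training fraction and
+log10 P (negative) when the cluster is deficient.  Test compounds inherit
their cluster's score and are ranked against their true calls by the
tie-aware AUC-ROC.  The split/train/test cycle repeats (100 times by
default) and the per-split AUCs are summarized as mean +/- SD.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, rankdata

from .enrichment import fisher_pvalue
from .som import ClusterAssignment

P_FLOOR = 1e-300  # avoids infinite -log10 P on degenerate tables
PREDICTIVE_AUC = 0.7


@dataclass(frozen=True)
class ClusterScore:
    score: float
    toxic_in_cluster: int
    total_in_cluster: int
    toxic_in_library: int
    total_in_library: int


@dataclass
class ClusterScoreTable:
    """(cluster -> signed -log10 P toxicity score) for one training split."""

    scores: dict[str, ClusterScore]

    def __getitem__(self, cluster: str) -> float:
        return self.scores[cluster].score

    def get(self, cluster: str, default: float = 0.0) -> float:
        cs = self.scores.get(cluster)
        return cs.score if cs is not None else default


@dataclass
class ModelEvaluation:
    endpoint: str
    model_kind: str  # activity | structure | combined | single-assay
    auc_per_split: list[float]
    auc_mean: float
    auc_sd: float
    n_splits_used: int
    unmodelable: bool = False


def split_train_test(
    compounds: Sequence[str], seed: int
) -> tuple[set[str], set[str]]:
    """Uniformly random unstratified half split (sizes differ by <= 1)."""
    comps = sorted(compounds)
    if len(comps) < 4:
        raise ValueError("need at least 4 compounds to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(comps))
    half = len(comps) // 2
    train = {comps[i] for i in perm[:half]}
    test = {comps[i] for i in perm[half:]}
    return train, test


def score_clusters(
    train_calls: Mapping[str, bool], assignment: ClusterAssignment
) -> ClusterScoreTable:
    """Signed -log10 Fisher P toxicity score per cluster, from training calls.

    Positive when the cluster's toxic fraction exceeds the training-set
    fraction (enriched), negative when deficient, 0 on an exact tie.
    Clusters without training compounds are absent.
    """
    total = len(train_calls)
    toxic_total = sum(bool(v) for v in train_calls.values())
    by_cluster: dict[str, list[str]] = {}
    for cid in train_calls:
        lab = assignment.labels.get(cid)
        if lab is None:
            raise KeyError(f"compound {cid!r} has no cluster label")
        by_cluster.setdefault(lab, []).append(cid)
    lib_frac = toxic_total / total if total else 0.0
    scores: dict[str, ClusterScore] = {}
    for lab, members in by_cluster.items():
        a = sum(bool(train_calls[c]) for c in members)
        b = len(members) - a
        c = toxic_total - a
        d = (total - toxic_total) - b
        frac = a / len(members)
        if frac > lib_frac:
            p = max(fisher_pvalue(a, b, c, d, enriched=True), P_FLOOR)
            score = -math.log10(p)
        elif frac < lib_frac:
            p = max(fisher_pvalue(a, b, c, d, enriched=False), P_FLOOR)
            score = math.log10(p)
        else:
            score = 0.0
        scores[lab] = ClusterScore(
            score=score, toxic_in_cluster=a, total_in_cluster=len(members),
            toxic_in_library=toxic_total, total_in_library=total,
        )
    return ClusterScoreTable(scores=scores)


def predict(
    test_compounds: Sequence[str],
    assignment: ClusterAssignment,
    scores: ClusterScoreTable,
    missing_policy: str = "neutral",
) -> dict[str, float]:
    """Assign each test compound its cluster's training score.

    Compounds whose cluster holds no training compounds score 0 under the
    default "neutral" policy or are dropped under "abstain".
    """
    if missing_policy not in ("neutral", "abstain"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    out: dict[str, float] = {}
    for cid in test_compounds:
        lab = assignment.labels.get(cid)
        if lab is None:
            raise KeyError(f"compound {cid!r} has no cluster label")
        cs = scores.scores.get(lab)
        if cs is None:
            if missing_policy == "neutral":
                out[cid] = 0.0
        else:
            out[cid] = cs.score
    return out


def roc_auc(
    scores: Mapping[str, float], truth: Mapping[str, bool]
) -> float:
    """Tie-aware AUC-ROC of a score against binary toxicity calls.

    Equals the cutoff-sweep trapezoidal area with compounds counted toxic
    at score > cutoff, and equivalently the rank statistic
    (concordant pairs + half ties) / (n_toxic * n_nontoxic).  Returns NaN
    when the truth is single-class (undefined, flagged by the caller).
    """
    common = [c for c in scores if c in truth]
    y = np.array([bool(truth[c]) for c in common])
    s = np.array([float(scores[c]) for c in common])
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _endpoint_seed(seed: int, endpoint: str) -> int:
    """Stable per-endpoint seed below 2^31."""
    return (int(seed) * 1_000_003 + zlib.crc32(endpoint.encode())) % (2**31)


def evaluate_model(
    calls: Mapping[str, bool],
    assignment: ClusterAssignment,
    endpoint: str,
    n_repeats: int = 100,
    seed: int = 0,
    model_kind: str = "activity",
    missing_policy: str = "neutral",
) -> ModelEvaluation:
    """Repeated split-half evaluation of the cluster-score model.

    ``calls`` maps compound -> toxic for one endpoint (already filtered).
    Splits are seeded from the master seed and the endpoint name, so
    adding or removing endpoints does not perturb other endpoints'
    splits.  Splits whose test half is single-class are dropped; if every
    split degenerates the endpoint is flagged unmodelable.
    """
    comps = [c for c in calls if c in assignment.labels]
    ss = np.random.SeedSequence(_endpoint_seed(seed, endpoint))
    child = ss.generate_state(n_repeats, dtype=np.uint32) & 0x7FFFFFFF
    aucs: list[float] = []
    for r in range(n_repeats):
        train, test = split_train_test(comps, int(child[r]))
        table = score_clusters({c: calls[c] for c in train}, assignment)
        preds = predict(sorted(test), assignment, table, missing_policy)
        auc = roc_auc(preds, {c: calls[c] for c in test})
        if not math.isnan(auc):
            aucs.append(auc)
    if not aucs:
        return ModelEvaluation(
            endpoint=endpoint, model_kind=model_kind, auc_per_split=[],
            auc_mean=float("nan"), auc_sd=float("nan"), n_splits_used=0,
            unmodelable=True,
        )
    return ModelEvaluation(
        endpoint=endpoint, model_kind=model_kind, auc_per_split=aucs,
        auc_mean=float(np.mean(aucs)), auc_sd=float(np.std(aucs, ddof=1))
        if len(aucs) > 1 else 0.0,
        n_splits_used=len(aucs),
    )


def evaluate_models(
    calls_by_endpoint: Mapping[str, Mapping[str, bool]],
    assignments: Mapping[str, ClusterAssignment],
    n_repeats: int = 100,
    seed: int = 0,
) -> list[ModelEvaluation]:
    """Evaluate every endpoint against every map kind."""
    out = []
    for ep in sorted(calls_by_endpoint):
        for kind in sorted(assignments):
            out.append(
                evaluate_model(
                    calls_by_endpoint[ep], assignments[kind], ep,
                    n_repeats=n_repeats, seed=seed, model_kind=kind,
                )
            )
    return out


def single_assay_auc(
    profiles: pd.DataFrame, calls: Mapping[str, bool]
) -> pd.DataFrame:
    """Predictivity of each assay readout alone for one endpoint.

    The score is |curve rank| (activity magnitude in either direction).
    Returns a frame (assay, auc, predictive) flagging assays with
    AUC > 0.7; constant columns score 0.5 by the tie rule.
    """
    common = [c for c in profiles.index if c in calls]
    truth = {c: bool(calls[c]) for c in common}
    rows = []
    for col in profiles.columns:
        scores = {
            c: float(abs(profiles.at[c, col])) for c in common
        }
        auc = roc_auc(scores, truth)
        rows.append((col, auc, bool(auc > PREDICTIVE_AUC)))
    return pd.DataFrame(rows, columns=["assay", "auc", "predictive"])


@dataclass(frozen=True)
class Correlation:
    r: float
    p_value: float
    n: int
    defined: bool = True


def correlate_repro_performance(
    concordances: Mapping[str, float], auc_means: Mapping[str, float]
) -> Correlation:
    """Pearson correlation of endpoint replicate concordance with model AUC."""
    common = [
        e for e in concordances
        if e in auc_means
        and not math.isnan(concordances[e])
        and not math.isnan(auc_means[e])
    ]
    if len(common) < 3:
        raise ValueError("need at least 3 endpoints with both quantities")
    x = np.array([concordances[e] for e in common])
    y = np.array([auc_means[e] for e in common])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return Correlation(float("nan"), float("nan"), len(common), False)
    r, p = pearsonr(x, y)
    return Correlation(float(r), float(p), len(common))


def evaluations_frame(evals: Sequence[ModelEvaluation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.endpoint, e.model_kind, e.auc_mean, e.auc_sd, e.n_splits_used,
             e.unmodelable)
            for e in evals
        ],
        columns=["endpoint", "model_kind", "auc_mean", "auc_sd", "n_splits",
                 "unmodelable"],
    )
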