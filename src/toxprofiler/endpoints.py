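"""Binary toxicity calls from in vivo endpoint measurements.

Dose endpoints (LD50-like, mg/kg) call a compound toxic below 300 mg/kg.
Other numeric endpoints call the most-toxic 35% of compounds toxic
(nearest-rank percentile; for the default lower-is-worse direction the
lowest 35%, boundary ties included).  Composite endpoints take a strict
majority vote over their component calls.  Endpoints are retained for
modelling only with at least 50 toxic and 50 non-toxic calls, and replicate
measurements quantify how reproducible the binary call itself is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DOSE_TOXIC_THRESHOLD = 300.0  # mg/kg, strict <
SCORE_TOXIC_PERCENTILE = 0.35
MIN_CALLS_PER_SIDE = 50
MIN_REPLICATED_COMPOUNDS = 20


@dataclass(frozen=True)
class EndpointMeta:
    """Endpoint descriptor: type, optional composite components, direction."""

    name: str
    endpoint_type: str  # dose | score | composite
    components: tuple[str, ...] = ()
    lower_is_toxic: bool = True
    species: str = ""
    route: str = ""

    def __post_init__(self) -> None:
        if self.endpoint_type not in ("dose", "score", "composite"):
            raise ValueError(f"unknown endpoint_type {self.endpoint_type!r}")
        if self.endpoint_type == "composite" and len(self.components) < 2:
            raise ValueError("composite endpoints need >= 2 components")


@dataclass
class EndpointTable:
    """Long-format endpoint measurements plus per-endpoint metadata.

    ``entries`` columns: compound_id, endpoint, value, replicate_index
    (>= 1; replicates beyond the first are extra measurements of the same
    compound).
    """

    entries: pd.DataFrame
    meta: dict[str, EndpointMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"compound_id", "endpoint", "value", "replicate_index"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"entries missing columns {sorted(missing)}")
        if len(self.entries) and (self.entries["replicate_index"] < 1).any():
            raise ValueError("replicate_index must be >= 1")

    def endpoints(self) -> list[str]:
        measured = list(dict.fromkeys(self.entries["endpoint"]))
        composites = [n for n, m in self.meta.items()
                      if m.endpoint_type == "composite"]
        return measured + [c for c in composites if c not in measured]

    def aggregated(self, endpoint: str) -> pd.Series:
        """Per-compound median over replicates for one endpoint."""
        sub = self.entries[self.entries["endpoint"] == endpoint]
        return sub.groupby("compound_id")["value"].median()

    def replicate_values(self, endpoint: str) -> dict[str, list[float]]:
        sub = self.entries[self.entries["endpoint"] == endpoint]
        return {
            cid: grp.sort_values("replicate_index")["value"].tolist()
            for cid, grp in sub.groupby("compound_id")
        }


@dataclass
class ToxCalls:
    """Binary toxic/non-toxic calls per (compound, endpoint).

    ``calls`` columns: compound_id, endpoint, toxic (bool).  ``retained``
    lists endpoints passing the >=50/>=50 filter.
    """

    calls: pd.DataFrame
    retained: list[str] = field(default_factory=list)

    def counts(self, endpoint: str) -> tuple[int, int]:
        sub = self.calls[self.calls["endpoint"] == endpoint]
        n_tox = int(sub["toxic"].sum())
        return n_tox, len(sub) - n_tox

    def endpoint_calls(self, endpoint: str) -> dict[str, bool]:
        sub = self.calls[self.calls["endpoint"] == endpoint]
        return dict(zip(sub["compound_id"], sub["toxic"].astype(bool)))


def _score_threshold(values: np.ndarray, lower_is_toxic: bool) -> float:
    """Nearest-rank boundary value of the most-toxic 35% tail."""
    n = values.size
    k = max(1, math.ceil(SCORE_TOXIC_PERCENTILE * n))
    ordered = np.sort(values)
    return float(ordered[k - 1] if lower_is_toxic else ordered[n - k])


def call_toxicity(
    values: Mapping[str, float] | pd.Series,
    endpoint_type: str,
    lower_is_toxic: bool = True,
) -> dict[str, bool]:
    """Binary calls for one endpoint from replicate-aggregated values.

    Dose: toxic iff value < 300 (strict).  Score: toxic iff the value falls
    in the most-toxic 35% by the nearest-rank percentile, boundary ties
    toxic.  Composite endpoints are handled by :func:`composite_call`.
    """
    if endpoint_type == "composite":
        raise ValueError("use composite_call for composite endpoints")
    if endpoint_type not in ("dose", "score"):
        raise ValueError(f"unknown endpoint_type {endpoint_type!r}")
    series = pd.Series(values, dtype=float)
    if series.empty:
        raise ValueError("values must be non-empty")
    if endpoint_type == "dose":
        return {c: bool(v < DOSE_TOXIC_THRESHOLD) for c, v in series.items()}
    thr = _score_threshold(series.to_numpy(), lower_is_toxic)
    if lower_is_toxic:
        return {c: bool(v <= thr) for c, v in series.items()}
    return {c: bool(v >= thr) for c, v in series.items()}


def composite_call(
    component_calls: Mapping[str, Mapping[str, bool]],
    components: Sequence[str],
) -> dict[str, bool]:
    """Strict-majority vote over a compound's available component calls.

    A compound is toxic iff toxic in strictly more than half of the
    component endpoints for which it has a call; compounds with no
    component data are absent from the result.
    """
    if len(components) < 2:
        raise ValueError("composite endpoints need >= 2 components")
    tallies: dict[str, list[int]] = {}
    for comp in components:
        for cid, call in component_calls.get(comp, {}).items():
            t = tallies.setdefault(cid, [0, 0])
            t[0] += int(bool(call))
            t[1] += 1
    return {cid: tox > total / 2 for cid, (tox, total) in tallies.items()}


def filter_endpoints(calls: ToxCalls) -> list[str]:
    """Endpoints with at least 50 toxic and 50 non-toxic calls."""
    kept = []
    for ep in dict.fromkeys(calls.calls["endpoint"]):
        n_tox, n_non = calls.counts(ep)
        if n_tox >= MIN_CALLS_PER_SIDE and n_non >= MIN_CALLS_PER_SIDE:
            kept.append(ep)
    return kept


def build_calls(table: EndpointTable) -> ToxCalls:
    """Aggregate replicates, call every endpoint, and apply the 50/50 filter.

    Measured endpoints are called first (replicates reduced by median),
    composites then vote over their components' calls.
    """
    per_endpoint: dict[str, dict[str, bool]] = {}
    for ep in table.endpoints():
        m = table.meta.get(ep, EndpointMeta(name=ep, endpoint_type="score"))
        if m.endpoint_type == "composite":
            continue
        agg = table.aggregated(ep)
        if agg.empty:
            continue
        per_endpoint[ep] = call_toxicity(agg, m.endpoint_type, m.lower_is_toxic)
    for ep, m in table.meta.items():
        if m.endpoint_type != "composite":
            continue
        per_endpoint[ep] = composite_call(per_endpoint, m.components)
    rows = [
        (cid, ep, tox)
        for ep, calls in per_endpoint.items()
        for cid, tox in calls.items()
    ]
    df = pd.DataFrame(rows, columns=["compound_id", "endpoint", "toxic"])
    out = ToxCalls(calls=df)
    out.retained = filter_endpoints(out)
    return out


@dataclass(frozen=True)
class ReproResult:
    """Replicate concordance of the binary call for one endpoint."""

    fraction_concordant: float
    defined: bool
    n_replicated: int
    score: float = float("nan")  # qHTS-style variant, optional


def endpoint_reproducibility(
    values: Mapping[str, Sequence[float]],
    endpoint_type: str,
    lower_is_toxic: bool = True,
) -> ReproResult:
    """Fraction of replicated compounds whose replicate calls all agree.

    Requires at least 20 compounds with >= 2 replicates; below that the
    result is flagged undefined.  Score-type thresholds are computed from
    the per-compound medians of the full table (the same boundary used for
    calling), then applied to each replicate.  Also reports a qHTS-style
    score variant 2*%both-toxic + %both-non-toxic - 2*%discordant on the
    concordant/discordant partition.
    """
    replicated = {c: list(v) for c, v in values.items() if len(v) >= 2}
    n_rep = len(replicated)
    if n_rep < MIN_REPLICATED_COMPOUNDS:
        return ReproResult(float("nan"), False, n_rep)
    if endpoint_type == "dose":
        def call(v: float) -> bool:
            return v < DOSE_TOXIC_THRESHOLD
    else:
        medians = np.array([float(np.median(v)) for v in values.values()])
        thr = _score_threshold(medians, lower_is_toxic)
        if lower_is_toxic:
            def call(v: float) -> bool:
                return v <= thr
        else:
            def call(v: float) -> bool:
                return v >= thr
    both_tox = both_non = discord = 0
    for reps in replicated.values():
        calls = {call(v) for v in reps}
        if len(calls) > 1:
            discord += 1
        elif calls == {True}:
            both_tox += 1
        else:
            both_non += 1
    frac = (both_tox + both_non) / n_rep
    score = 100.0 * (2 * both_tox + both_non - 2 * discord) / n_rep
    return ReproResult(frac, True, n_rep, score)


def summarize_endpoints(table: EndpointTable, calls: ToxCalls) -> pd.DataFrame:
    """Per-endpoint summary: call counts, retention, replicate concordance."""
    rows = []
    for ep in calls.calls["endpoint"].unique():
        n_tox, n_non = calls.counts(ep)
        m = table.meta.get(ep, EndpointMeta(name=ep, endpoint_type="score"))
        if m.endpoint_type == "composite":
            rep = ReproResult(float("nan"), False, 0)
        else:
            rep = endpoint_reproducibility(
                table.replicate_values(ep), m.endpoint_type, m.lower_is_toxic
            )
        rows.append(
            (ep, m.endpoint_type, n_tox, n_non, ep in calls.retained,
             rep.fraction_concordant, rep.n_replicated)
        )
    return pd.DataFrame(
        rows,
        columns=["endpoint", "type", "n_toxic", "n_nontoxic", "retained",
                 "concordance", "n_replicated"],
    )
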