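"""Per-cluster annotation-term enrichment by Fisher's exact test.

Each cluster is tested for over-representation of each mode-of-action
annotation term over the universe of annotated compounds.  Tests are
one-sided in the direction of the observed deviation (over-represented
terms get the upper hypergeometric tail, depleted terms the lower) and no
multiple-testing correction is applied by default; a Benjamini-Hochberg
FDR option is available.  Clusters are labelled by their most
significantly enriched term.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

UNANNOTATED_LABEL = "unannotated"


@dataclass(frozen=True)
class EnrichmentResult:
    """One cluster x term 2x2 test.

    a: in-cluster with term, b: in-cluster without, c: out-of-cluster with
    term, d: out-of-cluster without.  ``enriched`` is True when the
    in-cluster term fraction strictly exceeds the universe fraction.
    """

    cluster: str
    term: str
    a: int
    b: int
    c: int
    d: int
    p_value: float
    enriched: bool
    q_value: float = float("nan")


def fisher_pvalue(a: int, b: int, c: int, d: int, enriched: bool) -> float:
    """One-sided exact hypergeometric tail for a 2x2 table.

    Upper tail (>= a successes) when testing over-representation, lower
    tail (<= a) otherwise.  Identical to the one-sided Fisher exact test.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    N, K, n = a + b + c + d, a + c, a + b
    if enriched:
        return float(min(hypergeom.sf(a - 1, N, K, n), 1.0))
    return float(min(hypergeom.cdf(a, N, K, n), 1.0))


def fisher_enrichment(
    cluster_members: Iterable[str],
    term_members: Iterable[str],
    universe: Iterable[str],
    cluster: str = "",
    term: str = "",
) -> EnrichmentResult:
    """Test one cluster for enrichment of one annotation term.

    ``universe`` should contain only annotated compounds; cluster and term
    membership are intersected with it.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    cl = set(cluster_members) & uni
    tm = set(term_members) & uni
    a = len(cl & tm)
    b = len(cl) - a
    c = len(tm) - a
    d = len(uni) - a - b - c
    n_cl = a + b
    enriched = n_cl > 0 and a / n_cl > (a + c) / len(uni)
    p = fisher_pvalue(a, b, c, d, enriched)
    return EnrichmentResult(
        cluster=cluster, term=term, a=a, b=b, c=c, d=d,
        p_value=p, enriched=enriched,
    )


def enrich_clusters(
    clusters: Mapping[str, Iterable[str]],
    annotations: Mapping[str, Iterable[str]],
    fdr: bool = False,
) -> list[EnrichmentResult]:
    """All cluster x term tests over the annotated universe.

    ``clusters`` maps cluster label -> member compounds; ``annotations``
    maps compound -> term ids (compounds with no terms are excluded from
    the universe).  Only terms present in a cluster are tested for it.
    With ``fdr=True``, Benjamini-Hochberg adjusted q-values are attached
    across all tests.
    """
    ann = {c: set(t) for c, t in annotations.items() if t}
    universe = set(ann)
    term_members: dict[str, set[str]] = {}
    for cid, terms in ann.items():
        for t in terms:
            term_members.setdefault(t, set()).add(cid)
    results: list[EnrichmentResult] = []
    for lab in sorted(clusters):
        members = set(clusters[lab]) & universe
        present = sorted({t for cid in members for t in ann[cid]})
        for t in present:
            results.append(
                fisher_enrichment(members, term_members[t], universe,
                                  cluster=lab, term=t)
            )
    if fdr and results:
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests(
            [r.p_value for r in results], method="fdr_bh"
        )
        results = [replace(r, q_value=float(qi)) for r, qi in zip(results, q)]
    return results


def label_clusters(
    results: Sequence[EnrichmentResult],
    clusters: Mapping[str, Iterable[str]] | None = None,
) -> dict[str, tuple[str, float]]:
    """Label each cluster by its most significantly enriched term.

    Smallest p wins; ties break towards the larger in-cluster term count
    a, then the lexicographically smaller term id.  Clusters with no
    annotated member (or absent from ``results``) are labelled
    "unannotated" with p 1.0 when ``clusters`` is supplied.
    """
    best: dict[str, EnrichmentResult] = {}
    for r in results:
        if not r.enriched:
            continue
        cur = best.get(r.cluster)
        if (
            cur is None
            or r.p_value < cur.p_value
            or (r.p_value == cur.p_value and (-r.a, r.term) < (-cur.a, cur.term))
        ):
            best[r.cluster] = r
    labels = {c: (r.term, r.p_value) for c, r in best.items()}
    # clusters that were tested but had nothing enriched: fall back to the
    # least-deficient term so every annotated cluster gets a label
    seen = {r.cluster for r in results}
    for c in seen - set(labels):
        fallback = min(
            (r for r in results if r.cluster == c),
            key=lambda r: (r.p_value, -r.a, r.term),
        )
        labels[c] = (fallback.term, fallback.p_value)
    if clusters is not None:
        for c in set(clusters) - set(labels):
            labels[c] = (UNANNOTATED_LABEL, 1.0)
    return labels


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.cluster, r.term, r.a, r.b, r.c, r.d, r.p_value, r.enriched,
             r.q_value)
            for r in results
        ],
        columns=["cluster", "term", "a", "b", "c", "d", "p", "enriched", "q"],
    )
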