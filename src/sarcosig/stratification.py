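"""Sample stratification: top-fraction selection, hypergeometric enrichment,
set-overlap testing and signature-gene hierarchical clustering."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .scoring import rank_scores
from .signatures import GeneSignature, restrict_to_platform

__all__ = [
    "EnrichmentResult",
    "ClusterAssignment",
    "top_fraction",
    "hypergeometric_enrichment",
    "intersection_test",
    "cluster_samples",
    "annotate_clusters",
    "dendrogram_text",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One-sided (over-representation) hypergeometric test record.

    ``k`` successes in a selection of size ``n`` drawn from a universe of
    ``N`` containing ``K`` successes; ``p = P(X >= k)``.
    """

    category: str
    k: int
    K: int
    n: int
    N: int
    pvalue: float


def hypergeometric_enrichment(
    k: int, K: int, n: int, N: int, category: str = ""
) -> EnrichmentResult:
    """Upper-tail hypergeometric probability ``P(X >= k)``.

    X counts successes when ``n`` items are drawn without replacement from
    ``N`` items of which ``K`` are successes.  Computed through the scipy
    hypergeometric survival function (log-gamma based, stable for N in the
    hundreds and beyond).
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid bounds: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(category=category, k=k, K=K, n=n, N=N,
                            pvalue=min(p, 1.0))


def top_fraction(
    scores: pd.DataFrame | pd.Series, fraction: float, method: str = "ceil"
) -> set[str]:
    """The highest-scoring ``fraction`` of samples.

    ``scores`` is either a score table with ``score``/``rank`` columns or a
    plain Series of scores (ranked with the deterministic tie rule: ties
    broken by sample ID).  Selection size is ``ceil(fraction * n)`` by
    default, ``floor`` selectable; boundary ties are resolved by rank order.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if method not in ("ceil", "floor"):
        raise ValueError("method must be 'ceil' or 'floor'")
    if isinstance(scores, pd.DataFrame):
        ranks = scores["rank"]
    else:
        ranks = rank_scores(scores)
    n = len(ranks)
    if n == 0:
        raise ValueError("empty score table")
    size = math.ceil(fraction * n) if method == "ceil" else math.floor(fraction * n)
    return set(ranks.index[ranks <= size])


def intersection_test(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str],
    category: str = "intersection",
) -> EnrichmentResult:
    """Test whether two sample sets overlap more than chance within a universe.

    The overlap ``|A ∩ B|`` is tested as drawing ``|B|`` samples from the
    universe containing ``|A|`` marked ones; the resulting upper-tail p is
    symmetric in A and B.
    """
    A, B, U = set(set_a), set(set_b), set(universe)
    if not A <= U or not B <= U:
        raise ValueError("both sets must be contained in the universe")
    return hypergeometric_enrichment(
        k=len(A & B), K=len(A), n=len(B), N=len(U), category=category
    )


@dataclass
class ClusterAssignment:
    """Result of cutting a hierarchical clustering of samples into k groups."""

    labels: pd.Series  # sample_id -> cluster index in 1..k
    linkage: np.ndarray  # scipy linkage matrix (merge order and heights)
    k: int
    genes: list[str]
    enrichment: pd.DataFrame | None = field(default=None)

    @property
    def clusters(self) -> dict[int, set[str]]:
        return {
            int(c): set(members.index)
            for c, members in self.labels.groupby(self.labels)
        }


def cluster_samples(
    x: pd.DataFrame,
    sig: GeneSignature,
    k: int,
    distance: str = "euclidean",
    linkage: str = "complete",
    standardize: bool = True,
) -> ClusterAssignment:
    """Agglomerative clustering of samples on the signature genes.

    Rows are restricted to the signature genes found in the matrix and
    (by default) standardized per gene; samples are clustered with the
    given distance metric and linkage and the tree is cut into exactly
    ``k`` clusters.  Merge order and heights are kept in the scipy linkage
    matrix for inspection.
    """
    restricted, coverage = restrict_to_platform(sig, x.index)
    if coverage == 0 or len(restricted) == 0:
        raise ValueError("no usable signature gene on the platform")
    if not 1 <= k <= x.shape[1]:
        raise ValueError(f"k={k} outside [1, n_samples={x.shape[1]}]")

    sub = x.loc[sorted(restricted.genes)]
    if standardize:
        sd = sub.std(axis=1, ddof=1)
        sub = sub[sd > 0]
        if sub.empty:
            raise ValueError("all signature genes have zero variance")
        sub = sub.sub(sub.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)

    data = sub.to_numpy(float).T  # samples x genes
    Z = hierarchy.linkage(pdist(data, metric=distance), method=linkage)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(flat.astype(int), index=x.columns, name="cluster")
    labels.index.name = "sample_id"
    return ClusterAssignment(labels=labels, linkage=Z, k=int(k),
                             genes=list(sub.index))


def annotate_clusters(
    ca: ClusterAssignment, annotation: pd.Series
) -> pd.DataFrame:
    """Hypergeometric enrichment of every subtype label in every cluster.

    ``annotation`` maps sample_id -> subtype label and must cover every
    clustered sample.  Each cluster is treated as the selection and the
    whole cohort as the universe.  Returns one row per (cluster, label)
    with columns k, K, n, N, p and a ``dominant`` flag marking the minimal-p
    label within each cluster.
    """
    missing = set(ca.labels.index) - set(annotation.index)
    if missing:
        raise ValueError(f"unannotated samples: {sorted(missing)}")
    ann = annotation.loc[ca.labels.index]
    N = len(ann)
    rows = []
    for cluster, members in sorted(ca.clusters.items()):
        n = len(members)
        counts = ann.loc[sorted(members)].value_counts()
        for label in sorted(ann.unique()):
            k = int(counts.get(label, 0))
            K = int((ann == label).sum())
            res = hypergeometric_enrichment(k, K, n, N, category=str(label))
            rows.append(
                {"cluster": cluster, "label": label, "k": k, "K": K,
                 "n": n, "N": N, "pvalue": res.pvalue}
            )
    table = pd.DataFrame(rows)
    table["dominant"] = False
    for cluster, grp in table.groupby("cluster"):
        table.loc[grp["pvalue"].idxmin(), "dominant"] = True
    return table


def dendrogram_text(Z: np.ndarray, labels: Iterable[str]) -> str:
    """Newick-style text rendering of a linkage matrix (label:height nesting)."""
    labels = list(labels)
    n = len(labels)

    def render(node: int) -> str:
        if node < n:
            return labels[node]
        left, right, height = Z[node - n, 0], Z[node - n, 1], Z[node - n, 2]
        return f"({render(int(left))},{render(int(right))}):{height:.6g}"

    return render(2 * n - 2) + ";"
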