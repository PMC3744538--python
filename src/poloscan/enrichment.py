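"""Annotation-term clustering and hypergeometric enrichment.

Motif-positive proteins are grouped into clusters, one per annotation
term, and each cluster is scored by the probability of observing its
composition by chance: with *N* annotated proteins in the reference
universe, *K* of them carrying the term, and a hit set contributing *n*
annotated proteins of which *k* carry the term, the by-chance
probability is the upper tail of the hypergeometric distribution,

    P(X >= k) = sum_{x=k}^{min(n,K)} C(K,x) C(N-K,n-x) / C(N,n).

One-tailed, because the screen asks only about over-representation.
Clusters with P above the retention threshold (0.1 by default) are
discarded; no multiple-testing correction is applied by default, with
Benjamini–Hochberg available as an explicit opt-in.

Terms are flat labels partitioned into five namespaces: the three Gene
Ontology namespaces plus ``phase`` (cell-cycle phase) and ``cancer``
(cancer association).  Proteins may belong to any number of clusters;
clusters may overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .errors import DomainError

GO_NAMESPACES = ("biological_process", "cellular_component", "molecular_function")
NAMESPACES = GO_NAMESPACES + ("phase", "cancer")


class AnnotationSet:
    """Flat protein annotations across namespaces.

    Parameters
    ----------
    assignments:
        Mapping ``protein_id -> iterable of (namespace, term)`` pairs.
    universe_size:
        Number of annotated proteins in the reference universe (*N* of
        the enrichment statistic).  Defaults to the number of distinct
        annotated proteins in ``assignments`` and may not be smaller.
    """

    def __init__(self, assignments, universe_size: int | None = None):
        clean: dict[str, frozenset] = {}
        for pid, terms in assignments.items():
            terms = frozenset(terms)
            for ns, term in terms:
                if ns not in NAMESPACES:
                    raise DomainError(f"unknown namespace {ns!r} for protein {pid!r}")
                if not term or not isinstance(term, str):
                    raise DomainError(f"empty term for protein {pid!r}")
            if terms:
                clean[pid] = terms
        self.assignments = clean
        n_annotated = len(clean)
        if universe_size is None:
            universe_size = n_annotated
        if universe_size < n_annotated:
            raise DomainError(
                f"universe_size {universe_size} < {n_annotated} annotated proteins"
            )
        self.universe_size = int(universe_size)
        members: dict[tuple[str, str], set[str]] = {}
        for pid, terms in clean.items():
            for key in terms:
                members.setdefault(key, set()).add(pid)
        self._term_members = {k: frozenset(v) for k, v in members.items()}
        self.namespaces = frozenset(ns for ns, _ in self._term_members)

    def terms(self, namespaces=None):
        """Iterate ``((namespace, term), members)`` pairs, sorted."""
        for key in sorted(self._term_members):
            if namespaces is None or key[0] in namespaces:
                yield key, self._term_members[key]

    def term_members(self, namespace: str, term: str) -> frozenset:
        return self._term_members.get((namespace, term), frozenset())

    def terms_of(self, protein_id: str, namespace: str | None = None) -> set[str]:
        """Terms attached to a protein, optionally restricted to one namespace."""
        terms = self.assignments.get(protein_id, frozenset())
        if namespace is None:
            return {t for _, t in terms}
        return {t for ns, t in terms if ns == namespace}

    def is_annotated(self, protein_id: str, namespaces=None) -> bool:
        terms = self.assignments.get(protein_id)
        if not terms:
            return False
        if namespaces is None:
            return True
        return any(ns in namespaces for ns, _ in terms)

    def __eq__(self, other):
        return (
            isinstance(other, AnnotationSet)
            and self.assignments == other.assignments
            and self.universe_size == other.universe_size
        )

    def __repr__(self):
        return (
            f"AnnotationSet({len(self.assignments)} annotated proteins, "
            f"{len(self._term_members)} terms, N={self.universe_size})"
        )


@dataclass(frozen=True)
class Cluster:
    """An annotation-term-defined protein group with enrichment counts.

    ``members`` are the hit-set proteins carrying the term (k = |members|);
    ``N`` the annotated universe, ``K`` the term's carriers in the
    universe, ``n`` the annotated hit-set size, ``p_value`` the upper
    hypergeometric tail P(X >= k).
    """

    namespace: str
    term: str
    members: frozenset
    N: int
    K: int
    n: int
    k: int
    p_value: float

    def __post_init__(self):
        if not (0 <= self.k <= min(self.n, self.K) and self.K <= self.N and self.n <= self.N):
            raise DomainError(
                f"inconsistent cluster counts N={self.N} K={self.K} n={self.n} k={self.k}"
            )
        if not 0.0 < self.p_value <= 1.0:
            raise DomainError(f"p_value {self.p_value} outside (0, 1]")
        if self.k != len(self.members):
            raise DomainError("k != |members|")


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts term-carrying proteins among *n* draws without replacement
    from a universe of *N* containing *K* carriers.  Computed as a
    log-space sum of pmf terms over x = k .. min(n, K) for numerical
    stability in the far tail; the result lies in (0, 1].
    """
    for label, value in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(value) != value or value < 0:
            raise DomainError(f"{label} must be a non-negative integer, got {value}")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if not (k <= n <= N and K <= N and k <= K):
        raise DomainError(
            f"counts must satisfy 0 <= k <= min(n, K), n <= N, K <= N; "
            f"got N={N} K={K} n={n} k={k}"
        )
    # whole support is in the tail -> exactly 1
    if k <= max(0, n + K - N):
        return 1.0
    xs = np.arange(k, min(n, K) + 1)
    log_terms = hypergeom.logpmf(xs, N, K, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def cluster_proteins(
    hit_ids,
    annotations: AnnotationSet,
    namespaces=GO_NAMESPACES,
    min_members: int = 1,
) -> list[Cluster]:
    """Group hit proteins by annotation term and score each cluster.

    One cluster is produced per (namespace, term) annotating at least
    ``min_members`` hit proteins.  The annotated hit-set size *n* counts
    hit proteins carrying any annotation in the chosen namespaces and is
    shared by all clusters; unannotated hits are excluded from *n*.
    Clusters are sorted by ascending p-value, ties broken by descending
    k then term lexicographically.
    """
    if min_members < 1:
        raise DomainError(f"min_members must be >= 1, got {min_members}")
    namespaces = tuple(namespaces)
    for ns in namespaces:
        if ns not in NAMESPACES:
            raise DomainError(f"unknown namespace {ns!r}")
        if ns not in annotations.namespaces:
            raise DomainError(f"namespace {ns!r} absent from annotations")
    hit_ids = set(hit_ids)
    if not hit_ids:
        return []
    annotated_hits = {
        pid for pid in hit_ids if annotations.is_annotated(pid, namespaces)
    }
    n = len(annotated_hits)
    N = annotations.universe_size
    clusters = []
    for (ns, term), universe_members in annotations.terms(namespaces):
        members = universe_members & hit_ids
        if len(members) < min_members:
            continue
        K = len(universe_members)
        k = len(members)
        clusters.append(
            Cluster(
                namespace=ns,
                term=term,
                members=frozenset(members),
                N=N,
                K=K,
                n=n,
                k=k,
                p_value=hypergeom_tail(N, K, n, k),
            )
        )
    clusters.sort(key=lambda c: (c.p_value, -c.k, c.term, c.namespace))
    return clusters


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (FDR), via statsmodels."""
    from statsmodels.stats.multitest import multipletests

    if len(p_values) == 0:
        return np.array([])
    return multipletests(list(p_values), method="fdr_bh")[1]


def filter_clusters(clusters, alpha: float = 0.1, method: str | None = None):
    """Retain clusters with p <= alpha (inclusive), preserving order.

    ``method="bh"`` thresholds Benjamini–Hochberg-adjusted values
    instead of the raw ones; the default matches the screen's flat
    "discard p > 0.1" rule with no correction.
    """
    if not 0.0 < alpha <= 1.0:
        raise DomainError(f"alpha {alpha} outside (0, 1]")
    if method not in (None, "bh"):
        raise DomainError(f"unknown correction method {method!r}")
    clusters = list(clusters)
    if method == "bh":
        adjusted = benjamini_hochberg([c.p_value for c in clusters])
        return [c for c, q in zip(clusters, adjusted) if q <= alpha]
    return [c for c in clusters if c.p_value <= alpha]
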