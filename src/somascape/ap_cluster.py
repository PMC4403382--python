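"""Affinity propagation clustering and its hierarchical extension.

The implementation follows the classic message-passing form. With
similarity matrix s (preferences p(k) on the diagonal), the two messages
are iterated, damped by λ (new = λ·old + (1−λ)·computed):

    r(i,k) ← s(i,k) − max_{k'≠k} [ a(i,k') + s(i,k') ]
    a(i,k) ← min{0, r(k,k) + Σ_{i'∉{i,k}} max(0, r(i',k))}   (i ≠ k)
    a(k,k) ← Σ_{i'≠k} max(0, r(i',k))

with a initialized to 0. Exemplars are the points with r(k,k)+a(k,k) > 0;
every other point joins its most similar exemplar. The hierarchy re-runs
the procedure on the exemplars' own profile rows until the cluster count
stops shrinking.

An exhaustive exemplar-set oracle (n ≤ 12) is included so the approximate
optimizer can be validated against the exact net-similarity optimum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimilarityMatrix", "APConfig", "APResult", "APHierarchy",
    "similarity_from_profiles", "set_preference", "ap_iterate",
    "hierarchical_ap", "exhaustive_exemplar_oracle",
]


@dataclass
class SimilarityMatrix:
    """Pairwise similarities s(i,k); the diagonal carries the preferences."""

    s: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        if self.s.ndim != 2 or self.s.shape[0] != self.s.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.all(np.isfinite(self.s)):
            raise ValueError("similarity matrix must be finite")
        if self.labels is None:
            self.labels = [str(i) for i in range(self.s.shape[0])]
        if len(self.labels) != self.s.shape[0]:
            raise ValueError("label count mismatch")

    @property
    def n(self) -> int:
        return self.s.shape[0]


@dataclass
class APConfig:
    damping: float = 0.9
    max_iter: int = 1000
    conv_window: int = 50

    def __post_init__(self):
        if not (0 <= self.damping < 1):
            raise ValueError("damping must be in [0, 1)")


@dataclass
class APResult:
    exemplars: list[int]
    labels: np.ndarray          # per-point exemplar index
    r: np.ndarray
    a: np.ndarray
    iterations: int
    converged: bool
    net_similarity: float
    item_labels: list[str] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)


@dataclass
class APHierarchy:
    levels: list[APResult]
    #: per original case: exemplar index path through the levels
    leaf_paths: list[list[int]]

    @property
    def n_levels(self) -> int:
        return len(self.levels)


def similarity_from_profiles(profile_matrix, method: str = "pearson",
                             labels: list[str] | None = None) -> SimilarityMatrix:
    """Case-by-case similarity from a cases×features profile matrix.

    ``pearson``: s(i,k) = correlation of the two rows (requires per-row
    variance). ``neg_sq_euclid``: s(i,k) = −‖xᵢ−xₖ‖².
    The diagonal is left at the off-diagonal-maximum placeholder of each
    method (1 / 0); call :func:`set_preference` to set preferences.
    """
    X = np.asarray(profile_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 cases")
    if method == "pearson":
        sd = X.std(axis=1)
        if np.any(sd == 0):
            bad = int(np.nonzero(sd == 0)[0][0])
            name = labels[bad] if labels else str(bad)
            raise ValueError(f"zero-variance profile for case {name!r} "
                             "(Pearson similarity undefined)")
        s = np.corrcoef(X)
    elif method == "neg_sq_euclid":
        sq = np.sum(X ** 2, axis=1)
        s = -(sq[:, None] + sq[None, :] - 2 * X @ X.T)
        np.fill_diagonal(s, 0.0)
        s = np.minimum(s, 0.0)  # clip numerical noise above 0
    else:
        raise ValueError(f"unknown similarity method {method!r}")
    return SimilarityMatrix(s=s, labels=list(labels) if labels else None)


def set_preference(S: SimilarityMatrix, strategy="median") -> SimilarityMatrix:
    """Return a copy of S with a shared preference on the diagonal.

    ``strategy`` is "median" (median of off-diagonal similarities, the
    default), ``("quantile", q)``, or a scalar.
    """
    s = S.s.copy()
    off = s[~np.eye(S.n, dtype=bool)]
    if isinstance(strategy, str) and strategy == "median":
        pref = float(np.median(off)) if off.size else 0.0
    elif isinstance(strategy, tuple) and strategy[0] == "quantile":
        pref = float(np.quantile(off, strategy[1])) if off.size else 0.0
    elif np.isscalar(strategy):
        pref = float(strategy)
    else:
        raise ValueError(f"unknown preference strategy {strategy!r}")
    np.fill_diagonal(s, pref)
    return SimilarityMatrix(s=s, labels=list(S.labels))


def _assign(s: np.ndarray, exemplars: list[int]) -> np.ndarray:
    """Label each point with its highest-similarity exemplar (itself if it
    is one); ties go to the lower exemplar index."""
    ex = np.asarray(exemplars)
    labels = ex[np.argmax(s[:, ex], axis=1)]
    labels[ex] = ex
    return labels


def net_similarity(s: np.ndarray, exemplars: list[int],
                   labels: np.ndarray) -> float:
    """Σ of member-to-exemplar similarities plus exemplar preferences."""
    total = sum(s[k, k] for k in exemplars)
    ex = set(exemplars)
    total += sum(s[i, labels[i]] for i in range(s.shape[0]) if i not in ex)
    return float(total)


def ap_iterate(S: SimilarityMatrix, config: APConfig | None = None) -> APResult:
    """Run damped message passing until the exemplar set is stable.

    Convergence is declared when the exemplar set is unchanged for
    ``conv_window`` consecutive iterations; otherwise the best-seen state
    (highest net similarity) is returned with ``converged=False``.
    """
    config = config or APConfig()
    s = S.s
    n = S.n
    if n == 0:
        raise ValueError("empty similarity matrix")
    if n == 1:
        return APResult(exemplars=[0], labels=np.array([0]),
                        r=np.array([[s[0, 0]]]), a=np.zeros((1, 1)),
                        iterations=0, converged=True,
                        net_similarity=float(s[0, 0]),
                        item_labels=list(S.labels))
    s_true = S.s  # assignments and net similarity use the unjittered input
    # eps-scale deterministic jitter breaks the exact-duplicate degeneracy
    # (identical points otherwise leave the messages symmetric forever)
    scale = np.finfo(float).eps * np.abs(s).max() * 100 + np.finfo(float).tiny * 100
    s = s + np.random.default_rng(0).standard_normal((n, n)) * scale
    lam = config.damping
    r = np.zeros((n, n))
    a = np.zeros((n, n))
    idx = np.arange(n)
    best = None  # (net, exemplars, labels)
    prev_ex: tuple[int, ...] | None = None
    stable = 0
    iterations = 0
    converged = False
    for iterations in range(1, config.max_iter + 1):
        # responsibilities
        m = a + s
        top = np.argmax(m, axis=1)
        row_max = m[idx, top]
        m[idx, top] = -np.inf
        row_second = np.max(m, axis=1)
        r_new = s - row_max[:, None]
        r_new[idx, top] = s[idx, top] - row_second
        r = lam * r + (1 - lam) * r_new
        # availabilities
        rp = np.maximum(r, 0.0)
        np.fill_diagonal(rp, 0.0)
        colsum = rp.sum(axis=0)
        a_new = np.minimum(0.0, np.diag(r)[None, :] + colsum[None, :] - rp)
        np.fill_diagonal(a_new, colsum)
        a = lam * a + (1 - lam) * a_new
        # current exemplar estimate
        ex = tuple(np.nonzero(np.diag(r) + np.diag(a) > 0)[0])
        if ex:
            labels = _assign(s_true, list(ex))
            net = net_similarity(s_true, list(ex), labels)
            if best is None or net > best[0]:
                best = (net, list(ex), labels)
        if ex and ex == prev_ex:
            stable += 1
            if stable >= config.conv_window:
                converged = True
                break
        else:
            stable = 0
        prev_ex = ex if ex else None
    if prev_ex and converged:
        exemplars = list(prev_ex)
        labels = _assign(s_true, exemplars)
        net = net_similarity(s_true, exemplars, labels)
    elif best is not None:
        exemplars, labels, net = best[1], best[2], best[0]
    else:
        # messages never elected an exemplar; fall back to the single best
        # candidate by diagonal evidence
        k = int(np.argmax(np.diag(r) + np.diag(a)))
        exemplars = [k]
        labels = _assign(s_true, exemplars)
        net = net_similarity(s_true, exemplars, labels)
    return APResult(exemplars=exemplars, labels=labels, r=r, a=a,
                    iterations=iterations, converged=converged,
                    net_similarity=net, item_labels=list(S.labels))


def hierarchical_ap(profile_matrix, config: APConfig | None = None,
                    method: str = "pearson", preference="median",
                    labels: list[str] | None = None) -> APHierarchy:
    """Cluster cases, then re-cluster the exemplars' profile rows, repeating
    until the cluster count stops strictly decreasing (or one remains)."""
    X = np.asarray(profile_matrix, dtype=float)
    if labels is None:
        labels = [str(i) for i in range(X.shape[0])]
    levels: list[APResult] = []
    current_rows = np.arange(X.shape[0])  # indices into X at this level
    current_labels = list(labels)
    while True:
        S = set_preference(
            similarity_from_profiles(X[current_rows], method=method,
                                     labels=current_labels),
            preference)
        res = ap_iterate(S, config)
        if levels and res.n_clusters >= levels[-1].n_clusters:
            break
        levels.append(res)
        if res.n_clusters <= 1 or len(res.exemplars) < 2:
            break
        current_rows = current_rows[res.exemplars]
        current_labels = [current_labels[k] for k in res.exemplars]
    # compose leaf-to-root exemplar paths
    leaf_paths = []
    for i in range(X.shape[0]):
        path = []
        pos = i
        for res in levels:
            ex_label = int(res.labels[pos])
            path.append(ex_label)
            pos = res.exemplars.index(ex_label)
        leaf_paths.append(path)
    return APHierarchy(levels=levels, leaf_paths=leaf_paths)


def exhaustive_exemplar_oracle(S: SimilarityMatrix) -> tuple[list[int], float]:
    """Exact maximizer of net similarity over all non-empty exemplar sets.

    Brute force; refuses n > 12. Ties resolve to the lexicographically
    first subset.
    """
    n = S.n
    if n > 12:
        raise ValueError("oracle limited to n <= 12")
    if n == 0:
        raise ValueError("empty similarity matrix")
    s = S.s
    best_set: list[int] | None = None
    best_net = -np.inf
    subsets = sorted(
        itertools.chain.from_iterable(
            itertools.combinations(range(n), k) for k in range(1, n + 1)))
    for subset in subsets:
        ex = list(subset)
        labels = _assign(s, ex)
        net = net_similarity(s, ex, labels)
        if net > best_net:
            best_net = net
            best_set = ex
    return best_set, float(best_net)
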