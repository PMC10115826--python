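"""Orthogonality screening of trigger x switch fold-change matrices.

A trigger's *profile* is its row of normalized fold changes against a set
of switches.  Profiles are centered at 1 (the "no effect" baseline), and
the crosstalk between two triggers is measured by the cosine distance of
their centered profiles:

    d(i, j) = 1 - [(FC_i - 1) . (FC_j - 1)] / (||FC_i - 1|| ||FC_j - 1||)

A combination C of triggers scores the *minimum* pairwise distance over C
(max-min diversity); combinations scoring below a threshold (default 0.7)
are flagged as crosstalking.  Two search routes find the best combination
of a given size:

* :func:`best_combination_bruteforce` — exhaustive enumeration with an
  early-exit bound, exact in both profile modes;
* :func:`best_combination_maxmin` — binary search over the sorted unique
  pairwise distances with a clique feasibility test on the threshold
  graph, exact when pair distances do not depend on the combination
  (``profile_mode="full"``); in restricted mode it falls back to the
  pruned exhaustive search.

Profile modes: ``"restricted"`` limits each profile to the switches paired
with the triggers in C (requires a 1:1 trigger-switch pairing);
``"full"`` always uses the complete switch set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DegenerateProfileError, InvalidParameterError

__all__ = [
    "FoldChangeMatrix", "CombinationScore", "centered_profile",
    "pair_cosine_distance", "pairwise_distance_matrix", "combination_distance",
    "best_combination_bruteforce", "best_combination_maxmin",
    "sweep_best_combinations", "classify_orthogonal", "ORTHOGONALITY_THRESHOLD",
]

#: Combinations whose minimum pairwise distance falls below this are
#: flagged as crosstalking.
ORTHOGONALITY_THRESHOLD = 0.7

CENTER = 1.0  # fold-change baseline meaning "no effect"


@dataclass(frozen=True)
class FoldChangeMatrix:
    """Normalized fold-change profiles, triggers (rows) x switches (columns).

    When the matrix is square the i-th trigger is paired with the i-th
    switch, which is what the restricted profile mode relies on.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() <= 0).any():
            raise InvalidParameterError("fold changes must be > 0")

    @property
    def protein_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def switch_ids(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return len(self.values.index)

    @property
    def is_square(self) -> bool:
        return self.values.shape[0] == self.values.shape[1]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FoldChangeMatrix":
        return cls(values=df.astype(float))


@dataclass(frozen=True)
class CombinationScore:
    """A trigger subset with its minimum pairwise cosine distance."""

    combination: tuple[str, ...]      # protein ids, matrix order
    indices: tuple[int, ...]          # row positions, sorted
    distance: float
    argmin_pair: tuple[str, str]
    size: int

    def __post_init__(self) -> None:
        if self.size < 2:
            raise InvalidParameterError("a combination needs at least 2 proteins")


def centered_profile(fc_row: Sequence[float] | np.ndarray) -> np.ndarray:
    """Subtract the no-effect baseline (1) from every component."""
    row = np.asarray(fc_row, dtype=float)
    if row.size == 0:
        raise InvalidParameterError("empty fold-change row")
    return row - CENTER


def pair_cosine_distance(fc_i, fc_j) -> float:
    """1 minus the cosine of the two centered profiles (symmetric).

    0 means identical direction (full crosstalk), 1 means orthogonal
    centered profiles (ideal), up to 2 for opposed profiles.
    """
    u = centered_profile(fc_i)
    v = centered_profile(fc_j)
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise DegenerateProfileError("centered profile has zero norm")
    cos = float(np.dot(u, v)) / (nu * nv)
    return 1.0 - min(1.0, max(-1.0, cos))


def _as_matrix(matrix) -> FoldChangeMatrix:
    if isinstance(matrix, FoldChangeMatrix):
        return matrix
    return FoldChangeMatrix.from_frame(matrix)


def _resolve_indices(m: FoldChangeMatrix, combination: Iterable) -> tuple[int, ...]:
    ids = list(m.values.index)
    out = []
    for c in combination:
        if isinstance(c, (int, np.integer)):
            if not 0 <= int(c) < m.n_proteins:
                raise InvalidParameterError(f"protein index {c} out of range")
            out.append(int(c))
        else:
            try:
                out.append(ids.index(c))
            except ValueError:
                raise InvalidParameterError(f"unknown protein id {c!r}") from None
    if len(set(out)) != len(out):
        raise InvalidParameterError("combination contains duplicate proteins")
    return tuple(sorted(out))


def _check_mode(m: FoldChangeMatrix, profile_mode: str) -> None:
    if profile_mode not in ("restricted", "full"):
        raise InvalidParameterError(f"unknown profile mode {profile_mode!r}")
    if profile_mode == "restricted" and not m.is_square:
        raise InvalidParameterError(
            "restricted profile mode needs a square matrix with 1:1 "
            "trigger-switch pairing"
        )


def combination_distance(matrix, combination, profile_mode: str = "restricted") -> CombinationScore:
    """Minimum pairwise cosine distance over a combination.

    Ties in the argmin pair break to the lexicographically smallest sorted
    index pair (which is also the enumeration order used here).
    """
    m = _as_matrix(matrix)
    _check_mode(m, profile_mode)
    idx = _resolve_indices(m, combination)
    if len(idx) < 2:
        raise InvalidParameterError("combination must contain at least 2 proteins")
    arr = m.values.to_numpy()
    cols = np.array(idx) if profile_mode == "restricted" else np.arange(arr.shape[1])
    best = np.inf
    best_pair = None
    for i, j in itertools.combinations(idx, 2):
        d = pair_cosine_distance(arr[i, cols], arr[j, cols])
        if d < best:
            best = d
            best_pair = (i, j)
    ids = m.protein_ids
    return CombinationScore(
        combination=tuple(ids[k] for k in idx),
        indices=idx,
        distance=float(best),
        argmin_pair=(ids[best_pair[0]], ids[best_pair[1]]),
        size=len(idx),
    )


def pairwise_distance_matrix(matrix, profile_mode: str = "full") -> pd.DataFrame:
    """All pairwise centered-cosine distances (full-profile by definition
    unless the restriction is the full set anyway)."""
    m = _as_matrix(matrix)
    arr = m.values.to_numpy()
    n = m.n_proteins
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pair_cosine_distance(arr[i], arr[j])
        out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=m.values.index, columns=m.values.index)


def _check_n(m: FoldChangeMatrix, n: int) -> None:
    if not 2 <= n <= m.n_proteins:
        raise InvalidParameterError(
            f"set size N={n} out of range [2, {m.n_proteins}]"
        )


def best_combination_bruteforce(matrix, n: int, profile_mode: str = "restricted") -> CombinationScore:
    """Exhaustive best-subset search.

    Enumerates subsets in lexicographic index order and keeps the first
    maximizer, so ties resolve to the lexicographically smallest subset.
    A running lower bound prunes the pair loop (any pair below the current
    best disqualifies the subset immediately).
    """
    m = _as_matrix(matrix)
    _check_mode(m, profile_mode)
    _check_n(m, n)
    arr = m.values.to_numpy()
    n_prot = m.n_proteins
    full_cols = np.arange(arr.shape[1])
    # full mode: precompute pair distances once
    pre = None
    if profile_mode == "full":
        pre = np.zeros((n_prot, n_prot))
        for i, j in itertools.combinations(range(n_prot), 2):
            d = pair_cosine_distance(arr[i], arr[j])
            pre[i, j] = pre[j, i] = d

    best_score = -np.inf
    best_idx: tuple[int, ...] | None = None
    best_pair: tuple[int, int] | None = None
    for combo in itertools.combinations(range(n_prot), n):
        cols = np.array(combo) if profile_mode == "restricted" else full_cols
        subset_min = np.inf
        subset_pair = None
        pruned = False
        for i, j in itertools.combinations(combo, 2):
            d = pre[i, j] if pre is not None else pair_cosine_distance(arr[i, cols], arr[j, cols])
            if d < subset_min:
                subset_min = d
                subset_pair = (i, j)
                if subset_min <= best_score:  # cannot beat the incumbent
                    pruned = True
                    break
        if not pruned and subset_min > best_score:
            best_score = subset_min
            best_idx = combo
            best_pair = subset_pair
    ids = m.protein_ids
    return CombinationScore(
        combination=tuple(ids[k] for k in best_idx),
        indices=tuple(best_idx),
        distance=float(best_score),
        argmin_pair=(ids[best_pair[0]], ids[best_pair[1]]),
        size=n,
    )


def _lex_smallest_clique(adj: np.ndarray, size: int) -> tuple[int, ...] | None:
    """Lexicographically smallest clique of a given size, by DFS in
    increasing vertex order (subsets are visited in sorted-tuple lex order)."""
    n = adj.shape[0]

    def extend(clique: list[int], candidates: list[int]) -> tuple[int, ...] | None:
        if len(clique) == size:
            return tuple(clique)
        if len(clique) + len(candidates) < size:
            return None
        for pos, v in enumerate(candidates):
            if len(clique) + len(candidates) - pos < size:
                return None
            nxt = [u for u in candidates[pos + 1:] if adj[v, u]]
            clique.append(v)
            found = extend(clique, nxt)
            if found is not None:
                return found
            clique.pop()
        return None

    return extend([], list(range(n)))


def best_combination_maxmin(matrix, n: int, profile_mode: str = "full") -> CombinationScore:
    """Optimized max-min search, contract-identical to the brute force.

    Binary-searches the sorted unique pairwise distances for the largest
    threshold t such that the graph with edges {d >= t} contains a clique
    of size N (exact max-clique via networkx), then returns the
    lexicographically smallest N-clique at the optimal threshold.  Exact
    only when pair distances are independent of the combination, i.e. in
    full-profile mode; restricted mode delegates to the pruned exhaustive
    search.
    """
    m = _as_matrix(matrix)
    _check_mode(m, profile_mode)
    _check_n(m, n)
    if profile_mode == "restricted":
        return best_combination_bruteforce(m, n, profile_mode="restricted")

    dist = pairwise_distance_matrix(m).to_numpy()
    n_prot = m.n_proteins
    if n == n_prot:  # single candidate: the full set
        return combination_distance(m, range(n_prot), profile_mode="full")

    iu = np.triu_indices(n_prot, k=1)
    levels = np.unique(dist[iu])

    def feasible(t: float) -> bool:
        g = nx.Graph()
        g.add_nodes_from(range(n_prot))
        g.add_edges_from(zip(*np.nonzero(np.triu(dist >= t, k=1))))
        clique, _ = nx.max_weight_clique(g, weight=None)
        return len(clique) >= n

    lo, hi = 0, len(levels) - 1  # levels[0] is always feasible (global min)
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if feasible(levels[mid]):
            lo = mid
        else:
            hi = mid - 1
    t_opt = levels[lo]
    adj = dist >= t_opt
    np.fill_diagonal(adj, False)
    idx = _lex_smallest_clique(adj, n)
    return combination_distance(m, idx, profile_mode="full")


def sweep_best_combinations(
    matrix,
    n_min: int = 3,
    n_max: int = 17,
    profile_mode: str = "full",
    method: str = "auto",
) -> list[CombinationScore]:
    """Best combination for every set size N in [n_min, n_max] inclusive.

    In full-profile mode the best distance is non-increasing in N (a
    superset can only add pairs to the minimum).  ``method`` is ``"auto"``
    (max-min in full mode, pruned brute force in restricted mode),
    ``"bruteforce"`` or ``"maxmin"``.
    """
    m = _as_matrix(matrix)
    _check_mode(m, profile_mode)
    if not 2 <= n_min <= n_max <= m.n_proteins:
        raise InvalidParameterError(
            f"sweep range [{n_min}, {n_max}] out of bounds for {m.n_proteins} proteins"
        )
    if method == "auto":
        method = "maxmin" if profile_mode == "full" else "bruteforce"
    search = best_combination_maxmin if method == "maxmin" else best_combination_bruteforce
    return [search(m, n, profile_mode=profile_mode) for n in range(n_min, n_max + 1)]


def classify_orthogonal(score, threshold: float = ORTHOGONALITY_THRESHOLD) -> bool:
    """True when a combination's distance reaches the orthogonality
    threshold (boundary inclusive); below it the combination crosstalks."""
    d = score.distance if isinstance(score, CombinationScore) else float(score)
    return d >= threshold
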