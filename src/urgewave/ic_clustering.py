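"""Spatial clustering of IC equivalent-dipole coordinates.

Dipole coordinates (mm) are partitioned with best-of-restarts k-means and the
cluster count is selected by internal validity indices: Silhouette (argmax),
Davies-Bouldin (argmin) and Calinski-Harabasz (argmax).  An index whose score
curve is monotone over the scanned range is flagged as showing no optimum.
The unique-subject count per cluster is reported and used to break exact
ties between adjacent candidate counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .exceptions import DegenerateInputError, ParameterError
from .synthetic import DipoleSet

INDEX_NAMES = ("silhouette", "davies_bouldin", "calinski_harabasz")


@dataclass
class ClusterSolution:
    assignments: np.ndarray          # cluster id per IC
    k: int
    centroids: np.ndarray            # (k, 3) mm
    inertia: float                   # within-cluster sum of squares
    unique_subjects: np.ndarray      # unique-subject count per cluster
    scores: dict | None = None


def partition_dipoles(
    dipoles: DipoleSet, k: int, n_restarts: int = 50, seed=None
) -> ClusterSolution:
    """Best-of-restarts k-means partition of the dipole coordinates."""
    x = dipoles.coordinates
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k > x.shape[0]:
        raise ParameterError("k cannot exceed the number of ICs")
    seed_int = int(np.random.default_rng(seed).integers(2**31 - 1)) if not isinstance(seed, (int, np.integer)) else int(seed)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed_int)
    assignments = km.fit_predict(x)
    uniq = np.array(
        [len(np.unique(dipoles.subject[assignments == c])) for c in range(k)]
    )
    return ClusterSolution(
        assignments=assignments,
        k=k,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        unique_subjects=uniq,
    )


def index_scores(solution: ClusterSolution, dipoles: DipoleSet) -> dict:
    """Silhouette / Davies-Bouldin / Calinski-Harabasz on Euclidean distances."""
    x = dipoles.coordinates
    labels = solution.assignments
    if not 2 <= solution.k < x.shape[0]:
        raise DegenerateInputError("indices need 2 <= k < n_ICs")
    return {
        "silhouette": float(silhouette_score(x, labels)),
        "davies_bouldin": float(davies_bouldin_score(x, labels)),
        "calinski_harabasz": float(calinski_harabasz_score(x, labels)),
    }


def _is_monotone(v: np.ndarray) -> bool:
    d = np.diff(v)
    return bool(np.all(d >= 0) or np.all(d <= 0))


@dataclass
class KSelection:
    table: pd.DataFrame              # one row per k with the three scores
    best: dict                       # index name -> optimal k (or None)
    no_optimum: dict                 # index name -> bool (monotone curve)
    solutions: dict                  # k -> ClusterSolution


def select_k(
    dipoles: DipoleSet,
    k_range=range(2, 21),
    n_restarts: int = 50,
    seed=None,
) -> KSelection:
    """Partition and score every k; report per-index optima and score curves.

    Exact score ties between candidate counts are broken toward the solution
    with the higher mean unique-subject count per cluster.
    """
    ks = list(k_range)
    n = dipoles.coordinates.shape[0]
    if min(ks) < 2 or max(ks) > n - 1:
        raise ParameterError("k_range must lie within [2, n_ICs - 1]")
    ss = np.random.SeedSequence(seed if isinstance(seed, (int, np.integer)) else None)
    child = ss.spawn(len(ks))
    rows, solutions = [], {}
    for i, k in enumerate(ks):
        sol = partition_dipoles(
            dipoles, k, n_restarts, int(child[i].generate_state(1)[0] % (2**31 - 1))
        )
        sol.scores = index_scores(sol, dipoles)
        solutions[k] = sol
        rows.append({"k": k, **sol.scores})
    table = pd.DataFrame(rows)

    def tie_break(cands):
        if len(cands) == 1:
            return int(cands[0])
        means = [solutions[int(k)].unique_subjects.mean() for k in cands]
        return int(cands[int(np.argmax(means))])

    best, no_opt = {}, {}
    for name in INDEX_NAMES:
        v = table[name].to_numpy()
        no_opt[name] = _is_monotone(v)
        target = v.min() if name == "davies_bouldin" else v.max()
        cands = table["k"].to_numpy()[v == target]
        best[name] = None if no_opt[name] else tie_break(cands)
    return KSelection(table=table, best=best, no_optimum=no_opt, solutions=solutions)
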