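"""Recurring connectivity-state analysis.

All subject-window connectivity vectors are pooled and clustered with
k-means under the Manhattan (L1) distance — centroid update is the
componentwise median, the minimizer of summed L1 distance — repeated from
many random initializations and keeping the lowest-objective solution.
The number of states is chosen by the elbow of the cluster-validity
curve (ratio of within- to between-cluster distance).  Per-subject state
dynamics are summarized as frequency, mean dwell time, intertransition
interval, and number of transitions, and centroid stability is assessed
by split-half and bootstrap resampling of subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "ClusterModel",
    "StabilityReport",
    "kmeans_l1",
    "cluster_validity",
    "select_k",
    "find_elbow",
    "state_metrics",
    "run_lengths",
    "stability_analysis",
    "relabel_by_frequency",
    "match_states",
]


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray        # (k, n_features)
    assignments: np.ndarray      # (n_rows,), values 0..k-1
    objective: float             # total L1 distance to assigned centroids
    n_init: int
    seed: int | None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmin(cdist(np.asarray(X), self.centroids, metric="cityblock"), axis=1)


def _l1_assign(X: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    D = cdist(X, C, metric="cityblock")
    lab = np.argmin(D, axis=1)  # argmin takes the lowest index on ties
    return lab, D[np.arange(X.shape[0]), lab]


def _kmeans_l1_single(
    X: np.ndarray, k: int, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float]:
    n = X.shape[0]
    C = X[rng.choice(n, size=k, replace=False)].copy()
    lab, dist = _l1_assign(X, C)
    for _ in range(max_iter):
        for j in range(k):
            members = lab == j
            if not np.any(members):
                # re-seed an emptied centroid at the row farthest from its own
                C[j] = X[int(np.argmax(dist))]
            else:
                C[j] = np.median(X[members], axis=0)
        new_lab, dist = _l1_assign(X, C)
        if np.array_equal(new_lab, lab):
            lab = new_lab
            break
        lab = new_lab
    return C, lab, float(dist.sum())


def kmeans_l1(
    X: np.ndarray,
    k: int,
    n_init: int = 500,
    max_iter: int = 100,
    seed: int | None = None,
) -> ClusterModel:
    """L1 (Manhattan) k-means: best of ``n_init`` random-row initializations.

    Assignment is to the nearest centroid under L1 (ties to the lowest
    centroid index); the update step is the componentwise median, so the
    objective is non-increasing within each initialization.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    if X.shape[0] < k:
        raise ValueError(f"{X.shape[0]} rows < k={k}")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_init):
        C, lab, obj = _kmeans_l1_single(X, k, max_iter, rng)
        if best is None or obj < best[2]:
            best = (C, lab, obj)
    C, lab, obj = best
    return ClusterModel(k=k, centroids=C, assignments=lab, objective=obj,
                        n_init=n_init, seed=seed)


def cluster_validity(X: np.ndarray, model: ClusterModel) -> float:
    """Within/between distance ratio: mean L1 distance of rows to their own
    centroid over the mean pairwise L1 distance among centroids."""
    if model.k < 2:
        raise ValueError("validity ratio requires k >= 2")
    X = np.asarray(X, dtype=float)
    # rows keep their fitted assignment
    dist = cdist(X, model.centroids, metric="cityblock")[
        np.arange(X.shape[0]), model.assignments
    ]
    within = float(dist.mean())
    pair = cdist(model.centroids, model.centroids, metric="cityblock")
    iu = np.triu_indices(model.k, k=1)
    between = float(pair[iu].mean())
    if between == 0:
        raise ValueError("identical centroids: between-cluster distance is zero")
    return within / between


def find_elbow(ks: np.ndarray, values: np.ndarray) -> tuple[int, bool]:
    """Elbow of a curve: the k maximizing perpendicular distance from the
    chord joining the curve's endpoints, after normalizing both axes to
    [0, 1].  Returns (k_star, has_elbow); a (near-)linear curve has no
    elbow and returns the smallest k with has_elbow=False."""
    ks = np.asarray(ks, dtype=float)
    v = np.asarray(values, dtype=float)
    if ks.size < 3:
        return int(ks[0]), False
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    vrange = v.max() - v.min()
    if vrange == 0:
        return int(ks[0]), False
    y = (v - v[0]) / vrange
    # distance from the line through (x0,y0) and (x1,y1)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    if dist.max() < 1e-9:
        return int(ks[0]), False
    return int(ks[int(np.argmax(dist))]), True


def select_k(
    X: np.ndarray,
    k_range: range = range(2, 9),
    n_init: int = 50,
    max_iter: int = 100,
    seed: int | None = None,
) -> tuple[int, pd.DataFrame, bool]:
    """Fit k-means over ``k_range`` and pick k by the elbow criterion of the
    validity curve.  Returns (k_star, curve, has_elbow)."""
    ks, vals = [], []
    rng = np.random.default_rng(seed)
    for k in k_range:
        model = kmeans_l1(X, k, n_init=n_init, max_iter=max_iter,
                          seed=int(rng.integers(2**31 - 1)))
        val = cluster_validity(X, model)
        if not np.isfinite(val):
            raise ValueError(f"non-finite validity at k={k}")
        ks.append(k)
        vals.append(val)
    k_star, has_elbow = find_elbow(np.array(ks), np.array(vals))
    curve = pd.DataFrame({"k": ks, "validity": vals})
    return k_star, curve, has_elbow


# ---------------------------------------------------------------------------
# State dynamics metrics
# ---------------------------------------------------------------------------


def run_lengths(seq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximal runs of a label sequence: (labels, lengths), in order."""
    seq = np.asarray(seq)
    if seq.size == 0:
        raise ValueError("empty assignment sequence")
    change = np.flatnonzero(seq[1:] != seq[:-1])
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [seq.size]])
    return seq[starts], ends - starts


def state_metrics(
    assignments: dict[str, np.ndarray], states: list | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject state dynamics.

    Returns (per_state, per_subject):

    * per_state: subject_id, state, frequency (proportion of windows),
      mean_dwell (mean maximal-run length, NaN if the state never occurs;
      runs touching the sequence edges count);
    * per_subject: subject_id, n_transitions (runs - 1) and
      intertransition_interval (W / number of runs).
    """
    if states is None:
        all_states = sorted({s for seq in assignments.values() for s in np.unique(seq)})
    else:
        all_states = list(states)
    state_set = set(all_states)
    per_state_rows, per_subj_rows = [], []
    for sid, seq in assignments.items():
        seq = np.asarray(seq)
        unknown = set(np.unique(seq)) - state_set
        if unknown:
            raise ValueError(f"subject {sid!r}: unknown state index {sorted(unknown)}")
        W = seq.size
        labs, lens = run_lengths(seq)
        for s in all_states:
            runs = lens[labs == s]
            per_state_rows.append({
                "subject_id": sid,
                "state": s,
                "frequency": float((seq == s).sum()) / W,
                "mean_dwell": float(runs.mean()) if runs.size else np.nan,
            })
        per_subj_rows.append({
            "subject_id": sid,
            "n_transitions": int(labs.size - 1),
            "intertransition_interval": W / labs.size,
        })
    return pd.DataFrame(per_state_rows), pd.DataFrame(per_subj_rows)


def relabel_by_frequency(model: ClusterModel) -> tuple[ClusterModel, np.ndarray]:
    """Relabel states by descending total assignment count so labels are
    comparable across runs.  Returns (new model, old->new permutation)."""
    counts = np.bincount(model.assignments, minlength=model.k)
    order = np.argsort(-counts, kind="stable")
    perm = np.empty(model.k, dtype=int)
    perm[order] = np.arange(model.k)
    return ClusterModel(
        k=model.k,
        centroids=model.centroids[order],
        assignments=perm[model.assignments],
        objective=model.objective,
        n_init=model.n_init,
        seed=model.seed,
    ), perm


def match_states(reference: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-to-one matching of centroids to reference centroids maximizing the
    summed Pearson correlation (Hungarian assignment).  Returns
    (column_for_each_reference_row, matched correlations)."""
    k = reference.shape[0]
    corr = np.empty((k, centroids.shape[0]))
    for i in range(k):
        for j in range(centroids.shape[0]):
            corr[i, j] = np.corrcoef(reference[i], centroids[j])[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    return cols, corr[rows, cols]


# ---------------------------------------------------------------------------
# Stability resampling
# ---------------------------------------------------------------------------


@dataclass
class StabilityReport:
    scheme: str                          # "split_half" | "bootstrap"
    similarities: np.ndarray             # (n_effective_replicates, k)
    n_replicates: int
    n_skipped: int
    seed: int | None

    @property
    def median_similarity(self) -> np.ndarray:
        return np.median(self.similarities, axis=0)


def stability_analysis(
    X: np.ndarray,
    row_subjects: np.ndarray,
    k: int,
    scheme: str = "split_half",
    n_replicates: int = 100,
    n_init: int = 20,
    seed: int | None = None,
    reference: ClusterModel | None = None,
) -> StabilityReport:
    """Centroid stability under subject resampling.

    split_half: subjects are randomly halved, each half clustered, and the
    two centroid sets matched one-to-one by maximal correlation; the matched
    correlations are the per-state similarities.  bootstrap: subjects
    resampled with replacement, clustered, and compared to the full-data
    (or supplied reference) centroids.
    """
    X = np.asarray(X, dtype=float)
    row_subjects = np.asarray(row_subjects)
    if X.shape[0] < 2 * k:
        raise ValueError("need at least 2k rows for stability resampling")
    if scheme not in ("split_half", "bootstrap"):
        raise ValueError(f"unknown scheme {scheme!r}")
    subjects = np.unique(row_subjects)
    rng = np.random.default_rng(seed)
    if scheme == "bootstrap" and reference is None:
        reference = kmeans_l1(X, k, n_init=n_init, seed=int(rng.integers(2**31 - 1)))

    sims, skipped = [], 0
    for _ in range(n_replicates):
        if scheme == "split_half":
            perm = rng.permutation(subjects)
            half_a = set(perm[: subjects.size // 2])
            mask = np.isin(row_subjects, list(half_a))
            Xa, Xb = X[mask], X[~mask]
            if (np.unique(Xa, axis=0).shape[0] < k) or (np.unique(Xb, axis=0).shape[0] < k):
                skipped += 1
                continue
            ma = kmeans_l1(Xa, k, n_init=n_init, seed=int(rng.integers(2**31 - 1)))
            mb = kmeans_l1(Xb, k, n_init=n_init, seed=int(rng.integers(2**31 - 1)))
            _, corr = match_states(ma.centroids, mb.centroids)
        else:
            take = rng.choice(subjects, size=subjects.size, replace=True)
            idx = np.concatenate([np.flatnonzero(row_subjects == s) for s in take])
            Xb = X[idx]
            if np.unique(Xb, axis=0).shape[0] < k:
                skipped += 1
                continue
            mb = kmeans_l1(Xb, k, n_init=n_init, seed=int(rng.integers(2**31 - 1)))
            _, corr = match_states(reference.centroids, mb.centroids)
        sims.append(corr)
    return StabilityReport(
        scheme=scheme,
        similarities=np.array(sims) if sims else np.empty((0, k)),
        n_replicates=n_replicates,
        n_skipped=skipped,
        seed=seed,
    )
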