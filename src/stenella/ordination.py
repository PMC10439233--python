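"""Ordination and group-structure statistics on a dissimilarity matrix.

Four analyses operate directly on the pairwise DTW dissimilarities:

* non-metric multidimensional scaling (NMMDS, Kruskal stress-1) for
  visualizing repertoire overlap;
* PAM k-medoids clustering with labeled-accuracy scoring, to ask how well
  unlabeled whistles separate into the two ecotypes;
* the multi-response permutation procedure (MRPP), testing whether
  within-group dissimilarities are smaller than expected under random
  labeling, with the chance-corrected effect size A;
* a multivariate dispersion (PERMDISP-style) test comparing group spread as
  distance to the group centroid in principal-coordinate space, with a
  Levene-type F and a permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.manifold import MDS

from .dtw import DissimilarityMatrix


@dataclass(frozen=True)
class MrppResult:
    empirical_delta: float
    expected_delta: float
    p_value: float
    effect_size_a: float


@dataclass(frozen=True)
class DispersionResult:
    F_statistic: float
    p_value: float
    group_dispersion: dict


# ---------------------------------------------------------------------------
# NMMDS
# ---------------------------------------------------------------------------


def nmmds(
    D: DissimilarityMatrix,
    dims: int = 2,
    restarts: int = 4,
    seed: int = 0,
    max_iter: int = 300,
) -> tuple[np.ndarray, float]:
    """Two-dimensional non-metric MDS by SMACOF with monotone regression.

    Runs ``restarts`` random initializations and returns the configuration
    with the lowest Kruskal stress-1, as ``(coordinates, stress)``.
    """
    if len(D) < 3:
        raise ValueError("NMMDS needs at least 3 points")
    best = None
    for r in range(restarts):
        model = MDS(
            n_components=dims,
            metric_mds=False,
            metric="precomputed",
            init="random",
            n_init=1,
            max_iter=max_iter,
            random_state=(seed + r) % 2**31,
            normalized_stress=True,
            eps=1e-9,
        )
        coords = model.fit_transform(D.D)
        if best is None or model.stress_ < best[1]:
            best = (coords, float(model.stress_))
    return best


# ---------------------------------------------------------------------------
# PAM k-medoids
# ---------------------------------------------------------------------------


def pam(D: np.ndarray, k: int, max_swaps: int = 200) -> np.ndarray:
    """Partitioning Around Medoids on a precomputed distance matrix.

    Greedy BUILD then steepest-descent SWAP until no swap lowers the total
    distance-to-medoid objective; ties broken toward the lowest index.
    Returns the medoid indices.
    """
    n = len(D)
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        d_near = D[:, medoids].min(axis=1)
        gains = np.array(
            [np.maximum(d_near - D[:, c], 0.0).sum() if c not in medoids else -1.0 for c in range(n)]
        )
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def objective(meds: list[int]) -> float:
        return float(D[:, meds].min(axis=1).sum())

    current = objective(medoids)
    for _ in range(max_swaps):
        best_delta, best_pair = 0.0, None
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1 :]
                delta = objective(trial) - current
                if delta < best_delta - 1e-12:
                    best_delta, best_pair = delta, (mi, h)
        if best_pair is None:
            break
        medoids[best_pair[0]] = best_pair[1]
        medoids = sorted(medoids)
        current = objective(medoids)
    return np.array(medoids)


def kmedoids_accuracy(
    D: DissimilarityMatrix,
    labels: list[str],
    k: int = 2,
    seed: int = 0,
) -> dict:
    """Blind k=2 clustering scored against the two-class ecotype labels.

    Accuracy is the best of the two cluster-to-label mappings; the confusion
    matrix is reported with rows = predicted (mapped cluster) and columns =
    reference label, classes in alphabetical order.
    """
    classes = sorted(set(labels))
    if k != 2 or len(classes) != 2:
        raise ValueError("two-class scoring requires k=2 and exactly two label values")
    medoids = pam(D.D, k)
    assign = np.argmin(D.D[:, medoids], axis=1)
    y = np.array([classes.index(l) for l in labels])
    # two possible mappings of cluster id -> class index
    acc0 = float(np.mean(assign == y))
    acc1 = float(np.mean((1 - assign) == y))
    pred = assign if acc0 >= acc1 else 1 - assign
    cm = np.zeros((2, 2), dtype=int)
    for p, r in zip(pred, y):
        cm[p, r] += 1
    return {
        "assignment": pred,
        "medoids": medoids,
        "confusion": cm,
        "classes": classes,
        "accuracy": max(acc0, acc1),
    }


# ---------------------------------------------------------------------------
# MRPP
# ---------------------------------------------------------------------------


def _weighted_within_delta(D: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """delta = sum_g (n_g/N) * mean within-group pairwise dissimilarity."""
    N = len(codes)
    delta = 0.0
    for g in range(n_groups):
        idx = np.where(codes == g)[0]
        n_g = len(idx)
        sub = D[np.ix_(idx, idx)]
        mean_within = sub[np.triu_indices(n_g, 1)].mean()
        delta += (n_g / N) * mean_within
    return delta


def mrpp(
    D: DissimilarityMatrix,
    groups: list[str],
    n_perm: int = 10000,
    seed: int = 0,
) -> MrppResult:
    """Multi-response permutation procedure with group weights n_g/N.

    The empirical delta is the size-weighted mean within-group dissimilarity;
    the null distribution permutes group labels ``n_perm`` times.  p is the
    proportion of permuted deltas <= the empirical delta, with the (count+1)/
    (n_perm+1) correction; the effect size A = 1 - delta/E[delta] is 0 under
    chance-level grouping and approaches 1 for internally homogeneous groups.
    """
    names = sorted(set(groups))
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    codes = np.array([names.index(g) for g in groups])
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = names[int(np.argmin(counts))]
        raise ValueError(f"group {small!r} has fewer than 2 members")
    emp = _weighted_within_delta(D.D, codes, len(names))
    rng = np.random.default_rng(seed)
    perm_deltas = np.empty(n_perm)
    for i in range(n_perm):
        perm_deltas[i] = _weighted_within_delta(D.D, rng.permutation(codes), len(names))
    expected = float(perm_deltas.mean())
    p = (int(np.sum(perm_deltas <= emp)) + 1) / (n_perm + 1)
    return MrppResult(float(emp), expected, float(p), 1.0 - emp / expected)


# ---------------------------------------------------------------------------
# Multivariate dispersion (PERMDISP-style)
# ---------------------------------------------------------------------------


def pcoa_embedding(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding of a dissimilarity matrix.

    Returns (real coordinates, imaginary coordinates): axes with positive
    eigenvalues and, separately, axes for the negative eigenvalues of the
    Gower-centered matrix.  Squared distances in the imaginary space are
    subtracted, the standard correction for non-Euclidean dissimilarities.
    """
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = 1e-9 * max(1.0, abs(vals).max())
    pos = vals > tol
    neg = vals < -tol
    real = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return real, imag


def _centroid_distances(real: np.ndarray, imag: np.ndarray, codes: np.ndarray) -> np.ndarray:
    d = np.empty(len(codes))
    for g in np.unique(codes):
        idx = codes == g
        cr = real[idx].mean(axis=0)
        ci = imag[idx].mean(axis=0) if imag.size else np.zeros(0)
        d2 = ((real[idx] - cr) ** 2).sum(axis=1)
        if imag.size:
            d2 = d2 - ((imag[idx] - ci) ** 2).sum(axis=1)
        d[idx] = np.sqrt(np.clip(d2, 0.0, None))
    return d


def _anova_f(values: np.ndarray, codes: np.ndarray) -> float:
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    groups = np.unique(codes)
    for g in groups:
        v = values[codes == g]
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    df_b = len(groups) - 1
    df_w = len(values) - len(groups)
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return float((ss_between / df_b) / (ss_within / df_w))


def multivariate_dispersion(
    D: DissimilarityMatrix,
    groups: list[str],
    n_perm: int = 10000,
    seed: int = 0,
) -> DispersionResult:
    """Levene-type comparison of group spread on a dissimilarity matrix.

    Each whistle's dispersion is its distance to its group centroid in
    principal-coordinate space (negative-eigenvalue axes subtracted in the
    squared distance).  Group dispersions are compared by a one-way ANOVA F;
    significance comes from permuting the group labels ``n_perm`` times with
    centroids and distances recomputed under each relabeling, which keeps
    the test exact under exchangeability even at small group sizes.
    """
    names = sorted(set(groups))
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    codes = np.array([names.index(g) for g in groups])
    if np.bincount(codes).min() < 2:
        raise ValueError("every group needs >= 2 members")
    if np.allclose(D.D, 0.0):
        raise ValueError("degenerate embedding: all points identical")
    real, imag = pcoa_embedding(D.D)
    dist = _centroid_distances(real, imag, codes)
    f_obs = _anova_f(dist, codes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _anova_f(_centroid_distances(real, imag, perm), perm) >= f_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    per_group = {name: float(dist[codes == i].mean()) for i, name in enumerate(names)}
    return DispersionResult(f_obs, float(p), per_group)
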