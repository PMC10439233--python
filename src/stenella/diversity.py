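"""Repertoire diversity and similarity from category abundance vectors.

Diversity is quantified with Hill numbers — the effective number of equally
abundant whistle categories — at orders q = 0 (richness), 1 (Shannon) and 2
(Simpson).  Because a sample never exhausts a repertoire, observed values
are complemented by asymptotic (Chao-type) estimates and by coverage-based
rarefaction/extrapolation (R/E) curves, which compare assemblages at equal
*sample coverage* (the estimated fraction of whistles in the repertoire
belonging to already-observed categories) rather than equal sample size.
Bootstrap confidence intervals use the standard unseen-category-adjusted
multinomial resampling.

Between-repertoire similarity uses the abundance-based Horn index (entropy
overlap, sensitive to common categories) and the Morisita-Horn index
(dominance overlap, driven by squared relative abundances), and a
permutation test asks whether the observed proportion of ecotype-specific
categories exceeds chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import gammaln
from scipy.stats import hypergeom

_QS = (0, 1, 2)


@dataclass
class AbundanceVector:
    """Category abundance sample: counts per category plus the f1/f2 tallies."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        for k, v in self.counts.items():
            if v < 0 or int(v) != v:
                raise ValueError(f"count for {k!r} must be a non-negative integer")
        self.counts = {k: int(v) for k, v in self.counts.items() if v > 0}

    @classmethod
    def from_counts(cls, values) -> "AbundanceVector":
        return cls({f"c{i}": int(v) for i, v in enumerate(values)})

    @property
    def x(self) -> np.ndarray:
        return np.array(sorted(self.counts.values(), reverse=True), dtype=int)

    @property
    def n(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def s_obs(self) -> int:
        return len(self.counts)

    @property
    def f1(self) -> int:
        return int(np.sum(self.x == 1))

    @property
    def f2(self) -> int:
        return int(np.sum(self.x == 2))


# ---------------------------------------------------------------------------
# Observed and asymptotic Hill numbers
# ---------------------------------------------------------------------------


def hill_observed(a: AbundanceVector, q: int) -> float:
    """Empirical Hill number of order q for the sample itself."""
    if q not in _QS:
        raise ValueError("only q in {0, 1, 2} is supported")
    if a.n < 1:
        raise ValueError("empty assemblage")
    p = a.x / a.n
    if q == 0:
        return float(a.s_obs)
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(1.0 / np.sum(p**2))


def chao1(a: AbundanceVector) -> float:
    """Chao1 lower-bound richness; bias-corrected form when f2 = 0."""
    n, f1, f2 = a.n, a.f1, a.f2
    if f2 > 0:
        return a.s_obs + (n - 1) / n * f1**2 / (2.0 * f2)
    return a.s_obs + (n - 1) / n * f1 * (f1 - 1) / 2.0


def _chao_jost_entropy(a: AbundanceVector) -> float:
    """Asymptotic Shannon entropy (nats) with the unseen-species correction."""
    x, n = a.x, a.n
    # sum_i (x/n) * (psi(n) - psi(x)) written as a harmonic partial sum
    known = sum(xi / n * np.sum(1.0 / np.arange(xi, n)) for xi in x)
    f1, f2 = a.f1, a.f2
    if f1 == 0:
        return float(known)
    if f2 > 0:
        A = 2.0 * f2 / ((n - 1) * f1 + 2.0 * f2)
    elif f1 > 1:
        A = 2.0 / ((n - 1) * (f1 - 1) + 2.0)
    else:
        A = 1.0
    if A >= 1.0:
        return float(known)
    r = np.arange(1, n)
    correction = f1 / n * (1 - A) ** (1 - n) * (-np.log(A) - np.sum((1 - A) ** r / r))
    return float(known + correction)


def hill_asymptotic(a: AbundanceVector, q: int) -> tuple[float, bool]:
    """Asymptotic Hill-number estimate; second value flags unreliability
    (every category a singleton, so the unseen mass is unidentifiable)."""
    if q not in _QS:
        raise ValueError("only q in {0, 1, 2} is supported")
    if a.n < 1:
        raise ValueError("empty assemblage")
    unreliable = a.f1 == a.n
    if q == 0:
        return float(max(chao1(a), a.s_obs)), unreliable
    if q == 1:
        return float(np.exp(_chao_jost_entropy(a))), unreliable
    x, n = a.x, a.n
    denom = np.sum(x * (x - 1)) / (n * (n - 1)) if n > 1 else 0.0
    if denom <= 0:
        return hill_observed(a, 2), True
    return float(1.0 / denom), unreliable


def sample_coverage(a: AbundanceVector) -> float:
    """Estimated coverage C-hat = 1 - (f1/n) * (n-1)f1 / ((n-1)f1 + 2f2)."""
    if a.n < 1:
        raise ValueError("empty assemblage")
    n, f1, f2 = a.n, a.f1, a.f2
    if f1 == 0:
        return 1.0
    denom = (n - 1) * f1 + 2.0 * f2
    ratio = (n - 1) * f1 / denom if denom > 0 else 1.0
    return float(1.0 - (f1 / n) * ratio)


# ---------------------------------------------------------------------------
# Rarefaction / extrapolation
# ---------------------------------------------------------------------------


def _lncomb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefied_richness(a: AbundanceVector, m: int) -> float:
    """Expected number of categories in a random subsample of size m <= n."""
    x, n = a.x, a.n
    if not 1 <= m <= n:
        raise ValueError("m must be in [1, n]")
    keep = x > n - m  # categories certain to appear
    terms = np.zeros(len(x))
    rest = ~keep
    terms[rest] = np.exp(_lncomb(n - x[rest], m) - _lncomb(n, m))
    return float(a.s_obs - terms.sum())


def _rarefied_shannon(a: AbundanceVector, m: int) -> float:
    """Exact E[entropy of a size-m hypergeometric subsample] (nats)."""
    x, n = a.x, a.n
    h = 0.0
    for xi in np.unique(x):
        mult = int(np.sum(x == xi))
        ks = np.arange(max(1, m - (n - xi)), min(xi, m) + 1)
        pmf = hypergeom.pmf(ks, n, xi, m)
        h += mult * float(np.sum(pmf * (-(ks / m) * np.log(ks / m))))
    return h


def _rarefied_simpson(a: AbundanceVector, m: int) -> float:
    """Closed-form Hill q=2 at any size m >= 1 (valid for extrapolation)."""
    x, n = a.x, a.n
    s2 = np.sum(x * (x - 1)) / (n * (n - 1)) if n > 1 else 0.0
    val = 1.0 / m + (1.0 - 1.0 / m) * s2
    return float(1.0 / val)


def coverage_at_size(a: AbundanceVector, m: int) -> float:
    """Expected sample coverage of a subsample (m < n) or extrapolated
    coverage (m > n)."""
    x, n = a.x, a.n
    if m < 1:
        raise ValueError("m must be >= 1")
    if m >= n:
        f1, f2 = a.f1, a.f2
        if f1 == 0:
            return 1.0
        denom = (n - 1) * f1 + 2.0 * f2
        A = (n - 1) * f1 / denom if denom > 0 else 1.0
        return float(1.0 - f1 / n * A ** (m - n + 1))
    sub = x[x <= n - m]
    terms = np.exp(_lncomb(n - sub, m) - _lncomb(n - 1, m)) if len(sub) else np.zeros(0)
    return float(1.0 - np.sum(sub / n * terms))


def diversity_at_size(a: AbundanceVector, q: int, m: int) -> float:
    """Interpolated (m <= n) or extrapolated (m > n) Hill number at size m."""
    if q not in _QS:
        raise ValueError("only q in {0, 1, 2} is supported")
    n = a.n
    if m < 1:
        raise ValueError("m must be >= 1")
    if q == 2:
        return _rarefied_simpson(a, m)
    if m <= n:
        if q == 0:
            return rarefied_richness(a, m)
        return float(np.exp(_rarefied_shannon(a, m)))
    if q == 0:
        s_asy, _ = hill_asymptotic(a, 0)
        f0 = s_asy - a.s_obs
        f1 = a.f1
        if f0 <= 0 or f1 == 0:
            return float(a.s_obs)
        return float(a.s_obs + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** (m - n)))
    # q == 1: blend observed and asymptotic entropy by sample fractions
    h_obs = np.log(hill_observed(a, 1))
    h_asy = np.log(hill_asymptotic(a, 1)[0])
    h_asy = max(h_asy, h_obs)
    w = n / m
    return float(np.exp(w * h_obs + (1.0 - w) * h_asy))


def _bootstrap_assemblage(a: AbundanceVector) -> np.ndarray:
    """Chao-style bootstrap community: adjusted probabilities for observed
    categories plus equal shares of the unseen mass over f0-hat categories."""
    x, n = a.x, a.n
    c_hat = sample_coverage(a)
    p = x / n
    lam_den = np.sum(p * (1 - p) ** n)
    lam = (1.0 - c_hat) / lam_den if lam_den > 0 else 0.0
    p_adj = p * (1.0 - lam * (1 - p) ** n)
    s_asy, _ = hill_asymptotic(a, 0)
    f0 = max(int(round(s_asy - a.s_obs)), 0)
    if f0 > 0 and c_hat < 1.0:
        unseen = np.full(f0, (1.0 - c_hat) / f0)
        return np.concatenate([p_adj, unseen])
    return p_adj


def coverage_re_curves(
    a: AbundanceVector,
    q_set=(0, 1, 2),
    extrapolate_to: int | None = None,
    ci_level: float = 0.84,
    n_boot: int = 200,
    seed: int = 0,
    n_grid: int = 30,
) -> dict:
    """Coverage-based rarefaction/extrapolation curves with bootstrap CIs.

    Returns {q: record-array-like dict with m, coverage, diversity, lo, hi}.
    ``extrapolate_to`` defaults to 2n.  CIs default to the 84% level, under
    which non-overlap approximates a 5% pairwise test.
    """
    if a.n < 2:
        raise ValueError("need n >= 2")
    m_max = extrapolate_to or 2 * a.n
    grid = np.unique(np.clip(np.round(np.linspace(1, m_max, n_grid)).astype(int), 1, None))
    if a.n not in grid:
        grid = np.sort(np.append(grid, a.n))
    rng = np.random.default_rng(seed)
    probs = _bootstrap_assemblage(a)
    boot_samples = []
    for _ in range(n_boot):
        counts = rng.multinomial(a.n, probs)
        boot_samples.append(AbundanceVector.from_counts(counts[counts > 0]))
    z = (1.0 - ci_level) / 2.0
    out = {}
    for q in q_set:
        div = np.array([diversity_at_size(a, q, int(m)) for m in grid])
        cov = np.array([coverage_at_size(a, int(m)) for m in grid])
        boot = np.array(
            [[diversity_at_size(b, q, int(m)) for m in grid] for b in boot_samples]
        )
        se = boot.std(axis=0, ddof=1)
        zq = float(abs(np.round(_norm_ppf(z), 6)))
        out[q] = {
            "m": grid,
            "coverage": cov,
            "diversity": div,
            "lo": div - zq * se,
            "hi": div + zq * se,
        }
    return out


def _norm_ppf(p: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(p))


def diversity_at_coverage(a: AbundanceVector, q: int, target_coverage: float, m_max: int | None = None) -> float:
    """Hill number at a target coverage, by inverting the coverage-size map.

    Searches integer sizes up to ``m_max`` (default 4n) for the smallest m
    whose expected coverage reaches the target, then evaluates diversity
    there; errors if the target exceeds the attainable coverage.
    """
    m_max = m_max or 4 * a.n
    lo, hi = 1, m_max
    if coverage_at_size(a, m_max) < target_coverage:
        raise ValueError(
            f"target coverage {target_coverage} above extrapolated maximum "
            f"{coverage_at_size(a, m_max):.4f}"
        )
    while lo < hi:
        mid = (lo + hi) // 2
        if coverage_at_size(a, mid) >= target_coverage:
            hi = mid
        else:
            lo = mid + 1
    return diversity_at_size(a, q, lo)


# ---------------------------------------------------------------------------
# Brute-force oracles (tiny n) — kept simple and independent of the formulas
# ---------------------------------------------------------------------------


def rarefied_richness_bruteforce(a: AbundanceVector, m: int) -> float:
    """Average category count over every size-m subsample (n <= ~12)."""
    individuals = [cat for cat, cnt in sorted(a.counts.items()) for _ in range(cnt)]
    vals = [len(set(sub)) for sub in combinations(individuals, m)]
    return float(np.mean(vals))


def rarefied_shannon_bruteforce(a: AbundanceVector, m: int) -> float:
    """Average exp(entropy) over every size-m subsample (n <= ~12)."""
    individuals = [cat for cat, cnt in sorted(a.counts.items()) for _ in range(cnt)]
    hs = []
    for sub in combinations(individuals, m):
        _, counts = np.unique(np.array(sub), return_counts=True)
        p = counts / m
        hs.append(-np.sum(p * np.log(p)))
    return float(np.exp(np.mean(hs)))


# ---------------------------------------------------------------------------
# Similarity indices
# ---------------------------------------------------------------------------


def _aligned_props(a: AbundanceVector, b: AbundanceVector) -> tuple[np.ndarray, np.ndarray]:
    cats = sorted(set(a.counts) | set(b.counts))
    p = np.array([a.counts.get(c, 0) for c in cats], float)
    q = np.array([b.counts.get(c, 0) for c in cats], float)
    return p / p.sum(), q / q.sum()


def horn_morisita(a: AbundanceVector, b: AbundanceVector) -> dict:
    """Horn and Morisita-Horn similarity between two assemblages, in [0, 1].

    Horn: 1 - (H(mean of p, q) - mean of H(p), H(q)) / ln 2, the normalized
    entropy gain of pooling with equal weights.  Morisita-Horn:
    2 sum(p q) / (sum p^2 + sum q^2).
    """
    if a.n == 0 or b.n == 0:
        raise ValueError("empty assemblage")
    p, q = _aligned_props(a, b)

    def H(v):
        v = v[v > 0]
        return -np.sum(v * np.log(v))

    pooled = (p + q) / 2.0
    horn = 1.0 - (H(pooled) - (H(p) + H(q)) / 2.0) / math.log(2.0)
    mh_den = np.sum(p**2) + np.sum(q**2)
    mh = 2.0 * np.sum(p * q) / mh_den if mh_den > 0 else 0.0
    return {"horn": float(np.clip(horn, 0.0, 1.0)), "morisita_horn": float(mh)}


# ---------------------------------------------------------------------------
# Ecotype-specificity permutation test
# ---------------------------------------------------------------------------


def ecotype_specificity_test(
    category_counts: dict[str, dict[str, int]],
    n_perm: int = 1000,
    seed: int = 0,
    rule: str = "distance_from_mean",
) -> dict:
    """Test whether ecotype-specific categories exceed chance expectation.

    ``category_counts`` maps category_id -> {ecotype: whistle count}.  The
    observed statistic is the fraction of categories containing whistles of
    only one ecotype.  The null permutes whistle ecotype labels while
    preserving category sizes and per-ecotype totals; the two-tailed p is the
    fraction of permuted proportions at least as far from the permuted mean
    as the observed (with the +1 correction).  ``rule='quantile'`` instead
    doubles the one-sided tail probability.
    """
    ecotypes = sorted({e for v in category_counts.values() for e in v if v[e] > 0})
    if len(ecotypes) < 2:
        raise ValueError("need whistles of both ecotypes")
    if len(category_counts) < 2:
        raise ValueError("need >= 2 categories")
    sizes = np.array([sum(v.values()) for v in category_counts.values()])
    labels = np.concatenate(
        [
            np.repeat(ecotypes.index(e), v.get(e, 0))
            for v in category_counts.values()
            for e in ecotypes
        ]
    )

    def specific_fraction(lab: np.ndarray) -> float:
        start = 0
        spec = 0
        for s in sizes:
            seg = lab[start : start + s]
            if np.all(seg == seg[0]):
                spec += 1
            start += s
        return spec / len(sizes)

    observed = specific_fraction(labels)
    rng = np.random.default_rng(seed)
    perm = np.array([specific_fraction(rng.permutation(labels)) for _ in range(n_perm)])
    mean_perm = float(perm.mean())
    if rule == "distance_from_mean":
        count = int(np.sum(np.abs(perm - mean_perm) >= abs(observed - mean_perm)))
        p = (count + 1) / (n_perm + 1)
    elif rule == "quantile":
        upper = (int(np.sum(perm >= observed)) + 1) / (n_perm + 1)
        lower = (int(np.sum(perm <= observed)) + 1) / (n_perm + 1)
        p = min(1.0, 2.0 * min(upper, lower))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return {"observed": float(observed), "permuted_mean": mean_perm, "p_value": float(p)}
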