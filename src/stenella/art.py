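"""Unsupervised categorization of whistle contours (ARTwarp-style ART2).

Contours are presented sequentially to an adaptive-resonance network.  Each
input is compared by dynamic time warping to every category's *reference
contour* (the evolving average of its members); if the best similarity
reaches the vigilance threshold the whistle joins that category and the
reference is updated by a warped running average, otherwise the whistle
founds a new category.  Full passes over the data repeat until no whistle
changes category.  The default vigilance of 96% follows the level shown to
recover bottlenose dolphin signature whistle categories.

Similarity between two frequency traces is 100 * (1 - mean local ratio
difference |fa - fb| / max(fa, fb)) along the optimal warping path, so
identical traces score 100 and a trace doubled in frequency scores 50.

Category reference contours are classified into the six-class contour
taxonomy (ascending/upsweep, descending/downsweep, convex, concave, sine,
constant) by counting significant direction reversals of the smoothed trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .contours import WhistleContour

SHAPE_CLASSES = ("ascending", "descending", "convex", "concave", "sine", "constant")


@dataclass(frozen=True)
class ArtConfig:
    """ART2 categorization settings.

    vigilance : percent similarity required to join an existing category.
    learning_rate : None for the 1/(category size) running mean, or a fixed
        fraction applied at every reference update.
    resample_ms : common time grid for the DTW comparisons.
    seed : governs the (single, fixed) presentation order.
    """

    vigilance: float = 96.0
    learning_rate: float | None = None
    max_iterations: int = 50
    resample_ms: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.vigilance < 100:
            raise ValueError("vigilance must be in (0, 100)")
        if self.learning_rate is not None and not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")


@dataclass
class Category:
    category_id: int
    reference: np.ndarray  # kHz, uniform grid
    member_ids: list[str] = field(default_factory=list)


@dataclass
class Repertoire:
    """Result of a categorization run: the category table and assignment."""

    categories: list[Category]
    assignment: dict[str, int]
    converged: bool
    n_iterations: int
    config: ArtConfig

    def category_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {c.category_id: 0 for c in self.categories}
        for cid in self.assignment.values():
            sizes[cid] += 1
        return sizes

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"whistle_id": list(self.assignment), "category_id": list(self.assignment.values())}
        )


# ---------------------------------------------------------------------------
# DTW similarity on frequency traces
# ---------------------------------------------------------------------------


@njit(cache=True)
def _accumulate(local: np.ndarray):
    """DP over steps {(1,0),(0,1),(1,1)}; ties in cost go to shorter paths."""
    n, m = local.shape
    cost = np.empty((n, m))
    steps = np.empty((n, m))
    big = 1e300
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                cost[i, j] = local[0, 0]
                steps[i, j] = 1.0
                continue
            bc, bs = big, big
            if i > 0 and j > 0 and (
                cost[i - 1, j - 1] < bc or (cost[i - 1, j - 1] == bc and steps[i - 1, j - 1] < bs)
            ):
                bc, bs = cost[i - 1, j - 1], steps[i - 1, j - 1]
            if i > 0 and (cost[i - 1, j] < bc or (cost[i - 1, j] == bc and steps[i - 1, j] < bs)):
                bc, bs = cost[i - 1, j], steps[i - 1, j]
            if j > 0 and (cost[i, j - 1] < bc or (cost[i, j - 1] == bc and steps[i, j - 1] < bs)):
                bc, bs = cost[i, j - 1], steps[i, j - 1]
            cost[i, j] = bc + local[i, j]
            steps[i, j] = bs + 1.0
    return cost, steps


def _warp_path(cost: np.ndarray, steps: np.ndarray) -> list[tuple[int, int]]:
    i, j = cost.shape[0] - 1, cost.shape[1] - 1
    path = [(i, j)]
    while i > 0 or j > 0:
        cands = []
        if i > 0 and j > 0:
            cands.append((cost[i - 1, j - 1], steps[i - 1, j - 1], i - 1, j - 1))
        if i > 0:
            cands.append((cost[i - 1, j], steps[i - 1, j], i - 1, j))
        if j > 0:
            cands.append((cost[i, j - 1], steps[i, j - 1], i, j - 1))
        _, _, i, j = min(cands, key=lambda c: (c[0], c[1]))
        path.append((i, j))
    path.reverse()
    return path


def _ratio_local(fa: np.ndarray, fb: np.ndarray) -> np.ndarray:
    return np.abs(fa[:, None] - fb[None, :]) / np.maximum(fa[:, None], fb[None, :])


def similarity_arrays(fa: np.ndarray, fb: np.ndarray) -> tuple[float, list[tuple[int, int]]]:
    """Similarity percent and optimal warping path for two traces (kHz)."""
    if len(fa) == 0 or len(fb) == 0:
        raise ValueError("empty contour")
    local = _ratio_local(np.asarray(fa, float), np.asarray(fb, float))
    cost, steps = _accumulate(local)
    sim = 100.0 * (1.0 - cost[-1, -1] / steps[-1, -1])
    return float(sim), _warp_path(cost, steps)


def art_similarity(a: WhistleContour, b: WhistleContour, resample_ms: float = 10.0) -> float:
    """DTW contour similarity in [0, 100]; 100 iff the traces are identical."""
    fa = a.resampled(resample_ms).freqs / 1000.0
    fb = b.resampled(resample_ms).freqs / 1000.0
    return similarity_arrays(fa, fb)[0]


def _warp_onto(reference: np.ndarray, member: np.ndarray, path: list[tuple[int, int]]) -> np.ndarray:
    """Average the member's frequencies aligned to each reference index."""
    sums = np.zeros(len(reference))
    counts = np.zeros(len(reference))
    for i, j in path:
        sums[i] += member[j]
        counts[i] += 1
    counts[counts == 0] = 1.0
    return sums / counts


# ---------------------------------------------------------------------------
# Categorization
# ---------------------------------------------------------------------------


def categorize(contours: list[WhistleContour], cfg: ArtConfig = ArtConfig()) -> Repertoire:
    """ART2 categorization of a whistle set at the configured vigilance.

    Whistles are presented in a seed-determined random order, the same in
    every pass; passes repeat until an entire pass produces no reassignment
    (or ``max_iterations`` is reached, in which case the repertoire is
    returned with ``converged=False`` and a warning).
    """
    if not contours:
        raise ValueError("need at least one contour")
    traces = {c.whistle_id: c.resampled(cfg.resample_ms).freqs / 1000.0 for c in contours}
    order = list(np.random.default_rng(cfg.seed).permutation(len(contours)))
    ids = [contours[i].whistle_id for i in order]

    categories: list[Category] = []
    assignment: dict[str, int] = {}
    next_id = 0
    converged = False
    n_iter = 0
    for n_iter in range(1, cfg.max_iterations + 1):
        changed = 0
        for wid in ids:
            trace = traces[wid]
            best_sim, best_cat, best_path = -1.0, None, None
            for cat in categories:
                sim, path = similarity_arrays(cat.reference, trace)
                if sim > best_sim:
                    best_sim, best_cat, best_path = sim, cat, path
            old = assignment.get(wid)
            if best_cat is not None and best_sim >= cfg.vigilance:
                if old != best_cat.category_id:
                    changed += 1
                    if old is not None:
                        prev = next(c for c in categories if c.category_id == old)
                        prev.member_ids.remove(wid)
                    best_cat.member_ids.append(wid)
                    assignment[wid] = best_cat.category_id
                lr = cfg.learning_rate or 1.0 / len(best_cat.member_ids)
                warped = _warp_onto(best_cat.reference, trace, best_path)
                best_cat.reference = (1.0 - lr) * best_cat.reference + lr * warped
            else:
                if old is not None:
                    prev = next(c for c in categories if c.category_id == old)
                    prev.member_ids.remove(wid)
                cat = Category(next_id, trace.copy(), [wid])
                assignment[wid] = next_id
                next_id += 1
                categories.append(cat)
                changed += 1
        categories = [c for c in categories if c.member_ids]
        if changed == 0:
            converged = True
            break
    if not converged:
        warnings.warn(f"ART categorization did not converge in {cfg.max_iterations} passes")
    return Repertoire(categories, assignment, converged, n_iter, cfg)


# ---------------------------------------------------------------------------
# Shape taxonomy
# ---------------------------------------------------------------------------


def _significant_reversals(f: np.ndarray, min_excursion: float) -> tuple[int, int]:
    """Count direction reversals with hysteresis ``min_excursion`` (kHz).

    Returns (number of reversals, initial direction sign).
    """
    direction = 0
    first_direction = 0
    reversals = 0
    anchor = f[0]
    for x in f[1:]:
        if direction == 0:
            if x - anchor >= min_excursion:
                direction = first_direction = 1
                anchor = x
            elif anchor - x >= min_excursion:
                direction = first_direction = -1
                anchor = x
        elif direction == 1:
            if x > anchor:
                anchor = x
            elif anchor - x >= min_excursion:
                reversals += 1
                direction = -1
                anchor = x
        else:
            if x < anchor:
                anchor = x
            elif x - anchor >= min_excursion:
                reversals += 1
                direction = 1
                anchor = x
    return reversals, first_direction


def classify_shape(
    contour: WhistleContour | np.ndarray,
    flat_band: float = 1.0,
    min_excursion: float = 0.5,
) -> str:
    """Assign a contour (or reference trace in kHz) to one of six classes.

    constant: total excursion <= ``flat_band`` kHz.  Otherwise the trace is
    smoothed (moving average over 10% of its length) and significant
    direction reversals (>= ``min_excursion`` kHz) are counted: none ->
    ascending or descending by net slope; one -> convex (up-then-down) or
    concave (down-then-up); two or more -> sine.
    """
    if isinstance(contour, WhistleContour):
        f = contour.freqs / 1000.0
    else:
        f = np.asarray(contour, float)
    if f.max() - f.min() <= flat_band:
        return "constant"
    win = max(1, int(round(0.1 * len(f))))
    kernel = np.ones(win) / win
    smooth = np.convolve(f, kernel, mode="valid") if win > 1 else f
    reversals, first_dir = _significant_reversals(smooth, min_excursion)
    if reversals >= 2:
        return "sine"
    if reversals == 1:
        return "convex" if first_dir > 0 else "concave"
    net = smooth[-1] - smooth[0]
    return "ascending" if net >= 0 else "descending"


# ---------------------------------------------------------------------------
# Repertoire composition
# ---------------------------------------------------------------------------


def repertoire_composition(rep: Repertoire, labels: dict[str, str]) -> dict:
    """Per-ecotype shape-class abundances and the category sharing table.

    A category is *shared* iff it contains at least one whistle of each
    ecotype; abundances count whistles by the shape class of their
    category's reference contour.
    """
    missing = [w for w in rep.assignment if w not in labels]
    if missing:
        raise ValueError(f"whistles without ecotype label: {missing[:3]}")
    ecotypes = sorted(set(labels[w] for w in rep.assignment))
    shapes = {c.category_id: classify_shape(c.reference) for c in rep.categories}
    abundance = {e: {s: 0 for s in SHAPE_CLASSES} for e in ecotypes}
    cat_ecos: dict[int, set] = {c.category_id: set() for c in rep.categories}
    for wid, cid in rep.assignment.items():
        e = labels[wid]
        abundance[e][shapes[cid]] += 1
        cat_ecos[cid].add(e)
    sharing: dict[str, int] = {f"unique_{e}": 0 for e in ecotypes}
    sharing["shared"] = 0
    for cid, ecos in cat_ecos.items():
        if len(ecos) > 1:
            sharing["shared"] += 1
        else:
            sharing[f"unique_{next(iter(ecos))}"] += 1
    return {
        "n_categories": len(rep.categories),
        "category_shapes": shapes,
        "abundance_by_shape": abundance,
        "sharing": sharing,
    }
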