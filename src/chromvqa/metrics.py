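"""Evaluation machinery for sampled conformation ensembles.

Groups of related measures:

* **Distributional fidelity against the enumeration oracle** — coverage and
  empirical probability of the top likelihood quantile, empirical Shannon
  entropy, and the likelihood ratio of the learned distribution over the
  uniform distribution partitioned by excitation (energy) level.
* **Contact recovery** — AUC / average precision of inferred contact
  probabilities against the binary target, plus mean/max inferred
  probability over the positive pairs, and two Dice–Sørensen variants.
* **Consensus structure quality** — scale-invariant RMSD and Spearman rank
  correlation between model and target distance matrices.
* **Ensemble-vs-ensemble comparison** — Jensen–Shannon divergence between
  empirical distributions (at the level of discrete contact sets, with a
  pluggable state-key hook for embedding-based variants) and paired F1
  scores under an optimal one-to-one assignment.
* **Landscape ruggedness** — empirical maximum information content (H_M) of
  the objective over parameter space, from symbolised cost differences along
  random walks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import jensenshannon
from scipy.stats import spearmanr
from sklearn.metrics import average_precision_score, roc_auc_score

from . import lattice
from .engine import EnsembleSample
from .likelihood import ContactMap
from .oracle import likelihood_quantile

__all__ = [
    "MetricsReport",
    "coverage_and_empirical_probability",
    "empirical_entropy",
    "likelihood_ratio_by_level",
    "contact_recovery_scores",
    "dsi",
    "consensus_scores",
    "ensemble_js_divergence",
    "paired_f1",
    "landscape_mic",
]

logger = logging.getLogger(__name__)


@dataclass
class MetricsReport:
    """Named scalar results plus the settings they were computed under."""

    values: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def add(self, name: str, value: float) -> None:
        value = float(value)
        if not np.isfinite(value):
            raise ValueError(f"metric {name!r} is not finite: {value}")
        self.values[name] = value


def coverage_and_empirical_probability(
    ens: EnsembleSample, phi: np.ndarray, q: float
) -> tuple[float, float]:
    """Coverage of, and empirical shot probability at/above, the upper-``q``
    likelihood quantile of the enumerated universe.

    Coverage counts *distinct* sampled states inside the top set over the
    top-set size; empirical probability is the shot-weighted fraction of
    measurements landing at or above the threshold.
    """
    phi = np.asarray(phi, dtype=float)
    threshold = likelihood_quantile(phi, q)
    top = np.flatnonzero(phi >= threshold)
    if top.size == 0:
        raise ValueError("top quantile set is empty")
    top_set = set(top.tolist())
    idx, cnt = ens.arrays()
    inside = np.array([int(k) in top_set for k in idx])
    coverage = float(inside.sum()) / top.size
    empirical = float(cnt[inside].sum()) / cnt.sum()
    return coverage, empirical


def empirical_entropy(ens: EnsembleSample) -> float:
    """Base-2 Shannon entropy of the empirical state distribution, bits."""
    _, cnt = ens.arrays()
    total = cnt.sum()
    if total <= 0:
        raise ValueError("ensemble is empty")
    p = cnt / total
    return float(-(p * np.log2(p)).sum())


def likelihood_ratio_by_level(
    ens: EnsembleSample, phi: np.ndarray, bins: int = 20
) -> np.ndarray:
    """Likelihood ratio (learned over uniform) per excitation-level bin.

    States are ranked by phi and split into ``bins`` equal-occupancy bins;
    bin 0 holds the lowest-energy (highest-phi) states.  The ratio in a bin
    is the empirical shot mass there divided by the uniform state mass
    (ratios average to 1 under uniform bin-occupancy weighting).
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    phi = np.asarray(phi, dtype=float)
    size = phi.size
    order = np.argsort(-phi, kind="stable")  # descending phi = ascending energy
    bin_of_rank = (np.arange(size) * bins) // size
    bin_of_state = np.empty(size, dtype=int)
    bin_of_state[order] = bin_of_rank
    idx, cnt = ens.arrays()
    shot_mass = np.zeros(bins)
    np.add.at(shot_mass, bin_of_state[idx], cnt)
    shot_mass /= cnt.sum()
    uniform_mass = np.bincount(bin_of_state, minlength=bins) / size
    return shot_mass / uniform_mass


def _eligible(pc: ContactMap, inferred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    iu, ju = pc.scored_pairs()
    return pc.entries[iu, ju].astype(int), np.asarray(inferred, dtype=float)[iu, ju]


def contact_recovery_scores(pc: ContactMap, inferred: np.ndarray) -> dict[str, float]:
    """AUC / average precision of the inferred probabilities against the
    binary target, over pairs at separation >= 2, plus the mean and max
    inferred probability over the positive pairs.

    With single-class labels AUC is undefined and reported as ``nan``
    (average precision is still returned).
    """
    y, s = _eligible(pc, inferred)
    if y.size == 0:
        raise ValueError("no eligible pairs")
    out: dict[str, float] = {}
    if y.min() == y.max():
        out["auc"] = float("nan")
        logger.warning("single-class contact labels; AUC undefined")
    else:
        out["auc"] = float(roc_auc_score(y, s))
    out["ap"] = float(average_precision_score(y, s)) if y.any() else float("nan")
    pos = s[y == 1]
    out["mean_pos"] = float(pos.mean()) if pos.size else float("nan")
    out["max_pos"] = float(pos.max()) if pos.size else float("nan")
    return out


def dsi(pc: ContactMap, inferred: np.ndarray) -> dict[str, float]:
    """Weighted and maximum-threshold Dice–Sørensen indices.

    DSI_w = 2 sum(pi * pi~) / sum(pi + pi~);  DSI_m maximises the Dice
    between the target and the thresholded indicator ``pi~ > t`` over
    ``t in {0} ∪ {distinct pi~ values}`` (including t = 0 keeps the
    all-included candidate reachable when pi~ is constant).
    """
    y, s = _eligible(pc, inferred)
    denom_w = y.sum() + s.sum()
    if denom_w == 0:
        logger.info("target and inferred contacts both empty; DSI defined as 1")
        return {"dsi_w": 1.0, "dsi_m": 1.0}
    dsi_w = 2.0 * float(y @ s) / float(denom_w)
    best = 0.0
    for t in np.concatenate(([0.0], np.unique(s))):
        ind = (s > t).astype(int)
        denom = y.sum() + ind.sum()
        dice = 2.0 * float(y @ ind) / denom if denom > 0 else 1.0
        best = max(best, dice)
    return {"dsi_w": dsi_w, "dsi_m": best}


def consensus_scores(
    d: "lattice.SquaredDistances | np.ndarray", target_d: np.ndarray
) -> dict[str, float]:
    """Scale-invariant RMSD and Spearman rank correlation between a model
    distance matrix and a target distance matrix.

    The RMSD minimises over a positive scalar rescaling of the model
    distances; the optimum is the least-squares projection
    ``s* = sum(D Dt) / sum(D^2)`` over the upper triangle.
    """
    d2 = d.d2 if isinstance(d, lattice.SquaredDistances) else np.asarray(d, dtype=float)
    dist = np.sqrt(d2)
    target_d = np.asarray(target_d, dtype=float)
    if dist.shape != target_d.shape:
        raise ValueError("distance matrices must share a shape")
    iu, ju = np.triu_indices(dist.shape[0], k=1)
    x = dist[iu, ju]
    t = target_d[iu, ju]
    if np.all(x == 0):
        raise ValueError("model distances are all zero")
    s_star = float(x @ t) / float(x @ x)
    rmsd = float(np.sqrt(np.mean((s_star * x - t) ** 2)))
    rho = spearmanr(x, t).statistic
    return {"rmsd": rmsd, "spearman": float(rho), "scale": s_star}


def _contact_key(ens: EnsembleSample) -> dict:
    """Map states to their contact sets, merging counts."""
    idx, cnt = ens.arrays()
    coords = lattice.decode_many(ens.N, idx)
    out: dict[frozenset, int] = {}
    for k, c in zip(range(len(idx)), cnt):
        conf = lattice.Conformation(ens.N, coords[k])
        key = lattice.contact_set(conf)
        out[key] = out.get(key, 0) + int(c)
    return out


def ensemble_js_divergence(
    a: EnsembleSample,
    b: EnsembleSample,
    state_key: Callable[[EnsembleSample], dict] | None = None,
) -> float:
    """Jensen–Shannon divergence (base 2, in [0, 1]) between two empirical
    ensemble distributions.

    By default states are first mapped to their discrete contact sets, so
    conformations with identical contacts merge; pass ``state_key`` to
    substitute an embedding-based grouping.
    """
    if a.N != b.N:
        raise ValueError(f"bead counts differ: {a.N} vs {b.N}")
    keyfn = state_key or _contact_key
    da, db = keyfn(a), keyfn(b)
    support = sorted(set(da) | set(db), key=repr)
    p = np.array([da.get(k, 0) for k in support], dtype=float)
    q = np.array([db.get(k, 0) for k in support], dtype=float)
    # scipy returns the JS *distance* (sqrt of the divergence)
    return float(jensenshannon(p, q, base=2) ** 2)


def _binary_upper(m) -> np.ndarray:
    arr = m.entries if isinstance(m, ContactMap) else np.asarray(m)
    iu, ju = np.triu_indices(arr.shape[0], k=1)
    return (arr[iu, ju] > 0).astype(int)


def _f1(a: np.ndarray, b: np.ndarray) -> float:
    tp = int(a @ b)
    denom = 2 * tp + int((a & ~b).sum()) + int((~a.astype(bool) & b.astype(bool)).sum())
    return 2.0 * tp / denom if denom > 0 else 1.0


def paired_f1(
    a: Sequence,
    b: Sequence,
    thresholds: Sequence[float] | None = None,
) -> dict:
    """Optimal one-to-one pairing of two sets of binary contact matrices by
    F1 score (rectangular linear sum assignment, maximising total F1).

    Duplicates are removed from the first set before matching.  Returns the
    matched scores and, for each threshold on the grid, the fraction of
    matched pairs at or above it.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both matrix sets must be nonempty")
    va = []
    seen = set()
    for m in a:
        v = _binary_upper(m)
        key = v.tobytes()
        if key not in seen:
            seen.add(key)
            va.append(v)
    vb = [_binary_upper(m) for m in b]
    f1 = np.array([[_f1(x, y) for y in vb] for x in va])
    rows, cols = linear_sum_assignment(f1, maximize=True)
    scores = f1[rows, cols]
    grid = np.asarray(
        thresholds if thresholds is not None else np.round(np.arange(0.0, 1.0, 0.1), 1)
    )
    frac = {float(t): float(np.mean(scores >= t)) for t in grid}
    return {"scores": scores, "pairs": list(zip(rows.tolist(), cols.tolist())), "fraction_at_or_above": frac}


def landscape_mic(
    objective: Callable[[np.ndarray], float],
    p: int,
    seed: int | np.random.Generator | None = None,
    *,
    samples_per_param: int = 128,
    num_walks: int = 64,
    walk_len_per_param: int = 64,
    step: float = np.pi / 20.0,
    eps_grid_size: int = 40,
) -> float:
    """Empirical maximum information content H_M of a cost landscape.

    ``128 p`` uniform samples over ``[0, 2pi)^p`` set the cost normalisation;
    ``64`` random walks of ``64 p`` steps each (uniform per-coordinate
    perturbations of half-width ``step``) produce cost sequences whose
    consecutive differences are symbolised as {-1, 0, +1} against a
    sensitivity ``eps``.  The information content at ``eps`` is the entropy
    (base 6) of consecutive *unequal* symbol pairs; H_M is the maximum over
    an ``eps`` grid spanning the observed difference magnitudes, averaged
    over walks.  Higher H_M means a more rugged landscape.
    """
    if p < 1:
        raise ValueError("parameter count must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_samples = samples_per_param * p
    samples = np.array(
        [objective(rng.uniform(0.0, 2.0 * np.pi, size=p)) for _ in range(n_samples)]
    )
    lo, hi = samples.min(), samples.max()
    scale = hi - lo if hi > lo else 1.0

    walk_len = walk_len_per_param * p
    diffs = []
    for _ in range(num_walks):
        theta = rng.uniform(0.0, 2.0 * np.pi, size=p)
        costs = np.empty(walk_len + 1)
        costs[0] = objective(theta)
        for t in range(walk_len):
            theta = theta + rng.uniform(-step, step, size=p)
            costs[t + 1] = objective(theta)
        # round away last-ulp jitter so exactly-equal costs symbolise as ties
        diffs.append(np.round(np.diff((costs - lo) / scale), 12))

    mags = np.abs(np.concatenate(diffs))
    pos = mags[mags > 0]
    if pos.size == 0:
        return 0.0
    eps_grid = np.concatenate(
        ([0.0], np.geomspace(pos.min(), mags.max(), eps_grid_size))
    )

    best = 0.0
    for eps in eps_grid:
        h_walks = []
        for d in diffs:
            sym = np.zeros(len(d), dtype=int)
            sym[d > eps] = 1
            sym[d < -eps] = -1
            pairs = sym[:-1] * 4 + sym[1:]  # unique code per ordered pair
            a, b = sym[:-1], sym[1:]
            unequal = a != b
            total = len(pairs)
            if total == 0 or not unequal.any():
                h_walks.append(0.0)
                continue
            codes, counts = np.unique(pairs[unequal], return_counts=True)
            prob = counts / total
            h_walks.append(float(-(prob * (np.log(prob) / np.log(6.0))).sum()))
        best = max(best, float(np.mean(h_walks)))
    return best
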