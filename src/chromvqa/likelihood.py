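"""Probabilistic model scoring conformations against a binary contact map.

The likelihood of a conformation's squared-distance matrix ``D2`` given a
binary contact map ``pi_c`` factorises over bead pairs with sequence
separation >= 2.  A pair in contact contributes an *attractive* propensity

    f_plus = (1 - |D2 - r^2| / (sep^2 - r^2)) ** (sep^2 / D2),

peaked at ``D2 = r^2``; the exponent steeply penalises near-clashes.  A pair
not in contact contributes a *neutral* logistic propensity

    f_minus = 1 - 1 / (1 + exp(4 (D2 - r^2))),

roughly flat except for distances at or below the contact radius.  The
training objective over an ensemble of sampled structures interpolates, via
``alpha in [0, 1]``, between the mean per-structure log-likelihood (alpha=0,
the single-cell / consensus regime) and the log-likelihood of the ensemble's
mean squared-distance matrix (alpha=1, the bulk / population regime).

All evaluation is done in log space with the propensity base clamped to
``[base_floor, 1]`` and ``D2`` floored in the exponent, so clashing
conformations receive a large-but-finite penalty instead of an undefined
value; the normalising constant of the likelihood is dropped throughout, so
values are comparable only within a fixed ``(N, pi_c, r)``.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .lattice import DEFAULT_RADIUS, SquaredDistances

__all__ = [
    "ContactMap",
    "ModelConfig",
    "attractive_propensity",
    "neutral_propensity",
    "structure_log_likelihood",
    "aggregated_objective",
    "read_contact_map",
    "write_contact_map",
]


@dataclass(frozen=True)
class ModelConfig:
    """Model hyper-parameters.

    r
        Contact radius in lattice-step units (default 1.5).
    alpha
        Aggregation weight in [0, 1]; 0 scores each structure individually,
        1 scores the ensemble-mean squared-distance matrix.
    base_floor
        Positive clamp on the attractive-propensity base before the log.
    d2_floor
        Positive floor on D2 in the attractive exponent (guards clashes).
    exponent_cap
        Optional cap on the ``sep^2 / D2`` exponent.  The attractive power
        was designed for short polymers (N below ~150) where it doubles as a
        clash penalty; on longer chains a cap keeps the penalty bounded.
        ``None`` (default) leaves the exponent unclipped.
    """

    r: float = DEFAULT_RADIUS
    alpha: float = 0.0
    base_floor: float = 1e-12
    d2_floor: float = 1e-9
    exponent_cap: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if self.r <= 0:
            raise ValueError("contact radius must be positive")
        if self.base_floor <= 0 or self.d2_floor <= 0:
            raise ValueError("floors must be positive")


class ContactMap:
    """Binary symmetric contact matrix with zero diagonal.

    Entries at sequence separation < 2 may be stored but are never scored by
    the objective (the likelihood product runs over ``j >= i + 2``).
    """

    def __init__(self, entries: np.ndarray):
        entries = np.asarray(entries)
        if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
            raise ValueError("contact map must be square")
        if not np.array_equal(entries, entries.T):
            raise ValueError("contact map must be symmetric")
        vals = np.unique(entries)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("contact map entries must be 0 or 1")
        self.entries = entries.astype(np.int8)
        np.fill_diagonal(self.entries, 0)

    @property
    def N(self) -> int:
        return self.entries.shape[0]

    @classmethod
    def from_pairs(cls, N: int, pairs: Sequence[tuple[int, int]]) -> "ContactMap":
        m = np.zeros((N, N), dtype=np.int8)
        for i, j in pairs:
            m[i, j] = m[j, i] = 1
        return cls(m)

    def scored_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle index pair arrays at separation >= 2."""
        return np.triu_indices(self.N, k=2)

    def contact_pairs(self) -> frozenset[tuple[int, int]]:
        """Contacts at separation >= 2 (the scored positives)."""
        iu, ju = self.scored_pairs()
        on = self.entries[iu, ju] == 1
        return frozenset(zip(iu[on].tolist(), ju[on].tolist()))


def _log_f_plus(
    d2: np.ndarray, sep2: np.ndarray, cfg: ModelConfig
) -> np.ndarray:
    """log of the attractive propensity, vectorised and clash-safe."""
    r2 = cfg.r * cfg.r
    denom = sep2 - r2
    if np.any(denom <= 0):
        raise ValueError(
            "sequence separation must exceed the contact radius for an "
            "attractive pair"
        )
    base = 1.0 - np.abs(d2 - r2) / denom
    base = np.clip(base, cfg.base_floor, 1.0)
    exponent = sep2 / np.maximum(d2, cfg.d2_floor)
    if cfg.exponent_cap is not None:
        exponent = np.minimum(exponent, cfg.exponent_cap)
    return exponent * np.log(base)


def _log_f_minus(d2: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    """log of the neutral (logistic) propensity; stable for large |D2-r^2|."""
    x = 4.0 * (d2 - cfg.r * cfg.r)
    # log(1 - 1/(1+e^x)) = log sigmoid(x) = -log1p(e^{-x})
    return -np.logaddexp(0.0, -x)


def attractive_propensity(d2: float, sep: int, cfg: ModelConfig | None = None) -> float:
    """Likelihood factor for a pair in contact; in [0, 1], peaked at D2=r^2."""
    cfg = cfg or ModelConfig()
    if sep <= cfg.r:
        raise ValueError(f"separation {sep} must exceed the radius {cfg.r}")
    return float(np.exp(_log_f_plus(np.asarray(float(d2)), np.asarray(float(sep * sep)), cfg)))


def neutral_propensity(d2: float, cfg: ModelConfig | None = None) -> float:
    """Likelihood factor for a pair not in contact; strictly increasing in D2."""
    cfg = cfg or ModelConfig()
    return float(np.exp(_log_f_minus(np.asarray(float(d2)), cfg)))


def structure_log_likelihood(
    d: SquaredDistances | np.ndarray, pc: ContactMap, cfg: ModelConfig | None = None
) -> float:
    """Log-likelihood of one squared-distance matrix given the contact map.

    Sums ``pi * log f_plus + (1 - pi) * log f_minus`` over pairs with
    separation >= 2; the additive constant is dropped.  Always <= 0 and
    finite (the clamps guarantee this even for clashing conformations).
    """
    cfg = cfg or ModelConfig()
    d2 = d.d2 if isinstance(d, SquaredDistances) else np.asarray(d, dtype=float)
    if d2.shape != pc.entries.shape:
        raise ValueError(f"shape mismatch: distances {d2.shape} vs contacts {pc.entries.shape}")
    iu, ju = pc.scored_pairs()
    if len(iu) == 0:
        return 0.0
    pi = pc.entries[iu, ju].astype(float)
    dv = d2[iu, ju]
    sep2 = ((ju - iu).astype(float)) ** 2
    ll = np.zeros_like(dv)
    pos = pi == 1.0
    if np.any(pos):
        ll[pos] = _log_f_plus(dv[pos], sep2[pos], cfg)
    if np.any(~pos):
        ll[~pos] = _log_f_minus(dv[~pos], cfg)
    return float(ll.sum())


def aggregated_objective(
    d2_stack: np.ndarray,
    counts: np.ndarray,
    pc: ContactMap,
    cfg: ModelConfig | None = None,
    log_likelihoods: np.ndarray | None = None,
) -> float:
    """The training cost over a weighted ensemble of structures (>= 0 up to
    the dropped constant; minimised by the engine).

    cost = -(1 - alpha) * <log L(D2_k)>_k  -  alpha * log L(<D2_k>_k)

    where ``<.>_k`` is the count-weighted mean over sampled structures.  All
    samples enter, clashing conformations included — the likelihood itself
    penalises them.

    Pass ``log_likelihoods`` to reuse per-structure scores already computed
    (the engine caches them across optimiser evaluations).
    """
    cfg = cfg or ModelConfig()
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("ensemble is empty")
    d2_stack = np.asarray(d2_stack, dtype=float)
    if d2_stack.ndim != 3 or len(d2_stack) != len(counts):
        raise ValueError("d2_stack must be (k, N, N) aligned with counts")
    w = counts / total
    cost = 0.0
    if cfg.alpha < 1.0:
        if log_likelihoods is None:
            log_likelihoods = np.array(
                [structure_log_likelihood(m, pc, cfg) for m in d2_stack]
            )
        cost -= (1.0 - cfg.alpha) * float(w @ np.asarray(log_likelihoods, dtype=float))
    if cfg.alpha > 0.0:
        mean_d2 = np.tensordot(w, d2_stack, axes=1)
        cost -= cfg.alpha * structure_log_likelihood(mean_d2, pc, cfg)
    return cost


def read_contact_map(path_or_buf) -> ContactMap:
    """Read a dense 0/1 matrix from tab-delimited text, symmetrising with a
    logical OR of the two triangles (a warning is issued if they differ)."""
    m = np.loadtxt(path_or_buf, dtype=float)
    m = np.atleast_2d(m)
    if not np.array_equal(m, m.T):
        warnings.warn("asymmetric contact matrix; symmetrising with logical OR")
        m = np.logical_or(m > 0, m.T > 0).astype(np.int8)
    return ContactMap(m.astype(np.int8))


def write_contact_map(pc: ContactMap, path_or_buf=sys.stdout) -> None:
    np.savetxt(path_or_buf, pc.entries, fmt="%d", delimiter="\t")
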