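"""Brute-force enumeration of the lattice conformational universe.

For small polymers every spin string can be enumerated: there are
``8^(N-2)`` states.  Enumeration supplies (i) simulated Hi-C targets —
clash-free states are partitioned into groups sharing an identical contact
set, and each group's contact set defines a binary target map — and (ii) the
ground-truth likelihood distribution ``phi`` over all states, against which
sampled ensembles are judged (coverage, quantile and likelihood-ratio
analyses).  It is also the independent verifier for the variational engine:
the statevector expectation of the objective must match the phi-weighted
enumeration exactly.

State index convention: the integer value of the spin bitstring with qubit 0
least significant (bead 2's x axis), bit 1 <-> spin +1.  No symmetry
reduction (e.g. merging mirror images) is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import lattice
from .lattice import CLASH_DISTANCE, DEFAULT_RADIUS, SpinString
from .likelihood import ContactMap, ModelConfig, structure_log_likelihood

__all__ = [
    "StructureUniverse",
    "TargetGroup",
    "enumerate_universe",
    "partition_groups",
    "sample_target",
    "ground_truth_distribution",
    "likelihood_quantile",
]

#: Enumeration guard; 8^8 ~ 1.7e7 states already needs gigabytes.
MAX_N_DEFAULT = 10


@dataclass
class StructureUniverse:
    """All ``8^(N-2)`` spin strings with clash flags and contact sets."""

    N: int
    r: float
    d2: np.ndarray = field(repr=False)  # (M, N, N) squared distances
    clash_free: np.ndarray = field(repr=False)  # (M,) bool
    contacts: list[frozenset[tuple[int, int]]] = field(repr=False)

    @property
    def size(self) -> int:
        return len(self.clash_free)

    def spin_string(self, index: int) -> SpinString:
        return SpinString.from_bits(self.N, index)

    def to_json(self) -> str:
        """Cache bundle: clash flags and contact sets (d2 is recomputed)."""
        return json.dumps(
            {
                "N": self.N,
                "r": self.r,
                "clash_free": self.clash_free.astype(int).tolist(),
                "contacts": [sorted(map(list, c)) for c in self.contacts],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "StructureUniverse":
        """Rebuild from a cache bundle, recomputing the distance stack."""
        rec = json.loads(text)
        u = enumerate_universe(rec["N"], rec["r"])
        cached_flags = np.asarray(rec["clash_free"], dtype=bool)
        if not np.array_equal(u.clash_free, cached_flags):
            raise ValueError("cache bundle inconsistent with enumeration")
        return u


@dataclass(frozen=True)
class TargetGroup:
    """Clash-free states sharing the contact set ``chi``; the group's contact
    map is the simulated Hi-C target."""

    chi: tuple[tuple[int, int], ...]
    members: tuple[int, ...]
    contact_map: ContactMap

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("target group has no members")


def enumerate_universe(
    N: int, r: float = DEFAULT_RADIUS, *, max_n: int = MAX_N_DEFAULT
) -> StructureUniverse:
    """Decode, clash-flag and contact-annotate every spin string.

    ``N`` above the guard (default 10) must be overridden explicitly via
    ``max_n``; at N=10 the universe already holds ~1.7e7 states.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if N > max_n:
        raise ValueError(
            f"N={N} exceeds the enumeration guard {max_n}; pass max_n explicitly"
        )
    size = 8 ** (N - 2)
    bits = np.arange(size, dtype=np.int64)
    coords = lattice.decode_many(N, bits)
    d2 = lattice.squared_distance_matrices(coords)

    iu, ju = np.triu_indices(N, k=1)
    off = d2[:, iu, ju]
    clash_free = np.all(off >= CLASH_DISTANCE * CLASH_DISTANCE, axis=1)

    sep_ok = (ju - iu) > r
    close = off <= r * r
    hit = sep_ok[None, :] & close
    pair_list = list(zip(iu.tolist(), ju.tolist()))
    contacts = [
        frozenset(p for p, h in zip(pair_list, row) if h) for row in hit
    ]
    return StructureUniverse(N=N, r=r, d2=d2, clash_free=clash_free, contacts=contacts)


def partition_groups(u: StructureUniverse) -> dict[tuple[tuple[int, int], ...], TargetGroup]:
    """Partition the clash-free states by their contact set.

    Returns a dict keyed by the sorted tuple of contact pairs; group members
    are disjoint and their union is exactly the clash-free states.
    """
    buckets: dict[tuple[tuple[int, int], ...], list[int]] = {}
    for k in np.flatnonzero(u.clash_free):
        key = tuple(sorted(u.contacts[k]))
        buckets.setdefault(key, []).append(int(k))
    return {
        key: TargetGroup(
            chi=key,
            members=tuple(members),
            contact_map=ContactMap.from_pairs(u.N, key),
        )
        for key, members in buckets.items()
    }


def sample_target(
    u: StructureUniverse, seed: int | np.random.Generator | None = None
) -> TargetGroup:
    """Uniformly select one target group (reproducible under ``seed``)."""
    groups = partition_groups(u)
    keys = sorted(groups.keys())
    rng = np.random.default_rng(seed)
    return groups[keys[rng.integers(len(keys))]]


def ground_truth_distribution(
    u: StructureUniverse, pc: ContactMap, cfg: ModelConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood ``phi[k] = exp(log L(state k))`` over the whole universe.

    Returns ``(phi, phi_normalised)`` with the second summing to 1.  Higher
    phi corresponds to a lower excitation (energy) level.
    """
    cfg = cfg or ModelConfig()
    ll = np.array([structure_log_likelihood(m, pc, cfg) for m in u.d2])
    phi = np.exp(ll)
    return phi, phi / phi.sum()


def universe_log_likelihoods(
    u: StructureUniverse, pc: ContactMap, cfg: ModelConfig | None = None
) -> np.ndarray:
    """Per-state log-likelihood vector (the log of ``phi``)."""
    cfg = cfg or ModelConfig()
    return np.array([structure_log_likelihood(m, pc, cfg) for m in u.d2])


def likelihood_quantile(phi: np.ndarray, q: float) -> float:
    """Empirical upper-``q`` quantile threshold of the phi values.

    Linear-interpolation quantile over the multiset; states with
    ``phi >= Q(phi, q)`` form the "top" set (ties included).
    """
    phi = np.asarray(phi, dtype=float)
    if phi.size == 0:
        raise ValueError("phi is empty")
    if not 0.0 <= q < 1.0:
        raise ValueError(f"q must be in [0, 1), got {q}")
    return float(np.quantile(phi, q))
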