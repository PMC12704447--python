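"""Cubic-lattice polymer encoding of chromatin conformations.

A structure with ``N`` beads (genomic loci at fixed resolution) is threaded
through a cubic lattice: bead 0 sits at the origin, bead 1 at
``(1,1,1)/sqrt(3)``, and every later bead occupies one of the eight corners of
a unit cube centred on its predecessor.  The corner choice for bead ``i >= 2``
is encoded by three spin variables ``(z_x, z_y, z_z) in {-1,+1}``, so a whole
conformation is a spin string of length ``3(N-2)`` — the genotype optimised by
the variational engine and the outcome of one circuit measurement.

Every lattice step has Euclidean norm 1 (the coordinate unit is the lattice
step; no physical nm scale is assigned).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "SpinString",
    "Conformation",
    "SquaredDistances",
    "decode_spins",
    "encode_coords",
    "squared_distance_matrix",
    "contact_set",
    "is_clash_free",
    "spins_from_bits",
    "bits_from_spins",
]

_SQRT3 = np.sqrt(3.0)

#: Default contact radius, in lattice-step units.
DEFAULT_RADIUS = 1.5

#: Minimum pairwise distance below which a conformation is a spatial clash.
CLASH_DISTANCE = 0.25


@dataclass(frozen=True)
class SpinString:
    """Spin variables for beads ``2..N-1``, bead-major then axis (x, y, z).

    Bit convention shared with the engine's measurement decoding:
    bit 1 <-> spin +1, qubit 0 (least significant) <-> bead 2's x axis.
    """

    N: int
    spins: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"bead count must be >= 2, got {self.N}")
        expected = 3 * (self.N - 2)
        if len(self.spins) != expected:
            raise ValueError(
                f"spin vector has length {len(self.spins)}, expected {expected} "
                f"for N={self.N}"
            )
        if any(s not in (-1, 1) for s in self.spins):
            raise ValueError("spin entries must be -1 or +1")

    @classmethod
    def from_iterable(cls, N: int, spins: Iterable[int]) -> "SpinString":
        return cls(N, tuple(int(s) for s in spins))

    def to_bits(self) -> int:
        return bits_from_spins(self.spins)

    @classmethod
    def from_bits(cls, N: int, bits: int) -> "SpinString":
        return cls(N, spins_from_bits(bits, 3 * (N - 2)))


def spins_from_bits(bits: int, length: int) -> tuple[int, ...]:
    """Expand an integer bitstring (qubit 0 = LSB) into a +/-1 spin tuple."""
    if bits < 0 or bits >= (1 << length):
        raise ValueError(f"bitstring {bits} out of range for {length} qubits")
    return tuple(1 if (bits >> k) & 1 else -1 for k in range(length))


def bits_from_spins(spins: Iterable[int]) -> int:
    """Pack a +/-1 spin sequence into an integer (qubit 0 = LSB)."""
    out = 0
    for k, s in enumerate(spins):
        if s == 1:
            out |= 1 << k
        elif s != -1:
            raise ValueError("spin entries must be -1 or +1")
    return out


@dataclass(frozen=True)
class Conformation:
    """``N`` bead positions on the lattice, one row per bead."""

    N: int
    coords: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (self.N, 3):
            raise ValueError(f"coords must be {self.N}x3, got {coords.shape}")
        object.__setattr__(self, "coords", coords)

    def to_xyz(self) -> str:
        """Plain xyz-style text: one ``x y z`` row per bead."""
        return "\n".join(" ".join(f"{v:.12g}" for v in row) for row in self.coords)

    def to_json(self, spins: SpinString | None = None) -> str:
        rec = {"N": self.N, "coords": self.coords.tolist()}
        if spins is not None:
            rec["spins"] = list(spins.spins)
        return json.dumps(rec)


@dataclass(frozen=True)
class SquaredDistances:
    """Symmetric matrix of squared Euclidean distances between beads."""

    N: int
    d2: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d2 = np.asarray(self.d2, dtype=float)
        if d2.shape != (self.N, self.N):
            raise ValueError(f"d2 must be {self.N}x{self.N}, got {d2.shape}")
        object.__setattr__(self, "d2", d2)


def decode_spins(s: SpinString) -> Conformation:
    """Decode a spin string into lattice coordinates.

    Bead 0 is fixed at the origin and bead 1 at ``(1,1,1)/sqrt(3)``; bead
    ``i >= 2`` is the prefix sum of its predecessors' unit steps.
    """
    coords = np.empty((s.N, 3), dtype=float)
    coords[0] = 0.0
    coords[1] = 1.0 / _SQRT3
    if s.N > 2:
        steps = np.asarray(s.spins, dtype=float).reshape(s.N - 2, 3) / _SQRT3
        coords[2:] = coords[1] + np.cumsum(steps, axis=0)
    return Conformation(s.N, coords)


def encode_coords(c: Conformation) -> SpinString:
    """Recover the spin string from coordinates (sign of step differences)."""
    if c.N == 2:
        return SpinString(2, ())
    steps = np.diff(c.coords[1:], axis=0) * _SQRT3
    spins = np.rint(steps).astype(int).ravel()
    if not np.all(np.abs(spins) == 1):
        raise ValueError("coordinates are not a valid lattice conformation")
    return SpinString.from_iterable(c.N, spins)


def decode_many(N: int, bits: np.ndarray) -> np.ndarray:
    """Vectorised decode: array of bitstring integers -> (len, N, 3) coords."""
    bits = np.asarray(bits, dtype=np.int64)
    L = 3 * (N - 2)
    spins = ((bits[:, None] >> np.arange(L)) & 1) * 2 - 1  # (M, L)
    coords = np.empty((len(bits), N, 3), dtype=float)
    coords[:, 0] = 0.0
    coords[:, 1] = 1.0 / _SQRT3
    if N > 2:
        steps = spins.reshape(len(bits), N - 2, 3) / _SQRT3
        coords[:, 2:] = coords[:, 1, None, :] + np.cumsum(steps, axis=1)
    return coords


def squared_distance_matrix(c: Conformation) -> SquaredDistances:
    """All-pairs squared Euclidean distances of a conformation."""
    diff = c.coords[:, None, :] - c.coords[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    np.fill_diagonal(d2, 0.0)
    return SquaredDistances(c.N, d2)


def squared_distance_matrices(coords: np.ndarray) -> np.ndarray:
    """Vectorised all-pairs squared distances for a (M, N, 3) stack."""
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    d2 = np.einsum("mijk,mijk->mij", diff, diff)
    idx = np.arange(coords.shape[1])
    d2[:, idx, idx] = 0.0
    return d2


def contact_set(c: Conformation, r: float = DEFAULT_RADIUS) -> frozenset[tuple[int, int]]:
    """Pairs ``(i, j)``, ``i < j``, within Euclidean distance ``r`` and
    sequence separation ``|i - j| > r`` (with the default ``r = 1.5`` this
    means separation >= 2, so bonded neighbours never count as contacts)."""
    if r <= 0:
        raise ValueError("contact radius must be positive")
    d2 = squared_distance_matrix(c).d2
    iu, ju = np.triu_indices(c.N, k=1)
    sep_ok = (ju - iu) > r
    close = d2[iu, ju] <= r * r
    return frozenset(zip(iu[sep_ok & close].tolist(), ju[sep_ok & close].tolist()))


def is_clash_free(c: Conformation, min_dist: float = CLASH_DISTANCE) -> bool:
    """True iff every off-diagonal pairwise distance is >= ``min_dist``.

    Nonzero inter-bead distances on this lattice are >= 1, so with the
    default threshold 1/4 this is equivalent to "no two beads coincide".
    """
    if min_dist <= 0:
        raise ValueError("min_dist must be positive")
    d2 = squared_distance_matrix(c).d2
    iu, ju = np.triu_indices(c.N, k=1)
    return bool(np.all(d2[iu, ju] >= min_dist * min_dist))
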