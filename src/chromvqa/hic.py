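"""Hi-C calibration: frequency matrices to binary targets and back.

Contact frequency and spatial distance follow an inverse power law
``D[i,j] ∝ f[i,j]^(-lambda)``.  Taking the minimum nonzero adjacent-bin
frequency ``f_unit`` as the frequency of a unit-distance pair, a bin pair is
declared in contact when ``f[i,j] / f_unit >= r^(-1/lambda)`` — i.e. when
the power law places it within the contact radius.  The reverse mapping
turns model distances into inferred contact probabilities: 1 inside the
radius, ``(r / D)^(1/lambda)`` outside (``lambda = 1/3`` gives the classic
cubic decay).

Input is a dense whitespace/tab-delimited symmetric matrix (balanced
matrices are accepted but balancing is never performed here); bins whose
rows are entirely zero (unmappable) are dropped before calibration, with an
index map retained.  Bead order equals bin order along the chromosome,
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import lattice
from .lattice import CLASH_DISTANCE, SquaredDistances
from .likelihood import ContactMap

__all__ = [
    "FrequencyMatrix",
    "CalibrationConfig",
    "binarize_frequencies",
    "inferred_contact_matrix",
    "ensemble_mean_inferred",
    "read_frequency_matrix",
]


@dataclass(frozen=True)
class CalibrationConfig:
    """Power-law exponent and contact radius for calibration."""

    lam: float = 1.0 / 3.0
    r: float = lattice.DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.r <= 0:
            raise ValueError("contact radius must be positive")

    @property
    def threshold_ratio(self) -> float:
        """Frequency ratio above which a pair is a contact: r^(-1/lambda)."""
        return self.r ** (-1.0 / self.lam)


@dataclass(frozen=True)
class FrequencyMatrix:
    """Symmetric nonnegative contact-frequency matrix with its unit
    frequency (minimum nonzero adjacent-bin entry) derived on construction."""

    f: np.ndarray = field(repr=False)
    kept_bins: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        if f.ndim != 2 or f.shape[0] != f.shape[1]:
            raise ValueError("frequency matrix must be square")
        if not np.allclose(f, f.T):
            raise ValueError("frequency matrix must be symmetric")
        if np.any(f < 0):
            raise ValueError("frequencies must be nonnegative")
        object.__setattr__(self, "f", f)
        if not self.kept_bins:
            object.__setattr__(self, "kept_bins", tuple(range(f.shape[0])))

    @property
    def N(self) -> int:
        return self.f.shape[0]

    @property
    def f_unit(self) -> float:
        adj = np.diagonal(self.f, offset=1)
        nz = adj[adj > 0]
        if nz.size == 0:
            raise ValueError(
                "all adjacent-bin frequencies are zero; f_unit is undefined"
            )
        return float(nz.min())

    @classmethod
    def from_dense(cls, f: np.ndarray) -> "FrequencyMatrix":
        """Drop all-zero rows/columns (unmappable bins), keeping the map
        from retained bead index to original bin index."""
        f = np.asarray(f, dtype=float)
        keep = np.flatnonzero(f.sum(axis=0) > 0)
        return cls(f=f[np.ix_(keep, keep)], kept_bins=tuple(int(k) for k in keep))


def read_frequency_matrix(path_or_buf) -> FrequencyMatrix:
    """Dense whitespace/tab-delimited text -> FrequencyMatrix (zero bins
    dropped).  NaNs (common in balanced matrices) are treated as zero."""
    f = np.loadtxt(path_or_buf, dtype=float)
    f = np.nan_to_num(np.atleast_2d(f), nan=0.0)
    return FrequencyMatrix.from_dense(f)


def binarize_frequencies(fm: FrequencyMatrix, cal: CalibrationConfig) -> ContactMap:
    """Calibrate a frequency matrix into a binary contact target."""
    ratio = fm.f / fm.f_unit
    entries = (ratio >= cal.threshold_ratio).astype(np.int8)
    entries = np.logical_or(entries, entries.T).astype(np.int8)
    np.fill_diagonal(entries, 0)
    return ContactMap(entries)


def inferred_contact_matrix(
    d: SquaredDistances | np.ndarray, cal: CalibrationConfig
) -> np.ndarray:
    """Inferred contact probabilities from pairwise distances: 1 within the
    radius, ``(r / D)^(1/lambda)`` beyond it (continuous at ``D = r``)."""
    d2 = d.d2 if isinstance(d, SquaredDistances) else np.asarray(d, dtype=float)
    dist = np.sqrt(d2)
    out = np.ones_like(dist)
    far = dist > cal.r
    out[far] = (cal.r / dist[far]) ** (1.0 / cal.lam)
    np.fill_diagonal(out, 1.0)
    return out


def ensemble_mean_inferred(
    ens, cal: CalibrationConfig
) -> tuple[np.ndarray, dict[str, int]]:
    """Count-weighted mean inferred contact matrix over a sampled ensemble.

    Conformations containing a spatial clash (any pairwise distance below
    1/4) are dropped before averaging; the report states how many shots
    survived.  Raises if every shot clashes.
    """
    idx, cnt = ens.arrays()
    if cnt.sum() == 0:
        raise ValueError("ensemble is empty")
    coords = lattice.decode_many(ens.N, idx)
    d2 = lattice.squared_distance_matrices(coords)
    iu, ju = np.triu_indices(ens.N, k=1)
    clash_free = np.all(d2[:, iu, ju] >= CLASH_DISTANCE**2, axis=1)
    kept = int(cnt[clash_free].sum())
    dropped = int(cnt[~clash_free].sum())
    if kept == 0:
        raise ValueError("every sampled conformation contains a spatial clash")
    w = cnt[clash_free].astype(float) / kept
    mats = np.stack(
        [inferred_contact_matrix(m, cal) for m in d2[clash_free]]
    )
    mean = np.tensordot(w, mats, axes=1)
    report = {"shots_kept": kept, "shots_dropped": dropped}
    return mean, report
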