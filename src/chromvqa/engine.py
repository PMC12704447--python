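"""Variational engine: ansatz, statevector simulation, sampling, training.

The generative model is a hardware-efficient real-amplitude ansatz on
``3(N-2)`` qubits: a layer of single-qubit y-rotations, then ``reps``
repetitions of (reverse-linear CNOT entangling block + rotation layer), for
``(reps + 1) * 3(N-2)`` parameters — ``9(N-2)`` at the default two
repetitions.  Because RY rotations and CNOTs have real matrix entries, the
prepared state has strictly real amplitudes, which suffices: the objective
Hamiltonian is diagonal in the computational (Z) basis.

Simulation is an exact statevector evolution followed by a multinomial draw
of shots — distributionally identical to per-shot circuit execution at desk
scale.  Training closes the loop classically: sample an ensemble, score it
with the aggregated likelihood objective, and update the parameters with a
derivative-free linear-approximation optimiser (COBYLA), returning the best
parameters seen (not the last).  A pluggable backend seam
(``simulate_probabilities`` is the only quantum touchpoint) would admit a
hardware client, but none ships.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from . import lattice
from .likelihood import ContactMap, ModelConfig, structure_log_likelihood

__all__ = [
    "AnsatzSpec",
    "TrainConfig",
    "TrainResult",
    "EnsembleSample",
    "StateScoreCache",
    "build_ansatz",
    "simulate_amplitudes",
    "simulate_probabilities",
    "sample_measurements",
    "sample_ensemble",
    "expected_objective",
    "train",
]


@dataclass(frozen=True)
class AnsatzSpec:
    """Layout of the real-amplitude ansatz for an ``N``-bead polymer."""

    N: int
    reps: int = 2

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    @property
    def num_qubits(self) -> int:
        return 3 * (self.N - 2)

    @property
    def parameter_count(self) -> int:
        return (self.reps + 1) * self.num_qubits

    @property
    def entangling_pairs(self) -> list[tuple[int, int]]:
        """(control, target) CNOT couplings of one block, reverse-linear
        order: (n-2, n-1), (n-3, n-2), ..., (0, 1)."""
        n = self.num_qubits
        return [(i, i + 1) for i in range(n - 2, -1, -1)]


def build_ansatz(N: int, reps: int = 2) -> AnsatzSpec:
    """Ansatz spec with ``3(N-2)`` qubits and ``(reps+1)*3(N-2)`` parameters.

    ``N = 2`` is the degenerate zero-qubit case (the two fixed beads)."""
    return AnsatzSpec(N=N, reps=reps)


def _apply_ry(state: np.ndarray, n: int, qubit: int, theta: float) -> None:
    c = np.cos(theta / 2.0)
    s = np.sin(theta / 2.0)
    view = state.reshape(1 << (n - 1 - qubit), 2, 1 << qubit)
    a0 = view[:, 0, :].copy()
    a1 = view[:, 1, :].copy()
    view[:, 0, :] = c * a0 - s * a1
    view[:, 1, :] = s * a0 + c * a1


def _apply_cx(state: np.ndarray, n: int, control: int, target: int) -> None:
    view = state.reshape([2] * n)
    axc = n - 1 - control
    axt = n - 1 - target
    i10: list = [slice(None)] * n
    i11: list = [slice(None)] * n
    i10[axc] = i11[axc] = 1
    i10[axt] = 0
    i11[axt] = 1
    tmp = view[tuple(i10)].copy()
    view[tuple(i10)] = view[tuple(i11)]
    view[tuple(i11)] = tmp


def simulate_amplitudes(spec: AnsatzSpec, theta: np.ndarray) -> np.ndarray:
    """Real amplitudes of ``|psi(theta)>`` over the computational basis.

    Basis index convention: qubit 0 is the least significant bit, matching
    the lattice spin-string packing (qubit 0 = bead 2's x axis).
    """
    theta = np.asarray(theta, dtype=float).ravel()
    if len(theta) != spec.parameter_count:
        raise ValueError(
            f"expected {spec.parameter_count} parameters, got {len(theta)}"
        )
    n = spec.num_qubits
    state = np.zeros(1 << n, dtype=float)
    state[0] = 1.0
    if n == 0:
        return state
    for q in range(n):
        _apply_ry(state, n, q, theta[q])
    for rep in range(1, spec.reps + 1):
        for control, target in spec.entangling_pairs:
            _apply_cx(state, n, control, target)
        off = rep * n
        for q in range(n):
            _apply_ry(state, n, q, theta[off + q])
    return state


def simulate_probabilities(spec: AnsatzSpec, theta: np.ndarray) -> np.ndarray:
    """Measurement distribution over the ``2^num_qubits`` basis states."""
    amp = simulate_amplitudes(spec, theta)
    return amp * amp


@dataclass
class EnsembleSample:
    """Multiset of measured spin strings: state index -> shot count."""

    N: int
    counts: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(state indices, counts) as aligned arrays, index-sorted."""
        idx = np.array(sorted(self.counts), dtype=np.int64)
        cnt = np.array([self.counts[int(i)] for i in idx], dtype=np.int64)
        return idx, cnt

    def spin_strings(self) -> list[lattice.SpinString]:
        return [lattice.SpinString.from_bits(self.N, int(k)) for k in sorted(self.counts)]

    def to_json(self) -> str:
        width = 3 * (self.N - 2)
        return json.dumps(
            {
                "N": self.N,
                "total": self.total,
                "counts": {
                    format(k, f"0{width}b") if width else "": v
                    for k, v in sorted(self.counts.items())
                },
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "EnsembleSample":
        rec = json.loads(text)
        counts = {int(k, 2) if k else 0: int(v) for k, v in rec["counts"].items()}
        return cls(N=rec["N"], counts=counts)


def sample_measurements(
    probabilities: np.ndarray,
    shots: int,
    seed: int | np.random.Generator | None = None,
    *,
    N: int | None = None,
) -> EnsembleSample:
    """Multinomial draw of ``shots`` measurements from a basis distribution."""
    if shots < 1:
        raise ValueError("shots must be >= 1")
    probabilities = np.asarray(probabilities, dtype=float)
    size = len(probabilities)
    if N is None:
        qubits = int(round(np.log2(size)))
        if 1 << qubits != size or qubits % 3 != 0:
            raise ValueError("cannot infer N from the distribution size")
        N = qubits // 3 + 2
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draw = rng.multinomial(shots, probabilities / probabilities.sum())
    nz = np.flatnonzero(draw)
    return EnsembleSample(N=N, counts={int(k): int(draw[k]) for k in nz})


def sample_ensemble(
    spec: AnsatzSpec,
    theta: np.ndarray,
    shots: int = 4096,
    seed: int | np.random.Generator | None = None,
) -> EnsembleSample:
    """Prepare ``|psi(theta)>`` and draw ``shots`` conformations."""
    probs = simulate_probabilities(spec, theta)
    return sample_measurements(probs, shots, seed, N=spec.N)


class StateScoreCache:
    """Per-state squared distances and log-likelihoods, indexed by spin
    bitstring value.

    For universes up to ``precompute_limit`` states everything is built
    up-front (vectorised); larger polymers fall back to lazy decoding of the
    states actually sampled.
    """

    def __init__(
        self,
        pc: ContactMap,
        cfg: ModelConfig | None = None,
        precompute_limit: int = 1 << 15,
    ):
        self.pc = pc
        self.cfg = cfg or ModelConfig()
        self.N = pc.N
        self.size = 8 ** (self.N - 2)
        self._full = self.size <= precompute_limit
        self._iu, self._ju = np.triu_indices(self.N, k=1)
        if self._full:
            coords = lattice.decode_many(self.N, np.arange(self.size, dtype=np.int64))
            self.d2_all = lattice.squared_distance_matrices(coords)
            self.ll_all = np.array(
                [structure_log_likelihood(m, pc, self.cfg) for m in self.d2_all]
            )
            self.clash_free_all = self._clash_free(self.d2_all)
        else:
            self._d2: dict[int, np.ndarray] = {}
            self._ll: dict[int, float] = {}
            self._cf: dict[int, bool] = {}

    def _clash_free(self, d2_stack: np.ndarray) -> np.ndarray:
        off = d2_stack[:, self._iu, self._ju]
        return np.all(off >= lattice.CLASH_DISTANCE**2, axis=1)

    def lookup(self, indices: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(d2 stack, log-likelihoods, clash-free flags) for state indices."""
        indices = np.asarray(indices, dtype=np.int64)
        if self._full:
            return self.d2_all[indices], self.ll_all[indices], self.clash_free_all[indices]
        missing = [int(k) for k in indices if int(k) not in self._ll]
        if missing:
            coords = lattice.decode_many(self.N, np.array(missing, dtype=np.int64))
            d2s = lattice.squared_distance_matrices(coords)
            flags = self._clash_free(d2s)
            for k, m, cf in zip(missing, d2s, flags):
                self._d2[k] = m
                self._ll[k] = structure_log_likelihood(m, self.pc, self.cfg)
                self._cf[k] = bool(cf)
        d2 = np.stack([self._d2[int(k)] for k in indices])
        ll = np.array([self._ll[int(k)] for k in indices])
        cf = np.array([self._cf[int(k)] for k in indices])
        return d2, ll, cf

    def objective(
        self,
        indices: np.ndarray,
        weights: np.ndarray,
        include_clashes: bool = True,
    ) -> float:
        """Aggregated objective over a weighted set of states.

        With ``include_clashes=False`` the clash-containing states are
        dropped before aggregation (falling back to the clash-inclusive cost
        when nothing survives, so the optimiser always sees a slope).
        """
        weights = np.asarray(weights, dtype=float)
        total = weights.sum()
        if total <= 0:
            raise ValueError("ensemble is empty")
        d2, ll, cf = self.lookup(indices)
        if not include_clashes and cf.any():
            d2, ll, weights = d2[cf], ll[cf], weights[cf]
            total = weights.sum()
        w = weights / total
        alpha = self.cfg.alpha
        cost = 0.0
        if alpha < 1.0:
            cost -= (1.0 - alpha) * float(w @ ll)
        if alpha > 0.0:
            mean_d2 = np.tensordot(w, d2, axes=1)
            cost -= alpha * structure_log_likelihood(mean_d2, self.pc, self.cfg)
        return cost


def expected_objective(
    spec: AnsatzSpec,
    theta: np.ndarray,
    cache: StateScoreCache,
    include_clashes: bool = True,
) -> float:
    """Exact (infinite-shot) objective: the statevector distribution over the
    full universe fed straight into the aggregated objective.

    Requires a fully precomputed cache; this is the deterministic limit the
    shot-based objective converges to, and the quantity the enumeration
    oracle cross-checks.  ``include_clashes=False`` conditions the
    distribution on clash-free states, matching the training default.
    """
    if not cache._full:
        raise ValueError("expected_objective needs a fully precomputed cache")
    probs = simulate_probabilities(spec, theta)
    if not include_clashes and cache.clash_free_all.any():
        mass = probs[cache.clash_free_all].sum()
        if mass > 0:
            probs = np.where(cache.clash_free_all, probs, 0.0) / mass
    alpha = cache.cfg.alpha
    cost = 0.0
    if alpha < 1.0:
        cost -= (1.0 - alpha) * float(probs @ cache.ll_all)
    if alpha > 0.0:
        mean_d2 = np.tensordot(probs, cache.d2_all, axes=1)
        cost -= alpha * structure_log_likelihood(mean_d2, cache.pc, cache.cfg)
    return cost


@dataclass(frozen=True)
class TrainConfig:
    """Optimiser settings for one variational run.

    shots
        Measurements per objective evaluation (default 4096).
    seed
        Seeds both the uniform ``[0, 2pi)`` parameter initialisation and the
        per-evaluation shot sampling.
    max_evals
        Total budget of objective evaluations across COBYLA restarts.
    initial_step
        COBYLA's initial trust-region radius, radians.  When a COBYLA run
        converges with budget left, the optimiser restarts from the best
        parameters seen with the next radius in ``restart_steps`` (last
        entry reused), a cheap escape from premature trust-region collapse
        on a noisy objective.
    tol
        Convergence tolerance on the trust-region radius.
    include_clashes
        Whether clash-containing conformations enter the training
        objective.  Off by default: scoring only the clash-free shots keeps
        the cost on the likelihood scale instead of being dominated by the
        clamped clash penalties, which flattens every other feature of the
        landscape; clash mass still shrinks during training because only
        clash-free states earn likelihood reward.
    """

    shots: int = 4096
    seed: int | None = None
    max_evals: int = 2000
    initial_step: float = 0.7
    restart_steps: tuple[float, ...] = (0.3, 0.1)
    tol: float = 1e-3
    include_clashes: bool = False

    def __post_init__(self) -> None:
        if self.shots < 1:
            raise ValueError("shots must be >= 1")


@dataclass
class TrainResult:
    theta_star: np.ndarray
    best_cost: float
    cost_trace: list[float]
    evaluations: int
    seed: int | None

    def to_json(self) -> str:
        return json.dumps(
            {
                "theta": self.theta_star.tolist(),
                "best_cost": self.best_cost,
                "cost_trace": self.cost_trace,
                "evaluations": self.evaluations,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TrainResult":
        rec = json.loads(text)
        return cls(
            theta_star=np.asarray(rec["theta"], dtype=float),
            best_cost=rec["best_cost"],
            cost_trace=list(rec["cost_trace"]),
            evaluations=rec["evaluations"],
            seed=rec.get("seed"),
        )


def train(
    pc: ContactMap,
    cfg: ModelConfig | None = None,
    tcfg: TrainConfig | None = None,
    *,
    spec: AnsatzSpec | None = None,
    cache: StateScoreCache | None = None,
) -> TrainResult:
    """One variational run against a binary contact target.

    Each objective evaluation prepares ``|psi(theta)>`` exactly, draws
    ``shots`` measurements, decodes them to conformations and scores the
    ensemble with the aggregated likelihood objective; COBYLA updates theta.
    Returns the best parameters seen across all evaluations.
    """
    cfg = cfg or ModelConfig()
    tcfg = tcfg or TrainConfig()
    spec = spec or build_ansatz(pc.N)
    if spec.N != pc.N:
        raise ValueError(f"ansatz N={spec.N} does not match contact map N={pc.N}")
    cache = cache or StateScoreCache(pc, cfg)

    rng = np.random.default_rng(tcfg.seed)
    if spec.num_qubits == 0:
        # Degenerate two-bead polymer: the single fixed conformation.
        cost = cache.objective(np.array([0]), np.array([1.0]))
        return TrainResult(
            theta_star=np.empty(0),
            best_cost=cost,
            cost_trace=[cost],
            evaluations=1,
            seed=tcfg.seed,
        )
    theta0 = rng.uniform(0.0, 2.0 * np.pi, size=spec.parameter_count)
    shot_rng = np.random.default_rng(rng.integers(2**31))

    trace: list[float] = []
    best = {"cost": np.inf, "theta": theta0.copy()}

    class _BudgetExhausted(Exception):
        pass

    def objective(theta: np.ndarray) -> float:
        if len(trace) >= tcfg.max_evals:
            raise _BudgetExhausted
        probs = simulate_probabilities(spec, theta)
        ens = sample_measurements(probs, tcfg.shots, shot_rng, N=spec.N)
        idx, cnt = ens.arrays()
        cost = cache.objective(idx, cnt, include_clashes=tcfg.include_clashes)
        if not np.isfinite(cost):
            raise FloatingPointError(
                f"non-finite objective {cost} at evaluation {len(trace) + 1}"
            )
        trace.append(cost)
        if cost < best["cost"]:
            best["cost"] = cost
            best["theta"] = np.array(theta, copy=True)
        return cost

    steps = (tcfg.initial_step,) + tuple(tcfg.restart_steps)
    stage = 0
    # num_vars + 2 is COBYLA's minimum working budget per run
    min_budget = spec.parameter_count + 2
    while len(trace) < tcfg.max_evals:
        budget = tcfg.max_evals - len(trace)
        if stage > 0 and budget < min_budget:
            break
        rhobeg = steps[min(stage, len(steps) - 1)]
        stage += 1
        try:
            minimize(
                objective,
                best["theta"],
                method="COBYLA",
                tol=tcfg.tol,
                options={"maxiter": budget, "rhobeg": rhobeg},
            )
        except _BudgetExhausted:
            break
    return TrainResult(
        theta_star=best["theta"],
        best_cost=float(best["cost"]),
        cost_trace=trace,
        evaluations=len(trace),
        seed=tcfg.seed,
    )
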