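"""Experiment orchestration and command-line interface.

One integer seed reproduces an entire experiment: it is split through a
fixed ``numpy.random.SeedSequence`` fan-out into named stage seeds (target
selection, per-trial parameter initialisation, ensemble sampling), so two
runs of the same config are identical apart from timestamps.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import click
import numpy as np
import yaml

from . import engine, hic, metrics, oracle
from .likelihood import ModelConfig, read_contact_map, write_contact_map

__all__ = ["ExperimentConfig", "run_experiment", "main"]

logger = logging.getLogger(__name__)


def split_seed(seed: int, n: int = 3) -> list[int]:
    """Fan one global seed out into ``n`` stage seeds (< 2^31)."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


@dataclass
class ExperimentConfig:
    """Flat experiment configuration (YAML-loadable, CLI-overridable)."""

    N: int = 6
    r: float = 1.5
    alpha: float = 0.0
    shots: int = 4096
    lam: float = 1.0 / 3.0
    trials: int = 10
    seed: int = 0
    max_evals: int = 2000
    q: float = 0.5
    bins: int = 20
    outdir: str | None = None

    def __post_init__(self) -> None:
        ModelConfig(r=self.r, alpha=self.alpha)  # re-validate module invariants
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if self.shots < 1:
            raise ValueError("shots must be >= 1")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Simulate a target, train ``trials`` times, sample, evaluate.

    Returns (and optionally writes) a JSON-serialisable bundle with the
    config echo, per-trial training results, ensembles and metric reports.
    Deterministic given ``cfg.seed``.
    """
    t0 = time.time()
    stage = "setup"
    bundle: dict = {"config": asdict(cfg), "trials": []}
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    try:
        target_seed, init_base, sampling_base = split_seed(cfg.seed)

        stage = "simulate-targets"
        u = oracle.enumerate_universe(cfg.N, cfg.r)
        target = oracle.sample_target(u, target_seed)
        mcfg = ModelConfig(r=cfg.r, alpha=cfg.alpha)
        phi, _ = oracle.ground_truth_distribution(u, target.contact_map, mcfg)
        cache = engine.StateScoreCache(target.contact_map, mcfg)
        logger.info(
            "target group: %d contacts, %d members (universe %d states)",
            len(target.chi), len(target.members), u.size,
        )
        bundle["target"] = {"chi": [list(p) for p in target.chi], "members": len(target.members)}

        cal = hic.CalibrationConfig(lam=cfg.lam, r=cfg.r)
        spec = engine.build_ansatz(cfg.N)
        for trial in range(cfg.trials):
            stage = f"train[{trial}]"
            tcfg = engine.TrainConfig(
                shots=cfg.shots,
                seed=(init_base + trial) & 0x7FFFFFFF,
                max_evals=cfg.max_evals,
            )
            result = engine.train(target.contact_map, mcfg, tcfg, spec=spec, cache=cache)
            stage = f"sample[{trial}]"
            ens = engine.sample_ensemble(
                spec, result.theta_star, cfg.shots, (sampling_base + trial) & 0x7FFFFFFF
            )
            stage = f"evaluate[{trial}]"
            report = metrics.MetricsReport(meta={"q": cfg.q, "alpha": cfg.alpha, "lam": cfg.lam, "seed": cfg.seed})
            cov, emp = metrics.coverage_and_empirical_probability(ens, phi, cfg.q)
            report.add("coverage", cov)
            report.add("empirical_probability", emp)
            report.add("entropy_bits", metrics.empirical_entropy(ens))
            mean_inferred, clash_report = hic.ensemble_mean_inferred(ens, cal)
            for k, v in metrics.contact_recovery_scores(target.contact_map, mean_inferred).items():
                if np.isfinite(v):
                    report.add(k, v)
            for k, v in metrics.dsi(target.contact_map, mean_inferred).items():
                report.add(k, v)
            ratios = metrics.likelihood_ratio_by_level(ens, phi, cfg.bins)
            bundle["trials"].append(
                {
                    "train": json.loads(result.to_json()),
                    "ensemble": json.loads(ens.to_json()),
                    "metrics": {"values": report.values, "meta": report.meta},
                    "clash_filter": clash_report,
                    "likelihood_ratio_by_level": ratios.tolist(),
                }
            )
            logger.info(
                "trial %d: best cost %.4f, empirical prob %.3f, entropy %.2f bits",
                trial, result.best_cost, emp, report.values["entropy_bits"],
            )
            if outdir:
                (outdir / f"trace_{trial}.txt").write_text(
                    "\n".join(f"{c:.10g}" for c in result.cost_trace)
                )
    except Exception as exc:
        bundle["error"] = {"stage": stage, "message": str(exc)}
        if outdir:
            (outdir / "bundle.json").write_text(json.dumps(bundle, indent=1))
        raise RuntimeError(f"experiment failed at stage {stage}: {exc}") from exc
    bundle["elapsed_s"] = round(time.time() - t0, 3)
    if outdir:
        (outdir / "bundle.json").write_text(json.dumps(bundle, indent=1))
    return bundle


def _n_from_theta(theta: np.ndarray) -> int:
    p = len(theta)
    if p % 9 != 0:
        raise click.ClickException(f"parameter vector length {p} is not 9(N-2)")
    return p // 9 + 2


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="INFO-level stage logging.")
def main(verbose: bool) -> None:
    """Variational quantum sampling of 3D genome conformations."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )


@main.command("simulate-targets")
@click.option("--n", "n_beads", type=int, required=True, help="Bead count.")
@click.option("--r", type=float, default=1.5, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True, help="Target contact map TSV.")
def cli_simulate_targets(n_beads: int, r: float, seed: int, out: str) -> None:
    """Enumerate the universe and sample one target contact group."""
    u = oracle.enumerate_universe(n_beads, r)
    target = oracle.sample_target(u, seed)
    with open(out, "w") as fh:
        write_contact_map(target.contact_map, fh)
    click.echo(
        f"N={n_beads}: {u.size} states, {int(u.clash_free.sum())} clash-free; "
        f"target has {len(target.chi)} contacts and {len(target.members)} members -> {out}"
    )


@main.command("train")
@click.option("--contacts", type=click.Path(exists=True), required=True)
@click.option("--alpha", type=float, default=0.0, show_default=True)
@click.option("--shots", type=int, default=4096, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--max-evals", type=int, default=1000, show_default=True)
@click.option("--out", type=click.Path(), required=True, help="Run JSON.")
def cli_train(contacts: str, alpha: float, shots: int, seed: int, max_evals: int, out: str) -> None:
    """Train the variational sampler against a contact map TSV."""
    pc = read_contact_map(contacts)
    result = engine.train(
        pc,
        ModelConfig(alpha=alpha),
        engine.TrainConfig(shots=shots, seed=seed, max_evals=max_evals),
    )
    Path(out).write_text(result.to_json())
    click.echo(f"best cost {result.best_cost:.6f} after {result.evaluations} evaluations -> {out}")


@main.command("sample")
@click.option("--run", "run_path", type=click.Path(exists=True), required=True)
@click.option("--shots", type=int, default=4096, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True, help="Ensemble JSON.")
def cli_sample(run_path: str, shots: int, seed: int, out: str) -> None:
    """Sample an ensemble from a trained run's optimal parameters."""
    result = engine.TrainResult.from_json(Path(run_path).read_text())
    spec = engine.build_ansatz(_n_from_theta(result.theta_star))
    ens = engine.sample_ensemble(spec, result.theta_star, shots, seed)
    Path(out).write_text(ens.to_json())
    click.echo(f"{len(ens.counts)} distinct states over {ens.total} shots -> {out}")


@main.command("evaluate")
@click.option("--ensemble", "ens_path", type=click.Path(exists=True), required=True)
@click.option("--contacts", type=click.Path(exists=True), required=True)
@click.option("--q", type=float, default=0.5, show_default=True)
@click.option("--lam", type=float, default=1.0 / 3.0, show_default=True)
@click.option("--out", type=click.Path(), default=None, help="Metrics JSON (default stdout).")
def cli_evaluate(ens_path: str, contacts: str, q: float, lam: float, out: str | None) -> None:
    """Score a sampled ensemble against a contact map TSV."""
    ens = engine.EnsembleSample.from_json(Path(ens_path).read_text())
    pc = read_contact_map(contacts)
    mcfg = ModelConfig()
    report = metrics.MetricsReport(meta={"q": q, "lam": lam})
    u = oracle.enumerate_universe(ens.N)
    phi, _ = oracle.ground_truth_distribution(u, pc, mcfg)
    cov, emp = metrics.coverage_and_empirical_probability(ens, phi, q)
    report.add("coverage", cov)
    report.add("empirical_probability", emp)
    report.add("entropy_bits", metrics.empirical_entropy(ens))
    mean_inferred, clash_report = hic.ensemble_mean_inferred(ens, hic.CalibrationConfig(lam=lam))
    for k, v in metrics.contact_recovery_scores(pc, mean_inferred).items():
        if np.isfinite(v):
            report.add(k, v)
    for k, v in metrics.dsi(pc, mean_inferred).items():
        report.add(k, v)
    payload = json.dumps({"values": report.values, "meta": report.meta, "clash_filter": clash_report}, indent=1)
    if out:
        Path(out).write_text(payload)
    else:
        click.echo(payload)


@main.command("binarize")
@click.option("--freq", type=click.Path(exists=True), required=True, help="Dense frequency TSV.")
@click.option("--lam", type=float, default=1.0 / 3.0, show_default=True)
@click.option("--r", type=float, default=1.5, show_default=True)
@click.option("--out", type=click.Path(), required=True, help="Contact map TSV.")
def cli_binarize(freq: str, lam: float, r: float, out: str) -> None:
    """Calibrate a contact-frequency matrix into a binary target."""
    fm = hic.read_frequency_matrix(freq)
    pc = hic.binarize_frequencies(fm, hic.CalibrationConfig(lam=lam, r=r))
    with open(out, "w") as fh:
        write_contact_map(pc, fh)
    n_contacts = len(pc.contact_pairs())
    click.echo(f"{fm.N} bins kept, {n_contacts} contacts at lambda={lam} -> {out}")


@main.command("landscape")
@click.option("--contacts", type=click.Path(exists=True), required=True)
@click.option("--alpha", type=float, default=0.0, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(), default=None)
def cli_landscape(contacts: str, alpha: float, seed: int, out: str | None) -> None:
    """Empirical maximum information content of the objective landscape."""
    pc = read_contact_map(contacts)
    mcfg = ModelConfig(alpha=alpha)
    spec = engine.build_ansatz(pc.N)
    cache = engine.StateScoreCache(pc, mcfg)
    h_m = metrics.landscape_mic(
        lambda th: engine.expected_objective(spec, th, cache), spec.parameter_count, seed
    )
    payload = json.dumps({"alpha": alpha, "H_M": h_m})
    if out:
        Path(out).write_text(payload)
    else:
        click.echo(payload)


@main.command("run")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--n", "n_beads", type=int, default=None)
@click.option("--alpha", type=float, default=None)
@click.option("--shots", type=int, default=None)
@click.option("--trials", type=int, default=None)
@click.option("--seed", type=int, default=None)
@click.option("--max-evals", type=int, default=None)
@click.option("--outdir", type=click.Path(), default=None)
def cli_run(config_path, n_beads, alpha, shots, trials, seed, max_evals, outdir) -> None:
    """Full workflow: simulate target, train, sample, evaluate."""
    overrides = {
        "N": n_beads, "alpha": alpha, "shots": shots, "trials": trials,
        "seed": seed, "max_evals": max_evals, "outdir": outdir,
    }
    if config_path:
        cfg = ExperimentConfig.from_yaml(config_path, **overrides)
    else:
        cfg = ExperimentConfig(**{k: v for k, v in overrides.items() if v is not None})
    bundle = run_experiment(cfg)
    med = np.median([t["metrics"]["values"]["empirical_probability"] for t in bundle["trials"]])
    click.echo(f"{cfg.trials} trials in {bundle['elapsed_s']}s; median empirical probability {med:.3f}")
    if not cfg.outdir:
        json.dump(bundle, sys.stdout, indent=1)


if __name__ == "__main__":
    main()
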