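"""Synthetic multi-cohort expression collections with a machine-readable truth.

The generator emulates the input structure of the cross-cancer meta-analysis:
a collection of case/control expression studies split into disease groups
(default 10 lung-cancer + 5 breast-cancer + 5 leukemia datasets, 20 samples
per arm, 2000 genes), with

* planted *winner* genes — a case-vs-control shift of a configured size (in
  noise-SD units) and direction, applied in a seeded random subset of each
  group's datasets of a configured fraction (the "direction consistency"
  the vote-counting layer keys on);
* planted *coexpression modules* — module genes load on a shared per-sample
  latent factor, ``x = baseline + sd·(√ρ·f + √(1−ρ)·ε)``, so any two module
  genes have expected Pearson correlation ρ;
* transcription-factor labels over a seeded random gene subset plus any
  explicitly marked winners;
* survival times whose hazard is log-linear in chosen genes' standardized
  expression, with exponential censoring tuned to a target censoring rate.

All randomness flows from the single config seed through
``numpy.random.SeedSequence`` spawns, so a config is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datasets import ExpressionDataset

BASELINE_MEAN = 8.0  # log2-scale intensity center


@dataclass(frozen=True)
class PlantedWinner:
    """One gene's planted case-control effect.

    ``fractions`` maps disease group → fraction of that group's datasets in
    which the effect is planted; ``effect_size`` is in units of the gene's
    noise SD; ``direction`` is ``up`` or ``down``.
    """

    gene: str
    direction: str
    fractions: dict[str, float]
    effect_size: float
    is_tf: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        for g, f in self.fractions.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"fraction for {g} outside [0, 1]: {f}")


@dataclass(frozen=True)
class PlantedModule:
    """A coexpression module: genes sharing a latent factor at correlation rho."""

    module_id: str
    genes: tuple[str, ...]
    correlation: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.correlation < 1.0):
            raise ValueError("module correlation must lie in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Study design of a synthetic collection (defaults mirror the analysis
    design: 10 LC + 5 BC + 5 LK studies, 20 samples per arm, 2000 genes)."""

    seed: int
    n_datasets: dict[str, int] = field(
        default_factory=lambda: {"LC": 10, "BC": 5, "LK": 5})
    samples_per_arm: int = 20
    n_genes: int = 2000
    winners: tuple[PlantedWinner, ...] = ()
    modules: tuple[PlantedModule, ...] = ()
    tf_fraction: float = 0.05
    noise_sd: float = 1.0
    censoring_rate: float = 0.3
    base_rate: float = 1.0 / 24.0  # events per month: median OS ~ 17 months
    survival_betas: dict[str, float] = field(default_factory=dict)

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


def _planted_dataset_indices(cfg: SimulationConfig, rng: np.random.Generator
                             ) -> dict[str, dict[str, np.ndarray]]:
    """For each winner and group, the seeded dataset indices carrying the effect."""
    chosen: dict[str, dict[str, np.ndarray]] = {}
    for w in cfg.winners:
        per_group = {}
        for group, frac in w.fractions.items():
            n = cfg.n_datasets.get(group, 0)
            k = int(round(frac * n))
            per_group[group] = np.sort(rng.choice(n, size=k, replace=False))
        chosen[w.gene] = per_group
    return chosen


def simulate_collection(cfg: SimulationConfig
                        ) -> tuple[list[ExpressionDataset], pd.DataFrame]:
    """Generate the dataset collection and its truth table.

    Returns ``(datasets, truth)`` where ``truth`` is indexed by gene with
    columns ``is_winner``, ``direction``, ``effect_size``, ``module_id``,
    ``is_tf``, ``survival_beta``.
    """
    genes = cfg.gene_names()
    gene_set = set(genes)
    for w in cfg.winners:
        if w.gene not in gene_set:
            raise ValueError(f"planted winner {w.gene!r} not among the genes")
    for m in cfg.modules:
        missing = [g for g in m.genes if g not in gene_set]
        if missing:
            raise ValueError(f"module {m.module_id}: unknown genes {missing[:5]}")

    root = np.random.SeedSequence(cfg.seed)
    ss_design, ss_data = root.spawn(2)
    design_rng = np.random.default_rng(ss_design)
    planted = _planted_dataset_indices(cfg, design_rng)

    n_tf = int(round(cfg.tf_fraction * cfg.n_genes))
    tf_idx = design_rng.choice(cfg.n_genes, size=n_tf, replace=False)
    tf_genes = {genes[i] for i in tf_idx} | {w.gene for w in cfg.winners if w.is_tf}

    gene_pos = {g: i for i, g in enumerate(genes)}
    module_rows = {m.module_id: np.array([gene_pos[g] for g in m.genes])
                   for m in cfg.modules}

    datasets: list[ExpressionDataset] = []
    data_children = iter(ss_data.spawn(sum(cfg.n_datasets.values())))
    for group, n_group in cfg.n_datasets.items():
        for d in range(n_group):
            rng = np.random.default_rng(next(data_children))
            n_per_arm = cfg.samples_per_arm
            n_samples = 2 * n_per_arm
            X = BASELINE_MEAN + cfg.noise_sd * rng.standard_normal(
                (cfg.n_genes, n_samples))
            for m in cfg.modules:
                rows = module_rows[m.module_id]
                f = rng.standard_normal(n_samples)
                eps = rng.standard_normal((len(rows), n_samples))
                X[rows] = BASELINE_MEAN + cfg.noise_sd * (
                    np.sqrt(m.correlation) * f
                    + np.sqrt(1.0 - m.correlation) * eps)
            case_cols = slice(n_per_arm, n_samples)  # controls first
            # effect sizes are in noise-SD units; at zero noise fall back to a
            # unit reference SD so noiseless collections still carry effects
            ref_sd = cfg.noise_sd if cfg.noise_sd > 0 else 1.0
            for w in cfg.winners:
                if d in planted.get(w.gene, {}).get(group, ()):
                    delta = w.effect_size * ref_sd
                    if w.direction == "down":
                        delta = -delta
                    X[gene_pos[w.gene], case_cols] += delta
            ds_id = f"SYN-{group}-{d + 1:02d}"
            samples = [f"{ds_id}-C{i + 1:02d}" for i in range(n_per_arm)] + \
                      [f"{ds_id}-T{i + 1:02d}" for i in range(n_per_arm)]
            classes = ["control"] * n_per_arm + ["case"] * n_per_arm
            datasets.append(ExpressionDataset(
                dataset_id=ds_id,
                disease_group=group,
                values=pd.DataFrame(X, index=pd.Index(genes, name="gene_id"),
                                    columns=samples),
                sample_class=pd.Series(classes, index=samples),
            ))

    truth = pd.DataFrame({
        "is_winner": False, "direction": "none", "effect_size": 0.0,
        "module_id": "", "is_tf": False, "survival_beta": 0.0,
    }, index=pd.Index(genes, name="gene_id"))
    for w in cfg.winners:
        truth.loc[w.gene, ["is_winner", "direction", "effect_size"]] = \
            [True, w.direction, w.effect_size]
    for m in cfg.modules:
        truth.loc[list(m.genes), "module_id"] = m.module_id
    truth.loc[sorted(tf_genes), "is_tf"] = True
    for g, beta in cfg.survival_betas.items():
        truth.loc[g, "survival_beta"] = beta
    return datasets, truth


def _censoring_scale(rates: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with mean P(censor first) = target."""
    if target <= 0:
        return 0.0
    if target >= 1:
        raise ValueError("censoring_rate must be < 1")

    def frac_censored(c: float) -> float:
        return float(np.mean(c / (c + rates))) - target

    lo, hi = 1e-12, 1e12
    return float(brentq(frac_censored, lo, hi, maxiter=200))


def simulate_survival(expression: pd.DataFrame, betas: dict[str, float],
                      base_rate: float = 1.0 / 24.0, censoring_rate: float = 0.3,
                      seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """Exponential survival with log-linear dependence on expression.

    ``expression`` is genes × subjects; each subject's event rate is
    ``base_rate * exp(sum_g beta_g * z_g)`` with z the per-gene standardized
    expression. Censoring is independent exponential with its rate tuned so
    the expected censored fraction equals ``censoring_rate``. Returns a
    DataFrame with ``subject_id``, ``time``, ``event`` and one column per
    gene in ``betas``.
    """
    rng = np.random.default_rng(seed)
    subjects = list(expression.columns)
    eta = np.zeros(len(subjects))
    for gene, beta in betas.items():
        x = expression.loc[gene].to_numpy(dtype=float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        eta += beta * z
    rates = base_rate * np.exp(eta)
    event_time = rng.exponential(1.0 / rates)
    if censoring_rate > 0:
        c = _censoring_scale(rates, censoring_rate)
        censor_time = rng.exponential(1.0 / c, size=len(subjects))
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time, event = event_time, np.ones(len(subjects), dtype=int)
    out = pd.DataFrame({"subject_id": subjects, "time": time, "event": event})
    for gene in betas:
        out[gene] = expression.loc[gene].to_numpy(dtype=float)
    return out


def default_scenario(seed: int, n_genes: int = 2000, samples_per_arm: int = 20,
                     effect_size: float = 2.0, noise_sd: float = 1.0
                     ) -> SimulationConfig:
    """A standard planted scenario exercising every pipeline stage.

    Plants 12 common winners (consistent in 9/10 LC and some BC/LK datasets),
    6 unique-LC winners (8/10 LC, nothing elsewhere), two 10-gene coexpression
    modules over the first winner genes plus neighbours, TF labels on half of
    the winners, and survival effects on three winner TFs.
    """
    width = len(str(n_genes))

    def g(i: int) -> str:
        return f"G{i:0{width}d}"

    winners: list[PlantedWinner] = []
    for i in range(12):  # common winners: seen in LC and in other groups
        direction = "up" if i % 2 == 0 else "down"
        winners.append(PlantedWinner(
            gene=g(i + 1), direction=direction,
            fractions={"LC": 0.9, "BC": 0.6, "LK": 0.4},
            effect_size=effect_size, is_tf=(i % 2 == 0)))
    for i in range(6):  # unique-LC winners: no effect outside LC
        direction = "down" if i % 2 == 0 else "up"
        winners.append(PlantedWinner(
            gene=g(13 + i), direction=direction,
            fractions={"LC": 0.8, "BC": 0.0, "LK": 0.0},
            effect_size=effect_size, is_tf=(i < 3)))

    modules = (
        PlantedModule("M1", tuple(g(i) for i in range(1, 11)), correlation=0.9),
        PlantedModule("M2", tuple(g(i) for i in range(21, 31)), correlation=0.9),
    )
    betas = {g(1): np.log(3.0), g(3): np.log(2.0), g(13): -np.log(2.0)}
    return SimulationConfig(
        seed=seed, n_genes=n_genes, samples_per_arm=samples_per_arm,
        winners=tuple(winners), modules=modules, noise_sd=noise_sd,
        survival_betas=betas)
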