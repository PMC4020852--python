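"""Synthetic data with planted ground truth for every pipeline stage.

Three generators mirror the three arms of the study design:

* :func:`simulate_attribution_dataset` — a ligand-stimulation microarray
  experiment over a receptor design matrix, with response genes planted
  per receptor: treated fluorescence is multiplied by the effect size in
  every receptor-positive cell line and left at baseline elsewhere.
* :func:`simulate_cohort` — paired tumor-marker values with a target
  Spearman correlation via a Gaussian copula over lognormal marginals.
* :func:`simulate_intervention` — two-group (vehicle/treated) positive
  measurements with specified means and coefficient of variation.

Noise is multiplicative lognormal throughout: fluorescence and
concentrations are positive quantities whose measurement error scales
with the signal. A generator parameterized by coefficient of variation
(CV) keeps the noise level interpretable; CV = 0 degenerates to exact
means, which the recovery oracles rely on.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionExperiment, ReceptorDesign

#: baseline fluorescence of an unregulated probe set, arbitrary linear units
DEFAULT_BASELINE = 500.0
#: two hybridizations per (line, condition), matching duplicate-array designs
DEFAULT_REPLICATES = 2


@dataclass
class SimulationConfig:
    """Ground-truth parameters of a planted attribution experiment.

    ``n_planted_per_receptor`` genes are planted for every receptor that
    has at least one positive line; the planted sets are disjoint.
    ``n_context_specific`` extra genes respond in a single cell line only
    (cell-type-specific responses, the confounder the minimum-positive-line
    rule guards against). ``noise_cv`` is the coefficient of variation of
    the multiplicative lognormal noise applied independently to every
    array measurement.
    """

    design: ReceptorDesign
    n_genes: int = 1000
    n_planted_per_receptor: int = 50
    effect_size: float = 2.0
    noise_cv: float = 0.05
    n_duplicate_probesets: int = 1
    n_replicates: int = DEFAULT_REPLICATES
    baseline_mean: float = DEFAULT_BASELINE
    n_context_specific: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect_size must be strictly positive")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be strictly positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.n_duplicate_probesets < 1 or self.n_replicates < 1:
            raise ValueError("need at least one probe set and one replicate")
        if len(self.design.receptors) < 1 or len(self.design.cell_lines) < 1:
            raise ValueError("design needs >=1 receptor and >=1 cell line")


@dataclass
class PlantedTruth:
    """Which genes were planted for which receptor, and their probe sets."""

    receptor_genes: dict[str, frozenset[str]]
    gene_probe_sets: dict[str, tuple[str, ...]]
    context_specific: dict[str, str] = field(default_factory=dict)  # gene -> line

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for receptor, genes in self.receptor_genes.items():
            overlap = seen & set(genes)
            if overlap:
                raise ValueError(
                    f"planted gene sets overlap at {sorted(overlap)}")
            seen |= set(genes)
        for gene in seen:
            if not self.gene_probe_sets.get(gene):
                raise ValueError(f"planted gene {gene!r} has no probe sets")

    def annotation(self) -> dict[str, str]:
        """Probe-set -> gene map covering every simulated gene."""
        return {ps: gene for gene, pss in self.gene_probe_sets.items()
                for ps in pss}

    def probe_sets_for(self, receptor: str) -> frozenset[str]:
        return frozenset(ps for g in self.receptor_genes[receptor]
                         for ps in self.gene_probe_sets[g])


def _lognormal_factors(rng: np.random.Generator, cv: float,
                       shape) -> np.ndarray:
    """Unit-mean multiplicative noise with the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv ** 2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=shape)


def simulate_attribution_dataset(config: SimulationConfig
                                 ) -> tuple[ExpressionExperiment, PlantedTruth]:
    """Simulate a full stimulation experiment with planted response genes.

    Control fluorescence of every probe set is ``baseline_mean`` times
    independent lognormal noise. Treated fluorescence carries the same
    baseline times ``effect_size`` for genes planted for receptor R in
    every R-positive line (times 1 elsewhere), again with independent
    noise per array. Duplicate probe sets of a gene are independent noisy
    reporters of the same gene-level signal. Deterministic given the seed.
    """
    cfg = config
    design = cfg.design
    rng = np.random.default_rng(cfg.seed)

    planted_receptors = [r for r in design.receptors
                         if design.positive_lines(r)]
    n_planted_total = (cfg.n_planted_per_receptor * len(planted_receptors)
                       + cfg.n_context_specific)
    if n_planted_total > cfg.n_genes:
        raise ValueError(
            f"cannot plant {n_planted_total} genes among {cfg.n_genes}")

    width = len(str(cfg.n_genes))
    genes = [f"GENE{i:0{width}d}" for i in range(cfg.n_genes)]
    gene_probe_sets = {
        g: tuple(f"{g}_at{j + 1}" for j in range(cfg.n_duplicate_probesets))
        for g in genes
    }

    cursor = 0
    receptor_genes: dict[str, frozenset[str]] = {}
    for r in planted_receptors:
        receptor_genes[r] = frozenset(
            genes[cursor:cursor + cfg.n_planted_per_receptor])
        cursor += cfg.n_planted_per_receptor
    context_specific: dict[str, str] = {}
    lines = design.cell_lines
    for i in range(cfg.n_context_specific):
        context_specific[genes[cursor]] = lines[i % len(lines)]
        cursor += 1
    truth = PlantedTruth(receptor_genes, gene_probe_sets, context_specific)

    # gene x line matrix of treated-over-control effect multipliers
    effect = pd.DataFrame(1.0, index=genes, columns=lines)
    for r, gset in receptor_genes.items():
        for line in design.positive_lines(r):
            effect.loc[list(gset), line] = cfg.effect_size
    for gene, line in context_specific.items():
        effect.loc[gene, line] = cfg.effect_size

    probe_index = [ps for g in genes for ps in gene_probe_sets[g]]
    # per-probe effect rows (duplicate probe sets share the gene signal)
    eff = np.repeat(effect.to_numpy(), cfg.n_duplicate_probesets, axis=0)

    columns = []
    blocks = []
    n_probes = len(probe_index)
    for li, line in enumerate(lines):
        for cond in ("control", "treated"):
            mult = eff[:, li] if cond == "treated" else 1.0
            for rep in range(1, cfg.n_replicates + 1):
                noise = _lognormal_factors(rng, cfg.noise_cv, n_probes)
                blocks.append(cfg.baseline_mean * mult * noise)
                columns.append((line, cond, str(rep)))
    values = pd.DataFrame(
        np.column_stack(blocks), index=pd.Index(probe_index, name="probe_set"),
        columns=pd.MultiIndex.from_tuples(
            columns, names=["cell_line", "condition", "replicate"]))
    exp = ExpressionExperiment(values, metadata={
        "seed": cfg.seed, "noise_cv": cfg.noise_cv,
        "effect_size": cfg.effect_size,
        "n_planted_per_receptor": cfg.n_planted_per_receptor})
    return exp, truth


def simulate_cohort(n: int, rho_target: float,
                    marginal_means: tuple[float, float] = (1.0, 1.0),
                    marginal_cvs: tuple[float, float] = (0.8, 0.8),
                    seed: int = 0) -> pd.DataFrame:
    """Simulate paired marker values with a target Spearman correlation.

    A bivariate Gaussian copula with Pearson parameter
    ``r = 2 sin(pi * rho_s / 6)`` yields population Spearman ``rho_s``
    after the monotone lognormal marginal transforms (the relation is
    exact for the copula; sample estimates fluctuate). The returned table
    carries the normalized markers, a positive housekeeping column, and
    raw columns ``raw_a = marker_a * housekeeping`` (likewise ``raw_b``)
    so the normalization step can be exercised end to end.
    """
    if abs(rho_target) > 1:
        raise ValueError("rho_target must lie in [-1, 1]")
    if n < 3:
        raise ValueError("need n >= 3 samples")
    rng = np.random.default_rng(seed)
    r = 2.0 * np.sin(np.pi * rho_target / 6.0)
    z1 = rng.standard_normal(n)
    z2 = r * z1 + np.sqrt(max(0.0, 1.0 - r ** 2)) * rng.standard_normal(n)

    def marginal(z: np.ndarray, mean: float, cv: float) -> np.ndarray:
        if mean <= 0:
            raise ValueError("marginal means must be positive")
        if cv == 0:
            return np.full_like(z, mean)
        sigma2 = np.log1p(cv ** 2)
        return np.exp(np.log(mean) - sigma2 / 2.0 + np.sqrt(sigma2) * z)

    marker_a = marginal(z1, marginal_means[0], marginal_cvs[0])
    marker_b = marginal(z2, marginal_means[1], marginal_cvs[1])
    housekeeping = marginal(rng.standard_normal(n), 1.0, 0.1)
    return pd.DataFrame({
        "marker_a": marker_a,
        "marker_b": marker_b,
        "housekeeping": housekeeping,
        "raw_a": marker_a * housekeeping,
        "raw_b": marker_b * housekeeping,
    }, index=pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample_id"))


def simulate_intervention(n_per_group: int, mean_control: float,
                          mean_treated: float, cv: float,
                          seed: int = 0) -> pd.DataFrame:
    """Simulate a two-group animal experiment.

    Lognormal measurements with the stated group means and common CV;
    ``cv = 0`` gives every animal exactly the group mean.
    """
    if mean_control <= 0 or mean_treated <= 0:
        raise ValueError("group means must be positive")
    if n_per_group < 1:
        raise ValueError("need at least one animal per group")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)

    def draws(mean: float) -> np.ndarray:
        return mean * _lognormal_factors(rng, cv, n_per_group)

    veh = draws(mean_control)
    trt = draws(mean_treated)
    return pd.DataFrame({
        "animal_id": [f"V{i + 1}" for i in range(n_per_group)]
        + [f"T{i + 1}" for i in range(n_per_group)],
        "group": ["vehicle"] * n_per_group + ["treated"] * n_per_group,
        "measurement": np.concatenate([veh, trt]),
    })
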