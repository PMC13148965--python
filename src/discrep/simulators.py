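"""Irreplicability simulators and replicate experiments.

Two generators reproduce canonical ways multi-study summaries go wrong:

* **Batch-effect contamination** — case-control experiments on a
  quantitative trait in which a subset of experiments carries a batch
  covariate confounded with case status; the per-experiment analysis
  (OLS of trait on case status, batch term omitted) yields inflated,
  heterogeneous effect estimates.
* **Publication-bias selection** — binary-outcome studies whose inclusion
  probability decays with the study's P-value, ``exp(-c * p^(3/2))``,
  skewing the collected funnel of log odds ratios.

Defaults follow the study designs these scenarios emulate: 10 experiments
of 100 individuals with 4 contaminated (batch), and 20 studies with
sample sizes 10x100 / 6x200 / 4x240 (publication bias), both with a
low-level intrinsic heterogeneity of k = 0.25 around the generating
effect.  ``run_experiment`` repeats a scenario, computes a posterior-PRP
per replicate dataset, and reports the proportion flagged at the 0.05
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import special, stats

from .effects import EffectTable
from .reference_model import MCMCConfig, posterior_prp
from .statistics import StatisticSpec

__all__ = [
    "BatchSimConfig",
    "PubBiasSimConfig",
    "ExperimentReport",
    "simulate_batch_dataset",
    "simulate_pubbias_dataset",
    "simulate_reference_dataset",
    "run_experiment",
]


@dataclass(frozen=True)
class BatchSimConfig:
    """Batch-effect scenario: m case-control experiments, some contaminated.

    ``eta`` scales the batch coefficient (``beta_batch ~ N(0, eta^2)``);
    ``eta = 0`` recovers the contamination-free reference scenario.  The
    per-experiment true effect is drawn as ``N(beta_true_mean,
    k^2 beta_true_mean^2)``; set ``share_beta_true`` to draw it once per
    dataset instead.
    """

    m: int = 10
    n_per_experiment: int = 100
    n_contaminated: int = 4
    case_prob: float = 0.4
    label_agreement: float = 0.8
    beta_true_mean: float = 0.1
    k: float = 0.25
    eta: float = 0.0
    share_beta_true: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.n_contaminated <= self.m:
            raise ValueError("n_contaminated must be between 0 and m")
        for name in ("case_prob", "label_agreement"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.eta < 0:
            raise ValueError("eta must be nonnegative")


@dataclass(frozen=True)
class PubBiasSimConfig:
    """Publication-bias scenario: selected binary-outcome studies.

    Selection keeps a candidate study with probability
    ``exp(-c * p^(3/2))``; rejected slots are regenerated at the same
    sample size until the full set is collected.  ``c = 0`` disables
    selection.
    """

    sample_sizes: tuple = (100,) * 10 + (200,) * 6 + (240,) * 4
    control_frac: float = 0.6
    log_or_mean: float = math.log(2.0 / 3.0)
    k: float = 0.25
    u_range: tuple = (0.6, 0.9)
    c: float = 0.0
    max_attempts_per_study: int = 100_000

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("selection strength c must be nonnegative")
        if not 0.0 < self.control_frac < 1.0:
            raise ValueError("control_frac must be in (0, 1)")

    @property
    def n_studies(self) -> int:
        return len(self.sample_sizes)


@dataclass(frozen=True)
class ExperimentReport:
    """Posterior-PRPs over scenario replicates with the flagged proportion."""

    prps: np.ndarray
    threshold: float
    flagged_proportion: float
    n_replicates: int
    mean_prp: float
    posterior_beta_means: np.ndarray
    mean_posterior_beta_bar: float
    mean_acceptance_ratio: float
    statistic_name: str
    seed: int


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Slope and standard error of OLS of y on x with intercept."""
    n = x.size
    xc = x - x.mean()
    sxx = float(xc @ xc)
    b = float(xc @ y) / sxx
    resid = y - y.mean() - b * xc
    s2 = float(resid @ resid) / (n - 2)
    return b, math.sqrt(s2 / sxx)


def simulate_batch_dataset(
    config: BatchSimConfig, rng: np.random.Generator
) -> EffectTable:
    """One batch-effect dataset: m per-experiment (beta_hat, se) rows.

    Per experiment: case labels x ~ Bernoulli(case_prob); batch labels
    agree with x for ~``label_agreement`` of individuals; trait
    ``y = beta_true * x + beta_batch * cbatch + eps`` with unit Gaussian
    noise (batch term only in the first ``n_contaminated`` experiments).
    The returned effects are the OLS coefficients of y on x alone — the
    analysis a practitioner unaware of the batch structure would run.
    """
    n = config.n_per_experiment
    beta_hat = np.empty(config.m)
    se = np.empty(config.m)
    shared = rng.normal(config.beta_true_mean, config.k * abs(config.beta_true_mean))
    for j in range(config.m):
        while True:
            x = (rng.random(n) < config.case_prob).astype(float)
            if 0.0 < x.mean() < 1.0:
                break
        beta_true = (
            shared
            if config.share_beta_true
            else rng.normal(config.beta_true_mean, config.k * abs(config.beta_true_mean))
        )
        y = beta_true * x + rng.standard_normal(n)
        if j < config.n_contaminated and config.eta > 0:
            agree = rng.random(n) < config.label_agreement
            cbatch = np.where(agree, x, 1.0 - x)
            y = y + rng.normal(0.0, config.eta) * cbatch
        beta_hat[j], se[j] = _ols_slope(x, y)
    return EffectTable(beta_hat=beta_hat, se=se)


def _fit_two_group_logit(
    y_case: int, n_case: int, y_ctrl: int, n_ctrl: int
) -> Optional[tuple[float, float, float]]:
    """Logistic-regression slope for a binary covariate, from the 2x2 table.

    With a single binary predictor the maximum-likelihood slope is the
    sample log odds ratio and its Wald standard error is
    sqrt(sum of reciprocal cell counts).  Returns None on separation
    (any empty cell), where the MLE is not finite.
    """
    a, b = y_case, n_case - y_case
    c, d = y_ctrl, n_ctrl - y_ctrl
    if min(a, b, c, d) == 0:
        return None
    beta = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    p = 2.0 * stats.norm.sf(abs(beta / se))
    return beta, se, p


def simulate_pubbias_dataset(
    config: PubBiasSimConfig, rng: np.random.Generator
) -> EffectTable:
    """One publication-bias dataset of selected binary-outcome studies.

    For each study slot: draw a baseline rate u ~ Uniform(u_range) giving
    the intercept logit(u), a treatment log odds ratio
    ``N(log_or_mean, k^2 log_or_mean^2)``, simulate Bernoulli outcomes for
    the control/treatment groups, fit the logistic model, and keep the
    study with probability ``exp(-c * p^(3/2))``; otherwise regenerate at
    the same sample size.  Separated fits are regenerated as well.
    """
    m = config.n_studies
    beta_hat = np.empty(m)
    se = np.empty(m)
    for j, n in enumerate(config.sample_sizes):
        n_ctrl = round(config.control_frac * n)
        n_case = n - n_ctrl
        for _ in range(config.max_attempts_per_study):
            u = rng.uniform(*config.u_range)
            b0 = math.log(u / (1.0 - u))
            bt = rng.normal(config.log_or_mean, config.k * abs(config.log_or_mean))
            y_ctrl = rng.binomial(n_ctrl, special.expit(b0))
            y_case = rng.binomial(n_case, special.expit(b0 + bt))
            fit = _fit_two_group_logit(y_case, n_case, y_ctrl, n_ctrl)
            if fit is None:
                continue
            beta, s, p = fit
            if rng.random() < math.exp(-config.c * p**1.5):
                beta_hat[j], se[j] = beta, s
                break
        else:
            raise RuntimeError(
                f"study {j}: no candidate accepted in "
                f"{config.max_attempts_per_study} attempts (c={config.c})"
            )
    return EffectTable(beta_hat=beta_hat, se=se)


def simulate_reference_dataset(
    m: int,
    beta_bar: float,
    k: float,
    se: np.ndarray | float,
    rng: np.random.Generator,
) -> EffectTable:
    """Draw an effect table directly from the reference replicability model.

    ``beta_j ~ N(beta_bar, k^2 beta_bar^2)``, then
    ``beta_hat_j ~ N(beta_j, se_j^2)``.
    """
    se = np.broadcast_to(np.asarray(se, dtype=float), (m,)).copy()
    betas = rng.normal(beta_bar, k * abs(beta_bar), size=m)
    return EffectTable(beta_hat=rng.normal(betas, se), se=se)


def run_experiment(
    scenario: Union[BatchSimConfig, PubBiasSimConfig],
    stat: StatisticSpec,
    replicates: int,
    mcmc: MCMCConfig,
    threshold: float = 0.05,
) -> ExperimentReport:
    """Repeat a scenario and summarize its posterior-PRP distribution.

    Per-replicate RNG streams and sampler seeds derive deterministically
    from ``mcmc.seed``, so the whole experiment reproduces from one master
    seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if isinstance(scenario, BatchSimConfig):
        simulate = simulate_batch_dataset
    elif isinstance(scenario, PubBiasSimConfig):
        simulate = simulate_pubbias_dataset
    else:
        raise TypeError(f"unsupported scenario type {type(scenario).__name__}")

    master = np.random.SeedSequence(int(mcmc.seed))
    data_seeds, chain_seeds = master.spawn(2)
    data_streams = [np.random.default_rng(s) for s in data_seeds.spawn(replicates)]
    chain_ints = chain_seeds.generate_state(replicates) % (2**31)

    prps = np.empty(replicates)
    beta_means = np.empty(replicates)
    acc = np.empty(replicates)
    for r in range(replicates):
        try:
            data = simulate(scenario, data_streams[r])
            result = posterior_prp(
                data,
                stat,
                MCMCConfig(
                    iterations=mcmc.iterations,
                    burn_in_rate=mcmc.burn_in_rate,
                    seed=int(chain_ints[r]),
                    proposal_scale_beta=mcmc.proposal_scale_beta,
                    proposal_scale_nu=mcmc.proposal_scale_nu,
                    point_estimate_stat=mcmc.point_estimate_stat,
                    fix_k_zero=mcmc.fix_k_zero,
                ),
            )
        except Exception as exc:  # noqa: BLE001 - annotate replicate index
            raise RuntimeError(f"replicate {r} failed: {exc}") from exc
        prps[r] = result.prp
        beta_means[r] = float(np.mean(result.diagnostics.trace["beta_bar"]))
        acc[r] = result.diagnostics.acceptance_ratio
    return ExperimentReport(
        prps=prps,
        threshold=threshold,
        flagged_proportion=float(np.mean(prps <= threshold)),
        n_replicates=replicates,
        mean_prp=float(prps.mean()),
        posterior_beta_means=beta_means,
        mean_posterior_beta_bar=float(beta_means.mean()),
        mean_acceptance_ratio=float(acc.mean()),
        statistic_name=stat.name,
        seed=int(mcmc.seed),
    )
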