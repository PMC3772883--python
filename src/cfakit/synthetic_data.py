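"""Ground-truth generators for every input the pipeline needs.

Real standardization correlation tables for commercial test batteries are
proprietary, so the package generates surrogates with known truth instead:

* exact implied population matrices (no sampling noise),
* finite-N sample correlation matrices from multivariate-normal draws, and
* a three-band battery emulating a standardization design — one estimation
  band (N=1000) plus two generalization bands (N=400 each) whose free
  loadings are perturbed to mimic cross-population drift.

The default ground truth is the published modified-CHC loading set over the
15 adult-battery subtests (`MODIFIED_CHC_WEIGHTS`), the most completely
printed parameter set available; the modified six-independent-factor set is
available as an alternative.  Uniquenesses are always completed so the
population diagonal is exactly 1.  All randomness flows through explicit
integer seeds; one named generator per operation call, no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corr_data import CorrelationSample
from .estimator import ParamLayout
from .model_spec import (
    SUBTESTS,
    FactorModelSpec,
    FactorStructure,
    LoadingPattern,
    MODIFIED_6INDEP_WEIGHTS,
    MODIFIED_CHC_WEIGHTS,
    build_catalog,
    k_orthogonal,
)

__all__ = [
    "SyntheticConfig",
    "InfeasibleParameterError",
    "modified_chc_truth",
    "modified_6indep_truth",
    "exact_population_matrix",
    "sample_matrix",
    "wais_like_battery",
    "six_equal_factor_sim",
]


class InfeasibleParameterError(ValueError):
    """Structural variance reaches or exceeds 1 before adding uniqueness."""


@dataclass(frozen=True)
class SyntheticConfig:
    """A generating model: spec + structural parameter values.

    ``true_params`` covers the loading and factor-structure blocks of the
    spec's parameter vector; uniquenesses are completed automatically so
    the population diagonal is exactly 1.
    """

    spec: FactorModelSpec
    true_params: np.ndarray
    n_obs: int = 1000
    n_populations: int = 1
    perturbation_sd: float = 0.0
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.perturbation_sd < 0:
            raise ValueError("perturbation_sd must be >= 0")
        layout = ParamLayout(self.spec)
        tp = np.asarray(self.true_params, dtype=float)
        if tp.shape != (layout.nl + layout.ns,):
            raise ValueError(
                f"true_params must cover the {layout.nl + layout.ns} structural "
                f"parameters, got {tp.size}"
            )
        object.__setattr__(self, "true_params", tp)


def _population_matrix(spec: FactorModelSpec, structural: np.ndarray) -> np.ndarray:
    """Implied matrix with uniquenesses completing the diagonal to 1."""
    layout = ParamLayout(spec)
    theta = np.concatenate([structural, np.zeros(layout.p)])
    common = layout.sigma(theta)
    h2 = np.diag(common).copy()
    if np.any(h2 >= 1.0):
        i = int(np.argmax(h2))
        raise InfeasibleParameterError(
            f"structural variance of {spec.pattern.row_labels[i]!r} is "
            f"{h2[i]:.4f} >= 1; no non-negative uniqueness completes the diagonal"
        )
    Sigma = common + np.diag(1.0 - h2)
    return (Sigma + Sigma.T) / 2.0


def full_true_vector(config: SyntheticConfig) -> np.ndarray:
    """Complete parameter vector (structural + completing uniquenesses)."""
    layout = ParamLayout(config.spec)
    theta = np.concatenate([config.true_params, np.zeros(layout.p)])
    h2 = np.diag(layout.sigma(theta)).copy()
    theta[layout.theta_sl] = 1.0 - h2
    return theta


def modified_chc_truth() -> SyntheticConfig:
    """Default generating model: the published modified-CHC solution."""
    catalog = build_catalog()
    spec = catalog["modified_chc"]
    layout = ParamLayout(spec)
    params = MODIFIED_CHC_WEIGHTS[layout.free_rows, layout.free_cols]
    return SyntheticConfig(spec=spec, true_params=params, label="modified_chc truth")


def modified_6indep_truth() -> SyntheticConfig:
    """Alternative generating model: the six-independent-factor solution."""
    catalog = build_catalog()
    spec = catalog["modified_6indep"]
    layout = ParamLayout(spec)
    params = MODIFIED_6INDEP_WEIGHTS[layout.free_rows, layout.free_cols]
    return SyntheticConfig(spec=spec, true_params=params, label="modified_6indep truth")


def exact_population_matrix(config: SyntheticConfig) -> CorrelationSample:
    """The implied population matrix itself, packaged as a noise-free sample."""
    Sigma = _population_matrix(config.spec, config.true_params)
    return CorrelationSample(
        names=config.spec.pattern.row_labels,
        R=Sigma,
        n_obs=config.n_obs,
        label=config.label,
    )


def sample_matrix(config: SyntheticConfig, seed: int | None = None) -> CorrelationSample:
    """Pearson correlations of N multivariate-normal draws from the truth."""
    p = config.spec.p
    if config.n_obs <= p:
        raise ValueError(f"n_obs={config.n_obs} must exceed p={p}")
    Sigma = _population_matrix(config.spec, config.true_params)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    L = np.linalg.cholesky(Sigma)
    X = rng.standard_normal((config.n_obs, p)) @ L.T
    R = np.corrcoef(X, rowvar=False)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return CorrelationSample(
        names=config.spec.pattern.row_labels,
        R=R,
        n_obs=config.n_obs,
        label=config.label,
    )


def _perturbed(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Structural parameters with additive Gaussian drift on free loadings."""
    layout = ParamLayout(config.spec)
    params = config.true_params.copy()
    params[: layout.nl] += rng.normal(0.0, config.perturbation_sd, layout.nl)
    return params


def wais_like_battery(
    seed: int,
    perturbation_sd: float = 0.03,
    n_core: int = 1000,
    n_outer: int = 400,
) -> list[CorrelationSample]:
    """Three-band surrogate standardization design over the 15 subtests.

    Band "ages 20-54" (N=1000) is drawn from the modified-CHC truth; bands
    "ages 16-19" and "ages 55-69" (N=400 each) are drawn from copies of the
    truth whose free loadings received independent N(0, perturbation_sd)
    drift, with uniquenesses re-completed to unit diagonal.  With
    ``perturbation_sd=0`` all three bands share one population matrix.
    """
    base = modified_chc_truth()
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(5)
    bands = []
    core = SyntheticConfig(
        spec=base.spec, true_params=base.true_params,
        n_obs=n_core, label="ages 20-54",
    )
    bands.append(sample_matrix(core, seed=int(kids[0].generate_state(1)[0] % 2**31)))
    for label, kid_p, kid_s in (
        ("ages 16-19", kids[1], kids[2]),
        ("ages 55-69", kids[3], kids[4]),
    ):
        rng = np.random.default_rng(kid_p)
        params = base.true_params.copy()
        layout = ParamLayout(base.spec)
        params[: layout.nl] += rng.normal(0.0, perturbation_sd, layout.nl)
        cfg = SyntheticConfig(
            spec=base.spec, true_params=params, n_obs=n_outer, label=label
        )
        bands.append(sample_matrix(cfg, seed=int(kid_s.generate_state(1)[0] % 2**31)))
    return bands


def six_equal_factor_sim(
    loading: float,
    n_obs: int,
    seed: int,
    n_tests: int = 15,
    exact: bool = False,
) -> CorrelationSample:
    """Six orthogonal factors of equal positive loading on every test.

    The population matrix is exchangeable: every off-diagonal equals
    6 * loading^2 and every uniqueness 1 - 6 * loading^2.  Used to probe
    how a fully crossed orthogonal fit absorbs variance into a dominant
    general factor with mixed-sign secondary factors.  ``exact=True``
    returns the population matrix itself.
    """
    if not 6.0 * loading**2 < 1.0:
        raise ValueError("need 6 * loading^2 < 1 for positive uniquenesses")
    spec = k_orthogonal(6, tuple(f"T{i + 1}" for i in range(n_tests)))
    layout = ParamLayout(spec)
    cfg = SyntheticConfig(
        spec=spec,
        true_params=np.full(layout.nl, loading),
        n_obs=n_obs,
        seed=seed,
        label="six equal orthogonal factors",
    )
    return exact_population_matrix(cfg) if exact else sample_matrix(cfg)
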