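"""Stepwise model modification driven by Lagrange-multiplier and Wald tests.

At a converged fit, two one-parameter projections are available without
refitting:

* the Lagrange-multiplier (score) statistic for freeing a currently fixed
  loading cell — the squared score divided by its information, partialed
  for the free parameters; and
* the Wald statistic for fixing a currently free loading — the squared
  estimate over its sampling variance.

Both are referred to a chi-square with 1 df.  The stepwise search mirrors
the classical diagnostic-index workflow: add the largest significant LM
candidate; otherwise drop the smallest non-significant Wald loading; after
every accepted step refit and require the ACTUAL chi-square change to meet
the same criterion, rolling the step back and stopping if it does not.
Candidates are loading cells only (no error covariances or factor
correlations), the per-step alpha is uncorrected, and ties break
lexicographically by (subtest order, factor order) so the search is
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .corr_data import CorrelationSample
from .estimator import (
    ConvergenceError,
    FitResult,
    ParamLayout,
    embed_start,
    expected_information_F,
    fit_model,
    information_matrix,
)
from .model_spec import FactorModelSpec, with_fixed_cell, with_free_cell

__all__ = [
    "ModStep",
    "ModificationLog",
    "lagrange_rank",
    "wald_rank",
    "stepwise_modify",
    "StepwiseModification",
    "candidate_cells",
]


@dataclass(frozen=True)
class ModStep:
    action: str  # "ADD" or "DROP"
    parameter: tuple[str, str]  # (subtest, factor)
    projected_dchi2: float
    actual_dchi2: float
    p_value: float
    accepted: bool


@dataclass
class ModificationLog:
    steps: list[ModStep]
    initial_spec: str
    final_spec: str
    alpha: float
    oscillation: bool = False

    @property
    def n_added(self) -> int:
        return sum(1 for s in self.steps if s.accepted and s.action == "ADD")

    @property
    def n_dropped(self) -> int:
        return sum(1 for s in self.steps if s.accepted and s.action == "DROP")


def candidate_cells(spec: FactorModelSpec) -> list[tuple[str, str]]:
    """FIXED(0) loading cells, in (subtest order, factor order)."""
    pat = spec.pattern
    out = []
    for i, s in enumerate(pat.row_labels):
        for k, f in enumerate(pat.col_labels):
            if not pat.free[i, k] and pat.fixed[i, k] == 0.0:
                out.append((s, f))
    return out


def _free_loading_cells(spec: FactorModelSpec) -> list[tuple[str, str]]:
    pat = spec.pattern
    return [
        (pat.row_labels[i], pat.col_labels[k])
        for i, k in zip(*np.nonzero(pat.free))
    ]


def lagrange_rank(
    fit: FitResult,
    candidates: list[tuple[str, str]] | None = None,
) -> list[tuple[tuple[str, str], float, float]]:
    """Score-test projections for freeing fixed cells, largest first.

    Returns ``[(cell, projected_dchi2, p_value), ...]`` sorted by descending
    statistic (ties broken by cell order).  Parameters held at an active
    bound are excluded from the partialing set.
    """
    if candidates is None:
        candidates = candidate_cells(fit.spec)
    if not candidates:
        return []
    spec_aug = fit.spec
    for s, f in candidates:
        spec_aug = with_free_cell(spec_aug, s, f)
    layout_aug = ParamLayout(spec_aug)
    theta_aug = embed_start(fit, spec_aug)
    S = fit.sample.R
    _, logdet_S = np.linalg.slogdet(S)
    _, g = layout_aug.value_and_grad(theta_aug, S, logdet_S)
    H = expected_information_F(layout_aug, theta_aug)

    names = layout_aug.names
    cand_names = {f"lambda[{s},{f}]": (s, f) for s, f in candidates}
    active = set(fit.active_bounds)
    free_idx = [
        j for j, n in enumerate(names) if n not in cand_names and n not in active
    ]
    scale = (fit.n_obs - 1) / 2.0
    results = []
    Hff = H[np.ix_(free_idx, free_idx)]
    for j, name in enumerate(names):
        if name not in cand_names:
            continue
        hcf = H[j, free_idx]
        try:
            denom = H[j, j] - hcf @ np.linalg.solve(Hff, hcf)
        except np.linalg.LinAlgError:
            warnings.warn(f"singular partial information for {name}; skipped")
            continue
        if denom <= 1e-12:
            warnings.warn(f"non-positive partial information for {name}; skipped")
            continue
        stat = scale * g[j] ** 2 / denom
        stat = max(float(stat), 0.0)
        results.append((cand_names[name], stat, float(stats.chi2.sf(stat, 1))))
    order = {cell: r for r, cell in enumerate(candidates)}
    results.sort(key=lambda t: (-t[1], order[t[0]]))
    return results


def wald_rank(fit: FitResult) -> list[tuple[tuple[str, str], float, float]]:
    """Wald projections for fixing free loadings, smallest first.

    ``(estimate / SE)^2`` per free loading cell from the inverse observed
    information (active-bound parameters excluded), sorted ascending.
    """
    cells = _free_loading_cells(fit.spec)
    if not cells:
        return []
    layout = fit.layout
    info = information_matrix(fit)
    active = set(fit.active_bounds)
    keep = [j for j, n in enumerate(layout.names) if n not in active]
    cov = np.linalg.pinv(info[np.ix_(keep, keep)])
    var = dict(zip((layout.names[j] for j in keep), np.diag(cov)))
    est = dict(zip(layout.names, fit.theta_hat))
    results = []
    for s, f in cells:
        name = f"lambda[{s},{f}]"
        if name not in var:
            continue
        v = var[name]
        if v <= 0:
            warnings.warn(f"zero standard error for {name}; excluded")
            continue
        stat = float(est[name] ** 2 / v)
        results.append(((s, f), stat, float(stats.chi2.sf(stat, 1))))
    order = {cell: r for r, cell in enumerate(cells)}
    results.sort(key=lambda t: (t[1], order[t[0]]))
    return results


def stepwise_modify(
    spec: FactorModelSpec,
    sample: CorrelationSample,
    alpha: float = 0.05,
    max_steps: int = 50,
) -> tuple[FactorModelSpec, ModificationLog]:
    """Run the add/drop search from ``spec`` on ``sample``.

    Returns the final spec and the ordered modification log.  Deterministic
    given its inputs.
    """
    fit = fit_model(spec, sample)
    steps: list[ModStep] = []
    seen: dict[tuple[str, str], int] = {}
    oscillation = False
    current = spec

    for _ in range(max_steps):
        action = None
        lm = lagrange_rank(fit)
        if lm and lm[0][2] < alpha:
            action, cell, proj, pval = "ADD", lm[0][0], lm[0][1], lm[0][2]
        else:
            wald = wald_rank(fit)
            if wald and wald[0][2] >= alpha:
                action, cell, proj, pval = "DROP", wald[0][0], wald[0][1], wald[0][2]
        if action is None:
            break
        seen[cell] = seen.get(cell, 0) + 1
        if seen[cell] > 2:
            oscillation = True
            break
        if action == "ADD":
            new_spec = replace(
                with_free_cell(current, *cell), name=current.name + "+mod"
            )
        else:
            new_spec = replace(
                with_fixed_cell(current, *cell), name=current.name + "+mod"
            )
        try:
            new_fit = fit_model(new_spec, sample, start=embed_start(fit, new_spec))
        except ConvergenceError as err:
            new_fit = err.result
        if action == "ADD":
            actual = fit.chi2 - new_fit.chi2
            ok = stats.chi2.sf(max(actual, 0.0), 1) < alpha
        else:
            actual = new_fit.chi2 - fit.chi2
            ok = stats.chi2.sf(max(actual, 0.0), 1) >= alpha
        steps.append(ModStep(action, cell, proj, float(actual), pval, bool(ok)))
        if not ok:  # roll back and stop
            break
        current, fit = new_fit.spec, new_fit

    final = replace(current, name=spec.name + "_modified")
    log = ModificationLog(
        steps=steps,
        initial_spec=spec.name,
        final_spec=final.name,
        alpha=alpha,
        oscillation=oscillation,
    )
    return final, log


class StepwiseModification:
    """Estimator-style wrapper: ``fit(sample)`` runs the stepwise search.

    Attributes after fitting: ``spec_`` (final spec), ``log_``
    (ModificationLog), ``result_`` (FitResult of the final spec).
    """

    def __init__(self, spec: FactorModelSpec, *, alpha: float = 0.05, max_steps: int = 50):
        self.spec = spec
        self.alpha = alpha
        self.max_steps = max_steps

    def get_params(self, deep: bool = True) -> dict:
        return {"spec": self.spec, "alpha": self.alpha, "max_steps": self.max_steps}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: CorrelationSample, y=None):
        self.spec_, self.log_ = stepwise_modify(
            self.spec, X, alpha=self.alpha, max_steps=self.max_steps
        )
        self.result_ = fit_model(self.spec_, X)
        return self
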