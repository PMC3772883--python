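"""Fixed-loading cross-validation of fitted models to new populations.

A measurement structure estimated in one population generalizes to another
by freezing every structural parameter (loadings, factor covariances,
second-order loadings and disturbances) at its estimates and re-estimating
only the p subtest uniquenesses on the new sample.  Every cross-validated
model therefore has df = p(p+1)/2 - p (105 for a 15-subtest battery)
regardless of its original complexity, so all fit indices rank models
identically within one generalization sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .corr_data import CorrelationSample
from .estimator import FitResult, fit_model
from .fit_indices import compute_indices, null_model_fit
from .model_spec import FactorModelSpec, FactorStructure, LoadingPattern

__all__ = ["fixed_loading_spec", "cross_validate", "generalization_table"]


def fixed_loading_spec(fit: FitResult) -> FactorModelSpec:
    """Spec with all structural parameters of ``fit`` frozen; only Theta free."""
    pat = fit.spec.pattern
    Lam = fit.layout.loadings(fit.theta_hat)
    pattern = LoadingPattern(
        row_labels=pat.row_labels,
        col_labels=pat.col_labels,
        free=np.zeros_like(pat.free),
        fixed=Lam,
    )
    m = pat.m
    structure = FactorStructure("fixed", fixed_phi=fit.phi if m else np.eye(0))
    return FactorModelSpec(
        name=fit.spec.name,
        pattern=pattern,
        structure=structure,
        uniqueness_lower=fit.spec.uniqueness_lower,
    )


def cross_validate(fit: FitResult, new_sample: CorrelationSample) -> FitResult:
    """Refit only the uniquenesses of ``fit`` on ``new_sample``.

    chi^2 uses the new sample's N; the returned df is p(p+1)/2 - p.
    """
    source_names = fit.spec.pattern.row_labels
    if new_sample.names != source_names:
        raise ValueError(
            "variable names of the new sample do not match the fitted model"
        )
    return fit_model(fixed_loading_spec(fit), new_sample)


def generalization_table(
    fits: list[FitResult] | dict[str, FitResult],
    new_sample: CorrelationSample,
) -> pd.DataFrame:
    """Cross-validated index table on ``new_sample``: null row plus one per model."""
    if not isinstance(fits, dict):
        fits = {f.spec.name: f for f in fits}
    null_fit = null_model_fit(new_sample)
    rows = {"Null model": compute_indices(null_fit, null_fit).as_row()}
    for name, fit in fits.items():
        cv = cross_validate(fit, new_sample)
        rows[name] = compute_indices(cv, null_fit).as_row()
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "Model"
    return table
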