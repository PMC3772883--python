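"""SEM fit indices: chi^2, GFI, AGFI, CFI, RMSEA and the legacy CALIS AIC.

Definitions (q = p(p+1)/2 non-redundant moments, N the sample size):

* GFI   = 1 - tr[(Sigma^-1 S - I)^2] / tr[(Sigma^-1 S)^2]   (ML metric)
* AGFI  = 1 - (q / df) (1 - GFI)
* CFI   = 1 - max(chi2 - df, 0) / max(chi2_null - df_null, chi2 - df, 0)
* RMSEA = sqrt(max(chi2 - df, 0) / (df (N - 1)))
* aic_calis = chi2 - 2 df

The Akaike column of classical CALIS output is chi^2 - 2 df, not the
textbook -2 lnL + 2k form; it is named ``aic_calis`` here to avoid the
ambiguity.  The null (independence) model frees only the p uniquenesses,
so for unit-diagonal input its chi^2 has the closed form -(N-1) ln|R|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .corr_data import CorrelationSample
from .estimator import FitResult, fit_model
from .model_spec import null_spec

__all__ = ["FitIndexSet", "compute_indices", "null_model_fit", "gfi_ml", "indices_table"]


@dataclass(frozen=True)
class FitIndexSet:
    chi2: float
    df: int
    gfi: float
    agfi: float
    cfi: float
    rmsea: float
    aic_calis: float

    def as_row(self) -> dict:
        return {
            "df": self.df,
            "X2": self.chi2,
            "GFI": self.gfi,
            "AGFI": self.agfi,
            "CFI": self.cfi,
            "RMSEA": self.rmsea,
            "Akaike's": self.aic_calis,
        }


def gfi_ml(S: np.ndarray, Sigma: np.ndarray) -> float:
    """ML-metric goodness-of-fit index."""
    A = np.linalg.solve(Sigma, S)
    resid = A - np.eye(S.shape[0])
    return float(1.0 - np.trace(resid @ resid) / np.trace(A @ A))


def compute_indices(
    fit: FitResult,
    null_fit: FitResult,
    S: np.ndarray | None = None,
) -> FitIndexSet:
    """Index set for one fitted model against the uniqueness-only null."""
    if fit.n_obs != null_fit.n_obs:
        raise ValueError("fit and null_fit are from samples with different N")
    if S is None:
        if fit.sample is None:
            raise ValueError("fit carries no sample; pass S explicitly")
        S = fit.sample.R
    p = S.shape[0]
    q = p * (p + 1) // 2
    chi2, df, n = fit.chi2, fit.df, fit.n_obs
    gfi = gfi_ml(S, fit.Sigma_hat)
    if df > 0:
        agfi = 1.0 - (q / df) * (1.0 - gfi)
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    else:
        agfi = np.nan
        rmsea = np.nan
    d_model = max(chi2 - df, 0.0)
    denom = max(null_fit.chi2 - null_fit.df, d_model, 0.0)
    cfi = 1.0 - d_model / denom if denom > 0 else 1.0
    return FitIndexSet(
        chi2=chi2, df=df, gfi=gfi, agfi=agfi, cfi=cfi, rmsea=rmsea,
        aic_calis=chi2 - 2.0 * df,
    )


def null_model_fit(sample: CorrelationSample) -> FitResult:
    """Fit the independence model (diagonal Sigma, free uniquenesses)."""
    return fit_model(null_spec(sample.names), sample)


def indices_table(
    fits: dict[str, FitResult],
    null_fit: FitResult | None = None,
    S: np.ndarray | None = None,
) -> pd.DataFrame:
    """Publication-shaped index table: one row per model plus the null row."""
    any_fit = next(iter(fits.values()))
    if null_fit is None:
        if any_fit.sample is None:
            raise ValueError("pass null_fit explicitly when fits carry no sample")
        null_fit = null_model_fit(any_fit.sample)
    rows = {"Null model": compute_indices(null_fit, null_fit, S).as_row()}
    for name, fit in fits.items():
        rows[name] = compute_indices(fit, null_fit, S).as_row()
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "Model"
    return table
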