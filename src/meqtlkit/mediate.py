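"""Sobel mediation of SNP effects between methylation and expression.

Two ordinary least-squares regressions per pair,

    Y = mu1 + beta3 X + beta1 M + eps1        (outcome model)
    M = mu2 + beta2 X + eps2                  (mediator model)

give the Sobel statistic t = beta1 beta2 / sqrt(beta1^2 var(beta2) +
beta2^2 var(beta1)) for the indirect (mediated) effect, with a two-sided
normal p-value, and the mediation proportion rho = beta1 beta2 /
(beta3 + beta1 beta2). Both causal directions are assessed: SME treats
methylation as the mediator of a SNP effect on expression, SEM swaps
mediator and outcome. Inputs are expected to be covariate-residualized and
normalized upstream, so the regressions carry only intercept, exposure and
mediator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

__all__ = ["MediationFit", "fit_mediation", "mediation_proportion",
           "run_both_directions"]


@dataclass
class MediationFit:
    pair_id: str
    direction: str  # "SME" | "SEM"
    beta1: float  # mediator -> outcome (adjusted for exposure)
    beta2: float  # exposure -> mediator
    beta3: float  # exposure -> outcome (adjusted for mediator)
    var_beta1: float
    var_beta2: float
    sobel_t: float
    p: float
    rho: float  # mediation proportion; NaN when undefined
    flags: str = ""
    q: float = float("nan")


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients and their variances for y ~ X (X includes intercept)."""
    XtX = X.T @ X
    coef = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ coef
    dof = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / dof
    var = sigma2 * np.diag(np.linalg.inv(XtX))
    return coef, var


def fit_mediation(
    x: np.ndarray, m: np.ndarray, y: np.ndarray,
    pair_id: str = "", direction: str = "SME",
) -> MediationFit:
    """Sobel test and mediation proportion for one exposure/mediator/outcome
    triple."""
    x = np.asarray(x, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    if not (x.size == m.size == y.size):
        raise ValueError("x, m, y must have equal length")
    if np.ptp(x) == 0:
        raise ValueError("exposure is constant")
    if np.ptp(m) == 0:
        raise ValueError("mediator has zero variance")

    n = x.size
    ones = np.ones(n)
    # outcome model: Y ~ 1 + X + M
    coef_y, var_y = _ols(np.column_stack([ones, x, m]), y)
    beta3, beta1 = float(coef_y[1]), float(coef_y[2])
    var_b1 = float(var_y[2])
    # mediator model: M ~ 1 + X
    coef_m, var_m = _ols(np.column_stack([ones, x]), m)
    beta2 = float(coef_m[1])
    var_b2 = float(var_m[1])

    denom = np.sqrt(beta1**2 * var_b2 + beta2**2 * var_b1)
    t = beta1 * beta2 / denom if denom > 0 else 0.0
    p = max(float(2 * norm.sf(abs(t))), 1e-300)

    flags = []
    total = beta3 + beta1 * beta2
    if total == 0:
        rho = float("nan")
        flags.append("rho_undefined")
    else:
        rho = beta1 * beta2 / total
        if rho < 0 or rho > 1:
            flags.append("inconsistent_mediation")
    return MediationFit(
        pair_id=pair_id, direction=direction,
        beta1=beta1, beta2=beta2, beta3=beta3,
        var_beta1=var_b1, var_beta2=var_b2,
        sobel_t=float(t), p=p, rho=float(rho), flags=";".join(flags),
    )


def mediation_proportion(beta1: float, beta2: float, beta3: float) -> float:
    """rho = beta1*beta2 / (beta3 + beta1*beta2); the share of the total
    exposure effect that flows through the mediator. May fall outside [0, 1]
    under inconsistent mediation (opposing direct and indirect paths)."""
    denom = beta3 + beta1 * beta2
    if denom == 0:
        raise ZeroDivisionError("total effect is zero; rho undefined")
    return beta1 * beta2 / denom


def run_both_directions(
    pairs: pd.DataFrame,
    geno,
    methylation,
    expression,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """SME and SEM mediation for every pair, with per-direction BH q-values.

    ``pairs`` has columns (cpg, gene, snp). The three data sources are
    intersected on their common samples; fewer than 3 overlapping samples is
    an error. Pairs with a zero-variance mediator are skipped with a reason.
    """
    common = [
        s for s in geno.sample_ids
        if s in set(methylation.sample_ids) and s in set(expression.sample_ids)
    ]
    if len(common) < 3:
        raise ValueError(f"only {len(common)} overlapping samples")
    gpos = {s: i for i, s in enumerate(geno.sample_ids)}
    gidx = [gpos[s] for s in common]
    meth = methylation.subset_samples(common)
    expr = expression.subset_samples(common)
    snp_idx = {s: i for i, s in enumerate(geno.snp_ids)}
    m_idx = {f: i for i, f in enumerate(meth.feature_ids)}
    e_idx = {f: i for i, f in enumerate(expr.feature_ids)}

    fits: list[MediationFit] = []
    for _, row in pairs.iterrows():
        pid = f"{row['gene']}:{row['cpg']}"
        x = geno.dosages[gidx, snp_idx[row["snp"]]]
        mv = meth.values[m_idx[row["cpg"]]]
        ev = expr.values[e_idx[row["gene"]]]
        for direction, med, out in (("SME", mv, ev), ("SEM", ev, mv)):
            try:
                fits.append(fit_mediation(x, med, out, pid, direction))
            except ValueError as err:
                fits.append(
                    MediationFit(
                        pair_id=pid, direction=direction,
                        beta1=np.nan, beta2=np.nan, beta3=np.nan,
                        var_beta1=np.nan, var_beta2=np.nan,
                        sobel_t=np.nan, p=np.nan, rho=np.nan,
                        flags=f"skipped:{err}",
                    )
                )

    table = pd.DataFrame([vars(f) for f in fits])
    table["significant"] = False
    for direction in ("SME", "SEM"):
        mask = (table["direction"] == direction) & table["p"].notna()
        if mask.any():
            rej, q, _, _ = multipletests(
                table.loc[mask, "p"], alpha=fdr, method="fdr_bh"
            )
            table.loc[mask, "q"] = q
            table.loc[mask, "significant"] = rej
    return table
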