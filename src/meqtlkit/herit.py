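"""Heritability estimation and cis/trans partitioning by restricted maximum
likelihood with two genetic variance components.

Model: y = mu + g_c + g_t + e with g_c ~ MVN(0, sigma_c^2 K_cis),
g_t ~ MVN(0, sigma_t^2 K_trans), e ~ MVN(0, sigma_e^2 I). K_cis is built
from the SNPs inside the feature's cis window and K_trans from all remaining
SNPs. Average-information REML updates with step halving and boundary
clamping at zero; PVE fractions weight each component by the mean diagonal
of its relatedness matrix, so they are invariant to GRM scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .containers import GenotypeSet, KinshipMatrix
from .relate import centered_grm

__all__ = ["PveEstimate", "partition_pve", "cis_trans_grms"]


@dataclass
class PveEstimate:
    feature: str
    pve_total: float
    pve_cis: float
    pve_trans: float
    var_cis: float
    var_trans: float
    var_resid: float
    se_var: tuple
    converged: bool
    n_iter: int
    loglik: float


def _reml_loglik(theta, comps, y, X):
    n = y.size
    V = sum(t * K for t, K in zip(theta[:-1], comps)) + theta[-1] * np.eye(n)
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf, None
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_y = cho_solve((c, low), y)
    Vi_X = cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    sign, logdetX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf, None
    b = np.linalg.solve(XtViX, X.T @ Vi_y)
    Py = Vi_y - Vi_X @ b
    ll = -0.5 * (logdetV + logdetX + float(y @ Py))
    return ll, ((c, low), Vi_X, XtViX, Py)


def partition_pve(
    y: np.ndarray,
    K_cis: KinshipMatrix | np.ndarray,
    K_trans: KinshipMatrix | np.ndarray,
    feature: str = "",
    max_iter: int = 60,
    tol: float = 1e-6,
) -> PveEstimate:
    """AI-REML fit of the two-component model and the PVE partition.

    An all-zero component matrix (e.g. no trans SNPs) degenerates gracefully
    to the single-component fit. Negative variance updates are clamped at
    the zero boundary; non-convergence returns the last iterate flagged.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    Kc = K_cis.K if isinstance(K_cis, KinshipMatrix) else np.asarray(K_cis, float)
    Kt = K_trans.K if isinstance(K_trans, KinshipMatrix) else np.asarray(K_trans, float)

    comps, labels = [], []
    for K, lab in ((Kc, "cis"), (Kt, "trans")):
        if np.abs(K).max() > 0:
            comps.append(K)
            labels.append(lab)

    vy = max(float(np.var(y)), 1e-12)
    k = len(comps)
    theta = np.full(k + 1, vy / (k + 1))
    X = np.ones((n, 1))

    ll, aux = _reml_loglik(theta, comps, y, X)
    converged = False
    it = 0
    AI = np.eye(k + 1)
    for it in range(1, max_iter + 1):
        (cf, Vi_X, XtViX, Py) = aux
        mats = comps + [np.eye(n)]
        KPy = [K @ Py for K in mats]

        def P_dot(v):
            Vi_v = cho_solve(cf, v)
            return Vi_v - Vi_X @ np.linalg.solve(XtViX, X.T @ Vi_v)

        PKPy = [P_dot(v) for v in KPy]
        score = np.empty(k + 1)
        for i, K in enumerate(mats):
            Vi_K = cho_solve(cf, K)
            trPK = np.trace(Vi_K) - float(
                np.trace(np.linalg.solve(XtViX, X.T @ Vi_K @ Vi_X))
            )
            score[i] = -0.5 * (trPK - float(Py @ KPy[i]))
        AI = np.empty((k + 1, k + 1))
        for i in range(k + 1):
            for j in range(i, k + 1):
                AI[i, j] = AI[j, i] = 0.5 * float(KPy[i] @ PKPy[j])

        try:
            delta = np.linalg.solve(AI + 1e-10 * np.eye(k + 1), score)
        except np.linalg.LinAlgError:
            delta = score / max(np.abs(score).max(), 1.0)

        step = 1.0
        improved = False
        for _ in range(12):
            cand = np.maximum(theta + step * delta, 0.0)
            # keep the residual variance strictly positive
            cand[-1] = max(cand[-1], 1e-10 * vy)
            ll_new, aux_new = _reml_loglik(cand, comps, y, X)
            if ll_new >= ll - 1e-12:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        if abs(ll_new - ll) < tol and np.abs(cand - theta).max() < tol * vy:
            theta, ll, aux = cand, ll_new, aux_new
            converged = True
            break
        theta, ll, aux = cand, ll_new, aux_new

    theta = np.maximum(theta, 0.0)
    # variance-component SEs from the inverse average information
    try:
        se = tuple(np.sqrt(np.clip(np.diag(np.linalg.inv(AI)), 0, None)))
    except np.linalg.LinAlgError:
        se = tuple(np.full(k + 1, np.nan))

    var = {"cis": 0.0, "trans": 0.0}
    diag_w = {"cis": 1.0, "trans": 1.0}
    for t, K, lab in zip(theta[:-1], comps, labels):
        var[lab] = float(t)
        diag_w[lab] = float(np.mean(np.diag(K)))
    var_e = float(theta[-1])

    gc = var["cis"] * diag_w["cis"]
    gt = var["trans"] * diag_w["trans"]
    denom = gc + gt + var_e
    pve_cis = gc / denom if denom > 0 else 0.0
    pve_trans = gt / denom if denom > 0 else 0.0
    pve_cis = min(max(pve_cis, 0.0), 1.0)
    pve_trans = min(max(pve_trans, 0.0), 1.0 - pve_cis)
    return PveEstimate(
        feature=feature,
        pve_total=pve_cis + pve_trans,
        pve_cis=pve_cis,
        pve_trans=pve_trans,
        var_cis=var["cis"],
        var_trans=var["trans"],
        var_resid=var_e,
        se_var=se,
        converged=converged,
        n_iter=it,
        loglik=float(ll),
    )


def cis_trans_grms(
    geno: GenotypeSet,
    feature_chrom: str,
    feature_pos: int,
    window_bp: int = 50_000,
    maf_min: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardized GRMs from the cis-window SNPs and from all other SNPs.

    Returns (K_cis, K_trans); either may be the zero matrix when no SNP
    falls in (or out of) the window.
    """
    pos = geno.snp_map["pos"].to_numpy()
    chrom = geno.snp_map["chrom"].astype(str).to_numpy()
    in_cis = (chrom == str(feature_chrom)) & (
        np.abs(pos - int(feature_pos)) <= window_bp
    )
    n = geno.n_samples
    out = []
    for mask in (in_cis, ~in_cis):
        if mask.sum() == 0:
            out.append(np.zeros((n, n)))
            continue
        sub = GenotypeSet(
            geno.dosages[:, mask], geno.snp_map.loc[mask], list(geno.sample_ids)
        )
        try:
            out.append(centered_grm(sub, maf_min=maf_min).K)
        except ValueError:
            out.append(np.zeros((n, n)))
    return out[0], out[1]
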