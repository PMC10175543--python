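"""Linear-mixed-model cis-QTL mapping with permutation-based empirical FDR
and forward-backward conditional discovery.

Model per SNP-feature pair:

    y = mu + x beta + u + e,   u ~ MVN(0, sigma_u^2 K),   e ~ MVN(0, sigma_e^2 I)

testing H0: beta = 0 with a Wald statistic (beta/se)^2 ~ chi2_1. The fit is
exact per SNP: a one-time eigendecomposition K = U diag(d) U^T rotates the
model into independent observations with variances sigma_e^2 (lambda d_i + 1),
lambda = sigma_u^2 / sigma_e^2; lambda is optimized on the REML profile
(log10 grid over [-5, 5] plus Brent refinement) and (mu, beta) come from
closed-form GLS. With K = I the fit reduces exactly to ordinary least
squares (same beta, same SE with the n-p denominator).

Feature-level significance uses the minimum cis p-value per feature;
permuting sample labels (one shared permutation per replicate across all
features) yields the empirical null of these minima, from which the FDR at
each candidate threshold is the ratio of expected null calls to observed
calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .containers import GenotypeSet, KinshipMatrix, PhenotypeMatrix

__all__ = [
    "KinshipEigen",
    "LmmResult",
    "fit_lmm_wald",
    "CisScanResult",
    "cis_scan",
    "FdrResult",
    "empirical_fdr_curve",
    "permutation_fdr",
    "ConditionalSet",
    "conditional_stepwise",
]

_LOG10_BOUNDS = (-5.0, 5.0)
_GRID = np.linspace(*_LOG10_BOUNDS, 51)
_GRID_SCALAR = np.linspace(*_LOG10_BOUNDS, 21)
_P_FLOOR = 1e-300


@dataclass
class KinshipEigen:
    """Cached eigendecomposition K = U diag(d) U^T."""

    U: np.ndarray
    d: np.ndarray

    @classmethod
    def from_kinship(cls, kin: KinshipMatrix, psd_tol: float = 1e-8) -> "KinshipEigen":
        d, U = np.linalg.eigh(kin.K)
        if d.min() < -psd_tol:
            raise ValueError(
                f"kinship matrix is not PSD (min eigenvalue {d.min():.3g})"
            )
        return cls(U=U, d=np.clip(d, 0.0, None))


def _as_eigen(K) -> KinshipEigen:
    if isinstance(K, KinshipEigen):
        return K
    if isinstance(K, KinshipMatrix):
        return KinshipEigen.from_kinship(K)
    return KinshipEigen.from_kinship(KinshipMatrix(np.asarray(K),
        [str(i) for i in range(np.asarray(K).shape[0])]))


@dataclass
class LmmResult:
    """Single SNP-feature Wald fit."""

    beta: float
    se: float
    p: float
    log10_lambda: float
    sigma_u2: float
    sigma_e2: float
    degenerate: bool = False


def _reml_crit(t: float, ys: np.ndarray, Xs: np.ndarray, d: np.ndarray) -> float:
    """REML profile criterion in log10(lambda); smaller is better."""
    lam = 10.0**t
    w = 1.0 / (lam * d + 1.0)
    Xw = Xs * w[:, None]
    XtWX = Xs.T @ Xw
    XtWy = Xw.T @ ys
    try:
        coef = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf
    rss = float(ys @ (w * ys) - coef @ XtWy)
    if rss <= 0:
        rss = 1e-300
    n, p = Xs.shape
    sign, logdet = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    return (n - p) * np.log(rss) + np.sum(np.log(lam * d + 1.0)) + logdet


def fit_lmm_wald(
    y: np.ndarray,
    x: np.ndarray,
    K: KinshipMatrix | KinshipEigen | np.ndarray,
    covars: np.ndarray | None = None,
) -> LmmResult:
    """Exact single-SNP LMM Wald test.

    ``covars`` (n x q, without intercept) are additional fixed effects; the
    SNP coefficient is always the last column of the design.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("y and x must have equal length")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; no association test possible")
    eig = _as_eigen(K)
    n = y.size
    cols = [np.ones(n)]
    if covars is not None:
        C = np.atleast_2d(np.asarray(covars, dtype=float))
        if C.shape[0] != n:
            C = C.T
        cols.append(C)
    cols.append(x[:, None] if x.ndim == 1 else x)
    X = np.column_stack(cols)

    ys = eig.U.T @ y
    Xs = eig.U.T @ X
    d = eig.d

    # coarse grid then Brent refinement inside the best bracket
    crits = np.array([_reml_crit(t, ys, Xs, d) for t in _GRID_SCALAR])
    k = int(np.argmin(crits))
    lo = _GRID_SCALAR[max(k - 1, 0)]
    hi = _GRID_SCALAR[min(k + 1, len(_GRID_SCALAR) - 1)]
    res = minimize_scalar(
        _reml_crit, args=(ys, Xs, d), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    t_hat = float(res.x) if res.fun <= crits[k] else float(_GRID_SCALAR[k])

    lam = 10.0**t_hat
    w = 1.0 / (lam * d + 1.0)
    Xw = Xs * w[:, None]
    XtWX = Xs.T @ Xw
    XtWy = Xw.T @ ys
    coef = np.linalg.solve(XtWX, XtWy)
    rss = float(ys @ (w * ys) - coef @ XtWy)
    p_cols = X.shape[1]
    dof = n - p_cols
    degenerate = rss <= 1e-12 * max(float(ys @ (w * ys)), 1e-300)
    sigma_e2 = max(rss, 0.0) / dof
    cov = np.linalg.inv(XtWX) * sigma_e2
    beta = float(coef[-1])
    se = float(np.sqrt(max(cov[-1, -1], 0.0)))
    if degenerate or se == 0.0:
        pval = _P_FLOOR
        se = max(se, np.sqrt(np.finfo(float).tiny))
        degenerate = True
    else:
        pval = max(float(chi2.sf((beta / se) ** 2, df=1)), _P_FLOOR)
    return LmmResult(
        beta=beta, se=se, p=pval, log10_lambda=t_hat,
        sigma_u2=lam * sigma_e2, sigma_e2=sigma_e2, degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# batched cis scan


class _ScanContext:
    """Precomputed state shared across scans (observed + permutations)."""

    def __init__(
        self,
        geno: GenotypeSet,
        kin: KinshipMatrix,
        feature_map: pd.DataFrame,
        window_bp: int,
        maf_min: float,
    ):
        maf = geno.mafs()
        self.snp_keep = maf >= maf_min
        if self.snp_keep.sum() == 0:
            raise ValueError("no SNPs pass the MAF filter")
        self.geno = geno
        self.eig = KinshipEigen.from_kinship(kin)
        self.window_bp = int(window_bp)

        snp_map = geno.snp_map
        self.snp_ids = snp_map.index.to_numpy().astype(str)
        self.snp_pos = snp_map["pos"].to_numpy()
        self.snp_chrom = snp_map["chrom"].astype(str).to_numpy()
        self.maf = maf

        G = geno.dosages
        self.Gs = self.eig.U.T @ G  # rotated dosages
        self.c0 = self.eig.U.T @ np.ones(G.shape[0])
        self.d = self.eig.d

        # per-feature window membership (inclusive on both ends)
        self.windows: dict = {}
        for fid, row in feature_map.iterrows():
            on_chrom = self.snp_chrom == str(row["chrom"])
            idx = np.where(
                on_chrom
                & self.snp_keep
                & (np.abs(self.snp_pos - int(row["pos"])) <= self.window_bp)
            )[0]
            if idx.size:
                self.windows[fid] = idx
        if not self.windows:
            raise ValueError("no feature has any cis-SNP in the window")
        self.feature_map = feature_map

        # grid quantities shared across features
        lam = 10.0**_GRID
        self.Wg = 1.0 / (lam[:, None] * self.d[None, :] + 1.0)  # L x n
        self.grid_logdet_v = np.log(lam[:, None] * self.d[None, :] + 1.0).sum(axis=1)

    def scan_feature(self, ys: np.ndarray, idx: np.ndarray):
        """Wald stats for one rotated phenotype against its window SNPs.

        Returns (beta, se, p, lam_log10) arrays over the window SNPs.
        """
        X = self.Gs[:, idx]  # n x m rotated dosages
        c0 = self.c0
        n = ys.size
        Wg = self.Wg

        A = Wg @ (c0 * c0)               # L
        D = Wg @ (c0 * ys)               # L
        Gy = Wg @ (ys * ys)              # L
        B = Wg @ (c0[:, None] * X)       # L x m
        E = Wg @ (ys[:, None] * X)       # L x m
        F = Wg @ (X * X)                 # L x m

        det = A[:, None] * F - B**2
        bad = det <= 0
        det = np.where(bad, np.nan, det)
        beta = (A[:, None] * E - B * D[:, None]) / det
        mu = (F * D[:, None] - B * E) / det
        rss = Gy[:, None] - (mu * D[:, None] + beta * E)
        rss = np.clip(rss, 1e-300, None)
        crit = (
            (n - 2) * np.log(rss)
            + self.grid_logdet_v[:, None]
            + np.log(det)
        )
        crit = np.where(bad, np.inf, crit)

        k = np.nanargmin(crit, axis=0)  # per-SNP grid argmin
        h = _GRID[1] - _GRID[0]
        t_star = _GRID[k].astype(float)

        def crit_at(tvec: np.ndarray) -> np.ndarray:
            lam_ = 10.0**tvec
            W_ = 1.0 / (lam_[None, :] * self.d[:, None] + 1.0)
            a_ = (W_ * (c0 * c0)[:, None]).sum(axis=0)
            b_ = (W_ * (c0[:, None] * X)).sum(axis=0)
            f_ = (W_ * (X * X)).sum(axis=0)
            d_ = (W_ * (c0 * ys)[:, None]).sum(axis=0)
            e_ = (W_ * (ys[:, None] * X)).sum(axis=0)
            g_ = (W_ * (ys * ys)[:, None]).sum(axis=0)
            det_ = a_ * f_ - b_**2
            bad_ = det_ <= 0
            det_ = np.where(bad_, np.nan, det_)
            beta_ = (a_ * e_ - b_ * d_) / det_
            mu_ = (f_ * d_ - b_ * e_) / det_
            rss_ = np.clip(g_ - (mu_ * d_ + beta_ * e_), 1e-300, None)
            logdet_v = np.log(lam_[None, :] * self.d[:, None] + 1.0).sum(axis=0)
            out = (n - 2) * np.log(rss_) + logdet_v + np.log(det_)
            return np.where(bad_, np.inf, out)

        # successive parabolic refinement around the grid minimum
        delta = h
        c_mid = crit[k, np.arange(len(k))]
        for _ in range(4):
            cm = crit_at(t_star - delta)
            cp = crit_at(t_star + delta)
            denom = cp - 2 * c_mid + cm
            with np.errstate(divide="ignore", invalid="ignore"):
                shift = 0.5 * delta * (cm - cp) / denom
            shift = np.where(
                np.isfinite(shift) & (denom > 0),
                np.clip(shift, -delta, delta), 0.0,
            )
            t_new = np.clip(t_star + shift, *_LOG10_BOUNDS)
            c_new = crit_at(t_new)
            better = c_new <= c_mid
            t_star = np.where(better, t_new, t_star)
            c_mid = np.where(better, c_new, c_mid)
            delta /= 2.0

        # final closed-form GLS at the per-SNP lambda
        lam = 10.0**t_star
        W = 1.0 / (lam[None, :] * self.d[:, None] + 1.0)  # n x m
        a = (W * (c0 * c0)[:, None]).sum(axis=0)
        b = (W * (c0[:, None] * X)).sum(axis=0)
        f = (W * (X * X)).sum(axis=0)
        dd = (W * (c0 * ys)[:, None]).sum(axis=0)
        e = (W * (ys[:, None] * X)).sum(axis=0)
        g = (W * (ys * ys)[:, None]).sum(axis=0)
        det = a * f - b**2
        det = np.where(det > 0, det, np.nan)
        beta = (a * e - b * dd) / det
        mu = (f * dd - b * e) / det
        rss = np.clip(g - (mu * dd + beta * e), 0.0, None)
        sigma_e2 = rss / (n - 2)
        var_beta = sigma_e2 * a / det
        se = np.sqrt(np.clip(var_beta, 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            wald = (beta / se) ** 2
        p = np.where(
            np.isfinite(wald), chi2.sf(np.where(np.isfinite(wald), wald, 0.0), 1),
            np.nan,
        )
        p = np.clip(p, _P_FLOOR, 1.0)
        return beta, se, p, t_star

    def min_p_all(self, pheno_values: np.ndarray, feature_ids) -> pd.DataFrame:
        """Per-feature minimum p-value and argmin SNP (no record assembly)."""
        Ys = (self.eig.U.T @ pheno_values.T).T  # features x n rotated
        rows = []
        fid_to_row = {f: i for i, f in enumerate(feature_ids)}
        for fid, idx in self.windows.items():
            if fid not in fid_to_row:
                continue
            _, _, p, _ = self.scan_feature(Ys[fid_to_row[fid]], idx)
            rows.append((fid, *self._pick_min(fid, idx, p)))
        return pd.DataFrame(
            rows, columns=["feature", "min_p", "best_snp", "n_cis_snps"]
        ).set_index("feature")

    def _pick_min(self, fid, idx, p):
        """Tie-break min-p: smaller |distance|, then lexicographic SNP id."""
        pos = self.snp_pos[idx]
        fpos = int(self.feature_map.loc[fid, "pos"])
        order = np.lexsort((self.snp_ids[idx], np.abs(pos - fpos), p))
        j = order[0]
        return float(p[j]), str(self.snp_ids[idx[j]]), int(idx.size)


@dataclass
class CisScanResult:
    records: pd.DataFrame  # feature, snp, chrom, pos, beta, se, p, maf, dist
    min_p: pd.DataFrame    # per-feature min_p / best_snp / n_cis_snps
    context: "_ScanContext" = field(repr=False, default=None)


def cis_scan(
    pheno: PhenotypeMatrix,
    geno: GenotypeSet,
    kin: KinshipMatrix,
    window_bp: int = 50_000,
    maf_min: float = 0.01,
    context: _ScanContext | None = None,
) -> CisScanResult:
    """Full cis-window LMM Wald scan.

    Emits every SNP test for every feature with at least one cis-SNP
    (features without cis-SNPs are excluded from the analyzed set) plus the
    per-feature minimum-p table. Positions are 1-based and the window
    [pos - W, pos + W] is inclusive on both ends.
    """
    if pheno.sample_ids != geno.sample_ids:
        raise ValueError("phenotype and genotype sample ids do not match")
    ctx = context or _ScanContext(geno, kin, pheno.feature_map, window_bp, maf_min)
    Ys = (ctx.eig.U.T @ pheno.values.T).T

    frames = []
    minp_rows = []
    fid_to_row = {f: i for i, f in enumerate(pheno.feature_ids)}
    for fid, idx in ctx.windows.items():
        if fid not in fid_to_row:
            continue
        beta, se, p, _ = ctx.scan_feature(Ys[fid_to_row[fid]], idx)
        fpos = int(ctx.feature_map.loc[fid, "pos"])
        frames.append(
            pd.DataFrame(
                {
                    "feature": fid,
                    "snp": ctx.snp_ids[idx],
                    "chrom": ctx.snp_chrom[idx],
                    "pos": ctx.snp_pos[idx],
                    "beta": beta,
                    "se": se,
                    "p": p,
                    "maf": ctx.maf[idx],
                    "dist": ctx.snp_pos[idx] - fpos,
                }
            )
        )
        minp_rows.append((fid, *ctx._pick_min(fid, idx, p)))
    records = pd.concat(frames, ignore_index=True)
    min_p = pd.DataFrame(
        minp_rows, columns=["feature", "min_p", "best_snp", "n_cis_snps"]
    ).set_index("feature")
    return CisScanResult(records=records, min_p=min_p, context=ctx)


# ---------------------------------------------------------------------------
# permutation-based empirical FDR


@dataclass
class FdrResult:
    """Permutation-FDR outcome at the feature level.

    ``t_star`` is the largest observed minimum-p threshold whose estimated
    FDR is at or below the target (NaN when nothing passes); ``mecpgs`` are
    the features with min_p <= t_star; ``primary`` maps each to its argmin
    SNP, and ``meqtls`` lists every cis SNP-feature pair with p <= t_star at
    a called feature.
    """

    observed_min_p: pd.DataFrame
    perm_min_p: np.ndarray  # features x permutations
    curve: pd.DataFrame  # threshold -> fdr estimate
    t_star: float
    target_fdr: float
    mecpgs: list = field(default_factory=list)
    primary: dict = field(default_factory=dict)
    meqtls: pd.DataFrame | None = None
    scan: CisScanResult | None = field(repr=False, default=None)


def empirical_fdr_curve(
    observed_min_p: np.ndarray,
    perm_min_p: np.ndarray,
    target_fdr: float,
) -> tuple[pd.DataFrame, float]:
    """Ratio FDR estimator over the observed min-p support.

    FDR(t) = [mean over permutations of #{null min_p <= t}] /
    max(1, #{observed min_p <= t}); the chosen threshold t* is the largest
    observed value whose estimate stays at or below the target (NaN when
    none qualifies). The estimate is monotone non-decreasing in t whenever
    the null and observed distributions are ordered the usual way.
    """
    obs = np.asarray(observed_min_p, dtype=float)
    perm = np.atleast_2d(np.asarray(perm_min_p, dtype=float))
    n_perm = perm.shape[1]
    thresholds = np.unique(obs)
    obs_sorted = np.sort(obs)
    null_sorted = np.sort(perm.ravel())
    n_obs = np.searchsorted(obs_sorted, thresholds, side="right")
    n_null = np.searchsorted(null_sorted, thresholds, side="right") / n_perm
    fdr_hat = n_null / np.maximum(n_obs, 1)
    curve = pd.DataFrame({"threshold": thresholds, "fdr": fdr_hat})
    ok = fdr_hat <= target_fdr
    t_star = float(thresholds[ok].max()) if ok.any() else float("nan")
    return curve, t_star


def permutation_fdr(
    pheno: PhenotypeMatrix,
    geno: GenotypeSet,
    kin: KinshipMatrix,
    window_bp: int = 50_000,
    maf_min: float = 0.01,
    n_perm: int = 10,
    target_fdr: float = 0.05,
    seed: int = 0,
) -> FdrResult:
    """Empirical FDR from permuted sample labels.

    Each permutation shuffles the phenotype sample labels once for the whole
    matrix (preserving inter-feature correlation of the null) and repeats
    the full min-p computation. For threshold t swept over the observed
    minima, FDR(t) = mean_perm #{null min_p <= t} / max(1, #{observed <= t}).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not (0 < target_fdr < 1):
        raise ValueError("target_fdr must lie in (0, 1)")

    scan = cis_scan(pheno, geno, kin, window_bp, maf_min)
    ctx = scan.context
    obs = scan.min_p["min_p"].to_numpy()
    feature_ids = list(pheno.feature_ids)

    rng = np.random.default_rng(seed)
    n = len(pheno.sample_ids)
    perm_mat = np.empty((obs.size, n_perm))
    for r in range(n_perm):
        perm = rng.permutation(n)
        null_minp = ctx.min_p_all(pheno.values[:, perm], feature_ids)
        perm_mat[:, r] = null_minp["min_p"].to_numpy()

    curve, t_star = empirical_fdr_curve(obs, perm_mat, target_fdr)

    result = FdrResult(
        observed_min_p=scan.min_p,
        perm_min_p=perm_mat,
        curve=curve,
        t_star=t_star,
        target_fdr=target_fdr,
        scan=scan,
    )
    if np.isfinite(t_star):
        called = scan.min_p[scan.min_p["min_p"] <= t_star]
        result.mecpgs = list(called.index)
        result.primary = called["best_snp"].to_dict()
        rec = scan.records
        result.meqtls = rec[
            rec["feature"].isin(result.mecpgs) & (rec["p"] <= t_star)
        ].reset_index(drop=True)
    else:
        result.meqtls = scan.records.iloc[0:0]
    return result


# ---------------------------------------------------------------------------
# conditional stepwise selection


@dataclass
class ConditionalSet:
    """Ordered independent signals for one called feature.

    ``snps`` is the selection order (primary first); ``stats`` holds the
    conditional beta/se/p of each retained SNP in the final joint model.
    """

    feature: str
    snps: list[str]
    stats: pd.DataFrame  # snp, beta, se, p in the final joint model
    threshold: float


def conditional_stepwise(
    feature: str,
    y: np.ndarray,
    geno: GenotypeSet,
    kin: KinshipMatrix | KinshipEigen,
    threshold: float,
    window_idx: np.ndarray | None = None,
    max_signals: int = 20,
    collinear_r2: float = 0.999,
    max_rounds: int = 25,
) -> ConditionalSet:
    """Forward-backward stepwise conditional analysis for one feature.

    Forward: repeatedly add the cis-SNP with the smallest conditional
    p-value while that p-value is <= threshold. Backward: re-test each
    included SNP given all the others and drop any that is no longer
    significant; iterate to a fixed point. SNPs whose dosages are collinear
    with the span of the current model (R^2 > ``collinear_r2``) are skipped.
    """
    eig = _as_eigen(kin)
    G = geno.dosages if window_idx is None else geno.dosages[:, window_idx]
    ids = (
        geno.snp_ids.to_numpy()
        if window_idx is None
        else geno.snp_ids.to_numpy()[window_idx]
    )
    y = np.asarray(y, dtype=float)
    n, m = G.shape

    selected: list[int] = []

    def candidate_p(j: int) -> float:
        covars = G[:, selected] if selected else None
        try:
            return fit_lmm_wald(y, G[:, j], eig, covars=covars).p
        except (ValueError, np.linalg.LinAlgError):
            return 1.0

    def collinear(j: int) -> bool:
        if not selected:
            return np.ptp(G[:, j]) == 0
        X = np.column_stack([np.ones(n), G[:, selected]])
        x = G[:, j]
        coef, _, _, _ = np.linalg.lstsq(X, x, rcond=None)
        resid = x - X @ coef
        tot = np.var(x)
        if tot == 0:
            return True
        return 1.0 - resid.var() / tot > collinear_r2

    for _ in range(max_rounds):
        changed = False
        # forward
        while len(selected) < max_signals:
            best_j, best_p = -1, 1.1
            for j in range(m):
                if j in selected or collinear(j):
                    continue
                pj = candidate_p(j)
                if pj < best_p:
                    best_j, best_p = j, pj
            if best_j >= 0 and best_p <= threshold:
                selected.append(best_j)
                changed = True
            else:
                break
        # backward
        dropped = True
        while dropped and len(selected) > 1:
            dropped = False
            for j in list(selected):
                others = [k for k in selected if k != j]
                fit = fit_lmm_wald(y, G[:, j], eig, covars=G[:, others])
                if fit.p > threshold:
                    selected.remove(j)
                    dropped = changed = True
                    break
        if not changed:
            break

    # final joint model statistics
    rows = []
    for j in selected:
        others = [k for k in selected if k != j]
        covars = G[:, others] if others else None
        fit = fit_lmm_wald(y, G[:, j], eig, covars=covars)
        rows.append((str(ids[j]), fit.beta, fit.se, fit.p))
    stats = pd.DataFrame(rows, columns=["snp", "beta", "se", "p"])
    return ConditionalSet(
        feature=feature,
        snps=[str(ids[j]) for j in selected],
        stats=stats,
        threshold=threshold,
    )
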