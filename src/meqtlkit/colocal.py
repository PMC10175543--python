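"""Two-trait Bayes-factor colocalization of QTL signals.

For each SNP the evidence for association with a trait is summarized by the
Wakefield approximate Bayes factor computed from (beta, se): with z =
beta/se, V = se^2 and r = W/(W+V), ABF = sqrt(1-r) * exp(z^2 r / 2) where W
is the prior effect variance. Five hypotheses about a locus shared between
two traits (no association; trait 1 only; trait 2 only; two distinct causal
variants; one shared causal variant) are scored by summing ABF products
over causal-variant assignments, weighted by per-SNP priors p1, p2, p12.
All sums are carried in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "ColocPriors",
    "ColocResult",
    "wakefield_log_abf",
    "coloc_pair",
    "set_priors_from_counts",
    "calibrate_p12",
    "build_pairs",
    "prior_hypothesis_probs",
]

#: coloc's default prior effect s.d. for a quantitative trait
DEFAULT_W = 0.15**2


@dataclass
class ColocPriors:
    """Per-SNP priors: association with trait 1 only (p1), trait 2 only
    (p2), or both (p12)."""

    p1: float
    p2: float
    p12: float
    W: float = DEFAULT_W

    def __post_init__(self):
        if min(self.p1, self.p2, self.p12) <= 0:
            raise ValueError("priors must be strictly positive")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")


@dataclass
class ColocResult:
    pair_id: str
    pp: np.ndarray  # PP0..PP4
    n_snps: int
    log_abf1: np.ndarray = field(repr=False, default=None)
    log_abf2: np.ndarray = field(repr=False, default=None)

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


def wakefield_log_abf(beta, se, W: float = DEFAULT_W):
    """log approximate Bayes factor for association versus the null.

    Vectorized over SNPs; stable for |z| up to hundreds because everything
    stays in log space.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if W < 0:
        raise ValueError("prior variance W must be non-negative")
    V = se**2
    r = W / (W + V)
    z = beta / se
    return 0.5 * np.log1p(-r) + 0.5 * z**2 * r


def _log_sub(a: float, b: float) -> float:
    """log(e^a - e^b), -inf when the difference is non-positive."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_pair(
    beta1, se1, beta2, se2, priors: ColocPriors, pair_id: str = ""
) -> ColocResult:
    """Posterior over the five sharing hypotheses for one locus.

    Inputs are aligned per-SNP (beta, se) for the two traits. The
    unnormalized hypothesis weights are (1, p1*S1, p2*S2, p1*p2*(S1*S2-S12),
    p12*S12) with S1 = sum_i ABF1_i, S2 = sum_i ABF2_i, S12 = sum_i
    ABF1_i*ABF2_i; with a single SNP the two-distinct-variants weight is
    exactly zero.
    """
    lb1 = wakefield_log_abf(beta1, se1, priors.W)
    lb2 = wakefield_log_abf(beta2, se2, priors.W)
    if lb1.size == 0:
        raise ValueError("empty SNP set")
    if lb1.shape != lb2.shape:
        raise ValueError("trait summary statistics are not aligned")

    lS1 = logsumexp(lb1)
    lS2 = logsumexp(lb2)
    lS12 = logsumexp(lb1 + lb2)
    lcross = _log_sub(lS1 + lS2, lS12)  # sum over i != j

    lw = np.array(
        [
            0.0,
            np.log(priors.p1) + lS1,
            np.log(priors.p2) + lS2,
            np.log(priors.p1) + np.log(priors.p2) + lcross,
            np.log(priors.p12) + lS12,
        ]
    )
    pp = np.exp(lw - logsumexp(lw))
    pp /= pp.sum()
    return ColocResult(pair_id=pair_id, pp=pp, n_snps=lb1.size,
                       log_abf1=lb1, log_abf2=lb2)


def set_priors_from_counts(
    n_primary_1: int,
    n_cis_snps_1: int,
    n_primary_2: int,
    n_cis_snps_2: int,
    frac_shared: float,
    W: float = DEFAULT_W,
) -> ColocPriors:
    """Priors from observed QTL discovery rates.

    p1 + p12 is the fraction of examined cis-SNPs that are primary QTLs for
    trait 1 (likewise p2 + p12 for trait 2); p12 = frac_shared * (p1 + p12),
    the prior probability that a trait-1 QTL is also a trait-2 QTL.
    """
    if min(n_primary_1, n_cis_snps_1, n_primary_2, n_cis_snps_2) <= 0:
        raise ValueError("counts must be positive")
    if not (0 < frac_shared < 1):
        raise ValueError("frac_shared must lie in (0, 1)")
    s1 = n_primary_1 / n_cis_snps_1
    s2 = n_primary_2 / n_cis_snps_2
    p12 = frac_shared * s1
    p1 = s1 - p12
    p2 = s2 - p12
    if p1 <= 0 or p2 <= 0:
        raise ValueError("resulting p1 or p2 is non-positive")
    return ColocPriors(p1=p1, p2=p2, p12=p12, W=W)


def prior_hypothesis_probs(n_snps: int, priors: ColocPriors) -> np.ndarray:
    """Prior probability of each hypothesis H0..H4 on an m-SNP locus."""
    m = n_snps
    w = np.array(
        [
            1.0,
            m * priors.p1,
            m * priors.p2,
            m * (m - 1) * priors.p1 * priors.p2,
            m * priors.p12,
        ]
    )
    return w / w.sum()


def calibrate_p12(
    pair_inputs: list[tuple],
    candidate_p12: list[float],
    s1: float,
    s2: float,
    W: float = DEFAULT_W,
) -> tuple[float, pd.DataFrame]:
    """Internal empirical calibration of the sharing prior.

    ``pair_inputs`` is a list of (beta1, se1, beta2, se2) tuples; ``s1`` and
    ``s2`` are the fixed totals p1+p12 and p2+p12. For each candidate p12 the
    mean posterior PP4 across pairs is compared with the mean prior P(H4);
    the candidate whose posterior/prior ratio is nearest 1 on the log scale
    is chosen. When every ratio falls below 1 the data carry less sharing
    than even the smallest prior admits (e.g. pure-null pairs): the smallest
    candidate is returned and the diagnostics carry a warning.
    """
    if not candidate_p12:
        raise ValueError("need at least one candidate p12")
    rows = []
    for p12 in sorted(candidate_p12):
        p1 = s1 - p12
        p2 = s2 - p12
        if p1 <= 0 or p2 <= 0:
            rows.append((p12, np.nan, np.nan, np.nan, False))
            continue
        priors = ColocPriors(p1=p1, p2=p2, p12=p12, W=W)
        post, prior = [], []
        for beta1, se1, beta2, se2 in pair_inputs:
            res = coloc_pair(beta1, se1, beta2, se2, priors)
            post.append(res.pp4)
            prior.append(prior_hypothesis_probs(res.n_snps, priors)[4])
        ratio = float(np.mean(post) / np.mean(prior))
        rows.append((p12, float(np.mean(post)), float(np.mean(prior)), ratio, True))
    diag = pd.DataFrame(
        rows, columns=["p12", "mean_pp4", "mean_prior_h4", "ratio", "valid"]
    )
    valid = diag[diag["valid"] & np.isfinite(diag["ratio"])]
    if valid.empty:
        raise ValueError("no candidate p12 yields valid priors")
    if (valid["ratio"] < 1.0).all():
        chosen = float(valid["p12"].min())
        diag.attrs["warning"] = (
            "posterior sharing far below prior for every candidate; "
            "data may contain no colocalized pairs"
        )
    else:
        chosen = float(
            valid.loc[np.abs(np.log(valid["ratio"])).idxmin(), "p12"]
        )
    diag.attrs["chosen_p12"] = chosen
    return chosen, diag


def build_pairs(
    primary_eqtls: pd.DataFrame,
    meqtl_records: pd.DataFrame,
    meqtl_primary: dict,
    feature_map: pd.DataFrame,
    geno,
    threshold: float,
) -> pd.DataFrame:
    """eGene-meCpG pairs linked by a primary eQTL, pruned by LD.

    ``primary_eqtls`` has columns (gene, snp); ``meqtl_records`` is the
    association table (feature, snp, p); ``meqtl_primary`` maps each meCpG
    to its primary meQTL SNP. For each primary eQTL, every meCpG it is
    significantly associated with (p <= threshold) is a candidate; exactly
    one is kept, the one whose primary meQTL is in highest LD (r^2) with the
    eQTL, ties broken by CpG distance then id.
    """
    G = geno.dosages
    snp_idx = {s: i for i, s in enumerate(geno.snp_ids)}
    snp_pos = dict(zip(geno.snp_ids, geno.snp_map["pos"]))

    def r2(a: str, b: str) -> float:
        if a == b:
            return 1.0
        ga, gb = G[:, snp_idx[a]], G[:, snp_idx[b]]
        if ga.std() == 0 or gb.std() == 0:
            return 0.0
        return float(np.corrcoef(ga, gb)[0, 1] ** 2)

    sig = meqtl_records[meqtl_records["p"] <= threshold]
    rows = []
    for _, erec in primary_eqtls.iterrows():
        esnp = erec["snp"]
        hits = sig[sig["snp"] == esnp]
        if hits.empty:
            continue
        cands = []
        for cpg in hits["feature"].unique():
            msnp = meqtl_primary.get(cpg)
            if msnp is None or msnp not in snp_idx or esnp not in snp_idx:
                continue
            dist = abs(int(feature_map.loc[cpg, "pos"]) - snp_pos.get(esnp, 0))
            cands.append((cpg, msnp, r2(esnp, msnp), dist))
        if not cands:
            continue
        cands.sort(key=lambda c: (-c[2], c[3], c[0]))
        cpg, msnp, rr, _ = cands[0]
        rows.append((erec["gene"], esnp, cpg, msnp, rr))
    return pd.DataFrame(
        rows, columns=["gene", "eqtl_snp", "cpg", "meqtl_snp", "r2"]
    )
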