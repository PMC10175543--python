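"""Cross-study replication (Storey's pi1) and annotation enrichment.

pi1 estimates the fraction of true signals in a set of p-values (those of a
reference study's significant pairs evaluated in the present study):
pi0(lambda) = #{p > lambda} / (n (1 - lambda)) on a lambda grid, smoothed
and read off at the largest lambda; pi1 = 1 - pi0. Enrichment of feature
sets in genomic annotation categories uses Fisher's exact test with the
Woolf confidence interval for the odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact

__all__ = [
    "Pi1Estimate",
    "storey_pi1",
    "EnrichmentResult",
    "fisher_enrichment",
    "annotate_features",
]


@dataclass
class Pi1Estimate:
    pi1: float
    pi0: float
    lambdas: np.ndarray
    pi0_curve: np.ndarray
    method: str  # "smoother" | "fixed"
    n: int


def storey_pi1(
    p_values,
    method: str = "smoother",
    fixed_lambda: float = 0.5,
    lambdas: np.ndarray | None = None,
) -> Pi1Estimate:
    """Replication-rate estimate from a p-value set.

    ``smoother``: pi0(lambda) on lambda in {0.05, ..., 0.95}, a cubic
    least-squares fit through (lambda, pi0(lambda)) evaluated at the largest
    lambda (the qvalue-package convention, with the spline replaced by a
    deterministic cubic polynomial). ``fixed``: the plug-in estimator at a
    single lambda, pi0 = #{p > lambda} / (n (1 - lambda)).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 10:
        raise ValueError("need at least 10 p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")

    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    n = p.size
    pi0_curve = np.array(
        [(p > lam).sum() / (n * (1.0 - lam)) for lam in lambdas]
    )

    if method == "fixed":
        pi0 = (p > fixed_lambda).sum() / (n * (1.0 - fixed_lambda))
    elif method == "smoother":
        coeffs = np.polyfit(lambdas, pi0_curve, deg=3)
        pi0 = float(np.polyval(coeffs, lambdas.max()))
    else:
        raise ValueError(f"unknown method {method!r}")
    pi0 = float(np.clip(pi0, 0.0, 1.0))
    return Pi1Estimate(
        pi1=1.0 - pi0, pi0=pi0, lambdas=np.asarray(lambdas),
        pi0_curve=pi0_curve, method=method, n=n,
    )


@dataclass
class EnrichmentResult:
    label: str
    table: np.ndarray  # [[a, b], [c, d]]: rows in-set/out-set, cols in/out annotation
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    haldane_corrected: bool = False
    degenerate: bool = False


def fisher_enrichment(
    feature_flags, annotation_flags, label: str = ""
) -> EnrichmentResult:
    """Fisher's exact enrichment of a feature set in an annotation.

    OR = ad/bc on the 2x2 table (a = in-set & annotated, d = neither), with
    the Haldane 0.5 correction when any cell is zero; 95% CI by Woolf's
    log-OR formula; two-sided exact p from the hypergeometric distribution.
    """
    fs = np.asarray(feature_flags, dtype=bool)
    an = np.asarray(annotation_flags, dtype=bool)
    if fs.shape != an.shape:
        raise ValueError("flag vectors must have equal length")
    a = int((fs & an).sum())
    b = int((fs & ~an).sum())
    c = int((~fs & an).sum())
    d = int((~fs & ~an).sum())
    table = np.array([[a, b], [c, d]])

    degenerate = fs.all() or (~fs).all() or an.all() or (~an).all()
    _, p = fisher_exact(table, alternative="two-sided")

    corrected = min(a, b, c, d) == 0
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
    )
    odds = (aa * dd) / (bb * cc)
    half = 1.96 * np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return EnrichmentResult(
        label=label, table=table, odds_ratio=float(odds),
        ci_low=float(odds * np.exp(-half)), ci_high=float(odds * np.exp(half)),
        p=float(p), haldane_corrected=corrected, degenerate=degenerate,
    )


def annotate_features(
    feature_map: pd.DataFrame,
    annotations: pd.DataFrame,
    precedence: list[str],
    default_category: str = "Intergenic",
) -> pd.Series:
    """Assign each feature its highest-precedence overlapping category.

    ``feature_map`` holds 1-based point positions (columns chrom, pos);
    ``annotations`` is BED-like (chrom, start, end, category) with 0-based
    half-open intervals, so a feature at the BED end coordinate is NOT
    contained. Features overlapping nothing get ``default_category``.
    Earlier entries of ``precedence`` win; the result is independent of the
    input interval order.
    """
    bad = annotations[annotations["end"] <= annotations["start"]]
    if not bad.empty:
        raise ValueError(f"malformed intervals (end <= start): {len(bad)} rows")
    rank = {cat: i for i, cat in enumerate(precedence)}

    trees: dict[str, IntervalTree] = {}
    for chrom, sub in annotations.groupby(annotations["chrom"].astype(str)):
        trees[chrom] = IntervalTree.from_tuples(
            (int(r["start"]), int(r["end"]), r["category"])
            for _, r in sub.iterrows()
        )

    out = {}
    for fid, row in feature_map.iterrows():
        tree = trees.get(str(row["chrom"]))
        pos0 = int(row["pos"]) - 1  # convert 1-based point to 0-based
        cats = [iv.data for iv in tree[pos0]] if tree is not None else []
        cats = [c for c in cats if c in rank]
        out[fid] = (
            min(cats, key=lambda c: rank[c]) if cats else default_category
        )
    return pd.Series(out, name="category")
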