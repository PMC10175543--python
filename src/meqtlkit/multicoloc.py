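"""Multi-trait colocalization: posterior over all variant-sharing
configurations for up to three traits (GWAS trait, gene expression,
methylation).

A configuration assigns a subset of the traits to causal variants and
partitions that subset into sharing groups (traits in a group share one
variant; different groups have distinct variants). Three traits give 15
configurations; two give the familiar five colocalization hypotheses; one
gives null/causal. Group evidence at a SNP is the product of the member
traits' Wakefield ABFs; summing over distinct-SNP assignments across groups
uses a Moebius inclusion-exclusion over partitions of the groups, and the
posterior weights each configuration by order-specific priors (default
1e-4 / 1e-6 / 1e-7 per SNP for one-, two-, three-trait sharing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .colocal import wakefield_log_abf, DEFAULT_W

__all__ = [
    "MolocPriors",
    "MolocResult",
    "enumerate_configs",
    "moloc_triplet",
    "select_gwas_loci",
]


@dataclass
class MolocPriors:
    """Per-SNP priors by sharing order (must be strictly decreasing)."""

    p_one: float = 1e-4
    p_two: float = 1e-6
    p_three: float = 1e-7

    def __post_init__(self):
        ps = (self.p_one, self.p_two, self.p_three)
        if not all(0 < p < 1 for p in ps):
            raise ValueError("priors must lie in (0, 1)")
        if not (self.p_one > self.p_two > self.p_three):
            raise ValueError("priors must decrease with sharing order")

    def for_group_size(self, k: int) -> float:
        return (self.p_one, self.p_two, self.p_three)[k - 1]


@dataclass
class MolocResult:
    triplet_id: str
    configs: list
    posterior: np.ndarray
    n_snps: int
    skipped: bool = False
    reason: str = ""

    def ppa_all_shared(self) -> float:
        """Posterior that a single variant is shared by all traits."""
        n_traits = max((max(g) for cfg in self.configs for g in cfg if g),
                       default=-1) + 1
        for i, cfg in enumerate(self.configs):
            if len(cfg) == 1 and len(cfg[0]) == n_traits:
                return float(self.posterior[i])
        return 0.0

    def to_series(self, trait_names: list[str]) -> pd.Series:
        labels = []
        for cfg in self.configs:
            if not cfg:
                labels.append("null")
            else:
                labels.append(
                    "-".join("".join(trait_names[t] for t in sorted(g))
                             for g in cfg)
                )
        return pd.Series(self.posterior, index=labels)


def _partitions(items: tuple):
    """All set partitions of ``items`` into nonempty blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + (first,)] + part[i + 1:]
        yield part + [(first,)]


def enumerate_configs(n_traits: int) -> list[tuple[tuple[int, ...], ...]]:
    """Every variant-sharing configuration for ``n_traits`` traits.

    A configuration is a tuple of disjoint sharing groups (tuples of trait
    indices); traits absent from all groups have no causal variant. The
    empty tuple is the global null. Count = sum over trait subsets of the
    Bell number of the subset: 2, 5, 15, 52 for 1-4 traits.
    """
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    traits = tuple(range(n_traits))
    configs = []
    for r in range(n_traits + 1):
        for subset in combinations(traits, r):
            for part in _partitions(subset):
                configs.append(tuple(sorted(tuple(sorted(g)) for g in part)))
    # dedupe (partitions of the empty set yield one empty config)
    seen, out = set(), []
    for c in configs:
        if c not in seen:
            seen.add(c)
            out.append(c)
    return out


def _log_distinct_sum(group_labfs: list[np.ndarray]) -> float:
    """log of the sum over assignments of distinct SNPs to groups.

    Inclusion-exclusion over partitions rho of the group list:
    sum_{distinct} = sum_rho mu(rho) * prod_{block B} S(B) where S(B) is the
    same-SNP product sum over the groups merged in block B and
    mu(rho) = prod_B (-1)^{|B|-1} (|B|-1)!.
    """
    k = len(group_labfs)
    if k == 0:
        return 0.0
    total = 0.0
    for part in _partitions(tuple(range(k))):
        coeff = 1.0
        log_term = 0.0
        for block in part:
            coeff *= (-1) ** (len(block) - 1) * factorial(len(block) - 1)
            merged = sum(group_labfs[i] for i in block)
            log_term += logsumexp(merged)
        total += coeff * np.exp(log_term)
    if total <= 0:
        return -np.inf
    return float(np.log(total))


def moloc_triplet(
    betas: np.ndarray,
    ses: np.ndarray,
    priors: MolocPriors | None = None,
    W: float | list[float] = DEFAULT_W,
    triplet_id: str = "",
    min_snps: int = 10,
) -> MolocResult:
    """Posterior over sharing configurations for aligned multi-trait data.

    ``betas`` and ``ses`` are (n_traits, n_snps) arrays in the same SNP
    order. Loci with fewer than ``min_snps`` shared SNPs are skipped with a
    reason rather than scored. ``W`` may be a scalar or per-trait list of
    prior effect variances.
    """
    priors = priors or MolocPriors()
    betas = np.atleast_2d(np.asarray(betas, dtype=float))
    ses = np.atleast_2d(np.asarray(ses, dtype=float))
    n_traits, m = betas.shape
    configs = enumerate_configs(n_traits)
    if m < min_snps:
        return MolocResult(
            triplet_id=triplet_id, configs=configs,
            posterior=np.full(len(configs), np.nan), n_snps=m,
            skipped=True, reason=f"only {m} shared SNPs (< {min_snps})",
        )

    Ws = [W] * n_traits if np.isscalar(W) else list(W)
    labf = np.vstack(
        [wakefield_log_abf(betas[t], ses[t], Ws[t]) for t in range(n_traits)]
    )

    log_weights = []
    for cfg in configs:
        if not cfg:
            log_weights.append(0.0)  # null reference
            continue
        group_labfs = [labf[list(g)].sum(axis=0) for g in cfg]
        log_prior = sum(np.log(priors.for_group_size(len(g))) for g in cfg)
        log_weights.append(log_prior + _log_distinct_sum(group_labfs))
    lw = np.array(log_weights)
    post = np.exp(lw - logsumexp(lw))
    post /= post.sum()
    return MolocResult(
        triplet_id=triplet_id, configs=configs, posterior=post, n_snps=m
    )


def select_gwas_loci(
    gwas: pd.DataFrame,
    threshold: float = 1e-5,
    regions: pd.DataFrame | None = None,
    gap_bp: int = 1_000_000,
) -> list[dict]:
    """GWAS loci containing at least one signal below ``threshold``.

    With ``regions`` (BED-like columns chrom/start/end, 0-based half-open),
    each provided region is tested; otherwise loci are formed by clustering
    SNPs on each chromosome with gaps larger than ``gap_bp`` splitting loci.
    """
    if gwas.empty:
        return []
    loci = []
    if regions is not None:
        for _, reg in regions.iterrows():
            sub = gwas[
                (gwas["chrom"].astype(str) == str(reg["chrom"]))
                & (gwas["pos"] >= reg["start"] + 1)
                & (gwas["pos"] <= reg["end"])
            ]
            if not sub.empty and sub["p"].min() < threshold:
                loci.append(
                    {
                        "chrom": str(reg["chrom"]),
                        "start": int(reg["start"]),
                        "end": int(reg["end"]),
                        "min_p": float(sub["p"].min()),
                        "n_snps": len(sub),
                    }
                )
        return loci
    for chrom, sub in gwas.groupby(gwas["chrom"].astype(str)):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        breaks = np.where(np.diff(pos) > gap_bp)[0]
        start_idx = np.r_[0, breaks + 1]
        end_idx = np.r_[breaks, len(pos) - 1]
        for s, e in zip(start_idx, end_idx):
            block = sub.iloc[s:e + 1]
            if block["p"].min() < threshold:
                loci.append(
                    {
                        "chrom": chrom,
                        "start": int(block["pos"].min()) - 1,
                        "end": int(block["pos"].max()),
                        "min_p": float(block["p"].min()),
                        "n_snps": len(block),
                    }
                )
    return loci
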