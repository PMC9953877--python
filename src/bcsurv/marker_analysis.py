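"""Differential-marker scoring between two classes, and gene-set enrichment.

The class-comparison statistic is the signal-to-noise ratio (SNR)

    snr_g = (mu_1g - mu_2g) / (sigma_1g + sigma_2g)

with each class standard deviation floored at 0.2 |mean| (the usual
comparative-marker-selection convention; without it constant genes give
unbounded scores).  Significance comes from a phenotype-permutation null
— class labels permuted, two-sided p by |snr| with add-one correction,
exact enumeration when the number of distinct label splits is small —
followed by Benjamini-Hochberg FDR.

Enrichment of a gene set in an SNR-ranked list uses the weighted
Kolmogorov-Smirnov running sum (hits weighted by |score|^p, default
p = 1; misses decremented uniformly), with a phenotype-permutation
p-value; over-representation of a fixed marker set uses the upper-tail
hypergeometric probability.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metagene_clustering import ExpressionMatrix

__all__ = [
    "MarkerTable",
    "GeneSetCollection",
    "EnrichmentResult",
    "snr_score",
    "permutation_null",
    "gsea_es",
    "gsea_permutation_test",
    "hypergeom_overrep",
    "read_gmt",
]

SNR_SIGMA_FLOOR_FRAC = 0.2  # sigma >= 0.2 |mu| per class
_MIN_SIGMA = 1e-8           # absolute floor when mean is zero too


@dataclass
class MarkerTable:
    """Per-gene SNR scores with permutation p-values and BH q-values."""

    table: pd.DataFrame        # index = gene, columns snr, nominal_p, fdr_q
    class_labels: tuple
    n_permutations: int
    seed: Optional[int]
    exact: bool = False        # p-values from exhaustive label enumeration


@dataclass
class GeneSetCollection:
    sets: dict[str, list[str]]
    universe_size: int

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")


@dataclass
class EnrichmentResult:
    set_name: str
    es: float                  # in [-1, 1]
    nominal_p: float
    direction: str             # up | down
    n_permutations: int
    seed: Optional[int]


def _class_masks(labels: Sequence) -> tuple[np.ndarray, np.ndarray, tuple]:
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    m1 = labels == classes[0]
    m2 = labels == classes[1]
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    return m1, m2, tuple(classes)


def _snr(values: np.ndarray, m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    mu1 = values[:, m1].mean(axis=1)
    mu2 = values[:, m2].mean(axis=1)
    s1 = values[:, m1].std(axis=1, ddof=1)
    s2 = values[:, m2].std(axis=1, ddof=1)
    s1 = np.maximum(s1, np.maximum(SNR_SIGMA_FLOOR_FRAC * np.abs(mu1), _MIN_SIGMA))
    s2 = np.maximum(s2, np.maximum(SNR_SIGMA_FLOOR_FRAC * np.abs(mu2), _MIN_SIGMA))
    return (mu1 - mu2) / (s1 + s2)


def snr_score(expr: ExpressionMatrix | pd.DataFrame,
              labels: Sequence) -> pd.Series:
    """Signal-to-noise score per gene for a binary class comparison.

    The score is (mu_1 - mu_2)/(sigma_1 + sigma_2); class order follows
    first appearance in ``labels``.
    """
    df = expr.to_frame() if isinstance(expr, ExpressionMatrix) else expr
    m1, m2, _ = _class_masks(labels)
    return pd.Series(_snr(df.to_numpy(dtype=float), m1, m2),
                     index=df.index, name="snr")


def permutation_null(expr: ExpressionMatrix | pd.DataFrame, labels: Sequence,
                     n_perm: int = 1000, seed: Optional[int] = None,
                     two_sided: bool = True) -> MarkerTable:
    """Phenotype-permutation p-values (and BH q-values) for SNR scores.

    Monte-Carlo p-values use the add-one correction
    p = (1 + #{|snr_perm| >= |snr_obs|}) / (n_perm + 1), so they are never
    exactly zero.  When the number of distinct class splits is at most
    ``n_perm`` the full enumeration replaces sampling and p-values are
    exact fractions over all splits.
    """
    df = expr.to_frame() if isinstance(expr, ExpressionMatrix) else expr
    values = df.to_numpy(dtype=float)
    m1, m2, classes = _class_masks(labels)
    n = values.shape[1]
    n1 = int(m1.sum())
    obs = _snr(values, m1, m2)
    stat_obs = np.abs(obs) if two_sided else obs

    n_splits = math.comb(n, n1)
    exact = n_splits <= n_perm
    count = np.zeros(values.shape[0])
    if exact:
        total = 0
        for combo in itertools.combinations(range(n), n1):
            pm1 = np.zeros(n, dtype=bool)
            pm1[list(combo)] = True
            s = _snr(values, pm1, ~pm1)
            s = np.abs(s) if two_sided else s
            count += s >= stat_obs
            total += 1
        pvals = count / total
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            pm1 = np.zeros(n, dtype=bool)
            pm1[perm[:n1]] = True
            s = _snr(values, pm1, ~pm1)
            s = np.abs(s) if two_sided else s
            count += s >= stat_obs
        pvals = (1.0 + count) / (n_perm + 1.0)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    table = pd.DataFrame({"snr": obs, "nominal_p": pvals, "fdr_q": qvals},
                         index=df.index)
    return MarkerTable(table, classes,
                       n_splits if exact else n_perm, seed, exact)


def gsea_es(ranked: pd.Series, gene_set: Iterable[str],
            weight_p: float = 1.0) -> float:
    """Enrichment score of a gene set in a ranked, scored gene list.

    ``ranked`` maps gene -> score, ordered from most up- to most
    down-regulated.  The running sum increments at hits proportionally to
    |score|^weight_p (normalized over in-set genes) and decrements at
    misses by 1/(N - |set in list|); the ES is the signed extremum.
    """
    genes = np.asarray(ranked.index)
    scores = ranked.to_numpy(dtype=float)
    in_set = np.isin(genes, list(gene_set))
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set has no genes in the ranked list")
    n_miss = genes.size - n_hit
    if n_miss == 0:
        return 0.0  # set covers the whole list; the walk never deviates
    w = np.abs(scores) ** weight_p
    hit_w = np.where(in_set, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        hit_w = in_set.astype(float)
        denom = float(n_hit)
    steps = hit_w / denom - (~in_set) / n_miss
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea_permutation_test(expr: ExpressionMatrix | pd.DataFrame,
                          labels: Sequence, gene_set: Iterable[str],
                          set_name: str = "", weight_p: float = 1.0,
                          n_perm: int = 1000,
                          seed: Optional[int] = None) -> EnrichmentResult:
    """Phenotype-permutation p-value for a gene set's enrichment score.

    Genes are ranked by SNR between the two classes; the label
    permutation regenerates the ranking each time.  The nominal p is
    sign-matched: the observed ES is compared against permuted ES of the
    same sign, with add-one correction.
    """
    df = expr.to_frame() if isinstance(expr, ExpressionMatrix) else expr
    values = df.to_numpy(dtype=float)
    m1, m2, _ = _class_masks(labels)
    n = values.shape[1]
    n1 = int(m1.sum())

    def ranked_series(mask1, mask2):
        s = _snr(values, mask1, mask2)
        order = np.argsort(-s, kind="stable")
        return pd.Series(s[order], index=df.index[order])

    es_obs = gsea_es(ranked_series(m1, m2), gene_set, weight_p)
    rng = np.random.default_rng(seed)
    same_sign = 0
    as_extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pm1 = np.zeros(n, dtype=bool)
        pm1[perm[:n1]] = True
        es_p = gsea_es(ranked_series(pm1, ~pm1), gene_set, weight_p)
        if es_p * es_obs >= 0:
            same_sign += 1
            if abs(es_p) >= abs(es_obs):
                as_extreme += 1
    p = (1.0 + as_extreme) / (1.0 + same_sign)
    return EnrichmentResult(set_name, es_obs, min(p, 1.0),
                            "up" if es_obs >= 0 else "down", n_perm, seed)


def hypergeom_overrep(marker_set: Iterable[str], gene_set: Iterable[str],
                      universe_n: int) -> float:
    """Upper-tail hypergeometric p for the marker / gene-set overlap.

    P(X >= k) where X ~ Hypergeom(universe_n, |gene_set|, |marker_set|)
    and k is the observed overlap; an empty overlap gives p = 1.
    """
    markers = set(marker_set)
    gs = set(gene_set)
    if len(markers) > universe_n or len(gs) > universe_n:
        raise ValueError("set larger than the universe")
    k = len(markers & gs)
    return float(stats.hypergeom.sf(k - 1, universe_n, len(gs), len(markers)))


def read_gmt(path, universe_size: Optional[int] = None) -> GeneSetCollection:
    """Read a GMT file (name, description, members, tab-separated)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if not line.strip():
                    continue
                raise ValueError(f"{path}:{ln}: expected >= 3 tab-separated fields")
            name, _desc, *members = parts
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate set name {name!r}")
            if not members:
                raise ValueError(f"{path}:{ln}: empty gene set {name!r}")
            sets[name] = members
    if universe_size is None:
        universe_size = len({g for mem in sets.values() for g in mem})
    return GeneSetCollection(sets, universe_size)
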