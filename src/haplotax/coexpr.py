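"""Coexpression-module mining of candidate biosynthesis enzymes.

Given a TPM-scale expression panel, a set of known pathway genes and a
candidate enzyme family, the procedure is: log-transform and filter the
matrix, compute the Pearson correlation matrix over the labelled genes,
cluster it (average-linkage agglomerative on distance 1 - r), select the
cluster containing the most known pathway genes, and take the family genes
inside that cluster as candidates.  A clade- and position-aware greedy step
then shortlists a target number of candidates for experimental validation,
and a small helper computes how strongly a gene family is concentrated in
one genomic region (the tandem-cluster fraction).

Pearson on log2(TPM + 1) is the default correlation (the standard choice
for TPM panels); Spearman is available via ``method=``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.metrics import silhouette_score

from haplotax._util import round_half_up
from haplotax.io_formats import GenomeInterval


@dataclass
class GeneSetLabels:
    """Known-pathway and candidate-family gene memberships."""

    known_pathway: set[str]
    family: set[str]

    def validate_against(self, genes: Sequence[str]) -> None:
        pool = set(genes)
        missing = (self.known_pathway | self.family) - pool
        if missing:
            raise ValueError(
                f"{len(missing)} labelled genes absent from the matrix, "
                f"e.g. {sorted(missing)[:5]}"
            )


@dataclass
class CoexpressionModule:
    """The selected cluster and its labelled-gene content."""

    cluster_id: int
    members: list[str]
    n_known: int
    n_family: int
    mean_intra_corr: float
    candidates: list[str] = field(default_factory=list)


def normalize_expression(
    matrix: pd.DataFrame,
    min_expressed_samples: int = 3,
    min_value: float = 1.0,
) -> pd.DataFrame:
    """log2(TPM + 1) transform, dropping genes expressed in too few samples.

    A gene is kept iff at least min_expressed_samples samples have raw
    value >= min_value.  Samples are never dropped.
    """
    expressed = (matrix >= min_value).sum(axis=1) >= min_expressed_samples
    kept = matrix.loc[expressed]
    if kept.empty:
        raise ValueError("all genes dropped by the expression filter")
    return np.log2(kept + 1.0)


def correlation_matrix(
    matrix: pd.DataFrame,
    genes: Sequence[str] | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Pairwise gene-gene correlation across samples.

    Constant-expression genes have undefined correlation; they are assigned
    r = 0 against every other gene (diagonal stays 1).
    """
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sub = matrix if genes is None else matrix.loc[list(genes)]
    x = sub.to_numpy(dtype=float)
    if method == "spearman":
        x = np.apply_along_axis(rankdata, 1, x)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    x = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((x**2).sum(axis=1))
    constant = norms == 0
    norms[constant] = 1.0
    xn = x / norms[:, None]
    r = xn @ xn.T
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=sub.index, columns=sub.index)


def cluster_modules(corr: pd.DataFrame, k: int) -> pd.Series:
    """Cut an average-linkage tree on distance 1 - r into k clusters.

    Genes are processed in sorted-id order so the assignment is
    deterministic and invariant to input row order.
    """
    n = corr.shape[0]
    if not (2 <= k <= n):
        raise ValueError(f"k must be in [2, {n}], got {k}")
    order = sorted(corr.index)
    c = corr.loc[order, order].to_numpy(dtype=float)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry for squareform
    z = linkage(squareform(d, checks=False), method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    return pd.Series(labels, index=order, name="cluster")


def choose_k(
    corr: pd.DataFrame, k_range: Sequence[int] = range(2, 21)
) -> int:
    """Pick the cluster count maximizing the mean silhouette on 1 - r."""
    order = sorted(corr.index)
    d = 1.0 - corr.loc[order, order].to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    best_k, best_s = None, -math.inf
    for k in k_range:
        if k >= len(order):
            break
        labels = cluster_modules(corr, k).to_numpy()
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(d, labels, metric="precomputed")
        if s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no valid k in range")
    return best_k


def select_candidate_module(
    assignments: pd.Series,
    labels: GeneSetLabels,
    corr: pd.DataFrame | None = None,
) -> CoexpressionModule:
    """Select the cluster with the most known pathway genes.

    Ties are broken by the higher mean correlation between the cluster's
    family genes and its known genes (requires corr), then by cluster id.
    The module's candidate list is its family genes.
    """
    clustered_known = labels.known_pathway & set(assignments.index)
    if not clustered_known:
        raise ValueError("no known pathway gene was clustered")

    def _family_known_corr(members: list[str]) -> float:
        if corr is None:
            return 0.0
        fam = sorted(set(members) & labels.family)
        kn = sorted(set(members) & labels.known_pathway)
        if not fam or not kn:
            return -math.inf
        return float(corr.loc[fam, kn].to_numpy().mean())

    best = None
    for cid in sorted(assignments.unique()):
        members = sorted(assignments.index[assignments == cid])
        n_known = len(set(members) & labels.known_pathway)
        key = (n_known, _family_known_corr(members), -cid)
        if best is None or key > best[0]:
            best = (key, cid, members)
    _, cid, members = best

    fam = sorted(set(members) & labels.family)
    kn = sorted(set(members) & labels.known_pathway)
    if corr is not None and len(members) > 1:
        sub = corr.loc[members, members].to_numpy()
        iu = np.triu_indices(len(members), k=1)
        mean_r = float(sub[iu].mean())
    else:
        mean_r = 1.0
    return CoexpressionModule(
        cluster_id=int(cid),
        members=list(members),
        n_known=len(kn),
        n_family=len(fam),
        mean_intra_corr=mean_r,
        candidates=fam,
    )


def mine_candidates(
    matrix: pd.DataFrame,
    labels: GeneSetLabels,
    k: int | None = None,
    method: str = "pearson",
    min_expressed_samples: int = 3,
    min_value: float = 1.0,
) -> tuple[CoexpressionModule, pd.DataFrame, pd.Series]:
    """End-to-end mining: normalize, correlate labelled genes, cluster,
    select the known-gene-richest module.

    Returns (module, correlation matrix, cluster assignments).  k defaults
    to the silhouette-optimal cut in [2, 20].
    """
    labels.validate_against(matrix.index)
    norm = normalize_expression(matrix, min_expressed_samples, min_value)
    genes = sorted((labels.known_pathway | labels.family) & set(norm.index))
    corr = correlation_matrix(norm, genes, method=method)
    if k is None:
        k = choose_k(corr)
    assignments = cluster_modules(corr, k)
    module = select_candidate_module(assignments, labels, corr)
    return module, corr, assignments


def _genomic_distance(
    a: tuple[str, int], b: tuple[str, int]
) -> float:
    return abs(a[1] - b[1]) if a[0] == b[0] else math.inf


def shortlist_candidates(
    candidates: Sequence[str],
    clade_of: Mapping[str, str],
    position_of: Mapping[str, tuple[str, int]],
    n_target: int,
) -> list[str]:
    """Greedy clade- and position-diverse shortlist of n_target genes.

    Clades are visited by descending size (ties by clade name); from each
    clade not yet represented we pick the member maximizing the minimum
    genomic distance to the genes already picked (different chromosomes
    count as infinitely far; ties by gene id).  Once every clade is
    represented, further rounds pick additional members the same way.  This
    formalises the qualitative expert criterion of spanning evolutionary
    clades and chromosomal locations.
    """
    missing = [g for g in candidates if g not in clade_of or g not in position_of]
    if missing:
        raise ValueError(f"candidates without clade/position: {missing[:5]}")
    if n_target > len(candidates):
        warnings.warn(
            f"n_target={n_target} exceeds {len(candidates)} candidates; "
            "returning all",
            stacklevel=2,
        )
        return sorted(candidates)

    by_clade: dict[str, list[str]] = {}
    for g in sorted(candidates):
        by_clade.setdefault(clade_of[g], []).append(g)
    clade_order = sorted(by_clade, key=lambda c: (-len(by_clade[c]), c))

    picked: list[str] = []
    remaining = {c: list(gs) for c, gs in by_clade.items()}

    def _min_dist(g: str) -> float:
        if not picked:
            return math.inf
        return min(
            _genomic_distance(position_of[g], position_of[p]) for p in picked
        )

    while len(picked) < n_target:
        progress = False
        for clade in clade_order:
            if len(picked) >= n_target:
                break
            pool = remaining[clade]
            if not pool:
                continue
            # maximize spread; -inf never occurs since g is unpicked
            best = max(pool, key=lambda g: (_min_dist(g), g))
            # deterministic tie-break by gene id: max on (dist, g) prefers
            # the lexicographically largest; flip to smallest
            best_d = _min_dist(best)
            tied = sorted(g for g in pool if _min_dist(g) == best_d)
            best = tied[0]
            pool.remove(best)
            picked.append(best)
            progress = True
        if not progress:
            break
    return picked


def gene_cluster_fraction(
    gene_positions: Mapping[str, tuple[str, int]],
    region: GenomeInterval,
) -> tuple[int, int, int]:
    """How many family members fall inside one genomic region.

    Returns (count inside, total, percent rounded to integer) — the
    statistic behind statements like "84% of the subfamily (54 of 64)
    clusters in one chromosomal region".
    """
    total = len(gene_positions)
    if total == 0:
        raise ValueError("no gene positions given")
    inside = sum(
        1
        for chrom, pos in gene_positions.values()
        if region.contains_point(chrom, pos)
    )
    return inside, total, int(round_half_up(100.0 * inside / total, 0))


__all__ = [
    "GeneSetLabels",
    "CoexpressionModule",
    "normalize_expression",
    "correlation_matrix",
    "cluster_modules",
    "choose_k",
    "select_candidate_module",
    "mine_candidates",
    "shortlist_candidates",
    "gene_cluster_fraction",
]
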