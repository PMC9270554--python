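"""Signature-based cohort clustering, contingency analysis and contrast
correlation.

Patients are clustered on their expression over a gene signature
(agglomerative, Euclidean distance, complete linkage), the dendrogram is cut
into k clusters, and the cluster assignment is cross-tabulated against the
clinical staging (CP/AP/BC) with a Pearson chi-square test.  A separate
operation correlates two per-gene contrast vectors (e.g. the stable
blast-crisis-vs-chronic-phase "reprogramming" contrast against the
transient hypoxia-vs-normoxia "plasticity" contrast) with Spearman's rank
correlation and a Fisher-z confidence interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import chi2_contingency, spearmanr, t as t_dist

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignaturePanel:
    """A named gene panel (e.g. a 25-gene metabolic-plasticity signature)."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("panel must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel gene ids must be unique")


@dataclass
class CohortClustering:
    """Complete-linkage dendrogram and its k-cut.

    ``assignments`` maps each sample to a cluster id 1..k, numbered by
    decreasing cluster size (cluster 1 is the largest); ties in size break
    by order of first appearance.  ``linkage`` is the scipy linkage matrix.
    """

    linkage: np.ndarray
    k: int
    assignments: pd.Series
    genes_used: list[str]
    genes_missing: list[str]
    scaling: str

    def merged(self, merge_map: Mapping[int, str]) -> pd.Series:
        """Map cluster ids to named merged groups; unmapped clusters keep a
        'Cluster_<id>' name."""
        return self.assignments.map(
            lambda c: merge_map.get(c, f"Cluster_{c}")
        ).rename("group")


def cluster_cohort(
    matrix,
    panel: SignaturePanel,
    k: int,
    scaling: str = "none",
) -> CohortClustering:
    """Cluster cohort samples on their panel-restricted expression vectors.

    ``matrix`` is an ExpressionMatrix (log mode) or a genes x samples
    DataFrame.  Distance is Euclidean between sample profiles; linkage is
    complete.  ``scaling="per-gene-z"`` z-scores each gene across samples
    first (the convention of row-scaled heatmap displays); default is no
    scaling.  Panel genes absent from the matrix are dropped with a logged
    list, never imputed.
    """
    values = matrix.values if hasattr(matrix, "values") and hasattr(matrix, "groups") else matrix
    if scaling not in ("none", "per-gene-z"):
        raise ValueError(f"scaling must be 'none' or 'per-gene-z', got {scaling!r}")
    present = [g for g in panel.genes if g in values.index]
    missing = [g for g in panel.genes if g not in values.index]
    if missing:
        logger.warning(
            "panel %s: %d genes missing from matrix: %s",
            panel.name, len(missing), missing,
        )
    if not present:
        raise ValueError(f"no gene of panel {panel.name!r} is present in the matrix")
    n_samples = values.shape[1]
    if k > n_samples:
        raise ValueError(f"k={k} exceeds the number of samples ({n_samples})")
    sub = values.loc[present]
    if scaling == "per-gene-z":
        sd = sub.std(axis=1, ddof=1).replace(0.0, 1.0)
        sub = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    x = sub.to_numpy(dtype=float).T  # samples x genes
    z = hierarchy.linkage(x, method="complete", metric="euclidean")
    raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    # renumber clusters by decreasing size (1 = largest)
    sizes = pd.Series(raw).value_counts()
    order = sizes.sort_values(ascending=False, kind="mergesort").index
    relabel = {old: new + 1 for new, old in enumerate(order)}
    assignments = pd.Series(
        [relabel[c] for c in raw], index=values.columns, name="cluster"
    )
    return CohortClustering(
        linkage=z,
        k=int(assignments.nunique()),
        assignments=assignments,
        genes_used=present,
        genes_missing=missing,
        scaling=scaling,
    )


def auto_merge_cp(clustering: CohortClustering, labels: pd.Series) -> dict[int, str]:
    """Merge map joining every cluster whose plurality clinical label is CP
    into one group (named 'Cluster_' + joined ids); other clusters keep
    their own names."""
    cp_clusters = []
    for c in sorted(clustering.assignments.unique()):
        members = clustering.assignments.index[clustering.assignments == c]
        if labels[members].mode().iloc[0] == "CP":
            cp_clusters.append(c)
    if len(cp_clusters) > 1:
        name = "Cluster_" + "+".join(str(c) for c in cp_clusters)
        return {c: name for c in cp_clusters}
    return {}


def merge_by_plurality(clustering: CohortClustering, labels: pd.Series) -> dict[int, str]:
    """Merge map joining clusters that share the same plurality clinical
    label, collapsing a k-cluster cut to one group per dominant label (the
    two-metabolic-group view when one label's samples split across
    clusters)."""
    plurality = {}
    for c in sorted(clustering.assignments.unique()):
        members = clustering.assignments.index[clustering.assignments == c]
        plurality[c] = labels[members].mode().iloc[0]
    merge: dict[int, str] = {}
    for label in set(plurality.values()):
        group = [c for c, l in plurality.items() if l == label]
        if len(group) > 1:
            name = "Cluster_" + "+".join(str(c) for c in group)
            merge.update({c: name for c in group})
    return merge


@dataclass
class ContingencyResult:
    """Cluster x clinical-label cross-tabulation with a Pearson chi-square
    test (no continuity correction) and both composition views."""

    table: pd.DataFrame  # clusters (rows) x clinical labels (columns), counts
    chi2: float
    df: int
    p: float
    expected: pd.DataFrame
    row_pct: pd.DataFrame  # % of each cluster made of each class; rows sum 100
    col_pct: pd.DataFrame  # % of each class falling in each cluster; columns sum 100
    unreliable: bool  # any expected cell < 1
    mc_p: float | None = None  # Monte-Carlo permutation p when unreliable


def contingency_analysis(
    clustering: CohortClustering,
    labels: pd.Series,
    merge_map: Mapping[int, str] | None = None,
    seed: int | None = None,
    n_mc: int = 2000,
) -> ContingencyResult:
    """Cross-tabulate cluster membership (after optional merging) against
    clinical labels.

    Flags the chi-square as unreliable when any expected cell is below 1
    and, if a seed is given, adds a Monte-Carlo p-value from ``n_mc``
    label permutations (fraction of permuted chi-squares at least as large,
    add-one corrected)."""
    if not clustering.assignments.index.equals(labels.index):
        labels = labels.reindex(clustering.assignments.index)
        if labels.isna().any():
            raise ValueError("labels are not aligned to clustered samples")
    groups = (
        clustering.merged(merge_map)
        if merge_map
        else clustering.assignments.map(lambda c: f"Cluster_{c}")
    )
    table = pd.crosstab(groups, labels)
    chi2, p, df, expected = chi2_contingency(table.to_numpy(), correction=False)
    expected = pd.DataFrame(expected, index=table.index, columns=table.columns)
    row_pct = table.div(table.sum(axis=1), axis=0) * 100
    col_pct = table.div(table.sum(axis=0), axis=1) * 100
    unreliable = bool((expected.to_numpy() < 1).any())
    mc_p = None
    if unreliable and seed is not None:
        rng = np.random.default_rng(seed)
        lab = labels.to_numpy()
        grp = groups.to_numpy()
        hits = 0
        for _ in range(n_mc):
            perm = pd.crosstab(grp, rng.permutation(lab))
            c, _, _, _ = chi2_contingency(perm.to_numpy(), correction=False)
            hits += c >= chi2 - 1e-12
        mc_p = (1 + hits) / (n_mc + 1)
    return ContingencyResult(
        table=table,
        chi2=float(chi2),
        df=int(df),
        p=float(p),
        expected=expected,
        row_pct=row_pct,
        col_pct=col_pct,
        unreliable=unreliable,
        mc_p=mc_p,
    )


@dataclass
class SpearmanResult:
    rho: float
    ci_low: float
    ci_high: float
    p: float
    n: int


def contrast_correlation(
    deltaA: pd.Series | Sequence[float],
    deltaB: pd.Series | Sequence[float],
    ci_level: float = 0.95,
) -> SpearmanResult:
    """Spearman rank correlation between two per-gene contrast vectors.

    Vectors given as Series are aligned on their shared gene index; genes
    missing (or NaN) in either are dropped.  Ties receive average ranks.
    The confidence interval uses the Fisher z-transform with standard error
    1/sqrt(n-3); the two-sided p-value uses the t-approximation with n-2
    degrees of freedom.  Needs n >= 4 and non-constant vectors.
    """
    if isinstance(deltaA, pd.Series) and isinstance(deltaB, pd.Series):
        shared = deltaA.index.intersection(deltaB.index)
        a = deltaA[shared].to_numpy(dtype=float)
        b = deltaB[shared].to_numpy(dtype=float)
    else:
        a = np.asarray(deltaA, dtype=float)
        b = np.asarray(deltaB, dtype=float)
        if len(a) != len(b):
            raise ValueError("contrast vectors differ in length and carry no gene index")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = len(a)
    if n < 4:
        raise ValueError(f"need at least 4 shared genes, got {n}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = float(spearmanr(a, b).statistic)
    if abs(rho) >= 1.0:
        ci_low, ci_high = rho, rho
        p = 0.0
    else:
        z = np.arctanh(rho)
        se = 1.0 / np.sqrt(n - 3)
        from scipy.stats import norm
        zc = norm.ppf(0.5 + ci_level / 2)
        ci_low, ci_high = np.tanh(z - zc * se), np.tanh(z + zc * se)
        tstat = rho * np.sqrt((n - 2) / (1 - rho**2))
        p = float(2 * t_dist.sf(abs(tstat), df=n - 2))
    return SpearmanResult(
        rho=rho, ci_low=float(ci_low), ci_high=float(ci_high), p=p, n=n
    )
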