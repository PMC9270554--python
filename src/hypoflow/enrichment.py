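"""Expression filtering, signal-to-noise ranking and gene-set enrichment.

Genes are ranked between two sample groups by the signal-to-noise statistic

    S2N = (x1_bar - x2_bar) / (s1 + s2),

with each group standard deviation floored at a fraction (default 0.2) of
the absolute group mean — necessary at n = 3 per group, where raw standard
deviations are unstable.  A gene set is scored along the ranked list with
the weighted Kolmogorov-Smirnov running sum: walking down the list, a set
member ("hit") increments the sum by |score|**p normalised over the hits,
a non-member decrements by 1/(N - N_hits); the enrichment score ES is the
signed maximum deviation of this walk, bounded in [-1, 1].  Significance
comes from gene-set permutation: random same-size sets are scored and the
nominal p-value is the add-one fraction of permuted |ES| at least as
extreme with the observed sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

DEFAULT_SD_FLOOR_FRACTION = 0.2
# absolute lower bound on the floored SD, so genes with near-zero means do
# not produce unbounded scores
DEFAULT_SD_ABS_FLOOR = 0.2


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with per-sample group labels.

    ``mode`` is "counts" (non-negative integers, RNA-seq) or "log" (real
    log-intensities, microarray).  Gene ids must be unique and every sample
    must carry a group label.
    """

    values: pd.DataFrame
    groups: pd.Series
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "log"):
            raise ValueError(f"mode must be 'counts' or 'log', got {self.mode!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dups[:5])}")
        self.groups = pd.Series(self.groups)
        unlabelled = [s for s in self.values.columns if s not in self.groups.index]
        if unlabelled:
            raise ValueError(f"samples without a group label: {unlabelled[:5]}")
        if self.mode == "counts":
            arr = self.values.to_numpy()
            if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
                raise ValueError("counts mode requires non-negative integer values")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


@dataclass(frozen=True)
class GeneSet:
    """One GMT record: a named collection of gene ids."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate members")


@dataclass
class RankedList:
    """Genes ordered by descending score with per-group summary statistics
    retained.  Ties are broken lexicographically by gene id so runs are
    bit-reproducible."""

    table: pd.DataFrame  # columns: gene, score, mean1, mean2, sd1, sd2
    group1: str
    group2: str
    n1: int
    n2: int

    @property
    def genes(self) -> list[str]:
        return self.table["gene"].tolist()

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


def filter_expressed(
    matrix: ExpressionMatrix, min_count: int
) -> ExpressionMatrix:
    """Keep exactly the genes with at least ``min_count`` counts in EVERY
    sample; row order is preserved.  Only defined for counts data — on
    log-intensities the threshold has no meaning."""
    if matrix.mode != "counts":
        raise ValueError("filter_expressed is only defined for counts mode")
    keep = (matrix.values >= min_count).all(axis=1)
    return ExpressionMatrix(
        values=matrix.values.loc[keep], groups=matrix.groups, mode=matrix.mode
    )


def _group_arrays(
    matrix: ExpressionMatrix, group1: str, group2: str
) -> tuple[np.ndarray, np.ndarray]:
    s1 = matrix.samples_in(group1)
    s2 = matrix.samples_in(group2)
    if set(s1) & set(s2):
        raise ValueError("groups overlap")
    if len(s1) < 2 or len(s2) < 2:
        raise ValueError("each group needs at least 2 samples")
    return (
        matrix.values[s1].to_numpy(dtype=float),
        matrix.values[s2].to_numpy(dtype=float),
    )


def rank_signal_to_noise(
    matrix: ExpressionMatrix,
    group1: str,
    group2: str,
    sd_floor_fraction: float = DEFAULT_SD_FLOOR_FRACTION,
    sd_abs_floor: float = DEFAULT_SD_ABS_FLOOR,
    denominator: str = "sum",
) -> RankedList:
    """Rank genes by signal-to-noise between two groups.

    Each group SD is floored at max(sd_floor_fraction * |group mean|,
    sd_abs_floor) before forming (mean1 - mean2) / (sd1 + sd2).
    ``denominator="difference"`` computes the denominator as (sd1 - sd2)
    verbatim — an audit mode only: a difference of SDs can be zero or
    negative and is not a dispersion measure.
    """
    if denominator not in ("sum", "difference"):
        raise ValueError("denominator must be 'sum' or 'difference'")
    a1, a2 = _group_arrays(matrix, group1, group2)
    m1, m2 = a1.mean(axis=1), a2.mean(axis=1)
    s1, s2 = a1.std(axis=1, ddof=1), a2.std(axis=1, ddof=1)
    f1 = np.maximum(sd_floor_fraction * np.abs(m1), sd_abs_floor)
    f2 = np.maximum(sd_floor_fraction * np.abs(m2), sd_abs_floor)
    s1f, s2f = np.maximum(s1, f1), np.maximum(s2, f2)
    if denominator == "sum":
        score = (m1 - m2) / (s1f + s2f)
    else:
        denom = s1f - s2f
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(denom != 0, (m1 - m2) / denom, np.nan)
    table = pd.DataFrame(
        {
            "gene": matrix.values.index,
            "score": score,
            "mean1": m1,
            "mean2": m2,
            "sd1": s1f,
            "sd2": s2f,
        }
    )
    table = table.sort_values(
        ["score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return RankedList(
        table=table, group1=group1, group2=group2, n1=a1.shape[1], n2=a2.shape[1]
    )


def log_fold_change(
    matrix: ExpressionMatrix,
    group1: str,
    group2: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2 contrast between two groups.

    Counts mode: columns are first scaled to a common library size (the mean
    total count), then log2((mean1 + pc) / (mean2 + pc)).  Log mode: the
    values are already logarithms, so the contrast is mean1 - mean2.
    """
    if matrix.mode == "counts":
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0 in counts mode")
        libsize = matrix.values.sum(axis=0)
        scaled = matrix.values / libsize * libsize.mean()
        norm = ExpressionMatrix(scaled, matrix.groups, mode="log")  # reuse grouping
        a1, a2 = _group_arrays(norm, group1, group2)
        lfc = np.log2((a1.mean(axis=1) + pseudocount) / (a2.mean(axis=1) + pseudocount))
    else:
        a1, a2 = _group_arrays(matrix, group1, group2)
        lfc = a1.mean(axis=1) - a2.mean(axis=1)
    return pd.Series(lfc, index=matrix.values.index, name="log2fc")


@dataclass
class EnrichmentScoreResult:
    es: float
    running_sum: np.ndarray
    leading_edge: list[str]
    hit_positions: np.ndarray  # 0-based ranks of set members in the list
    n_hits: int


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight: float = 1.0
) -> EnrichmentScoreResult:
    """Weighted KS enrichment score with full running-sum profile.

    The leading edge is the set members at or before the extremum for a
    positive ES, and at or after it for a negative ES.  When the maximum and
    minimum deviations tie in magnitude the positive one is reported.
    """
    genes = ranked.table["gene"].to_numpy()
    member = np.isin(genes, list(gene_set.genes))
    n = len(genes)
    n_hits = int(member.sum())
    if n_hits == 0:
        raise ValueError(f"no member of {gene_set.name!r} appears in the ranked list")
    if n_hits == n:
        raise ValueError("gene set covers the whole list: no misses to decrement")
    w = np.abs(ranked.scores) ** weight
    w_hit = np.where(member, w, 0.0)
    total = w_hit.sum()
    if total == 0:  # all member scores are exactly zero: fall back to equal weights
        w_hit = member.astype(float)
        total = w_hit.sum()
    steps = w_hit / total - (~member) / (n - n_hits)
    running = np.cumsum(steps)
    mx, mn = running.max(), running.min()
    # positive deviation preferred on (near-)exact magnitude ties
    if mx >= -mn - 1e-12:
        es = float(mx)
        extremum = int(np.argmax(running))
        leading = genes[: extremum + 1][member[: extremum + 1]]
    else:
        es = float(mn)
        extremum = int(np.argmin(running))
        leading = genes[extremum + 1 :][member[extremum + 1 :]]
    return EnrichmentScoreResult(
        es=es,
        running_sum=running,
        leading_edge=list(leading),
        hit_positions=np.flatnonzero(member),
        n_hits=n_hits,
    )


def _es_from_positions(
    weights: np.ndarray, positions: np.ndarray, n: int
) -> np.ndarray:
    """Enrichment scores for many hit-position vectors at once.

    ``weights`` is |score|**p over the full ranked list (length n);
    ``positions`` is a (B, k) array of 0-based hit ranks.  The running sum
    is piecewise linear between hits, so its extrema occur only immediately
    after a hit (local maxima candidates) or immediately before one (local
    minima candidates); evaluating those 2k candidates reproduces the full
    O(n) walk exactly.
    """
    b, k = positions.shape
    pos = np.sort(positions, axis=1)
    w = weights[pos]
    cum = np.cumsum(w, axis=1)
    total = cum[:, -1:]
    degenerate = (total == 0.0)[:, 0]
    if degenerate.any():
        w = np.where(degenerate[:, None], 1.0, w)
        cum = np.cumsum(w, axis=1)
        total = cum[:, -1:]
    cum = cum / total
    d = 1.0 / (n - k)
    j = np.arange(1, k + 1)
    after = cum - (pos + 1 - j) * d
    before = np.concatenate([np.zeros((b, 1)), cum[:, :-1]], axis=1) - (pos - j + 1) * d
    mx = after.max(axis=1)
    mn = np.minimum(before.min(axis=1), 0.0)
    return np.where(mx >= -mn - 1e-12, mx, mn)


@dataclass
class EnrichmentResult:
    name: str
    n_hits: int
    es: float
    nes: float
    p: float
    fdr: float
    leading_edge: list[str] = field(default_factory=list)


def gsea_permutation(
    ranked: RankedList,
    sets: Sequence[GeneSet],
    n_perm: int = 1000,
    mode: str = "gene_set",
    seed: int = 0,
    weight: float = 1.0,
    matrix: ExpressionMatrix | None = None,
) -> pd.DataFrame:
    """Permutation significance for a collection of gene sets.

    Default mode "gene_set" (appropriate at 3 samples per group) draws, for
    each set, ``n_perm`` random same-size sets from the ranked genes;
    nominal p = (1 + #{|ES_perm| >= |ES_obs|, same sign}) /
    (1 + #{same sign}), NES = ES_obs / mean(|ES_perm| of matching sign),
    and FDR is
    Benjamini-Hochberg across sets on the nominal p-values (simpler than
    the NES-pooled FDR of the original GSEA procedure).

    Mode "phenotype" permutes sample group labels and re-ranks; it needs
    ``matrix`` and at least 7 samples per group for enough distinct
    permutations, otherwise it warns and falls back to gene-set mode.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("gene_set", "phenotype"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    if mode == "phenotype":
        if matrix is None:
            raise ValueError("phenotype mode requires the expression matrix")
        if min(ranked.n1, ranked.n2) < 7:
            warnings.warn(
                "phenotype permutation with <7 samples per group has too few "
                "distinct permutations; falling back to gene_set mode"
            )
            mode = "gene_set"

    rng = np.random.default_rng(seed)
    n = len(ranked)
    weights_full = np.abs(ranked.scores) ** weight

    rows = []
    if mode == "gene_set":
        for gs in sets:
            obs = enrichment_score(ranked, gs, weight=weight)
            k = obs.n_hits
            # k smallest of iid uniforms = a uniform random k-subset of ranks
            perm_pos = np.argpartition(rng.random((n_perm, n)), k, axis=1)[:, :k]
            es_perm = _es_from_positions(weights_full, perm_pos, n)
            rows.append((gs, obs, es_perm))
    else:
        s_all = matrix.samples_in(ranked.group1) + matrix.samples_in(ranked.group2)
        labels = np.array(
            [ranked.group1] * ranked.n1 + [ranked.group2] * ranked.n2
        )
        obs_by_set = {gs.name: enrichment_score(ranked, gs, weight=weight) for gs in sets}
        es_perm_by_set = {gs.name: np.empty(n_perm) for gs in sets}
        for b in range(n_perm):
            perm = rng.permutation(labels)
            groups_perm = pd.Series(perm, index=s_all)
            mat_perm = ExpressionMatrix(
                matrix.values[s_all], groups_perm, mode=matrix.mode
            )
            ranked_perm = rank_signal_to_noise(mat_perm, ranked.group1, ranked.group2)
            for gs in sets:
                es_perm_by_set[gs.name][b] = enrichment_score(
                    ranked_perm, gs, weight=weight
                ).es
        rows = [(gs, obs_by_set[gs.name], es_perm_by_set[gs.name]) for gs in sets]

    records = []
    for gs, obs, es_perm in rows:
        same_sign = es_perm >= 0 if obs.es >= 0 else es_perm < 0
        extreme = same_sign & (np.abs(es_perm) >= abs(obs.es))
        # add-one p normalised within the same-sign permutation subset, the
        # GSEA convention; dividing by all permutations would cap the null
        # p-value near the sign fraction (~0.5) and break null uniformity
        p = (1 + int(extreme.sum())) / (1 + int(same_sign.sum()))
        denom = np.abs(es_perm[same_sign]).mean() if same_sign.any() else np.nan
        nes = obs.es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        records.append(
            {
                "name": gs.name,
                "n_hits": obs.n_hits,
                "ES": obs.es,
                "NES": nes,
                "p": p,
                "leading_edge": ";".join(obs.leading_edge),
            }
        )
    out = pd.DataFrame(records)
    out["FDR"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out[["name", "n_hits", "ES", "NES", "p", "FDR", "leading_edge"]]
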