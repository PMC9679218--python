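"""Community processing and decomposer attribution.

OTU count tables (samples x OTUs with taxonomy lineages) are rarefied to a
common depth, stripped of rare OTUs, standardized to relative abundance and
square-root transformed. Bray-Curtis dissimilarity feeds non-metric
multidimensional scaling and pairwise PERMANOVA; decomposer taxa are nominated
by Pearson correlation of genus-level transformed abundance with per-sample
label uptake (delta-delta-13C) of biomarker fatty acids.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class CommunityError(ValueError):
    pass


#: ranks of a 7-level semicolon lineage
LINEAGE_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


def parse_lineage(lineage: str, rank: str = "genus") -> str:
    """Extract one rank from a semicolon-separated 7-rank lineage string."""
    parts = [p.strip() for p in lineage.split(";")]
    idx = LINEAGE_RANKS.index(rank)
    return parts[idx] if idx < len(parts) and parts[idx] else "unclassified"


def rarefy(counts: pd.DataFrame, threshold: int, seed: int | None = None) -> pd.DataFrame:
    """Subsample each sample (row) without replacement to ``threshold`` reads.

    Samples with fewer reads than the threshold are dropped with a warning.
    Retained rows sum exactly to the threshold.
    """
    if threshold < 1:
        raise CommunityError("rarefaction threshold must be >= 1")
    rng = np.random.default_rng(seed)
    totals = counts.sum(axis=1)
    keep = totals >= threshold
    if not keep.all():
        warnings.warn(
            f"dropped {(~keep).sum()} sample(s) below {threshold} reads: "
            f"{list(counts.index[~keep])}"
        )
    rows = []
    for _, row in counts.loc[keep].iterrows():
        rows.append(rng.multivariate_hypergeometric(row.to_numpy().astype(np.int64), threshold))
    return pd.DataFrame(rows, index=counts.index[keep], columns=counts.columns)


def filter_rare(
    counts: pd.DataFrame, min_rel_abundance: float = 0.01, mode: str = "max"
) -> pd.DataFrame:
    """Drop OTUs that never reach ``min_rel_abundance`` relative abundance.

    ``mode='max'`` keeps an OTU reaching the floor in at least one sample;
    ``mode='mean'`` applies the floor to the across-sample mean instead.
    """
    rel = counts.div(counts.sum(axis=1), axis=0)
    if mode == "max":
        keep = rel.max(axis=0) >= min_rel_abundance
    elif mode == "mean":
        keep = rel.mean(axis=0) >= min_rel_abundance
    else:
        raise CommunityError(f"unknown filter mode {mode!r}")
    if not keep.any():
        raise CommunityError("rare-OTU filter removed every OTU")
    return counts.loc[:, keep]


def transform(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample relative abundance followed by element-wise square root."""
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise CommunityError(f"zero-sum sample(s): {list(counts.index[totals == 0])}")
    return np.sqrt(counts.div(totals, axis=0))


def bray_curtis(matrix) -> pd.DataFrame:
    """Bray-Curtis dissimilarity: d(i,j) = sum|x_i - x_j| / sum(x_i + x_j).

    Pairs of all-zero samples are undefined and set to NaN with a warning.
    """
    if isinstance(matrix, pd.DataFrame):
        index, x = matrix.index, matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        index = pd.RangeIndex(x.shape[0])
    if x.shape[0] < 2:
        raise CommunityError("need at least two samples")
    diff = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=-1)
    total = (x[:, None, :] + x[None, :, :]).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(total > 0, diff / np.where(total == 0, np.nan, total), np.nan)
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        warnings.warn("undefined Bray-Curtis pair(s) between all-zero samples")
    return pd.DataFrame(d, index=index, columns=index)


@dataclass
class OrdinationResult:
    """NMDS coordinates (centered), Kruskal stress-1, and variable fits."""

    coordinates: pd.DataFrame
    stress: float
    restart_stresses: np.ndarray
    vector_fits: pd.DataFrame | None = None


def nmds(
    dissimilarity: pd.DataFrame,
    k: int = 2,
    restarts: int = 8,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | None = None,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1; best of random restarts."""
    from sklearn.manifold import MDS

    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    if n < k + 1:
        raise CommunityError(f"need at least {k + 1} samples for {k}-d ordination")
    rng = np.random.default_rng(seed)
    best = None
    stresses = []
    for _ in range(max(restarts, 1)):
        mds = MDS(
            n_components=k,
            metric_mds=False,
            metric="precomputed",
            n_init=1,
            init="random",
            max_iter=max_iter,
            eps=tol,
            normalized_stress=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        coords = mds.fit_transform(d)
        stresses.append(float(mds.stress_))
        if best is None or mds.stress_ < best[0]:
            best = (float(mds.stress_), coords)
    stress, coords = best
    coords = coords - coords.mean(axis=0)
    if stress > 0.2:
        warnings.warn(f"NMDS stress {stress:.3f} > 0.2: ordination may be unreliable")
    index = dissimilarity.index if isinstance(dissimilarity, pd.DataFrame) else pd.RangeIndex(n)
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=index, columns=[f"NMDS{i+1}" for i in range(k)]),
        stress=stress,
        restart_stresses=np.asarray(stresses),
    )


def fit_vectors(coordinates: pd.DataFrame, variables: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of each variable against each ordination axis."""
    out = {}
    for name, series in variables.items():
        rs = []
        for axis in coordinates.columns:
            if np.std(series) == 0 or np.std(coordinates[axis]) == 0:
                rs.append(np.nan)
            else:
                rs.append(stats.pearsonr(series, coordinates[axis])[0])
        out[name] = rs
    return pd.DataFrame(out, index=coordinates.columns).T


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    t: float
    p_value: float
    n_permutations: int
    method: str  # "exhaustive" or "monte-carlo"


def _pseudo_f(d2: np.ndarray, in_a: np.ndarray) -> float:
    """One-way pseudo-F from squared dissimilarities for a 2-group labelling."""
    n = d2.shape[0]
    n_a = int(in_a.sum())
    n_b = n - n_a
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    a_idx = np.flatnonzero(in_a)
    b_idx = np.flatnonzero(~in_a)
    ss_within = 0.0
    for idx, size in ((a_idx, n_a), (b_idx, n_b)):
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(size, 1)].sum() / size
    ss_among = ss_total - ss_within
    return (ss_among / 1.0) / (ss_within / (n - 2))


def permanova_pairwise(
    dissimilarity,
    groups,
    n_permutations: int = 9999,
    seed: int | None = None,
    exhaustive_limit: int = 10_000,
) -> PermanovaResult:
    """Two-group PERMANOVA on a dissimilarity matrix.

    The pseudo-F follows the among/within sums of squared dissimilarities;
    the pairwise t statistic is sqrt(F). The p-value permutes group labels:
    exhaustively when the number of distinct relabelings (label-swap
    symmetric) is at most ``exhaustive_limit``, by Monte Carlo otherwise
    (observed labelling included in the reference set).
    """
    d = np.asarray(dissimilarity, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise CommunityError("pairwise PERMANOVA requires exactly two groups")
    in_a = groups == levels[0]
    n = d.shape[0]
    n_a = int(in_a.sum())
    if min(n_a, n - n_a) < 2:
        raise CommunityError("each group needs at least two samples")
    d2 = d**2
    f_obs = _pseudo_f(d2, in_a)

    from math import comb

    n_distinct = comb(n, n_a) // (2 if 2 * n_a == n else 1)
    if n_distinct <= exhaustive_limit:
        if 2 * n_a == n:
            # fix sample 0's group to collapse the label-swap symmetry
            combos = (
                (0,) + rest for rest in itertools.combinations(range(1, n), n_a - 1)
            )
        else:
            combos = itertools.combinations(range(n), n_a)
        count = 0
        total = 0
        for combo in combos:
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            if _pseudo_f(d2, mask) >= f_obs - 1e-12:
                count += 1
            total += 1
        assert total == n_distinct
        p = count / n_distinct
        return PermanovaResult(f_obs, float(np.sqrt(f_obs)), p, n_distinct, "exhaustive")

    rng = np.random.default_rng(seed)
    count = 1  # the observed labelling
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n_a]] = True
        if _pseudo_f(d2, mask) >= f_obs - 1e-12:
            count += 1
    p = count / (n_permutations + 1)
    return PermanovaResult(f_obs, float(np.sqrt(f_obs)), p, n_permutations, "monte-carlo")


# ---------------------------------------------------------------------------
# decomposer attribution


def aggregate_rank(
    counts: pd.DataFrame, taxonomy: pd.Series, rank: str = "genus"
) -> pd.DataFrame:
    """Sum OTU counts to one taxonomic rank (columns become rank labels)."""
    labels = taxonomy.loc[counts.columns].map(lambda s: parse_lineage(s, rank))
    return counts.T.groupby(labels.values).sum().T


def correlate_decomposers(
    counts: pd.DataFrame,
    taxonomy: pd.Series,
    ddelta: pd.DataFrame,
    threshold: float = 0.9,
    rank: str = "genus",
) -> pd.DataFrame:
    """Pearson r between taxon abundance and per-sample biomarker uptake.

    ``counts`` are samples x OTUs (post rarefaction/filtering); ``ddelta`` is
    samples x compounds of delta-delta-13C values. Abundances are aggregated
    to ``rank``, standardized and square-root transformed before correlation.
    Returns a long table (taxon, compound, r, candidate), with zero-variance
    taxa and compounds skipped.
    """
    shared = counts.index.intersection(ddelta.index)
    if len(shared) < 3:
        raise CommunityError("need at least three paired samples")
    agg = aggregate_rank(counts.loc[shared], taxonomy, rank)
    z = transform(agg)
    records = []
    for taxon in z.columns:
        tv = z[taxon].to_numpy()
        if np.std(tv) == 0:
            continue
        for compound in ddelta.columns:
            cv = ddelta.loc[shared, compound].to_numpy(dtype=float)
            if np.std(cv) == 0:
                continue
            r = stats.pearsonr(tv, cv)[0]
            records.append((taxon, compound, r, r > threshold))
    return pd.DataFrame(records, columns=["taxon", "compound", "r", "candidate"])


def counts_vs_rate_regression(counts_per_sample, rates):
    """OLS of taxon sequence counts against mineralization rate: slope, R^2."""
    res = stats.linregress(np.asarray(counts_per_sample, float), np.asarray(rates, float))
    return {"slope": res.slope, "intercept": res.intercept, "r_squared": res.rvalue**2}
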