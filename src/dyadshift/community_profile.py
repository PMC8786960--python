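"""Community-level taxonomic statistics comparing mothers and infants.

Alpha diversity (Shannon, in nats), Bray-Curtis dissimilarities, PERMANOVA
on the resulting distance matrix, and a two-sample diversity comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats


def shannon_diversity(abundances) -> float:
    """Shannon's diversity index H = -sum p_i ln p_i, in nats.

    The input is renormalized to sum 1; zero entries contribute nothing.

    Raises
    ------
    ValueError
        If the profile is all zero or has a negative entry.
    """
    p = np.asarray(abundances, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValueError("cannot compute diversity of an all-zero profile")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


def diversity_table(profile: pd.DataFrame) -> pd.Series:
    """Shannon diversity per sample of a samples x species profile."""
    return pd.Series(
        {sid: shannon_diversity(profile.loc[sid].values) for sid in profile.index},
        name="shannon",
    )


def bray_curtis(profile: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarities of a samples x species profile.

    BC(a, b) = 1 - 2 sum_i min(a_i, b_i) / (sum a_i + sum b_i). Returns a
    symmetric zero-diagonal DataFrame indexed by sample id.
    """
    if len(profile) < 2:
        raise ValueError("need at least 2 samples for a distance matrix")
    totals = profile.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError(
            f"samples with zero total abundance: {list(profile.index[totals <= 0])}"
        )
    condensed = pdist(profile.values, metric="braycurtis")
    return pd.DataFrame(
        squareform(condensed), index=profile.index, columns=profile.index
    )


def _permanova_ss(sq: np.ndarray, labels: np.ndarray, groups: np.ndarray):
    """Among/within sums of squares of squared distances for given labels."""
    n = sq.shape[0]
    ss_total = sq[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = sq[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_total - ss_within, ss_within


def permanova(
    dist: pd.DataFrame,
    groups,
    n_permutations: int = 999,
    seed: int | None = None,
) -> dict:
    """One-way PERMANOVA on a distance matrix.

    Pseudo-F is computed from the among/within decomposition of squared
    distances; R^2 = SS_among / SS_total; the p-value is the permutation
    estimate (1 + #{permuted F >= observed F}) / (1 + n_permutations), ties
    counted as >= (conservative).

    Parameters
    ----------
    dist : DataFrame
        Symmetric zero-diagonal distance matrix.
    groups : sequence or mapping
        Group label per sample, aligned with ``dist.index`` (a mapping or
        Series is reindexed by sample id).

    Returns
    -------
    dict with keys ``F``, ``R2``, ``p``, ``n_permutations``.
    """
    if isinstance(groups, (dict, pd.Series)):
        labels = np.asarray([groups[s] for s in dist.index])
    else:
        labels = np.asarray(list(groups))
    if len(labels) != len(dist):
        raise ValueError("group labels do not match the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if (counts < 2).any():
        raise ValueError(
            f"every group needs >= 2 samples; offending groups: "
            f"{list(uniq[counts < 2])}"
        )
    d = np.asarray(dist.values, dtype=float)
    if not np.allclose(d, d.T, atol=1e-12) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    sq = d ** 2
    n, k = len(labels), len(uniq)

    ss_total, ss_among, ss_within = _permanova_ss(sq, labels, uniq)
    if ss_within <= 0 or ss_total <= 0:
        raise ValueError("zero within-group variance; PERMANOVA undefined")
    f_obs = (ss_among / (k - 1)) / (ss_within / (n - k))

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        _, ss_a, ss_w = _permanova_ss(sq, perm, uniq)
        f_perm = np.inf if ss_w <= 0 else (ss_a / (k - 1)) / (ss_w / (n - k))
        if f_perm >= f_obs:
            n_ge += 1
    return {
        "F": float(f_obs),
        "R2": float(ss_among / ss_total),
        "p": (1 + n_ge) / (1 + n_permutations),
        "n_permutations": n_permutations,
    }


def compare_diversity(values_a, values_b) -> dict:
    """Equal-variance two-sample Student's t-test on diversity values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance; t statistic undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return {"t": float(t), "p": float(p)}
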