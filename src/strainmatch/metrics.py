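"""Diversity and composition metrics: Shannon, Bray-Curtis, Jaccard,
Prevotella/Bacteroides ratio, COG renormalisation, PCoA and PERMANOVA.

Abundance profiles are rows of a samples x species relative-abundance table
whose rows sum to at most 1, the remainder being an explicit ``UNKNOWN``
(unclassified) fraction.  Shannon diversity is computed in nats on the
observed species renormalised to sum 1 (the unknown fraction excluded by
default).  PERMANOVA is implemented in the distance-based linear model
(hat-matrix) form so a single categorical or continuous predictor can be
tested with a permutation p-value, as in vegan's adonis2.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis, jaccard, pdist, squareform
from scipy.stats import entropy
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

logger = logging.getLogger(__name__)


def shannon_index(
    abundances, include_unknown: bool = False, unknown_fraction: float = 0.0
) -> float:
    """Shannon diversity H = -sum q ln q in nats.

    ``abundances`` is a vector of nonnegative species relative abundances;
    they are renormalised to sum 1 before the entropy is taken, so the
    unknown fraction is excluded unless ``include_unknown`` is set (in which
    case ``unknown_fraction`` enters as one extra pseudo-species).
    """
    q = np.asarray(abundances, dtype=float)
    if include_unknown and unknown_fraction > 0:
        q = np.append(q, unknown_fraction)
    q = q[q > 0]
    if q.size == 0:
        raise ValueError("all-zero abundance profile")
    return float(entropy(q))  # scipy normalises and uses natural log


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity between two abundance vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.sum() == 0 and b.sum() == 0:
        raise ValueError("both profiles are all-zero")
    return float(braycurtis(a, b))


def jaccard_binary(a, b) -> float:
    """Jaccard dissimilarity on presence/absence (abundance > 0)."""
    pa = np.asarray(a, dtype=float) > 0
    pb = np.asarray(b, dtype=float) > 0
    if not pa.any() and not pb.any():
        raise ValueError("both profiles are empty")
    return float(jaccard(pa, pb))


def dissimilarity_matrix(
    abundance: pd.DataFrame, metric: str = "bray-curtis"
) -> pd.DataFrame:
    """Square symmetric dissimilarity matrix over the table's samples.

    ``metric`` is ``"bray-curtis"`` or ``"jaccard-binary"``; the UNKNOWN
    column, if present, is excluded.
    """
    data = abundance.drop(columns=["UNKNOWN"], errors="ignore")
    x = data.to_numpy(dtype=float)
    if metric == "bray-curtis":
        condensed = pdist(x, metric="braycurtis")
    elif metric == "jaccard-binary":
        condensed = pdist(x > 0, metric="jaccard")
    else:
        raise ValueError(f"unknown metric: {metric}")
    return pd.DataFrame(
        squareform(condensed), index=data.index, columns=data.index
    )


def pb_ratio(
    profile: pd.Series,
    prevotella_taxa: list[str] | None = None,
    bacteroides_taxa: list[str] | None = None,
) -> float:
    """Prevotella/Bacteroides genus abundance ratio for one sample.

    Genus membership defaults to species whose name starts with the genus
    prefix (``Prevotella_``/``Bacteroides_``); explicit taxa lists override.
    A zero denominator with positive numerator gives +inf; 0/0 is undefined
    and returns NaN (logged).  Ratios above 1 indicate Prevotella dominance.
    """
    if prevotella_taxa is None:
        prevotella_taxa = [s for s in profile.index if s.startswith("Prevotella_")]
    if bacteroides_taxa is None:
        bacteroides_taxa = [
            s for s in profile.index if s.startswith("Bacteroides_")
        ]
    num = float(profile.reindex(prevotella_taxa).fillna(0).sum())
    den = float(profile.reindex(bacteroides_taxa).fillna(0).sum())
    if den == 0:
        if num == 0:
            logger.warning("P/B ratio undefined (0/0)")
            return float("nan")
        return float("inf")
    return num / den


def cog_renormalise(annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-sample renormalised COG functional-category profiles.

    ``annotations`` has columns ``sample_id, gene_id, category`` with one row
    per (gene, category); genes with several categories occupy several rows
    and count once per category, unannotated genes carry the ``NA``
    category.  Raw category weights are counts divided by the number of
    distinct genes; the final vector is renormalised to sum exactly 1 (the
    multi-annotation load makes the raw weights sum to more than 1).
    Samples with zero genes are omitted and logged.

    Returns a samples x categories table.
    """
    profiles = {}
    for sample, group in annotations.groupby("sample_id"):
        n_genes = group["gene_id"].nunique()
        if n_genes == 0:
            logger.warning("sample %s has no genes; omitted", sample)
            continue
        weights = group["category"].value_counts() / n_genes
        profiles[sample] = weights / weights.sum()
    out = pd.DataFrame.from_dict(profiles, orient="index").fillna(0.0)
    out.index.name = "sample_id"
    return out.sort_index().sort_index(axis=1)


@dataclass
class PcoaResult:
    """Principal-coordinates embedding of a dissimilarity matrix."""

    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues incl. negative ones
    proportion_explained: np.ndarray


def pcoa(d: pd.DataFrame, k: int = 2) -> PcoaResult:
    """Classical (metric) multidimensional scaling via Gower centring.

    Negative eigenvalues (non-Euclidean input) are reported, not corrected.
    ``k`` is truncated (with a warning) if fewer positive axes exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    dm = DistanceMatrix(d.to_numpy(dtype=float), ids=[str(i) for i in d.index])
    res = _skbio_pcoa(dm, method="eigh", number_of_dimensions=0)
    eigvals = res.eigvals.to_numpy()
    n_pos = int((eigvals > 1e-12).sum())
    if k > n_pos:
        logger.warning(
            "requested %d axes but only %d positive eigenvalues; truncating",
            k,
            n_pos,
        )
        k = max(n_pos, 1)
    coords = res.samples.iloc[:, :k].copy()
    coords.index = d.index
    coords.columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=coords,
        eigenvalues=eigvals,
        proportion_explained=res.proportion_explained.to_numpy(),
    )


@dataclass
class PermanovaResult:
    """One-term PERMANOVA: pseudo-F, R-squared and permutation p-value."""

    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    centred = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    return centred


def _design_matrix(predictor) -> np.ndarray:
    x = np.asarray(predictor)
    n = x.shape[0]
    if x.dtype.kind in "OUSb":  # categorical labels
        levels = pd.unique(x)
        if len(levels) < 2:
            raise ValueError("categorical predictor needs >= 2 groups")
        dummies = np.column_stack(
            [(x == lv).astype(float) for lv in levels[1:]]
        )
        return np.column_stack([np.ones(n), dummies])
    x = x.astype(float)
    if np.ptp(x) == 0:
        raise ValueError("continuous predictor is constant")
    return np.column_stack([np.ones(n), x])


def permanova(
    d: pd.DataFrame,
    predictor,
    n_permutations: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    Distance-based linear model with a single term: the Gower-centred
    inner-product matrix G is partitioned by the predictor's hat matrix H,
    giving pseudo-F = (tr(HG)/(m-1)) / (tr((I-H)G)/(n-m)) where m is the
    number of model columns.  The predictor may be categorical (labels) or
    continuous (numeric covariate).  p = (1 + #{F_perm >= F_obs}) /
    (1 + n_permutations); with ``exhaustive=True`` all n! observation
    permutations are enumerated instead (small n only) and
    p = #{F_perm >= F_obs} / n! over the full permutation group (identity
    included).
    """
    dmat = d.to_numpy(dtype=float)
    n = dmat.shape[0]
    x = _design_matrix(predictor)
    m = x.shape[1]
    if m >= n:
        raise ValueError("more model columns than samples")
    h = x @ np.linalg.pinv(x.T @ x) @ x.T
    g = _gower_center(dmat)
    ss_total = float(np.trace(g))
    ss_model = float(np.sum(h * g.T))  # tr(HG)
    ss_resid = ss_total - ss_model
    df_model, df_resid = m - 1, n - m
    f_obs = (ss_model / df_model) / (ss_resid / df_resid)
    r_squared = ss_model / ss_total

    def _f_of_perm(idx: np.ndarray) -> float:
        gp = g[np.ix_(idx, idx)]
        ssm = float(np.sum(h * gp.T))
        return (ssm / df_model) / ((ss_total - ssm) / df_resid)

    if exhaustive:
        fs = [
            _f_of_perm(np.array(p)) for p in itertools.permutations(range(n))
        ]
        p_value = float(np.mean([f >= f_obs - 1e-12 for f in fs]))
        n_perm = len(fs)
    else:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            idx = rng.permutation(n)
            if _f_of_perm(idx) >= f_obs - 1e-12:
                count += 1
        p_value = (1 + count) / (1 + n_permutations)
        n_perm = n_permutations
    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(r_squared),
        p_value=float(p_value),
        n_permutations=n_perm,
    )
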