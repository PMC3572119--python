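"""Signature extraction: hierarchical clustering, NMF background analysis,
and direct pairwise-strain contrasts.

Hierarchical clustering of normalized sample profiles checks the basic
quality signal of a pooled-triplicate screen: aliquots of the same strain
should merge first ("perfect triplicate clustering") and strains should
separate.  When strains group by genetic background rather than disease,
a non-negative matrix factorization of the linear abundance matrix is
used to score each miRNA's participation in background-aligned factors;
the lowest-scoring (background-insensitive) assays form a candidate
cross-background signature.  Finally, closely related disease models that
share a control can be contrasted directly against each other to extract
a disease-specific signature.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datamodel import ScreenConfig
from .normalize import NormalizedTable
from .screen import bh_adjust, delta_delta_cq, per_mirna_test, signed_fold_change

__all__ = [
    "LinkageTree",
    "ClusterAssignment",
    "FactorModel",
    "hierarchical_cluster",
    "clustering_purity",
    "nmf_factorize",
    "background_insensitivity_ranking",
    "direct_contrast_screen",
    "abundance_matrix",
]


@dataclass
class LinkageTree:
    """A sample dendrogram: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray  # (n-1, 4) scipy format: node_a, node_b, height, size
    labels: tuple[str, ...]
    metric: str
    method: str
    n_dropped_rows: int = 0

    def merges(self) -> list[tuple[int, int, float, int]]:
        return [(int(a), int(b), float(h), int(n)) for a, b, h, n in self.linkage]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.linkage, columns=["node_a", "node_b", "height", "size"])


@dataclass
class ClusterAssignment:
    """Flat clusters at one cut, with strain purity.

    ``purity`` is the fraction of samples sitting in a cluster whose
    majority strain they share: purity = (1/n) * sum over clusters of the
    max within-cluster strain count.  ``perfect`` additionally requires
    one cluster per strain.
    """

    assignment: dict[str, int]
    purity: float
    perfect: bool
    k: int


@dataclass
class FactorModel:
    """Non-negative factorization W @ H of an abundance matrix.

    ``basis`` (miRNA x k) holds the per-assay factor loadings, and
    ``coefficients`` (k x samples) the per-sample factor activities.
    ``background_score`` (filled by the ranking step) is the fraction of
    each assay's basis mass on background-aligned factors.
    """

    basis: pd.DataFrame
    coefficients: pd.DataFrame
    rank: int
    reconstruction_error: float
    error_trace: list[float]
    converged: bool
    seed: int
    background_score: pd.Series | None = None


def hierarchical_cluster(
    norm: NormalizedTable, metric: str = "euclidean", method: str = "average"
) -> LinkageTree:
    """Cluster samples of a normalized table.

    Exogenous spike-in assays are excluded; assay rows containing any
    missing value are dropped (complete-case; the count is recorded on
    the tree).  Defaults are Euclidean distance on corrected Cq with
    average linkage; both are configurable and the labels are recorded in
    the output.
    """
    endo = [m for m in norm.panel.endogenous_ids if m in norm.values.index]
    complete = norm.values.loc[endo].dropna(axis=0, how="any")
    n_dropped = len(endo) - complete.shape[0]
    if complete.shape[1] < 2:
        raise ValueError("clustering requires at least 2 samples")
    if complete.shape[0] == 0:
        raise ValueError("no complete assay rows available for clustering")
    X = complete.to_numpy(dtype=float).T  # samples x assays
    Z = hierarchy.linkage(pdist(X, metric=metric), method=method)
    return LinkageTree(
        linkage=Z,
        labels=tuple(complete.columns),
        metric=metric,
        method=method,
        n_dropped_rows=n_dropped,
    )


def clustering_purity(
    tree: LinkageTree, strain_labels: dict[str, str], k: int
) -> ClusterAssignment:
    """Cut the dendrogram into k flat clusters and score strain purity."""
    n = len(tree.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    flat = hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")
    assignment = {label: int(c) for label, c in zip(tree.labels, flat)}
    strains = [strain_labels[label] for label in tree.labels]
    df = pd.DataFrame({"cluster": flat, "strain": strains})
    purity = float(
        df.groupby("cluster")["strain"].agg(lambda s: s.value_counts().iloc[0]).sum() / n
    )
    n_strains = len(set(strains))
    perfect = purity == 1.0 and k == n_strains and df["cluster"].nunique() == n_strains
    return ClusterAssignment(assignment=assignment, purity=purity, perfect=perfect, k=k)


# ---------------------------------------------------------------------------
# NMF
# ---------------------------------------------------------------------------

_EPS = 1e-12


def abundance_matrix(norm: NormalizedTable) -> pd.DataFrame:
    """Linear relative abundance 2^(C - value) for NMF input.

    For corrected-Cq tables C is the table maximum, guaranteeing a
    non-negative matrix bounded below by 1 for the least abundant assay
    while preserving all fold relationships.  Referent-scheme tables are
    already log2 abundances and are simply exponentiated after shifting
    by the table minimum.  Spike-ins are excluded and rows with missing
    values are dropped.
    """
    endo = [m for m in norm.panel.endogenous_ids if m in norm.values.index]
    complete = norm.values.loc[endo].dropna(axis=0, how="any")
    if norm.scheme == "global_mean":
        c = float(complete.to_numpy().max())
        return 2.0 ** (c - complete)
    c = float(complete.to_numpy().min())
    return 2.0 ** (complete - c)


def nmf_factorize(
    abundance: pd.DataFrame,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> FactorModel:
    """Multiplicative-update NMF minimizing the Frobenius error.

    Classic Lee-Seung updates with uniform random non-negative
    initialization scaled to the data; the Frobenius reconstruction
    error is recorded at every iteration and is non-increasing.  Updates
    stop when the relative error improvement drops below ``tol`` or at
    ``max_iter`` (flagged on the model).  Negative input entries are a
    hard error: callers transform Cq-scale data with
    :func:`abundance_matrix` first.
    """
    X = abundance.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("abundance matrix contains missing values")
    if (X < 0).any():
        raise ValueError("abundance matrix must be non-negative")
    if k < 1:
        raise ValueError("rank k must be >= 1")
    n, m = X.shape
    rng = np.random.default_rng(seed)
    scale = math.sqrt(max(X.mean(), _EPS) / k)
    W = rng.uniform(_EPS, 1.0, size=(n, k)) * scale
    H = rng.uniform(_EPS, 1.0, size=(k, m)) * scale

    norm_x = np.linalg.norm(X)
    errors: list[float] = []
    converged = False
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ H @ H.T + _EPS)
        err = float(np.linalg.norm(X - W @ H))
        errors.append(err)
        if len(errors) > 1:
            prev = errors[-2]
            if prev - err <= tol * max(norm_x, _EPS):
                converged = True
                break
    basis = pd.DataFrame(W, index=abundance.index, columns=[f"factor_{j+1}" for j in range(k)])
    coeff = pd.DataFrame(H, index=basis.columns, columns=abundance.columns)
    return FactorModel(
        basis=basis,
        coefficients=coeff,
        rank=k,
        reconstruction_error=errors[-1],
        error_trace=errors,
        converged=converged,
        seed=seed,
    )


def _background_aligned_factors(
    model: FactorModel, group_labels: dict[str, str]
) -> list[str]:
    """Factors whose coefficient profile tracks background groups.

    A factor is background-aligned when the between-group variance of its
    per-sample coefficients exceeds the within-group variance.  Ties in
    the implied factor-to-group assignment resolve by factor index.
    """
    aligned: list[str] = []
    groups = pd.Series({s: group_labels[s] for s in model.coefficients.columns})
    for factor in model.coefficients.index:  # index order = deterministic tie-break
        coefs = model.coefficients.loc[factor]
        overall = coefs.mean()
        between = 0.0
        within = 0.0
        for _, idx in groups.groupby(groups).groups.items():
            sub = coefs.loc[idx]
            between += len(sub) * (sub.mean() - overall) ** 2
            within += ((sub - sub.mean()) ** 2).sum()
        between /= len(coefs)
        within /= len(coefs)
        if between > within:
            aligned.append(factor)
    return aligned


def background_insensitivity_ranking(
    model: FactorModel,
    group_labels: dict[str, str],
    n_select: int,
) -> pd.DataFrame:
    """Rank assays by how little of their signal lives on background factors.

    ``background_score(m)`` is the share of assay m's basis mass carried
    by background-aligned factors (0 = fully background-free, 1 = fully
    background-driven).  Returns the ``n_select`` lowest-scoring assays
    first, the full ranking in the frame; the score is also stored on the
    model.
    """
    if model.rank < len(set(group_labels.values())):
        raise ValueError("NMF rank must be >= number of background groups")
    aligned = _background_aligned_factors(model, group_labels)
    mass = model.basis.sum(axis=1)
    bg_mass = model.basis[aligned].sum(axis=1) if aligned else pd.Series(0.0, index=model.basis.index)
    score = (bg_mass / (mass + _EPS)).clip(0.0, 1.0)
    model.background_score = score
    ranking = (
        pd.DataFrame({"mirna_id": score.index, "background_score": score.to_numpy()})
        .sort_values(["background_score", "mirna_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    ranking["selected"] = ranking.index < n_select
    return ranking


def direct_contrast_screen(
    norm: NormalizedTable,
    strains: list[str],
    config: ScreenConfig | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """All pairwise differential contrasts among related disease strains.

    Instead of comparing each strain to the shared healthy control, the
    strains are contrasted directly with each other; the signature set is
    the assays significant after BH (q <= alpha) with |FC| at or above
    the threshold in at least one pair.  Pair results are antisymmetric:
    swapping the pair flips the FC sign (reciprocal magnitude).

    Returns (pairwise results frame, signature miRNA list).
    """
    config = config or ScreenConfig()
    if len(strains) < 2:
        raise ValueError("need at least 2 strains to contrast")
    mirnas = [m for m in norm.panel.endogenous_ids if m in norm.values.index]

    rows = []
    for s1, s2 in itertools.combinations(strains, 2):
        for mirna in mirnas:
            ddcq = delta_delta_cq(norm, s1, s2, mirna)
            rows.append(
                {
                    "mirna_id": mirna,
                    "strain": s1,
                    "control_strain": s2,
                    "delta_delta_cq": ddcq,
                    "signed_fc": signed_fold_change(ddcq),
                    "p_value": per_mirna_test(norm, s1, s2, mirna),
                }
            )
    result = pd.DataFrame(rows)
    result["q_value"] = np.nan
    for (s1, s2), idx in result.groupby(["strain", "control_strain"]).groups.items():
        result.loc[idx, "q_value"] = bh_adjust(result.loc[idx, "p_value"].to_numpy())
    sig_mask = (
        (result["q_value"] <= config.alpha)
        & (result["signed_fc"].abs() >= config.fc_threshold)
    )
    signature = sorted(result.loc[sig_mask, "mirna_id"].unique())
    return result, signature
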