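"""Sequential knockoff generation for unphased genotype dosages.

A knockoff copy of a genotype matrix is a synthetic matrix that preserves
the LD (correlation) structure of the original but is conditionally
independent of any phenotype given the original genotypes.  Knockoff
columns act as negative controls in the selection filter.

The generator sweeps variants in genomic order.  For each variant it fits
a linear auto-regressive model of the dosage on a small set of nearby
correlated variants (and on the already-generated knockoff columns of
those neighbors), then forms each knockoff copy as fitted value plus an
independently permuted residual.  Permuting residuals rather than sampling
from a parametric law keeps the construction robust for rare variants,
whose dosage distribution is zero-inflated and highly skewed; the output
is continuous-valued and deliberately not rounded or clipped to {0,1,2}.

Variants in tight LD (|r| > 0.75) are handled as one cluster: cluster
co-members are excluded from each other's predictor sets and their
residuals are permuted jointly (the same permutation per copy), so the
knockoffs of a tight cluster are not near-copies of the originals and the
cluster remains detectable as a unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .panel import GenotypePanel

__all__ = [
    "TightLDClusters",
    "NeighborSet",
    "ConditionalModel",
    "KnockoffSet",
    "cluster_tight_ld",
    "select_neighbors",
    "fit_conditional_mean",
    "generate_knockoffs",
    "exchangeability_slope",
]

#: pairwise-|r| bound above which two variants share a tight-LD cluster
TIGHT_LD_R = 0.75
#: minimum |r| for a variant to enter a conditioning set
NEIGHBOR_MIN_R = 0.05
#: half-width (bp) of the window from which neighbors are drawn
NEIGHBOR_SPAN_BP = 100_000


@dataclass(frozen=True)
class TightLDClusters:
    """Cluster id per variant; cross-cluster pairs all have |r| <= 0.75."""

    assignment: np.ndarray

    def members(self, cid: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cid)


@dataclass(frozen=True)
class NeighborSet:
    """Conditioning set B_j for one target variant."""

    target: int
    members: np.ndarray
    K_cap: int


@dataclass
class ConditionalModel:
    intercept: float
    coef: np.ndarray
    fitted: np.ndarray
    residual: np.ndarray


@dataclass
class KnockoffSet:
    """M exchangeable synthetic copies of a genotype panel."""

    copies: list  # list of n x p arrays
    M: int
    seed: int

    def __getitem__(self, m: int) -> np.ndarray:
        return self.copies[m]


def exchangeability_slope(
    panel: GenotypePanel, knockoffs: "KnockoffSet", min_r: float = 0.1
) -> float:
    """Identity-regression slope of cor(G_j, G~_k) on cor(G_j, G_k), j != k.

    A valid knockoff set reproduces the original cross-correlation
    structure, so the scatter lies on the identity and the slope is ~1.
    Pairs whose sample correlation is below ``min_r`` are excluded: their
    true correlation is zero within sampling noise, and regressing noise
    on noise would attenuate the slope without measuring exchangeability.
    """
    G = panel.dosages - panel.dosages.mean(axis=0)
    sd = G.std(axis=0)
    Gs = G / np.where(sd > 0, sd, 1.0)
    C0 = Gs.T @ Gs / panel.n
    xs, ys = [], []
    for m in range(knockoffs.M):
        Gk = knockoffs[m] - knockoffs[m].mean(axis=0)
        sdk = Gk.std(axis=0)
        Gks = Gk / np.where(sdk > 0, sdk, 1.0)
        Cx = Gs.T @ Gks / panel.n
        for j in range(panel.p):
            for k in range(panel.p):
                if j != k and abs(C0[j, k]) >= min_r:
                    xs.append(C0[j, k])
                    ys.append(Cx[j, k])
    x, y = np.asarray(xs), np.asarray(ys)
    if x.size == 0:
        raise ValueError("no variant pairs exceed the correlation floor")
    return float(np.sum(x * y) / np.sum(x * x))


def _abs_corr(dosages: np.ndarray) -> np.ndarray:
    """|correlation| matrix with zero-variance columns giving r = 0."""
    X = dosages - dosages.mean(axis=0)
    sd = X.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    C = (X / safe).T @ (X / safe) / X.shape[0]
    C[sd == 0, :] = 0.0
    C[:, sd == 0] = 0.0
    np.fill_diagonal(C, 1.0)
    return np.abs(np.clip(C, -1.0, 1.0))


def cluster_tight_ld(panel: GenotypePanel) -> TightLDClusters:
    """Single-linkage clustering at distance 1 - |r|, cut at |r| = 0.75.

    Single linkage guarantees that after cutting the dendrogram no pair of
    variants in *different* clusters has |r| > 0.75 (chains of high
    correlation are absorbed into one cluster).
    """
    p = panel.p
    if p == 1:
        return TightLDClusters(np.zeros(1, dtype=int))
    R = _abs_corr(panel.dosages)
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="single")
    # cut strictly below distance 1 - 0.75 so |r| = 0.75 stays cross-cluster
    labels = fcluster(Z, t=(1.0 - TIGHT_LD_R) - 1e-12, criterion="distance")
    return TightLDClusters(labels.astype(int))


def select_neighbors(
    panel: GenotypePanel,
    clusters: TightLDClusters,
    j: int,
    abs_r: np.ndarray | None = None,
) -> NeighborSet:
    """Top-K most correlated variants near j, excluding j's tight cluster.

    Candidates must lie within +/-100 kb of the target on the same
    chromosome and have |r| > 0.05; at most ``K = floor(n^(1/3))`` are
    kept, ranked by |r| with ties broken by genomic distance, then index.
    """
    if abs_r is None:
        abs_r = _abs_corr(panel.dosages)
    K_cap = int(np.floor(panel.n ** (1.0 / 3.0) + 1e-9))
    dist = np.abs(panel.positions - panel.positions[j])
    cand = (
        (dist <= NEIGHBOR_SPAN_BP)
        & (panel.chrom == panel.chrom[j])
        & (abs_r[j] > NEIGHBOR_MIN_R)
        & (clusters.assignment != clusters.assignment[j])
    )
    idx = np.flatnonzero(cand)
    if idx.size == 0:
        return NeighborSet(j, idx, K_cap)
    order = np.lexsort((idx, dist[idx], -abs_r[j, idx]))
    return NeighborSet(j, idx[order][:K_cap], K_cap)


def fit_conditional_mean(
    g: np.ndarray, design: np.ndarray | None
) -> ConditionalModel:
    """Least-squares fit of one dosage column on a (possibly empty) design.

    Rank-deficient designs are resolved by the minimum-norm solution via a
    tiny ridge (1e-6) on the normal equations; an empty design reduces to
    the intercept-only fit (fitted = column mean).
    """
    n = g.shape[0]
    gc = g - g.mean()
    if design is None or design.size == 0:
        fitted = np.full(n, g.mean())
        return ConditionalModel(float(g.mean()), np.zeros(0), fitted, g - fitted)
    Xc = design - design.mean(axis=0)
    A = Xc.T @ Xc
    A[np.diag_indices_from(A)] += 1e-6
    coef = np.linalg.solve(A, Xc.T @ gc)
    fitted = g.mean() + Xc @ coef
    return ConditionalModel(float(g.mean()), coef, fitted, g - fitted)


def generate_knockoffs(
    panel: GenotypePanel,
    M: int = 5,
    seed: int = 0,
    clusters: TightLDClusters | None = None,
) -> KnockoffSet:
    """Generate M knockoff copies of the panel.

    Variants are processed in genomic-position order; a tight-LD cluster is
    generated jointly when its first member is reached.  For each cluster
    the conditional means of all members are fitted (excluding cluster
    co-members from the predictors), M permutations of individuals are
    drawn, and for each copy the same permutation is applied to every
    member's residual vector, preserving within-cluster residual
    correlation.  The design for variant j holds j's original neighbors
    plus all M knockoff columns of neighbors already generated, capped at
    K*(M+1) columns in |r| order.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    n, p = panel.n, panel.p
    if clusters is None:
        clusters = cluster_tight_ld(panel)
    abs_r = _abs_corr(panel.dosages)
    K_cap = int(np.floor(n ** (1.0 / 3.0) + 1e-9))
    max_cols = K_cap * (M + 1)

    copies = [np.empty((n, p)) for _ in range(M)]
    generated = np.zeros(p, dtype=bool)
    order = np.argsort(panel.positions, kind="stable")

    for j in order:
        if generated[j]:
            continue
        cid = clusters.assignment[j]
        cluster_members = np.flatnonzero(clusters.assignment == cid)
        fits = {}
        for t in cluster_members:
            nb = select_neighbors(panel, clusters, int(t), abs_r=abs_r)
            cols = [panel.dosages[:, nb.members]] if nb.members.size else []
            done = nb.members[generated[nb.members]]
            for k in done:  # |r|-sorted already
                for m in range(M):
                    cols.append(copies[m][:, k][:, None])
            design = np.hstack(cols)[:, :max_cols] if cols else None
            fits[int(t)] = fit_conditional_mean(panel.dosages[:, t], design)
        perms = [rng.permutation(n) for _ in range(M)]
        for t, model in fits.items():
            for m in range(M):
                copies[m][:, t] = model.fitted + model.residual[perms[m]]
            generated[t] = True
    return KnockoffSet(copies=copies, M=M, seed=seed)
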