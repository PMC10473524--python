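"""Between-population structure from Y-STR repeat counts.

The molecular distance between two haplotypes is the sum over loci of
squared repeat-count differences (the stepwise-mutation-consistent choice
underlying Rst); a Hamming-style step count is available by flag.  From the
pairwise distance matrix the module derives:

* mean pairwise differences within (PiX) and between (PiXY) populations and
  Nei's net divergence PiXY - (PiX + PiY)/2;
* a one-level distance-based AMOVA giving variance components and
  Rst = sigma_among / (sigma_among + sigma_within), with a label-permutation
  test;
* classical (Torgerson) metric MDS of a population distance matrix;
* agglomerative clustering (UPGMA / Ward.D2) with Newick export.

Microvariant alleles are rounded to the nearest integer (half away from
zero) before differencing, and the unphased DYS385 pair is excluded by
default; an opt-in flag differencing the ascending-sorted pair positionally
is provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from ystrkit.datamodel import HaplotypeTable, round_half_away

logger = logging.getLogger(__name__)

METRICS = ("sum_squared_steps", "step_count")


# ---------------------------------------------------------------------------
# haplotype-level distances


def profile_matrix(
    table: HaplotypeTable,
    loci: tuple[str, ...] | None = None,
    include_dys385: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Complete rows as an integer matrix plus their population labels.

    Multi-copy loci are excluded unless ``include_dys385`` adds the sorted
    pair as two positional columns.  Rows with missing data at any used
    locus are dropped.
    """
    loci = tuple(loci) if loci is not None else table.panel.loci
    single = tuple(l for l in loci if l not in table.panel.multi_copy)
    X, kept = table.integer_matrix(single)
    labels = [table.populations[i] for i in kept]
    if include_dys385:
        extra_cols = []
        multi = [l for l in loci if l in table.panel.multi_copy]
        keep2 = []
        for j, i in enumerate(kept):
            vals = []
            ok = True
            for locus in multi:
                v = table.alleles.at[i, locus]
                if v is None:
                    ok = False
                    break
                vals.extend(round_half_away(x) for x in v)
            if ok:
                extra_cols.append(vals)
                keep2.append(j)
        X = np.hstack([X[keep2], np.asarray(extra_cols, dtype=np.int64)])
        labels = [labels[j] for j in keep2]
    return X, labels


def pairwise_delta(x, y, metric: str = "sum_squared_steps", weights=None) -> float:
    """Molecular distance between two complete integer haplotype vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("haplotype vectors differ in length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing allele in distance computation")
    d = np.rint(x) - np.rint(y)
    w = np.ones_like(d) if weights is None else np.asarray(weights, dtype=float)
    if metric == "sum_squared_steps":
        return float(np.sum(w * d * d))
    if metric == "step_count":
        return float(np.sum(w * np.abs(d)))
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def delta_matrix(X: np.ndarray, metric: str = "sum_squared_steps") -> np.ndarray:
    """All-pairs molecular distance matrix for an integer profile matrix."""
    X = np.asarray(X, dtype=np.float64)
    diff = X[:, None, :] - X[None, :, :]
    if metric == "sum_squared_steps":
        return np.einsum("ijk,ijk->ij", diff, diff)
    if metric == "step_count":
        return np.abs(diff).sum(axis=2)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


# ---------------------------------------------------------------------------
# Pi matrices


@dataclass(frozen=True)
class PiMatrices:
    pops: tuple[str, ...]
    PiXY: np.ndarray  # symmetric; diagonal holds PiX
    PiX: np.ndarray  # within-population means
    corrected: np.ndarray  # PiXY - (PiX + PiY)/2; zero diagonal


@dataclass(frozen=True)
class RstResult:
    sigma_among: float
    sigma_within: float
    rst: float
    p_value: float | None = None
    n_permutations: int = 0


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        object.__setattr__(self, "values", v)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path, metric: str = "") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float), metric)


def _group_indices(labels: list[str]) -> dict[str, np.ndarray]:
    groups: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    return {k: np.asarray(v) for k, v in groups.items()}


def pi_matrices(
    table: HaplotypeTable,
    metric: str = "sum_squared_steps",
    loci: tuple[str, ...] | None = None,
    include_dys385: bool = False,
) -> PiMatrices:
    """Mean pairwise differences within/between populations and the
    corrected (net) divergence PiXY - (PiX + PiY)/2."""
    X, labels = profile_matrix(table, loci, include_dys385)
    groups = _group_indices(labels)
    if len(groups) < 2:
        raise ValueError("need >= 2 populations")
    for pop, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"population {pop!r} has < 2 complete rows")
    D = delta_matrix(X, metric)
    pops = tuple(groups)
    P = len(pops)
    pix = np.zeros(P)
    pixy = np.zeros((P, P))
    for a, pa in enumerate(pops):
        ia = groups[pa]
        sub = D[np.ix_(ia, ia)]
        pix[a] = sub[np.triu_indices(len(ia), k=1)].mean()
        pixy[a, a] = pix[a]
        for b in range(a + 1, P):
            ib = groups[pops[b]]
            pixy[a, b] = pixy[b, a] = D[np.ix_(ia, ib)].mean()
    corrected = pixy - (pix[:, None] + pix[None, :]) / 2.0
    np.fill_diagonal(corrected, 0.0)
    return PiMatrices(pops, pixy, pix, corrected)


# ---------------------------------------------------------------------------
# AMOVA / Rst


def _amova_components(D: np.ndarray, groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """One-level distance-based AMOVA variance components (sigma_a, sigma_w).

    SSD(total) = sum_{i<j} d_ij / N; SSD(within) = sum_p sum_{i<j in p} d_ij / n_p;
    sigma_w = SSD(within)/(N-P); sigma_a = (SSD(among)/(P-1) - sigma_w)/n_bar
    with n_bar = (N - sum n_p^2 / N)/(P-1), the standard unequal-size
    coefficient.
    """
    N = D.shape[0]
    P = len(groups)
    if N <= P:
        raise ValueError(
            "AMOVA needs at least one population with more than one member "
            f"(N={N}, P={P}: no within-population degrees of freedom)"
        )
    ssd_total = D[np.triu_indices(N, k=1)].sum() / N
    ssd_within = 0.0
    for idx in groups.values():
        sub = D[np.ix_(idx, idx)]
        ssd_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / (N - P)
    n_bar = (N - sum(len(idx) ** 2 for idx in groups.values()) / N) / (P - 1)
    sigma_a = (ssd_among / (P - 1) - sigma_w) / n_bar
    return sigma_a, sigma_w


def _rst_from_components(sigma_a: float, sigma_w: float) -> float:
    tot = sigma_a + sigma_w
    if tot == 0.0:
        return 0.0
    return sigma_a / tot


def amova_rst(
    table: HaplotypeTable,
    metric: str = "sum_squared_steps",
    permutations: int = 0,
    seed: int | None = None,
    loci: tuple[str, ...] | None = None,
    include_dys385: bool = False,
) -> RstResult:
    """One-level AMOVA Rst over the table's population labels.

    With ``permutations > 0`` a label-permutation test is run; the observed
    statistic is included in the null set (the standard +1 correction), so
    p = (1 + #{Rst* >= Rst}) / (permutations + 1).  A seed is mandatory for
    a permutation test (reproducibility contract).
    """
    if permutations > 0 and seed is None:
        raise ValueError("permutation test requires a seed")
    X, labels = profile_matrix(table, loci, include_dys385)
    groups = _group_indices(labels)
    if len(groups) < 2:
        raise ValueError("need >= 2 populations")
    D = delta_matrix(X, metric)
    sigma_a, sigma_w = _amova_components(D, groups)
    rst = _rst_from_components(sigma_a, sigma_w)
    p_value = None
    if permutations > 0:
        rng = np.random.default_rng(seed)
        lab = np.asarray(labels)
        hits = 1  # observed statistic counts as one null draw
        for _ in range(permutations):
            perm = rng.permutation(len(lab))
            pg = _group_indices(list(lab[perm]))
            sa, sw = _amova_components(D, pg)
            if _rst_from_components(sa, sw) >= rst - 1e-12:
                hits += 1
        p_value = hits / (permutations + 1)
    return RstResult(sigma_a, sigma_w, rst, p_value, permutations)


def rst_matrix(
    table: HaplotypeTable,
    metric: str = "sum_squared_steps",
    loci: tuple[str, ...] | None = None,
    include_dys385: bool = False,
) -> DistanceMatrix:
    """Pairwise-population Rst matrix (negative estimates retained)."""
    pops = list(dict.fromkeys(table.populations))
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    by_pop = table.by_population()
    P = len(pops)
    vals = np.zeros((P, P))
    for a in range(P):
        for b in range(a + 1, P):
            sub = by_pop[pops[a]]
            other = by_pop[pops[b]]
            pair = HaplotypeTable(
                sub.sample_ids + other.sample_ids,
                sub.populations + other.populations,
                pd.concat([sub.alleles, other.alleles], ignore_index=True),
                table.panel,
            )
            res = amova_rst(pair, metric, loci=loci, include_dys385=include_dys385)
            vals[a, b] = vals[b, a] = res.rst
    return DistanceMatrix(tuple(pops), vals, metric=f"rst[{metric}]")


# ---------------------------------------------------------------------------
# MDS


@dataclass(frozen=True)
class MdsResult:
    labels: tuple[str, ...]
    coordinates: np.ndarray  # labels x dims, axes ordered by eigenvalue
    eigenvalues: np.ndarray  # all eigenvalues, descending
    positive_mass_captured: float  # share of positive-eigenvalue mass in the kept axes


def classical_mds(D: DistanceMatrix, dims: int = 2) -> MdsResult:
    """Classical (Torgerson) metric MDS.

    Negative dissimilarities (possible for Rst) are clipped to zero with a
    log message.  The double-centred Gram matrix B = -1/2 J (D*D) J is
    eigendecomposed; coordinates are the top-``dims`` axes scaled by the
    square roots of their eigenvalues.  Deterministic up to the sign of each
    axis.
    """
    vals = np.array(D.values, dtype=float)
    if (vals < 0).any():
        logger.info("classical_mds: clipping %d negative entries to 0", int((vals < 0).sum()))
        vals = np.clip(vals, 0.0, None)
    n = vals.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (vals * vals) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_pos = int((eigval > 1e-12).sum())
    if dims > n_pos:
        logger.warning(
            "classical_mds: only %d positive eigenvalues for %d requested dims; padding with zeros",
            n_pos,
            dims,
        )
    coords = np.zeros((n, dims))
    k = min(dims, n_pos)
    coords[:, :k] = eigvec[:, :k] * np.sqrt(eigval[:k])
    pos_mass = eigval[eigval > 1e-12].sum()
    captured = float(eigval[:k].sum() / pos_mass) if pos_mass > 0 else 0.0
    return MdsResult(D.labels, coords, eigval, captured)


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass(frozen=True)
class ClusterResult:
    labels: tuple[str, ...]
    assignments: dict[str, int]
    linkage_matrix: np.ndarray
    method: str

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge heights as branch lengths."""
        n = len(self.labels)
        Z = self.linkage_matrix
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h, _cnt) in enumerate(Z):
            a, b = int(a), int(b)
            left = f"{node[a]}:{h - height[a]:.6g}"
            right = f"{node[b]}:{h - height[b]:.6g}"
            node[n + k] = f"({left},{right})"
            height[n + k] = h
        return node[n + len(Z) - 1] + ";"


def hierarchical_clusters(
    D: DistanceMatrix, linkage: str = "upgma", k: int = 2
) -> ClusterResult:
    """Agglomerative clustering of a population distance matrix.

    ``upgma`` is average linkage; ``ward`` follows the Ward.D2 convention
    (squared dissimilarities).  Cutting the tree at ``k`` clusters yields the
    partition.  Negative dissimilarities are clipped to zero.
    """
    methods = {"upgma": "average", "ward": "ward"}
    if linkage not in methods:
        raise ValueError(f"unknown linkage {linkage!r}; choose from {sorted(methods)}")
    n = len(D.labels)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range 1..{n}")
    vals = np.clip(D.values, 0.0, None)
    Z = sch.linkage(squareform(vals, checks=False), method=methods[linkage])
    flat = sch.fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(D.labels, dict(zip(D.labels, map(int, flat))), Z, linkage)
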