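"""Signed bicor/TOM co-expression network with adaptive tree cutting.

The network is built in a single block: biweight midcorrelation of all
protein pairs, signed soft-threshold adjacency a_ij = ((1+cor)/2)^beta,
mean-denominator topological overlap, average-linkage clustering of
1 - TOM, an adaptive (dynamic-hybrid style) branch cut with a PAM
assignment stage, eigenprotein-based merging of near-duplicate modules,
and finally iterative kME reassignment under three membership rules:

1. a protein moves to the module of its best kME when that best kME
   exceeds its current module's kME by more than ``kme_max_gap``;
2. an unassigned protein is assigned whenever some kME exceeds
   ``kme_assign_min``;
3. a protein is unassigned (grey, M0) when all its kMEs fall below
   ``kme_assign_min``.

Modules are named M1..Mk by decreasing member count; M0 collects
unassigned proteins.  Eigenproteins are unit-variance first principal
component scores, signed so the mean member correlation is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._bicor import bicor_matrix_kernel, bicor_cross_kernel, MIN_PAIR_OBS

GREY = "M0"

# Core-scatter presets for deep-split levels 0..4 (most aggressive last);
# the minimum-gap requirement is 3/4 of the scatter headroom.  Both are
# expressed relative to the dendrogram height range between the 5th
# percentile of merge heights and the cut height.
DEEP_SPLIT_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)


@dataclass
class NetworkParams:
    """Network construction parameters (defaults: signed bicor network,
    soft power 9, deep split 4, minimum module size 20, merge cut height
    0.07, mean TOM denominator, PAM stage respecting the dendrogram,
    kME assignment floor 0.30 with a 0.10 gap over at most 30
    reassignment iterations)."""

    soft_power: float = 9.0
    deep_split: int = 4
    min_module_size: int = 20
    merge_cut_height: float = 0.07
    tom_denominator: str = "mean"
    network_sign: str = "signed"
    pam_stage: bool = True
    pam_respects_dendro: bool = True
    kme_assign_min: float = 0.30
    kme_max_gap: float = 0.10
    reassign_max_iter: int = 30
    cut_height_fraction: float = 0.99

    def __post_init__(self):
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if not 0 < self.merge_cut_height < 1:
            raise ValueError("merge_cut_height must lie in (0, 1)")
        for name in ("kme_assign_min", "kme_max_gap"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.deep_split not in range(len(DEEP_SPLIT_CORE_SCATTER)):
            raise ValueError("deep_split must be an integer in 0..4")


@dataclass
class ModulePartition:
    labels: pd.Series                 # protein -> M1..Mk or M0
    eigenproteins: pd.DataFrame       # modules x samples, unit variance
    kme: pd.DataFrame                 # proteins x modules
    proportion_variance: pd.Series    # per module
    n_reassign_iterations: int = 0
    converged: bool = True
    params: dict = field(default_factory=dict)

    @property
    def module_sizes(self) -> pd.Series:
        sizes = self.labels[self.labels != GREY].value_counts()
        return sizes.reindex(self.eigenproteins.index).fillna(0).astype(int)


# --------------------------------------------------------------------------
# correlation


def bicor(x, y) -> float:
    """Biweight midcorrelation of two vectors, pairwise-complete.

    Falls back to Pearson when either vector's MAD is zero (with a
    warning); returns NaN when fewer than 4 paired observations remain.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < MIN_PAIR_OBS:
        warnings.warn("bicor: fewer than 4 paired observations", stacklevel=2)
        return float("nan")
    x, y = x[ok], y[ok]
    mx, my = np.median(x), np.median(y)
    madx = np.median(np.abs(x - mx))
    mady = np.median(np.abs(y - my))
    if madx == 0.0 or mady == 0.0:
        warnings.warn("bicor: zero MAD, falling back to Pearson", stacklevel=2)
        xs = x - x.mean()
        ys = y - y.mean()
        den = np.sqrt((xs**2).sum() * (ys**2).sum())
        return float("nan") if den == 0 else float((xs * ys).sum() / den)
    ux = (x - mx) / (9.0 * madx)
    uy = (y - my) / (9.0 * mady)
    wx = np.where(np.abs(ux) < 1, (1 - ux**2) ** 2, 0.0)
    wy = np.where(np.abs(uy) < 1, (1 - uy**2) ** 2, 0.0)
    xt = (x - mx) * wx
    yt = (y - my) * wy
    den = np.sqrt((xt**2).sum() * (yt**2).sum())
    if den == 0:
        return float("nan")
    return float(np.clip((xt * yt).sum() / den, -1.0, 1.0))


def bicor_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """All-pairs bicor of protein profiles (rows), pairwise-complete.

    Pairs with fewer than 4 shared samples come back NaN; callers that
    build adjacencies treat NaN as correlation 0 (neutral adjacency).
    """
    X = matrix.to_numpy(float)
    M = np.isfinite(X)
    C, n_fb = bicor_matrix_kernel(np.where(M, X, 0.0), M)
    if n_fb:
        warnings.warn(f"bicor_matrix: {n_fb} pairs used a Pearson fallback "
                      "or had <4 complete observations", stacklevel=2)
    return pd.DataFrame(C, index=matrix.index, columns=matrix.index)


# --------------------------------------------------------------------------
# adjacency / TOM


def signed_adjacency(cor, beta: float = 9.0) -> np.ndarray:
    """Signed soft-threshold adjacency a_ij = ((1 + cor_ij)/2)^beta.

    NaN correlations become neutral (cor 0); the diagonal is zeroed for
    connectivity computations.
    """
    c = np.asarray(cor, float)
    if np.nanmax(np.abs(c)) > 1 + 1e-12:
        raise ValueError("correlations must lie in [-1, 1]")
    a = ((1.0 + np.where(np.isnan(c), 0.0, c)) / 2.0) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def tom_similarity(adjacency, denominator: str = "mean") -> np.ndarray:
    """Topological overlap matrix from a symmetric, zero-diagonal adjacency.

    TOM_ij = (L_ij + a_ij) / (D_ij + 1 - a_ij) with L_ij the shared
    neighbour weight sum and D_ij the mean (or min) of the two node
    connectivities; TOM_ii = 1.
    """
    A = np.asarray(adjacency, float)
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    L = A @ A                     # zero diagonal makes this exclude u in {i, j}
    if denominator == "mean":
        D = (k[:, None] + k[None, :]) / 2.0
    elif denominator == "min":
        D = np.minimum(k[:, None], k[None, :])
    else:
        raise ValueError(f"unknown TOM denominator {denominator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A) / (D + 1.0 - A)
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


# --------------------------------------------------------------------------
# average-linkage clustering (own implementation: deterministic
# lowest-index tie-breaking, scipy-compatible linkage matrix)


def cluster_dendrogram(dissimilarity) -> np.ndarray:
    """Average-linkage merge tree of a symmetric dissimilarity matrix.

    Returns a (n-1) x 4 linkage matrix in scipy convention (children,
    height, size).  Equal dissimilarities are broken toward the lowest
    cluster indices, so merge order is fully deterministic.
    """
    D = np.asarray(dissimilarity, float).copy()
    n = D.shape[0]
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("dissimilarity must be square and symmetric")
    if not np.isfinite(D).all():
        raise ValueError("dissimilarity contains non-finite values")
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, bool)
    sizes = np.ones(n)
    ids = np.arange(n)            # current scipy cluster id per slot
    Z = np.empty((n - 1, 4))
    for step in range(n - 1):
        sub = np.where(active)[0]
        block = D[np.ix_(sub, sub)]
        flat = np.argmin(block)   # first occurrence = lowest (i, j) pair
        i_s, j_s = divmod(flat, block.shape[1])
        if i_s > j_s:
            i_s, j_s = j_s, i_s
        i, j = sub[i_s], sub[j_s]
        h = D[i, j]
        a, b = sorted((ids[i], ids[j]))
        Z[step] = (a, b, h, sizes[i] + sizes[j])
        # Lance-Williams average-linkage update into slot i
        ni, nj = sizes[i], sizes[j]
        new = (ni * D[i, :] + nj * D[j, :]) / (ni + nj)
        D[i, :] = new
        D[:, i] = new
        D[i, i] = np.inf
        active[j] = False
        D[j, :] = np.inf
        D[:, j] = np.inf
        sizes[i] = ni + nj
        ids[i] = n + step
    return Z


def _tree_arrays(Z: np.ndarray, n: int):
    """Leaf membership and height per node (leaves 0..n-1, merges n..2n-2)."""
    members: list[np.ndarray] = [np.array([i]) for i in range(n)]
    heights = np.zeros(2 * n - 1)
    for step in range(n - 1):
        a, b = int(Z[step, 0]), int(Z[step, 1])
        members.append(np.concatenate([members[a], members[b]]))
        heights[n + step] = Z[step, 2]
    return members, heights


# --------------------------------------------------------------------------
# adaptive branch cut


def dynamic_hybrid_cut(Z: np.ndarray, dissimilarity, params: NetworkParams) -> np.ndarray:
    """Adaptive branch cut of an average-linkage tree.

    Branches are split top-down wherever the merge gap is informative
    and both sub-branches are large enough; small side branches become
    strays.  A candidate branch survives as a module only if it has at
    least ``min_module_size`` members and its mean within-branch
    dissimilarity (core scatter) stays below a deep-split-controlled
    bound.  The optional PAM stage then assigns strays to the module
    with the smallest average dissimilarity, restricted to modules in
    the same static-cut component when ``pam_respects_dendro``.

    Returns integer labels, 0 marking unassigned objects.
    """
    D = np.asarray(dissimilarity, float)
    n = D.shape[0]
    members, heights = _tree_arrays(Z, n)
    merge_h = Z[:, 2]
    cut_height = params.cut_height_fraction * merge_h.max() if n > 1 else 0.0
    ref_height = np.percentile(merge_h, 5) if n > 1 else 0.0
    span = max(cut_height - ref_height, 1e-12)
    mcs = DEEP_SPLIT_CORE_SCATTER[params.deep_split]
    max_scatter = ref_height + mcs * span
    min_gap = (1.0 - mcs) * 0.75 * span
    min_size = params.min_module_size

    children = {n + s: (int(Z[s, 0]), int(Z[s, 1])) for s in range(n - 1)}

    # static-cut components: merges at or below the cut height
    absorbed = set()
    comp_roots = []
    for s in range(n - 1):
        if Z[s, 2] <= cut_height:
            absorbed.add(int(Z[s, 0]))
            absorbed.add(int(Z[s, 1]))
    for node in range(2 * n - 1):
        if node in absorbed:
            continue
        if node >= n and heights[node] > cut_height:
            continue
        comp_roots.append(node)
    singles = [node for node in range(n) if node not in absorbed]
    comp_roots = sorted(set(comp_roots) | set(singles))

    def scatter(idx: np.ndarray) -> float:
        if idx.size < 2:
            return 0.0
        sub = D[np.ix_(idx, idx)]
        m = idx.size
        return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))

    labels = np.zeros(n, int)
    strays: list[int] = []
    comp_of = np.full(n, -1, int)
    clusters: list[tuple[np.ndarray, int]] = []   # (member idx, component id)

    def split(node: int, out: list[np.ndarray], stray_out: list[int]) -> None:
        size = members[node].size
        if node < n or size < 2 * min_size:
            out.append(members[node])
            return
        left, right = children[node]
        gap = heights[node] - max(heights[left], heights[right])
        v_l = members[left].size >= min_size
        v_r = members[right].size >= min_size
        if gap >= min_gap and v_l and v_r:
            split(left, out, stray_out)
            split(right, out, stray_out)
        elif gap >= min_gap and v_l and not v_r:
            stray_out.extend(members[right].tolist())
            split(left, out, stray_out)
        elif gap >= min_gap and v_r and not v_l:
            stray_out.extend(members[left].tolist())
            split(right, out, stray_out)
        else:
            out.append(members[node])

    for cid, root in enumerate(comp_roots):
        comp_of[members[root]] = cid
        if members[root].size < min_size:
            strays.extend(members[root].tolist())
            continue
        cands: list[np.ndarray] = []
        split(root, cands, strays)
        for cand in cands:
            if cand.size >= min_size and scatter(cand) <= max_scatter:
                clusters.append((cand, cid))
            else:
                strays.extend(cand.tolist())

    for k, (idx, _) in enumerate(clusters, start=1):
        labels[idx] = k

    if params.pam_stage and clusters and strays:
        for obj in strays:
            best, best_d = 0, np.inf
            for k, (idx, cid) in enumerate(clusters, start=1):
                if params.pam_respects_dendro and cid != comp_of[obj]:
                    continue
                d = float(D[obj, idx].mean())
                if d < best_d:
                    best, best_d = k, d
            if best and best_d <= cut_height:
                labels[obj] = best
    return labels


# --------------------------------------------------------------------------
# eigenproteins, merging, kME


def _standardized_rows(matrix: pd.DataFrame) -> np.ndarray:
    """Rows standardized to mean 0 / SD 1, missing cells mean-imputed
    (imputation is for this computation only)."""
    X = matrix.to_numpy(float)
    mean = np.nanmean(X, axis=1, keepdims=True)
    X = np.where(np.isnan(X), mean, X)
    X = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return X / sd


def module_eigenproteins(matrix: pd.DataFrame, labels: pd.Series
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """First-principal-component summary profile per module.

    Returns (eigenproteins, proportion of variance explained).  The
    eigenprotein has unit variance over samples and is signed so the
    mean member correlation with it is positive.  A singleton module's
    eigenprotein is its standardized member (flagged via a warning).
    """
    modules = [m for m in labels.unique() if m != GREY]
    rows, pves = [], []
    for mod in modules:
        sub = matrix.loc[labels.index[labels == mod]]
        X = _standardized_rows(sub)
        if X.shape[0] == 1:
            warnings.warn(f"module {mod}: single member, eigenprotein is the "
                          "standardized profile", stacklevel=2)
            e = X[0]
            pve = 1.0
        else:
            U, S, Vt = np.linalg.svd(X, full_matrices=False)
            e = Vt[0]
            pve = float(S[0] ** 2 / (S**2).sum())
        e = e - e.mean()
        sd = e.std()
        e = e / sd if sd > 0 else e
        mean_cor = np.mean(X @ e) / len(e)   # mean member covariance with e
        if mean_cor < 0:
            e = -e
        rows.append(e)
        pves.append(pve)
    eig = pd.DataFrame(rows, index=pd.Index(modules, name="module"),
                       columns=matrix.columns)
    return eig, pd.Series(pves, index=eig.index, name="proportion_variance")


def kme_table(matrix: pd.DataFrame, eigenproteins: pd.DataFrame) -> pd.DataFrame:
    """kME_pm = bicor(protein p, eigenprotein m), pairwise-complete."""
    X = matrix.to_numpy(float)
    MX = np.isfinite(X)
    Y = eigenproteins.to_numpy(float)
    MY = np.isfinite(Y)
    K = bicor_cross_kernel(np.where(MX, X, 0.0), MX, np.where(MY, Y, 0.0), MY)
    return pd.DataFrame(K, index=matrix.index, columns=eigenproteins.index)


def merge_close_modules(matrix: pd.DataFrame, labels: pd.Series,
                        merge_cut_height: float = 0.07) -> pd.Series:
    """Merge modules whose eigenproteins are nearly identical.

    Iteratively: compute eigenproteins, find the closest module pair by
    1 - Pearson correlation, merge it if below ``merge_cut_height``,
    recompute, repeat until no pair is close enough.  Merging closest
    pairs first makes the fixed point independent of label order.
    """
    labels = labels.copy()
    while True:
        modules = [m for m in labels.unique() if m != GREY]
        if len(modules) < 2:
            return labels
        eig, _ = module_eigenproteins(matrix, labels)
        E = eig.to_numpy()
        C = np.corrcoef(E)
        diss = 1.0 - C
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_cut_height:
            return labels
        keep, drop = eig.index[i], eig.index[j]
        labels[labels == drop] = keep


def _rename_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != GREY].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], str(m)))
    mapping = {old: f"M{i + 1}" for i, old in enumerate(order)}
    mapping[GREY] = GREY
    return labels.map(mapping)


def iterative_reassignment(matrix: pd.DataFrame, labels: pd.Series,
                           params: NetworkParams | None = None) -> ModulePartition:
    """Apply the three kME membership rules until no label changes.

    Eigenproteins and kMEs are recomputed every iteration.  Returns the
    final partition with modules renamed M1..Mk by decreasing size and
    a ``converged`` flag (False when ``reassign_max_iter`` is hit).
    """
    params = params or NetworkParams()
    labels = labels.astype(object).copy()
    amin, gap_max = params.kme_assign_min, params.kme_max_gap
    converged = False
    n_iter = 0
    seen: set[int] = set()
    for n_iter in range(1, params.reassign_max_iter + 1):
        present = [m for m in labels.unique() if m != GREY]
        if not present:
            converged = True
            break
        eig, _ = module_eigenproteins(matrix, labels)
        kme = kme_table(matrix, eig)
        K = np.nan_to_num(kme.to_numpy(), nan=0.0)
        kmax = K.max(axis=1)
        argmax = np.asarray(kme.columns)[K.argmax(axis=1)]
        new = labels.to_numpy(object).copy()
        cur = labels.to_numpy(object)
        col_of = {m: i for i, m in enumerate(kme.columns)}
        cur_k = np.array([K[r, col_of[c]] if c in col_of else -np.inf
                          for r, c in enumerate(cur)])
        move = (cur != GREY) & ((kmax - cur_k) > gap_max)
        assign = (cur == GREY) & (kmax > amin)
        new[move] = argmax[move]
        new[assign] = argmax[assign]
        new[kmax < amin] = GREY
        # modules shrunk below the minimum size dissolve to grey; the
        # assignment rule re-homes their members next iteration
        counts = pd.Series(new).value_counts()
        for mod, cnt in counts.items():
            if mod != GREY and cnt < params.min_module_size:
                new[new == mod] = GREY
        if (new == cur).all():
            converged = True
            break
        state = hash(tuple(new))
        if state in seen:        # limit cycle: further iteration is futile
            labels = pd.Series(new, index=labels.index, name="module")
            break
        seen.add(state)
        labels = pd.Series(new, index=labels.index, name="module")
    labels = _rename_by_size(labels)
    eig, pve = module_eigenproteins(matrix, labels)
    order = eig.index.tolist()
    kme = kme_table(matrix, eig)
    return ModulePartition(labels=labels, eigenproteins=eig, kme=kme,
                           proportion_variance=pve,
                           n_reassign_iterations=n_iter, converged=converged,
                           params=asdict(params))


# --------------------------------------------------------------------------
# orchestration


def build_network(matrix: pd.DataFrame, params: NetworkParams | None = None
                  ) -> ModulePartition:
    """Full single-block network build: bicor -> adjacency -> TOM ->
    average linkage -> adaptive cut (+PAM) -> module merge -> iterative
    kME reassignment."""
    params = params or NetworkParams()
    cor = bicor_matrix(matrix)
    A = signed_adjacency(cor.to_numpy(), params.soft_power)
    tom = tom_similarity(A, params.tom_denominator)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    Z = cluster_dendrogram(diss)
    raw = dynamic_hybrid_cut(Z, diss, params)
    labels = pd.Series([f"M{v}" if v else GREY for v in raw],
                       index=matrix.index, name="module")
    if (labels != GREY).any():
        labels = merge_close_modules(matrix, labels, params.merge_cut_height)
    return iterative_reassignment(matrix, labels, params)


class CoexpressionNetwork(BaseEstimator):
    """Estimator wrapper around :func:`build_network`.

    ``fit(X)`` takes a proteins x samples log2 abundance DataFrame and
    exposes ``labels_``, ``eigenproteins_``, ``kme_``,
    ``proportion_variance_`` and the full ``partition_``.
    """

    def __init__(self, soft_power: float = 9.0, deep_split: int = 4,
                 min_module_size: int = 20, merge_cut_height: float = 0.07,
                 tom_denominator: str = "mean", pam_stage: bool = True,
                 pam_respects_dendro: bool = True, kme_assign_min: float = 0.30,
                 kme_max_gap: float = 0.10, reassign_max_iter: int = 30):
        self.soft_power = soft_power
        self.deep_split = deep_split
        self.min_module_size = min_module_size
        self.merge_cut_height = merge_cut_height
        self.tom_denominator = tom_denominator
        self.pam_stage = pam_stage
        self.pam_respects_dendro = pam_respects_dendro
        self.kme_assign_min = kme_assign_min
        self.kme_max_gap = kme_max_gap
        self.reassign_max_iter = reassign_max_iter

    def _params(self) -> NetworkParams:
        return NetworkParams(
            soft_power=self.soft_power, deep_split=self.deep_split,
            min_module_size=self.min_module_size,
            merge_cut_height=self.merge_cut_height,
            tom_denominator=self.tom_denominator, pam_stage=self.pam_stage,
            pam_respects_dendro=self.pam_respects_dendro,
            kme_assign_min=self.kme_assign_min, kme_max_gap=self.kme_max_gap,
            reassign_max_iter=self.reassign_max_iter)

    def fit(self, X: pd.DataFrame, y=None) -> "CoexpressionNetwork":
        part = build_network(X, self._params())
        self.partition_ = part
        self.labels_ = part.labels
        self.eigenproteins_ = part.eigenproteins
        self.kme_ = part.kme
        self.proportion_variance_ = part.proportion_variance
        return self

    def fit_predict(self, X: pd.DataFrame, y=None) -> pd.Series:
        return self.fit(X).labels_
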