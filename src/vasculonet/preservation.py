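"""Permutation Zsummary module-preservation statistics.

For each reference-network module the question is whether its members
still behave like a module in a second (test) network.  Three density
statistics measure cohesion of the member set in the test data (mean
signed correlation, mean adjacency, proportion of variance explained
by the set's eigenprotein) and three connectivity statistics measure
agreement of network position between reference and test (correlation
of intramodular connectivity, of kME, and of the within-module
correlation entries).  Each observed statistic is standardized against
random same-size protein sets drawn from the test network:
Z = (observed - null mean) / null SD.  Zdensity and Zconnectivity are
the medians of their statistic groups and Zsummary their mean, with
one-sided upper-tail normal p.  Zsummary below 1.96 reads as not
preserved, 1.96..10 as moderate, above 10 as high preservation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .network import bicor_matrix, GREY

DENSITY_STATS = ("mean_signed_cor", "mean_adjacency", "prop_var_explained")
CONNECTIVITY_STATS = ("cor_kIM", "cor_kME", "cor_cor")


@dataclass
class PreservationResult:
    table: pd.DataFrame            # per module: observed stats, Zs, p
    n_permutations: int
    seed: int | None

    def zsummary(self) -> pd.Series:
        return self.table["Zsummary"]


def z_to_p(z) -> float | np.ndarray:
    """One-sided upper-tail standard normal p, full precision in the far
    tail (no 1 - CDF cancellation)."""
    return sps.norm.sf(z)


def classify_preservation(result: PreservationResult) -> pd.Series:
    """Zsummary < 1.96: not preserved; 1.96..10: moderate; > 10: high."""
    z = result.table["Zsummary"]
    cat = pd.Series("moderate", index=z.index, name="preservation")
    cat[z < 1.96] = "not preserved"
    cat[z > 10] = "high"
    return cat


def _set_stats(idx: np.ndarray, cor_ref: np.ndarray, cor_test: np.ndarray,
               Xr: np.ndarray, Xt: np.ndarray, beta: float) -> np.ndarray:
    """The six preservation statistics for one protein set."""
    m = idx.size
    ct = cor_test[np.ix_(idx, idx)]
    cr = cor_ref[np.ix_(idx, idx)]
    iu = np.triu_indices(m, k=1)
    off_t = ct[iu]
    off_r = cr[iu]
    mean_cor = off_t.mean()
    adj_t = ((1.0 + ct) / 2.0) ** beta
    adj_r = ((1.0 + cr) / 2.0) ** beta
    np.fill_diagonal(adj_t, 0.0)
    np.fill_diagonal(adj_r, 0.0)
    mean_adj = adj_t[iu].mean()

    def eig_and_kme(X):
        Xs = X[idx]
        Xs = Xs - Xs.mean(axis=1, keepdims=True)
        sd = Xs.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        Xs = Xs / sd
        U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
        e = Vt[0]
        pve = S[0] ** 2 / (S**2).sum()
        if np.mean(Xs @ e) < 0:
            e = -e
        n = Xs.shape[1]
        kme = (Xs @ e) / (n * max(e.std(), 1e-12))
        return float(pve), kme

    pve_t, kme_t = eig_and_kme(Xt)
    _, kme_r = eig_and_kme(Xr)

    def safe_cor(a, b):
        if a.std() == 0 or b.std() == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    k_r = adj_r.sum(axis=1)
    k_t = adj_t.sum(axis=1)
    return np.array([
        mean_cor, mean_adj, pve_t,
        safe_cor(k_r, k_t), safe_cor(kme_r, kme_t), safe_cor(off_r, off_t),
    ])


def module_preservation(reference: pd.DataFrame, labels: pd.Series,
                        test: pd.DataFrame, n_permutations: int = 500,
                        seed: int | None = None, beta: float = 9.0,
                        min_module_size: int = 3) -> PreservationResult:
    """Zsummary preservation of reference modules in a test network.

    Modules are evaluated on the protein intersection of the two
    matrices; modules with fewer than ``min_module_size`` intersecting
    proteins are skipped with a warning column.  Null sets are drawn
    uniformly without replacement from the test network's proteins.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1 (null undefined otherwise)")
    shared = reference.index.intersection(test.index)
    ref = reference.loc[shared]
    tst = test.loc[shared]
    lab = labels.reindex(shared)
    cor_ref = bicor_matrix(ref).to_numpy()
    cor_test = bicor_matrix(tst).to_numpy()
    np.nan_to_num(cor_ref, copy=False)
    np.nan_to_num(cor_test, copy=False)
    Xr = np.nan_to_num(ref.to_numpy(float),
                       nan=np.nanmean(ref.to_numpy(float)))
    Xt = np.nan_to_num(tst.to_numpy(float),
                       nan=np.nanmean(tst.to_numpy(float)))

    rng = np.random.default_rng(seed)
    modules = [m for m in pd.unique(lab.dropna()) if m != GREY]
    pos = {p: i for i, p in enumerate(shared)}
    rows = []
    stat_names = DENSITY_STATS + CONNECTIVITY_STATS
    n_total = len(shared)
    null_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for mod in modules:
        idx = np.array([pos[p] for p in lab.index[lab == mod]])
        if idx.size < min_module_size:
            continue
        obs = _set_stats(idx, cor_ref, cor_test, Xr, Xt, beta)
        m = idx.size
        if m not in null_cache:
            null = np.empty((n_permutations, 6))
            for b in range(n_permutations):
                rand = rng.choice(n_total, size=m, replace=False)
                null[b] = _set_stats(rand, cor_ref, cor_test, Xr, Xt, beta)
            null_cache[m] = (null.mean(axis=0), null.std(axis=0, ddof=1))
        mu, sd = null_cache[m]
        z = np.where(sd > 1e-12, (obs - mu) / np.where(sd == 0, 1.0, sd), 0.0)
        z_density = float(np.median(z[:3]))
        z_conn = float(np.median(z[3:]))
        z_summary = (z_density + z_conn) / 2.0
        row = {"module": mod, "module_size": m,
               "Zdensity": z_density, "Zconnectivity": z_conn,
               "Zsummary": z_summary, "p": float(z_to_p(z_summary))}
        row.update({f"obs_{s}": obs[i] for i, s in enumerate(stat_names)})
        row.update({f"null_mean_{s}": mu[i] for i, s in enumerate(stat_names)})
        row.update({f"null_sd_{s}": sd[i] for i, s in enumerate(stat_names)})
        rows.append(row)
    table = pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame()
    return PreservationResult(table=table, n_permutations=n_permutations,
                              seed=seed)
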