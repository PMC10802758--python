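"""Sample QC and nuisance-variance removal.

Three stages: per-sample cell-type marker scores (the mean z-score of a
cell type's marker proteins stands in for its proportion), flagging of
fractionation failures (samples depleted of endothelial signal but
enriched for neuronal proteins), and nonparametric bootstrap regression
that subtracts nuisance covariate contributions (neuronal score, age,
sex, PMI, TMT batch) while *protecting* diagnosis effects: diagnosis
terms are in the model so nuisance coefficients are estimated
conditional on them, but their contribution is never subtracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

DEFAULT_NUISANCE = ("neuronal_score", "age", "sex", "PMI", "batch")
DEFAULT_PROTECTED = ("diagnosis",)


@dataclass
class RegressionReport:
    coefficients: pd.DataFrame        # protein x term, median bootstrap coefficient
    n_boot: int
    seed: int | None
    protected_terms: list[str]
    nuisance_terms: list[str]
    excluded_samples: list[str]


def score_cell_types(matrix: pd.DataFrame, markers: dict[str, set[str]],
                     min_markers: int = 3) -> pd.DataFrame:
    """Per-sample cell-type enrichment z-scores.

    Each protein is z-scored across samples (missing ignored; zero-SD
    proteins score 0 everywhere); a sample's score for a cell type is
    the mean z over that type's marker proteins found in the matrix.
    Cell types matching fewer than ``min_markers`` proteins are dropped
    with a warning.
    """
    from .io import symbol_of
    X = matrix.to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(X, axis=1, keepdims=True)
        sd = np.nanstd(X, axis=1, keepdims=True)
    z = np.where(sd > 0, (X - mean) / np.where(sd == 0, 1.0, sd), 0.0)
    sym = pd.Index([symbol_of(p) for p in matrix.index])
    scores = {}
    for ct, syms in markers.items():
        rows = np.flatnonzero(sym.isin({s.upper() for s in syms}))
        if rows.size < min_markers:
            warnings.warn(f"cell type {ct!r}: only {rows.size} markers matched; "
                          "excluded", stacklevel=2)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            scores[ct] = np.nanmean(z[rows], axis=0)
    out = pd.DataFrame(scores, index=matrix.columns)
    out.index.name = "sample"
    return out


def flag_outliers(scores: pd.DataFrame, endothelial_floor_z: float = -2.0,
                  neuronal_ceiling_z: float = 2.0,
                  endothelial: str = "endothelial",
                  neuronal: str = "neuron") -> list[str]:
    """Samples lacking endothelial enrichment *and* enriched for neurons.

    Flags samples with endothelial z below the floor and neuronal z
    above the ceiling; both thresholds configurable (an infinite floor
    vacuously flags nothing).
    """
    if endothelial not in scores.columns or neuronal not in scores.columns:
        return []
    lo = scores[endothelial] < endothelial_floor_z
    hi = scores[neuronal] > neuronal_ceiling_z
    return scores.index[lo & hi].tolist()


def _build_design(traits: pd.DataFrame, scores: pd.DataFrame | None,
                  nuisance, protected):
    """Design blocks per term; categorical terms one-hot with first level
    as reference.  Returns (column matrix, column names, term of each
    column, samples used, excluded samples)."""
    cols, names, terms = [], [], []
    frames = {}
    for term in list(nuisance) + list(protected):
        if term == "batch":
            frames[term] = traits["batch"].astype(str)
        elif term == "neuronal_score":
            if scores is None or "neuron" not in scores.columns:
                raise ValueError("neuronal_score requested but no neuron scores given")
            frames[term] = scores["neuron"].reindex(traits.index)
        elif term == "diagnosis":
            frames[term] = traits["diagnosis"].astype(str)
        else:
            frames[term] = pd.to_numeric(traits[term], errors="coerce")
    cov = pd.DataFrame(frames)
    ok = cov.notna().all(axis=1)
    excluded = cov.index[~ok].tolist()
    cov = cov.loc[ok]
    for term, series in cov.items():
        if series.dtype == object:
            levels = sorted(series.unique())
            ref = "CTL" if term == "diagnosis" and "CTL" in levels else levels[0]
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((series == lev).to_numpy(float))
                names.append(f"{term}[{lev}]")
                terms.append(term)
        else:
            x = series.to_numpy(float)
            cols.append(x - x.mean())      # centred: correction is mean-preserving
            names.append(term)
            terms.append(term)
    X = np.column_stack([np.ones(len(cov))] + cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the collinear terms by testing each column's marginal rank
        collinear = []
        for j in range(1, X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                collinear.append(names[j - 1])
        raise ValueError(f"rank-deficient design; collinear terms: {collinear}")
    return X, names, terms, cov.index.tolist(), excluded


class CovariateRegressor(BaseEstimator, TransformerMixin):
    """Bootstrap linear regression with protected diagnosis effects.

    ``fit`` regresses each protein's log2 abundance on nuisance +
    protected terms (batch as indicator contrasts), case-resampling
    ``n_boot`` times and taking the per-term median coefficient;
    ``transform`` subtracts nuisance contributions only.  With
    ``n_boot=1`` and ``resample=False`` this reduces exactly to
    ordinary single-fit residualization.
    """

    def __init__(self, nuisance=DEFAULT_NUISANCE, protected=DEFAULT_PROTECTED,
                 n_boot: int = 1000, seed: int | None = None, resample: bool = True):
        self.nuisance = nuisance
        self.protected = protected
        self.n_boot = n_boot
        self.seed = seed
        self.resample = resample

    def fit(self, X: pd.DataFrame, traits: pd.DataFrame,
            scores: pd.DataFrame | None = None) -> "CovariateRegressor":
        traits = traits.copy()
        matrix = X
        design, names, terms, used, excluded = _build_design(
            traits.loc[[s for s in matrix.columns if s in traits.index]],
            scores, self.nuisance, self.protected)
        Y = matrix[used].to_numpy(float)
        # per-protein mean imputation for the fit only
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            row_mean = np.nanmean(Y, axis=1, keepdims=True)
        row_mean = np.where(np.isnan(row_mean), 0.0, row_mean)
        Yf = np.where(np.isnan(Y), row_mean, Y).T        # samples x proteins
        n = design.shape[0]
        rng = np.random.default_rng(self.seed)
        boots = np.empty((self.n_boot, design.shape[1], Yf.shape[1]))
        for b in range(self.n_boot):
            if self.resample:
                take = rng.integers(0, n, n)
            else:
                take = np.arange(n)
            Xb, Yb = design[take], Yf[take]
            coef, *_ = np.linalg.lstsq(Xb, Yb, rcond=None)
            boots[b] = coef
        med = np.median(boots, axis=0)                   # terms x proteins
        self.coefficients_ = pd.DataFrame(
            med[1:].T, index=matrix.index, columns=names)
        self.design_ = pd.DataFrame(design[:, 1:], index=used, columns=names)
        self.column_terms_ = terms
        self.samples_used_ = used
        self.report_ = RegressionReport(
            coefficients=self.coefficients_, n_boot=self.n_boot, seed=self.seed,
            protected_terms=[t for t in self.protected],
            nuisance_terms=[t for t in self.nuisance],
            excluded_samples=excluded)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        nuis_cols = [j for j, t in enumerate(self.column_terms_)
                     if t in set(self.nuisance)]
        names = [self.design_.columns[j] for j in nuis_cols]
        contrib = self.design_[names].to_numpy() @ \
            self.coefficients_[names].to_numpy().T      # samples x proteins
        out = X.copy()
        out.loc[:, self.samples_used_] = \
            X[self.samples_used_].to_numpy() - contrib.T
        return out

    def fit_transform(self, X: pd.DataFrame, traits: pd.DataFrame = None,
                      scores: pd.DataFrame | None = None, **kw) -> pd.DataFrame:
        return self.fit(X, traits, scores).transform(X)


def bootstrap_regress(matrix: pd.DataFrame, traits: pd.DataFrame,
                      scores: pd.DataFrame | None = None,
                      nuisance=DEFAULT_NUISANCE, protected=DEFAULT_PROTECTED,
                      n_boot: int = 1000, seed: int | None = None,
                      resample: bool = True):
    """Functional wrapper: returns (corrected matrix, RegressionReport)."""
    est = CovariateRegressor(nuisance=nuisance, protected=protected,
                             n_boot=n_boot, seed=seed, resample=resample)
    corrected = est.fit_transform(matrix, traits, scores)
    return corrected, est.report_


def variance_partition(matrix: pd.DataFrame, traits: pd.DataFrame,
                       scores: pd.DataFrame | None = None,
                       terms=("batch", "diagnosis", "age", "sex", "PMI")
                       ) -> pd.DataFrame:
    """Per-protein fraction of variance attributable to each trait.

    Sequential sums of squares from the full linear model, averaged over
    every ordering of the (small) term set so the attribution is
    order-independent; fractions plus residual sum to 1 per protein.
    """
    design, names, term_of, used, _ = _build_design(
        traits.loc[[s for s in matrix.columns if s in traits.index]],
        scores, terms, ())
    Y = matrix[used].to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_mean = np.nanmean(Y, axis=1, keepdims=True)
    row_mean = np.where(np.isnan(row_mean), 0.0, row_mean)
    Yc = np.where(np.isnan(Y), row_mean, Y).T
    Yc = Yc - Yc.mean(axis=0, keepdims=True)
    total = (Yc**2).sum(axis=0)
    total[total == 0] = 1.0

    blocks = {t: design[:, [j + 1 for j, tj in enumerate(term_of) if tj == t]]
              for t in dict.fromkeys(term_of)}
    term_list = list(blocks)
    acc = {t: np.zeros(Yc.shape[1]) for t in term_list}
    orders = list(permutations(term_list))
    for order in orders:
        Q = np.ones((design.shape[0], 1)) / np.sqrt(design.shape[0])
        for t in order:
            B = blocks[t]
            B_perp = B - Q @ (Q.T @ B)
            qb, rb = np.linalg.qr(B_perp)
            keep = np.abs(np.diag(rb)) > 1e-10
            qb = qb[:, keep]
            proj = qb.T @ Yc
            acc[t] += (proj**2).sum(axis=0)
            Q = np.hstack([Q, qb])
    frac = pd.DataFrame({t: acc[t] / len(orders) / total for t in term_list},
                        index=matrix.index)
    frac["residual"] = 1.0 - frac.sum(axis=1)
    return frac
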