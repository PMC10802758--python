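"""Two-way median-polish batch correction over GIS-ratio denominators.

TMT batches shift whole channels on the log2 scale.  Because every
batch carries at least one pooled global internal standard (GIS)
channel, the per-batch level of each protein can be anchored to its GIS
median: iteratively (a) subtract, per protein and batch, the median
over that batch's denominator samples from all of the batch's entries
(row polish), then (b) subtract each sample's median over proteins
(column polish), until the largest absolute adjustment in a full pass
falls below tolerance.  Working additively in log2 space is equivalent
to the sample/GIS ratio formulation on raw abundances.

After convergence the pre-correction per-protein median over the
denominator samples is added back so corrected values remain
interpretable abundances; this choice makes the correction exactly
idempotent.  Missing values are ignored by every median; GIS columns
are carried through and stay flagged in the design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class TamporResult:
    corrected: pd.DataFrame
    n_iterations: int
    converged: bool
    convergence_trace: list[float]
    denominators_used: dict[str, list[str]]
    flagged_proteins: list[str] = field(default_factory=list)


class TamporCorrector(BaseEstimator, TransformerMixin):
    """Median-polish batch correction as a transformer.

    Parameters
    ----------
    use_all_non_gis : bool, default False
        Denominator samples per batch: the batch's GIS channels
        (default) or all of its non-GIS channels.
    tolerance : float, default 1e-8
        Convergence threshold on the largest absolute adjustment (log2
        units) applied in a full row+column pass.  A matrix already
        satisfying both centering conditions terminates immediately.
    max_iterations : int, default 250
    """

    def __init__(self, use_all_non_gis: bool = False, tolerance: float = 1e-8,
                 max_iterations: int = 250):
        self.use_all_non_gis = use_all_non_gis
        self.tolerance = tolerance
        self.max_iterations = max_iterations

    def fit(self, X: pd.DataFrame, design: pd.DataFrame) -> "TamporCorrector":
        self.result_ = self._polish(X, design)
        return self

    def transform(self, X: pd.DataFrame, design: pd.DataFrame | None = None) -> pd.DataFrame:
        if design is not None:
            return self._polish(X, design).corrected
        return self.result_.corrected

    def fit_transform(self, X: pd.DataFrame, design: pd.DataFrame = None, **kw) -> pd.DataFrame:
        return self.fit(X, design).result_.corrected

    # internal ---------------------------------------------------------
    def _polish(self, X: pd.DataFrame, design: pd.DataFrame) -> TamporResult:
        from .io import validate_design
        validate_design(X, design, require_gis=not self.use_all_non_gis)
        sub = design.loc[list(X.columns)]
        batches = sub["batch"].to_numpy()
        is_gis = sub["is_gis"].to_numpy(bool)

        denominators: dict[str, list[str]] = {}
        denom_mask = np.zeros(X.shape[1], bool)
        for batch in pd.unique(batches):
            in_batch = batches == batch
            if self.use_all_non_gis:
                d = in_batch & ~is_gis
            else:
                d = in_batch & is_gis
            if not d.any():
                raise ValueError(f"batch {batch!r} has no denominator samples")
            denominators[str(batch)] = [X.columns[i] for i in np.flatnonzero(d)]
            denom_mask |= d

        vals = X.to_numpy(float).copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            addback = np.nanmedian(np.where(denom_mask[None, :], vals, np.nan), axis=1)
        # proteins unobserved in every denominator sample: centre on 0
        flagged_rows = set(np.flatnonzero(np.isnan(addback)))
        addback = np.where(np.isnan(addback), 0.0, addback)

        trace: list[float] = []
        converged = False
        n_iter = 0
        batch_masks = {b: batches == b for b in pd.unique(batches)}
        for n_iter in range(1, self.max_iterations + 1):
            max_adj = 0.0
            for batch, in_batch in batch_masks.items():
                d = in_batch & (is_gis if not self.use_all_non_gis else ~is_gis)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    med = np.nanmedian(vals[:, d], axis=1)
                bad = np.isnan(med)
                if bad.any():
                    # denominator unobserved for these proteins in this
                    # batch: flag them and fall back to the batch's other
                    # samples so the cell is still centred (a zero term
                    # would leave the raw offset as a gross artifact)
                    flagged_rows.update(np.flatnonzero(bad))
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        fb = np.nanmedian(vals[:, in_batch & ~d], axis=1)
                    med = np.where(bad, np.where(np.isnan(fb), 0.0, fb), med)
                vals[:, in_batch] -= med[:, None]
                if med.size:
                    max_adj = max(max_adj, float(np.max(np.abs(med))))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                col_med = np.nanmedian(vals, axis=0)
            col_med = np.where(np.isnan(col_med), 0.0, col_med)
            vals -= col_med[None, :]
            if col_med.size:
                max_adj = max(max_adj, float(np.max(np.abs(col_med))))
            trace.append(max_adj)
            if max_adj < self.tolerance:
                converged = True
                break

        vals += addback[:, None]
        corrected = pd.DataFrame(vals, index=X.index, columns=X.columns)
        return TamporResult(
            corrected=corrected, n_iterations=n_iter, converged=converged,
            convergence_trace=trace, denominators_used=denominators,
            flagged_proteins=[X.index[i] for i in sorted(flagged_rows)],
        )


def tampor_correct(matrix: pd.DataFrame, design: pd.DataFrame,
                   use_all_non_gis: bool = False, tolerance: float = 1e-8,
                   max_iterations: int = 250) -> TamporResult:
    """Functional wrapper over :class:`TamporCorrector`; returns the full result."""
    est = TamporCorrector(use_all_non_gis=use_all_non_gis, tolerance=tolerance,
                          max_iterations=max_iterations)
    est.fit(matrix, design)
    return est.result_
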