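"""Group statistics, trait correlations, fraction ratios and the
amyloid-beta peptide computations.

Per-protein differential abundance across CTL/AD/PSP uses one-way ANOVA
with Tukey-Kramer post hoc pairwise p-values; Tukey p-values below
10^-8.5 are imprecisely estimated in the extreme tail and are replaced
by a Bonferroni-corrected (x3, capped at 1) two-tailed unequal-variance
t-test p, with the substitution flagged.  Module-trait association is
the biweight midcorrelation of each eigenprotein with each numeric or
binary-coded trait, with the Student t transform for significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._tukey import studentized_range_sf
from .network import bicor

TUKEY_FALLBACK_THRESHOLD = 10.0 ** -8.5
GROUP_ORDER = ("CTL", "AD", "PSP")
PAIRS = (("AD", "CTL"), ("PSP", "CTL"), ("AD", "PSP"))


def anova_tukey(matrix: pd.DataFrame, groups: pd.Series,
                group_order=GROUP_ORDER) -> pd.DataFrame:
    """One-way ANOVA with Tukey-Kramer pairwise p per protein.

    Proteins with fewer than 2 non-missing values in any group are
    skipped (``skipped`` flag, NaN statistics), as are zero-variance
    degenerate rows.  Pairwise Tukey p below 10^-8.5 fall back to
    min(1, 3 x Welch t p), flagged per pair.
    """
    groups = groups.reindex(matrix.columns)
    levels = [g for g in group_order if (groups == g).any()]
    if len(levels) < 2:
        raise ValueError("need at least 2 diagnosis groups")
    k = len(levels)
    X = matrix.to_numpy(float)
    n_g, mean_g, var_g = {}, {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for g in levels:
            cols = (groups == g).to_numpy()
            sub = X[:, cols]
            n_g[g] = np.isfinite(sub).sum(axis=1)
            mean_g[g] = np.nanmean(sub, axis=1)
            var_g[g] = np.nanvar(sub, axis=1, ddof=1)

    N = sum(n_g.values())
    grand = sum(n_g[g] * mean_g[g] for g in levels) / N
    ssb = sum(n_g[g] * (mean_g[g] - grand) ** 2 for g in levels)
    ssw = sum((n_g[g] - 1) * var_g[g] for g in levels)
    skipped = np.zeros(X.shape[0], bool)
    for g in levels:
        skipped |= n_g[g] < 2
    skipped |= (ssw + ssb) == 0          # all values identical
    df_w = N - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (k - 1)) / (ssw / df_w)
        anova_p = sps.f.sf(F, k - 1, df_w)
    anova_p[skipped] = np.nan

    out = pd.DataFrame(index=matrix.index)
    for g in levels:
        out[f"mean_{g}"] = mean_g[g]
        out[f"n_{g}"] = n_g[g]
    out["anova_p"] = anova_p
    mse = np.where(df_w > 0, ssw / np.maximum(df_w, 1), np.nan)
    ok = ~skipped
    for a, b in PAIRS:
        if a not in levels or b not in levels:
            continue
        diff = mean_g[a] - mean_g[b]
        se = np.sqrt(mse / 2.0 * (1.0 / n_g[a] + 1.0 / n_g[b]))
        with np.errstate(divide="ignore", invalid="ignore"):
            qstat = np.abs(diff) / se
        p_pair = np.full(X.shape[0], np.nan)
        rows = np.flatnonzero(ok & np.isfinite(qstat))
        if rows.size:
            dfv = df_w[rows] if np.ndim(df_w) else np.full(rows.size, df_w)
            # group by integer df so each call is a single quadrature
            p_rows = np.empty(rows.size)
            for d in np.unique(dfv):
                m = dfv == d
                p_rows[m] = studentized_range_sf(qstat[rows][m], k, float(d))
            p_pair[rows] = p_rows
        fallback = np.zeros(X.shape[0], bool)
        low = ok & (p_pair < TUKEY_FALLBACK_THRESHOLD)
        if low.any():
            idx = np.flatnonzero(low)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = diff[idx] / np.sqrt(var_g[a][idx] / n_g[a][idx]
                                        + var_g[b][idx] / n_g[b][idx])
                num = (var_g[a][idx] / n_g[a][idx] + var_g[b][idx] / n_g[b][idx]) ** 2
                den = (var_g[a][idx] / n_g[a][idx]) ** 2 / (n_g[a][idx] - 1) \
                    + (var_g[b][idx] / n_g[b][idx]) ** 2 / (n_g[b][idx] - 1)
                df_welch = num / den
            p_t = 2.0 * sps.t.sf(np.abs(t), df_welch)
            p_pair[idx] = np.minimum(1.0, 3.0 * p_t)
            fallback[idx] = True
        out[f"log2FC_{a}_vs_{b}"] = diff
        out[f"p_{a}_vs_{b}"] = p_pair
        out[f"fallback_{a}_vs_{b}"] = fallback
    out["skipped"] = skipped
    return out


def module_trait_correlation(eigenproteins: pd.DataFrame, traits: pd.DataFrame,
                             trait_columns=None) -> pd.DataFrame:
    """bicor of each module eigenprotein with each trait, with Student-t p.

    Diagnosis expands into binary 0/1 indicator traits.  Ordinal scores
    are correlated as numeric.  Constant traits give NaN (recorded, not
    raised).  Returns a tidy frame (module, trait, bicor, p).
    """
    tr = traits.loc[[s for s in eigenproteins.columns if s in traits.index]].copy()
    if "diagnosis" in tr.columns:
        for g in sorted(tr["diagnosis"].dropna().unique()):
            tr[str(g)] = (tr["diagnosis"] == g).astype(float)
        tr = tr.drop(columns=["diagnosis"])
    if trait_columns is not None:
        tr = tr[list(trait_columns)]
    tr = tr.apply(pd.to_numeric, errors="coerce")
    n_min = 4
    rows = []
    for mod in eigenproteins.index:
        e = eigenproteins.loc[mod, tr.index].to_numpy(float)
        for col in tr.columns:
            x = tr[col].to_numpy(float)
            ok = np.isfinite(e) & np.isfinite(x)
            if ok.sum() < n_min or np.nanstd(x[ok]) == 0:
                rows.append((mod, col, np.nan, np.nan))
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = bicor(e[ok], x[ok])
            n = int(ok.sum())
            if not np.isfinite(r) or abs(r) >= 1.0:
                p = 0.0 if np.isfinite(r) else np.nan
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = 2.0 * sps.t.sf(abs(t), n - 2)
            rows.append((mod, col, r, p))
    return pd.DataFrame(rows, columns=["module", "trait", "bicor", "p"])


@dataclass
class EnrichmentRatios:
    per_protein: pd.Series            # mean log2(vascular/bulk), shared proteins
    unique_to_vascular: list
    unique_to_bulk: list
    module_means: pd.Series | None = None


def log2_enrichment(vascular: pd.DataFrame, bulk: pd.DataFrame,
                    labels: pd.Series | None = None) -> EnrichmentRatios:
    """Per-protein mean log2(vascular/bulk) over paired samples.

    Proteins present in only one fraction are flagged unique rather
    than ratioed; module-level means are attached when labels are given.
    """
    samples = vascular.columns.intersection(bulk.columns)
    if len(samples) == 0:
        raise ValueError("no paired samples between fractions")
    shared = vascular.index.intersection(bulk.index)
    diff = vascular.loc[shared, samples] - bulk.loc[shared, samples]
    per_protein = diff.mean(axis=1, skipna=True).rename("log2_vascular_over_bulk")
    uniq_v = vascular.index.difference(bulk.index).tolist()
    uniq_b = bulk.index.difference(vascular.index).tolist()
    module_means = None
    if labels is not None:
        lab = labels.reindex(shared)
        module_means = per_protein.groupby(lab).mean().rename("module_mean")
    return EnrichmentRatios(per_protein=per_protein, unique_to_vascular=uniq_v,
                            unique_to_bulk=uniq_b, module_means=module_means)


def select_classifier_proteins(diff: pd.DataFrame, enrichment: EnrichmentRatios,
                               min_fold: float = 3.0, alpha: float = 0.05
                               ) -> list[str]:
    """Supervised-clustering input rule: unique to the vascular fraction
    or at least ``min_fold``-enriched there, and pairwise-significant in
    all three group comparisons."""
    pcols = [c for c in diff.columns if c.startswith("p_")]
    sig = (diff[pcols] < alpha).all(axis=1)
    enriched = enrichment.per_protein.reindex(diff.index) >= np.log2(min_fold)
    unique = diff.index.isin(enrichment.unique_to_vascular)
    return diff.index[(enriched.fillna(False).to_numpy() | unique) &
                      sig.to_numpy()].tolist()


def normalize_reporter_channels(peptides: pd.DataFrame) -> pd.DataFrame:
    """Scale linear-scale reporter channels to the largest channel sum.

    Each channel (column) is multiplied by (max column sum)/(its own
    column sum), so afterwards every column sums to the pre-scaling
    maximum.  A zero channel sum is an error naming the channel.
    """
    sums = peptides.sum(axis=0, skipna=True)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise ValueError(f"zero summed intensity in channel(s): {zero}")
    factors = sums.max() / sums
    return peptides * factors


AB40_PEPTIDE = "GAIIGLMVGGVV"
AB42_PEPTIDE = "GAIIGLMVGGVVIA"


@dataclass
class AbetaRatios:
    ab40_over_ab42: pd.DataFrame      # fractions x samples, log2 ratios
    vascular_over_bulk: pd.DataFrame  # peptides x paired samples, log2 ratios


def abeta_ratios(vascular_peptides: pd.DataFrame, bulk_peptides: pd.DataFrame,
                 log2_input: bool = True) -> AbetaRatios:
    """log2(Abeta40/Abeta42) per sample and log2(vascular/bulk) per peptide.

    Rows are matched by exact C-terminal tryptic peptide sequence;
    a missing row is an error citing the sequence.  Inputs are expected
    on the log2 scale (as after peptide-level median-polish correction);
    pass ``log2_input=False`` for raw linear intensities.
    """
    mats = {}
    for name, mat in (("vascular", vascular_peptides), ("bulk", bulk_peptides)):
        for pep in (AB40_PEPTIDE, AB42_PEPTIDE):
            if pep not in mat.index:
                raise ValueError(f"{name} peptide table lacks row {pep!r}")
        mats[name] = np.log2(mat) if not log2_input else mat
    ratio4042 = pd.DataFrame(
        {name: m.loc[AB40_PEPTIDE] - m.loc[AB42_PEPTIDE]
         for name, m in mats.items()}).T
    samples = mats["vascular"].columns.intersection(mats["bulk"].columns)
    vb = (mats["vascular"].loc[[AB40_PEPTIDE, AB42_PEPTIDE], samples]
          - mats["bulk"].loc[[AB40_PEPTIDE, AB42_PEPTIDE], samples])
    return AbetaRatios(ab40_over_ab42=ratio4042, vascular_over_bulk=vb)
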