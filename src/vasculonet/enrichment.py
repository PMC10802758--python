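"""Overrepresentation machinery: Fisher cell-type tests, permutation
GWAS risk enrichment, biofluid overlap and set accounting.

All hypergeometric tests are one-tailed (greater) on an explicit
background universe with Benjamini-Hochberg FDR over the rows of each
call.  GWAS risk enrichment standardizes each module's mean -log10 p of
nominally significant risk genes against random same-size gene sets
(a normalized enrichment score, NES), with a permutation FDR from the
pooled null NES distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io import symbol_of
from .network import GREY


def modules_as_gene_sets(labels: pd.Series, include_grey: bool = False
                         ) -> dict[str, set[str]]:
    """Module label -> set of gene symbols (isoform collisions collapse)."""
    out: dict[str, set[str]] = {}
    for pid, lab in labels.items():
        if lab == GREY and not include_grey:
            continue
        out.setdefault(lab, set()).add(symbol_of(pid))
    return out


def fisher_set_enrichment(module_sets: dict[str, set[str]],
                          category_sets: dict[str, set[str]],
                          background: set[str],
                          alternative: str = "greater") -> pd.DataFrame:
    """One-tailed Fisher/hypergeometric enrichment of categories in modules.

    Every tested set is intersected with the background first.  The odds
    ratio uses a Haldane 0.5 correction when any 2x2 cell is empty; BH
    FDR is computed across all rows of this call.
    """
    if not background:
        raise ValueError("empty background universe")
    if alternative != "greater":
        raise ValueError("only the one-tailed 'greater' alternative is supported")
    bg = {s.upper() for s in background}
    N = len(bg)
    rows = []
    for mod, mset in module_sets.items():
        m = {s.upper() for s in mset} & bg
        for cat, cset in category_sets.items():
            c = {s.upper() for s in cset} & bg
            if not c:
                continue
            k = len(m & c)
            p = float(sps.hypergeom.sf(k - 1, N, len(c), len(m)))
            a, b = k, len(m) - k
            cc, d = len(c) - k, N - len(m) - len(c) + k
            if min(a, b, cc, d) == 0:
                a, b, cc, d = a + 0.5, b + 0.5, cc + 0.5, d + 0.5
            rows.append((mod, cat, k, len(m), len(c), N, (a * d) / (b * cc), p))
    table = pd.DataFrame(rows, columns=[
        "module", "category", "overlap", "module_size", "category_size",
        "background_size", "odds_ratio", "p"])
    if len(table):
        table["fdr"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["fdr"] = pd.Series(dtype=float)
    return table


@dataclass
class GwasEnrichment:
    table: pd.DataFrame               # per module NES, permutation FDR, flags
    contributing_genes: dict          # module -> list of nominally sig genes
    n_permutations: int
    seed: int | None
    ensemble_rule: str = "mean -log10 p across studies containing the gene"


def ensemble_gene_pvalues(tables: list[pd.Series]) -> pd.Series:
    """Per-gene mean of -log10 p across the studies containing the gene."""
    if not tables:
        raise ValueError("at least one gene-level study table is required")
    logs = pd.concat([-np.log10(t.clip(lower=1e-300)) for t in tables], axis=1)
    return pd.Series(10.0 ** -logs.mean(axis=1, skipna=True), index=logs.index,
                     name="ensemble_p")


def gwas_permutation_enrichment(labels: pd.Series, tables: list[pd.Series],
                                nominal_cut: float = 0.05, n_perm: int = 10_000,
                                seed: int | None = None) -> GwasEnrichment:
    """Permutation NES of GWAS gene-level risk per module.

    Observed score: mean -log10(ensemble p) over module member genes
    with ensemble p below ``nominal_cut``; modules with no such genes
    get NES 0 and are never flagged.  Null: the same score on random
    same-size gene sets from the network background.  NES standardizes
    the observed score against the module's null mean/SD; the
    permutation p is the upper-tail fraction of the module's own null
    scores at the observed score (the module's null already contains
    any planted signal reachable by chance draws, so its own tail is
    the exact permutation test), BH-adjusted across modules into a
    permutation FDR.
    """
    ens = ensemble_gene_pvalues(tables)
    module_sets = modules_as_gene_sets(labels)
    network_genes = pd.Index(sorted({symbol_of(p) for p in labels.index}))
    network_genes = network_genes[network_genes.isin(ens.index)]
    logp = -np.log10(ens.reindex(network_genes).clip(lower=1e-300).to_numpy())
    sig = ens.reindex(network_genes).to_numpy() < nominal_cut
    score_of = pd.Series(logp, index=network_genes)
    rng = np.random.default_rng(seed)

    def set_score(mask: np.ndarray) -> float:
        hit = mask & sig
        return float(logp[hit].mean()) if hit.any() else 0.0

    rows, contrib = [], {}
    gene_pos = {g: i for i, g in enumerate(network_genes)}
    for mod, genes in sorted(module_sets.items()):
        present = [g for g in genes if g in gene_pos]
        size = len(present)
        mask = np.zeros(len(network_genes), bool)
        mask[[gene_pos[g] for g in present]] = True
        obs = set_score(mask)
        contrib[mod] = sorted(g for g in present if ens[g] < nominal_cut)
        if size == 0:
            rows.append((mod, 0, 0, 0.0, np.nan, np.nan, 0.0, np.nan))
            continue
        null = np.empty(n_perm)
        for b in range(n_perm):
            pick = rng.choice(len(network_genes), size=size, replace=False)
            m = np.zeros(len(network_genes), bool)
            m[pick] = True
            null[b] = set_score(m)
        mu, sd = null.mean(), null.std(ddof=1)
        if not contrib[mod]:
            nes, perm_p = 0.0, np.nan
        else:
            nes = (obs - mu) / sd if sd > 1e-12 else 0.0
            # mid-p: ties at the observed score count half.  Real
            # gene-level p-values are continuous, so ties only occur in
            # degenerate synthetic score distributions; there the
            # standard estimator is needlessly conservative.
            greater = int((null > obs).sum())
            ties = int((null == obs).sum())
            perm_p = (1 + greater + 0.5 * ties) / (1 + n_perm)
        rows.append((mod, size, len(contrib[mod]), obs, mu, sd, nes, perm_p))
    table = pd.DataFrame(rows, columns=[
        "module", "n_genes", "n_sig_genes", "observed", "null_mean",
        "null_sd", "NES", "perm_p"]).set_index("module")
    testable = table["perm_p"].notna()
    fdr = np.full(len(table), np.nan)
    if testable.any():
        fdr[np.flatnonzero(testable.to_numpy())] = multipletests(
            table.loc[testable, "perm_p"], method="fdr_bh")[1]
    table["fdr"] = fdr
    table["flagged_5"] = (table["fdr"] < 0.05) & testable
    table["flagged_10"] = (table["fdr"] < 0.10) & testable
    return GwasEnrichment(table=table, contributing_genes=contrib,
                          n_permutations=n_perm, seed=seed)


def biofluid_overlap(labels: pd.Series, biofluid_tables: dict[str, pd.DataFrame],
                     direction: str = "all", alpha: float = 0.05) -> pd.DataFrame:
    """Overlap of brain modules with biofluid proteomes.

    Category sets per fluid: all detected proteins, significantly
    increased (p < alpha, log2FC > 0) or decreased; background is the
    full network protein list.  Empty categories are reported untestable
    (NaN p) rather than silently dropped.
    """
    if direction not in ("all", "increased", "decreased"):
        raise ValueError(f"unknown direction {direction!r}")
    module_sets = modules_as_gene_sets(labels)
    background = {symbol_of(p) for p in labels.index}
    categories: dict[str, set[str]] = {}
    untestable = []
    for fluid, df in biofluid_tables.items():
        prot = df["protein"].astype(str).str.upper()
        if direction == "all":
            sel = prot
        elif direction == "increased":
            sel = prot[(df["p"] < alpha) & (df["log2FC"] > 0)]
        else:
            sel = prot[(df["p"] < alpha) & (df["log2FC"] < 0)]
        cset = set(sel) & background
        name = f"{fluid}_{direction}"
        if cset:
            categories[name] = cset
        else:
            untestable.append(name)
    table = fisher_set_enrichment(module_sets, categories, background) \
        if categories else pd.DataFrame(columns=[
            "module", "category", "overlap", "module_size", "category_size",
            "background_size", "odds_ratio", "p", "fdr"])
    for name in untestable:
        table = pd.concat([table, pd.DataFrame([{
            "module": "-", "category": name, "overlap": 0, "module_size": 0,
            "category_size": 0, "background_size": len(background),
            "odds_ratio": np.nan, "p": np.nan, "fdr": np.nan}])],
            ignore_index=True)
    return table


@dataclass
class SetOverlap:
    unique_to_a: list
    unique_to_b: list
    shared: list

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.unique_to_a), len(self.unique_to_b), len(self.shared)


def set_overlap(universe_a, universe_b) -> SetOverlap:
    """Exact partition of A union B into (unique to A, unique to B, shared)."""
    a, b = set(universe_a), set(universe_b)
    return SetOverlap(unique_to_a=sorted(a - b), unique_to_b=sorted(b - a),
                      shared=sorted(a & b))
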