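"""Synthetic multi-batch TMT cohorts with planted, fully recorded structure.

The generator emulates the statistical shape of a paired vascular/bulk
TMT-MS study: log2 abundance matrices built from a module factor model,
per-batch log2 offsets with pooled internal-standard (GIS) channels,
nuisance covariate slopes, protected diagnosis effects on selected
modules, per-protein vascular-over-bulk enrichment, cell-type marker
sets tied to modules, gene-level GWAS p-value tables with left-shifted
risk modules, and biofluid differential-abundance tables echoing a brain
module.  Every planted signal is returned in ``SyntheticCohort.truth``
so recovery can be scored exactly.

All randomness flows through ``numpy.random.default_rng`` (PCG64); the
same config and seed reproduce the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio

GROUPS = ("CTL", "AD", "PSP")


class ConfigError(ValueError):
    """A generator configuration violated its invariants."""


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe the desk-scale cohort used throughout the test
    suite: 1,000 proteins, 20 samples per diagnosis group across three
    TMT batches with one GIS channel each, eight planted co-expression
    modules with within-module correlation 0.6, +-1 log2 batch offsets,
    an age slope of 0.02 log2/year on a fifth of the proteins, and a
    protected +0.5 log2 AD effect on the first (matrisome-like) module.
    """

    n_proteins: int = 1000
    n_samples_per_group: int = 20
    n_batches: int = 3
    gis_per_batch: int = 1
    module_sizes: tuple[int, ...] = (150, 120, 100, 90, 80, 70, 60, 50)
    within_module_cor: float = 0.6
    loading_spread: float = 0.15
    structure_seed: int = 1234
    noise_sd: float = 1.0
    baseline_mean: float = 10.0
    baseline_sd: float = 1.5
    batch_offsets: tuple[float, ...] = (1.0, -1.0, 0.0)
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.02, "sex": 0.2, "PMI": 0.01})
    covariate_affected_fraction: float = 0.2
    disease_effects: dict = field(
        default_factory=lambda: {0: {"AD": 0.5}, 3: {"AD": -0.5, "PSP": 0.4}})
    marker_assignment: dict = field(default_factory=lambda: {
        "endothelial": 1, "pericyte": 2, "SMC": 3, "fibroblast": 4,
        "neuron": 5, "astrocyte": 6, "oligodendrocyte": 7})
    markers_per_type: int = 20
    vascular_enrichment: dict | None = None   # module index -> log2 shift
    gwas_enriched_modules: tuple[int, ...] = (0,)
    missing_rate: float = 0.05
    gis_noise_sd: float = 0.05
    n_unique_vascular: int = 50
    n_unique_bulk: int = 30
    n_contaminated_samples: int = 0
    contamination_shift: float = 6.0   # gross fractionation failure
    seed: int = 0

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_samples(self) -> int:
        return self.n_samples_per_group * len(GROUPS)

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_proteins:
            raise ConfigError("module_sizes: sum exceeds n_proteins")
        if any(s < 20 for s in self.module_sizes):
            raise ConfigError("module_sizes: detectable modules need >= 20 members")
        for name, val in (("within_module_cor", self.within_module_cor),
                          ("missing_rate", self.missing_rate),
                          ("covariate_affected_fraction", self.covariate_affected_fraction)):
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name}: must lie in [0, 1]")
        if len(self.batch_offsets) != self.n_batches:
            raise ConfigError("batch_offsets: need one offset per batch")
        if self.gis_per_batch < 1:
            raise ConfigError("gis_per_batch: every batch needs a GIS channel")
        if self.n_contaminated_samples > self.n_samples:
            raise ConfigError("n_contaminated_samples: exceeds cohort size")
        for ct, m in self.marker_assignment.items():
            if not 0 <= m < self.n_modules:
                raise ConfigError(f"marker_assignment: module {m} for {ct!r} out of range")
        for m in self.disease_effects:
            if not 0 <= m < self.n_modules:
                raise ConfigError(f"disease_effects: module index {m} out of range")
        for m in self.gwas_enriched_modules:
            if not 0 <= m < self.n_modules:
                raise ConfigError(f"gwas_enriched_modules: module index {m} out of range")


@dataclass
class SyntheticTruth:
    """Everything that was planted, keyed the way downstream stages see it."""

    module_labels: pd.Series            # protein -> M1..Mk / M0
    covariate_effects: pd.DataFrame     # protein, covariate, slope
    disease_effects: dict               # module label -> {group: log2 shift}
    vascular_enrichment: pd.Series      # protein -> log2 vascular/bulk shift
    marker_sets: dict                   # cell type -> set of symbols
    gwas_enriched_modules: tuple        # module labels
    contaminated_samples: list
    unique_vascular: list
    unique_bulk: list
    factor_scores: pd.DataFrame         # module label x sample latent factors
    loadings: pd.Series | None = None   # protein -> factor loading (hubness)


@dataclass
class SyntheticCohort:
    vascular: pd.DataFrame
    bulk: pd.DataFrame
    design: pd.DataFrame
    traits: pd.DataFrame
    truth: SyntheticTruth
    config: GeneratorConfig

    def write(self, outdir) -> None:
        """Write the cohort in the same formats the readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        vio.write_abundance_matrix(self.vascular, outdir / "vascular.tsv")
        vio.write_abundance_matrix(self.bulk, outdir / "bulk.tsv")
        vio.write_batch_design(self.design, outdir / "design.tsv")
        vio.write_traits(self.traits, outdir / "traits.tsv")
        vio.write_marker_gmt(self.truth.marker_sets, outdir / "markers.gmt")
        vio.write_table(self.truth.module_labels.rename("module").reset_index(),
                        outdir / "truth_modules.tsv")


def _module_label(idx: int) -> str:
    return f"M{idx + 1}"


def _make_traits(cfg: GeneratorConfig, rng: np.random.Generator,
                 samples: list[str], groups: np.ndarray) -> pd.DataFrame:
    n = len(samples)
    age = np.clip(rng.normal(75, 8, n), 55, 95).round(1)
    sex = rng.integers(0, 2, n)
    pmi = np.clip(rng.normal(12, 4, n), 2, 30).round(1)
    cerad = np.empty(n, int)
    braak = np.empty(n, int)
    caa = np.empty(n, int)
    gliosis = np.empty(n, int)
    apoe = np.empty(n, int)
    for i, g in enumerate(groups):
        if g == "AD":
            cerad[i] = rng.choice([2, 3], p=[0.4, 0.6])
            braak[i] = rng.choice([4, 5, 6], p=[0.3, 0.4, 0.3])
            caa[i] = rng.choice([1, 2, 3], p=[0.4, 0.35, 0.25])
            gliosis[i] = rng.choice([1, 2, 3], p=[0.3, 0.4, 0.3])
            apoe[i] = rng.choice([0, 1, 2], p=[0.35, 0.45, 0.20])
        elif g == "PSP":
            cerad[i] = rng.choice([0, 1], p=[0.7, 0.3])
            braak[i] = rng.choice([2, 3, 4], p=[0.4, 0.4, 0.2])
            caa[i] = rng.choice([0, 1], p=[0.8, 0.2])
            gliosis[i] = rng.choice([1, 2, 3], p=[0.4, 0.4, 0.2])
            apoe[i] = rng.choice([0, 1, 2], p=[0.60, 0.30, 0.10])
        else:
            cerad[i] = rng.choice([0, 1], p=[0.8, 0.2])
            braak[i] = rng.choice([0, 1, 2], p=[0.5, 0.3, 0.2])
            caa[i] = rng.choice([0, 1], p=[0.9, 0.1])
            gliosis[i] = rng.choice([0, 1], p=[0.7, 0.3])
            apoe[i] = rng.choice([0, 1, 2], p=[0.70, 0.25, 0.05])
    return pd.DataFrame({
        "diagnosis": groups, "age": age, "sex": sex, "PMI": pmi,
        "CERAD": cerad, "Braak": braak, "CAA": caa,
        "gliosis": gliosis, "APOE4_dose": apoe,
    }, index=pd.Index(samples, name="sample"))


def _default_enrichment(cfg: GeneratorConfig) -> dict:
    """Module-level log2 vascular/bulk shifts mirroring NVU biology:
    vascular cell-type modules enriched, the neuronal module depleted,
    and the disease (matrisome-like) module moderately enriched."""
    shifts = {m: 0.0 for m in range(cfg.n_modules)}
    vascular_types = {"endothelial", "pericyte", "SMC", "fibroblast"}
    for ct, m in cfg.marker_assignment.items():
        if ct in vascular_types:
            shifts[m] = 2.0
        elif ct == "neuron":
            shifts[m] = -1.5
    shifts[0] = max(shifts.get(0, 0.0), 1.8)
    return shifts


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate one paired vascular/bulk cohort.

    Abundance model, on the log2 scale::

        x_ps = baseline_p + sqrt(r) * f_{m(p),s} + covariate terms
               + disease shift + batch offset + sqrt(1-r) * noise

    with ``f`` a per-module latent factor shared between the two
    fractions.  The vascular fraction additionally carries the planted
    per-protein vascular/bulk enrichment; each fraction has independent
    residual noise.  GIS channels are the per-batch mean of biological
    channels plus small noise; missingness is inserted completely at
    random afterwards.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    p, n = cfg.n_proteins, cfg.n_samples
    proteins = [f"GEN{i:04d}|P{i:05d}" for i in range(p)]
    symbols = [vio.symbol_of(pid) for pid in proteins]
    samples = [f"S{i + 1:03d}" for i in range(n)]
    groups = np.repeat(GROUPS, cfg.n_samples_per_group)
    batches = np.array([f"b{(i % cfg.n_batches) + 1}" for i in range(n)])

    # module membership: first sum(sizes) proteins, in blocks
    labels = np.full(p, "M0", dtype=object)
    pos = 0
    module_members: dict[str, np.ndarray] = {}
    for m, size in enumerate(cfg.module_sizes):
        idx = np.arange(pos, pos + size)
        labels[idx] = _module_label(m)
        module_members[_module_label(m)] = idx
        pos += size
    labels = pd.Series(labels, index=proteins, name="module")

    traits = _make_traits(cfg, rng, samples, groups)

    # Per-protein loadings (hub structure) come from a *structure* seed so
    # replicate cohorts (same config, different seed) share the same
    # biology: module membership and hubness persist, noise does not.
    # Symmetric spread around sqrt(r) keeps the mean pairwise
    # within-module correlation E[l_i]*E[l_j] exactly at r.
    r = cfg.within_module_cor
    rng_struct = np.random.default_rng(cfg.structure_seed)
    loadings = np.clip(
        rng_struct.uniform(np.sqrt(r) - cfg.loading_spread,
                           np.sqrt(r) + cfg.loading_spread, p), 0.05, 1.0)
    if cfg.loading_spread == 0 or r == 1.0:
        loadings = np.full(p, np.sqrt(r))

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, p)
    factors = rng.standard_normal((cfg.n_modules, n))
    # Orthogonalize latent factors against the modelled design (group
    # indicators and covariates) so the only group/covariate structure
    # in the data is what was planted: planted slopes are then exactly
    # recoverable by least squares on noise-free data.
    design_cols = [np.ones(n)]
    for g in GROUPS[1:]:
        design_cols.append((groups == g).astype(float))
    for cov in ("age", "sex", "PMI"):
        design_cols.append(traits[cov].to_numpy(float))
    Q, _ = np.linalg.qr(np.column_stack(design_cols))
    factors = factors - (factors @ Q) @ Q.T
    fsd = factors.std(axis=1, keepdims=True)
    factors = factors / np.where(fsd == 0, 1.0, fsd)

    signal = np.tile(baseline[:, None], (1, n))
    resid_sd = np.full(p, cfg.noise_sd)
    for m in range(cfg.n_modules):
        idx = module_members[_module_label(m)]
        signal[idx] += loadings[idx, None] * factors[m]
        resid_sd[idx] = cfg.noise_sd * np.sqrt(np.clip(1.0 - loadings[idx] ** 2,
                                                       0.0, None))

    # nuisance covariate slopes on a random subset of proteins
    cov_rows = []
    for cov, slope in cfg.covariate_effects.items():
        n_aff = int(round(cfg.covariate_affected_fraction * p))
        affected = rng.choice(p, size=n_aff, replace=False)
        x = traits[cov].to_numpy(float)
        x = x - x.mean()
        signal[affected] += slope * x[None, :]
        cov_rows.extend((proteins[i], cov, slope) for i in affected)
    covariate_truth = pd.DataFrame(cov_rows, columns=["protein", "covariate", "slope"])

    # protected diagnosis effects on module members
    disease_truth: dict[str, dict[str, float]] = {}
    for m, eff in cfg.disease_effects.items():
        lab = _module_label(m)
        disease_truth[lab] = dict(eff)
        idx = module_members[lab]
        for grp, shift in eff.items():
            signal[np.ix_(idx, groups == grp)] += shift

    enrich_map = cfg.vascular_enrichment if cfg.vascular_enrichment is not None \
        else _default_enrichment(cfg)
    enrichment = np.zeros(p)
    for m, shift in enrich_map.items():
        enrichment[module_members[_module_label(m)]] = shift
    enrichment = pd.Series(enrichment, index=proteins, name="log2_vascular_over_bulk")

    batch_shift = np.array([cfg.batch_offsets[int(b[1:]) - 1] for b in batches])

    def _assemble(frac_shift: np.ndarray) -> np.ndarray:
        noise = resid_sd[:, None] * rng.standard_normal((p, n))
        mat = signal + frac_shift[:, None] + noise
        mat = mat + batch_shift[None, :]
        return mat

    vasc = _assemble(enrichment.to_numpy())
    bulk = _assemble(np.zeros(p))

    contaminated: list[str] = []
    if cfg.n_contaminated_samples:
        # fractionation failures: neuron-module proteins up, endothelial down
        picks = rng.choice(n, size=cfg.n_contaminated_samples, replace=False)
        contaminated = [samples[i] for i in sorted(picks)]
        neu = cfg.marker_assignment.get("neuron")
        endo = cfg.marker_assignment.get("endothelial")
        for i in picks:
            if neu is not None:
                vasc[module_members[_module_label(neu)], i] += cfg.contamination_shift
            if endo is not None:
                vasc[module_members[_module_label(endo)], i] -= cfg.contamination_shift

    def _with_gis(mat: np.ndarray, tag: str):
        cols = list(samples)
        out = [mat]
        gis_names, gis_batches = [], []
        for b in range(cfg.n_batches):
            bmask = batches == f"b{b + 1}"
            for g in range(cfg.gis_per_batch):
                name = f"GIS{tag}{b + 1}" if cfg.gis_per_batch == 1 \
                    else f"GIS{tag}{b + 1}.{g + 1}"
                chan = mat[:, bmask].mean(axis=1) + \
                    rng.normal(0.0, cfg.gis_noise_sd, p)
                out.append(chan[:, None])
                gis_names.append(name)
                gis_batches.append(f"b{b + 1}")
        full = np.hstack(out)
        df = pd.DataFrame(full, index=pd.Index(proteins, name="protein"),
                          columns=cols + gis_names)
        if cfg.missing_rate > 0:
            mask = rng.random(df.shape) < cfg.missing_rate
            df = df.mask(mask)
        return df, gis_names, gis_batches

    vasc_df, vgis, vgis_b = _with_gis(vasc, "v")
    bulk_df, bgis, bgis_b = _with_gis(bulk, "b")

    # fraction-unique proteins: drop from the other matrix entirely
    uniq_v = [proteins[i] for i in
              rng.choice(np.arange(pos, p), size=min(cfg.n_unique_vascular, p - pos),
                         replace=False)] if cfg.n_unique_vascular else []
    remaining = sorted(set(range(pos, p)) - {proteins.index(q) for q in uniq_v})
    uniq_b = [proteins[i] for i in
              rng.choice(remaining, size=min(cfg.n_unique_bulk, len(remaining)),
                         replace=False)] if cfg.n_unique_bulk else []
    bulk_df = bulk_df.drop(index=uniq_v)
    vasc_df = vasc_df.drop(index=uniq_b)

    design = pd.DataFrame({
        "batch": list(batches) + vgis_b + bgis_b,
        "is_gis": [False] * n + [True] * (len(vgis) + len(bgis)),
    }, index=pd.Index(samples + vgis + bgis, name="sample"))

    marker_sets = {
        ct: {symbols[i] for i in
             module_members[_module_label(m)][:cfg.markers_per_type]}
        for ct, m in cfg.marker_assignment.items()
    }
    # cell types with no representation in the matrix (exercises the
    # <3-matched-markers warning path downstream)
    for ct in vio.CELL_TYPES:
        if ct not in marker_sets:
            marker_sets[ct] = {f"ABSENT{ct[:3].upper()}{i}" for i in range(5)}

    truth = SyntheticTruth(
        module_labels=labels,
        covariate_effects=covariate_truth,
        disease_effects=disease_truth,
        vascular_enrichment=enrichment,
        marker_sets=marker_sets,
        gwas_enriched_modules=tuple(_module_label(m) for m in cfg.gwas_enriched_modules),
        contaminated_samples=contaminated,
        unique_vascular=uniq_v,
        unique_bulk=uniq_b,
        factor_scores=pd.DataFrame(
            factors, index=[_module_label(m) for m in range(cfg.n_modules)],
            columns=samples),
        loadings=pd.Series(loadings, index=proteins, name="loading"),
    )
    return SyntheticCohort(vascular=vasc_df, bulk=bulk_df, design=design,
                           traits=traits, truth=truth, config=cfg)


def generate_gwas_stats(truth: SyntheticTruth, n_background_genes: int = 2000,
                        enrichment_pshift: float = 0.1, n_studies: int = 3,
                        study_correlation: float = 0.8, seed: int = 0,
                        fixed_enriched_p: float | None = None) -> list[pd.Series]:
    """Gene-level association p-value tables, one per simulated study.

    Background genes draw p ~ Uniform(0, 1) marginally, correlated
    across studies through a Gaussian copula with ``study_correlation``
    (gene-level statistics from overlapping GWAS cohorts sharing one LD
    structure are strongly correlated between studies, not
    independent).  Genes belonging to the truth's enriched modules draw
    p ~ Beta(a, 1) with ``a = enrichment_pshift`` (a < 1 left-shifts
    the distribution; a = 1 is the uniform null).  ``fixed_enriched_p``
    pins the enriched genes to a single p-value instead.
    """
    for lab in truth.gwas_enriched_modules:
        if lab not in set(truth.module_labels):
            raise ConfigError(f"enriched module {lab!r} absent from truth labels")
    if not 0 < enrichment_pshift:
        raise ConfigError("enrichment_pshift must be positive")
    if not 0 <= study_correlation <= 1:
        raise ConfigError("study_correlation must lie in [0, 1]")
    from scipy.special import ndtr
    rng = np.random.default_rng(seed)
    network_genes = [vio.symbol_of(pid) for pid in truth.module_labels.index]
    enriched = {vio.symbol_of(pid)
                for pid, lab in truth.module_labels.items()
                if lab in truth.gwas_enriched_modules}
    extra = [f"BGENE{i:05d}" for i in range(n_background_genes)]
    genes = pd.Index(dict.fromkeys(network_genes + extra))
    common = rng.standard_normal(len(genes))
    rho = np.sqrt(study_correlation)
    tables = []
    for _ in range(n_studies):
        z = rho * common + np.sqrt(1.0 - rho**2) * rng.standard_normal(len(genes))
        pvals = ndtr(z)
        mask = genes.isin(enriched)
        if fixed_enriched_p is not None:
            pvals[mask] = fixed_enriched_p
        elif enrichment_pshift != 1.0:
            pvals[mask] = rng.beta(enrichment_pshift, 1.0, int(mask.sum()))
        tables.append(pd.Series(pvals, index=genes, name="P"))
    return tables


def generate_biofluid_tables(truth: SyntheticTruth, concordant_module: str = "M1",
                             detected_fraction: float = 0.4, seed: int = 0,
                             alpha_planted: float = 0.01) -> dict[str, pd.DataFrame]:
    """Biofluid (CSF/plasma) DE tables with planted brain concordance.

    Proteins of ``concordant_module`` detected in the fluid are planted
    as significantly *increased* (positive log2FC, small p); all other
    detected proteins get null fold changes and uniform p-values.
    """
    rng = np.random.default_rng(seed)
    tables = {}
    symbols = np.array([vio.symbol_of(pid) for pid in truth.module_labels.index])
    member = truth.module_labels.to_numpy() == concordant_module
    for fluid in ("CSF", "plasma"):
        detected = rng.random(len(symbols)) < detected_fraction
        detected |= member  # the echoed module is fully detected
        sym = symbols[detected]
        is_mem = member[detected]
        log2fc = rng.normal(0.0, 0.2, len(sym))
        pvals = rng.uniform(0.0, 1.0, len(sym))
        log2fc[is_mem] = rng.normal(0.8, 0.15, int(is_mem.sum()))
        pvals[is_mem] = rng.uniform(0.0, alpha_planted, int(is_mem.sum()))
        tables[fluid] = pd.DataFrame(
            {"protein": sym, "log2FC": log2fc, "p": pvals})
    return tables


AB40_PEPTIDE = "GAIIGLMVGGVV"
AB42_PEPTIDE = "GAIIGLMVGGVVIA"


def generate_abeta_peptides(n_peptides: int = 200, n_samples: int = 12,
                            ab40_vascular_fold: float = 5.0,
                            ab42_bulk_fold: float = 5.0,
                            seed: int = 0) -> dict[str, pd.DataFrame]:
    """Paired linear-scale peptide intensity matrices for the Abeta analysis.

    The two amyloid-beta C-terminal tryptic peptides are planted with
    Abeta40 enriched in the vascular fraction and Abeta42 in the bulk
    fraction (defaults exceed the 4-fold regime of interest); remaining
    peptides are unenriched filler.
    """
    rng = np.random.default_rng(seed)
    peptides = [AB40_PEPTIDE, AB42_PEPTIDE] + \
        ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 10)) + f"{i}"
         for i in range(n_peptides - 2)]
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    base = rng.lognormal(mean=10, sigma=1, size=(n_peptides, n_samples))
    bulk = base * rng.lognormal(0, 0.1, size=base.shape)
    vasc = base * rng.lognormal(0, 0.1, size=base.shape)
    vasc[0] *= ab40_vascular_fold
    bulk[1] *= ab42_bulk_fold
    idx = pd.Index(peptides, name="peptide")
    return {"vascular": pd.DataFrame(vasc, index=idx, columns=samples),
            "bulk": pd.DataFrame(bulk, index=idx, columns=samples)}
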