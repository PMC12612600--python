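"""Synthetic clonal seed orchards with known genetic architecture.

The generator produces exactly the data-generating process the mixed models
assume, so that every downstream estimator can be checked by parameter
recovery: clonal genetic values drawn from ``Sigma_site (x) K`` with K a
realized marker-based GRM, a separable AR1 x AR1 spatial residual field on
the planting grid, an independent nugget, and fixed site/population effects.
Spectral phenotypes add a band dimension whose genetic signal is smooth in
wavelength (squared-exponential cross-band correlation).

Default condition set (one orchard, Nepomuk-like): 31 clones, 200 ramets on
a 15 x 15 grid, 5,000 array SNPs, unit total phenotypic variance split as
genetic sigma_a^2 = 0.29, spatial sigma_xi^2 = 0.20 (rho_row = rho_col =
0.4) and nugget the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .genomics import GrMatrix, SnpMatrix, grm_yang, stabilize_psd
from .phenotypes import SpectraTable


class SimulationError(ValueError):
    pass


def _per_site(value, n_sites: int) -> tuple:
    """Broadcast a scalar setting to one value per site."""
    if np.isscalar(value):
        return (float(value),) * n_sites
    t = tuple(float(v) for v in value)
    if len(t) != n_sites:
        raise SimulationError(f"expected {n_sites} per-site values, got {len(t)}")
    return t


@dataclass
class SimulationConfig:
    """Truth parameters for one simulated study.

    ``site_clone_counts`` / ``n_shared_clones`` describe partially
    overlapping clone sets across two sites (the shared clones are the first
    ``n_shared_clones`` of each site's set).  All variance settings may be a
    scalar (shared across sites) or one value per site.
    """

    n_clones: int = 31
    ramets_per_clone: int | list | None = None
    ramets_per_site: int | tuple = 200
    n_sites: int = 1
    site_clone_counts: tuple | None = None
    n_shared_clones: int | None = None
    grid_rows: int | tuple = 15
    grid_cols: int | tuple = 15
    n_snps: int = 5000
    maf_distribution: tuple | float = (1.5, 1.5)
    n_populations: int = 2
    population_fst: float = 0.02
    n_half_sib_pairs: int = 0
    true_genetic_variance: float | tuple = 0.29
    cross_site_genetic_correlation: float = 0.99
    true_spatial_variance: float | tuple = 0.20
    spatial_rho_col: float | tuple = 0.4
    spatial_rho_row: float | tuple = 0.4
    true_nugget: float | tuple = 0.51
    mean: float = 10.0
    site_effects: tuple = (0.0, 0.3)
    population_effect_sd: float = 0.1
    n_bands: int = 220
    band_correlation_length: float = 25.0
    band_start_nm: float = 429.0
    band_step_nm: float = 2.2374  # 220 bands spanning ~429-919 nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites not in (1, 2):
            raise SimulationError("n_sites must be 1 or 2")
        for v in (
            *_per_site(self.true_genetic_variance, self.n_sites),
            *_per_site(self.true_spatial_variance, self.n_sites),
            *_per_site(self.true_nugget, self.n_sites),
        ):
            if v < 0:
                raise SimulationError("variances must be non-negative")
        if not -1.0 <= self.cross_site_genetic_correlation <= 1.0:
            raise SimulationError("|cross-site genetic correlation| must be <= 1")
        for r in (*_per_site(self.spatial_rho_col, self.n_sites),
                  *_per_site(self.spatial_rho_row, self.n_sites)):
            if not -1.0 < r < 1.0:
                raise SimulationError("spatial rho must lie in (-1, 1)")
        counts = self.clone_counts_per_site()
        for s in range(self.n_sites):
            rows = _per_site(self.grid_rows, self.n_sites)[s]
            cols = _per_site(self.grid_cols, self.n_sites)[s]
            if rows * cols < self.site_ramet_counts()[s]:
                raise SimulationError(
                    f"site {s}: grid {int(rows)}x{int(cols)} cannot hold "
                    f"{self.site_ramet_counts()[s]} ramets"
                )
            if counts[s] > self.n_clones:
                raise SimulationError("site clone count exceeds n_clones")

    def clone_counts_per_site(self) -> tuple:
        if self.site_clone_counts is not None:
            return tuple(int(c) for c in self.site_clone_counts)
        return (self.n_clones,) * self.n_sites

    def site_ramet_counts(self) -> tuple:
        return tuple(int(v) for v in _per_site(self.ramets_per_site, self.n_sites))

    def site_clone_indices(self) -> list:
        """Clone indices planted at each site; shared clones come first."""
        counts = self.clone_counts_per_site()
        if self.n_sites == 1:
            return [np.arange(counts[0])]
        shared = self.n_shared_clones if self.n_shared_clones is not None else min(counts)
        if shared > min(counts) or sum(counts) - shared > self.n_clones:
            raise SimulationError("inconsistent clone sharing across sites")
        s1 = np.arange(counts[0])
        s2 = np.concatenate([np.arange(shared), counts[0] + np.arange(counts[1] - shared)])
        return [s1, s2]


@dataclass
class OrchardDesign:
    """Per-ramet records: ramet_id, site, row, col, clone, population."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"ramet_id", "site", "row", "col", "clone", "population"}
        missing = required - set(self.table.columns)
        if missing:
            raise SimulationError(f"design table lacks columns {sorted(missing)}")
        if self.table.duplicated(["site", "row", "col"]).any():
            raise SimulationError("duplicate grid cells within a site")

    @property
    def n_ramets(self) -> int:
        return len(self.table)

    def clones(self) -> list:
        return sorted(self.table["clone"].unique())


@dataclass
class SimulatedStudy:
    design: OrchardDesign
    genotypes: SnpMatrix
    grm: GrMatrix
    true_clonal_values: pd.DataFrame  # clone x site
    phenotypes: pd.DataFrame  # design columns + value + truth components
    truth: SimulationConfig
    spectra: SpectraTable | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    n_clones: int,
    n_snps: int,
    maf_distribution: tuple | float = (1.5, 1.5),
    n_populations: int = 1,
    seed: int | np.random.Generator = 0,
    population_fst: float = 0.02,
    n_half_sib_pairs: int = 0,
) -> SnpMatrix:
    """Array-like biallelic dosages for unrelated (or weakly related) clones.

    Ancestral allele frequencies are Beta-shaped on (0.02, 0.5), mimicking
    array-ascertained SNPs; populations perturb frequencies with a
    Balding-Nichols model at the given Fst.  Optional half-sib clone pairs
    share one parental haplotype (weak relatedness as found among plus trees
    selected from neighboring stands); off by default.
    """
    if n_clones < 2 or n_snps < 1:
        raise SimulationError("need n_clones >= 2 and n_snps >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if np.isscalar(maf_distribution):
        p = np.full(n_snps, float(maf_distribution))
    else:
        a, b = maf_distribution
        p = 0.02 + 0.48 * rng.beta(a, b, size=n_snps)
    pop_of_clone = np.arange(n_clones) % max(n_populations, 1)
    dos = np.empty((n_clones, n_snps))
    pop_freqs = {}
    for pop in range(max(n_populations, 1)):
        if n_populations > 1 and population_fst > 0:
            f = population_fst
            pf = rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f)
            pf = np.clip(pf, 1e-4, 1 - 1e-4)
        else:
            pf = p
        pop_freqs[pop] = pf
    for i in range(n_clones):
        dos[i] = rng.binomial(2, pop_freqs[pop_of_clone[i]])
    for k in range(min(n_half_sib_pairs, n_clones // 2)):
        i, j = 2 * k, 2 * k + 1
        pf = pop_freqs[pop_of_clone[i]]
        shared = rng.binomial(1, pf)
        dos[i] = shared + rng.binomial(1, pf)
        dos[j] = shared + rng.binomial(1, pf)
    geno = SnpMatrix(
        clone_ids=np.array([f"C{i + 1:03d}" for i in range(n_clones)], dtype=object),
        snp_ids=np.array([f"SNP{j + 1:05d}" for j in range(n_snps)], dtype=object),
        dosages=dos,
    )
    geno.population_of_clone = {  # type: ignore[attr-defined]
        f"C{i + 1:03d}": int(pop_of_clone[i]) for i in range(n_clones)
    }
    return geno


# ---------------------------------------------------------------------------
# orchard design
# ---------------------------------------------------------------------------


def simulate_orchard_design(
    config: SimulationConfig, seed: int | np.random.Generator | None = None
) -> OrchardDesign:
    """Assign ramets of each site's clones to unique grid cells.

    Ramets are spread as evenly as possible over the site's clones (mimicking
    "up to 7 ramets per clone where available") and planted at randomly
    chosen occupied cells of the row/column grid, leaving the remaining
    cells empty (mortality/unplanted gaps).
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.seed if seed is None else seed)
    )
    rows_per_site = _per_site(config.grid_rows, config.n_sites)
    cols_per_site = _per_site(config.grid_cols, config.n_sites)
    site_clones = config.site_clone_indices()
    pop_of_clone = np.arange(config.n_clones) % max(config.n_populations, 1)
    records = []
    ramet_no = 0
    for s in range(config.n_sites):
        clones = site_clones[s]
        n_ramets = config.site_ramet_counts()[s]
        if config.ramets_per_clone is not None:
            reps = (
                [int(config.ramets_per_clone)] * len(clones)
                if np.isscalar(config.ramets_per_clone)
                else list(config.ramets_per_clone)
            )
            n_ramets = sum(reps)
        else:
            base, extra = divmod(n_ramets, len(clones))
            reps = [base + (1 if i < extra else 0) for i in range(len(clones))]
        nr, nc = int(rows_per_site[s]), int(cols_per_site[s])
        if nr * nc < n_ramets:
            raise SimulationError(
                f"site {s}: grid {nr}x{nc} cannot hold {n_ramets} ramets"
            )
        cells = [(r + 1, c + 1) for r in range(nr) for c in range(nc)]
        chosen = rng.permutation(len(cells))[:n_ramets]
        clone_list = np.repeat(clones, reps)
        rng.shuffle(clone_list)
        for cell_idx, clone in zip(chosen, clone_list):
            ramet_no += 1
            r, c = cells[cell_idx]
            records.append(
                {
                    "ramet_id": f"R{ramet_no:05d}",
                    "site": f"S{s + 1}",
                    "row": r,
                    "col": c,
                    "clone": f"C{clone + 1:03d}",
                    "population": f"P{pop_of_clone[clone] + 1}",
                }
            )
    return OrchardDesign(table=pd.DataFrame(records))


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _spatial_field(rows, cols, rho_row, rho_col, variance, rng) -> np.ndarray:
    """Exact draw from the separable AR1 field, via the Kronecker Cholesky
    square root on the full grid, subset to occupied cells."""
    if variance == 0.0:
        return np.zeros(len(rows))
    r_max, c_max = int(max(rows)), int(max(cols))
    from .mixed_models import ar1_correlation

    lr = np.linalg.cholesky(ar1_correlation(rho_row, np.arange(1, r_max + 1)))
    lc = np.linalg.cholesky(ar1_correlation(rho_col, np.arange(1, c_max + 1)))
    z = rng.standard_normal((r_max, c_max))
    field_full = lr @ z @ lc.T  # covariance AR1(row) x AR1(col)
    idx_r = np.asarray(rows, dtype=int) - 1
    idx_c = np.asarray(cols, dtype=int) - 1
    return np.sqrt(variance) * field_full[idx_r, idx_c]


def _check_psd_chol(m: np.ndarray, what: str) -> np.ndarray:
    try:
        return np.linalg.cholesky(m)
    except np.linalg.LinAlgError as exc:
        raise SimulationError(f"{what} is not positive definite") from exc


def simulate_phenotypes(
    design: OrchardDesign,
    grm: GrMatrix,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
) -> SimulatedStudy:
    """Phenotypes decomposing exactly as mean + fixed effects + clonal value
    + spatial residual + nugget under the stored truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tbl = design.table.reset_index(drop=True)
    clones = list(grm.clone_ids)
    missing = set(tbl["clone"]) - set(clones)
    if missing:
        raise SimulationError(f"design clones absent from GRM: {sorted(missing)[:5]}")
    q = grm.n_clones
    n_sites = config.n_sites
    va = _per_site(config.true_genetic_variance, n_sites)
    ra = config.cross_site_genetic_correlation
    if n_sites == 1:
        sigma = np.array([[va[0]]])
    else:
        c = ra * np.sqrt(va[0] * va[1])
        sigma = np.array([[va[0], c], [c, va[1]]])
    if sigma.max() > 0:
        lk = _check_psd_chol(grm.values, "GRM")
        if n_sites == 2 and abs(ra) >= 1.0 - 1e-12:
            # perfectly correlated sites: one clonal draw scaled per site
            base = lk @ rng.standard_normal(q)
            u = np.column_stack(
                [np.sqrt(va[0]) * base, np.sign(ra) * np.sqrt(va[1]) * base]
            )
        else:
            ls = _check_psd_chol(sigma, "site genetic covariance")
            u = lk @ rng.standard_normal((q, n_sites)) @ ls.T
    else:
        u = np.zeros((q, n_sites))
    clone_pos = {c_: i for i, c_ in enumerate(clones)}
    site_labels = sorted(tbl["site"].unique())
    vxi = _per_site(config.true_spatial_variance, n_sites)
    rho_c = _per_site(config.spatial_rho_col, n_sites)
    rho_r = _per_site(config.spatial_rho_row, n_sites)
    veta = _per_site(config.true_nugget, n_sites)
    pops = sorted(tbl["population"].unique())
    pop_eff = {
        p: (config.population_effect_sd * rng.standard_normal() if len(pops) > 1 else 0.0)
        for p in pops
    }
    value = np.empty(len(tbl))
    comp = {k: np.empty(len(tbl)) for k in ("fixed", "genetic", "spatial", "nugget")}
    for s, site in enumerate(site_labels):
        mask = (tbl["site"] == site).to_numpy()
        sub = tbl.loc[mask]
        fixed = (
            config.mean
            + (config.site_effects[s] if s < len(config.site_effects) else 0.0)
            + np.array([pop_eff[p] for p in sub["population"]])
        )
        genet = u[[clone_pos[c_] for c_ in sub["clone"]], s]
        spat = _spatial_field(
            sub["row"].to_numpy(), sub["col"].to_numpy(), rho_r[s], rho_c[s], vxi[s], rng
        )
        nug = np.sqrt(veta[s]) * rng.standard_normal(mask.sum())
        comp["fixed"][mask] = fixed
        comp["genetic"][mask] = genet
        comp["spatial"][mask] = spat
        comp["nugget"][mask] = nug
        value[mask] = fixed + genet + spat + nug
    pheno = tbl.copy()
    pheno["value"] = value
    for k, v in comp.items():
        pheno[f"true_{k}"] = v
    true_u = pd.DataFrame(u, index=clones, columns=site_labels[:n_sites])
    geno = getattr(grm, "_genotypes", None)
    return SimulatedStudy(
        design=design,
        genotypes=geno,
        grm=grm,
        true_clonal_values=true_u,
        phenotypes=pheno,
        truth=config,
    )


def simulate_spectra(
    design: OrchardDesign,
    grm: GrMatrix,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
) -> SpectraTable:
    """Per-band phenotypes with band-smooth genetic structure.

    Clonal genetic values over bands are drawn from ``K (x) C`` where C is a
    squared-exponential cross-band correlation with bandwidth
    ``band_correlation_length`` (in band-grid nm units), scaled per band by
    the genetic variance; residuals are an independent per-band nugget.
    An infinite bandwidth gives one shared genetic signal across all bands.
    """
    if config.n_bands < 2:
        raise SimulationError("n_bands must be >= 2")
    if config.band_correlation_length <= 0:
        raise SimulationError("band_correlation_length must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tbl = design.table.reset_index(drop=True)
    q = grm.n_clones
    b = config.n_bands
    wl = config.band_start_nm + config.band_step_nm * np.arange(b)
    if np.isinf(config.band_correlation_length):
        corr = np.ones((b, b))
        lc = np.ones((b, 1)) / 1.0  # rank-one: same signal everywhere
        zdim = 1
    else:
        d = (wl[:, None] - wl[None, :]) / config.band_correlation_length
        corr = np.exp(-0.5 * d * d)
        corr += 1e-8 * np.eye(b)
        lc = np.linalg.cholesky(corr)
        zdim = b
    va = _per_site(config.true_genetic_variance, config.n_sites)[0]
    veta = _per_site(config.true_nugget, config.n_sites)[0]
    lk = _check_psd_chol(grm.values, "GRM")
    u = lk @ rng.standard_normal((q, zdim)) @ (np.sqrt(va) * lc).T  # q x b
    clone_pos = {c_: i for i, c_ in enumerate(grm.clone_ids)}
    rows = np.array([clone_pos[c_] for c_ in tbl["clone"]])
    mean_profile = 0.25 + 0.1 * np.sin((wl - wl[0]) / (wl[-1] - wl[0]) * np.pi)
    refl = mean_profile[None, :] + u[rows] + np.sqrt(veta) * rng.standard_normal((len(tbl), b))
    return SpectraTable(
        ramet_ids=tbl["ramet_id"].to_numpy(),
        wavelengths=wl,
        reflectance=refl,
        level="canopy",
        genetic_values=u,
    )


def simulate_paired_traits(
    design: OrchardDesign,
    grm: GrMatrix,
    genetic_variances: tuple,
    genetic_correlation: float,
    residual_variances: tuple,
    residual_correlation: float,
    means: tuple = (0.0, 0.0),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Two responses on the same ramets (two traits, or one trait in two
    years) with specified genetic and residual correlations; the generative
    inverse of the bivariate model."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tbl = design.table.reset_index(drop=True)
    q = grm.n_clones
    va1, va2 = genetic_variances
    cg = genetic_correlation * np.sqrt(va1 * va2)
    sig_g = np.array([[va1, cg], [cg, va2]])
    ve1, ve2 = residual_variances
    ce = residual_correlation * np.sqrt(ve1 * ve2)
    sig_e = np.array([[ve1, ce], [ce, ve2]])
    lk = _check_psd_chol(grm.values, "GRM")
    if abs(genetic_correlation) >= 1.0 - 1e-12:
        base = lk @ rng.standard_normal(q)
        sgn = np.sign(genetic_correlation)
        u = np.column_stack([np.sqrt(va1) * base, sgn * np.sqrt(va2) * base])
    else:
        lg = _check_psd_chol(sig_g, "genetic covariance")
        u = lk @ rng.standard_normal((q, 2)) @ lg.T
    le = _check_psd_chol(sig_e + 1e-12 * np.eye(2), "residual covariance")
    e = rng.standard_normal((len(tbl), 2)) @ le.T
    clone_pos = {c_: i for i, c_ in enumerate(grm.clone_ids)}
    rows = np.array([clone_pos[c_] for c_ in tbl["clone"]])
    out = tbl.copy()
    out["trait1"] = means[0] + u[rows, 0] + e[:, 0]
    out["trait2"] = means[1] + u[rows, 1] + e[:, 1]
    out.attrs["true_clonal_values"] = u.tolist()
    return out


# ---------------------------------------------------------------------------
# full study + I/O
# ---------------------------------------------------------------------------


def simulate_study(
    config: SimulationConfig, with_spectra: bool = False
) -> SimulatedStudy:
    """End-to-end: genotypes -> Yang GRM -> design -> phenotypes (+ spectra).

    All randomness derives from ``config.seed`` through independent spawned
    streams, so identical configs give byte-identical studies.
    """
    ss = np.random.SeedSequence(config.seed)
    r_geno, r_design, r_pheno, r_spec = (np.random.default_rng(c) for c in ss.spawn(4))
    geno = simulate_genotypes(
        config.n_clones, config.n_snps, config.maf_distribution,
        config.n_populations, r_geno, config.population_fst, config.n_half_sib_pairs,
    )
    grm = stabilize_psd(grm_yang(geno), jitter=1e-4)
    grm._genotypes = geno  # type: ignore[attr-defined]
    design = simulate_orchard_design(config, r_design)
    study = simulate_phenotypes(design, grm, config, r_pheno)
    study.genotypes = geno
    if with_spectra:
        study.spectra = simulate_spectra(design, grm, config, r_spec)
    return study


def write_study(study: SimulatedStudy, outdir) -> dict:
    """Write design/traits CSV, genotypes in PLINK .raw layout, truth YAML."""
    from pathlib import Path

    from .genomics import write_plink_raw

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "design": out / "design.csv",
        "traits": out / "traits.csv",
        "genotypes": out / "genotypes.raw",
        "truth": out / "truth.yaml",
    }
    study.design.table.to_csv(paths["design"], index=False)
    study.phenotypes.to_csv(paths["traits"], index=False)
    write_plink_raw(study.genotypes, paths["genotypes"])
    truth = asdict(study.truth)
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump({k: _yamlable(v) for k, v in truth.items()}, fh, sort_keys=True)
    if study.spectra is not None:
        from .phenotypes import write_spectra_wide

        paths["spectra"] = out / "spectra.csv"
        write_spectra_wide(study.spectra, paths["spectra"])
    return {k: str(v) for k, v in paths.items()}


def _yamlable(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v
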