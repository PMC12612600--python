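"""Replicated parameter-recovery studies on synthetic orchards.

These routines validate the whole pipeline end to end: simulate an orchard
with known truth (genotypes -> Yang GRM -> spatially correlated phenotypes),
fit the genomic mixed model by REML, and summarize how well heritability and
genetic correlations are recovered over replicates.  Study dimensions mirror
the field data the models were designed for: a Nepomuk-like single site
(31 clones / 200 ramets), a Plasy-like single site (29 clones / 148 ramets),
and a two-site layout sharing 24 clones.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .genetic_params import heritability, trait_pair_correlation, type_b_correlation
from .mixed_models import ConvergenceError, FitControls, ModelError, build_model_data, fit_reml
from .synthetic import SimulationConfig, simulate_paired_traits, simulate_study

# one orchard's worth of defaults; spatial fraction and AR1 decay fixed once
SPATIAL_VARIANCE = 0.20
RHO = 0.4

NEPOMUK = dict(n_clones=31, ramets_per_site=200, grid_rows=15, grid_cols=15)
PLASY = dict(n_clones=29, ramets_per_site=148, grid_rows=13, grid_cols=13)


def _config_single_site(h2: float, n_clones: int, ramets: int, rows: int, cols: int,
                        n_snps: int, seed: int) -> SimulationConfig:
    return SimulationConfig(
        n_clones=n_clones, ramets_per_site=ramets, n_sites=1,
        grid_rows=rows, grid_cols=cols, n_snps=n_snps,
        true_genetic_variance=h2, true_spatial_variance=SPATIAL_VARIANCE,
        spatial_rho_col=RHO, spatial_rho_row=RHO,
        true_nugget=1.0 - h2 - SPATIAL_VARIANCE, seed=seed,
    )


def _fit_study(study, controls: FitControls):
    data = build_model_data(study.phenotypes, study.phenotypes["value"], study.grm)
    return fit_reml(data, "multi_site_univariate", controls)


def recover_h2_single_site(
    true_h2: float,
    n_clones: int,
    ramets: int,
    grid: tuple[int, int],
    n_snps: int = 5000,
    n_replicates: int = 30,
    seed: int = 1,
) -> dict:
    """Mean REML H^2 over replicate single-site simulations at known truth."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n_replicates)]
    controls = FitControls(spatial=True, compute_ai=False)
    ests = []
    for rs in seeds:
        cfg = _config_single_site(true_h2, n_clones, ramets, grid[0], grid[1], n_snps, rs)
        study = simulate_study(cfg)
        try:
            fit = _fit_study(study, controls)
            ests.append(heritability(fit, fit.groups[0]).h2)
        except (ModelError, ConvergenceError):
            continue
    ests = np.asarray(ests)
    return {
        "mean_h2": float(ests.mean()),
        "sd_h2": float(ests.std(ddof=1)),
        "n_ok": int(ests.size),
        "n_replicates": n_replicates,
        "true_h2": true_h2,
        "estimates": ests.tolist(),
    }


def _two_site_config(h2_per_site: float, r_b: float, seed: int,
                     n_snps: int = 5000) -> SimulationConfig:
    return SimulationConfig(
        n_clones=36,  # 31 + 29 with 24 shared
        site_clone_counts=(31, 29), n_shared_clones=24,
        ramets_per_site=(200, 148), n_sites=2,
        grid_rows=(15, 13), grid_cols=(15, 13), n_snps=n_snps,
        true_genetic_variance=h2_per_site,
        cross_site_genetic_correlation=r_b,
        true_spatial_variance=SPATIAL_VARIANCE,
        spatial_rho_col=RHO, spatial_rho_row=RHO,
        true_nugget=1.0 - h2_per_site - SPATIAL_VARIANCE, seed=seed,
    )


def recover_pooled_h2(
    true_h2: float,
    r_b: float = 0.99,
    n_snps: int = 5000,
    n_replicates: int = 30,
    seed: int = 1,
    with_se: bool = True,
) -> dict:
    """Pooled two-site H^2 recovery; also compares the pooled SE with the
    per-site SEs from the same joint fit (the pooled estimate should be the
    more precise one in most replicates)."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n_replicates)]
    controls = FitControls(spatial=True, compute_ai=with_se)
    pooled, se_wins = [], []
    for rs in seeds:
        study = simulate_study(_two_site_config(true_h2, r_b, rs, n_snps))
        try:
            fit = _fit_study(study, controls)
        except (ModelError, ConvergenceError):
            continue
        est = heritability(fit, "pooled")
        pooled.append(est.h2)
        if with_se:
            site_ses = [heritability(fit, g).se for g in fit.groups]
            if np.isfinite(est.se) and all(np.isfinite(s) for s in site_ses):
                se_wins.append(est.se <= max(site_ses))
    pooled = np.asarray(pooled)
    return {
        "mean_h2": float(pooled.mean()),
        "sd_h2": float(pooled.std(ddof=1)),
        "n_ok": int(pooled.size),
        "n_replicates": n_replicates,
        "true_h2": true_h2,
        "se_reduction_fraction": float(np.mean(se_wins)) if se_wins else float("nan"),
        "estimates": pooled.tolist(),
    }


def recover_type_b(
    true_r_b: float,
    h2_per_site: float = 0.25,
    n_snps: int = 5000,
    n_replicates: int = 30,
    seed: int = 1,
) -> dict:
    """Mean estimated cross-site genetic correlation at known truth."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n_replicates)]
    controls = FitControls(spatial=True, compute_ai=False)
    ests, boundaries = [], 0
    for rs in seeds:
        study = simulate_study(_two_site_config(h2_per_site, true_r_b, rs, n_snps))
        try:
            fit = _fit_study(study, controls)
            est = type_b_correlation(fit)
        except (ModelError, ConvergenceError):
            continue
        if est.defined and np.isfinite(est.value):
            ests.append(est.value)
            boundaries += int(est.boundary)
    ests = np.asarray(ests)
    return {
        "mean_r_b": float(ests.mean()),
        "sd_r_b": float(ests.std(ddof=1)),
        "n_ok": int(ests.size),
        "n_boundary": boundaries,
        "n_replicates": n_replicates,
        "true_r_b": true_r_b,
        "estimates": ests.tolist(),
    }


def recover_year_to_year(
    true_r_g: float,
    residual_correlation: float = 0.3,
    h2: float = 0.25,
    n_clones: int = 67,
    ramets: int = 900,
    grid: tuple[int, int] = (32, 31),
    n_snps: int = 5000,
    n_replicates: int = 30,
    seed: int = 1,
) -> dict:
    """Bivariate (two-year) genetic-correlation recovery on one large site."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n_replicates)]
    controls = FitControls(spatial=False, compute_ai=False)
    ests = []
    for rs in seeds:
        cfg = _config_single_site(h2, n_clones, ramets, grid[0], grid[1], n_snps, rs)
        study = simulate_study(cfg)  # provides genotypes/GRM/design
        rng = np.random.default_rng(rs + 1)
        paired = simulate_paired_traits(
            study.design, study.grm,
            genetic_variances=(h2, h2), genetic_correlation=true_r_g,
            residual_variances=(1 - h2, 1 - h2),
            residual_correlation=residual_correlation,
            means=(10.0, 10.2), seed=rng,
        )
        try:
            _, est = trait_pair_correlation(
                paired, paired["trait1"], paired["trait2"], study.grm,
                kind="year_to_year", controls=controls,
            )
        except (ModelError, ConvergenceError):
            continue
        if est.defined and np.isfinite(est.value):
            ests.append(est.value)
    ests = np.asarray(ests)
    return {
        "mean_r_g": float(ests.mean()),
        "sd_r_g": float(ests.std(ddof=1)),
        "n_ok": int(ests.size),
        "n_replicates": n_replicates,
        "true_r_g": true_r_g,
        "estimates": ests.tolist(),
    }
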