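"""Heritabilities, genetic correlations and per-wavelength scans.

Broad-sense heritability on clonal material is H^2 = sigma_g^2 / sigma_p^2
where the phenotypic variance sums the genetic variance, the spatially
structured residual variance and the nugget (a switch exposes the
exclude-spatial alternative).  Cross-site stability is summarized by the
type B genetic correlation r_B = cov_a(S1,S2) / sqrt(var_a(S1) var_a(S2));
between-trait (type A) and between-year correlations come from bivariate
fits.  Standard errors are delta-method transforms of the inverse
average-information matrix; correlations pinned at +/-1 are boundary-flagged
and reported without an SE.  Significance is by likelihood-ratio test, with
the half-and-half chi-square mixture for variances tested on the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomics import GrMatrix
from .mixed_models import (
    ConvergenceError,
    FitControls,
    ModelError,
    VarianceComponentFit,
    build_bivariate_data,
    build_model_data,
    fit_reml,
    lrt,
)
from .phenotypes import SpectraTable

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05


@dataclass
class HeritabilityEstimate:
    h2: float
    se: float  # NaN when any involved parameter is boundary-pinned
    scope: str  # site label or "pooled"
    sigma_g: float
    sigma_xi: float
    sigma_eta: float
    p_value: float | None = None
    significant: bool | None = None

    @property
    def sigma_p(self) -> float:
        return self.sigma_g + self.sigma_xi + self.sigma_eta


@dataclass
class CorrelationEstimate:
    kind: str  # type_A, type_B, year_to_year
    value: float
    se: float  # NaN at the boundary
    boundary: bool
    p_value: float | None = None
    defined: bool = True


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------


def _site_components(fit: VarianceComponentFit, s: int) -> tuple[float, float, float]:
    vg = fit.genetic.variances[s]
    vxi = fit.residual.spatial_variance[s] if fit.residual.spatial_variance else 0.0
    veta = fit.residual.nugget[s] if fit.residual.nugget else fit.residual.trait_variances[s]
    return vg, vxi, veta


def _h2_gradient_se(fit: VarianceComponentFit, weights: dict[int, float],
                    include_spatial: bool) -> float:
    """Delta-method SE of a ramet-weighted combination of per-site H^2."""
    if fit.param_cov is None or fit.any_boundary:
        return float("nan")
    names = fit.param_names
    grad = np.zeros(len(names))
    for s, w in weights.items():
        vg, vxi, veta = _site_components(fit, s)
        vp = vg + (vxi if include_spatial else 0.0) + veta
        if vp <= 0:
            return float("nan")
        d_vg = (vp - vg) / vp**2
        d_env = -vg / vp**2
        for i, n_ in enumerate(names):
            if n_ == f"va_s{s}":
                grad[i] += w * d_vg
            elif n_ == f"veta_s{s}" or (n_ == f"vxi_s{s}" and include_spatial):
                grad[i] += w * d_env
    var = float(grad @ np.nan_to_num(fit.param_cov) @ grad)
    return float(np.sqrt(max(var, 0.0)))


def heritability(
    fit: VarianceComponentFit,
    scope: str = "pooled",
    p_value: float | None = None,
    alpha: float = ALPHA_DEFAULT,
    include_spatial: bool = True,
) -> HeritabilityEstimate:
    """H^2 for one site, or the ramet-count-weighted pooled value.

    ``include_spatial`` keeps the AR1 field variance inside sigma_p^2
    (default); the alternative counts only the nugget as environmental.
    """
    groups = fit.groups
    if scope == "pooled":
        weights = {
            s: fit.group_n_obs[g] / fit.n_obs for s, g in enumerate(groups)
        }
    else:
        if scope not in groups:
            raise ModelError(f"scope {scope!r} not among fitted groups {groups}")
        weights = {groups.index(scope): 1.0}
    h2 = 0.0
    tot_g = tot_xi = tot_eta = 0.0
    for s, w in weights.items():
        vg, vxi, veta = _site_components(fit, s)
        vp = vg + (vxi if include_spatial else 0.0) + veta
        if vp <= 0:
            raise ModelError("all variance components are zero; H^2 undefined")
        h2 += w * vg / vp
        tot_g += w * vg
        tot_xi += w * vxi
        tot_eta += w * veta
    se = _h2_gradient_se(fit, weights, include_spatial)
    return HeritabilityEstimate(
        h2=float(h2), se=se, scope=scope,
        sigma_g=tot_g, sigma_xi=tot_xi, sigma_eta=tot_eta,
        p_value=p_value,
        significant=None if p_value is None else bool(p_value < alpha),
    )


def heritability_with_test(
    design: pd.DataFrame,
    values,
    grm: GrMatrix,
    controls: FitControls | None = None,
    alpha: float = ALPHA_DEFAULT,
    include_spatial: bool = True,
) -> tuple[VarianceComponentFit, dict[str, HeritabilityEstimate]]:
    """Fit the genomic model, test sigma_g^2 = 0 by boundary-mixture LRT and
    return per-scope heritability estimates."""
    from dataclasses import replace as dc_replace

    controls = controls or FitControls()
    data = build_model_data(design, values, grm)
    full = fit_reml(data, "multi_site_univariate", controls)
    reduced = fit_reml(
        data, "multi_site_univariate", dc_replace(controls, genetic=False, compute_ai=False)
    )
    _, p = lrt(full, reduced, "variance_on_boundary")
    scopes = list(full.groups) + (["pooled"] if len(full.groups) > 1 else [])
    ests = {
        sc: heritability(full, sc, p_value=p, alpha=alpha, include_spatial=include_spatial)
        for sc in scopes
    }
    return full, ests


# ---------------------------------------------------------------------------
# genetic correlations
# ---------------------------------------------------------------------------


def _correlation_from_fit(
    fit: VarianceComponentFit, kind: str, p_value: float | None
) -> CorrelationEstimate:
    v1, v2 = fit.genetic.variances
    if v1 <= 0 or v2 <= 0 or fit.boundary_flags.get("va_s0") or fit.boundary_flags.get(
        "va_t0"
    ) or fit.boundary_flags.get("va_s1") or fit.boundary_flags.get("va_t1"):
        return CorrelationEstimate(
            kind=kind, value=float("nan"), se=float("nan"),
            boundary=True, p_value=p_value, defined=False,
        )
    r = fit.genetic.covariance / np.sqrt(v1 * v2)
    # the estimate is at a boundary if the genetic correlation itself is
    # pinned, or (bivariate) if the residual correlation collapsed, which
    # happens for degenerate trait pairs and invalidates the AI matrix
    boundary = (
        bool(fit.boundary_flags.get("ra", False))
        or abs(r) >= 0.999
        or bool(fit.boundary_flags.get("re", False))
    )
    se = float("nan")
    if not boundary and fit.param_cov is not None and "ra" in fit.param_names:
        i = fit.param_names.index("ra")
        se = float(np.sqrt(max(fit.param_cov[i, i], 0.0)))
    value = float(np.sign(r)) if abs(r) > 1 else float(r)
    return CorrelationEstimate(
        kind=kind, value=value, se=se, boundary=boundary, p_value=p_value
    )


def type_b_correlation(
    fit: VarianceComponentFit, p_value: float | None = None
) -> CorrelationEstimate:
    """Cross-site genetic correlation from a two-site fit."""
    if len(fit.groups) != 2 or fit.model != "multi_site_univariate":
        raise ModelError("type B correlation needs a two-site fit")
    return _correlation_from_fit(fit, "type_B", p_value)


def type_b_with_test(
    design: pd.DataFrame,
    values,
    grm: GrMatrix,
    controls: FitControls | None = None,
) -> tuple[VarianceComponentFit, CorrelationEstimate]:
    """Two-site fit plus the covariance-zero LRT for the type B correlation."""
    from dataclasses import replace as dc_replace

    controls = controls or FitControls()
    data = build_model_data(design, values, grm)
    if len(data.groups) != 2:
        raise ModelError("type B correlation needs observations at two sites")
    full = fit_reml(data, "multi_site_univariate", controls)
    reduced = fit_reml(
        data, "multi_site_univariate",
        dc_replace(controls, fix_genetic_corr=0.0, compute_ai=False),
    )
    _, p = lrt(full, reduced, "covariance_zero")
    return full, type_b_correlation(full, p_value=p)


def trait_pair_correlation(
    design: pd.DataFrame,
    values1,
    values2,
    grm: GrMatrix,
    kind: str = "type_A",
    controls: FitControls | None = None,
) -> tuple[VarianceComponentFit, CorrelationEstimate]:
    """Genetic correlation between two traits (type A) or the same trait in
    two years (``year_to_year``), from a bivariate genomic fit."""
    from dataclasses import replace as dc_replace

    if kind not in ("type_A", "year_to_year"):
        raise ModelError("kind must be 'type_A' or 'year_to_year'")
    controls = controls or FitControls(spatial=False)
    data = build_bivariate_data(design, values1, values2, grm)
    full = fit_reml(data, "bivariate", controls)
    reduced = fit_reml(
        data, "bivariate", dc_replace(controls, fix_genetic_corr=0.0, compute_ai=False)
    )
    try:
        _, p = lrt(full, reduced, "covariance_zero")
    except ModelError:
        # a boundary-pinned full fit (e.g. degenerate, perfectly correlated
        # responses) has no valid chi-square reference; report no p-value
        if not full.any_boundary:
            raise
        p = float("nan")
    return full, _correlation_from_fit(full, kind, p)


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

SCAN_COLUMNS = [
    "wavelength", "scope", "estimate", "se", "p_value", "significant",
    "boundary", "n_ramets", "n_clones", "status",
]


@dataclass
class GeneticParameterTable:
    """Per-trait or per-wavelength genetic parameters with fixed schema."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=1)


def wavelength_scan(
    spectra: SpectraTable,
    design: pd.DataFrame,
    grm: GrMatrix,
    controls: FitControls | None = None,
    alpha: float = ALPHA_DEFAULT,
    scopes: list | None = None,
) -> GeneticParameterTable:
    """Per-band heritability scan: one independent genomic fit per band.

    Bands whose fit fails are recorded with the failure reason rather than
    dropped.  Deterministic given data and controls.
    """
    controls = controls or FitControls(spatial=False)
    merged = design.reset_index(drop=True).merge(
        pd.DataFrame({"ramet_id": spectra.ramet_ids}), on="ramet_id"
    )
    rows = []
    n_fail = 0
    ramet_order = {r: i for i, r in enumerate(spectra.ramet_ids)}
    idx = merged["ramet_id"].map(ramet_order).to_numpy()
    for b, wl in enumerate(spectra.wavelengths):
        values = spectra.reflectance[idx, b]
        try:
            fit, ests = heritability_with_test(
                merged, values, grm, controls=controls, alpha=alpha
            )
            use_scopes = scopes or (["pooled"] if len(fit.groups) > 1 else list(fit.groups))
            for sc in use_scopes:
                e = ests[sc]
                rows.append(
                    {
                        "wavelength": wl, "scope": sc, "estimate": e.h2, "se": e.se,
                        "p_value": e.p_value, "significant": e.significant,
                        "boundary": fit.any_boundary,
                        "n_ramets": fit.n_obs, "n_clones": grm.n_clones, "status": "ok",
                    }
                )
        except (ModelError, ConvergenceError) as exc:
            n_fail += 1
            rows.append(
                {
                    "wavelength": wl, "scope": "pooled", "estimate": np.nan,
                    "se": np.nan, "p_value": np.nan, "significant": None,
                    "boundary": False, "n_ramets": 0, "n_clones": grm.n_clones,
                    "status": f"failed: {exc}",
                }
            )
    if n_fail == len(spectra.wavelengths):
        raise ModelError("every band failed to fit")
    return GeneticParameterTable(pd.DataFrame(rows, columns=SCAN_COLUMNS))


def correlation_with_nft(
    spectra: SpectraTable,
    nft_values: pd.Series,
    design: pd.DataFrame,
    grm: GrMatrix,
    controls: FitControls | None = None,
    alpha: float = ALPHA_DEFAULT,
) -> GeneticParameterTable:
    """Per-band type A genetic correlation between reflectance and one
    needle functional trait (``nft_values`` indexed by ramet_id)."""
    controls = controls or FitControls(spatial=False)
    merged = design.reset_index(drop=True).merge(
        pd.DataFrame({"ramet_id": spectra.ramet_ids}), on="ramet_id"
    )
    ramet_order = {r: i for i, r in enumerate(spectra.ramet_ids)}
    idx = merged["ramet_id"].map(ramet_order).to_numpy()
    trait = merged["ramet_id"].map(nft_values).to_numpy(dtype=float)
    rows = []
    n_fail = 0
    for b, wl in enumerate(spectra.wavelengths):
        values = spectra.reflectance[idx, b]
        try:
            fit, est = trait_pair_correlation(
                merged, values, trait, grm, kind="type_A", controls=controls
            )
            rows.append(
                {
                    "wavelength": wl, "scope": "type_A", "estimate": est.value,
                    "se": est.se, "p_value": est.p_value,
                    "significant": None if est.p_value is None else bool(est.p_value < alpha),
                    "boundary": est.boundary, "n_ramets": fit.n_obs,
                    "n_clones": grm.n_clones, "status": "ok" if est.defined else "undefined",
                }
            )
        except (ModelError, ConvergenceError) as exc:
            n_fail += 1
            rows.append(
                {
                    "wavelength": wl, "scope": "type_A", "estimate": np.nan,
                    "se": np.nan, "p_value": np.nan, "significant": None,
                    "boundary": False, "n_ramets": 0, "n_clones": grm.n_clones,
                    "status": f"failed: {exc}",
                }
            )
    if n_fail == len(spectra.wavelengths):
        raise ModelError("every band failed to fit")
    return GeneticParameterTable(pd.DataFrame(rows, columns=SCAN_COLUMNS))


def plot_scan(table: GeneticParameterTable, path, ylabel: str = "$H^2$") -> None:
    """Per-band curve with an SE ribbon, written to a figure file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for scope, sub in table.table.groupby("scope"):
        sub = sub[sub["status"] == "ok"]
        ax.plot(sub["wavelength"], sub["estimate"], label=str(scope))
        lo = sub["estimate"] - sub["se"]
        hi = sub["estimate"] + sub["se"]
        ax.fill_between(sub["wavelength"], lo, hi, alpha=0.25)
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
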