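"""REML machinery for genomic mixed models on clonal field trials.

Two model families are supported, both with a marker-based relationship
matrix K among clones:

* ``multi_site_univariate`` — one trait observed on ramets at one or two
  sites.  Random clonal effects are nested within site with genetic
  covariance ``Sigma_a (x) K`` (per-site genetic variances plus a cross-site
  covariance); residuals are, per site, a separable first-order
  autoregressive field on the planting grid plus an independent nugget:
  ``sigma_xi^2 AR1(rho_col) (x) AR1(rho_row) + sigma_eta^2 I``.

* ``bivariate`` — two traits (or the same trait in two years) stacked.
  Genetic covariance ``Sigma_a (x) K`` over (trait, clone); residual
  covariance ``Sigma_e (x) I`` across co-observed ramets (units observed for
  only one trait contribute an independent residual).

The restricted log-likelihood is evaluated through the mixed-model-equations
identity  ``log|V| + log|X'V^-1 X| = log|R| + log|G| + log|C|``  and
``y'Py = y'R^-1 y - b'C^-1 b`` (C the MME coefficient matrix), which keeps
every solve at the size of the fixed+random effect vector rather than the
data vector.  Variances are optimized on the log scale and correlations
through a tanh bijection; standard errors come from the inverse
average-information matrix at the optimum, with boundary-pinned parameters
reported without an SE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .genomics import GrMatrix

logger = logging.getLogger(__name__)

LOG2PI = float(np.log(2 * np.pi))
_LOGV_LO, _LOGV_HI = -15.0, 6.0  # log-variance bounds on the standardized scale
_Z_MAX = 7.0  # atanh-scale bound for correlations and AR1 rho
_BOUNDARY_MARGIN = 0.5


class ModelError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    """REML optimization failed; carries the optimizer trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


# ---------------------------------------------------------------------------
# covariance building blocks
# ---------------------------------------------------------------------------


def ar1_correlation(rho: float, coords) -> np.ndarray:
    """AR1 correlation matrix: entry (i, j) = rho^|coord_i - coord_j|."""
    if not -1.0 < rho < 1.0:
        raise ModelError(f"AR1 rho={rho} outside (-1, 1)")
    c = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ModelError("AR1 coordinates must be finite")
    return _ar1_pow(rho, np.abs(c[:, None] - c[None, :]))


def _ar1_pow(rho: float, d: np.ndarray) -> np.ndarray:
    # d holds integer-valued grid distances, so a negative rho is well defined
    if rho == 0.0:
        return (d == 0).astype(float)
    if rho < 0:
        return np.where(d % 2 == 0, 1.0, -1.0) * np.abs(rho) ** d
    return rho**d


@dataclass(frozen=True)
class GeneticCovariance:
    """Per-group genetic (co)variances; groups are sites or traits."""

    variances: tuple  # one per group
    covariance: float = 0.0  # between the two groups (ignored for 1 group)
    structure: str = "multi_site"

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.variances):
            raise ModelError("genetic variances must be non-negative")
        if len(self.variances) == 2:
            bound = np.sqrt(self.variances[0] * self.variances[1])
            if abs(self.covariance) > bound * (1 + 1e-9):
                raise ModelError("genetic covariance implies |correlation| > 1")

    @property
    def n_groups(self) -> int:
        return len(self.variances)

    def matrix(self) -> np.ndarray:
        if self.n_groups == 1:
            return np.array([[self.variances[0]]])
        v1, v2 = self.variances
        return np.array([[v1, self.covariance], [self.covariance, v2]])

    @property
    def correlation(self) -> float:
        v1, v2 = self.variances
        if v1 <= 0 or v2 <= 0:
            return float("nan")
        return self.covariance / np.sqrt(v1 * v2)


@dataclass(frozen=True)
class ResidualCovariance:
    """Residual structure: per-site AR1 x AR1 spatial + nugget, or bivariate
    ``Sigma_e (x) I``."""

    spatial_variance: tuple = ()  # sigma_xi^2 per site
    rho_col: tuple = ()
    rho_row: tuple = ()
    nugget: tuple = ()  # sigma_eta^2 per site
    trait_variances: tuple = ()  # bivariate
    trait_covariance: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.spatial_variance + self.nugget + self.trait_variances):
            raise ModelError("residual variances must be non-negative")
        for r in self.rho_col + self.rho_row:
            if not -1.0 < r < 1.0:
                raise ModelError("AR1 rho must lie in (-1, 1)")
        if len(self.trait_variances) == 2:
            bound = np.sqrt(self.trait_variances[0] * self.trait_variances[1])
            if abs(self.trait_covariance) > bound * (1 + 1e-9):
                raise ModelError("residual covariance implies |correlation| > 1")


def assemble_genetic_covariance(g: GeneticCovariance, K: GrMatrix | np.ndarray) -> np.ndarray:
    """Kronecker product of the group covariance with the GRM (group-major)."""
    k = K.values if isinstance(K, GrMatrix) else np.asarray(K, dtype=float)
    return np.kron(g.matrix(), k)


def assemble_residual_covariance(r: ResidualCovariance, design: pd.DataFrame) -> np.ndarray:
    """Dense residual covariance over ramets, block-diagonal across sites.

    ``design`` needs columns site/row/col, ordered as the data vector.
    """
    sites = list(dict.fromkeys(design["site"]))
    n = len(design)
    out = np.zeros((n, n))
    for s_idx, site in enumerate(sites):
        mask = (design["site"] == site).to_numpy()
        sub = design.loc[mask]
        if sub.duplicated(["row", "col"]).any():
            raise ModelError(f"duplicate (site,row,col) within site {site!r}")
        rows = sub["row"].to_numpy(float)
        cols = sub["col"].to_numpy(float)
        v_xi = r.spatial_variance[s_idx]
        gamma = v_xi * _ar1_pow(r.rho_col[s_idx], np.abs(cols[:, None] - cols[None, :])) * _ar1_pow(
            r.rho_row[s_idx], np.abs(rows[:, None] - rows[None, :])
        )
        gamma[np.diag_indices_from(gamma)] = v_xi + r.nugget[s_idx]
        out[np.ix_(mask, mask)] = gamma
    return out


# ---------------------------------------------------------------------------
# model data
# ---------------------------------------------------------------------------


@dataclass
class ModelData:
    """Response, design matrices and structural indices for one REML fit."""

    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray  # n x (n_groups * n_clones) incidence, group-major
    design: pd.DataFrame  # per-observation site/row/col (+ group for bivariate)
    K: GrMatrix
    groups: list  # site or trait labels, order matching Z blocks
    group_of_obs: np.ndarray  # group index per observation
    clone_of_obs: np.ndarray  # clone index (into K.clone_ids) per observation
    pair_index: np.ndarray | None = None  # bivariate: ramet pairing

    def __post_init__(self) -> None:
        n = self.y.size
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ModelError("row counts of y, X, Z disagree")
        if self.Z.shape[1] != len(self.groups) * self.K.n_clones:
            raise ModelError("Z columns do not map onto (group x GRM clone)")


def _drop_redundant_columns(X: np.ndarray) -> np.ndarray:
    """Reduce X to full column rank (pivoted QR), logging dropped columns."""
    if X.shape[1] == 0:
        return X
    from scipy.linalg import qr as sqr

    _, r, piv = sqr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        logger.info("dropping %d redundant fixed-effect columns", X.shape[1] - rank)
    keep = np.sort(piv[:rank])
    return X[:, keep]


def _population_dummies(design: pd.DataFrame, within: str) -> np.ndarray:
    """Population-within-group fixed-effect columns; singleton levels are
    merged into a catch-all level to preserve estimability."""
    labels = design[within].astype(str) + "/" + design["population"].astype(str)
    counts = labels.value_counts()
    merged = labels.where(labels.map(counts) > 1, other="_pooled")
    return pd.get_dummies(merged, dtype=float).to_numpy()


def build_model_data(
    design: pd.DataFrame,
    values: np.ndarray | pd.Series,
    grm: GrMatrix,
    use_population: bool = True,
) -> ModelData:
    """Assemble a univariate (single- or multi-site) ModelData.

    ``design`` needs columns clone, site, row, col and (optionally)
    population; rows align with ``values``.  Clones must all be present in
    the GRM.
    """
    design = design.reset_index(drop=True)
    y = np.asarray(values, dtype=float)
    if y.size != len(design):
        raise ModelError("values and design row counts differ")
    ok = np.isfinite(y)
    design, y = design.loc[ok].reset_index(drop=True), y[ok]
    sites = sorted(design["site"].unique())
    clone_pos = {c: i for i, c in enumerate(grm.clone_ids)}
    missing = set(design["clone"]) - set(clone_pos)
    if missing:
        raise ModelError(f"clones absent from GRM: {sorted(missing)[:5]}")
    cols = [np.ones((len(design), 1))]
    if len(sites) > 1:
        cols.append(pd.get_dummies(design["site"], dtype=float).to_numpy()[:, 1:])
    if use_population and "population" in design.columns:
        cols.append(_population_dummies(design, "site"))
    X = _drop_redundant_columns(np.column_stack(cols))
    q = grm.n_clones
    group_of = design["site"].map({s: i for i, s in enumerate(sites)}).to_numpy()
    clone_of = design["clone"].map(clone_pos).to_numpy()
    Z = np.zeros((len(design), len(sites) * q))
    Z[np.arange(len(design)), group_of * q + clone_of] = 1.0
    return ModelData(
        y=y, X=X, Z=Z, design=design, K=grm, groups=sites,
        group_of_obs=group_of, clone_of_obs=clone_of,
    )


def build_bivariate_data(
    design: pd.DataFrame,
    values1: np.ndarray | pd.Series,
    values2: np.ndarray | pd.Series,
    grm: GrMatrix,
    use_population: bool = True,
) -> ModelData:
    """Stack two responses measured on the ramets of one design.

    Missing values are allowed in either response; residual covariance is
    estimated only between co-observed ramets.
    """
    design = design.reset_index(drop=True)
    y1 = np.asarray(values1, dtype=float)
    y2 = np.asarray(values2, dtype=float)
    if y1.size != len(design) or y2.size != len(design):
        raise ModelError("responses and design row counts differ")
    obs1, obs2 = np.isfinite(y1), np.isfinite(y2)
    clone_pos = {c: i for i, c in enumerate(grm.clone_ids)}
    missing = set(design["clone"]) - set(clone_pos)
    if missing:
        raise ModelError(f"clones absent from GRM: {sorted(missing)[:5]}")
    shared = set(design.loc[obs1, "clone"]) & set(design.loc[obs2, "clone"])
    if len(shared) < 2:
        raise ModelError("fewer than 2 clones shared between the two responses")
    frames, ys, groups_of, ramet_of = [], [], [], []
    for t, (yv, obs) in enumerate(((y1, obs1), (y2, obs2))):
        sub = design.loc[obs].copy()
        sub.attrs = {}
        sub["trait"] = t
        frames.append(sub)
        ys.append(yv[obs])
        groups_of.append(np.full(obs.sum(), t))
        ramet_of.append(np.flatnonzero(obs))
    stacked = pd.concat(frames, ignore_index=True)
    y = np.concatenate(ys)
    group_of = np.concatenate(groups_of)
    ramet_idx = np.concatenate(ramet_of)
    cols = [pd.get_dummies(stacked["trait"], dtype=float).to_numpy()]  # per-trait mean
    if use_population and "population" in stacked.columns:
        cols.append(_population_dummies(stacked, "trait"))
    X = _drop_redundant_columns(np.column_stack(cols))
    q = grm.n_clones
    clone_of = stacked["clone"].map(clone_pos).to_numpy()
    Z = np.zeros((len(stacked), 2 * q))
    Z[np.arange(len(stacked)), group_of * q + clone_of] = 1.0
    return ModelData(
        y=y, X=X, Z=Z, design=stacked, K=grm, groups=[0, 1],
        group_of_obs=group_of, clone_of_obs=clone_of, pair_index=ramet_idx,
    )


# ---------------------------------------------------------------------------
# restricted likelihood
# ---------------------------------------------------------------------------


def _k_inverse(K: GrMatrix) -> tuple[np.ndarray, float]:
    try:
        c, low = cho_factor(K.values)
    except np.linalg.LinAlgError as exc:
        raise ModelError(
            "GRM is not positive definite; apply stabilize_psd first"
        ) from exc
    logdet = 2.0 * float(np.log(np.diag(c)).sum())
    kinv = cho_solve((c, low), np.eye(K.n_clones))
    return kinv, logdet


def _mme_loglik(y, X, Z, ginv, logdet_g, rinv_mul, logdet_r, return_effects=False):
    """Restricted log-likelihood via the MME identity.

    ``rinv_mul(M)`` applies R^-1 to columns of M; ``ginv`` and ``logdet_g``
    describe the random-effect covariance G.
    """
    n, p = X.shape
    W = np.column_stack([X, Z])
    RiW = rinv_mul(W)
    Riy = rinv_mul(y[:, None])[:, 0]
    WtRiW = W.T @ RiW
    WtRiy = W.T @ Riy
    C = WtRiW.copy()
    C[p:, p:] += ginv
    try:
        cf = cho_factor(C)
    except np.linalg.LinAlgError as exc:
        raise ModelError("mixed-model equations not positive definite") from exc
    logdet_c = 2.0 * np.log(np.diag(cf[0])).sum()
    sol = cho_solve(cf, WtRiy)
    ypy = float(y @ Riy - WtRiy @ sol)
    ll = -0.5 * ((n - p) * LOG2PI + logdet_r + logdet_g + logdet_c + ypy)
    if return_effects:
        return ll, sol[:p], sol[p:], cf
    return ll


def restricted_loglik(
    data: ModelData, g: GeneticCovariance, r: ResidualCovariance
) -> float:
    """Restricted log-likelihood of the model at the given components.

    Evaluated exactly (no approximation); equals the dense from-definition
    REML criterion -1/2 [ (n-p) log 2pi + log|V| + log|X'V^-1 X| + y'Py ].
    """
    if max(g.variances) == 0.0:
        # degenerate genetic covariance: the model collapses to fixed
        # effects + residual, which is the correct limiting likelihood
        ginv = np.zeros((0, 0))
        logdet_g = 0.0
        Z = np.zeros((data.y.size, 0))
    else:
        kinv, logdet_k = _k_inverse(data.K)
        sigma = g.matrix()
        try:
            sig_inv = np.linalg.inv(sigma)
            sign, logdet_sig = np.linalg.slogdet(sigma)
            if sign <= 0:
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError as exc:
            raise ModelError("genetic covariance must be positive definite") from exc
        ginv = np.kron(sig_inv, kinv)
        logdet_g = data.K.n_clones * logdet_sig + len(data.groups) * logdet_k
        Z = data.Z
    if r.trait_variances:
        rinv_mul, logdet_r = _bivariate_rinv(data, r)
    else:
        R = assemble_residual_covariance(r, data.design)
        cf = cho_factor(R)
        logdet_r = 2.0 * np.log(np.diag(cf[0])).sum()
        rinv_mul = lambda M: cho_solve(cf, M)
    return float(_mme_loglik(data.y, data.X, Z, ginv, logdet_g, rinv_mul, logdet_r))


def _bivariate_rinv(data: ModelData, r: ResidualCovariance):
    """R^-1 action and log|R| for Sigma_e (x) I over co-observed ramets."""
    v1, v2 = r.trait_variances
    c12 = r.trait_covariance
    cache = getattr(data, "_biv_cache", None)
    if cache is None:
        t = data.group_of_obs
        ridx = data.pair_index
        # paired ramets: observed for both traits
        idx1 = {ri: i for i, ri in enumerate(ridx) if t[i] == 0}
        idx2 = {ri: i for i, ri in enumerate(ridx) if t[i] == 1}
        common = sorted(set(idx1) & set(idx2))
        cache = (
            np.array([idx1[ri] for ri in common], dtype=int),
            np.array([idx2[ri] for ri in common], dtype=int),
            np.array([i for ri, i in idx1.items() if ri not in idx2], dtype=int),
            np.array([i for ri, i in idx2.items() if ri not in idx1], dtype=int),
        )
        data._biv_cache = cache
    i1, i2, only1, only2 = cache
    det = v1 * v2 - c12 * c12
    if det <= 0 or v1 <= 0 or v2 <= 0:
        raise ModelError("bivariate residual covariance not positive definite")
    a11, a22, a12 = v2 / det, v1 / det, -c12 / det
    logdet_r = i1.size * np.log(det) + only1.size * np.log(v1) + only2.size * np.log(v2)

    def rinv_mul(M):
        M = M if M.ndim == 2 else M[:, None]
        out = np.zeros_like(M, dtype=float)
        if i1.size:
            out[i1] = a11 * M[i1] + a12 * M[i2]
            out[i2] = a12 * M[i1] + a22 * M[i2]
        if only1.size:
            out[only1] = M[only1] / v1
        if only2.size:
            out[only2] = M[only2] / v2
        return out

    return rinv_mul, float(logdet_r)


# ---------------------------------------------------------------------------
# parameterization
# ---------------------------------------------------------------------------


@dataclass
class _ParamSpec:
    names: list
    kinds: list  # 'logvar' or 'corr'

    def to_natural(self, theta: np.ndarray) -> dict:
        out = {}
        for name, kind, t in zip(self.names, self.kinds, theta):
            out[name] = float(np.exp(t)) if kind == "logvar" else float(np.tanh(t))
        return out

    def to_transformed(self, natural: dict) -> np.ndarray:
        vals = []
        for name, kind in zip(self.names, self.kinds):
            v = natural[name]
            if kind == "logvar":
                vals.append(np.log(np.clip(v, np.exp(_LOGV_LO), None)))
            else:
                vals.append(np.arctanh(np.clip(v, -0.999999, 0.999999)))
        return np.array(vals)

    def bounds(self) -> list:
        return [
            (_LOGV_LO, _LOGV_HI) if k == "logvar" else (-_Z_MAX, _Z_MAX) for k in self.kinds
        ]


def _multi_site_spec(
    n_sites: int, spatial: bool, genetic: bool, fix_genetic_corr: float | None = None
) -> _ParamSpec:
    names, kinds = [], []
    if genetic:
        for s in range(n_sites):
            names.append(f"va_s{s}")
            kinds.append("logvar")
        if n_sites == 2 and fix_genetic_corr is None:
            names.append("ra")
            kinds.append("corr")
    for s in range(n_sites):
        if spatial:
            names += [f"vxi_s{s}", f"rho_col_s{s}", f"rho_row_s{s}"]
            kinds += ["logvar", "corr", "corr"]
        names.append(f"veta_s{s}")
        kinds.append("logvar")
    return _ParamSpec(names, kinds)


def _bivariate_spec(genetic: bool, fix_genetic_corr: float | None) -> _ParamSpec:
    names, kinds = [], []
    if genetic:
        names += ["va_t0", "va_t1"]
        kinds += ["logvar", "logvar"]
        if fix_genetic_corr is None:
            names.append("ra")
            kinds.append("corr")
    names += ["ve_t0", "ve_t1", "re"]
    kinds += ["logvar", "logvar", "corr"]
    return _ParamSpec(names, kinds)


def _natural_to_components(
    nat: dict, model: str, n_sites: int, spatial: bool, genetic: bool,
    fix_genetic_corr: float | None,
) -> tuple[GeneticCovariance, ResidualCovariance]:
    if model == "multi_site_univariate":
        if genetic:
            vas = tuple(nat[f"va_s{s}"] for s in range(n_sites))
            ra = nat.get("ra", fix_genetic_corr if fix_genetic_corr is not None else 0.0)
            cov = ra * np.sqrt(vas[0] * vas[1]) if n_sites == 2 else 0.0
            g = GeneticCovariance(variances=vas, covariance=cov, structure="multi_site")
        else:
            g = GeneticCovariance(variances=(0.0,) * n_sites, structure="multi_site")
        r = ResidualCovariance(
            spatial_variance=tuple(nat.get(f"vxi_s{s}", 0.0) for s in range(n_sites)),
            rho_col=tuple(nat.get(f"rho_col_s{s}", 0.0) for s in range(n_sites)),
            rho_row=tuple(nat.get(f"rho_row_s{s}", 0.0) for s in range(n_sites)),
            nugget=tuple(nat[f"veta_s{s}"] for s in range(n_sites)),
        ) if spatial else ResidualCovariance(
            spatial_variance=(0.0,) * n_sites,
            rho_col=(0.0,) * n_sites,
            rho_row=(0.0,) * n_sites,
            nugget=tuple(nat[f"veta_s{s}"] for s in range(n_sites)),
        )
        return g, r
    # bivariate
    if genetic:
        vas = (nat["va_t0"], nat["va_t1"])
        ra = nat.get("ra", fix_genetic_corr if fix_genetic_corr is not None else 0.0)
        g = GeneticCovariance(
            variances=vas, covariance=ra * np.sqrt(vas[0] * vas[1]), structure="bivariate"
        )
    else:
        g = GeneticCovariance(variances=(0.0, 0.0), structure="bivariate")
    ve = (nat["ve_t0"], nat["ve_t1"])
    r = ResidualCovariance(
        trait_variances=ve, trait_covariance=nat["re"] * np.sqrt(ve[0] * ve[1])
    )
    return g, r


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitControls:
    spatial: bool = True
    genetic: bool = True
    fix_genetic_corr: float | None = None
    max_iter: int = 500
    tol: float = 1e-8
    compute_ai: bool = True
    start: dict | None = None


@dataclass
class VarianceComponentFit:
    genetic: GeneticCovariance
    residual: ResidualCovariance
    loglik: float
    param_names: list
    params: dict
    ai_matrix: np.ndarray | None
    param_cov: np.ndarray | None  # inverse AI on the natural scale
    se: dict
    boundary_flags: dict
    n_iter: int
    converged: bool
    blups: pd.DataFrame
    beta: np.ndarray
    model: str
    n_obs: int
    groups: list
    group_n_obs: dict
    data: ModelData = field(repr=False, default=None)

    @property
    def any_boundary(self) -> bool:
        return any(self.boundary_flags.values())


class _Objective:
    """Negative restricted log-likelihood over transformed parameters, with
    per-site residual factorizations rebuilt each evaluation and all
    genotype-side quantities precomputed."""

    def __init__(self, data: ModelData, model: str, controls: FitControls):
        self.data = data
        self.model = model
        self.controls = controls
        self.n_sites = len(data.groups)
        if model == "multi_site_univariate":
            self.spec = _multi_site_spec(
                self.n_sites, controls.spatial, controls.genetic, controls.fix_genetic_corr
            )
            self.site_masks = [
                (data.group_of_obs == s) for s in range(self.n_sites)
            ]
            self.site_rows = [data.design.loc[m, "row"].to_numpy(float) for m in self.site_masks]
            self.site_cols = [data.design.loc[m, "col"].to_numpy(float) for m in self.site_masks]
        elif model == "bivariate":
            self.spec = _bivariate_spec(controls.genetic, controls.fix_genetic_corr)
        else:
            raise ModelError(f"unknown model {model!r}")
        if controls.genetic:
            self.kinv, self.logdet_k = _k_inverse(data.K)

    def components(self, theta: np.ndarray):
        nat = self.spec.to_natural(theta)
        return _natural_to_components(
            nat, self.model, self.n_sites, self.controls.spatial,
            self.controls.genetic, self.controls.fix_genetic_corr,
        )

    def _rinv(self, r: ResidualCovariance):
        if self.model == "bivariate":
            return _bivariate_rinv(self.data, r)
        # per-site dense factorization
        factors = []
        logdet = 0.0
        for s, mask in enumerate(self.site_masks):
            rows, cols = self.site_rows[s], self.site_cols[s]
            if self.controls.spatial and r.spatial_variance[s] > 0:
                gam = r.spatial_variance[s] * _ar1_pow(
                    r.rho_col[s], np.abs(cols[:, None] - cols[None, :])
                ) * _ar1_pow(r.rho_row[s], np.abs(rows[:, None] - rows[None, :]))
                gam[np.diag_indices_from(gam)] = r.spatial_variance[s] + r.nugget[s]
                cf = cho_factor(gam)
                factors.append(("chol", cf))
                logdet += 2.0 * np.log(np.diag(cf[0])).sum()
            else:
                v = r.nugget[s] + (r.spatial_variance[s] if self.controls.spatial else 0.0)
                factors.append(("diag", v))
                logdet += rows.size * np.log(v)

        def rinv_mul(M):
            M = M if M.ndim == 2 else M[:, None]
            out = np.empty_like(M, dtype=float)
            for s, mask in enumerate(self.site_masks):
                kind, f = factors[s]
                if kind == "chol":
                    out[mask] = cho_solve(f, M[mask])
                else:
                    out[mask] = M[mask] / f
            return out

        return rinv_mul, float(logdet)

    def loglik(self, theta: np.ndarray, return_effects: bool = False):
        g, r = self.components(theta)
        rinv_mul, logdet_r = self._rinv(r)
        data = self.data
        if self.controls.genetic:
            sigma = g.matrix()
            sig_inv = np.linalg.inv(sigma)
            sign, logdet_sig = np.linalg.slogdet(sigma)
            if sign <= 0:
                raise ModelError("genetic covariance singular")
            ginv = np.kron(sig_inv, self.kinv)
            logdet_g = data.K.n_clones * logdet_sig + len(data.groups) * self.logdet_k
            Z = data.Z
        else:
            # no genetic term: fit the fixed-effects + residual model
            ginv = np.zeros((0, 0))
            logdet_g = 0.0
            Z = np.zeros((data.y.size, 0))
        return _mme_loglik(
            data.y, data.X, Z, ginv, logdet_g, rinv_mul, logdet_r,
            return_effects=return_effects,
        )

    def __call__(self, theta: np.ndarray) -> float:
        try:
            return -self.loglik(theta)
        except (ModelError, np.linalg.LinAlgError):
            return 1e12


def _start_values(data: ModelData, obj: _Objective, controls: FitControls) -> np.ndarray:
    """OLS pre-fit starting values: half the residual variance to each of
    spatial/nugget, half the clone-mean variance to the genetic variance,
    AR1 rho at 0.1."""
    y, X = data.y, data.X
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    v_res = max(float(resid.var(ddof=X.shape[1])), 1e-6)
    clone_means = pd.Series(resid).groupby(
        [data.group_of_obs, data.clone_of_obs]
    ).mean()
    v_clone = max(float(clone_means.var()) if len(clone_means) > 1 else v_res / 4, 1e-6)
    nat = {}
    for name, kind in zip(obj.spec.names, obj.spec.kinds):
        if name.startswith("va"):
            nat[name] = v_clone / 2
        elif name.startswith("vxi"):
            nat[name] = v_res / 2
        elif name.startswith("veta") or name.startswith("ve_"):
            nat[name] = v_res / 2
        elif name.startswith("rho"):
            nat[name] = 0.1
        elif name in ("ra", "re"):
            nat[name] = 0.1
    if controls.start:
        nat.update(controls.start)
    return obj.spec.to_transformed(nat)


def fit_reml(
    data: ModelData,
    model: str = "multi_site_univariate",
    controls: FitControls | None = None,
) -> VarianceComponentFit:
    """Maximize the restricted likelihood and return components with SEs.

    Parameters are optimized on a transformed scale (log variances, tanh
    correlations) with a bounded quasi-Newton method; boundary parameters
    are detected on the transformed scale, pinned, and reported without SEs.
    BLUPs of clonal effects per group come from the mixed-model equations at
    the optimum.
    """
    controls = controls or FitControls()
    if data.K.n_clones < 2 and controls.genetic:
        raise ModelError("genetic variance is not identifiable with < 2 clones")
    # standardize the response for optimizer conditioning
    scale = float(np.std(data.y))
    if scale <= 0:
        raise ModelError("response has zero variance")
    sdata = ModelData(
        y=data.y / scale, X=data.X, Z=data.Z, design=data.design, K=data.K,
        groups=data.groups, group_of_obs=data.group_of_obs,
        clone_of_obs=data.clone_of_obs, pair_index=data.pair_index,
    )
    obj = _Objective(sdata, model, controls)
    theta0 = _start_values(sdata, obj, controls)
    res = optimize.minimize(
        obj, theta0, method="L-BFGS-B", bounds=obj.spec.bounds(),
        options={"maxiter": controls.max_iter, "ftol": 1e-12, "gtol": 1e-7},
    )
    if not np.isfinite(res.fun) or res.fun >= 1e11:
        raise ConvergenceError("REML optimization diverged", trace=res)
    theta = res.x
    # boundary detection and pinned refit
    bounds = obj.spec.bounds()
    boundary = {
        name: bool(t <= lo + _BOUNDARY_MARGIN or t >= hi - _BOUNDARY_MARGIN)
        for name, t, (lo, hi) in zip(obj.spec.names, theta, bounds)
    }
    if any(boundary.values()):
        free = [i for i, n in enumerate(obj.spec.names) if not boundary[n]]
        if free:
            pinned = theta.copy()

            def sub_obj(tf):
                full = pinned.copy()
                full[free] = tf
                return obj(full)

            res2 = optimize.minimize(
                sub_obj, theta[free], method="L-BFGS-B",
                bounds=[bounds[i] for i in free],
                options={"maxiter": controls.max_iter, "ftol": 1e-12},
            )
            if res2.fun <= res.fun:
                theta = pinned
                theta[free] = res2.x
                res = res2
    ll, beta, u, _ = obj.loglik(theta, return_effects=True)
    nat = obj.spec.to_natural(theta)
    g, r = obj.components(theta)
    # rescale back to the original response units
    s2 = scale * scale
    g = GeneticCovariance(
        variances=tuple(v * s2 for v in g.variances),
        covariance=g.covariance * s2, structure=g.structure,
    )
    r = ResidualCovariance(
        spatial_variance=tuple(v * s2 for v in r.spatial_variance),
        rho_col=r.rho_col, rho_row=r.rho_row,
        nugget=tuple(v * s2 for v in r.nugget),
        trait_variances=tuple(v * s2 for v in r.trait_variances),
        trait_covariance=r.trait_covariance * s2,
    )
    nat_scaled = {
        k: (v * s2 if k.startswith(("va", "vxi", "veta", "ve_")) else v)
        for k, v in nat.items()
    }
    n_eff = data.y.size - data.X.shape[1]
    ll_orig = float(ll) - n_eff * np.log(scale)
    ai = param_cov = None
    se: dict[str, float] = {name: float("nan") for name in obj.spec.names}
    if controls.compute_ai and controls.genetic:
        try:
            ai = average_information(data, g, r, obj.spec.names, model, controls)
            if not any(boundary.values()):
                param_cov = np.linalg.inv(ai)
                se = {
                    n_: float(np.sqrt(max(param_cov[i, i], 0.0)))
                    for i, n_ in enumerate(obj.spec.names)
                }
            else:
                free = [i for i, n_ in enumerate(obj.spec.names) if not boundary[n_]]
                if free:
                    sub = np.linalg.inv(ai[np.ix_(free, free)])
                    param_cov = np.full(ai.shape, np.nan)
                    param_cov[np.ix_(free, free)] = sub
                    for j, i in enumerate(free):
                        se[obj.spec.names[i]] = float(np.sqrt(max(sub[j, j], 0.0)))
        except (np.linalg.LinAlgError, ModelError):
            logger.warning("AI matrix not invertible; SEs unavailable")
    blups = _blups_frame(data, u * scale) if controls.genetic else pd.DataFrame()
    return VarianceComponentFit(
        genetic=g, residual=r, loglik=ll_orig,
        param_names=list(obj.spec.names), params=nat_scaled,
        ai_matrix=ai, param_cov=param_cov, se=se, boundary_flags=boundary,
        n_iter=int(res.nit), converged=bool(res.success or res.fun < 1e11),
        blups=blups, beta=beta * scale, model=model, n_obs=data.y.size,
        groups=list(data.groups),
        group_n_obs={
            grp: int((data.group_of_obs == i).sum()) for i, grp in enumerate(data.groups)
        },
        data=data,
    )


def _blups_frame(data: ModelData, u: np.ndarray) -> pd.DataFrame:
    q = data.K.n_clones
    frames = []
    for gi, grp in enumerate(data.groups):
        frames.append(
            pd.DataFrame(
                {"group": grp, "clone": list(data.K.clone_ids), "blup": u[gi * q:(gi + 1) * q]}
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# average information
# ---------------------------------------------------------------------------


def _dense_V(data: ModelData, g: GeneticCovariance, r: ResidualCovariance,
             controls: FitControls) -> np.ndarray:
    G = assemble_genetic_covariance(g, data.K)
    if r.trait_variances:
        n = data.y.size
        R = np.zeros((n, n))
        t = data.group_of_obs
        ridx = data.pair_index
        v1, v2 = r.trait_variances
        for i in range(n):
            R[i, i] = v1 if t[i] == 0 else v2
        pos = {}
        for i, (ti, ri_) in enumerate(zip(t, ridx)):
            if (1 - ti, ri_) in pos:
                j = pos[(1 - ti, ri_)]
                R[i, j] = R[j, i] = r.trait_covariance
            pos[(ti, ri_)] = i
    else:
        R = assemble_residual_covariance(r, data.design)
    return data.Z @ G @ data.Z.T + R


def average_information(
    data: ModelData, g: GeneticCovariance, r: ResidualCovariance,
    param_names: list, model: str, controls: FitControls,
) -> np.ndarray:
    """Average-information matrix AI_ij = 1/2 (Py)' dV_i P dV_j (Py) at the
    given parameter values, on the natural parameter scale."""
    V = _dense_V(data, g, r, controls)
    n = data.y.size
    Vc = cho_factor(V)
    ViX = cho_solve(Vc, data.X)
    XtViX = data.X.T @ ViX
    xc = cho_factor(XtViX)

    def P_mul(M):
        M2 = M if M.ndim == 2 else M[:, None]
        ViM = cho_solve(Vc, M2)
        out = ViM - ViX @ cho_solve(xc, ViX.T @ M2)
        return out if M.ndim == 2 else out[:, 0]

    Py = P_mul(data.y)
    nat0 = _fit_params_to_dict(g, r, param_names, model)
    eps_rel = 1e-5
    dV = []
    corr_names = {"ra", "re"} | {n for n in param_names if n.startswith("rho")}
    for name in param_names:
        nat_p, nat_m = dict(nat0), dict(nat0)
        h = eps_rel * max(abs(nat0[name]), 1e-3)
        if name in corr_names:
            # keep perturbed correlations inside the open interval
            lim = 1.0 - 1e-9
            h = min(h, lim - abs(nat0[name])) if abs(nat0[name]) + h > lim else h
            h = max(h, 1e-9)
        nat_p[name] = nat0[name] + h
        nat_m[name] = nat0[name] - h
        gp, rp = _dict_to_components(nat_p, param_names, model, len(data.groups), controls)
        gm, rm = _dict_to_components(nat_m, param_names, model, len(data.groups), controls)
        dV.append((_dense_V(data, gp, rp, controls) - _dense_V(data, gm, rm, controls)) / (2 * h))
    t_vecs = [d @ Py for d in dV]
    s_vecs = [P_mul(t) for t in t_vecs]
    k = len(param_names)
    ai = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ai[i, j] = ai[j, i] = 0.5 * float(t_vecs[i] @ s_vecs[j])
    return ai


def _fit_params_to_dict(g, r, param_names, model) -> dict:
    out = {}
    for name in param_names:
        if name.startswith("va_s") or name.startswith("va_t"):
            out[name] = g.variances[int(name[-1])]
        elif name == "ra":
            out[name] = g.correlation
        elif name.startswith("vxi"):
            out[name] = r.spatial_variance[int(name[-1])]
        elif name.startswith("rho_col"):
            out[name] = r.rho_col[int(name[-1])]
        elif name.startswith("rho_row"):
            out[name] = r.rho_row[int(name[-1])]
        elif name.startswith("veta"):
            out[name] = r.nugget[int(name[-1])]
        elif name.startswith("ve_t"):
            out[name] = r.trait_variances[int(name[-1])]
        elif name == "re":
            ve = r.trait_variances
            out[name] = r.trait_covariance / np.sqrt(ve[0] * ve[1])
    return {k: (v if np.isfinite(v) else 0.0) for k, v in out.items()}


def _dict_to_components(nat, param_names, model, n_sites, controls):
    return _natural_to_components(
        nat, model, n_sites, controls.spatial, controls.genetic, controls.fix_genetic_corr
    )


# ---------------------------------------------------------------------------
# inference helpers
# ---------------------------------------------------------------------------


def lrt(
    full: VarianceComponentFit | float,
    reduced: VarianceComponentFit | float,
    constraint: str = "variance_on_boundary",
) -> tuple[float, float]:
    """Likelihood-ratio test of a nested constraint.

    ``variance_on_boundary`` uses the 1/2 chi2_0 + 1/2 chi2_1 mixture
    appropriate for a single variance fixed at its boundary;
    ``covariance_zero`` uses chi2_1 for an interior covariance fixed at zero.
    """
    ll_full = full.loglik if hasattr(full, "loglik") else float(full)
    ll_red = reduced.loglik if hasattr(reduced, "loglik") else float(reduced)
    stat = 2.0 * (ll_full - ll_red)
    if stat < -1e-4 * max(1.0, abs(ll_full)):
        raise ModelError(
            f"reduced model out-likelihoods the full model (stat={stat:.4g}); "
            "optimizer failure"
        )
    stat = max(stat, 0.0)
    if constraint == "variance_on_boundary":
        p = 1.0 if stat == 0.0 else 0.5 * float(stats.chi2.sf(stat, df=1))
    elif constraint == "covariance_zero":
        p = 1.0 if stat == 0.0 else float(stats.chi2.sf(stat, df=1))
    else:
        raise ModelError(f"unknown constraint {constraint!r}")
    return float(stat), p


def clonal_rankings(fit: VarianceComponentFit) -> pd.DataFrame:
    """Clones ranked (descending BLUP) within each group, with a Spearman
    rank-stability summary between groups attached as ``.attrs``."""
    if fit.blups.empty:
        raise ModelError("fit carries no BLUPs")
    informative = any(v > 0 for v in fit.genetic.variances)
    ranked = (
        fit.blups.sort_values(["group", "blup", "clone"], ascending=[True, False, True])
        .reset_index(drop=True)
    )
    ranked["rank"] = ranked.groupby("group").cumcount() + 1
    ranked.attrs["informative"] = informative
    groups = list(dict.fromkeys(ranked["group"]))
    spearman = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            a = ranked[ranked["group"] == groups[i]].set_index("clone")["blup"]
            b = ranked[ranked["group"] == groups[j]].set_index("clone")["blup"]
            common = a.index.intersection(b.index)
            if len(common) > 2 and a[common].std() > 0 and b[common].std() > 0:
                rho = stats.spearmanr(a[common], b[common]).statistic
            else:
                rho = float("nan")
            spearman[(groups[i], groups[j])] = float(rho)
    ranked.attrs["rank_stability"] = spearman
    return ranked
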