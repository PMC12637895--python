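"""Phylogenetic linear mixed models for activity metrics.

Each activity metric (onset, median, offset, duration) is modelled as

    y ~ N(X beta, V),
    V = s2_sp * Z_sp C Z_sp' + s2_cell * Z_cell Z_cell' + s2_e * I,

with C the Brownian species covariance from the phylogeny, optional random
temperature slopes per grouping, and fixed effects for temperature (linear
or natural cubic spline), daylength, wingspan, an optional temperature x
wingspan interaction and an optional observation-count term. Variance
components are estimated by REML (bounded quasi-Newton on log-variances),
fixed effects by GLS at the optimum with Wald intervals. Model comparison
uses exact row-level leave-one-out predictive log-density conditional on
the estimated variance components, mirrored on an SE-overlap decision
rule; marginal AIC (ML fit) is available as a cheaper criterion.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats

Z95 = float(stats.norm.ppf(0.975))


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of one candidate model."""

    response: str = "duration"
    temperature: str = "linear"  # "linear" | "spline"
    spline_df: int = 4
    interaction: bool = False  # temperature x wingspan
    include_n_obs: bool = False
    extra_columns: tuple[str, ...] = ()  # e.g. a noise predictor in simulations

    @property
    def name(self) -> str:
        parts = [self.response, self.temperature]
        if self.interaction:
            parts.append("txw")
        if self.include_n_obs:
            parts.append("nobs")
        parts.extend(self.extra_columns)
        return "-".join(parts)


@dataclasses.dataclass(frozen=True)
class RandomSpec:
    """Which random terms enter V; defaults are intercepts for both groupings."""

    species_intercept: bool = True
    cell_intercept: bool = True
    species_temp_slope: bool = False
    cell_temp_slope: bool = False


@dataclasses.dataclass
class ModelFit:
    spec_name: str
    coef: pd.DataFrame  # term, estimate, se, ci_lower, ci_upper
    varcomp: dict[str, float]
    loglik: float
    method: str  # "reml" | "ml"
    converged: bool
    n: int
    resid_marginal: np.ndarray
    resid_conditional: np.ndarray
    species: np.ndarray
    cells: np.ndarray
    X: np.ndarray
    y: np.ndarray
    V: np.ndarray
    objective_history: list[float]

    @property
    def beta(self) -> np.ndarray:
        return self.coef["estimate"].to_numpy()


def design_matrix(
    frame: pd.DataFrame, spec: ModelSpec, scaled: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects matrix for a model frame (intercept first).

    The spline encoding is a natural cubic basis on (scaled) temperature
    with interior knots at quantiles; its columns replace the single linear
    temperature column and are named temp_spline_1.. in basis order, so
    "the first spline component" is well defined for reporting.
    """
    suffix = "_z" if scaled else ""
    cols: list[np.ndarray] = [np.ones(len(frame))]
    names = ["intercept"]
    temp = frame["temp_c" + suffix].to_numpy(dtype=float)
    if spec.temperature == "linear":
        cols.append(temp)
        names.append("temp")
    elif spec.temperature == "spline":
        if spec.spline_df < 3:
            raise ValueError("spline_df must be >= 3")
        # the cr basis spans the constant, so build one extra function,
        # center the columns (identifiability against the intercept) and
        # drop the last; leaves spline_df columns jointly full rank with
        # the model intercept, ordered left-to-right along temperature
        raw = np.asarray(
            patsy.dmatrix(
                f"cr(x, df={spec.spline_df + 1}) - 1", {"x": temp}, return_type="matrix"
            )
        )
        basis = (raw - raw.mean(axis=0))[:, : spec.spline_df]
        for j in range(basis.shape[1]):
            cols.append(basis[:, j])
            names.append(f"temp_spline_{j + 1}")
    else:
        raise ValueError(f"unknown temperature encoding {spec.temperature!r}")
    cols.append(frame["daylength_h" + suffix].to_numpy(dtype=float))
    names.append("daylength")
    wing = frame["wingspan" + suffix].to_numpy(dtype=float)
    cols.append(wing)
    names.append("wingspan")
    if spec.interaction:
        cols.append(temp * wing)
        names.append("temp:wingspan")
    if spec.include_n_obs:
        cols.append(frame["n_obs" + suffix].to_numpy(dtype=float))
        names.append("n_obs")
    for extra in spec.extra_columns:
        cols.append(frame[extra].to_numpy(dtype=float))
        names.append(extra)
    X = np.column_stack(cols)
    _check_full_rank(X, names)
    return X, names


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        dependent = [names[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"design matrix is rank deficient; dependent columns: {dependent}")


def _random_parts(
    X_temp: np.ndarray | None,
    C_species: np.ndarray | None,
    species: np.ndarray,
    cells: np.ndarray,
    random_spec: RandomSpec,
) -> tuple[list[str], list[np.ndarray], list[tuple[np.ndarray, np.ndarray]]]:
    """Covariance contributions G_k (n x n) with their BLUP factors (Z, Gu)."""
    names: list[str] = []
    Gs: list[np.ndarray] = []
    blup: list[tuple[np.ndarray, np.ndarray]] = []

    def indicator(codes: np.ndarray, k: int) -> np.ndarray:
        Z = np.zeros((len(codes), k))
        Z[np.arange(len(codes)), codes] = 1.0
        return Z

    sp_levels, sp_codes = np.unique(species, return_inverse=True)
    cell_levels, cell_codes = np.unique(cells, return_inverse=True)
    Z_sp = indicator(sp_codes, len(sp_levels))
    Z_cell = indicator(cell_codes, len(cell_levels))
    C = np.eye(len(sp_levels)) if C_species is None else np.asarray(C_species, float)
    if C.shape != (len(sp_levels), len(sp_levels)):
        raise ValueError("C_species shape does not match the number of species levels")
    eigmin = float(np.linalg.eigvalsh(C).min())
    if eigmin < -1e-8:
        raise ValueError(f"C_species is not positive semidefinite (min eig {eigmin:.3g})")

    if random_spec.species_intercept:
        names.append("species")
        Gs.append(Z_sp @ C @ Z_sp.T)
        blup.append((Z_sp, C))
    if random_spec.cell_intercept:
        names.append("cell")
        Gs.append(Z_cell @ Z_cell.T)
        blup.append((Z_cell, np.eye(len(cell_levels))))
    if random_spec.species_temp_slope or random_spec.cell_temp_slope:
        if X_temp is None:
            raise ValueError("temperature column required for random slopes")
        t = X_temp[:, None]
        if random_spec.species_temp_slope:
            names.append("species_slope")
            Gs.append((t @ t.T) * (Z_sp @ C @ Z_sp.T))
            blup.append((Z_sp * t, C))
        if random_spec.cell_temp_slope:
            names.append("cell_slope")
            Gs.append((t @ t.T) * (Z_cell @ Z_cell.T))
            blup.append((Z_cell * t, np.eye(len(cell_levels))))
    return names, Gs, blup


def fit_phylo_lmm(
    y: np.ndarray,
    X: np.ndarray,
    C_species: np.ndarray | None,
    species: Sequence,
    cells: Sequence,
    random_spec: RandomSpec = RandomSpec(),
    names: Sequence[str] | None = None,
    temp_column: np.ndarray | None = None,
    method: str = "reml",
    spec_name: str = "model",
) -> ModelFit:
    """Fit the marginal phylogenetic mixed model by REML (or ML).

    With no random terms requested the model collapses to V = s2_e I and
    the GLS solution is exactly OLS. Non-convergence of the optimizer is
    reported on the fit, never silenced.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    species = np.asarray(species)
    cells = np.asarray(cells)
    n, p = X.shape
    if method not in ("reml", "ml"):
        raise ValueError(f"unknown method {method!r}")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    _check_full_rank(X, names)

    vc_names, Gs, blup = _random_parts(temp_column, C_species, species, cells, random_spec)
    k = len(Gs)
    I = np.eye(n)
    history: list[float] = []

    def build_V(theta: np.ndarray) -> np.ndarray:
        V = np.exp(theta[k]) * I
        for j in range(k):
            V = V + np.exp(theta[j]) * Gs[j]
        return V

    def neg2ll(theta: np.ndarray) -> float:
        V = build_V(theta)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        Vi_X = np.linalg.solve(V, X)
        Vi_y = np.linalg.solve(V, y)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        quad = float(r @ np.linalg.solve(V, r))
        out = logdet + quad
        if method == "reml":
            sign, logdet_x = np.linalg.slogdet(XtViX)
            if sign <= 0:
                return 1e12
            out += logdet_x
        return out

    var_y = max(float(np.var(y)), 1e-8)
    theta0 = np.log(np.full(k + 1, var_y / (k + 1)))
    if k == 0:
        theta_hat = np.array([np.log(var_y)])
        res_success = True
        # 1-D problem has a closed form up to the REML df factor; polish it
        opt = optimize.minimize_scalar(
            lambda t: neg2ll(np.array([t])),
            bounds=(np.log(var_y) - 20, np.log(var_y) + 10),
            method="bounded",
        )
        theta_hat = np.array([float(opt.x)])
        history.append(float(opt.fun))
    else:
        res = optimize.minimize(
            neg2ll,
            theta0,
            method="L-BFGS-B",
            bounds=[(-25.0, 12.0)] * (k + 1),
            callback=lambda xk: history.append(neg2ll(xk)),
            options={"maxiter": 200, "ftol": 1e-11},
        )
        theta_hat = res.x
        res_success = bool(res.success)

    V = build_V(theta_hat)
    Vi_X = np.linalg.solve(V, X)
    XtViX = X.T @ Vi_X
    beta = np.linalg.solve(XtViX, Vi_X.T @ y)
    cov_beta = np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov_beta))
    resid = y - X @ beta

    # BLUPs for conditional residuals: u_k = s2_k G_u Z' V^-1 r
    Vi_r = np.linalg.solve(V, resid)
    cond = resid.copy()
    for j, (Z, Gu) in enumerate(blup):
        u = np.exp(theta_hat[j]) * (Gu @ (Z.T @ Vi_r))
        cond = cond - Z @ u

    varcomp = {nm: float(np.exp(theta_hat[j])) for j, nm in enumerate(vc_names)}
    varcomp["residual"] = float(np.exp(theta_hat[k]))
    const = (n - p) if method == "reml" else n
    loglik = -0.5 * (neg2ll(theta_hat) + const * np.log(2 * np.pi))

    coef = pd.DataFrame(
        {
            "term": list(names),
            "estimate": beta,
            "se": se,
            "ci_lower": beta - Z95 * se,
            "ci_upper": beta + Z95 * se,
        }
    )
    return ModelFit(
        spec_name=spec_name,
        coef=coef,
        varcomp=varcomp,
        loglik=float(loglik),
        method=method,
        converged=res_success,
        n=n,
        resid_marginal=resid,
        resid_conditional=cond,
        species=species,
        cells=cells,
        X=X,
        y=y,
        V=V,
        objective_history=history,
    )


def fit_response(
    frame: pd.DataFrame,
    spec: ModelSpec,
    C_species: np.ndarray | None,
    species_order: Sequence[str] | None = None,
    random_spec: RandomSpec = RandomSpec(),
    method: str = "reml",
) -> ModelFit:
    """Build the design for a spec and fit it on a scaled model frame.

    ``species_order`` gives the taxon order of C_species's rows; it must
    cover every species in the frame.
    """
    X, names = design_matrix(frame, spec)
    species = frame["species"].to_numpy()
    cells = list(zip(frame["cell_row"], frame["cell_col"]))
    cells = np.array([f"{r}_{c}" for r, c in cells])
    C = C_species
    if C is not None and species_order is not None:
        levels = np.unique(species)
        idx = [list(species_order).index(s) for s in levels]
        C = np.asarray(C_species)[np.ix_(idx, idx)]
    temp = frame["temp_c_z"].to_numpy(dtype=float)
    return fit_phylo_lmm(
        frame[spec.response].to_numpy(dtype=float),
        X,
        C,
        species,
        cells,
        random_spec=random_spec,
        names=names,
        temp_column=temp,
        method=method,
        spec_name=spec.name,
    )


def loo_pointwise(fit: ModelFit) -> np.ndarray:
    """Exact leave-one-out predictive log-densities, one per row.

    Variance components are held at their full-data REML estimates; for
    each left-out row the fixed effects are refit on the remaining rows
    and the predictive distribution of the held-out response conditions on
    the remaining responses through V (so random-effect information is
    carried over, as it would be in a predictive density).
    """
    X, y, V = fit.X, fit.y, fit.V
    n, p = X.shape
    Q = np.linalg.inv(V)
    M = Q @ X  # rows m_i
    g = Q @ y
    S = X.T @ M
    t_full = X.T @ g
    out = np.empty(n)
    for i in range(n):
        x_i = X[i]
        m_i = M[i]
        qii = Q[i, i]
        u_i = m_i - qii * x_i  # X_{-i}' q_i
        g_i = g[i]
        w_i = g_i - qii * y[i]  # q_i' y_{-i}
        A = S - np.outer(x_i, m_i) - np.outer(m_i, x_i) + qii * np.outer(x_i, x_i)
        A -= np.outer(u_i, u_i) / qii
        b = t_full - x_i * g_i - m_i * y[i] + qii * x_i * y[i]
        b -= u_i * w_i / qii
        beta = np.linalg.solve(A, b)
        # conditional of row i given the rest, via the precision matrix
        resid_q = g_i - m_i @ beta  # (Q (y - X beta))_i
        mean_i = x_i @ beta - (resid_q - qii * (y[i] - x_i @ beta)) / qii
        var_i = 1.0 / qii
        out[i] = stats.norm.logpdf(y[i], loc=mean_i, scale=np.sqrt(var_i))
    return out


def compare_models(
    frame: pd.DataFrame,
    specs: Sequence[ModelSpec],
    C_species: np.ndarray | None,
    species_order: Sequence[str] | None = None,
    random_spec: RandomSpec = RandomSpec(),
    criterion: str = "loo",
) -> pd.DataFrame:
    """Rank candidate specs against the first (baseline) spec.

    A challenger "wins" only when its criterion is better than the
    baseline's and the difference exceeds its standard error (pointwise-
    difference SE for LOO; AIC has no SE, so any improvement counts).
    Returns one row per spec with elpd/aic, diff vs baseline, se_diff and
    the win flag.
    """
    if len(specs) < 2:
        raise ValueError("need at least two candidate specs")
    if criterion not in ("loo", "aic"):
        raise ValueError(f"unknown criterion {criterion!r}")
    rows = []
    base_pointwise: np.ndarray | None = None
    base_value: float | None = None
    for j, spec in enumerate(specs):
        fit = fit_response(
            frame, spec, C_species, species_order, random_spec,
            method="reml" if criterion == "loo" else "ml",
        )
        if criterion == "loo":
            pw = loo_pointwise(fit)
            value = float(pw.sum())
        else:
            n_par = fit.X.shape[1] + len(fit.varcomp)
            value = float(-2.0 * fit.loglik + 2.0 * n_par)  # lower is better
            pw = None
        if j == 0:
            base_pointwise, base_value = pw, value
            diff = 0.0
            se_diff = 0.0
            wins = False
        else:
            if criterion == "loo":
                assert base_pointwise is not None
                d = pw - base_pointwise
                diff = float(d.sum())
                se_diff = float(d.std(ddof=1) * np.sqrt(len(d)))
                wins = diff > 0 and diff > se_diff
            else:
                diff = value - base_value
                se_diff = float("nan")
                wins = diff < 0
        rows.append(
            {
                "spec": spec.name,
                "criterion": criterion,
                "value": value,
                "diff_vs_baseline": diff,
                "se_diff": se_diff,
                "wins": wins,
            }
        )
    return pd.DataFrame(rows)


def vif(X: np.ndarray, names: Sequence[str] | None = None) -> pd.DataFrame:
    """Variance inflation factors, VIF_j = 1/(1 - R2_j), intercept excluded.

    ``X`` holds the predictor columns only; each is regressed on the others
    plus an intercept. Exact collinearity is an error (infinite VIF).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two predictor columns")
    if names is None:
        names = [f"x{j}" for j in range(p)]
    out = []
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, _, rank, _ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        if ss_tot == 0:
            raise ValueError(f"column {names[j]!r} is constant")
        r2 = 1.0 - ss_res / ss_tot
        if r2 > 1.0 - 1e-12:
            raise ValueError(f"column {names[j]!r} is exactly collinear with the others")
        out.append({"term": names[j], "vif": 1.0 / (1.0 - r2)})
    return pd.DataFrame(out)


def species_residuals(fit: ModelFit) -> dict[str, float]:
    """Marginal residuals averaged per species (trait input for signal tests)."""
    frame = pd.DataFrame({"species": fit.species, "resid": fit.resid_marginal})
    return frame.groupby("species")["resid"].mean().to_dict()
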