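"""Nested binomial use-encounter habitat-association models.

Behavioural states decoded along the track are turned into two stacked
binary responses: (i) P(ARS | encounter) — was the seal in either ARS state
rather than transit when it encountered this habitat — and (ii)
P(focussed ARS | ARS). Each response is modelled on the logit scale as a
penalized additive model:

* treatment-coded categorical terms up to a three-way interaction of
  region x geomorphology x substrate;
* an optional cubic-spline smooth of potential energy anomaly (PEA), by
  default one smoother per region, penalized on curvature with an extra
  null-space (double) penalty so an uninformative smooth can shrink to zero
  ("select" behaviour);
* a per-individual Gaussian random intercept, fitted as ridge-penalized
  dummy coefficients.

Coefficients are estimated by penalized IRLS; smoothing parameters and the
random-intercept variance by generalized Fellner-Schall updates, which
ascend the Laplace-approximate restricted marginal likelihood. Predictions
propagate uncertainty by sampling coefficient vectors from the Gaussian
posterior approximation N(beta_hat, (X'WX + S)^-1); draws from the two
models multiply into scale-specific foraging probabilities
P(fARS) = P(ARS|enc) P(fARS|ARS) and P(bARS) = P(ARS|enc) (1 - P(fARS|ARS)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import interpolate, special

from .hmm import sample_state_sequences

__all__ = [
    "GAMMSpec",
    "SmoothSpec",
    "UseEncounterData",
    "FittedGAMM",
    "PredictionDraws",
    "build_response",
    "fit_gamm",
    "select_model",
    "posterior_predict",
    "region_prevalence",
    "state_uncertainty_sensitivity",
    "residual_autocorrelation",
]

ARS_STATES = ("fARS", "bARS")
MOVEMENT_STATES = ("fARS", "bARS", "Tr")
#: habitat levels rarer than this are suppressed from default prediction grids
MIN_LEVEL_OBS = 100


# --------------------------------------------------------------------------
# responses
# --------------------------------------------------------------------------


@dataclass
class UseEncounterData:
    """Movement-state intervals with the two nested binary responses."""

    data: pd.DataFrame            # covariates + individual
    response_ars: pd.Series       # 1 = fARS or bARS, 0 = transit
    response_fars: pd.Series      # on ARS rows only: 1 = fARS, 0 = bARS
    n_dropped_missing: int = 0

    @property
    def ars_rows(self) -> pd.Index:
        return self.response_fars.dropna().index


def build_response(decoded: pd.DataFrame, state_col: str = "state",
                   covariate_cols=("region", "geomorphology", "substrate", "pea"),
                   individual_col: str = "individual") -> UseEncounterData:
    """Code the nested binomial responses from decoded states.

    Non-diving and unknown intervals are excluded (surface activity is not
    contingent on behaviour-specific habitat); rows with missing covariates
    are dropped and counted. A 4-state decoding (merged ``ARS`` label) is
    rejected because the nested coding is undefined for it.
    """
    states = decoded[state_col]
    if (states == "ARS").any():
        raise ValueError("nested responses need a 5-state decoding (fARS/bARS), "
                         "got a merged 'ARS' label")
    d = decoded.loc[states.isin(MOVEMENT_STATES)].copy()
    cols = [c for c in covariate_cols if c in d.columns]
    complete = d[cols].notna().all(axis=1) if cols else pd.Series(True, index=d.index)
    n_dropped = int((~complete).sum())
    d = d.loc[complete]
    r1 = d[state_col].isin(ARS_STATES).astype(int)
    r2 = pd.Series(np.where(r1 == 1, (d[state_col] == "fARS").astype(float), np.nan),
                   index=d.index)
    if r2.notna().sum() == 0:
        warnings.warn("no ARS intervals: the focussed-vs-broad model cannot be fitted")
    keep = list(cols) + [individual_col]
    return UseEncounterData(d[keep], r1, r2, n_dropped)


# --------------------------------------------------------------------------
# model specification and design matrices
# --------------------------------------------------------------------------


@dataclass
class SmoothSpec:
    """Cubic-spline smooth of one continuous covariate.

    ``k`` is the basis dimension; ``by`` fits a separate smoother per level
    of a categorical column; ``shrinkage`` adds the null-space penalty so the
    whole term can be penalized to zero.
    """

    col: str = "pea"
    k: int = 6
    by: str | None = "region"
    shrinkage: bool = True

    def __post_init__(self):
        if self.k < 4:
            raise ValueError("cubic spline basis needs k >= 4")


@dataclass
class GAMMSpec:
    """Model formula: categorical terms, optional smooth, random intercept."""

    categorical_terms: tuple = (("region",), ("geomorphology",), ("substrate",),
                                ("region", "geomorphology"), ("region", "substrate"),
                                ("geomorphology", "substrate"),
                                ("region", "geomorphology", "substrate"))
    smooth: SmoothSpec | None = field(default_factory=SmoothSpec)
    random_intercept: str | None = "individual"
    k_grid: tuple = (4, 5, 6, 8, 10)

    def drop_term(self, term) -> "GAMMSpec":
        if term == "smooth":
            return replace(self, smooth=None)
        return replace(self, categorical_terms=tuple(
            t for t in self.categorical_terms if t != term))


def _bspline_knots(x, k):
    """Clamped cubic B-spline knot vector with quantile interior knots."""
    lo, hi = float(np.min(x)), float(np.max(x))
    span = max(hi - lo, 1e-8)
    lo -= 1e-3 * span
    hi += 1e-3 * span
    n_interior = k - 4
    if n_interior > 0:
        interior = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1])
        interior = np.clip(interior, lo + 1e-9, hi - 1e-9)
    else:
        interior = np.array([])
    return np.concatenate([[lo] * 4, np.sort(interior), [hi] * 4])


def _bspline_design(x, knots):
    x = np.clip(np.asarray(x, dtype=float), knots[0], knots[-1])
    return interpolate.BSpline.design_matrix(x, knots, 3).toarray()


def _second_deriv_gram(knots):
    """Exact integral of products of second derivatives of the basis.

    Second derivatives of cubic B-splines are piecewise linear, so Simpson's
    rule on each knot span integrates their products exactly.
    """
    k = len(knots) - 4
    S = np.zeros((k, k))
    spans = np.unique(knots)
    eye = np.eye(k)
    for a, b in zip(spans[:-1], spans[1:]):
        if b <= a:
            continue
        pts = np.array([a, 0.5 * (a + b), b])
        D = np.empty((3, k))
        for j in range(k):
            spl = interpolate.BSpline(knots, eye[j], 3)
            D[:, j] = spl.derivative(2)(pts)
        w = (b - a) / 6.0 * np.array([1.0, 4.0, 1.0])
        S += D.T @ (D * w[:, None])
    return S


class _SmoothBlock:
    """Reparameterised spline block with diagonal penalties.

    The curvature penalty is eigendecomposed so its range becomes a diagonal
    penalty; the constant direction of the null space is dropped (absorbed by
    the intercept / categorical terms) and the remaining null direction
    carries the optional shrinkage penalty.
    """

    def __init__(self, x, k):
        self.knots = _bspline_knots(x, k)
        S = _second_deriv_gram(self.knots)
        d, U = np.linalg.eigh(S)
        order = np.argsort(d)[::-1]
        d, U = d[order], U[:, order]
        tol = max(d.max(), 1.0) * 1e-9
        null = d < tol
        d = np.where(null, 0.0, d)
        # identify and drop the constant null direction
        grid = np.linspace(self.knots[0], self.knots[-1], 64)
        BU = _bspline_design(grid, self.knots) @ U
        null_idx = np.where(null)[0]
        const = null_idx[np.argmin(np.std(BU[:, null_idx], axis=0))]
        keep = np.array([i for i in range(len(d)) if i != const])
        self.U = U[:, keep]
        self.pen_range = d[keep]
        self.pen_null = np.where(d[keep] == 0.0, 1.0, 0.0)
        self.col_means = None

    def design(self, x):
        B = _bspline_design(x, self.knots) @ self.U
        if self.col_means is None:
            self.col_means = B.mean(axis=0)
        return B - self.col_means


class _Design:
    """Full design matrix with term blocks and diagonal penalties."""

    def __init__(self, spec: GAMMSpec, data: pd.DataFrame):
        self.spec = spec
        self.levels = {}
        cols = [np.ones((len(data), 1))]
        names = ["(intercept)"]
        self.term_cols = {"(intercept)": [0]}
        self.penalties = []   # (label, col_index_array, diag_values)
        start = 1
        all_cats = sorted({c for t in spec.categorical_terms for c in t})
        if spec.smooth is not None and spec.smooth.by:
            all_cats.append(spec.smooth.by)
        for c in all_cats:
            self.levels.setdefault(c, tuple(pd.unique(data[c].dropna())))
        for term in spec.categorical_terms:
            X = self._term_matrix(term, data)
            cols.append(X)
            idx = list(range(start, start + X.shape[1]))
            self.term_cols[term] = idx
            start += X.shape[1]
        self.smooth_blocks = {}
        if spec.smooth is not None:
            sm = spec.smooth
            x = pd.to_numeric(data[sm.col], errors="coerce").to_numpy()
            by_levels = self.levels[sm.by] if sm.by else (None,)
            for lev in by_levels:
                block = _SmoothBlock(x[~np.isnan(x)], sm.k)
                B = block.design(x)
                if lev is not None:
                    B = B * (data[sm.by] == lev).to_numpy()[:, None]
                cols.append(np.nan_to_num(B))
                idx = np.arange(start, start + B.shape[1])
                label = ("smooth", lev)
                self.smooth_blocks[label] = block
                self.term_cols.setdefault("smooth", []).extend(idx.tolist())
                self.penalties.append((f"sp_{lev}", idx, block.pen_range.copy()))
                if sm.shrinkage:
                    self.penalties.append((f"sp_null_{lev}", idx, block.pen_null.copy()))
                start += B.shape[1]
        self.re_levels = None
        if spec.random_intercept is not None:
            self.re_levels = tuple(pd.unique(data[spec.random_intercept]))
            Z = (data[spec.random_intercept].to_numpy()[:, None]
                 == np.asarray(self.re_levels, dtype=object)[None, :]).astype(float)
            cols.append(Z)
            idx = np.arange(start, start + Z.shape[1])
            self.term_cols["random_intercept"] = idx.tolist()
            self.penalties.append(("re", idx, np.ones(Z.shape[1])))
            start += Z.shape[1]
        self.X = np.hstack(cols)
        self.p = self.X.shape[1]
        self.fixed_cols = [i for i in range(self.p)
                           if i not in self.term_cols.get("random_intercept", [])]

    def _dummies(self, col, data):
        levels = self.levels[col]
        vals = data[col].to_numpy()
        unseen = set(pd.unique(data[col].dropna())) - set(levels)
        if unseen:
            raise ValueError(f"unseen levels in {col!r}: {sorted(unseen)}")
        return (vals[:, None] == np.asarray(levels[1:], dtype=object)[None, :]).astype(float)

    def _term_matrix(self, term, data):
        X = self._dummies(term[0], data)
        for c in term[1:]:
            D = self._dummies(c, data)
            X = np.einsum("ni,nj->nij", X, D).reshape(len(data), -1)
        return X

    def predict_matrix(self, grid: pd.DataFrame, include_re: bool = False) -> np.ndarray:
        cols = [np.ones((len(grid), 1))]
        for term in self.spec.categorical_terms:
            cols.append(self._term_matrix(term, grid))
        if self.spec.smooth is not None:
            sm = self.spec.smooth
            x = pd.to_numeric(grid[sm.col], errors="coerce").to_numpy()
            by_levels = self.levels[sm.by] if sm.by else (None,)
            for lev in by_levels:
                block = self.smooth_blocks[("smooth", lev)]
                B = _bspline_design(x, block.knots) @ block.U - block.col_means
                if lev is not None:
                    B = B * (grid[sm.by] == lev).to_numpy()[:, None]
                cols.append(np.nan_to_num(B))
        if self.re_levels is not None:
            cols.append(np.zeros((len(grid), len(self.re_levels))))
        return np.hstack(cols)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


@dataclass
class FittedGAMM:
    """Penalized-likelihood fit of one nested binomial model."""

    design: _Design
    beta: np.ndarray
    cov: np.ndarray               # Bayesian posterior covariance (X'WX + S)^-1
    lambdas: dict
    loglik: float
    deviance: float
    edf: float
    edf_by_term: dict
    aic: float
    fitted: np.ndarray
    y: np.ndarray
    data_index: pd.Index
    converged: bool = True

    @property
    def random_intercept_sd(self) -> float | None:
        lam = self.lambdas.get("re")
        return None if lam is None else float(1.0 / np.sqrt(lam))

    def predict(self, grid: pd.DataFrame) -> np.ndarray:
        """Population-level predicted probabilities (random intercepts = 0)."""
        Xp = self.design.predict_matrix(grid)
        return special.expit(Xp @ self.beta)


def _penalty_diag(design: _Design, lambdas: dict) -> np.ndarray:
    s = np.zeros(design.p)
    for label, idx, diag in design.penalties:
        s[idx] += lambdas[label] * diag
    return s


def fit_gamm(data: pd.DataFrame, response: pd.Series, spec: GAMMSpec,
             max_outer: int = 40, max_pirls: int = 60, tol: float = 1e-3) -> FittedGAMM:
    """Fit one penalized logistic additive model with random intercepts.

    Coefficients by penalized IRLS; each smoothing parameter (and the
    random-intercept precision) by the generalized Fellner-Schall update,
    which increases the Laplace-approximate REML criterion at every step.
    Complete separation in a covariate cell is warned about; the penalties
    keep the fit finite.
    """
    y = response.dropna()
    d = data.loc[y.index]
    for term in spec.categorical_terms:
        for c in term:
            if d[c].nunique() < 2:
                raise ValueError(f"categorical covariate {c!r} has < 2 levels")
    design = _Design(spec, d)
    X = design.X
    yv = y.to_numpy(dtype=float)
    n, p = X.shape
    lambdas = {label: 1.0 for label, _, _ in design.penalties}
    beta = np.zeros(p)
    beta[0] = special.logit(np.clip(yv.mean(), 1e-3, 1 - 1e-3))
    eta = X @ beta
    XtWX = None
    for outer in range(max_outer):
        s_diag = _penalty_diag(design, lambdas)
        for it in range(max_pirls):
            mu = special.expit(eta)
            w = np.clip(mu * (1 - mu), 1e-10, None)
            z = eta + (yv - mu) / w
            Xw = X * w[:, None]
            XtWX = X.T @ Xw
            H = XtWX + np.diag(s_diag)
            beta_new = np.linalg.solve(H, Xw.T @ z)
            eta_new = X @ beta_new
            delta = np.max(np.abs(eta_new - eta)) if it else np.inf
            beta, eta = beta_new, eta_new
            if it and delta < 1e-7 * (1 + np.max(np.abs(eta))):
                break
        if not design.penalties:
            break
        V = np.linalg.inv(XtWX + np.diag(s_diag))
        moved = 0.0
        for label, idx, diag in design.penalties:
            lam = lambdas[label]
            rank = int(np.sum(diag > 0))
            tr_VS = float(np.sum(np.diag(V)[idx] * diag))
            bsb = float(np.sum(diag * beta[idx] ** 2))
            num = rank / lam - tr_VS
            if bsb < 1e-12 or num <= 0:
                new = min(lam * 10.0, 1e8)
            else:
                new = np.clip(lam * num / bsb, lam / 30.0, lam * 30.0)
                new = np.clip(new, 1e-7, 1e8)
            moved = max(moved, abs(np.log(new) - np.log(lam)))
            lambdas[label] = new
        if moved < tol:
            break
    mu = special.expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cell_sep = (mu > 1 - 1e-6) | (mu < 1e-6)
    if cell_sep.any():
        warnings.warn(f"{int(cell_sep.sum())} fitted probabilities at the boundary "
                      "(possible separation); penalties keep the fit finite")
    s_diag = _penalty_diag(design, lambdas)
    XtWX = X.T @ (X * w[:, None])
    V = np.linalg.inv(XtWX + np.diag(s_diag))
    F_diag = np.sum(V * XtWX, axis=1)    # diag(V @ XtWX)
    edf_by_term = {t: float(np.sum(F_diag[list(ix)])) for t, ix in design.term_cols.items()}
    edf = float(F_diag.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = float(np.sum(special.xlogy(yv, mu) + special.xlogy(1 - yv, 1 - mu)))
    dev = -2.0 * ll
    return FittedGAMM(
        design=design, beta=beta, cov=V, lambdas=dict(lambdas), loglik=ll,
        deviance=dev, edf=edf, edf_by_term=edf_by_term, aic=dev + 2.0 * edf,
        fitted=mu, y=yv, data_index=y.index,
    )


# --------------------------------------------------------------------------
# model selection
# --------------------------------------------------------------------------


def _droppable(spec: GAMMSpec):
    """Terms removable without violating marginality."""
    out = []
    for term in spec.categorical_terms:
        nested = any(set(term) < set(other) for other in spec.categorical_terms)
        if not nested:
            out.append(term)
    if spec.smooth is not None:
        out.append("smooth")
    return out


def select_model(data: pd.DataFrame, response: pd.Series, spec: GAMMSpec,
                 delta_aic: float = 2.0) -> tuple:
    """Backwards AIC selection with smooth-basis-dimension choice.

    The basis dimension ``k`` of the smooth is first chosen over
    ``spec.k_grid`` by minimum AIC of the full model. Then terms are dropped
    iteratively: at each step the candidate whose removal yields the lowest
    AIC is removed if that AIC does not exceed the current AIC by more than
    ``delta_aic`` (the boundary counts as removable). Marginality is
    honoured: a main effect is never dropped while an interaction containing
    it remains. Returns ``(fit, reduced_spec, trace)``.
    """
    trace = []
    if spec.smooth is not None:
        best_k, best_aic = None, np.inf
        for k in spec.k_grid:
            cand = replace(spec, smooth=replace(spec.smooth, k=k))
            aic = fit_gamm(data, response, cand).aic
            trace.append({"action": f"k={k}", "aic": aic})
            if aic < best_aic:
                best_k, best_aic = k, aic
        spec = replace(spec, smooth=replace(spec.smooth, k=best_k))
    current = fit_gamm(data, response, spec)
    trace.append({"action": "full", "aic": current.aic})
    while True:
        candidates = _droppable(spec)
        if not candidates:
            break
        best = None
        for term in candidates:
            cand_spec = spec.drop_term(term)
            fit = fit_gamm(data, response, cand_spec)
            trace.append({"action": f"drop {term}", "aic": fit.aic})
            if best is None or fit.aic < best[1].aic:
                best = (term, fit, cand_spec)
        term, fit, cand_spec = best
        if fit.aic <= current.aic + delta_aic:
            spec, current = cand_spec, fit
            trace.append({"action": f"removed {term}", "aic": fit.aic})
        else:
            break
    return current, spec, pd.DataFrame(trace)


# --------------------------------------------------------------------------
# posterior prediction and propagation
# --------------------------------------------------------------------------


@dataclass
class PredictionDraws:
    """Posterior-sampled probabilities on a prediction grid.

    ``p_fars_given_ars`` holds the draws of P(fARS | ARS); the scale-specific
    foraging probabilities ``p_fars`` and ``p_bars`` are stored as the
    propagated products, and P(ARS | encounter) is their sum, so the
    propagation identity P(fARS) + P(bARS) = P(ARS|enc) holds exactly per
    draw. All matrices are (n_draws, n_rows).
    """

    grid: pd.DataFrame
    p_fars: np.ndarray
    p_bars: np.ndarray
    p_fars_given_ars: np.ndarray

    @property
    def p_ars(self) -> np.ndarray:
        return self.p_fars + self.p_bars

    def summary(self) -> pd.DataFrame:
        out = self.grid.copy()
        for name, mat in (("p_ars", self.p_ars), ("p_fars", self.p_fars),
                          ("p_bars", self.p_bars)):
            out[f"{name}_mean"] = mat.mean(axis=0)
            out[f"{name}_lo95"] = np.percentile(mat, 2.5, axis=0)
            out[f"{name}_hi95"] = np.percentile(mat, 97.5, axis=0)
        return out


def _safe_cholesky(V):
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        warnings.warn("posterior covariance not positive definite; "
                      "repaired by eigenvalue clipping")
        vals, vecs = np.linalg.eigh((V + V.T) / 2)
        vals = np.clip(vals, 1e-12 * vals.max(), None)
        return vecs * np.sqrt(vals)


def _draw_probs(fit: FittedGAMM, grid: pd.DataFrame, n_draws, rng) -> np.ndarray:
    Xp = fit.design.predict_matrix(grid)
    L = _safe_cholesky(fit.cov)
    draws = fit.beta[None, :] + rng.standard_normal((n_draws, len(fit.beta))) @ L.T
    return special.expit(draws @ Xp.T)


def posterior_predict(fit_ars: FittedGAMM, fit_fars: FittedGAMM,
                      grid: pd.DataFrame, n_draws: int = 1000,
                      seed=None) -> PredictionDraws:
    """Sample both models' posteriors on a grid and propagate the product.

    Coefficient vectors are drawn from N(beta_hat, cov); random intercepts
    are set to zero (population-level curves). The two models are sampled
    independently.
    """
    rng = np.random.default_rng(seed)
    p1 = _draw_probs(fit_ars, grid, n_draws, rng)
    p2 = _draw_probs(fit_fars, grid, n_draws, rng)
    p_fars = p1 * p2
    return PredictionDraws(
        grid=grid.reset_index(drop=True),
        p_fars=p_fars,
        p_bars=p1 - p_fars,
        p_fars_given_ars=p2,
    )


def region_prevalence(ue: UseEncounterData, n_draws: int = 1000, seed=None,
                      region_col: str = "region") -> tuple:
    """Regional prevalence of each ARS scale: region-only nested models.

    Fits models (i) and (ii) with region as sole fixed covariate plus the
    individual random intercept, then predicts per region with full
    propagation. Returns ``(draws, fit_ars, fit_fars)``.
    """
    spec = GAMMSpec(categorical_terms=((region_col,),), smooth=None)
    fit1 = fit_gamm(ue.data, ue.response_ars, spec)
    fit2 = fit_gamm(ue.data, ue.response_fars, spec)
    regions = fit1.design.levels[region_col]
    grid = pd.DataFrame({region_col: list(regions)})
    return posterior_predict(fit1, fit2, grid, n_draws, seed), fit1, fit2


def prediction_grid(ue: UseEncounterData, cols=("region", "geomorphology", "substrate"),
                    min_obs: int = MIN_LEVEL_OBS) -> pd.DataFrame:
    """Observed covariate combinations with at least ``min_obs`` intervals."""
    counts = ue.data.groupby(list(cols), observed=True).size()
    keep = counts[counts >= min_obs].reset_index().drop(columns=0)
    if "pea" in ue.data.columns:
        keep["pea"] = float(ue.data["pea"].median())
    return keep


def state_uncertainty_sensitivity(local_probs: pd.DataFrame, habitat: pd.DataFrame,
                                  grid: pd.DataFrame, spec: GAMMSpec,
                                  n_iter: int = 100, seed=None) -> pd.DataFrame:
    """Refit the nested models under resampled state sequences.

    Per iteration a state sequence is drawn from the HMM's local state
    probabilities, the responses are rebuilt and both models refitted with
    the given (fixed) specification, and population-level predictions on the
    grid are stored. The spread across iterations measures how much
    state-assignment uncertainty propagates into the habitat results.
    Iterations that fail to fit are recorded and skipped.
    """
    ss = np.random.SeedSequence(seed)
    draw_seed, _ = ss.spawn(2)
    draws = sample_state_sequences(local_probs, n_draws=n_iter, seed=draw_seed)
    rows = {"p_ars": [], "p_fars": []}
    failures = 0
    for d in range(n_iter):
        tab = habitat.copy()
        tab["state"] = draws.iloc[:, d]
        try:
            ue = build_response(tab)
            f1 = fit_gamm(ue.data, ue.response_ars, spec)
            f2 = fit_gamm(ue.data, ue.response_fars, spec)
        except (ValueError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            warnings.warn(f"iteration {d} failed: {exc}")
            failures += 1
            continue
        p1 = f1.predict(grid)
        rows["p_ars"].append(p1)
        rows["p_fars"].append(p1 * f2.predict(grid))
    out = grid.copy()
    for key in rows:
        mat = np.asarray(rows[key])
        out[f"{key}_iter_mean"] = mat.mean(axis=0)
        out[f"{key}_iter_sd"] = mat.std(axis=0)
    out.attrs["n_failed"] = failures
    return out


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------


def deviance_residuals(fit: FittedGAMM) -> pd.Series:
    mu = np.clip(fit.fitted, 1e-12, 1 - 1e-12)
    y = fit.y
    d2 = -2.0 * (special.xlogy(y, mu) + special.xlogy(1 - y, 1 - mu))
    return pd.Series(np.sign(y - mu) * np.sqrt(np.clip(d2, 0, None)),
                     index=fit.data_index)


def residual_autocorrelation(fit: FittedGAMM, individuals: pd.Series,
                             max_lag: int = 10) -> pd.DataFrame:
    """Within-individual deviance-residual autocorrelation at lags 1-10.

    Returns one row per individual per lag with the correlation and the
    approximate 95% white-noise band (+-1.96/sqrt(n)); individuals with too
    few rows are skipped with a note column.
    """
    resid = deviance_residuals(fit)
    rows = []
    for ind, idx in individuals.loc[resid.index].groupby(
            individuals.loc[resid.index]).groups.items():
        r = resid.loc[idx].to_numpy()
        n = len(r)
        if n < 3:
            rows.append({"individual": ind, "lag": np.nan, "acf": np.nan,
                         "band": np.nan, "note": "too few rows"})
            continue
        r = r - r.mean()
        denom = np.sum(r * r)
        band = 1.96 / np.sqrt(n)
        for lag in range(1, min(max_lag, n - 1) + 1):
            rows.append({"individual": ind, "lag": lag,
                         "acf": float(np.sum(r[lag:] * r[:-lag]) / denom),
                         "band": band, "note": ""})
    return pd.DataFrame(rows)
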