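"""A MaxEnt-equivalent presence-background model.

The model is the penalized Gibbs / log-linear form MaxEnt is equivalent to:
with features f(x) (here a linear and a quadratic term per predictor, min-max
scaled to [0, 1] over the fitting sample) and a background base measure w,
weights lambda minimize the convex objective

    -(1/m) sum_presences lambda . f(x)
    + log sum_background w(x) exp(lambda . f(x))
    + sum_j beta_j |lambda_j|,        beta_j = beta * s_j / sqrt(m),

where s_j is the feature's standard deviation over the presences (floored),
mirroring MaxEnt's sample-size-dependent per-feature penalty scale.  The raw
output P(x) = w(x) exp(lambda . f(x)) / Z is a probability distribution over
the background sample.  Model selection follows a two-stage AICc procedure:
every candidate predictor subset is fitted unpenalized (beta = 0) and the
AICc-minimal subset is kept; that subset is then refitted over the 31-value
regularization grid beta = 0, 0.5, ..., 15 and the AICc-minimal fit wins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .grids import GridSpec
from .species import OccurrenceSet

DEFAULT_BETA_GRID = tuple(np.arange(0, 15.0001, 0.5))  # 31 values

_WEIGHT_EPS = 1e-8  # |lambda| below this counts as zero in k


@dataclass
class PreparedOccurrences:
    """Spatially thinned presences: one record per grid cell."""

    species_id: str
    cells: np.ndarray  # (m, 2) unique (row, col), row-major order
    pass_min_records: bool
    min_records: int = 30

    @property
    def m(self) -> int:
        return len(self.cells)


@dataclass
class BackgroundSet:
    """Background cells drawn from the biased-effort density within a region."""

    cells: np.ndarray  # (n_unique, 2)
    counts: np.ndarray  # multiplicity of each unique cell
    n_bg: int

    @property
    def weights(self) -> np.ndarray:
        return self.counts / self.counts.sum()


@dataclass
class FeatureSpec:
    """Linear + quadratic features per predictor with min-max scaling bounds."""

    predictor_names: tuple
    lower: np.ndarray  # (2p,) bounds over the fitting sample, raw feature space
    upper: np.ndarray
    quadratic: bool = True

    @property
    def feature_names(self) -> tuple:
        out = []
        for n in self.predictor_names:
            out += [n, f"{n}^2"] if self.quadratic else [n]
        return tuple(out)

    def _raw(self, X: np.ndarray) -> np.ndarray:
        if not self.quadratic:
            return np.asarray(X, dtype=float)
        raw = np.empty((X.shape[0], 2 * X.shape[1]))
        raw[:, 0::2] = X
        raw[:, 1::2] = X**2
        return raw

    def transform(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Raw predictor matrix (n, p) -> scaled feature matrix."""
        raw = self._raw(X)
        if clamp:
            raw = np.clip(raw, self.lower, self.upper)
        span = self.upper - self.lower
        safe = np.where(span > 1e-12, span, 1.0)
        scaled = (raw - self.lower) / safe
        scaled[:, span <= 1e-12] = 0.0
        return scaled


def build_feature_spec(
    predictor_names: tuple, sample: np.ndarray, quadratic: bool = True
) -> FeatureSpec:
    """Scaling bounds from the fitting sample (presences plus background)."""
    spec = FeatureSpec(
        predictor_names=tuple(predictor_names),
        lower=np.zeros(0),
        upper=np.zeros(0),
        quadratic=quadratic,
    )
    raw = spec._raw(sample)
    spec.lower = raw.min(axis=0)
    spec.upper = raw.max(axis=0)
    return spec


@dataclass
class MaxEntModel:
    """Fitted weights and normalizer of the log-linear model."""

    spec: FeatureSpec
    lambdas: np.ndarray  # (2p,)
    beta: float
    penalty_scales: np.ndarray  # beta_j before the beta multiplier (s_j / sqrt m)
    log_z: float  # log normalizer over the weighted background (likelihood scale)
    log_z_pred: float  # uniform-base normalizer used by the output transform
    entropy: float  # entropy of the uniform-base raw distribution
    loglik: float  # sum over presences of log raw output
    m: int  # number of presences
    converged: bool
    aicc: float = np.nan

    @property
    def k(self) -> int:
        return int(np.sum(np.abs(self.lambdas) > _WEIGHT_EPS))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.spec.transform(X) @ self.lambdas

    def to_json(self) -> str:
        return json.dumps(
            {
                "predictors": list(self.spec.predictor_names),
                "quadratic": self.spec.quadratic,
                "lower": self.spec.lower.tolist(),
                "upper": self.spec.upper.tolist(),
                "lambdas": self.lambdas.tolist(),
                "beta": self.beta,
                "log_z": self.log_z,
                "log_z_pred": self.log_z_pred,
                "entropy": self.entropy,
                "m": self.m,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MaxEntModel":
        d = json.loads(text)
        spec = FeatureSpec(
            tuple(d["predictors"]), np.array(d["lower"]), np.array(d["upper"]),
            d.get("quadratic", True),
        )
        return cls(
            spec=spec,
            lambdas=np.array(d["lambdas"]),
            beta=d["beta"],
            penalty_scales=np.zeros(len(d["lambdas"])),
            log_z=d["log_z"],
            log_z_pred=d["log_z_pred"],
            entropy=d["entropy"],
            loglik=np.nan,
            m=d["m"],
            converged=True,
        )


def prepare_occurrences(
    raw: OccurrenceSet, grid: GridSpec, min_records: int = 30
) -> PreparedOccurrences:
    """Thin to one record per grid cell and apply the minimum-record rule.

    The retained record per cell is the first one; output cells are sorted in
    row-major order so thinning is deterministic.
    """
    records = np.asarray(raw.records, dtype=int).reshape(-1, 2)
    if len(records) and (
        records.min() < 0
        or records[:, 0].max() >= grid.n_rows
        or records[:, 1].max() >= grid.n_cols
    ):
        raise ValueError("occurrence records off the grid")
    if len(records) == 0:
        cells = np.empty((0, 2), dtype=int)
    else:
        flat = np.unique(records[:, 0] * grid.n_cols + records[:, 1])
        cells = np.column_stack([flat // grid.n_cols, flat % grid.n_cols])
    return PreparedOccurrences(
        species_id=raw.species_id,
        cells=cells,
        pass_min_records=len(cells) >= min_records,
        min_records=min_records,
    )


def sample_bias_background(
    density: np.ndarray,
    mask: np.ndarray,
    n_bg: int,
    seed: int = 0,
) -> BackgroundSet:
    """Draw background cells with replacement, P(cell) proportional to density.

    ``density`` is the target-group record density (survey effort) per cell;
    cells outside ``mask`` have zero probability.
    """
    w = np.where(mask, np.maximum(density, 0.0), 0.0).ravel()
    total = w.sum()
    if total <= 0:
        raise ValueError("density is zero everywhere inside the mask")
    rng = np.random.default_rng(seed)
    draws = rng.choice(len(w), size=n_bg, replace=True, p=w / total)
    uniq, counts = np.unique(draws, return_counts=True)
    cells = np.column_stack(np.unravel_index(uniq, mask.shape))
    return BackgroundSet(cells=cells, counts=counts, n_bg=n_bg)


def _fit_gibbs(
    F_pres: np.ndarray,
    F_bg: np.ndarray,
    w_bg: np.ndarray,
    beta: float,
    penalty_scales: np.ndarray,
    max_iter: int,
    tol: float,
    trace: list | None = None,
) -> tuple[np.ndarray, bool]:
    """L1-penalized fit via positive/negative weight splitting + L-BFGS-B."""
    d = F_pres.shape[1]
    mean_pres = F_pres.mean(axis=0)
    logw = np.log(w_bg)
    pen = beta * penalty_scales

    def obj_grad(theta):
        lam = theta[:d] - theta[d:]
        eta = F_bg @ lam + logw
        lz = logsumexp(eta)
        q = np.exp(eta - lz)
        g = -mean_pres + q @ F_bg
        f = -mean_pres @ lam + lz + pen @ (theta[:d] + theta[d:])
        grad = np.concatenate([g + pen, -g + pen])
        return f, grad

    callback = None
    if trace is not None:
        trace.append(obj_grad(np.zeros(2 * d))[0])
        callback = lambda xk: trace.append(obj_grad(xk)[0])
    res = minimize(
        obj_grad,
        np.zeros(2 * d),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * d),
        callback=callback,
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
    )
    lam = res.x[:d] - res.x[d:]
    lam[np.abs(lam) < _WEIGHT_EPS] = 0.0
    return lam, bool(res.success)


def fit_maxent(
    presence_X: np.ndarray,
    background_X: np.ndarray,
    beta: float = 0.0,
    background_weights: np.ndarray | None = None,
    include_presences: bool = True,
    spec: FeatureSpec | None = None,
    quadratic: bool = True,
    max_iter: int = 1000,
    tol: float = 1e-12,
    objective_trace: list | None = None,
) -> MaxEntModel:
    """Fit the penalized log-linear model.

    Parameters
    ----------
    presence_X, background_X
        Raw predictor values at presence cells (m, p) and background cells
        (n, p).  The predictor order defines the feature order.
    beta
        Regularization multiplier (>= 0); per-feature penalties are
        ``beta * s_j / sqrt(m)`` with s_j the feature SD over presences.
    background_weights
        Base-measure weights per background row (multiplicities); uniform if
        omitted.  Presences are appended to the background by default
        (target-group background semantics), each with weight 1 draw.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    presence_X = np.atleast_2d(np.asarray(presence_X, dtype=float))
    background_X = np.atleast_2d(np.asarray(background_X, dtype=float))
    m = presence_X.shape[0]
    if m < 1:
        raise ValueError("need at least one presence")

    if background_weights is None:
        background_weights = np.ones(background_X.shape[0])
    if include_presences:
        bg_X = np.vstack([background_X, presence_X])
        bg_w = np.concatenate([background_weights, np.ones(m)])
    else:
        bg_X, bg_w = background_X, np.asarray(background_weights, dtype=float)
    bg_w = bg_w / bg_w.sum()

    if spec is None:
        spec = build_feature_spec(
            tuple(f"x{j}" for j in range(presence_X.shape[1])),
            np.vstack([presence_X, background_X]),
            quadratic=quadratic,
        )
    F_pres = spec.transform(presence_X)
    F_bg = spec.transform(bg_X)
    if not (np.all(np.isfinite(F_pres)) and np.all(np.isfinite(F_bg))):
        raise ValueError("non-finite features after scaling")

    s = np.maximum(F_pres.std(axis=0), 1e-3)
    penalty_scales = s / np.sqrt(m)
    lam, converged = _fit_gibbs(
        F_pres, F_bg, bg_w, beta, penalty_scales, max_iter, tol, trace=objective_trace
    )

    eta_bg = F_bg @ lam + np.log(bg_w)
    log_z = float(logsumexp(eta_bg))
    loglik = float(np.sum(F_pres @ lam) - m * log_z)
    # uniform-base normalizer and entropy drive the bounded output transform
    eta_unif = F_bg @ lam
    log_z_pred = float(logsumexp(eta_unif))
    q = np.exp(eta_unif - log_z_pred)
    entropy = float(-np.sum(q * np.log(np.maximum(q, 1e-300))))

    model = MaxEntModel(
        spec=spec,
        lambdas=lam,
        beta=beta,
        penalty_scales=penalty_scales,
        log_z=log_z,
        log_z_pred=log_z_pred,
        entropy=entropy,
        loglik=loglik,
        m=m,
        converged=converged,
    )
    model.aicc = aicc(model)
    return model


def aicc(model: MaxEntModel, loglik: float | None = None, m: int | None = None) -> float:
    """Small-sample-corrected AIC: 2k - 2LL + 2k(k+1)/(m-k-1).

    k counts non-zero weights; when m <= k + 1 (or the log-likelihood is not
    finite) the criterion is undefined and reported as +inf.
    """
    ll = model.loglik if loglik is None else loglik
    mm = model.m if m is None else m
    k = model.k
    if not np.isfinite(ll) or mm <= k + 1:
        return float("inf")
    return float(2 * k - 2 * ll + 2 * k * (k + 1) / (mm - k - 1))


def predict_suitability(model: MaxEntModel, predictor_values: np.ndarray) -> np.ndarray:
    """Suitability in [0, 1] via the complementary log-log transform.

    ``predictor_values`` is (n, p) raw values in the model's predictor order;
    features are clamped to their training bounds.  The transform
    ``1 - exp(-exp(H + eta))`` (H the entropy of the raw background
    distribution, eta the normalized linear predictor) is strictly monotone
    in the raw output, so every downstream rank-based quantity (thresholds,
    the Boyce index) is invariant to this choice.
    """
    predictor_values = np.atleast_2d(np.asarray(predictor_values, dtype=float))
    if predictor_values.shape[1] != len(model.spec.predictor_names):
        raise ValueError("predictor column count does not match the model")
    eta = model.linear_predictor(predictor_values) - model.log_z_pred
    return 1.0 - np.exp(-np.exp(np.minimum(model.entropy + eta, 30.0)))


def predict_on_landscape(model: MaxEntModel, landscape) -> np.ndarray:
    """Suitability raster over a landscape providing all model predictors."""
    from .species import predictor_stack

    names, stack = predictor_stack(landscape)
    try:
        idx = [names.index(p) for p in model.spec.predictor_names]
    except ValueError as e:
        raise ValueError(f"landscape is missing a model predictor: {e}") from e
    X = stack[idx].reshape(len(idx), -1).T
    return predict_suitability(model, X).reshape(landscape.grid.shape)


def select_model(
    presence_X: np.ndarray,
    background_X: np.ndarray,
    pool_names: tuple,
    candidate_sets: list,
    beta_grid: tuple = DEFAULT_BETA_GRID,
    background_weights: np.ndarray | None = None,
    include_presences: bool = True,
) -> tuple[MaxEntModel, "SelectionDiagnostics"]:
    """Two-stage AICc model selection.

    Stage 1 fits every candidate predictor set unpenalized (beta = 0) and
    keeps the AICc-minimal set; stage 2 refits that set at every value of the
    regularization grid and returns the AICc-minimal model.  Ties break by
    smaller k, then smaller beta, then lexicographic set order.
    """
    if not candidate_sets:
        raise ValueError("need at least one candidate set")
    name_to_col = {n: i for i, n in enumerate(pool_names)}

    def sub(X, names):
        return X[:, [name_to_col[n] for n in names]]

    stage1 = []
    for cand in sorted(candidate_sets):
        mdl = fit_maxent(
            sub(presence_X, cand), sub(background_X, cand), beta=0.0,
            background_weights=background_weights, include_presences=include_presences,
        )
        mdl.spec = FeatureSpec(tuple(cand), mdl.spec.lower, mdl.spec.upper, mdl.spec.quadratic)
        stage1.append((mdl.aicc, mdl.k, tuple(cand), mdl))
    stage1.sort(key=lambda t: (t[0], t[1], t[2]))
    best_set = stage1[0][2]
    if not np.isfinite(stage1[0][0]):
        raise ValueError("all candidate fits have undefined AICc; species unusable")

    stage2 = []
    for beta in beta_grid:
        mdl = fit_maxent(
            sub(presence_X, best_set), sub(background_X, best_set), beta=float(beta),
            background_weights=background_weights, include_presences=include_presences,
        )
        mdl.spec = FeatureSpec(tuple(best_set), mdl.spec.lower, mdl.spec.upper, mdl.spec.quadratic)
        stage2.append((mdl.aicc, mdl.k, float(beta), mdl))
    stage2.sort(key=lambda t: (t[0], t[1], t[2]))
    best = stage2[0][3]
    diag = SelectionDiagnostics(
        stage1_aicc={t[2]: t[0] for t in stage1},
        selected_set=best_set,
        n_stage2_fits=len(stage2),
        stage2_aicc={t[2]: t[0] for t in stage2},
        selected_beta=best.beta,
    )
    return best, diag


@dataclass
class SelectionDiagnostics:
    stage1_aicc: dict
    selected_set: tuple
    n_stage2_fits: int
    stage2_aicc: dict
    selected_beta: float
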