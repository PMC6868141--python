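"""Cross-validated model evaluation: continuous Boyce index and thresholds.

Species retention follows a presence-only evaluation protocol: presences and
background are split into 10 random folds, the model is refitted on each
calibration set, and the continuous Boyce index (CBI) is computed on the
left-out presences.  The CBI slides a window (10% of the suitability range,
101 windows by default) across the suitability range; in each window P is
the fraction of evaluation presences and E the fraction of background, and
the index is the Spearman rank correlation between P/E and the window
midpoint.  It ranges from -1 to 1; a species is retained when the 95%
confidence interval of its fold-mean CBI lies above zero.

The habitat threshold is the 90%-sensitivity rule: per fold, the largest
suitability value (drawn from the observed calibration-presence values) that
still classifies at least 90% of calibration presences as suitable; the
final threshold is the average over folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .maxent import FeatureSpec, fit_maxent, predict_suitability


@dataclass
class FoldAssignment:
    k: int
    presence_folds: np.ndarray
    background_folds: np.ndarray


@dataclass
class CBIResult:
    fold_cbis: np.ndarray  # NaN where undefined
    mean: float
    ci_low: float
    ci_high: float
    retained: bool
    n_undefined: int
    fold_models: list = field(default_factory=list)


@dataclass
class ThresholdResult:
    fold_thresholds: np.ndarray
    threshold: float  # mean over folds


def kfold_split(m: int, n_bg: int, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Random near-equal folds for presences and background, separately."""
    if m < k:
        raise ValueError(f"need at least {k} presences for {k}-fold CV, got {m}")
    rng = np.random.default_rng(seed)

    def labels(n):
        lab = np.arange(n) % k
        return lab[rng.permutation(n)]

    return FoldAssignment(k=k, presence_folds=labels(m), background_folds=labels(n_bg))


def continuous_boyce_index(
    presence_suit: np.ndarray,
    background_suit: np.ndarray,
    n_windows: int = 101,
    window_frac: float = 0.1,
    background_weights: np.ndarray | None = None,
) -> float:
    """Continuous Boyce index of evaluation presences against background.

    ``background_weights`` (cell multiplicities) weight the expected
    fraction E.  Returns NaN when undefined (fewer than 2 windows with
    background mass, or a constant P/E series).
    """
    presence_suit = np.asarray(presence_suit, dtype=float)
    background_suit = np.asarray(background_suit, dtype=float)
    if len(presence_suit) == 0 or len(background_suit) == 0:
        return float("nan")
    if np.ptp(presence_suit) == 0:
        return float("nan")  # single-valued presences: index undefined
    if background_weights is None:
        bw = np.ones(len(background_suit))
    else:
        bw = np.asarray(background_weights, dtype=float)
    bw = bw / bw.sum()
    lo = background_suit.min()
    hi = background_suit.max()
    rng_width = hi - lo
    if rng_width <= 0:
        return float("nan")
    w = window_frac * rng_width
    mids = np.linspace(lo + w / 2, hi - w / 2, n_windows)
    lows = mids - w / 2
    highs = mids + w / 2
    p = np.array(
        [np.mean((presence_suit >= a) & (presence_suit <= b)) for a, b in zip(lows, highs)]
    )
    e = np.array(
        [bw[(background_suit >= a) & (background_suit <= b)].sum() for a, b in zip(lows, highs)]
    )
    keep = e > 0
    if keep.sum() < 2:
        return float("nan")
    ratio = p[keep] / e[keep]
    if np.all(ratio == ratio[0]):
        return float("nan")
    rho, _ = stats.spearmanr(mids[keep], ratio)
    return float(rho)


def sensitivity_threshold(
    fold_presence_suit: list, target: float = 0.90
) -> ThresholdResult:
    """Per-fold 90%-sensitivity thresholds and their average.

    Each element of ``fold_presence_suit`` holds the suitability values of
    one fold's calibration presences.  The per-fold threshold is the largest
    observed value t with mean(values >= t) >= target.
    """
    thresholds = []
    for vals in fold_presence_suit:
        vals = np.asarray(vals, dtype=float)
        if len(vals) == 0:
            raise ValueError("empty fold")
        cand = np.unique(vals)[::-1]  # descending
        t = vals.min()
        for c in cand:
            if np.mean(vals >= c) >= target:
                t = c
                break
        thresholds.append(t)
    thresholds = np.array(thresholds)
    return ThresholdResult(fold_thresholds=thresholds, threshold=float(thresholds.mean()))


def evaluate_species(
    presence_X: np.ndarray,
    background_X: np.ndarray,
    predictor_names: tuple,
    beta: float,
    k: int = 10,
    seed: int = 0,
    background_weights: np.ndarray | None = None,
    n_windows: int = 101,
    window_frac: float = 0.1,
    max_undefined: int = 3,
    ci_method: str = "folds",
    n_boot: int = 1000,
) -> CBIResult:
    """k-fold cross-validated CBI with a 95% CI retention rule.

    The model (fixed predictor set and beta from prior selection) is
    refitted on each calibration split; the CBI of each fold uses the
    left-out presences against the left-out background.  The CI is the
    Student-t interval across folds (``ci_method='bootstrap'`` resamples
    folds instead).  Retention requires the lower bound > 0 and at most
    ``max_undefined`` undefined folds.
    """
    m, n_bg = len(presence_X), len(background_X)
    folds = kfold_split(m, n_bg, k=k, seed=seed)
    if background_weights is None:
        background_weights = np.ones(n_bg)

    cbis = np.full(k, np.nan)
    models: list = []
    for i in range(k):
        p_cal = presence_X[folds.presence_folds != i]
        p_test = presence_X[folds.presence_folds == i]
        b_cal = background_X[folds.background_folds != i]
        b_test = background_X[folds.background_folds == i]
        w_cal = background_weights[folds.background_folds != i]
        mdl = fit_maxent(p_cal, b_cal, beta=beta, background_weights=w_cal)
        mdl.spec = FeatureSpec(tuple(predictor_names), mdl.spec.lower, mdl.spec.upper, mdl.spec.quadratic)
        models.append(mdl)
        suit_test_p = predict_suitability(mdl, p_test)
        suit_test_b = predict_suitability(mdl, b_test)
        cbis[i] = continuous_boyce_index(
            suit_test_p, suit_test_b, n_windows=n_windows, window_frac=window_frac,
            background_weights=background_weights[folds.background_folds == i],
        )

    defined = cbis[np.isfinite(cbis)]
    n_undef = int(k - len(defined))
    if len(defined) == 0:
        return CBIResult(cbis, np.nan, np.nan, np.nan, False, n_undef, models)
    mean, lo, hi = fold_confidence_interval(defined, method=ci_method, seed=seed,
                                            n_boot=n_boot)
    retained = bool(lo > 0 and n_undef <= max_undefined)
    return CBIResult(cbis, mean, float(lo), float(hi), retained, n_undef, models)


def fold_confidence_interval(
    defined: np.ndarray, method: str = "folds", seed: int = 0, n_boot: int = 1000
) -> tuple[float, float, float]:
    """Mean and 95% CI of the defined fold CBIs (Student-t or bootstrap)."""
    defined = np.asarray(defined, dtype=float)
    mean = float(defined.mean())
    if len(defined) == 1:
        return mean, mean, mean
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = rng.choice(defined, size=(n_boot, len(defined)), replace=True).mean(axis=1)
        lo, hi = (float(x) for x in np.quantile(boots, [0.025, 0.975]))
        return mean, lo, hi
    sd = defined.std(ddof=1)
    if sd == 0:
        return mean, mean, mean
    tcrit = stats.t.ppf(0.975, len(defined) - 1)
    half = float(tcrit * sd / np.sqrt(len(defined)))
    return mean, mean - half, mean + half
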