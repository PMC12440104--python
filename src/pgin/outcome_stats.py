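"""Outcome statistics: group comparisons, enrichment, and Cox modeling.

Group comparisons use Mann-Whitney U tests (exact when group sizes permit
and no ties are present) with Benjamini-Hochberg correction applied across
the family of pairs tested in one call. Enrichment of a binary carrier
status against a binary outcome is a Fisher exact test; both the
conditional-MLE odds ratio with its exact confidence interval and the
plain cross-product odds ratio are reported, since published tables rarely
say which convention they print. The gestational-age-to-event model is a
Cox proportional-hazards fit with the penalizer chosen by k-fold
cross-validated partial log-likelihood, a scaled-Schoenfeld-residual
proportionality check at p < 0.05, and a single square-and-refit pass for
features that fail it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import proportional_hazard_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import FitError, ParameterError

logger = logging.getLogger("pgin")

GROUP_LABELS = ("EP-N", "NTT-N", "EP-PE", "NTT-PE")
EARLY_PRETERM_WEEKS = 34.0


# ---------------------------------------------------------------------------
# Group derivation and rank tests
# ---------------------------------------------------------------------------


def derive_groups(metadata: pd.DataFrame) -> pd.DataFrame:
    """Attach the EP/NTT x PE/N group label.

    Early preterm is strictly ``ga_weeks < 34``; the label is composed with
    the preeclampsia flag.
    """
    for col in ("ga_weeks", "pe"):
        if col not in metadata.columns:
            raise ParameterError(f"metadata lacks required column {col!r}")
    bad = metadata["ga_weeks"].isna()
    if bad.any():
        raise ParameterError(
            f"missing gestational age for sample(s): {list(metadata.index[bad])[:5]}"
        )
    ep = metadata["ga_weeks"] < EARLY_PRETERM_WEEKS
    pe = metadata["pe"].astype(bool)
    out = metadata.copy()
    out["group"] = np.where(ep, "EP", "NTT") + np.where(pe, "-PE", "-N")
    return out


def compare_groups(
    values: pd.Series,
    labels: pd.Series,
    pairs: list[tuple[str, str]] | None = None,
    sided: str = "two",
    alternative_greater_first: bool = True,
    correction: str = "bh",
) -> pd.DataFrame:
    """Pairwise Mann-Whitney U tests with BH correction across the family.

    ``sided='one'`` tests whether the first group of each pair tends to be
    greater (or smaller, with ``alternative_greater_first=False``). Exact
    p-values are used when SciPy's exact method applies (small groups, no
    ties); otherwise the continuity-corrected normal approximation.
    """
    labels = labels.astype(str)
    groups = list(pd.unique(labels))
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    if sided not in ("one", "two"):
        raise ParameterError("sided must be 'one' or 'two'")
    rows = []
    for a, b in pairs:
        xa = values[labels == a].dropna().to_numpy(float)
        xb = values[labels == b].dropna().to_numpy(float)
        if len(xa) < 1 or len(xb) < 1:
            raise ParameterError(f"group {a if len(xa) < 1 else b!r} has no observations")
        alt = "two-sided" if sided == "two" else ("greater" if alternative_greater_first else "less")
        u, p = stats.mannwhitneyu(xa, xb, alternative=alt, method="auto")
        rows.append({"group_a": a, "group_b": b, "n_a": len(xa), "n_b": len(xb), "U": float(u), "p": float(p)})
    out = pd.DataFrame(rows)
    if correction == "bh" and len(out):
        out["p_adj"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(pvals, float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Enrichment (Fisher exact)
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    name: str
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float  # conditional MLE
    ci_low: float
    ci_high: float
    sample_odds_ratio: float  # cross-product ad/bc
    p_value: float
    undefined_or: bool = False


def enrichment_test(
    carrier_flags=None,
    outcome_flags=None,
    table=None,
    name: str = "",
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Fisher exact test on carriers x outcome.

    Either two boolean vectors or an explicit 2x2 table
    ``[[carrier&outcome, carrier&~outcome], [~carrier&outcome,
    ~carrier&~outcome]]``. The two-sided p sums all tables at most as
    probable as the observed one under the hypergeometric null. With an
    empty margin the odds ratio is flagged undefined but the p-value is
    still returned.
    """
    if table is None:
        c = np.asarray(carrier_flags, bool)
        o = np.asarray(outcome_flags, bool)
        if c.shape != o.shape or c.size == 0:
            raise ParameterError("carrier and outcome flags must be equal-length, non-empty")
        table = [
            [int(np.sum(c & o)), int(np.sum(c & ~o))],
            [int(np.sum(~c & o)), int(np.sum(~c & ~o))],
        ]
    ((a, b), (cc, d)) = [list(map(int, r)) for r in table]
    if min(a, b, cc, d) < 0 or a + b + cc + d == 0:
        raise ParameterError("2x2 table must be non-negative with a positive total")
    _, p = stats.fisher_exact([[a, b], [cc, d]], alternative="two-sided")
    undefined = (a + b == 0) or (cc + d == 0) or (a + cc == 0) or (b + d == 0)
    sample_or = math.inf if (b * cc == 0 and a * d > 0) else (
        math.nan if b * cc == 0 else (a * d) / (b * cc)
    )
    if undefined:
        or_mle, lo, hi = math.nan, math.nan, math.nan
    else:
        res = stats.contingency.odds_ratio([[a, b], [cc, d]], kind="conditional")
        ci = res.confidence_interval(confidence_level=1 - alpha)
        or_mle, lo, hi = float(res.statistic), float(ci.low), float(ci.high)
    return EnrichmentResult(
        name=name,
        table=((a, b), (cc, d)),
        odds_ratio=or_mle,
        ci_low=lo,
        ci_high=hi,
        sample_odds_ratio=sample_or,
        p_value=float(p),
        undefined_or=undefined or not math.isfinite(sample_or),
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    coefficients: pd.Series  # log-hazard per unit
    hazard_ratios: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p_values: pd.Series
    penalizer: float
    ph_pass: dict[str, bool]
    transformed_features: list[str] = field(default_factory=list)
    model: CoxPHFitter | None = None
    data: pd.DataFrame | None = None
    duration_col: str = "ga_weeks"
    event_col: str = "pe"
    original: pd.DataFrame | None = None  # pre-transform feature values


def _cv_penalizer(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    penalizer_grid,
    k_folds: int,
    seed: int,
) -> float:
    """Mean held-out partial log-likelihood over deterministic folds;
    ties favour the smaller penalizer."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(df))
    folds = np.array_split(order, k_folds)
    best_p, best_score = None, -np.inf
    for pen in sorted(penalizer_grid):
        scores = []
        for f in folds:
            test_idx = df.index[f]
            train = df.drop(index=test_idx)
            test = df.loc[test_idx]
            if test[event_col].sum() == 0 or train[event_col].sum() == 0:
                continue
            cph = CoxPHFitter(penalizer=pen)
            try:
                cph.fit(train, duration_col=duration_col, event_col=event_col)
            except ConvergenceError:
                scores.append(-np.inf)
                continue
            scores.append(cph.score(test, scoring_method="log_likelihood"))
        mean = float(np.mean(scores)) if scores else -np.inf
        if mean > best_score + 1e-12:
            best_p, best_score = pen, mean
    return best_p if best_p is not None else min(penalizer_grid)


def fit_cox(
    table: pd.DataFrame,
    features: list[str],
    duration_col: str = "ga_weeks",
    event_col: str = "pe",
    penalizer_grid=(0.0, 0.01, 0.1, 1.0),
    k_folds: int | None = 5,
    seed: int = 0,
    check_ph: bool = True,
) -> CoxFit:
    """Gestational-age-to-event Cox model.

    Selects the penalizer from ``penalizer_grid`` by mean held-out partial
    log-likelihood over ``k_folds`` folds (skipped when ``k_folds`` is
    None, using the smallest grid value), fits, then tests each feature's
    proportionality via the scaled-Schoenfeld score test; failing features
    are replaced by their squares and the model refit once.
    """
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ParameterError(f"features absent from table: {missing}")
    df = table[features + [duration_col, event_col]].copy()
    df[event_col] = df[event_col].astype(bool).astype(int)
    if df.isna().any().any():
        raise ParameterError("missing values in Cox model inputs")
    if df[event_col].sum() > 0 and df.loc[df[event_col] == 1, duration_col].nunique() == 1 and df[event_col].all():
        raise FitError("all events share one duration; partial likelihood is degenerate")

    if k_folds is not None and len(penalizer_grid) > 1:
        pen = _cv_penalizer(df, duration_col, event_col, penalizer_grid, k_folds, seed)
    else:
        pen = min(penalizer_grid)

    def _fit(frame: pd.DataFrame) -> CoxPHFitter:
        cph = CoxPHFitter(penalizer=pen)
        try:
            cph.fit(frame, duration_col=duration_col, event_col=event_col)
        except ConvergenceError as exc:
            raise FitError(f"Cox fit failed to converge: {exc}") from exc
        return cph

    cph = _fit(df)
    transformed: list[str] = []
    ph_pass: dict[str, bool] = {}
    original = df[features].copy()
    if check_ph:
        ph = proportional_hazard_test(cph, df, time_transform="rank")
        pvals = ph.summary["p"]
        for feat in features:
            pv = float(pvals.loc[feat]) if feat in pvals.index else 1.0
            ph_pass[feat] = pv >= 0.05
        failing = [f for f in features if not ph_pass[f]]
        if failing:
            logger.info("fit_cox: squaring non-proportional feature(s): %s", failing)
            for f in failing:
                df[f"{f}_sq"] = df[f] ** 2
                df = df.drop(columns=f)
                transformed.append(f)
            cph = _fit(df)

    summ = cph.summary
    return CoxFit(
        coefficients=summ["coef"],
        hazard_ratios=summ["exp(coef)"],
        ci_low=summ["exp(coef) lower 95%"],
        ci_high=summ["exp(coef) upper 95%"],
        p_values=summ["p"],
        penalizer=float(pen),
        ph_pass=ph_pass,
        transformed_features=transformed,
        model=cph,
        data=df,
        duration_col=duration_col,
        event_col=event_col,
        original=original,
    )


def partial_effect_curves(
    fit: CoxFit,
    feature: str,
    percentiles: tuple[float, float] = (10.0, 90.0),
    times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Cumulative-incidence curves at low/high values of one feature.

    Covariate rows are built at the feature's requested percentiles (on
    the original scale, squared if the feature was transformed) with every
    other feature at its mean. Returns a week-indexed table with one
    column per percentile; curves are non-decreasing.
    """
    for q in percentiles:
        if not (0.0 < q < 100.0):
            raise ParameterError(f"percentile must be in (0, 100), got {q}")
    if fit.model is None or fit.data is None:
        raise ParameterError("fit carries no model")
    model_cols = [c for c in fit.data.columns if c not in (fit.duration_col, fit.event_col)]
    col = f"{feature}_sq" if feature in fit.transformed_features else feature
    if col not in model_cols:
        raise ParameterError(f"feature {feature!r} not in the fitted model")
    base_vals = (
        fit.original[feature] if fit.original is not None and feature in fit.original else fit.data[col]
    )
    rows = []
    for q in percentiles:
        v = float(np.percentile(base_vals.to_numpy(float), q))
        row = fit.data[model_cols].mean()
        row[col] = v**2 if feature in fit.transformed_features else v
        rows.append(row)
    X = pd.DataFrame(rows, index=[f"p{int(q)}" for q in percentiles])
    sf = fit.model.predict_survival_function(X)
    if times is not None:
        # step-function semantics: survival is 1 before the first observed
        # event, constant between events
        sf = sf.reindex(sf.index.union(np.asarray(times, float))).ffill().fillna(1.0)
        sf = sf.loc[np.asarray(times, float)]
    ci = 1.0 - sf
    ci.columns = X.index
    ci.index.name = "ga_weeks"
    return ci
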