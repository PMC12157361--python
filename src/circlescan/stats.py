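"""Association and survival statistics for cohort tables.

Thin, opinionated wrappers exposing exactly what the pipeline needs:
standard and Firth-penalized logistic regression returning tidy
per-term results, Benjamini-Hochberg FDR, Mann-Whitney tests (exact by
enumeration at small n, mid-ranks for ties), 2x2 odds ratios with
Fisher's exact test, and Cox proportional hazards with Efron tie
handling. Standard logistic fits use statsmodels and Cox fits use
lifelines; the Firth penalization is implemented in
:mod:`circlescan.firth`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .firth import fit_firth_logistic_arrays

__all__ = [
    "AssociationResult",
    "SurvivalResult",
    "SeparationError",
    "fit_logistic",
    "fit_firth_logistic",
    "bh_fdr",
    "mann_whitney",
    "or_2x2",
    "fit_cox",
    "encode_amplification",
    "encode_feature",
    "run_association_suite",
]


class SeparationError(RuntimeError):
    """Raised when ML logistic estimates diverge (data separation)."""


@dataclass
class AssociationResult:
    term: str
    log_odds: float
    odds_ratio: float
    ci95: tuple[float, float]
    p: float
    q: float | None = None

    @classmethod
    def from_log_odds(cls, term, log_odds, ci_log, p):
        return cls(
            term=term,
            log_odds=float(log_odds),
            odds_ratio=float(math.exp(log_odds)),
            ci95=(float(math.exp(ci_log[0])), float(math.exp(ci_log[1]))),
            p=float(p),
        )


@dataclass
class SurvivalResult:
    term: str
    hazard_ratio: float
    ci95: tuple[float, float]
    p: float


def _design(X: pd.DataFrame | np.ndarray, add_intercept: bool):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = [f"x{j}" for j in range(mat.shape[1])]
    if add_intercept:
        mat = np.column_stack([np.ones(len(mat)), mat])
        names = ["intercept", *names]
    return mat, names


def fit_logistic(
    X, y, add_intercept: bool = True, include_intercept_in_results: bool = False
) -> list[AssociationResult]:
    """Maximum-likelihood logistic regression (Newton scoring, Wald CIs).

    Constant covariate columns and separated data raise errors; for
    separated data the error message points at the Firth variant.
    """
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    mat, names = _design(X, add_intercept)
    y = np.asarray(y, dtype=float)
    start = 1 if (add_intercept and not include_intercept_in_results) else 0
    for j in range(1 if add_intercept else 0, mat.shape[1]):
        if np.ptp(mat[:, j]) == 0:
            raise ValueError(f"covariate column {names[j]!r} is constant")
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            fit = sm.Logit(y, mat).fit(disp=0, method="newton", tol=1e-8,
                                       maxiter=200)
    except Exception as exc:  # statsmodels PerfectSeparationError and kin
        raise SeparationError(
            f"logistic fit failed ({exc}); data may be separated — "
            "consider fit_firth_logistic"
        ) from exc
    if not np.all(np.isfinite(fit.bse)) or np.max(np.abs(fit.params)) > 1e2:
        raise SeparationError(
            "non-finite or diverging estimates indicate separation — "
            "consider fit_firth_logistic"
        )
    ci = fit.conf_int()
    return [
        AssociationResult.from_log_odds(names[j], fit.params[j], ci[j],
                                        fit.pvalues[j])
        for j in range(start, mat.shape[1])
    ]


def fit_firth_logistic(
    X, y, add_intercept: bool = True, include_intercept_in_results: bool = False,
    profile_ci: bool = True,
) -> list[AssociationResult]:
    """Firth-penalized logistic regression; finite under separation."""
    mat, names = _design(X, add_intercept)
    res = fit_firth_logistic_arrays(mat, np.asarray(y, dtype=float), names=names,
                                    profile_ci=profile_ci)
    start = 1 if (add_intercept and not include_intercept_in_results) else 0
    return [
        AssociationResult.from_log_odds(
            res.names[j], res.params[j], res.conf_int[j], res.pvalues[j]
        )
        for j in range(start, mat.shape[1])
    ]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x (mid-ranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = ranks[: len(x)].sum()
    return r_x - len(x) * (len(x) + 1) / 2.0


EXACT_MW_MAX_N = 12


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney test.

    For n_x + n_y <= 12 the p-value is exact, by enumerating all
    assignments of the pooled mid-ranks to the two groups; larger
    samples use the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = len(x), len(y)
    u_obs = _u_statistic(x, y)
    mu = n_x * n_y / 2.0

    if n_x + n_y <= EXACT_MW_MAX_N:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        dev_obs = abs(u_obs - mu)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n_x + n_y), n_x):
            r_x = ranks[list(idx)].sum()
            u = r_x - n_x * (n_x + 1) / 2.0
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
        return u_obs, count / total

    # normal approximation with tie correction
    pooled = np.concatenate([x, y])
    n = n_x + n_y
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    sigma2 = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u_obs, 1.0
    z = (u_obs - mu) / math.sqrt(sigma2)
    return u_obs, float(2.0 * sps.norm.sf(abs(z)))


def or_2x2(a: int, b: int, c: int, d: int, method: str = "sample"):
    """2x2 odds ratio with p-value.

    ``sample`` returns the cross-product ratio ad/bc (0.5 added to every
    cell iff any cell is zero) with Fisher's exact p; ``fisher_exact``
    returns the conditional ML odds ratio with the exact p. The exact
    two-sided p sums all tables with probability <= the observed one.
    """
    counts = (a, b, c, d)
    if any(v < 0 for v in counts):
        raise ValueError("counts must be non-negative")
    if sum(counts) == 0:
        raise ValueError("all-zero table")
    table = [[a, b], [c, d]]
    fisher = sps.fisher_exact(table, alternative="two-sided")
    if method == "sample":
        if 0 in counts:
            a2, b2, c2, d2 = (v + 0.5 for v in counts)
        else:
            a2, b2, c2, d2 = counts
        return (a2 * d2) / (b2 * c2), float(fisher.pvalue)
    if method == "fisher_exact":
        return float(fisher.statistic), float(fisher.pvalue)
    raise ValueError(f"unknown method {method!r}")


AMPLIFICATION_LEVELS = ("ecdna", "other_focal", "none")


def encode_amplification(
    amp_class: pd.Series, reference: str = "other_focal"
) -> pd.DataFrame:
    """Dummy-encode the three-level amplification factor.

    The default reference level is "other focal amplification" so the
    ecDNA coefficient is the ecDNA-vs-chromosomal-amplification
    contrast.
    """
    levels = [lvl for lvl in AMPLIFICATION_LEVELS if lvl != reference]
    bad = set(amp_class.unique()) - set(AMPLIFICATION_LEVELS)
    if bad:
        raise ValueError(f"unknown amplification levels {sorted(bad)}")
    return pd.DataFrame(
        {f"amp_{lvl}": (amp_class == lvl).astype(float) for lvl in levels},
        index=amp_class.index,
    )


def fit_cox(
    df: pd.DataFrame,
    covariates: list[str],
    time_col: str = "time",
    event_col: str = "event",
) -> list[SurvivalResult]:
    """Cox proportional hazards (Efron ties) with Wald CIs via lifelines."""
    from lifelines import CoxPHFitter

    if df[event_col].sum() == 0:
        raise ValueError("no events in the data")
    if (df[time_col] <= 0).any():
        raise ValueError("survival times must be positive")
    data = df[[time_col, event_col, *covariates]].astype(float)
    cph = CoxPHFitter()
    cph.fit(data, duration_col=time_col, event_col=event_col,
            fit_options={"precision": 1e-9, "max_steps": 500})
    summary = cph.summary
    return [
        SurvivalResult(
            term=term,
            hazard_ratio=float(row["exp(coef)"]),
            ci95=(
                float(np.exp(row["coef lower 95%"])),
                float(np.exp(row["coef upper 95%"])),
            ),
            p=float(row["p"]),
        )
        for term, row in summary.iterrows()
    ]


def encode_feature(values: pd.Series) -> pd.Series:
    """Encode a numeric feature the way prevalence dictates.

    Features present (non-zero) in fewer than half the samples become
    present/absent indicators; features present in at least half become
    above/below-median indicators.
    """
    values = pd.to_numeric(values)
    present = values != 0
    if present.mean() < 0.5:
        return present.astype(float).rename(values.name)
    return (values > values.median()).astype(float).rename(values.name)


def run_association_suite(
    cohort: pd.DataFrame, models: list[dict]
) -> pd.DataFrame:
    """Fit a list of logistic models and FDR-adjust within each family.

    Each model spec is a mapping with keys ``name``, ``outcome``
    (binary column), ``terms`` (list of {col, encode} where encode is
    one of continuous/binary/feature/categorical) and optional
    ``method`` ("standard", the default, or "firth"). q-values are
    computed per model family (the ``name``).
    """
    rows = []
    for spec in models:
        name = spec["name"]
        outcome = cohort[spec["outcome"]].astype(float)
        pieces = []
        for term in spec["terms"]:
            col, encode = term["col"], term.get("encode", "continuous")
            if col not in cohort.columns:
                raise ValueError(f"missing covariate column {col!r}")
            series = cohort[col]
            if encode == "continuous":
                pieces.append(pd.to_numeric(series).astype(float).rename(col))
            elif encode == "binary":
                pieces.append(series.astype(float).rename(col))
            elif encode == "feature":
                pieces.append(encode_feature(series))
            elif encode == "categorical":
                dummies = pd.get_dummies(series, prefix=col, drop_first=True)
                pieces.extend(dummies[c].astype(float) for c in dummies.columns)
            else:
                raise ValueError(f"unknown encoding {encode!r}")
        X = pd.concat(pieces, axis=1)
        fitter = (
            fit_firth_logistic if spec.get("method") == "firth" else fit_logistic
        )
        results = fitter(X, outcome)
        for res in results:
            rows.append(
                {
                    "model": name,
                    "term": res.term,
                    "log_odds": res.log_odds,
                    "odds_ratio": res.odds_ratio,
                    "ci_low": res.ci95[0],
                    "ci_high": res.ci95[1],
                    "p": res.p,
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["q"] = np.nan
        for name, idx in table.groupby("model").groups.items():
            table.loc[idx, "q"] = bh_fdr(table.loc[idx, "p"].to_numpy())
    return table
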