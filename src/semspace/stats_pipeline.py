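"""Inferential machinery: covariate screening, GLMs, FDR, replication.

The analysis sequence mirrors the study design it serves:

1. **Covariate screening.** Each semantic measure is correlated with the
   candidate covariates (age, sex, education, word TTR, word count) by
   Spearman *partial* correlation controlling for language and group,
   on the pooled two-language table.  The resulting p-values are
   Benjamini-Hochberg corrected jointly across all measure x candidate
   pairs, and candidates with q < 0.05 enter that measure's models.
2. **Group GLMs.** Per measure and per dataset,
   ``measure ~ group + covariates``.  Every model is first fit as
   Gaussian/identity; if the deviance goodness-of-fit test (deviance vs
   chi-square with residual df) rejects at 0.05 and the response is
   strictly positive, the model is refit as Gamma/log (in practice this
   is triggered by the positively skewed perplexity).  Group-term
   p-values are FDR-corrected across measures within each dataset.
3. **MMSE GLMs** within the pAD group: ``measure ~ MMSE + covariates``,
   FDR within dataset.
4. **Crosslingual replication.** An English effect counts as replicated
   in Greek when the coefficients share a sign and the English
   coefficient lies inside the Greek 95% confidence interval.

Coding conventions: female = 1 / male = 0; pAD = 1 / NC = 0; Greek
(``el``) = 1 / English = 0; MMSE entered raw.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .semantic_metrics import MEASURE_COLUMNS

logger = logging.getLogger(__name__)

DEFAULT_CANDIDATES = ("age", "sex_female", "education", "word_ttr", "word_count")


class FitError(ValueError):
    """Raised when a GLM cannot be fit (singular design, bad response)."""


@dataclass(frozen=True)
class TermResult:
    coef: float
    se: float
    z: float
    p: float
    ci_low: float
    ci_high: float
    q: float = math.nan


@dataclass
class RegressionResult:
    """Fitted GLM summary for one measure."""

    measure: str
    family: str  # "gaussian_identity" or "gamma_log"
    terms: dict[str, TermResult]
    gof_p: float
    n: int
    focal_term: str = "group_pad"

    @property
    def focal(self) -> TermResult:
        return self.terms[self.focal_term]


@dataclass(frozen=True)
class ReplicationVerdict:
    measure: str
    term: str
    coef_en: float
    coef_el: float
    ci_el: tuple[float, float]
    sign_match: bool
    ci_containment: bool

    @property
    def replicated(self) -> bool:
        return self.sign_match and self.ci_containment


# ---------------------------------------------------------------------------
# multiple-testing correction


def fdr_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Spearman partial correlation


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Spearman correlation of ``x`` and ``y`` given rank covariates.

    All variables are rank-transformed, the covariates (plus intercept)
    are projected out of the ranked ``x`` and ``y``, and the Pearson
    correlation of the residuals is tested with the t approximation on
    ``n - k - 2`` degrees of freedom (k = number of covariates).
    Returns ``(nan, nan)`` when x or y is constant after ranking.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    cov = np.empty((n, 0)) if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    if cov.shape[0] != n:
        cov = cov.T
    if cov.shape[0] != n:
        raise ValueError("covariate rows must match x")
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} observations, got {n}")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return math.nan, math.nan
    design = np.column_stack([np.ones(n)] + [stats.rankdata(cov[:, j]) for j in range(k)])
    res_x = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    res_y = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    denom = np.linalg.norm(res_x) * np.linalg.norm(res_y)
    if denom == 0.0:
        return math.nan, math.nan
    rho = float(np.clip(res_x @ res_y / denom, -1.0, 1.0))
    df = n - k - 2
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt(df / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return rho, float(p)


def screen_covariates(
    features: pd.DataFrame,
    measures: Sequence[str] = MEASURE_COLUMNS,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    alpha: float = 0.05,
) -> tuple[dict[str, tuple[str, ...]], pd.DataFrame]:
    """Select per-measure covariates by partial Spearman + joint FDR.

    ``features`` is the pooled table (both languages) with
    ``language_el`` and ``group_pad`` columns, which are controlled for
    in every correlation.  Returns the per-measure selected-candidate
    sets and the full screening table (rho, p, q per pair).
    """
    controls = [c for c in ("language_el", "group_pad") if features[c].nunique() > 1]
    rows = []
    for measure in measures:
        for cand in candidates:
            sub = features[[measure, cand, *controls]].dropna()
            if len(sub) <= len(controls) + 2 or sub[cand].nunique() < 2:
                continue
            rho, p = partial_spearman(
                sub[measure].to_numpy(),
                sub[cand].to_numpy(),
                sub[controls].to_numpy() if controls else None,
            )
            if math.isnan(p):
                continue
            rows.append({"measure": measure, "candidate": cand, "rho": rho, "p": p})
    table = pd.DataFrame(rows, columns=["measure", "candidate", "rho", "p"])
    if len(table):
        table["q"] = fdr_adjust(table["p"].to_numpy())
    else:
        table["q"] = []
    selected = {
        m: tuple(table.loc[(table["measure"] == m) & (table["q"] < alpha), "candidate"])
        for m in measures
    }
    return selected, table


# ---------------------------------------------------------------------------
# GLM fitting


def _check_design(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # name the offending terms: columns linearly dependent on the rest
        bad = []
        for j, name in enumerate(design.columns):
            others = np.delete(x, j, axis=1)
            beta, *_ = np.linalg.lstsq(others, x[:, j], rcond=None)
            if np.allclose(others @ beta, x[:, j], atol=1e-8):
                bad.append(name)
        raise FitError(f"singular design matrix; collinear terms: {bad or list(design.columns)}")


def fit_glm(
    measure: Sequence[float],
    predictors: pd.DataFrame,
    family: str = "auto",
    measure_name: str = "measure",
    focal_term: str | None = None,
    gof_alpha: float = 0.05,
) -> RegressionResult:
    """Fit ``measure ~ intercept + predictors`` as a GLM.

    ``family="auto"`` fits Gaussian/identity first and switches to
    Gamma/log only when the deviance goodness-of-fit test rejects at
    ``gof_alpha`` *and* the response is strictly positive.  Coefficient
    inference is Wald (z and normal-based 95% CI).
    """
    y = np.asarray(measure, dtype=float)
    if family not in ("auto", "gaussian_identity", "gamma_log"):
        raise ValueError(f"unknown family {family!r}")
    design = sm.add_constant(predictors.astype(float), has_constant="add")
    if len(y) <= design.shape[1] + 1:
        raise FitError(f"too few observations ({len(y)}) for {design.shape[1]} terms")
    _check_design(design)

    def _fit(fam) -> sm.GLM:
        return sm.GLM(y, design, family=fam).fit()

    if family == "gamma_log" and np.any(y <= 0):
        raise FitError("gamma_log requires a strictly positive response")

    chosen = family
    if family in ("auto", "gaussian_identity"):
        res = _fit(sm.families.Gaussian())
        chosen = "gaussian_identity"
        gof_p = float(stats.chi2.sf(res.deviance, res.df_resid))
        if family == "auto" and gof_p < gof_alpha and np.all(y > 0):
            res = _fit(sm.families.Gamma(link=sm.families.links.Log()))
            chosen = "gamma_log"
            gof_p = float(stats.chi2.sf(res.deviance, res.df_resid))
    else:
        res = _fit(sm.families.Gamma(link=sm.families.links.Log()))
        chosen = "gamma_log"
        gof_p = float(stats.chi2.sf(res.deviance, res.df_resid))

    ci = res.conf_int()
    terms = {
        name: TermResult(
            coef=float(res.params[name]),
            se=float(res.bse[name]),
            z=float(res.tvalues[name]),
            p=float(res.pvalues[name]),
            ci_low=float(ci.loc[name, 0]),
            ci_high=float(ci.loc[name, 1]),
        )
        for name in design.columns
    }
    focal = focal_term or (predictors.columns[0] if len(predictors.columns) else "const")
    return RegressionResult(
        measure=measure_name,
        family=chosen,
        terms=terms,
        gof_p=gof_p,
        n=len(y),
        focal_term=focal,
    )


# ---------------------------------------------------------------------------
# per-dataset analyses


def _run_measure_models(
    features: pd.DataFrame,
    focal: str,
    measures: Sequence[str],
    screened: Mapping[str, Sequence[str]] | None,
    gof_alpha: float,
) -> tuple[list[RegressionResult], dict[str, str]]:
    screened = screened or {}
    results: list[RegressionResult] = []
    failures: dict[str, str] = {}
    for measure in measures:
        if measure not in features.columns:
            continue
        covs = [c for c in screened.get(measure, ()) if c != focal]
        if measure == "ppl" and "subword_ttr" not in covs:
            # perplexity is confounded with subword lexical diversity, which
            # is always regressed out of the PPL models
            covs = [*covs, "subword_ttr"]
        cols = [measure, focal, *covs]
        sub = features[cols].dropna()
        if sub.empty or sub[measure].isna().all():
            failures[measure] = "no complete cases"
            continue
        try:
            results.append(
                fit_glm(
                    sub[measure].to_numpy(),
                    sub[[focal, *covs]],
                    family="auto",
                    measure_name=measure,
                    focal_term=focal,
                    gof_alpha=gof_alpha,
                )
            )
        except (FitError, ValueError) as exc:
            failures[measure] = str(exc)
            logger.warning("model for %s failed: %s", measure, exc)
    # FDR across measures within the dataset, on the focal-term p-values
    if results:
        qvals = fdr_adjust([r.focal.p for r in results])
        for r, q in zip(results, qvals):
            r.terms[r.focal_term] = dataclasses.replace(r.focal, q=float(q))
    return results, failures


def run_group_analysis(
    features: pd.DataFrame,
    screened: Mapping[str, Sequence[str]] | None = None,
    measures: Sequence[str] = MEASURE_COLUMNS,
    gof_alpha: float = 0.05,
) -> tuple[list[RegressionResult], dict[str, str]]:
    """Group-difference GLMs for one dataset (one language).

    One ``measure ~ group + screened covariates`` model per measure;
    the PPL model always additionally adjusts for subword TTR.  Focal
    (group) p-values are FDR-corrected across measures.  Per-measure
    failures are reported, never raised.
    """
    return _run_measure_models(features, "group_pad", measures, screened, gof_alpha)


def run_mmse_analysis(
    features: pd.DataFrame,
    screened: Mapping[str, Sequence[str]] | None = None,
    measures: Sequence[str] = MEASURE_COLUMNS,
    gof_alpha: float = 0.05,
) -> tuple[list[RegressionResult], dict[str, str]]:
    """MMSE GLMs within the pAD group of one dataset."""
    pad = features[features["group_pad"] == 1]
    return _run_measure_models(pad, "mmse", measures, screened, gof_alpha)


# ---------------------------------------------------------------------------
# crosslingual replication


def _sign_match(a: float, b: float) -> bool:
    # a zero coefficient matches either sign (non-strict)
    return a == 0.0 or b == 0.0 or (a > 0) == (b > 0)


def assess_replication(
    english: RegressionResult, greek: RegressionResult, term: str
) -> ReplicationVerdict:
    """Replicated = same coefficient sign AND English coefficient inside
    the Greek 95% CI."""
    for res in (english, greek):
        if term not in res.terms:
            raise KeyError(f"term {term!r} absent from model for {res.measure!r}")
    b_en = english.terms[term].coef
    t_el = greek.terms[term]
    return ReplicationVerdict(
        measure=english.measure,
        term=term,
        coef_en=b_en,
        coef_el=t_el.coef,
        ci_el=(t_el.ci_low, t_el.ci_high),
        sign_match=_sign_match(b_en, t_el.coef),
        ci_containment=t_el.ci_low <= b_en <= t_el.ci_high,
    )


# ---------------------------------------------------------------------------
# tabular export


def results_to_frame(results: Sequence[RegressionResult], dataset: str = "") -> pd.DataFrame:
    rows = []
    for r in results:
        for name, t in r.terms.items():
            rows.append(
                {
                    "dataset": dataset,
                    "measure": r.measure,
                    "family": r.family,
                    "term": name,
                    "coef": t.coef,
                    "se": t.se,
                    "z": t.z,
                    "p": t.p,
                    "q": t.q,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "gof_p": r.gof_p,
                    "n": r.n,
                }
            )
    return pd.DataFrame(rows)


def verdicts_to_frame(verdicts: Sequence[ReplicationVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "measure": v.measure,
                "term": v.term,
                "coef_en": v.coef_en,
                "coef_el": v.coef_el,
                "ci_el_low": v.ci_el[0],
                "ci_el_high": v.ci_el[1],
                "sign_match": v.sign_match,
                "ci_containment": v.ci_containment,
                "replicated": v.replicated,
            }
            for v in verdicts
        ]
    )
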