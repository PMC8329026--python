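"""Mixed-model comparisons and the correlation screen.

The study design compares behavioural measures across a condition factor
(fragmented vs non-fragmented instruction, or fragment sequence Utt-1..4)
and participant role (instructor vs builder), with random intercepts
absorbing interaction-level and instructed-object-level variance, and
participant-level variance for pupil responses.

Every model is fitted by maximum likelihood (not REML), because fixed-effect
structures are compared across fits.  Each fixed term is tested by a
likelihood-ratio chi-square between nested fits: main effects are tested by
dropping them from the main-effects model, and the interaction is tested
against the two-main-effects model.  Degrees of freedom equal the number of
fixed-effect columns the term adds.

The exploratory screen correlates each measure with the number of fragments
per instruction (Spearman rho, midrank ties), Bonferroni-adjusts the
p-values, and flags for reporting only coefficients with |rho| > 0.15 that
survive adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .core import CorrelationResult, StatsResult, ValidationError


@dataclass
class ModelSpec:
    """One mixed-model analysis: response, fixed factors, random intercepts.

    ``fixed`` lists factor column names; an interaction is written
    ``"a:b"``.  ``random_intercepts`` lists grouping columns (e.g.
    interaction_id, referent_id, participant_id).
    """

    response: str
    fixed: list[str]
    random_intercepts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.fixed:
            raise ValidationError("at least one fixed factor is required")

    @property
    def main_effects(self) -> list[str]:
        return [f for f in self.fixed if ":" not in f]

    @property
    def interactions(self) -> list[str]:
        return [f for f in self.fixed if ":" in f]


def _formula(response: str, terms: Sequence[str]) -> str:
    if not terms:
        return f"{response} ~ 1"
    parts = []
    for term in terms:
        if ":" in term:
            a, b = term.split(":")
            parts.append(f"C({a}):C({b})")
        else:
            parts.append(f"C({term})")
    return f"{response} ~ " + " + ".join(parts)


def _fit_ml(formula: str, df: pd.DataFrame, random: Sequence[str],
            log: list[str]) -> tuple[float, int]:
    """ML fit; returns (log-likelihood, number of fixed-effect columns).

    One random intercept uses it as the grouping factor directly; several
    are encoded as crossed variance components over a single trivial group.
    A singular or non-converging fit falls back to a reduced random
    structure, logged; exhausting all structures raises with diagnostics.
    """
    attempts: list[list[str]] = [list(random)]
    for k in range(len(random) - 1, -1, -1):
        attempts.append(list(random[:k]))
    last_err: Exception | None = None
    for attempt in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)
                if not attempt:
                    res = smf.ols(formula, data=df).fit()
                    return float(res.llf), int(res.model.exog.shape[1])
                if len(attempt) == 1:
                    model = MixedLM.from_formula(
                        formula, data=df, groups=df[attempt[0]].astype(str))
                else:
                    vc = {r: f"0 + C({r})" for r in attempt[1:]}
                    model = MixedLM.from_formula(
                        formula, data=df, groups=df[attempt[0]].astype(str),
                        re_formula="1", vc_formula=vc)
                res = None
                for method in (None, "powell", "lbfgs"):
                    kwargs = {} if method is None else {"method": method,
                                                        "maxiter": 500}
                    try:
                        cand = model.fit(reml=False, **kwargs)
                    except Exception:
                        continue
                    if np.isfinite(cand.llf):
                        res = cand
                        break
            if res is None:
                raise RuntimeError("no optimizer reached a finite log-likelihood")
            if attempt != list(random):
                log.append(
                    f"random structure reduced from {list(random)} to {attempt} "
                    f"for '{formula}'")
            return float(res.llf), int(res.model.exog.shape[1])
        except Exception as err:   # singular fit, LinAlgError, etc.
            last_err = err
            continue
    raise ValidationError(
        f"mixed model failed to converge for '{formula}' with random "
        f"intercepts {list(random)}: {last_err}")


def fit_and_test(rows: pd.DataFrame, spec: ModelSpec) -> StatsResult:
    """Fit the design and test each fixed term by a likelihood-ratio test.

    Rows with an undefined (NaN) response are dropped listwise.  Requires
    at least two observed levels per fixed factor.
    """
    cols = {spec.response, *{c for f in spec.fixed for c in f.split(":")}}
    missing = cols - set(rows.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    df = rows.dropna(subset=[spec.response]).copy()
    if df.empty:
        raise ValidationError(f"no complete rows for response {spec.response!r}")
    factor_cols = sorted({c for f in spec.fixed for c in f.split(":")})
    for c in factor_cols:
        if df[c].nunique() < 2:
            raise ValidationError(f"fixed factor {c!r} has fewer than 2 levels")

    log: list[str] = []
    mains = spec.main_effects
    inters = spec.interactions
    terms: dict[str, tuple[float, int, float]] = {}

    # Standardize the response for the fits: the LRT is invariant to affine
    # rescaling, and unit scale keeps the optimizer well conditioned for
    # responses of very small magnitude (e.g. slopes in mm/frame).
    fit_df = df.copy()
    sd = float(fit_df[spec.response].std(ddof=0))
    if sd == 0:
        # a constant response carries no evidence for any term
        factor_cols0 = sorted({c for f in spec.fixed for c in f.split(":")})
        terms = {f: (0.0, 1, 1.0) for f in spec.fixed}
        return StatsResult(
            response=spec.response, terms=terms,
            cell_summary=summarize_cells(df, spec.response, factor_cols0),
            model=f"{spec.response} ~ constant", warnings=["constant response"])
    fit_df[spec.response] = (fit_df[spec.response]
                             - fit_df[spec.response].mean()) / sd

    ll_main, k_main = _fit_ml(_formula(spec.response, mains), fit_df,
                              spec.random_intercepts, log)
    for m in mains:
        reduced = [f for f in mains if f != m]
        ll_red, k_red = _fit_ml(_formula(spec.response, reduced), fit_df,
                                spec.random_intercepts, log)
        chi2 = max(0.0, 2.0 * (ll_main - ll_red))
        dof = k_main - k_red
        p = float(sps.chi2.sf(chi2, dof)) if dof > 0 else 1.0
        terms[m] = (chi2, dof, max(p, 1e-300))
    for inter in inters:
        ll_full, k_full = _fit_ml(_formula(spec.response, mains + [inter]),
                                  fit_df, spec.random_intercepts, log)
        chi2 = max(0.0, 2.0 * (ll_full - ll_main))
        dof = k_full - k_main
        p = float(sps.chi2.sf(chi2, dof)) if dof > 0 else 1.0
        terms[inter] = (chi2, dof, max(p, 1e-300))

    cells = summarize_cells(df, spec.response, factor_cols)
    desc = (f"{spec.response} ~ {' + '.join(spec.fixed)} "
            f"+ (1 | {', '.join(spec.random_intercepts) or 'none'}), ML")
    return StatsResult(response=spec.response, terms=terms, cell_summary=cells,
                       model=desc, warnings=log)


def summarize_cells(rows: pd.DataFrame, response: str,
                    factors: Sequence[str]) -> pd.DataFrame:
    """Unweighted per-cell mean, sample SD, and n for one response.

    Cells with a single row report an empty (NaN) SD; cells with no rows are
    simply absent, never zero-filled.
    """
    df = rows.dropna(subset=[response])
    grouped = df.groupby(list(factors), observed=True)[response]
    out = grouped.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count")
    return out.reset_index()


def correlation_screen(
    per_instruction: pd.DataFrame,
    measures: Sequence[str],
    fragments_col: str = "n_fragments",
    bonferroni_m: Optional[int] = None,
    alpha: float = 0.05,
    rho_threshold: float = 0.15,
) -> list[CorrelationResult]:
    """Spearman screen of each measure against fragment count.

    ``bonferroni_m`` defaults to the number of measures actually screened.
    Constant measures have no defined rank correlation; they are returned
    with rho = NaN and a note, never a reported flag.
    """
    if len(per_instruction) < 3:
        raise ValidationError("correlation screen needs at least 3 instructions")
    m = bonferroni_m if bonferroni_m is not None else len(measures)
    results: list[CorrelationResult] = []
    for name in measures:
        sub = per_instruction[[name, fragments_col]].dropna()
        if len(sub) < 3:
            results.append(CorrelationResult(
                measure=name, rho=float("nan"), p_adjusted=1.0, reported=False,
                n=len(sub), note="fewer than 3 complete instructions"))
            continue
        if sub[name].nunique() == 1 or sub[fragments_col].nunique() == 1:
            results.append(CorrelationResult(
                measure=name, rho=float("nan"), p_adjusted=1.0, reported=False,
                n=len(sub), note="constant variable; rho undefined"))
            continue
        rho, p = sps.spearmanr(sub[name], sub[fragments_col])
        p_adj = min(1.0, float(p) * m)
        reported = bool(abs(rho) > rho_threshold and p_adj < alpha)
        results.append(CorrelationResult(
            measure=name, rho=float(rho), p_adjusted=p_adj, reported=reported,
            n=len(sub)))
    return results
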