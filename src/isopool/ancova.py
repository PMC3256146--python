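"""Paired-covariate ANCOVA of competition responses.

Each response of the competing Dactylis (per-ion N uptake, RGR, biomass) is
regressed on the same metric for the isolated Dactylis paired from the same
block (the covariate), with location and fertiliser — plus harvest for
biomass — as fixed effects and all two-way interactions. The full model is
then simplified backwards: the least-significant interaction term (by
nested-model F comparison) is removed while its comparison p exceeds alpha;
main effects are never removed. Coefficients are reported under treatment
contrasts; sequential (type-I) F tables, residual diagnostics and the
simplification trail accompany every fit.

Block is deliberately kept out of the main models and tested separately
against each response. The 1:1-line summary classifies each treatment cell
as below / on / above the line of equality (competition / no net
interaction / facilitation) with a paired test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import het_breuschpagan

from .errors import ValidationError


@dataclass
class AncovaResult:
    """Fitted and simplified ANCOVA with its audit trail."""

    final_formula: str
    coefficients: pd.DataFrame
    anova_table: pd.DataFrame
    simplification_trail: list[dict] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    transformation_applied: str = "none"
    dropped_factors: list[str] = field(default_factory=list)
    model: object = None            # statsmodels results of the final model
    full_model: object = None       # statsmodels results of the full model


def _term_lists(factors: list[str], covariate: str) -> tuple[list[str], list[str]]:
    """Canonical main-effect and two-way-interaction term order."""
    mains = [covariate] + [f"C({f})" for f in factors]
    interactions = [f"{a}:{b}" for a, b in itertools.combinations(mains, 2)]
    return mains, interactions


def _fit(response: str, terms: list[str], data: pd.DataFrame):
    formula = f"{response} ~ " + " + ".join(terms) if terms else f"{response} ~ 1"
    return smf.ols(formula, data=data).fit()


def _check_rank(fit, terms) -> None:
    exog = fit.model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        raise ValidationError(
            f"rank-deficient design ({rank} < {exog.shape[1]} columns); "
            f"aliased terms among: {terms}")


def _backward_eliminate(response: str, mains: list[str],
                        interactions: list[str], data: pd.DataFrame,
                        alpha: float):
    """Remove interactions by largest comparison p while p > alpha.

    Exact ties are broken towards the term latest in canonical order, so
    the trail is fully deterministic.
    """
    current = list(interactions)
    trail: list[dict] = []
    step = 0
    while current:
        full = _fit(response, mains + current, data)
        comparisons = []
        for term in current:
            reduced_terms = mains + [t for t in current if t != term]
            reduced = _fit(response, reduced_terms, data)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmp_tab = anova_lm(reduced, full)
            p = float(cmp_tab["Pr(>F)"].iloc[1])
            ss_diff = float(cmp_tab["ss_diff"].iloc[1])
            tss = float(full.centered_tss)
            if np.isnan(p) or ss_diff < 1e-10 * max(tss, 1e-300):
                # numerically-zero contribution (e.g. exact fit): the term
                # adds nothing an F comparison can detect
                p = 1.0
            comparisons.append((term, p))
        worst_p = max(p for _, p in comparisons)
        if not (worst_p > alpha):
            break
        # tie-break: latest in canonical order among the maximal p-values
        candidates = [t for t, p in comparisons if p == worst_p]
        victim = max(candidates, key=interactions.index)
        step += 1
        trail.append({"step": step, "removed": victim, "p_value": worst_p})
        current.remove(victim)
    return current, trail


def residual_checks(fit, alpha: float = 0.05) -> dict:
    """Normality (Shapiro–Wilk) and heteroscedasticity (Breusch–Pagan).

    Returns the test statistics/p-values and, when either check fails at
    ``alpha``, recommends a natural-log transformation of response and
    covariate (the standard variance-stabilising choice for positive,
    multiplicative ecological data).
    """
    resid = np.asarray(fit.resid)
    sh_stat, sh_p = scipy.stats.shapiro(resid)
    bp_stat, bp_p, _, _ = het_breuschpagan(resid, fit.model.exog)
    out = {"shapiro_stat": float(sh_stat), "shapiro_p": float(sh_p),
           "breusch_pagan_stat": float(bp_stat),
           "breusch_pagan_p": float(bp_p),
           "normality_ok": sh_p >= alpha, "homoscedastic": bp_p >= alpha}
    out["recommend_log"] = not (out["normality_ok"] and out["homoscedastic"])
    return out


def fit_ancova(data: pd.DataFrame, response: str = "response",
               covariate: str = "covariate",
               factors: tuple[str, ...] = ("location", "fertiliser"),
               include_harvest: bool = False, alpha: float = 0.05,
               transform: str = "auto") -> AncovaResult:
    """Fit, simplify and diagnose one competition ANCOVA.

    Parameters
    ----------
    data : DataFrame
        Complete response/covariate pairs with the factor columns.
    include_harvest : bool
        Add harvest as a fixed effect (used for the biomass response, where
        both harvests contribute points).
    alpha : float
        Threshold for interaction removal, diagnostics and transformation.
    transform : str
        ``"auto"`` applies a log transform (to response and covariate) and
        refits once when diagnostics fail and all values are positive;
        ``"none"`` and ``"log"`` force the choice.
    """
    data = data.dropna(subset=[response, covariate]).copy()
    factor_list = list(factors) + (["harvest"] if include_harvest else [])
    dropped = [f for f in factor_list if data[f].nunique() < 2]
    factor_list = [f for f in factor_list if f not in dropped]

    def _run(df: pd.DataFrame) -> tuple:
        mains, interactions = _term_lists(factor_list, covariate)
        full = _fit(response, mains + interactions, df)
        _check_rank(full, mains + interactions)
        if full.df_resid < 2:
            raise ValidationError(
                f"only {full.df_resid:.0f} residual df in the full model")
        kept, trail = _backward_eliminate(response, mains, interactions,
                                          df, alpha)
        final = _fit(response, mains + kept, df)
        return full, final, trail, mains + kept

    full, final, trail, final_terms = _run(data)
    diagnostics = residual_checks(final, alpha)
    applied = "none"
    want_log = (transform == "log"
                or (transform == "auto" and diagnostics["recommend_log"]))
    if want_log:
        if (data[response] > 0).all() and (data[covariate] > 0).all():
            logged = data.copy()
            logged[response] = np.log(logged[response])
            logged[covariate] = np.log(logged[covariate])
            full, final, trail, final_terms = _run(logged)
            diagnostics = residual_checks(final, alpha)
            applied = "log"
        else:
            diagnostics["note"] = ("log transformation recommended but "
                                   "suppressed: non-positive values present")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seq = anova_lm(final, typ=1)
    coef = pd.DataFrame({"estimate": final.params, "se": final.bse,
                         "t": final.tvalues, "p": final.pvalues})
    return AncovaResult(
        final_formula=f"{response} ~ " + " + ".join(final_terms),
        coefficients=coef, anova_table=seq, simplification_trail=trail,
        diagnostics=diagnostics, transformation_applied=applied,
        dropped_factors=dropped, model=final, full_model=full)


def block_check(data: pd.DataFrame, responses: list[str],
                block: str = "block", alpha: float = 0.05) -> pd.DataFrame:
    """One-way test of block against each response (report only).

    Block never enters the main models; this reports the per-response
    F-test p-value so a strong spatial effect would be noticed. A single
    observed block yields a warning row with NaN p.
    """
    rows = []
    for resp in responses:
        sub = data.dropna(subset=[resp])
        if sub[block].nunique() < 2:
            warnings.warn(f"block check skipped for {resp}: <2 blocks",
                          stacklevel=2)
            rows.append({"response": resp, "f_stat": np.nan, "p": np.nan,
                         "significant": False, "note": "single block"})
            continue
        fit = smf.ols(f"{resp} ~ C({block})", data=sub).fit()
        p = float(fit.f_pvalue) if np.isfinite(fit.fvalue) else 1.0
        rows.append({"response": resp, "f_stat": float(fit.fvalue), "p": p,
                     "significant": p < alpha, "note": ""})
    return pd.DataFrame(rows)


def one_to_one_summary(data: pd.DataFrame, response: str = "response",
                       covariate: str = "covariate",
                       by: tuple[str, ...] = ("location", "fertiliser"),
                       alpha: float = 0.05) -> pd.DataFrame:
    """Classify each treatment cell against the line of equality.

    Per cell: mean ± SE of response and covariate and a paired t-test of
    their difference. Cells significantly below the 1:1 line indicate
    competition (the competing plant captures less than its isolated
    counterpart), above the line facilitation, otherwise "on" the line.
    """
    rows = []
    for key, grp in data.dropna(subset=[response, covariate]).groupby(
            list(by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        diff = grp[response].to_numpy() - grp[covariate].to_numpy()
        n = len(diff)
        mean_diff = float(np.mean(diff)) if n else np.nan
        if n < 2 or np.allclose(diff, diff[0]):
            # degenerate: no variance in the paired differences
            p = 1.0 if (n == 0 or abs(mean_diff) < 1e-12) else 0.0
            t_stat = np.nan
        else:
            t_stat, p = scipy.stats.ttest_rel(grp[response], grp[covariate])
            t_stat, p = float(t_stat), float(p)
        if p < alpha and mean_diff < 0:
            cls = "below"
        elif p < alpha and mean_diff > 0:
            cls = "above"
        else:
            cls = "on"
        row = dict(zip(by, key))
        row.update({
            "n": n,
            "mean_response": float(grp[response].mean()),
            "se_response": float(grp[response].sem()) if n > 1 else np.nan,
            "mean_covariate": float(grp[covariate].mean()),
            "se_covariate": float(grp[covariate].sem()) if n > 1 else np.nan,
            "mean_difference": mean_diff, "t": t_stat, "p": p,
            "classification": cls,
        })
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset assembly: competing response vs paired isolated covariate
# ---------------------------------------------------------------------------

_PAIR_KEY = ["site", "block", "replicate", "fertiliser", "label"]


def _paired(df: pd.DataFrame, value: str, extra_key: list[str] | None = None
            ) -> pd.DataFrame:
    key = _PAIR_KEY + (extra_key or [])
    dact = df[df["species"] == "Dactylis"] if "species" in df else df
    mixed = dact[dact["combination"] == "mixed"][key + [value]]
    iso = dact[dact["combination"] == "isolated"][key + [value]]
    merged = mixed.merge(iso, on=key, suffixes=("_mixed", "_isolated"))
    merged = merged.rename(columns={f"{value}_mixed": "response",
                                    f"{value}_isolated": "covariate",
                                    "site": "location"})
    return merged


def build_uptake_dataset(uptake_df: pd.DataFrame, ion: str) -> pd.DataFrame:
    """Competing vs isolated per-capita uptake of one ion, paired by block."""
    sub = uptake_df[uptake_df["ion"] == ion]
    return _paired(sub, "per_capita_rate_mg_g_d")


def build_rgr_dataset(rgr_df: pd.DataFrame) -> pd.DataFrame:
    """Competing vs isolated RGR, paired by block (both ion labels)."""
    return _paired(rgr_df, "rgr_per_d")


def build_biomass_dataset(pot_df: pd.DataFrame) -> pd.DataFrame:
    """Competing vs isolated Dactylis biomass per harvest, paired by block."""
    sub = pot_df[pot_df["species"] == "Dactylis"].rename(
        columns={"plant_biomass_g": "biomass"})
    return _paired(sub, "biomass", extra_key=["harvest"])
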