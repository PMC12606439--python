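"""Strain-level genotype-by-environment tests on replicate activity summaries.

For each reporter, UPS activity is compared between the two parental strains
(BY, RM) and between the baseline environment (SC) and one other environment
with the linear mixed model

    activity ~ strain * environment + (1 | replicate)

where the random intercept captures variation among independent biological
replicates (transformants), grouped as replicate-within-strain.  The
interaction term is the strain-level GxE test.  If the random-effect variance
estimate is zero or the fit is degenerate, the model falls back to a
fixed-effects two-way ANOVA (Type II sums of squares) and flags the fallback.

Families of tests are Bonferroni-corrected with the family size that emerges
from the pipeline's own exclusion accounting: one model test per
reporter x non-baseline environment that survives the GFP-below-control
exclusion, and twice that many per-strain t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.tools.sm_exceptions import ConvergenceWarning

BASELINE = "SC"


@dataclass
class GxeTestResult:
    """ANOVA p-values for one reporter, one environment vs the baseline."""

    reporter: str
    environment: str
    baseline: str = BASELINE
    p_strain: float = float("nan")
    p_environment: float = float("nan")
    p_interaction: float = float("nan")
    coef_strain: float = float("nan")
    coef_environment: float = float("nan")
    coef_interaction: float = float("nan")
    fallback_used: bool = False
    n_obs: int = 0
    n_tests: int = 0
    significant: bool = False


def _check_design(sub: pd.DataFrame, environment: str, baseline: str) -> None:
    counts = sub.groupby(["strain", "environment"], observed=True).size()
    strains = sub["strain"].unique()
    if len(strains) != 2:
        raise ValueError(f"need exactly 2 strains, got {list(strains)}")
    for s in strains:
        for e in (baseline, environment):
            if counts.get((s, e), 0) < 2:
                raise ValueError(f"missing or underfilled cell ({s}, {e}) "
                                 "in the 2x2 design (need >= 2 replicates)")


def fit_interaction_model(records: pd.DataFrame, reporter: str, environment: str,
                          baseline: str = BASELINE,
                          share_replicates: bool = True) -> GxeTestResult:
    """Fit the strain x environment model for one reporter/environment pair.

    ``records`` needs columns strain, reporter, environment, replicate,
    activity.  When ``share_replicates`` is true the same replicate id across
    environments refers to the same transformant, so the random-intercept
    group is (strain, replicate); otherwise each (strain, environment,
    replicate) is its own group, which degenerates to per-observation noise.
    """
    sub = records[(records["reporter"] == reporter)
                  & records["environment"].isin([baseline, environment])].copy()
    _check_design(sub, environment, baseline)
    # center the response so results are exactly invariant to a constant shift
    sub["activity"] = sub["activity"] - sub["activity"].mean()
    if share_replicates:
        sub["group"] = sub["strain"].astype(str) + ":" + sub["replicate"].astype(str)
    else:
        sub["group"] = (sub["strain"].astype(str) + ":" + sub["environment"].astype(str)
                        + ":" + sub["replicate"].astype(str))
    # reference levels: BY strain, baseline environment
    formula = (f"activity ~ C(strain, Treatment('BY')) * "
               f"C(environment, Treatment('{baseline}'))")
    result = GxeTestResult(reporter=reporter, environment=environment,
                           baseline=baseline, n_obs=len(sub))

    fitted = None
    if sub["group"].nunique() < len(sub):  # random intercept only if groups repeat
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            for method in ("bfgs", "powell", "lbfgs"):
                try:
                    md = smf.mixedlm(formula, sub, groups=sub["group"])
                    fitted = md.fit(reml=True, method=method)
                    re_var = float(np.asarray(fitted.cov_re).ravel()[0])
                    if (not fitted.converged or not np.isfinite(re_var)
                            or re_var < 1e-8 * max(fitted.scale, 1e-12)
                            or not np.all(np.isfinite(fitted.pvalues.drop("Group Var", errors="ignore")))):
                        fitted = None
                    else:
                        break
                except (np.linalg.LinAlgError, ValueError):
                    fitted = None

    if fitted is not None:
        params, pvalues = fitted.params, fitted.pvalues
        for name in params.index:
            if name in ("Intercept", "Group Var"):
                continue
            is_strain = "strain" in name
            is_env = "environment" in name
            if is_strain and is_env:
                result.p_interaction = float(pvalues[name])
                result.coef_interaction = float(params[name])
            elif is_strain:
                result.p_strain = float(pvalues[name])
                result.coef_strain = float(params[name])
            elif is_env:
                result.p_environment = float(pvalues[name])
                result.coef_environment = float(params[name])
    else:
        # fixed-effects fallback; replicate enters as a fixed blocking factor
        # (the fixed-effects analog of the random intercept) whenever the
        # grouping is non-trivial, so the within-replicate pairing survives
        fb_formula = formula
        if sub["group"].nunique() < len(sub):
            fb_formula += " + C(group)"
        ols = smf.ols(fb_formula, sub).fit()
        table = anova_lm(ols, typ=2)
        for name in table.index:
            if name == "Residual":
                continue
            p = float(table.loc[name, "PR(>F)"])
            if ":" in name:
                result.p_interaction = p
            elif "strain" in name:
                result.p_strain = p
            elif "environment" in name:
                result.p_environment = p
        for name in ols.params.index:
            if name == "Intercept":
                continue
            if ":" in name:
                result.coef_interaction = float(ols.params[name])
            elif "strain" in name:
                result.coef_strain = float(ols.params[name])
            elif "environment" in name:
                result.coef_environment = float(ols.params[name])
        result.fallback_used = True
    return result


def bonferroni_family(results: list[GxeTestResult], alpha: float = 0.05) -> float:
    """Flag significance at the Bonferroni threshold ``alpha / m``.

    ``m`` is the family size, i.e. the number of fitted tests after
    exclusions.  Returns the threshold; results are annotated in place.
    """
    m = len(results)
    if m == 0:
        raise ValueError("empty test family")
    threshold = alpha / m
    for r in results:
        r.n_tests = m
        r.significant = bool(r.p_interaction < threshold)
    return threshold


def count_model_family(summaries: pd.DataFrame, baseline: str = BASELINE) -> int:
    """Number of reporter x environment model tests after exclusions.

    One test per (reporter, non-baseline environment) combination in which
    neither the environment group nor the reporter's baseline group is
    excluded.  The per-strain t-test family is twice this number.
    """
    m = 0
    for (reporter, env), grp in summaries.groupby(["reporter", "environment"], observed=True):
        if env == baseline:
            continue
        base = summaries[(summaries["reporter"] == reporter)
                         & (summaries["environment"] == baseline)]
        if base.empty or grp.empty:
            continue
        if grp["excluded"].any() or base["excluded"].any():
            continue
        m += 1
    return m


def environment_effect(records: pd.DataFrame, strain: str, reporter: str,
                       environment: str, baseline: str = BASELINE,
                       plate_paired: bool = False) -> float:
    """Mean activity change caused by an environment, per strain.

    ``delta = mean(activity in env) - mean(activity in baseline)``; negative
    values mean the environment lowered UPS activity.  For plate-paired
    reporters the baseline from the same plate is used (per-plate deltas,
    averaged), so constant plate offsets cancel.
    """
    sub = records[(records["strain"] == strain) & (records["reporter"] == reporter)]
    env_rec = sub[sub["environment"] == environment]
    base_rec = sub[sub["environment"] == baseline]
    if base_rec.empty:
        raise ValueError(f"no baseline ({baseline}) records for {strain}/{reporter}")
    if env_rec.empty:
        raise ValueError(f"no {environment} records for {strain}/{reporter}")
    if plate_paired and "plate" in records.columns:
        deltas = []
        for plate, grp in env_rec.groupby("plate"):
            base_plate = base_rec[base_rec["plate"] == plate]
            if base_plate.empty:
                raise ValueError(f"no same-plate baseline for plate {plate!r}")
            deltas.append(grp["activity"].mean() - base_plate["activity"].mean())
        return float(np.mean(deltas))
    return float(env_rec["activity"].mean() - base_rec["activity"].mean())


@dataclass
class StrainTTest:
    strain: str
    reporter: str
    environment: str
    t: float
    p: float
    n_tests: int = 0
    significant: bool = False


def per_strain_ttests(records: pd.DataFrame, baseline: str = BASELINE,
                      alpha: float = 0.05,
                      family_size: int | None = None) -> list[StrainTTest]:
    """Welch t-tests of each strain's activity between baseline and environment.

    Two-tailed, unequal-variance.  The Bonferroni family defaults to the
    number of tests performed (2 strains x model tests); pass ``family_size``
    to impose the family counted by :func:`count_model_family` times two.
    """
    out: list[StrainTTest] = []
    for (strain, reporter, env), grp in records.groupby(
            ["strain", "reporter", "environment"], observed=True):
        if env == baseline:
            continue
        base = records[(records["strain"] == strain)
                       & (records["reporter"] == reporter)
                       & (records["environment"] == baseline)]
        if len(grp) < 2 or len(base) < 2:
            raise ValueError(f"need >= 2 replicates per group for {strain}/{reporter}/{env}")
        a = grp["activity"].to_numpy(dtype=float)
        b = base["activity"].to_numpy(dtype=float)
        if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        out.append(StrainTTest(strain, reporter, env, float(t), float(p)))
    m = family_size if family_size is not None else len(out)
    if m > 0:
        for r in out:
            r.n_tests = m
            r.significant = bool(r.p < alpha / m)
    return out


def simulate_activity_records(interaction: float = 0.0, strain_effect: float = 0.5,
                              env_effect: float = -0.5, n_replicates: int = 8,
                              replicate_sd: float = 0.3, noise_sd: float = 0.3,
                              reporter: str = "rep", environment: str = "E",
                              baseline: str = BASELINE,
                              seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Generate a balanced 2x2 replicate set under the interaction model.

    Activity = strain effect (RM) + environment effect + interaction (RM in
    the non-baseline environment) + a replicate-level random intercept shared
    across environments + residual noise.  Used for calibration and power
    checks of :func:`fit_interaction_model`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for strain in ("BY", "RM"):
        rep_int = rng.normal(0.0, replicate_sd, size=n_replicates)
        for env in (baseline, environment):
            mu = (strain_effect * (strain == "RM")
                  + env_effect * (env != baseline)
                  + interaction * ((strain == "RM") and (env != baseline)))
            vals = mu + rep_int + rng.normal(0.0, noise_sd, size=n_replicates)
            for i, v in enumerate(vals):
                rows.append({"strain": strain, "reporter": reporter,
                             "environment": env, "replicate": f"r{i}",
                             "plate": "p1", "activity": float(v)})
    return pd.DataFrame(rows)
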