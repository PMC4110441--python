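"""Inference on fitted multilevel factor models.

Turns fitted models into the quantities a cluster-bias analysis reports:
model chi-square against the saturated model, RMSEA and CFI, chi-square
difference tests between nested models, the three-step cluster-bias
procedure (baseline -> Level-2 residuals zero -> Level-3 residuals zero),
latent and observed intraclass correlations, per-indicator bias-variance
proportions, and Wald tests of higher-level residual variances.

A note on the difference tests: fixing variances at their zero boundary
makes the likelihood-ratio statistic a mixture of chi-square distributions;
referring it to the central chi-square, as done here (and in standard
practice), yields a *conservative* test.  Every report carries that caveat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from . import engine
from .engine import FitOptions, FitResult, HierarchicalData, standard_errors
from .model_spec import build_cluster_bias_models, degrees_of_freedom

__all__ = [
    "BOUNDARY_CAVEAT",
    "FitIndexReport",
    "DifferenceTest",
    "WaldRow",
    "ClusterBiasReport",
    "model_chisq",
    "fit_indices",
    "chisq_difference",
    "cluster_bias_test",
    "factor_icc",
    "observed_icc",
    "bias_proportions",
    "residual_variance_wald",
]

BOUNDARY_CAVEAT = (
    "Variances are tested at their zero boundary; the central chi-square "
    "reference distribution makes this test conservative."
)


@dataclass
class FitIndexReport:
    """Overall goodness-of-fit of one model against the saturated model."""

    model: str
    chisq: float
    df: int
    p_value: float
    rmsea: float
    cfi: float
    n_obs: int

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "chisq": self.chisq,
            "df": self.df,
            "p_value": self.p_value,
            "rmsea": self.rmsea,
            "cfi": self.cfi,
            "n_obs": self.n_obs,
        }


@dataclass
class DifferenceTest:
    """Chi-square difference between a restricted and a full model."""

    delta_chisq: float
    delta_df: int
    p_value: float
    verdict: str
    boundary_conservative: bool = False
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "delta_chisq": self.delta_chisq,
            "delta_df": self.delta_df,
            "p_value": self.p_value,
            "verdict": self.verdict,
            "boundary_conservative": self.boundary_conservative,
            "note": self.note,
        }


@dataclass
class WaldRow:
    indicator: str
    estimate: float
    se: float | None
    z: float | None
    p_value: float | None
    significant: bool | None
    at_boundary: bool

    def to_dict(self) -> dict:
        return {
            "indicator": self.indicator,
            "estimate": self.estimate,
            "se": self.se,
            "z": self.z,
            "p_value": self.p_value,
            "significant": self.significant,
            "at_boundary": self.at_boundary,
        }


def _check_same_data(a: FitResult, b: FitResult) -> None:
    if a.data_fingerprint != b.data_fingerprint:
        raise ValueError("fits were computed on different data")


def model_chisq(fit: FitResult, saturated: FitResult):
    """(chi-square, df) of a structured model against the saturated model."""
    if not (fit.converged and saturated.converged):
        raise ValueError("both fits must have converged")
    _check_same_data(fit, saturated)
    chisq = max(0.0, 2.0 * (saturated.loglik - fit.loglik))
    df = degrees_of_freedom(fit.spec) - degrees_of_freedom(saturated.spec)
    return chisq, df


def fit_indices(chisq: float, df: int, chisq_baseline: float, df_baseline: int, n_obs: int):
    """(RMSEA, CFI) from chi-square statistics.

    RMSEA = sqrt(max(chisq - df, 0) / (df * N)) with N the total number of
    Level-1 units; CFI uses the independence model as baseline and is
    clipped to [0, 1].
    """
    if df <= 0:
        raise ValueError("fit indices require df > 0")
    if n_obs <= 0:
        raise ValueError("fit indices require N > 0")
    if df_baseline <= 0:
        raise ValueError("baseline df must be positive")
    excess = max(chisq - df, 0.0)
    rmsea = float(np.sqrt(excess / (df * n_obs)))
    denom = max(chisq_baseline - df_baseline, excess, 0.0)
    cfi = 1.0 if denom == 0.0 else 1.0 - excess / denom
    return rmsea, float(min(max(cfi, 0.0), 1.0))


def _is_nested(restricted: FitResult, full: FitResult) -> bool:
    return set(restricted.table.labels) <= set(full.table.labels)


def chisq_difference(
    restricted: FitResult, full: FitResult, alpha: float = 0.05
) -> DifferenceTest:
    """Likelihood-ratio difference test of nested fits.

    ``delta_df`` is the free-parameter difference; the p-value refers the
    statistic to the central chi-square, with a conservativeness note when
    the restriction pins variances at zero.
    """
    if not (restricted.converged and full.converged):
        raise ValueError("both fits must have converged")
    _check_same_data(restricted, full)
    if not _is_nested(restricted, full):
        raise ValueError("restricted model is not nested in the full model")
    delta_df = full.n_free - restricted.n_free
    delta = max(0.0, 2.0 * (full.loglik - restricted.loglik))
    if delta_df == 0:
        p = 1.0
    else:
        p = float(sps.chi2.sf(delta, delta_df))
    dropped = set(full.table.labels) - set(restricted.table.labels)
    boundary = any(
        r.lower_bound == 0.0 for r in full.table.rows if r.label in dropped
    )
    verdict = "bias detected" if (delta_df > 0 and p < alpha) else "no bias detected"
    return DifferenceTest(
        delta_chisq=float(delta),
        delta_df=int(delta_df),
        p_value=p,
        verdict=verdict,
        boundary_conservative=boundary,
        note=BOUNDARY_CAVEAT if boundary else "",
    )


def factor_icc(phi1: float, phi2: float, phi3: float = 0.0):
    """Intraclass correlations of the common factor.

    Valid when loadings are equal across levels, which puts the factor on
    one scale: icc_level2 = phi2 / (phi1 + phi2 + phi3), and analogously
    for icc_level3.
    """
    if min(phi1, phi2, phi3) < 0:
        raise ValueError("factor variances must be nonnegative")
    total = phi1 + phi2 + phi3
    if total <= 0:
        raise ValueError("total factor variance must be positive")
    return phi2 / total, phi3 / total


def observed_icc(saturated: FitResult) -> dict:
    """Per-indicator variance shares at each higher level from a saturated fit."""
    if not saturated.converged:
        raise ValueError("saturated fit did not converge")
    mo = saturated.implied()
    total = sum(np.diag(s) for s in mo.sigma_by_level)
    names = saturated.spec.indicator_names
    out = {}
    for v, name in enumerate(names):
        icc2 = float(mo.sigma_by_level[1][v, v] / total[v]) if len(mo.sigma_by_level) >= 2 else 0.0
        icc3 = float(mo.sigma_by_level[2][v, v] / total[v]) if len(mo.sigma_by_level) >= 3 else 0.0
        out[name] = (icc2, icc3)
    return out


def bias_proportions(fit: FitResult, level: int) -> dict:
    """Per-indicator share of residual (bias) variance at ``level``.

    ``prop_within_level`` = theta_m[v] / Sigma_m[v, v] (model-implied total
    at that level, including common- and doublet-factor contributions);
    ``prop_total`` = theta_m[v] / Sigma_total[v, v].
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    compiled = engine.compile_spec(fit.spec)
    mu, mats = compiled.matrices(fit.estimates)
    if not (1 <= level <= len(mats)):
        raise ValueError(f"model has no level {level}")
    mo = fit.implied()
    sig_m = mo.sigma_by_level[level - 1]
    sig_tot = sum(mo.sigma_by_level)
    theta_m = mats[level - 1][2]
    out = {}
    for v, name in enumerate(fit.spec.indicator_names):
        if sig_m[v, v] <= 0 or sig_tot[v, v] <= 0:
            if theta_m[v] == 0:
                out[name] = {"prop_within_level": 0.0, "prop_total": 0.0}
                continue
            raise ValueError(f"zero implied variance for indicator {name!r}")
        out[name] = {
            "prop_within_level": float(theta_m[v] / sig_m[v, v]),
            "prop_total": float(theta_m[v] / sig_tot[v, v]),
        }
    return out


def residual_variance_wald(
    fit: FitResult, level: int, alpha: float = 0.05, data=None
) -> list:
    """Wald z-tests of each indicator's residual variance at ``level``.

    Boundary-pinned estimates are flagged and not tested (the Wald statistic
    is meaningless on the boundary).  Requires standard errors; if absent
    and ``data`` is given they are computed first.
    """
    if fit.std_errors is None:
        if data is None:
            raise ValueError("fit has no standard errors; pass the data to compute them")
        standard_errors(fit, data)
    rows = []
    by_slot = {}
    for i, r in enumerate(fit.table.rows):
        for s in r.slots:
            if s.matrix == "theta" and s.level == level:
                by_slot[s.row] = i
    for v, name in enumerate(fit.spec.indicator_names):
        i = by_slot.get(v)
        if i is None:
            continue  # fixed residual, nothing to test
        est = float(fit.estimates[i])
        if fit.boundary is not None and fit.boundary[i]:
            rows.append(WaldRow(name, est, None, None, None, None, True))
            continue
        se = fit.std_errors[i]
        if not np.isfinite(se) or se <= 0:
            rows.append(WaldRow(name, est, None, None, None, None, False))
            continue
        z = est / se
        p = float(2.0 * sps.norm.sf(abs(z)))
        rows.append(WaldRow(name, est, float(se), float(z), p, p < alpha, False))
    return rows


@dataclass
class ClusterBiasReport:
    """Full output of the three-step cluster-bias testing sequence."""

    n_levels: int
    alpha: float
    fit_table: list  # FitIndexReport per available model
    level2_test: DifferenceTest | None
    level3_test: DifferenceTest | None
    wald_level2: list
    wald_level3: list
    bias_level2: dict
    bias_level3: dict
    factor_icc_level2: float | None
    factor_icc_level3: float | None
    observed_iccs: dict
    unavailable: list = field(default_factory=list)
    notes: list = field(default_factory=list)
    fits: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_levels": self.n_levels,
            "alpha": self.alpha,
            "fit_table": [r.to_dict() for r in self.fit_table],
            "level2_test": self.level2_test.to_dict() if self.level2_test else None,
            "level3_test": self.level3_test.to_dict() if self.level3_test else None,
            "wald_level2": [w.to_dict() for w in self.wald_level2],
            "wald_level3": [w.to_dict() for w in self.wald_level3],
            "bias_level2": self.bias_level2,
            "bias_level3": self.bias_level3,
            "factor_icc_level2": self.factor_icc_level2,
            "factor_icc_level3": self.factor_icc_level3,
            "observed_iccs": {k: list(v) for k, v in self.observed_iccs.items()},
            "unavailable": self.unavailable,
            "notes": self.notes,
        }

    def to_text(self) -> str:
        lines = []
        lines.append(f"Cluster-bias test ({self.n_levels}-level model, alpha = {self.alpha:g})")
        lines.append("")
        lines.append("Fit measures")
        lines.append(f"{'Model':<28}{'df':>5}{'chisq':>12}{'RMSEA':>8}{'CFI':>7}")
        for r in self.fit_table:
            lines.append(
                f"{r.model:<28}{r.df:>5}{r.chisq:>12.2f}{r.rmsea:>8.2f}{r.cfi:>7.2f}"
            )
        for name, test, lbl in (
            ("Level 2", self.level2_test, "classes"),
            ("Level 3", self.level3_test, "schools"),
        ):
            if test is None:
                continue
            lines.append("")
            lines.append(
                f"{name} invariance test ({lbl}): "
                f"delta chisq({test.delta_df}) = {test.delta_chisq:.2f}, "
                f"p = {test.p_value:.3g} -> {test.verdict}"
            )
        for level, table in (("Level 2", self.bias_level2), ("Level 3", self.bias_level3)):
            if not table:
                continue
            lines.append("")
            lines.append(f"Proportion of {level} variance due to bias")
            lines.append(f"{'Indicator':<12}{'within level':>14}{'of total':>10}")
            for name, d in table.items():
                lines.append(
                    f"{name:<12}{d['prop_within_level']:>14.3f}{d['prop_total']:>10.3f}"
                )
        if self.factor_icc_level2 is not None:
            lines.append("")
            icc3 = f", Level 3: {self.factor_icc_level3:.3f}" if self.factor_icc_level3 is not None else ""
            lines.append(f"Factor ICC  Level 2: {self.factor_icc_level2:.3f}{icc3}")
        if self.unavailable:
            lines.append("")
            lines.append("Unavailable (nonconvergence): " + ", ".join(self.unavailable))
        for n in self.notes:
            lines.append("")
            lines.append("Note: " + n)
        return "\n".join(lines)


def cluster_bias_test(
    data: HierarchicalData,
    doublets: Sequence = (),
    alpha: float = 0.05,
    options: FitOptions | None = None,
    compute_wald: bool = True,
) -> ClusterBiasReport:
    """Run the full testing sequence for strong factorial invariance.

    Fits the baseline model (equal loadings across levels), the model with
    all Level-2 residual variances fixed at zero, and -- for three-level
    data -- the model with Level-3 residual variances fixed at zero (this
    last one is compared against the baseline, whose Level-2 residuals are
    free).  A significant chi-square difference at a level means the
    indicators carry cluster-level variance beyond the common factor, i.e.
    measurement bias with respect to that clustering variable.
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    stats = engine.compute_sufficient_stats(data)
    L = data.n_levels
    models = build_cluster_bias_models(data.p, doublets, n_levels=L, indicator_names=data.indicator_names)
    opts = options or FitOptions()

    fits: dict = {}
    unavailable: list = []
    fits["baseline"] = engine.fit_ml(models.baseline, stats, opts)
    warm = _warm_start(fits["baseline"], models.level2_constrained)
    fits["level2_constrained"] = engine.fit_ml(
        models.level2_constrained, stats, _with_start(opts, warm)
    )
    if L == 3:
        warm = _warm_start(fits["baseline"], models.level3_constrained)
        fits["level3_constrained"] = engine.fit_ml(
            models.level3_constrained, stats, _with_start(opts, warm)
        )
    saturated = engine.fit_saturated(stats, L, opts)
    independence = engine.fit_independence(stats, L, opts)
    fits["saturated"] = saturated
    fits["independence"] = independence

    fit_table: list = []
    chisq_b = df_b = None
    if independence.converged and saturated.converged:
        chisq_b, df_b = model_chisq(independence, saturated)
    for name in ("baseline", "level2_constrained", "level3_constrained"):
        f = fits.get(name)
        if f is None:
            continue
        if not (f.converged and saturated.converged):
            unavailable.append(name if not f.converged else "saturated")
            continue
        chisq, df = model_chisq(f, saturated)
        if chisq_b is not None and df > 0:
            rmsea, cfi = fit_indices(chisq, df, chisq_b, df_b, stats.n)
        else:
            rmsea, cfi = (0.0, 1.0) if df == 0 else (np.nan, np.nan)
        fit_table.append(
            FitIndexReport(
                model=name,
                chisq=chisq,
                df=df,
                p_value=float(sps.chi2.sf(chisq, df)) if df > 0 else 1.0,
                rmsea=rmsea,
                cfi=cfi,
                n_obs=stats.n,
            )
        )

    level2_test = level3_test = None
    if fits["baseline"].converged and fits["level2_constrained"].converged:
        level2_test = chisq_difference(fits["level2_constrained"], fits["baseline"], alpha)
    else:
        unavailable.append("level2 comparison")
    if L == 3:
        if fits["baseline"].converged and fits["level3_constrained"].converged:
            level3_test = chisq_difference(fits["level3_constrained"], fits["baseline"], alpha)
        else:
            unavailable.append("level3 comparison")

    wald2: list = []
    wald3: list = []
    bias2: dict = {}
    bias3: dict = {}
    icc2 = icc3 = None
    base = fits["baseline"]
    if base.converged:
        if compute_wald:
            standard_errors(base, stats)
            wald2 = residual_variance_wald(base, 2, alpha)
            if L == 3:
                wald3 = residual_variance_wald(base, 3, alpha)
        bias2 = bias_proportions(base, 2)
        if L == 3:
            bias3 = bias_proportions(base, 3)
        est = base.estimates_by_label()
        phi2 = est.get("phi2", 0.0)
        phi3 = est.get("phi3", 0.0) if L == 3 else 0.0
        icc2, icc3 = factor_icc(1.0, max(phi2, 0.0), max(phi3, 0.0))
        if L == 2:
            icc3 = None

    observed = observed_icc(saturated) if saturated.converged else {}
    notes = [BOUNDARY_CAVEAT]
    notes.append("CFI baseline: independence model (diagonal covariance at every level, free means).")
    return ClusterBiasReport(
        n_levels=L,
        alpha=alpha,
        fit_table=fit_table,
        level2_test=level2_test,
        level3_test=level3_test,
        wald_level2=wald2,
        wald_level3=wald3,
        bias_level2=bias2,
        bias_level3=bias3,
        factor_icc_level2=icc2,
        factor_icc_level3=icc3,
        observed_iccs=observed,
        unavailable=sorted(set(unavailable)),
        notes=notes,
        fits=fits,
    )


def _warm_start(full_fit: FitResult, restricted_spec) -> np.ndarray | None:
    """Map a full fit's estimates onto a nested spec's parameter vector."""
    if not full_fit.converged:
        return None
    est = full_fit.estimates_by_label()
    table = restricted_spec.parameter_table()
    if not set(r.label for r in table.rows) <= set(est):
        return None
    return np.array([est[r.label] for r in table.rows])


def _with_start(opts: FitOptions, start) -> FitOptions:
    if start is None:
        return opts
    return FitOptions(
        maxiter=opts.maxiter,
        gtol=opts.gtol,
        ftol=opts.ftol,
        n_restarts=opts.n_restarts,
        jitter=opts.jitter,
        seed=opts.seed,
        start=start,
    )
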