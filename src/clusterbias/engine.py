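"""Full-information ML estimation of multilevel factor models.

The observed vector of student i in class c in school s is modelled as

    y_ics = mu + u_s + v_cs + e_ics,

with independent normal components, cov(u) = Sigma_3, cov(v) = Sigma_2 and
cov(e) = Sigma_1.  The exact joint log-likelihood of all observations is
evaluated from lossless sufficient statistics: the pooled within-class
scatter drives the Sigma_1 part, while each school contributes the joint
density of its class-mean vectors, whose covariance is block-diagonal in
V_c = Sigma_2 + Sigma_1 / n_c plus a shared Sigma_3 block.  The school
block is inverted with the Woodbury identity in a form that never inverts
Sigma_3, so rank-deficient (or zero) higher-level covariances are handled
exactly -- essential because the cluster-bias test evaluates models right
on that boundary.

Estimation is quasi-Newton (L-BFGS-B) with lower bounds of zero on all
variance parameters, moment-based starting values, and seeded jittered
restarts on nonconvergence.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .model_spec import (
    Fixed,
    Free,
    ModelSpec,
    ParameterTable,
    independence_spec,
    saturated_spec,
)

__all__ = [
    "HierarchicalData",
    "SufficientStats",
    "ImpliedMoments",
    "FitOptions",
    "FitResult",
    "preprocess",
    "compute_sufficient_stats",
    "CompiledSpec",
    "compile_spec",
    "implied_moments",
    "loglik",
    "fit_ml",
    "fit_saturated",
    "fit_independence",
    "standard_errors",
]

logger = logging.getLogger(__name__)

_PENALTY = 1e15  # objective value returned at inadmissible parameter points
POOLED_CLASS_LABEL = "__pooled__"


# ---------------------------------------------------------------------------
# data containers


@dataclass
class HierarchicalData:
    """Nested observations: N x p indicators with class (and school) labels.

    ``school_id is None`` marks two-level data (classes are the only
    clustering variable).  Class labels are canonical: a class belongs to
    exactly one school.
    """

    indicators: np.ndarray
    class_id: np.ndarray
    school_id: np.ndarray | None
    indicator_names: tuple

    def __post_init__(self):
        self.indicators = np.asarray(self.indicators, dtype=float)
        if self.indicators.ndim != 2 or self.indicators.shape[0] < 1:
            raise ValueError("indicators must be a nonempty N x p matrix")
        self.class_id = np.asarray(self.class_id)
        if len(self.class_id) != self.indicators.shape[0]:
            raise ValueError("class_id length must equal N")
        if self.school_id is not None:
            self.school_id = np.asarray(self.school_id)
            if len(self.school_id) != self.indicators.shape[0]:
                raise ValueError("school_id length must equal N")
            pairs = {}
            for c, s in zip(self.class_id, self.school_id):
                if pairs.setdefault(c, s) != s:
                    raise ValueError(f"class label {c!r} appears under two schools")
        self.indicator_names = tuple(self.indicator_names)
        if len(self.indicator_names) != self.indicators.shape[1]:
            raise ValueError("indicator_names length must equal p")

    @property
    def n(self) -> int:
        return self.indicators.shape[0]

    @property
    def p(self) -> int:
        return self.indicators.shape[1]

    @property
    def n_levels(self) -> int:
        return 3 if self.school_id is not None else 2

    def summary(self) -> dict:
        classes, counts = np.unique(self.class_id, return_counts=True)
        out = {
            "n_observations": int(self.n),
            "n_indicators": int(self.p),
            "n_classes": int(len(classes)),
            "mean_class_size": float(self.n / len(classes)),
        }
        if self.school_id is not None:
            schools = np.unique(self.school_id)
            out["n_schools"] = int(len(schools))
            out["mean_school_size"] = float(self.n / len(schools))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.indicators, columns=list(self.indicator_names))
        df.insert(0, "class", self.class_id)
        if self.school_id is not None:
            df.insert(0, "school", self.school_id)
        return df


def preprocess(
    table,
    school_col: str | None,
    class_col: str,
    indicator_cols: Sequence,
    missing_class_policy: str = "pool",
) -> HierarchicalData:
    """Build :class:`HierarchicalData` from a long-format table.

    Rows with missing indicator values are dropped (complete-case; the count
    is logged).  A missing class label is handled per policy: ``"pool"``
    places all such rows of a school into one pseudo-class (so a school with
    no class information becomes a single cluster), ``"drop"`` removes the
    rows.  Class labels are canonicalized as (school, class) pairs; a raw
    class label shared by two schools is rejected by name because it almost
    always signals an identifier error.
    """
    if isinstance(table, (str, bytes)) or hasattr(table, "read"):
        table = pd.read_csv(table)
    df = table.copy()
    cols = list(indicator_cols) + [class_col] + ([school_col] if school_col else [])
    missing_cols = [c for c in cols if c not in df.columns]
    if missing_cols:
        raise KeyError(f"columns not found in data: {missing_cols}")
    if school_col is not None and class_col == school_col:
        raise ValueError("school and class columns must be distinct")

    ind = df[list(indicator_cols)].apply(pd.to_numeric, errors="coerce")
    keep = ind.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d rows with missing indicator values", n_dropped)
    df = df.loc[keep].reset_index(drop=True)
    ind = ind.loc[keep].reset_index(drop=True)

    cls = df[class_col].astype("string")
    if school_col is not None:
        sch = df[school_col].astype("string")
        keep2 = sch.notna()
        if not keep2.all():
            logger.info("dropped %d rows with missing school id", int((~keep2).sum()))
            df, ind, cls, sch = df[keep2], ind[keep2], cls[keep2], sch[keep2]
        if missing_class_policy == "pool":
            cls = cls.fillna(POOLED_CLASS_LABEL)
        elif missing_class_policy == "drop":
            keep3 = cls.notna()
            df, ind, cls, sch = df[keep3], ind[keep3], cls[keep3], sch[keep3]
        else:
            raise ValueError(f"unknown missing_class_policy {missing_class_policy!r}")
        if len(df) == 0:
            raise ValueError("no usable rows after preprocessing")
        # reject a raw (non-pooled) class label that spans schools
        raw = pd.DataFrame({"s": sch.to_numpy(), "c": cls.to_numpy()})
        spans = raw[raw["c"] != POOLED_CLASS_LABEL].groupby("c")["s"].nunique()
        bad = spans[spans > 1]
        if len(bad):
            raise ValueError(
                f"class label {bad.index[0]!r} appears under {int(bad.iloc[0])} schools"
            )
        canon = (sch.astype(str) + "::" + cls.astype(str)).to_numpy()
        return HierarchicalData(
            ind.to_numpy(dtype=float), canon, sch.astype(str).to_numpy(), tuple(indicator_cols)
        )
    else:
        keep3 = cls.notna() if missing_class_policy == "drop" else np.ones(len(cls), bool)
        cls = cls.fillna(POOLED_CLASS_LABEL)
        df, ind, cls = df[keep3], ind[keep3], cls[keep3]
        if len(df) == 0:
            raise ValueError("no usable rows after preprocessing")
        return HierarchicalData(
            ind.to_numpy(dtype=float), cls.astype(str).to_numpy(), None, tuple(indicator_cols)
        )


@dataclass
class SufficientStats:
    """Lossless reduction of nested data for the structured likelihood.

    Classes are sorted so schools are contiguous; ``school_starts`` indexes
    the first class of each school (``None`` for two-level data).  ``s_w``
    is the pooled within-class scatter sum_c sum_i (y - ybar_c)(y - ybar_c)'.
    """

    class_sizes: np.ndarray
    class_means: np.ndarray
    school_starts: np.ndarray | None
    s_w: np.ndarray
    n: int
    p: int
    indicator_names: tuple
    grand_mean: np.ndarray = field(init=False)
    fingerprint: str = field(init=False)

    def __post_init__(self):
        self.grand_mean = self.class_sizes @ self.class_means / self.n
        h = hashlib.sha256()
        h.update(self.class_sizes.tobytes())
        h.update(np.ascontiguousarray(self.class_means).tobytes())
        h.update(np.ascontiguousarray(self.s_w).tobytes())
        self.fingerprint = h.hexdigest()[:16]

    @property
    def n_classes(self) -> int:
        return len(self.class_sizes)

    @property
    def n_schools(self) -> int:
        return len(self.school_starts) if self.school_starts is not None else 0


def compute_sufficient_stats(data: HierarchicalData) -> SufficientStats:
    Y = data.indicators
    if data.school_id is not None:
        # \x1f separator keeps the school prefix sortable and splittable
        keys = np.array(
            [f"{s}\x1f{c}" for s, c in zip(data.school_id, data.class_id)]
        )
        school_of_row = data.school_id.astype(str)
    else:
        keys = data.class_id.astype(str)
        school_of_row = None
    uniq, codes = np.unique(keys, return_inverse=True)
    C = len(uniq)
    counts = np.bincount(codes, minlength=C).astype(float)
    means = np.zeros((C, data.p))
    np.add.at(means, codes, Y)
    means /= counts[:, None]
    s_w = Y.T @ Y - (means * counts[:, None]).T @ means
    s_w = 0.5 * (s_w + s_w.T)

    school_starts = None
    if school_of_row is not None:
        # np.unique sorts keys; the school prefix makes schools contiguous
        school_of_class = np.array([u.split("\x1f", 1)[0] for u in uniq])
        change = np.flatnonzero(
            np.concatenate(([True], school_of_class[1:] != school_of_class[:-1]))
        )
        school_starts = change
    return SufficientStats(
        class_sizes=counts,
        class_means=means,
        school_starts=school_starts,
        s_w=s_w,
        n=data.n,
        p=data.p,
        indicator_names=data.indicator_names,
    )


def _as_stats(data) -> SufficientStats:
    if isinstance(data, SufficientStats):
        return data
    if isinstance(data, HierarchicalData):
        return compute_sufficient_stats(data)
    raise TypeError(f"expected HierarchicalData or SufficientStats, got {type(data)!r}")


# ---------------------------------------------------------------------------
# implied moments


@dataclass
class ImpliedMoments:
    """Mean vector and per-level covariance matrices implied by parameters."""

    mu: np.ndarray
    sigma_by_level: list


class CompiledSpec:
    """A ModelSpec flattened into index arrays for fast theta -> matrices."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.table = spec.parameter_table()
        self.n_free = len(self.table)
        p = spec.p
        self.p = p
        self.n_levels = spec.n_levels
        self.lam0, self.phi0, self.th0 = [], [], []
        self.k_by_level = []
        fills: dict = {}
        for lv in spec.levels:
            k = lv.loadings.k
            self.k_by_level.append(k)
            lam = np.zeros((p, k))
            phi = np.zeros((k, k))
            th = np.zeros(p)
            for i in range(p):
                for j in range(k):
                    e = lv.loadings.entries[i][j]
                    if isinstance(e, Fixed):
                        lam[i, j] = e.value
            for i in range(k):
                for j in range(k):
                    e = lv.factor_cov[i][j]
                    if isinstance(e, Fixed):
                        phi[i, j] = e.value
            for j in range(p):
                e = lv.residual_var[j]
                if isinstance(e, Fixed):
                    th[j] = e.value
            self.lam0.append(lam)
            self.phi0.append(phi)
            self.th0.append(th)
        self.mu0 = np.zeros(p)
        for j, e in enumerate(spec.intercepts):
            if isinstance(e, Fixed):
                self.mu0[j] = e.value

        # fill lists: (param_index, level-1, row, col) per matrix kind
        lam_f, phi_f, th_f, nu_f = [], [], [], []
        for idx, row in enumerate(self.table.rows):
            for s in row.slots:
                if s.matrix == "lambda":
                    lam_f.append((idx, s.level - 1, s.row, s.col))
                elif s.matrix == "phi":
                    phi_f.append((idx, s.level - 1, s.row, s.col))
                elif s.matrix == "theta":
                    th_f.append((idx, s.level - 1, s.row))
                elif s.matrix == "nu":
                    nu_f.append((idx, s.row))
        self._lam_f, self._phi_f, self._th_f, self._nu_f = lam_f, phi_f, th_f, nu_f
        self.lower_bounds = np.array([r.lower_bound for r in self.table.rows])

    def matrices(self, theta: np.ndarray):
        """Expand a parameter vector: (mu, [(Lambda, Phi, Theta_diag), ...])."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_free,):
            raise ValueError(f"theta must have length {self.n_free}, got {theta.shape}")
        if not np.all(np.isfinite(theta)):
            raise ValueError("non-finite parameter values")
        lam = [a.copy() for a in self.lam0]
        phi = [a.copy() for a in self.phi0]
        th = [a.copy() for a in self.th0]
        mu = self.mu0.copy()
        for idx, m, i, j in self._lam_f:
            lam[m][i, j] = theta[idx]
        for idx, m, i, j in self._phi_f:
            phi[m][i, j] = theta[idx]
            phi[m][j, i] = theta[idx]
        for idx, m, j in self._th_f:
            th[m][j] = theta[idx]
        for idx, j in self._nu_f:
            mu[j] = theta[idx]
        return mu, list(zip(lam, phi, th))

    def moments(self, theta: np.ndarray) -> ImpliedMoments:
        mu, mats = self.matrices(theta)
        sig = []
        for lam, phi, th in mats:
            s = lam @ phi @ lam.T + np.diag(th)
            sig.append(0.5 * (s + s.T))
        return ImpliedMoments(mu=mu, sigma_by_level=sig)


def compile_spec(spec: ModelSpec) -> CompiledSpec:
    return CompiledSpec(spec)


def implied_moments(spec: ModelSpec, theta) -> ImpliedMoments:
    """Sigma_m = Lambda_m Phi_m Lambda_m' + Theta_m per level, mu from intercepts."""
    return compile_spec(spec).moments(np.asarray(theta, dtype=float))


# ---------------------------------------------------------------------------
# likelihood


def loglik(stats: SufficientStats, moments: ImpliedMoments) -> float:
    """Exact joint multivariate-normal log-density of all observations.

    Includes the full -(Np/2) log(2 pi) constant.  Returns ``-inf`` when a
    required covariance block is singular / not positive definite (the
    optimizer treats that as a barrier).
    """
    p = stats.p
    L = len(moments.sigma_by_level)
    mu = np.asarray(moments.mu, dtype=float)
    if mu.shape != (p,):
        raise ValueError(f"mean vector has length {mu.shape}, expected {p}")
    for s in moments.sigma_by_level:
        if np.asarray(s).shape != (p, p):
            raise ValueError("level covariance has wrong shape")
    S1 = np.asarray(moments.sigma_by_level[0], dtype=float)
    S2 = np.asarray(moments.sigma_by_level[1], dtype=float) if L >= 2 else None
    use_school = L == 3 and stats.school_starts is not None
    S3 = np.asarray(moments.sigma_by_level[2], dtype=float) if L == 3 else None
    if L == 3 and stats.school_starts is None:
        raise ValueError("three-level model requires school-level data")

    N, C = stats.n, stats.n_classes
    sizes = stats.class_sizes
    try:
        c1 = linalg.cho_factor(S1, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    logdet1 = 2.0 * np.sum(np.log(np.diag(c1[0])))
    ll = -0.5 * (
        (N - C) * logdet1 + float(np.trace(linalg.cho_solve(c1, stats.s_w, check_finite=False)))
    )

    # Class-mean part: V_c = Sigma_2 + Sigma_1 / n_c, cached per unique size.
    # The orthogonal split of a class into (mean, deviations) expresses the
    # mean coordinate as sqrt(n_c) * ybar; writing its density in terms of
    # ybar itself costs a Jacobian factor n_c^(p/2) per class.
    ll -= 0.5 * p * float(np.sum(np.log(sizes)))
    d = stats.class_means - mu
    uniq_sizes, size_code = np.unique(sizes, return_inverse=True)
    Vinv = np.empty((len(uniq_sizes), p, p))
    logdetV = np.empty(len(uniq_sizes))
    eye = np.eye(p)
    for g, n_c in enumerate(uniq_sizes):
        V = S1 / n_c if S2 is None else S2 + S1 / n_c
        try:
            cv = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return -np.inf
        logdetV[g] = 2.0 * np.sum(np.log(np.diag(cv[0])))
        Vinv[g] = linalg.cho_solve(cv, eye, check_finite=False)
    counts_per_group = np.bincount(size_code, minlength=len(uniq_sizes)).astype(float)
    logdet_sum = counts_per_group @ logdetV
    u = np.einsum("cij,cj->ci", Vinv[size_code], d)
    q1 = float(np.einsum("ci,ci->", d, u))

    q2 = 0.0
    logdetB_sum = 0.0
    if use_school:
        starts = stats.school_starts
        A = np.add.reduceat(Vinv[size_code], starts, axis=0)  # S x p x p
        g_vec = np.add.reduceat(u, starts, axis=0)  # S x p
        B = eye + S3 @ A  # batched: (S, p, p)
        sign, ld = np.linalg.slogdet(B)
        if np.any(sign <= 0):
            return -np.inf
        logdetB_sum = float(np.sum(ld))
        try:
            M = np.linalg.solve(B, np.broadcast_to(S3, B.shape))  # (I + S3 A)^-1 S3... see note
        except np.linalg.LinAlgError:
            return -np.inf
        # M solves (I + S3 A) M = S3, i.e. M = (I + S3 A)^-1 S3 = S3 (I + A S3)^-1,
        # the symmetric Woodbury core; no inverse of S3 is ever taken.
        q2 = float(np.einsum("si,sij,sj->", g_vec, M, g_vec))

    ll += -0.5 * (logdet_sum + logdetB_sum) - 0.5 * (q1 - q2)
    ll += -0.5 * N * p * np.log(2.0 * np.pi)
    return float(ll)


# ---------------------------------------------------------------------------
# starting values


def moment_estimates(stats: SufficientStats, n_levels: int):
    """Crude moment-based decomposition (mu, Sigma_1, Sigma_2, Sigma_3 hats).

    Used only for starting values; diagonals are floored at a small positive
    fraction of the total variance so starts stay interior.
    """
    p, N, C = stats.p, stats.n, stats.n_classes
    mu_hat = stats.grand_mean.copy()
    if N > C:
        S1 = stats.s_w / (N - C)
    else:
        d = stats.class_means - mu_hat
        S1 = (d.T * stats.class_sizes) @ d / max(N - 1, 1)
    scale = float(np.mean(np.diag(S1))) or 1.0
    floor = 1e-3 * scale

    if C > 1:
        Bcls = np.cov(stats.class_means, rowvar=False).reshape(p, p)
        S23 = Bcls - S1 * float(np.mean(1.0 / stats.class_sizes))
    else:
        S23 = np.zeros((p, p))
    np.fill_diagonal(S23, np.maximum(np.diag(S23), floor))

    S3 = np.zeros((p, p))
    if n_levels == 3 and stats.school_starts is not None and stats.n_schools > 1:
        starts = stats.school_starts
        wsum = np.add.reduceat(stats.class_sizes, starts)
        smeans = np.add.reduceat(stats.class_means * stats.class_sizes[:, None], starts, axis=0)
        smeans /= wsum[:, None]
        Bsch = np.cov(smeans, rowvar=False).reshape(p, p)
        cbar = C / stats.n_schools
        nbar_s = N / stats.n_schools
        S3 = Bsch - S23 / cbar - S1 / nbar_s
        np.fill_diagonal(S3, np.clip(np.diag(S3), floor, None))
    S2 = S23 - S3
    np.fill_diagonal(S2, np.maximum(np.diag(S2), floor))
    sig = [S1, S2]
    if n_levels == 3:
        sig.append(S3)
    return mu_hat, sig[: max(n_levels, 1)]


def default_start(compiled: CompiledSpec, stats: SufficientStats) -> np.ndarray:
    """Data-driven starting values per parameter role.

    Identity-loading factors (saturated/independence specs) start at the
    moment estimate of the corresponding covariance cell; common-factor
    loadings split the within variance half/half with the residual; higher
    level factor variances start at the diagonal variance ratio.
    """
    spec = compiled.spec
    L = spec.n_levels
    mu_hat, sig_hat = moment_estimates(stats, L)
    while len(sig_hat) < L:
        sig_hat.append(np.zeros((stats.p, stats.p)))
    scale = float(np.mean(np.diag(sig_hat[0]))) or 1.0
    diag_mean = [max(float(np.mean(np.diag(s))), 1e-3 * scale) for s in sig_hat]

    def factor_kind(m: int, col: int) -> str:
        lam0 = compiled.lam0[m]
        has_free = any(c == col and lv == m for _, lv, _, c in compiled._lam_f)
        if not has_free:
            colvals = lam0[:, col]
            if np.count_nonzero(colvals) == 1 and np.isclose(colvals.sum(), 1.0):
                return "identity"
            return "doublet"
        return "common"

    x = np.empty(compiled.n_free)
    for idx, row in enumerate(compiled.table.rows):
        if row.start_value is not None:
            x[idx] = row.start_value
            continue
        s = row.slots[0]
        m = s.level - 1
        if s.matrix == "nu":
            x[idx] = mu_hat[s.row]
        elif s.matrix == "theta":
            x[idx] = max(0.5 * float(sig_hat[m][s.row, s.row]), 1e-3 * scale)
        elif s.matrix == "lambda":
            x[idx] = np.sqrt(max(0.5 * float(sig_hat[0][s.row, s.row]), 1e-3 * scale))
        elif s.matrix == "phi":
            kind = factor_kind(m, s.col)
            if kind == "identity":
                if s.row == s.col:
                    x[idx] = max(float(sig_hat[m][s.row, s.col]), 1e-3 * scale)
                else:
                    x[idx] = float(sig_hat[m][s.row, s.col])
            elif kind == "doublet":
                x[idx] = 0.05 * diag_mean[m] + 1e-3 * scale
            else:
                if s.row == s.col:
                    x[idx] = float(np.clip(diag_mean[m] / diag_mean[0], 0.02, 50.0))
                else:
                    x[idx] = 0.0
        else:  # pragma: no cover
            x[idx] = 0.1
    lower = compiled.lower_bounds
    bounded = np.isfinite(lower)
    x[bounded] = np.maximum(x[bounded], lower[bounded] + 1e-4 * scale)
    return x


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitOptions:
    """Optimizer settings; all stochastic elements are seeded."""

    maxiter: int = 500
    gtol: float = 1e-5
    ftol: float = 1e-11
    n_restarts: int = 3
    jitter: float = 0.25
    seed: int = 0
    start: np.ndarray | None = None


@dataclass
class FitResult:
    """Estimates, log-likelihood and convergence diagnostics of one fit."""

    spec: ModelSpec
    table: ParameterTable
    estimates: np.ndarray
    loglik: float
    converged: bool
    n_iterations: int
    gradient_norm: float
    n_free: int
    n_obs: int
    n_classes: int
    n_schools: int
    data_fingerprint: str
    std_errors: np.ndarray | None = None
    boundary: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def estimate(self, label: str) -> float:
        for r, est in zip(self.table.rows, self.estimates):
            if r.label == label:
                return float(est)
        raise KeyError(label)

    def estimates_by_label(self) -> dict:
        return {r.label: float(e) for r, e in zip(self.table.rows, self.estimates)}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.table.rows):
            s = r.slots[0]
            rows.append(
                {
                    "label": r.label,
                    "level": s.level,
                    "matrix": s.matrix,
                    "row": s.row,
                    "col": s.col,
                    "estimate": float(self.estimates[i]),
                    "se": (
                        float(self.std_errors[i])
                        if self.std_errors is not None and np.isfinite(self.std_errors[i])
                        else np.nan
                    ),
                    "at_boundary": bool(self.boundary[i]) if self.boundary is not None else False,
                }
            )
        return pd.DataFrame(rows)

    def implied(self) -> ImpliedMoments:
        return implied_moments(self.spec, self.estimates)

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "gradient_norm": self.gradient_norm,
            "n_free_parameters": self.n_free,
            "n_obs": self.n_obs,
            "n_classes": self.n_classes,
            "n_schools": self.n_schools,
            "estimates": self.to_frame().to_dict(orient="records"),
        }


def _make_objective(compiled: CompiledSpec, stats: SufficientStats):
    def nll(x):
        try:
            mo = compiled.moments(x)
        except ValueError:
            return _PENALTY
        ll = loglik(stats, mo)
        if not np.isfinite(ll):
            return _PENALTY
        return -ll

    return nll


def fit_ml(spec: ModelSpec, data, options: FitOptions | None = None) -> FitResult:
    """Maximize the structured likelihood over the spec's free parameters.

    Deterministic given (data, spec, options): starting values are
    moment-based and restart jitter is drawn from ``options.seed``.
    Nonconvergence is reported in ``converged``/``diagnostics``, never
    silently ignored.
    """
    opts = options or FitOptions()
    stats = _as_stats(data)
    if spec.p != stats.p:
        raise ValueError(f"spec has p={spec.p} but data has p={stats.p}")
    if spec.n_levels == 3 and stats.school_starts is None:
        raise ValueError("three-level spec requires data with a school level")
    compiled = compile_spec(spec)
    nll = _make_objective(compiled, stats)
    lower = compiled.lower_bounds
    bounds = [(lb if np.isfinite(lb) else None, None) for lb in lower]
    x0 = np.asarray(opts.start, dtype=float) if opts.start is not None else default_start(compiled, stats)
    if x0.shape != (compiled.n_free,):
        raise ValueError("start vector has wrong length")
    x0 = np.where(np.isfinite(lower), np.maximum(x0, lower), x0)

    rng = np.random.default_rng(opts.seed)
    scale = max(float(np.mean(np.diag(stats.s_w)) / max(stats.n - stats.n_classes, 1)), 1e-6)
    best = None
    n_attempts = 0
    for attempt in range(1 + opts.n_restarts):
        if attempt == 0:
            xa = x0
        else:
            xa = x0 * (1.0 + opts.jitter * rng.standard_normal(x0.shape))
            xa = xa + 0.05 * np.sqrt(scale) * rng.standard_normal(x0.shape)
            xa = np.where(np.isfinite(lower), np.maximum(xa, lower + 1e-4 * scale), xa)
        res = optimize.minimize(
            nll,
            xa,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": opts.maxiter,
                "maxfun": 50 * opts.maxiter * max(compiled.n_free, 1),
                "ftol": opts.ftol,
                "gtol": opts.gtol,
            },
        )
        n_attempts += 1
        ok = bool(res.success) and np.isfinite(res.fun) and res.fun < _PENALTY / 10
        if best is None or res.fun < best[0].fun:
            best = (res, ok)
        if ok:
            break
    res, converged = best
    grad_norm = float(np.max(np.abs(res.jac))) if np.all(np.isfinite(res.jac)) else np.inf
    est = np.asarray(res.x, dtype=float)
    tol_b = 1e-6 * max(scale, 1.0)
    boundary = np.where(np.isfinite(lower), est - lower <= tol_b, False)
    result = FitResult(
        spec=spec,
        table=compiled.table,
        estimates=est,
        loglik=float(-res.fun),
        converged=converged,
        n_iterations=int(res.nit),
        gradient_norm=grad_norm,
        n_free=compiled.n_free,
        n_obs=stats.n,
        n_classes=stats.n_classes,
        n_schools=stats.n_schools,
        data_fingerprint=stats.fingerprint,
        boundary=boundary,
        diagnostics={
            "n_attempts": n_attempts,
            "optimizer_message": str(res.message),
            "optimizer_success": bool(res.success),
        },
    )
    for r, e in zip(compiled.table.rows, est):
        r.estimate = float(e)
    if not converged:
        logger.warning("fit of %r did not converge: %s", spec.name, res.message)
    return result


def _unstructured_start(spec: ModelSpec, stats: SufficientStats) -> np.ndarray:
    compiled = compile_spec(spec)
    return default_start(compiled, stats)


def fit_saturated(data, n_levels: int | None = None, options: FitOptions | None = None) -> FitResult:
    """ML fit of the unstructured model: free mu and free Sigma_m per level.

    Its log-likelihood is the reference point for the model chi-square.  For
    single-level data this is the closed-form sample mean / ML covariance,
    found numerically through the same engine.  With few higher-level
    clusters the unstructured Sigma_3 may be inestimable; that surfaces as
    ``converged=False`` with restart diagnostics rather than an exception.
    """
    stats = _as_stats(data)
    if n_levels is None:
        n_levels = 3 if stats.school_starts is not None else 2
    spec = saturated_spec(stats.p, n_levels, stats.indicator_names)
    return fit_ml(spec, stats, options)


def fit_independence(data, n_levels: int | None = None, options: FitOptions | None = None) -> FitResult:
    """ML fit with diagonal Sigma_m at every level and free means (CFI baseline)."""
    stats = _as_stats(data)
    if n_levels is None:
        n_levels = 3 if stats.school_starts is not None else 2
    spec = independence_spec(stats.p, n_levels, stats.indicator_names)
    return fit_ml(spec, stats, options)


# ---------------------------------------------------------------------------
# standard errors


def standard_errors(fit: FitResult, data, h_rel: float = 1e-4) -> FitResult:
    """Attach SEs from the inverse observed information (numeric Hessian).

    Second differences of the log-likelihood at the optimum; parameters
    pinned at their lower bound are excluded (flagged, no SE), since the
    information matrix is not the right curvature object on the boundary.
    """
    if not fit.converged:
        raise ValueError("standard errors require a converged fit")
    stats = _as_stats(data)
    if stats.fingerprint != fit.data_fingerprint:
        raise ValueError("data does not match the data used for the fit")
    compiled = compile_spec(fit.spec)
    nll = _make_objective(compiled, stats)
    x = fit.estimates.copy()
    free = ~fit.boundary
    idx = np.flatnonzero(free)
    q = len(idx)
    se = np.full(fit.n_free, np.nan)
    if q:
        h = h_rel * np.maximum(np.abs(x[idx]), 1.0)
        H = np.empty((q, q))
        f0 = nll(x)
        for a in range(q):
            ia = idx[a]
            for b in range(a, q):
                ib = idx[b]
                if a == b:
                    xp, xm = x.copy(), x.copy()
                    xp[ia] += h[a]
                    xm[ia] -= h[a]
                    H[a, a] = (nll(xp) - 2 * f0 + nll(xm)) / h[a] ** 2
                else:
                    xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
                    xpp[ia] += h[a]
                    xpp[ib] += h[b]
                    xpm[ia] += h[a]
                    xpm[ib] -= h[b]
                    xmp[ia] -= h[a]
                    xmp[ib] += h[b]
                    xmm[ia] -= h[a]
                    xmm[ib] -= h[b]
                    H[a, b] = H[b, a] = (nll(xpp) - nll(xpm) - nll(xmp) + nll(xmm)) / (
                        4 * h[a] * h[b]
                    )
        try:
            cov = linalg.inv(H)
            diag = np.diag(cov)
            good = diag > 0
            se_vals = np.full(q, np.nan)
            se_vals[good] = np.sqrt(diag[good])
            se[idx] = se_vals
            failed = not np.all(good)
        except linalg.LinAlgError:
            failed = True
    else:
        failed = False
    fit.std_errors = se
    fit.diagnostics["se_information_singular"] = bool(failed)
    for r, s_val in zip(fit.table.rows, se):
        r.std_error = float(s_val) if np.isfinite(s_val) else None
    return fit
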