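"""Synthetic multilevel factor data and Monte-Carlo studies.

Data are generated from the three-level random-effects factor model

    y = tau + lambda * (eta_3 + eta_2 + eta_1) + doublet terms
          + e_1 [+ e_2 + e_3],

with all latent components independent normal.  Nonzero residual terms
``e_2``/``e_3`` at the class/school level inject strong-invariance
violations (cluster bias); a per-cluster loading perturbation injects a
weak-invariance violation, which the cluster-bias test flags through the
same higher-level residual variance.

Studies spawn independent per-replicate random substreams from one master
seed, so rejection rates are reproducible bit-for-bit and replicates are
order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import engine, inference
from .engine import FitOptions, HierarchicalData
from .model_spec import build_cluster_bias_models, with_residuals_fixed

__all__ = [
    "DoubletTruth",
    "SimulationDesign",
    "StudyResult",
    "simulate_dataset",
    "type1_error_study",
    "power_study",
]


@dataclass
class DoubletTruth:
    """True structure of one doublet (method) factor: unit loadings on
    ``indicators``, one variance per level."""

    indicators: tuple
    variances: tuple  # length n_levels

    def __post_init__(self):
        self.indicators = tuple(int(i) for i in self.indicators)
        self.variances = tuple(float(v) for v in self.variances)


@dataclass
class SimulationDesign:
    """Cluster layout plus generating parameter values.

    ``classes_per_school`` / ``students_per_class`` accept a constant, a
    per-school (per-class) list, or ``{"choices": [...], "probs": [...]}``
    to draw unbalanced sizes from a discrete distribution.  ``phi`` holds
    the common-factor variance per level (Level 1 first; length 2 for
    two-level designs); ``residual_var`` one length-p vector per level
    (zeros at a higher level encode the invariance null).
    ``loading_sd_level2`` > 0 perturbs the loading vector per class
    (weak-invariance violation).
    """

    n_schools: int
    classes_per_school: object
    students_per_class: object
    loadings: Sequence
    phi: Sequence
    residual_var: Sequence
    intercepts: Sequence | None = None
    doublets: Sequence = ()
    loading_sd_level2: float = 0.0
    n_levels: int = 3
    seed: int = 0

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.phi = tuple(float(v) for v in self.phi)
        self.residual_var = [np.asarray(v, dtype=float) for v in self.residual_var]
        p = len(self.loadings)
        self.intercepts = (
            np.zeros(p) if self.intercepts is None else np.asarray(self.intercepts, dtype=float)
        )
        self.doublets = tuple(
            d if isinstance(d, DoubletTruth) else DoubletTruth(*d) for d in self.doublets
        )
        if self.n_levels not in (2, 3):
            raise ValueError("n_levels must be 2 or 3")
        if len(self.phi) != self.n_levels:
            raise ValueError("phi needs one variance per level")
        if len(self.residual_var) != self.n_levels:
            raise ValueError("residual_var needs one vector per level")
        for v in self.residual_var:
            if v.shape != (p,):
                raise ValueError("each residual_var vector must have length p")
            if np.any(v < 0):
                raise ValueError("variances must be nonnegative")
        if min(self.phi) < 0:
            raise ValueError("factor variances must be nonnegative")
        if self.n_schools < 1:
            raise ValueError("at least one school")
        for d in self.doublets:
            if len(d.variances) != self.n_levels:
                raise ValueError("doublet variances need one value per level")
            for i in d.indicators:
                if not (0 <= i < p):
                    raise ValueError(f"doublet index {i} out of range")

    @property
    def p(self) -> int:
        return len(self.loadings)

    def doublet_index_sets(self) -> list:
        return [set(d.indicators) for d in self.doublets]


def _draw_sizes(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec, dict):
        choices = np.asarray(spec["choices"], dtype=int)
        probs = np.asarray(spec.get("probs")) if spec.get("probs") is not None else None
        return rng.choice(choices, size=n, p=probs)
    arr = np.atleast_1d(np.asarray(spec, dtype=int))
    if arr.size == 1:
        return np.full(n, int(arr[0]))
    if arr.size != n:
        raise ValueError(f"size list has {arr.size} entries, expected {n}")
    return arr


def simulate_dataset(design: SimulationDesign, seed: int | None = None) -> HierarchicalData:
    """Draw one dataset from the design; deterministic given the seed.

    ``seed`` overrides ``design.seed``; it may also be a
    ``numpy.random.SeedSequence`` or ``Generator`` (used by the study
    drivers to hand each replicate its own substream).
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(design.seed if seed is None else seed)
    p = design.p
    lam = design.loadings
    three = design.n_levels == 3
    n_schools = design.n_schools if three else 1
    cps = _draw_sizes(design.classes_per_school, n_schools, rng)
    n_classes = int(cps.sum())
    spc = _draw_sizes(design.students_per_class, n_classes, rng)
    N = int(spc.sum())

    school_of_class = np.repeat(np.arange(n_schools), cps)
    class_of_row = np.repeat(np.arange(n_classes), spc)
    school_of_row = school_of_class[class_of_row]

    Y = np.tile(design.intercepts, (N, 1))

    # school-level components
    if three:
        eta3 = rng.normal(0.0, np.sqrt(design.phi[2]), n_schools)
        e3 = rng.normal(0.0, np.sqrt(design.residual_var[2]), (n_schools, p))
        Y += np.outer(eta3[school_of_row], lam) + e3[school_of_row]
    # class-level components
    eta2 = rng.normal(0.0, np.sqrt(design.phi[1]), n_classes)
    e2 = rng.normal(0.0, np.sqrt(design.residual_var[1]), (n_classes, p))
    if design.loading_sd_level2 > 0:
        lam_c = lam + rng.normal(0.0, design.loading_sd_level2, (n_classes, p))
        Y += lam_c[class_of_row] * eta2[class_of_row, None] + e2[class_of_row]
    else:
        Y += np.outer(eta2[class_of_row], lam) + e2[class_of_row]
    # student-level components
    eta1 = rng.normal(0.0, np.sqrt(design.phi[0]), N)
    e1 = rng.normal(0.0, np.sqrt(design.residual_var[0]), (N, p))
    if design.loading_sd_level2 > 0:
        Y += lam_c[class_of_row] * eta1[:, None] + e1
    else:
        Y += np.outer(eta1, lam) + e1
    # doublet (method) factors, orthogonal to the common factor
    for d in design.doublets:
        mask = np.zeros(p)
        mask[list(d.indicators)] = 1.0
        if three and d.variances[2] > 0:
            f3 = rng.normal(0.0, np.sqrt(d.variances[2]), n_schools)
            Y += np.outer(f3[school_of_row], mask)
        if d.variances[1] > 0:
            f2 = rng.normal(0.0, np.sqrt(d.variances[1]), n_classes)
            Y += np.outer(f2[class_of_row], mask)
        if d.variances[0] > 0:
            f1 = rng.normal(0.0, np.sqrt(d.variances[0]), N)
            Y += np.outer(f1, mask)

    names = tuple(f"y{j + 1}" for j in range(p))
    class_labels = np.array([f"s{s + 1}c{c + 1}" for s, c in zip(school_of_class, np.arange(n_classes))])
    # class label indexes globally; prefix keeps (school, class) canonical
    class_id = class_labels[class_of_row]
    school_id = (
        np.array([f"s{s + 1}" for s in school_of_row]) if three else None
    )
    return HierarchicalData(Y, class_id, school_id, names)


def implied_level_covariances(design: SimulationDesign) -> list:
    """The design's level-wise covariance matrices (for diagnostics/tests)."""
    lam = design.loadings
    out = []
    for m in range(design.n_levels):
        s = design.phi[m] * np.outer(lam, lam) + np.diag(design.residual_var[m])
        for d in design.doublets:
            mask = np.zeros(design.p)
            mask[list(d.indicators)] = 1.0
            s = s + d.variances[m] * np.outer(mask, mask)
        out.append(s)
    return out


@dataclass
class StudyResult:
    """Replicate-level outcomes of a Monte-Carlo study of the Delta-chisq test."""

    n_replicates: int
    tested_level: int
    alphas: tuple
    delta_chisq: np.ndarray
    p_values: np.ndarray
    converged: np.ndarray
    master_seed: int
    unreliable: bool = field(init=False)

    def __post_init__(self):
        frac_bad = 1.0 - float(np.mean(self.converged))
        self.unreliable = frac_bad > 0.20

    def rejection_rate(self, alpha: float) -> float:
        ok = self.converged
        if not ok.any():
            return float("nan")
        return float(np.mean(self.p_values[ok] < alpha))

    def mc_se(self, alpha: float) -> float:
        r = self.rejection_rate(alpha)
        m = int(self.converged.sum())
        return float(np.sqrt(r * (1.0 - r) / m)) if m else float("nan")

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "tested_level": self.tested_level,
            "master_seed": self.master_seed,
            "n_converged": int(self.converged.sum()),
            "unreliable": self.unreliable,
            "rejection_rates": {
                f"{a:g}": {"rate": self.rejection_rate(a), "mc_se": self.mc_se(a)}
                for a in self.alphas
            },
        }

    def summary(self) -> str:
        lines = [
            f"Monte-Carlo study of the Level-{self.tested_level} difference test: "
            f"{int(self.converged.sum())}/{self.n_replicates} replicates converged"
            + (" (UNRELIABLE: >20% nonconvergence)" if self.unreliable else "")
        ]
        for a in self.alphas:
            lines.append(
                f"  alpha={a:g}: rejection rate {self.rejection_rate(a):.3f} "
                f"(MC-SE {self.mc_se(a):.3f})"
            )
        return "\n".join(lines)


def _difference_study(
    design: SimulationDesign,
    n_replicates: int,
    alphas,
    tested_level: int,
    seed: int | None,
    fit_options: FitOptions | None,
) -> StudyResult:
    if tested_level not in (2, 3):
        raise ValueError("tested_level must be 2 or 3")
    if tested_level == 3 and design.n_levels != 3:
        raise ValueError("testing Level 3 requires a three-level design")
    alphas = tuple(np.atleast_1d(alphas).astype(float))
    master = design.seed if seed is None else int(seed)
    streams = np.random.SeedSequence(master).spawn(n_replicates)
    models = build_cluster_bias_models(
        design.p, design.doublet_index_sets(), n_levels=design.n_levels
    )
    constrained_spec = (
        models.level2_constrained if tested_level == 2 else models.level3_constrained
    )
    opts = fit_options or FitOptions()

    delta = np.full(n_replicates, np.nan)
    pvals = np.full(n_replicates, np.nan)
    conv = np.zeros(n_replicates, dtype=bool)
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        data = simulate_dataset(design, seed=rng)
        stats = engine.compute_sufficient_stats(data)
        full = engine.fit_ml(models.baseline, stats, opts)
        warm = inference._warm_start(full, constrained_spec)
        restricted = engine.fit_ml(
            constrained_spec, stats, inference._with_start(opts, warm)
        )
        if not (full.converged and restricted.converged):
            continue
        test = inference.chisq_difference(restricted, full)
        delta[r] = test.delta_chisq
        pvals[r] = test.p_value
        conv[r] = True
    return StudyResult(
        n_replicates=n_replicates,
        tested_level=tested_level,
        alphas=alphas,
        delta_chisq=delta,
        p_values=pvals,
        converged=conv,
        master_seed=master,
    )


def type1_error_study(
    design: SimulationDesign,
    n_replicates: int,
    alphas=(0.05,),
    tested_level: int = 3,
    seed: int | None = None,
    fit_options: FitOptions | None = None,
) -> StudyResult:
    """Empirical rejection rate of the Delta-chisq test under the null.

    The design must satisfy the null at the tested level (zero residual
    variance there); the boundary mixture makes the central chi-square
    reference conservative, so the rate should fall at or below the nominal
    alpha.
    """
    if n_replicates < 50:
        raise ValueError("use at least 50 replicates for a rate estimate")
    null_resid = design.residual_var[tested_level - 1]
    if np.any(null_resid != 0):
        raise ValueError(
            f"design violates the Level-{tested_level} null: residual variances "
            f"{null_resid.tolist()} are not all zero"
        )
    return _difference_study(design, n_replicates, alphas, tested_level, seed, fit_options)


def power_study(
    design: SimulationDesign,
    n_replicates: int,
    alphas=(0.05,),
    tested_level: int = 2,
    seed: int | None = None,
    fit_options: FitOptions | None = None,
) -> StudyResult:
    """Rejection rate with bias injected at the tested level (power estimate).

    With zero injected bias this degenerates to the type-I error rate.
    """
    return _difference_study(design, n_replicates, alphas, tested_level, seed, fit_options)
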