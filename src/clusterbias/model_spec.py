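"""Specification of two- and three-level confirmatory factor models.

A multilevel factor model decomposes the total covariance matrix of p
indicators into independent level-wise components, e.g. for three-level
data (students in classes in schools)::

    Sigma_total = Sigma_L3 + Sigma_L2 + Sigma_L1,
    Sigma_Lm    = Lambda_m Phi_m Lambda_m' + Theta_m,

with per-level loadings ``Lambda_m`` (p x k), factor covariances ``Phi_m``
(k x k) and diagonal residual variances ``Theta_m``.  Every matrix cell is a
*pattern entry*: either :class:`Fixed` at a numeric value or :class:`Free`
with a label.  Two free entries sharing a label are constrained equal, which
is how cross-level loading equality (the invariance restriction) is encoded.

The module builds the three model specs used by the test for cluster bias
(:func:`build_cluster_bias_models`), counts free parameters and degrees of
freedom, validates identification heuristics, and round-trips specs through
a plain YAML/JSON-able dictionary form.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence, Union

import yaml

__all__ = [
    "Fixed",
    "Free",
    "LoadingPattern",
    "LevelModel",
    "ModelSpec",
    "ParamRow",
    "ParameterTable",
    "Slot",
    "ClusterBiasModels",
    "build_cluster_bias_models",
    "with_residuals_fixed",
    "saturated_spec",
    "independence_spec",
    "count_free_parameters",
    "degrees_of_freedom",
    "validate",
    "spec_to_dict",
    "spec_from_dict",
    "spec_to_yaml",
    "spec_from_yaml",
]


class Fixed(NamedTuple):
    """A pattern entry fixed at a constant value."""

    value: float


class Free(NamedTuple):
    """A free pattern entry.

    Entries sharing a ``label`` are estimated as one parameter (equality
    constraint).  ``start`` optionally overrides the data-driven default
    starting value.
    """

    label: str
    start: float | None = None


Entry = Union[Fixed, Free]


def _entry_to_str(entry: Entry) -> str:
    if isinstance(entry, Fixed):
        return f"fix:{entry.value:g}"
    if entry.start is None:
        return f"free:{entry.label}"
    return f"free:{entry.label}:{entry.start:g}"


def _entry_from_str(s: str) -> Entry:
    parts = str(s).split(":")
    if parts[0] == "fix" and len(parts) == 2:
        return Fixed(float(parts[1]))
    if parts[0] == "free" and len(parts) in (2, 3):
        start = float(parts[2]) if len(parts) == 3 else None
        return Free(parts[1], start)
    raise ValueError(f"unparseable pattern entry {s!r}")


def _check_entry(entry: Entry, where: str) -> None:
    if not isinstance(entry, (Fixed, Free)):
        raise TypeError(f"{where}: expected Fixed or Free, got {entry!r}")


@dataclass(frozen=True)
class LoadingPattern:
    """p x k grid of loading entries with indicator and factor names."""

    entries: tuple
    indicator_names: tuple
    factor_names: tuple

    def __post_init__(self):
        entries = tuple(tuple(row) for row in self.entries)
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "indicator_names", tuple(self.indicator_names))
        object.__setattr__(self, "factor_names", tuple(self.factor_names))
        p, k = len(entries), len(self.factor_names)
        if p < 1 or k < 1:
            raise ValueError("loading pattern needs p >= 1 indicators and k >= 1 factors")
        if len(self.indicator_names) != p:
            raise ValueError("indicator_names length does not match rows")
        for i, row in enumerate(entries):
            if len(row) != k:
                raise ValueError(f"loading row {i} has {len(row)} entries, expected {k}")
            for j, e in enumerate(row):
                _check_entry(e, f"loading[{i},{j}]")

    @property
    def p(self) -> int:
        return len(self.entries)

    @property
    def k(self) -> int:
        return len(self.factor_names)


@dataclass(frozen=True)
class LevelModel:
    """Factor structure of one level: loadings, factor covariance, residuals.

    ``factor_cov`` is a k x k symmetric pattern; ``residual_var`` holds the
    p diagonal entries of Theta (Theta is diagonal by construction at every
    level -- specific covariances are modelled as doublet factors instead).
    """

    level_index: int
    loadings: LoadingPattern
    factor_cov: tuple
    residual_var: tuple

    def __post_init__(self):
        fc = tuple(tuple(row) for row in self.factor_cov)
        object.__setattr__(self, "factor_cov", fc)
        object.__setattr__(self, "residual_var", tuple(self.residual_var))
        k, p = self.loadings.k, self.loadings.p
        if len(fc) != k or any(len(row) != k for row in fc):
            raise ValueError("factor_cov must be k x k")
        for i in range(k):
            for j in range(k):
                _check_entry(fc[i][j], f"factor_cov[{i},{j}]")
                if fc[i][j] != fc[j][i]:
                    raise ValueError("factor_cov pattern must be symmetric")
        if len(self.residual_var) != p:
            raise ValueError("residual_var must have p entries")
        for j, e in enumerate(self.residual_var):
            _check_entry(e, f"residual_var[{j}]")


@dataclass(frozen=True)
class ModelSpec:
    """An ordered stack of level models (Level 1 first) plus intercepts.

    Cross-level equality constraints are carried by shared ``Free`` labels;
    the canonical use is one shared label per indicator's loading, which
    ties Lambda across levels (the invariance restriction).
    """

    levels: tuple
    intercepts: tuple
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(self.levels))
        object.__setattr__(self, "intercepts", tuple(self.intercepts))
        L = len(self.levels)
        if L not in (1, 2, 3):
            raise ValueError("a spec has 1, 2 or 3 levels")
        p = self.levels[0].loadings.p
        for m, lv in enumerate(self.levels, start=1):
            if lv.level_index != m:
                raise ValueError("levels must be ordered Level 1 first with indices 1..L")
            if lv.loadings.p != p:
                raise ValueError("all levels must share the indicator count p")
            if lv.loadings.indicator_names != self.levels[0].loadings.indicator_names:
                raise ValueError("all levels must share indicator order")
        if len(self.intercepts) != p:
            raise ValueError("intercepts must have p entries")
        for j, e in enumerate(self.intercepts):
            _check_entry(e, f"intercepts[{j}]")

    @property
    def p(self) -> int:
        return self.levels[0].loadings.p

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def indicator_names(self) -> tuple:
        return self.levels[0].loadings.indicator_names

    def parameter_table(self) -> "ParameterTable":
        return ParameterTable.from_spec(self)


class Slot(NamedTuple):
    """Position of one matrix cell: (level, matrix, row, col).

    ``matrix`` is one of ``lambda | phi | theta | nu``; intercepts use
    level 0 (they belong to the mean structure, not to a covariance level).
    """

    level: int
    matrix: str
    row: int
    col: int


@dataclass
class ParamRow:
    label: str
    slots: list
    lower_bound: float
    start_value: float | None = None
    estimate: float | None = None
    std_error: float | None = None


@dataclass
class ParameterTable:
    """Free parameters of a spec: one row per distinct label.

    Slots of one row all receive the same value when a parameter vector is
    expanded into matrices; variance-type rows carry lower bound 0.
    """

    rows: list

    @classmethod
    def from_spec(cls, spec: ModelSpec) -> "ParameterTable":
        index: dict = {}
        rows: list = []

        def add(entry: Entry, slot: Slot, is_variance: bool):
            if not isinstance(entry, Free):
                return
            row = index.get(entry.label)
            if row is None:
                row = ParamRow(
                    label=entry.label,
                    slots=[slot],
                    lower_bound=0.0 if is_variance else -math.inf,
                    start_value=entry.start,
                )
                index[entry.label] = row
                rows.append(row)
            else:
                row.slots.append(slot)
                if is_variance:
                    row.lower_bound = max(row.lower_bound, 0.0)
                if row.start_value is None and entry.start is not None:
                    row.start_value = entry.start

        for lv in spec.levels:
            m = lv.level_index
            p, k = lv.loadings.p, lv.loadings.k
            for i in range(p):
                for j in range(k):
                    add(lv.loadings.entries[i][j], Slot(m, "lambda", i, j), False)
            for i in range(k):
                for j in range(i + 1):
                    add(lv.factor_cov[i][j], Slot(m, "phi", i, j), i == j)
            for j in range(p):
                add(lv.residual_var[j], Slot(m, "theta", j, j), True)
        for j in range(spec.p):
            add(spec.intercepts[j], Slot(0, "nu", j, 0), False)
        return cls(rows=rows)

    @property
    def labels(self) -> list:
        return [r.label for r in self.rows]

    def __len__(self) -> int:
        return len(self.rows)


def count_free_parameters(spec: ModelSpec) -> int:
    """Number of distinct free parameters (equality-tied entries count once)."""
    return len(spec.parameter_table())


def degrees_of_freedom(spec: ModelSpec) -> int:
    """Sample moments minus free parameters.

    The moment count is p means plus one p x p covariance matrix per level:
    ``p + L * p(p+1)/2``.
    """
    p, L = spec.p, spec.n_levels
    moments = p + L * p * (p + 1) // 2
    df = moments - count_free_parameters(spec)
    if df < 0:
        raise ValueError(
            f"over-parameterized spec: {count_free_parameters(spec)} free parameters "
            f"but only {moments} sample moments"
        )
    return df


def validate(spec: ModelSpec) -> list:
    """Identification and admissibility heuristics; findings, not exceptions.

    An empty list means the spec looks structurally admissible. Checks:
    negative fixed variances, factors with no scale restriction at any
    level, and labels reused across slots with incompatible bounds.
    """
    findings: list = []

    # negative fixed variances
    for lv in spec.levels:
        for j, e in enumerate(lv.residual_var):
            if isinstance(e, Fixed) and e.value < 0:
                findings.append(
                    f"negative fixed variance: Theta level {lv.level_index} "
                    f"indicator {j} = {e.value}"
                )
        for i in range(lv.loadings.k):
            e = lv.factor_cov[i][i]
            if isinstance(e, Fixed) and e.value < 0:
                findings.append(
                    f"negative fixed variance: Phi level {lv.level_index} factor {i} = {e.value}"
                )

    # scale restriction per (level, factor): the factor variance is fixed,
    # or some loading is fixed nonzero, or its loading labels are shared
    # with a level where one of those holds (cross-level tie sets the scale).
    def scaled_locally(lv: LevelModel, col: int) -> bool:
        if isinstance(lv.factor_cov[col][col], Fixed):
            return True
        return any(
            isinstance(lv.loadings.entries[i][col], Fixed)
            and lv.loadings.entries[i][col].value != 0
            for i in range(lv.loadings.p)
        )

    for lv in spec.levels:
        for col in range(lv.loadings.k):
            if scaled_locally(lv, col):
                continue
            labels = {
                e.label
                for e in (lv.loadings.entries[i][col] for i in range(lv.loadings.p))
                if isinstance(e, Free)
            }
            tied_ok = any(
                other is not lv
                and scaled_locally(other, col)
                and col < other.loadings.k
                and labels
                and labels
                & {
                    e.label
                    for e in (other.loadings.entries[i][col] for i in range(other.loadings.p))
                    if isinstance(e, Free)
                }
                for other in spec.levels
            )
            if not tied_ok:
                findings.append(
                    f"no scale restriction for factor "
                    f"{lv.loadings.factor_names[col]!r} at level {lv.level_index}"
                )

    # incompatible reuse of a label across variance and unbounded slots
    table = spec.parameter_table()
    for row in table.rows:
        kinds = {s.matrix for s in row.slots}
        if row.lower_bound == 0.0 and ("lambda" in kinds or "nu" in kinds):
            findings.append(
                f"label {row.label!r} shared between a variance slot and an "
                f"unbounded slot"
            )
    return findings


# ---------------------------------------------------------------------------
# builders


class ClusterBiasModels(NamedTuple):
    baseline: ModelSpec
    level2_constrained: ModelSpec
    level3_constrained: ModelSpec | None


def _default_names(p: int, doublet_sets) -> tuple:
    ind = tuple(f"y{j + 1}" for j in range(p))
    fac = ("g",) + tuple(f"d{m + 1}" for m in range(len(doublet_sets)))
    return ind, fac


def build_cluster_bias_models(
    p: int,
    doublet_sets: Sequence = (),
    n_levels: int = 3,
    indicator_names: Sequence | None = None,
    fix_first_loading: bool = False,
) -> ClusterBiasModels:
    """Construct the baseline and constrained specs of the cluster-bias test.

    The baseline model has one common factor with loadings free but tied
    across all levels, common-factor variance fixed at 1 at Level 1 and free
    at the higher levels, free diagonal residual variances everywhere, and
    free intercepts.  Each ``doublet_sets`` entry adds an orthogonal method
    factor with loadings fixed at 1 on its indicators and a free variance at
    every level (the reparameterization of a residual covariance).

    ``level2_constrained`` fixes all p Level-2 residual variances at zero
    (doublet variances stay free); ``level3_constrained`` does the same at
    Level 3.  For ``n_levels=2`` the third spec is ``None``.

    ``fix_first_loading=True`` selects the alternative identification (first
    common-factor loading fixed at 1, Level-1 factor variance free).

    Parameters use 0-based indicator indices.
    """
    if p < 3:
        raise ValueError(f"p={p}: at least 3 indicators are needed to identify a factor model")
    if n_levels not in (2, 3):
        raise ValueError("n_levels must be 2 or 3")
    doublet_sets = [sorted(set(int(i) for i in s)) for s in doublet_sets]
    seen: set = set()
    for s in doublet_sets:
        if len(s) < 2:
            raise ValueError(f"doublet set {s} needs at least 2 distinct indicators")
        for i in s:
            if not (0 <= i < p):
                raise ValueError(f"doublet indicator index {i} out of range for p={p}")
            if i in seen:
                raise ValueError(f"indicator {i} appears in more than one doublet set")
            seen.add(i)

    ind_names = tuple(indicator_names) if indicator_names else _default_names(p, doublet_sets)[0]
    if len(ind_names) != p:
        raise ValueError("indicator_names length must equal p")
    fac_names = _default_names(p, doublet_sets)[1]
    k = 1 + len(doublet_sets)

    def level_model(m: int) -> LevelModel:
        rows = []
        for i in range(p):
            row: list = []
            if fix_first_loading and i == 0:
                row.append(Fixed(1.0))
            else:
                row.append(Free(f"lam{i + 1}"))
            for d, members in enumerate(doublet_sets):
                row.append(Fixed(1.0) if i in members else Fixed(0.0))
            rows.append(tuple(row))
        loadings = LoadingPattern(tuple(rows), ind_names, fac_names)

        fc = [[Fixed(0.0)] * k for _ in range(k)]
        if fix_first_loading:
            fc[0][0] = Free(f"phi{m}")
        else:
            fc[0][0] = Fixed(1.0) if m == 1 else Free(f"phi{m}")
        for d in range(len(doublet_sets)):
            fc[d + 1][d + 1] = Free(f"psi{d + 1}_l{m}")
        theta = tuple(Free(f"theta{j + 1}_l{m}") for j in range(p))
        return LevelModel(m, loadings, tuple(tuple(r) for r in fc), theta)

    intercepts = tuple(Free(f"nu{j + 1}") for j in range(p))
    baseline = ModelSpec(
        levels=tuple(level_model(m) for m in range(1, n_levels + 1)),
        intercepts=intercepts,
        name="baseline",
    )
    l2 = with_residuals_fixed(baseline, 2, 0.0, name="level2_constrained")
    l3 = (
        with_residuals_fixed(baseline, 3, 0.0, name="level3_constrained")
        if n_levels == 3
        else None
    )
    return ClusterBiasModels(baseline, l2, l3)


def with_residuals_fixed(
    spec: ModelSpec, level_index: int, value: float = 0.0, name: str | None = None
) -> ModelSpec:
    """Copy of ``spec`` with all residual variances at one level fixed."""
    levels = []
    for lv in spec.levels:
        if lv.level_index == level_index:
            lv = replace(lv, residual_var=tuple(Fixed(value) for _ in lv.residual_var))
        levels.append(lv)
    if not any(lv.level_index == level_index for lv in spec.levels):
        raise ValueError(f"spec has no level {level_index}")
    return ModelSpec(tuple(levels), spec.intercepts, name=name or spec.name)


def _identity_loading_level(p: int, m: int, ind_names, pattern: str) -> LevelModel:
    """Level with Lambda = I fixed, Theta = 0 and a free Phi (full or diag)."""
    fac_names = tuple(f"f{j + 1}" for j in range(p))
    rows = tuple(
        tuple(Fixed(1.0) if i == j else Fixed(0.0) for j in range(p)) for i in range(p)
    )
    loadings = LoadingPattern(rows, ind_names, fac_names)
    fc = [[Fixed(0.0)] * p for _ in range(p)]
    for i in range(p):
        for j in range(i + 1):
            if i == j:
                fc[i][j] = Free(f"s{m}_{i + 1}_{j + 1}")
            elif pattern == "full":
                fc[i][j] = Free(f"s{m}_{i + 1}_{j + 1}")
            fc[j][i] = fc[i][j]
    theta = tuple(Fixed(0.0) for _ in range(p))
    return LevelModel(m, loadings, tuple(tuple(r) for r in fc), theta)


def saturated_spec(p: int, n_levels: int, indicator_names: Sequence | None = None) -> ModelSpec:
    """Unstructured mean vector plus one unstructured covariance per level."""
    ind = tuple(indicator_names) if indicator_names else tuple(f"y{j + 1}" for j in range(p))
    levels = tuple(_identity_loading_level(p, m, ind, "full") for m in range(1, n_levels + 1))
    intercepts = tuple(Free(f"nu{j + 1}") for j in range(p))
    return ModelSpec(levels, intercepts, name="saturated")


def independence_spec(p: int, n_levels: int, indicator_names: Sequence | None = None) -> ModelSpec:
    """Free means, diagonal covariance at every level (CFI baseline model)."""
    ind = tuple(indicator_names) if indicator_names else tuple(f"y{j + 1}" for j in range(p))
    levels = tuple(_identity_loading_level(p, m, ind, "diag") for m in range(1, n_levels + 1))
    intercepts = tuple(Free(f"nu{j + 1}") for j in range(p))
    return ModelSpec(levels, intercepts, name="independence")


# ---------------------------------------------------------------------------
# serialization


def spec_to_dict(spec: ModelSpec) -> dict:
    def level_dict(lv: LevelModel) -> dict:
        return {
            "level_index": lv.level_index,
            "factor_names": list(lv.loadings.factor_names),
            "loadings": [[_entry_to_str(e) for e in row] for row in lv.loadings.entries],
            "factor_cov": [[_entry_to_str(e) for e in row] for row in lv.factor_cov],
            "residual_var": [_entry_to_str(e) for e in lv.residual_var],
        }

    return {
        "name": spec.name,
        "indicator_names": list(spec.indicator_names),
        "levels": [level_dict(lv) for lv in spec.levels],
        "intercepts": [_entry_to_str(e) for e in spec.intercepts],
    }


def spec_from_dict(d: dict) -> ModelSpec:
    ind = tuple(d["indicator_names"])
    levels = []
    for lv in d["levels"]:
        loadings = LoadingPattern(
            tuple(tuple(_entry_from_str(e) for e in row) for row in lv["loadings"]),
            ind,
            tuple(lv["factor_names"]),
        )
        levels.append(
            LevelModel(
                int(lv["level_index"]),
                loadings,
                tuple(tuple(_entry_from_str(e) for e in row) for row in lv["factor_cov"]),
                tuple(_entry_from_str(e) for e in lv["residual_var"]),
            )
        )
    return ModelSpec(
        tuple(levels),
        tuple(_entry_from_str(e) for e in d["intercepts"]),
        name=d.get("name", ""),
    )


def spec_to_yaml(spec: ModelSpec) -> str:
    return yaml.safe_dump(spec_to_dict(spec), sort_keys=False)


def spec_from_yaml(text: str) -> ModelSpec:
    return spec_from_dict(yaml.safe_load(text))
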