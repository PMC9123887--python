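"""Grouped (hierarchical) GAM variants and posterior smooth contrasts.

For one candidate variable grouped by an environmental cluster factor the
family of nested models is:

* **G** — the global model, one smooth shared by all hours;
* **S** — the smooth replaced by per-cluster smooths under a single shared
  smoothing penalty (factor-smooth interaction, shared penalty);
* **I** — per-cluster smooths, each with its own smoothing penalty;
* **GS** — S plus a global smooth of the variable;
* **GI** — I plus a global smooth penalized on its squared *first*
  derivative, so the global component is shrunk harder than the
  cluster-level deviations.

Whenever a grouped smooth enters, the cluster factor itself is added as a
main effect so the group smooths (which are centered) only carry shape.

The posterior contrast follows the prediction-matrix route: build X_p rows
over a grid for each of the two clusters, zero every column not belonging
to the compared smooth blocks, subtract, and propagate the coefficient
covariance for pointwise confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .gam import BasisSpec, FittedGAM, ModelSpec, aic_weights, fit

VARIANTS = ("G", "S", "I", "GS", "GI")


@dataclass
class GroupedModelSpec:
    base: ModelSpec
    grouped_variable: str  # the label of the smooth in the base spec
    group_factor: str
    variant: str
    model: ModelSpec = field(init=False)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        self.model = build_grouped(
            self.base, self.grouped_variable, self.group_factor, self.variant
        )


def _find_smooth(base: ModelSpec, label: str) -> BasisSpec:
    for s in base.smooths:
        if s.label == label or s.variables == (label,) or ",".join(s.variables) == label:
            return s
    raise ValidationError(f"no smooth for {label!r} in base model")


def build_grouped(
    base: ModelSpec, variable: str, group_factor: str, variant: str
) -> ModelSpec:
    """Model spec for one variant of the grouped family (see module docs)."""
    if variant not in VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}")
    if variant == "G":
        return ModelSpec(base.response, list(base.smooths), list(base.linear))
    target = _find_smooth(base, variable)
    others = [s for s in base.smooths if s is not target]
    shared = variant in ("S", "GS")
    grouped = BasisSpec(
        kind=target.kind,
        variables=target.variables,
        k=target.k,
        by_group=group_factor,
        shared_penalty=shared,
        period=target.period,
    )
    smooths = [*others, grouped]
    if variant == "GS":
        smooths.append(target)
    elif variant == "GI":
        smooths.append(
            BasisSpec(
                kind=target.kind,
                variables=target.variables,
                k=target.k,
                penalty_order=1,
                period=target.period,
            )
        )
    linear = list(base.linear)
    if group_factor not in linear:
        linear.append(group_factor)
    return ModelSpec(base.response, smooths, linear)


def enumerate_grouped(
    base: ModelSpec, variables: list[str], group_factor: str
) -> list[GroupedModelSpec]:
    """All non-global variants for each candidate variable (the 4×4 family)."""
    return [
        GroupedModelSpec(base, v, group_factor, variant)
        for v in variables
        for variant in ("GS", "S", "GI", "I")
    ]


@dataclass
class ModelComparisonRow:
    variable: str
    variant: str
    aic: float
    delta_aic: float
    weight_all: float
    weight_row: float
    nonsignificant: list[str]


def compare_grouped(
    global_fit: FittedGAM,
    grouped_fits: dict[tuple[str, str], FittedGAM],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """δAIC (vs the global model) and AIC weights for the grouped family.

    Weights are reported two ways: across the whole compared set including
    the global model (``weight_all``) and within each variable's row of four
    variants (``weight_row``).
    """
    n_ref = global_fit.n
    for (var, variant), f in grouped_fits.items():
        if f.n != n_ref or not np.array_equal(f.y, global_fit.y):
            raise ValidationError(f"fit ({var},{variant}) was not made on the same records")
    rows = []
    all_aics = [global_fit.aic] + [f.aic for f in grouped_fits.values()]
    w_all = aic_weights(np.array(all_aics))
    keys = list(grouped_fits.keys())
    for var in sorted({v for v, _ in keys}):
        row_keys = [k for k in keys if k[0] == var]
        row_aics = np.array([global_fit.aic] + [grouped_fits[k].aic for k in row_keys])
        w_row = aic_weights(row_aics)
        for j, k in enumerate(row_keys):
            f = grouped_fits[k]
            rows.append(
                ModelComparisonRow(
                    variable=var,
                    variant=k[1],
                    aic=f.aic,
                    delta_aic=f.aic - global_fit.aic,
                    weight_all=float(w_all[1 + keys.index(k)]),
                    weight_row=float(w_row[1 + j]),
                    nonsignificant=f.nonsignificant_terms(alpha),
                ).__dict__
            )
    rows.append(
        ModelComparisonRow(
            variable="(global)",
            variant="G",
            aic=global_fit.aic,
            delta_aic=0.0,
            weight_all=float(w_all[0]),
            weight_row=np.nan,
            nonsignificant=global_fit.nonsignificant_terms(alpha),
        ).__dict__
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# smooth-difference contrast


@dataclass
class DifferenceCurve:
    grid: np.ndarray
    difference: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    group_a: object
    group_b: object
    significant_intervals: list[tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        sig = np.zeros(len(self.grid), dtype=bool)
        for lo, hi in self.significant_intervals:
            sig |= (self.grid >= lo) & (self.grid <= hi)
        return pd.DataFrame(
            {
                "grid": self.grid,
                "difference": self.difference,
                "se": self.se,
                "lower": self.lower,
                "upper": self.upper,
                "significant": sig,
            }
        )


def _significant_intervals(grid: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    flags = (lo > 0) | (hi < 0)
    out = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        if not f and start is not None:
            out.append((float(grid[start]), float(grid[i - 1])))
            start = None
    if start is not None:
        out.append((float(grid[start]), float(grid[-1])))
    return out


def smooth_difference(
    fitted: FittedGAM,
    term: str,
    group_a,
    group_b,
    n_grid: int = 200,
    level: float = 0.95,
    include_group_offset: bool = False,
) -> DifferenceCurve:
    """Pointwise contrast between two cluster-level smooths of one term.

    ``diff = X_new β̂`` and ``se² = diag(X_new V̂β X_newᵀ)`` where ``X_new`` is
    the difference of the two groups' prediction rows with every column not
    belonging to the compared smooth blocks set to zero.  Intervals are
    pointwise, at the stated level.  With ``include_group_offset`` the
    cluster main-effect dummies are retained, so the contrast includes the
    clusters' mean offset as well as their shape difference.
    """
    bterm = next((t for t in fitted.design.terms if t.label == term), None)
    if bterm is None:
        raise ValidationError(f"no term {term!r} in fit")
    if bterm.spec.by_group is None:
        raise ValidationError(f"term {term!r} is not grouped")
    for g in (group_a, group_b):
        if g not in bterm.levels:
            raise ValidationError(f"unknown group {g!r} for term {term!r}")

    if bterm.spec.kind == "tensor":
        raise ValidationError("smooth_difference supports univariate grouped terms")
    var = bterm.spec.variables[0]
    if bterm.spec.period is not None:
        lo, hi = bterm.spec.period
        grid_vals = np.linspace(lo, hi, n_grid, endpoint=False)
    else:
        lo, hi = bterm.var_ranges[var]
        grid_vals = np.linspace(lo, hi, n_grid)

    grid_df = pd.DataFrame({var: grid_vals})
    sl_term = fitted.design.term_slices[term]
    p = len(fitted.beta)

    def rows_for(group) -> np.ndarray:
        X = np.zeros((n_grid, p))
        X[:, sl_term] = bterm.predict_mat(grid_df, group=group)
        return X

    X_new = rows_for(group_a) - rows_for(group_b)
    # zero everything outside the compared smooth blocks
    keep = np.zeros(p, dtype=bool)
    base = sl_term.start
    for g in (group_a, group_b):
        gs = bterm.group_slice(g)
        keep[base + gs.start : base + gs.stop] = True
    if include_group_offset:
        gf = bterm.spec.by_group
        if gf in fitted.design.term_slices:
            sl_f = fitted.design.term_slices[gf]
            cats = next(c for n, k, c in fitted.design.linear_info if n == gf)
            offs = np.zeros(p)
            for g, sign in ((group_a, 1.0), (group_b, -1.0)):
                if g in cats[1:]:
                    offs[sl_f.start + cats[1:].index(g)] = sign
            X_new[:, sl_f] = offs[sl_f]
            keep[sl_f] = True
    X_new[:, ~keep] = 0.0

    diff = X_new @ fitted.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X_new, fitted.covariance, X_new), 0.0))
    from scipy.stats import norm

    zq = norm.ppf(0.5 + level / 2.0)
    lo_ci = diff - zq * se
    hi_ci = diff + zq * se
    return DifferenceCurve(
        grid=grid_vals,
        difference=diff,
        se=se,
        lower=lo_ci,
        upper=hi_ci,
        level=level,
        group_a=group_a,
        group_b=group_b,
        significant_intervals=_significant_intervals(grid_vals, lo_ci, hi_ci),
    )


def fit_variant_family(
    base: ModelSpec,
    data: pd.DataFrame,
    variable: str,
    group_factor: str,
    variants=("S", "I", "GS", "GI"),
    criterion: str = "reml",
    maxfev: int | None = None,
) -> dict[str, FittedGAM]:
    """Fit G plus the requested grouped variants of one variable."""
    out = {"G": fit(build_grouped(base, variable, group_factor, "G"), data, criterion, maxfev=maxfev)}
    for v in variants:
        out[v] = fit(build_grouped(base, variable, group_factor, v), data, criterion, maxfev=maxfev)
    return out
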