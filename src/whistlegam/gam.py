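"""Penalized-spline Poisson GAM engine.

Smooth terms are built from cubic regression splines parameterized by their
values at knots, so every univariate penalty is the exact integrated squared
second derivative of the fitted spline (first derivative for the
weakly-penalized global smooths of the grouped-model family).  Supported
basis kinds:

``cyclic``
    cyclic cubic regression spline — value and first two derivatives match
    at the ends of the declared period (hour of day, moon fraction).
``cubic``
    natural cubic regression spline on quantile knots.
``thinplate``
    1-D thin-plate regression spline: radial basis ``r³/12`` at data-derived
    centers, reduced by eigen-truncation (low-rank approximation), with the
    polynomial null space handled explicitly.
``tensor``
    row-wise Kronecker product of two marginal cubic bases with one
    marginal penalty (and one smoothing parameter) per margin.

Any univariate or tensor smooth can additionally be replicated per level of
a grouping factor (``by_group``) with either one shared smoothing penalty
across the levels or one penalty per level — the building blocks of the
grouped-model family.

Fitting is penalized IRLS; smoothing parameters are chosen by a
Laplace-approximate restricted-likelihood criterion (default) or by GCV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, null_space
from scipy.special import gammaln
from scipy.stats import chi2, norm

from .errors import FitError, ValidationError

_KIND_ALIASES = {
    "cyclic-cubic": "cyclic",
    "thin-plate": "thinplate",
    "factor-smooth-shared": "cyclic",  # marginal kind must be given explicitly
    "factor-smooth-individual": "cyclic",
}


@dataclass(frozen=True)
class BasisSpec:
    """Declaration of one smooth term.

    ``period`` is the (lo, hi) domain for cyclic kinds.  ``by_group`` turns
    the smooth into a factor-smooth with ``shared_penalty`` controlling
    whether the group smooths share one smoothing parameter.
    ``penalty_order`` 2 is curvature; 1 penalizes the squared first
    derivative (the strongly-penalized global smooth of variant GI).
    """

    kind: str
    variables: tuple[str, ...]
    k: int = 10
    by_group: str | None = None
    shared_penalty: bool = True
    penalty_order: int = 2
    period: tuple[float, float] | None = None

    def __post_init__(self):
        object.__setattr__(self, "kind", _KIND_ALIASES.get(self.kind, self.kind))
        if isinstance(self.variables, str):
            object.__setattr__(self, "variables", (self.variables,))
        else:
            object.__setattr__(self, "variables", tuple(self.variables))
        if self.kind not in ("cyclic", "cubic", "thinplate", "tensor"):
            raise ValidationError(f"unknown basis kind {self.kind!r}")
        if self.kind == "tensor" and len(self.variables) != 2:
            raise ValidationError("tensor basis requires exactly 2 variables")
        if self.kind != "tensor" and len(self.variables) != 1:
            raise ValidationError(f"{self.kind} basis requires exactly 1 variable")
        if self.kind == "cyclic" and self.period is None:
            raise ValidationError("cyclic basis requires a declared period")

    @property
    def label(self) -> str:
        inner = ",".join(self.variables)
        tag = "te" if self.kind == "tensor" else "s"
        if self.by_group:
            pen = "s" if self.shared_penalty else "i"
            return f"{tag}({inner},by={self.by_group},{pen})"
        if self.penalty_order == 1:
            return f"{tag}({inner},m=1)"
        return f"{tag}({inner})"


@dataclass
class ModelSpec:
    """A Poisson log-link additive model: response ~ smooths + linear terms."""

    response: str
    smooths: list[BasisSpec] = field(default_factory=list)
    linear: list[str] = field(default_factory=list)

    def with_smooth(self, spec: BasisSpec) -> "ModelSpec":
        return ModelSpec(self.response, [*self.smooths, spec], list(self.linear))


# ---------------------------------------------------------------------------
# cubic regression spline machinery (value-at-knot parameterization)


def _crs_matrices(knots: np.ndarray, cyclic: bool, period: float | None):
    """Return (F, S): second-derivative map δ = F β and penalty S = ∫(f″)²."""
    k = len(knots)
    if cyclic:
        h = np.empty(k)
        h[:-1] = np.diff(knots)
        h[-1] = period - (knots[-1] - knots[0])
        B = np.zeros((k, k))
        D = np.zeros((k, k))
        for j in range(k):
            jm, jp = (j - 1) % k, (j + 1) % k
            B[j, j] = (h[jm] + h[j]) / 3.0
            B[j, jp] += h[j] / 6.0
            B[j, jm] += h[jm] / 6.0
            D[j, j] = -1.0 / h[jm] - 1.0 / h[j]
            D[j, jp] += 1.0 / h[j]
            D[j, jm] += 1.0 / h[jm]
        F = np.linalg.solve(B, D)
        S = D.T @ F
    else:
        h = np.diff(knots)
        B = np.zeros((k - 2, k - 2))
        D = np.zeros((k - 2, k))
        for i in range(k - 2):
            B[i, i] = (h[i] + h[i + 1]) / 3.0
            if i + 1 < k - 2:
                B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
            D[i, i] = 1.0 / h[i]
            D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            D[i, i + 2] = 1.0 / h[i + 1]
        Fi = np.linalg.solve(B, D)
        F = np.vstack([np.zeros(k), Fi, np.zeros(k)])
        S = D.T @ Fi
    S = (S + S.T) / 2.0
    return F, S


def _crs_design(x: np.ndarray, knots: np.ndarray, F: np.ndarray, cyclic: bool, period: float | None):
    k = len(knots)
    x = np.asarray(x, dtype=float)
    if cyclic:
        x = knots[0] + (x - knots[0]) % period
        edges = np.append(knots, knots[0] + period)
    else:
        x = np.clip(x, knots[0], knots[-1])
        edges = knots
    j = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    xl, xr = edges[j], edges[j + 1]
    h = xr - xl
    am = (xr - x) / h
    ap = (x - xl) / h
    cm = ((xr - x) ** 3 / h - h * (xr - x)) / 6.0
    cp = ((x - xl) ** 3 / h - h * (x - xl)) / 6.0
    jp = (j + 1) % k if cyclic else j + 1
    X = np.zeros((len(x), k))
    rows = np.arange(len(x))
    X[rows, j % k] += am
    X[rows, jp] += ap
    X += cm[:, None] * F[j % k] + cp[:, None] * F[jp]
    return X


def _first_derivative_penalty(knots, F, cyclic, period, domain):
    """Gram matrix of basis first derivatives, by fine-grid quadrature."""
    grid = np.linspace(domain[0], domain[1], 2001)
    X = _crs_design(grid, knots, F, cyclic, period)
    dX = np.gradient(X, grid, axis=0)
    w = np.full(len(grid), grid[1] - grid[0])
    w[0] = w[-1] = (grid[1] - grid[0]) / 2.0
    S = dX.T @ (dX * w[:, None])
    return (S + S.T) / 2.0


def _quantile_knots(x: np.ndarray, k: int) -> np.ndarray:
    ux = np.unique(x)
    if k > len(ux):
        raise ValidationError(f"k={k} exceeds the {len(ux)} distinct covariate values")
    q = np.linspace(0.0, 1.0, k)
    knots = np.quantile(ux, q)
    return np.unique(knots)


# ---------------------------------------------------------------------------
# raw (uncentered) bases


class _RawBasis:
    """Evaluates a basis for arbitrary new data and carries its penalties."""

    def __init__(self, gen: Callable[[pd.DataFrame], np.ndarray], penalties, null_dim: int):
        self.gen = gen
        self.penalties = penalties
        self.null_dim = null_dim


def _build_univariate(spec: BasisSpec, x: np.ndarray) -> _RawBasis:
    if spec.kind == "cyclic":
        lo, hi = spec.period
        period = hi - lo
        knots = lo + np.arange(spec.k) * period / spec.k
        if spec.k > len(np.unique(np.asarray(x))):
            raise ValidationError(f"k={spec.k} exceeds distinct values of {spec.variables[0]}")
        F, S = _crs_matrices(knots, cyclic=True, period=period)
        if spec.penalty_order == 1:
            S = _first_derivative_penalty(knots, F, True, period, (lo, hi))
        var = spec.variables[0]
        gen = lambda df: _crs_design(df[var].to_numpy(float), knots, F, True, period)
        return _RawBasis(gen, [S], null_dim=1 if spec.penalty_order == 2 else 1)
    if spec.kind == "cubic":
        knots = _quantile_knots(np.asarray(x, float), spec.k)
        F, S = _crs_matrices(knots, cyclic=False, period=None)
        if spec.penalty_order == 1:
            S = _first_derivative_penalty(knots, F, False, None, (knots[0], knots[-1]))
        var = spec.variables[0]
        gen = lambda df: _crs_design(df[var].to_numpy(float), knots, F, False, None)
        return _RawBasis(gen, [S], null_dim=2 if spec.penalty_order == 2 else 1)
    if spec.kind == "thinplate":
        return _build_tprs(spec, np.asarray(x, float))
    raise ValidationError(spec.kind)


def _build_tprs(spec: BasisSpec, x: np.ndarray, max_centers: int = 150) -> _RawBasis:
    """Low-rank 1-D thin-plate regression spline (η(r) = r³/12, m = 2).

    The covariate is standardized internally, making the term exactly
    equivariant to centering and scaling of its inputs.
    """
    xm, xs = float(np.mean(x)), float(np.std(x) or 1.0)
    xn0 = (np.asarray(x, float) - xm) / xs
    centers = np.unique(xn0)
    if spec.k >= len(centers) + 2:
        raise ValidationError(
            f"k={spec.k} too large for {len(centers)} distinct values of {spec.variables[0]}"
        )
    if len(centers) > max_centers:
        centers = np.unique(np.quantile(centers, np.linspace(0, 1, max_centers)))
    eta = lambda r: np.abs(r) ** 3 / 12.0
    E = eta(centers[:, None] - centers[None, :])
    w_eig, U = np.linalg.eigh(E)
    order = np.argsort(-np.abs(w_eig))
    kk = min(spec.k, len(centers)) - 2  # leave room for the polynomial part
    kk = max(kk, 1)
    Uk = U[:, order[:kk]]
    T = np.column_stack([np.ones_like(centers), centers])
    C = T.T @ Uk  # 2 x kk constraints T' delta = 0
    Z = null_space(C) if kk > 2 else np.eye(kk)
    Sz = Z.T @ (Uk.T @ E @ Uk) @ Z
    Sz = (Sz + Sz.T) / 2.0
    var = spec.variables[0]

    def gen(df: pd.DataFrame) -> np.ndarray:
        xn = (df[var].to_numpy(float) - xm) / xs
        Ex = eta(xn[:, None] - centers[None, :])
        radial = Ex @ Uk @ Z
        return np.column_stack([radial, xn])

    p_rad = Z.shape[1]
    S = np.zeros((p_rad + 1, p_rad + 1))
    S[:p_rad, :p_rad] = Sz
    return _RawBasis(gen, [S], null_dim=1)


def _build_tensor(spec: BasisSpec, data: pd.DataFrame) -> _RawBasis:
    v1, v2 = spec.variables
    k = spec.k
    kn1 = _quantile_knots(data[v1].to_numpy(float), k)
    kn2 = _quantile_knots(data[v2].to_numpy(float), k)
    F1, S1 = _crs_matrices(kn1, cyclic=False, period=None)
    F2, S2 = _crs_matrices(kn2, cyclic=False, period=None)
    p1, p2 = len(kn1), len(kn2)

    def gen(df: pd.DataFrame) -> np.ndarray:
        X1 = _crs_design(df[v1].to_numpy(float), kn1, F1, False, None)
        X2 = _crs_design(df[v2].to_numpy(float), kn2, F2, False, None)
        return np.einsum("ij,ik->ijk", X1, X2).reshape(len(df), p1 * p2)

    P1 = np.kron(S1, np.eye(p2))
    P2 = np.kron(np.eye(p1), S2)
    return _RawBasis(gen, [P1, P2], null_dim=4)


# ---------------------------------------------------------------------------
# term assembly (centering constraints, grouping)


class BuiltTerm:
    """A smooth term ready for the design matrix.

    ``X`` is the centered (identifiable) block, ``penalties`` the list of
    penalty matrices in the centered coordinates; each entry of ``penalties``
    gets its own smoothing parameter.
    """

    def __init__(self, spec: BasisSpec, data: pd.DataFrame):
        self.spec = spec
        self.label = spec.label
        if spec.kind == "tensor":
            raw = _build_tensor(spec, data)
        else:
            raw = _build_univariate(spec, data[spec.variables[0]].to_numpy())
        self._raw = raw
        self.var_ranges = {
            v: (float(data[v].min()), float(data[v].max())) for v in spec.variables
        }

        if spec.by_group is None:
            Xr = raw.gen(data)
            Z = self._center_transform(Xr)
            self.X = Xr @ Z
            self._transforms = [(None, Z)]
            self.penalties = [Z.T @ S @ Z for S in raw.penalties]
        else:
            groups = pd.Categorical(data[spec.by_group])
            self.levels = list(groups.categories)
            blocks, transforms, pen_blocks = [], [], []
            for lev in self.levels:
                mask = np.asarray(groups == lev)
                Xr = raw.gen(data)
                Z = self._center_transform(Xr[mask])
                Xg = (Xr @ Z) * mask[:, None]
                blocks.append(Xg)
                transforms.append((lev, Z))
                pen_blocks.append([Z.T @ S @ Z for S in raw.penalties])
            self.X = np.hstack(blocks)
            self._transforms = transforms
            dims = [b.shape[1] for b in blocks]
            offsets = np.concatenate([[0], np.cumsum(dims)])
            p = offsets[-1]
            n_pen = len(raw.penalties)
            if spec.shared_penalty:
                self.penalties = []
                for ip in range(n_pen):
                    S = np.zeros((p, p))
                    for g in range(len(self.levels)):
                        sl = slice(offsets[g], offsets[g + 1])
                        S[sl, sl] = pen_blocks[g][ip]
                    self.penalties.append(S)
            else:
                self.penalties = []
                for g in range(len(self.levels)):
                    for ip in range(n_pen):
                        S = np.zeros((p, p))
                        sl = slice(offsets[g], offsets[g + 1])
                        S[sl, sl] = pen_blocks[g][ip]
                        self.penalties.append(S)
            self._group_offsets = offsets

    @staticmethod
    def _center_transform(X: np.ndarray) -> np.ndarray:
        c = X.sum(axis=0, keepdims=True)
        nc = np.linalg.norm(c)
        if nc < 1e-12:
            return np.eye(X.shape[1])
        Z = null_space(c / nc)
        return Z

    @property
    def width(self) -> int:
        return self.X.shape[1]

    def predict_mat(self, newdata: pd.DataFrame, group=None) -> np.ndarray:
        """Design rows for new data.

        For grouped terms, either ``newdata`` carries the grouping column or
        ``group`` forces a level for every row.
        """
        Xr = self._raw.gen(newdata)
        if self.spec.by_group is None:
            return Xr @ self._transforms[0][1]
        if group is not None:
            g = pd.Categorical([group] * len(newdata), categories=self.levels)
        else:
            g = pd.Categorical(newdata[self.spec.by_group], categories=self.levels)
        blocks = []
        for lev, Z in self._transforms:
            mask = np.asarray(g == lev, dtype=float)
            blocks.append((Xr @ Z) * mask[:, None])
        return np.hstack(blocks)

    def group_slice(self, group) -> slice:
        """Column range (within the term block) belonging to one group level."""
        if self.spec.by_group is None:
            raise ValidationError(f"term {self.label} is not grouped")
        g = self.levels.index(group)
        return slice(self._group_offsets[g], self._group_offsets[g + 1])


def build_basis(spec: BasisSpec, data: pd.DataFrame) -> tuple[np.ndarray, list[np.ndarray]]:
    """Design block and penalty matrices for one smooth term (centered)."""
    term = BuiltTerm(spec, data)
    return term.X, term.penalties


# ---------------------------------------------------------------------------
# design assembly


class Design:
    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        n = len(data)
        cols = [np.ones((n, 1))]
        names = ["(Intercept)"]
        self.term_slices: dict[str, slice] = {}
        self.linear_info: list[tuple[str, str, list]] = []
        pos = 1
        for name in spec.linear:
            col = data[name]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                cats = list(pd.Categorical(col).categories)
                dummies = np.column_stack(
                    [(pd.Categorical(col, categories=cats) == c).astype(float) for c in cats[1:]]
                ) if len(cats) > 1 else np.zeros((n, 0))
                cols.append(dummies)
                self.term_slices[name] = slice(pos, pos + dummies.shape[1])
                self.linear_info.append((name, "factor", cats))
                names += [f"{name}[{c}]" for c in cats[1:]]
                pos += dummies.shape[1]
            else:
                cols.append(col.to_numpy(float)[:, None])
                self.term_slices[name] = slice(pos, pos + 1)
                self.linear_info.append((name, "numeric", []))
                names.append(name)
                pos += 1
        self.terms: list[BuiltTerm] = []
        for bs in spec.smooths:
            t = BuiltTerm(bs, data)
            self.terms.append(t)
            cols.append(t.X)
            self.term_slices[t.label] = slice(pos, pos + t.width)
            names += [f"{t.label}.{i}" for i in range(t.width)]
            pos += t.width
        self.X = np.hstack(cols)
        self.names = names
        self.p = pos
        # full-size penalties with Frobenius normalization for conditioning
        self.penalties: list[tuple[str, np.ndarray]] = []
        for t in self.terms:
            sl = self.term_slices[t.label]
            for S in t.penalties:
                Sf = np.zeros((self.p, self.p))
                nrm = np.linalg.norm(S)
                Sf[sl, sl] = S / nrm if nrm > 0 else S
                self.penalties.append((t.label, Sf))

    def predict_matrix(self, newdata: pd.DataFrame, group=None) -> np.ndarray:
        n = len(newdata)
        cols = [np.ones((n, 1))]
        for name, kind, cats in self.linear_info:
            if kind == "numeric":
                cols.append(newdata[name].to_numpy(float)[:, None])
            else:
                cc = pd.Categorical(newdata[name], categories=cats)
                cols.append(
                    np.column_stack([(cc == c).astype(float) for c in cats[1:]])
                    if len(cats) > 1
                    else np.zeros((n, 0))
                )
        for t in self.terms:
            cols.append(t.predict_mat(newdata, group=group))
        return np.hstack(cols)


# ---------------------------------------------------------------------------
# Poisson likelihood helpers


def _poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(t - (y - mu)))


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def _pirls(X, y, S_total, beta0=None, max_iter=200, tol=1e-9):
    n, p = X.shape
    ridge = 1e-10 * np.eye(p)
    if beta0 is None:
        mu = (y + np.mean(y) + 0.1) / 2.0
        eta = np.log(mu)
        beta = None
    else:
        beta = beta0.copy()
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
    prev = np.inf
    trace = []
    beta_prev = beta
    for it in range(max_iter):
        w = mu
        z = eta + (y - mu) / mu
        XtW = X.T * w
        A = XtW @ X + S_total + ridge
        try:
            cfac = cho_factor(A)
        except np.linalg.LinAlgError as exc:
            raise FitError("penalized normal equations not positive definite", trace) from exc
        beta = cho_solve(cfac, XtW @ z)
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        pdev = _poisson_deviance(y, mu) + float(beta @ S_total @ beta)
        trace.append(pdev)
        step = (
            np.max(np.abs(beta - beta_prev)) / (1.0 + np.max(np.abs(beta)))
            if beta_prev is not None
            else np.inf
        )
        if np.isfinite(prev) and (abs(prev - pdev) < tol * (abs(pdev) + 0.1) or step < 1e-10):
            return beta, mu, cfac, trace
        prev = pdev
        beta_prev = beta
    raise FitError(f"PIRLS did not converge in {max_iter} iterations", trace)


# ---------------------------------------------------------------------------
# fitted model


@dataclass
class TermSummary:
    label: str
    kind: str
    edf: float
    p_value: float
    estimate: float  # edf for smooths, slope for numeric linear terms


@dataclass
class FittedGAM:
    """Everything downstream contrasts and decompositions need."""

    spec: ModelSpec
    design: Design
    beta: np.ndarray
    covariance: np.ndarray  # Bayesian posterior covariance of beta
    lambdas: dict[str, list[float]]
    edf_by_term: dict[str, float]
    edf_total: float
    deviance: float
    null_deviance: float
    aic: float
    loglik: float
    criterion: str
    convergence: list
    y: np.ndarray
    n: int

    @property
    def deviance_explained(self) -> float:
        return 1.0 - self.deviance / self.null_deviance

    def predict(self, newdata: pd.DataFrame, kind: str = "response", group=None) -> np.ndarray:
        eta = self.design.predict_matrix(newdata, group=group) @ self.beta
        return np.exp(eta) if kind == "response" else eta

    def linear_predictor(self) -> np.ndarray:
        return self.design.X @ self.beta

    def term_effect(
        self, label: str, grid: pd.DataFrame, group=None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Centered effect of one smooth term on the link scale, with SE."""
        term = next(t for t in self.design.terms if t.label == label)
        sl = self.design.term_slices[label]
        Xg = term.predict_mat(grid, group=group)
        eff = Xg @ self.beta[sl]
        V = self.covariance[sl, sl]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, V, Xg), 0.0))
        return eff, se

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, kind, _ in self.design.linear_info:
            sl = self.design.term_slices[name]
            b = self.beta[sl]
            V = self.covariance[sl, sl]
            if kind == "numeric":
                se = float(np.sqrt(V[0, 0]))
                z = b[0] / se if se > 0 else np.inf
                pv = 2.0 * norm.sf(abs(z))
                rows.append(TermSummary(name, "linear", 1.0, pv, float(b[0])))
            else:
                Vi = np.linalg.pinv(V, rcond=1e-10)
                stat = float(b @ Vi @ b)
                df = max(1, len(b))
                rows.append(TermSummary(name, "factor", float(len(b)), chi2.sf(stat, df), np.nan))
        for t in self.design.terms:
            sl = self.design.term_slices[t.label]
            b = self.beta[sl]
            V = self.covariance[sl, sl]
            Vi = np.linalg.pinv(V, rcond=1e-10)
            stat = float(b @ Vi @ b)
            edf = self.edf_by_term[t.label]
            df = max(1, int(round(edf)))
            rows.append(TermSummary(t.label, t.spec.kind, edf, chi2.sf(stat, df), edf))
        return pd.DataFrame([r.__dict__ for r in rows])

    def nonsignificant_terms(self, alpha: float = 0.01) -> list[str]:
        s = self.summary()
        return list(s.loc[s["p_value"] > alpha, "label"])


def _reml_value(X, y, pens, rho, state, rank_total, null_dim):
    lam = np.exp(np.clip(rho, -15.0, 20.0))
    S_total = sum(l * S for l, (_, S) in zip(lam, pens)) if pens else np.zeros((X.shape[1],) * 2)
    beta, mu, cfac, trace = _pirls(X, y, S_total, beta0=state.get("beta"))
    state["beta"] = beta
    ll = _poisson_loglik(y, mu)
    pen = float(beta @ S_total @ beta)
    logdet_H = 2.0 * np.sum(np.log(np.diag(cfac[0])))
    if pens:
        ev = np.linalg.eigvalsh(S_total)
        ev = np.sort(ev)[::-1][:rank_total]
        ev = np.maximum(ev, 1e-300)
        logdet_S = float(np.sum(np.log(ev)))
    else:
        logdet_S = 0.0
    v = -ll + 0.5 * pen + 0.5 * logdet_H - 0.5 * logdet_S - 0.5 * null_dim * np.log(2.0 * np.pi)
    return v, beta, mu, S_total


def _gcv_value(X, y, pens, rho, state):
    lam = np.exp(np.clip(rho, -15.0, 20.0))
    S_total = sum(l * S for l, (_, S) in zip(lam, pens)) if pens else np.zeros((X.shape[1],) * 2)
    beta, mu, cfac, _ = _pirls(X, y, S_total, beta0=state.get("beta"))
    state["beta"] = beta
    H = (X.T * mu) @ X
    edf = float(np.trace(cho_solve(cfac, H)))
    n = len(y)
    dev = _poisson_deviance(y, mu)
    return n * dev / (n - 1.4 * edf) ** 2, beta, mu, S_total


def fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    criterion: str = "reml",
    lambdas: dict[str, list[float]] | np.ndarray | None = None,
    maxfev: int | None = None,
) -> FittedGAM:
    """Fit the penalized Poisson GAM.

    Smoothing parameters are optimized on the log scale by Nelder–Mead over
    the chosen criterion unless ``lambdas`` fixes them (an array in penalty
    order, or a dict keyed by term label).
    """
    y = data[spec.response].to_numpy(float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValidationError("response must be non-negative integers")
    design = Design(spec, data)
    X = design.X
    n, p = X.shape
    if n < 10 * max(1, len(spec.smooths)):
        raise ValidationError(f"need at least {10 * len(spec.smooths)} rows for {len(spec.smooths)} smooths")
    pens = design.penalties
    m = len(pens)

    if m:
        S_sum = sum(S for _, S in pens)
        ev = np.linalg.eigvalsh(S_sum)
        rank_total = int(np.sum(ev > ev.max() * 1e-9))
    else:
        rank_total = 0
    null_dim = p - rank_total

    state: dict = {}
    if lambdas is not None or m == 0:
        if isinstance(lambdas, dict):
            queues = {k: list(v) if isinstance(v, (list, tuple)) else [v] for k, v in lambdas.items()}
            lam = []
            for label, _ in pens:
                q = queues[label]
                lam.append(q.pop(0) if len(q) > 1 else q[0])
            lam = np.asarray(lam, float)
        elif lambdas is None:
            lam = np.zeros(0)
        else:
            lam = np.asarray(lambdas, float)
        # same bounds the optimizer works under; e^20 ≈ 5e8 is effectively the
        # smoothing limit while keeping the normal equations well conditioned
        rho_opt = np.clip(np.log(np.maximum(lam, 1e-300)), -15.0, 20.0) if m else np.zeros(0)
        conv_log = ["fixed smoothing parameters"]
    else:
        rho0 = np.zeros(m)

        def objective(rho):
            try:
                if criterion == "gcv":
                    v, *_ = _gcv_value(X, y, pens, rho, state)
                else:
                    v, *_ = _reml_value(X, y, pens, rho, state, rank_total, null_dim)
            except FitError:
                return 1e12
            return v

        res = optimize.minimize(
            objective,
            rho0,
            method="Nelder-Mead",
            options={
                "maxfev": maxfev or max(300, 120 * m),
                "xatol": 1e-2,
                "fatol": 1e-4,
            },
        )
        rho_opt = np.clip(res.x, -15.0, 20.0)
        conv_log = [f"{criterion} optimization: {res.message}", f"criterion={res.fun:.4f}"]

    lam_opt = np.exp(rho_opt) if m else np.zeros(0)
    S_total = sum(l * S for l, (_, S) in zip(lam_opt, pens)) if m else np.zeros((p, p))
    beta, mu, cfac, trace = _pirls(X, y, S_total, beta0=state.get("beta"))
    H = (X.T * mu) @ X
    Finf = cho_solve(cfac, H)  # (H+S)^-1 H, the edf matrix
    Vb = cho_solve(cfac, np.eye(p))
    Vb = (Vb + Vb.T) / 2.0
    edf_diag = np.diag(Finf)
    edf_by_term = {}
    for label, sl in design.term_slices.items():
        edf_by_term[label] = float(edf_diag[sl].sum())
    edf_total = float(edf_diag.sum())
    dev = _poisson_deviance(y, mu)
    mu0 = np.full(n, y.mean())
    null_dev = _poisson_deviance(y, mu0)
    ll = _poisson_loglik(y, mu)
    aic = -2.0 * ll + 2.0 * edf_total
    lam_by_term: dict[str, list[float]] = {}
    for (label, _), l in zip(pens, lam_opt):
        lam_by_term.setdefault(label, []).append(float(l))
    phat = dev / max(n - edf_total, 1.0)
    if phat > 2.0:
        warnings.warn(f"overdispersion suspected (deviance/df = {phat:.2f})")
    return FittedGAM(
        spec=spec,
        design=design,
        beta=beta,
        covariance=Vb,
        lambdas=lam_by_term,
        edf_by_term=edf_by_term,
        edf_total=edf_total,
        deviance=dev,
        null_deviance=null_dev,
        aic=aic,
        loglik=ll,
        criterion=criterion,
        convergence=conv_log + [f"pirls iterations: {len(trace)}"],
        y=y,
        n=n,
    )


# ---------------------------------------------------------------------------
# deviance decomposition, AIC weights, forward selection


def deviance_decomposition(fitted: FittedGAM, term: str) -> dict:
    """Relative deviance share of one term, by zeroing its contribution.

    The term's columns are removed from the linear predictor with all other
    coefficients held fixed (no refit); the share is
    ``(DE_full − DE_excluded) / DE_full`` on the deviance-explained scale.
    """
    if term == "none":
        return {
            "term": "none",
            "dev_explained_excluded": fitted.deviance_explained,
            "share": 0.0,
        }
    if term not in fitted.design.term_slices:
        raise ValidationError(f"unknown term {term!r}")
    sl = fitted.design.term_slices[term]
    eta = fitted.linear_predictor().copy()
    # remove only the centered contribution: uncentered columns (linear terms,
    # factor dummies) keep their mean level in the intercept
    Xt = fitted.design.X[:, sl]
    eta -= (Xt - Xt.mean(axis=0)) @ fitted.beta[sl]
    mu = np.exp(np.clip(eta, -30, 30))
    dev_excl = _poisson_deviance(fitted.y, mu)
    de_full = fitted.deviance_explained
    de_excl = 1.0 - dev_excl / fitted.null_deviance
    return {
        "term": term,
        "dev_explained_excluded": de_excl,
        "share": (de_full - de_excl) / de_full,
    }


def aic_weights(aics: np.ndarray) -> np.ndarray:
    """Akaike weights: w_i = exp(−Δ_i/2) / Σ exp(−Δ_j/2)."""
    aics = np.asarray(aics, dtype=float)
    if aics.size < 2 or not np.all(np.isfinite(aics)):
        raise ValidationError("aic_weights needs >= 2 finite values")
    d = aics - aics.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


@dataclass
class SelectionStep:
    round: int
    candidate: str
    aic: float
    delta_aic: float
    weight: float
    kept: bool
    tie: bool = False


@dataclass
class SelectionTrace:
    steps: list[SelectionStep]
    final_spec: ModelSpec
    final_aic: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])


def forward_select(
    candidates: list[BasisSpec | str],
    base: ModelSpec,
    data: pd.DataFrame,
    criterion: str = "reml",
    stop_delta: float = -2.0,
    maxfev: int | None = None,
) -> SelectionTrace:
    """Forward stepwise selection by AIC.

    Each round refits the current model with every remaining candidate added,
    keeps the candidate with the lowest AIC, and stops when the best
    improvement no longer beats ``stop_delta`` (default −2).  Exact AIC ties
    resolve to the lexicographically first label and are flagged in the trace.
    """

    def label_of(c):
        return c if isinstance(c, str) else c.label

    current = ModelSpec(base.response, list(base.smooths), list(base.linear))
    current_fit = fit(current, data, criterion=criterion, maxfev=maxfev)
    steps: list[SelectionStep] = []
    remaining = list(candidates)
    rnd = 0
    while remaining:
        rnd += 1
        trials = []
        for c in sorted(remaining, key=label_of):
            trial = (
                current.with_smooth(c)
                if isinstance(c, BasisSpec)
                else ModelSpec(current.response, list(current.smooths), [*current.linear, c])
            )
            try:
                f = fit(trial, data, criterion=criterion, maxfev=maxfev)
                trials.append((c, trial, f))
            except (FitError, ValidationError):
                trials.append((c, trial, None))
        aics = np.array(
            [t[2].aic if t[2] is not None else np.inf for t in trials], dtype=float
        )
        finite = np.isfinite(aics)
        if not finite.any():
            break
        weights = np.zeros(len(aics))
        weights[finite] = aic_weights(aics[finite]) if finite.sum() > 1 else 1.0
        best = int(np.argmin(aics))  # argmin takes the first (lexicographic) on ties
        tie = bool(np.sum(aics == aics[best]) > 1)
        delta = aics[best] - current_fit.aic
        keep = delta < stop_delta
        for i, (c, trial, f) in enumerate(trials):
            steps.append(
                SelectionStep(
                    round=rnd,
                    candidate=label_of(c),
                    aic=float(aics[i]),
                    delta_aic=float(aics[i] - current_fit.aic),
                    weight=float(weights[i]),
                    kept=keep and i == best,
                    tie=tie and i == best,
                )
            )
        if not keep:
            break
        c, current, current_fit = trials[best][0], trials[best][1], trials[best][2]
        remaining = [r for r in remaining if label_of(r) != label_of(c)]
    return SelectionTrace(steps=steps, final_spec=current, final_aic=current_fit.aic)
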