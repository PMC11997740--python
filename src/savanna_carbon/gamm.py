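"""Penalized additive mixed models with double-penalty shrinkage.

A compact Gaussian/identity GAMM engine for the driver analysis:

* one-dimensional smooths are penalized regression splines (cubic B-spline
  basis, second-order difference penalty) under a sum-to-zero constraint;
* every smooth carries a *double penalty*: the usual wiggliness penalty on
  the range space of the difference penalty plus a second penalty on its
  null space (the linear trend), so REML can shrink an uninformative
  smooth all the way to zero effective degrees of freedom and effectively
  drop it from the model;
* two-way interactions are tensor products of the constrained marginal
  bases, which excludes the marginal main effects from the interaction
  space (the main effects are separate model terms); the tensor block
  carries one penalty per margin plus a null-space penalty;
* a grouping factor can enter as a ridge-penalized random intercept in
  addition to a parametric fixed effect;
* smoothing parameters are chosen by restricted maximum likelihood (REML),
  profiling out the error variance, with the criterion minimized over log
  smoothing parameters by L-BFGS-B.

For a Gaussian response the model is y = X beta + e with block penalty
S(lambda) = sum_j lambda_j S_j; the REML score used is

    (n - M_p) [log(2 pi D_p / (n - M_p)) + 1] + log|X'X + S| - log|S|_+

with D_p the penalized residual sum of squares, M_p the number of
unpenalized coefficients and |S|_+ the determinant of the penalized block.
Partial effects are centred about the model mean; reported effective
degrees of freedom per term are tr(F) restricted to the term's
coefficients, F = (X'X + S)^-1 X'X.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

__all__ = ["GammSpec", "GammFit", "SmoothBasis", "fit_gamm", "default_gamm_spec"]


# --------------------------------------------------------------------------
# Bases
# --------------------------------------------------------------------------


def _tps_eta(r: np.ndarray) -> np.ndarray:
    """Thin-plate spline radial basis for one dimension (order m=2)."""
    return r**3 / 12.0


class SmoothBasis:
    """Low-rank thin-plate regression spline basis for one predictor.

    Knots are (a subsample of) the observed covariate values; the radial
    basis matrix at the knots is eigen-truncated to the k leading
    components, the thin-plate constraint removes the polynomial span from
    the wiggly part, and the constant is dropped for identifiability. The
    resulting term has k-2 penalized wiggliness coefficients plus one
    unpenalized linear coefficient — the null space that the second
    (shrinkage) penalty acts on.
    """

    def __init__(self, name: str, x: np.ndarray, k: int = 9, max_knots: int = 2000):
        x = np.asarray(x, dtype=float)
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi - lo <= 0:
            raise ValueError(f"smooth term {name!r}: predictor is constant")
        uniq = np.unique(x)
        # a term cannot carry more basis functions than distinct values
        k = min(k, len(uniq) - 1)
        if k < 4:
            raise ValueError(
                f"smooth term {name!r}: only {len(uniq)} distinct values; "
                "needs at least 5 for a smooth"
            )
        self.name, self.k = name, k
        self.lo, self.hi = lo, hi
        if len(uniq) > max_knots:
            qs = np.linspace(0.0, 1.0, max_knots)
            knots = np.unique(np.quantile(uniq, qs))
        else:
            knots = uniq
        self.knots = knots
        nk = len(knots)
        e_kk = _tps_eta(np.abs(knots[:, None] - knots[None, :]))
        w, u = np.linalg.eigh(e_kk)
        order = np.argsort(np.abs(w))[::-1][: k - 2 + 2]
        # keep k components before the 2 constraint dims are removed
        d = w[order]
        u_k = u[:, order]
        t_k = np.column_stack([np.ones(nk), knots])
        c = t_k.T @ u_k  # 2 x k
        _, _, vh = np.linalg.svd(c)
        z = vh[2:].T  # k x (k-2)
        self._proj = u_k @ z  # nk x (k-2): delta = proj @ coef
        s = z.T @ (z * d[:, None])
        s = 0.5 * (s + s.T)
        self.x_mean = float(x.mean())
        wig = _tps_eta(np.abs(x[:, None] - knots[None, :])) @ self._proj
        self._wig_means = wig.mean(axis=0)
        # columns: k-2 centred wiggly terms, then the centred linear term
        raw = np.column_stack([wig - self._wig_means, x - self.x_mean])
        # standardise columns to unit RMS so X'X and the penalty live on
        # comparable scales (the penalty transforms with 1/scale)
        self._col_scale = np.sqrt(np.mean(raw**2, axis=0))
        self._col_scale[self._col_scale == 0] = 1.0
        self.X = raw / self._col_scale
        dim = self.dim
        s_range = np.zeros((dim, dim))
        s_range[: dim - 1, : dim - 1] = s
        s_range = (s_range.T / self._col_scale).T / self._col_scale
        scale = np.abs(s_range).max()
        if scale > 0:
            s_range /= scale
        # eigen-truncation can leave (near-)zero or slightly negative
        # wiggliness eigenvalues; those directions join the null-space
        # penalty so that the double penalty spans the whole term space
        self.S_range, self.S_null = _split_range_null(s_range)
        self.null_dim = int(round(np.trace(self.S_null)))

    @property
    def dim(self) -> int:
        return self.k - 1

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        wig = _tps_eta(np.abs(x[:, None] - self.knots[None, :])) @ self._proj
        raw = np.column_stack([wig - self._wig_means, x - self.x_mean])
        return raw / self._col_scale


class TensorBasis:
    """Tensor-product interaction of two constrained marginal bases; the
    marginal main effects are excluded by construction."""

    def __init__(self, m1: SmoothBasis, m2: SmoothBasis):
        self.m1, self.m2 = m1, m2
        self.name = f"{m1.name}:{m2.name}"
        self.X = _rowwise_kron(m1.X, m2.X)
        i1, i2 = np.eye(m1.dim), np.eye(m2.dim)
        self.S1 = np.kron(m1.S_range + m1.S_null, i2)
        self.S2 = np.kron(i1, m2.S_range + m2.S_null)
        # joint null space: directions unpenalized by both margins
        nn = _null_basis(self.S1 + self.S2)
        self.S_null = nn @ nn.T

    @property
    def dim(self) -> int:
        return self.m1.dim * self.m2.dim

    def evaluate(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        return _rowwise_kron(self.m1.evaluate(x1), self.m2.evaluate(x2))


def _rowwise_kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)


def _null_basis(s: np.ndarray, rtol: float = 1e-7) -> np.ndarray:
    w, u = np.linalg.eigh(s)
    tol = max(w.max(), 1.0) * rtol
    return u[:, w <= tol]


def _split_range_null(s: np.ndarray, rtol: float = 1e-7) -> tuple[np.ndarray, np.ndarray]:
    """Split a (possibly indefinite, truncation-tainted) penalty into a PSD
    range-space penalty and a complementary null-space penalty."""
    w, u = np.linalg.eigh(0.5 * (s + s.T))
    tol = max(w.max(), 1.0) * rtol
    pos = w > tol
    s_range = (u[:, pos] * w[pos]) @ u[:, pos].T
    s_null = u[:, ~pos] @ u[:, ~pos].T
    return s_range, s_null


# --------------------------------------------------------------------------
# Model specification and fit container
# --------------------------------------------------------------------------


@dataclass
class GammSpec:
    """Model structure: response, smooth terms, parametric terms, tensor
    interactions, optional random-intercept factor."""

    response: str
    smooth: list[str] = field(default_factory=list)
    parametric: list[str] = field(default_factory=list)
    tensor: list[tuple[str, str]] = field(default_factory=list)
    random_intercept: str | None = None
    k: int = 9
    tensor_k: int = 5


def default_gamm_spec(response: str = "AGC") -> GammSpec:
    """The study's driver model: eight plot-level smooths, methuselah
    presence and vegetation type as parametric terms, vegetation type also
    as random intercept, and fire x browsing tensor interactions."""
    return GammSpec(
        response=response,
        smooth=[
            "browsing_understorey",
            "browsing_overstorey",
            "woodcutting_intensity",
            "fire_intensity",
            "wild_grazer_density",
            "domestic_grazer_density",
            "soil_n_pct",
            "cec_cmol_kg",
        ],
        parametric=["methuselah_present", "vegetation_type"],
        tensor=[
            ("fire_intensity", "browsing_overstorey"),
            ("fire_intensity", "browsing_understorey"),
        ],
        random_intercept="vegetation_type",
    )


@dataclass
class GammFit:
    """Fitted penalized additive model."""

    spec: GammSpec
    terms: dict  # name -> dict(type, slice, basis/levels)
    beta: np.ndarray
    cov_beta: np.ndarray  # Bayesian posterior covariance, phi * (X'X+S)^-1
    lambdas: dict[str, float]
    edf: dict[str, float]
    edf_total: float
    phi: float  # error variance
    deviance_explained: float  # fraction in [0, 1]
    adj_r2: float
    p_values: dict[str, float]
    fitted: np.ndarray
    residuals: np.ndarray
    intercept: float
    converged: bool
    n: int

    def partial_effect(self, term: str, grid: np.ndarray | None = None, n_grid: int = 100):
        """Centred partial-effect curve of a smooth term on a grid.

        Returns a DataFrame with the grid, the estimated effect and a
        pointwise +-2 SE band; the effect is centred about the model mean
        (zero line = mean response at reference conditions).
        """
        info = self.terms[term]
        if info["type"] not in ("smooth", "tensor"):
            raise ValueError(f"{term!r} is not a smooth term")
        sl = info["slice"]
        basis = info["basis"]
        if info["type"] == "smooth":
            if grid is None:
                grid = np.linspace(basis.lo, basis.hi, n_grid)
            xg = basis.evaluate(grid)
            eff = xg @ self.beta[sl]
            se = np.sqrt(np.einsum("ij,jk,ik->i", xg, self.cov_beta[sl, sl], xg))
            return pd.DataFrame({term: grid, "effect": eff, "se": se})
        raise ValueError("use partial_surface for tensor terms")

    def partial_surface(self, term: str, n_grid: int = 25) -> pd.DataFrame:
        info = self.terms[term]
        basis = info["basis"]
        g1 = np.linspace(basis.m1.lo, basis.m1.hi, n_grid)
        g2 = np.linspace(basis.m2.lo, basis.m2.hi, n_grid)
        gg1, gg2 = np.meshgrid(g1, g2, indexing="ij")
        xg = basis.evaluate(gg1.ravel(), gg2.ravel())
        eff = xg @ self.beta[info["slice"]]
        return pd.DataFrame(
            {basis.m1.name: gg1.ravel(), basis.m2.name: gg2.ravel(), "effect": eff}
        )

    def partial_effect_table(self, n_grid: int = 100) -> pd.DataFrame:
        """Long-format table of all 1-D partial effects (for replotting)."""
        frames = []
        for name, info in self.terms.items():
            if info["type"] != "smooth":
                continue
            df = self.partial_effect(name, n_grid=n_grid)
            frames.append(
                pd.DataFrame(
                    {"term": name, "x": df[name], "effect": df["effect"], "se": df["se"]}
                )
            )
        return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# Design assembly and REML fit
# --------------------------------------------------------------------------


def _build_design(data: pd.DataFrame, spec: GammSpec):
    n = len(data)
    cols: list[np.ndarray] = [np.ones((n, 1))]
    terms: dict[str, dict] = {"(intercept)": {"type": "parametric", "slice": slice(0, 1)}}
    penalties: list[tuple[str, slice, np.ndarray]] = []
    pos = 1

    for name in spec.parametric:
        x = data[name]
        if x.dtype == bool or x.dtype == object or isinstance(x.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(x, drop_first=True).to_numpy(dtype=float)
        else:
            dummies = x.to_numpy(dtype=float)[:, None]
        sl = slice(pos, pos + dummies.shape[1])
        cols.append(dummies)
        terms[name] = {"type": "parametric", "slice": sl}
        pos = sl.stop

    marginals: dict[str, SmoothBasis] = {}
    for name in spec.smooth:
        basis = SmoothBasis(name, data[name].to_numpy(dtype=float), k=spec.k)
        sl = slice(pos, pos + basis.dim)
        cols.append(basis.X)
        terms[name] = {"type": "smooth", "slice": sl, "basis": basis}
        penalties.append((f"{name}.range", sl, basis.S_range))
        penalties.append((f"{name}.null", sl, basis.S_null))
        marginals[name] = basis
        pos = sl.stop

    for n1, n2 in spec.tensor:
        # marginals are rebuilt at the (smaller) tensor basis dimension
        tb = TensorBasis(
            SmoothBasis(n1, data[n1].to_numpy(dtype=float), k=spec.tensor_k),
            SmoothBasis(n2, data[n2].to_numpy(dtype=float), k=spec.tensor_k),
        )
        sl = slice(pos, pos + tb.dim)
        cols.append(tb.X)
        terms[tb.name] = {"type": "tensor", "slice": sl, "basis": tb}
        penalties.append((f"{tb.name}.m1", sl, tb.S1))
        penalties.append((f"{tb.name}.m2", sl, tb.S2))
        penalties.append((f"{tb.name}.null", sl, tb.S_null))
        pos = sl.stop

    if spec.random_intercept is not None:
        levels = pd.Categorical(data[spec.random_intercept])
        zmat = pd.get_dummies(levels).to_numpy(dtype=float)
        sl = slice(pos, pos + zmat.shape[1])
        cols.append(zmat)
        terms[f"re({spec.random_intercept})"] = {
            "type": "random",
            "slice": sl,
            "levels": list(levels.categories),
        }
        penalties.append((f"re({spec.random_intercept})", sl, np.eye(zmat.shape[1])))
        pos = sl.stop

    X = np.hstack(cols)
    n_unpenalized = sum(
        (t["slice"].stop - t["slice"].start)
        for t in terms.values()
        if t["type"] == "parametric"
    )
    return X, terms, penalties, n_unpenalized


def _penalized_block_logdet(penalties, lam, p) -> float:
    """log|S|_+ over the penalized block; penalties within one term slice
    are summed before the determinant, blocks are independent."""
    by_slice: dict[tuple[int, int], np.ndarray] = {}
    for (name, sl, s), l in zip(penalties, lam):
        key = (sl.start, sl.stop)
        acc = by_slice.setdefault(key, np.zeros_like(s))
        acc += l * s
    total = 0.0
    for (a, b), s in by_slice.items():
        sign, logdet = np.linalg.slogdet(s)
        if sign <= 0:
            return -np.inf
        total += logdet
    return total


def fit_gamm(data: pd.DataFrame, spec: GammSpec, *, maxiter: int = 200) -> GammFit:
    """Fit the penalized additive model by REML.

    Raises on missing values; non-convergence of the smoothing-parameter
    optimisation is surfaced as a warning and recorded on the fit.
    """
    used = [spec.response, *spec.smooth, *spec.parametric]
    used += [c for pair in spec.tensor for c in pair]
    if spec.random_intercept:
        used.append(spec.random_intercept)
    sub = data[sorted(set(used))]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values in model columns: {bad}")

    y = data[spec.response].to_numpy(dtype=float)
    X, terms, penalties, n_unpen = _build_design(data, spec)
    n, p = X.shape
    if n <= n_unpen + 1:
        raise ValueError("not enough rows to fit the model")
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    m_p = n_unpen

    def embed(sl: slice, s: np.ndarray) -> np.ndarray:
        out = np.zeros((p, p))
        out[sl, sl] = s
        return out

    embedded = [(name, sl, s) for name, sl, s in penalties]

    def assemble(lam: np.ndarray) -> np.ndarray:
        s_tot = np.zeros((p, p))
        for (name, sl, s), l in zip(embedded, lam):
            s_tot[sl, sl] += l * s
        return s_tot

    def reml(rho: np.ndarray) -> float:
        lam = np.exp(rho)
        s_tot = assemble(lam)
        a = XtX + s_tot
        try:
            chol = np.linalg.cholesky(a + 1e-10 * np.eye(p))
        except np.linalg.LinAlgError:
            return 1e10
        beta = _chol_solve(chol, Xty)
        d_p = max(yty - beta @ Xty, 1e-12)
        log_det_a = 2.0 * np.sum(np.log(np.diag(chol)))
        log_det_s = _penalized_block_logdet(embedded, lam, p)
        if not np.isfinite(log_det_s):
            return 1e10
        nm = n - m_p
        return nm * (np.log(2.0 * np.pi * d_p / nm) + 1.0) + log_det_a - log_det_s

    if embedded:
        rho0 = np.zeros(len(embedded))
        res = optimize.minimize(
            reml,
            rho0,
            method="L-BFGS-B",
            bounds=[(-12.0, 22.0)] * len(embedded),
            options={"maxiter": maxiter, "maxfun": 20 * maxiter * (len(embedded) + 1)},
        )
        converged = bool(res.success)
        if not converged:
            warnings.warn(
                f"REML optimisation did not fully converge: {res.message}", RuntimeWarning
            )
        lam = np.exp(res.x)
    else:  # purely parametric model: nothing to smooth
        converged = True
        lam = np.empty(0)

    s_tot = assemble(lam)
    a = XtX + s_tot
    chol = np.linalg.cholesky(a + 1e-10 * np.eye(p))
    beta = _chol_solve(chol, Xty)
    a_inv = _chol_inverse(chol)
    f_mat = a_inv @ XtX
    fitted = X @ beta
    residuals = y - fitted
    rss = float(residuals @ residuals)
    edf_diag = np.diag(f_mat)
    edf = {}
    for name, info in terms.items():
        sl = info["slice"]
        edf[name] = float(np.sum(edf_diag[sl]))
    edf_total = float(np.sum(edf_diag))
    phi = rss / max(n - edf_total, 1.0)
    cov_beta = phi * a_inv

    tss = float(np.sum((y - y.mean()) ** 2))
    dev_expl = 1.0 - rss / tss if tss > 0 else 0.0
    adj_r2 = 1.0 - (rss / max(n - edf_total, 1.0)) / (tss / (n - 1)) if n > 1 and tss > 0 else 0.0

    p_values = {}
    for name, info in terms.items():
        if info["type"] not in ("smooth", "tensor"):
            continue
        sl = info["slice"]
        b = beta[sl]
        v = cov_beta[sl, sl]
        # Wald-type test with rank ~ edf (approximate)
        r = max(int(np.ceil(edf[name])), 1)
        w, u = np.linalg.eigh(v)
        keep = w > max(w.max(), 1e-300) * 1e-8
        if not keep.any():
            p_values[name] = 1.0
            continue
        v_inv = (u[:, keep] / w[keep]) @ u[:, keep].T
        stat = float(b @ v_inv @ b)
        p_values[name] = float(chi2.sf(stat, df=r))

    lambdas = {name: float(l) for (name, _, _), l in zip(embedded, lam)}
    return GammFit(
        spec=spec,
        terms=terms,
        beta=beta,
        cov_beta=cov_beta,
        lambdas=lambdas,
        edf=edf,
        edf_total=edf_total,
        phi=phi,
        deviance_explained=dev_expl,
        adj_r2=adj_r2,
        p_values=p_values,
        fitted=fitted,
        residuals=residuals,
        intercept=float(beta[0]),
        converged=converged,
        n=n,
    )


def _chol_solve(chol: np.ndarray, b: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    z = solve_triangular(chol, b, lower=True)
    return solve_triangular(chol.T, z, lower=False)


def _chol_inverse(chol: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    inv_l = solve_triangular(chol, np.eye(chol.shape[0]), lower=True)
    return inv_l.T @ inv_l
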