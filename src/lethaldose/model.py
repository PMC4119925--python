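"""Negative binomial regression of colony counts with per-strain P-splines.

The mean count μ for observation i with strain s, experiment e and dose d is

    log μ_i = β0 + α_s + γ_{e(s)} + f_s(√d_i)

with a log link, a categorical strain main effect α, a fixed experiment
effect γ nested within strain, and one penalized cubic B-spline smooth f_s
of square-root dose per strain.  Counts are negative binomial with a single
dispersion θ (variance μ + μ²/θ; Poisson as θ → ∞).  Because the initial
inoculum is unknown, its size is absorbed into the intercept and the
experiment effects; survival fractions are ratios of predicted means, which
those terms cancel out of.

Fitting maximises the NB log-likelihood minus ½ Σ_s λ_s βₛᵀPβₛ by penalized
iteratively reweighted least squares, alternating with profile-likelihood
updates of θ.  Smoothing parameters are chosen per strain on a log₁₀ grid by
coordinate descent, under a Laplace-approximate restricted marginal
likelihood by default (corrected AIC available as an alternative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from numba import njit
from scipy.interpolate import BSpline
from scipy.linalg import null_space
from scipy.optimize import minimize_scalar
from scipy.special import digamma, gammaln, xlogy

from .assay import ToleranceDataset
from .basis import SplineBasisSpec, build_bspline_basis, build_difference_penalty

__all__ = [
    "ModelSpec",
    "NBFit",
    "DegenerateFitError",
    "fit_penalized_nb",
    "select_smoothing",
    "predict_mean",
    "load_model_spec",
]

_LOG_THETA_BOUNDS = (np.log(1e-3), np.log(1e8))


class DegenerateFitError(ValueError):
    """The data cannot support a fit (e.g. a strain with all-zero counts)."""


@dataclass(frozen=True)
class ModelSpec:
    """Model configuration: basis, smoothing grid and criterion, dispersion start.

    ``lambda_grid`` is the candidate set for per-strain smoothing
    parameters (default 21 points, log-spaced 1e-4…1e6).  ``criterion``
    chooses between the Laplace-approximate restricted marginal likelihood
    (``"laml"``, the default, matching how NB additive models are usually
    smoothed) and corrected AIC (``"aicc"``).  Convergence tolerances:
    relative penalized-deviance change < ``tol`` (default 1e-8), at most
    ``max_iter`` (200) IRLS iterations.
    """

    basis: SplineBasisSpec = field(default_factory=SplineBasisSpec)
    lambda_grid: tuple[float, ...] = tuple(10.0 ** np.linspace(-4.0, 6.0, 21))
    criterion: str = "laml"
    theta_init: float = 1.0
    max_iter: int = 200
    tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.criterion not in ("laml", "aicc"):
            raise ValueError("criterion must be 'laml' or 'aicc'")


def load_model_spec(path) -> ModelSpec:
    """Build a ModelSpec from a YAML file (keys num_basis, degree,
    penalty_order, lambda_grid, theta_init; all optional)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    basis = SplineBasisSpec(
        num_basis=int(cfg.get("num_basis", 8)),
        degree=int(cfg.get("degree", 3)),
        penalty_order=int(cfg.get("penalty_order", 2)),
    )
    spec = ModelSpec(basis=basis)
    if "lambda_grid" in cfg:
        spec = replace(spec, lambda_grid=tuple(float(v) for v in cfg["lambda_grid"]))
    if "criterion" in cfg:
        spec = replace(spec, criterion=str(cfg["criterion"]))
    if "theta_init" in cfg:
        spec = replace(spec, theta_init=float(cfg["theta_init"]))
    return spec


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


@dataclass
class _Smooth:
    """Per-strain centred spline block and its penalty."""

    strain: str
    knots: np.ndarray
    degree: int
    transform: np.ndarray  # num_basis x (num_basis - 1) sum-to-zero reparametrization
    penalty: np.ndarray  # transformed difference penalty
    cols: slice
    x_lo: float
    x_hi: float
    rank: int = 0  # rank of the transformed penalty
    logdet_pos: float = 0.0  # sum of log positive penalty eigenvalues


@dataclass
class _Design:
    X: np.ndarray
    strain_levels: list[str]
    exp_levels: dict[str, list[str]]
    strain_cols: dict[str, int]  # strain -> dummy column (ref strain absent)
    exp_cols: dict[tuple[str, str], int]
    n_param: int
    smooths: dict[str, _Smooth]
    counts: np.ndarray  # original (unrounded) counts
    strain_rows: np.ndarray = None  # per-row strain label
    dose_rows: np.ndarray = None  # per-row dose

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _build_design(ds: ToleranceDataset, spec: ModelSpec) -> _Design:
    frame = ds.frame
    n = len(frame)
    strains = ds.strains
    strain_arr = frame["strain"].to_numpy()
    exp_arr = frame["experiment"].to_numpy()
    x = np.sqrt(frame["dose"].to_numpy(dtype=float))

    exp_levels = {s: ds.experiments(s) for s in strains}
    param_blocks = [np.ones((n, 1))]
    strain_cols: dict[str, int] = {}
    exp_cols: dict[tuple[str, str], int] = {}
    col = 1
    for s in strains[1:]:
        param_blocks.append((strain_arr == s).astype(float)[:, None])
        strain_cols[s] = col
        col += 1
    for s in strains:
        for e in exp_levels[s][1:]:
            param_blocks.append(((strain_arr == s) & (exp_arr == e)).astype(float)[:, None])
            exp_cols[(s, e)] = col
            col += 1
    n_param = col

    smooth_blocks = []
    smooths: dict[str, _Smooth] = {}
    for s in strains:
        rows = strain_arr == s
        xs = x[rows]
        B, knots, used = build_bspline_basis(xs, spec.basis)
        # sum-to-zero over the strain's observed rows for identifiability
        Z = null_space(B.sum(axis=0)[None, :])
        if used.penalty_order > 0:
            P = Z.T @ build_difference_penalty(used.num_basis, used.penalty_order) @ Z
        else:
            P = np.zeros((Z.shape[1], Z.shape[1]))
        block = np.zeros((n, Z.shape[1]))
        block[rows] = B @ Z
        sl = slice(col, col + Z.shape[1])
        ev = np.linalg.eigvalsh(P)
        pos = ev[ev > max(ev.max(), 1.0) * 1e-10] if ev.size else ev
        smooths[s] = _Smooth(
            s, knots, used.degree, Z, P, sl, float(xs.min()), float(xs.max()),
            rank=int(pos.size), logdet_pos=float(np.log(pos).sum()) if pos.size else 0.0,
        )
        smooth_blocks.append(block)
        col += Z.shape[1]

    X = np.hstack(param_blocks + smooth_blocks)
    return _Design(
        X=X,
        strain_levels=strains,
        exp_levels=exp_levels,
        strain_cols=strain_cols,
        exp_cols=exp_cols,
        n_param=n_param,
        smooths=smooths,
        counts=frame["count"].to_numpy(dtype=float),
        strain_rows=strain_arr,
        dose_rows=frame["dose"].to_numpy(dtype=float),
    )


def _penalty_block(design: _Design, strain: str) -> np.ndarray:
    sm = design.smooths[strain]
    P = np.zeros((design.p, design.p))
    P[sm.cols, sm.cols] = sm.penalty
    return P


def _penalty_matrix(design: _Design, lambdas: dict[str, float]) -> np.ndarray:
    P = np.zeros((design.p, design.p))
    for s, sm in design.smooths.items():
        P[sm.cols, sm.cols] += lambdas[s] * sm.penalty
    return P


# ---------------------------------------------------------------------------
# Likelihood pieces
# ---------------------------------------------------------------------------


def _nb_deviance(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    dev = xlogy(y, y / mu) - (y + theta) * np.log((y + theta) / (mu + theta))
    return float(2.0 * dev.sum())


def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    # gammaln(y + 1) omitted: constant in (mu, theta)
    return float(
        np.sum(
            gammaln(y + theta)
            - gammaln(theta)
            + theta * np.log(theta / (theta + mu))
            + xlogy(y, mu / (theta + mu))
        )
    )


def _profile_theta(y: np.ndarray, mu: np.ndarray, warm: float | None = None) -> float:
    """Profile-ML dispersion given the current means.

    Newton iteration on log θ from a warm start when available, falling
    back to bounded scalar minimisation.
    """
    lo, hi = _LOG_THETA_BOUNDS

    def score(lt: float) -> float:
        t = np.exp(lt)
        r = t + mu
        # d loglik / d log(theta)
        return t * float(
            np.sum(digamma(y + t) - digamma(t) + np.log(t / r) + 1.0 - (y + t) / r)
        )

    if warm is not None:
        # secant iteration on the profile score, warm-started
        lt0 = float(np.clip(np.log(warm), lo, hi))
        lt1 = lt0 + 0.05
        s0, s1 = score(lt0), score(lt1)
        for _ in range(40):
            if s1 == s0:
                break
            lt2 = lt1 - s1 * (lt1 - lt0) / (s1 - s0)
            if not np.isfinite(lt2):
                break
            lt2 = float(np.clip(lt2, lo, hi))
            if abs(lt2 - lt1) < 1e-8:
                return float(np.exp(lt2))
            lt0, s0, lt1 = lt1, s1, lt2
            s1 = score(lt1)
            if lt1 in (lo, hi) and lt0 in (lo, hi):
                return float(np.exp(lt1))
    res = minimize_scalar(
        lambda lt: -_nb_loglik(y, mu, np.exp(lt)),
        bounds=_LOG_THETA_BOUNDS,
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(np.exp(res.x))


@dataclass
class _PIRLSResult:
    """Result of one (possibly batched) penalized IRLS run.

    When batched, ``beta`` is (B, p), ``mu`` (B, n), ``deviance`` and
    ``converged`` length-B vectors; single fits are squeezed to the
    unbatched shapes.
    """

    beta: np.ndarray
    mu: np.ndarray
    deviance: np.ndarray | float
    pen_dev_trace: list
    converged: np.ndarray | bool
    info: np.ndarray  # XᵀWX + P at convergence
    xtwx: np.ndarray


@njit(cache=False)
def _dev_nb(y, mu, theta):  # pragma: no cover - exercised via _pirls
    dev = 0.0
    for i in range(y.shape[0]):
        if y[i] > 0.0:
            dev += y[i] * np.log(y[i] / mu[i])
        dev -= (y[i] + theta) * np.log((y[i] + theta) / (mu[i] + theta))
    return 2.0 * dev


@njit(cache=False)
def _chol_solve(A, b):  # pragma: no cover - exercised via _pirls
    """Solve A x = b for SPD A; returns (x, ok)."""
    p = A.shape[0]
    L = np.zeros((p, p))
    for j in range(p):
        s = A[j, j]
        for k in range(j):
            s -= L[j, k] * L[j, k]
        if s <= 0.0:
            return b, False
        L[j, j] = np.sqrt(s)
        for i in range(j + 1, p):
            s2 = A[i, j]
            for k in range(j):
                s2 -= L[i, k] * L[j, k]
            L[i, j] = s2 / L[j, j]
    x = np.empty(p)
    for i in range(p):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * x[k]
        x[i] = s / L[i, i]
    for i in range(p - 1, -1, -1):
        s = x[i]
        for k in range(i + 1, p):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]
    return x, True


@njit(cache=False)
def _pirls_core(X, y, Pb, beta, have_start, theta, max_iter, tol):  # pragma: no cover
    B, p = beta.shape
    n = X.shape[0]
    mu = np.empty((B, n))
    dev_out = np.empty(B)
    conv = np.zeros(B, np.bool_)
    trace = np.full((B, max_iter), np.nan)
    n_iter = np.zeros(B, np.int64)
    info = np.empty((B, p, p))
    xtwx = np.empty((B, p, p))
    for b in range(B):
        P = Pb[b]
        bet = beta[b].copy()
        if have_start:
            eta = np.minimum(np.maximum(X @ bet, -40.0), 40.0)
            m = np.exp(eta)
            pen_dev = _dev_nb(y, m, theta) + bet @ (P @ bet)
            # chain: the previous batch element's solution is often the
            # better start along an ordered penalty grid
            if b > 0 and conv[b - 1]:
                bet_c = beta[b - 1]
                eta_c = np.minimum(np.maximum(X @ bet_c, -40.0), 40.0)
                m_c = np.exp(eta_c)
                pen_c = _dev_nb(y, m_c, theta) + bet_c @ (P @ bet_c)
                if pen_c < pen_dev:
                    bet, eta, m, pen_dev = bet_c.copy(), eta_c, m_c, pen_c
        else:
            m = y + 0.5
            eta = np.log(m)
            pen_dev = np.inf
        started = have_start
        A = np.empty((p, p))
        rhs = np.empty(p)
        for it in range(max_iter):
            for j in range(p):
                rhs[j] = 0.0
                for k in range(p):
                    A[j, k] = P[j, k]
            for i in range(n):
                w = m[i] / (1.0 + m[i] / theta)
                z = eta[i] + (y[i] - m[i]) / m[i]
                wz = w * z
                xi = X[i]
                for j in range(p):
                    rhs[j] += wz * xi[j]
                    wj = w * xi[j]
                    for k in range(p):
                        A[j, k] += wj * xi[k]
            beta_new, ok = _chol_solve(A, rhs)
            if not ok:
                beta_new = np.linalg.solve(A, rhs)
            if not started:
                bet_t = beta_new
                eta_t = np.minimum(np.maximum(X @ bet_t, -40.0), 40.0)
                m_t = np.exp(eta_t)
                pen_new = _dev_nb(y, m_t, theta) + bet_t @ (P @ bet_t)
                started = True
            else:
                step = 1.0
                target = pen_dev + 1e-10 * (1.0 + abs(pen_dev))
                while True:
                    bet_t = bet + step * (beta_new - bet)
                    eta_t = np.minimum(np.maximum(X @ bet_t, -40.0), 40.0)
                    m_t = np.exp(eta_t)
                    pen_new = _dev_nb(y, m_t, theta) + bet_t @ (P @ bet_t)
                    if pen_new <= target or step < 1e-4:
                        break
                    step *= 0.5
            delta = pen_dev - pen_new
            bet, eta, m, pen_dev = bet_t, eta_t, m_t, pen_new
            trace[b, it] = pen_dev
            n_iter[b] = it + 1
            if np.isfinite(delta) and abs(delta) < tol * (abs(pen_dev) + 0.1):
                conv[b] = True
                break
        beta[b] = bet
        mu[b] = m
        dev_out[b] = _dev_nb(y, m, theta)
        # curvature at the final coefficients
        for j in range(p):
            for k in range(p):
                xtwx[b, j, k] = 0.0
        for i in range(n):
            w = m[i] / (1.0 + m[i] / theta)
            xi = X[i]
            for j in range(p):
                wj = w * xi[j]
                for k in range(p):
                    xtwx[b, j, k] += wj * xi[k]
        for j in range(p):
            for k in range(p):
                info[b, j, k] = xtwx[b, j, k] + P[j, k]
    return beta, mu, dev_out, conv, trace, n_iter, info, xtwx


def _quad(beta: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Batched quadratic forms βᵀPβ."""
    return ((beta[:, None, :] @ P)[:, 0, :] * beta).sum(axis=-1)


def _pirls(
    X: np.ndarray,
    y: np.ndarray,
    P: np.ndarray,
    beta0: np.ndarray | None = None,
    theta: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> _PIRLSResult:
    """Penalized IRLS for the NB log-link model at fixed θ and λ.

    ``P`` may be (p, p) for a single fit or (B, p, p) for B simultaneous
    fits of the same data under different penalties (used by the λ grid
    search).  Step-halving keeps each penalized deviance non-increasing
    across iterations; convergence is declared per element on relative
    change < ``tol``.
    """
    single = P.ndim == 2
    Pb = np.ascontiguousarray(P[None] if single else P)
    B = Pb.shape[0]
    n, p = X.shape
    have_start = beta0 is not None
    if have_start:
        beta = np.ascontiguousarray(
            np.broadcast_to(np.atleast_2d(beta0), (B, p)), dtype=float
        ).copy()
    else:
        beta = np.zeros((B, p))
    beta, mu, deviance, converged, trace, n_iter, info, xtwx = _pirls_core(
        np.ascontiguousarray(X, dtype=float),
        np.ascontiguousarray(y, dtype=float),
        Pb,
        beta,
        have_start,
        float(theta),
        int(max_iter),
        float(tol),
    )
    if single:
        return _PIRLSResult(
            beta=beta[0],
            mu=mu[0],
            deviance=float(deviance[0]),
            pen_dev_trace=[float(v) for v in trace[0, : n_iter[0]]],
            converged=bool(converged[0]),
            info=info[0],
            xtwx=xtwx[0],
        )
    traces = [trace[b, : n_iter[b]] for b in range(B)]
    return _PIRLSResult(beta, mu, deviance, traces, converged, info, xtwx)


def _edf(design: _Design, res: _PIRLSResult):
    """Effective degrees of freedom tr[(XᵀWX + P)⁻¹XᵀWX], total and per smooth."""
    H = np.linalg.solve(res.info, res.xtwx)
    if H.ndim == 2:
        per_smooth = {
            s: float(np.trace(H[sm.cols, sm.cols])) for s, sm in design.smooths.items()
        }
        return per_smooth, float(np.trace(H))
    total = np.trace(H, axis1=-2, axis2=-1)
    per_smooth = {
        s: np.trace(H[:, sm.cols, sm.cols], axis1=-2, axis2=-1)
        for s, sm in design.smooths.items()
    }
    return per_smooth, total


# ---------------------------------------------------------------------------
# Fitted-model container and public operations
# ---------------------------------------------------------------------------


@dataclass
class NBFit:
    """Fitted penalized NB model; see :func:`fit_penalized_nb`."""

    design: _Design
    spec: ModelSpec
    coefficients: np.ndarray
    lambdas: dict[str, float]
    theta: float
    converged: bool
    deviance: float
    edf: dict[str, float]
    edf_total: float
    fitted: np.ndarray
    y: np.ndarray
    pen_dev_trace: list[float]
    dose_unit: str = ""
    stress_name: str = ""
    d_max: dict[str, float] = field(default_factory=dict)
    _splines: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def strains(self) -> list[str]:
        return self.design.strain_levels

    def _spline(self, strain: str):
        if strain not in self._splines:
            if strain not in self.design.smooths:
                raise KeyError(f"unknown strain {strain!r}")
            sm = self.design.smooths[strain]
            gamma = sm.transform @ self.coefficients[sm.cols]
            spl = BSpline(sm.knots, gamma, sm.degree, extrapolate=False)
            self._splines[strain] = (spl, spl.derivative())
        return self._splines[strain]

    def smooth_value(self, strain: str, x: np.ndarray) -> np.ndarray:
        """Per-strain smooth f_s evaluated at √dose values ``x``.

        Inside the observed √dose range the centred B-spline is used;
        beyond it the linear predictor is extended linearly from the
        boundary value and slope.
        """
        sm = self.design.smooths.get(strain)
        if sm is None:
            raise KeyError(f"unknown strain {strain!r}")
        spl, der = self._spline(strain)
        x = np.asarray(x, dtype=float)
        out = np.empty(x.shape)
        inside = (x >= sm.x_lo) & (x <= sm.x_hi)
        out[inside] = spl(x[inside])
        lo, hi = ~inside & (x < sm.x_lo), ~inside & (x > sm.x_hi)
        if lo.any():
            out[lo] = spl(sm.x_lo) + der(sm.x_lo) * (x[lo] - sm.x_lo)
        if hi.any():
            out[hi] = spl(sm.x_hi) + der(sm.x_hi) * (x[hi] - sm.x_hi)
        return out

    def linear_predictor(self, strain: str, experiment: str, dose: np.ndarray) -> np.ndarray:
        if strain not in self.design.exp_levels:
            raise KeyError(f"unknown strain {strain!r}")
        if experiment not in self.design.exp_levels[strain]:
            raise KeyError(f"unknown experiment {experiment!r} for strain {strain!r}")
        dose = np.asarray(dose, dtype=float)
        eta = np.full(dose.shape, self.coefficients[0])
        if strain in self.design.strain_cols:
            eta += self.coefficients[self.design.strain_cols[strain]]
        key = (strain, experiment)
        if key in self.design.exp_cols:
            eta += self.coefficients[self.design.exp_cols[key]]
        return eta + self.smooth_value(strain, np.sqrt(dose))


def predict_mean(fit: NBFit, strain: str, experiment: str, dose) -> np.ndarray:
    """Predicted mean count exp(η) at the given doses; strictly positive."""
    dose = np.asarray(dose, dtype=float)
    if dose.size == 0:
        return np.empty(0)
    if np.any(dose < 0):
        raise ValueError("dose must be >= 0")
    return np.exp(fit.linear_predictor(strain, experiment, dose))


def _normalize_lambdas(design: _Design, lambdas) -> dict[str, float]:
    if np.isscalar(lambdas):
        return {s: float(lambdas) for s in design.strain_levels}
    out = {s: float(lambdas[s]) for s in design.strain_levels}
    if any(v < 0 for v in out.values()):
        raise ValueError("smoothing parameters must be >= 0")
    return out


def _aicc(deviance: float, edf_total: float, n: int) -> float:
    denom = n - edf_total - 1.0
    if denom <= 0:
        return np.inf
    return deviance + 2.0 * edf_total * n / denom


def _select(
    design: _Design,
    y: np.ndarray,
    spec: ModelSpec,
    beta0: np.ndarray | None = None,
    theta0: float | None = None,
    theta_is_fixed: bool = False,
) -> tuple[dict[str, float], float, np.ndarray]:
    """Coordinate-descent grid search for per-strain λ at a fixed θ.

    The criterion is the spec'd one in ``spec.criterion``: negative
    Laplace-approximate restricted marginal likelihood (deviance + βᵀPβ
    + log|XᵀWX + P| − log|P|₊, dropping λ-free constants) or corrected
    AIC.  θ is pinned during the grid search to a pilot profile-ML
    estimate at λ = 1 (two refinement rounds, or one when a warm-start θ
    is supplied); the final fit re-profiles it.  ``beta0``/``theta0``
    only warm-start the numerics — the selected λ depend on the data
    alone.
    """
    grid = np.asarray(spec.lambda_grid, dtype=float)
    lam = {s: 1.0 for s in design.strain_levels}
    res = _pirls(design.X, y, _penalty_matrix(design, lam), beta0=beta0,
                 theta=theta0 if theta0 is not None else spec.theta_init,
                 max_iter=spec.max_iter, tol=spec.tol)
    if theta_is_fixed:
        theta = theta0
    else:
        theta = _profile_theta(y, res.mu, warm=theta0)
        if theta0 is None:
            res = _pirls(design.X, y, _penalty_matrix(design, lam), beta0=res.beta,
                         theta=theta, max_iter=spec.max_iter, tol=spec.tol)
            theta = _profile_theta(y, res.mu, warm=theta)

    warm = res.beta
    n = design.n
    blocks = {s: _penalty_block(design, s) for s in design.strain_levels}
    any_finite = False
    seen: dict[str, tuple] = {}
    for _sweep in range(2):
        for s in design.strain_levels:
            context = tuple(lam[t] for t in design.strain_levels if t != s)
            # identical data + other-strain penalties give the identical
            # grid evaluation, so a repeat sweep can be skipped outright
            if seen.get(s) == (context, lam[s]):
                continue
            others = sum(
                (lam[t] * blocks[t] for t in design.strain_levels if t != s),
                np.zeros((design.p, design.p)),
            )
            # all grid candidates for this strain fit in one batched IRLS
            Pstack = others[None, :, :] + grid[:, None, None] * blocks[s][None, :, :]
            r = _pirls(design.X, y, Pstack, beta0=warm, theta=theta,
                       max_iter=spec.max_iter, tol=spec.tol)
            if spec.criterion == "aicc":
                _, edf_total = _edf(design, r)
                crit = np.array([_aicc(d, e, n) for d, e in zip(r.deviance, edf_total)])
            else:
                logdet_a = np.linalg.slogdet(r.info)[1]
                logdet_p = np.array(
                    [
                        sum(
                            design.smooths[t].rank * np.log(lam_t)
                            + design.smooths[t].logdet_pos
                            for t, lam_t in (
                                [(s, g)] + [(t, lam[t]) for t in lam if t != s]
                            )
                        )
                        for g in grid
                    ]
                )
                crit = r.deviance + _quad(r.beta, Pstack) + logdet_a - logdet_p
            crit[~r.converged] = np.inf
            if np.isfinite(crit).any():
                any_finite = True
                best = int(np.argmin(crit))
                lam[s] = float(grid[best])
                warm = r.beta[best]
                seen[s] = (context, lam[s])
    if not any_finite:
        warnings.warn("smoothing criterion non-finite on the whole grid; "
                      "falling back to heaviest smoothing", stacklevel=2)
        lam = {s: float(grid.max()) for s in design.strain_levels}
    return lam, theta, warm


def select_smoothing(ds: ToleranceDataset, spec: ModelSpec | None = None) -> dict[str, float]:
    """Per-strain smoothing parameters minimising the spec's criterion —
    Laplace-approximate restricted marginal likelihood by default, or
    corrected AIC deviance + 2·edf·n/(n − edf − 1) — over the λ grid
    (coordinate descent, two sweeps).  Deterministic given the data."""
    spec = spec or ModelSpec()
    design = _build_design(ds, spec)
    y = _rounded_counts(design)
    lam, _, _ = _select(design, y, spec)
    return lam


def _rounded_counts(design: _Design) -> np.ndarray:
    # c.f.u./mL values are back-calculated scaled counts; the NB likelihood
    # needs integers, so round to nearest.
    return np.rint(design.counts)


def _fit_from_design(
    design: _Design,
    y: np.ndarray,
    spec: ModelSpec,
    lambdas=None,
    dose_unit: str = "",
    stress_name: str = "",
    d_max: dict[str, float] | None = None,
    beta0: np.ndarray | None = None,
    theta0: float | None = None,
    theta_fixed: float | None = None,
) -> NBFit:
    # all-zero strain counts cannot identify a curve on the log scale
    for s in design.strain_levels:
        if np.all(y[design.strain_rows == s] == 0):
            raise DegenerateFitError(f"strain {s!r} has all-zero counts")

    warm = beta0
    if lambdas is None:
        lam, theta0, warm = _select(
            design, y, spec, beta0=beta0,
            theta0=theta_fixed if theta_fixed is not None else theta0,
            theta_is_fixed=theta_fixed is not None,
        )
    else:
        lam = _normalize_lambdas(design, lambdas)

    if theta_fixed is not None:
        theta = theta_fixed
    else:
        theta = theta0 if theta0 is not None else spec.theta_init
    P = _penalty_matrix(design, lam)
    res = _pirls(design.X, y, P, beta0=warm, theta=theta,
                 max_iter=spec.max_iter, tol=spec.tol)
    if theta_fixed is None:
        # alternate profile-ML dispersion updates with IRLS refits
        for _ in range(15):
            theta_new = _profile_theta(y, res.mu, warm=theta)
            done = abs(np.log(theta_new / theta)) < 1e-3
            theta = theta_new
            res = _pirls(design.X, y, P, beta0=res.beta, theta=theta,
                         max_iter=spec.max_iter, tol=spec.tol)
            if done:
                break
    if not res.converged:
        warnings.warn("penalized IRLS did not converge", stacklevel=2)
    edf_s, edf_total = _edf(design, res)
    return NBFit(
        design=design,
        spec=spec,
        coefficients=res.beta,
        lambdas=lam,
        theta=theta,
        converged=res.converged,
        deviance=res.deviance,
        edf=edf_s,
        edf_total=edf_total,
        fitted=res.mu,
        y=y,
        pen_dev_trace=res.pen_dev_trace,
        dose_unit=dose_unit,
        stress_name=stress_name,
        d_max=d_max or {},
    )


def fit_penalized_nb(
    ds: ToleranceDataset,
    spec: ModelSpec | None = None,
    lambdas=None,
    theta: float | None = None,
) -> NBFit:
    """Fit the penalized NB dose–response model.

    Parameters
    ----------
    ds
        Validated tolerance dataset (plate duplicates as separate rows).
    spec
        Model configuration; defaults to an 8-function cubic basis with a
        second-difference penalty.
    lambdas
        Optional fixed smoothing parameter(s) — a scalar or a mapping
        strain → λ.  When omitted, per-strain λ are selected by corrected
        AIC (:func:`select_smoothing`) before the final fit.
    theta
        Optional fixed NB dispersion.  When omitted, θ is estimated by
        profile maximum likelihood, alternating with the IRLS updates.

    Returns
    -------
    NBFit
        Coefficients, smoothing parameters, dispersion θ (profile ML),
        per-smooth effective degrees of freedom, fitted means, and the
        penalized-deviance trace of the final IRLS run.
    """
    spec = spec or ModelSpec()
    design = _build_design(ds, spec)
    y = _rounded_counts(design)
    d_max = {s: ds.max_dose(s) for s in ds.strains}
    return _fit_from_design(
        design, y, spec, lambdas=lambdas, theta_fixed=theta,
        dose_unit=ds.dose_unit, stress_name=ds.stress_name, d_max=d_max,
    )
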