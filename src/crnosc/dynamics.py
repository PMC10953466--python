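"""Mass-action dynamics: vector field, equilibria, integrals, simulation.

The mass-action differential equation of a network with stoichiometric
matrix ``Gamma``, source matrix ``Gamma_l`` and rate constants ``kappa`` is

    dx/dt = Gamma (kappa o x^{Gamma_l^T}),

where ``o`` is the entrywise product and ``x^A`` the vector of monomials
with exponent rows from ``A``.  For three-reaction rank-two networks the
positive equilibria solve the log-linear system
``a_j . log x = log(|u_j|/kappa_j) + log|mu|`` derived from
``kappa o x^{Gamma_l^T} = mu u``, which this module solves directly instead
of running Newton iterations: existence and uniqueness then follow from the
linear algebra, not from numerics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.integrate import solve_ivp

from . import _exact
from ._exact import sign
from .network import Network, NetworkError, kernel_sign_vector


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class MassActionSystem:
    """A network with positive rate constants; an evaluable vector field."""

    net: Network
    kappa: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.kappa) != self.net.m:
            raise NetworkError("kappa length must equal the number of reactions")
        if any(k <= 0 for k in self.kappa):
            raise NetworkError("rate constants must be positive")

    @property
    def _kappa_arr(self) -> np.ndarray:
        return np.asarray(self.kappa, dtype=float)

    def monomials(self, x: np.ndarray) -> np.ndarray:
        """kappa o x^{Gamma_l^T}: one rate term per reaction."""
        x = np.asarray(x, dtype=float)
        expo = self.net.gamma_l.T  # m x n
        with np.errstate(divide="ignore"):
            return self._kappa_arr * np.prod(x[None, :] ** expo, axis=1)

    def rhs(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.net.n,):
            raise NetworkError("state dimension mismatch")
        return self.net.gamma @ self.monomials(x)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """Analytic Jacobian; requires x > 0 entrywise."""
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise NetworkError("jacobian requires a positive state")
        v = self.monomials(x)  # m
        # d(monomial_j)/dx_l = a_lj * v_j / x_l
        dmono = v[:, None] * (self.net.gamma_l.T / x[None, :])  # m x n
        return self.net.gamma @ dmono


def rhs(sys: MassActionSystem, x) -> np.ndarray:
    return sys.rhs(np.asarray(x, dtype=float))


def jacobian(sys: MassActionSystem, x) -> np.ndarray:
    return sys.jacobian(np.asarray(x, dtype=float))


def rhs_exact(net: Network, kappa, x) -> list[Fraction]:
    """Vector field with exact Fraction arithmetic (rational kappa, x)."""
    kappa = [Fraction(k) for k in kappa]
    x = [Fraction(v) for v in x]
    gl = net.gamma_l
    gamma = net.gamma
    v = []
    for j in range(net.m):
        term = kappa[j]
        for i in range(net.n):
            term *= x[i] ** int(gl[i, j])
        v.append(term)
    return [
        sum(Fraction(int(gamma[i, j])) * v[j] for j in range(net.m))
        for i in range(net.n)
    ]


# ---------------------------------------------------------------------------
# equilibria of (n, 3, 2) systems
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EquilibriumPoint:
    x: tuple[float, ...]
    mu: float
    residual: float


@dataclass(frozen=True)
class EquilibriumSet:
    """Solution set of the log-linear equilibrium system.

    In log coordinates the positive equilibria form the affine set
    ``(log x, log|mu|) = particular + basis @ theta``.  ``unique`` holds
    exactly when the basis is empty (sources affinely independent, n=2).
    """

    system: MassActionSystem
    u: tuple[int, ...]
    mu_sign: int
    particular: tuple[float, ...] | None  # length n+1, last entry log|mu|
    basis: tuple[tuple[float, ...], ...]  # each length n+1
    empty: bool = False

    @property
    def unique(self) -> bool:
        return not self.empty and len(self.basis) == 0

    @property
    def dim(self) -> int:
        return len(self.basis)

    def point_at(self, theta=()) -> EquilibriumPoint:
        if self.empty:
            raise NetworkError("no positive equilibria")
        vec = np.asarray(self.particular, dtype=float)
        for t, b in zip(np.atleast_1d(np.asarray(theta, dtype=float)), self.basis):
            vec = vec + t * np.asarray(b)
        x = np.exp(vec[:-1])
        mu = self.mu_sign * float(np.exp(vec[-1]))
        res = float(np.max(np.abs(self.system.rhs(x))))
        return EquilibriumPoint(tuple(x), mu, res)

    def intersect_class(
        self, x0, theta_range=(-12.0, 12.0), grid: int = 600
    ) -> list[EquilibriumPoint]:
        """Equilibria on the stoichiometric class of x0 (numeric root find).

        Only implemented for one-parameter equilibrium families (the cases
        arising from three-reaction networks with n=3); finds all sign
        changes of the class constraint along the family.
        """
        if self.empty:
            return []
        if self.dim == 0:
            pt = self.point_at()
            w = _left_kernel_float(self.system.net)
            x0 = np.asarray(x0, dtype=float)
            if w.size == 0 or np.allclose(w @ (np.asarray(pt.x) - x0), 0, atol=1e-9):
                return [pt]
            return []
        if self.dim > 1:
            return self._intersect_class_multistart(x0)
        w = _left_kernel_float(self.system.net)
        x0 = np.asarray(x0, dtype=float)

        def gap(theta: float) -> np.ndarray:
            vec = np.asarray(self.particular) + theta * np.asarray(self.basis[0])
            with np.errstate(over="ignore", invalid="ignore"):
                return w @ (np.exp(np.minimum(vec[:-1], 500.0)) - x0)

        from scipy.optimize import brentq

        thetas = np.linspace(*theta_range, grid)
        vals = np.array([gap(t) for t in thetas])
        roots: list[float] = []
        if vals.ndim == 1:
            vals = vals[:, None]
        # all class constraints must vanish simultaneously; scan the first,
        # then check the rest at each root
        for a, b, fa, fb in zip(thetas[:-1], thetas[1:], vals[:-1, 0], vals[1:, 0]):
            if fa == 0.0:
                roots.append(float(a))
            elif fa * fb < 0:
                roots.append(float(brentq(lambda t: gap(t)[0], a, b, xtol=1e-13)))
        out = []
        for r in roots:
            if np.max(np.abs(gap(r))) < 1e-7 * (1 + np.max(np.abs(x0))):
                out.append(self.point_at((r,)))
        return out


    def _intersect_class_multistart(self, x0) -> list[EquilibriumPoint]:
        """Roots of the class constraints over a k-parameter family (k >= 2)
        by damped root finding from a coarse grid of starts."""
        from scipy.optimize import root

        w = _left_kernel_float(self.system.net)
        x0 = np.asarray(x0, dtype=float)
        basis = np.asarray(self.basis)

        def gap(theta: np.ndarray) -> np.ndarray:
            vec = np.asarray(self.particular) + basis.T @ theta
            with np.errstate(over="ignore", invalid="ignore"):
                return w @ (np.exp(np.minimum(vec[:-1], 500.0)) - x0)

        found: list[np.ndarray] = []
        grid = np.linspace(-3.0, 3.0, 5)
        for start in np.array(np.meshgrid(*[grid] * self.dim)).reshape(self.dim, -1).T:
            res = root(gap, start, method="hybr")
            if not res.success:
                continue
            if np.max(np.abs(gap(res.x))) > 1e-8 * (1 + np.max(np.abs(x0))):
                continue
            if any(np.linalg.norm(res.x - f) < 1e-6 for f in found):
                continue
            found.append(res.x)
        return [self.point_at(tuple(theta)) for theta in found]


def _left_kernel_float(net: Network) -> np.ndarray:
    basis = _exact.left_nullspace([list(r) for r in net.gamma.tolist()])
    if not basis:
        return np.zeros((0, net.n))
    return np.array([[float(x) for x in w] for w in basis])


def positive_equilibria(sys: MassActionSystem) -> EquilibriumSet:
    """Positive equilibria of a dynamically nontrivial (n, 3, 2) system.

    Solves the log-linear system a_j . log x - log|mu| = log(|u_j|/kappa_j).
    Raises if the kernel vector u is not strictly one-signed (no positive
    equilibrium can exist).
    """
    net = sys.net
    u = kernel_sign_vector(net)
    signs = {sign(v) for v in u}
    if signs not in ({1}, {-1}):
        raise NetworkError("kernel vector not strictly one-signed: no positive equilibria")
    mu_sign = next(iter(signs))
    a = net.gamma_l.T.astype(float)  # 3 x n
    mat = np.hstack([a, -np.ones((3, 1))])  # unknowns (log x, log|mu|)
    b = np.log(np.abs(np.asarray(u, dtype=float)) / np.asarray(sys.kappa))
    sol = np.linalg.lstsq(mat, b, rcond=None)[0]
    # consistency: residual of the linear system must vanish
    if np.linalg.norm(mat @ sol - b) > 1e-9 * (1 + np.linalg.norm(b)):
        return EquilibriumSet(sys, u, mu_sign, None, (), empty=True)
    # nullspace of mat -> family directions in log coordinates
    _, s, vt = np.linalg.svd(mat)
    tol = max(mat.shape) * s[0] * np.finfo(float).eps
    null = vt[int(np.sum(s > tol)):]
    basis = tuple(tuple(row) for row in null)
    return EquilibriumSet(sys, u, mu_sign, tuple(sol), basis)


def equilibrium_mu(sys: MassActionSystem, x) -> float:
    """Scalar mu with kappa o x^{Gamma_l^T} = mu u at an equilibrium x."""
    u = np.asarray(kernel_sign_vector(sys.net), dtype=float)
    v = sys.monomials(np.asarray(x, dtype=float))
    ratios = v / u
    if np.max(np.abs(ratios - ratios.mean())) > 1e-6 * (1 + abs(ratios.mean())):
        raise NetworkError("state is not an equilibrium (monomials not parallel to u)")
    return float(ratios.mean())


# ---------------------------------------------------------------------------
# first integrals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FirstIntegral:
    """Conserved quantity sum_i alpha_i x_i + sum_i beta_i log x_i."""

    kind: str  # "linear" | "logarithmic"
    alpha: tuple[float, ...]
    beta: tuple[float, ...]

    def value(self, x) -> float:
        x = np.asarray(x, dtype=float)
        out = float(np.dot(self.alpha, x))
        if any(self.beta):
            out += float(np.dot(self.beta, np.log(x)))
        return out

    def lie_derivative(self, sys: MassActionSystem, x) -> float:
        x = np.asarray(x, dtype=float)
        f = sys.rhs(x)
        return float(np.dot(self.alpha, f) + np.dot(np.asarray(self.beta) / x, f))


def _lv_no_diagonal_data(sys: MassActionSystem):
    """Return (r, B) if the ODE is Lotka-Volterra with no diagonal term.

    That is dx_i/dt = x_i (r_i + sum_{k != i} b_ik x_k): every reaction that
    changes species i must contain exactly one X_i in its source and have
    source molecularity <= 2 with no 2X_i source.
    """
    net = sys.net
    gamma, gl = net.gamma, net.gamma_l
    n = net.n
    r = np.zeros(n)
    b = np.zeros((n, n))
    for j in range(net.m):
        src = gl[:, j]
        if src.sum() > 2:
            return None
        for i in range(n):
            cij = gamma[i, j]
            if cij == 0:
                continue
            if src[i] != 1:
                return None
            rest = src.copy()
            rest[i] -= 1
            k = np.flatnonzero(rest)
            if k.size == 0:
                r[i] += cij * sys.kappa[j]
            else:
                b[i, k[0]] += cij * sys.kappa[j]
    return r, b


def conserved_quantities(sys: MassActionSystem) -> list[FirstIntegral]:
    """All linear first integrals, plus closed-form logarithmic integrals
    for Lotka-Volterra-type systems with no diagonal term.

    Linear integrals are the left kernel of Gamma (exact).  For a planar
    LV system dx/dt = x(r1 + b12 y), dy/dt = y(r2 + b21 x) the quantity
    r1 log y - r2 log x + b12 y - b21 x is conserved; for a rank-two
    three-species LV system with zero intrinsic rates and conservation
    vector d the quantity d1 d2 b23 log x1 + d2 d3 b31 log x2 +
    d1 d3 b12 log x3 is conserved.  Each candidate is admitted only after
    its Lie derivative is checked to vanish coefficient-wise.
    """
    net = sys.net
    out: list[FirstIntegral] = []
    for w in _exact.left_nullspace([list(r) for r in net.gamma.tolist()]):
        out.append(
            FirstIntegral("linear", tuple(float(x) for x in w), (0.0,) * net.n)
        )
    data = _lv_no_diagonal_data(sys)
    if data is not None:
        r, b = data
        if net.n == 2:
            cand = FirstIntegral(
                "logarithmic", (-b[1, 0], b[0, 1]), (-r[1], r[0])
            )
            if _integral_checks_out(sys, cand):
                out.append(cand)
        elif net.n == 3 and np.max(np.abs(r)) < 1e-14:
            w = _left_kernel_float(net)
            if w.shape[0] == 1:
                d = w[0]
                beta = (
                    d[0] * d[1] * b[1, 2],
                    d[1] * d[2] * b[2, 0],
                    d[0] * d[2] * b[0, 1],
                )
                cand = FirstIntegral("logarithmic", (0.0,) * 3, beta)
                if _integral_checks_out(sys, cand):
                    out.append(cand)
    return out


def _integral_checks_out(sys: MassActionSystem, integral: FirstIntegral) -> bool:
    rng = np.random.default_rng(0)
    scale = max(
        1.0, max(abs(a) for a in integral.alpha), max(abs(bb) for bb in integral.beta)
    )
    for _ in range(8):
        x = rng.uniform(0.2, 3.0, sys.net.n)
        if abs(integral.lie_derivative(sys, x)) > 1e-9 * scale:
            return False
    return True


# ---------------------------------------------------------------------------
# simulation and periodicity
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    times: np.ndarray
    states: np.ndarray  # (len(times), n)
    status: str  # "completed" | "hit_boundary" | "blow_up"
    integral_drift: dict[int, float] = field(default_factory=dict)

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]


def simulate(
    sys: MassActionSystem,
    x0,
    t_end: float,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    max_state: float = 1e8,
    dense: bool = False,
):
    """Adaptive integration of the mass-action ODE from a positive state.

    Center orbits are neutrally stable, so the default tolerances are tight
    (loose tolerances turn closed orbits into fake spirals).  The positive
    orthant is forward invariant for the exact flow; a numerically escaping
    trajectory terminates with status ``hit_boundary`` and exceeding
    ``max_state`` terminates with ``blow_up``.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 <= 0):
        raise SimulationError("initial state must be positive")

    def f(_t, x):
        return sys.rhs(x)

    def hit_boundary(_t, x):
        return float(np.min(x))

    hit_boundary.terminal = True
    hit_boundary.direction = -1

    def blow_up(_t, x):
        return float(max_state - np.max(np.abs(x)))

    blow_up.terminal = True
    blow_up.direction = -1

    res = solve_ivp(
        f,
        (0.0, t_end),
        x0,
        method="DOP853",
        rtol=rtol,
        atol=atol,
        events=[hit_boundary, blow_up],
        dense_output=dense,
    )
    if res.status == 1:
        status = "hit_boundary" if len(res.t_events[0]) else "blow_up"
    elif res.status == 0:
        status = "completed"
    else:
        raise SimulationError(f"integration failed: {res.message}")
    traj = Trajectory(res.t, res.y.T, status)
    linear = [fi for fi in conserved_quantities(sys) if fi.kind == "linear"]
    for i, fi in enumerate(linear):
        vals = traj.states @ np.asarray(fi.alpha)
        traj.integral_drift[i] = float(np.max(np.abs(vals - vals[0])))
    if dense:
        traj.sol = res.sol  # type: ignore[attr-defined]
    return traj


def class_plane_basis(net: Network) -> np.ndarray:
    """Orthonormal basis (n x 2) of the stoichiometric subspace (rank 2)."""
    gamma = net.gamma.astype(float)
    u, s, _ = np.linalg.svd(gamma)
    if int(np.sum(s > 1e-10 * s[0])) != 2:
        raise NetworkError("stoichiometric subspace is not two-dimensional")
    return u[:, :2]


def detect_periodicity(
    sys: MassActionSystem,
    x0,
    t_max: float = 400.0,
    closure_rtol: float = 1e-4,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> dict:
    """Poincare-section test for a periodic orbit through x0.

    Works in coordinates on the two-dimensional stoichiometric class of x0.
    The section is the line through x0 normal to the flow; the orbit is
    declared periodic iff the first return lands within ``closure_rtol``
    (relative to the orbit's extent) of x0.  A verdict of non-periodicity
    is only issued with positive evidence (monotone spiral or convergence
    to an equilibrium); otherwise the test is inconclusive.
    """
    x0 = np.asarray(x0, dtype=float)
    basis = class_plane_basis(sys.net)
    f0 = sys.rhs(x0)
    v0 = basis.T @ f0
    speed0 = np.linalg.norm(v0)
    if speed0 < 1e-12 * (1 + np.linalg.norm(x0)):
        return {"periodic": False, "reason": "started at an equilibrium"}
    normal = v0 / speed0

    def section(_t, x):
        return float(normal @ (basis.T @ (x - x0)))

    section.terminal = False
    section.direction = 1

    def hit_boundary(_t, x):
        return float(np.min(x))

    hit_boundary.terminal = True
    hit_boundary.direction = -1

    def blow_up(_t, x):
        return float(1e8 - np.max(np.abs(x)))

    blow_up.terminal = True
    blow_up.direction = -1

    res = solve_ivp(
        lambda _t, x: sys.rhs(x),
        (0.0, t_max),
        x0,
        method="DOP853",
        rtol=rtol,
        atol=atol,
        events=[section, hit_boundary, blow_up],
        dense_output=True,
    )
    crossings = [t for t in res.t_events[0] if t > 1e-8]
    if not crossings:
        if len(res.t_events[2]):
            return {"periodic": False, "reason": "unbounded orbit"}
        xf = res.y[:, -1]
        if np.linalg.norm(sys.rhs(xf)) < 1e-7 * speed0:
            return {"periodic": False, "reason": "converged to an equilibrium"}
        return {"periodic": None, "reason": "no section return within t_max"}
    # closure is judged relative to the extent of the first loop only: a
    # diverging spiral must not be normalised by its own blow-up scale
    first_loop = res.y[:, res.t <= crossings[0]]
    extent = float(
        np.max(np.linalg.norm(basis.T @ (first_loop - x0[:, None]), axis=0))
    )
    scale = max(extent, 1e-12)
    returns = [np.asarray(res.sol(t)) for t in crossings[:3]]
    errs = [float(np.linalg.norm(basis.T @ (xr - x0))) / scale for xr in returns]
    if errs[0] < closure_rtol:
        return {
            "periodic": True,
            "period": float(crossings[0]),
            "closure_error": errs[0],
        }
    if len(res.t_events[2]):
        return {
            "periodic": False,
            "reason": "unbounded orbit",
            "closure_error": errs[0],
        }
    if len(errs) >= 2 and (errs[1] > errs[0] > closure_rtol or errs[1] < errs[0]):
        # monotone drift of the return point: spiral, not a closed orbit
        return {
            "periodic": False,
            "reason": "return map drifts monotonically",
            "closure_error": errs[0],
        }
    return {"periodic": None, "reason": "ambiguous return map", "closure_error": errs[0]}
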