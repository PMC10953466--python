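"""Reduced Jacobian, planar stability formulas, and the first focal value.

For a dynamically nontrivial (n, 3, 2) mass-action system with kernel
vector u = c x d (c, d the two privileged rows of Gamma) and positive
equilibrium x_bar with kappa o x_bar^{Gamma_l^T} = mu u, the reduced
Jacobian on the stoichiometric class is

    J_red = mu [c^T; d^T] Delta_u Gamma_l^T Delta_{1/x_bar} Gamma_tilde,

with Gamma = Gamma_tilde [c^T; d^T].  Its determinant expands by
Cauchy-Binet into a sum over species pairs (i, j) of terms
Gamma_tilde[{i,j}] / (x_i x_j) * orientation(i, j), where orientation is
the signed area datum 1.(a_i x a_j) of the projected source complexes.
The expansion carries a positive normalisation that is never used in the
theory, so this module asserts sign agreement (and positive
proportionality) between the matrix determinant and the expansion, not
literal equality.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from . import _exact
from ._exact import sign
from .dynamics import (
    MassActionSystem,
    equilibrium_mu,
    positive_equilibria,
    simulate,
)
from .network import Network, NetworkError, kernel_sign_vector


# ---------------------------------------------------------------------------
# orientation of source complexes
# ---------------------------------------------------------------------------


def source_orientation(net: Network, i: int, j: int) -> int:
    """Sign of 1.(a_i x a_j) for species rows a_i, a_j of Gamma_l (m=3).

    Positive means the three source complexes, projected onto the (i, j)
    species plane, are traversed counterclockwise in reaction order.
    """
    if net.m != 3:
        raise NetworkError("source_orientation requires exactly 3 reactions")
    gl = net.gamma_l
    cr = _exact.cross3(gl[i].tolist(), gl[j].tolist())
    return sign(sum(cr))


def orientation_value(net: Network, i: int, j: int) -> int:
    """The integer 1.(a_i x a_j) itself (twice the signed area)."""
    gl = net.gamma_l
    return int(sum(_exact.cross3(gl[i].tolist(), gl[j].tolist())))


# ---------------------------------------------------------------------------
# reduced Jacobian
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReducedJacobianReport:
    gamma_tilde: tuple[tuple[Fraction, ...], ...]  # n x 2, exact
    jred: np.ndarray  # 2 x 2
    det: float
    det_sign: int
    trace: float
    mu: float
    u: tuple[int, ...]
    cauchy_binet_terms: dict[tuple[int, int], float]
    cauchy_binet_sign: int
    privileged_rows: tuple[int, int]


def _gamma_tilde(net: Network) -> tuple[list[list[Fraction]], tuple[int, int]]:
    """Exact Gamma_tilde with Gamma = Gamma_tilde [c^T; d^T]; the block of
    Gamma_tilde at the privileged rows is the 2x2 identity."""
    rows = [list(r) for r in net.gamma.tolist()]
    i1, i2 = _exact.independent_rows(rows, 2)
    m_t = [list(col) for col in zip(rows[i1], rows[i2])]  # 3 x 2, = [c d] columns
    gt: list[list[Fraction]] = []
    for row in rows:
        coeffs = _exact.solve(m_t, row)
        if coeffs is None:  # pragma: no cover - impossible at rank 2
            raise NetworkError("row not in the span of the privileged rows")
        gt.append(coeffs)
    return gt, (i1, i2)


def reduced_jacobian(
    sys: MassActionSystem, x, residual_tol: float = 1e-8
) -> ReducedJacobianReport:
    """Reduced Jacobian of an (n, 3, 2) system at a positive equilibrium.

    The determinant is computed from the 2x2 matrix and cross-checked in
    sign against the Cauchy-Binet expansion over species pairs.
    """
    net = sys.net
    x = np.asarray(x, dtype=float)
    res = float(np.max(np.abs(sys.rhs(x))))
    scale = float(np.max(sys.monomials(x)))
    if res > residual_tol * max(1.0, scale):
        raise NetworkError(f"state is not an equilibrium (residual {res:.2e})")
    u = kernel_sign_vector(net)
    mu = equilibrium_mu(sys, x)
    gt_exact, (i1, i2) = _gamma_tilde(net)
    gt = np.array([[float(v) for v in row] for row in gt_exact])
    cd = net.gamma[[i1, i2], :].astype(float)  # [c^T; d^T]
    jred = (
        mu
        * cd
        @ np.diag(np.asarray(u, dtype=float))
        @ net.gamma_l.T.astype(float)
        @ np.diag(1.0 / x)
        @ gt
    )
    det = float(np.linalg.det(jred))
    terms: dict[tuple[int, int], float] = {}
    total = 0.0
    for i in range(net.n):
        for j in range(i + 1, net.n):
            minor = float(gt_exact[i][0] * gt_exact[j][1] - gt_exact[i][1] * gt_exact[j][0])
            if minor == 0.0:
                continue
            t = minor / (x[i] * x[j]) * orientation_value(net, i, j)
            terms[(i, j)] = t
            total += t
    det_scale = max(abs(det), 1.0) * 1e-12
    det_sign = 0 if abs(det) < det_scale else sign(det)
    cb_sign = sign(mu) * (0 if abs(total) < 1e-12 else sign(total))
    if det_sign != 0 and cb_sign != 0 and det_sign != cb_sign:
        raise AssertionError(
            "matrix determinant and Cauchy-Binet expansion disagree in sign"
        )
    return ReducedJacobianReport(
        gamma_tilde=tuple(tuple(r) for r in gt_exact),
        jred=jred,
        det=det,
        det_sign=det_sign,
        trace=float(np.trace(jred)),
        mu=mu,
        u=u,
        cauchy_binet_terms=terms,
        cauchy_binet_sign=cb_sign,
        privileged_rows=(i1, i2),
    )


# ---------------------------------------------------------------------------
# planar determinant / trace
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlanarStability:
    det: float
    trace: float
    klass: str  # saddle | center_candidate | stable_focus_or_node | ...
    mu: float
    u: tuple[int, ...]
    trace_formula: float  # Eq.-(18)-style trace, cross-check
    det_sign_rule: int  # sign predicted by the orientation/kernel sign rule


def planar_det_tr(
    sys: MassActionSystem, x=None, zero_tol: float = 1e-9
) -> PlanarStability:
    """det J and tr J at the unique positive equilibrium of a (2, 3, 2) system.

    The determinant sign is cross-checked against the rule
    sgn det J = orientation(sources) * sgn mu, and the trace against the
    kernel-weighted formula mu (1/x sum a_i c_i u_i + 1/y sum b_i d_i u_i).
    """
    net = sys.net
    if net.n != 2 or net.m != 3:
        raise NetworkError("planar_det_tr requires a (2, 3, *) network")
    if x is None:
        eq = positive_equilibria(sys)
        if eq.empty or not eq.unique:
            raise NetworkError("no unique positive equilibrium")
        x = eq.point_at().x
    x = np.asarray(x, dtype=float)
    jac = sys.jacobian(x)
    det = float(np.linalg.det(jac))
    tr = float(np.trace(jac))
    u = kernel_sign_vector(net)
    mu = equilibrium_mu(sys, x)
    a = net.gamma_l[0]
    b = net.gamma_l[1]
    c = net.gamma[0]
    d = net.gamma[1]
    uf = np.asarray(u, dtype=float)
    tr_formula = mu * (
        float(a @ (c * uf)) / x[0] + float(b @ (d * uf)) / x[1]
    )
    det_sign_rule = source_orientation(net, 0, 1) * sign(mu)
    scale = float(np.max(np.abs(jac))) or 1.0
    if abs(det) < zero_tol * scale**2:
        klass = "degenerate"
    elif det < 0:
        klass = "saddle"
    elif abs(tr) < zero_tol * scale:
        klass = "center_candidate"
    elif tr < 0:
        klass = "stable_focus_or_node"
    else:
        klass = "unstable_focus_or_node"
    return PlanarStability(det, tr, klass, mu, u, tr_formula, det_sign_rule)


# ---------------------------------------------------------------------------
# first focal value
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FocalValue:
    l1: float
    omega: float
    kind: str  # "supercritical" | "subcritical" | "vertical_candidate"
    x: tuple[float, ...]
    kappa: tuple[float, ...]


def _quadratic_hessians(sys: MassActionSystem) -> list[np.ndarray]:
    """Constant Hessians of the (necessarily quadratic) planar RHS."""
    net = sys.net
    h = [np.zeros((2, 2)) for _ in range(2)]
    for j in range(net.m):
        a = net.gamma_l[:, j]
        if a.sum() != 2:
            continue
        k = sys.kappa[j]
        if a[0] == 2:
            hj = np.array([[2.0 * k, 0.0], [0.0, 0.0]])
        elif a[1] == 2:
            hj = np.array([[0.0, 0.0], [0.0, 2.0 * k]])
        else:
            hj = np.array([[0.0, k], [k, 0.0]])
        for i in range(2):
            h[i] = h[i] + net.gamma[i, j] * hj
    return h


def first_focal_value(
    sys: MassActionSystem,
    x=None,
    trace_tol: float = 1e-7,
    vertical_tol: float = 1e-8,
) -> FocalValue:
    """First focal value L1 at a center candidate of a planar quadratic system.

    The equilibrium is translated to the origin and the linear part brought
    to [[0, -w], [w, 0]]; the standard planar normal-form coefficient is
    then evaluated on the transformed quadratic nonlinearity (cubic terms
    vanish identically for bimolecular sources).  L1 < 0 at a Hopf point
    means the bifurcation is supercritical.  Values below ``vertical_tol``
    (after scaling by the nonlinearity size and w) are reported as
    ``vertical_candidate`` rather than given a sign.
    """
    net = sys.net
    if net.n != 2:
        raise NetworkError("first focal value implemented for planar systems")
    if x is None:
        x = positive_equilibria(sys).point_at().x
    x = np.asarray(x, dtype=float)
    jac = sys.jacobian(x)
    det = float(np.linalg.det(jac))
    tr = float(np.trace(jac))
    scale = float(np.max(np.abs(jac))) or 1.0
    if det <= 0:
        raise NetworkError("not a center candidate: det J <= 0")
    if abs(tr) > trace_tol * scale:
        raise NetworkError(f"not at a Hopf point: tr J = {tr:.2e}")
    omega = float(np.sqrt(det))
    j11, j12 = jac[0, 0], jac[0, 1]
    # tr J = 0, det J > 0 forces j12 != 0 (j11^2 + j12 j21 = -omega^2)
    t = np.array([[j12, 0.0], [-j11, -omega]])
    tinv = np.linalg.inv(t)
    hess = _quadratic_hessians(sys)
    # Hessians of xi' = T^-1 F(x_bar + T xi): H~_k = sum_i Tinv[k,i] T^T H_i T
    hts = [t.T @ h @ t for h in hess]
    hf = tinv[0, 0] * hts[0] + tinv[0, 1] * hts[1]
    hg = tinv[1, 0] * hts[0] + tinv[1, 1] * hts[1]
    f_xx, f_xy, f_yy = hf[0, 0], hf[0, 1], hf[1, 1]
    g_xx, g_xy, g_yy = hg[0, 0], hg[0, 1], hg[1, 1]
    l1 = (
        f_xy * (f_xx + f_yy)
        - g_xy * (g_xx + g_yy)
        - f_xx * g_xx
        + f_yy * g_yy
    ) / (16.0 * omega)
    nl_scale = max(abs(v) for v in (f_xx, f_xy, f_yy, g_xx, g_xy, g_yy))
    threshold = vertical_tol * max(nl_scale**2 / omega, 1e-30)
    if abs(l1) < threshold:
        kind = "vertical_candidate"
    else:
        kind = "supercritical" if l1 < 0 else "subcritical"
    return FocalValue(float(l1), omega, kind, tuple(x), tuple(sys.kappa))


def find_hopf_kappa(
    net: Network,
    free_index: int = 0,
    fixed: float = 1.0,
    log_range: tuple[float, float] = (-6.0, 6.0),
    grid: int = 200,
) -> tuple[float, ...] | None:
    """Rate constants at which tr J = 0 for a planar (2, 3, 2) network.

    Varies one rate constant (the others fixed) and locates a sign change
    of the trace at the unique positive equilibrium by bisection to ~1e-12.
    """
    from scipy.optimize import brentq

    def trace_at(log_k: float) -> float:
        kappa = [fixed] * net.m
        kappa[free_index] = float(np.exp(log_k))
        sys = MassActionSystem(net, tuple(kappa))
        return planar_det_tr(sys).trace

    logs = np.linspace(*log_range, grid)
    vals = [trace_at(v) for v in logs]
    for a, b, fa, fb in zip(logs[:-1], logs[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            root = float(a)
        elif fa * fb < 0:
            root = float(brentq(trace_at, a, b, xtol=1e-13))
        else:
            continue
        kappa = [fixed] * net.m
        kappa[free_index] = float(np.exp(root))
        return tuple(kappa)
    return None


def hopf_side_check(
    net: Network,
    critical_kappa,
    free_index: int,
    rel_offsets=(0.05, 0.1),
    n_returns: int = 400,
    rtol: float = 1e-9,
) -> dict:
    """Numerical corroboration of a supercritical Hopf bifurcation.

    On the unstable side of the critical parameter the return map of the
    flow, started near the equilibrium, converges to a finite radius (the
    limit cycle); the limiting amplitudes must shrink as the parameter
    approaches the critical value.  Returns the amplitude per offset.
    """
    amplitudes = {}
    for off in rel_offsets:
        kappa = list(critical_kappa)
        kappa[free_index] *= 1.0 + off
        sys = MassActionSystem(net, tuple(kappa))
        eq = positive_equilibria(sys).point_at()
        ps = planar_det_tr(sys, eq.x)
        if ps.trace < 0:  # wrong side; try the other one
            kappa[free_index] = critical_kappa[free_index] / (1.0 + off)
            sys = MassActionSystem(net, tuple(kappa))
            eq = positive_equilibria(sys).point_at()
        amplitudes[off] = _limit_cycle_amplitude(
            sys, np.asarray(eq.x), n_returns=n_returns, rtol=rtol
        )
    return amplitudes


def _limit_cycle_amplitude(
    sys: MassActionSystem,
    x_eq: np.ndarray,
    n_returns: int,
    rtol: float,
    t_max: float = 4000.0,
) -> float | None:
    """Limiting return-map radius around an unstable planar focus, or None.

    Uses a Poincare section on the ray from the equilibrium through the
    initial point: successive same-direction crossings of the line through
    the equilibrium pick out one side automatically, and their distances to
    the equilibrium converge to the limit-cycle amplitude.
    """
    from scipy.integrate import solve_ivp

    x0 = x_eq * (1.0 + 1e-3)
    ray = (x0 - x_eq) / np.linalg.norm(x0 - x_eq)
    perp = np.array([-ray[1], ray[0]])

    def section(_t, x):
        return float(perp @ (x - x_eq))

    # the crossing direction on the ray side is set by the rotation sense
    section.direction = float(np.sign(perp @ sys.rhs(x0)) or 1.0)
    section.terminal = False

    res = solve_ivp(
        lambda _t, x: sys.rhs(x),
        (0.0, t_max),
        x0,
        method="DOP853",
        rtol=rtol,
        atol=1e-12,
        events=[section],
    )
    if not len(res.t_events[0]):
        return None
    radii = [
        float(np.linalg.norm(xe - x_eq))
        for te, xe in zip(res.t_events[0], res.y_events[0])
        if te > 1e-6 and float(ray @ (xe - x_eq)) > 0
    ][: n_returns]
    if len(radii) < 10:
        return None
    tail = radii[-5:]
    if max(tail) - min(tail) > 1e-3 * tail[-1]:
        return None  # not converged to a cycle
    return tail[-1]
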