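"""Constrained optimisation internals for the joint diet/calibration fit.

The objective

    Q(pi, c) = sum_j || clr(pi_j @ T(c)) - clr(y_j) ||^2,
    T(c)[i] = closure(c * xbar[i]),

is a nonlinear least-squares function of the diet matrix ``pi`` (rows on
the simplex) and the calibration coefficients ``c`` (bounded below,
fixed sum).  Two stages are used:

1. a block-coordinate stage — each predator's diet given the
   coefficients, then the coefficients given all diets, both solved
   with SLSQP and analytic gradients;
2. an active-set Levenberg–Marquardt polish with analytic Jacobians.

The Jacobian is block-angular: residuals of predator ``j`` depend only
on ``pi_j`` and on ``c``, so the damped Gauss–Newton normal equations
are solved by eliminating each diet block and forming a Schur
complement on the coefficient block (size < K).  Equality constraints
(unit row sums, fixed coefficient sum) are removed exactly by an
orthonormal zero-sum basis (Helmert), and bound constraints by fixing
variables at their bounds with a Lagrange-multiplier release test.
Near a zero-residual solution the Gauss–Newton steps converge
quadratically, which is what drives ``Q`` down to the order of squared
machine rounding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, helmert
from scipy.optimize import minimize

_HELMERT_CACHE: dict[int, np.ndarray | None] = {}


def _zero_sum_basis(n: int) -> np.ndarray | None:
    """Orthonormal basis (n x (n-1)) of the zero-sum subspace of R^n."""
    if n <= 1:
        return None
    N = _HELMERT_CACHE.get(n)
    if N is None:
        N = helmert(n).T
        _HELMERT_CACHE[n] = N
    return N


def transformed_means(xbar: np.ndarray, c: np.ndarray):
    """Prey means mapped to predator space; also returns row scales s_i."""
    u = xbar * c
    s = u.sum(axis=1)
    return u / s[:, None], s


def residuals(pi: np.ndarray, c: np.ndarray, xbar: np.ndarray, z: np.ndarray):
    """clr residual matrix r (J x K) plus intermediates (yhat, T, s).

    ``z`` holds the clr-transformed observed predator signatures.  The
    residual is invariant to rescaling rows of ``pi`` or the vector
    ``c``, which is why exact renormalisation at the end of a fit does
    not change Q.
    """
    T, s = transformed_means(xbar, c)
    yhat = pi @ T
    logy = np.log(yhat)
    r = logy - logy.mean(axis=1, keepdims=True) - z
    return r, yhat, T, s


def q_value(pi, c, xbar, z) -> float:
    r = residuals(pi, c, xbar, z)[0]
    return float((r * r).sum())


def gradients(pi, c, xbar, z):
    """Analytic gradients of Q w.r.t. pi (J x I) and c (K)."""
    r, yhat, T, s = residuals(pi, c, xbar, z)
    rho = r / yhat
    m = rho @ T.T                     # J x I
    gpi = 2.0 * m
    w = pi / s                        # J x I
    a = w @ xbar                      # J x K
    gc = 2.0 * ((a * rho).sum(axis=0) - xbar.T @ (w * m).sum(axis=0))
    return gpi, gc, r, yhat, T, s


# ---------------------------------------------------------------------------
# SLSQP sub-problems (block-coordinate stage)
# ---------------------------------------------------------------------------

def fit_diet_slsqp(z_j, T, x0, maxiter: int = 200, ftol: float = 1e-14):
    """One predator's diet given fixed transformed means (classical QFASA)."""
    I = T.shape[0]

    def fun(p):
        yhat = np.maximum(p @ T, 1e-300)
        logy = np.log(yhat)
        r = logy - logy.mean() - z_j
        return float(r @ r), 2.0 * (T @ (r / yhat))

    res = minimize(
        fun,
        x0,
        jac=True,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * I,
        constraints=[{
            "type": "eq",
            "fun": lambda p: p.sum() - 1.0,
            "jac": lambda p: np.ones(I),
        }],
        options={"maxiter": maxiter, "ftol": ftol},
    )
    p = np.clip(res.x, 0.0, None)
    total = p.sum()
    if total <= 0.0:
        p = np.full(I, 1.0 / I)
    else:
        p = p / total
    return p, res


def fit_cc_slsqp(c0, pi, xbar, z, lb, csum, maxiter: int = 200, ftol: float = 1e-14):
    """Calibration coefficients given fixed diets."""
    K = xbar.shape[1]

    def fun(c):
        c = np.maximum(c, 1e-12)
        gpi, gc, r, yhat, T, s = gradients(pi, c, xbar, z)
        return float((r * r).sum()), gc

    res = minimize(
        fun,
        c0,
        jac=True,
        method="SLSQP",
        bounds=[(lb, None)] * K,
        constraints=[{
            "type": "eq",
            "fun": lambda c: c.sum() - csum,
            "jac": lambda c: np.ones(K),
        }],
        options={"maxiter": maxiter, "ftol": ftol},
    )
    c = np.maximum(res.x, lb)
    return c * (csum / c.sum()), res


# ---------------------------------------------------------------------------
# Active-set Levenberg–Marquardt polish
# ---------------------------------------------------------------------------

@dataclass
class PolishResult:
    pi: np.ndarray
    c: np.ndarray
    objective: float
    n_iterations: int
    status: str                      # "converged" | "stalled" | "maxiter"
    kkt_residual: float


def _release_fixed(values, free, grad, axis_groups):
    """Release bound-fixed variables whose KKT multiplier is negative.

    ``axis_groups`` yields (free_mask_row, grad_row) pairs sharing one
    equality constraint; the multiplier of the sum constraint is
    estimated as the mean gradient over free components.
    """
    for fmask, grow in axis_groups:
        if fmask.all() or not fmask.any():
            continue
        mu = grow[fmask].mean()
        kappa = 1e-9 * (1.0 + np.abs(grow).max())
        fixed_idx = np.where(~fmask)[0]
        release = grow[fixed_idx] - mu < -kappa
        fmask[fixed_idx[release]] = True


def kkt_residual(pi, c, xbar, z, lb, c_fixed: bool) -> float:
    """Infinity-norm of the projected KKT residual at (pi, c)."""
    gpi, gc = gradients(pi, c, xbar, z)[:2]
    worst = 0.0
    for j in range(pi.shape[0]):
        free = pi[j] > 0.0
        if free.any():
            mu = gpi[j, free].mean()
            worst = max(worst, float(np.abs(gpi[j, free] - mu).max()))
            if not free.all():
                viol = mu - gpi[j, ~free]       # fixed vars need g >= mu
                worst = max(worst, float(np.clip(viol, 0.0, None).max()))
    if not c_fixed:
        free = c > lb + 1e-12
        if free.any():
            nu = gc[free].mean()
            worst = max(worst, float(np.abs(gc[free] - nu).max()))
            if not free.all():
                viol = nu - gc[~free]
                worst = max(worst, float(np.clip(viol, 0.0, None).max()))
    return worst



def lm_polish(
    pi,
    c,
    xbar,
    z,
    lb: float = 0.02,
    csum: float | None = None,
    c_fixed: bool = False,
    q_tol: float = 1e-26,
    max_iter: int = 300,
    lam0: float = 1e-10,
    trace: bool = False,
) -> PolishResult:
    """Drive Q towards zero with damped, structured Gauss–Newton steps.

    Trial points are *projected*: diet entries are clipped at zero and
    each row renormalised, coefficients clipped at their lower bound.
    Both projections are cost-free because Q is invariant to the scale
    of every diet row and of the coefficient vector — the equality
    constraints only pin down a normalisation, they do not shape the
    objective.  The Helmert reduction removes those same scale
    directions from the Gauss–Newton system so the damped normal
    equations stay well posed.
    """
    pi = np.array(pi, dtype=float)
    c = np.array(c, dtype=float)
    J, I = pi.shape
    K = xbar.shape[1]
    if csum is None:
        csum = float(K)

    lam = lam0
    status = "maxiter"
    it = 0
    stall = 0
    Q = q_value(pi, c, xbar, z)
    while it < max_iter:
        it += 1
        if Q < q_tol:
            status = "converged"
            break
        gpi, gc, r, yhat, T, s = gradients(pi, c, xbar, z)

        # -- active sets with multiplier release ---------------------------
        free_pi = pi > 0.0
        _release_fixed(pi, free_pi, gpi, ((free_pi[j], gpi[j]) for j in range(J)))
        if c_fixed:
            free_c = np.zeros(K, dtype=bool)
        else:
            free_c = c > lb
            _release_fixed(c, free_c, gc, ((free_c, gc),))

        w_all = pi / s                      # J x I
        a_all = w_all @ xbar                # J x K

        # -- reduced Jacobian blocks ---------------------------------------
        diet_blocks = []                    # (idx, Ared) per predator
        for j in range(J):
            idx = np.flatnonzero(free_pi[j])
            Nj = _zero_sum_basis(idx.size)
            if Nj is None:
                diet_blocks.append((idx, None))
                continue
            Aj = (T[idx] / yhat[j]).T       # K x f_j
            Aj = Aj - Aj.mean(axis=0)
            diet_blocks.append((idx, Aj @ Nj))
        cidx = np.flatnonzero(free_c)
        Nc = _zero_sum_basis(cidx.size)
        B_blocks = None
        if Nc is not None:
            B_blocks = []
            for j in range(J):
                G = np.diag(a_all[j]) - T.T @ (w_all[j][:, None] * xbar)
                B = G / yhat[j][:, None]
                B = B - B.mean(axis=0)
                B_blocks.append(B[:, cidx] @ Nc)

        # damping scale from block diagonals
        dscale = 0.0
        nblocks = 0
        for (idx, Ared) in diet_blocks:
            if Ared is not None:
                dscale += (Ared * Ared).sum() / Ared.shape[1]
                nblocks += 1
        if B_blocks is not None:
            for B in B_blocks:
                dscale += (B * B).sum() / B.shape[1]
                nblocks += 1
        dscale = dscale / max(nblocks, 1) + 1e-300

        def solve_step(lam_eff):
            """Damped block-angular normal equations via Schur complement."""
            nv = Nc.shape[1] if Nc is not None else 0
            S = lam_eff * np.eye(nv) if nv else None
            hv = np.zeros(nv) if nv else None
            partial = []
            for j, (idx, Ared) in enumerate(diet_blocks):
                Bj = B_blocks[j] if B_blocks is not None else None
                if Bj is not None:
                    S += Bj.T @ Bj
                    hv += Bj.T @ r[j]
                if Ared is None:
                    partial.append(None)
                    continue
                M = Ared.T @ Ared + lam_eff * np.eye(Ared.shape[1])
                g = Ared.T @ r[j]
                try:
                    cf = cho_factor(M)
                except np.linalg.LinAlgError:
                    return None
                if Bj is not None:
                    C = Ared.T @ Bj
                    MC = cho_solve(cf, C)
                    S -= C.T @ MC
                    hv -= MC.T @ g
                    partial.append((cf, g, C))
                else:
                    partial.append((cf, g, None))
            if nv:
                try:
                    v = np.linalg.solve(S, -hv)
                except np.linalg.LinAlgError:
                    return None
            else:
                v = np.zeros(0)
            dpi = np.zeros_like(pi)
            for j, (idx, Ared) in enumerate(diet_blocks):
                part = partial[j]
                if part is None:
                    continue
                cf, g, C = part
                rhs = g + (C @ v if C is not None else 0.0)
                u = cho_solve(cf, -rhs)
                dpi[j, idx] = _zero_sum_basis(idx.size) @ u
            dc = np.zeros(K)
            if nv:
                dc[cidx] = Nc @ v
            return dpi, dc

        # -- damped trial steps with projection ----------------------------
        accepted = False
        for _ in range(60):
            step = solve_step(lam * dscale)
            if step is None:
                lam = max(lam, 1e-12) * 10.0
                continue
            dpi, dc = step
            pi_t = np.clip(pi + dpi, 0.0, None)
            rowsum = pi_t.sum(axis=1)
            if np.any(rowsum < 0.1):        # wild step: damp harder
                lam = max(lam, 1e-12) * 10.0
                continue
            pi_t = pi_t / rowsum[:, None]
            c_t = c if c_fixed else np.clip(c + dc, lb, None)
            Q_t = q_value(pi_t, c_t, xbar, z)
            if Q_t < Q:
                rel = (Q - Q_t) / Q
                pi, c, Q = pi_t, c_t, Q_t
                lam = max(lam * 0.25, 1e-14)
                stall = stall + 1 if rel < 1e-9 else 0
                accepted = True
                break
            lam = max(lam, 1e-12) * 10.0
            if lam > 1e12:
                break
        if trace:
            print(
                f"  lm it={it} Q={Q:.6e} lam={lam:.1e} "
                f"free_pi={int(free_pi.sum())} free_c={int(free_c.sum())} "
                f"accepted={accepted}"
            )
        if not accepted or stall >= 5:
            status = "stalled" if not accepted else "flat"
            break
    if Q < q_tol:
        status = "converged"

    # exact renormalisation: Q is invariant to row scales of pi and to the
    # overall scale of c, so this only restores the constraints.
    pi = pi / pi.sum(axis=1, keepdims=True)
    if not c_fixed:
        c = c * (csum / c.sum())
    Q = q_value(pi, c, xbar, z)
    kkt = kkt_residual(pi, c, xbar, z, lb, c_fixed)
    return PolishResult(pi, c, Q, it, status, kkt)
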