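"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: the control oracle
discretizes the dynamics exactly (piecewise-constant input, augmented-matrix
segment integrals) and solves the resulting ridge regression directly; the
Gramian oracle integrates the defining matrix integral by quadrature.
"""

import numpy as np
import scipy.linalg


def discretized_control_cost(a, b, c, x0, yf, rho, tf, n_steps):
    """Minimum of the soft-constrained cost over piecewise-constant inputs.

    The terminal output is linear in the input samples when the dynamics are
    propagated exactly segment by segment, so the minimizer is a ridge
    regression solved in closed form — an independent check on the
    Gramian-based continuous-time solution.
    """
    n = a.shape[0]
    n_inputs = b.shape[1]
    dt = tf / n_steps
    aug = np.zeros((2 * n, 2 * n))
    aug[:n, :n] = a * dt
    aug[:n, n:] = np.eye(n) * dt
    seg = scipy.linalg.expm(aug)[:n, n:]  # int_0^dt e^{A s} ds
    prop = scipy.linalg.expm(a * tf)
    step_back = scipy.linalg.expm(-a * dt)
    d0 = c @ prop @ x0
    m = np.zeros((c.shape[0], n_inputs * n_steps))
    cur = prop @ step_back  # e^{A (tf - t_0 - dt)}
    for k in range(n_steps):
        m[:, n_inputs * k : n_inputs * (k + 1)] = c @ (cur @ seg @ b)
        cur = cur @ step_back
    h = m.T @ m + rho * dt * np.eye(n_inputs * n_steps)
    u = np.linalg.solve(h, m.T @ (yf - d0))
    resid = yf - d0 - m @ u
    return float(resid @ resid + rho * dt * (u @ u))


def gramian_quadrature(a, b, t_end, n_points=4000):
    """Composite-Simpson quadrature of ``int_0^T e^{At} BB^T e^{A^T t} dt``."""
    if n_points % 2:
        n_points += 1
    ts = np.linspace(0.0, t_end, n_points + 1)
    dt = ts[1] - ts[0]
    step = scipy.linalg.expm(a * dt)
    w = np.zeros((a.shape[0], a.shape[0]))
    e = np.eye(a.shape[0])
    for k in range(n_points + 1):
        integrand = (e @ b) @ (e @ b).T
        if k in (0, n_points):
            weight = 1.0
        else:
            weight = 4.0 if k % 2 else 2.0
        w += weight * integrand
        e = step @ e
    return w * dt / 3.0


def pearson_by_hand(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym)))
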