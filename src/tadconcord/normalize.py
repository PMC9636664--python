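"""Contact-matrix balancing.

Hi-C counts carry multiplicative per-bin biases (mappability, GC content,
restriction-site density). Balancing divides them out by rescaling toward
equal row/column marginals. Five standard methods are provided:

``VC``
    Vanilla coverage: divide by the product of row marginals, then rescale
    so the total sum matches the input.
``SQRT_VC``
    Vanilla coverage with the square root of the marginal product; a milder
    correction.
``KR``
    Knight-Ruiz: find a diagonal scaling ``d`` so that ``diag(d) M diag(d)``
    is doubly stochastic (all unmasked row sums 1).
``ICE``
    Iterative correction: repeatedly divide by row marginals until they are
    uniform; the result is rescaled to unit mean over unmasked entries.
``SCN``
    Sequential component normalization: alternate row/column L2
    normalization, then symmetrize.

Bins with zero marginal sum are removed before balancing and restored as
zero rows/columns afterwards; every method would otherwise divide by zero
on them.
"""

from __future__ import annotations

import numpy as np

from .contact import ContactMatrix

__all__ = ["normalize", "ConvergenceError", "METHODS"]

METHODS = ("VC", "SQRT_VC", "KR", "ICE", "SCN")

DEFAULT_TOL = 1e-5
DEFAULT_MAX_ITER = {"ICE": 200, "SCN": 200, "KR": 3000}


class ConvergenceError(RuntimeError):
    """Balancing failed to reach tolerance within the iteration budget."""

    def __init__(self, method: str, residual: float, max_iter: int) -> None:
        self.method = method
        self.residual = residual
        self.max_iter = max_iter
        super().__init__(
            f"{method} did not converge in {max_iter} iterations "
            f"(final residual {residual:.3g})"
        )


def normalize(
    matrix: ContactMatrix,
    method: str,
    max_iter: int | None = None,
    tol: float = DEFAULT_TOL,
) -> ContactMatrix:
    """Balance a contact matrix with one of the five standard methods.

    Parameters
    ----------
    matrix
        Input matrix; its masked (all-zero) bins are excluded from
        balancing and restored as zeros in the output.
    method
        One of ``VC``, ``SQRT_VC``, ``KR``, ``ICE``, ``SCN``
        (case-insensitive).
    max_iter
        Iteration budget for the iterative methods; defaults to 200 for
        ICE/SCN and 3000 for KR. Ignored by VC/SQRT_VC.
    tol
        Convergence tolerance on the marginal uniformity (KR/ICE) or the
        iterate change (SCN).

    Raises
    ------
    ConvergenceError
        If the iteration budget is exhausted before reaching ``tol``.
    ValueError
        On an unknown method or an all-zero matrix.
    """
    method = method.upper().replace("-", "_")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    keep = matrix.unmasked()
    if keep.size == 0:
        raise ValueError("all-zero matrix cannot be balanced")
    sub = matrix.values[np.ix_(keep, keep)]
    if max_iter is None:
        max_iter = DEFAULT_MAX_ITER.get(method, 0)

    if method == "VC":
        out_sub = _vc(sub, sqrt=False)
    elif method == "SQRT_VC":
        out_sub = _vc(sub, sqrt=True)
    elif method == "KR":
        d = _kr_scaling(sub, tol=tol, max_iter=max_iter)
        out_sub = sub * np.outer(d, d)
    elif method == "ICE":
        out_sub = _ice(sub, tol=tol, max_iter=max_iter)
    else:  # SCN
        out_sub = _scn(sub, tol=tol, max_iter=max_iter)

    out = np.zeros_like(matrix.values)
    out[np.ix_(keep, keep)] = out_sub
    out = 0.5 * (out + out.T)  # remove floating-point asymmetry
    return ContactMatrix(out, matrix.binning)


def _vc(m: np.ndarray, sqrt: bool) -> np.ndarray:
    r = m.sum(axis=1)
    denom = np.outer(r, r)
    if sqrt:
        denom = np.sqrt(denom)
    out = m / denom
    total = out.sum()
    if total == 0:
        raise ValueError("all-zero matrix cannot be balanced")
    return out * (m.sum() / total)


def _ice(m: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    w = m.astype(float).copy()
    residual = np.inf
    for _ in range(max_iter):
        s = w.sum(axis=1)
        s = s / s.mean()
        residual = np.abs(s - 1).max()
        if residual < tol:
            return w / w.mean()  # unit mean over unmasked entries
        w /= np.outer(s, s)
    raise ConvergenceError("ICE", float(residual), max_iter)


def _kr_scaling(a: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Knight-Ruiz inner-outer iteration for the balancing vector.

    Finds x > 0 with diag(x) A diag(x) doubly stochastic, via an inexact
    Newton method with CG inner iterations (Knight & Ruiz 2013).
    """
    n = a.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    stop_tol = tol * 0.5

    v = x * (a @ x)
    rk = 1 - v
    rho_km1 = rk @ rk
    rout = rold = rho_km1
    i = 0  # outer iterations
    total_inner = 0

    while np.sqrt(rout) > stop_tol:
        i += 1
        if i > max_iter:
            raise ConvergenceError("KR", float(np.sqrt(rout)), max_iter)
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, stop_tol**2)
        while rho_km1 > innertol:  # inner CG
            k += 1
            total_inner += 1
            if total_inner > max_iter * 50:
                raise ConvergenceError("KR", float(np.sqrt(rout)), max_iter)
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (a @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y += gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y += gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
        x = x * y
        v = x * (a @ x)
        rk = 1 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta = g * rat
        if g * eta**2 > 0.1:
            eta = max(eta, g * eta**2)
        eta = max(min(eta, etamax), stop_tol / (2 * res_norm) if res_norm > 0 else etamax)
    return x


def _scn(m: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    w = m.astype(float).copy()
    residual = np.inf
    for _ in range(max_iter):
        col_norm = np.linalg.norm(w, axis=0)
        col_norm[col_norm == 0] = 1.0
        w = w / col_norm
        row_norm = np.linalg.norm(w, axis=1)
        row_norm[row_norm == 0] = 1.0
        w = w / row_norm[:, None]
        residual = np.abs(w - w.T).max()
        if residual < tol:
            return 0.5 * (w + w.T)
    raise ConvergenceError("SCN", float(residual), max_iter)
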