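"""Brute-force definitional oracles, independent of the package's fast paths.

The CCA oracle solves the generalized eigenproblem of the canonical
correlation definition assembled directly from XX', YY' and XY'; the MSI
oracle builds the joint correlation matrix, the block inverse-square-root
transform and the eigenvalue entropy step by step with generic dense
linear algebra (``fractional_matrix_power``), never sharing code with the
implementations under test.
"""

import numpy as np
import scipy.linalg


def _center_rows(a):
    return a - a.mean(axis=1, keepdims=True)


def cca_oracle(x, y):
    """Maximal canonical correlation via the generalized eigenproblem.

    max_w rho subject to  [[0, Cxy], [Cyx, 0]] w = rho [[Cxx, 0], [0, Cyy]] w.
    """
    x = _center_rows(np.atleast_2d(np.asarray(x, float)))
    y = _center_rows(np.atleast_2d(np.asarray(y, float)))
    m = x.shape[1]
    cxx = x @ x.T / m
    cyy = y @ y.T / m
    cxy = x @ y.T / m
    n, p = cxx.shape[0], cyy.shape[0]
    a = np.zeros((n + p, n + p))
    a[:n, n:] = cxy
    a[n:, :n] = cxy.T
    b = np.zeros((n + p, n + p))
    b[:n, :n] = cxx
    b[n:, n:] = cyy
    eigvals = scipy.linalg.eigh(a, b, eigvals_only=True)
    return float(eigvals[-1])


def msi_oracle(x, y):
    """Synchronization index assembled element by element from definitions."""
    x = _center_rows(np.atleast_2d(np.asarray(x, float)))
    y = _center_rows(np.atleast_2d(np.asarray(y, float)))
    m = x.shape[1]
    n, q = x.shape[0], y.shape[0]
    p = n + q
    c = np.empty((p, p))
    c[:n, :n] = x @ x.T / m
    c[n:, n:] = y @ y.T / m
    c[:n, n:] = x @ y.T / m
    c[n:, :n] = c[:n, n:].T
    u = np.zeros((p, p))
    u[:n, :n] = np.real(scipy.linalg.fractional_matrix_power(c[:n, :n], -0.5))
    u[n:, n:] = np.real(scipy.linalg.fractional_matrix_power(c[n:, n:], -0.5))
    r = u @ c @ u.T
    lam = np.real(np.linalg.eigvals(r))
    lam = np.clip(lam, 0.0, None)
    lam = lam / lam.sum()
    entropy = sum(v * np.log(v) for v in lam if v > 0)
    return float(1.0 + entropy / np.log(p))
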