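"""Orthonormal polynomial basis with exact analytic first derivatives.

The waveform is represented as ``B @ b`` where the columns of ``B`` are
polynomials of increasing exact degree, orthonormal with respect to the
discrete inner product over the sample grid. A latency shift is modeled
through the matrix ``D`` holding the exact analytic derivative (per ms) of
each basis polynomial; ``D`` is never obtained by finite differences.

The polynomials are built by a Stieltjes three-term recurrence on a time
variable rescaled to [-1, 1] (raw monomials over hundreds of samples are
numerically singular), with full re-orthogonalization of each new column so
that orthonormality holds to near machine precision at high degree. The
derivative columns are propagated through the same recurrence and carry the
``2 / (t_max - t_min)`` chain-rule factor, so D is in units of B per ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from swale.errors import InvalidInputError

__all__ = ["BasisSet", "make_polynomial_basis"]


@dataclass(frozen=True)
class BasisSet:
    """Orthonormal polynomial basis B and its analytic derivative D.

    Attributes
    ----------
    time_axis : (T,) ndarray
        Sample times in ms, strictly increasing.
    B : (T, q) ndarray
        Basis values; ``B.T @ B`` is the identity.
    D : (T, q) ndarray
        First derivatives of the same polynomials with respect to time
        (units of B per ms). Column 0 is identically zero.
    """

    time_axis: np.ndarray
    B: np.ndarray
    D: np.ndarray
    basis_id: str = field(default="orthonormal-polynomial")

    @property
    def n_samples(self) -> int:
        return self.B.shape[0]

    @property
    def n_basis(self) -> int:
        return self.B.shape[1]

    def to_text(self, path, which: str = "B") -> None:
        """Export B or D as delimited text for inspection."""
        mat = {"B": self.B, "D": self.D}[which]
        np.savetxt(path, mat, delimiter=",")


def make_polynomial_basis(
    n_samples: int, n_basis: int, time_axis: np.ndarray | None = None
) -> BasisSet:
    """Construct an orthonormal polynomial basis on a sample grid.

    Parameters
    ----------
    n_samples : int
        Number of time samples T.
    n_basis : int
        Number of basis functions q (polynomial degrees 0..q-1); q <= T.
    time_axis : array-like of shape (T,), optional
        Sample times in ms, strictly increasing. Defaults to 0..T-1.

    Returns
    -------
    BasisSet

    Raises
    ------
    InvalidInputError
        If q > T, q < 1, or the time axis is not strictly increasing.
    """
    if n_basis < 1:
        raise InvalidInputError(f"n_basis must be >= 1, got {n_basis}")
    if n_basis > n_samples:
        raise InvalidInputError(
            f"n_basis ({n_basis}) may not exceed n_samples ({n_samples})"
        )
    if time_axis is None:
        time_axis = np.arange(n_samples, dtype=float)
    t = np.asarray(time_axis, dtype=float)
    if t.ndim != 1 or t.size != n_samples:
        raise InvalidInputError(
            f"time_axis must be a length-{n_samples} vector, got shape {t.shape}"
        )
    if n_samples > 1 and np.any(np.diff(t) <= 0):
        raise InvalidInputError("time_axis must be strictly increasing (no duplicates)")

    # Rescale to x in [-1, 1]; dx/dt carries into the derivative columns.
    if n_samples == 1:
        x = np.zeros(1)
        dxdt = 0.0
    else:
        span = t[-1] - t[0]
        x = 2.0 * (t - t[0]) / span - 1.0
        dxdt = 2.0 / span

    T, q = n_samples, n_basis
    B = np.empty((T, q))
    Dx = np.empty((T, q))  # derivatives with respect to x

    # Stieltjes recurrence with re-orthogonalization against all previous
    # columns; the same corrections are applied to the derivative columns so
    # D stays the exact derivative of the (corrected) polynomial in B.
    nrm = np.sqrt(float(T))
    B[:, 0] = 1.0 / nrm
    Dx[:, 0] = 0.0
    for j in range(1, q):
        p = x * B[:, j - 1]
        dp = B[:, j - 1] + x * Dx[:, j - 1]
        for _ in range(2):  # twice is enough (Kahan/Parlett)
            c = B[:, :j].T @ p
            p = p - B[:, :j] @ c
            dp = dp - Dx[:, :j] @ c
        nrm = np.linalg.norm(p)
        if nrm < 1e-13:
            raise InvalidInputError(
                "degenerate sample grid: cannot build polynomial of degree "
                f"{j} on {T} distinct points"
            )
        B[:, j] = p / nrm
        Dx[:, j] = dp / nrm

    D = Dx * dxdt
    D[:, 0] = 0.0
    return BasisSet(time_axis=t, B=B, D=D, basis_id=f"orthopoly(q={q},T={T})")
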