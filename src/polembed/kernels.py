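"""Screened Coulomb interaction kernels for fluctuating charges and dipoles.

Two families are implemented:

* **Ohno** — charge-charge only, used by the FQ model.  Interpolates smoothly
  between the mean atomic hardness at contact and bare 1/r at long range::

      T(r) = η̄ / sqrt(1 + η̄² r²),   η̄ = (η_i + η_j)/2

* **Gaussian (erf-screened)** — used by the FQFμ model.  Charges and dipoles
  are treated as spherical Gaussian distributions; interaction of two sites
  with widths R_i, R_j is the erf-screened Coulomb kernel with combined width
  R̄ = sqrt(R_i² + R_j²)::

      T^qq(r)  = erf(r/R̄)/r
      T^qμ(r)  = −∇ T^qq        (3-vector)
      T^μμ(r)  = −∇∇ T^qq       (3×3)

All arguments and results in atomic units.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

from .system import GeometryError, ParameterError

_TWO_OVER_SQRT_PI = 2.0 / np.sqrt(np.pi)


def ohno_kernel(r: float, eta_i: float, eta_j: float) -> float:
    """Ohno charge-charge kernel.

    Equals η̄ at r=0 (charge self-interaction governed by hardness) and
    decays to 1/r at large separation.
    """
    if eta_i <= 0 or eta_j <= 0:
        raise ParameterError("hardnesses must be positive")
    eta = 0.5 * (eta_i + eta_j)
    return eta / np.sqrt(1.0 + eta * eta * np.asarray(r, dtype=float) ** 2)


def _erf_t_and_derivs(r: float, rbar: float) -> tuple[float, float, float]:
    """t(r)=erf(r/R̄)/r and its first two radial derivatives."""
    u = r / rbar
    g = _TWO_OVER_SQRT_PI * np.exp(-u * u) / rbar  # d erf(r/R̄)/dr
    e = erf(u)
    t = e / r
    t1 = g / r - e / r**2
    t2 = -2.0 * u / rbar * g / r - 2.0 * g / r**2 + 2.0 * e / r**3
    return t, t1, t2


def gaussian_kernels(r_vec: np.ndarray, R_i: float, R_j: float):
    """erf-screened kernels between two Gaussian sites.

    Returns ``(T_qq, T_qmu, T_mumu)`` where ``T_qmu = -∇T_qq`` (3-vector)
    and ``T_mumu = -∇∇T_qq`` (3×3 matrix), gradients with respect to
    ``r_vec = r_i - r_j``.
    """
    if R_i <= 0 or R_j <= 0:
        raise ParameterError("Gaussian widths must be positive")
    r_vec = np.asarray(r_vec, dtype=float)
    r = float(np.linalg.norm(r_vec))
    if r == 0.0:
        raise GeometryError("coincident sites in gaussian_kernels")
    rbar = np.hypot(R_i, R_j)
    t, t1, t2 = _erf_t_and_derivs(r, rbar)
    rhat = r_vec / r
    t_qmu = -t1 * rhat
    # ∇∇t for a radial function: (t'' − t'/r) r̂r̂ᵀ + (t'/r) I
    t_mumu = -((t2 - t1 / r) * np.outer(rhat, rhat) + (t1 / r) * np.eye(3))
    return t, t_qmu, t_mumu


def erf_coulomb(r, width):
    """Damped Coulomb erf(r/width)/r, elementwise; → 1/r for r ≫ width."""
    r = np.asarray(r, dtype=float)
    out = np.empty_like(r)
    small = r < 1e-12
    out[~small] = erf(r[~small] / width) / r[~small]
    # r→0 limit of erf(r/w)/r
    out[small] = _TWO_OVER_SQRT_PI / width
    return out
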