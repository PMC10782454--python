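"""First-order ¹H spectrum synthesis from averaged shifts and couplings.

Averaged couplings with J ≥ 0.5 Hz (inclusive) are kept, converted to ppm at
the spectrometer field (Hz / MHz = ppm), used to build first-order multiplets
(each coupling to n equivalent partners splits a line into a binomial n+1
pattern at ±J/2 spacings), and convoluted with unit-area Lorentzians of
FWHM 0.002 ppm.  Each proton contributes unit integrated area, so multiplet
integrals are proportional to proton counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nmr import ConfigError, SpectrumTable


@dataclass
class SpectrumCurve:
    ppm: np.ndarray
    intensity: np.ndarray
    sticks: list  # (position ppm, weight) pairs actually convoluted


def lorentzian(x: np.ndarray, x0: float, fwhm: float) -> np.ndarray:
    """Unit-area Lorentzian; value at x0 ± FWHM/2 is half the peak value."""
    gamma = 0.5 * fwhm
    return (gamma / np.pi) / ((x - x0) ** 2 + gamma ** 2)


def filter_couplings(j_values, j_min_hz: float = 0.5):
    """Inclusive threshold on averaged couplings: keep J ≥ j_min."""
    return {k: j for k, j in dict(j_values).items() if abs(j) >= j_min_hz}


def first_order_multiplet(delta0: float,
                          splittings: list[tuple[float, int]]) -> list[tuple[float, float]]:
    """Stick pattern for one group: center shift + (J_ppm, n_partners) list.

    Each coupling to n equivalent spin-1/2 partners produces n+1 lines with
    binomial weights at spacings J about the center; weights sum to 1.
    """
    from math import comb

    sticks = [(delta0, 1.0)]
    for j_ppm, n in splittings:
        pattern = [(j_ppm * (k - n / 2.0), comb(n, k) / 2.0 ** n)
                   for k in range(n + 1)]
        sticks = [(pos + off, w * wt) for pos, w in sticks for off, wt in pattern]
    return sticks


def synthesize_spectrum(table: SpectrumTable,
                        field_mhz: float | None = None,
                        fwhm_ppm: float | None = None,
                        j_min_hz: float = 0.5,
                        ppm_grid: np.ndarray | None = None,
                        pad_ppm: float = 0.05,
                        points: int = 20000) -> SpectrumCurve:
    """Convolute the averaged table into a 1D spectrum curve.

    Couplings are read from ``table.group_j`` with pair labels resolved
    through ``table.groups.pairs``; a coupling named (A, B) splits group A by
    the proton count of B and vice versa.  The integrated spectrum equals the
    total number of contributing protons.
    """
    field = table.field_mhz if field_mhz is None else field_mhz
    fwhm = table.fwhm_ppm if fwhm_ppm is None else fwhm_ppm
    if fwhm <= 0:
        raise ConfigError("Lorentzian FWHM must be positive")
    if field <= 0:
        raise ConfigError("spectrometer field must be positive")

    kept = filter_couplings(table.group_j.to_dict(), j_min_hz)
    split_of: dict[str, list[tuple[float, int]]] = {g: [] for g in table.groups.groups}
    for label, j_hz in kept.items():
        if label not in table.groups.pairs:
            continue
        a, b = table.groups.pairs[label]
        j_ppm = j_hz / field
        split_of[a].append((j_ppm, table.groups.proton_count(b)))
        split_of[b].append((j_ppm, table.groups.proton_count(a)))

    sticks: list[tuple[float, float]] = []
    for label, delta0 in table.group_delta.items():
        n_protons = table.groups.proton_count(label)
        for pos, w in first_order_multiplet(float(delta0), split_of.get(label, [])):
            sticks.append((pos, w * n_protons))

    if ppm_grid is None:
        lo = min(p for p, _ in sticks) - pad_ppm
        hi = max(p for p, _ in sticks) + pad_ppm
        ppm_grid = np.linspace(lo, hi, points)
    intensity = np.zeros_like(ppm_grid, dtype=float)
    for pos, w in sticks:
        intensity += w * lorentzian(ppm_grid, pos, fwhm)
    return SpectrumCurve(ppm=ppm_grid, intensity=intensity, sticks=sticks)
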