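"""NMR observable post-processing: referencing, coupling conversion,
ensemble averaging, and solvent-polarity correlation.

Chemical shifts follow the standard referencing rule δ = σ_ref − σ_iso with
TMS references σ_ref(¹H) = 31.7 and σ_ref(¹³C) = 182.852.  Scalar couplings
come from the isotropic reduced coupling K via

    J = h · (γ_α/2π) · (γ_β/2π) · K        [K in SI units, J in Hz]

Per-snapshot tables are averaged arithmetically over snapshots and then over
symmetry-equivalent nuclei; a running-mean trace is retained so convergence
with the number of snapshots can be inspected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .units import GYROMAGNETIC_RATIOS, PLANCK_H, SHIELDING_REFERENCES


class ConfigError(ValueError):
    """Missing reference value, isotope, or inconsistent configuration."""


def shielding_to_shift(sigma_iso, reference=None, nucleus: str | None = None):
    """δ (ppm) from isotropic shielding: δ = σ_ref − σ_iso.

    ``reference`` may be given directly, or looked up from the isotope label
    (e.g. "1H", "13C").  Vectorized over σ_iso.
    """
    if reference is None:
        if nucleus is None or nucleus not in SHIELDING_REFERENCES:
            raise ConfigError(f"no shielding reference for nucleus {nucleus!r}")
        reference = SHIELDING_REFERENCES[nucleus]
    return reference - np.asarray(sigma_iso, dtype=float) + 0.0 \
        if np.ndim(sigma_iso) else float(reference - sigma_iso)


def reduced_to_J(k_iso: float, isotope_a: str, isotope_b: str) -> float:
    """Scalar coupling J (Hz) from the isotropic reduced coupling K (SI).

    Symmetric in the two isotopes.  γ values: ¹H from CODATA, heteronuclei
    from standard NMR tables (see units.GYROMAGNETIC_RATIOS).
    """
    try:
        ga = GYROMAGNETIC_RATIOS[isotope_a]
        gb = GYROMAGNETIC_RATIOS[isotope_b]
    except KeyError as exc:
        raise ConfigError(f"unknown isotope: {exc.args[0]!r}") from None
    return PLANCK_H * (ga / (2.0 * np.pi)) * (gb / (2.0 * np.pi)) * k_iso


def kirkwood_function(epsilon: float, ndigits: int | None = 3) -> float:
    """Kirkwood–Bauer–Magat dielectric polarity index K(ε) = (ε−1)/(2ε+1).

    0 for vacuum (ε=1), → 1/2 in the conductor limit.  Rounded to three
    decimals by default for comparison with printed tables; pass
    ``ndigits=None`` for the raw value.
    """
    if epsilon < 1:
        raise ValueError(f"static permittivity must be >= 1, got {epsilon}")
    k = (epsilon - 1.0) / (2.0 * epsilon + 1.0)
    return round(k, ndigits) if ndigits is not None else k


@dataclass(frozen=True)
class SolventPolarity:
    """One solvent's polarity descriptors: ε, Reichardt E_T^N, K(ε), AN."""

    name: str
    epsilon: float
    e_t_n: float
    k_eps: float
    an: float

    def __post_init__(self):
        if abs(kirkwood_function(self.epsilon) - round(self.k_eps, 3)) > 5e-4:
            raise ValueError(
                f"{self.name}: K(ε)={self.k_eps} inconsistent with ε={self.epsilon}")

    def scales(self) -> dict[str, float]:
        return {"E_T^N": self.e_t_n, "K(eps)": self.k_eps, "AN": self.an}


@dataclass(frozen=True)
class EquivalenceGroups:
    """Named groups of symmetry-equivalent nuclei and named coupling pairs.

    ``groups`` maps a label (e.g. "methyl", "N-ortho") to nucleus indices;
    ``pairs`` maps a coupling label (e.g. "J_N") to two group labels.
    """

    groups: Mapping[str, tuple[int, ...]]
    pairs: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        seen: set[int] = set()
        for label, idx in self.groups.items():
            s = set(idx)
            if seen & s:
                raise ValueError(f"group {label!r} overlaps another group")
            seen |= s
        for label, (a, b) in self.pairs.items():
            if a not in self.groups or b not in self.groups:
                raise ValueError(f"pair {label!r} references undefined groups")

    def group_of(self, nucleus: int) -> str | None:
        for label, idx in self.groups.items():
            if nucleus in idx:
                return label
        return None

    def proton_count(self, label: str) -> int:
        return len(self.groups[label])


@dataclass
class SpectrumTable:
    """Averaged per-nucleus and per-group NMR observables.

    ``nucleus_sigma`` / ``nucleus_delta`` are ensemble means per nucleus;
    ``group_delta`` averages over equivalence groups; ``half_differences``
    reports (max−min)/2 of the averaged shifts inside each group (spread
    between nominally equivalent nuclei).  The J ≥ threshold filter is
    applied only to the *averaged* couplings, at spectrum synthesis.
    """

    nucleus_sigma: pd.Series
    nucleus_delta: pd.Series
    group_delta: pd.Series
    group_j: pd.Series
    group_k: pd.Series
    half_differences: pd.Series
    running_mean: pd.DataFrame
    groups: EquivalenceGroups
    n_snapshots: int
    field_mhz: float = 400.0
    fwhm_ppm: float = 0.002


def ensemble_average(shift_tables: Sequence[pd.Series],
                     groups: EquivalenceGroups,
                     coupling_tables: Sequence[Mapping] = (),
                     reference=None, nucleus: str = "1H",
                     values_are: str = "sigma",
                     coupling_values_are: str = "J",
                     isotope_of=None,
                     field_mhz: float = 400.0,
                     fwhm_ppm: float = 0.002) -> SpectrumTable:
    """Average per-snapshot NMR tables over snapshots, then over groups.

    ``shift_tables`` holds one pandas Series per snapshot (index: nucleus id,
    values: σ_iso or δ per ``values_are``); ``coupling_tables`` one mapping
    per snapshot from a coupling-pair label (or nucleus-index pair) to J in
    Hz — or to K in SI units with ``coupling_values_are="K"``, in which case
    ``isotope_of`` maps nucleus/pair labels to isotopes (default ¹H–¹H).

    Referencing is linear, so referencing before or after averaging gives
    identical shifts.
    """
    if len(shift_tables) == 0:
        raise ValueError("need at least one snapshot")
    index = shift_tables[0].index
    for t in shift_tables[1:]:
        if not t.index.equals(index):
            raise ValueError("inconsistent nucleus sets across snapshots")
    stacked = pd.concat(shift_tables, axis=1)
    nucleus_mean = stacked.mean(axis=1)

    if values_are == "sigma":
        nucleus_sigma = nucleus_mean
        nucleus_delta = pd.Series(
            shielding_to_shift(nucleus_mean.values, reference, nucleus),
            index=index)
    elif values_are == "delta":
        nucleus_delta = nucleus_mean
        ref = reference if reference is not None else SHIELDING_REFERENCES.get(nucleus)
        nucleus_sigma = (ref - nucleus_delta) if ref is not None \
            else pd.Series(np.nan, index=index)
    else:
        raise ConfigError(f"values_are must be 'sigma' or 'delta', got {values_are!r}")

    group_delta = {}
    half_diff = {}
    running = {}
    cum = stacked.cumsum(axis=1).div(np.arange(1, stacked.shape[1] + 1), axis=1)
    for label, idx in groups.groups.items():
        members = nucleus_delta.loc[list(idx)]
        group_delta[label] = float(members.mean())
        half_diff[label] = float((members.max() - members.min()) / 2.0)
        trace = cum.loc[list(idx)].mean(axis=0)
        if values_are == "sigma":
            ref = reference if reference is not None else SHIELDING_REFERENCES[nucleus]
            trace = ref - trace
        running[label] = trace.to_numpy()
    running_mean = pd.DataFrame(running)
    running_mean.index.name = "snapshot"

    group_j: dict[str, float] = {}
    group_k: dict[str, float] = {}
    if coupling_tables:
        keys = set(coupling_tables[0])
        for t in coupling_tables[1:]:
            if set(t) != keys:
                raise ValueError("inconsistent coupling sets across snapshots")
        for key in keys:
            vals = np.array([t[key] for t in coupling_tables], dtype=float)
            mean = float(vals.mean())
            label = key if isinstance(key, str) else str(key)
            if coupling_values_are == "K":
                iso_a = iso_b = "1H"
                if isotope_of is not None:
                    iso_a, iso_b = isotope_of(key)
                group_k[label] = mean
                group_j[label] = reduced_to_J(mean, iso_a, iso_b)
            else:
                group_j[label] = mean
                group_k[label] = np.nan

    return SpectrumTable(
        nucleus_sigma=nucleus_sigma, nucleus_delta=nucleus_delta,
        group_delta=pd.Series(group_delta, dtype=float),
        group_j=pd.Series(group_j, dtype=float),
        group_k=pd.Series(group_k, dtype=float),
        half_differences=pd.Series(half_diff, dtype=float),
        running_mean=running_mean, groups=groups,
        n_snapshots=len(shift_tables),
        field_mhz=field_mhz, fwhm_ppm=fwhm_ppm)


def polarity_correlation(shifts: pd.DataFrame,
                         scales: Sequence[SolventPolarity]) -> pd.DataFrame:
    """Least-squares correlation of shifts with solvent polarity indexes.

    ``shifts``: rows = proton groups, columns = solvent names (δ in ppm).
    Returns one row per (group, scale) with slope, intercept, R², p-value,
    and a ``degenerate`` flag when the abscissa has no variance.
    """
    if shifts.shape[1] < 3:
        raise ValueError("need at least three solvents for a correlation")
    by_name = {s.name: s for s in scales}
    missing = [c for c in shifts.columns if c not in by_name]
    if missing:
        raise ValueError(f"no polarity data for solvents: {missing}")
    rows = []
    scale_names = next(iter(by_name.values())).scales().keys()
    for scale in scale_names:
        x = np.array([by_name[c].scales()[scale] for c in shifts.columns])
        degenerate = bool(np.ptp(x) < 1e-12)
        for group, y in shifts.iterrows():
            yv = y.to_numpy(dtype=float)
            if degenerate:
                rows.append(dict(group=group, scale=scale, slope=np.nan,
                                 intercept=np.nan, r2=np.nan, pvalue=np.nan,
                                 degenerate=True))
                continue
            fit = stats.linregress(x, yv)
            rows.append(dict(group=group, scale=scale, slope=fit.slope,
                             intercept=fit.intercept, r2=fit.rvalue**2,
                             pvalue=fit.pvalue, degenerate=False))
    return pd.DataFrame(rows)
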