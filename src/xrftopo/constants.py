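"""Element-wise physical constants and the elemental mixture rule.

Every physical constant used anywhere in xrftopo (mass attenuation
coefficients mu_j, photoionization cross-sections tau_j, fluorescence
yields omega_j, transition probabilities p_ij, jump factors J_j, line
and edge energies) is served by this module from a frozen JSON table
shipped with the package.  Swapping the constants backend therefore
changes results in exactly one place; ``scripts/make_constants_tables.py``
regenerates the table.

Units: energies in eV, cross-sections in cm^2/g.  Tabulation covers
100-3000 eV; queries outside that range raise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "ElementRecord",
    "EmissionLine",
    "get_element",
    "element_symbols",
    "line_energy",
    "edge_energy",
    "mixture_mu",
    "mixture_tau_weighted",
    "yield_factor",
    "LookupError_",
]


class LookupError_(KeyError):
    """Unknown element symbol or emission-line label."""


@dataclass(frozen=True)
class EmissionLine:
    """One characteristic emission line of an element.

    ``jump_factor`` is the FP-literature jump factor (r-1)/r in (0,1),
    the fraction of photoionization events occurring in the shell that
    feeds this line; the raw absorption jump ratio r is kept alongside
    for transparency.
    """

    element: str
    label: str
    energy_eV: float
    fluorescence_yield: float
    transition_probability: float
    jump_factor: float
    jump_ratio: float

    def __post_init__(self):
        assert 0.0 < self.fluorescence_yield < 1.0
        assert 0.0 < self.transition_probability <= 1.0
        assert 0.0 < self.jump_factor < 1.0


class ElementRecord:
    """Tabulated constants for one element.

    mu(E) and tau(E) are evaluated by log-log interpolation of the
    frozen table, which carries points tightly bracketing the K edge so
    the absorption discontinuity is preserved.
    """

    def __init__(self, symbol: str, raw: dict):
        self.symbol = symbol
        self.Z = int(raw["Z"])
        self.atomic_mass = float(raw["atomic_mass"])
        self.k_edge_eV = raw.get("k_edge_eV")
        self._e = np.asarray(raw["energy_eV"], dtype=float)
        self._tau = np.asarray(raw["tau"], dtype=float)
        self._scatter = float(raw["scatter_mu"])
        self._log_e = np.log(self._e)
        self._log_tau = np.log(np.maximum(self._tau, 1e-300))
        self.lines: dict[str, EmissionLine] = {
            lab: EmissionLine(
                element=symbol,
                label=lab,
                energy_eV=rec["energy_eV"],
                fluorescence_yield=rec["fluorescence_yield"],
                transition_probability=rec["transition_probability"],
                jump_factor=rec["jump_factor"],
                jump_ratio=raw.get("jump_ratio", float("nan")),
            )
            for lab, rec in raw.get("lines", {}).items()
        }

    # -- cross sections -------------------------------------------------
    def _check_range(self, E):
        E = np.asarray(E, dtype=float)
        if np.any(E < self._e[0]) or np.any(E > self._e[-1]):
            raise ValueError(
                f"energy outside tabulated range "
                f"[{self._e[0]:g}, {self._e[-1]:g}] eV for {self.symbol}"
            )
        return E

    def tau(self, E):
        """Photoionization mass cross-section, cm^2/g."""
        E = self._check_range(E)
        return np.exp(np.interp(np.log(E), self._log_e, self._log_tau))

    def mu(self, E):
        """Total mass attenuation coefficient, cm^2/g (tau + scattering)."""
        return self.tau(E) + self._scatter

    def line(self, label: str) -> EmissionLine:
        try:
            return self.lines[label]
        except KeyError:
            raise LookupError_(
                f"element {self.symbol} has no tabulated line {label!r}"
            ) from None


def _load() -> dict[str, ElementRecord]:
    with resources.files("xrftopo.data").joinpath("constants.json").open() as fh:
        raw = json.load(fh)
    return {sym: ElementRecord(sym, rec) for sym, rec in raw["elements"].items()}


_TABLE: dict[str, ElementRecord] = _load()


def element_symbols() -> list[str]:
    return list(_TABLE)


def get_element(symbol: str) -> ElementRecord:
    try:
        return _TABLE[symbol]
    except KeyError:
        raise LookupError_(f"unknown element symbol {symbol!r}") from None


def line_energy(element: str, line: str = "K-alpha") -> float:
    """Tabulated emission-line energy in eV (e.g. C K-alpha -> 277)."""
    return get_element(element).line(line).energy_eV


def edge_energy(element: str) -> float | None:
    return get_element(element).k_edge_eV


def _check_fractions(mass_fractions: Mapping[str, float]) -> None:
    vals = np.asarray(list(mass_fractions.values()), dtype=float)
    if np.any(vals < 0):
        raise ValueError("mass fractions must be nonnegative")
    if abs(vals.sum() - 1.0) > 1e-9:
        raise ValueError(f"mass fractions sum to {vals.sum()!r}, expected 1")


def mixture_mu(mass_fractions: Mapping[str, float], E) -> float | np.ndarray:
    """Mixture-rule mass attenuation mu_s(E) = sum_j w_j mu_j(E), cm^2/g.

    ``mass_fractions`` must be nonnegative and sum to 1 within 1e-9.
    """
    _check_fractions(mass_fractions)
    out = sum(w * get_element(sym).mu(E) for sym, w in mass_fractions.items())
    return float(out) if np.isscalar(E) else out


def mixture_tau_weighted(mass_fractions: Mapping[str, float], element: str, E) -> float:
    """w_j tau_j(E) for one element of a mixture (the per-element
    photoionization share of the mixture absorption)."""
    _check_fractions(mass_fractions)
    w = mass_fractions.get(element, 0.0)
    return float(w * get_element(element).tau(E))


def yield_factor(line: EmissionLine, solid_angle_fraction: float) -> float:
    """Y_ij = (Omega/4pi) * omega_j * p_ij * J_j for one detector."""
    if not 0.0 <= solid_angle_fraction <= 1.0:
        raise ValueError("solid_angle_fraction must be in [0, 1]")
    return (
        solid_angle_fraction
        * line.fluorescence_yield
        * line.transition_probability
        * line.jump_factor
    )
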