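"""Solubility-derivative decompositions from Kirkwood-Buff integrals.

A cosolvent ("cosolvent", e.g. a deep eutectic solvent acting as a
hydrotrope) raises the molar solubility of a dilute solute when the solute
prefers it over water. For a binary solvent the derivative of the log
solubility with respect to the cosolvent concentration is

    (d ln c_solute / d c_cosolvent) =
        (G_solute-cosolvent - G_solute-water)
        / (1 + c_cosolvent (G_cosolvent-cosolvent - G_cosolvent-water))

so a positive KBI difference in the numerator is solubility-enhancing, while
cosolvent self-clustering (a growing denominator) damps the effect. When the
primary solvent is itself a binary mixture (water + a buffer solute such as
glycine), the decomposition extends to the bracket

    c_cos (G_s-cos - G_s-w)
      - c_buf (G_s-buf - G_s-w) * c_cos (G_cos-buf - G_buf-w)
          / (1 + c_buf (G_buf-buf - G_buf-w))

which, multiplied by (d mu_cos / d c_cos)/kT, gives kT times the solubility
derivative. The activity-coefficient factor is rarely evaluated in
simulation studies; by default the bracket itself is reported (it carries
the sign and trend information), and the factor is applied only when the
caller supplies it.

Concentrations enter the formulas as number densities (molecules/nm^3) so
that c * G is dimensionless; molar inputs are converted with
N_Avogadro / 10^24 = 0.602214076 (molecules/nm^3 per mol/L).

Uncertainties: only KBIs carry sigma (concentrations are treated as exact).
Differences combine in quadrature, sigma = sqrt(s12^2 + s13^2); composite
expressions are propagated to first order through the exact gradient with
respect to every KBI, which keeps correlations through shared KBIs (the
solute-water KBI appears in two ternary terms) consistent with a Monte-Carlo
propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rdf_kbi import KBIEstimate

__all__ = [
    "NUMBER_DENSITY_PER_MOLAR",
    "KBISet",
    "SolvationDecomposition",
    "binary_derivative",
    "ternary_decomposition",
    "propagate_difference_sigma",
]

#: molecules/nm^3 per mol/L
NUMBER_DENSITY_PER_MOLAR = 0.602214076

#: canonical role names for the species entering the decompositions
ROLES = ("solute", "cosolvent", "water", "buffer")


def _key(a: str, b: str) -> tuple[str, str]:
    return tuple(sorted((a, b)))


@dataclass
class KBISet:
    """Extrapolated KBIs for the species pairs of a solute/cosolvent/water
    (/buffer) mixture, with the composition.

    ``kbis`` maps unordered role pairs (any order) to :class:`KBIEstimate`;
    ``c_cosolvent`` and ``c_buffer`` are number densities in molecules/nm^3
    (use :meth:`from_molar` for mol/L inputs). The solute is at infinite
    dilution. ``temperature`` (K) is carried for callers that apply the
    activity factor.
    """

    kbis: dict[tuple[str, str], KBIEstimate]
    c_cosolvent: float
    c_buffer: float = 0.0
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.c_cosolvent < 0 or self.c_buffer < 0:
            raise ValueError("concentrations must be non-negative")
        self.kbis = {_key(*pair): est for pair, est in self.kbis.items()}

    @classmethod
    def from_molar(cls, kbis: dict[tuple[str, str], KBIEstimate],
                   c_cosolvent_molar: float, c_buffer_molar: float = 0.0,
                   temperature: float = 298.15) -> "KBISet":
        return cls(kbis, c_cosolvent_molar * NUMBER_DENSITY_PER_MOLAR,
                   c_buffer_molar * NUMBER_DENSITY_PER_MOLAR, temperature)

    def get(self, a: str, b: str) -> KBIEstimate:
        try:
            return self.kbis[_key(a, b)]
        except KeyError:
            raise KeyError(f"KBI for pair ({a}, {b}) missing from the set") from None

    def require(self, pairs: list[tuple[str, str]]) -> None:
        for a, b in pairs:
            self.get(a, b)


@dataclass
class SolvationDecomposition:
    """Named terms (value, sigma) of a solubility-derivative decomposition."""

    kind: str
    terms: dict[str, tuple[float, float]]
    value: float
    sigma: float
    interpretation: str = ""
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sigma < 0 or any(s < 0 for _, s in self.terms.values()):
            raise ValueError("sigmas must be non-negative")


def propagate_difference_sigma(s12: float, s13: float) -> float:
    """Quadrature combination sqrt(s12^2 + s13^2) of two KBI uncertainties."""
    if s12 < 0 or s13 < 0:
        raise ValueError("sigmas must be non-negative")
    return float(np.hypot(s12, s13))


def _first_order_sigma(func, values: np.ndarray, sigmas: np.ndarray) -> float:
    """First-order (delta-method) sigma of func(values) via central differences."""
    grads = np.empty_like(values)
    for k in range(len(values)):
        h = max(1e-6, 1e-6 * abs(values[k]))
        up, down = values.copy(), values.copy()
        up[k] += h
        down[k] -= h
        grads[k] = (func(up) - func(down)) / (2.0 * h)
    return float(np.sqrt(np.sum((grads * sigmas) ** 2)))


BINARY_PAIRS = [("solute", "cosolvent"), ("solute", "water"),
                ("cosolvent", "cosolvent"), ("cosolvent", "water")]

TERNARY_PAIRS = [("solute", "cosolvent"), ("solute", "water"),
                 ("solute", "buffer"), ("cosolvent", "buffer"),
                 ("buffer", "water"), ("buffer", "buffer")]


def binary_derivative(kbis: KBISet) -> SolvationDecomposition:
    """Binary solubility derivative (d ln c_solute / d c_cosolvent).

    Returns the preferential-interaction numerator, the self-clustering
    denominator and their ratio, each with a propagated sigma.
    """
    kbis.require(BINARY_PAIRS)
    ests = [kbis.get(*p) for p in BINARY_PAIRS]
    g = np.array([e.G_infinity for e in ests])
    s = np.array([e.sigma for e in ests])
    c = kbis.c_cosolvent

    def numerator(v):
        return v[0] - v[1]

    def denominator(v):
        return 1.0 + c * (v[2] - v[3])

    num = numerator(g)
    den = denominator(g)
    if abs(den) < 1e-12:
        raise ZeroDivisionError(
            "self-clustering denominator is singular (1 + c dG = 0)")

    def ratio(v):
        return numerator(v) / denominator(v)

    s_num = propagate_difference_sigma(s[0], s[1])
    s_den = c * propagate_difference_sigma(s[2], s[3])
    s_ratio = _first_order_sigma(ratio, g, s)
    sign = "solubility-enhancing" if num > 0 else (
        "solubility-reducing" if num < 0 else "neutral")
    interpretation = (f"G_solute-cosolvent - G_solute-water = {num:.4g} nm^3 "
                      f"({sign} preferential interaction)")
    return SolvationDecomposition(
        kind="binary",
        terms={"numerator": (num, s_num), "denominator": (den, s_den)},
        value=num / den, sigma=s_ratio, interpretation=interpretation,
        inputs={"c_cosolvent": c})


def ternary_decomposition(kbis: KBISet, dmu_dc: float | None = None,
                          grouping: str = "per-term") -> SolvationDecomposition:
    """Ternary-solvent decomposition of the solubility derivative.

    ``grouping`` selects how the buffer-mediated correction attaches to the
    bracket. The default ``"per-term"`` follows

        bracket = c_cos dG1 - c_buf dG2 * c_cos dG3 / (1 + c_buf dG4)

    (only the second product is divided by the buffer self-clustering
    denominator); ``"shared-fraction"`` divides the whole difference,

        bracket = (c_cos dG1 - c_buf dG2) * c_cos dG3 / (1 + c_buf dG4),

    an alternative reading of the same printed expression. When ``dmu_dc``
    (the cosolvent activity derivative over kT, 1/(molecules/nm^3)) is given,
    the returned value is bracket * dmu_dc; otherwise the bracket itself.
    """
    if grouping not in ("per-term", "shared-fraction"):
        raise ValueError("grouping must be 'per-term' or 'shared-fraction'")
    kbis.require(TERNARY_PAIRS)
    ests = [kbis.get(*p) for p in TERNARY_PAIRS]
    g = np.array([e.G_infinity for e in ests])
    s = np.array([e.sigma for e in ests])
    c_cos, c_buf = kbis.c_cosolvent, kbis.c_buffer

    # v = [G_s-cos, G_s-w, G_s-buf, G_cos-buf, G_buf-w, G_buf-buf]
    def term1(v):
        return c_cos * (v[0] - v[1])

    def term2(v):
        return c_buf * (v[2] - v[1])

    def term3(v):
        return c_cos * (v[3] - v[4])

    def denom(v):
        return 1.0 + c_buf * (v[5] - v[4])

    def bracket(v):
        if grouping == "per-term":
            return term1(v) - term2(v) * term3(v) / denom(v)
        return (term1(v) - term2(v)) * term3(v) / denom(v)

    den = denom(g)
    if abs(den) < 1e-12:
        raise ZeroDivisionError(
            "buffer self-clustering denominator is singular (1 + c dG = 0)")
    terms = {
        "cosolvent_preference": (term1(g), c_cos * propagate_difference_sigma(s[0], s[1])),
        "buffer_preference": (term2(g), c_buf * propagate_difference_sigma(s[2], s[1])),
        "cosolvent_buffer_coupling": (term3(g), c_cos * propagate_difference_sigma(s[3], s[4])),
        "buffer_self_clustering": (den, c_buf * propagate_difference_sigma(s[5], s[4])),
        "bracket": (bracket(g), _first_order_sigma(bracket, g, s)),
    }
    value, sigma = terms["bracket"]
    if dmu_dc is not None:
        value *= dmu_dc
        sigma *= abs(dmu_dc)
    interpretation = ("bracket > 0: cosolvent enhances solute solubility"
                      if value > 0 else
                      "bracket < 0: cosolvent reduces solute solubility"
                      if value < 0 else "neutral")
    return SolvationDecomposition(
        kind="ternary", terms=terms, value=float(value), sigma=float(sigma),
        interpretation=interpretation,
        inputs={"c_cosolvent": c_cos, "c_buffer": c_buf,
                "dmu_dc": dmu_dc, "grouping": grouping})
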