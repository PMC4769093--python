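"""Oligomer growth models: CCS as a function of oligomer order.

Three competing geometries for how an amyloid oligomer's collision cross
section grows with the number of monomers n:

* **isotropic** — self-similar growth in all dimensions,
  ``sigma_n = sigma_monomer * n**(2/3)`` (one free parameter);
* **linear** — growth in a single dimension (a protofibril),
  ``sigma_n = a*n + k`` where ``a`` is the cross section added per monomer in
  the fibril body and ``k`` the contribution of the fibril cap (two free
  parameters);
* **spherical** — a perfect sphere of typical protein density
  ``rho = 0.44 Da/A^3``: the volume is ``n*M/rho``, the CCS the projected
  area ``pi*r**2`` of the corresponding radius (zero free parameters).

Extended, fibril-like assembly shows up as the linear model winning the
comparison from the trimer on; compact assembly favours the isotropic or
spherical curves.  Models are fitted by least squares to a series of
(n, CCS) points — conventionally the lowest charge state of each oligomer,
which is the least affected by Coulombically driven unfolding — and compared
by the small-sample-corrected Akaike information criterion (AICc).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Typical density of proteins and their complexes, Da per cubic Angstrom.
DEFAULT_DENSITY = 0.44

_N_PARAMS = {"isotropic": 1, "linear": 2, "spherical": 0}


@dataclass
class CcsSeries:
    """Measured CCS per oligomer order.

    ``points`` is a list of (n, ccs, z) tuples: oligomer order, CCS in square
    Angstroms and the charge state the CCS was measured at.
    """

    points: list[tuple[int, float, int]]
    provenance: str = ""

    def __post_init__(self) -> None:
        ns = [p[0] for p in self.points]
        if len(set(ns)) != len(ns):
            raise ValueError("oligomer orders in a CcsSeries must be distinct")
        for n, ccs, _z in self.points:
            if n < 1:
                raise ValueError(f"oligomer order must be >= 1, got {n}")
            if not ccs > 0:
                raise ValueError(f"ccs must be positive, got {ccs}")

    @property
    def n(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def ccs(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)


@dataclass
class GrowthFit:
    """One fitted growth model: parameters, residuals, and AICc."""

    model: str
    params: dict[str, float] = field(default_factory=dict)
    rss: float = 0.0
    aicc: float = 0.0
    selected: bool = False


def predict_isotropic(n, sigma_monomer: float):
    """Isotropic-growth CCS, ``sigma_monomer * n**(2/3)``."""
    if not sigma_monomer > 0:
        raise ValueError("sigma_monomer must be positive")
    return sigma_monomer * np.asarray(n, dtype=float) ** (2.0 / 3.0)


def predict_linear(n, a: float, k: float):
    """Linear (single-dimension) growth CCS, ``a*n + k``."""
    return a * np.asarray(n, dtype=float) + k


def predict_spherical(n, monomer_mass: float, rho: float = DEFAULT_DENSITY):
    """CCS of a perfect sphere of mass ``n*monomer_mass`` and density rho.

    Volume ``V = n*M/rho``, radius ``r = (3V / 4 pi)**(1/3)``, projected area
    ``pi * r**2``.
    """
    if not rho > 0:
        raise ValueError(f"density must be positive, got {rho}")
    if not monomer_mass > 0:
        raise ValueError("monomer_mass must be positive")
    volume = np.asarray(n, dtype=float) * monomer_mass / rho
    radius = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    return math.pi * radius**2


def predict(fit: GrowthFit, n, monomer_mass: float | None = None):
    """Evaluate a fitted model at oligomer order(s) n."""
    if fit.model == "isotropic":
        return predict_isotropic(n, fit.params["sigma_monomer"])
    if fit.model == "linear":
        return predict_linear(n, fit.params["a"], fit.params["k"])
    if fit.model == "spherical":
        if monomer_mass is None:
            raise ValueError("spherical prediction needs monomer_mass")
        return predict_spherical(n, monomer_mass, fit.params.get("rho", DEFAULT_DENSITY))
    raise ValueError(f"unknown growth model {fit.model!r}")


def _aicc(rss: float, n_obs: int, n_params: int) -> float:
    # Guard log(0) on exact fits; the floor keeps ordering (fewer params win
    # ties via the penalty term).
    rss = max(rss, 1e-300)
    aic = n_obs * math.log(rss / n_obs) + 2 * n_params
    denom = n_obs - n_params - 1
    if denom <= 0:
        return math.inf
    return aic + 2 * n_params * (n_params + 1) / denom


def fit_growth(
    series: CcsSeries,
    monomer_mass: float,
    rho: float = DEFAULT_DENSITY,
    fit_rho: bool = False,
    weighting: str = "relative",
) -> list[GrowthFit]:
    """Fit all three growth models and select one by lowest AICc.

    The spherical model is parameter-free with rho fixed at 0.44 Da/A^3 by
    default; pass ``fit_rho=True`` to treat the density as one free
    parameter.  Requires at least three points.  Returns the three
    :class:`GrowthFit` objects with exactly one ``selected``.

    With the default ``weighting="relative"`` the least-squares residuals
    are taken relative to the measured CCS (weights 1/ccs), matching the
    multiplicative error structure of calibrated CCS measurements; on
    noiseless data the fitted parameters are identical to the unweighted
    (``weighting="absolute"``) fit.
    """
    if len(series.points) < 3:
        raise ValueError(f"need >= 3 points to compare models, got {len(series.points)}")
    if weighting not in ("relative", "absolute"):
        raise ValueError(f"unknown weighting {weighting!r}")
    n = series.n
    y = series.ccs
    w = 1.0 / y if weighting == "relative" else np.ones_like(y)
    n_obs = len(n)
    fits: list[GrowthFit] = []

    def wrss(pred: np.ndarray) -> float:
        return float(np.sum(((y - pred) * w) ** 2))

    # isotropic: closed-form weighted LS for the scale on the n^(2/3) basis
    basis = n ** (2.0 / 3.0)
    sigma = float(np.sum(basis * y * w**2) / np.sum(basis**2 * w**2))
    rss_iso = wrss(sigma * basis)
    fits.append(
        GrowthFit("isotropic", {"sigma_monomer": sigma}, rss_iso, _aicc(rss_iso, n_obs, 1))
    )

    # linear: weighted LS line in n (polyfit weights multiply residuals)
    a, k = np.polyfit(n, y, 1, w=w)
    rss_lin = wrss(a * n + k)
    fits.append(
        GrowthFit("linear", {"a": float(a), "k": float(k)}, rss_lin, _aicc(rss_lin, n_obs, 2))
    )

    # spherical: parameter-free (or 1-parameter in rho); prediction scales as
    # rho**(-2/3), so the rho fit is again a closed-form scale fit
    if fit_rho:
        base = np.asarray(predict_spherical(n, monomer_mass, 1.0))
        scale = float(np.sum(base * y * w**2) / np.sum(base**2 * w**2))  # rho**(-2/3)
        rho_hat = scale ** (-1.5)
        rss_sph = wrss(base * scale)
        fits.append(
            GrowthFit("spherical", {"rho": rho_hat}, rss_sph, _aicc(rss_sph, n_obs, 1))
        )
    else:
        pred = np.asarray(predict_spherical(n, monomer_mass, rho))
        rss_sph = wrss(pred)
        fits.append(
            GrowthFit("spherical", {"rho": rho}, rss_sph, _aicc(rss_sph, n_obs, 0))
        )

    best = min(fits, key=lambda f: (f.aicc, _N_PARAMS[f.model]))
    best.selected = True
    return fits


def selected_model(fits: list[GrowthFit]) -> GrowthFit:
    """Return the fit flagged as selected."""
    for f in fits:
        if f.selected:
            return f
    raise ValueError("no model selected")
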