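"""Critical N dilution curve, NNI, and CC-based NNI estimation models.

The critical N concentration Nc(SDM) = A * SDM**B (defaults A = 4.15,
B = −0.38, SDM in t/ha, Nc in % of dry matter) is the minimum shoot N
concentration permitting maximum growth at a given biomass; the negative
exponent expresses N dilution as the canopy develops.  The nitrogen
nutrition index NNI = SNC / Nc is 1 at optimum, below 1 under deficiency
and above 1 under luxury uptake.

Two routes estimate NNI from canopy cover:

* the **direct** route fits NNI = a * CC**b on observed (CC, NNI) pairs;
* the **indirect** route composes fitted SNC = a_s * CC**b_s and
  SDM = a_d * CC**b_d through the definition of NNI, which stays a power
  law with closed-form parameters

      a' = a_s * a_d**(−B) / A        b' = b_s − B * b_d

  (at the default curve: a' = a_s * a_d**0.38 / 4.15 and
  b' = b_s + 0.38 * b_d).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .allometry import AllometricResults, fit_allometric

__all__ = [
    "CriticalNCurve",
    "critical_n",
    "nni",
    "classify_n_status",
    "NNIModel",
    "fit_direct",
    "compose_indirect",
    "sna_from_sdm_snc",
]

#: kg N / ha per (t/ha * % of dry matter): 1 t/ha at 1% N carries 10 kg N
SNA_UNIT_FACTOR = 10.0


@dataclass(frozen=True)
class CriticalNCurve:
    """Critical N dilution curve Nc = A * SDM**B.

    A is the critical SNC (% of dry matter) at SDM = 1 t/ha; B < 0 is the
    dilution exponent.
    """

    A: float = 4.15
    B: float = -0.38

    def __post_init__(self):
        if self.A <= 0:
            raise ValueError(f"curve coefficient A must be > 0, got {self.A}")
        if self.B >= 0:
            raise ValueError(
                f"dilution exponent B must be < 0, got {self.B}"
            )

    def predict(self, sdm):
        return critical_n(sdm, self)


DEFAULT_CURVE = CriticalNCurve()


def _require_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not (np.isfinite(arr).all() and (arr > 0).all()):
        raise ValueError(f"{name} must be strictly positive and finite")
    return arr


def critical_n(sdm, curve: CriticalNCurve = DEFAULT_CURVE):
    """Critical shoot N concentration (% of dry matter) at biomass ``sdm``.

    ``sdm`` in t/ha, scalar or array, strictly positive.
    """
    sdm = _require_positive("sdm", sdm)
    out = curve.A * sdm ** curve.B
    return float(out) if out.ndim == 0 else out


def nni(snc, sdm, curve: CriticalNCurve = DEFAULT_CURVE):
    """Nitrogen nutrition index: observed SNC over critical SNC.

    ``snc`` in % of dry matter, ``sdm`` in t/ha; both strictly positive.
    """
    snc = _require_positive("snc", snc)
    out = snc / critical_n(sdm, curve)
    return float(out) if np.ndim(out) == 0 else out


def classify_n_status(nni_value, tol: float = 0.05):
    """Classify NNI as ``deficient`` / ``optimal`` / ``surplus``.

    Values below 1 − tol are deficient, above 1 + tol surplus, the band
    in between optimal.  Accepts scalars or arrays.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    arr = _require_positive("nni_value", nni_value)
    labels = np.where(
        arr < 1.0 - tol, "deficient",
        np.where(arr > 1.0 + tol, "surplus", "optimal"),
    )
    return str(labels) if labels.ndim == 0 else labels


@dataclass(frozen=True)
class NNIModel:
    """Power-law CC→NNI estimator, NNI = a' * CC**b'.

    ``provenance`` records either the direct :class:`AllometricResults`
    or the (a_s, b_s, a_d, b_d, curve) tuple the model was composed from.
    """

    a_prime: float
    b_prime: float
    method: str  # "direct" | "indirect"
    stage: str | None = None
    provenance: Any = None

    def __post_init__(self):
        if self.a_prime <= 0:
            raise ValueError(f"a' must be > 0, got {self.a_prime}")
        if self.method not in ("direct", "indirect"):
            raise ValueError(f"unknown method {self.method!r}")

    def predict(self, cc):
        """Estimated NNI at canopy cover ``cc`` (strictly positive)."""
        cc = _require_positive("cc", cc)
        out = self.a_prime * cc ** self.b_prime
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "a_prime": self.a_prime,
            "b_prime": self.b_prime,
            "method": self.method,
            "stage": self.stage,
        }

    def equation(self) -> str:
        return f"NNI = {self.a_prime:.3g} CC^{self.b_prime:.3g}"


def fit_direct(cc, nni_values, stage: str | None = None) -> NNIModel:
    """Fit NNI = a * CC**b directly on observed pairs (log-linear OLS)."""
    res: AllometricResults = fit_allometric(cc, nni_values)
    return NNIModel(
        a_prime=res.a, b_prime=res.b, method="direct",
        stage=stage, provenance=res,
    )


def compose_indirect(
    a_s: float, b_s: float, a_d: float, b_d: float,
    curve: CriticalNCurve = DEFAULT_CURVE,
    stage: str | None = None,
) -> NNIModel:
    """Compose CC→SNC and CC→SDM power laws into a CC→NNI power law.

    Substituting SNC = a_s CC^b_s and SDM = a_d CC^b_d into
    NNI = SNC / (A SDM^B) gives, exactly,

        a' = a_s * a_d**(−B) / A        b' = b_s − B * b_d.

    No fitting takes place; the identity holds pointwise for every CC.
    """
    if a_s <= 0 or a_d <= 0:
        raise ValueError(
            f"coefficients must be > 0, got a_s={a_s}, a_d={a_d}"
        )
    a_prime = a_s * a_d ** (-curve.B) / curve.A
    b_prime = b_s - curve.B * b_d
    return NNIModel(
        a_prime=float(a_prime), b_prime=float(b_prime),
        method="indirect", stage=stage,
        provenance=(a_s, b_s, a_d, b_d, curve),
    )


def sna_from_sdm_snc(sdm, snc):
    """Shoot N accumulation (kg/ha) from SDM (t/ha) and SNC (%).

    Single place for the unit conversion SNA = 10 * SDM * SNC.
    """
    sdm = _require_positive("sdm", sdm)
    snc = _require_positive("snc", snc)
    out = SNA_UNIT_FACTOR * sdm * snc
    return float(out) if np.ndim(out) == 0 else out
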