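"""Fractionation-corrected dose and the logistic tumor-response model.

EQD2 converts a radiotherapy schedule (total dose D delivered in n
fractions of d Gy) to the equivalent total dose in 2-Gy fractions under
the linear-quadratic model:

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta)

alpha/beta defaults to 10 Gy, the conventional tumor value, but is
configuration.

The tumor-response-probability (TRP) model scores each patient's chance of
a pathological complete response from EQD2, a tumor-volume covariate and
clinical nodal status:

    TRP = logistic(b0 + b1*EQD2 + b_tumor_size*Y_vol + b_N_stage*Y_N)

with Y_N = 0 for clinical N0 and 1 for N1-2.  The b coefficients are
published model constants and are deliberately configuration-only: the
package ships no default values, and a missing coefficient raises a
configuration error rather than silently scoring with zeros.  Volume
covariates other than the one the coefficients were fitted on (e.g. RTV or
TCTV in place of CATV) must first be median-normalized onto the reference
volume's scale — see :func:`normalize_to_reference_median` — because the
linear predictor is only invariant to a volume rescaling if the volume
coefficient is rescaled inversely.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.special import expit

from .errors import ConfigurationError, ParameterError

__all__ = [
    "DoseScheme",
    "TRPCoefficients",
    "eqd2",
    "trp",
    "normalize_to_reference_median",
]


@dataclass(frozen=True)
class DoseScheme:
    """A fractionation schedule: total dose, fraction count, dose per fraction."""

    total_dose_gy: float
    n_fractions: int
    dose_per_fraction_gy: float | None = None
    alpha_beta_gy: float = 10.0

    def __post_init__(self) -> None:
        if self.total_dose_gy <= 0 or self.n_fractions <= 0:
            raise ParameterError("total dose and fraction count must be positive")
        if self.alpha_beta_gy <= 0:
            raise ParameterError(f"alpha/beta must be positive, got {self.alpha_beta_gy}")
        d = self.dose_per_fraction_gy
        if d is None:
            object.__setattr__(
                self, "dose_per_fraction_gy", self.total_dose_gy / self.n_fractions
            )
        else:
            if d <= 0:
                raise ParameterError("dose per fraction must be positive")
            if abs(self.n_fractions * d - self.total_dose_gy) > 1e-6 * self.total_dose_gy:
                raise ParameterError(
                    f"inconsistent scheme: {self.n_fractions} x {d} Gy != {self.total_dose_gy} Gy"
                )


@dataclass(frozen=True)
class TRPCoefficients:
    """Coefficients of the logistic dose-response model (no shipped defaults).

    b0: intercept; b1: per-Gy EQD2 coefficient; b_tumor_size: per-cm**3
    volume coefficient; b_n_stage: nodal-status (N1-2 vs N0) coefficient.
    """

    b0: float
    b1: float
    b_tumor_size: float
    b_n_stage: float

    def __post_init__(self) -> None:
        for name in ("b0", "b1", "b_tumor_size", "b_n_stage"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise ConfigurationError(f"TRP coefficient {name} must be a finite number")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "TRPCoefficients":
        missing = [k for k in ("b0", "b1", "b_tumor_size", "b_n_stage") if k not in mapping]
        if missing:
            raise ConfigurationError(
                "TRP coefficients missing from configuration: " + ", ".join(missing)
            )
        return cls(**{k: float(mapping[k]) for k in ("b0", "b1", "b_tumor_size", "b_n_stage")})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TRPCoefficients":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping of coefficient names")
        return cls.from_mapping(data.get("trp_coefficients", data))


def eqd2(scheme: DoseScheme) -> float:
    """Equivalent dose in 2-Gy fractions, in Gy."""
    ab = scheme.alpha_beta_gy
    return scheme.total_dose_gy * (scheme.dose_per_fraction_gy + ab) / (2.0 + ab)


def trp(
    coefs: TRPCoefficients,
    eqd2_gy: float | np.ndarray,
    volume_cm3: float | np.ndarray,
    n_positive: int | np.ndarray,
) -> float | np.ndarray:
    """Probability of a pathological complete response, strictly in (0, 1).

    ``n_positive`` is 0 for clinical N0 and 1 for N1-2.
    """
    if np.any(np.asarray(volume_cm3) < 0):
        raise ParameterError("volume must be non-negative")
    lp = (
        coefs.b0
        + coefs.b1 * np.asarray(eqd2_gy, dtype=float)
        + coefs.b_tumor_size * np.asarray(volume_cm3, dtype=float)
        + coefs.b_n_stage * np.asarray(n_positive, dtype=float)
    )
    out = expit(lp)
    return float(out) if np.ndim(out) == 0 else out


def normalize_to_reference_median(values, reference) -> np.ndarray:
    """Rescale ``values`` so their median equals the median of ``reference``.

    Used to put alternative volume definitions on the scale of the volume
    the dose-response coefficients were fitted on.  The median is the
    midpoint of the two central order statistics for even n.
    """
    values = np.asarray(values, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if values.size == 0 or reference.size == 0:
        raise ParameterError("values and reference must be non-empty")
    med = np.median(values)
    if med == 0:
        raise ParameterError("cannot normalize values with zero median")
    return values * (np.median(reference) / med)
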