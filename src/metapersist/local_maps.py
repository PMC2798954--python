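"""Intra-patch population maps: logistic, Ricker and Nicholson-Bailey.

All maps are expressed in *density* form, where the density ``x = n / N`` is
the local abundance rescaled by the per-patch carrying-capacity scale ``N``.
The deterministic maps describe the mean of the corresponding stochastic
(individual-based) dynamics; the conversion back to integer counts lives in
:mod:`metapersist.stochastic`.

Families
--------
logistic
    ``x' = lam * x * (1 - x)``, valid on [0, 1] for ``lam <= 4``.
ricker
    ``x' = x * exp(r * (1 - x))``, valid on [0, inf).
nicholson_bailey
    Host-parasitoid pair ``h' = lam * h * exp(-a p)``,
    ``p' = c * h * (1 - exp(-a p))`` where ``exp(-a p)`` is the probability
    that a host escapes parasitism, ``a`` the parasitoid search efficiency
    and ``c`` the number of parasitoids emerging from an infected host.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "LocalMapSpec",
    "map_mean",
    "map_jacobian",
    "nb_fixed_point",
    "fixed_point",
    "validate_density",
    "integer_fecundity",
]

FAMILIES = ("logistic", "ricker", "nicholson_bailey")


class ConfigurationError(ValueError):
    """Raised when a map specification violates its family's constraints."""


@dataclass(frozen=True)
class LocalMapSpec:
    """Family + parameters of the intra-patch dynamic.

    Parameters
    ----------
    family : {"logistic", "ricker", "nicholson_bailey"}
    N : int
        Carrying-capacity scale (individuals per patch). Sets the strength
        of demographic noise: relative fluctuations scale like 1/sqrt(N).
    lam : float, optional
        Maximum fecundity (offspring per individual); logistic and
        Nicholson-Bailey families.
    r : float, optional
        Ricker growth rate.
    a : float, optional
        Parasitoid search efficiency (Nicholson-Bailey only).
    c : int, optional
        Parasitoids produced per infected host (Nicholson-Bailey only).
    """

    family: str
    N: int = 1000
    lam: Optional[float] = None
    r: Optional[float] = None
    a: Optional[float] = None
    c: Optional[int] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.N < 1 or int(self.N) != self.N:
            raise ConfigurationError("N must be a positive integer")
        if self.family == "logistic":
            if self.lam is None or not self.lam > 0:
                raise ConfigurationError("logistic family requires lam > 0")
            if self.lam > 4:
                raise ConfigurationError("logistic lam > 4 maps the unit interval outside itself")
        elif self.family == "ricker":
            if self.r is None or not self.r > 0:
                raise ConfigurationError("ricker family requires r > 0")
        else:  # nicholson_bailey
            if self.lam is None or not self.lam > 0:
                raise ConfigurationError("nicholson_bailey requires lam > 0")
            if self.a is None or not self.a > 0:
                raise ConfigurationError("nicholson_bailey requires search efficiency a > 0")
            if self.c is None or self.c < 1 or int(self.c) != self.c:
                raise ConfigurationError("nicholson_bailey requires integer c >= 1")

    @property
    def n_species(self) -> int:
        return 2 if self.family == "nicholson_bailey" else 1


def integer_fecundity(spec: LocalMapSpec, *, tol: float = 1e-9) -> int:
    """Integer per-capita offspring number required by the stochastic engine.

    The binomial reaction step needs an integer first argument: ``lam`` for
    the logistic and Nicholson-Bailey families, ``exp(r)`` for Ricker
    (e.g. r = ln 2, ln 3, ln 16 ...). Raises ``ConfigurationError`` if the
    spec does not satisfy the rule, so misconfiguration is caught at
    construction time rather than mid-run.
    """
    if spec.family == "ricker":
        value = float(np.exp(spec.r))
        name = "exp(r)"
    else:
        value = float(spec.lam)
        name = "lam"
    rounded = int(round(value))
    if rounded < 1 or abs(value - rounded) > tol:
        raise ConfigurationError(
            f"stochastic use requires {name} to be a positive integer; got {value!r}"
        )
    return rounded


def validate_density(spec: LocalMapSpec, x: np.ndarray) -> np.ndarray:
    """Check (and return as ndarray) a density state for ``spec``.

    For one-species families ``x`` is any array of nonnegative densities
    (logistic additionally bounded by 1). For Nicholson-Bailey the last axis
    has length 2 and holds (host, parasitoid) densities.
    """
    arr = np.asarray(x, dtype=float)
    if spec.family == "nicholson_bailey":
        if arr.shape[-1] != 2:
            raise ValueError("Nicholson-Bailey state needs a trailing (host, parasitoid) axis of length 2")
    if np.any(arr < 0):
        raise ValueError("densities must be nonnegative")
    if spec.family == "logistic" and np.any(arr > 1):
        raise ValueError("logistic densities must not exceed 1")
    return arr


def map_mean(spec: LocalMapSpec, x) -> np.ndarray:
    """One-generation image of the deterministic map, elementwise.

    ``x`` may be a scalar, an array of per-patch densities, or for
    Nicholson-Bailey an array with a trailing (host, parasitoid) axis (a
    2-tuple ``(h, p)`` is also accepted and stacked on the last axis).
    """
    if spec.family == "nicholson_bailey" and isinstance(x, tuple):
        x = np.stack([np.asarray(x[0], dtype=float), np.asarray(x[1], dtype=float)], axis=-1)
    arr = validate_density(spec, x)
    if spec.family == "logistic":
        return spec.lam * arr * (1.0 - arr)
    if spec.family == "ricker":
        return arr * np.exp(spec.r * (1.0 - arr))
    h = arr[..., 0]
    p = arr[..., 1]
    esc = np.exp(-spec.a * p)
    return np.stack([spec.lam * h * esc, spec.c * h * (1.0 - esc)], axis=-1)


def map_jacobian(spec: LocalMapSpec, x) -> np.ndarray:
    """Analytic Jacobian of :func:`map_mean` at ``x``.

    One-species families return the scalar derivative (elementwise over the
    input shape); Nicholson-Bailey returns arrays with trailing shape (2, 2)
    ordered (host, parasitoid).
    """
    if spec.family == "nicholson_bailey" and isinstance(x, tuple):
        x = np.stack([np.asarray(x[0], dtype=float), np.asarray(x[1], dtype=float)], axis=-1)
    arr = validate_density(spec, x)
    if spec.family == "logistic":
        return spec.lam * (1.0 - 2.0 * arr)
    if spec.family == "ricker":
        return np.exp(spec.r * (1.0 - arr)) * (1.0 - spec.r * arr)
    h = arr[..., 0]
    p = arr[..., 1]
    esc = np.exp(-spec.a * p)
    j = np.empty(arr.shape[:-1] + (2, 2))
    j[..., 0, 0] = spec.lam * esc
    j[..., 0, 1] = -spec.a * spec.lam * h * esc
    j[..., 1, 0] = spec.c * (1.0 - esc)
    j[..., 1, 1] = spec.c * spec.a * h * esc
    return j


def nb_fixed_point(spec: LocalMapSpec) -> tuple[float, float]:
    """Coexistence fixed point (h*, p*) of the Nicholson-Bailey map.

    ``p* = ln(lam)/a`` and ``h* = lam * ln(lam) / (a * c * (lam - 1))``.
    Exists only for ``lam > 1`` (otherwise the host cannot sustain the
    parasitoid); the point is always unstable, which is what makes the
    dynamic extinction-prone.
    """
    if spec.family != "nicholson_bailey":
        raise ValueError("nb_fixed_point applies to the nicholson_bailey family only")
    if spec.lam <= 1:
        raise ConfigurationError("no coexistence fixed point for lam <= 1")
    p_star = np.log(spec.lam) / spec.a
    h_star = spec.lam * np.log(spec.lam) / (spec.a * spec.c * (spec.lam - 1.0))
    return float(h_star), float(p_star)


def fixed_point(spec: LocalMapSpec):
    """Nontrivial fixed point of the single-patch map.

    logistic: ``1 - 1/lam`` (for lam > 1); ricker: ``1``; Nicholson-Bailey:
    the coexistence point from :func:`nb_fixed_point`.
    """
    if spec.family == "logistic":
        if spec.lam <= 1:
            return 0.0
        return 1.0 - 1.0 / spec.lam
    if spec.family == "ricker":
        return 1.0
    return nb_fixed_point(spec)
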