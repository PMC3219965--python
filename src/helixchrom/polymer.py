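"""Closed-form polymer statistics for chromatin contact-frequency decay.

The chromatin fiber is treated as a freely jointed chain of Kuhn segments of
length ``S`` kb (``S * L`` nm, with ``L`` the linear mass density in nm/kb).
Random crosslinking (collision) frequency between two sites separated by
``s`` kb is a function of the number of Kuhn segments ``beta`` that
effectively separate them, which in turn is set by the mean spatial distance
``<R>`` between the sites:

    beta = (<R> / (S * L))**2

Three chain geometries are supported:

* ``linear``   -- <R> = L * sqrt(s * S), hence beta = s / S.
* ``circular`` -- a Gaussian ring with apparent circle size ``c`` kb:
  <R> = L * sqrt(S * s * (c - s) / c), hence beta = s (c - s) / (S c).
* ``helix``    -- the statistical helix: the fiber is wound, on population
  average, on a helix of mean diameter ``D`` nm and mean step (pitch) ``P``
  nm. A separation of ``s`` kb corresponds to ``s * L`` nm of fiber path, i.e.
  a winding angle theta = 2 pi s L / sqrt(pi^2 D^2 + P^2), and

      <R>^2 = D^2 sin^2(theta / 2) + (P theta / (2 pi))^2

  (chord across the cylinder plus axial rise).  For P = 0 this is a closed
  circle of diameter D with period pi D / L kb; at a full geometric turn the
  chord vanishes and <R> = P.

The crosslinking frequency follows the worm-like chain interpolation used
throughout the 3C literature:

    X(s) = 0.53 * k * beta^(-3/2) * exp(-1.8 / beta)

with ``k`` the crosslinking efficiency absorbing experimental scale (X is
strictly linear in k).  X is singular at beta = 0 (s = 0 or a full closed
turn of a P = 0 helix); such inputs raise rather than return infinities.

Units are fixed: s in kb, S in kb, L in nm/kb, D/P/<R> in nm, volumes in
nm^3/kb and um^3 (1 um^3 = 1e9 nm^3).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "PolymerDomainError",
    "SingularSeparationError",
    "PolymerModel",
    "VolumeReport",
    "mean_spatial_distance",
    "kuhn_segments",
    "kuhn_segments_from_distance",
    "crosslink_frequency",
    "helix_turn_length",
    "helix_turn_length_approx",
    "helix_turn_kb",
    "volumetric_density",
    "fiber_reference_density",
    "helix_volumetric_density",
    "volume_report",
    "predict_spatial_distance_curve",
    "MAMMAL_LINEAR_MASS_DENSITY",
    "YEAST_LINEAR_MASS_DENSITY",
]

#: nm of chromatin fiber per kb of DNA (6 nucleosomes / 11 nm, 190 bp repeat).
MAMMAL_LINEAR_MASS_DENSITY = 9.6
#: yeast chromatin is less compact along the fiber axis.
YEAST_LINEAR_MASS_DENSITY = 11.1

#: diameter (nm) of the canonical compact chromatin fiber used as the
#: volumetric reference.
FIBER_DIAMETER_NM = 30.0
#: axial extent of 1 kb of that fiber (nm) -- equals L for the mammal default.
FIBER_RISE_NM_PER_KB = 9.6

NM3_PER_UM3 = 1e9

_FAMILIES = ("linear", "circular", "helix")


class PolymerDomainError(ValueError):
    """Input outside the geometric domain of the model (e.g. negative s)."""


class SingularSeparationError(PolymerDomainError):
    """beta = 0 makes the crosslinking frequency singular (coincident sites)."""


@dataclass(frozen=True)
class PolymerModel:
    """Parameter set for one chain geometry.

    Only the parameters of the chosen family are required: ``c`` for
    ``circular``; ``D`` and ``P`` for ``helix``.  ``L`` is a fixed physical
    constant of the fit, never a free parameter.
    """

    family: str
    S: float
    k: float = 1.0
    L: float = MAMMAL_LINEAR_MASS_DENSITY
    c: float | None = None
    D: float | None = None
    P: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown polymer family {self.family!r}")
        if not (self.k > 0):
            raise ValueError("crosslinking efficiency k must be > 0")
        if not (self.S > 0):
            raise ValueError("Kuhn segment length S must be > 0 kb")
        if not (self.L > 0):
            raise ValueError("linear mass density L must be > 0 nm/kb")
        if self.family == "circular":
            if self.c is None or not (self.c > 0):
                raise ValueError("circular family requires apparent circle size c > 0 kb")
        if self.family == "helix":
            if self.D is None or self.D < 0:
                raise ValueError("helix family requires diameter D >= 0 nm")
            if self.P is None or self.P < 0:
                raise ValueError("helix family requires step P >= 0 nm")
            if self.D == 0 and self.P == 0:
                raise ValueError("helix with D = P = 0 is degenerate")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "k": self.k,
            "S": self.S,
            "L": self.L,
            "c": self.c,
            "D": self.D,
            "P": self.P,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PolymerModel":
        known = {"family", "k", "S", "L", "c", "D", "P"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown model keys: {sorted(unknown)}")
        return cls(**{key: d[key] for key in known & set(d)})

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "PolymerModel":
        return cls.from_dict(json.loads(text))

    def with_params(self, **kwargs) -> "PolymerModel":
        return replace(self, **kwargs)

    @property
    def kuhn_length_nm(self) -> float:
        return self.S * self.L


def _as_array(s) -> tuple[np.ndarray, bool]:
    arr = np.asarray(s, dtype=float)
    return arr, arr.ndim == 0


def _check_separation(model: PolymerModel, s: np.ndarray) -> None:
    if np.any(s < 0):
        raise PolymerDomainError("site separation s must be >= 0 kb")
    if model.family == "circular" and np.any(s > model.c):
        raise PolymerDomainError(
            f"circular model: s must satisfy 0 <= s <= c = {model.c} kb"
        )


def helix_turn_kb(model: PolymerModel) -> float:
    """Genomic content (kb) of one full geometric turn of the helix.

    One turn consumes sqrt((pi D)^2 + P^2) nm of fiber path.
    """
    if model.family != "helix":
        raise ValueError("helix_turn_kb requires a helix model")
    return math.sqrt((math.pi * model.D) ** 2 + model.P**2) / model.L


def mean_spatial_distance(model: PolymerModel, s):
    """Mean spatial distance <R> (nm) between sites separated by ``s`` kb."""
    arr, scalar = _as_array(s)
    _check_separation(model, arr)
    if model.family == "linear":
        r = model.L * np.sqrt(arr * model.S)
    elif model.family == "circular":
        r = model.L * np.sqrt(model.S * arr * (model.c - arr) / model.c)
    else:
        turn = helix_turn_kb(model)
        theta = 2.0 * math.pi * arr / turn
        chord = model.D * np.sin(theta / 2.0)
        rise = model.P * theta / (2.0 * math.pi)
        r = np.sqrt(chord**2 + rise**2)
    return float(r) if scalar else r


def kuhn_segments_from_distance(model: PolymerModel, r):
    """Number of Kuhn segments implied by a mean spatial distance (nm)."""
    arr, scalar = _as_array(r)
    beta = (arr / (model.S * model.L)) ** 2
    return float(beta) if scalar else beta


def kuhn_segments(model: PolymerModel, s):
    """beta(s): effective number of Kuhn segments, by the family's own formula.

    Numerically identical (to rounding) to routing the family's <R> through
    ``kuhn_segments_from_distance`` -- the property tests pin this down.
    """
    arr, scalar = _as_array(s)
    _check_separation(model, arr)
    if model.family == "linear":
        beta = arr / model.S
    elif model.family == "circular":
        beta = arr * (model.c - arr) / (model.S * model.c)
    else:
        turn = helix_turn_kb(model)
        theta = 2.0 * math.pi * arr / turn
        sl2 = (model.S * model.L) ** 2
        beta = (model.D**2 * np.sin(theta / 2.0) ** 2 + (model.P * theta / (2.0 * math.pi)) ** 2) / sl2
    return float(beta) if scalar else beta


def crosslink_frequency(model: PolymerModel, s):
    """Random crosslinking frequency X(s) (arbitrary units, linear in k)."""
    arr, scalar = _as_array(s)
    beta = kuhn_segments(model, arr)
    beta_arr = np.asarray(beta, dtype=float)
    if np.any(beta_arr <= 0):
        raise SingularSeparationError(
            "beta = 0 (coincident sites or exact closed turn): X(s) is singular"
        )
    x = 0.53 * model.k * beta_arr ** (-1.5) * np.exp(-1.8 / beta_arr)
    return float(x) if scalar else x


def helix_turn_length_approx(model: PolymerModel) -> float:
    """First-order closed-form turn length: geometric turn / (1 + (P/(pi D))^2)."""
    if model.family != "helix" or not model.D or model.D <= 0:
        raise ValueError("requires a helix model with D > 0")
    return helix_turn_kb(model) / (1.0 + (model.P / (math.pi * model.D)) ** 2)


def helix_turn_length(model: PolymerModel, *, grid_step: float | None = None) -> float:
    """Turn length Sh (kb): the first local maximum of X(s) past the initial decay.

    Locates the first downward zero crossing of dX/ds (d2X/ds2 < 0) for s
    beyond the small-s mode of X, by scanning and bisecting the numerical
    derivative; equivalently the first local minimum of <R> near one
    geometric turn.  With ``grid_step`` set, a brute-force grid search at
    that resolution is used instead (the independent oracle path).
    """
    if model.family != "helix":
        raise PolymerDomainError("turn length is defined for the helix family only")
    if not (model.D and model.D > 0):
        raise PolymerDomainError("turn length requires D > 0")
    s_max = 4.0 * math.pi * model.D / model.L
    # The small-s mode of X sits at s ~ 1.2 S for the locally linear chain;
    # start safely beyond it.
    s_lo = max(3.0 * 1.2 * model.S, 1e-3)

    def neg_x(s: float) -> float:
        return -crosslink_frequency(model, s)

    if grid_step is not None:
        grid = np.arange(s_lo, s_max, grid_step)
        x = crosslink_frequency(model, grid)
        interior = (x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])
        idx = np.nonzero(interior)[0]
        if idx.size == 0:
            raise PolymerDomainError(
                f"no interior maximum of X(s) found in ({s_lo:.3g}, {s_max:.3g}] kb"
            )
        return float(grid[idx[0] + 1])

    def dx(s: float, h: float = 1e-4) -> float:
        return (crosslink_frequency(model, s + h) - crosslink_frequency(model, s - h)) / (2 * h)

    scan = np.geomspace(s_lo, s_max, 4096)
    d = np.array([dx(v) for v in scan])
    sign_flip = np.nonzero((d[:-1] > 0) & (d[1:] <= 0))[0]
    if sign_flip.size == 0:
        raise PolymerDomainError(
            f"no interior maximum of X(s) found in ({s_lo:.3g}, {s_max:.3g}] kb"
        )
    i = sign_flip[0]
    root = brentq(dx, scan[i], scan[i + 1], xtol=1e-6)
    # polish on -X itself to be robust to derivative noise
    res = minimize_scalar(
        neg_x, bounds=(root - 0.5, root + 0.5), method="bounded",
        options={"xatol": 1e-7},
    )
    return float(res.x)


def volumetric_density(diameter_nm: float, r_nm: float, s_kb: float) -> float:
    """Volumetric mass density (nm^3/kb): envelope cylinder of the structure.

    pi (D/2)^2 <R> / s -- cross-section of the enclosing cylinder times axial
    extent <R> per ``s`` kb of DNA.
    """
    if s_kb <= 0:
        raise PolymerDomainError("s must be > 0 kb")
    if diameter_nm <= 0 or r_nm <= 0:
        raise PolymerDomainError("diameter and <R> must be > 0 nm")
    return math.pi * (diameter_nm / 2.0) ** 2 * r_nm / s_kb


def fiber_reference_density(
    diameter_nm: float = FIBER_DIAMETER_NM,
    rise_nm_per_kb: float = FIBER_RISE_NM_PER_KB,
) -> float:
    """Reference density of the compact 30-nm fiber (~6.8e3 nm^3/kb)."""
    return volumetric_density(diameter_nm, rise_nm_per_kb, 1.0)


def helix_volumetric_density(
    model: PolymerModel, fiber_diameter_nm: float = FIBER_DIAMETER_NM
) -> float:
    """Density of the statistical helix, evaluated over one full turn.

    Per turn the envelope cylinder has cross-section pi (D/2)^2 and height
    <R> = P (the axial rise at a full turn, where the chord term of the
    spatial-distance law vanishes).  The DNA content of that turn is the
    fiber path length of the turn divided by L, with the path measured on
    the wound fiber of thickness ``fiber_diameter_nm`` (helix diameter
    D + fiber thickness); this evaluation point is what reproduces the
    companion genome-scale volume arithmetic self-consistently.
    """
    if model.family != "helix":
        raise PolymerDomainError("helix density requires a helix model")
    if not (model.D and model.D > 0) or not (model.P and model.P > 0):
        raise PolymerDomainError("helix density requires D > 0 and P > 0")
    kb_per_turn = (
        math.sqrt((math.pi * (model.D + fiber_diameter_nm)) ** 2 + model.P**2) / model.L
    )
    return volumetric_density(model.D, model.P, kb_per_turn)


@dataclass(frozen=True)
class VolumeReport:
    """Volumetric summary of a helix model against the 30-nm fiber reference."""

    Vs: float  # nm^3/kb, statistical helix
    V_fiber: float  # nm^3/kb, 30-nm fiber reference
    fold: float  # Vs / V_fiber
    genome_volume: float  # um^3 for the given genome size
    nucleus_volume: float  # um^3, sphere at the given nuclear diameter
    diploid_genome_kb: float
    nucleus_diameter_um: float

    def to_dict(self) -> dict:
        return {
            "Vs_nm3_per_kb": self.Vs,
            "V_fiber_nm3_per_kb": self.V_fiber,
            "fold": self.fold,
            "genome_volume_um3": self.genome_volume,
            "nucleus_volume_um3": self.nucleus_volume,
            "diploid_genome_kb": self.diploid_genome_kb,
            "nucleus_diameter_um": self.nucleus_diameter_um,
        }


def volume_report(
    model: PolymerModel,
    diploid_genome_kb: float = 6.0e6,
    nucleus_diameter_um: float = 10.0,
) -> VolumeReport:
    """Genome-scale volume arithmetic for a helix model."""
    if diploid_genome_kb <= 0:
        raise ValueError("genome size must be > 0 kb")
    if nucleus_diameter_um <= 0:
        raise ValueError("nuclear diameter must be > 0 um")
    vs = helix_volumetric_density(model)
    v_fiber = fiber_reference_density()
    genome_volume = vs * diploid_genome_kb / NM3_PER_UM3
    nucleus_volume = (4.0 / 3.0) * math.pi * (nucleus_diameter_um / 2.0) ** 3
    return VolumeReport(
        Vs=vs,
        V_fiber=v_fiber,
        fold=vs / v_fiber,
        genome_volume=genome_volume,
        nucleus_volume=nucleus_volume,
        diploid_genome_kb=diploid_genome_kb,
        nucleus_diameter_um=nucleus_diameter_um,
    )


def predict_spatial_distance_curve(
    model: PolymerModel,
    s_grid: Sequence[float] | np.ndarray,
    se: Mapping[str, float] | None = None,
):
    """Tabulate <R>(s) over a grid, optionally with a +/- 1 SE envelope.

    ``se`` maps free-parameter names (e.g. ``{"D": 4.80, "P": 8.75}``) to
    standard errors; the envelope is first-order propagation with numerical
    gradients, for comparison against FISH distance measurements.
    """
    import pandas as pd

    grid = np.asarray(list(s_grid), dtype=float)
    r = mean_spatial_distance(model, grid)
    out = pd.DataFrame({"separation_kb": grid, "R_nm": np.atleast_1d(r)})
    if se:
        var = np.zeros_like(np.atleast_1d(r))
        for name, sigma in se.items():
            value = getattr(model, name)
            if value is None:
                raise ValueError(f"model has no parameter {name!r}")
            h = max(abs(value), 1.0) * 1e-6
            up = mean_spatial_distance(model.with_params(**{name: value + h}), grid)
            dn = mean_spatial_distance(model.with_params(**{name: value - h}), grid)
            grad = (np.atleast_1d(up) - np.atleast_1d(dn)) / (2 * h)
            var = var + (grad * sigma) ** 2
        envelope = np.sqrt(var)
        out["R_lo_nm"] = out["R_nm"] - envelope
        out["R_hi_nm"] = out["R_nm"] + envelope
    return out
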