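"""Probe mechanics: layered-cylinder flexural rigidity, Euler buckling load,
and end-loaded cantilever deflection.

A fiber probe is modeled as concentric cylindrical layers bending together,
so the composite flexural rigidity is the sum of each layer's E*I with
I = pi (D_out^4 - D_in^4) / 64.  The strong D^4 scaling is why a 7 um carbon
fiber with a micron of parylene insulation is four orders of magnitude more
compliant than a 90 um silica tube, and why it cannot be inserted into the
brain without a stiff shaft: the Euler critical load P_cr = pi^2 K / (Ke L)^2
collapses with length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

__all__ = ["MATERIALS", "ProbeLayer", "ProbeSpec", "flexural_rigidity",
           "buckling_load", "tip_deflection", "solid_cylinder",
           "silica_tube_probe", "microprobe_stack"]

# Young's moduli (N/m^2).  Handbook values; override per layer as needed.
MATERIALS = {
    "fused_silica": 72e9,
    "carbon_fiber": 234e9,     # high-modulus PAN fiber (grade 34-700 class)
    "parylene_c": 2.8e9,
    "tungsten": 3.5e11,
}

# Euler effective-length factors by end condition.
END_CONDITION_FACTORS = {
    "fixed-free": 2.0,
    "pinned-pinned": 1.0,
    "fixed-pinned": 0.699,
    "fixed-fixed": 0.5,
}


@dataclass(frozen=True)
class ProbeLayer:
    """One concentric layer: material name or modulus, inner/outer diameter (m)."""

    material: str
    d_outer: float
    d_inner: float = 0.0
    E: float = None

    def __post_init__(self):
        if self.E is None:
            if self.material not in MATERIALS:
                raise ValueError(f"unknown material {self.material!r}; give E "
                                 f"explicitly or use one of {sorted(MATERIALS)}")
            object.__setattr__(self, "E", MATERIALS[self.material])
        if not (self.d_outer > self.d_inner >= 0.0):
            raise ValueError("require d_outer > d_inner >= 0")
        if self.E <= 0:
            raise ValueError("Young's modulus must be positive")

    @property
    def rigidity(self) -> float:
        """E * I of this annulus, N m^2."""
        return self.E * np.pi * (self.d_outer ** 4 - self.d_inner ** 4) / 64.0


@dataclass(frozen=True)
class ProbeSpec:
    """Ordered concentric layer stack with a free length and end condition."""

    layers: tuple
    length: float = 0.01
    end_condition: str = "fixed-free"

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("free length must be positive")
        layers = tuple(sorted(self.layers, key=lambda l: l.d_outer))
        for inner, outer in zip(layers, layers[1:]):
            if outer.d_inner < inner.d_outer - 1e-12:
                raise ValueError(
                    f"overlapping layers: {outer.material} inner diameter "
                    f"{outer.d_inner} < {inner.material} outer diameter "
                    f"{inner.d_outer}")
        object.__setattr__(self, "layers", layers)


def flexural_rigidity(spec: Union[ProbeSpec, Sequence[ProbeLayer]]) -> float:
    """Composite flexural rigidity K = sum_i E_i pi (D_out,i^4 - D_in,i^4)/64."""
    layers = spec.layers if isinstance(spec, ProbeSpec) else ProbeSpec(tuple(spec)).layers
    return float(sum(l.rigidity for l in layers))


def buckling_load(K: float, L: float, end_condition: str = "fixed-free") -> float:
    """Euler critical axial load P_cr = pi^2 K / (Ke L)^2."""
    if K <= 0 or L <= 0:
        raise ValueError("K and L must be positive")
    if end_condition not in END_CONDITION_FACTORS:
        raise ValueError(f"unknown end condition {end_condition!r}; expected one "
                         f"of {sorted(END_CONDITION_FACTORS)}")
    ke = END_CONDITION_FACTORS[end_condition]
    return float(np.pi ** 2 * K / (ke * L) ** 2)


def tip_deflection(K: float, L: float, F: float) -> float:
    """End-loaded cantilever tip deflection delta = F L^3 / (3 K)."""
    if K <= 0 or L <= 0:
        raise ValueError("K and L must be positive")
    return float(F * L ** 3 / (3.0 * K))


# --------------------------------------------------------------------------
# reference geometries
# --------------------------------------------------------------------------

def solid_cylinder(material: str, diameter: float, E: float = None) -> ProbeLayer:
    return ProbeLayer(material=material, d_outer=diameter, d_inner=0.0, E=E)


def silica_tube_probe(diameter: float = 90e-6, length: float = 0.01) -> ProbeSpec:
    """Conventional carbon-fiber electrode housing: 90 um fused-silica cylinder."""
    return ProbeSpec(layers=(solid_cylinder("fused_silica", diameter),),
                     length=length)


def microprobe_stack(cf_diameter: float = 7e-6, outer_diameter: float = 10e-6,
                     length: float = 0.01) -> ProbeSpec:
    """Microinvasive probe: carbon-fiber core with a conformal parylene-C shell."""
    return ProbeSpec(layers=(
        solid_cylinder("carbon_fiber", cf_diameter),
        ProbeLayer(material="parylene_c", d_outer=outer_diameter,
                   d_inner=cf_diameter),
    ), length=length)
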