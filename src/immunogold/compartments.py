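"""Somato-dendritic compartment taxonomy for CA1 pyramidal cells.

A compartment is a (layer, class) pair: the CA1 lamina the profile was
imaged in and the kind of neuronal structure it is.  Eleven such pairs
enter the surface-density gradient analysis; axon terminals are handled
separately by the presynaptic analysis.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class Layer(str, enum.Enum):
    """CA1 laminae (stratum radiatum split into proximal and distal)."""

    SO = "so"
    SP = "sp"
    SR_PROX = "sr_prox"
    SR_DIST = "sr_dist"
    SLM = "slm"


class Klass(str, enum.Enum):
    SOMA = "soma"
    APICAL_DENDRITE = "apical_dendrite"
    OBLIQUE_DENDRITE = "oblique_dendrite"
    SPINE = "spine"
    AXON_TERMINAL = "axon_terminal"


@dataclass(frozen=True)
class CompartmentClass:
    layer: Layer
    klass: Klass

    def __post_init__(self) -> None:
        if self.klass is Klass.SOMA and self.layer is not Layer.SP:
            raise ValueError("somata occur only in stratum pyramidale")

    @property
    def key(self) -> str:
        return f"{self.layer.value}/{self.klass.value}"

    @classmethod
    def from_key(cls, key: str) -> "CompartmentClass":
        layer, klass = key.split("/")
        return cls(Layer(layer), Klass(klass))


#: The eleven compartments of the density-gradient analysis, ordered
#: soma -> apical -> oblique -> spine within each layer, somatic layer first.
GRADIENT_COMPARTMENTS: tuple[CompartmentClass, ...] = (
    CompartmentClass(Layer.SP, Klass.SOMA),
    CompartmentClass(Layer.SP, Klass.APICAL_DENDRITE),
    CompartmentClass(Layer.SO, Klass.APICAL_DENDRITE),
    CompartmentClass(Layer.SO, Klass.OBLIQUE_DENDRITE),
    CompartmentClass(Layer.SO, Klass.SPINE),
    CompartmentClass(Layer.SR_PROX, Klass.APICAL_DENDRITE),
    CompartmentClass(Layer.SR_PROX, Klass.OBLIQUE_DENDRITE),
    CompartmentClass(Layer.SR_PROX, Klass.SPINE),
    CompartmentClass(Layer.SLM, Klass.APICAL_DENDRITE),
    CompartmentClass(Layer.SLM, Klass.OBLIQUE_DENDRITE),
    CompartmentClass(Layer.SLM, Klass.SPINE),
)
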