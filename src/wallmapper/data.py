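"""Reference parameter sets used throughout the package.

``MATERIAL_WALLS`` holds the fitted wall parameters for the three surfaces
the mapping procedure was developed on.  ``DEFAULT_PROBE_SET`` is the
probe-atom LJ set used for parameterizing surfaces against an aqueous
glycine solution: the GAFF atom types of zwitterionic glycine plus the
SPC/E water oxygen (water hydrogens carry no LJ interaction and cannot be
probes).  ``GRAPHITE_CARBON``/``ALKANE_*`` are the slab-atom parameters
(GAFF aromatic carbon; GAFF aliphatic carbon and hydrogen).

All values are standard published force-field constants (epsilon in
kcal/mol, sigma in nm).
"""

from __future__ import annotations

from .potentials import LJPair, WallParams

__all__ = [
    "MATERIAL_WALLS",
    "DEFAULT_PROBE_SET",
    "GRAPHITE_CARBON",
    "ALKANE_CARBON",
    "ALKANE_HYDROGEN",
    "EXPERIMENTAL_DENSITIES",
]

#: Fitted (eps_ww, sigma_ww) for the reference materials.
MATERIAL_WALLS: dict[str, WallParams] = {
    "heptane": WallParams(eps_ww=5.7, sigma_ww=0.18, material_label="heptane"),
    "tridecane": WallParams(eps_ww=8.2, sigma_ww=0.18, material_label="tridecane"),
    "graphite": WallParams(eps_ww=17.2, sigma_ww=0.34, material_label="graphite"),
}

#: GAFF zwitterionic-glycine atom types + SPC/E water oxygen.
DEFAULT_PROBE_SET: dict[str, LJPair] = {
    "c3": LJPair(0.1094, 0.339967),   # sp3 carbon (CH2)
    "c": LJPair(0.0860, 0.339967),    # carboxylate carbon
    "o": LJPair(0.2100, 0.295992),    # carboxylate oxygen
    "n4": LJPair(0.1700, 0.325000),   # ammonium nitrogen
    "hn": LJPair(0.0157, 0.106908),   # H on N
    "hx": LJPair(0.0157, 0.195998),   # H on C adjacent to N+
    "ow": LJPair(0.1553, 0.316557),   # SPC/E water oxygen
}

#: GAFF aromatic carbon (graphite slab atoms).
GRAPHITE_CARBON = LJPair(0.0860, 0.339967)
#: GAFF aliphatic carbon / hydrogen (alkane slab atoms).
ALKANE_CARBON = LJPair(0.1094, 0.339967)
ALKANE_HYDROGEN = LJPair(0.0157, 0.264953)

#: Experimental liquid mass densities at 298 K, g/cm^3 (configuration
#: inputs for the pseudo-crystalline alkane slab builders).
EXPERIMENTAL_DENSITIES: dict[str, float] = {
    "heptane": 0.6795,
    "tridecane": 0.7564,
}
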