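"""Published AKIII reference values used as bookkeeping inputs.

Per-residue energy changes (kJ/mol) reported for the three ligand
binding sites of E. coli aspartokinase III during the steered-MD release
of lysine from the regulatory site, plus per-residue evolutionary
conservation scores (Rate4Site / ConSurf convention, more negative =
more conserved) for the mutated pathway residues.

Each binding-site table maps residue id -> (bond, angle, dihedral,
electrostatic, vdw, total) where ``total`` is the value as printed at
3 decimal places; the component sum reproduces it to within the 3-dp
rounding of the addends (<= 0.0015 kJ/mol).
"""

from __future__ import annotations

#: Lysine (regulatory) binding site.
LYSINE_SITE_ENERGY_CHANGES: dict[int, tuple[float, ...]] = {
    318: (3.276, 2.585, 0.897, -1.240, 1.320, 6.838),
    321: (3.698, -1.098, -2.461, -2.170, 0.329, -1.702),
    324: (0.765, 3.844, -3.360, -0.758, 0.056, 0.547),
    325: (-0.617, 0.508, 2.133, -0.642, -1.490, -0.108),
    338: (2.259, 0.356, -0.667, -5.134, 2.755, -0.432),
    339: (1.937, 2.045, -4.372, 1.603, 0.290, 1.502),
    340: (1.683, 3.485, 5.204, -4.656, -1.265, 4.452),
    345: (-0.385, 1.588, 1.410, 1.120, 0.023, 3.755),
    346: (4.522, 1.331, 0.735, 0.781, 1.889, 9.258),
}

#: Aspartate (substrate) binding site.
ASPARTATE_SITE_ENERGY_CHANGES: dict[int, tuple[float, ...]] = {
    8: (0.413, 9.457, -0.467, -1.612, -1.047, 6.744),
    45: (2.641, -0.504, 2.294, 3.697, -0.149, 7.979),
    198: (3.496, -3.054, -0.028, 2.959, -2.274, 1.099),
    199: (-0.512, 3.177, 0.743, 0.055, 1.857, 5.321),
    201: (-0.934, 3.150, -1.119, -4.695, -0.027, -3.625),
    202: (-1.995, 2.895, 4.351, -0.517, -0.256, 4.479),
    222: (0.261, 1.852, 2.227, 3.277, -0.490, 7.127),
    39: (0.701, 1.684, -0.433, 2.523, 1.232, 5.707),
    119: (1.014, -0.205, 0.450, -4.943, 1.340, -2.344),
    184: (0.312, 0.471, 2.273, -0.513, -1.084, 1.459),
}

#: ADP binding site (residue 201/202 region overlaps the aspartate site).
ADP_SITE_ENERGY_CHANGES: dict[int, tuple[float, ...]] = {
    227: (-0.552, -1.894, -2.998, 2.152, -0.638, -3.930),
    232: (1.605, -0.597, -3.068, -1.342, -2.302, -5.704),
    257: (-1.516, 3.465, 2.746, 1.075, 0.331, 6.100),
    258: (3.013, -3.922, 0.986, -0.637, -0.265, -0.825),
    221: (-3.959, 2.281, -1.835, 2.776, 1.216, 0.478),
    202: (-1.995, 2.895, 4.351, -0.517, -0.256, 4.479),
}

ALL_SITE_TABLES: dict[str, dict[int, tuple[float, ...]]] = {
    "lysine": LYSINE_SITE_ENERGY_CHANGES,
    "aspartate": ASPARTATE_SITE_ENERGY_CHANGES,
    "adp": ADP_SITE_ENERGY_CHANGES,
}

#: Conservation scores for the single-mutant pathway residues
#: (protein-normalised; more negative = more conserved).
MUTANT_CONSERVATION_SCORES: dict[int, float] = {
    106: -0.2880,
    165: 0.8030,
    245: -0.8590,
    292: 1.1990,
    306: -0.3040,
    443: -0.7910,
}

#: Pathway endpoints: lysine-site sources and aspartate-site sinks.
LYSINE_SITE_SOURCES: tuple[int, ...] = (338, 340, 346)
ASPARTATE_SITE_SINKS: tuple[int, ...] = (39, 119, 202, 201)
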