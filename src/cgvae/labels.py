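"""Neuromark fMRI 1.0 component labels.

The 53 independent components (ICs) of the Neuromark fMRI 1.0 template,
ordered by functional subdomain: Subcortical (SC), Auditory (AUD),
Sensorimotor (SM), Visual (VIS), Cognitive Control (CC), Default Mode
Network (DMN), Cerebellar (CB). The keyword strings are the conventional
short names used to reference components in connectivity figures.
"""

from __future__ import annotations

# (keyword, subdomain) in matrix row/column order.
COMPONENTS: list[tuple[str, str]] = [
    # Subcortical (5)
    ("Caud-69", "SC"),
    ("Sub/HypoT-53", "SC"),
    ("Put-98", "SC"),
    ("Caud-99", "SC"),
    ("Thal-45", "SC"),
    # Auditory (2)
    ("STG-21", "AUD"),
    ("MTG-56", "AUD"),
    # Sensorimotor (9)
    ("PoCG-3", "SM"),
    ("LPoCG-9", "SM"),
    ("ParaCL-2", "SM"),
    ("RPoCG-11", "SM"),
    ("SPL-27", "SM"),
    ("ParaCL-54", "SM"),
    ("PreCG-66", "SM"),
    ("SPL-80", "SM"),
    ("PoCG-72", "SM"),
    # Visual (9)
    ("CalcG-16", "VIS"),
    ("MOG-5", "VIS"),
    ("MTG-62", "VIS"),
    ("Cuneus-15", "VIS"),
    ("RMOG-12", "VIS"),
    ("FusiG-93", "VIS"),
    ("IOG-20", "VIS"),
    ("LingualG-8", "VIS"),
    ("MTG-77", "VIS"),
    # Cognitive Control (17)
    ("IPL-68", "CC"),
    ("Insula-33", "CC"),
    ("SMFG-43", "CC"),
    ("IFG-70", "CC"),
    ("R-IFG-61", "CC"),
    ("MiFG-55", "CC"),
    ("IPL-63", "CC"),
    ("RIPL-79", "CC"),
    ("SMA-84", "CC"),
    ("SFG-96", "CC"),
    ("MiFG-88", "CC"),
    ("HiPP-48", "CC"),
    ("LIPL-81", "CC"),
    ("MCC-37", "CC"),
    ("IFG-67", "CC"),
    ("MiFG-38", "CC"),
    ("HiPP-83", "CC"),
    # Default Mode (7)
    ("PC-32", "DMN"),
    ("PC-40", "DMN"),
    ("ACC-23", "DMN"),
    ("PCC-71", "DMN"),
    ("ACC-17", "DMN"),
    ("PC-51", "DMN"),
    ("PCC-94", "DMN"),
    # Cerebellar (4)
    ("CB-13", "CB"),
    ("CB-18", "CB"),
    ("CB-4", "CB"),
    ("CB-7", "CB"),
]

KEYWORDS: list[str] = [k for k, _ in COMPONENTS]
SUBDOMAINS: list[str] = [s for _, s in COMPONENTS]

SUBDOMAIN_ORDER: list[str] = ["SC", "AUD", "SM", "VIS", "CC", "DMN", "CB"]
SUBDOMAIN_SIZES: list[int] = [5, 2, 9, 9, 17, 7, 4]

N_COMPONENTS = 53

assert len(COMPONENTS) == N_COMPONENTS
assert sum(SUBDOMAIN_SIZES) == N_COMPONENTS


def subdomain_blocks(sizes: list[int] | None = None) -> list[range]:
    """Index ranges of each subdomain block along the matrix axes."""
    sizes = SUBDOMAIN_SIZES if sizes is None else sizes
    blocks, start = [], 0
    for s in sizes:
        blocks.append(range(start, start + s))
        start += s
    return blocks
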