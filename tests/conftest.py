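"""Shared fixtures: reference residue maps and synthetic inputs."""

import pytest

# Checklist residue maps of the two reference proteins, keyed by module.
# Entries are (1-based index, residue letter).

SCPML39_MAP = {
    "zf_C3HC": {
        "r": (89, "R"), "st": (92, "S"), "g": (118, "G"), "omega_g": (119, "W"),
        "c1": (134, "C"), "c2": (137, "C"), "h": (172, "H"), "c3": (176, "C"),
        "omega_f": (178, "W"),
    },
    "Rsm1": {
        "r": (202, "R"), "st": (205, "T"), "g": (256, "G"), "omega_g": (257, "Y"),
        "c1": (268, "C"), "c2": (271, "C"), "h": (288, "H"), "c3": (292, "C"),
        "omega_f": (294, "Y"),
    },
}

SPRSM1_MAP = {
    "zf_C3HC": {
        "r": (49, "R"), "st": (52, "T"), "g": (74, "G"), "omega_g": (75, "W"),
        "c1": (85, "C"), "c2": (88, "C"), "h": (126, "H"), "c3": (130, "C"),
        "omega_f": (132, "W"),
    },
    "Rsm1": {
        "r": (156, "R"), "st": (159, "S"), "g": (204, "G"), "omega_g": (205, "W"),
        "c1": (216, "C"), "c2": (219, "C"), "h": (241, "H"), "c3": (245, "C"),
        "omega_f": (247, "W"),
    },
}


@pytest.fixture
def scpml39_map():
    return {k: dict(v) for k, v in SCPML39_MAP.items()}


@pytest.fixture
def sprsm1_map():
    return {k: dict(v) for k, v in SPRSM1_MAP.items()}
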