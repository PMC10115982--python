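"""The standardized 42-name head-and-neck organ-at-risk roster.

Names follow TG-263-style standardized nomenclature.  Each OAR carries an
organ class used by the default plan-quality template: ``serial`` organs
(cord-like, where the maximum dose governs toxicity) are scored on a
near-maximum statistic (D0.03cc), ``parallel`` organs (gland-like, where
mean dose governs function loss) on Dmean.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

# name -> organ class
OAR_ROSTER_42: Dict[str, str] = {
    "Brain": "parallel",
    "Brainstem": "serial",
    "SpinalCord": "serial",
    "OpticChiasm": "serial",
    "OpticNrv_L": "serial",
    "OpticNrv_R": "serial",
    "Eye_L": "parallel",
    "Eye_R": "parallel",
    "Lens_L": "serial",
    "Lens_R": "serial",
    "Retina_L": "serial",
    "Retina_R": "serial",
    "Glnd_Lacrimal_L": "parallel",
    "Glnd_Lacrimal_R": "parallel",
    "Cochlea_L": "serial",
    "Cochlea_R": "serial",
    "Ear_External_L": "parallel",
    "Ear_External_R": "parallel",
    "Bone_Mastoid_L": "parallel",
    "Bone_Mastoid_R": "parallel",
    "Pituitary": "serial",
    "Parotid_L": "parallel",
    "Parotid_R": "parallel",
    "Glnd_Submand_L": "parallel",
    "Glnd_Submand_R": "parallel",
    "Cavity_Oral": "parallel",
    "Lips": "parallel",
    "Mandible": "serial",
    "TMJoint_L": "serial",
    "TMJoint_R": "serial",
    "Larynx": "parallel",
    "Glottis": "parallel",
    "Musc_Constrict_S": "parallel",
    "Musc_Constrict_M": "parallel",
    "Musc_Constrict_I": "parallel",
    "Esophagus": "parallel",
    "Thyroid": "parallel",
    "Trachea": "serial",
    "BrachialPlex_L": "serial",
    "BrachialPlex_R": "serial",
    "A_Carotid_L": "serial",
    "A_Carotid_R": "serial",
}

assert len(OAR_ROSTER_42) == 42

ROSTER_NAMES: List[str] = list(OAR_ROSTER_42)

# Illustrative dose limits (Gy) for the default template: serial organs get a
# D0.03cc ceiling, parallel organs a Dmean ceiling.  These echo common
# head-and-neck planning guidance but are deliberately labelled illustrative;
# a clinical template is a required configuration input.
DEFAULT_LIMITS_GY: Dict[str, float] = {
    "serial": 50.0,
    "parallel": 26.0,
}


def roster_subset(n: int) -> List[str]:
    """First ``n`` roster names (reduced phantoms for cheap tests)."""
    if not 1 <= n <= 42:
        raise ValueError("roster subset size must be in [1, 42]")
    return ROSTER_NAMES[:n]
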