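"""Published reference values for the mouse MICAL constructs.

Global kinetic parameters of the MO (monooxygenase domain alone) and MO-CH
(monooxygenase plus calponin-homology domain) constructs from the global
non-essential-activator fits, the assay designs they were measured on, the
per-F-actin apparent constants as printed, and the solution-mass reference
numbers.  These serve as ground truth for the synthetic generator and as
inputs to the report-style arithmetic (catalytic power, fold changes, mass
deviations).
"""

from __future__ import annotations

import pandas as pd

from .assay import AssayDesign
from .kinetics import GlobalKineticParams

__all__ = [
    "PARAMS_MO",
    "PARAMS_MO_CH",
    "DESIGN_MO",
    "DESIGN_MO_CH",
    "APPARENT_MO",
    "APPARENT_MO_CH",
    "SEQUENCE_MASS_MO_CH_DA",
    "BSA_DIMER_MASS_DA",
    "SEC_MASS_MO_CH_DA",
    "I0_RATIO_MASS_MO_CH_DA",
    "ENZYME_CONC_UM",
]

#: enzyme concentration used throughout the assays (600 nM, Gill-von Hippel)
ENZYME_CONC_UM = 0.6

#: MO global fit (alpha restrained to 1: F-actin does not change NADPH affinity)
PARAMS_MO = GlobalKineticParams(k_cat=0.68, K_M=28.8, K_act=9.3, alpha=1.0, beta=4.7)

#: MO-CH global fit (alpha free: strong positive coupling, alpha = 0.16)
PARAMS_MO_CH = GlobalKineticParams(k_cat=1.7, K_M=37.7, K_act=10.5, alpha=0.16, beta=7.43)

# Assay grids.  The NADPH series spanned 3-100 µM (six levels, MO) and
# 10-150 µM (five levels, MO-CH); intermediate MO levels are not printed and
# are taken roughly log-spaced.  The 0.45 µM F-actin level follows the
# apparent-constant table header.
DESIGN_MO = AssayDesign(
    substrate_levels=(3.0, 6.0, 12.0, 25.0, 50.0, 100.0),
    activator_levels=(0.0, 0.45, 0.9, 2.2, 7.5),
    enzyme_conc=ENZYME_CONC_UM,
    replicates=3,
    noise_cv=0.03,
)

DESIGN_MO_CH = AssayDesign(
    substrate_levels=(10.0, 25.0, 50.0, 100.0, 150.0),
    activator_levels=(0.0, 2.0, 4.0, 8.0),
    enzyme_conc=ENZYME_CONC_UM,
    replicates=3,
    noise_cv=0.03,
)

#: printed apparent constants per F-actin level (k_cat_app s⁻¹, K_M_app µM)
APPARENT_MO = pd.DataFrame({
    "activator_uM": [0.0, 0.45, 0.9, 2.2, 7.5],
    "k_cat_app": [0.68, 0.71, 0.80, 1.18, 1.72],
    "K_M_app": [28.8, 23.3, 24.0, 26.2, 25.5],
})

APPARENT_MO_CH = pd.DataFrame({
    "activator_uM": [0.0, 2.0, 4.0, 8.0],
    "k_cat_app": [1.7, 7.9, 10.0, 10.3],
    "K_M_app": [37.7, 23.9, 17.5, 9.9],
})

#: MO-CH monomer mass computed from sequence + FAD, Da
SEQUENCE_MASS_MO_CH_DA = 68425.0

#: dimeric bovine serum albumin standard used for the I(0)-ratio method, Da
BSA_DIMER_MASS_DA = 132000.0

#: published solution-mass estimates for MO-CH, Da
SEC_MASS_MO_CH_DA = 61455.0
I0_RATIO_MASS_MO_CH_DA = 55000.0
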