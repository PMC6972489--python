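"""Tissue and acquisition constants used throughout the calibration pipeline.

Per-tissue values are ordered (GM, WM, CSF) everywhere.
"""

# Longitudinal relaxation times, seconds
T1_GM_S = 1.3
T1_WM_S = 1.0
T1_CSF_S = 4.3
T1_TISSUE_S = (T1_GM_S, T1_WM_S, T1_CSF_S)

# Apparent transverse relaxation times, milliseconds
T2STAR_GM_MS = 60.0
T2STAR_WM_MS = 50.0
T2STAR_CSF_MS = 400.0
T2STAR_TISSUE_MS = (T2STAR_GM_MS, T2STAR_WM_MS, T2STAR_CSF_MS)

# Brain-blood water partition coefficients, mL/g
LAMBDA_GM = 0.98
LAMBDA_WM = 0.82
LAMBDA_CSF = 1.15
LAMBDA_TISSUE = (LAMBDA_GM, LAMBDA_WM, LAMBDA_CSF)

# Brain-average partition coefficient: equal-weight mean of GM and WM
LAMBDA_AVG = 0.5 * LAMBDA_GM + 0.5 * LAMBDA_WM

# Arterial blood
T1_BLOOD_S = 1.65
# T2* of arterial blood is not tabulated with the tissue constants above;
# 50 ms is a typical 3T value and is exposed as a configurable default.
T2STAR_BLOOD_MS = 50.0

# Labeling efficiency defaults (consensus-paper values, configurable)
ALPHA_PASL = 0.98
ALPHA_PCASL = 0.85

# Default presaturation efficiency for control-averaging calibration
PRESAT_EFFICIENCY_A = 0.90

# mL/g/s -> mL/100 g/min
CBF_UNIT_FACTOR = 6000.0
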