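"""Small bundled example data.

``SAMPLE_FIXATION_23`` is a 23-sample horizontal fixation trace (degrees
of visual angle, 250 Hz) used as the worked example for phase-space
reconstruction with lag 4 and embedding dimension 3 (15 states).  Sample
15 (1-based) carries a positive sign amid otherwise negative values —
almost certainly a transcription error in the trace's source, but it is
preserved verbatim so the documented reconstruction is reproduced cell
for cell, anomaly included.

``SAMPLE_FIXATION_23_CLEAN`` restores the negative sign on that sample.
The embedding-parameter estimators (average mutual information, false
nearest neighbors) are statistics of the signal and are corrupted by the
sign flip, so the calibration path (AMI lag 4, FNN dimension 3) uses the
corrected trace.
"""

import numpy as np

SAMPLE_FIXATION_23 = np.array([
    -3.2406, -3.2393, -3.2428, -3.2439, -3.2388, -3.2241, -3.2065, -3.1910,
    -3.1842, -3.1828, -3.1846, -3.1857, -3.1871, -3.1869, 3.1871, -3.1841,
    -3.1760, -3.1617, -3.1440, -3.1280, -3.1186, -3.1171, -3.1231,
])

SAMPLE_FIXATION_23_CLEAN = SAMPLE_FIXATION_23.copy()
SAMPLE_FIXATION_23_CLEAN[14] = -3.1871
SAMPLE_FIXATION_23_CLEAN.setflags(write=False)
SAMPLE_FIXATION_23.setflags(write=False)
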