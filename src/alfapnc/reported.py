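"""Published benchmark values used as inputs to aggregate arithmetic.

Validation-set R² of each model × feature group × growth stage from the
source field study, plus its stage-level mean |r| statistics for raw
texture features and selected texture indices.  These numbers are data
(inputs to the relative-improvement and averaging operations), not
results computed by this package; they let the comparison arithmetic be
exercised and let synthetic-data runs be placed next to the published
benchmark.
"""

from __future__ import annotations

import pandas as pd

#: Validation-set R² by (stage, feature_set, model).
VALIDATION_R2: dict[tuple[str, str, str], float] = {
    # branching
    ("branching", "VIs", "RFR"): 0.58,
    ("branching", "VIs", "SVR"): 0.56,
    ("branching", "VIs", "BPNN"): 0.53,
    ("branching", "VIs", "XGB"): 0.64,
    ("branching", "TIs", "RFR"): 0.58,
    ("branching", "TIs", "SVR"): 0.54,
    ("branching", "TIs", "BPNN"): 0.52,
    ("branching", "TIs", "XGB"): 0.61,
    ("branching", "VIs+TIs", "RFR"): 0.62,
    ("branching", "VIs+TIs", "SVR"): 0.59,
    ("branching", "VIs+TIs", "BPNN"): 0.59,
    ("branching", "VIs+TIs", "XGB"): 0.73,
    # budding
    ("budding", "VIs", "RFR"): 0.64,
    ("budding", "VIs", "SVR"): 0.59,
    ("budding", "VIs", "BPNN"): 0.52,
    ("budding", "VIs", "XGB"): 0.76,
    ("budding", "TIs", "RFR"): 0.61,
    ("budding", "TIs", "SVR"): 0.56,
    ("budding", "TIs", "BPNN"): 0.54,
    ("budding", "TIs", "XGB"): 0.74,
    ("budding", "VIs+TIs", "RFR"): 0.71,
    ("budding", "VIs+TIs", "SVR"): 0.60,
    ("budding", "VIs+TIs", "BPNN"): 0.58,
    ("budding", "VIs+TIs", "XGB"): 0.80,
    # initial flowering
    ("initial_flowering", "VIs", "RFR"): 0.58,
    ("initial_flowering", "VIs", "SVR"): 0.58,
    ("initial_flowering", "VIs", "BPNN"): 0.51,
    ("initial_flowering", "VIs", "XGB"): 0.69,
    ("initial_flowering", "TIs", "RFR"): 0.59,
    ("initial_flowering", "TIs", "SVR"): 0.57,
    ("initial_flowering", "TIs", "BPNN"): 0.56,
    ("initial_flowering", "TIs", "XGB"): 0.64,
    ("initial_flowering", "VIs+TIs", "RFR"): 0.63,
    ("initial_flowering", "VIs+TIs", "SVR"): 0.61,
    ("initial_flowering", "VIs+TIs", "BPNN"): 0.58,
    ("initial_flowering", "VIs+TIs", "XGB"): 0.75,
}

#: Stage-level mean |r| of all 48 raw texture features vs PNC.
MEAN_ABS_R_TFV: dict[str, float] = {
    "branching": 0.26,
    "budding": 0.30,
    "initial_flowering": 0.23,
}

#: Stage-level mean |r| of the three selected texture indices vs PNC.
MEAN_ABS_R_TI: dict[str, float] = {
    "branching": 0.62,
    "budding": 0.61,
    "initial_flowering": 0.62,
}


def validation_r2_table() -> pd.DataFrame:
    rows = [
        {"stage": s, "feature_set": f, "model": m, "r2": v}
        for (s, f, m), v in VALIDATION_R2.items()
    ]
    return pd.DataFrame(rows)


def stage_mean_r2(model: str, feature_set: str) -> float:
    """Mean validation R² of one model × feature set over the 3 stages."""
    t = validation_r2_table()
    sub = t[(t["model"] == model) & (t["feature_set"] == feature_set)]
    return float(sub["r2"].mean())
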