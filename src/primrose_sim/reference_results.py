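"""Published per-1000-patient results of the original PRIMROSE
cost-effectiveness analysis, used as fixture inputs.

The original analysis ran 1000 real UK primary-care SMI patients through
an Excel implementation of the model with coefficient tables that were
never published in full, so its absolute results cannot be recomputed from
scratch.  What *can* be recomputed exactly is every derived quantity: the
incremental costs and QALYs against the no-algorithm arm, the net monetary
benefit identities, events prevented, percentage event reductions and
per-patient savings.  This module freezes the published headline numbers
(mean costs, QALYs, NMBs and event counts per 1000 patients over 10 years
at the 10% risk threshold) so those derivations can be exercised and
checked by the package's own economics functions.
"""

from __future__ import annotations

ARMS = ("general_lipid", "smi_lipid", "general_bmi", "smi_bmi", "none")

#: Mean discounted total cost (GBP) per 1000 patients over 10 years.
TOTAL_COST_DISCOUNTED = {
    "general_lipid": 1_666_228.0,
    "smi_lipid": 1_671_497.0,
    "general_bmi": 1_676_569.0,
    "smi_bmi": 1_659_340.0,
    "none": 1_712_136.0,
}

#: Mean undiscounted total cost (GBP) per 1000 patients over 10 years.
TOTAL_COST_UNDISCOUNTED = {
    "general_lipid": 1_929_885.0,
    "smi_lipid": 1_935_933.0,
    "general_bmi": 1_941_887.0,
    "smi_bmi": 1_921_859.0,
    "none": 1_985_044.0,
}

#: Mean discounted QALYs per 1000 patients over 10 years (printed rounded).
QALYS_DISCOUNTED = {
    "general_lipid": 6828.0,
    "smi_lipid": 6827.0,
    "general_bmi": 6826.0,
    "smi_bmi": 6830.0,
    "none": 6815.0,
}

#: Published mean NMB at £20 000 and £30 000 per QALY (computed in the
#: original analysis from unrounded QALYs, so they differ slightly from
#: wtp × rounded-QALYs − cost).
NMB = {
    20000.0: {
        "general_lipid": 134_898_309.0,
        "smi_lipid": 134_872_660.0,
        "general_bmi": 134_841_184.0,
        "smi_bmi": 134_942_106.0,
        "none": 134_593_353.0,
    },
    30000.0: {
        "general_lipid": 203_180_577.0,
        "smi_lipid": 203_144_739.0,
        "general_bmi": 203_100_060.0,
        "smi_bmi": 203_242_828.0,
        "none": 202_746_098.0,
    },
}

#: Mean event counts per 1000 patients over 10 years.
EVENTS = {
    "primary_nonfatal_chd": {
        "general_lipid": 81.87, "smi_lipid": 82.53, "general_bmi": 82.98,
        "smi_bmi": 81.25, "none": 87.57,
    },
    "primary_fatal_chd": {
        "general_lipid": 9.26, "smi_lipid": 9.33, "general_bmi": 9.38,
        "smi_bmi": 9.18, "none": 9.89,
    },
    "primary_nonfatal_stroke": {
        "general_lipid": 104.18, "smi_lipid": 104.64, "general_bmi": 104.92,
        "smi_bmi": 103.43, "none": 108.77,
    },
    "primary_fatal_stroke": {
        "general_lipid": 7.25, "smi_lipid": 7.27, "general_bmi": 7.30,
        "smi_bmi": 7.18, "none": 7.55,
    },
    "secondary_nonfatal": {
        "general_lipid": 14.77, "smi_lipid": 14.97, "general_bmi": 15.15,
        "smi_bmi": 14.48, "none": 17.20,
    },
    "secondary_fatal": {
        "general_lipid": 6.53, "smi_lipid": 6.64, "general_bmi": 6.65,
        "smi_bmi": 6.41, "none": 7.78,
    },
    "death_other": {
        "general_lipid": 119.43, "smi_lipid": 119.40, "general_bmi": 119.35,
        "smi_bmi": 119.40, "none": 119.05,
    },
}

#: Patients (of 1000) classified high risk at the 10% threshold, and how
#: many of those were not already on statins (new prescriptions).
HIGH_RISK_COUNTS = {
    "general_lipid": {"high": 268, "new_statin": 210},
    "smi_lipid": {"high": 241, "new_statin": 182},
    "general_bmi": {"high": 222, "new_statin": 175},
    "smi_bmi": {"high": 326, "new_statin": 255},
}


def primary_events(arm: str) -> float:
    """Total primary events (fatal + non-fatal, CHD + stroke) for an arm."""
    return (EVENTS["primary_nonfatal_chd"][arm] + EVENTS["primary_fatal_chd"][arm]
            + EVENTS["primary_nonfatal_stroke"][arm] + EVENTS["primary_fatal_stroke"][arm])


def secondary_events(arm: str) -> float:
    """Total secondary events (fatal + non-fatal) for an arm."""
    return EVENTS["secondary_nonfatal"][arm] + EVENTS["secondary_fatal"][arm]
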