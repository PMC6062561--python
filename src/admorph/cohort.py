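"""Subject inclusion/exclusion and disease-group stratification.

Longitudinal diagnosis trajectories (diagnosis per visit month) are mapped
to exactly one of the analysis groups HC, sMCI, pMCI, AD, or an explicit
exclusion with reason:

* any reversion to a less severe stage (AD -> MCI, MCI -> HC, ...) excludes
  the subject entirely;
* baseline early-MCI (EMCI) or subjective-memory-complaint (SMC) subjects
  are excluded;
* baseline MCI converting to AD within two years is progressive MCI (pMCI);
* baseline MCI still MCI at two years and at the last available diagnosis
  is stable MCI (sMCI); without an observed diagnosis at two years or later
  the subject is excluded (insufficient follow-up);
* baseline MCI converting later than two years is excluded (late converter);
* baseline HC subjects who later convert keep the HC label cross-sectionally
  but are flagged for exclusion from longitudinal analyses.

"Two years" is compared against visit months with a configurable window
(default +/- 3 months) to absorb visit-scheduling jitter.
"""

from __future__ import annotations

import pandas as pd

DIAGNOSES = ("HC", "SMC", "EMCI", "MCI", "AD")
_SEVERITY = {"HC": 0, "SMC": 1, "EMCI": 2, "MCI": 3, "AD": 4}

LABEL_COLUMNS = ["subject", "label", "reason", "include_longitudinal"]


def _stratify_one(months, dxs, conversion_months: float, window: float):
    """Label one trajectory; returns (label, reason, include_longitudinal)."""
    unknown = [d for d in dxs if d not in _SEVERITY]
    if unknown:
        raise ValueError(f"unknown diagnosis codes: {sorted(set(unknown))}")
    if len(months) != len(set(months)) or list(months) != sorted(months):
        raise ValueError("visit months must be strictly increasing")
    if months[0] != 0:
        raise ValueError("baseline visit (month 0) missing")

    sev = [_SEVERITY[d] for d in dxs]
    if any(b < a for a, b in zip(sev, sev[1:])):
        return "excluded", "reverter", False

    baseline = dxs[0]
    if baseline in ("EMCI", "SMC"):
        return "excluded", f"baseline_{baseline}", False

    if baseline == "AD":
        return "AD", "", True

    if baseline == "MCI":
        ad_months = [m for m, d in zip(months, dxs) if d == "AD"]
        if ad_months:
            if ad_months[0] <= conversion_months + window:
                return "pMCI", "", True
            return "excluded", "late_converter", False
        mci_late = [m for m, d in zip(months, dxs) if d == "MCI" and m >= conversion_months - window]
        if mci_late and dxs[-1] == "MCI":
            return "sMCI", "", True
        return "excluded", "insufficient_followup", False

    # baseline HC: converters stay HC cross-sectionally, drop longitudinally
    if any(d != "HC" for d in dxs):
        return "HC", "hc_converter", False
    return "HC", "", True


def stratify(
    trajectories: pd.DataFrame,
    conversion_months: float = 24.0,
    window: float = 3.0,
) -> pd.DataFrame:
    """Stratify a diagnosis table into analysis groups.

    ``trajectories`` has columns ``subject``, ``month`` and ``diagnosis``
    with diagnosis codes from {HC, SMC, EMCI, MCI, AD}.  Returns one row per
    subject with columns ``subject``, ``label`` (HC/sMCI/pMCI/AD/excluded),
    ``reason`` and ``include_longitudinal``.
    """
    required = {"subject", "month", "diagnosis"}
    missing = required - set(trajectories.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
    rows = []
    for subject, group in trajectories.sort_values("month").groupby("subject"):
        label, reason, longi = _stratify_one(
            list(group["month"]), list(group["diagnosis"]), conversion_months, window
        )
        rows.append(
            {"subject": subject, "label": label, "reason": reason,
             "include_longitudinal": longi}
        )
    return pd.DataFrame(rows, columns=LABEL_COLUMNS)
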