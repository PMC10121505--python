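"""Published per-stratum contingency counts for fracture detection.

True/false positive/negative counts of an automated insufficiency-fracture
classifier against a radiologist consensus reference, for 1000 lumbar
vertebral bodies in 200 patients, stratified by vertebral level, acquiring
institution, scanner vendor and magnetic field strength.  These counts are
the inputs from which all diagnostic-performance point estimates are
recomputed; no performance numbers are stored here.
"""

from __future__ import annotations

from .stats import ContingencyCounts

__all__ = ["FRACTURE_CONTINGENCY", "STRATUM_TOTALS", "expand_to_rows"]

#: (TP, FP, TN, FN) per stratum.
_RAW: dict[str, tuple[int, int, int, int]] = {
    "entire": (224, 24, 738, 14),
    "L1": (89, 5, 103, 3),
    "L2": (49, 12, 136, 3),
    "L3": (35, 2, 161, 2),
    "L4": (29, 3, 165, 3),
    "L5": (22, 2, 173, 3),
    "in-house": (112, 13, 365, 5),
    "outside": (112, 11, 373, 9),
    "Siemens": (113, 13, 369, 5),
    "GE": (50, 7, 162, 1),
    "Philips": (61, 4, 207, 8),
    "1.5T": (119, 9, 393, 9),
    "3.0T": (105, 15, 345, 5),
}

FRACTURE_CONTINGENCY: dict[str, ContingencyCounts] = {
    name: ContingencyCounts(tp=tp, fp=fp, tn=tn, fn=fn, stratum=name)
    for name, (tp, fp, tn, fn) in _RAW.items()
}

#: Printed per-stratum vertebra totals, for internal-consistency checks.
STRATUM_TOTALS: dict[str, int] = {
    "entire": 1000,
    "L1": 200, "L2": 200, "L3": 200, "L4": 200, "L5": 200,
    "in-house": 495, "outside": 505,
    "Siemens": 500, "GE": 220, "Philips": 280,
    "1.5T": 530, "3.0T": 470,
}


def expand_to_rows(counts: ContingencyCounts) -> list[dict]:
    """Expand a contingency row into per-vertebra predicted/reference labels."""
    rows = []
    for _ in range(counts.tp):
        rows.append({"stratum": counts.stratum, "predicted": 1, "reference": 1})
    for _ in range(counts.fp):
        rows.append({"stratum": counts.stratum, "predicted": 1, "reference": 0})
    for _ in range(counts.tn):
        rows.append({"stratum": counts.stratum, "predicted": 0, "reference": 0})
    for _ in range(counts.fn):
        rows.append({"stratum": counts.stratum, "predicted": 0, "reference": 1})
    return rows
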