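"""Dual-luciferase reporter normalization.

Each well's firefly (FLuc) reading is normalized to its Renilla (RLuc)
co-transfection control; technical replicates are averaged per construct,
and each construct's ratio is divided by the control construct's ratio.
When several plates (independent experiments) are supplied, the plate is
the unit of error: the across-plate mean +/- SE of the normalized value is
reported, mirroring triplicate-experiment error bars.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger("granulekit")


@dataclass
class Well:
    construct: str
    replicate: int
    fluc: float
    rluc: float


@dataclass
class PlateData:
    wells: list[Well]
    control: str

    def __post_init__(self) -> None:
        constructs = {w.construct for w in self.wells}
        if self.control not in constructs:
            raise ValueError(f"control {self.control!r} missing from plate")


def normalize_plate(plate: PlateData) -> dict[str, float]:
    """Per-construct FLuc/RLuc ratio normalized to the control construct.

    Wells with RLuc <= 0 are excluded with a warning; a control ratio of 0
    is fatal.  The control construct always normalizes to exactly 1.
    """
    ratios: dict[str, list[float]] = {}
    for w in plate.wells:
        if w.rluc <= 0:
            log.warning("excluding well %s/%d: RLuc = %g", w.construct,
                        w.replicate, w.rluc)
            continue
        ratios.setdefault(w.construct, []).append(w.fluc / w.rluc)
    if not ratios.get(plate.control):
        raise ValueError("no usable control wells")
    mean_ratio = {c: float(np.mean(v)) for c, v in ratios.items()}
    control_ratio = mean_ratio[plate.control]
    if control_ratio == 0:
        raise ValueError("control FLuc/RLuc ratio is 0; cannot normalize")
    return {c: r / control_ratio for c, r in mean_ratio.items()}


def normalize_reporter(plates: PlateData | list[PlateData]) -> dict[str, dict]:
    """Normalized ratio per construct, mean +/- SE across plates.

    A single plate yields SE 0 with ``se_defined=False``.
    """
    if isinstance(plates, PlateData):
        plates = [plates]
    per_plate = [normalize_plate(p) for p in plates]
    constructs = sorted({c for p in per_plate for c in p})
    out = {}
    for c in constructs:
        vals = np.array([p[c] for p in per_plate if c in p])
        n = len(vals)
        out[c] = dict(
            normalized_ratio=float(vals.mean()),
            se=float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            n_experiments=n,
            se_defined=n > 1,
        )
    return out
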