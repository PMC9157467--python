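"""Chemical-shift perturbation (CSP) mapping between two buffer conditions.

The combined amide perturbation per residue is

    delta = sqrt(ddH^2 + (ddN / nitrogen_scale)^2)    [ppm]

with the conventional nitrogen scale of 5. Residues are tiered by inclusive
thresholds (moderate >= 0.015 ppm, strong >= 0.020 ppm by default) and can be
mapped onto a structure through the B-factor column for coloring.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from hbondnmr.structio import Model, ShiftTable

logger = logging.getLogger(__name__)


class Tier(enum.Enum):
    NONE = 0
    MODERATE = 1
    STRONG = 2


@dataclass(frozen=True)
class CspConfig:
    nitrogen_scale: float = 5.0
    threshold_moderate: float = 0.015  # ppm
    threshold_strong: float = 0.020  # ppm

    def __post_init__(self):
        if self.nitrogen_scale <= 0:
            raise ValueError("nitrogen_scale must be positive")
        if not (0 < self.threshold_moderate <= self.threshold_strong):
            raise ValueError("need 0 < threshold_moderate <= threshold_strong")


@dataclass(frozen=True)
class CspRecord:
    residue_number: int
    ddH: float  # ppm, condition A minus condition B
    ddN: float  # ppm
    delta: float  # ppm, combined
    tier: Tier


@dataclass
class CspResult:
    records: list[CspRecord]
    unmatched_a: list[int]  # residues only in table A (e.g. broadened out in B)
    unmatched_b: list[int]


def _tier(delta: float, config: CspConfig) -> Tier:
    if delta >= config.threshold_strong:
        return Tier.STRONG
    if delta >= config.threshold_moderate:
        return Tier.MODERATE
    return Tier.NONE


def compute_csp(
    table_a: ShiftTable, table_b: ShiftTable, config: CspConfig = CspConfig()
) -> CspResult:
    """Per-residue combined perturbation between two shift tables.

    ddH/ddN are table A minus table B; residues present in only one table
    (or without shifts, e.g. prolines) are reported as unmatched, never
    silently dropped.
    """
    a = table_a.data.set_index("residue_number")
    b = table_b.data.set_index("residue_number")
    usable_a = set(a.index[np.isfinite(a["dH_ppm"]) & np.isfinite(a["dN_ppm"])])
    usable_b = set(b.index[np.isfinite(b["dH_ppm"]) & np.isfinite(b["dN_ppm"])])
    shared = sorted(usable_a & usable_b)
    if not shared:
        raise ValueError(
            f"tables {table_a.condition_label!r} and {table_b.condition_label!r} "
            "share no residues with measurable shifts"
        )
    records = []
    for resnum in shared:
        ddh = float(a.loc[resnum, "dH_ppm"] - b.loc[resnum, "dH_ppm"])
        ddn = float(a.loc[resnum, "dN_ppm"] - b.loc[resnum, "dN_ppm"])
        delta = float(np.hypot(ddh, ddn / config.nitrogen_scale))
        records.append(CspRecord(resnum, ddh, ddn, delta, _tier(delta, config)))
    return CspResult(
        records=records,
        unmatched_a=sorted(usable_a - usable_b),
        unmatched_b=sorted(usable_b - usable_a),
    )


def perturbed_residues(records: Sequence[CspRecord]) -> tuple[list[int], list[int]]:
    """Residue lists (moderate-or-stronger, strong) sorted by residue number."""
    moderate_plus = sorted(r.residue_number for r in records if r.tier != Tier.NONE)
    strong = sorted(r.residue_number for r in records if r.tier == Tier.STRONG)
    return moderate_plus, strong


def patch_compactness(
    residues: Sequence[int], model: Model
) -> tuple[np.ndarray, float]:
    """Centroid and maximum pairwise C-alpha distance of a residue set.

    A genuine interaction surface forms a spatially compact patch, so its
    max pairwise distance is small compared to an equally sized random
    residue selection. Residues without a C-alpha are skipped with a warning.
    """
    index = model.atom_index()
    coords = []
    chains = {a.chain_id for a in model.atoms}
    for resnum in residues:
        ca = None
        for chain_id in chains:
            ca = index.get((chain_id, resnum, "CA"))
            if ca is not None:
                break
        if ca is None:
            logger.warning("residue %d lacks CA; skipped in patch statistics", resnum)
            continue
        coords.append(ca.pos)
    if not coords:
        raise ValueError("no residues with CA atoms in selection")
    pts = np.vstack(coords)
    centroid = pts.mean(axis=0)
    max_dist = 0.0
    for i, j in combinations(range(len(pts)), 2):
        max_dist = max(max_dist, float(np.linalg.norm(pts[i] - pts[j])))
    return centroid, max_dist
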