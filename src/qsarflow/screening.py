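"""Candidate screening: activity ranking and pharmacokinetic rule gates.

Designed molecules are scored with the fitted activity model, compared
against a reference potency, and gated by classical rule-based filters:

* Lipinski's rule of five (MW <= 500, logP <= 5, HBD <= 5, HBA <= 10,
  inclusive bounds), with a configurable violation budget;
* blood-brain-barrier and CNS permeability three-way classifications on
  logBB and logPS with strict cutoffs;
* absorption/metabolism/toxicity gates (HIA, Caco-2, CYP2D6 inhibition,
  AMES mutagenicity, hepatotoxicity, skin sensitization).

ADMET endpoint values are *inputs* here — predicted by external services
— never computed from structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .applicability_domain import ADReport
from .dataset_io import Dataset
from .mlr_core import MLRModel, predict

__all__ = [
    "ADMETProfile",
    "ScreeningConfig",
    "ScreeningReport",
    "screen_candidates",
    "lipinski_profile",
    "bbb_cns_classify",
    "admet_gate",
]


@dataclass
class ADMETProfile:
    """Drug-likeness and pharmacokinetic endpoint values for one compound."""

    id: str
    logp: float
    mw: float
    hba: int
    hbd: int
    caco2: float | None = None  # log Papp in 10^-6 cm/s
    hia: float | None = None  # % absorbed
    logbb: float | None = None
    logps: float | None = None
    cyp2d6_inhibitor: bool | None = None
    total_clearance: float | None = None
    ames_toxic: bool | None = None
    ld50: float | None = None
    hepatotoxic: bool | None = None
    skin_sensitizer: bool | None = None

    def __post_init__(self):
        if self.hia is not None and not (0 <= self.hia <= 100):
            raise ValueError(f"{self.id}: HIA must lie in [0, 100], got {self.hia}")
        if self.hba < 0 or self.hbd < 0:
            raise ValueError(f"{self.id}: HBA/HBD must be non-negative")


@dataclass
class LipinskiBounds:
    mw_max: float = 500.0
    logp_max: float = 5.0
    hbd_max: int = 5
    hba_max: int = 10


@dataclass
class ScreeningConfig:
    """Reference potency and every rule threshold, in one place."""

    reference_pic50: float = 7.259
    lipinski: LipinskiBounds = field(default_factory=LipinskiBounds)
    max_lipinski_violations: int = 2
    logbb_permeant: float = 0.3
    logbb_poor: float = -1.0
    logps_penetrant: float = -2.0
    logps_blocked: float = -3.0
    hia_min: float = 80.0
    caco2_min: float = 0.9

    def __post_init__(self):
        if not self.logbb_poor < self.logbb_permeant:
            raise ValueError("logbb_poor must be below logbb_permeant")
        if not self.logps_blocked < self.logps_penetrant:
            raise ValueError("logps_blocked must be below logps_penetrant")


@dataclass
class ScreeningReport:
    """Ranked candidate predictions."""

    table: pd.DataFrame  # columns: id, predicted_pic50, improved, in_domain, rank
    reference_pic50: float


def screen_candidates(
    model: MLRModel,
    candidates: Dataset,
    cfg: ScreeningConfig | None = None,
    ad: ADReport | None = None,
) -> ScreeningReport:
    """Predict and rank candidate activities against the reference.

    Candidates are ranked by predicted pIC50 descending, ties broken by
    id; ``improved`` flags predictions strictly above the reference.  When
    an applicability-domain report is supplied, ``in_domain`` records
    whether each candidate's leverage stayed inside h*.
    """
    cfg = cfg or ScreeningConfig()
    rows = []
    for rec, role in zip(candidates.records, candidates.role_labels):
        if role != "candidate":
            continue
        pred = predict(model, rec.descriptors)
        in_domain = None
        if ad is not None and rec.id in ad.category:
            in_domain = ad.category[rec.id] == "inside"
        rows.append(
            {
                "id": rec.id,
                "predicted_pic50": pred,
                "improved": pred > cfg.reference_pic50,
                "in_domain": in_domain,
            }
        )
    table = pd.DataFrame(rows, columns=["id", "predicted_pic50", "improved", "in_domain"])
    if len(table):
        table = table.sort_values(
            ["predicted_pic50", "id"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        table["rank"] = np.arange(1, len(table) + 1)
    else:
        table["rank"] = pd.Series(dtype=int)
    return ScreeningReport(table=table, reference_pic50=cfg.reference_pic50)


def lipinski_profile(
    profile: ADMETProfile, cfg: ScreeningConfig | None = None
) -> tuple[int, bool]:
    """Count rule-of-five violations; pass iff within the violation budget.

    Bounds are inclusive: logP = 5.0 or MW = 500 are compliant.
    """
    cfg = cfg or ScreeningConfig()
    b = cfg.lipinski
    violations = sum(
        [
            profile.mw > b.mw_max,
            profile.logp > b.logp_max,
            profile.hbd > b.hbd_max,
            profile.hba > b.hba_max,
        ]
    )
    return violations, violations <= cfg.max_lipinski_violations


def bbb_cns_classify(
    profile: ADMETProfile, cfg: ScreeningConfig | None = None
) -> tuple[str, str]:
    """Three-way BBB (logBB) and CNS (logPS) classification.

    Strict cutoffs: logBB > 0.3 permeant, logBB < -1 poor, otherwise
    intermediate; logPS > -2 penetrant, logPS < -3 blocked, otherwise
    intermediate.
    """
    cfg = cfg or ScreeningConfig()
    if profile.logbb is None or profile.logps is None:
        raise ValueError(f"{profile.id}: logBB and logPS are required")
    if profile.logbb > cfg.logbb_permeant:
        bbb = "permeant"
    elif profile.logbb < cfg.logbb_poor:
        bbb = "poor"
    else:
        bbb = "intermediate"
    if profile.logps > cfg.logps_penetrant:
        cns = "penetrant"
    elif profile.logps < cfg.logps_blocked:
        cns = "blocked"
    else:
        cns = "intermediate"
    return bbb, cns


ADMET_RULES = ("hia", "caco2", "cyp2d6", "ames", "hepatotoxicity", "skin_sensitization")


def admet_gate(
    profile: ADMETProfile, cfg: ScreeningConfig | None = None
) -> dict[str, bool]:
    """Per-rule absorption/metabolism/toxicity verdicts plus the conjunction.

    Passing means: HIA above ``hia_min``, Caco-2 log permeability above
    ``caco2_min``, no CYP2D6 inhibition, AMES-negative, non-hepatotoxic
    and non-sensitizing.
    """
    cfg = cfg or ScreeningConfig()
    required = ["hia", "caco2", "cyp2d6_inhibitor", "ames_toxic", "hepatotoxic", "skin_sensitizer"]
    missing = [f for f in required if getattr(profile, f) is None]
    if missing:
        raise ValueError(f"{profile.id}: missing ADMET fields {missing}")
    verdicts = {
        "hia": profile.hia > cfg.hia_min,
        "caco2": profile.caco2 > cfg.caco2_min,
        "cyp2d6": not profile.cyp2d6_inhibitor,
        "ames": not profile.ames_toxic,
        "hepatotoxicity": not profile.hepatotoxic,
        "skin_sensitization": not profile.skin_sensitizer,
    }
    verdicts["overall"] = all(verdicts.values())
    return verdicts
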