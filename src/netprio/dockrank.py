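"""Docking-table ligand ranking, multi-target profiles, assay candidates.

Docking scores and MM-GBSA binding free energies are consumed as tabulated
inputs, never computed.  The primary ranking key is the docking score (more
negative is better); binding free energy only breaks ties and informs the
final assay-candidate choice among compounds that passed molecular-dynamics
triage (an externally supplied list — MD itself is out of scope).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

TOP_K_LIGANDS = 3

_TYPOGRAPHY = str.maketrans({"−": "-", "′": "'", "″": '"'})


def _key(name: str) -> str:
    """ASCII-normalized compound key (typographic primes/minus mapped)."""
    return str(name).translate(_TYPOGRAPHY)


@dataclass(frozen=True)
class DockingRecord:
    """One compound x target row of a docking result table."""

    compound_name: str
    compound_id: str
    formula: str
    mz: float
    rt_min: float
    target: str
    docking_score: float
    dg_bind: float

    def __post_init__(self) -> None:
        if not self.target:
            raise ValidationError("target must be non-empty")
        for name in ("docking_score", "dg_bind"):
            value = getattr(self, name)
            if value is None or value != value or abs(value) == float("inf"):
                raise ValidationError(f"{name} must be finite, got {value!r}")

    @property
    def compound_key(self) -> str:
        return _key(self.compound_name)


@dataclass
class LigandProfile:
    """Cross-target profile of one compound appearing in any top-k set."""

    compound_name: str
    targets_hit: set[str] = field(default_factory=set)
    best_scores: dict[str, tuple[float, float]] = field(default_factory=dict)


def records_from_frame(df: pd.DataFrame) -> list[DockingRecord]:
    """Build DockingRecords from a docking table frame."""
    return [DockingRecord(row["compound_name"], row.get("compound_id", ""),
                          row.get("formula", ""), float(row.get("mz", float("nan")) or 0.0),
                          float(row.get("rt_min", 0.0) or 0.0), row["target"],
                          float(row["docking_score"]), float(row["dg_bind"]))
            for _, row in df.iterrows()]


def rank_ligands(records: list[DockingRecord], target: str,
                 k: int = TOP_K_LIGANDS) -> list[DockingRecord]:
    """Top-k ligands for a target by ascending docking score.

    Ties break by ascending binding free energy, then compound name.  An
    unknown target yields an empty list with a warning.
    """
    rows = [r for r in records if r.target == target]
    if not rows:
        logger.warning("no docking records for target %r", target)
        return []
    rows.sort(key=lambda r: (r.docking_score, r.dg_bind, r.compound_key))
    return rows[:k]


def multitarget_profile(records: list[DockingRecord],
                        k: int = TOP_K_LIGANDS) -> dict[str, LigandProfile]:
    """Cross-target profiles of every compound in any per-target top-k set.

    Keyed by the ASCII-normalized compound name; the display name keeps the
    original typography.
    """
    targets = sorted({r.target for r in records})
    profiles: dict[str, LigandProfile] = {}
    for target in targets:
        for rec in rank_ligands(records, target, k):
            prof = profiles.setdefault(rec.compound_key,
                                       LigandProfile(compound_name=rec.compound_name))
            prof.targets_hit.add(target)
            prof.best_scores[target] = (rec.docking_score, rec.dg_bind)
    return profiles


def select_assay_candidates(profiles: dict[str, LigandProfile],
                            records: list[DockingRecord],
                            md_pass: set[str] | None = None,
                            k: int = TOP_K_LIGANDS) -> dict[str, str]:
    """One assay candidate per target, deduplicated across targets by name.

    For each target, the member of its top-k set with the best (lowest)
    binding free energy among the externally supplied MD-pass compound list.
    An empty MD-pass list falls back to the docking-rank-1 compound with a
    warning.  Returns {target: compound_name}; the union of values is the
    deduplicated assay set.
    """
    md_keys = {_key(name) for name in md_pass} if md_pass else set()
    candidates: dict[str, str] = {}
    for target in sorted({r.target for r in records}):
        top = rank_ligands(records, target, k)
        if not top:
            continue
        eligible = [r for r in top if r.compound_key in md_keys]
        if not eligible:
            if md_keys:
                logger.warning("target %s: no top-%d compound passed MD; "
                               "falling back to docking rank 1", target, k)
            else:
                logger.warning("target %s: empty MD-pass list; using docking rank 1", target)
            candidates[target] = top[0].compound_name
            continue
        eligible.sort(key=lambda r: (r.dg_bind, r.compound_key))
        candidates[target] = eligible[0].compound_name
    return candidates


def assay_set(candidates: dict[str, str]) -> set[str]:
    """Deduplicated union of per-target assay candidates (normalized names)."""
    return {_key(name) for name in candidates.values()}
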