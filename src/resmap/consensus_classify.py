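"""Threshold classification of residue contributions and replicate consensus.

A residue contributes substantially through a channel when the corresponding
energy clears its threshold (inclusive):

    sc_elec : side-chain electrostatics  >= 1.0 kcal/mol
    mc_elec : main-chain electrostatics  >= 1.0 kcal/mol
    np      : non-polar (buried surface) >= 0.5 kcal/mol

The three flags map bijectively onto seven non-empty categories (plus
``none``). Consensus across biological replicates is flag-wise majority
voting (configurable fraction, default 0.5) over the replicates in which the
position is resolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

from .electrostatics import ElecRecord
from .nonpolar import NonpolarRecord

__all__ = [
    "Thresholds",
    "ContributionCall",
    "ConsensusRecord",
    "CATEGORIES",
    "classify_residue",
    "consensus",
    "count_contributors",
]


@dataclass(frozen=True)
class Thresholds:
    elec: float = 1.0  # kcal/mol, applies to sc and mc electrostatics
    nonpolar: float = 0.5  # kcal/mol


# flag triple (sc_elec, mc_elec, np) -> category label
CATEGORIES: dict[tuple[bool, bool, bool], str] = {
    (False, False, False): "none",
    (False, False, True): "np",
    (True, False, False): "sc_elec",
    (False, True, False): "mc_elec",
    (True, True, False): "sc+mc_elec",
    (True, False, True): "sc_elec+np",
    (False, True, True): "mc_elec+np",
    (True, True, True): "sc+mc_elec+np",
}

# molecular-viewer palette for the seven contributing categories
CATEGORY_COLORS: dict[str, str] = {
    "np": "green",
    "sc_elec": "red",
    "mc_elec": "yellow",
    "sc+mc_elec": "orange",
    "sc_elec+np": "magenta",
    "mc_elec+np": "cyan",
    "sc+mc_elec+np": "purple",
}


@dataclass
class ContributionCall:
    residue_id: Hashable
    res_name: str
    sc_elec: bool
    mc_elec: bool
    np: bool
    category: str
    elec: ElecRecord | None = None
    nonpolar: NonpolarRecord | None = None

    @property
    def contributes(self) -> bool:
        return self.category != "none"


def classify_residue(
    elec: ElecRecord | None,
    nonpolar: NonpolarRecord | None,
    thresholds: Thresholds = Thresholds(),
) -> ContributionCall:
    """Apply the contribution thresholds to one residue's energy records.

    Either record may be absent (treated as zero contribution through that
    channel); when both are present they must refer to the same residue.
    """
    if elec is None and nonpolar is None:
        raise ValueError("need at least one energy record")
    if elec is not None and nonpolar is not None and elec.residue_id != nonpolar.residue_id:
        raise ValueError(
            f"mismatched residues: {elec.residue_id} vs {nonpolar.residue_id}"
        )
    rid = elec.residue_id if elec is not None else nonpolar.residue_id
    name = elec.res_name if elec is not None else nonpolar.res_name
    sc = bool(elec is not None and elec.ddg_elec_sc >= thresholds.elec)
    mc = bool(elec is not None and elec.ddg_elec_mc >= thresholds.elec)
    np_flag = bool(nonpolar is not None and nonpolar.ddg_np >= thresholds.nonpolar)
    return ContributionCall(
        residue_id=rid,
        res_name=name,
        sc_elec=sc,
        mc_elec=mc,
        np=np_flag,
        category=CATEGORIES[(sc, mc, np_flag)],
        elec=elec,
        nonpolar=nonpolar,
    )


@dataclass
class ConsensusRecord:
    position: Hashable  # reference position (or residue id)
    res_name: str
    calls: list[ContributionCall | None]  # one slot per replicate; None = unresolved
    consensus_flags: tuple[bool, bool, bool]
    consensus_category: str
    support: tuple[float, float, float] | None  # per-flag support fraction; None if unresolved

    @property
    def contributes(self) -> bool:
        return self.consensus_category != "none"


def consensus(
    calls_by_replicate: Sequence[Mapping[Hashable, ContributionCall]],
    fraction: float = 0.5,
) -> list[ConsensusRecord]:
    """Fuse per-replicate contribution calls into consensus records.

    Each flag is set iff it is supported in at least ``fraction`` of the
    replicates in which the position is resolved; unresolved positions are
    excluded from the denominator. A position resolved in no replicate is
    reported with category ``none`` and undefined support.
    """
    if not calls_by_replicate:
        raise ValueError("need at least one replicate")
    positions: dict[Hashable, None] = {}
    for rep in calls_by_replicate:
        for pos in rep:
            positions.setdefault(pos)

    records = []
    for pos in positions:
        slots = [rep.get(pos) for rep in calls_by_replicate]
        resolved = [c for c in slots if c is not None]
        if not resolved:
            records.append(
                ConsensusRecord(pos, "?", slots, (False, False, False), "none", None)
            )
            continue
        n = len(resolved)
        support = (
            float(sum(bool(c.sc_elec) for c in resolved)) / n,
            float(sum(bool(c.mc_elec) for c in resolved)) / n,
            float(sum(bool(c.np) for c in resolved)) / n,
        )
        flags = tuple(bool(s >= fraction and s > 0) for s in support)
        records.append(
            ConsensusRecord(
                position=pos,
                res_name=resolved[0].res_name,
                calls=slots,
                consensus_flags=flags,  # type: ignore[arg-type]
                consensus_category=CATEGORIES[flags],  # type: ignore[index]
                support=support,
            )
        )
    return records


def count_contributors(
    records: Sequence[ConsensusRecord],
    side_chains: set[str] | None = None,
) -> int:
    """Number of consensus contributors (category != none), optionally
    restricted to positions whose chain id is in ``side_chains`` (positions
    are expected to be (chain, resseq, icode) triples in that case)."""
    n = 0
    for rec in records:
        if not rec.contributes:
            continue
        if side_chains is not None:
            chain = rec.position[0] if isinstance(rec.position, tuple) else None
            if chain not in side_chains:
                continue
        n += 1
    return n
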