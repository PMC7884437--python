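"""End-to-end orchestration: from structures (files or synthetic) to
consensus residue maps, cross-interface region assignment and reports.

The pipeline per replicate is: read -> place polar hydrogens -> assign
parameters -> interface shell -> buried-area (ddG_np) -> FDPB charge
deletions (ddG_elec, whole residue and side chain) -> threshold
classification; calls are then fused across replicates into a consensus map.
Replicate positions are keyed by (side, resseq, icode), i.e. replicates of
the same complex are expected to share residue numbering.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import consensus_classify as cc
from . import electrostatics as es
from . import nonpolar as npl
from . import structmotif as sm
from . import structure_model as smod
from . import synthetic_data as syn

logger = logging.getLogger("resmap")

__all__ = [
    "RunConfig",
    "ResidueMap",
    "run_complex_map",
    "assign_partner_regions",
    "write_reports",
    "residue_map_to_json",
    "residue_map_from_json",
]


@dataclass
class StructureInput:
    path: str
    side_a: list[str]
    side_b: list[str]
    model_index: int = 0


@dataclass
class RunConfig:
    """Everything one analysis run needs; loadable from YAML."""

    seed: int = 0
    output_dir: str = "resmap_out"
    structures: list[StructureInput] = field(default_factory=list)
    synthetic: syn.SyntheticSpec | None = None
    n_noisy_replicates: int = 0  # extra noisy copies of a synthetic dimer
    environment: es.PBEnvironment = field(default_factory=es.PBEnvironment)
    protocol: es.GridProtocol = field(default_factory=es.GridProtocol)
    thresholds: cc.Thresholds = field(default_factory=cc.Thresholds)
    consensus_fraction: float = 0.5
    shell_cutoff: float = 15.0
    sasa_probe: float = 1.4
    sasa_n_points: int = 960
    parameter_table_path: str | None = None
    strict_parameters: bool = True
    keep_hetero: bool = False
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    long_range_cutoff: float = 5.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        kwargs: dict[str, Any] = {}
        for key in (
            "seed", "output_dir", "n_noisy_replicates", "consensus_fraction",
            "shell_cutoff", "sasa_probe", "sasa_n_points", "parameter_table_path",
            "strict_parameters", "keep_hetero", "long_range_cutoff",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "structures" in raw:
            kwargs["structures"] = [StructureInput(**s) for s in raw["structures"]]
        if "synthetic" in raw and raw["synthetic"] is not None:
            s = dict(raw["synthetic"])
            for key in ("saltbridges", "burial_only", "loop_span"):
                if key in s:
                    s[key] = tuple(tuple(x) for x in s[key]) if key != "loop_span" else tuple(s[key])
            kwargs["synthetic"] = syn.SyntheticSpec(**s)
        if "environment" in raw:
            kwargs["environment"] = es.PBEnvironment(**raw["environment"])
        if "protocol" in raw:
            kwargs["protocol"] = es.GridProtocol(**raw["protocol"])
        if "thresholds" in raw:
            kwargs["thresholds"] = cc.Thresholds(**raw["thresholds"])
        if "regions" in raw:
            kwargs["regions"] = {k: tuple(v) for k, v in raw["regions"].items()}
        return cls(**kwargs)


PositionKey = tuple[str, int, str]  # (side letter, resseq, icode)


@dataclass
class ResidueMap:
    """Consensus residue map of one complex, both interface sides."""

    records: list[cc.ConsensusRecord]  # positions keyed (side, resseq, icode)
    replicate_labels: list[str]
    annotations: dict[str, Any] = field(default_factory=dict)
    region_assignments: dict[PositionKey, dict[str, Any]] = field(default_factory=dict)

    def side_records(self, side: str) -> list[cc.ConsensusRecord]:
        return [r for r in self.records if r.position[0] == side]

    def contributor_positions(self, side: str | None = None) -> set[PositionKey]:
        return {
            r.position
            for r in self.records
            if r.contributes and (side is None or r.position[0] == side)
        }


def _gather_replicates(config: RunConfig) -> list[tuple[smod.DimerReplicate, str]]:
    table = smod.load_parameter_table(config.parameter_table_path)
    replicates: list[tuple[smod.DimerReplicate, str]] = []
    for s in config.structures:
        raw = smod.read_structure(
            Path(s.path).read_text(), model_index=s.model_index, keep_hetero=config.keep_hetero
        )
        prepared = smod.assign_parameters(
            smod.place_polar_hydrogens(raw), table, strict=config.strict_parameters
        )
        rep = smod.DimerReplicate(
            prepared, frozenset(s.side_a), frozenset(s.side_b), label=Path(s.path).name
        )
        replicates.append((rep, rep.label))
    if config.synthetic is not None:
        base, _ = syn.make_helix_dimer(config.synthetic)
        replicates.append((base, base.label))
        if config.n_noisy_replicates > 0:
            for i, rep in enumerate(
                syn.make_replicates(
                    base,
                    config.n_noisy_replicates,
                    config.synthetic.noise_sigma,
                    seed=config.seed,
                )
            ):
                replicates.append((rep, rep.label))
    if not replicates:
        raise ValueError("no input structures (configure 'structures' or 'synthetic')")
    return replicates


def map_replicate_calls(
    replicate: smod.DimerReplicate,
    config: RunConfig,
) -> dict[PositionKey, cc.ContributionCall]:
    """Run energies + classification for one replicate."""
    t0 = time.time()
    shell = es.interface_shell(replicate, cutoff=config.shell_cutoff)
    mono_a, mono_b = smod.split_complex(replicate)
    np_records = {
        r.residue_id: r
        for r in npl.buried_area_per_residue(
            replicate.complex, mono_a, mono_b,
            probe=config.sasa_probe, n_points=config.sasa_n_points,
            threshold=config.thresholds.nonpolar,
        )
    }
    elec_records = {
        r.residue_id: r
        for r in es.residue_scan(
            replicate, config.environment, config.protocol, shell=shell
        )
    }
    calls: dict[PositionKey, cc.ContributionCall] = {}
    for rid in shell:
        call = cc.classify_residue(
            elec_records.get(rid), np_records.get(rid), config.thresholds
        )
        key = (replicate.side_of(rid), rid[1], rid[2])
        calls[key] = call
    logger.info(
        "replicate %s: %d shell residues, %d contributors, %.1f s",
        replicate.label, len(shell), sum(c.contributes for c in calls.values()),
        time.time() - t0,
    )
    return calls


def run_complex_map(config: RunConfig) -> ResidueMap:
    """Execute the full per-complex analysis and consensus fusion."""
    replicates = _gather_replicates(config)
    calls_by_rep = []
    for rep, label in replicates:
        try:
            calls_by_rep.append(map_replicate_calls(rep, config))
        except Exception as exc:
            raise RuntimeError(f"replicate {label} failed during analysis: {exc}") from exc
    records = cc.consensus(calls_by_rep, fraction=config.consensus_fraction)
    records.sort(key=lambda r: (r.position[0], r.position[1], r.position[2]))
    rmap = ResidueMap(records, [label for _, label in replicates])
    if config.regions:
        assign_partner_regions(rmap, config.regions, replicates[0][0], config.long_range_cutoff)
    return rmap


def assign_partner_regions(
    rmap: ResidueMap,
    regions: dict[str, tuple[int, int]],
    replicate: smod.DimerReplicate,
    long_range_cutoff: float = 5.0,
) -> dict[PositionKey, dict[str, Any]]:
    """Assign each contributing side-A residue to a named side-B region.

    The region is the one containing the closest (minimum heavy-atom
    distance) *contributing* side-B residue; the pair is flagged long-range
    when that distance exceeds ``long_range_cutoff`` (electrostatic
    interactions can act across > 5 A of solvent).
    """
    spans = sorted(regions.items(), key=lambda kv: kv[1][0])
    for (n1, s1), (n2, s2) in zip(spans, spans[1:]):
        if s1[1] >= s2[0]:
            raise ValueError(f"overlapping region definitions: {n1} and {n2}")

    cx = replicate.complex
    heavy = cx.heavy_mask
    coords = cx.coords

    def residue_coords(key: PositionKey) -> np.ndarray | None:
        side_chains = replicate.side_a_chains if key[0] == "A" else replicate.side_b_chains
        for chain in side_chains:
            rid = (chain, key[1], key[2])
            if rid in cx.residues:
                idx = [i for i in cx.residues[rid] if heavy[i]]
                return coords[idx]
        return None

    contributors_b = [
        r for r in rmap.side_records("B") if r.contributes
    ]
    out: dict[PositionKey, dict[str, Any]] = {}
    for rec in rmap.side_records("A"):
        if not rec.contributes:
            continue
        xa = residue_coords(rec.position)
        best: tuple[float, PositionKey] | None = None
        for other in contributors_b:
            xb = residue_coords(other.position)
            if xa is None or xb is None:
                continue
            d = float(np.sqrt(((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2).min()))
            if best is None or d < best[0]:
                best = (d, other.position)
        if best is None:
            logger.warning("no contributing partner residues for %s", rec.position)
            out[rec.position] = {"region": None, "partner": None, "distance": None, "long_range": None}
            continue
        d, partner = best
        region = next(
            (name for name, (lo, hi) in regions.items() if lo <= partner[1] <= hi), None
        )
        out[rec.position] = {
            "region": region,
            "partner": list(partner),
            "distance": round(d, 3),
            "long_range": d > long_range_cutoff,
        }
    rmap.region_assignments = out
    return out


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def _record_row(rec: cc.ConsensusRecord) -> dict[str, Any]:
    resolved = [c for c in rec.calls if c is not None]
    mean = lambda vals: round(float(np.mean(vals)), 4) if vals else None
    return {
        "side": rec.position[0],
        "resseq": rec.position[1],
        "icode": rec.position[2],
        "res_name": rec.res_name,
        "consensus_category": rec.consensus_category,
        "sc_elec": rec.consensus_flags[0],
        "mc_elec": rec.consensus_flags[1],
        "np": rec.consensus_flags[2],
        "support_sc": None if rec.support is None else round(rec.support[0], 3),
        "support_mc": None if rec.support is None else round(rec.support[1], 3),
        "support_np": None if rec.support is None else round(rec.support[2], 3),
        "n_resolved": len(resolved),
        "ddg_elec_sc_mean": mean([c.elec.ddg_elec_sc for c in resolved if c.elec]),
        "ddg_elec_mc_mean": mean([c.elec.ddg_elec_mc for c in resolved if c.elec]),
        "ddg_elec_res_mean": mean([c.elec.ddg_elec_res for c in resolved if c.elec]),
        "ddg_np_mean": mean([c.nonpolar.ddg_np for c in resolved if c.nonpolar]),
        "buried_area_mean": mean([c.nonpolar.buried_area for c in resolved if c.nonpolar]),
        "replicate_categories": ";".join(
            "-" if c is None else c.category for c in rec.calls
        ),
        "replicate_energies": [
            None
            if c is None
            else {
                "ddg_elec_sc": None if c.elec is None else c.elec.ddg_elec_sc,
                "ddg_elec_res": None if c.elec is None else c.elec.ddg_elec_res,
                "ddg_np": None if c.nonpolar is None else c.nonpolar.ddg_np,
                "buried_area": None if c.nonpolar is None else c.nonpolar.buried_area,
            }
            for c in rec.calls
        ],
    }


def residue_map_to_json(rmap: ResidueMap) -> str:
    doc = {
        "replicates": rmap.replicate_labels,
        "annotations": rmap.annotations,
        "region_assignments": {
            "|".join(map(str, k)): v for k, v in sorted(rmap.region_assignments.items())
        },
        "records": [_record_row(r) for r in rmap.records],
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def residue_map_from_json(text: str) -> ResidueMap:
    """Rebuild a ResidueMap (consensus level; per-replicate energies are kept
    only as category strings) from its JSON report."""
    doc = json.loads(text)
    records = []
    for row in doc["records"]:
        flags = (row["sc_elec"], row["mc_elec"], row["np"])
        support = (
            None
            if row["support_sc"] is None
            else (row["support_sc"], row["support_mc"], row["support_np"])
        )
        calls: list[cc.ContributionCall | None] = []
        energies = row.get("replicate_energies") or [None] * len(
            row["replicate_categories"].split(";")
        )
        for cat, en in zip(row["replicate_categories"].split(";"), energies):
            if cat == "-":
                calls.append(None)
                continue
            inv = {v: k for k, v in cc.CATEGORIES.items()}[cat]
            rid = (row["side"], row["resseq"], row["icode"])
            elec_rec = None
            np_rec = None
            if en is not None and en["ddg_elec_res"] is not None:
                from .electrostatics import ElecRecord

                elec_rec = ElecRecord(
                    rid, row["res_name"], en["ddg_elec_res"], en["ddg_elec_sc"]
                )
            if en is not None and en["ddg_np"] is not None:
                from .nonpolar import NonpolarRecord

                np_rec = NonpolarRecord(
                    rid, row["res_name"], en["buried_area"], en["ddg_np"],
                    bool(inv[2]),
                )
            calls.append(
                cc.ContributionCall(
                    residue_id=rid,
                    res_name=row["res_name"],
                    sc_elec=inv[0], mc_elec=inv[1], np=inv[2],
                    category=cat,
                    elec=elec_rec,
                    nonpolar=np_rec,
                )
            )
        records.append(
            cc.ConsensusRecord(
                position=(row["side"], row["resseq"], row["icode"]),
                res_name=row["res_name"],
                calls=calls,
                consensus_flags=flags,
                consensus_category=row["consensus_category"],
                support=support,
            )
        )
    rmap = ResidueMap(records, doc["replicates"], doc.get("annotations", {}))
    rmap.region_assignments = {
        tuple(_coerce(k)): v for k, v in doc.get("region_assignments", {}).items()
    }
    return rmap


def _coerce(key: str) -> tuple:
    side, resseq, icode = (key.split("|") + [""])[:3]
    return (side, int(resseq), icode)


PYMOL_PALETTE = cc.CATEGORY_COLORS


def write_reports(
    rmap: ResidueMap,
    output_dir: str | Path,
    formats: tuple[str, ...] = ("tsv", "json", "pml"),
) -> list[Path]:
    """Write the residue map as TSV, JSON and a molecular-viewer coloring
    script (seven-category palette). Byte-stable for equal inputs."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if "tsv" in formats:
        df = pd.DataFrame([_record_row(r) for r in rmap.records])
        p = outdir / "residue_map.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    if "json" in formats:
        p = outdir / "residue_map.json"
        p.write_text(residue_map_to_json(rmap))
        written.append(p)
    if "pml" in formats:
        lines = ["# consensus contribution categories", "color grey80, polymer"]
        for rec in rmap.records:
            if not rec.contributes:
                continue
            color = PYMOL_PALETTE[rec.consensus_category]
            lines.append(
                f"color {color}, (resi {rec.position[1]})  # side {rec.position[0]}"
                f" {rec.res_name} {rec.consensus_category}"
            )
        p = outdir / "color_by_category.pml"
        p.write_text("\n".join(lines) + "\n")
        written.append(p)
    return written
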