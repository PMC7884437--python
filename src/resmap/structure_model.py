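"""Atomic models of protein complexes for interface energy mapping.

Reads PDB coordinate files into a light-weight atomic model, places polar
(backbone amide) hydrogens, assigns partial charges and radii from a bundled
PARSE-style parameter table, splits complexes rigidly into their monomers and
enumerates replicate dimers from multi-copy asymmetric units.

Residue identity is the author numbering triple ``(chain_id, resseq, icode)``
throughout; coordinates are in Angstrom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "ParameterizedStructure",
    "DimerReplicate",
    "ParameterTable",
    "PDBParseError",
    "ParameterError",
    "load_parameter_table",
    "read_structure",
    "place_polar_hydrogens",
    "assign_parameters",
    "split_complex",
    "enumerate_replicates",
    "write_pqr",
    "read_pqr",
]

# Backbone atom names; their attached hydrogens are matched by prefix below.
BACKBONE_HEAVY = {"N", "CA", "C", "O", "OXT"}
BACKBONE_HYDROGENS = {"H", "HN", "H1", "H2", "H3", "HA", "HA2", "HA3"}

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

NOMINAL_CHARGE = {"ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

ResidueId = tuple[str, int, str]


class PDBParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class ParameterError(KeyError):
    """Raised when charge/radius assignment fails in strict mode."""


@dataclass
class Atom:
    """A single atom with optional charge/radius parameterization."""

    serial: int
    name: str
    element: str
    residue_id: ResidueId
    res_name: str
    coords: np.ndarray
    charge: float = 0.0
    radius: float = 0.0
    is_sidechain: bool = False
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} {self.name}: bad coordinates")


def _is_backbone(name: str) -> bool:
    return name in BACKBONE_HEAVY or name in BACKBONE_HYDROGENS


@dataclass
class ParameterizedStructure:
    """Ordered collection of atoms with a residue index.

    The same class holds both raw (unparameterized) and parameterized models;
    ``assign_parameters`` fills charges and radii in place of the zero
    defaults.
    """

    atoms: list[Atom]
    provenance: str = ""

    def __post_init__(self) -> None:
        self._index_residues()

    def _index_residues(self) -> None:
        self.residues: dict[ResidueId, list[int]] = {}
        for i, atom in enumerate(self.atoms):
            self.residues.setdefault(atom.residue_id, []).append(i)

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for rid in self.residues:
            seen.setdefault(rid[0])
        return list(seen)

    def residue_name(self, rid: ResidueId) -> str:
        return self.atoms[self.residues[rid][0]].res_name

    def residue_atoms(self, rid: ResidueId) -> list[Atom]:
        return [self.atoms[i] for i in self.residues[rid]]

    # -- array views used by the numerical modules -------------------------
    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([not a.is_hydrogen for a in self.atoms], dtype=bool)

    def chain_mask(self, chains: Iterable[str]) -> np.ndarray:
        chain_set = set(chains)
        return np.array([a.residue_id[0] in chain_set for a in self.atoms], dtype=bool)

    def subset(self, mask: np.ndarray, provenance: str | None = None) -> "ParameterizedStructure":
        atoms = [replace(a, coords=a.coords.copy()) for a, m in zip(self.atoms, mask) if m]
        return ParameterizedStructure(atoms, provenance or self.provenance)

    def net_residue_charges(self) -> dict[ResidueId, float]:
        return {rid: sum(self.atoms[i].charge for i in idx) for rid, idx in self.residues.items()}


@dataclass
class DimerReplicate:
    """A two-sided complex: one biological replicate of the dimer."""

    complex: ParameterizedStructure
    side_a_chains: frozenset[str]
    side_b_chains: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        self.side_a_chains = frozenset(self.side_a_chains)
        self.side_b_chains = frozenset(self.side_b_chains)
        if not self.side_a_chains or not self.side_b_chains:
            raise ValueError("both sides of a dimer replicate need at least one chain")
        if self.side_a_chains & self.side_b_chains:
            raise ValueError("side_a and side_b chain sets overlap")
        covered = self.side_a_chains | self.side_b_chains
        present = set(self.complex.chains)
        if covered != present:
            raise ValueError(
                f"replicate sides {sorted(covered)} do not cover complex chains {sorted(present)}"
            )

    def side_of(self, rid: ResidueId) -> str:
        return "A" if rid[0] in self.side_a_chains else "B"


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _prevalidate_pdb(pdb_text: str) -> None:
    # gemmi silently coerces malformed numeric fields; enforce the error
    # contract (name the offending line) with a fixed-column pre-scan.
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: truncated {rec} record")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise PDBParseError(
                    f"line {lineno}: non-numeric {what} coordinate field {line[lo:hi]!r}"
                ) from None


def read_structure(
    pdb_text: str,
    model_index: int = 0,
    keep_hetero: bool = False,
) -> ParameterizedStructure:
    """Parse PDB text into a raw (charge/radius-free) structure.

    One atom per ATOM/HETATM record of the selected model. Alternate
    locations are resolved to the highest-occupancy conformer (ties resolved
    to the first listed); waters are always dropped and non-protein
    heteroatoms are dropped unless ``keep_hetero`` is set.
    """
    _prevalidate_pdb(pdb_text)
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(str(exc)) from exc
    if len(st) == 0:
        raise PDBParseError("no models in PDB text")
    if not 0 <= model_index < len(st):
        raise PDBParseError(f"model index {model_index} out of range (have {len(st)})")
    model = st[model_index]

    atoms: list[Atom] = []
    serial = 0
    n_records = 0
    for chain in model:
        for residue in chain:
            name = residue.name.strip()
            if name in WATER_NAMES or residue.is_water():
                continue
            if name not in STANDARD_RESIDUES and not keep_hetero:
                continue
            rid: ResidueId = (
                chain.name,
                residue.seqid.num,
                (residue.seqid.icode or " ").strip() or "",
            )
            # altloc resolution: highest occupancy, ties -> first listed
            best: dict[str, gemmi.Atom] = {}
            for at in residue:
                n_records += 1
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ + 1e-9:
                    best[at.name] = at
            for at in best.values():
                serial += 1
                el = at.element.name.upper() if at.element else ""
                is_h = el == "H" or at.name.startswith("H")
                atoms.append(
                    Atom(
                        serial=serial,
                        name=at.name,
                        element=el or at.name[0],
                        residue_id=rid,
                        res_name=name,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        is_sidechain=not _is_backbone(at.name) and name in STANDARD_RESIDUES,
                        is_hydrogen=is_h,
                    )
                )
    if not atoms:
        raise PDBParseError(f"model {model_index} contains no retained atoms")
    return ParameterizedStructure(atoms, provenance=f"{st.name or 'pdb'}:model{model_index}")


# ---------------------------------------------------------------------------
# Polar hydrogen placement
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("zero-length vector")
    return v / n


def place_polar_hydrogens(structure: ParameterizedStructure) -> ParameterizedStructure:
    """Place backbone amide hydrogens geometrically.

    The amide H is put 1.0 A from N along the external bisector of the
    C(prev)-N-CA angle, i.e. in the peptide plane and anti to the preceding
    carbonyl. Existing hydrogens are preserved (idempotent); N-terminal
    residues and prolines get no amide H.
    """
    atoms = [replace(a, coords=a.coords.copy()) for a in structure.atoms]
    out = ParameterizedStructure(atoms, structure.provenance)
    by_chain: dict[str, list[ResidueId]] = {}
    for rid in out.residues:
        by_chain.setdefault(rid[0], []).append(rid)

    new_atoms: list[Atom] = []
    for chain_rids in by_chain.values():
        prev_c: np.ndarray | None = None
        for rid in chain_rids:
            res_atoms = {a.name: a for a in out.residue_atoms(rid)}
            res_name = out.residue_name(rid)
            has_h = any(n in res_atoms for n in ("H", "HN"))
            if res_name != "PRO" and not has_h:
                if prev_c is None:
                    warnings.warn(
                        f"no preceding carbonyl for {rid}: amide H not placed", stacklevel=2
                    )
                elif "N" not in res_atoms or "CA" not in res_atoms:
                    warnings.warn(f"missing backbone atoms in {rid}: skipped", stacklevel=2)
                else:
                    n_pos = res_atoms["N"].coords
                    try:
                        direction = _unit(_unit(n_pos - prev_c) + _unit(n_pos - res_atoms["CA"].coords))
                        new_atoms.append(
                            Atom(
                                serial=0,
                                name="H",
                                element="H",
                                residue_id=rid,
                                res_name=res_name,
                                coords=n_pos + direction,
                                is_sidechain=False,
                                is_hydrogen=True,
                            )
                        )
                    except ValueError:
                        warnings.warn(f"degenerate backbone geometry in {rid}: skipped", stacklevel=2)
            prev_c = res_atoms["C"].coords if "C" in res_atoms else None

    if not new_atoms:
        return out
    # splice each new H directly after its residue's N atom, keep residue order
    merged: list[Atom] = []
    pending = {a.residue_id: a for a in new_atoms}
    for atom in out.atoms:
        merged.append(atom)
        if atom.name == "N" and atom.residue_id in pending:
            merged.append(pending.pop(atom.residue_id))
    for i, a in enumerate(merged, start=1):
        a.serial = i
    return ParameterizedStructure(merged, out.provenance)


# ---------------------------------------------------------------------------
# Parameter assignment
# ---------------------------------------------------------------------------

DEFAULT_RADIUS_BY_ELEMENT = {"C": 1.70, "N": 1.50, "O": 1.40, "S": 1.85, "H": 1.00, "P": 1.90}


@dataclass
class ParameterTable:
    """Charge/radius lookup keyed by (residue name, atom name)."""

    entries: dict[tuple[str, str], tuple[float, float]]
    name: str = "parse-style"

    @classmethod
    def from_tsv(cls, text: str, name: str = "parse-style") -> "ParameterTable":
        entries = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("resname"):
                continue
            res, atom, q, r = line.split("\t")
            entries[(res, atom)] = (float(q), float(r))
        return cls(entries, name)

    def lookup(self, res_name: str, atom_name: str) -> tuple[float, float] | None:
        hit = self.entries.get((res_name, atom_name))
        if hit is None and atom_name in ("HN",):
            hit = self.entries.get((res_name, "H"))
        return hit

    def nominal_residue_charge(self, res_name: str) -> float:
        return NOMINAL_CHARGE.get(res_name, 0.0)


def load_parameter_table(path: str | None = None) -> ParameterTable:
    if path is not None:
        with open(path) as fh:
            return ParameterTable.from_tsv(fh.read(), name=path)
    text = resources.files("resmap.data").joinpath("parse_params.tsv").read_text()
    return ParameterTable.from_tsv(text)


def assign_parameters(
    structure: ParameterizedStructure,
    table: ParameterTable | None = None,
    strict: bool = True,
    charge_tolerance: float = 0.01,
) -> ParameterizedStructure:
    """Assign partial charges and radii to every atom.

    Terminal patches: the N of each chain's first residue is neutralized
    (no amide H is expected there) and OXT carries zero charge, i.e. neutral
    termini. In strict mode an unknown (residue, atom) pair is an error; in
    permissive mode it gets zero charge and an element-default radius, with a
    warning. Residues whose net charge deviates from the table's nominal
    integral charge by more than ``charge_tolerance`` are reported by warning
    (typically missing amide hydrogens).
    """
    table = table or load_parameter_table()
    atoms = [replace(a, coords=a.coords.copy()) for a in structure.atoms]
    first_rids = set()
    seen_chains: set[str] = set()
    for a in atoms:
        if a.residue_id[0] not in seen_chains:
            seen_chains.add(a.residue_id[0])
            first_rids.add(a.residue_id)

    unknown: list[str] = []
    for a in atoms:
        hit = table.lookup(a.res_name, a.name)
        if hit is None:
            if strict:
                unknown.append(f"{a.res_name} {a.name} in {a.residue_id}")
                continue
            warnings.warn(
                f"unparameterized atom {a.res_name}/{a.name} in {a.residue_id}: "
                "zero charge, element-default radius",
                stacklevel=2,
            )
            a.charge = 0.0
            a.radius = DEFAULT_RADIUS_BY_ELEMENT.get(a.element, 1.70)
        else:
            a.charge, a.radius = hit
        if a.residue_id in first_rids and a.name == "N":
            a.charge = 0.0  # neutral N-terminus patch
    if unknown:
        raise ParameterError("unparameterized atoms: " + "; ".join(unknown))

    out = ParameterizedStructure(atoms, structure.provenance)
    for rid, net in out.net_residue_charges().items():
        nominal = table.nominal_residue_charge(out.residue_name(rid))
        if rid in first_rids:
            continue  # neutral-terminus patch may shift the nominal value
        if abs(net - nominal) > charge_tolerance:
            warnings.warn(
                f"residue {rid} net charge {net:+.2f} deviates from nominal {nominal:+.0f} "
                "(missing hydrogens or atoms?)",
                stacklevel=2,
            )
    return out


# ---------------------------------------------------------------------------
# Splitting and replicate enumeration
# ---------------------------------------------------------------------------

def split_complex(
    replicate: DimerReplicate,
) -> tuple[ParameterizedStructure, ParameterizedStructure]:
    """Rigidly split a dimer into its two monomers (coordinates unchanged)."""
    cx = replicate.complex
    mask_a = cx.chain_mask(replicate.side_a_chains)
    mask_b = cx.chain_mask(replicate.side_b_chains)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("a replicate side selects no atoms")
    return (
        cx.subset(mask_a, provenance=cx.provenance + ":A"),
        cx.subset(mask_b, provenance=cx.provenance + ":B"),
    )


def _interchain_buried_area(structure: ParameterizedStructure, ca: str, cb: str) -> float:
    from . import nonpolar  # local import; nonpolar depends on this module

    pair = structure.subset(structure.chain_mask([ca, cb]))
    mono_a = structure.subset(structure.chain_mask([ca]))
    mono_b = structure.subset(structure.chain_mask([cb]))
    n_pts = 240  # coarse sampling is enough for pairing decisions
    sasa_pair = nonpolar.sasa(pair, n_points=n_pts).total
    sasa_a = nonpolar.sasa(mono_a, n_points=n_pts).total
    sasa_b = nonpolar.sasa(mono_b, n_points=n_pts).total
    return sasa_a + sasa_b - sasa_pair


def enumerate_replicates(
    structures: Sequence[ParameterizedStructure] | ParameterizedStructure,
    min_buried_area: float = 1.0,
) -> list[DimerReplicate]:
    """Enumerate cognate dimers across structures / multi-dimer units.

    Within each structure, chains are paired greedily by largest inter-chain
    buried surface area; each chain joins at most one replicate, and a chain
    with no contacting partner is excluded with a warning.
    """
    if isinstance(structures, ParameterizedStructure):
        structures = [structures]
    replicates: list[DimerReplicate] = []
    for si, st in enumerate(structures):
        chains = st.chains
        if len(chains) < 2:
            warnings.warn(f"structure {st.provenance}: fewer than two chains, skipped", stacklevel=2)
            continue
        scores = {}
        for i, ca in enumerate(chains):
            for cb in chains[i + 1 :]:
                ba = _interchain_buried_area(st, ca, cb)
                if ba > min_buried_area:
                    scores[(ca, cb)] = ba
        used: set[str] = set()
        for (ca, cb), _ in sorted(scores.items(), key=lambda kv: -kv[1]):
            if ca in used or cb in used:
                continue
            used.update((ca, cb))
            pair = st.subset(st.chain_mask([ca, cb]), provenance=f"{st.provenance}:{ca}{cb}")
            replicates.append(
                DimerReplicate(
                    complex=pair,
                    side_a_chains=frozenset([ca]),
                    side_b_chains=frozenset([cb]),
                    label=f"{st.provenance or si}:{ca}-{cb}",
                )
            )
        for ch in chains:
            if ch not in used:
                warnings.warn(
                    f"chain {ch} of {st.provenance} has no contacting partner: excluded",
                    stacklevel=2,
                )
    return replicates


# ---------------------------------------------------------------------------
# PQR-style round trip
# ---------------------------------------------------------------------------

def write_pdb(structure: ParameterizedStructure) -> str:
    """Serialize to minimal standard PDB text (single model, TER per chain)."""
    lines = []
    prev_chain = None
    serial = 0
    for a in structure.atoms:
        chain, resseq, icode = a.residue_id
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        serial += 1
        name = a.name if len(a.name) >= 4 else f" {a.name}"
        lines.append(
            f"ATOM  {serial:>5d} {name:<4s} {a.res_name:<3s} {chain:1s}{resseq:>4d}{icode or ' ':1s}"
            f"   {a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}"
        )
    lines += ["TER", "END"]
    return "\n".join(lines) + "\n"


def write_pqr(structure: ParameterizedStructure) -> str:
    """Serialize to PQR text (PDB columns, charge and radius in place of occ/B)."""
    lines = []
    for a in structure.atoms:
        chain, resseq, icode = a.residue_id
        name = a.name if len(a.name) >= 4 else f" {a.name}"
        lines.append(
            f"ATOM  {a.serial:>5d} {name:<4s} {a.res_name:<3s} {chain:1s}{resseq:>4d}{icode or ' ':1s}"
            f"   {a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}{a.charge:8.4f}{a.radius:7.4f}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_pqr(text: str) -> ParameterizedStructure:
    atoms = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            res_name = line[17:20].strip()
            chain = line[21].strip()
            resseq = int(line[22:26])
            icode = line[26].strip()
            xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            charge = float(line[54:62])
            radius = float(line[62:69])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed PQR record") from exc
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=name[0] if name[0] in "CNOSHP" else name[:1],
                residue_id=(chain, resseq, icode),
                res_name=res_name,
                coords=xyz,
                charge=charge,
                radius=radius,
                is_sidechain=not _is_backbone(name),
                is_hydrogen=name.startswith("H"),
            )
        )
    if not atoms:
        raise PDBParseError("no atoms in PQR text")
    return ParameterizedStructure(atoms, provenance="pqr")
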