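"""Synthetic structure generators for end-to-end testing of the pipeline.

Everything here is an analytic construction: ideal poly-alanine alpha
helices (1.5 A rise, 100 deg twist per residue) packed into two-chain
dimers, with planted interface features whose expected contribution calls
are emitted alongside as ground truth:

* salt bridges - facing positions mutated to Lys/Asp with pseudo side-chain
  atoms placed so the charged groups sit ~2.9 A apart across the interface
  (expected sc_elec calls on both partners);
* burial-only contributors - facing positions mutated to Leu with bulky
  apolar pseudo-atoms in van der Waals contact across the interface
  (expected np calls, no electrostatics);
* replicate sets - copies of a dimer with i.i.d. Gaussian coordinate noise
  on the heavy atoms (amide hydrogens re-placed afterwards);
* structure families - copies of a single helix in which a contiguous span
  is displaced by a controlled magnitude (smooth ramp inside the span) in
  some members, the planted dissimilar region for motif detection.

All generators are pure functions of their spec: the same seed gives
bit-identical structures. Point-charge systems for solver oracles
(Coulomb pairs, Born ions) are also built here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .structure_model import (
    Atom,
    DimerReplicate,
    ParameterizedStructure,
    assign_parameters,
    place_polar_hydrogens,
)

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "make_point_charge_system",
    "make_point_charge_dimer",
    "make_helix_dimer",
    "make_replicates",
    "make_motif_family",
]

RISE = 1.5  # A per residue
TWIST = math.radians(100.0)
CA_RADIUS = 2.3  # A, helix radius of the CA trace
FACING_COS = 0.25  # side chain counts as interface-facing above this


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic dimer / family generators."""

    seed: int = 0
    n_residues: int = 10  # per chain
    axis_separation: float = 14.0  # A between the two helix axes
    saltbridges: tuple[tuple[int, int], ...] = ((0, 9), (4, 5))  # (posA, posB), 0-based
    burial_only: tuple[tuple[str, int], ...] = (("A", 7), ("B", 2))  # (side, pos)
    jitter_sigma: float = 0.05  # A, seeded heavy-atom jitter of the base dimer
    # replicate noise
    noise_sigma: float = 0.2  # A
    n_replicates: int = 5
    # family / motif parameters
    family_length: int = 45
    loop_span: tuple[int, int] = (20, 30)  # inclusive, in 1-based residue numbering
    displacement: float = 3.0  # A
    n_members: int = 5
    n_displaced: int = 2
    displacement_mode: str = "same"  # "same" or "spread" directions across members


@dataclass
class GroundTruth:
    """Planted contribution calls emitted alongside a synthetic dimer."""

    sc_elec: set  # residue ids that must be called sc_elec
    nonpolar: set  # residue ids that must be called np
    contributors: set  # union: every residue expected to contribute

    def to_json_dict(self) -> dict:
        fmt = lambda s: sorted([list(r) for r in s])
        return {
            "sc_elec": fmt(self.sc_elec),
            "nonpolar": fmt(self.nonpolar),
            "contributors": fmt(self.contributors),
        }


# ---------------------------------------------------------------------------
# Point-charge systems (solver oracles)
# ---------------------------------------------------------------------------

def make_point_charge_system(
    charges: list[tuple[float, tuple[float, float, float]]],
    radius: float = 2.0,
    chain: str | list[str] = "A",
) -> ParameterizedStructure:
    """Bare charged spheres; each charge is its own residue.

    Used as the analytic fixture for Coulomb / Born / screening oracles.
    """
    chains = [chain] * len(charges) if isinstance(chain, str) else list(chain)
    atoms = []
    counters: dict[str, int] = {}
    for i, ((q, pos), ch) in enumerate(zip(charges, chains)):
        counters[ch] = counters.get(ch, 0) + 1
        atoms.append(
            Atom(
                serial=i + 1,
                name="Q",
                element="C",
                residue_id=(ch, counters[ch], ""),
                res_name="CHG",
                coords=np.asarray(pos, dtype=float),
                charge=float(q),
                radius=float(radius),
                is_sidechain=False,
                is_hydrogen=False,
            )
        )
    return ParameterizedStructure(atoms, provenance="point-charges")


def make_point_charge_dimer(
    charges_a: list[tuple[float, tuple[float, float, float]]],
    charges_b: list[tuple[float, tuple[float, float, float]]],
    radius: float = 2.0,
) -> DimerReplicate:
    system = make_point_charge_system(
        charges_a + charges_b,
        radius=radius,
        chain=["A"] * len(charges_a) + ["B"] * len(charges_b),
    )
    return DimerReplicate(system, frozenset("A"), frozenset("B"), label="point-charge dimer")


# ---------------------------------------------------------------------------
# Ideal helices
# ---------------------------------------------------------------------------

def _helix_backbone(
    n: int,
    axis_origin: np.ndarray,
    flip_x: bool,
    mirror_y: bool,
    phase: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """CA/N/C/O positions and outward radial unit vectors of an ideal helix.

    The helix axis runs along +x (or -x if flipped) through ``axis_origin``.
    """
    i = np.arange(n)
    theta = TWIST * i + phase
    x = RISE * i * (-1.0 if flip_x else 1.0)
    ysign = -1.0 if mirror_y else 1.0
    ca = axis_origin + np.column_stack(
        [x, ysign * CA_RADIUS * np.cos(theta), CA_RADIUS * np.sin(theta)]
    )
    radial = np.column_stack([np.zeros(n), ysign * np.cos(theta), np.sin(theta)])
    axis_dir = np.array([-1.0 if flip_x else 1.0, 0.0, 0.0])

    c = np.empty_like(ca)
    c[:-1] = ca[:-1] + 1.52 * _rows_unit(ca[1:] - ca[:-1])
    c[-1] = ca[-1] + 1.52 * axis_dir
    # N sits 1.33 A from the preceding carbonyl C, tipped ~20 deg off the
    # C->CA line toward the N-terminus so the amide plane is well defined
    n_at = np.empty_like(ca)
    u = _rows_unit(ca[1:] - c[:-1])
    w = -axis_dir[None, :] - (u @ -axis_dir)[:, None] * u
    w = _rows_unit(w)
    beta = math.radians(20.0)
    n_at[1:] = c[:-1] + 1.33 * (math.cos(beta) * u + math.sin(beta) * w)
    n_at[0] = ca[0] - 1.45 * _rows_unit((ca[1] - ca[0])[None, :])[0]
    o = c + 1.23 * axis_dir  # carbonyls roughly along the helix axis
    return ca, n_at, c, o, radial


def _rows_unit(v: np.ndarray) -> np.ndarray:
    v = np.atleast_2d(v)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _residue_atoms(
    chain: str,
    resseq: int,
    res_name: str,
    named_coords: list[tuple[str, np.ndarray]],
    serial_start: int,
) -> list[Atom]:
    from .structure_model import _is_backbone

    atoms = []
    for k, (name, xyz) in enumerate(named_coords):
        atoms.append(
            Atom(
                serial=serial_start + k,
                name=name,
                element=name[0],
                residue_id=(chain, resseq, ""),
                res_name=res_name,
                coords=np.asarray(xyz, float),
                is_sidechain=not _is_backbone(name),
                is_hydrogen=False,
            )
        )
    return atoms


def _build_chain(
    chain_id: str,
    res_names: list[str],
    sidechain_builder,
    axis_origin: np.ndarray,
    flip_x: bool,
    mirror_y: bool,
    phase: float,
    serial_start: int = 1,
) -> list[Atom]:
    n = len(res_names)
    ca, n_at, c, o, radial = _helix_backbone(n, axis_origin, flip_x, mirror_y, phase)
    atoms: list[Atom] = []
    serial = serial_start
    for i in range(n):
        coords = [("N", n_at[i]), ("CA", ca[i]), ("C", c[i]), ("O", o[i])]
        coords += sidechain_builder(i, ca[i], radial[i])
        res_atoms = _residue_atoms(chain_id, i + 1, res_names[i], coords, serial)
        serial += len(res_atoms)
        atoms.extend(res_atoms)
    return atoms


# ---------------------------------------------------------------------------
# Helix dimer with planted contributors
# ---------------------------------------------------------------------------

def make_helix_dimer(spec: SyntheticSpec = SyntheticSpec()) -> tuple[DimerReplicate, GroundTruth]:
    """Antiparallel poly-Ala helix dimer with planted interface features.

    Chain A runs along +x at y ~ 0; chain B is antiparallel at
    y = axis_separation, phased so that position j of B faces position
    n-1-j of A. Planted positions must face the partner (radial component
    toward it above ``FACING_COS``), otherwise a ValueError is raised.
    Returns the parameterized replicate (amide hydrogens placed, charges and
    radii assigned) plus the planted ground truth.
    """
    n = spec.n_residues
    d = spec.axis_separation
    phase_b = -TWIST * (n - 1)  # makes B_j face A_{n-1-j}

    names_a = ["ALA"] * n
    names_b = ["ALA"] * n
    for pa, pb in spec.saltbridges:
        names_a[pa] = "LYS"
        names_b[pb] = "ASP"
    for side, pos in spec.burial_only:
        (names_a if side == "A" else names_b)[pos] = "LEU"

    ca_a, _, _, _, rad_a = _helix_backbone(n, np.zeros(3), False, False, 0.0)
    origin_b = np.array([RISE * (n - 1), d, 0.0])
    ca_b, _, _, _, rad_b = _helix_backbone(n, origin_b, True, True, phase_b)

    def check_facing(side: str, pos: int) -> None:
        toward = np.array([0, 1.0, 0]) if side == "A" else np.array([0, -1.0, 0])
        rad = rad_a[pos] if side == "A" else rad_b[pos]
        if float(rad @ toward) < FACING_COS:
            raise ValueError(f"planted position {side}{pos} is not interface-facing")

    bridges: dict[tuple[str, int], np.ndarray] = {}
    for pa, pb in spec.saltbridges:
        check_facing("A", pa)
        check_facing("B", pb)
        bridges[("A", pa)] = ca_b[pb]
        bridges[("B", pb)] = ca_a[pa]
    burial_pos = set(spec.burial_only)
    for side, pos in spec.burial_only:
        check_facing(side, pos)

    def sidechains(side: str):
        ca_own, ca_other = (ca_a, ca_b) if side == "A" else (ca_b, ca_a)

        def build(i: int, ca: np.ndarray, radial: np.ndarray) -> list[tuple[str, np.ndarray]]:
            key = (side, i)
            if key in bridges:
                partner_ca = bridges[key]
                u = (partner_ca - ca) / np.linalg.norm(partner_ca - ca)
                dist = float(np.linalg.norm(partner_ca - ca))
                # amine N and carboxylate O ~2.9 A apart across the interface:
                # NZ-CG separation 3.98 A minus the 1.08 A OD projection
                if side == "A":  # Lys: terminal amine toward the partner
                    t_nz = 0.5 * (dist - 3.98) + 0.62  # NZ sits past the midpoint
                    return [("CB", ca + 1.53 * u), ("NZ", ca + t_nz * u)]
                # Asp: carboxylate facing the partner's amine
                t_cg = 0.5 * (dist - 3.98) - 0.62
                cg = ca + t_cg * u
                perp = np.cross(u, [1.0, 0, 0])
                if np.linalg.norm(perp) < 1e-6:
                    perp = np.cross(u, [0, 0, 1.0])
                perp /= np.linalg.norm(perp)
                e = u  # toward the amine
                od1 = cg + 1.25 * (math.cos(math.radians(30)) * e + math.sin(math.radians(30)) * perp)
                od2 = cg + 1.25 * (math.cos(math.radians(30)) * e - math.sin(math.radians(30)) * perp)
                return [("CB", ca + 1.53 * u), ("CG", cg), ("OD1", od1), ("OD2", od2)]
            if key in burial_pos:
                # bulky apolar pseudo-atoms reaching into vdW contact
                j = int(np.argmin(np.linalg.norm(ca_other - ca, axis=1)))
                u = (ca_other[j] - ca) / np.linalg.norm(ca_other[j] - ca)
                dist = float(np.linalg.norm(ca_other[j] - ca))
                opp = ("B" if side == "A" else "A", n - 1 - i)
                both = opp in burial_pos
                # apolar tips (at reach + 1.0) meet in vdW contact (~3.5 A)
                reach = (dist - 3.5) / 2.0 - 1.0 if both else dist - 1.53 - 3.5 - 1.0
                reach = max(reach, 1.5)
                perp = np.cross(u, [1.0, 0, 0])
                perp /= max(np.linalg.norm(perp), 1e-9)
                axis = np.array([1.0, 0, 0])
                return [
                    ("CB", ca + 1.53 * u),
                    ("CG", ca + reach * u),
                    ("CD1", ca + (reach + 1.0) * u + 1.1 * axis),
                    ("CD2", ca + (reach + 1.0) * u - 1.1 * axis),
                ]
            return [("CB", ca + 1.53 * radial)]

        return build

    atoms = _build_chain("A", names_a, sidechains("A"), np.zeros(3), False, False, 0.0)
    atoms += _build_chain(
        "B", names_b, sidechains("B"), origin_b, True, True, phase_b, serial_start=len(atoms) + 1
    )
    raw = ParameterizedStructure(atoms, provenance=f"helix-dimer(seed={spec.seed})")

    if spec.jitter_sigma > 0:
        rng = np.random.default_rng([spec.seed, 9151])
        noise = rng.normal(0.0, spec.jitter_sigma, size=(len(raw.atoms), 3))
        for a, dx in zip(raw.atoms, noise):
            a.coords = a.coords + dx

    prepared = assign_parameters(place_polar_hydrogens(raw))
    replicate = DimerReplicate(prepared, frozenset("A"), frozenset("B"), label=raw.provenance)

    sc_truth = {("A", pa + 1, "") for pa, _ in spec.saltbridges} | {
        ("B", pb + 1, "") for _, pb in spec.saltbridges
    }
    np_truth = {(side, pos + 1, "") for side, pos in spec.burial_only}
    truth = GroundTruth(
        sc_elec=sc_truth, nonpolar=np_truth, contributors=sc_truth | np_truth
    )
    return replicate, truth


def make_replicates(
    base: DimerReplicate,
    n: int,
    noise_sigma: float,
    seed: int = 0,
) -> list[DimerReplicate]:
    """Noisy copies of a dimer: i.i.d. Gaussian displacement of heavy atoms.

    Amide hydrogens are stripped, re-placed on the perturbed backbone and
    the parameters re-assigned, so each replicate is a self-consistent model.
    Seeds per replicate derive deterministically from ``seed``.
    """
    out = []
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        heavy = [a for a in base.complex.atoms if not a.is_hydrogen]
        atoms = []
        for a in heavy:
            a2 = replace(a, coords=a.coords + (rng.normal(0.0, noise_sigma, 3) if noise_sigma > 0 else 0.0))
            a2.charge = 0.0
            a2.radius = 0.0
            atoms.append(a2)
        raw = ParameterizedStructure(atoms, provenance=f"{base.complex.provenance}:rep{i}")
        prepared = assign_parameters(place_polar_hydrogens(raw))
        out.append(
            DimerReplicate(
                prepared, base.side_a_chains, base.side_b_chains, label=f"{base.label}:rep{i}"
            )
        )
    return out


# ---------------------------------------------------------------------------
# Structure families with a planted dissimilar span
# ---------------------------------------------------------------------------

def make_motif_family(spec: SyntheticSpec = SyntheticSpec()) -> tuple[list[ParameterizedStructure], tuple[int, int]]:
    """Family of single-chain helices with a displaced span in some members.

    In ``n_displaced`` members, every atom of residues inside ``loop_span``
    (1-based, inclusive) moves by ``displacement`` times a smooth ramp
    (1.0 mid-span, 0.7 at the span edges, 0 outside). All displaced members
    share one direction by default (the planted deviation from the scaffold
    equals ``displacement``); with ``displacement_mode="spread"`` each
    displaced member gets its own direction, so displaced-displaced pairs
    deviate by up to twice the magnitude. Returns the members plus the
    planted span.
    """
    n = spec.family_length
    lo, hi = spec.loop_span
    if not (1 <= lo <= hi <= n):
        raise ValueError("loop span outside chain bounds")
    members = []
    for m in range(spec.n_members):
        atoms = _build_chain(
            "A", ["ALA"] * n, lambda i, ca, radial: [("CB", ca + 1.53 * radial)],
            np.zeros(3), False, False, 0.0,
        )
        st = ParameterizedStructure(atoms, provenance=f"family-member-{m}(seed={spec.seed})")
        if m < spec.n_displaced and spec.displacement > 0:
            if spec.displacement_mode == "same":
                ang = 0.4
            else:
                ang = 2.0 * math.pi * m / max(spec.n_displaced, 1) + 0.4
            direction = np.array([0.0, math.cos(ang), math.sin(ang)])
            for a in st.atoms:
                pos = a.residue_id[1]
                if lo <= pos <= hi:
                    t = (pos - lo) / max(hi - lo, 1)
                    w = 0.7 + 0.3 * math.sin(math.pi * t)
                    a.coords = a.coords + spec.displacement * w * direction
        members.append(st)
    return members, (lo, hi)
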