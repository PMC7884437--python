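"""Structural superposition, family classification and dissimilar-motif
detection.

Correspondence between chains comes from global sequence alignment (BLOSUM62,
affine gaps), superposition from least-squares (Kabsch) fitting on the
corresponding C-alpha atoms with outlier trimming. Families are
single-linkage groups under an RMSD/coverage criterion. Within a family, the
per-position deviation profile is the maximum pairwise C-alpha distance after
superposing every member onto the reference in an iterated
structurally-similar-core frame; contiguous runs of positions whose deviation
exceeds a threshold in enough member pairs form structurally-dissimilar
motif regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .structure_model import ParameterizedStructure, ResidueId

__all__ = [
    "PairAlignment",
    "FamilyAlignment",
    "MotifRegion",
    "kabsch",
    "align_pair",
    "classify_families",
    "build_family_alignment",
    "deviation_profile",
    "detect_motifs",
    "family_to_fasta",
    "map_to_reference",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _chain_residues(struct: ParameterizedStructure, chain: str | None) -> list[ResidueId]:
    chains = struct.chains
    if chain is None:
        chain = chains[0]
    if chain not in chains:
        raise KeyError(f"chain {chain!r} not in structure (have {chains})")
    return [rid for rid in struct.residues if rid[0] == chain]


def _sequence_and_ca(
    struct: ParameterizedStructure, chain: str | None
) -> tuple[str, list[ResidueId], np.ndarray]:
    rids, seq, cas = [], [], []
    for rid in _chain_residues(struct, chain):
        ca = next((a for a in struct.residue_atoms(rid) if a.name == "CA"), None)
        if ca is None:
            continue
        rids.append(rid)
        seq.append(THREE_TO_ONE.get(struct.residue_name(rid), "X"))
        cas.append(ca.coords)
    return "".join(seq), rids, np.array(cas).reshape(-1, 3)


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares superposition of Q onto P.

    Returns (R, t, rmsd) with the proper rotation R (det = +1) and
    translation t such that R @ q + t approximates p.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - cq).T @ (P - cp)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    rmsd = float(np.sqrt(np.mean(np.sum((P - (Q @ R.T + t)) ** 2, axis=1))))
    return R, t, rmsd


@dataclass
class PairAlignment:
    correspondence: list[tuple[ResidueId, ResidueId]]
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    coverage: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def align_pair(
    struct_a: ParameterizedStructure,
    struct_b: ParameterizedStructure,
    chain_a: str | None = None,
    chain_b: str | None = None,
    min_pairs: int = 10,
    trim_rounds: int = 5,
) -> PairAlignment:
    """Sequence-guided rigid superposition of one chain of B onto one of A.

    Global sequence alignment supplies the residue correspondence; Kabsch
    fitting on the corresponding C-alphas is refined by dropping pairs more
    than twice the current RMSD away and re-fitting (at most ``trim_rounds``
    rounds, never below ``min_pairs`` pairs).
    """
    seq_a, rids_a, ca_a = _sequence_and_ca(struct_a, chain_a)
    seq_b, rids_b, ca_b = _sequence_and_ca(struct_b, chain_b)
    if len(rids_a) < min_pairs or len(rids_b) < min_pairs:
        raise ValueError("chains too short to align (need >= 10 residues with CA)")
    aln = _make_aligner().align(seq_a, seq_b)[0]
    pairs = [
        (ia, ib)
        for block_a, block_b in zip(aln.aligned[0], aln.aligned[1])
        for ia, ib in zip(range(*block_a), range(*block_b))
    ]
    if len(pairs) < min_pairs:
        raise ValueError(f"only {len(pairs)} corresponding C-alpha (need >= {min_pairs})")

    keep = np.arange(len(pairs))
    P = ca_a[[p[0] for p in pairs]]
    Q = ca_b[[p[1] for p in pairs]]
    R, t, rmsd = kabsch(P, Q)
    for _ in range(trim_rounds):
        d = np.linalg.norm(P[keep] - (Q[keep] @ R.T + t), axis=1)
        new_keep = keep[d <= max(2.0 * rmsd, 1e-6)]
        if len(new_keep) < min_pairs or len(new_keep) == len(keep):
            break
        keep = new_keep
        R, t, rmsd = kabsch(P[keep], Q[keep])
    corr = [(rids_a[pairs[i][0]], rids_b[pairs[i][1]]) for i in keep]
    coverage = len(keep) / min(len(rids_a), len(rids_b))
    return PairAlignment(corr, R, t, rmsd, coverage)


def classify_families(
    structures: list[ParameterizedStructure],
    rmsd_max: float = 1.5,
    coverage_min: float = 0.9,
    chain: str | None = None,
) -> list[list[int]]:
    """Single-linkage family partition of structures.

    Two members are linked iff their pairwise alignment reaches
    rmsd <= rmsd_max and coverage >= coverage_min; families are the connected
    components, reported as sorted index lists (order-independent).
    """
    n = len(structures)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in combinations(range(n), 2):
        try:
            aln = align_pair(structures[i], structures[j], chain, chain)
        except ValueError:
            continue
        if aln.rmsd <= rmsd_max and aln.coverage >= coverage_min:
            parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: g[0])


@dataclass
class FamilyAlignment:
    """A superposed structure family indexed by reference chain positions."""

    members: list[ParameterizedStructure]
    reference: int
    ref_rids: list[ResidueId]  # reference positions (alignment columns)
    aligned_ca: np.ndarray  # (n_members, n_positions, 3); NaN where unaligned
    member_rids: list[dict[int, ResidueId]]  # column -> member residue id
    core_threshold: float = 1.5
    chain: str | None = None  # chain the members were aligned on

    @property
    def n_positions(self) -> int:
        return len(self.ref_rids)


def build_family_alignment(
    members: list[ParameterizedStructure],
    reference: int = 0,
    chain: str | None = None,
    core_threshold: float = 1.5,
    max_rounds: int = 20,
) -> FamilyAlignment:
    """Superpose all members onto the reference in an iterated-core frame.

    The fitting core starts as every column aligned in all members and is
    iteratively restricted to columns whose max pairwise deviation is at most
    ``core_threshold``, so a genuinely dissimilar motif cannot bias the
    superposition frame.
    """
    if len(members) < 2:
        raise ValueError("a family alignment needs at least two members")
    _, ref_rids, ref_ca = _sequence_and_ca(members[reference], chain)
    n_pos = len(ref_rids)
    n_mem = len(members)
    raw_ca = np.full((n_mem, n_pos, 3), np.nan)
    member_rids: list[dict[int, ResidueId]] = [dict() for _ in members]
    raw_ca[reference] = ref_ca
    member_rids[reference] = {i: rid for i, rid in enumerate(ref_rids)}
    col_of_ref = {rid: i for i, rid in enumerate(ref_rids)}

    for m, member in enumerate(members):
        if m == reference:
            continue
        aln = align_pair(members[reference], member, chain, chain, trim_rounds=0)
        _, m_rids, m_ca = _sequence_and_ca(member, chain)
        idx_of = {rid: i for i, rid in enumerate(m_rids)}
        for rid_ref, rid_mem in aln.correspondence:
            col = col_of_ref[rid_ref]
            raw_ca[m, col] = m_ca[idx_of[rid_mem]]
            member_rids[m][col] = rid_mem

    aligned = raw_ca.copy()
    core = ~np.isnan(raw_ca).any(axis=(0, 2))
    if core.sum() < 3:
        raise ValueError("fewer than 3 columns aligned across all members")
    for _ in range(max_rounds):
        for m in range(n_mem):
            if m == reference:
                continue
            ok = core & ~np.isnan(raw_ca[m]).any(axis=1)
            R, t, _ = kabsch(aligned[reference][ok], raw_ca[m][ok])
            valid = ~np.isnan(raw_ca[m]).any(axis=1)
            aligned[m][valid] = raw_ca[m][valid] @ R.T + t
        dev = _max_pairwise_deviation(aligned)
        new_core = core & (np.nan_to_num(dev, nan=np.inf) <= core_threshold)
        if new_core.sum() < 3 or np.array_equal(new_core, core):
            break
        core = new_core
    return FamilyAlignment(
        members, reference, ref_rids, aligned, member_rids, core_threshold, chain
    )


def _max_pairwise_deviation(aligned: np.ndarray) -> np.ndarray:
    n_mem, n_pos, _ = aligned.shape
    dev = np.full(n_pos, np.nan)
    for i, j in combinations(range(n_mem), 2):
        d = np.linalg.norm(aligned[i] - aligned[j], axis=1)
        dev = np.where(np.isnan(dev), d, np.fmax(dev, d))
    return dev


@dataclass
class DeviationProfile:
    """Per-reference-position C-alpha deviations across a superposed family."""

    ref_rids: list[ResidueId]
    max_deviation: np.ndarray  # max pairwise CA distance per column; NaN = unresolved
    pair_distances: np.ndarray  # (n_pairs, n_positions), NaN where a member is missing

    def exceed_counts(self, threshold: float) -> np.ndarray:
        """Number of member pairs exceeding ``threshold`` at each position."""
        with np.errstate(invalid="ignore"):
            return np.nansum(self.pair_distances > threshold, axis=0).astype(int)


def deviation_profile(family: FamilyAlignment) -> DeviationProfile:
    """Max (and per-pair) C-alpha deviation at every aligned position."""
    if len(family.members) < 2:
        raise ValueError("deviation profile needs at least two members")
    n_mem = len(family.members)
    pairs = list(combinations(range(n_mem), 2))
    dists = np.full((len(pairs), family.n_positions), np.nan)
    for k, (i, j) in enumerate(pairs):
        dists[k] = np.linalg.norm(family.aligned_ca[i] - family.aligned_ca[j], axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        max_dev = np.nanmax(dists, axis=0)
    return DeviationProfile(family.ref_rids, max_dev, dists)


@dataclass
class MotifRegion:
    """A maximal contiguous run of structurally-dissimilar positions,
    reported as an inclusive reference sequence-number span."""

    start: int
    end: int
    start_rid: ResidueId
    end_rid: ResidueId
    flagged_columns: list[int]


def detect_motifs(
    profile: DeviationProfile,
    threshold: float = 1.5,
    min_pairs: int = 1,
    bridge_gaps: int = 0,
) -> list[MotifRegion]:
    """Structurally-dissimilar regions of a deviation profile.

    A position is flagged when at least ``min_pairs`` member pairs deviate by
    more than ``threshold`` (strict) there; regions are maximal contiguous
    flagged runs, optionally bridging unflagged gaps up to ``bridge_gaps``
    positions long.
    """
    counts = profile.exceed_counts(threshold)
    flagged = counts >= max(min_pairs, 1)
    if bridge_gaps > 0:
        flagged = flagged.copy()
        idx = np.flatnonzero(flagged)
        for a, b in zip(idx[:-1], idx[1:]):
            if 1 < b - a <= bridge_gaps + 1:
                flagged[a:b] = True
    regions: list[MotifRegion] = []
    start = None
    for i, f in enumerate(list(flagged) + [False]):
        if f and start is None:
            start = i
        elif not f and start is not None:
            cols = list(range(start, i))
            regions.append(
                MotifRegion(
                    start=profile.ref_rids[start][1],
                    end=profile.ref_rids[i - 1][1],
                    start_rid=profile.ref_rids[start],
                    end_rid=profile.ref_rids[i - 1],
                    flagged_columns=cols,
                )
            )
            start = None
    return regions


def family_to_fasta(family: FamilyAlignment) -> str:
    """Gapped FASTA of the structure-based family alignment (one row per
    member, columns are reference positions; '-' where a member is
    unaligned)."""
    lines = []
    for m, member in enumerate(family.members):
        seq = []
        for col in range(family.n_positions):
            rid = family.member_rids[m].get(col)
            if rid is None:
                seq.append("-")
            else:
                seq.append(THREE_TO_ONE.get(member.residue_name(rid), "X"))
        name = member.provenance or f"member_{m}"
        tag = " (reference)" if m == family.reference else ""
        lines.append(f">{name}{tag}")
        lines.append("".join(seq))
    return "\n".join(lines) + "\n"


def map_to_reference(
    family: FamilyAlignment,
    numbering_offset: int = 0,
    prefix: str = "",
) -> list[dict[ResidueId, str]]:
    """Label every member residue with its reference position.

    Aligned residues get ``prefix + reference sequence number (+ offset)``;
    member residues without a reference column get insertion labels
    ``<previous reference number><a, b, ...>``.
    """
    out: list[dict[ResidueId, str]] = []
    for m, member in enumerate(family.members):
        labels: dict[ResidueId, str] = {}
        col_by_rid = {rid: col for col, rid in family.member_rids[m].items()}
        _, m_rids, _ = _sequence_and_ca(member, family.chain)
        prev_num: int | None = None
        ins = 0
        for rid in m_rids:
            col = col_by_rid.get(rid)
            if col is not None:
                num = family.ref_rids[col][1] + numbering_offset
                labels[rid] = f"{prefix}{num}"
                prev_num, ins = num, 0
            else:
                ins += 1
                anchor = prev_num if prev_num is not None else 0
                labels[rid] = f"{prefix}{anchor}{chr(ord('a') + ins - 1)}"
        out.append(labels)
    return out
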