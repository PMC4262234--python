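"""Detection and interface analysis of disulphide-bonded loops in 3D structures.

Loops are found geometrically: every same-chain cysteine pair whose
S-gamma atoms sit at bonding distance (default window 1.6-2.5 A around the
canonical ~2.05 A S-S bond) and whose interior length is short (default
2-9 residues) is a candidate; knot-like overlapping bonds are removed.
Surface exposure uses per-residue solvent-accessible surface area
(Shrake-Rupley sphere sampling, probe 1.4 A); a residue is "surface" when
its SASA exceeds 2.5 A^2.  Interface residues are those with a heavy atom
within 3 A of another chain, and a loop's interface coverage is the share
of the chain's interface (by residue count or by buried area) that falls
inside the loop span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.PDBData import protein_letters_3to1
from Bio.PDB import PDBParser
from Bio.PDB.Model import Model
from Bio.PDB.SASA import ShrakeRupley
from Bio.PDB.Structure import Structure
from Bio.SVDSuperimposer import SVDSuperimposer
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: residue key used throughout this module: (chain id, 1-based residue number)
ResKey = tuple[str, int]

DEFAULT_BOND_WINDOW = (1.6, 2.5)
DEFAULT_INTERIOR_RANGE = (2, 9)
DEFAULT_MAX_PAIR_SPAN = 10
DEFAULT_SASA_THRESHOLD = 2.5
DEFAULT_CONTACT_CUTOFF = 3.0

from .loops import DisulphideLoop, filter_knotted


# ---------------------------------------------------------------------------
# parsing

def parse_structure(source, structure_id: str = "structure") -> Structure:
    """Parse PDB-format text into a Bio.PDB structure (first model only).

    ``source`` is a path or file-like object.  Hydrogens, waters and other
    hetero records are discarded; alternate locations resolve to the
    highest-occupancy conformer (Bio.PDB default).  Raises ``ValueError``
    for files without any protein ATOM record.
    """
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(structure_id, source)
    except Exception as exc:  # Bio.PDB raises several exception types
        raise ValueError(f"unparseable PDB input: {exc}") from exc

    if len(structure) == 0:
        raise ValueError("PDB input contains no model")
    model = structure[0]

    # strip hetero residues (waters, ligands, metals) and hydrogen atoms
    for chain in list(model):
        for residue in list(chain):
            if residue.id[0] != " ":
                chain.detach_child(residue.id)
                continue
            for atom in list(residue):
                if atom.element == "H" or atom.element == "D":
                    residue.detach_child(atom.id)
        if len(chain) == 0:
            model.detach_child(chain.id)

    if not any(True for _ in model.get_atoms()):
        raise ValueError("PDB input contains no protein ATOM records")

    # keep only the first model: detach the rest for a clean container
    for extra in list(structure)[1:]:
        structure.detach_child(extra.id)
    return structure


def _model(structure: Structure | Model) -> Model:
    return structure if isinstance(structure, Model) else structure[0]


def _heavy_atoms(model: Model):
    """Yield (chain_id, resseq, atom) for every heavy atom of amino-acid residues."""
    for chain in model:
        for residue in chain:
            for atom in residue:
                yield chain.id, residue.id[1], atom


def residue_one_letter(residue) -> str:
    return protein_letters_3to1.get(residue.get_resname().strip().upper(), "X")


# ---------------------------------------------------------------------------
# loop detection

def detect_disulphide_loops(
    structure: Structure | Model,
    interior_range: tuple[int, int] = DEFAULT_INTERIOR_RANGE,
    bond_window: tuple[float, float] = DEFAULT_BOND_WINDOW,
    max_pair_span: int = DEFAULT_MAX_PAIR_SPAN,
) -> list[DisulphideLoop]:
    """Find short disulphide-bonded loops by S-gamma geometry.

    Every same-chain cysteine pair with both S-gamma atoms present, an
    S-S distance inside ``bond_window`` (inclusive), interior length in
    ``interior_range`` and endpoint separation at most ``max_pair_span``
    becomes a candidate bond; knot-like overlapping candidates are then
    removed (see :func:`dsloop.loops.filter_knotted`).  Cysteines lacking
    an S-gamma atom are skipped with a logged warning.
    """
    model = _model(structure)
    lo, hi = bond_window
    imin, imax = interior_range
    loops: list[DisulphideLoop] = []

    for chain in model:
        cys = []
        for residue in chain:
            if residue.get_resname().strip().upper() != "CYS":
                continue
            if "SG" not in residue:
                logger.warning(
                    "cysteine %s:%d has no SG atom; skipped", chain.id, residue.id[1]
                )
                continue
            cys.append((residue.id[1], residue["SG"].coord))

        candidates = []
        for (ri, ci), (rj, cj) in combinations(cys, 2):
            i, j = sorted((ri, rj))
            interior_len = j - i - 1
            if not (imin <= interior_len <= imax):
                continue
            if j - i > max_pair_span:
                continue
            d = float(np.linalg.norm(ci - cj))
            if lo <= d <= hi:
                candidates.append((i, j))

        seqmap = {r.id[1]: residue_one_letter(r) for r in chain}
        for i, j in filter_knotted(sorted(candidates)):
            interior = "".join(
                seqmap[k] for k in range(i + 1, j) if k in seqmap
            )
            loops.append(
                DisulphideLoop(
                    source_id=model.get_parent().id if model.get_parent() else "structure",
                    chain=chain.id,
                    cys_i=i,
                    cys_j=j,
                    interior=interior,
                )
            )

    loops.sort(key=lambda lp: (lp.chain, lp.cys_i))
    return loops


# ---------------------------------------------------------------------------
# SASA

@dataclass(frozen=True)
class SasaProfile:
    """Per-residue solvent-accessible surface area in A^2."""

    areas: Mapping[ResKey, float]
    context: str  # "monomer" | "complex"
    probe_radius: float = 1.4
    n_points: int = 960

    def area(self, chain: str, resseq: int) -> float:
        return self.areas[(chain, resseq)]

    def chains(self) -> set[str]:
        return {c for c, _ in self.areas}


def compute_sasa(
    structure: Structure | Model,
    chains: Optional[Iterable[str]] = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> SasaProfile:
    """Shrake-Rupley per-residue SASA over the selected chains only.

    With ``chains=None`` all chains are used and the context is recorded as
    "complex" when more than one chain is present; selecting a single chain
    records "monomer" context (the chain scored in isolation).
    """
    model = _model(structure)
    selected = set(chains) if chains is not None else {c.id for c in model}
    missing = selected - {c.id for c in model}
    if missing:
        raise ValueError(f"chains {sorted(missing)} not present in structure")

    # score on a pruned copy so excluded chains do not occlude the surface
    work = model.copy()
    for chain in list(work):
        if chain.id not in selected:
            work.detach_child(chain.id)

    # the stock radii table is a defaultdict; check membership explicitly so
    # unknown elements fail loudly instead of silently getting a default
    from Bio.PDB.SASA import ATOMIC_RADII

    known = set(ATOMIC_RADII.keys())
    for _, _, atom in _heavy_atoms(work):
        element = (atom.element or "").strip().upper()
        if element not in known:
            raise ValueError(
                f"no van der Waals radius for element {element!r} "
                f"(atom {atom.get_full_id()})"
            )

    sr = ShrakeRupley(probe_radius=probe_radius, n_points=n_points)
    sr.compute(work, level="R")

    areas = {
        (chain.id, residue.id[1]): float(residue.sasa)
        for chain in work
        for residue in chain
    }
    context = "monomer" if len(selected) == 1 else "complex"
    return SasaProfile(areas=areas, context=context,
                       probe_radius=probe_radius, n_points=n_points)


def classify_surface(profile: SasaProfile,
                     threshold: float = DEFAULT_SASA_THRESHOLD) -> set[ResKey]:
    """Residues whose SASA strictly exceeds ``threshold`` (A^2)."""
    return {key for key, area in profile.areas.items() if area > threshold}


# ---------------------------------------------------------------------------
# interfaces

@dataclass(frozen=True)
class InterfaceMap:
    """Per-chain-pair interface residue sets at a heavy-atom cutoff."""

    by_pair: Mapping[tuple[str, str], frozenset[ResKey]]
    cutoff: float

    def residues(self, chain: str) -> set[ResKey]:
        """All interface residues on ``chain``, over every partner chain."""
        out: set[ResKey] = set()
        for pair, keys in self.by_pair.items():
            if chain in pair:
                out.update(k for k in keys if k[0] == chain)
        return out

    def all_residues(self) -> set[ResKey]:
        out: set[ResKey] = set()
        for keys in self.by_pair.values():
            out.update(keys)
        return out


def find_interface_residues(structure: Structure | Model,
                            cutoff: float = DEFAULT_CONTACT_CUTOFF) -> InterfaceMap:
    """Residues with any heavy atom within ``cutoff`` A of a different chain.

    The map is symmetric by construction: a contact pair contributes the
    residue on both chains of the pair.
    """
    model = _model(structure)
    coords: dict[str, np.ndarray] = {}
    keys: dict[str, list[ResKey]] = {}
    for chain in model:
        pts, ks = [], []
        for residue in chain:
            for atom in residue:
                pts.append(atom.coord)
                ks.append((chain.id, residue.id[1]))
        if pts:
            coords[chain.id] = np.asarray(pts, dtype=float)
            keys[chain.id] = ks

    by_pair: dict[tuple[str, str], frozenset[ResKey]] = {}
    for a, b in combinations(sorted(coords), 2):
        ta, tb = cKDTree(coords[a]), cKDTree(coords[b])
        hits = ta.query_ball_tree(tb, r=cutoff)
        found: set[ResKey] = set()
        for ia, jbs in enumerate(hits):
            if jbs:
                found.add(keys[a][ia])
                found.update(keys[b][jb] for jb in jbs)
        if found:
            by_pair[(a, b)] = frozenset(found)
    return InterfaceMap(by_pair=by_pair, cutoff=cutoff)


# ---------------------------------------------------------------------------
# coverage

@dataclass(frozen=True)
class CoverageResult:
    loop: DisulphideLoop
    mode: str  # "residue_count" | "buried_area"
    loop_share: float
    n_loop_interface_residues: int
    n_chain_interface_residues: int
    no_interface: bool = False

    @property
    def majority_of_interface(self) -> bool:
        """True when the loop covers strictly more than half of the interface."""
        return self.loop_share > 0.5


def loop_interface_coverage(
    loop: DisulphideLoop,
    imap: InterfaceMap,
    sasa_mono: Optional[SasaProfile] = None,
    sasa_cplx: Optional[SasaProfile] = None,
    mode: str = "buried_area",
) -> CoverageResult:
    """Fraction of the chain's interface contributed by the loop span.

    ``residue_count`` mode divides interface-residue counts; ``buried_area``
    mode divides summed per-residue buried area, where buried area is
    max(0, SASA_monomer - SASA_complex).  Chains without interface residues
    yield share 0 with ``no_interface=True``.
    """
    if mode not in ("residue_count", "buried_area"):
        raise ValueError(f"unknown coverage mode {mode!r}")
    chain = loop.chain
    iface = imap.residues(chain)
    loop_keys = {(chain, k) for k in range(loop.cys_i, loop.cys_j + 1)}
    loop_iface = loop_keys & iface

    if not iface:
        return CoverageResult(loop, mode, 0.0, 0, 0, no_interface=True)

    if mode == "residue_count":
        share = len(loop_iface) / len(iface)
    else:
        if sasa_mono is None or sasa_cplx is None:
            raise ValueError("buried_area mode requires monomer and complex SASA profiles")
        for prof, label in ((sasa_mono, "monomer"), (sasa_cplx, "complex")):
            if chain not in prof.chains():
                raise ValueError(f"chain {chain!r} absent from {label} SASA profile")

        def dsasa(key: ResKey) -> float:
            return max(0.0, sasa_mono.areas.get(key, 0.0) - sasa_cplx.areas.get(key, 0.0))

        total = sum(dsasa(k) for k in iface)
        if total <= 0.0:
            return CoverageResult(loop, mode, 0.0, len(loop_iface), len(iface),
                                  no_interface=True)
        share = sum(dsasa(k) for k in loop_iface) / total

    return CoverageResult(loop, mode, float(share), len(loop_iface), len(iface))


# ---------------------------------------------------------------------------
# dedup + superposition

def deduplicate_loops(loops: Sequence[DisulphideLoop]) -> list[DisulphideLoop]:
    """One representative per (accession, cys_i, cys_j).

    The representative is the loop from the lexicographically smallest
    structure id, making the selection deterministic.  Loops without an
    accession are keyed by their own source id.
    """
    best: dict[tuple, DisulphideLoop] = {}
    for lp in loops:
        key = (lp.accession or lp.source_id, lp.cys_i, lp.cys_j)
        cur = best.get(key)
        if cur is None or lp.source_id < cur.source_id:
            best[key] = lp
    return sorted(best.values(), key=lambda lp: (lp.accession or lp.source_id, lp.cys_i))


def superpose_calpha(model_coords: np.ndarray, reference_coords: np.ndarray) -> float:
    """Least-squares rigid-body C-alpha superposition RMSD (Kabsch/SVD).

    Coordinates are (n, 3) arrays paired by rank order; n >= 3 required.
    """
    x = np.asarray(model_coords, dtype=float)
    y = np.asarray(reference_coords, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"coordinate shapes differ or are not (n, 3): {x.shape} vs {y.shape}")
    if x.shape[0] < 3:
        raise ValueError("at least 3 C-alpha atoms are required for superposition")
    sup = SVDSuperimposer()
    sup.set(y, x)  # reference first per SVDSuperimposer convention
    sup.run()
    return float(sup.get_rms())


def calpha_coords(structure: Structure | Model, chain: str,
                  start: int, end: int) -> np.ndarray:
    """C-alpha coordinates of residues ``start..end`` (inclusive) on a chain."""
    model = _model(structure)
    out = []
    for residue in model[chain]:
        if start <= residue.id[1] <= end and "CA" in residue:
            out.append(residue["CA"].coord)
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------------
# survey table

def survey_structures(
    paths: Sequence,
    interior_range: tuple[int, int] = DEFAULT_INTERIOR_RANGE,
    bond_window: tuple[float, float] = DEFAULT_BOND_WINDOW,
    max_pair_span: int = DEFAULT_MAX_PAIR_SPAN,
    sasa_threshold: float = DEFAULT_SASA_THRESHOLD,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    coverage_mode: str = "buried_area",
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> pd.DataFrame:
    """Run detection + surface + interface + coverage over PDB files.

    Returns one row per detected loop with surface-residue and
    interface-residue counts and the interface coverage share.
    """
    rows = []
    for path in paths:
        sid = getattr(path, "stem", str(path))
        structure = parse_structure(path, structure_id=sid)
        model = structure[0]
        loops = detect_disulphide_loops(structure, interior_range, bond_window, max_pair_span)
        if not loops:
            continue
        sasa_cplx = compute_sasa(model, probe_radius=probe_radius, n_points=n_points)
        surface = classify_surface(sasa_cplx, sasa_threshold)
        imap = find_interface_residues(model, contact_cutoff)
        sasa_mono = {
            c.id: compute_sasa(model, chains=[c.id], probe_radius=probe_radius,
                               n_points=n_points)
            for c in model
        }
        for lp in loops:
            loop_keys = {(lp.chain, k) for k in range(lp.cys_i, lp.cys_j + 1)}
            cov = loop_interface_coverage(
                lp, imap,
                sasa_mono=sasa_mono[lp.chain], sasa_cplx=sasa_cplx,
                mode=coverage_mode,
            )
            rows.append({
                "structure_id": sid,
                "chain": lp.chain,
                "cys_i": lp.cys_i,
                "cys_j": lp.cys_j,
                "interior": lp.interior,
                "n_surface_residues": len(loop_keys & surface),
                "n_interface_residues": cov.n_loop_interface_residues,
                "coverage_mode": cov.mode,
                "loop_share": cov.loop_share,
                "majority_of_interface": cov.majority_of_interface,
            })
    columns = ["structure_id", "chain", "cys_i", "cys_j", "interior",
               "n_surface_residues", "n_interface_residues", "coverage_mode",
               "loop_share", "majority_of_interface"]
    return pd.DataFrame(rows, columns=columns)
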