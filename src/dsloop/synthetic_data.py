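"""Synthetic fixtures with the statistical structure the surveys assume.

Three generators cover the pipeline's three data domains:

* toy two-or-more-chain PDB structures with disulphide loops planted at a
  controllable S-gamma distance and chains at a controllable closest
  approach — pure metric scaffolds, not stereochemically valid proteins;
* multiple sequence alignments where interior loop columns copy the
  consensus with a boosted probability, emulating preferential loop
  conservation;
* PSI-MITAB interaction files with planted human-virus-human
  shared-interactor triangles and triangle-free noise edges.

All generators are deterministic for a fixed spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .conservation_survey import AA_ORDER, blosum62_background

CA_SPACING = 3.8  # A between consecutive C-alpha atoms in the extended chain

# fixed intra-residue offsets (x, z) relative to the C-alpha; y is constant
# per chain so the interchain closest approach equals the chain separation
_ATOM_OFFSETS = {
    "N": (-1.25, 0.35),
    "CA": (0.0, 0.0),
    "C": (1.25, 0.35),
    "O": (1.65, 1.25),
    "CB": (0.0, 1.50),
}
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "SG": "S"}


# ---------------------------------------------------------------------------
# structures

@dataclass(frozen=True)
class StructureSpec:
    """Blueprint for a toy multi-chain structure with planted loops.

    ``loop_plants`` entries are (chain id, cys position i, cys position j,
    target S-gamma distance in A).  ``inter_chain_gap`` is the exact
    closest heavy-atom approach between adjacent chains.
    """

    n_chains: int = 2
    chain_length: int = 30
    loop_plants: tuple[tuple[str, int, int, float], ...] = ()
    inter_chain_gap: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_chains < 1 or self.chain_length < 1:
            raise ValueError("n_chains and chain_length must be positive")
        if self.inter_chain_gap <= 0:
            raise ValueError("inter_chain_gap must be > 0")
        chain_ids = {chr(ord("A") + k) for k in range(self.n_chains)}
        seen: set[tuple[str, int]] = set()
        for chain, i, j, dist in self.loop_plants:
            if chain not in chain_ids:
                raise ValueError(f"plant on unknown chain {chain!r}")
            if not (1 <= i < j <= self.chain_length):
                raise ValueError(
                    f"plant ({chain}, {i}, {j}) outside chain of length {self.chain_length}"
                )
            if dist <= 0:
                raise ValueError(f"plant ({chain}, {i}, {j}) has non-positive S-S distance")
            for pos in ((chain, i), (chain, j)):
                if pos in seen:
                    raise ValueError(f"cysteine {pos} used by more than one plant")
                seen.add(pos)


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str, resseq: int,
                   x: float, y: float, z: float, element: str) -> str:
    padded = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {padded:4s} {resname:<3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def make_loop_structure(spec: StructureSpec, path=None) -> str:
    """Build a PDB-format toy structure per the spec; returns the text.

    Chains are parallel extended backbones (3.8 A C-alpha spacing) offset
    in y by exactly ``inter_chain_gap``; planted cysteine pairs get
    explicit S-gamma atoms separated by the requested distance (placed at
    the midpoint of the two C-alphas, so no unplanted pair comes close).
    Every residue is alanine except planted cysteines.
    """
    spec.validate()
    cys_positions = {(c, p) for c, i, j, _ in spec.loop_plants for p in (i, j)}
    # each plant gets its own SG z-level, 3 A apart, so S-gamma atoms of
    # different plants can never fall inside the default bond window
    sg_coords: dict[tuple[str, int], np.ndarray] = {}
    for plant_idx, (chain, i, j, dist) in enumerate(spec.loop_plants):
        mid_x = 0.5 * ((i - 1) + (j - 1)) * CA_SPACING
        z = 2.5 + 3.0 * plant_idx
        sg_coords[(chain, i)] = np.array([mid_x - 0.5 * dist, 0.0, z])
        sg_coords[(chain, j)] = np.array([mid_x + 0.5 * dist, 0.0, z])

    lines = []
    serial = 1
    for k in range(spec.n_chains):
        chain = chr(ord("A") + k)
        y = k * spec.inter_chain_gap
        for resseq in range(1, spec.chain_length + 1):
            is_cys = (chain, resseq) in cys_positions
            resname = "CYS" if is_cys else "ALA"
            ca_x = (resseq - 1) * CA_SPACING
            for name, (dx, dz) in _ATOM_OFFSETS.items():
                lines.append(_pdb_atom_line(
                    serial, name, resname, chain, resseq,
                    ca_x + dx, y, dz, _ELEMENTS[name],
                ))
                serial += 1
            if is_cys:
                sx, _, sz = sg_coords[(chain, resseq)]
                lines.append(_pdb_atom_line(
                    serial, "SG", resname, chain, resseq, sx, y, sz, "S",
                ))
                serial += 1
        lines.append(f"TER   {serial:5d}      {'ALA':<3s} {chain}{spec.chain_length:4d}")
        serial += 1
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# alignments

@dataclass(frozen=True)
class MsaSpec:
    """Blueprint for an alignment with planted loop-interior conservation.

    Each row copies the per-column consensus with probability
    ``base_conservation`` (plus ``loop_boost`` inside loop interiors) and
    otherwise draws from the background distribution.  ``loop_regions``
    entries are (start, end, cys_flanked): 1-based inclusive spans whose
    endpoints carry an invariant C in every row when cys_flanked.
    """

    n_rows: int = 50
    length: int = 120
    background: Optional[tuple[float, ...]] = None  # over AA_ORDER; default BLOSUM62
    base_conservation: float = 0.6
    loop_regions: tuple[tuple[int, int, bool], ...] = ()
    loop_boost: float = 0.3
    seed: int = 0

    def background_vector(self) -> np.ndarray:
        if self.background is None:
            return blosum62_background()
        v = np.asarray(self.background, dtype=float)
        if v.shape != (20,):
            raise ValueError("background must be a 20-vector")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1 within 1e-9")
        return v

    def validate(self) -> None:
        if self.n_rows < 1 or self.length < 1:
            raise ValueError("n_rows and length must be positive")
        if not (0.0 <= self.base_conservation <= 1.0):
            raise ValueError("base_conservation must lie in [0, 1]")
        if self.base_conservation + self.loop_boost > 1.0 + 1e-12:
            raise ValueError("base_conservation + loop_boost must be <= 1")
        self.background_vector()
        spans = sorted((s, e) for s, e, _ in self.loop_regions)
        for s, e in spans:
            if not (1 <= s < e <= self.length):
                raise ValueError(f"loop region ({s}, {e}) outside [1, {self.length}]")
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError(f"loop regions ({s1},{e1}) and ({s2},{e2}) overlap")


def make_conservation_msa(spec: MsaSpec, path=None) -> list[tuple[str, str]]:
    """Generate an aligned-FASTA MSA; returns [(id, sequence), ...].

    Row 1 ("ref") is the ungapped consensus itself; cys-flanked loop
    endpoints are invariant C in every row; interior columns copy the
    consensus with probability base + boost, all other columns with the
    base probability.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    bg = spec.background_vector()
    aa = np.frombuffer(AA_ORDER.encode(), dtype="S1").astype("U1")

    p_col = np.full(spec.length, spec.base_conservation)
    cys_cols: set[int] = set()
    for s, e, cys_flanked in spec.loop_regions:
        p_col[s : e - 1] = spec.base_conservation + spec.loop_boost  # interior columns
        if cys_flanked:
            cys_cols.update((s - 1, e - 1))

    consensus = rng.choice(20, size=spec.length, p=bg)
    cys_idx = AA_ORDER.index("C")
    for col in cys_cols:
        consensus[col] = cys_idx

    rows = [("ref", "".join(aa[consensus]))]
    for r in range(1, spec.n_rows):
        copy = rng.random(spec.length) < p_col
        draws = rng.choice(20, size=spec.length, p=bg)
        seq = np.where(copy, consensus, draws)
        for col in cys_cols:
            seq[col] = cys_idx
        rows.append((f"homolog_{r}", "".join(aa[seq])))

    if path is not None:
        with open(path, "w") as fh:
            for rid, seq in rows:
                fh.write(f">{rid}\n{seq}\n")
    return rows


# ---------------------------------------------------------------------------
# interaction networks

@dataclass(frozen=True)
class NetworkSpec:
    """Blueprint for a PSI-MITAB network with planted mimicry triangles.

    ``planted_triangles`` entries are (human loop-protein H, virus
    loop-protein V, shared human interactor X): each contributes the two
    edges H-X and V-X.  Noise edges are sampled among the remaining pairs
    under the constraint that no additional shared interactor appears for
    any planted (H, V) pair.
    """

    n_human: int = 10
    n_virus: int = 5
    planted_triangles: tuple[tuple[str, str, str], ...] = ()
    noise_edges: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_human < 0 or self.n_virus < 0 or self.noise_edges < 0:
            raise ValueError("counts must be >= 0")
        for h, v, x in self.planted_triangles:
            if len({h, v, x}) != 3:
                raise ValueError(f"triangle members ({h}, {v}, {x}) are not distinct")


def _mitab_line(acc_a: str, acc_b: str, taxid_a: str, taxid_b: str) -> str:
    cols = [
        f"uniprotkb:{acc_a}", f"uniprotkb:{acc_b}", "-", "-", "-", "-",
        'psi-mi:"MI:0045"(experimental interaction detection)', "-", "-",
        taxid_a, taxid_b, 'psi-mi:"MI:0915"(physical association)',
        "psi-mi:synthetic", "-", "-",
    ]
    return "\t".join(cols)


def make_interaction_network(spec: NetworkSpec, path=None) -> str:
    """Write a PSI-MITAB 2.5 file per the spec; returns the text.

    Humans are HUM0001.. and viruses VIR0001.. plus any planted
    identifiers; humans get taxid 9606, viruses the generic virus taxon.
    Noise edges are rejection-sampled (capped at 10x attempts) so that no
    planted (H, V) pair gains a shared interactor beyond its planted X.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    humans = [f"HUM{k + 1:04d}" for k in range(spec.n_human)]
    viruses = [f"VIR{k + 1:04d}" for k in range(spec.n_virus)]
    planted_h = [h for h, _, _ in spec.planted_triangles]
    planted_v = [v for _, v, _ in spec.planted_triangles]
    planted_x = [x for _, _, x in spec.planted_triangles]
    humans += [n for n in planted_h + planted_x if n not in humans]
    viruses += [n for n in planted_v if n not in viruses]
    is_virus = set(viruses)

    def taxid(node: str) -> str:
        return ('taxid:10239("Viruses")' if node in is_virus
                else 'taxid:9606(Homo sapiens)')

    edges: list[tuple[str, str]] = []
    edge_set: set[frozenset[str]] = set()

    def add_edge(a: str, b: str) -> None:
        key = frozenset((a, b))
        if key not in edge_set:
            edge_set.add(key)
            edges.append((a, b))

    planted_shared = {(h, v): x for h, v, x in spec.planted_triangles}
    for h, v, x in spec.planted_triangles:
        add_edge(h, x)
        add_edge(v, x)

    def creates_unplanted_triangle(a: str, b: str) -> bool:
        trial = edge_set | {frozenset((a, b))}

        def neighbours(n: str) -> set[str]:
            return {next(iter(e - {n})) for e in trial if n in e}

        for (h, v), x in planted_shared.items():
            if (neighbours(h) & neighbours(v)) - {x}:
                return True
        return False

    nodes = humans + viruses
    attempts = 0
    max_attempts = max(10 * spec.noise_edges, 10)
    placed = 0
    while placed < spec.noise_edges:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {spec.noise_edges} triangle-free noise edges "
                f"within {max_attempts} attempts"
            )
        attempts += 1
        a, b = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[a], nodes[b]
        if frozenset((a, b)) in edge_set or creates_unplanted_triangle(a, b):
            continue
        add_edge(a, b)
        placed += 1

    lines = ["#ID(A)\tID(B)\taltA\taltB\taliasA\taliasB\tmethod\tauthor\tpubid"
             "\ttaxidA\ttaxidB\ttype\tsourcedb\tinteractionID\tconfidence"]
    lines += [_mitab_line(a, b, taxid(a), taxid(b)) for a, b in edges]
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# prediction profiles

def make_prediction_profile(
    sequence: str,
    coil_regions: Sequence[tuple[int, int]] = (),
    exposed_regions: Sequence[tuple[int, int]] = (),
    path=None,
) -> str:
    """Write a per-residue prediction TSV (position, residue, ss, acc).

    Residues inside ``coil_regions`` (1-based inclusive spans) are labelled
    C, all others H; residues inside ``exposed_regions`` are labelled e
    (exposed), all others b (buried).  Overlapping same-label spans merge;
    out-of-bounds spans raise.
    """
    seq = sequence.upper()
    n = len(seq)

    def mask(spans, label) -> np.ndarray:
        m = np.zeros(n, dtype=bool)
        for s, e in spans:
            if not (1 <= s <= e <= n):
                raise ValueError(f"{label} span ({s}, {e}) outside sequence of length {n}")
            m[s - 1 : e] = True
        return m

    coil = mask(coil_regions, "coil")
    exposed = mask(exposed_regions, "exposed")
    lines = ["position\tresidue\tss\tacc"]
    for k in range(n):
        lines.append(
            f"{k + 1}\t{seq[k]}\t{'C' if coil[k] else 'H'}\t{'e' if exposed[k] else 'b'}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
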