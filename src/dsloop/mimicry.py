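"""Host-virus disulphide-loop mimicry detection.

Candidate loops are predicted from sequence plus per-residue secondary
structure (H/E/C) and solvent accessibility (exposed/buried) labels: a
Cys...Cys window qualifies when it is short, contains no internal
cysteine, its interior is not predicted helix or sheet, and strictly more
of its residues are predicted exposed than buried.

Human-virus loop similarity is the optimal pairwise alignment score of the
two interiors (flanking cysteines excluded) under BLOSUM62 with gap open
and extension penalties of -12, normalised by the viral interior's
self-alignment score; the quotient is at most 1 and equals 1 for identical
interiors.  A mimicry hit is a similar loop pair (similarity strictly
above 0.50 by default) whose human and viral proteins share at least one
human interactor in a merged interaction network.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Union

import networkx as nx
from Bio.Align import PairwiseAligner, substitution_matrices

from .loops import DisulphideLoop, interior_of

logger = logging.getLogger(__name__)

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
HUMAN_TAXID = "9606"
DEFAULT_SIM_THRESHOLD = 0.50
DEFAULT_MAX_TOTAL_LENGTH = 10  # "under 11 residues" including both cysteines


# ---------------------------------------------------------------------------
# sequence-based loop prediction

@dataclass(frozen=True)
class PredictedLoop:
    accession: str
    start: int  # 1-based position of the N-terminal cysteine
    end: int    # 1-based position of the C-terminal cysteine
    interior: str
    mean_exposure: float  # fraction of window residues predicted exposed

    @property
    def sequence(self) -> str:
        return "C" + self.interior + "C"


def predict_sequence_loops(
    sequence: str,
    ss_prediction: str,
    acc_prediction: str,
    accession: str = "",
    max_total_length: int = DEFAULT_MAX_TOTAL_LENGTH,
    interior_min: int = 2,
) -> list[PredictedLoop]:
    """Predict disulphide-loop candidates from sequence + state predictions.

    ``ss_prediction`` uses H/E/C per residue, ``acc_prediction`` uses
    e (exposed) / b (buried).  A Cys...Cys window is reported when:

    1. it starts and ends with cysteine,
    2. it has no internal cysteine,
    3. no interior residue is predicted helix (H) or sheet (E),
    4. strictly more window residues are exposed than buried (ties excluded).

    Overlapping candidates are all reported.
    """
    seq = sequence.upper()
    ss = ss_prediction.upper()
    acc = acc_prediction.lower()
    if not (len(seq) == len(ss) == len(acc)):
        raise ValueError(
            f"prediction length mismatch: seq {len(seq)}, ss {len(ss)}, acc {len(acc)}"
        )
    cys = [k + 1 for k, ch in enumerate(seq) if ch == "C"]
    out: list[PredictedLoop] = []
    for ai, i in enumerate(cys):
        for j in cys[ai + 1:]:
            if j - i + 1 > max_total_length:
                break
            interior = seq[i : j - 1]
            if j - i - 1 < interior_min:
                continue
            if "C" in interior:
                continue
            if any(ss[p] in "HE" for p in range(i, j - 1)):
                continue
            window = acc[i - 1 : j]
            n_exp = window.count("e")
            n_bur = window.count("b")
            if n_exp <= n_bur:
                continue
            out.append(
                PredictedLoop(
                    accession=accession, start=i, end=j, interior=interior,
                    mean_exposure=n_exp / len(window),
                )
            )
    return out


def read_prediction_profile(path) -> tuple[str, str, str]:
    """Read a per-residue prediction TSV (position, residue, ss, accessibility)."""
    seq, ss, acc = [], [], []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            _, residue, s, a = line.rstrip("\n").split("\t")
            seq.append(residue)
            ss.append(s)
            acc.append(a)
    return "".join(seq), "".join(ss), "".join(acc)


# ---------------------------------------------------------------------------
# similarity scoring

@dataclass(frozen=True)
class SimilarityResult:
    query_interior: str
    target_interior: str
    raw_score: float
    self_score: float

    @property
    def similarity(self) -> float:
        return self.raw_score / self.self_score


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float, mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aligner.mode = mode
    return aligner


def _check_interior(interior: str, role: str) -> str:
    seq = interior.upper()
    if not seq:
        raise ValueError(f"{role} interior is empty")
    bad = set(seq) - STANDARD_AA
    if bad:
        raise ValueError(f"{role} interior contains non-standard residue(s) {sorted(bad)}")
    return seq


def loop_similarity(
    query_interior: str,
    target_interior: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -12.0,
    gap_extend: float = -12.0,
    mode: str = "global",
) -> SimilarityResult:
    """Self-normalised alignment similarity of two loop interiors.

    The raw score is the optimal pairwise (dynamic-programming) alignment
    score of the interiors; the normaliser is the target (viral) interior
    aligned to itself.  The quotient is asymmetric in general and never
    exceeds 1.
    """
    q = _check_interior(query_interior, "query")
    t = _check_interior(target_interior, "target")
    aligner = _aligner(matrix, gap_open, gap_extend, mode)
    raw = float(aligner.score(q, t))
    self_score = float(aligner.score(t, t))
    if self_score <= 0:
        raise ValueError(f"target interior {t!r} has non-positive self score")
    return SimilarityResult(q, t, raw, self_score)


# ---------------------------------------------------------------------------
# interaction networks

_UNIPROT_ISOFORM = re.compile(r"^([A-Z][A-Z0-9]{5,9})-\d+$")


def _parse_interactor_id(fieldtext: str) -> Optional[str]:
    """Extract a protein accession from a MITAB interactor-ID field."""
    tokens = [t for t in fieldtext.strip().split("|") if t and t != "-"]
    if not tokens:
        return None
    preferred = [t for t in tokens if t.lower().startswith("uniprotkb:")] or tokens
    value = preferred[0].split(":", 1)[-1].strip().strip('"')
    if not value:
        return None
    m = _UNIPROT_ISOFORM.match(value)
    return m.group(1) if m else value


def _classify_taxon(fieldtext: str, virus_taxids: frozenset[str]) -> str:
    text = fieldtext.lower()
    ids = set(re.findall(r"taxid:(-?\d+)", text))
    if HUMAN_TAXID in ids:
        return "human"
    if ids & virus_taxids or "virus" in text:
        return "virus"
    return "other"


def parse_mitab(
    files: Union[str, Iterable],
    virus_taxids: Iterable[str] = (),
) -> nx.Graph:
    """Merge PSI-MITAB 2.5 files into one undirected interaction graph.

    Accessions come from the two interactor-ID columns (uniprotkb-prefixed
    IDs preferred, isoform suffixes collapsed to the parent accession);
    taxon columns label nodes human/virus/other (taxid 9606 = human; any
    taxid in ``virus_taxids`` or a taxon string containing "virus" =
    virus).  Duplicate edges merge with the union of their source tags;
    lines without two parsable IDs are skipped and counted.
    """
    if isinstance(files, (str, bytes, os.PathLike)) or hasattr(files, "read"):
        files = [files]
    vt = frozenset(str(t) for t in virus_taxids)
    graph = nx.Graph()
    for f in files:
        tag = getattr(f, "name", str(f))
        n_skipped = 0
        with open(f) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 2:
                    n_skipped += 1
                    continue
                ida = _parse_interactor_id(cols[0])
                idb = _parse_interactor_id(cols[1])
                if ida is None or idb is None or ida == idb:
                    n_skipped += 1
                    continue
                taxa = _classify_taxon(cols[9], vt) if len(cols) > 9 else "other"
                taxb = _classify_taxon(cols[10], vt) if len(cols) > 10 else "other"
                for node, taxon in ((ida, taxa), (idb, taxb)):
                    if node not in graph:
                        graph.add_node(node, taxon=taxon)
                    elif graph.nodes[node].get("taxon") == "other" and taxon != "other":
                        graph.nodes[node]["taxon"] = taxon
                if graph.has_edge(ida, idb):
                    graph.edges[ida, idb]["sources"].add(tag)
                else:
                    graph.add_edge(ida, idb, sources={tag})
        if n_skipped:
            logger.info("%s: skipped %d unparsable interaction line(s)", tag, n_skipped)
    return graph


# ---------------------------------------------------------------------------
# mimicry candidates

@dataclass(frozen=True)
class MimicryHit:
    human_accession: str
    human_loop: str   # full cyclic peptide, flanking cysteines included
    viral_accession: str
    viral_loop: str
    similarity: float
    shared_interactors: frozenset[str]


LoopInput = Union[DisulphideLoop, PredictedLoop, tuple[str, str]]


def _loop_records(items: Iterable[LoopInput]) -> list[tuple[str, str, str]]:
    """Normalise loop inputs to (accession, full loop peptide, interior)."""
    out = []
    for item in items:
        if isinstance(item, DisulphideLoop):
            acc = item.accession or item.source_id
            out.append((acc, "C" + item.interior + "C", item.interior))
        elif isinstance(item, PredictedLoop):
            out.append((item.accession, item.sequence, item.interior))
        else:
            acc, peptide = item
            out.append((acc, peptide.upper(), interior_of(peptide)))
    return out


def find_mimicry_candidates(
    human_loops: Iterable[LoopInput],
    viral_loops: Iterable[LoopInput],
    graph: nx.Graph,
    sim_threshold: float = DEFAULT_SIM_THRESHOLD,
    matrix: str = "BLOSUM62",
    gap_open: float = -12.0,
    gap_extend: float = -12.0,
    mode: str = "global",
) -> list[MimicryHit]:
    """Similar human/viral loop pairs whose proteins share an interactor.

    For every (human loop, viral loop) pair with self-normalised similarity
    strictly above ``sim_threshold``, a hit is emitted iff some protein X
    interacts with both the human and the viral protein; the shared
    interactor set is listed exhaustively.  Hits are sorted by descending
    similarity, then by accessions for a stable order.
    """
    hits: list[MimicryHit] = []
    for h_acc, h_pep, h_int in _loop_records(human_loops):
        if h_acc not in graph:
            continue
        h_nbrs = set(graph.neighbors(h_acc))
        for v_acc, v_pep, v_int in _loop_records(viral_loops):
            if v_acc not in graph:
                continue
            sim = loop_similarity(h_int, v_int, matrix=matrix, gap_open=gap_open,
                                  gap_extend=gap_extend, mode=mode).similarity
            if sim <= sim_threshold:
                continue
            shared = h_nbrs & set(graph.neighbors(v_acc)) - {h_acc, v_acc}
            if not shared:
                continue
            hits.append(
                MimicryHit(
                    human_accession=h_acc, human_loop=h_pep,
                    viral_accession=v_acc, viral_loop=v_pep,
                    similarity=sim, shared_interactors=frozenset(shared),
                )
            )
    hits.sort(key=lambda h: (-h.similarity, h.human_accession, h.viral_accession))
    return hits
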