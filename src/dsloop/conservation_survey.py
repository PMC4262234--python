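"""Evolutionary conservation of disulphide-bonded loop interiors.

Loops are read from sequence-level annotation tables (accession, sequence,
bond positions), conservation is scored per alignment column with the
Jensen-Shannon divergence between the column's residue distribution and a
background distribution, and each loop is summarised by the difference
between its interior mean score and the mean score of the juxtapeptide
flanks (up to ``flank_width`` reference positions on each side).  Loops
whose interior is much more conserved than the flanks (difference > 0.30
by default) are "preferentially conserved".

Because disulphide-forming cysteines are themselves strongly conserved,
the terminal cysteine columns never enter the interior mean; a loop is
considered alignable when at least one homolog row carries a cysteine in
both terminal columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO
from scipy import stats

from .loops import DisulphideLoop, filter_knotted

#: canonical amino-acid order used for every 20-vector in this package
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: k for k, a in enumerate(AA_ORDER)}

# BLOSUM62-derived background amino-acid frequencies (the distribution the
# matrix's log-odds were computed against), re-normalised to sum to 1.
_BLOSUM62_FREQS = {
    "A": 0.078, "R": 0.051, "N": 0.041, "D": 0.052, "C": 0.024,
    "Q": 0.034, "E": 0.059, "G": 0.083, "H": 0.025, "I": 0.062,
    "L": 0.092, "K": 0.056, "M": 0.024, "F": 0.044, "P": 0.043,
    "S": 0.059, "T": 0.055, "W": 0.014, "Y": 0.034, "V": 0.072,
}

GAP_CHARS = frozenset("-.")

DEFAULT_SEQ_INTERIOR_RANGE = (2, 8)
DEFAULT_FLANK_WIDTH = 4
DEFAULT_CONSERVATION_THRESHOLD = 0.30


def blosum62_background() -> np.ndarray:
    """BLOSUM62 background frequencies ordered by :data:`AA_ORDER`, sum 1."""
    v = np.array([_BLOSUM62_FREQS[a] for a in AA_ORDER], dtype=float)
    return v / v.sum()


# ---------------------------------------------------------------------------
# annotations

@dataclass(frozen=True)
class SeqLoopAnnotation:
    accession: str
    sequence: str
    bonds: tuple[tuple[int, int, bool], ...]  # (pos_a, pos_b, intrachain)
    family: str = ""


def parse_disulphide_annotations(path) -> tuple[list[SeqLoopAnnotation], list[str]]:
    """Read a disulphide annotation table (TSV).

    Columns: accession, sequence, bonds, [family].  Bonds are comma-joined
    ``a-b`` tokens (1-based cysteine positions); an ``:inter`` suffix marks
    an interchain bond, which is retained but flagged.

    Returns (annotations, errors): rows whose bond positions are not
    cysteines produce a record-level error message instead of an
    annotation; structurally malformed rows raise ``ValueError`` with the
    line number.
    """
    annotations: list[SeqLoopAnnotation] = []
    errors: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError("annotation file is empty (missing header row)")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected >= 3 tab-separated columns")
            accession, sequence = parts[0].strip(), parts[1].strip().upper()
            family = parts[3].strip() if len(parts) > 3 else ""
            bonds: list[tuple[int, int, bool]] = []
            bad = False
            for token in filter(None, (t.strip() for t in parts[2].split(","))):
                intra = True
                if token.endswith(":inter"):
                    intra = False
                    token = token[: -len(":inter")]
                try:
                    a_s, b_s = token.split("-")
                    a, b = int(a_s), int(b_s)
                except Exception as exc:
                    raise ValueError(f"line {lineno}: malformed bond token {token!r}") from exc
                if not (1 <= a <= len(sequence) and 1 <= b <= len(sequence)):
                    raise ValueError(f"line {lineno}: bond {a}-{b} outside sequence")
                if sequence[a - 1] != "C" or sequence[b - 1] != "C":
                    errors.append(
                        f"{accession}: bond {a}-{b} does not join two cysteines"
                    )
                    bad = True
                    continue
                bonds.append((min(a, b), max(a, b), intra))
            if not bad:
                annotations.append(
                    SeqLoopAnnotation(accession, sequence, tuple(bonds), family)
                )
    return annotations, errors


def extract_short_loops(
    annotations: Sequence[SeqLoopAnnotation],
    interior_range: tuple[int, int] = DEFAULT_SEQ_INTERIOR_RANGE,
) -> list[DisulphideLoop]:
    """Sequence-mode loops: intrachain bonds with a short interior.

    Interchain bonds are dropped; overlapping/interleaved bonds are removed
    by the same knot rules as the structural survey.  The knot rules see
    every intrachain bond of the protein, so a short loop nested inside a
    long bond is still rejected.
    """
    imin, imax = interior_range
    out: list[DisulphideLoop] = []
    for ann in annotations:
        intra = [(a, b) for a, b, flag in ann.bonds if flag]
        kept = filter_knotted(intra)
        for a, b in kept:
            if imin <= b - a - 1 <= imax:
                out.append(
                    DisulphideLoop(
                        source_id=ann.accession,
                        chain=None,
                        cys_i=a,
                        cys_j=b,
                        interior=ann.sequence[a : b - 1],
                        accession=ann.accession,
                    )
                )
    return out


def composition(
    loops: Sequence[DisulphideLoop],
    background: Optional[Mapping[str, float] | np.ndarray] = None,
) -> pd.DataFrame:
    """Amino-acid frequencies of loop interiors vs a background.

    Counts interior residues only — the bond-forming terminal cysteines are
    excluded by construction.  Returns a frame indexed by amino acid with
    loop_freq, background_freq and their ratio.
    """
    counts = np.zeros(20)
    total = 0
    for lp in loops:
        for aa in lp.interior:
            if aa in AA_INDEX:
                counts[AA_INDEX[aa]] += 1
                total += 1
    if total == 0:
        raise ValueError("no interior residues to count")
    if background is None:
        bg = blosum62_background()
    elif isinstance(background, Mapping):
        bg = np.array([background[a] for a in AA_ORDER], dtype=float)
    else:
        bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    freqs = counts / total
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bg > 0, freqs / bg, np.nan)
    return pd.DataFrame(
        {"loop_freq": freqs, "background_freq": bg, "ratio": ratio},
        index=pd.Index(list(AA_ORDER), name="aa"),
    )


# ---------------------------------------------------------------------------
# alignments + JS conservation

@dataclass(frozen=True)
class Alignment:
    """A reference-first multiple sequence alignment (rows of equal length)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise ValueError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def reference(self) -> str:
        return self.rows[0]

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        msa = AlignIO.read(path, "fasta")
        return cls(
            ids=tuple(rec.id for rec in msa),
            rows=tuple(str(rec.seq).upper() for rec in msa),
        )

    def ref_position_to_column(self) -> dict[int, int]:
        """Map 1-based ungapped reference positions to 0-based columns."""
        mapping: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(self.reference):
            if ch not in GAP_CHARS:
                pos += 1
                mapping[pos] = col
        return mapping


@dataclass(frozen=True)
class ConservationProfile:
    scores: np.ndarray        # per-column, in [0, 1]
    background: np.ndarray    # 20-vector over AA_ORDER
    gap_fractions: np.ndarray


def _js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Base-2 Jensen-Shannon divergence with equal mixture weights; in [0, 1]."""
    m = 0.5 * (p + q)

    def kl(a: np.ndarray, b: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def js_conservation(
    aln: Alignment,
    background: Optional[np.ndarray] = None,
    window: int = 0,
) -> ConservationProfile:
    """Per-column Jensen-Shannon conservation scores.

    Each column's amino-acid distribution (gaps and non-standard residues
    excluded) is compared with the background by base-2 JS divergence,
    which is already bounded by 1, then weighted by (1 - gap fraction) so
    gappy columns score low; all-gap columns score exactly 0.  ``window``
    columns of symmetric averaging may be applied afterwards (0 = off).
    """
    bg = blosum62_background() if background is None else np.asarray(background, float)
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background frequencies must sum to 1")
    n_rows = len(aln.rows)
    n_cols = aln.n_cols
    scores = np.zeros(n_cols)
    gap_frac = np.zeros(n_cols)
    for col in range(n_cols):
        counts = np.zeros(20)
        n_gap = 0
        for row in aln.rows:
            ch = row[col]
            if ch in AA_INDEX:
                counts[AA_INDEX[ch]] += 1
            else:
                n_gap += 1
        gap_frac[col] = n_gap / n_rows
        n_valid = counts.sum()
        if n_valid == 0:
            scores[col] = 0.0
            continue
        p = counts / n_valid
        scores[col] = _js_divergence(p, bg) * (1.0 - gap_frac[col])

    if window > 0:
        smoothed = np.empty_like(scores)
        for col in range(n_cols):
            lo, hi = max(0, col - window), min(n_cols, col + window + 1)
            smoothed[col] = scores[lo:hi].mean()
        scores = smoothed

    return ConservationProfile(scores=scores, background=bg, gap_fractions=gap_frac)


# ---------------------------------------------------------------------------
# loop records

@dataclass(frozen=True)
class LoopConservationRecord:
    accession: str
    span: tuple[int, int]
    interior_mean: float
    flank_mean: float
    difference: float
    cys_conserved: bool
    family: str = ""
    usable: bool = True


def map_loop_columns(
    loop: DisulphideLoop, aln: Alignment
) -> tuple[list[int], tuple[int, int], bool]:
    """Alignment columns of a loop's interior and terminal cysteines.

    ``cys_conserved`` is true when at least one homolog row (any row but
    the reference) carries a cysteine in *both* terminal columns; a gap or
    any other residue at either terminal disqualifies that row.
    """
    mapping = aln.ref_position_to_column()
    try:
        col_i = mapping[loop.cys_i]
        col_j = mapping[loop.cys_j]
    except KeyError as exc:
        raise ValueError(
            f"loop {loop.span} lies outside the reference row (position {exc})"
        ) from exc
    interior_cols = [mapping[p] for p in range(loop.cys_i + 1, loop.cys_j)
                     if p in mapping]
    cys_conserved = any(
        row[col_i] == "C" and row[col_j] == "C" for row in aln.rows[1:]
    )
    return interior_cols, (col_i, col_j), cys_conserved


def loop_flank_difference(
    profile: ConservationProfile,
    loop: DisulphideLoop,
    aln: Alignment,
    flank_width: int = DEFAULT_FLANK_WIDTH,
    other_loops: Sequence[DisulphideLoop] = (),
    family: str = "",
) -> LoopConservationRecord:
    """Interior-vs-juxtapeptide conservation difference for one loop.

    The interior mean runs over interior columns only (terminal cysteine
    columns excluded); the flank mean runs over up to ``flank_width``
    reference positions on each side of the loop, skipping positions off
    the sequence or inside any other loop's span.  Records without a
    usable flank position are flagged ``usable=False`` and carry NaN means.
    """
    interior_cols, _, cys_conserved = map_loop_columns(loop, aln)
    if not interior_cols:
        raise ValueError(f"loop {loop.span} has an empty interior")
    mapping = aln.ref_position_to_column()
    ref_len = len(mapping)

    def in_other_loop(pos: int) -> bool:
        return any(ol.cys_i <= pos <= ol.cys_j for ol in other_loops
                   if ol.span != loop.span)

    flank_cols = []
    for d in range(1, flank_width + 1):
        for pos in (loop.cys_i - d, loop.cys_j + d):
            if 1 <= pos <= ref_len and not in_other_loop(pos):
                flank_cols.append(mapping[pos])

    interior_mean = float(np.mean(profile.scores[interior_cols]))
    if not flank_cols:
        return LoopConservationRecord(
            accession=loop.accession or loop.source_id, span=loop.span,
            interior_mean=interior_mean, flank_mean=math.nan,
            difference=math.nan, cys_conserved=cys_conserved,
            family=family, usable=False,
        )
    flank_mean = float(np.mean(profile.scores[flank_cols]))
    return LoopConservationRecord(
        accession=loop.accession or loop.source_id, span=loop.span,
        interior_mean=interior_mean, flank_mean=flank_mean,
        difference=interior_mean - flank_mean, cys_conserved=cys_conserved,
        family=family, usable=True,
    )


def score_loops(
    aln: Alignment,
    loops: Sequence[DisulphideLoop],
    profile: Optional[ConservationProfile] = None,
    flank_width: int = DEFAULT_FLANK_WIDTH,
    require_cys_conserved: bool = True,
    family: str = "",
) -> list[LoopConservationRecord]:
    """Conservation records for all loops of one protein's alignment.

    By default only loops whose terminal cysteines align to cysteines in at
    least one homolog are scored (``require_cys_conserved=False`` keeps all).
    Unusable records (no flank) are returned flagged; callers exclude them
    from distributions.
    """
    if profile is None:
        profile = js_conservation(aln)
    records = []
    for lp in loops:
        rec = loop_flank_difference(profile, lp, aln, flank_width=flank_width,
                                    other_loops=loops, family=family)
        if require_cys_conserved and not rec.cys_conserved:
            continue
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# statistics

def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], alternative: str = "greater"
) -> tuple[float, float]:
    """One-sided Mann-Whitney U test (U of sample ``a``; midrank ties).

    Tie-free small samples (both sizes <= 20) use the exact null
    distribution; larger or tied samples use the tie-corrected normal
    approximation.  Degenerate all-tied input returns p = 0.5.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 0.5
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(a.size, b.size) <= 20) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def positional_profile(
    items: Iterable[tuple[ConservationProfile, Alignment, Sequence[DisulphideLoop]]],
    max_dist: int = 4,
) -> pd.DataFrame:
    """Conservation at distance d inside vs outside the bond, pooled over loops.

    For every loop and d = 1..max_dist, interior positions whose minimum
    distance to a terminal cysteine equals d go to the "inside" sample and
    positions d residues beyond the cysteines (outside every loop span) to
    the "outside" sample.  Reports per-distance means, standard errors and
    a one-sided Mann-Whitney p (inside > outside); distances with fewer
    than two contributing loops on either side are reported as missing.
    """
    inside: dict[int, list[float]] = {d: [] for d in range(1, max_dist + 1)}
    outside: dict[int, list[float]] = {d: [] for d in range(1, max_dist + 1)}
    n_loops_in: dict[int, int] = {d: 0 for d in range(1, max_dist + 1)}
    n_loops_out: dict[int, int] = {d: 0 for d in range(1, max_dist + 1)}

    for profile, aln, loops in items:
        mapping = aln.ref_position_to_column()
        ref_len = len(mapping)
        spans = [lp.span for lp in loops]
        for lp in loops:
            for d in range(1, max_dist + 1):
                ins = []
                for pos in range(lp.cys_i + 1, lp.cys_j):
                    if min(pos - lp.cys_i, lp.cys_j - pos) == d:
                        ins.append(profile.scores[mapping[pos]])
                outs = []
                for pos in (lp.cys_i - d, lp.cys_j + d):
                    if 1 <= pos <= ref_len and not any(
                        i <= pos <= j for i, j in spans
                    ):
                        outs.append(profile.scores[mapping[pos]])
                if ins:
                    inside[d].extend(ins)
                    n_loops_in[d] += 1
                if outs:
                    outside[d].extend(outs)
                    n_loops_out[d] += 1

    rows = []
    for d in range(1, max_dist + 1):
        ai, ao = np.array(inside[d]), np.array(outside[d])
        missing = n_loops_in[d] < 2 or n_loops_out[d] < 2
        if missing:
            rows.append({"distance": d, "inside_mean": math.nan,
                         "inside_se": math.nan, "outside_mean": math.nan,
                         "outside_se": math.nan, "n_inside": ai.size,
                         "n_outside": ao.size, "p": math.nan, "missing": True})
            continue
        _, p = mann_whitney_u(ai, ao, alternative="greater")
        rows.append({
            "distance": d,
            "inside_mean": float(ai.mean()),
            "inside_se": float(ai.std(ddof=1) / math.sqrt(ai.size)) if ai.size > 1 else math.nan,
            "outside_mean": float(ao.mean()),
            "outside_se": float(ao.std(ddof=1) / math.sqrt(ao.size)) if ao.size > 1 else math.nan,
            "n_inside": int(ai.size),
            "n_outside": int(ao.size),
            "p": p,
            "missing": False,
        })
    return pd.DataFrame(rows)


def preferentially_conserved(
    records: Sequence[LoopConservationRecord],
    threshold: float = DEFAULT_CONSERVATION_THRESHOLD,
) -> tuple[list[LoopConservationRecord], dict[str, int]]:
    """Records with interior-minus-flank difference strictly above threshold.

    Returns the subset plus a tally by family label; unlabelled records
    count under "Other".
    """
    subset = [r for r in records
              if r.usable and not math.isnan(r.difference) and r.difference > threshold]
    tally: dict[str, int] = {}
    for r in subset:
        label = r.family or "Other"
        tally[label] = tally.get(label, 0) + 1
    return subset, tally
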