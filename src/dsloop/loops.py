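"""Core loop objects shared by the structure and sequence surveys.

A disulphide-bonded loop is a short span of one protein chain whose two
terminal cysteines form an S-S bond, cyclising the interior residues.
Only non-overlapping ("non-knotted") loops qualify: spans that interleave,
share a cysteine, or enclose another bond's cysteine are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence


@dataclass(frozen=True)
class DisulphideLoop:
    """A Cys-...-Cys span on one chain or sequence.

    ``cys_i``/``cys_j`` are 1-based residue indices of the bond-forming
    cysteines (``cys_i < cys_j``); ``interior`` is the amino-acid string
    strictly between them.  ``source_id`` is the structure id in structure
    mode or the protein accession in sequence mode; ``accession`` may
    additionally carry the protein accession for structure-derived loops.
    """

    source_id: str
    chain: Optional[str]
    cys_i: int
    cys_j: int
    interior: str
    accession: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.cys_j <= self.cys_i:
            raise ValueError(f"cys_j must exceed cys_i, got ({self.cys_i}, {self.cys_j})")

    @property
    def interior_length(self) -> int:
        return self.cys_j - self.cys_i - 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.cys_i, self.cys_j)


def filter_knotted(bonds: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Drop cysteine-knot-like bonds from a same-chain candidate list.

    Rules, applied simultaneously over the full candidate set:

    1. two bonds sharing a cysteine endpoint -> both dropped;
    2. interleaved spans i1 < i2 < j1 < j2 -> both dropped;
    3. a bond whose interior contains another bond's cysteine -> dropped
       (for nested non-sharing spans this drops the outer, keeps the inner).

    Bonds are (i, j) index pairs with i < j; order of survivors preserved.
    """
    n = len(bonds)
    drop = [False] * n
    for a in range(n):
        ia, ja = bonds[a]
        if ja <= ia:
            raise ValueError(f"bond ({ia}, {ja}) is not ordered i < j")
        for b in range(a + 1, n):
            ib, jb = bonds[b]
            if {ia, ja} & {ib, jb}:
                drop[a] = drop[b] = True
            elif ia < ib < ja < jb or ib < ia < jb < ja:
                drop[a] = drop[b] = True
        for b in range(n):
            if b == a:
                continue
            ib, jb = bonds[b]
            if ia < ib < ja or ia < jb < ja:
                drop[a] = True
    return [bonds[k] for k in range(n) if not drop[k]]


def interior_of(loop_sequence: str) -> str:
    """Strip the flanking cysteines from a full cyclic-peptide sequence."""
    seq = loop_sequence.strip().upper()
    if len(seq) < 3 or not (seq.startswith("C") and seq.endswith("C")):
        raise ValueError(
            f"{loop_sequence!r} is not a disulphide loop sequence "
            "(must start and end with C and have a non-empty interior)"
        )
    return seq[1:-1]
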