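"""Pairwise-identity ranking of reference species against a query.

The survey's first-pass species assignment mimics a BLAST best-hit search,
but the reference sets here are desk-scale, so identity is computed against
every reference by direct comparison over shared unambiguous, ungapped
sites — no seeding heuristics or e-value model.  Ambiguity-compatible sites
(e.g. R vs A) count as mismatches for the identity percentage (conservative)
but are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seq_io import AMBIGUITY, ReferenceDB, Sequence, UNAMBIGUOUS

_CHARS = sorted(AMBIGUITY) + ["-"]
_CHAR_INDEX = {c: i for i, c in enumerate(_CHARS)}
_IS_BASE = np.array([c in UNAMBIGUOUS for c in _CHARS])
_COMPAT = np.zeros((len(_CHARS), len(_CHARS)), dtype=bool)
for _a in _CHARS:
    for _b in _CHARS:
        if _a != "-" and _b != "-":
            _COMPAT[_CHAR_INDEX[_a], _CHAR_INDEX[_b]] = bool(
                AMBIGUITY[_a] & AMBIGUITY[_b]
            )


_LUT = np.zeros(256, dtype=np.uint8)
for _c, _i in _CHAR_INDEX.items():
    _LUT[ord(_c)] = _i


def _encode(residues: str) -> np.ndarray:
    return _LUT[np.frombuffer(residues.encode(), dtype=np.uint8)]


def _ref_arrays(aln) -> tuple[np.ndarray, np.ndarray]:
    """Cached encoded reference matrix and unambiguous-base mask."""
    cached = getattr(aln, "_identity_cache", None)
    if cached is None or cached[0] != len(aln.sequences):
        arr = np.stack([_encode(s.residues) for s in aln.sequences])
        cached = (len(aln.sequences), arr, _IS_BASE[arr])
        aln._identity_cache = cached
    return cached[1], cached[2]


@dataclass(frozen=True)
class Hit:
    """One reference hit, with identity over the compared sites."""

    ref_id: str
    species: str
    identity_pct: float
    n_compared: int
    n_ambiguous_compatible: int = 0
    perfect: bool = False  # identity == 100
    strong: bool = False  # identity > 97


def identity(a: Sequence | str, b: Sequence | str) -> tuple[float, int, int]:
    """Percent identity over sites where both residues are unambiguous bases.

    Returns ``(identity_pct, n_compared, n_ambiguous_compatible)`` where the
    last term counts sites skipped for ambiguity but whose IUPAC expansions
    intersect.  Raises when no site is comparable.
    """
    ra = a.residues if isinstance(a, Sequence) else a
    rb = b.residues if isinstance(b, Sequence) else b
    if len(ra) != len(rb):
        raise ValueError("sequences differ in length")
    n = match = compat = 0
    for x, y in zip(ra, rb):
        if x in UNAMBIGUOUS and y in UNAMBIGUOUS:
            n += 1
            if x == y:
                match += 1
        elif x in AMBIGUITY and y in AMBIGUITY:
            if AMBIGUITY[x] & AMBIGUITY[y]:
                compat += 1
    if n == 0:
        raise ValueError("no comparable sites")
    return 100.0 * match / n, n, compat


def top_hits(
    query: Sequence, db: ReferenceDB, marker: str, n: int = 5
) -> list[Hit]:
    """Rank references by identity to a query already in reference frame.

    Hits are sorted descending by identity with ties broken by ``ref_id``;
    a hit at 100% is flagged ``perfect`` and one above 97% ``strong``.
    Raises when the query shares no comparable site with any reference.
    """
    aln = db.alignment(marker)
    if len(query) != aln.length:
        raise ValueError("query and reference differ in length")
    q = _encode(query.residues)
    q_base = _IS_BASE[q]
    arr, arr_base = _ref_arrays(aln)
    both = q_base[None, :] & arr_base
    nc = both.sum(axis=1)
    match = ((arr == q[None, :]) & both).sum(axis=1)
    compat = (_COMPAT[q[None, :], arr] & ~both).sum(axis=1)
    hits = []
    for k, ref in enumerate(aln.sequences):
        if nc[k] == 0:
            continue
        pct = 100.0 * match[k] / nc[k]
        hits.append(
            Hit(
                ref_id=ref.id,
                species=ref.species,
                identity_pct=float(pct),
                n_compared=int(nc[k]),
                n_ambiguous_compatible=int(compat[k]),
                perfect=(pct == 100.0),
                strong=(pct > 97.0),
            )
        )
    if not hits:
        raise ValueError(
            f"query {query.id}: zero comparable sites against every reference"
        )
    hits.sort(key=lambda h: (-h.identity_pct, h.ref_id))
    return hits[:n]


def best_species(hits: list[Hit]) -> Hit:
    """The leading hit (the similarity track's species call)."""
    return hits[0]


def write_hit_table(
    path: str | Path, table: dict[str, list[Hit]]
) -> None:
    """TSV of hits per query id."""
    rows = []
    for qid in sorted(table):
        for h in table[qid]:
            flags = ",".join(
                f for f, on in (("perfect", h.perfect), ("strong", h.strong))
                if on
            )
            rows.append(
                (qid, h.ref_id, h.species, round(h.identity_pct, 2),
                 h.n_compared, flags)
            )
    pd.DataFrame(
        rows,
        columns=["query_id", "ref_id", "species", "identity_pct",
                 "n_compared", "flags"],
    ).to_csv(path, sep="\t", index=False)
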