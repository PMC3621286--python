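"""Sequence and sample I/O.

Reads and writes aligned IUPAC DNA data (FASTA), the tab-separated sample
manifest of a market survey, and maps unaligned query fragments into the
coordinate frame of a pre-aligned reference set.

Conventions: coordinates are 0-based with half-open column ranges, the gap
character is ``'-'``, unknown residues are ``'N'``.  FASTA headers may follow
the ``id|species|marker`` dialect; plain headers yield ``species=None``.
IUPAC ambiguity codes are preserved on read and never silently resolved.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import pandas as pd
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN-")
UNAMBIGUOUS = frozenset("ACGT")

#: IUPAC code -> set of compatible unambiguous bases.
AMBIGUITY = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

MARKERS = ("cytb", "COI")

PRODUCT_TYPES = (
    "biltong", "carpaccio", "dry_sausage", "fresh_sausage", "mince_fresh",
    "smoked",
)

#: product types prepared as sausages, dissected at least twice
SAUSAGE_TYPES = ("dry_sausage", "fresh_sausage")


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the offending line number."""


class SequenceValidationError(ValueError):
    """A record contains characters outside the IUPAC DNA alphabet."""


@dataclass(frozen=True)
class Sequence:
    """A single (possibly gapped) DNA fragment.

    ``species`` is ``None`` for unidentified queries; ``marker`` is one of
    :data:`MARKERS`.
    """

    id: str
    residues: str
    species: str | None = None
    marker: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceValidationError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - IUPAC_DNA
        if bad:
            raise SequenceValidationError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class Alignment:
    """Equal-length gapped sequences; columns indexed 0-based."""

    sequences: list[Sequence]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment must contain at least one sequence")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        ids = [s.id for s in self.sequences]
        dup = [i for i, c in Counter(ids).items() if c > 1]
        if dup:
            raise ValueError(f"duplicate sequence ids: {dup}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def get(self, seq_id: str) -> Sequence:
        for s in self.sequences:
            if s.id == seq_id:
                return s
        raise KeyError(seq_id)

    def column(self, j: int) -> str:
        return "".join(s.residues[j] for s in self.sequences)


@dataclass
class SampleRecord:
    """One market sample: its label, product type and dissections.

    ``dissections`` is a list of ``(dissection_id, marker, sequence_id)``
    tuples; sausage products carry at least two dissected fractions.
    """

    sample_id: str
    commercial_label: str
    product_type: str
    dissections: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.product_type not in PRODUCT_TYPES:
            raise ValueError(f"unknown product type {self.product_type!r}")
        if not self.dissections:
            raise ValueError(f"sample {self.sample_id}: no dissections")


@dataclass
class ReferenceDB:
    """Per-marker reference alignments with a species class per sequence."""

    alignments: dict[str, Alignment]

    def __post_init__(self) -> None:
        for marker, aln in self.alignments.items():
            missing = [s.id for s in aln if s.species is None]
            if missing:
                raise ValueError(
                    f"{marker}: reference sequences without species: {missing}"
                )

    def markers(self) -> list[str]:
        return list(self.alignments)

    def alignment(self, marker: str) -> Alignment:
        return self.alignments[marker]

    def species(self, marker: str) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.alignments[marker]:
            seen.setdefault(s.species, None)
        return list(seen)

    def sequences_for(self, marker: str, species: str) -> list[Sequence]:
        return [s for s in self.alignments[marker] if s.species == species]


# ---------------------------------------------------------------------------
# FASTA

def _parse_header(header: str) -> tuple[str, str | None, str | None]:
    parts = header.split("|")
    seq_id = parts[0].strip()
    species = parts[1].strip() or None if len(parts) > 1 else None
    marker = parts[2].strip() or None if len(parts) > 2 else None
    return seq_id, species, marker


def read_fasta(path: str | Path, marker: str | None = None) -> list[Sequence]:
    """Read FASTA records, parsing ``id|species|marker`` headers when present.

    An explicit ``marker`` argument overrides any marker field in headers.
    Raises :class:`FastaParseError` on malformed input and
    :class:`SequenceValidationError` on illegal characters.
    """
    path = Path(path)
    # Pre-scan for records before the first header so we can report the line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: sequence data before first '>' header"
                )
            break
    out: list[Sequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id, species, hdr_marker = _parse_header(rec.description)
        out.append(
            Sequence(
                id=seq_id,
                residues=str(rec.seq).upper(),
                species=species,
                marker=marker or hdr_marker,
            )
        )
    return out


def write_fasta(path: str | Path, sequences: Iterable[Sequence]) -> None:
    records = []
    for s in sequences:
        header = s.id
        if s.species is not None or s.marker is not None:
            header = f"{s.id}|{s.species or ''}|{s.marker or ''}"
        records.append(SeqRecord(Seq(s.residues), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Manifest

MANIFEST_COLUMNS = [
    "sample_id", "label", "product_type", "dissection_id", "marker",
    "sequence_id",
]


def read_manifest(path: str | Path) -> list[SampleRecord]:
    """Read the tab-separated sample manifest (one row per dissection/marker)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    samples: dict[str, SampleRecord] = {}
    for row in df.itertuples(index=False):
        rec = samples.get(row.sample_id)
        if rec is None:
            rec = SampleRecord(
                sample_id=row.sample_id,
                commercial_label=row.label,
                product_type=row.product_type,
                dissections=[(row.dissection_id, row.marker, row.sequence_id)],
            )
            samples[row.sample_id] = rec
        else:
            rec.dissections.append(
                (row.dissection_id, row.marker, row.sequence_id)
            )
    return list(samples.values())


def write_manifest(path: str | Path, samples: Iterable[SampleRecord]) -> None:
    rows = []
    for s in samples:
        for dissection_id, marker, sequence_id in s.dissections:
            rows.append(
                (s.sample_id, s.commercial_label, s.product_type,
                 dissection_id, marker, sequence_id)
            )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Query mapping

def consensus(alignment: Alignment) -> str:
    """Majority-rule consensus over unambiguous bases; 'N' where none."""
    cols = []
    for j in range(alignment.length):
        counts = Counter(
            c for c in alignment.column(j) if c in UNAMBIGUOUS
        )
        if not counts:
            cols.append("N")
            continue
        best = max(counts.values())
        # lexicographic tie-break keeps the consensus deterministic
        cols.append(min(b for b, c in counts.items() if c == best))
    return "".join(cols)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    # end gaps free: short fragments may cover only part of the reference
    if hasattr(aligner, "end_insertion_score"):
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    else:  # pragma: no cover - older Bio.Align naming
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


def map_query_to_alignment(
    query: Sequence, ref: Alignment
) -> Sequence:
    """Re-express an ungapped query in the reference coordinate frame.

    Globally aligns the query against the reference consensus (match +1,
    mismatch -1, gap -2, end gaps free).  Reference columns not covered by
    the query are filled with ``'N'`` (leading/trailing) while internal
    deletions become ``'-'``; query insertions relative to the reference have
    no column and are dropped.  Emits a ``possible non-homolog`` warning when
    identity over covered columns falls below 50%.
    """
    if "-" in query.residues:
        raise ValueError(f"query {query.id} must be ungapped")
    cons = consensus(ref)
    aligner = _make_aligner()
    aln = aligner.align(cons, query.residues)[0]
    out = ["N"] * len(cons)
    covered_from, covered_to = None, 0
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            out[t0 + k] = query.residues[q0 + k]
        if covered_from is None:
            covered_from = t0
        covered_to = t1
    if covered_from is None:
        # no residue could be placed: degenerate non-homolog
        warnings.warn(
            f"query {query.id}: possible non-homolog (no alignable residues)",
            stacklevel=2,
        )
        return Sequence(
            id=query.id, residues="N" * len(cons), species=query.species,
            marker=query.marker,
        )
    # internal uncovered stretches are deletions relative to the reference
    for j in range(covered_from, covered_to):
        if out[j] == "N":
            out[j] = "-"
    mapped = "".join(out)
    n_cov = sum(
        1 for a, b in zip(mapped, cons) if a in UNAMBIGUOUS and b in UNAMBIGUOUS
    )
    n_match = sum(
        1
        for a, b in zip(mapped, cons)
        if a in UNAMBIGUOUS and b in UNAMBIGUOUS and a == b
    )
    if n_cov and n_match / n_cov < 0.5:
        warnings.warn(
            f"query {query.id}: possible non-homolog "
            f"({100 * n_match / n_cov:.1f}% identity to consensus)",
            stacklevel=2,
        )
    return Sequence(
        id=query.id, residues=mapped, species=query.species, marker=query.marker
    )


# ---------------------------------------------------------------------------
# Deletion masks

class NoOverlapError(ValueError):
    """A sequence pair shares no unambiguous, ungapped site."""


def pairwise_usable(a: Sequence | str, b: Sequence | str) -> set[int]:
    """Sites where both residues are unambiguous bases (pairwise deletion)."""
    ra = a.residues if isinstance(a, Sequence) else a
    rb = b.residues if isinstance(b, Sequence) else b
    if len(ra) != len(rb):
        raise ValueError("sequences differ in length")
    return {
        j for j, (x, y) in enumerate(zip(ra, rb))
        if x in UNAMBIGUOUS and y in UNAMBIGUOUS
    }


def deletion_mask(
    alignment: Alignment,
    mode: str = "partial",
    threshold: float = 0.95,
    pair: tuple[Sequence | str, Sequence | str] | None = None,
) -> set[int]:
    """Usable-site set under a missing-data treatment.

    ``pairwise`` (requires ``pair``): sites where both residues of the pair
    are in ACGT.  ``partial``: columns whose unambiguous fraction is at least
    ``threshold``.  ``complete``: columns free of gaps and ambiguities.
    """
    if mode == "pairwise":
        if pair is None:
            raise ValueError("pairwise mode requires a pair of sequences")
        return pairwise_usable(*pair)
    usable: set[int] = set()
    n = len(alignment)
    for j in range(alignment.length):
        col = alignment.column(j)
        frac = sum(1 for c in col if c in UNAMBIGUOUS) / n
        if mode == "partial":
            if frac >= threshold:
                usable.add(j)
        elif mode == "complete":
            if frac == 1.0:
                usable.add(j)
        else:
            raise ValueError(f"unknown deletion mode {mode!r}")
    return usable
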