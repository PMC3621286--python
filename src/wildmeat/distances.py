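"""Kimura 2-parameter distances and barcode-gap screening.

The K2P distance separates transition (P) and transversion (Q) proportions:

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Within-species summaries operate on unique sequences (haplotype collapse,
where equality ignores sites masked by the deletion mode), between-species
divergence is the net between-groups mean distance

    d_net = mean(d_between) - (mean(d_within_A) + mean(d_within_B)) / 2

with standard errors from bootstrap resampling of alignment columns.
Internal values are in substitutions/site; the x100 scale appears only in
reports.  Saturated pairs (log argument <= 0) raise, never clamp.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .seq_io import (
    Alignment,
    NoOverlapError,
    ReferenceDB,
    Sequence,
    UNAMBIGUOUS,
    pairwise_usable,
)

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


class SaturationError(ValueError):
    """K2P distance undefined: 1-2P-Q <= 0 or 1-2Q <= 0."""


@dataclass(frozen=True)
class DistanceResult:
    """K2P distance with its transition/transversion proportions."""

    d: float
    P: float
    Q: float
    n_sites: int


@dataclass(frozen=True)
class ThresholdConfig:
    """Published screening thresholds, all on the K2P x100 scale.

    ``within_max``/``between_min`` are the 1.5 / 2.5 within- and
    between-species guidelines; ``hebert_pct`` the 3% divergence threshold;
    ``fold_rule`` the 10-fold within-vs-between rule; ``B`` the bootstrap
    replicate count for standard errors.
    """

    within_max: float = 1.5
    between_min: float = 2.5
    hebert_pct: float = 3.0
    fold_rule: float = 10.0
    B: int = 1000

    def __post_init__(self) -> None:
        for name in ("within_max", "between_min", "hebert_pct", "fold_rule", "B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class GapRecord:
    """Per-species barcode-gap summary (quantities on the x100 scale)."""

    species: str
    max_within: float | None
    sister: str | None
    d_net: float | None
    se_net: float | None
    flags: dict[str, bool | None] = field(default_factory=dict)


def k2p(
    a: Sequence | str,
    b: Sequence | str,
    sites: Iterable[int] | None = None,
) -> DistanceResult:
    """K2P distance between two equal-length sequences.

    P and Q are computed over the pair's usable sites only: positions where
    both residues are unambiguous bases, intersected with ``sites`` when a
    column mask (e.g. from partial deletion) is supplied.
    """
    ra = a.residues if isinstance(a, Sequence) else a
    rb = b.residues if isinstance(b, Sequence) else b
    usable = pairwise_usable(ra, rb)
    if sites is not None:
        usable &= set(sites)
    n = len(usable)
    if n == 0:
        raise NoOverlapError("no usable sites shared by the pair")
    ts = tv = 0
    for j in usable:
        x, y = ra[j], rb[j]
        if x == y:
            continue
        if (x, y) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"distance undefined at P={P:.4f}, Q={Q:.4f} (saturation)"
        )
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return DistanceResult(d=d, P=P, Q=Q, n_sites=n)


def k2p_from_counts(P: float, Q: float) -> float:
    """Closed-form K2P distance from transition/transversion proportions."""
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError("saturated proportions")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def unique_sequences(sequences: list[Sequence]) -> list[Sequence]:
    """Collapse haplotypes: drop sequences identical to an earlier one.

    Equality ignores masked sites — two sequences are the same haplotype when
    they agree at every position where both are unambiguous.  Input order
    (then id) determines which representative is kept.
    """
    reps: list[Sequence] = []
    for s in sorted(sequences, key=lambda x: x.id):
        dup = False
        for r in reps:
            shared = pairwise_usable(s, r)
            if shared and all(s.residues[j] == r.residues[j] for j in shared):
                dup = True
                break
        if not dup:
            reps.append(s)
    return reps


_BASE_ORD = {ord(b): i for i, b in enumerate("ACGT")}
_TS_PARTNER_CODE = np.array([2, 3, 0, 1], dtype=np.uint8)


def _encode_bases(residues: str) -> np.ndarray:
    """uint8 codes 0-3 for ACGT, 255 for everything else."""
    raw = np.frombuffer(residues.encode(), dtype=np.uint8)
    codes = np.full(raw.shape, 255, dtype=np.uint8)
    for o, i in _BASE_ORD.items():
        codes[raw == o] = i
    return codes


def distance_matrix(
    sequences: list[Sequence], sites: Iterable[int] | None = None
) -> tuple[list[str], np.ndarray]:
    """Square symmetric K2P matrix (vectorized; same semantics as k2p)."""
    ids = [s.id for s in sequences]
    n = len(sequences)
    arr = np.stack([_encode_bases(s.residues) for s in sequences])
    unamb = arr < 4
    if sites is not None:
        col_ok = np.zeros(arr.shape[1], dtype=bool)
        col_ok[list(sites)] = True
        unamb = unamb & col_ok
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m = unamb[i] & unamb[j]
            ns = int(m.sum())
            if ns == 0:
                raise NoOverlapError(
                    f"no usable sites shared by {ids[i]} and {ids[j]}"
                )
            ai, aj = arr[i][m], arr[j][m]
            diff = ai != aj
            ts = int((_TS_PARTNER_CODE[ai[diff]] == aj[diff]).sum())
            P = ts / ns
            Q = (int(diff.sum()) - ts) / ns
            w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
            if w1 <= 0 or w2 <= 0:
                raise SaturationError(
                    f"saturated pair {ids[i]}/{ids[j]} (P={P:.3f}, Q={Q:.3f})"
                )
            d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
            mat[i, j] = mat[j, i] = d
    return ids, mat


def write_phylip_matrix(path: str | Path, ids: list[str], mat: np.ndarray) -> None:
    """PHYLIP-style square distance matrix (relaxed names, tab-separated)."""
    with open(path, "w") as fh:
        fh.write(f"{len(ids)}\n")
        for name, row in zip(ids, mat):
            fh.write(name + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


def max_within(
    db: ReferenceDB, species: str, marker: str
) -> float | None:
    """Maximum within-species K2P distance (x100) over unique sequences.

    Returns ``None`` ("not available") when the species has fewer than two
    sequences; a species whose sequences collapse to one haplotype has
    maximum 0.
    """
    seqs = db.sequences_for(marker, species)
    if len(seqs) < 2:
        return None
    uniq = unique_sequences(seqs)
    if len(uniq) < 2:
        return 0.0
    best = 0.0
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            best = max(best, k2p(uniq[i], uniq[j]).d)
    return 100.0 * best


def mean_within(db: ReferenceDB, species: str, marker: str) -> float:
    """Mean within-species K2P distance over unique-sequence pairs (0 if <2)."""
    uniq = unique_sequences(db.sequences_for(marker, species))
    if len(uniq) < 2:
        return 0.0
    ds = [
        k2p(uniq[i], uniq[j]).d
        for i in range(len(uniq))
        for j in range(i + 1, len(uniq))
    ]
    return float(np.mean(ds))


def _net_between_seqs(
    seqs_a: list[Sequence], seqs_b: list[Sequence]
) -> float:
    ua, ub = unique_sequences(seqs_a), unique_sequences(seqs_b)
    between = [k2p(x, y).d for x in ua for y in ub]
    d_ab = float(np.mean(between))

    def within(u: list[Sequence]) -> float:
        if len(u) < 2:
            return 0.0
        return float(np.mean([
            k2p(u[i], u[j]).d
            for i in range(len(u)) for j in range(i + 1, len(u))
        ]))

    return d_ab - (within(ua) + within(ub)) / 2.0


def _resample_columns(
    seqs: list[Sequence], cols: np.ndarray
) -> list[Sequence]:
    return [
        Sequence(
            id=s.id,
            residues="".join(s.residues[c] for c in cols),
            species=s.species,
            marker=s.marker,
        )
        for s in seqs
    ]


def net_between(
    db: ReferenceDB,
    species_a: str,
    species_b: str,
    marker: str,
    B: int = 1000,
    seed: int = 1,
) -> tuple[float, float]:
    """Net between-groups mean K2P distance and its bootstrap SE.

    The SE resamples alignment columns with replacement ``B`` times and
    recomputes the statistic; the point estimate uses the original columns.
    """
    if species_a == species_b:
        return 0.0, 0.0
    seqs_a = db.sequences_for(marker, species_a)
    seqs_b = db.sequences_for(marker, species_b)
    if not seqs_a or not seqs_b:
        raise KeyError(f"species missing from {marker} reference set")
    d_net = _net_between_seqs(seqs_a, seqs_b)
    length = len(seqs_a[0])
    rng = np.random.default_rng(seed)
    reps = np.empty(B)
    for b in range(B):
        cols = rng.integers(0, length, size=length)
        reps[b] = _net_between_seqs(
            _resample_columns(seqs_a, cols), _resample_columns(seqs_b, cols)
        )
    se = float(np.std(reps, ddof=1)) if B > 1 else 0.0
    return d_net, se


def gap_report(
    db: ReferenceDB,
    marker: str,
    sister_map: dict[str, str],
    cfg: ThresholdConfig | None = None,
    seed: int = 1,
) -> list[GapRecord]:
    """Per-species barcode-gap screen against its sister species.

    Flags (all on the x100 scale): ``within_ok`` max_within < within_max;
    ``between_ok`` d_net > between_min; ``hebert_ok`` max_within <
    hebert_pct; ``fold_ok`` d_net >= fold_rule x mean within; ``overlap``
    max_within >= d_net.  Species absent from ``sister_map`` are recorded
    with ``flags={'unevaluated': True}``.
    """
    cfg = cfg or ThresholdConfig()
    records = []
    for sp in db.species(marker):
        mw = max_within(db, sp, marker)
        sister = sister_map.get(sp)
        if sister is None:
            records.append(
                GapRecord(sp, mw, None, None, None, {"unevaluated": True})
            )
            continue
        d_net, se_net = net_between(db, sp, sister, marker, B=cfg.B, seed=seed)
        d_net100, se100 = 100.0 * d_net, 100.0 * se_net
        meanw100 = 100.0 * mean_within(db, sp, marker)
        flags: dict[str, bool | None] = {
            "within_ok": None if mw is None else mw < cfg.within_max,
            "between_ok": d_net100 > cfg.between_min,
            "hebert_ok": None if mw is None else mw < cfg.hebert_pct,
            "fold_ok": d_net100 >= cfg.fold_rule * meanw100,
            "overlap": None if mw is None else mw >= d_net100,
        }
        records.append(GapRecord(sp, mw, sister, d_net100, se100, flags))
    return records


def nearest_sisters(db: ReferenceDB, marker: str) -> dict[str, str]:
    """Sister map from the data: each species' nearest neighbor by d_net.

    A stand-in for an externally supplied sister map when no curated
    phylogeny is available.
    """
    species = db.species(marker)
    cache: dict[tuple[str, str], float] = {}

    def dnet(a: str, b: str) -> float:
        key = (min(a, b), max(a, b))
        if key not in cache:
            cache[key] = _net_between_seqs(
                db.sequences_for(marker, a), db.sequences_for(marker, b)
            )
        return cache[key]

    out = {}
    for sp in species:
        others = [o for o in species if o != sp]
        if not others:
            continue
        out[sp] = min(others, key=lambda o: (dnet(sp, o), o))
    return out


def gap_report_frame(records: list[GapRecord]) -> pd.DataFrame:
    """Tabular view of a gap report (one row per species)."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "species": r.species,
            "max_within": r.max_within,
            "sister": r.sister,
            "d_net": r.d_net,
            "se_net": r.se_net,
        }
        row.update(r.flags)
        rows.append(row)
    return pd.DataFrame(rows)
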