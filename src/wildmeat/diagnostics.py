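"""Character-based species diagnostics.

Learns, per species class, diagnostic residue states from a reference
alignment — single columns where a base is fixed within the class and absent
from every other class, or failing that a greedy conjunction of such fixed
columns that jointly excludes all other classes — and classifies queries
against the learned formulae with forensic non-exclusion semantics: an IUPAC
ambiguity at a diagnostic column whose expansion includes the diagnostic
residue cannot positively assign the query, but cannot rule the species out
either.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd

from .seq_io import AMBIGUITY, ReferenceDB, Sequence, UNAMBIGUOUS


@dataclass(frozen=True)
class DiagnosticRule:
    """A species plus a conjunction of (column, residue) literals.

    ``purity`` is the fraction of in-class training sequences matching the
    rule (1.0 for every emitted rule) and ``specificity`` the fraction of
    out-of-class sequences matching (0.0 for every emitted rule).
    """

    species: str
    literals: tuple[tuple[int, str], ...]
    purity: float = 1.0
    specificity: float = 0.0

    def __post_init__(self) -> None:
        if not self.literals:
            raise ValueError("rule needs at least one literal")
        cols = [c for c, _ in self.literals]
        if len(set(cols)) != len(cols):
            raise ValueError("literal columns must be distinct")


@dataclass
class ClassReport:
    """Training summary for one class."""

    species: str
    n_train: int
    diagnosable: bool
    efficiency: float  # fraction of in-class training sequences matched
    false_positives: list[str] = field(default_factory=list)
    misclassified: list[str] = field(default_factory=list)
    under_referenced: bool = False


@dataclass
class ClassifyOutcome:
    """Result of classifying one query.

    ``non_excluded``: the query carries an ambiguity at a diagnostic column
    compatible with the diagnostic residue — the species cannot be excluded.
    """

    status: str  # assigned | unassigned | non_excluded
    species: str | None = None
    matched_rule: DiagnosticRule | None = None
    ambiguous_sites: list[int] = field(default_factory=list)


def _fixed_columns(seqs: list[Sequence], length: int) -> dict[int, str]:
    """Columns where every sequence holds the same unambiguous base.

    Columns with a gap anywhere in the class are ineligible as literals.
    """
    fixed: dict[int, str] = {}
    for j in range(length):
        col = {s.residues[j] for s in seqs}
        if len(col) == 1:
            (b,) = col
            if b in UNAMBIGUOUS:
                fixed[j] = b
    return fixed


def _residue_matches(residue: str, base: str) -> str:
    """'exact', 'ambiguous' (expansion includes base) or 'no'."""
    if residue == base:
        return "exact"
    if residue in AMBIGUITY and base in AMBIGUITY[residue]:
        return "ambiguous"
    return "no"


def rule_matches(rule: DiagnosticRule, residues: str) -> tuple[str, list[int]]:
    """Match a query against one rule.

    Returns ``(status, ambiguous_sites)`` with status 'exact' (all literals
    hold with unambiguous residues), 'ambiguous' (compatible but at least one
    literal site is an IUPAC ambiguity), or 'no'.
    """
    ambiguous: list[int] = []
    for col, base in rule.literals:
        if col >= len(residues):
            raise ValueError("query shorter than reference frame")
        m = _residue_matches(residues[col], base)
        if m == "no":
            return "no", []
        if m == "ambiguous":
            ambiguous.append(col)
    return ("ambiguous" if ambiguous else "exact"), ambiguous


def learn(
    db: ReferenceDB,
    marker: str,
    max_literals: int = 3,
    min_ratio: float = 4.0,
    test_counts: dict[str, int] | None = None,
) -> tuple[dict[str, list[DiagnosticRule]], list[ClassReport]]:
    """Learn diagnostic rules for every species class of a marker.

    Single-column pure diagnostics are preferred; otherwise a conjunction of
    in-class-fixed columns is grown greedily (up to ``max_literals``),
    maximizing out-of-class exclusion.  Classes for which no sound rule
    exists are reported as undiagnosable and receive no rules.  Classes whose
    reference:test ratio falls below ``min_ratio`` are flagged
    under-referenced (a warning, not a failure).
    """
    aln = db.alignment(marker)
    classes = db.species(marker)
    if len(classes) < 2:
        raise ValueError("diagnostic learning needs at least 2 classes")
    length = aln.length
    members = {sp: db.sequences_for(marker, sp) for sp in classes}

    rules: dict[str, list[DiagnosticRule]] = {}
    reports: list[ClassReport] = []
    for sp in classes:
        ins = members[sp]
        outs = [s for other in classes if other != sp for s in members[other]]
        fixed = _fixed_columns(ins, length)

        def excludes(col: int, base: str, seq: Sequence) -> bool:
            return _residue_matches(seq.residues[col], base) == "no"

        # single-column pure diagnostics
        singles = [
            (col, base)
            for col, base in sorted(fixed.items())
            if all(excludes(col, base, o) for o in outs)
        ]
        sp_rules: list[DiagnosticRule] = []
        if singles:
            sp_rules = [
                DiagnosticRule(species=sp, literals=(lit,)) for lit in singles
            ]
        else:
            # greedy conjunction growth
            chosen: list[tuple[int, str]] = []
            remaining = list(outs)
            candidates = sorted(fixed.items())
            while remaining and len(chosen) < max_literals:
                best = None
                for col, base in candidates:
                    if any(col == c for c, _ in chosen):
                        continue
                    gain = sum(1 for o in remaining if excludes(col, base, o))
                    key = (-gain, col, base)
                    if best is None or key < best[0]:
                        best = (key, col, base, gain)
                if best is None or best[3] == 0:
                    break
                _, col, base, _ = best
                chosen.append((col, base))
                remaining = [o for o in remaining if not excludes(col, base, o)]
            if chosen and not remaining:
                sp_rules = [
                    DiagnosticRule(species=sp, literals=tuple(chosen))
                ]
        diagnosable = bool(sp_rules)
        if diagnosable:
            rules[sp] = sp_rules
        n_test = (test_counts or {}).get(sp)
        reports.append(
            ClassReport(
                species=sp,
                n_train=len(ins),
                diagnosable=diagnosable,
                efficiency=1.0 if diagnosable else 0.0,
                under_referenced=(
                    n_test is not None and n_test > 0
                    and len(ins) / n_test < min_ratio
                ),
            )
        )

    # misclassified training elements: members matching another class's rule
    for report in reports:
        for other_sp, other_rules in rules.items():
            if other_sp == report.species:
                continue
            for s in members[report.species]:
                if any(
                    rule_matches(r, s.residues)[0] == "exact"
                    for r in other_rules
                ):
                    report.misclassified.append(s.id)
        report.misclassified = sorted(set(report.misclassified))
    # false positives recorded on the rule-owning class
    by_sp = {r.species: r for r in reports}
    for sp, sp_rules in rules.items():
        fps = []
        for other in classes:
            if other == sp:
                continue
            for s in members[other]:
                if any(
                    rule_matches(r, s.residues)[0] == "exact" for r in sp_rules
                ):
                    fps.append(s.id)
        by_sp[sp].false_positives = sorted(set(fps))
    return rules, reports


def exhaustive_rules(
    db: ReferenceDB, marker: str, max_literals: int = 2
) -> dict[str, list[DiagnosticRule]]:
    """Reference learner: enumerate every sound conjunction up to a size.

    Intended as a correctness anchor for small instances; returns, per
    diagnosable class, all minimal sound rules (no sound proper sub-rule).
    """
    aln = db.alignment(marker)
    classes = db.species(marker)
    members = {sp: db.sequences_for(marker, sp) for sp in classes}
    out: dict[str, list[DiagnosticRule]] = {}
    for sp in classes:
        ins = members[sp]
        outs = [s for other in classes if other != sp for s in members[other]]
        fixed = sorted(_fixed_columns(ins, aln.length).items())
        sound: list[tuple[tuple[int, str], ...]] = []
        for k in range(1, max_literals + 1):
            for lits in combinations(fixed, k):
                if any(set(prev) <= set(lits) for prev in sound):
                    continue
                if all(
                    any(
                        _residue_matches(o.residues[c], b) == "no"
                        for c, b in lits
                    )
                    for o in outs
                ):
                    sound.append(lits)
        if sound:
            out[sp] = [DiagnosticRule(species=sp, literals=l) for l in sound]
    return out


def classify(
    query: Sequence | str, rules: dict[str, list[DiagnosticRule]],
    ref_length: int | None = None,
) -> ClassifyOutcome:
    """Classify a query (already in reference coordinates) against rules.

    Assigned iff exactly one species matches exactly; a single
    ambiguity-compatible species (and no exact match) yields non-exclusion;
    anything else is unassigned.  Deterministic and invariant to rule order.
    """
    residues = query.residues if isinstance(query, Sequence) else query
    if ref_length is not None and len(residues) != ref_length:
        raise ValueError(
            f"query length {len(residues)} != reference length {ref_length}"
        )
    exact: dict[str, DiagnosticRule] = {}
    ambiguous: dict[str, tuple[DiagnosticRule, list[int]]] = {}
    for sp in sorted(rules):
        for rule in rules[sp]:
            status, amb = rule_matches(rule, residues)
            if status == "exact":
                exact.setdefault(sp, rule)
            elif status == "ambiguous":
                ambiguous.setdefault(sp, (rule, amb))
    if len(exact) == 1:
        (sp, rule), = exact.items()
        return ClassifyOutcome(status="assigned", species=sp, matched_rule=rule)
    if len(exact) == 0 and len(ambiguous) == 1:
        (sp, (rule, amb)), = ambiguous.items()
        return ClassifyOutcome(
            status="non_excluded", species=sp, matched_rule=rule,
            ambiguous_sites=sorted(amb),
        )
    return ClassifyOutcome(status="unassigned")


def evaluate(
    rules: dict[str, list[DiagnosticRule]], held_out: list[Sequence]
) -> pd.DataFrame:
    """Per-class outcome percentages on a labeled held-out set."""
    if not held_out:
        raise ValueError("held-out set is empty")
    rows: dict[str, dict[str, int]] = {}
    for s in held_out:
        if s.species is None:
            raise ValueError(f"held-out sequence {s.id} is unlabeled")
        tally = rows.setdefault(
            s.species,
            {"n": 0, "assigned": 0, "unassigned": 0, "non_excluded": 0,
             "misassigned": 0},
        )
        tally["n"] += 1
        outcome = classify(s, rules)
        if outcome.status == "assigned":
            if outcome.species == s.species:
                tally["assigned"] += 1
            else:
                tally["misassigned"] += 1
        elif outcome.status == "non_excluded":
            tally["non_excluded"] += 1
        else:
            tally["unassigned"] += 1
    records = []
    for sp in sorted(rows):
        t = rows[sp]
        n = t["n"]
        records.append({
            "species": sp,
            "n": n,
            "pct_assigned": 100.0 * t["assigned"] / n,
            "pct_unassigned": 100.0 * t["unassigned"] / n,
            "pct_non_excluded": 100.0 * t["non_excluded"] / n,
            "pct_misassigned": 100.0 * t["misassigned"] / n,
        })
    return pd.DataFrame(records)


def write_rules(
    path: str | Path, rules: dict[str, list[DiagnosticRule]]
) -> None:
    """Serialize rules as TSV: species, column, residue, literal-group id."""
    rows = []
    for sp in sorted(rules):
        for gid, rule in enumerate(rules[sp]):
            for col, base in rule.literals:
                rows.append((sp, col, base, gid))
    pd.DataFrame(
        rows, columns=["species", "column", "residue", "group"]
    ).to_csv(path, sep="\t", index=False)


def read_rules(path: str | Path) -> dict[str, list[DiagnosticRule]]:
    df = pd.read_csv(path, sep="\t")
    rules: dict[str, list[DiagnosticRule]] = {}
    for (sp, _gid), grp in df.groupby(["species", "group"]):
        rules.setdefault(sp, []).append(
            DiagnosticRule(
                species=sp,
                literals=tuple(
                    (int(r.column), r.residue) for r in grp.itertuples()
                ),
            )
        )
    return rules
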