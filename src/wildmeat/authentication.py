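"""Per-marker species assignment, sample verdicts and substitution tables.

Three evidence tracks feed each assignment: pairwise-identity ranking
(similarity), species monophyly with bootstrap support on a tree containing
the query (phylogenetic), and the character-based diagnostic classifier.
A call is *validated* only when the tracks concur: perfect-or-strong
identity, monophyly with high support, and diagnostic assignment (or
non-exclusion).  Track disagreement falls back to the similarity leader at
reduced confidence.

A sample is scored *correct* when every marker/dissection assignment names
the species of its commercial label, and *false* when any does not; two or
more species across dissections flag a mixture.  Substitution statistics
aggregate verdicts by product type or by commercial label, with a game-only
percentage excluding the (all-correct) beef-labeled stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .diagnostics import ClassifyOutcome, DiagnosticRule, classify
from .phylo import MLConfig, Tree, monophyly
from .seq_io import ReferenceDB, SampleRecord, Sequence
from .similarity import top_hits


@dataclass
class MarkerAssignment:
    """Species call for one dissection/marker with its evidence trail."""

    sample_id: str
    dissection_id: str
    marker: str
    species_call: str | None
    confidence: str  # validated | similarity_only | non_excluded | unidentified
    identity_pct: float | None = None
    perfect: bool = False
    monophyletic: bool | None = None
    support: float | None = None
    diagnostic: ClassifyOutcome | None = None


@dataclass
class Verdict:
    """Authentication outcome for one market sample."""

    sample_id: str
    label: str
    product_type: str
    outcome: str  # correct | false | unresolved
    mixture: bool = False
    species_found: set[str] = field(default_factory=set)
    substitution_class: str = "none"  # none | domestic_or_alien | other_african_wild


@dataclass
class SubstitutionTable:
    """Counts and percentages of substitution, plus the overall summary.

    ``table`` has one row per group with N, n_false, pct (2 decimals) and
    pct_int (nearest integer, the precision used in narrative reporting).
    """

    table: pd.DataFrame
    total_n: int
    total_false: int
    overall_pct: float
    game_only_pct: float | None


def assign_marker(
    sample: SampleRecord,
    dissection_id: str,
    marker: str,
    query: Sequence,
    db: ReferenceDB,
    rules: dict[str, list[DiagnosticRule]],
    tree: Tree | None = None,
    cfg: MLConfig | None = None,
    mono_evidence: tuple[bool, float | None] | None = None,
) -> MarkerAssignment:
    """Combine the three evidence tracks into one species call.

    ``tree`` must contain the query as a tip (built on references plus this
    query); alternatively ``mono_evidence`` supplies a precomputed
    ``(is_monophyletic, support)`` pair (e.g. from a shared tree over all
    queries).  With neither, the phylogenetic track is skipped and the call
    cannot reach *validated* confidence.
    """
    cfg = cfg or MLConfig()
    if query is None:
        raise ValueError(
            f"sample {sample.sample_id}: no sequence for dissection "
            f"{dissection_id}/{marker}"
        )
    hits = top_hits(query, db, marker)
    lead = hits[0]
    sim_species = lead.species

    mono = None
    support = None
    if mono_evidence is not None:
        mono, support = mono_evidence
    elif tree is not None:
        species_tips = {s.id for s in db.sequences_for(marker, sim_species)}
        species_tips &= tree.tip_labels()
        mono, support = monophyly(tree, species_tips | {query.id})

    diag = classify(query, rules, ref_length=db.alignment(marker).length)

    strong = lead.perfect or lead.strong
    mono_ok = bool(mono) and (support is None or support >= cfg.support_high)
    diag_agrees = (
        diag.species == sim_species
        and diag.status in ("assigned", "non_excluded")
    )

    call: str | None = sim_species
    if strong and mono is not None and mono_ok and diag_agrees:
        # all three tracks concur
        confidence = (
            "non_excluded" if diag.status == "non_excluded" else "validated"
        )
    elif diag.status == "non_excluded" and diag.species == sim_species:
        confidence = "non_excluded"
    elif strong or diag.status in ("assigned", "non_excluded"):
        # partial evidence or track disagreement: similarity leader wins
        confidence = "similarity_only"
    else:
        confidence = "unidentified"
        call = None
    return MarkerAssignment(
        sample_id=sample.sample_id,
        dissection_id=dissection_id,
        marker=marker,
        species_call=call,
        confidence=confidence,
        identity_pct=lead.identity_pct,
        perfect=lead.perfect,
        monophyletic=mono,
        support=support,
        diagnostic=diag,
    )


def score_sample(
    assignments: list[MarkerAssignment],
    sample: SampleRecord,
    label_species: dict[str, str] | None = None,
    domestic_species: set[str] | None = None,
) -> Verdict:
    """Apply the concordance scoring rule to one sample's assignments.

    *Correct* iff every assignment resolves to the label's species; *false*
    when any resolved assignment names another species; *unresolved* when
    nothing contradicts the label but at least one assignment is uncalled.
    ``label_species`` maps commercial labels to species names (identity map
    by default); ``domestic_species`` drives the substitution class.
    """
    if not assignments:
        raise ValueError(f"sample {sample.sample_id}: no assignments")
    label_species = label_species or {}
    expected = label_species.get(
        sample.commercial_label, sample.commercial_label
    )
    calls = [a.species_call for a in assignments]
    found = {c for c in calls if c is not None}
    if any(c is not None and c != expected for c in calls):
        outcome = "false"
    elif all(c == expected for c in calls):
        outcome = "correct"
    else:
        outcome = "unresolved"
    mixture = len(found) >= 2
    sub_class = "none"
    if outcome == "false":
        foreign = found - {expected}
        domestic_species = domestic_species or set()
        if foreign & domestic_species:
            sub_class = "domestic_or_alien"
        else:
            sub_class = "other_african_wild"
    return Verdict(
        sample_id=sample.sample_id,
        label=sample.commercial_label,
        product_type=sample.product_type,
        outcome=outcome,
        mixture=mixture,
        species_found=found,
        substitution_class=sub_class,
    )


def substitution_stats(
    verdicts: list[Verdict],
    group_by: str = "product_type",
    beef_label: str = "Beef",
    beef_species: str = "Bos taurus",
) -> SubstitutionTable:
    """Aggregate verdicts into a substitution table.

    ``group_by`` is ``product_type`` or ``label``.  Percentages are
    100*n_false/N rounded to 2 decimals (pct) and to the nearest integer
    (pct_int).  The game-only percentage excludes the ``beef_label`` stratum
    and is rounded to 1 decimal, matching narrative precision.
    """
    if not verdicts:
        raise ValueError("no verdicts to summarize")
    unresolved = [v.sample_id for v in verdicts if v.outcome == "unresolved"]
    if unresolved:
        raise ValueError(f"unresolved verdicts: {unresolved[:5]}")
    key = {
        "product_type": lambda v: v.product_type,
        "label": lambda v: v.label,
    }[group_by]
    groups: dict[str, list[Verdict]] = {}
    for v in verdicts:
        groups.setdefault(key(v), []).append(v)
    rows = []
    for g in sorted(groups):
        vs = groups[g]
        n = len(vs)
        n_false = sum(1 for v in vs if v.outcome == "false")
        beef_sub = sum(
            1 for v in vs
            if v.outcome == "false" and beef_species in v.species_found
        )
        rows.append({
            group_by: g,
            "N": n,
            "n_false": n_false,
            "pct": round(100.0 * n_false / n, 2),
            "pct_int": int(round(100.0 * n_false / n)),
            "substituted_with_beef": beef_sub,
            "mixtures": sum(1 for v in vs if v.mixture),
            "species_found": ";".join(
                sorted({s for v in vs for s in v.species_found})
            ),
        })
    total_n = len(verdicts)
    total_false = sum(1 for v in verdicts if v.outcome == "false")
    overall = round(100.0 * total_false / total_n, 2)
    game = [v for v in verdicts if v.label != beef_label]
    game_only = (
        round(100.0 * sum(1 for v in game if v.outcome == "false") / len(game), 1)
        if game else None
    )
    return SubstitutionTable(
        table=pd.DataFrame(rows),
        total_n=total_n,
        total_false=total_false,
        overall_pct=overall,
        game_only_pct=game_only,
    )


def verdicts_frame(verdicts: list[Verdict]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "sample_id": v.sample_id,
            "label": v.label,
            "product_type": v.product_type,
            "outcome": v.outcome,
            "mixture": v.mixture,
            "species_found": ";".join(sorted(v.species_found)),
            "substitution_class": v.substitution_class,
        }
        for v in verdicts
    ])


def assignments_frame(assignments: list[MarkerAssignment]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "sample_id": a.sample_id,
            "dissection_id": a.dissection_id,
            "marker": a.marker,
            "species_call": a.species_call,
            "confidence": a.confidence,
            "identity_pct": (
                None if a.identity_pct is None else round(a.identity_pct, 2)
            ),
            "perfect": a.perfect,
            "monophyletic": a.monophyletic,
            "support": a.support,
            "diagnostic_status": (
                a.diagnostic.status if a.diagnostic else None
            ),
        }
        for a in assignments
    ])
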