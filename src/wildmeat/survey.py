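"""Published count structure of the South African game-meat market survey.

The survey's per-label and per-product substitution counts are the market's
ground truth at the aggregate level; this module expands them into a
consistent set of per-sample verdicts so that the substitution-statistics
machinery can be exercised (and its published percentages reproduced)
without the underlying sequence data.

The expansion solves a small transportation problem: per-label false and
correct counts are distributed over product types by north-west-corner
allocation so that both the per-label and per-product margins hold (both
total 146 samples, 101 false).  Beef is listed first and biltong is the
first product column, so the all-biltong beef stratum allocates correctly.
"""

from __future__ import annotations

from .authentication import Verdict

#: (label, species, N, correct, false, substituted_with_beef, mixtures)
LABEL_COUNTS = [
    ("Beef", "Bos taurus", 14, 14, 0, 0, 1),
    ("Blesbok", "Damaliscus pygargus", 2, 1, 1, 0, 0),
    ("Blue wildebeest", "Connochaetes taurinus", 1, 0, 1, 0, 0),
    ("Eland", "Tragelaphus oryx", 8, 1, 7, 2, 0),
    ("Game", "game", 5, 2, 3, 3, 0),
    ("Gemsbok", "Oryx gazella", 14, 4, 10, 3, 0),
    ("Impala", "Aepyceros melampus", 4, 2, 2, 1, 0),
    ("Kudu", "Tragelaphus strepsiceros", 39, 3, 36, 13, 5),
    ("Ostrich", "Struthio camelus", 23, 7, 16, 10, 5),
    ("Springbok", "Antidorcas marsupialis", 33, 8, 25, 11, 4),
    ("Warthog", "Phacochoerus africanus", 2, 2, 0, 0, 0),
    ("Zebra", "Equus burchelli", 1, 1, 0, 0, 0),
]

#: (product_type, N, false) — biltong first so beef's stratum fits there
PRODUCT_COUNTS = [
    ("biltong", 94, 65),
    ("carpaccio", 6, 2),
    ("dry_sausage", 29, 25),
    ("fresh_sausage", 2, 1),
    ("mince_fresh", 10, 5),
    ("smoked", 5, 3),
]


def _allocate(
    row_counts: list[tuple[str, int]], col_counts: list[tuple[str, int]]
) -> dict[tuple[str, str], int]:
    """North-west-corner allocation of a contingency table from its margins."""
    assert sum(n for _, n in row_counts) == sum(n for _, n in col_counts)
    alloc: dict[tuple[str, str], int] = {}
    cols = [[name, n] for name, n in col_counts]
    ci = 0
    for rname, remaining in row_counts:
        while remaining > 0:
            cname, avail = cols[ci]
            take = min(remaining, avail)
            if take > 0:
                alloc[(rname, cname)] = alloc.get((rname, cname), 0) + take
                cols[ci][1] -= take
                remaining -= take
            if cols[ci][1] == 0 and remaining > 0:
                ci += 1
            elif cols[ci][1] == 0 and remaining == 0:
                ci += 1
    return alloc


def survey_verdicts() -> list[Verdict]:
    """Per-sample verdicts consistent with the published count tables.

    False and correct samples are allocated to product types separately so
    both margins are honored; mixture flags are attached per label (to false
    verdicts where possible).  Species-found sets carry the label species
    for correct samples and a generic beef substitution for the counted
    beef-substituted samples (the per-sample species identities of the real
    market are not recoverable from counts alone).
    """
    false_rows = [(lab, f) for lab, _, _, _, f, _, _ in LABEL_COUNTS]
    correct_rows = [(lab, c) for lab, _, _, c, _, _, _ in LABEL_COUNTS]
    false_cols = [(p, f) for p, _, f in PRODUCT_COUNTS]
    correct_cols = [(p, n - f) for p, n, f in PRODUCT_COUNTS]
    false_alloc = _allocate(false_rows, false_cols)
    correct_alloc = _allocate(correct_rows, correct_cols)

    info = {lab: (sp, beef, mix) for lab, sp, _, _, _, beef, mix in LABEL_COUNTS}
    verdicts: list[Verdict] = []
    counter = 0
    per_label_done: dict[str, dict[str, int]] = {}
    for (lab, product), k in sorted(false_alloc.items()):
        sp, n_beef, _ = info[lab]
        for _ in range(k):
            done = per_label_done.setdefault(lab, {"beef": 0})
            with_beef = done["beef"] < n_beef
            if with_beef:
                done["beef"] += 1
            counter += 1
            verdicts.append(
                Verdict(
                    sample_id=f"M{counter:03d}",
                    label=lab,
                    product_type=product,
                    outcome="false",
                    species_found=(
                        {"Bos taurus"} if with_beef else {"substitute"}
                    ),
                    substitution_class=(
                        "domestic_or_alien" if with_beef
                        else "other_african_wild"
                    ),
                )
            )
    for (lab, product), k in sorted(correct_alloc.items()):
        sp, _, _ = info[lab]
        for _ in range(k):
            counter += 1
            verdicts.append(
                Verdict(
                    sample_id=f"M{counter:03d}",
                    label=lab,
                    product_type=product,
                    outcome="correct",
                    species_found={sp},
                )
            )
    # mixture flags per label, preferring false verdicts
    for lab, _, _, _, _, _, n_mix in LABEL_COUNTS:
        if n_mix == 0:
            continue
        candidates = [v for v in verdicts if v.label == lab]
        candidates.sort(key=lambda v: (v.outcome != "false", v.sample_id))
        for v in candidates[:n_mix]:
            v.mixture = True
    verdicts.sort(key=lambda v: v.sample_id)
    return verdicts
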