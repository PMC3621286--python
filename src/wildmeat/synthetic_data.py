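"""Forward simulation of reference databases and mislabeled markets.

Sequences evolve under the same K80 process the inference side assumes
(transition/transversion rate ratio ``kappa``, uniform rates among sites;
an optional gamma-rates toggle exists for misspecification experiments
only).  Each species carries within-species diversity arranged in
phylogeographic clusters (two by default, echoing the east/south splits
common in African ungulates), and markets draw commercially labeled samples
whose true species is substituted with a configurable probability, with
two-species mixtures across the dissections of sausage products.

Species names come from a packaged fictional taxonomy with designated
domestic/alien members so substitution-class logic is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import Tree, k80_transition_matrix
from .seq_io import (
    Alignment,
    ReferenceDB,
    SampleRecord,
    SAUSAGE_TYPES,
    Sequence,
)

BASES = "ACGT"

#: fictional game species available as commercial labels
GAME_SPECIES = (
    "Antidorca saliens",
    "Tragelaphoides spiralis",
    "Oryxion arenarius",
    "Strouthia cursor",
    "Aepyceron fulvus",
    "Damalina albifrons",
    "Connochaeton niger",
    "Kobos palustris",
    "Sylvicapron umbra",
    "Girafella reticulata",
)

#: fictional domestic or extra-continental species (substitutes only)
DOMESTIC_ALIEN_SPECIES = (
    "Bovina pratensis",
    "Equulea vectrix",
    "Suina glandifer",
    "Ovicula lanata",
    "Macropella saltatrix",
)

#: ambiguity code covering {base, its transition partner}
_AMBIG_FOR = {"A": "R", "G": "R", "C": "Y", "T": "Y"}

#: market product-type composition, echoing a dried-meat dominated survey
PRODUCT_WEIGHTS = {
    "biltong": 0.64,
    "dry_sausage": 0.20,
    "mince_fresh": 0.07,
    "carpaccio": 0.04,
    "smoked": 0.03,
    "fresh_sausage": 0.02,
}


@dataclass
class SimConfig:
    """Study-condition parameters of the simulated survey.

    ``species_tree_depth`` (expected substitutions/site between sister
    species, 0.10) and ``within_theta`` (expected within-species pairwise
    distance, 0.01) put the default regime deep in the barcode gap: within
    < 1.5 (x100), net between > 2.5, and the 10-fold rule holds.
    ``p_sub`` = 0.69 and ``p_mix`` = 0.48 mirror the observed market rates
    (101/146 substituted samples; 15 mixtures among 31 sausages).  Fragment
    lengths are the 358-bp cytb and 650-bp COI fragments.
    """

    n_species: int = 6
    species_tree_depth: float = 0.10
    kappa: float = 4.0
    within_theta: float = 0.01
    n_pop_clusters: int = 2
    frag_lengths: dict[str, int] = field(
        default_factory=lambda: {"cytb": 358, "COI": 650}
    )
    n_refs_per_species: int = 6
    n_samples: int = 100
    p_sub: float = 0.69
    p_mix: float = 0.48
    p_ambig: float = 0.001
    gamma_rates: float | None = None  # shape; None = uniform rates
    seed: int = 1

    def __post_init__(self) -> None:
        for p in ("p_sub", "p_mix", "p_ambig"):
            if not 0.0 <= getattr(self, p) <= 1.0:
                raise ValueError(f"{p} must be in [0, 1]")
        if any(l < 50 for l in self.frag_lengths.values()):
            raise ValueError("fragment lengths must be >= 50")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.n_species > len(GAME_SPECIES) + len(DOMESTIC_ALIEN_SPECIES):
            raise ValueError("not enough packaged species names")


def species_names(n_species: int) -> list[str]:
    """The first ``n_species`` packaged names: game first, then domestic."""
    pool = list(GAME_SPECIES) + list(DOMESTIC_ALIEN_SPECIES)
    return pool[:n_species]


def domestic_or_alien(species: str) -> bool:
    return species in DOMESTIC_ALIEN_SPECIES


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def evolve(
    parent_seq: str,
    t: float,
    kappa: float,
    rng: np.random.Generator,
    site_rates: np.ndarray | None = None,
) -> str:
    """Evolve a sequence for branch length ``t`` under K80.

    Per-site substitution follows the K80 transition probabilities at
    distance ``t`` (scaled by ``site_rates`` when supplied).
    """
    if t < 0:
        raise ValueError("branch length must be non-negative")
    codes = np.frombuffer(parent_seq.encode(), dtype=np.uint8)
    idx = np.zeros(len(parent_seq), dtype=np.int64)
    for i, b in enumerate(BASES):
        idx[codes == ord(b)] = i
    u = rng.random(len(idx))
    if site_rates is None:
        cum = np.cumsum(k80_transition_matrix(t, kappa), axis=1)
        child_idx = (cum[idx] < u[:, None]).sum(axis=1)
    else:
        child_idx = idx.copy()
        for rate in np.unique(site_rates):
            mask = site_rates == rate
            cum = np.cumsum(k80_transition_matrix(t * rate, kappa), axis=1)
            child_idx[mask] = (cum[idx[mask]] < u[mask, None]).sum(axis=1)
    out = np.empty(len(idx), dtype="U1")
    for i, b in enumerate(BASES):
        out[child_idx == i] = b
    return "".join(out)


def _random_species_tree(
    names: list[str], depth: float, rng: np.random.Generator
) -> Tree:
    """Random unrooted binary topology; every edge depth/2 long.

    Sister species then sit ``depth`` apart and non-sisters further, giving
    an unambiguous deep-split structure.
    """
    tree = Tree()
    half = depth / 2.0
    roots = [tree.new_node(label=name) for name in names]
    while len(roots) > 3:
        i, j = sorted(rng.choice(len(roots), size=2, replace=False))
        u = tree.new_node()
        tree.add_edge(roots[i], u, half)
        tree.add_edge(roots[j], u, half)
        roots = [r for k, r in enumerate(roots) if k not in (i, j)] + [u]
    center = tree.new_node()
    for r in roots:
        tree.add_edge(r, center, half)
    return tree


def _tip_depths(tree: Tree) -> dict[str, float]:
    """Path length from an arbitrary root tip to every tip."""
    root = tree.tips()[min(tree.tip_labels())]
    depths = {root: 0.0}
    stack = [root]
    while stack:
        u = stack.pop()
        for v, l in tree.adj[u].items():
            if v not in depths:
                depths[v] = depths[u] + l
                stack.append(v)
    return {lab: depths[nid] for nid, lab in tree.labels.items()}


def _species_ancestors(
    tree: Tree, length: int, kappa: float, rng: np.random.Generator,
    site_rates: np.ndarray | None,
) -> dict[str, str]:
    """Evolve a root sequence down the species tree to every tip."""
    root_tip = tree.tips()[min(tree.tip_labels())]
    root = next(iter(tree.adj[root_tip]))
    seqs = {root: random_sequence(length, rng)}
    out: dict[str, str] = {}
    stack = [root]
    seen = {root}
    while stack:
        u = stack.pop()
        for v in sorted(tree.adj[u]):
            if v in seen:
                continue
            seen.add(v)
            seqs[v] = evolve(seqs[u], tree.adj[u][v], kappa, rng, site_rates)
            if v in tree.labels:
                out[tree.labels[v]] = seqs[v]
            else:
                stack.append(v)
    return out


@dataclass
class Population:
    """Per-species, per-marker cluster ancestors used to draw individuals."""

    cluster_ancestors: list[str]
    tip_branch: float


def simulate_reference_db(
    cfg: SimConfig,
) -> tuple[ReferenceDB, Tree, dict[str, dict[str, Population]]]:
    """Simulate a reference database and return the generating species tree.

    Within-species structure: ``n_pop_clusters`` cluster ancestors sit at
    distance c from the species ancestor and individuals at distance w from
    their cluster ancestor, with w = theta/4 and c chosen so the expected
    pairwise within-species distance equals ``within_theta``.  References
    are spread evenly over clusters.  Returns ``(db, species_tree,
    populations)``; populations allow markets to draw fresh individuals from
    the same process.
    """
    rng = np.random.default_rng(cfg.seed)
    names = species_names(cfg.n_species)
    tree = _random_species_tree(
        sorted(names), cfg.species_tree_depth, rng
    )
    k = cfg.n_pop_clusters
    n = cfg.n_refs_per_species
    # individuals sit w from their cluster ancestor, cluster ancestors c from
    # the species ancestor; with f the cross-cluster fraction of reference
    # pairs, the expected mean pairwise within-species distance is
    # 2w + 2cf, solved to equal within_theta
    cluster_sizes = [len(range(j, n, k)) for j in range(k)]
    total_pairs = n * (n - 1) / 2
    cross_pairs = (n * n - sum(m * m for m in cluster_sizes)) / 2
    f = cross_pairs / total_pairs if total_pairs else 0.0
    if k == 1 or f == 0.0:
        w = cfg.within_theta / 2.0
        c = 0.0
    else:
        w = cfg.within_theta / 4.0
        c = cfg.within_theta / (4.0 * f)
    alignments: dict[str, Alignment] = {}
    populations: dict[str, dict[str, Population]] = {}
    for marker, length in cfg.frag_lengths.items():
        site_rates = None
        if cfg.gamma_rates is not None:
            site_rates = rng.gamma(
                cfg.gamma_rates, 1.0 / cfg.gamma_rates, size=length
            )
        ancestors = _species_ancestors(tree, length, cfg.kappa, rng, site_rates)
        populations[marker] = {}
        seqs: list[Sequence] = []
        for sp in sorted(names):
            clusters = [
                evolve(ancestors[sp], c, cfg.kappa, rng, site_rates)
                for _ in range(k)
            ]
            populations[marker][sp] = Population(
                cluster_ancestors=clusters, tip_branch=w
            )
            for i in range(cfg.n_refs_per_species):
                anc = clusters[i % k]
                residues = evolve(anc, w, cfg.kappa, rng, site_rates)
                seqs.append(
                    Sequence(
                        id=f"{sp.split()[0][:3]}{sp.split()[1][:3]}_"
                           f"{marker}_{i}",
                        residues=residues,
                        species=sp,
                        marker=marker,
                    )
                )
        alignments[marker] = Alignment(seqs)
    return ReferenceDB(alignments), tree, populations


def _inject_ambiguities(
    residues: str, p: float, rng: np.random.Generator
) -> str:
    if p == 0.0:
        return residues
    chars = list(residues)
    hits = np.nonzero(rng.random(len(chars)) < p)[0]
    for j in hits:
        chars[j] = _AMBIG_FOR[chars[j]]
    return "".join(chars)


def simulate_market(
    cfg: SimConfig,
    db: ReferenceDB,
    populations: dict[str, dict[str, Population]],
    seed: int | None = None,
) -> tuple[list[SampleRecord], dict[str, Sequence], pd.DataFrame]:
    """Simulate a labeled market with known substitutions.

    Each sample gets a game-species commercial label and a product type;
    with probability ``p_sub`` the true species is redrawn from the other
    species (domestic/alien included).  Sausages carry two dissections and,
    with probability ``p_mix``, a second species in the second dissection.
    Both markers are sequenced per dissection, with IUPAC ambiguities
    injected at rate ``p_ambig``.

    Returns ``(samples, sequences by id, truth table)``; the truth table has
    one row per sample with its label, true species set, and flags.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    names = species_names(cfg.n_species)
    game = [s for s in names if not domestic_or_alien(s)] or names
    product_types = list(PRODUCT_WEIGHTS)
    weights = np.array([PRODUCT_WEIGHTS[p] for p in product_types])
    weights = weights / weights.sum()

    samples: list[SampleRecord] = []
    seq_store: dict[str, Sequence] = {}
    truth_rows = []
    for i in range(cfg.n_samples):
        sid = f"S{i:04d}"
        label = game[rng.integers(len(game))]
        product = product_types[
            int(rng.choice(len(product_types), p=weights))
        ]
        substituted = bool(rng.random() < cfg.p_sub)
        if substituted:
            others = [s for s in names if s != label]
            true_primary = others[rng.integers(len(others))]
        else:
            true_primary = label
        is_sausage = product in SAUSAGE_TYPES
        species_per_dissection = [true_primary]
        mixed = False
        if is_sausage:
            if rng.random() < cfg.p_mix:
                others = [s for s in names if s != true_primary]
                species_per_dissection.append(
                    others[rng.integers(len(others))]
                )
                mixed = True
            else:
                species_per_dissection.append(true_primary)
        dissections = []
        for d, true_sp in enumerate(species_per_dissection):
            for marker in db.markers():
                pop = populations[marker][true_sp]
                anc = pop.cluster_ancestors[
                    rng.integers(len(pop.cluster_ancestors))
                ]
                residues = evolve(anc, pop.tip_branch, cfg.kappa, rng)
                residues = _inject_ambiguities(residues, cfg.p_ambig, rng)
                seq_id = f"{sid}_d{d}_{marker}"
                seq_store[seq_id] = Sequence(
                    id=seq_id, residues=residues, marker=marker
                )
                dissections.append((f"d{d}", marker, seq_id))
        samples.append(
            SampleRecord(
                sample_id=sid,
                commercial_label=label,
                product_type=product,
                dissections=dissections,
            )
        )
        truth_rows.append({
            "sample_id": sid,
            "label": label,
            "product_type": product,
            "true_species": ";".join(sorted(set(species_per_dissection))),
            "substituted": substituted or any(
                sp != label for sp in species_per_dissection
            ),
            "mixture": mixed,
        })
    truth = pd.DataFrame(truth_rows)
    return samples, seq_store, truth
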