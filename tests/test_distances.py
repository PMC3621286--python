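"""K2P distance engine: closed forms, properties, summaries, bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wildmeat.distances import (
    SaturationError,
    ThresholdConfig,
    _net_between_seqs,
    gap_report,
    k2p,
    k2p_from_counts,
    max_within,
    mean_within,
    net_between,
    unique_sequences,
)
from wildmeat.seq_io import NoOverlapError, Sequence
from tests.conftest import make_db

dna = st.text(alphabet="ACGT", min_size=4, max_size=40)


class TestK2P:
    def test_identical_sequences_zero(self):
        r = k2p("ACGTACGT", "ACGTACGT")
        assert (r.d, r.P, r.Q) == (0.0, 0.0, 0.0)

    def test_closed_form_p10_q05(self):
        assert k2p_from_counts(0.1, 0.05) == pytest.approx(0.17018, abs=1e-5)

    def test_single_transition_in_four_sites(self):
        r = k2p("ACGT", "GCGT")
        assert r.P == 0.25 and r.Q == 0.0
        assert r.d == pytest.approx(-0.5 * math.log(0.5), abs=1e-12)
        assert r.d == pytest.approx(0.34657, abs=1e-5)

    def test_ambiguous_sites_excluded(self):
        # site 0 ambiguous in a: only 3 usable sites, 1 transition
        r = k2p("RCGT", "ACGA")  # site 3 T->A transversion
        assert r.n_sites == 3
        assert r.Q == pytest.approx(1 / 3)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p("ACAC", "CACA")  # all transversions, Q=1

    def test_no_overlap_raises(self):
        with pytest.raises(NoOverlapError):
            k2p("NNNN", "ACGT")

    @settings(max_examples=100, derandomize=True)
    @given(dna, dna)
    def test_symmetry(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        try:
            ra = k2p(a, b)
        except SaturationError:
            return
        rb = k2p(b, a)
        assert ra == rb

    @settings(max_examples=100, derandomize=True)
    @given(dna)
    def test_self_distance_zero(self, a):
        assert k2p(a, a).d == 0.0

    def test_adding_a_difference_strictly_increases_d(self):
        a = "ACGTACGTACGTACGTACGT"
        b = a[:19] + "G"  # one transition
        c = "G" + b[1:]  # a second transition
        assert k2p(a, b).d < k2p(a, c).d

    def test_k2p_at_least_jc_on_random_pairs(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        checked = 0
        while checked < 1000:
            n = 60
            a = bases[rng.integers(4, size=n)]
            b = a.copy()
            mut = rng.random(n) < 0.15
            b[mut] = bases[rng.integers(4, size=mut.sum())]
            try:
                r = k2p("".join(a), "".join(b))
            except SaturationError:
                continue
            p = r.P + r.Q
            if p >= 0.74:
                continue
            jc = -0.75 * math.log(1 - 4 * p / 3)
            assert r.d >= jc - 1e-12
            checked += 1


class TestDistanceMatrix:
    def test_matches_scalar_k2p_with_ambiguities(self):
        from wildmeat.distances import distance_matrix

        rng = np.random.default_rng(6)
        bases = np.array(list("ACGT"))
        anc = rng.choice(bases, size=50)
        seqs = []
        for i in range(6):
            row = anc.copy()
            mut = rng.random(50) < 0.08
            row[mut] = bases[rng.integers(4, size=mut.sum())]
            amb = rng.random(50) < 0.05
            row[amb] = rng.choice(np.array(list("RN-")), size=amb.sum())
            seqs.append(Sequence(f"s{i}", "".join(row)))
        ids, mat = distance_matrix(seqs)
        for i in range(6):
            for j in range(i + 1, 6):
                assert mat[i, j] == pytest.approx(k2p(seqs[i], seqs[j]).d)

    def test_respects_column_mask(self):
        from wildmeat.distances import distance_matrix

        seqs = [Sequence("a", "AACC"), Sequence("b", "AACA")]
        _, full = distance_matrix(seqs)
        _, masked = distance_matrix(seqs, sites={0, 2})
        assert masked[0, 1] == pytest.approx(k2p(seqs[0], seqs[1], sites={0, 2}).d)
        assert masked[0, 1] != pytest.approx(full[0, 1])


class TestWithinBetween:
    def test_single_sequence_not_available(self):
        db = make_db("cytb", {"Solo unus": ["ACGTACGT"]})
        assert max_within(db, "Solo unus", "cytb") is None

    def test_identical_pair_zero(self):
        db = make_db("cytb", {"Geminus par": ["ACGTACGT", "ACGTACGT"]})
        assert max_within(db, "Geminus par", "cytb") == 0.0

    def test_max_within_is_max_over_unique_pairs(self):
        rows = ["ACGTACGTAC", "ACGTACGTAC", "ACGTACGTAG", "ACGAACGTAG"]
        db = make_db("cytb", {"Varia multa": rows})
        uniq = unique_sequences(db.sequences_for("cytb", "Varia multa"))
        expected = 100 * max(
            k2p(uniq[i], uniq[j]).d
            for i in range(len(uniq)) for j in range(i + 1, len(uniq))
        )
        assert max_within(db, "Varia multa", "cytb") == pytest.approx(expected)

    def test_haplotype_collapse_ignores_masked_sites(self):
        # same haplotype up to an N: collapses to one unique sequence
        seqs = [
            Sequence("a", "ACGTACGT", species="X"),
            Sequence("b", "ACGTACNT", species="X"),
        ]
        assert len(unique_sequences(seqs)) == 1

    def test_net_between_same_species_zero(self, two_species_db):
        d, se = net_between(two_species_db, "Alpha ferox", "Alpha ferox",
                            "cytb", B=10)
        assert (d, se) == (0.0, 0.0)

    def test_net_between_formula_identity(self, two_species_db):
        a = two_species_db.sequences_for("cytb", "Alpha ferox")
        b = two_species_db.sequences_for("cytb", "Beta mitis")
        d_ab = np.mean([k2p(x, y).d for x in a for y in b])
        d_a = k2p(a[0], a[1]).d
        d_b = k2p(b[0], b[1]).d
        expected = d_ab - (d_a + d_b) / 2
        got, _ = net_between(two_species_db, "Alpha ferox", "Beta mitis",
                             "cytb", B=5)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_bootstrap_se_matches_bruteforce_resampling(self):
        rng = np.random.default_rng(0)
        bases = "ACGT"
        n_cols = 40
        anc = "".join(rng.choice(list(bases), size=n_cols))

        def mutate(s, k, rng):
            s = list(s)
            for j in rng.choice(len(s), size=k, replace=False):
                s[j] = bases[(bases.index(s[j]) + 2) % 4]  # transition
            return "".join(s)

        sa = [Sequence(f"a{i}", mutate(anc, 1, rng), species="A") for i in range(2)]
        sb = [Sequence(f"b{i}", mutate(anc, 4, rng), species="B") for i in range(2)]
        from wildmeat.seq_io import Alignment, ReferenceDB
        db = ReferenceDB({"cytb": Alignment(sa + sb)})

        d100, se100 = net_between(db, "A", "B", "cytb", B=100, seed=3)
        assert d100 == pytest.approx(_net_between_seqs(sa, sb))
        # independent brute-force resampling oracle at 10x the replicates
        rng = np.random.default_rng(99)
        reps = []
        for _ in range(1000):
            cols = rng.integers(0, n_cols, size=n_cols)
            ra = [Sequence(s.id, "".join(s.residues[c] for c in cols),
                           species="A") for s in sa]
            rb = [Sequence(s.id, "".join(s.residues[c] for c in cols),
                           species="B") for s in sb]
            reps.append(_net_between_seqs(ra, rb))
        se_oracle = float(np.std(reps, ddof=1))
        assert se100 == pytest.approx(se_oracle, rel=0.2)

    def test_bootstrap_se_of_constant_statistic_is_zero(self):
        # every column identical across the alignment -> resampling cannot
        # change the statistic
        sa = [Sequence("a0", "ACGTACGTAC", species="A"),
              Sequence("a1", "ACGTACGTAC", species="A")]
        sb = [Sequence("b0", "ACGTACGTAC", species="B"),
              Sequence("b1", "ACGTACGTAC", species="B")]
        from wildmeat.seq_io import Alignment, ReferenceDB
        db = ReferenceDB({"cytb": Alignment(sa + sb)})
        d, se = net_between(db, "A", "B", "cytb", B=50, seed=1)
        assert (d, se) == (0.0, 0.0)


def test_phylip_matrix_writer(tmp_path):
    from wildmeat.distances import distance_matrix, write_phylip_matrix

    seqs = [Sequence("a", "AACC"), Sequence("b", "AACA"), Sequence("c", "AACC")]
    ids, mat = distance_matrix(seqs)
    p = tmp_path / "dist.phy"
    write_phylip_matrix(p, ids, mat)
    lines = p.read_text().splitlines()
    assert lines[0] == "3"
    name, *vals = lines[1].split("\t")
    assert name == "a" and len(vals) == 3
    assert float(vals[0]) == 0.0


class TestGapReport:
    def test_deep_split_passes_all_flags(self, two_species_db):
        cfg = ThresholdConfig(B=20)
        recs = gap_report(
            two_species_db, "cytb",
            {"Alpha ferox": "Beta mitis", "Beta mitis": "Alpha ferox"}, cfg,
        )
        for r in recs:
            assert r.flags["within_ok"] and r.flags["between_ok"]
            assert r.flags["overlap"] is False

    def test_missing_sister_marked_unevaluated(self, two_species_db):
        recs = gap_report(two_species_db, "cytb", {}, ThresholdConfig(B=5))
        assert all(r.flags == {"unevaluated": True} for r in recs)

    def test_flags_match_direct_enumeration(self, deep_split_db):
        cfg_sim, db, _, _ = deep_split_db
        species = db.species("cytb")
        sister = {sp: min(o for o in species if o != sp) for sp in species}
        cfg = ThresholdConfig(B=10)
        recs = gap_report(db, "cytb", sister, cfg, seed=2)
        for r in recs:
            mw = max_within(db, r.species, "cytb")
            dnet = 100 * _net_between_seqs(
                db.sequences_for("cytb", r.species),
                db.sequences_for("cytb", r.sister),
            )
            meanw = 100 * mean_within(db, r.species, "cytb")
            assert r.max_within == pytest.approx(mw)
            assert r.d_net == pytest.approx(dnet)
            assert r.flags["within_ok"] == (mw < cfg.within_max)
            assert r.flags["between_ok"] == (dnet > cfg.between_min)
            assert r.flags["hebert_ok"] == (mw < cfg.hebert_pct)
            assert r.flags["fold_ok"] == (dnet >= cfg.fold_rule * meanw)
            assert r.flags["overlap"] == (mw >= dnet)
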