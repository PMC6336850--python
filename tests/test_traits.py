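"""Trait classifiers: rhodopsin residues, c-ring motifs, peptidases, operon."""
import itertools

import numpy as np
import pandas as pd
import pytest

from mgii import simulate as sim, traits as tr


class TestRhodopsin:
    def _aligned(self, r97, r108, r105):
        seq = list(tr.REFERENCE_RHODOPSIN)
        seq[tr.POS_PUMP_1 - 1] = r97
        seq[tr.POS_PUMP_2 - 1] = r108
        seq[tr.POS_TUNING - 1] = r105
        return "".join(seq)

    @pytest.mark.parametrize("r97,r108,r105,pumping,tuning", [
        ("D", "E", "Q", True, "blue"),
        ("D", "K", "M", True, "green"),
        ("D", "K", "Q", True, "blue"),
        ("A", "E", "Q", False, "blue"),       # flagged: tuning without pump pair
        ("D", "R", "M", False, "green"),
        ("D", "E", "A", True, "indeterminate"),
    ])
    def test_residue_rules(self, r97, r108, r105, pumping, tuning):
        call = tr.classify_rhodopsin(self._aligned(r97, r108, r105), aligned=True)
        assert call.is_proton_pumping is pumping
        assert call.tuning == tuning
        if not pumping and tuning != "indeterminate":
            assert call.flagged

    def test_alignment_maps_diagnostic_columns(self, rng):
        # mutated copy of the reference still maps 97/108/105 correctly
        seq = self._aligned("D", "E", "M")
        chars = list(seq)
        diagnostic = {tr.POS_PUMP_1 - 1, tr.POS_PUMP_2 - 1, tr.POS_TUNING - 1}
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for i in rng.choice(len(chars), size=12, replace=False):
            if i not in diagnostic:
                chars[i] = aa[int(rng.integers(0, 20))]
        call = tr.classify_rhodopsin("".join(chars))
        assert call.is_proton_pumping and call.tuning == "green"

    def test_short_aligned_sequence_rejected(self):
        with pytest.raises(ValueError):
            tr.classify_rhodopsin("MAD", aligned=True)


class TestCRingMotif:
    @pytest.mark.parametrize("seq,cls,pos", [
        ("MALPESAAIKW", "MGIIa-type", 3),
        ("MALPETIGLKW", "MGIIb-type", 3),
        ("MAAAAAA", "none", None),
        ("LPESGGI", "MGIIa-type", 1),
    ])
    def test_examples(self, seq, cls, pos):
        call = tr.scan_cring_motif(seq)
        assert call.motif_class == cls
        assert call.match_position == pos

    def test_both_motifs_give_conflict(self):
        call = tr.scan_cring_motif("LPESAAI" + "GG" + "LPETIAL")
        assert call.motif_class == "conflict"

    def test_agrees_with_sliding_window_oracle_exhaustively(self):
        """Exhaustive check at length 7 over the motif alphabet."""
        def oracle(seq):
            a = b = False
            for i in range(len(seq) - 6):
                w = seq[i:i + 7]
                if w[:4] == "LPES" and w[6] == "I":
                    a = True
                if w[:5] == "LPETI" and w[6] == "L":
                    b = True
            if a and b:
                return "conflict"
            return "MGIIa-type" if a else "MGIIb-type" if b else "none"

        alphabet = "LPESTI"
        for chars in itertools.product(alphabet, repeat=7):
            seq = "".join(chars)
            assert tr.scan_cring_motif(seq).motif_class == oracle(seq)

    def test_agrees_with_oracle_on_random_longer_sequences(self, rng):
        alphabet = "LPESTIA"
        for _ in range(2000):
            n = int(rng.integers(7, 13))
            seq = "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))
            got = tr.scan_cring_motif(seq).motif_class
            a = tr.MOTIF_MGIIA.search(seq) is not None
            b = tr.MOTIF_MGIIB.search(seq) is not None
            want = "conflict" if (a and b) else \
                "MGIIa-type" if a else "MGIIb-type" if b else "none"
            assert got == want


class TestPeptidases:
    def _tables(self, score, loc, sp):
        hits = pd.DataFrame([{"protein": "p1", "family": "M01", "score": score}])
        locs = pd.DataFrame([{"protein": "p1", "localization": loc}]) if loc else None
        sps = pd.DataFrame([{"protein": "p1", "has_signal_peptide": sp}])
        return hits, locs, sps

    @pytest.mark.parametrize("score,loc,sp,expected", [
        (80, "extracellular", False, True),
        (80, "outer membrane", False, True),
        (80, "unknown", True, True),
        (80, "unknown", False, False),
        (74, "extracellular", True, False),   # below the bitscore floor
        (75, "extracellular", False, True),   # inclusive floor
        (80, "cytoplasmic", True, False),
    ])
    def test_rule_combinations(self, score, loc, sp, expected):
        calls = tr.call_extracellular_peptidases(*self._tables(score, loc, sp))
        assert calls[0].is_extracellular_call is expected

    def test_missing_localization_treated_as_unknown(self):
        hits = pd.DataFrame([{"protein": "p1", "family": "M01", "score": 90}])
        sps = pd.DataFrame([{"protein": "p1", "has_signal_peptide": True}])
        calls = tr.call_extracellular_peptidases(hits, None, sps)
        assert calls[0].localization == "unknown"
        assert calls[0].is_extracellular_call

    def test_duplicate_rows_keep_max_score(self, caplog):
        hits = pd.DataFrame([
            {"protein": "p1", "family": "M01", "score": 60},
            {"protein": "p1", "family": "M01", "score": 90},
        ])
        locs = pd.DataFrame([{"protein": "p1", "localization": "extracellular"}])
        calls = tr.call_extracellular_peptidases(hits, locs, None)
        assert len(calls) == 1 and calls[0].hmm_score == 90


class TestOperon:
    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["genome", "contig", "gene_index", "annotation"])

    def test_colocalized_components_present(self):
        genes = self._genes([("g1", "c1", 4, "K07331"), ("g1", "c1", 5, "K07332"),
                             ("g1", "c1", 6, "K07333"), ("g1", "c1", 7, "PF01917")])
        call = tr.detect_flagellum_operon(genes)[0]
        assert call.is_present and call.span == (4, 7)

    def test_flagellin_on_other_contig_absent(self):
        genes = self._genes([("g1", "c1", 1, "K07331"), ("g1", "c1", 2, "K07332"),
                             ("g1", "c1", 3, "K07333"), ("g1", "c2", 1, "PF01917")])
        call = tr.detect_flagellum_operon(genes)[0]
        assert not call.is_present
        assert call.components_found == frozenset({"FlaH", "FlaI", "FlaJ", "flagellin"})

    def test_window_limits_colocalization(self):
        genes = self._genes([("g1", "c1", 1, "K07331"), ("g1", "c1", 2, "K07332"),
                             ("g1", "c1", 3, "K07333"), ("g1", "c1", 30, "PF01917")])
        assert not tr.detect_flagellum_operon(genes, window=10)[0].is_present
        assert tr.detect_flagellum_operon(genes, window=29)[0].is_present


class TestOccurrenceMatrix:
    def _assignment(self, mapping):
        from mgii.clades import CladeAssignment
        return CladeAssignment(labels=mapping, mrca={}, mrca_depth={})

    def test_fractions(self):
        calls = pd.DataFrame({"pr": [True, True, False, False],
                              "flagellum": [True, True, True, True],
                              "peptidase": [False, False, False, False]},
                             index=["g1", "g2", "g3", "g4"])
        asn = self._assignment({g: "s1" for g in calls.index})
        occ = tr.occurrence_matrix(calls, asn)
        assert occ.loc["s1", "pr"] == 0.5
        assert occ.loc["s1", "flagellum"] == 1.0
        assert occ.loc["s1", "peptidase"] == 0.0

    def test_invariant_to_genome_ordering(self):
        calls = pd.DataFrame({"t": [True, False, True]}, index=["g1", "g2", "g3"])
        asn = self._assignment({"g1": "s1", "g2": "s1", "g3": "s2"})
        occ1 = tr.occurrence_matrix(calls, asn)
        occ2 = tr.occurrence_matrix(calls.iloc[::-1], asn)
        assert occ1.equals(occ2)
        assert ((occ1.values >= 0) & (occ1.values <= 1)).all()


class TestPlantedRecovery:
    def test_generator_and_classifiers_agree_on_planted_traits(self, rng):
        """Round-trip a randomized trait plan through the classifiers."""
        residues = ["D", "A", "K", "E", "Q", "M", "R"]
        plan = {}
        for i in range(40):
            traits = [
                {"kind": "rhodopsin",
                 "r97": residues[int(rng.integers(0, len(residues)))],
                 "r108": residues[int(rng.integers(0, len(residues)))],
                 "r105": residues[int(rng.integers(0, len(residues)))]},
                {"kind": "cring",
                 "clade": "MGIIa" if rng.random() < 0.5 else "MGIIb"},
                {"kind": "operon", "present": bool(rng.random() < 0.5)},
            ]
            plan[f"g{i:03d}"] = traits
        spec = sim.SimSpec(seed=77, tree=sim.two_taxon_tree(0.01),
                           ancestor_length=15_000, trait_plan=plan)
        proteins, coords, ann, planted = sim.simulate_trait_proteins(spec)
        operon_calls = {c.genome_id: c.is_present
                        for c in tr.detect_flagellum_operon(ann["genes"])}
        for _, row in planted.iterrows():
            if row["kind"] == "rhodopsin":
                call = tr.classify_rhodopsin(proteins[row["protein"]])
                assert f"pumping={call.is_proton_pumping},tuning={call.tuning}" == row["expected"]
            elif row["kind"] == "cring":
                assert tr.scan_cring_motif(proteins[row["protein"]]).motif_class == row["expected"]
            elif row["kind"] == "operon":
                assert str(operon_calls[row["genome"]]) == row["expected"]
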