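import numpy as np
import pytest

from oracles import oracle_best
from quantmir.assign import Assigner, Assignment, assign_read, end_profile
from quantmir.references import (Hairpin, MatureMiRNA, ReferenceSet,
                                 make_spikein_ladder, revcomp)


def windows_of(ref):
    return [(m.id, ref.hairpins[m.hairpin_id].template, m.start - 1,
             m.end - m.start + 1) for m in ref.matures]


class TestExactMatches:
    def test_mature_exact(self, tiny_ref):
        m = tiny_ref.matures[0]
        a = assign_read(m.sequence, tiny_ref)
        assert (a.ref_id, a.ref_class, a.iso_class) == (m.id, "miRNA", "exact")
        assert a.offset5 == a.trim3 == a.ext3 == 0 and a.tail == ""

    def test_spikein_exact(self, tiny_ref):
        s = tiny_ref.spikeins[0]
        a = assign_read(s.sequence, tiny_ref)
        assert (a.ref_id, a.ref_class) == (s.id, "spikein")

    def test_pirna_exact(self, ref):
        pid, seq = next(iter(ref.pirnas.items()))
        a = assign_read(seq, ref)
        assert (a.ref_id, a.ref_class) == (pid, "piRNA")

    def test_random_sequence_unassigned(self, tiny_ref):
        a = assign_read("ACGT" * 5 + "AC", tiny_ref)
        assert a.ref_class in ("unassigned", "miRNA")  # overwhelmingly unassigned
        # guaranteed-unassignable: alternating homopolymer far from any ref
        b = assign_read("A" * 22, tiny_ref)
        assert b.ref_class == "unassigned"

    def test_identical_matures_are_ambiguous(self):
        rng = np.random.default_rng(1)
        mat = "".join("ACGT"[i] for i in rng.integers(0, 4, 22))
        hps, mats = {}, []
        for i in range(2):
            hid = f"h{i}"
            hps[hid] = Hairpin(id=hid, sequence=revcomp(mat) + "GATTACAA" + mat)
            mats.append(MatureMiRNA(id=f"m{i}", hairpin_id=hid, arm="3p",
                                    sequence=mat, start=31, end=52))
        rs = ReferenceSet(matures=mats, hairpins=hps, pirnas={},
                          spikeins=[], families={})
        assert assign_read(mat, rs).ref_class == "ambiguous"


class TestIsomirClassification:
    def test_trim_one_drops_modal_length(self, tiny_ref):
        m = tiny_ref.matures[0]
        a = assign_read(m.sequence[:-1], tiny_ref)
        assert (a.ref_id, a.iso_class, a.trim3) == (m.id, "iso3p_trim", 1)
        assert a.length == len(m.sequence) - 1

    def test_nta_tail_mismatching_template(self, tiny_ref):
        m = tiny_ref.matures[0]
        ctx0 = tiny_ref.hairpins[m.hairpin_id].context3[0]
        tail = "T" if ctx0 != "T" else "A"
        a = assign_read(m.sequence + tail, tiny_ref)
        assert (a.ref_id, a.iso_class, a.tail) == (m.id, "nta", tail)

    def test_templated_extension(self, tiny_ref):
        m = tiny_ref.matures[0]
        ctx0 = tiny_ref.hairpins[m.hairpin_id].context3[0]
        a = assign_read(m.sequence + ctx0, tiny_ref)
        assert (a.ref_id, a.iso_class, a.ext3) == (m.id, "iso3p_ext_templated", 1)

    def test_five_prime_offset(self, tiny_ref):
        m = tiny_ref.matures[0]
        hp = tiny_ref.hairpins[m.hairpin_id]
        shifted = hp.sequence[m.start - 2 : m.end - 1]  # 5' offset -1
        a = assign_read(shifted, tiny_ref)
        assert (a.ref_id, a.iso_class, a.offset5) == (m.id, "iso5p", -1)

    def test_trim_plus_tail(self, tiny_ref):
        m = tiny_ref.matures[0]
        body = m.sequence[:-1]
        tail = "T" if m.sequence[-1] != "T" else "A"
        a = assign_read(body + tail, tiny_ref)
        assert (a.ref_id, a.iso_class) == (m.id, "nta")
        assert a.trim3 == 1 and a.tail == tail

    def test_deterministic(self, tiny_ref):
        m = tiny_ref.matures[1]
        insert = m.sequence[:-1] + "TT"
        assert assign_read(insert, tiny_ref) == assign_read(insert, tiny_ref)


class TestOracleEquivalence:
    def test_matches_exhaustive_decomposition(self, tiny_ref):
        """assign_read agrees with brute-force enumeration of all allowed
        (offset5, trim3, ext3, tail) decompositions on random inserts."""
        rng = np.random.default_rng(23)
        letters = np.array(list("ACGT"))
        wins = windows_of(tiny_ref)
        assigner = Assigner(tiny_ref)
        n_matched = 0
        for trial in range(400):
            if trial % 2:
                insert = "".join(letters[rng.integers(0, 4, rng.integers(20, 25))])
            else:  # perturb a real mature so the isomiR branch is exercised
                m = tiny_ref.matures[rng.integers(0, 3)]
                tpl = tiny_ref.hairpins[m.hairpin_id].template
                off = int(rng.integers(-2, 3))
                d3 = int(rng.integers(-3, 3))
                a, b = m.start - 1 + off, m.end + d3
                if a < 0 or b <= a:
                    continue
                insert = tpl[a:b] + "".join(letters[rng.integers(0, 4, rng.integers(0, 3))])
            if not (18 <= len(insert) <= 30):
                continue
            got = assigner(insert)
            # exact spike-in hits are out of the isomiR oracle's scope
            if got.ref_class == "spikein":
                continue
            decs, ambiguous = oracle_best(insert, wins)
            if not decs:
                assert got.ref_class == "unassigned", insert
            elif ambiguous:
                assert got.ref_class == "ambiguous", insert
            else:
                rid, off, trim3, ext3, tail = decs[0]
                assert got.ref_id == rid, insert
                assert (got.offset5, got.trim3, got.ext3, got.tail) == \
                       (off, trim3, ext3, tail), insert
                n_matched += 1
        assert n_matched > 100  # the isomiR branch was genuinely exercised


class TestEndProfile:
    def _assignments(self, rows):
        out = []
        for iso, tail, length, n in rows:
            out += [Assignment("m", "miRNA", iso, tail=tail, length=length)] * n
        return out

    def test_trim_dominated_profile(self):
        prof = end_profile(self._assignments(
            [("iso3p_trim", "", 23, 95), ("exact", "", 24, 5)]))
        assert prof["modal_length"] == 23
        assert prof["iso_fractions"]["iso3p_trim"] == pytest.approx(0.95)

    def test_all_exact_no_tails(self):
        prof = end_profile(self._assignments([("exact", "", 22, 10)]))
        assert prof["iso_fractions"]["nta"] == 0.0
        assert prof["u_tail_fraction"] is None

    def test_u_fraction_of_tails(self):
        prof = end_profile(self._assignments(
            [("nta", "T", 23, 3), ("nta", "A", 23, 1)]))
        assert prof["u_tail_fraction"] == pytest.approx(0.75)

    def test_modal_tie_prefers_shorter(self):
        prof = end_profile(self._assignments(
            [("exact", "", 22, 5), ("iso3p_trim", "", 21, 5)]))
        assert prof["modal_length"] == 21

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            end_profile([])
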