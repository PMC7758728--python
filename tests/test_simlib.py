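import re

import numpy as np
import pytest

from oracles import expected_distinct_umis
from quantmir.simlib import (ConditionConfig, PrepModel, StageProfile,
                             apply_depletion, make_wt_profile, read_fastq,
                             simulate_library, write_fastq)


class TestWtProfile:
    def test_family_share_and_total(self, ref):
        prof = make_wt_profile(ref, "2cell", 100000.0, family_share=0.5,
                               rng_seed=3)
        fam = ref.family_members()
        fam_sum = sum(v for k, v in prof.molecules.items() if k in fam)
        assert fam_sum == pytest.approx(50000.0, abs=0.5)
        assert prof.total == pytest.approx(100000.0, abs=0.5)

    def test_zero_family_share(self, ref):
        prof = make_wt_profile(ref, "2cell", 1000.0, family_share=0.0, rng_seed=3)
        assert all(prof.molecules[m] == 0.0 for m in ref.family_members())

    def test_seed_reproducibility(self, ref):
        a = make_wt_profile(ref, "L1", 5000.0, 0.4, rng_seed=9)
        b = make_wt_profile(ref, "L1", 5000.0, 0.4, rng_seed=9)
        assert a.molecules == b.molecules

    def test_nonpositive_total_rejected(self, ref):
        with pytest.raises(ValueError):
            make_wt_profile(ref, "2cell", 0.0, 0.5, rng_seed=1)


class TestDepletion:
    def test_uniform_retention_scales_total(self, ref):
        prof = make_wt_profile(ref, "2cell", 10000.0, 0.5, rng_seed=5)
        cond = ConditionConfig(retention={m: 0.35 for m in prof.molecules})
        dep = apply_depletion(prof, cond)
        assert dep.total == pytest.approx(0.35 * prof.total)

    def test_full_depletion_empties_profile(self, ref):
        prof = make_wt_profile(ref, "2cell", 10000.0, 0.5, rng_seed=5)
        cond = ConditionConfig(retention={m: 0.0 for m in prof.molecules})
        assert apply_depletion(prof, cond).molecules == {}

    def test_microprocessor_resistant_mirna_persists(self, ref):
        """Retention 1 for mir-52 only, 0 elsewhere: only mir-52 remains."""
        prof = make_wt_profile(ref, "3fold", 10000.0, 0.5, rng_seed=5)
        retention = {m: 0.0 for m in prof.molecules}
        retention["mir-52"] = 1.0
        dep = apply_depletion(prof, ConditionConfig(retention=retention))
        assert set(dep.molecules) == {"mir-52"}
        assert dep.molecules["mir-52"] == prof.molecules["mir-52"]

    def test_out_of_range_retention_rejected(self):
        with pytest.raises(ValueError):
            ConditionConfig(retention={"mir-35": 1.5})


class TestSimulateLibrary:
    def test_spikein_only_library_is_structural(self, ref):
        prof = StageProfile("2cell", {}, n_embryos=2)
        prep = PrepModel(rng_seed=1)
        reads, gt = simulate_library(prof, ConditionConfig(), ref, prep)
        assert len(reads) > 0
        assert set(gt.reads["ref_id"]) <= ref.spikein_ids
        pattern = re.compile(
            r"^[ACGT]{4}[ACGT]{18,30}[ACGT]{6}" + prep.barcode)
        for _, seq in reads[:500]:
            assert pattern.match(seq), seq
            assert len(seq) == prep.read_length

    def test_read_conservation(self, ref):
        prof = StageProfile("2cell", {"mir-35": 500.0}, n_embryos=5)
        reads, gt = simulate_library(prof, ConditionConfig(), ref,
                                     PrepModel(rng_seed=2))
        assert len(reads) == gt.per_ref["reads"].sum() == len(gt.reads)
        assert (gt.per_ref["reads"] >= gt.per_ref["ligated"]).all()

    def test_seed_gives_byte_identical_fastq(self, ref, tmp_path):
        prof = StageProfile("2cell", {"mir-35": 200.0}, n_embryos=5)
        paths = []
        for name in ("a.fastq", "b.fastq"):
            reads, _ = simulate_library(prof, ConditionConfig(), ref,
                                        PrepModel(rng_seed=7))
            paths.append(write_fastq(reads, tmp_path / name))
        assert paths[0].read_bytes() == paths[1].read_bytes()
        assert read_fastq(paths[0])[0][1]  # round-trips

    def test_mirtron_trimming_fraction(self, ref):
        """p_trim1=0.95 reproduces the ~95% 1-nt-trimmed phenotype."""
        prof = StageProfile("gastrulation", {"mir-51": 2000.0}, n_embryos=10)
        cond = ConditionConfig(mirtron_mods={"mir-51": {"p_trim1": 0.95}})
        reads, gt = simulate_library(prof, cond, ref, PrepModel(rng_seed=3))
        row = gt.per_ref.set_index("ref_id").loc["mir-51"]
        n = row["ligated"]
        frac = row["n_trim"] / n
        tol = 3 * np.sqrt(0.95 * 0.05 / n)
        assert frac == pytest.approx(0.95, abs=tol)
        mat = ref.sequence_of("mir-51")
        trimmed = gt.reads[gt.reads["event"] == "trim1"]["insert"]
        assert (trimmed == mat[:-1]).all()

    def test_nta_event_appends_single_u(self, ref):
        prof = StageProfile("gastrulation", {"mir-35": 1000.0}, n_embryos=10)
        cond = ConditionConfig(mirtron_mods={"mir-35": {"p_nta_u": 0.35}})
        _, gt = simulate_library(prof, cond, ref, PrepModel(rng_seed=4))
        mat = ref.sequence_of("mir-35")
        tailed = gt.reads[gt.reads["event"] == "nta"]["insert"]
        assert len(tailed) > 0 and (tailed == mat + "T").all()

    def test_umi_collisions_match_birthday_expectation(self, ref):
        """Distinct (insert, UMI) pairs for ~1000 ligated molecules equal the
        molecule count minus the closed-form expected 10-nt UMI collisions."""
        prof = StageProfile("2cell", {"mir-35": 20000.0}, n_embryos=1)
        prep = PrepModel(rng_seed=6, pcr_dup_mean=4.0)
        _, gt = simulate_library(prof, ConditionConfig(), ref, prep)
        sub = gt.reads[gt.reads["ref_id"] == "mir-35"]
        n_lig = int(gt.per_ref.set_index("ref_id").loc["mir-35", "ligated"])
        assert n_lig == pytest.approx(1000, abs=150)
        distinct = len(set(zip(sub["insert"], sub["umi"])))
        expected = expected_distinct_umis(n_lig)
        assert n_lig - 5 <= distinct <= n_lig
        assert distinct == pytest.approx(expected, abs=5)

    def test_contamination_reads_are_decoys(self, ref):
        prof = StageProfile("2cell", {"mir-35": 1000.0}, n_embryos=5)
        cond = ConditionConfig(contamination_rate=0.05)
        _, gt = simulate_library(prof, cond, ref, PrepModel(rng_seed=9))
        decoy = gt.per_ref[gt.per_ref["ref_id"].str.startswith("decoy-")]
        endo = gt.per_ref[~gt.per_ref["ref_id"].str.startswith("decoy-")]
        frac = decoy["ligated"].sum() / endo["ligated"].sum()
        assert frac == pytest.approx(0.05, rel=0.5)

    def test_short_read_length_rejected(self, ref):
        prof = StageProfile("2cell", {}, n_embryos=1)
        with pytest.raises(ValueError, match="read_length"):
            simulate_library(prof, ConditionConfig(), ref,
                             PrepModel(rng_seed=0, read_length=42))
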