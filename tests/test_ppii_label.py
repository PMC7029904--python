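import math

import numpy as np
import pytest

from ppiipred import structgeom as sg
from ppiipred.ppii_label import (
    LabelledSequence,
    PPIICriteria,
    assign_ppii,
    passes_dihedral_filter,
    passes_trans_filter,
    segment_regularity,
    write_residue_tsv,
    write_segment_bed,
)
from ppiipred.structgeom import DihedralRecord

from conftest import random_angle_list


def rec(phi=None, psi=None, omega=None, ca=None, idx=1):
    return DihedralRecord(res_index=idx, phi=phi, psi=psi, omega=omega,
                          ca_pseudo=ca)


STRICT = PPIICriteria(mode="strict")
NONSTRICT = PPIICriteria(mode="non_strict")


class TestDihedralFilter:
    def test_canonical_ppii_passes_strict(self):
        assert passes_dihedral_filter(rec(phi=-75, psi=145), STRICT)

    def test_wrap_band_passes_strict(self):
        assert passes_dihedral_filter(rec(phi=-75, psi=-170), STRICT)

    def test_phi_band_only_in_strict(self):
        r = rec(phi=-120, psi=145)
        assert not passes_dihedral_filter(r, STRICT)
        assert passes_dihedral_filter(r, NONSTRICT)

    def test_psi_outside_both_bands(self):
        assert not passes_dihedral_filter(rec(phi=-75, psi=-45), STRICT)
        assert not passes_dihedral_filter(rec(phi=-75, psi=-45), NONSTRICT)

    def test_undefined_required_angles_fail(self):
        assert not passes_dihedral_filter(rec(phi=-75, psi=None), STRICT)
        assert not passes_dihedral_filter(rec(phi=None, psi=145), STRICT)
        # non-strict does not need phi
        assert passes_dihedral_filter(rec(phi=None, psi=145), NONSTRICT)


class TestTransFilter:
    def test_inside_band(self):
        assert passes_trans_filter(rec(ca=-100.0), STRICT)

    def test_below_band(self):
        assert not passes_trans_filter(rec(ca=-150.0), STRICT)

    def test_undefined_fails(self):
        assert not passes_trans_filter(rec(ca=None), STRICT)

    def test_omega_mode(self):
        crit = PPIICriteria(trans_filter="omega")
        assert passes_trans_filter(rec(omega=178.0), crit)
        assert passes_trans_filter(rec(omega=-170.0), crit)
        assert not passes_trans_filter(rec(omega=10.0), crit)
        assert not passes_trans_filter(rec(omega=None), crit)

    def test_off_mode_passes_everything(self):
        crit = PPIICriteria(trans_filter="off")
        assert passes_trans_filter(rec(), crit)


class TestSegmentRegularity:
    def test_identical_angles_zero(self):
        recs = [rec(phi=-75, psi=145, idx=i) for i in range(5)]
        assert segment_regularity(recs) == 0.0

    def test_single_step_three_four_five(self):
        # one step of length 5 = hypot(3, 4), divided by n = 2
        recs = [rec(phi=0.0, psi=0.0), rec(phi=4.0, psi=3.0)]
        assert segment_regularity(recs) == pytest.approx(2.5)

    def test_wrapped_difference(self):
        recs = [rec(phi=0.0, psi=-179.0), rec(phi=0.0, psi=179.0)]
        assert segment_regularity(recs) == pytest.approx(1.0)

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            segment_regularity([rec(phi=0.0, psi=0.0)])

    def test_division_by_n_not_n_minus_1(self):
        recs = [rec(phi=0.0, psi=0.0), rec(phi=0.0, psi=10.0),
                rec(phi=0.0, psi=20.0)]
        # two steps of 10 each, n = 3
        assert segment_regularity(recs) == pytest.approx(20.0 / 3.0)


def brute_force_segments(marked, min_len, records, regularity_max):
    """Independent oracle: exhaustively test every window for being a
    maximal all-marked run, then apply length and regularity filters."""
    n = len(marked)
    segs = []
    for start in range(n):
        for end in range(start, n):
            if not all(marked[start:end + 1]):
                continue
            left_ok = start == 0 or not marked[start - 1]
            right_ok = end == n - 1 or not marked[end + 1]
            if not (left_ok and right_ok):
                continue
            if end - start + 1 < min_len:
                continue
            run = records[start:end + 1]
            if len(run) >= 2:
                reg = segment_regularity(run)
            else:
                reg = 0.0
            if regularity_max is not None and reg > regularity_max:
                continue
            segs.append((start + 1, end + 1))
    return segs


class TestAssignPpii:
    def test_fixture_chain_strict_segment(self):
        angles = (
            [{"phi": -60.0, "psi": -45.0, "omega": 180.0}] * 10
            + [{"phi": -75.0, "psi": 145.0, "omega": 180.0}] * 5
            + [{"phi": -120.0, "psi": 130.0, "omega": 180.0}] * 10
        )
        chain = sg.build_backbone(angles)
        out = assign_ppii(chain, STRICT)
        assert len(out.segments) == 1
        seg = out.segments[0]
        assert seg.length >= 3
        # segment confined to the PPII block (residues 11..15)
        assert seg.start >= 11 and seg.end <= 15

    def test_beta_fails_strict_passes_nonstrict_phi(self):
        # phi=-120 fails the strict phi band; psi=130 is in band2
        r = rec(phi=-120.0, psi=130.0, ca=-100.0)
        assert not passes_dihedral_filter(r, STRICT)
        assert passes_dihedral_filter(r, NONSTRICT)

    def test_two_qualifying_residues_no_segment(self):
        angles = (
            [{"phi": -60.0, "psi": -45.0, "omega": 180.0}] * 6
            + [{"phi": -75.0, "psi": 145.0, "omega": 180.0}] * 2
            + [{"phi": -60.0, "psi": -45.0, "omega": 180.0}] * 6
        )
        chain = sg.build_backbone(angles)
        out = assign_ppii(chain, PPIICriteria(mode="strict", trans_filter="off"))
        assert out.segments == []
        assert sum(out.labels) == 0

    def test_empty_chain(self):
        out = assign_ppii(sg.BackboneChain(chain_id="A"), STRICT)
        assert out.labels == [] and out.segments == []

    def test_labels_match_segments(self, ppii_chain):
        out = assign_ppii(ppii_chain, STRICT)
        inside = set()
        for seg in out.segments:
            inside.update(range(seg.start, seg.end + 1))
        for i, lab in enumerate(out.labels, start=1):
            assert lab == (1 if i in inside else 0)

    def test_segment_residues_pass_filters(self, ppii_chain):
        records = sg.chain_dihedrals(ppii_chain)
        out = assign_ppii(ppii_chain, STRICT, records=records)
        assert out.segments
        for seg in out.segments:
            for i in range(seg.start - 1, seg.end):
                assert passes_dihedral_filter(records[i], STRICT)
                assert passes_trans_filter(records[i], STRICT)

    @pytest.mark.parametrize("seed", range(10))
    def test_brute_force_oracle_short_chains(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        # mix of conformations with noise so runs fragment unpredictably
        angles = []
        for _ in range(n):
            base = [(-75.0, 145.0), (-60.0, -45.0), (-120.0, 130.0)][
                int(rng.integers(0, 3))]
            angles.append({
                "phi": base[0] + float(rng.normal(0, 25)),
                "psi": base[1] + float(rng.normal(0, 25)),
                "omega": 180.0,
            })
        chain = sg.build_backbone(angles)
        for crit in (STRICT, NONSTRICT,
                     PPIICriteria(mode="strict", regularity_max=15.0)):
            records = sg.chain_dihedrals(chain)
            marked = [passes_trans_filter(r, crit)
                      and passes_dihedral_filter(r, crit) for r in records]
            want = brute_force_segments(marked, crit.min_len, records,
                                        crit.regularity_max)
            got = [(s.start, s.end)
                   for s in assign_ppii(chain, crit).segments]
            assert got == want

    @pytest.mark.parametrize("seed", range(50))
    def test_strict_subset_of_nonstrict(self, seed):
        rng = np.random.default_rng(1000 + seed)
        angles = []
        for _ in range(15):
            base = [(-75.0, 145.0), (-95.0, 150.0), (-120.0, 130.0)][
                int(rng.integers(0, 3))]
            angles.append({
                "phi": base[0] + float(rng.normal(0, 10)),
                "psi": base[1] + float(rng.normal(0, 10)),
                "omega": 180.0,
            })
        chain = sg.build_backbone(angles)
        strict = PPIICriteria(mode="strict", regularity_max=None)
        nonstrict = PPIICriteria(mode="non_strict", regularity_max=None)
        ls = assign_ppii(chain, strict).labels
        ln = assign_ppii(chain, nonstrict).labels
        for a, b in zip(ls, ln):
            assert a <= b

    def test_raising_regularity_max_monotone(self, rng):
        angles = random_angle_list(rng, 18, omega_range=(175.0, 180.0))
        # force everything near ppii so runs form, with noise
        for a in angles:
            a["phi"] = -75.0 + float(rng.normal(0, 20))
            a["psi"] = 145.0 + float(rng.normal(0, 20))
        chain = sg.build_backbone(angles)
        prev = -1
        for rmax in (5.0, 15.0, 30.0, 60.0, None):
            crit = PPIICriteria(mode="strict", regularity_max=rmax,
                                trans_filter="off")
            count = len(assign_ppii(chain, crit).segments)
            assert count >= prev
            prev = count

    def test_lowering_min_len_monotone(self, ppii_chain):
        prev = -1
        for ml in (6, 4, 3, 2, 1):
            crit = PPIICriteria(mode="strict", min_len=ml)
            labelled = sum(assign_ppii(ppii_chain, crit).labels)
            assert labelled >= prev
            prev = labelled


class TestOutputs:
    def test_residue_tsv_and_bed(self, tmp_path, ppii_chain):
        records = sg.chain_dihedrals(ppii_chain)
        out = assign_ppii(ppii_chain, STRICT, records=records)
        tsv = tmp_path / "res.tsv"
        bed = tmp_path / "seg.bed"
        write_residue_tsv(ppii_chain, out, records, tsv)
        write_segment_bed(out, bed)
        lines = tsv.read_text().splitlines()
        assert len(lines) == 1 + len(ppii_chain)
        bed_lines = bed.read_text().splitlines()
        assert len(bed_lines) == len(out.segments)
        # BED uses 0-based half-open: length = end - start
        for line, seg in zip(bed_lines, out.segments):
            _, start, end, length, _ = line.split("\t")
            assert int(end) - int(start) == int(length) == seg.length


class TestCriteriaValidation:
    def test_bad_mode(self):
        with pytest.raises(ValueError):
            PPIICriteria(mode="loose")

    def test_bad_min_len(self):
        with pytest.raises(ValueError):
            PPIICriteria(min_len=0)

    def test_bad_trans_filter(self):
        with pytest.raises(ValueError):
            PPIICriteria(trans_filter="maybe")
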