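"""Kinetic model: preset registry, closed forms, trajectory sampling."""

import math

import numpy as np
import pytest

from ribotrace.emission import trace_rng
from ribotrace.kinetics import (
    DELIVERY_TIME,
    MOVIE_LENGTH,
    NONROT,
    PIC,
    ROT,
    CodonProgram,
    CodonSlot,
    PRESET_NAMES,
    default_program,
    expected_fractions,
    make_preset,
    sample_trajectory,
)


def deterministic_preset(**over):
    """All branches toward completion, constant dwells (floor == mean)."""
    base = dict(
        p_decode_sup=1.0,
        p_pre_dis=0.0,
        p_continue_late=1.0,
        bleach_rate_green=0.0,
        bleach_rate_red=0.0,
        dwell_floor=1e9,
    )
    base.update(over)
    preset = make_preset("Ser", 50, 1.0, **base)
    from ribotrace.kinetics import PostBranch
    import dataclasses

    return dataclasses.replace(preset, p_post=PostBranch(1.0, 0.0, 0.0))


class TestProgram:
    def test_default_program_shape(self):
        prog = default_program()
        assert len(prog) == 6
        assert prog.sup_index == 2
        assert [s.dye_labeled for s in prog.slots] == [True, False, True, True, True, True]

    def test_program_rejects_bad_indices_and_missing_suppressor(self):
        with pytest.raises(ValueError):
            CodonProgram((CodonSlot(2, "Phe", True),))
        with pytest.raises(ValueError):
            CodonProgram((CodonSlot(1, "Phe", True), CodonSlot(2, "Phe", True)))


class TestPresets:
    def test_registry_carries_measured_branch_values(self):
        assert make_preset("UTu1", 50, 1.0).p_decode_sup == pytest.approx(0.83)
        assert make_preset("supD", 50, 1.0).p_post.continue_ == pytest.approx(0.84)
        assert make_preset("UTu1", 50, 1.0).p_pre_dis == pytest.approx(0.09)
        assert make_preset("UTu1", 50, 1.0).t_disassembly_mean == pytest.approx(9.0)
        assert make_preset("UTu1", 50, 1.0).t_decode_sup_mean == pytest.approx(7.0)

    def test_unknown_name_lists_valid_presets(self):
        with pytest.raises(KeyError) as exc:
            make_preset("tRNAxyz", 50, 1.0)
        for name in PRESET_NAMES:
            assert name in str(exc.value)

    def test_concentration_scaling(self):
        assert make_preset("UTu1", 200, 1.0).t_arrival_mean == pytest.approx(
            make_preset("UTu1", 50, 1.0).t_arrival_mean / 4
        )
        # suppressor decoding dwell scales with suppressor TC
        assert make_preset("UTu1", 50, 2.0).t_decode_sup_mean == pytest.approx(3.5)
        # the high-concentration condition has its own branch triple
        assert make_preset("UTu1", 200, 1.0).p_post.continue_ == pytest.approx(0.72)

    def test_invalid_concentration(self):
        with pytest.raises(ValueError):
            make_preset("UTu1", -1, 1.0)

    def test_post_branch_must_normalize(self):
        from ribotrace.kinetics import PostBranch
        import dataclasses

        p = make_preset("UTu1", 50, 1.0)
        with pytest.raises(ValueError):
            dataclasses.replace(p, p_post=PostBranch(0.5, 0.5, 0.5))


class TestExpectedFractions:
    def test_survival_is_product_of_pre_survival_and_continue(self):
        f = expected_fractions(make_preset("UTu1", 50, 1.0))
        # (1 - 0.09) * 0.2308 = 0.2100
        assert f["p_survive_codon3_given_decode"] == pytest.approx(0.21, abs=5e-4)
        assert f["p_post_dis_given_decode"] == pytest.approx(0.64, abs=5e-4)

    def test_forced_pre_disassembly_kills_survival(self):
        p = make_preset("UTu1", 50, 1.0, p_pre_dis=1.0)
        assert expected_fractions(p)["p_survive_codon3_given_decode"] == 0.0

    def test_natural_suppressor_rarely_disassembles(self):
        f = expected_fractions(make_preset("supD", 50, 1.0))
        assert f["p_post_dis_given_decode"] == pytest.approx(0.01)

    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_fractions_are_probabilities_and_marginalize(self, name):
        p = make_preset(name, 50, 1.0)
        f = expected_fractions(p)
        assert all(0.0 <= v <= 1.0 for v in f.values())
        total = (
            f["p_post_dis_given_decode"]
            + f["p_survive_codon3_given_decode"]
            + f["p_censor_given_decode"]
        )
        assert total == pytest.approx(1.0 - p.p_pre_dis, abs=1e-9)


class TestSampling:
    def test_deterministic_preset_gives_six_cycles_byte_stable(self):
        preset = deterministic_preset()
        prog = default_program()
        t1 = sample_trajectory(prog, preset, trace_rng(3, 0), "a")
        t2 = sample_trajectory(prog, preset, trace_rng(3, 0), "a")
        assert [iv.to_record() for iv in t1.intervals] == [
            iv.to_record() for iv in t2.intervals
        ]
        rot_codons = [iv.codon for iv in t1.intervals if iv.state == ROT]
        assert rot_codons == [1, 2, 3, 4, 5, 6]
        assert t1.outcome_truth == "COMPLETED"
        assert t1.last_codon_truth == 6

    def test_reproducibility_across_presets(self, ut50_preset):
        prog = default_program()
        a = sample_trajectory(prog, ut50_preset, trace_rng(9, 4), "a")
        b = sample_trajectory(prog, ut50_preset, trace_rng(9, 4), "a")
        assert [iv.to_record() for iv in a.intervals] == [iv.to_record() for iv in b.intervals]
        assert a.outcome_truth == b.outcome_truth

    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_trajectory_invariants(self, name):
        preset = make_preset(name, 50, 1.0)
        prog = default_program()
        for i in range(150):
            traj = sample_trajectory(prog, preset, trace_rng(55, i), "t")
            traj.validate()
            assert traj.intervals[0].state == PIC
            assert traj.intervals[-1].t_end == pytest.approx(MOVIE_LENGTH)
            # rotations alternate with non-rotated states, codons nondecreasing
            seq = [(iv.state, iv.codon) for iv in traj.intervals if iv.state in (NONROT, ROT)]
            collapsed = [s for j, s in enumerate(seq) if j == 0 or s != seq[j - 1]]
            codons = [k for _, k in collapsed]
            assert codons == sorted(codons)
            for j, (st, k) in enumerate(collapsed):
                if st == ROT:
                    assert j > 0 and collapsed[j - 1] == (NONROT, k)
            # dye occupancy stays within two labelled tRNAs
            assert all(0 <= iv.cy5_count <= 2 for iv in traj.intervals)
            # nothing mechanistic before delivery
            post = [iv for iv in traj.intervals if iv.state not in (PIC, "BLEACHED")]
            assert all(iv.t_start >= DELIVERY_TIME for iv in post)

    def test_degenerate_probability_presets_terminate(self):
        prog = default_program()
        for over in (
            dict(p_decode_sup=0.0),
            dict(p_pre_dis=1.0),
            dict(p_continue_late=0.0),
        ):
            preset = make_preset("UTu1", 50, 1.0, **over)
            traj = sample_trajectory(prog, preset, trace_rng(1, 0), "t")
            traj.validate()

    def test_monte_carlo_matches_closed_form_small(self, ut50_preset):
        """Branch fractions from sampled truths track the closed forms."""
        prog = default_program()
        n = 4000
        decode = pre = post = surv = 0
        n1 = 0
        preset = make_preset("UTu1", 50, 1.0, bleach_rate_green=0.0, bleach_rate_red=0.0)
        for i in range(n):
            t = sample_trajectory(prog, preset, trace_rng(77, i), "t")
            if t.last_codon_truth >= 1:
                n1 += 1
                if t.last_codon_truth >= 2:
                    decode += 1
                    if t.last_codon_truth >= 3:
                        surv += 1
        f = expected_fractions(preset)
        p_hat = decode / n1
        se = math.sqrt(f["p_decode_codon2"] * 0.17 / n1)
        assert abs(p_hat - f["p_decode_codon2"]) < 4 * se
        p_surv = surv / decode
        se = math.sqrt(p_surv * (1 - p_surv) / decode)
        assert abs(p_surv - f["p_survive_codon3_given_decode"]) < 4 * se

    def test_dwell_means_recovered_from_ground_truth(self, ut50_preset):
        """Sample means of ground-truth dwells match the preset means."""
        prog = default_program()
        preset = make_preset("UTu1", 50, 1.0, bleach_rate_green=0.0, bleach_rate_red=0.0)
        decode_dwells = []
        rot_dwells = []
        for i in range(3000):
            t = sample_trajectory(prog, preset, trace_rng(13, i), "t")
            rotated = {iv.codon for iv in t.intervals if iv.state == ROT}
            for iv in t.intervals:
                if iv.state == NONROT and iv.codon == 2 and 2 in rotated:
                    decode_dwells.append(iv.t_end - iv.t_start)
                if iv.state == ROT and iv.codon == 1:
                    rot_dwells.append(iv.t_end - iv.t_start)
        assert np.mean(decode_dwells) == pytest.approx(preset.t_decode_sup_mean, rel=0.05)
        assert np.mean(rot_dwells) == pytest.approx(preset.t_rotated_mean, rel=0.05)
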