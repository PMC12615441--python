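"""Quality assurance gate, ROI means, and grouping schemes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from phosphoshift.qa import (
    ShiftSignature,
    group_by_scheme,
    qa_mask,
    roi_mean_shifts,
)
from phosphoshift.simulate import ANALYSIS_RESONANCES, LABELS, GroundTruth


def _frame(voxels):
    """Build a fit frame from {(i,j,k): {resonance: (shift, crlb)}}."""
    rows = []
    for (i, j, k), res in voxels.items():
        for name, (shift, crlb_pct) in res.items():
            rows.append({
                "i": i, "j": j, "k": k, "resonance": name,
                "amplitude": 1.0, "shift_ppm": shift, "damping": 30.0,
                "phase": 0.0, "crlb_amp_pct": crlb_pct,
                "crlb_shift_ppm": 0.001, "converged": True, "noise_sd": 0.1,
            })
    return pd.DataFrame(rows)


def _uniform_voxel(shift=1.0, crlb=(10.0, 12.0, 15.0, 20.0)):
    return {name: (shift, c) for name, c in zip(ANALYSIS_RESONANCES, crlb)}


class TestQaMask:
    def test_all_below_threshold_passes(self):
        frame = _frame({(0, 0, 0): _uniform_voxel()})
        assert qa_mask(frame).qa_pass.all()

    def test_exactly_at_threshold_fails(self):
        # the gate is strictly "below 35 %": equality is excluded
        frame = _frame({(0, 0, 0): _uniform_voxel(crlb=(35.0, 1.0, 1.0, 1.0))})
        assert not qa_mask(frame, 35.0).qa_pass.any()

    def test_non_converged_voxel_fails(self):
        frame = _frame({(0, 0, 0): _uniform_voxel()})
        frame["converged"] = False
        assert not qa_mask(frame).qa_pass.any()

    def test_missing_crlb_fails(self):
        frame = _frame({(0, 0, 0): _uniform_voxel(crlb=(np.nan, 1.0, 1.0, 1.0))})
        assert not qa_mask(frame).qa_pass.any()

    def test_missing_resonance_fails(self):
        frame = _frame({(0, 0, 0): _uniform_voxel()})
        frame = frame[frame.resonance != "Pi"]
        assert not qa_mask(frame).qa_pass.any()

    def test_matches_brute_force_recount(self, rng):
        voxels = {}
        for n in range(60):
            crlbs = tuple(rng.uniform(0, 70, size=4))
            voxels[(n, 0, 0)] = _uniform_voxel(crlb=crlbs)
        frame = _frame(voxels)
        got = qa_mask(frame, 35.0).set_index(["i", "j", "k"])["qa_pass"]
        for key, res in voxels.items():
            expected = all(c < 35.0 for _, c in res.values())
            assert got.loc[key] == expected

    @given(st.lists(st.tuples(*[st.floats(0, 80)] * 4), min_size=1, max_size=30))
    def test_monotone_in_threshold(self, crlb_rows):
        frame = _frame({
            (n, 0, 0): _uniform_voxel(crlb=row) for n, row in enumerate(crlb_rows)
        })
        low = qa_mask(frame, 20.0).qa_pass
        high = qa_mask(frame, 50.0).qa_pass
        assert (high | ~low).all()  # raising the threshold never drops a pass

    def test_positive_threshold_required(self):
        with pytest.raises(ValueError):
            qa_mask(_frame({(0, 0, 0): _uniform_voxel()}), 0.0)


def _mini_truth(labels, grade="HGG", idh="WT", pid="P01"):
    labels = np.asarray(labels, dtype=np.int8)
    shape = labels.shape
    return GroundTruth(
        ph=np.full(shape, 7.0), mg=np.full(shape, 0.8), ion=np.full(shape, 0.15),
        labels=labels, patient_id=pid, grade=grade, idh=idh,
    )


class TestRoiMeans:
    def test_single_voxel_roi(self):
        frame = _frame({(0, 0, 0): _uniform_voxel(shift=2.5)})
        truth = _mini_truth([[[LABELS["CE"]]]])
        qa = qa_mask(frame)
        table = roi_mean_shifts(frame, truth, qa)
        ce = table[table.roi == "CE"].iloc[0]
        assert ce.d_pi == 2.5 and ce.n_voxels_after_qa == 1

    def test_mean_excludes_failing_voxels(self):
        voxels = {}
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
        for n, v in enumerate(vals):
            crlb = (50.0,) * 4 if n < 3 else (5.0,) * 4  # first 3 fail QA
            voxels[(n, 0, 0)] = _uniform_voxel(shift=v, crlb=crlb)
        frame = _frame(voxels)
        truth = _mini_truth(np.full((10, 1, 1), LABELS["CE"]))
        table = roi_mean_shifts(frame, truth, qa_mask(frame))
        ce = table[table.roi == "CE"].iloc[0]
        assert ce.d_pi == pytest.approx(np.mean(vals[3:]))
        assert ce.n_voxels_before_qa == 10 and ce.n_voxels_after_qa == 7

    def test_empty_roi_reported_missing(self, caplog):
        frame = _frame({(0, 0, 0): _uniform_voxel(crlb=(99.0,) * 4)})
        truth = _mini_truth([[[LABELS["CE"]]]])
        with caplog.at_level("WARNING"):
            table = roi_mean_shifts(frame, truth, qa_mask(frame))
        assert len(table) == 0
        assert "missing" in caplog.text

    def test_permutation_invariance(self, rng):
        vals = rng.normal(size=8)
        voxels = {(n, 0, 0): _uniform_voxel(shift=v) for n, v in enumerate(vals)}
        truth = _mini_truth(np.full((8, 1, 1), LABELS["NAWM"]))
        frame = _frame(voxels)
        shuffled = frame.sample(frac=1.0, random_state=1).reset_index(drop=True)
        t1 = roi_mean_shifts(frame, truth, qa_mask(frame))
        t2 = roi_mean_shifts(shuffled, truth, qa_mask(shuffled))
        assert t1[t1.roi == "NAWM"].d_pi.iloc[0] == pytest.approx(
            t2[t2.roi == "NAWM"].d_pi.iloc[0]
        )

    def test_wht_unites_tumor_compartments(self):
        labels = np.array([[[LABELS["CE"], LABELS["EDM"], LABELS["NAWM"]]]])
        voxels = {
            (0, 0, 0): _uniform_voxel(shift=1.0),
            (0, 0, 1): _uniform_voxel(shift=3.0),
            (0, 0, 2): _uniform_voxel(shift=10.0),
        }
        frame = _frame(voxels)
        table = roi_mean_shifts(frame, _mini_truth(labels), qa_mask(frame))
        wht = table[table.roi == "WHT"].iloc[0]
        assert wht.d_pi == pytest.approx(2.0)  # NAWM voxel excluded


def _roi_table():
    rows = []
    patients = (
        [(f"P{i:02d}", "HGG", "WT") for i in range(1, 8)]
        + [("P08", "HGG", "mut"), ("P09", "LGG", "mut"), ("P10", "LGG", "mut"),
           ("P11", "unclassified", "NA")]
    )
    for pid, grade, idh in patients:
        rois = ["NAWM", "WHT"] + (["NCE"] if grade == "LGG" else ["CE", "EDM"])
        for roi in rois:
            rows.append({
                "patient": pid, "grade": grade, "idh": idh, "roi": roi,
                "d_pi": 4.8, "d_gamma": -2.5, "d_alpha": -7.5, "d_beta": -16.6,
            })
    return pd.DataFrame(rows)


class TestGrouping:
    def test_compartment_scheme_sizes(self):
        groups = group_by_scheme(_roi_table(), "compartment")
        sizes = {g: len(df) for g, df in groups.items()}
        assert sizes == {"HGG-CE": 8, "HGG-EDM": 8, "LGG-NCE": 2, "NAWM": 11}

    def test_idh_scheme_sizes_with_separate_unclassified(self):
        groups = group_by_scheme(_roi_table(), "idh")
        assert len(groups["WT"]) == 7
        assert len(groups["mut"]) == 3
        assert len(groups["unclassified"]) == 1

    def test_single_patient_cohort_groups_without_error(self):
        table = _roi_table()
        solo = table[table.patient == "P01"]
        groups = group_by_scheme(solo, "compartment")
        assert len(groups["HGG-CE"]) == 1

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            group_by_scheme(_roi_table(), "grade")


class TestShiftSignature:
    def test_alpha_referenced_triple_recomputed(self):
        sig = ShiftSignature(d_pi=4.8, d_gamma=-2.5, d_alpha=-7.5, d_beta=-16.6)
        assert sig.rel_alpha == pytest.approx((12.3, 5.0, -9.1))
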