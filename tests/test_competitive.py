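import warnings

import numpy as np
import pandas as pd
import pytest

from competage.competitive import build_design, downsample_reference_analysis, fit_plate
from competage.pipeline import prepare_points
from competage.plate_io import PlateLayout


def layout_of(wells, channels=None):
    """wells: list of (well_id, role)."""
    channels = channels or {}
    df = pd.DataFrame(
        {
            "plate_id": "P1",
            "well_id": [w for w, _ in wells],
            "role": [r for _, r in wells],
            "strain": [w for w, _ in wells],
            "condition": "SC",
            "mutant_channel": [channels.get(w, "RFP") for w, _ in wells],
        }
    )
    return PlateLayout("P1", df)


def points_from_truth(layout, days, hours, A, S, G, C=None, noise=None, rng=None):
    """Construct y = A_w + sgn*(S_w*T + G_w*t) + C_{T,t} observations."""
    rows = []
    cells = [(d, h) for d in days for h in hours]
    C = C if C is not None else {c: 0.0 for c in cells}
    for w in layout.competition_wells:
        sgn = 1.0 if layout.mutant_channel_of(w) == "RFP" else -1.0
        is_mut = layout.role_of(w) == "mutant_competition"
        for d, h in cells:
            y = A[w] + C[(d, h)]
            if is_mut:
                y += sgn * (S[w] * d + G[w] * h)
            if noise:
                y += rng.normal(0, noise)
            rows.append({"well_id": w, "day": d, "hour": h, "y": y,
                         "valid": True, "reason_invalid": ""})
    return pd.DataFrame(rows)


def oracle_constrained_ols(points, layout):
    """Independent solver: builds its own dense design column by column and
    solves the KKT (normal equations + Lagrange multiplier on sum C = 0)."""
    pts = points[points["valid"]]
    wells = [w for w in layout.competition_wells if w in set(pts["well_id"])]
    muts = [w for w in layout.mutant_wells if w in set(pts["well_id"])]
    cells = sorted({(d, h) for d, h in zip(pts["day"], pts["hour"])})
    names = [f"A[{w}]" for w in wells]
    for w in muts:
        names += [f"S[{w}]", f"G[{w}]"]
    names += [f"C[{d:g},{h:g}]" for d, h in cells]
    cols = []
    for name in names:
        kind, arg = name[0], name[2:-1]
        if kind == "A":
            col = (pts["well_id"] == arg).astype(float).to_numpy()
        elif kind in "SG":
            sgn = 1.0 if layout.mutant_channel_of(arg) == "RFP" else -1.0
            reg = pts["day"] if kind == "S" else pts["hour"]
            col = sgn * np.where(pts["well_id"] == arg, reg, 0.0)
        else:
            d, h = (float(v) for v in arg.split(","))
            col = ((pts["day"] == d) & (pts["hour"] == h)).astype(float).to_numpy()
        cols.append(np.asarray(col, dtype=float))
    X = np.column_stack(cols)
    y = pts["y"].to_numpy(dtype=float)
    p = X.shape[1]
    c = np.zeros(p)
    c[p - len(cells):] = 1.0
    kkt = np.zeros((p + 1, p + 1))
    kkt[:p, :p] = X.T @ X
    kkt[:p, p] = c
    kkt[p, :p] = c
    rhs = np.concatenate([X.T @ y, [0.0]])
    beta = np.linalg.solve(kkt, rhs)[:p]
    return pd.Series(beta, index=names)


DAYS = (0.0, 2.0, 5.0)
HOURS = (1.0, 4.0)


def three_well_setup():
    layout = layout_of([
        ("A1", "reference_competition"),
        ("A2", "reference_competition"),
        ("A3", "mutant_competition"),
    ])
    A = {"A1": 0.4, "A2": -0.2, "A3": 0.7}
    S = {"A3": -0.05}
    G = {"A3": 0.02}
    cells = [(d, h) for d in DAYS for h in HOURS]
    C = {c: v for c, v in zip(cells, [0.1, -0.05, 0.02, -0.03, 0.04, -0.08])}
    return layout, A, S, G, C


class TestDesign:
    def test_parameter_counting(self):
        layout, A, S, G, C = three_well_setup()
        pts = points_from_truth(layout, DAYS, HOURS, A, S, G, C)
        design = build_design(pts, layout)
        assert len(pts) == 18
        assert len(design.param_names) == 3 + 2 + 6  # A blocks, S+G, C cells
        assert design.constraint.sum() == 6
        assert design.reduction.shape == (11, 10)

    def test_reference_only_plate_has_no_sg_columns(self):
        layout = layout_of([("A1", "reference_competition")])
        pts = points_from_truth(layout, DAYS, HOURS, {"A1": 0.3}, {}, {})
        design = build_design(pts, layout)
        assert design.param_names == ["A[A1]"] + [n for n in design.param_names if n.startswith("C")]

    def test_zero_reference_wells_hard_error(self):
        layout = layout_of([("A1", "mutant_competition")])
        pts = points_from_truth(layout, DAYS, HOURS, {"A1": 0.0}, {"A1": 0.0}, {"A1": 0.0})
        with pytest.raises(ValueError, match="reference"):
            build_design(pts, layout)

    def test_cell_without_reference_warns(self):
        layout, A, S, G, C = three_well_setup()
        pts = points_from_truth(layout, DAYS, HOURS, A, S, G, C)
        pts = pts[~((pts["well_id"] != "A3") & (pts["day"] == 5.0) & (pts["hour"] == 4.0))]
        with pytest.warns(UserWarning, match="no reference observation"):
            build_design(pts, layout)


class TestFit:
    def test_noiseless_exact_recovery(self):
        layout, A, S, G, C = three_well_setup()
        # constraint-satisfying C: make the configured cells sum to zero
        shift = sum(C.values()) / len(C)
        C = {k: v - shift for k, v in C.items()}
        pts = points_from_truth(layout, DAYS, HOURS, A, S, G, C)
        fit = fit_plate(pts, layout)
        w = fit.wells.set_index("well_id")
        assert w.loc["A3", "S"] == pytest.approx(S["A3"], abs=1e-8)
        assert w.loc["A3", "G"] == pytest.approx(G["A3"], abs=1e-8)
        for well in ("A1", "A2", "A3"):
            assert w.loc[well, "A"] == pytest.approx(A[well], abs=1e-8)
        for _, row in fit.batch_terms.iterrows():
            assert row["C"] == pytest.approx(C[(row["day"], row["hour"])], abs=1e-8)
        assert fit.diagnostics["rss"] == pytest.approx(0.0, abs=1e-16)

    def test_reference_wells_report_structural_zeros(self, noisy_small_points, noisy_small_plate):
        fit = fit_plate(noisy_small_points, noisy_small_plate.layout)
        refs = fit.wells[fit.wells["role"] == "reference_competition"]
        assert (refs["S"] == 0.0).all() and (refs["G"] == 0.0).all()

    def test_constraint_satisfied(self, noisy_small_points, noisy_small_plate):
        fit = fit_plate(noisy_small_points, noisy_small_plate.layout)
        assert fit.batch_terms["C"].sum() == pytest.approx(0.0, abs=1e-10)

    def test_all_reference_plate_no_batch_structure(self):
        layout = layout_of([("A1", "reference_competition"), ("A2", "reference_competition")])
        pts = points_from_truth(layout, DAYS, HOURS, {"A1": 0.5, "A2": -0.1}, {}, {})
        fit = fit_plate(pts, layout)
        assert np.allclose(fit.batch_terms["C"], 0.0, atol=1e-10)
        assert fit.diagnostics["rss"] == pytest.approx(0.0, abs=1e-18)

    def test_oracle_equivalence_random_instances(self):
        """fit_plate matches an independently coded KKT solver on random
        small instances, including mixed channel orientations."""
        rng = np.random.default_rng(2024)
        for trial in range(30):
            n_wells = rng.integers(2, 13)
            n_ref = rng.integers(1, n_wells + 1)
            wells = [(f"A{i + 1}" if i < 12 else f"B{i - 11}",
                      "reference_competition" if i < n_ref else "mutant_competition")
                     for i in range(n_wells)]
            channels = {w: ("RFP" if rng.random() < 0.7 else "CFP") for w, _ in wells}
            layout = layout_of(wells, channels)
            days = sorted(rng.choice([0.0, 1.0, 2.0, 3.0], size=rng.integers(2, 5), replace=False))
            hours = sorted(rng.choice([1.0, 2.5, 4.0], size=rng.integers(2, 4), replace=False))
            pts = pd.DataFrame(
                [
                    {"well_id": w, "day": d, "hour": h, "y": rng.normal(),
                     "valid": True, "reason_invalid": ""}
                    for w, _ in wells for d in days for h in hours
                ]
            )
            fit = fit_plate(pts, layout)
            oracle = oracle_constrained_ols(pts, layout)
            got = fit.params[oracle.index]
            np.testing.assert_allclose(got.to_numpy(), oracle.to_numpy(), atol=1e-8,
                                       err_msg=f"trial {trial}")

    def test_negating_y_negates_all_parameters(self):
        layout, A, S, G, C = three_well_setup()
        rng = np.random.default_rng(3)
        pts = points_from_truth(layout, DAYS, HOURS, A, S, G, C, noise=0.05, rng=rng)
        flipped = pts.assign(y=-pts["y"])
        f1, f2 = fit_plate(pts, layout), fit_plate(flipped, layout)
        np.testing.assert_allclose(f2.params.to_numpy(), -f1.params.to_numpy(), atol=1e-10)
        assert f2.diagnostics["rss"] == pytest.approx(f1.diagnostics["rss"], rel=1e-9)

    def test_channel_swap_leaves_s_invariant(self):
        """Swapping RFP<->CFP in the data and the mutant_channel labels
        (a physical relabeling of the fluorophores) leaves S and G
        unchanged and negates A and C."""
        layout, A, S, G, C = three_well_setup()
        rng = np.random.default_rng(4)
        pts = points_from_truth(layout, DAYS, HOURS, A, S, G, C, noise=0.05, rng=rng)
        swapped_entries = layout.entries.assign(mutant_channel="CFP")
        swapped_layout = PlateLayout("P1", swapped_entries)
        swapped_pts = pts.assign(y=-pts["y"])
        f1 = fit_plate(pts, layout)
        f2 = fit_plate(swapped_pts, swapped_layout)
        w1, w2 = f1.wells.set_index("well_id"), f2.wells.set_index("well_id")
        assert w2.loc["A3", "S"] == pytest.approx(w1.loc["A3", "S"], abs=1e-10)
        assert w2.loc["A3", "G"] == pytest.approx(w1.loc["A3", "G"], abs=1e-10)
        np.testing.assert_allclose(w2["A"], -w1["A"], atol=1e-10)
        np.testing.assert_allclose(f2.batch_terms["C"], -f1.batch_terms["C"], atol=1e-10)

    def test_cell_shift_moves_only_that_batch_term(self):
        """Adding a constant to all y of one (day, hour) cell changes that
        cell's C (and the A block through re-centering) but no S or G."""
        layout, A, S, G, C = three_well_setup()
        rng = np.random.default_rng(5)
        pts = points_from_truth(layout, DAYS, HOURS, A, S, G, C, noise=0.05, rng=rng)
        shifted = pts.copy()
        cell = (pts["day"] == 2.0) & (pts["hour"] == 4.0)
        shifted.loc[cell, "y"] += 0.8
        f1, f2 = fit_plate(pts, layout), fit_plate(shifted, layout)
        w1, w2 = f1.wells.set_index("well_id"), f2.wells.set_index("well_id")
        assert w2.loc["A3", "S"] == pytest.approx(w1.loc["A3", "S"], abs=1e-10)
        assert w2.loc["A3", "G"] == pytest.approx(w1.loc["A3", "G"], abs=1e-10)
        b1 = f1.batch_terms.set_index(["day", "hour"])["C"]
        b2 = f2.batch_terms.set_index(["day", "hour"])["C"]
        dC = (b2 - b1)
        assert dC.loc[(2.0, 4.0)] == pytest.approx(0.8 - 0.8 / 6, abs=1e-10)
        others = dC.drop(index=(2.0, 4.0))
        np.testing.assert_allclose(others, -0.8 / 6, atol=1e-10)

    def test_rank_deficiency_names_aliased_parameters(self):
        layout = layout_of([
            ("A1", "reference_competition"),
            ("A2", "mutant_competition"),
        ])
        # mutant observed at a single hour: G aliased with A
        rows = [
            {"well_id": "A1", "day": d, "hour": h, "y": 0.1, "valid": True, "reason_invalid": ""}
            for d in DAYS for h in HOURS
        ] + [
            {"well_id": "A2", "day": d, "hour": 1.0, "y": 0.2, "valid": True, "reason_invalid": ""}
            for d in DAYS
        ]
        with pytest.raises(ValueError, match=r"aliased"):
            fit_plate(pd.DataFrame(rows), layout)

    def test_simulated_recovery_with_noise(self, noisy_small_plate, noisy_small_points):
        fit = fit_plate(noisy_small_points, noisy_small_plate.layout)
        truth = noisy_small_plate.well_truth.set_index("well_id")
        mut = fit.wells[fit.wells["role"] == "mutant_competition"].set_index("well_id")
        err = (mut["S"] - truth.loc[mut.index, "S_true"]).abs()
        # errors consistent with the fit's own uncertainty on a small design
        assert (err <= 3 * mut["se_S"]).all()
        assert err.mean() < 0.02


class TestDownsampling:
    def test_full_reference_draw_equals_full_fit(self, noisy_small_points, noisy_small_plate):
        layout = noisy_small_plate.layout
        full = fit_plate(noisy_small_points, layout)
        tab = downsample_reference_analysis(noisy_small_points, layout, [8], 1, seed=0)
        mut = full.wells[full.wells["role"] == "mutant_competition"]
        assert tab.loc[0, "mean_ci95_width"] == pytest.approx(
            float((mut["ci_high_S"] - mut["ci_low_S"]).mean())
        )

    def test_deterministic_given_seed(self, noisy_small_points, noisy_small_plate):
        args = (noisy_small_points, noisy_small_plate.layout, [2, 5], 4)
        t1 = downsample_reference_analysis(*args, seed=7)
        t2 = downsample_reference_analysis(*args, seed=7)
        pd.testing.assert_frame_equal(t1, t2)

    def test_oversized_grid_entry_skipped(self, noisy_small_points, noisy_small_plate):
        with pytest.warns(UserWarning, match="skipped"):
            tab = downsample_reference_analysis(
                noisy_small_points, noisy_small_plate.layout, [2, 50], 2, seed=1
            )
        assert list(tab["n_refs"]) == [2]

    def test_precision_improves_with_references(self, noisy_small_points, noisy_small_plate):
        tab = downsample_reference_analysis(
            noisy_small_points, noisy_small_plate.layout, [1, 4, 8], 8, seed=11
        )
        sd = tab["mean_sd_S"].to_numpy()
        assert sd[0] > sd[-1]
        assert (np.diff(tab["mean_ci95_width"]) <= 1e-12).all()
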