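import numpy as np
import pandas as pd
import pytest

from revscreen import (
    build_layout,
    call_degs,
    fold_changes,
    gene_counts,
    generate_screen,
    normalize,
    overlap_percent,
    size_factors,
)
from revscreen.quantify import FoldChangeProfile, read_profiles, write_profiles


def _wells(plate, n):
    return [f"{plate}_A{i + 1:02d}" for i in range(n)]


def _counts(rows, genes):
    return pd.DataFrame(rows, columns=genes)


class TestSizeFactors:
    def test_identical_wells_give_unit_factors(self):
        genes = [f"C{i}" for i in range(5)]
        df = _counts([[10, 20, 30, 40, 50]] * 4, genes)
        df.index = _wells("P1", 4)
        f = size_factors(df, genes)
        assert np.allclose(f, 1.0)

    def test_scaled_well_scaled_factor(self):
        genes = [f"C{i}" for i in range(5)]
        rows = [[10, 20, 30, 40, 50]] * 4
        df = _counts(rows, genes)
        df.index = _wells("P1", 4)
        df.iloc[0] *= 3
        f = size_factors(df, genes)
        assert f.iloc[0] / f.iloc[1] == pytest.approx(3.0)
        assert np.allclose(f.iloc[1:], f.iloc[1])

    def test_recovers_true_depth_on_nb_screen(self, tmp_path):
        from revscreen import generate_probe_set

        probes = generate_probe_set(7, 6, 33, seed=21)
        layout = build_layout([f"C{i}" for i in range(20)], replicates=2, dmso_per_plate=8)
        truth, synth = generate_screen(
            probes, layout, {}, tmp_path / "fq",
            reads_per_well=10_000, error_rate=0.0, depth_sigma=0.5, seed=4,
        )
        g = gene_counts(truth, probes)
        f = size_factors(g, probes.control_genes)
        depth = pd.Series(synth.depth_factors).loc[f.index]
        r = np.corrcoef(f, depth)[0, 1]
        assert r >= 0.9

    def test_all_zero_well_fails_naming_it(self):
        genes = [f"C{i}" for i in range(4)]
        df = _counts([[5, 5, 5, 5], [0, 0, 0, 0]], genes)
        df.index = _wells("P1", 2)
        with pytest.raises(ValueError, match="P1_A02"):
            size_factors(df, genes)

    def test_fallback_when_no_gene_everywhere_nonzero(self, caplog):
        genes = [f"C{i}" for i in range(3)]
        df = _counts([[10, 0, 5], [0, 10, 5], [10, 10, 0]], genes)
        df.index = _wells("P1", 3)
        with caplog.at_level("WARNING"):
            f = size_factors(df, genes)
        assert (f > 0).all()
        assert "falling back" in caplog.text


def test_normalization_absorbs_per_well_scaling():
    """Scaling one well's raw counts is absorbed by its size factor: the
    normalized matrix is unchanged up to the plate-wide geometric-mean-1
    rescale, so all within-plate signal ratios are preserved exactly."""
    genes = [f"C{i}" for i in range(6)]
    rng = np.random.default_rng(0)
    raw = pd.DataFrame(rng.integers(50, 500, (4, 6)), columns=genes, index=_wells("P1", 4))
    f1 = size_factors(raw, genes)
    n1 = normalize(raw, f1)
    scaled = raw.copy().astype(float)
    scaled.iloc[2] *= 7.5
    f2 = size_factors(scaled, genes)
    n2 = normalize(scaled, f2)
    ratio = n2.to_numpy() / n1.to_numpy()
    assert np.allclose(ratio, ratio.flat[0], rtol=1e-9)
    # and the scaled well's factor took the full x7.5 relative to the others
    assert (f2.iloc[2] / f2.iloc[0]) / (f1.iloc[2] / f1.iloc[0]) == pytest.approx(7.5)


class TestFoldChanges:
    def _norm_layout(self):
        layout = build_layout(["DRUG"], replicates=3, dmso_per_plate=3)
        genes = ["G1", "G2"]
        keys = layout.well_keys()
        rng = np.random.default_rng(1)
        base = rng.normal(100, 3, size=(len(keys), 2))
        norm = pd.DataFrame(base, index=keys, columns=genes)
        return norm, layout

    def test_signal_equal_to_dmso_mean_gives_unit_fc(self):
        layout = build_layout(["DRUG"], replicates=2, dmso_per_plate=2)
        keys = layout.well_keys()
        norm = pd.DataFrame(100.0, index=keys, columns=["G1"])
        prof = fold_changes(norm, layout)["DRUG"]
        assert prof.table.loc["G1", "fold_change"] == pytest.approx(1.0)
        assert prof.table.loc["G1", "log2fc"] == pytest.approx(0.0)

    def test_dmso_like_compound_centered_at_one(self, tmp_path):
        from revscreen import generate_probe_set

        probes = generate_probe_set(7, 6, 33, seed=13)
        layout = build_layout(["VEH"], replicates=8, dmso_per_plate=16)
        truth, _ = generate_screen(
            probes, layout, {}, tmp_path / "fq",
            reads_per_well=10_000, error_rate=0.0, seed=6,
        )
        g = gene_counts(truth, probes)
        norm = normalize(g, size_factors(g, probes.control_genes))
        prof = fold_changes(norm, layout)["VEH"]
        assert abs(prof.table["log2fc"].median()) <= 0.05

    def test_planted_effect_recovered(self, tmp_path):
        """A planted log2 effect of -2 comes back as fold change ~0.25;
        averaging over the planted genes integrates out NB well noise."""
        from revscreen import generate_probe_set

        probes = generate_probe_set(7, 6, 33, seed=17)
        planted = {g: -2.0 for g in probes.signature_up}
        layout = build_layout(["DRUG"], replicates=4, dmso_per_plate=16)
        truth, _ = generate_screen(
            probes, layout, {"DRUG": planted}, tmp_path / "fq",
            reads_per_well=20_000, error_rate=0.0, seed=8,
        )
        g = gene_counts(truth, probes)
        norm = normalize(g, size_factors(g, probes.control_genes))
        prof = fold_changes(norm, layout)["DRUG"]
        assert 0.2 <= prof.table.loc[list(planted), "fold_change"].mean() <= 0.32

    def test_single_well_uses_normal_score(self):
        layout = build_layout(["SOLO"], replicates=1, dmso_per_plate=6)
        keys = layout.well_keys()
        rng = np.random.default_rng(2)
        norm = pd.DataFrame(rng.normal(100, 5, (len(keys), 1)), index=keys, columns=["G1"])
        prof = fold_changes(norm, layout)["SOLO"]
        assert prof.n_wells == 1
        assert 0 < prof.table.loc["G1", "p_value"] <= 1

    def test_cross_plate_compound_gets_combined_profile(self):
        import pandas as pd

        rows = []
        for plate in ("P01", "P02"):
            rows += [(plate, "A01", "DMSO", 0.0, 24.0), (plate, "A02", "DMSO", 0.0, 24.0),
                     (plate, "A03", "DRUG", 1.0, 24.0), (plate, "A04", "DRUG", 1.0, 24.0)]
        from revscreen.plates import PlateLayout

        layout = PlateLayout(pd.DataFrame(
            rows, columns=["plate", "well", "treatment", "dose_uM", "time_h"]))
        keys = layout.well_keys()
        rng = np.random.default_rng(3)
        norm = pd.DataFrame(rng.normal(100, 4, (len(keys), 2)), index=keys, columns=["G1", "G2"])
        prof = fold_changes(norm, layout)["DRUG"]
        assert prof.plate == "combined"
        assert len(prof.per_plate) == 2
        assert prof.n_wells == 4


class TestCallDegs:
    def _prof(self, fc, p):
        t = pd.DataFrame({"fold_change": [fc], "log2fc": [np.log2(fc)], "p_value": [p]},
                         index=["G"])
        return FoldChangeProfile("X", t, "P1", 2)

    def test_boundary_fold_change_is_excluded(self):
        assert call_degs(self._prof(2.0, 0.001)) == ([], [])

    def test_strong_repression_is_a_down_deg(self):
        assert call_degs(self._prof(0.25, 0.001)) == ([], ["G"])

    def test_nonsignificant_p_excluded(self):
        assert call_degs(self._prof(8.0, 0.5)) == ([], [])

    def test_monotone_in_p_and_fold_change(self):
        up1, _ = call_degs(self._prof(3.0, 0.04))
        up2, _ = call_degs(self._prof(4.0, 0.01))
        assert set(up1) <= set(up2)


class TestOverlapPercent:
    def test_printed_counts_round_to_fifteen(self):
        a = {f"g{i}" for i in range(73)}
        b = {f"g{i}" for i in range(11)} | {f"h{i}" for i in range(300)}
        pct, disp = overlap_percent(a, b)
        assert disp == 15
        assert pct == pytest.approx(100 * 11 / 73)

    def test_disjoint_and_subset(self):
        assert overlap_percent({"a"}, {"b"})[0] == 0.0
        assert overlap_percent({"a", "b"}, {"a", "b", "c"})[0] == 100.0

    def test_empty_query_fails(self):
        with pytest.raises(ValueError):
            overlap_percent(set(), {"a"})


def test_profile_tsv_roundtrip(tmp_path):
    t = pd.DataFrame(
        {"fold_change": [2.0, 0.5], "log2fc": [1.0, -1.0], "p_value": [0.01, 0.2]},
        index=["G1", "G2"],
    )
    profiles = {"X": FoldChangeProfile("X", t, "P1", 2)}
    path = tmp_path / "fc.tsv"
    write_profiles(profiles, path)
    back = read_profiles(path)
    pd.testing.assert_frame_equal(back["X"].table, t, check_names=False)
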