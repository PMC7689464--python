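import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vesicleshift as vs
from vesicleshift.errors import (
    DegenerateProfileError,
    DimensionError,
    DuplicateIdError,
    SchemaError,
)
from vesicleshift.profiles import UNASSIGNED


def _write_table(path, rows, scheme, extra_cols=()):
    cols = ["accession", *extra_cols, *scheme.column_names()]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False)
    return path


class TestReadDataset:
    def test_shape_bookkeeping(self, tmp_path, toy_scheme):
        rows = [[f"P{i}", *range(6)] for i in range(3)]
        ds = vs.read_dataset(
            _write_table(tmp_path / "t.tsv", rows, toy_scheme), toy_scheme
        )
        assert ds.values.shape == (3, 6)
        assert ds.protein_ids == ["P0", "P1", "P2"]

    def test_missing_values_dropped(self, tmp_path, toy_scheme):
        rows = [
            ["P0", 1, 2, 3, 4, 5, 6],
            ["P1", 1, None, 3, 4, 5, 6],
            ["P2", 1, 2, 3, 4, 5, 6],
        ]
        ds = vs.read_dataset(
            _write_table(tmp_path / "t.tsv", rows, toy_scheme), toy_scheme
        )
        assert ds.n_proteins == 2
        assert "P1" not in ds.protein_ids

    def test_duplicate_accessions_rejected(self, tmp_path, toy_scheme):
        rows = [["P0", *range(6)], ["P0", *range(6)]]
        with pytest.raises(DuplicateIdError):
            vs.read_dataset(
                _write_table(tmp_path / "t.tsv", rows, toy_scheme), toy_scheme
            )

    def test_scheme_mismatch_raises(self, tmp_path, toy_scheme):
        other = vs.FractionScheme(("F1", "F2", "F3"), ("R1", "R2"), "treatment")
        rows = [["P0", *range(6)]]
        with pytest.raises(SchemaError):
            vs.read_dataset(
                _write_table(tmp_path / "t.tsv", rows, toy_scheme), other
            )

    def test_column_order_in_file_is_irrelevant(self, tmp_path, toy_scheme):
        rows = [["P0", 1, 2, 3, 4, 5, 6], ["P1", 6, 5, 4, 3, 2, 1]]
        path = _write_table(tmp_path / "a.tsv", rows, toy_scheme)
        df = pd.read_csv(path, sep="\t")
        shuffled = df[list(df.columns[::-1])]
        shuffled.to_csv(tmp_path / "b.tsv", sep="\t", index=False)
        a = vs.read_dataset(path, toy_scheme)
        b = vs.read_dataset(tmp_path / "b.tsv", toy_scheme)
        np.testing.assert_array_equal(a.values, b.values)


class TestContaminantFilter:
    @pytest.fixture()
    def ds(self, toy_scheme):
        return vs.ProfileDataset(
            protein_ids=["HIGH", "HIGHMARK", "LOW", "BLOCKED"],
            values=np.ones((4, 6)),
            scheme=toy_scheme,
        )

    def test_threshold_and_marker_exemption(self, ds):
        tab = vs.ContaminantTable({"HIGH": 0.15, "HIGHMARK": 0.15, "LOW": 0.05})
        markers = vs.MarkerMap({"HIGHMARK": "golgi"})
        out = vs.filter_contaminants(ds, tab, markers, threshold=0.1, blocklist=[])
        assert "HIGH" not in out.protein_ids  # freq >= 0.1, not a marker
        assert "HIGHMARK" in out.protein_ids  # marker exemption
        assert "LOW" in out.protein_ids  # below threshold

    def test_blocklist_removal(self, ds):
        out = vs.filter_contaminants(
            ds, vs.ContaminantTable({}), vs.MarkerMap({}), blocklist=["BLOCKED"]
        )
        assert "BLOCKED" not in out.protein_ids
        assert out.n_proteins == 3

    def test_never_removes_markers(self, ds):
        tab = vs.ContaminantTable({p: 0.99 for p in ds.protein_ids})
        markers = vs.MarkerMap({p: "golgi" for p in ds.protein_ids})
        out = vs.filter_contaminants(ds, tab, markers, blocklist=[])
        assert out.protein_ids == ds.protein_ids


class TestNormaliseRows:
    def test_arithmetic(self, toy_scheme):
        ds = vs.ProfileDataset(
            ["P0"], np.array([[2.0, 2, 4, 1, 1, 2]]), toy_scheme
        )
        out = vs.normalise_rows(ds)
        np.testing.assert_allclose(
            out.values[0], [0.25, 0.25, 0.5, 0.25, 0.25, 0.5]
        )

    def test_idempotent(self, normalised_sim):
        _, control, *_ = normalised_sim
        again = vs.normalise_rows(control)
        np.testing.assert_allclose(again.values, control.values, atol=1e-12)

    def test_block_sums_to_one(self, normalised_sim):
        _, control, *_ = normalised_sim
        sums = control.blocks().sum(axis=2)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_all_zero_block_raises(self, toy_scheme):
        ds = vs.ProfileDataset(
            ["P0"], np.array([[0.0, 0, 0, 1, 1, 2]]), toy_scheme
        )
        with pytest.raises(DegenerateProfileError):
            vs.normalise_rows(ds)


class TestALR:
    def test_equal_parts_map_to_zero(self):
        np.testing.assert_allclose(
            vs.alr_transform(np.full(4, 0.25)), np.zeros(3), atol=1e-12
        )

    def test_log2_analytic(self):
        out = vs.alr_transform(np.array([0.5, 0.25, 0.25]))
        np.testing.assert_allclose(out, [np.log(2.0), 0.0], atol=1e-12)

    def test_round_trip_on_dirichlet_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            d = rng.integers(3, 12)
            x = rng.dirichlet(np.full(d, rng.uniform(0.5, 5.0)))
            np.testing.assert_allclose(
                vs.inverse_alr(vs.alr_transform(x)), x, atol=1e-9
            )

    @given(
        st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=2, max_size=15)
    )
    @settings(max_examples=100, derandomize=True)
    def test_round_trip_property(self, parts):
        x = np.asarray(parts) / np.sum(parts)
        np.testing.assert_allclose(
            vs.inverse_alr(vs.alr_transform(x)), x, atol=1e-9
        )

    def test_zero_replacement_keeps_transform_finite(self):
        out = vs.alr_transform(np.array([0.6, 0.4, 0.0]))
        assert np.all(np.isfinite(out))

    def test_dimension_error(self):
        with pytest.raises(DimensionError):
            vs.alr_transform(np.array([1.0]))


class TestConcatenateReplicates:
    def test_block_ordering(self, toy_scheme):
        ds = vs.ProfileDataset(
            ["P0"], np.arange(6, dtype=float)[None, :], toy_scheme
        )
        vec = vs.concatenate_replicates(ds)[0]
        # replicate-major: R1 F1..F3 then R2 F1..F3
        np.testing.assert_array_equal(vec, [0, 1, 2, 3, 4, 5])

    def test_single_replicate_identity(self):
        scheme = vs.FractionScheme(("F1", "F2", "F3"), ("R1",), "c")
        values = np.random.default_rng(0).random((4, 3))
        ds = vs.ProfileDataset([f"P{i}" for i in range(4)], values, scheme)
        np.testing.assert_array_equal(vs.concatenate_replicates(ds), values)


class TestPCA:
    def test_line_explains_all_variance(self):
        t = np.linspace(0, 1, 50)
        X = np.column_stack([t, 2 * t])
        _, evr = vs.pca_projection(X, 2)
        assert evr[0] == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_cloud_has_equal_variances(self, rng):
        X = rng.normal(size=(10000, 4))
        _, evr = vs.pca_projection(X, 4)
        np.testing.assert_allclose(evr, 0.25, atol=0.02)

    def test_deterministic_and_row_order_invariant(self, rng):
        X = rng.normal(size=(60, 5))
        s1, _ = vs.pca_projection(X, 3)
        s2, _ = vs.pca_projection(X, 3)
        np.testing.assert_array_equal(s1, s2)
        perm = rng.permutation(60)
        s3, _ = vs.pca_projection(X[perm], 3)
        np.testing.assert_allclose(s3, s1[perm], atol=1e-9)

    def test_sign_convention(self, rng):
        X = rng.normal(size=(40, 3))
        # flipping the data flips scores but the convention restores them
        s1, _ = vs.pca_projection(X, 2)
        s2, _ = vs.pca_projection(-X + X.mean(axis=0) * 2, 2)
        assert abs(abs(s1[0, 0]) - abs(s2[0, 0])) < 1e-9


class TestClassifySupervised:
    @pytest.fixture()
    def separated(self):
        """5 well-separated classes; half the markers are held out as unknowns."""
        rng = np.random.default_rng(7)
        scheme = vs.FractionScheme(
            tuple(f"F{i}" for i in range(4)), ("R1",), "c"
        )
        centers = rng.normal(0, 10, size=(5, 4))
        ids, values, truth, marked = [], [], {}, {}
        for k in range(5):
            for j in range(40):
                pid = f"C{k}_{j}"
                ids.append(pid)
                values.append(centers[k] + rng.normal(0, 0.3, 4))
                truth[pid] = f"class{k}"
                if j < 20:
                    marked[pid] = f"class{k}"
        ds = vs.ProfileDataset(ids, np.array(values), scheme)
        return ds, vs.MarkerMap(marked), truth

    def test_held_out_markers_correctly_assigned(self, separated):
        ds, markers, truth = separated
        result = vs.classify_supervised(ds, markers, fdr=0.05)
        held_out = [p for p in ds.protein_ids if p not in markers]
        correct = np.mean([result[p] == truth[p] for p in held_out])
        assert correct >= 0.99

    def test_markers_keep_curated_labels(self, separated):
        ds, markers, _ = separated
        result = vs.classify_supervised(ds, markers, fdr=0.05)
        for pid, cls in markers.entries.items():
            assert result[pid] == cls

    def test_fdr_zero_is_conservative(self, separated):
        ds, markers, truth = separated
        strict = vs.classify_supervised(ds, markers, fdr=0.0)
        loose = vs.classify_supervised(ds, markers, fdr=0.5)
        n_strict = (strict != UNASSIGNED).sum()
        n_loose = (loose != UNASSIGNED).sum()
        assert n_strict <= n_loose
        assigned = strict[(strict != UNASSIGNED)]
        wrong = [p for p in assigned.index if assigned[p] != truth[p]]
        assert not wrong

    def test_small_class_excluded_with_warning(self, separated):
        ds, markers, _ = separated
        entries = dict(markers.entries)
        entries["C0_25"] = "tiny_class"
        with pytest.warns(UserWarning, match="tiny_class"):
            vs.classify_supervised(ds, vs.MarkerMap(entries), fdr=0.05)
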