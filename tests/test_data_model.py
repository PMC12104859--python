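"""Data model, CSV round-trips, validation diagnostics, composition summaries."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from harvestmeta.data_model import (
    BIOMES,
    POOLS,
    REFERENCE_TYPES,
    TREATMENTS,
    Dataset,
    SchemaError,
    ValidationError,
    assign_time_class,
    read_dataset,
    summarize_dataset,
    validate_table,
    write_dataset,
)
from harvestmeta.synthetic import default_config, generate_dataset

from conftest import make_obs_frame


def roundtrip(ds: Dataset, tmp_path) -> Dataset:
    p = tmp_path / "ds.csv"
    write_dataset(ds, p)
    return read_dataset(p)


class TestRoundTrip:
    def test_identity_on_small_fixture(self, tiny_dataset, tmp_path):
        back = roundtrip(tiny_dataset, tmp_path)
        assert len(back) == 3
        assert back.equals(tiny_dataset)

    def test_synthetic_roundtrip_preserves_optional_fields(self, tmp_path):
        ds, _ = generate_dataset(default_config(seed=5))
        back = roundtrip(ds, tmp_path)
        assert back.equals(ds)
        # missingness pattern survives: absent stays absent
        assert back.df["se_treatment"].isna().equals(ds.df["se_treatment"].isna())

    def test_empty_dataset_writes_header_only(self, tmp_path):
        ds = Dataset(df=pd.DataFrame())
        p = tmp_path / "empty.csv"
        write_dataset(ds, p)
        text = p.read_text()
        assert text.count("\n") == 1
        assert "study_id" in text
        assert len(read_dataset(p)) == 0

    def test_output_is_byte_stable(self, tiny_dataset, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_dataset(tiny_dataset, p1)
        write_dataset(tiny_dataset, p2)
        assert p1.read_bytes() == p2.read_bytes()

    # random valid tables: draw per-row optional-field patterns and check
    # read(write(ds)) is the identity
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_roundtrip_property(self, data, tmp_path_factory):
        n = data.draw(st.integers(1, 8))
        rows = []
        for i in range(n):
            has_var = data.draw(st.booleans())
            rows.append(
                (
                    f"S{data.draw(st.integers(1, 3))}",
                    f"u{i}",
                    data.draw(st.sampled_from(POOLS)),
                    data.draw(st.sampled_from(TREATMENTS)),
                    data.draw(st.sampled_from(BIOMES)),
                    data.draw(st.sampled_from(REFERENCE_TYPES)),
                    data.draw(st.floats(0, 110, allow_nan=False)),
                    data.draw(st.floats(0.1, 500, allow_nan=False)),
                    data.draw(st.floats(0.1, 500, allow_nan=False)),
                    data.draw(st.floats(0, 50)) if has_var else None,
                    data.draw(st.floats(0, 50)) if has_var else None,
                    data.draw(st.integers(1, 20)) if has_var else None,
                    data.draw(st.integers(1, 20)) if has_var else None,
                    None,
                )
            )
        ds = Dataset(df=make_obs_frame(rows))
        tmp = tmp_path_factory.mktemp("rt") / "ds.csv"
        write_dataset(ds, tmp)
        assert read_dataset(tmp).equals(ds)


class TestValidation:
    def test_zero_control_rejected_names_denominator(self, tiny_frame, tmp_path):
        tiny_frame.loc[0, "mean_control"] = 0.0
        p = tmp_path / "bad.csv"
        tiny_frame.to_csv(p, index=False)
        with pytest.raises(ValidationError, match="denominator"):
            read_dataset(p)
        ds = read_dataset(p, strict=False)
        assert len(ds) == 2
        assert any(i.column == "mean_control" for i in ds.issues)

    def test_unknown_category_lists_allowed_levels(self, tiny_frame, tmp_path):
        tiny_frame.loc[1, "pool"] = "canopy"
        p = tmp_path / "bad.csv"
        tiny_frame.to_csv(p, index=False)
        with pytest.raises(ValidationError, match="live_trees"):
            read_dataset(p)

    def test_missing_required_column_is_schema_error(self, tiny_frame, tmp_path):
        p = tmp_path / "bad.csv"
        tiny_frame.drop(columns=["biome"]).to_csv(p, index=False)
        with pytest.raises(SchemaError, match="biome"):
            read_dataset(p)

    def test_se_without_n_rejected(self, tiny_frame, tmp_path):
        tiny_frame.loc[0, "n_treatment"] = None
        p = tmp_path / "bad.csv"
        tiny_frame.to_csv(p, index=False)
        with pytest.raises(ValidationError, match="se_treatment"):
            read_dataset(p)

    def test_soft_violations_warn_but_keep_rows(self, tiny_frame, tmp_path):
        tiny_frame.loc[2, "sampling_depth"] = 300.0  # outside 7-150 cm
        tiny_frame.loc[0, "time_since_treatment"] = 150.0  # beyond horizon
        p = tmp_path / "soft.csv"
        tiny_frame.to_csv(p, index=False)
        ds = read_dataset(p)  # strict: soft issues must not raise
        assert len(ds) == 3
        warns = [i for i in ds.issues if i.level == "warning"]
        assert {i.column for i in warns} == {"sampling_depth", "time_since_treatment"}

    def test_every_bad_row_gets_a_diagnostic(self, tiny_frame):
        tiny_frame.loc[0, "mean_control"] = -1.0
        tiny_frame.loc[1, "treatment"] = "coppice"
        clean, issues = validate_table(Dataset(df=tiny_frame).df)
        assert len(clean) == 1
        assert {i.row for i in issues if i.level == "error"} == {0, 1}

    def test_duplicate_key_rejected(self, tiny_frame, tmp_path):
        dup = pd.concat([tiny_frame, tiny_frame.iloc[[0]]], ignore_index=True)
        p = tmp_path / "dup.csv"
        dup.to_csv(p, index=False)
        with pytest.raises(ValidationError, match="duplicate"):
            read_dataset(p)

    def test_sd_dialect_converts_to_se(self, tiny_frame, tmp_path):
        p = tmp_path / "sd.csv"
        tiny_frame.to_csv(p, index=False)
        se_ds = read_dataset(p, dispersion="se")
        sd_ds = read_dataset(p, dispersion="sd")
        n = tiny_frame.loc[0, "n_treatment"]
        assert sd_ds.df.loc[0, "se_treatment"] == pytest.approx(
            se_ds.df.loc[0, "se_treatment"] / np.sqrt(n)
        )

    def test_absent_unit_id_synthesized_unique(self, tiny_frame, tmp_path):
        tiny_frame["unit_id"] = None
        p = tmp_path / "nounits.csv"
        tiny_frame.to_csv(p, index=False)
        ds = read_dataset(p)
        assert ds.df["unit_id"].notna().all()
        assert ds.df["unit_id"].is_unique

    def test_column_mapping_renames_source_columns(self, tiny_frame, tmp_path):
        renamed = tiny_frame.rename(columns={"mean_treatment": "C_cut", "pool": "stock"})
        p = tmp_path / "mapped.csv"
        renamed.to_csv(p, index=False)
        cmap = tmp_path / "map.yaml"
        cmap.write_text("mean_treatment: C_cut\npool: stock\n")
        ds = read_dataset(p, column_map=cmap)
        assert len(ds) == 3
        with pytest.raises(SchemaError):
            read_dataset(p)


class TestSummary:
    def test_biome_shares_half_half(self):
        rows = [
            ("S1", f"u{i}", "live_trees", "clearcut",
             "boreal" if i < 2 else "temperate", "old_forest",
             5.0, 10.0, 20.0, None, None, None, None, None)
            for i in range(4)
        ]
        s = summarize_dataset(Dataset(df=make_obs_frame(rows)))
        assert s.biome.loc["boreal", "percent"] == pytest.approx(50.0)
        assert s.biome.loc["temperate", "percent"] == pytest.approx(50.0)

    def test_percentages_sum_to_100(self):
        ds, _ = generate_dataset(default_config(seed=2))
        s = summarize_dataset(ds)
        for table in (s.biome, s.treatment, s.pool):
            assert table["percent"].sum() == pytest.approx(100.0)

    def test_variance_completeness_tracks_generator_rate(self):
        ds, _ = generate_dataset(default_config(seed=7))
        s = summarize_dataset(ds)
        # missing_variance_rate 0.19 -> completeness ~0.81 (binomial error)
        p = 1 - 0.19
        tol = 3 * np.sqrt(p * (1 - p) / len(ds))
        assert abs(s.variance_complete_fraction - p) < tol

    def test_empty_dataset_yields_empty_summary(self):
        s = summarize_dataset(Dataset(df=pd.DataFrame()))
        assert s.empty
        assert s.n_observations == 0


class TestTimeClasses:
    def test_decade_bins_and_open_top(self):
        out = assign_time_class([0, 9.9, 10, 55, 119, 120, 130])
        assert list(out) == [
            "[0,10)", "[0,10)", "[10,20)", "[50,60)", "[110,120)",
            "[120,inf)", "[120,inf)",
        ]

    def test_custom_edges(self):
        out = assign_time_class([5, 15], edges=[0, 12, 24])
        assert list(out) == ["[0,12)", "[12,24)"]
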