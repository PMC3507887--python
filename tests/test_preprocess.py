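"""Preprocessing: log2 transform, expressed calls, background-median
normalization, probe collapse and replicate merging."""

import numpy as np
import pandas as pd
import pytest

from twotissue.errors import ValidationError
from twotissue.preprocess import (
    ExpressionCall,
    IntensityMatrix,
    classify_expressed,
    collapse_probes,
    log2_transform,
    merge_duplicates,
    normalize_median_null,
    NormalizedMatrix,
)


def _matrix(values, probes=None, samples=None, groups=None, tissue="heart"):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    groups = groups or ["control", "treated"] * (len(samples) // 2 + 1)
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "subject_id": [f"subj{j}" for j in range(len(samples))],
            "tissue": tissue,
            "group": groups[: len(samples)],
            "replicate": 1,
        }
    ).set_index("sample_id")
    return IntensityMatrix(
        values=pd.DataFrame(values, index=pd.Index(probes, name="probe_id"), columns=samples),
        metadata=meta,
    )


class TestLog2Transform:
    def test_elementwise_values(self):
        m = _matrix([[1.0, 1024.0], [2.0, 8.0]])
        out = log2_transform(m)
        np.testing.assert_allclose(out.values.to_numpy(), [[0.0, 10.0], [1.0, 3.0]])
        assert out.scale == "log2"

    def test_random_matrix_matches_scalar_oracle(self):
        rng = np.random.default_rng(4)
        raw = rng.uniform(0.5, 5000.0, size=(3, 2))
        out = log2_transform(_matrix(raw)).values.to_numpy()
        for i in range(3):
            for j in range(2):
                assert out[i, j] == pytest.approx(np.log2(raw[i, j]))

    def test_nonpositive_cell_error_names_probe_and_sample(self):
        m = _matrix([[1.0, 2.0], [3.0, -1.0]])
        with pytest.raises(ValidationError, match=r"p1.*s1"):
            log2_transform(m)

    def test_metadata_preserved(self):
        m = _matrix([[1.0, 2.0]])
        out = log2_transform(m)
        pd.testing.assert_frame_equal(out.metadata, m.metadata)


class TestClassifyExpressed:
    def test_strict_threshold_boundary(self):
        # avg 7.3 is expressed; avg exactly 7.2 is background
        m = pd.DataFrame(
            {"a": [7.3, 7.2, 5.0], "b": [7.3, 7.2, 5.0]},
            index=pd.Index(["hi", "edge", "lo"], name="probe_id"),
        )
        call = classify_expressed(m, threshold=7.2)
        assert call.table.loc["hi", "expressed"]
        assert not call.table.loc["edge", "expressed"]
        assert not call.table.loc["lo", "expressed"]

    def test_partition_is_exhaustive_and_exclusive(self, small_dataset):
        heart, *_ = small_dataset
        call = classify_expressed(log2_transform(heart), 7.2)
        assert set(call.expressed_probes) | set(call.null_probes) == set(
            heart.values.index
        )
        assert not (set(call.expressed_probes) & set(call.null_probes))

    def test_fixed_threshold_invariant_to_column_order(self, small_dataset):
        heart, *_ = small_dataset
        log2 = log2_transform(heart)
        call1 = classify_expressed(log2.values, 7.2)
        call2 = classify_expressed(log2.values[log2.values.columns[::-1]], 7.2)
        pd.testing.assert_series_equal(call1.table["expressed"], call2.table["expressed"])

    def test_auto_threshold_recovers_truth_partition(self, small_dataset):
        heart, _, _, truth = small_dataset
        call = classify_expressed(log2_transform(heart), "auto")
        # background at 5, expressed means >= 8: the antimode separates exactly
        truth_flags = truth.probe_info.set_index("probe_id")["expressed_true"]
        agree = (call.table["expressed"] == truth_flags.loc[call.table.index]).mean()
        assert agree == 1.0
        assert 5.0 < call.threshold < 8.0

    def test_auto_on_unimodal_distribution_errors(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.normal(7.0, 0.5, size=(500, 4)))
        with pytest.raises(ValidationError, match="unimodal"):
            classify_expressed(m, "auto")

    def test_single_array_rejected(self):
        m = pd.DataFrame({"only": [1.0, 2.0]})
        with pytest.raises(ValidationError, match="2 arrays"):
            classify_expressed(m, 7.2)


def _call_for(values, null_probes):
    table = pd.DataFrame(
        {
            "avg_log2": values.mean(axis=1),
            "expressed": ~values.index.isin(null_probes),
        }
    )
    return ExpressionCall(table=table, threshold=0.0)


class TestNormalizeMedianNull:
    def test_median_of_three_null_values_subtracted(self):
        values = pd.DataFrame({"a": [1.0, 2.0, 3.0, 10.0]},
                              index=["n1", "n2", "n3", "e1"])
        call = _call_for(values, ["n1", "n2", "n3"])
        out = normalize_median_null(values, call)
        np.testing.assert_allclose(out.values["a"], [-1.0, 0.0, 1.0, 8.0])
        assert out.medians["a"] == 2.0

    def test_constant_null_values_subtract_exactly(self):
        values = pd.DataFrame({"a": [4.0, 4.0, 9.0]}, index=["n1", "n2", "e1"])
        out = normalize_median_null(values, _call_for(values, ["n1", "n2"]))
        np.testing.assert_allclose(out.values["a"], [0.0, 0.0, 5.0])

    def test_injected_offsets_recovered(self):
        rng = np.random.default_rng(8)
        base = rng.normal(5.0, 0.3, size=(200, 4))
        offsets = np.array([0.7, -1.2, 0.0, 2.5])
        values = pd.DataFrame(base + offsets, index=[f"n{i}" for i in range(200)])
        call = _call_for(values, list(values.index))
        out = normalize_median_null(values, call)
        base_medians = np.median(base, axis=0)
        np.testing.assert_allclose(
            out.medians.to_numpy() - base_medians, offsets, atol=1e-9
        )

    def test_null_median_is_zero_after_normalization(self, small_dataset):
        heart, *_ = small_dataset
        log2 = log2_transform(heart)
        call = classify_expressed(log2, 7.2)
        out = normalize_median_null(log2, call)
        null_medians = out.values.loc[call.null_probes].median(axis=0)
        np.testing.assert_allclose(null_medians, 0.0, atol=1e-9)

    def test_idempotent(self, small_dataset):
        heart, *_ = small_dataset
        log2 = log2_transform(heart)
        call = classify_expressed(log2, 7.2)
        once = normalize_median_null(log2, call)
        twice = normalize_median_null(once.values, call, metadata=log2.metadata)
        pd.testing.assert_frame_equal(once.values, twice.values)
        np.testing.assert_allclose(twice.medians, 0.0, atol=1e-12)

    def test_empty_null_set_errors(self):
        values = pd.DataFrame({"a": [1.0, 2.0]}, index=["e1", "e2"])
        with pytest.raises(ValidationError):
            normalize_median_null(values, _call_for(values, []))


def _norm(values):
    return NormalizedMatrix(values=values, metadata=None)


class TestCollapseProbes:
    def test_largest_average_probe_kept(self):
        values = pd.DataFrame(
            {"a": [8.0, 9.0], "b": [8.0, 9.0]}, index=["p_lo", "p_hi"]
        )
        pm = pd.DataFrame({"probe_id": ["p_lo", "p_hi"], "gene_symbol": ["G1", "G1"]})
        out = collapse_probes(_norm(values), pm)
        assert list(out.values.index) == ["G1"]
        assert out.provenance["G1"] == "p_hi"
        np.testing.assert_allclose(out.values.loc["G1"], [9.0, 9.0])

    def test_tie_broken_to_smallest_probe_id(self):
        values = pd.DataFrame({"a": [5.0, 5.0]}, index=["pB", "pA"])
        pm = pd.DataFrame({"probe_id": ["pA", "pB"], "gene_symbol": ["G", "G"]})
        out = collapse_probes(_norm(values), pm)
        assert out.provenance["G"] == "pA"

    def test_single_probe_identity(self):
        values = pd.DataFrame({"a": [3.0], "b": [4.0]}, index=["p0"])
        pm = pd.DataFrame({"probe_id": ["p0"], "gene_symbol": ["G"]})
        out = collapse_probes(_norm(values), pm)
        np.testing.assert_allclose(out.values.loc["G"], [3.0, 4.0])

    def test_unmapped_probes_dropped(self):
        values = pd.DataFrame({"a": [1.0, 2.0]}, index=["mapped", "orphan"])
        pm = pd.DataFrame({"probe_id": ["mapped"], "gene_symbol": ["G"]})
        out = collapse_probes(_norm(values), pm)
        assert list(out.values.index) == ["G"]

    def test_matches_brute_force_groupby_oracle(self, small_dataset):
        heart, _, pm, _ = small_dataset
        log2 = log2_transform(heart)
        call = classify_expressed(log2, 7.2)
        norm = normalize_median_null(log2, call)
        out = collapse_probes(norm, pm)
        # independent recomputation: explicit per-gene max-average scan
        mapping = pm.set_index("probe_id")["gene_symbol"]
        avg = norm.values.mean(axis=1)
        expected = {}
        for probe, gene in mapping.items():
            if probe not in avg.index:
                continue
            best = expected.get(gene)
            if (
                best is None
                or avg[probe] > avg[best]
                or (avg[probe] == avg[best] and probe < best)
            ):
                expected[gene] = probe
        assert len(out.values) == len(expected)
        assert dict(out.provenance) == expected
        assert len(out.values) <= len(norm.values)


class TestMergeDuplicates:
    def _meta(self, rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "subject_id", "tissue", "group", "replicate"]
        ).set_index("sample_id")

    def test_identical_replicates_merge_to_same_column(self):
        values = pd.DataFrame({"a1": [1.0, 2.0], "a2": [1.0, 2.0]})
        meta = self._meta([("a1", "s1", "heart", "control", 1),
                           ("a2", "s1", "heart", "control", 2)])
        merged, mmeta, corr = merge_duplicates(values, meta)
        np.testing.assert_allclose(merged["heart_s1"], [1.0, 2.0])
        assert list(mmeta.index) == ["heart_s1"]

    def test_replicate_mean(self):
        values = pd.DataFrame({"a1": [4.0], "a2": [6.0]})
        meta = self._meta([("a1", "s1", "heart", "control", 1),
                           ("a2", "s1", "heart", "control", 2)])
        merged, *_ = merge_duplicates(values, meta)
        assert merged.loc[0, "heart_s1"] == 5.0

    def test_replicates_in_different_groups_rejected(self):
        values = pd.DataFrame({"a1": [1.0], "a2": [1.0]})
        meta = self._meta([("a1", "s1", "heart", "control", 1),
                           ("a2", "s1", "heart", "treated", 2)])
        with pytest.raises(ValidationError, match="s1"):
            merge_duplicates(values, meta)

    def test_noisy_replicates_highly_correlated(self):
        rng = np.random.default_rng(2)
        signal = rng.normal(8.0, 2.0, size=500)
        noise_sd = 0.05 * 2.0
        values = pd.DataFrame(
            {
                "a1": signal + rng.normal(0, noise_sd, 500),
                "a2": signal + rng.normal(0, noise_sd, 500),
            }
        )
        meta = self._meta([("a1", "s1", "heart", "control", 1),
                           ("a2", "s1", "heart", "control", 2)])
        *_, corr = merge_duplicates(values, meta)
        assert (corr["pearson_r"] > 0.99).all()

    def test_generated_duplicates_agree(self, small_dataset):
        heart, *_ = small_dataset
        log2 = log2_transform(heart)
        merged, mmeta, corr = merge_duplicates(log2.values, log2.metadata)
        assert len(corr) == heart.metadata["replicate"].eq(2).sum()
        # correlation over all probes includes the iid background class,
        # which caps attainable r below the signal-only case
        assert (corr["pearson_r"] > 0.95).all()
        # one column per subject after merging
        assert merged.shape[1] == heart.metadata["subject_id"].nunique()
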