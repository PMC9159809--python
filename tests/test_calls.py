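"""Alteration-calling rules: fences, expression outliers, hypomethylation,
copy-number increase, and miRNA z-score downregulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from moma.calls import (
    HypomethProbeSet,
    call_cn_increase,
    call_expression_outliers,
    call_mirna_downregulation,
    call_probe_hypomethylation,
    call_sample_hypomethylation,
    tukey_fences,
)
from moma.io import CopyNumberCalls, MethylationData

from conftest import make_expression
from oracles import bh_oracle, fences_oracle

finite_floats = st.floats(
    min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
)


class TestTukeyFences:
    @pytest.mark.parametrize(
        "values, q1, q3, lower, upper",
        [
            ([1, 2, 3, 4, 100], 2.0, 4.0, -1.0, 7.0),
            ([5, 5, 5, 5], 5.0, 5.0, 5.0, 5.0),
            ([0, 10], 2.5, 7.5, -5.0, 15.0),
        ],
    )
    def test_worked_examples(self, values, q1, q3, lower, upper):
        f = tukey_fences(values)
        assert f.q1 == pytest.approx(q1)
        assert f.q3 == pytest.approx(q3)
        assert f.lower == pytest.approx(lower)
        assert f.upper == pytest.approx(upper)

    def test_too_few_values(self):
        with pytest.raises(ValueError, match=">= 2"):
            tukey_fences([1.0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            tukey_fences([1.0, float("nan"), 2.0])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(finite_floats, min_size=2, max_size=50),
        st.floats(min_value=0.5, max_value=3.0),
    )
    def test_matches_brute_force_oracle(self, values, mult):
        f = tukey_fences(values, multiplier=mult)
        lo, hi = fences_oracle(values, multiplier=mult)
        scale = max(1.0, max(abs(v) for v in values))
        assert f.lower == pytest.approx(lo, abs=1e-12 * scale)
        assert f.upper == pytest.approx(hi, abs=1e-12 * scale)
        assert f.lower <= f.upper


def _expr_from_log2(normal_log2, tumour_log2):
    """Build a matrix whose log2(FPKM+1) values are exactly as given."""
    roles, vals = {}, {}
    for i, v in enumerate(tumour_log2):
        roles[f"t{i}"] = "T"
    for i, v in enumerate(normal_log2):
        roles[f"n{i}"] = "N"
    fpkm = {
        f"t{i}": 2.0**v - 1 for i, v in enumerate(tumour_log2)
    } | {f"n{i}": 2.0**v - 1 for i, v in enumerate(normal_log2)}
    return make_expression({"G": [fpkm[s] for s in roles]}, roles)


class TestExpressionOutliers:
    def test_clear_overexpression(self):
        em = _expr_from_log2([4, 5, 6, 7], [12])
        # normals: q1=4.75, q3=6.25, iqr=1.5, upper fence 8.5 < 12
        assert call_expression_outliers("G", em).tolist() == [True]

    def test_value_at_fence_is_not_called(self):
        em = _expr_from_log2([4, 5, 6, 7], [8.5])
        assert call_expression_outliers("G", em).tolist() == [False]

    def test_zero_iqr(self):
        em = _expr_from_log2([5, 5, 5, 5], [5, 5.01])
        out = call_expression_outliers("G", em)
        assert out.tolist() == [False, True]

    def test_under_direction_uses_lower_fence(self):
        em = _expr_from_log2([4, 5, 6, 7], [1, 5])
        # lower fence 4.75 - 1.5*1.5 = 2.5
        assert call_expression_outliers("G", em, "under").tolist() == [True, False]

    def test_absent_gene(self):
        em = _expr_from_log2([4, 5], [6])
        with pytest.raises(KeyError, match="NOPE"):
            call_expression_outliers("NOPE", em)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(0, 15), min_size=3, max_size=12),
        st.floats(0, 15),
        st.floats(0.01, 5),
    )
    def test_monotone_in_tumour_value(self, normals, tum, bump):
        """Raising a tumour sample's expression never un-calls it."""
        before = call_expression_outliers("G", _expr_from_log2(normals, [tum])).iloc[0]
        after = call_expression_outliers(
            "G", _expr_from_log2(normals, [tum + bump])
        ).iloc[0]
        assert after or not before


def _meth(tumour_beta, normal_beta, gene="G1"):
    """One-probe methylation dataset."""
    samples = [f"t{i}" for i in range(len(tumour_beta))] + [
        f"n{i}" for i in range(len(normal_beta))
    ]
    beta = pd.DataFrame([tumour_beta + normal_beta], index=["cg1"], columns=samples)
    return MethylationData(
        beta=beta,
        probe_gene=pd.Series({"cg1": gene}),
        probe_region=pd.Series({"cg1": "gene_body"}),
        sample_role=pd.Series(
            ["tumour"] * len(tumour_beta) + ["non_malignant"] * len(normal_beta),
            index=samples,
        ),
    )


class TestProbeHypomethylation:
    def test_clear_hypomethylation_kept(self):
        md = _meth([0.55, 0.6, 0.65, 0.6, 0.6], [0.8, 0.82, 0.78, 0.8, 0.8])
        ps = call_probe_hypomethylation(md)
        row = ps.table.loc["cg1"]
        assert row["delta_beta"] == pytest.approx(-0.2)
        assert row["q"] < 0.05
        assert bool(row["kept"])

    def test_small_effect_gated_regardless_of_p(self):
        md = _meth([0.75] * 10, [0.8] * 10)
        ps = call_probe_hypomethylation(md)
        assert ps.table.loc["cg1", "delta_beta"] == pytest.approx(-0.05)
        assert not ps.table.loc["cg1", "kept"]

    def test_identical_distributions_not_kept(self):
        md = _meth([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        ps = call_probe_hypomethylation(md)
        assert not ps.table.loc["cg1", "kept"]

    def test_zero_variance_equal_means_gives_p_one(self):
        md = _meth([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        ps = call_probe_hypomethylation(md)
        assert ps.table.loc["cg1", "p"] == 1.0

    def test_bh_family_is_joint_across_genes(self):
        """q-values must be corrected over all probes of all genes at once."""
        samples = [f"t{i}" for i in range(5)] + [f"n{i}" for i in range(5)]
        rng = np.random.default_rng(0)
        rows, genes = [], []
        for k in range(6):
            rows.append(
                np.concatenate([rng.uniform(0.3, 0.5, 5), rng.uniform(0.6, 0.8, 5)])
            )
            genes.append("G1" if k < 3 else "G2")
        beta = pd.DataFrame(rows, index=[f"cg{k}" for k in range(6)], columns=samples)
        md = MethylationData(
            beta=beta,
            probe_gene=pd.Series(genes, index=beta.index),
            probe_region=pd.Series(["other"] * 6, index=beta.index),
            sample_role=pd.Series(["tumour"] * 5 + ["non_malignant"] * 5, index=samples),
        )
        ps = call_probe_hypomethylation(md)
        expected_q = bh_oracle(ps.table["p"].to_numpy())
        assert np.allclose(ps.table["q"].to_numpy(), expected_q)


class TestSampleHypomethylation:
    def test_no_kept_probes_means_all_false(self):
        md = _meth([0.5, 0.5], [0.8, 0.8])
        empty = HypomethProbeSet(
            table=pd.DataFrame(
                {"gene": [], "delta_beta": [], "p": [], "q": [], "kept": []}
            )
        )
        out = call_sample_hypomethylation("G1", empty, md)
        assert not out.any() and len(out) == 2

    def test_zero_iqr_fence(self):
        md = _meth([0.5, 0.8], [0.8, 0.8, 0.8, 0.8])
        ps = HypomethProbeSet(
            table=pd.DataFrame(
                {"gene": ["G1"], "delta_beta": [-0.2], "p": [0.001], "q": [0.001],
                 "kept": [True]},
                index=["cg1"],
            )
        )
        out = call_sample_hypomethylation("G1", ps, md)
        # lower fence is 0.8: 0.5 < 0.8 called, 0.8 not (strict)
        assert out.tolist() == [True, False]


class TestCopyNumber:
    @pytest.mark.parametrize(
        "call, expected",
        [(-2, False), (-1, False), (0, False), (1, True), (2, True)],
    )
    def test_gain_and_amplification_count(self, call, expected):
        cn = CopyNumberCalls(calls=pd.DataFrame({"s": [call]}, index=["g"]))
        assert bool(call_cn_increase(cn).iloc[0, 0]) is expected


class TestMirnaDownregulation:
    def _em(self, normal, tumour):
        roles = {f"t{i}": "T" for i in range(len(tumour))}
        roles |= {f"n{i}": "N" for i in range(len(normal))}
        return make_expression({"m": list(tumour) + list(normal)}, roles)

    def test_two_sd_below_is_called(self):
        # reference [8, 10, 12]: mean 10, sample sd exactly 2
        normal = [8.0, 10.0, 12.0]
        assert np.std(normal, ddof=1) == pytest.approx(2.0)
        em = self._em(normal, [6.0, 10.0])
        out = call_mirna_downregulation(em)
        assert out.iloc[0].tolist() == [True, False]  # z = -2 and z = 0

    def test_threshold_is_strict(self):
        normal = [8.0, 10.0, 12.0]
        em = self._em(normal, [10 - 1.645 * 2])
        assert not call_mirna_downregulation(em).iloc[0, 0]

    def test_zero_reference_sd_never_calls(self):
        em = self._em([5, 5, 5], [0.0])
        assert not call_mirna_downregulation(em).iloc[0, 0]
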