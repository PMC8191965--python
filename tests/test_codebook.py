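"""Codebook schema validation and recoding of raw answers to indicators."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wellcount as wc
from wellcount.codebook import CodebookError, RecodeError, VariableRule


def make_codebook(**kwargs):
    defaults = dict(
        domains=(
            wc.DomainSpec(
                name="A",
                variables=(
                    VariableRule(column="q1", rule_kind="category_set",
                                 achieving=("Yes",), labels=("Yes", "No")),
                    VariableRule(column="q2", rule_kind="threshold_ge", cutoff=7),
                ),
            ),
        )
    )
    defaults.update(kwargs)
    return wc.Codebook(**defaults)


class TestCodebookSchema:
    def test_default_codebook_has_nine_ecology_variables(self):
        cb = wc.default_codebook()
        assert cb.m["Ecological Diversity and Resilience"] == 9
        assert cb.n_domains == 6
        assert list(cb.domain_names) == list(wc.DOMAINS)  # order preserved

    def test_roundtrips_through_json(self, tmp_path):
        cb = wc.default_codebook()
        path = tmp_path / "cb.json"
        cb.to_json(path)
        loaded = wc.load_codebook(path)
        assert loaded.to_dict() == cb.to_dict()

    def test_yaml_is_an_accepted_dialect(self, tmp_path):
        import yaml

        cb = make_codebook()
        path = tmp_path / "cb.yaml"
        path.write_text(yaml.safe_dump(cb.to_dict()))
        assert wc.load_codebook(path).to_dict() == cb.to_dict()

    def test_minimal_single_passthrough_codebook_is_valid(self):
        cb = wc.Codebook(
            domains=(
                wc.DomainSpec(
                    name="only",
                    variables=(VariableRule(column="q", rule_kind="binary_passthrough"),),
                ),
            )
        )
        assert cb.m == {"only": 1}

    def test_variable_in_two_domains_is_a_schema_error(self):
        with pytest.raises(CodebookError, match="q7"):
            wc.Codebook(
                domains=(
                    wc.DomainSpec(name="A", variables=(
                        VariableRule(column="q7", rule_kind="binary_passthrough"),)),
                    wc.DomainSpec(name="B", variables=(
                        VariableRule(column="q7", rule_kind="binary_passthrough"),)),
                )
            )

    def test_unknown_rule_kind_is_a_schema_error(self, tmp_path):
        bad = {"domains": [{"name": "A", "variables": [
            {"column": "q1", "rule_kind": "median_split"}]}]}
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(bad))
        with pytest.raises(CodebookError, match="median_split"):
            wc.load_codebook(path)

    def test_empty_domain_and_bad_weight_rejected(self):
        with pytest.raises(CodebookError):
            wc.DomainSpec(name="empty", variables=())
        with pytest.raises(CodebookError):
            wc.DomainSpec(
                name="w", weight=0.0,
                variables=(VariableRule(column="q", rule_kind="binary_passthrough"),),
            )


class TestRecode:
    def test_threshold_and_category_rules(self):
        cb = make_codebook()
        raw = pd.DataFrame({"q1": ["Yes", "Yes", "No"], "q2": [7, 6, 8]})
        out = wc.recode(raw, cb)
        assert out.data["q1"].tolist() == [1, 1, 0]
        assert out.data["q2"].tolist() == [1, 0, 1]
        assert out.m == {"A": 2}
        assert len(out.data) == len(raw)  # no rows dropped

    def test_category_set_toy_enumeration(self):
        # rows (Yes,Yes),(Yes,No),(No,No) -> (1,1),(1,0),(0,0)
        cb = wc.Codebook(domains=(wc.DomainSpec(name="A", variables=(
            VariableRule(column="u", rule_kind="category_set", achieving=("Yes",)),
            VariableRule(column="v", rule_kind="category_set", achieving=("Yes",)),
        )),))
        raw = pd.DataFrame({"u": ["Yes", "Yes", "No"], "v": ["Yes", "No", "No"]})
        out = wc.recode(raw, cb).data
        assert out.to_numpy().tolist() == [[1, 1], [1, 0], [0, 0]]

    def test_missing_code_scored_zero_under_as_zero(self):
        rule = VariableRule(column="q", rule_kind="category_set", achieving=("Yes",),
                            missing_codes=("prefer not to say",))
        out = rule.apply(pd.Series(["prefer not to say", "Yes", None]))
        assert out.tolist() == [0.0, 1.0, 0.0]

    def test_as_missing_policy_propagates_nan(self):
        rule = VariableRule(column="q", rule_kind="threshold_ge", cutoff=3,
                            missing_policy="as_missing")
        out = rule.apply(pd.Series([5, None, 1]))
        assert out[0] == 1.0 and np.isnan(out[1]) and out[2] == 0.0

    def test_missing_column_error_names_it(self):
        with pytest.raises(RecodeError, match="q2"):
            wc.recode(pd.DataFrame({"q1": ["Yes"]}), make_codebook())

    def test_unknown_category_error_reports_row(self):
        cb = make_codebook()
        raw = pd.DataFrame({"q1": ["Yes", "Maybe"], "q2": [7, 7]})
        with pytest.raises(RecodeError, match="row 1"):
            wc.recode(raw, cb)

    def test_recode_is_idempotent_via_passthrough(self, default_cfg):
        raw = wc.generate(default_cfg, seed=5)
        matrix = wc.recode(raw, default_cfg.codebook)
        passthrough = wc.Codebook(domains=tuple(
            wc.DomainSpec(name=d, variables=tuple(
                VariableRule(column=c, rule_kind="binary_passthrough")
                for c in cols))
            for d, cols in matrix.domains.items()))
        again = wc.recode(matrix.data, passthrough)
        pd.testing.assert_frame_equal(again.data, matrix.data)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.one_of(st.integers(-3, 12), st.none()), min_size=1, max_size=8),
           st.integers(0, 10))
    def test_threshold_rule_output_is_binary_under_as_zero(self, values, cutoff):
        rule = VariableRule(column="q", rule_kind="threshold_ge", cutoff=cutoff)
        out = rule.apply(pd.Series(values, dtype=object))
        assert set(out.unique()) <= {0.0, 1.0}


class TestHopefulness:
    def test_scale_extremes(self):
        assert wc.recode_hopefulness(8) == 1
        assert wc.recode_hopefulness(1, cutoff=2) == 0

    def test_highly_positive_share(self):
        arr = wc.recode_hopefulness(np.array([8, 7, 6, 1]))
        assert arr.mean() == 0.5

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            wc.recode_hopefulness(9)
        with pytest.raises(ValueError, match="scale"):
            wc.recode_hopefulness(0)

    def test_missing_stays_missing(self):
        out = wc.recode_hopefulness(np.array([np.nan, 8.0]))
        assert np.isnan(out[0]) and out[1] == 1.0


class TestIncomeRegrouping:
    def test_boundary_600_is_low(self):
        assert wc.regroup_income(600).group == "LOW"
        assert wc.regroup_income(601).group == "HIGH"

    def test_no_income_maps_low_with_flag(self):
        g = wc.regroup_income("No income")
        assert g.group == "LOW" and g.no_income

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            wc.regroup_income(-5)

    def test_vectorised_form(self):
        out = wc.regroup_income(np.array([0, 600, 601, "No income", None], dtype=object))
        assert out["group"].tolist()[:4] == ["LOW", "LOW", "HIGH", "LOW"]
        assert pd.isna(out["group"].iloc[4])
        assert out["no_income"].tolist() == [False, False, False, True, False]
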