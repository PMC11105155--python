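import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycocomp.architecture_rules import (
    ArchitectureRule,
    builtin_rulesets,
    classify_proteome,
    evaluate_rule,
    load_ruleset_file,
    ProteinDomainProfile,
    profiles_from_table,
    Requirement,
)
from mycocomp.io_formats import DataError, DomainAnnotationTable

DOMAINS = ["GATA", "PAS_3", "PAS_9", "FRQ", "7tm_1", "PAZ", "Piwi",
           "Ribonuclease_3", "DEAD", "DNA_methylase", "Other1", "Other2"]


def brute_force_check(counts: dict[str, int], rule: ArchitectureRule) -> bool:
    """Expand the rule into an explicit boolean formula over the profile."""
    clauses = []
    for dom, req in rule.required:
        n = counts.get(dom, 0)
        clauses.append(n == req.count if req.mode == "exact" else n >= req.count)
    clauses.extend(counts.get(dom, 0) == 0 for dom in rule.forbidden)
    clauses.extend(
        any(counts.get(dom, 0) >= 1 for dom in group)
        for group in rule.alternatives
    )
    return all(clauses)


@st.composite
def rules(draw):
    req_doms = draw(st.lists(st.sampled_from(DOMAINS), max_size=3, unique=True))
    required = tuple(
        (d, Requirement(draw(st.integers(1, 3)),
                        draw(st.sampled_from(["exact", "min"]))))
        for d in req_doms
    )
    forbidden = frozenset(
        draw(st.lists(
            st.sampled_from([d for d in DOMAINS if d not in req_doms]),
            max_size=2, unique=True))
    )
    alternatives = tuple(
        frozenset(draw(st.lists(st.sampled_from(DOMAINS), min_size=1,
                                max_size=3, unique=True)))
        for _ in range(draw(st.integers(0, 2)))
    )
    return ArchitectureRule("r", required, forbidden, alternatives)


profiles = st.dictionaries(st.sampled_from(DOMAINS), st.integers(1, 4), max_size=6)


_CIRCADIAN = {r.name: r for r in builtin_rulesets()["circadian"]}
_RNAI = {r.name: r for r in builtin_rulesets()["rnai"]}


@pytest.fixture
def circadian():
    return _CIRCADIAN


@pytest.fixture
def rnai():
    return _RNAI


class TestEvaluateRule:
    def test_wc1_needs_one_each(self, circadian):
        p = {"GATA": 1, "PAS_3": 1, "PAS_9": 1}
        assert evaluate_rule(p, circadian["WC1"])
        assert not evaluate_rule(p, circadian["WC2"])  # PAS_9 forbidden

    def test_wc2_forbids_pas9(self, circadian):
        assert evaluate_rule({"GATA": 1, "PAS_3": 1}, circadian["WC2"])

    def test_wc1_frequency_matters(self, circadian):
        assert not evaluate_rule({"GATA": 2, "PAS_3": 1, "PAS_9": 1},
                                 circadian["WC1"])

    def test_ago_needs_paz_and_piwi(self, rnai):
        assert not evaluate_rule({"PAZ": 2}, rnai["Ago"])
        assert evaluate_rule({"PAZ": 1, "Piwi": 1}, rnai["Ago"])

    def test_dicer_alt_alternatives(self, rnai):
        assert evaluate_rule({"Ribonuclease_3": 1, "DEAD": 1}, rnai["Dicer_Alt"])
        assert evaluate_rule({"Ribonuclease_3": 1, "PAZ": 1}, rnai["Dicer_Alt"])
        assert not evaluate_rule({"Ribonuclease_3": 1}, rnai["Dicer_Alt"])

    def test_rid_needs_two_methylase_domains(self):
        rid = builtin_rulesets()["rid"][0]
        assert evaluate_rule({"DNA_methylase": 2}, rid)
        assert evaluate_rule({"DNA_methylase": 3}, rid)
        assert not evaluate_rule({"DNA_methylase": 1}, rid)

    def test_empty_profile_matches_nothing(self):
        for ruleset in builtin_rulesets().values():
            for rule in ruleset:
                assert not evaluate_rule({}, rule)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(profile=profiles, rule=rules())
    def test_equals_brute_force_formula(self, profile, rule):
        assert evaluate_rule(profile, rule) == brute_force_check(profile, rule)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(profile=profiles, rule=rules(),
           extra=st.sampled_from(DOMAINS))
    def test_irrelevant_domain_never_flips_to_false(self, profile, rule, extra):
        """Adding a domain only breaks a match if it is forbidden or breaks
        an exact count."""
        if not evaluate_rule(profile, rule):
            return
        grown = dict(profile)
        grown[extra] = grown.get(extra, 0) + 1
        if extra in rule.forbidden or any(
            d == extra and r.mode == "exact" for d, r in rule.required
        ):
            return
        assert evaluate_rule(grown, rule)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(profile=profiles)
    def test_wc1_wc2_mutually_exclusive(self, profile):
        circ = {r.name: r for r in builtin_rulesets()["circadian"]}
        assert not (
            evaluate_rule(profile, circ["WC1"]) and evaluate_rule(profile, circ["WC2"])
        )


class TestRulesets:
    def test_builtin_sets_present(self):
        sets = builtin_rulesets()
        assert set(sets) == {"circadian", "rnai", "rid", "light"}
        assert {r.name for r in sets["circadian"]} == {"FRQ", "WC1", "WC2", "Rhodopsin"}
        assert {r.name for r in sets["rnai"]} == {"RDRP", "Dicer", "Ago", "Dicer_Alt"}
        assert {r.name for r in sets["light"]} == {
            "Bac_rhodopsin", "DNA_photolyase", "FAD_binding_7", "PHY",
            "GpcrRhopsn4", "GAF",
        }

    def test_min_counts_relaxes_exact(self):
        wc1 = {r.name: r for r in builtin_rulesets(min_counts=True)["circadian"]}["WC1"]
        assert evaluate_rule({"GATA": 2, "PAS_3": 1, "PAS_9": 1}, wc1)

    def test_custom_yaml_round_trip(self, tmp_path):
        p = tmp_path / "rules.yaml"
        p.write_text(
            "myset:\n"
            "  R1:\n"
            "    required:\n"
            "      D1: {count: 2, mode: exact}\n"
            "    forbidden: [D2]\n"
            "    alternatives:\n"
            "      - [D3, D4]\n"
        )
        rules_by_set = load_ruleset_file(p)
        (rule,) = rules_by_set["myset"]
        assert evaluate_rule({"D1": 2, "D3": 1}, rule)
        assert not evaluate_rule({"D1": 2, "D3": 1, "D2": 1}, rule)

    def test_required_forbidden_overlap_rejected(self):
        with pytest.raises(DataError, match="overlap"):
            ArchitectureRule(
                "bad", (("D", Requirement(1, "min")),), frozenset({"D"})
            )


class TestClassifyProteome:
    def _table(self, rows):
        df = pd.DataFrame(
            rows, columns=["species", "gene_id", "domain_id", "domain_type", "secreted"]
        )
        totals = {sp: 100 for sp in df["species"].unique()}
        return DomainAnnotationTable(df, totals)

    def test_counts_per_rule_and_species(self):
        table = self._table(
            [
                ("A", "g1", "GATA", "PFAM", False),
                ("A", "g1", "PAS_3", "PFAM", False),
                ("A", "g1", "PAS_9", "PFAM", False),
                ("A", "g2", "GATA", "PFAM", False),
                ("A", "g2", "PAS_3", "PFAM", False),
            ]
        )
        counts = classify_proteome(table, builtin_rulesets()["circadian"])
        assert counts["A"]["WC1"] == 1 and counts["A"]["WC2"] == 1

    def test_multi_rule_membership(self):
        table = self._table(
            [
                ("A", "g1", "Dicer_dimer", "PFAM", False),
                ("A", "g1", "Ribonuclease_3", "PFAM", False),
                ("A", "g1", "DEAD", "PFAM", False),
            ]
        )
        counts = classify_proteome(table, builtin_rulesets()["rnai"])
        assert counts["A"]["Dicer"] == 1 and counts["A"]["Dicer_Alt"] == 1

    def test_duplicated_profile_counts_twice(self):
        table = self._table(
            [
                ("A", "g1", "FRQ", "PFAM", False),
                ("A", "g2", "FRQ", "PFAM", False),
            ]
        )
        assert classify_proteome(table, builtin_rulesets()["circadian"])["A"]["FRQ"] == 2

    def test_domain_copies_within_protein(self):
        table = self._table(
            [
                ("A", "g1", "DNA_methylase", "PFAM", False),
                ("A", "g1", "DNA_methylase", "PFAM", False),
                ("A", "g2", "DNA_methylase", "PFAM", False),
            ]
        )
        profs = {p.gene_id: p.as_dict() for p in profiles_from_table(table)}
        assert profs["g1"] == {"DNA_methylase": 2}
        counts = classify_proteome(table, builtin_rulesets()["rid"])
        assert counts["A"]["RID_candidate"] == 1
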