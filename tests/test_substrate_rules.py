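"""Substrate rule table and classification engine."""

from __future__ import annotations

from collections import Counter

import pytest

from pulkit.feature_annotation import annotate_genome
from pulkit.model import COMPLETE, NO_SUSCD, PUL, ValidationError
from pulkit.pul_detection import detect_puls
from pulkit.substrate_rules import (
    classify_pul,
    default_rule_table,
    load_rule_table,
    summarize_predictions,
)
from pulkit.synthetic_data import GeneratorConfig, generate_genome, template_registry


def make_pul(families: dict, n_sulfatases=0, pair=True, susE=False, pul_id="P1"):
    gene_families, gene_ids = {}, []
    i = 0
    for fam, count in families.items():
        for _ in range(count):
            i += 1
            gid = f"g{i}"
            gene_ids.append(gid)
            gene_families[gid] = frozenset({fam})
    for _ in range(max(0, 2 - len(gene_ids)) + n_sulfatases + (2 if pair else 0)):
        i += 1
        gene_ids.append(f"g{i}")
        gene_families[f"g{i}"] = frozenset()
    return PUL(
        pul_id=pul_id,
        genome_id="G",
        contig_id="c1",
        gene_ids=gene_ids,
        susCD_pairs=[(gene_ids[-2], gene_ids[-1])] if pair else [],
        completeness=COMPLETE if pair else NO_SUSCD,
        family_multiset=Counter(families),
        n_sulfatases=n_sulfatases,
        n_peptidases=0,
        susE_gene_ids=["gE"] if susE else [],
        gene_families=gene_families,
    )


class TestRuleTable:
    def test_four_laminarin_variants(self, rules):
        laminarin_variants = {r.variant for r in rules if r.substrate == "laminarin" and r.variant}
        assert laminarin_variants == {"A", "B", "C/D"}  # C and D reported jointly

    def test_family_labels_are_cazy_style(self, rules):
        from pulkit.feature_annotation import parent_family

        for rule in rules:
            fams = {f for f, _ in rule.required} | set(rule.forbidden)
            for fam_set, _ in rule.any_of:
                fams |= fam_set
            for fam in fams:
                assert parent_family(fam) == fam

    def test_duplicate_rule_name_rejected(self, tmp_path, rules):
        p = tmp_path / "rules.yaml"
        p.write_text(
            "- name: laminarin_A\n  substrate: laminarin\n  priority: 99\n"
            "  required: {GH16: 1}\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            load_rule_table(p, base=rules)

    def test_user_rules_extend_table(self, tmp_path, rules):
        p = tmp_path / "rules.yaml"
        p.write_text(
            "- name: pectin\n  substrate: pectin\n  priority: 40\n"
            "  required: {GH28: 1}\n  any_of:\n"
            "    - {families: [PL1, PL9], min_distinct: 1}\n"
        )
        table = load_rule_table(p, base=rules)
        pul = make_pul({"GH28": 1, "PL1": 2})
        assert classify_pul(pul, table).substrate == "pectin"


class TestClassifyPul:
    @pytest.mark.parametrize(
        "families,n_sulf,kwargs,substrate,variant",
        [
            ({"GH16": 2, "GH3": 1}, 0, {}, "laminarin", "A"),
            ({"GH16": 1, "GH30": 1, "GH17": 2}, 0, {}, "laminarin", "B"),
            ({"GH16": 1, "GH30": 1, "GH5": 1}, 0, {}, "laminarin", "C/D"),
            ({"PL6": 1, "PL7": 2, "PL17": 1, "PL12": 1}, 0, {}, "alginate", None),
            ({"GH92": 3, "GH2": 1, "GH88": 1}, 4, {}, "alpha_mannan_sulfated", None),
            ({"GH13": 1, "GH65": 1, "GH31": 1}, 0, {"susE": True}, "alpha14_glucan", "branched"),
            ({"GH13": 1, "GH65": 1}, 0, {}, "alpha14_glucan", "simple"),
            ({"GH76": 1, "GH125": 1}, 0, {}, "alpha_mannan", None),
            ({"GH130": 1, "GH26": 2}, 0, {}, "beta_mannan", None),
            ({"GH29": 1, "GH95": 1}, 3, {}, "fcsp", None),
            ({"GH10": 1, "GH43": 2}, 2, {}, "xylan_sulfated", "sulfated"),
            ({"GH10": 1, "GH43": 1, "GH115": 1}, 0, {}, "xylan", "glucuronoxylan"),
            ({"GH10": 1, "GH51": 1}, 0, {}, "xylan", "arabinoxylan"),
        ],
    )
    def test_signature_matching(self, rules, families, n_sulf, kwargs, substrate, variant):
        pred = classify_pul(make_pul(families, n_sulfatases=n_sulf, **kwargs), rules)
        assert (pred.substrate, pred.variant) == (substrate, variant)

    def test_lone_gh13_unclassified(self, rules):
        pred = classify_pul(make_pul({"GH13": 1}), rules)
        assert pred.substrate == "unclassified"
        assert pred.matched_rule is None and pred.ambiguity == []

    def test_variant_outranks_class_rule_and_reports_ambiguity(self, rules):
        pred = classify_pul(make_pul({"GH16": 2, "GH3": 1}), rules)
        assert pred.matched_rule == "laminarin_A"
        assert "laminarin" in pred.ambiguity

    def test_sulfatase_tristate_separates_mannan_subtypes(self, rules):
        with_sulf = classify_pul(make_pul({"GH92": 2}, n_sulfatases=3), rules)
        without = classify_pul(make_pul({"GH76": 1}), rules)
        assert with_sulf.substrate == "alpha_mannan_sulfated"
        assert without.substrate == "alpha_mannan"
        # GH76 alongside sulfatases falls back to the class rule
        mixed = classify_pul(make_pul({"GH76": 1}, n_sulfatases=1), rules)
        assert mixed.matched_rule == "alpha_mannan"

    def test_classification_is_pure_function_of_composition(self, rules):
        a = classify_pul(make_pul({"GH16": 2, "GH3": 1}), rules)
        b = classify_pul(make_pul({"GH16": 2, "GH3": 1}, pul_id="P2"), rules)
        assert (a.substrate, a.variant, a.matched_rule, a.ambiguity) == (
            b.substrate,
            b.variant,
            b.matched_rule,
            b.ambiguity,
        )

    def test_variant_matches_imply_class_match(self, dataset, config, rules):
        """Variant rules refine class rules: wherever a variant rule of a
        substrate with a class-level rule matches, the class rule matches too."""
        from pulkit.substrate_rules import rule_matches

        class_rules = {r.substrate: r for r in rules if r.variant is None and r.priority >= 50}
        checked = 0
        for genome in dataset.genomes:
            assignments = annotate_genome(genome, dataset.evidence[genome.genome_id], config)
            for pul in detect_puls(genome, assignments):
                pred = classify_pul(pul, rules)
                if pred.variant and pred.substrate in class_rules:
                    assert rule_matches(class_rules[pred.substrate], pul) is not None
                    checked += 1
        assert checked > 0

    def test_planted_templates_classify_to_generating_rule(self, config, rules):
        """Noise-free planted PULs classify back to their template's rule."""
        registry = template_registry()
        mix = {name: 1 for name in registry}
        cfg = GeneratorConfig(seed=21, n_genomes=1, substrate_mix=mix, evidence_noise=0.0)
        genome, evidence, truth = generate_genome(cfg)
        assignments = annotate_genome(genome, evidence, config)
        puls = detect_puls(genome, assignments)
        assert len(puls) == len(registry)
        expected = {tuple(r.gene_ids.split(";")): r.expected_rule for r in truth.itertuples()}
        for pul in puls:
            pred = classify_pul(pul, rules)
            assert pred.matched_rule == expected[tuple(pul.gene_ids)]


class TestSummarizePredictions:
    def _prediction_set(self, rules, n_genomes, laminarin_genomes):
        puls, preds = [], []
        for i in range(laminarin_genomes):
            pul = make_pul({"GH16": 2, "GH3": 1}, pul_id=f"G{i}_P1")
            pul.genome_id = f"G{i}"
            puls.append(pul)
            preds.append(classify_pul(pul, rules))
        return preds, puls, [f"G{i}" for i in range(n_genomes)]

    def test_prevalence_rounded_to_integer_percent(self, rules):
        preds, puls, genomes = self._prediction_set(rules, 53, 33)
        sub_df, _ = summarize_predictions(preds, puls, genomes)
        row = sub_df.set_index("substrate").loc["laminarin"]
        assert (row.n_isolates, row.pct_isolates) == (33, 62)

    def test_empty_predictions_give_empty_table(self, rules):
        sub_df, var_df = summarize_predictions([], [], ["G1", "G2"])
        assert sub_df.empty and var_df.empty

    def test_multiple_puls_one_isolate(self, rules):
        puls, preds = [], []
        for i in range(3):
            pul = make_pul({"GH16": 2, "GH3": 1}, pul_id=f"G0_P{i}")
            pul.genome_id = "G0"
            puls.append(pul)
            preds.append(classify_pul(pul, rules))
        sub_df, var_df = summarize_predictions(preds, puls, ["G0", "G1"])
        row = sub_df.set_index("substrate").loc["laminarin"]
        assert (row.n_puls, row.n_isolates, row.pct_isolates) == (3, 1, 50)
        assert var_df.set_index(["substrate", "variant"]).loc[("laminarin", "A"), "n_puls"] == 3
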