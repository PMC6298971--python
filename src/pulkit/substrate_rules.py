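"""Declarative substrate classification of PULs.

Each rule states a family-composition signature (required family
counts, "at least n distinct families of this set" clauses, forbidden
families) plus tri-state constraints on PUL-internal sulfatase genes
and on the presence of a susCDE-like gene triplet.  Rules are ranked by
priority: variant-specific signatures (laminarin A-D, the xylan
subtypes, ...) rank before class-level fallbacks, so a PUL matching
both is reported at the variant level with the class match listed under
``ambiguity``.

The built-in table encodes signatures for laminarin (four variants),
alpha-1,4-glucans (branched and simple), a trehalose-like
alpha-1,1-glucan placeholder, alginate, sulfated and non-sulfated
alpha-mannans, beta-mannan, fucose-containing sulfated polysaccharides
(FCSP) and three beta-xylan subtypes.  Users may extend or override it
with a YAML table.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import yaml

from .model import (
    PUL,
    SubstratePrediction,
    SubstrateRule,
    UNCLASSIFIED,
    ValidationError,
)

#: xylan backbone signature shared by the xylan subtype rules
XYLAN_CORE = frozenset({"GH10", "GH43"})


def default_rule_table() -> list[SubstrateRule]:
    """The built-in substrate signature table (lower priority = preferred)."""
    rules = [
        # -- laminarin variants -------------------------------------------
        SubstrateRule(
            name="laminarin_A",
            substrate="laminarin",
            variant="A",
            priority=10,
            required=(("GH16", 2), ("GH3", 1)),
            forbidden=frozenset({"GH17", "GH30"}),
        ),
        SubstrateRule(
            name="laminarin_B",
            substrate="laminarin",
            variant="B",
            priority=11,
            required=(("GH17", 2), ("GH30", 1)),
        ),
        # Variants C and D share GH16+GH30 without GH17 plus a GH5 glucan
        # hydrolase; no diagnostic family separates them, so they are
        # reported jointly unless a user rule splits them.
        SubstrateRule(
            name="laminarin_C_or_D",
            substrate="laminarin",
            variant="C/D",
            priority=12,
            required=(("GH16", 1), ("GH30", 1), ("GH5", 1)),
            forbidden=frozenset({"GH17"}),
        ),
        # -- alpha-glucans -------------------------------------------------
        SubstrateRule(
            name="alpha14_glucan_branched",
            substrate="alpha14_glucan",
            variant="branched",
            priority=13,
            required=(("GH13", 1), ("GH65", 1), ("GH31", 1)),  # GH97 optional
            requires_susCDE="yes",
        ),
        SubstrateRule(
            name="alpha14_glucan_simple",
            substrate="alpha14_glucan",
            variant="simple",
            priority=14,
            required=(("GH13", 1), ("GH65", 1)),
            requires_susCDE="no",
        ),
        # Trehalose-like alpha-1,1-glucan: conservative placeholder keyed
        # on a trehalase family until a vetted signature is configured.
        SubstrateRule(
            name="alpha11_glucan",
            substrate="alpha11_glucan",
            priority=15,
            required=(("GH37", 1),),
        ),
        # -- alginate ------------------------------------------------------
        SubstrateRule(
            name="alginate",
            substrate="alginate",
            priority=16,
            any_of=((frozenset({"PL6", "PL7", "PL17"}), 2),),  # PL12 optional
        ),
        # -- mannans -------------------------------------------------------
        SubstrateRule(
            name="alpha_mannan_sulfated",
            substrate="alpha_mannan_sulfated",
            priority=17,
            required=(("GH92", 2),),
            requires_sulfatase="yes",
        ),
        SubstrateRule(
            name="alpha_mannan_plain",
            substrate="alpha_mannan",
            priority=18,
            any_of=((frozenset({"GH76", "GH125", "GH38"}), 1),),
            requires_sulfatase="no",
        ),
        SubstrateRule(
            name="beta_mannan",
            substrate="beta_mannan",
            priority=19,
            required=(("GH130", 1), ("GH26", 1)),
        ),
        # -- fucose-containing sulfated polysaccharides --------------------
        SubstrateRule(
            name="fcsp",
            substrate="fcsp",
            priority=20,
            any_of=((frozenset({"GH29", "GH95"}), 1),),
            requires_sulfatase="yes",
        ),
        # -- beta-xylans ---------------------------------------------------
        SubstrateRule(
            name="xylan_glucurono",
            substrate="xylan",
            variant="glucuronoxylan",
            priority=21,
            any_of=((XYLAN_CORE, 1), (frozenset({"GH67", "GH115"}), 1)),
        ),
        SubstrateRule(
            name="xylan_arabino",
            substrate="xylan",
            variant="arabinoxylan",
            priority=22,
            required=(("GH51", 1),),
            any_of=((XYLAN_CORE, 1),),
        ),
        SubstrateRule(
            name="xylan_sulfated",
            substrate="xylan_sulfated",
            variant="sulfated",
            priority=23,
            any_of=((XYLAN_CORE, 1),),
            requires_sulfatase="yes",
        ),
        # -- class-level fallbacks ----------------------------------------
        SubstrateRule(
            name="laminarin",
            substrate="laminarin",
            priority=60,
            any_of=((frozenset({"GH16", "GH17"}), 1),),
        ),
        SubstrateRule(
            name="alpha_mannan",
            substrate="alpha_mannan",
            priority=61,
            any_of=((frozenset({"GH92", "GH76", "GH125", "GH38"}), 1),),
        ),
        SubstrateRule(
            name="xylan",
            substrate="xylan",
            priority=62,
            any_of=((XYLAN_CORE, 1),),
        ),
    ]
    validate_rule_table(rules)
    return rules


def validate_rule_table(rules: Sequence[SubstrateRule]) -> None:
    names = [r.name for r in rules]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate rule names: {dupes}")
    prios = [r.priority for r in rules]
    if len(prios) != len(set(prios)):
        raise ValidationError("rule priorities must be unique")


def load_rule_table(path, base: Optional[Sequence[SubstrateRule]] = None) -> list[SubstrateRule]:
    """Load rules from YAML, optionally appended to a base table.

    Schema per rule: name, substrate, priority, and optionally variant,
    required ({family: min_count}), any_of (list of {families: [...],
    min_distinct: n}), forbidden ([...]), requires_sulfatase,
    requires_susCDE.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    rules = list(base) if base else []
    for entry in raw:
        rules.append(
            SubstrateRule(
                name=entry["name"],
                substrate=entry["substrate"],
                priority=int(entry["priority"]),
                variant=entry.get("variant"),
                required=tuple(
                    (fam, int(cnt)) for fam, cnt in sorted(entry.get("required", {}).items())
                ),
                any_of=tuple(
                    (frozenset(c["families"]), int(c.get("min_distinct", 1)))
                    for c in entry.get("any_of", [])
                ),
                forbidden=frozenset(entry.get("forbidden", [])),
                requires_sulfatase=entry.get("requires_sulfatase", "any"),
                requires_susCDE=entry.get("requires_susCDE", "any"),
            )
        )
    validate_rule_table(rules)
    return rules


def rule_matches(rule: SubstrateRule, pul: PUL) -> Optional[dict[str, list[str]]]:
    """Evaluate one rule against a PUL.

    Returns a clause -> satisfying-genes map when the rule matches, else
    None.  Classification is a pure function of the PUL's family
    multiset, sulfatase count and susCDE status.
    """
    fams = pul.family_multiset
    evidence: dict[str, list[str]] = {}

    def genes_with(family: str) -> list[str]:
        return sorted(g for g, fs in pul.gene_families.items() if family in fs)

    for fam, min_count in rule.required:
        if fams.get(fam, 0) < min_count:
            return None
        evidence[f"required:{fam}>={min_count}"] = genes_with(fam)
    for fam_set, min_distinct in rule.any_of:
        present = sorted(f for f in fam_set if fams.get(f, 0) > 0)
        if len(present) < min_distinct:
            return None
        clause = f"any_of:{'|'.join(sorted(fam_set))}>={min_distinct}"
        evidence[clause] = sorted(
            {g for f in present for g in genes_with(f)}
        )
    for fam in rule.forbidden:
        if fams.get(fam, 0) > 0:
            return None
    if rule.requires_sulfatase == "yes" and pul.n_sulfatases < 1:
        return None
    if rule.requires_sulfatase == "no" and pul.n_sulfatases > 0:
        return None
    has_susCDE = pul.has_susCD_pair and pul.has_susE
    if rule.requires_susCDE == "yes" and not has_susCDE:
        return None
    if rule.requires_susCDE == "no" and pul.has_susE:
        return None
    return evidence


def classify_pul(pul: PUL, rule_table: Sequence[SubstrateRule]) -> SubstratePrediction:
    """Match every rule; report the best-priority match, others as ambiguity."""
    matches: list[tuple[SubstrateRule, dict]] = []
    for rule in rule_table:
        ev = rule_matches(rule, pul)
        if ev is not None:
            matches.append((rule, ev))
    if not matches:
        return SubstratePrediction(pul_id=pul.pul_id)
    # stable: priority first, then table order (sort is stable)
    matches.sort(key=lambda m: m[0].priority)
    best, ev = matches[0]
    return SubstratePrediction(
        pul_id=pul.pul_id,
        substrate=best.substrate,
        variant=best.variant,
        matched_rule=best.name,
        evidence=ev,
        ambiguity=[r.name for r, _ in matches[1:]],
    )


def summarize_predictions(
    predictions: Iterable[SubstratePrediction],
    puls: Iterable[PUL],
    genome_ids: Sequence[str],
):
    """Prevalence tables: per-substrate PUL and isolate counts, per-variant counts.

    Percentages are isolate prevalences rounded to integer percent.
    Returns (substrate_table, variant_table) as DataFrames.
    """
    import pandas as pd

    genome_of = {p.pul_id: p.genome_id for p in puls}
    n_genomes = len(genome_ids)
    per_substrate: dict[str, dict] = {}
    per_variant: dict[tuple[str, str], int] = {}
    for pred in predictions:
        sub = pred.substrate
        rec = per_substrate.setdefault(sub, {"n_puls": 0, "genomes": set()})
        rec["n_puls"] += 1
        if pred.pul_id in genome_of:
            rec["genomes"].add(genome_of[pred.pul_id])
        if pred.variant:
            key = (sub, pred.variant)
            per_variant[key] = per_variant.get(key, 0) + 1

    sub_rows = [
        {
            "substrate": sub,
            "n_puls": rec["n_puls"],
            "n_isolates": len(rec["genomes"]),
            "pct_isolates": round(100 * len(rec["genomes"]) / n_genomes)
            if n_genomes
            else 0,
        }
        for sub, rec in sorted(per_substrate.items())
    ]
    var_rows = [
        {"substrate": sub, "variant": var, "n_puls": n}
        for (sub, var), n in sorted(per_variant.items())
    ]
    sub_df = pd.DataFrame(sub_rows, columns=["substrate", "n_puls", "n_isolates", "pct_isolates"])
    var_df = pd.DataFrame(var_rows, columns=["substrate", "variant", "n_puls"])
    return sub_df, var_df
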