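"""Rule-based classification of proteins by their Pfam domain content.

Each rule constrains a protein's domain multiset: required domains with an
exact or minimum copy number, forbidden domains, and "alternatives" groups
where at least one member must be present. The builtin rule sets encode
curated candidate definitions for circadian components (FRQ, WC1, WC2,
rhodopsin), light-sensing single-domain surveys, the core RNAi machinery
(RDRP, Dicer, Ago, alternative Dicer), and RID-like cytosine
methyltransferases (two or more DNA_methylase domains — copy number stands
in for tandem adjacency, since domain coordinates are not in the input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .io_formats import DataError, DomainAnnotationTable


@dataclass(frozen=True)
class Requirement:
    count: int
    mode: str  # "exact" | "min"

    def __post_init__(self) -> None:
        if self.count < 1:
            raise DataError(f"requirement count must be >= 1, got {self.count}")
        if self.mode not in ("exact", "min"):
            raise DataError(f"requirement mode must be exact|min, got {self.mode!r}")

    def satisfied(self, n: int) -> bool:
        return n == self.count if self.mode == "exact" else n >= self.count


@dataclass(frozen=True)
class ArchitectureRule:
    name: str
    required: tuple[tuple[str, Requirement], ...] = ()
    forbidden: frozenset[str] = frozenset()
    alternatives: tuple[frozenset[str], ...] = ()

    def __post_init__(self) -> None:
        req_domains = {d for d, _ in self.required}
        if req_domains & self.forbidden:
            raise DataError(
                f"rule {self.name!r}: required and forbidden overlap"
            )


@dataclass(frozen=True)
class ProteinDomainProfile:
    gene_id: str
    species: str
    domain_counts: tuple[tuple[str, int], ...]

    def as_dict(self) -> dict[str, int]:
        return dict(self.domain_counts)


def evaluate_rule(profile: ProteinDomainProfile | dict[str, int],
                  rule: ArchitectureRule) -> bool:
    """True iff the profile satisfies every constraint of the rule."""
    counts = profile if isinstance(profile, dict) else profile.as_dict()
    for dom, req in rule.required:
        if not req.satisfied(counts.get(dom, 0)):
            return False
    for dom in rule.forbidden:
        if counts.get(dom, 0) > 0:
            return False
    for group in rule.alternatives:
        if not any(counts.get(dom, 0) > 0 for dom in group):
            return False
    return True


def _rule_from_config(name: str, cfg: dict) -> ArchitectureRule:
    required = []
    for dom, spec in (cfg.get("required") or {}).items():
        if isinstance(spec, int):
            required.append((dom, Requirement(spec, "min")))
        else:
            required.append(
                (dom, Requirement(int(spec.get("count", 1)),
                                  str(spec.get("mode", "min"))))
            )
    forbidden = frozenset(cfg.get("forbidden") or [])
    alternatives = tuple(frozenset(g) for g in (cfg.get("alternatives") or []))
    return ArchitectureRule(name, tuple(required), forbidden, alternatives)


def load_ruleset_file(path: str | Path) -> dict[str, list[ArchitectureRule]]:
    """Load rule sets from a YAML config.

    Layout: top-level mapping ruleset_name -> {rule_name -> {required:
    {domain: {count, mode}}, forbidden: [...], alternatives: [[...]]}}.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out: dict[str, list[ArchitectureRule]] = {}
    for ruleset, rules in doc.items():
        out[ruleset] = [_rule_from_config(n, c or {}) for n, c in rules.items()]
    return out


def builtin_rulesets(min_counts: bool = False) -> dict[str, list[ArchitectureRule]]:
    """The shipped curated rule sets (circadian, light, rnai, rid).

    ``min_counts=True`` relaxes every exact-count requirement to a minimum,
    for sensitivity analyses of the "expected frequency" interpretation.
    """
    ref = resources.files("mycocomp").joinpath("rules/builtin.yaml")
    with resources.as_file(ref) as path:
        sets = load_ruleset_file(path)
    if min_counts:
        sets = {
            name: [
                ArchitectureRule(
                    r.name,
                    tuple((d, Requirement(q.count, "min")) for d, q in r.required),
                    r.forbidden,
                    r.alternatives,
                )
                for r in rules
            ]
            for name, rules in sets.items()
        }
    return sets


def profiles_from_table(table: DomainAnnotationTable,
                        domain_type: str = "PFAM") -> list[ProteinDomainProfile]:
    """One profile per (species, gene): the multiset of its domain rows."""
    rows = table.rows[table.rows["domain_type"] == domain_type]
    grouped = rows.groupby(["species", "gene_id"])["domain_id"].value_counts()
    profiles: dict[tuple[str, str], dict[str, int]] = {}
    for (sp, gene, dom), n in grouped.items():
        profiles.setdefault((sp, gene), {})[dom] = int(n)
    return [
        ProteinDomainProfile(gene, sp, tuple(sorted(counts.items())))
        for (sp, gene), counts in profiles.items()
    ]


def classify_proteome(
    table: DomainAnnotationTable,
    rules: list[ArchitectureRule],
    domain_type: str = "PFAM",
) -> dict[str, dict[str, int]]:
    """Count proteins matching each rule, per species.

    A protein may satisfy several rules and is counted once for each
    (the categories are reported independently).
    """
    out: dict[str, dict[str, int]] = {
        sp: {r.name: 0 for r in rules} for sp in table.species
    }
    for profile in profiles_from_table(table, domain_type):
        counts = profile.as_dict()
        for rule in rules:
            if evaluate_rule(counts, rule):
                out[profile.species][rule.name] += 1
    return out
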