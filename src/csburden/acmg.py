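"""ACMG/AMP evidence combination into a pathogenicity class.

This module only *combines* evidence codes that a curator has already
assigned (PVS1, PS1-PS4, PM1-PM6, PP1-PP5, BA1, BS1-BS4, BP1-BP7); it
never derives codes from annotations.  The published 2015 combining
rules live in a packaged YAML table (:data:`RULES_PATH`) rather than in
branching code, so every rule row can be audited and tested.

PP5/BP6 (reputable-source assertions) are retained in the vocabulary
despite their later deprecation by ClinGen, because dominant-family
loss-of-function classifications in the literature still cite them.

Semantics: pathogenic-direction and benign-direction rule lists are
evaluated independently on the category counts (number of PVS, PS, PM,
PP, BA, BS, BP codes present); if both directions fire, the evidence is
internally conflicting and the variant is a VUS.  If neither fires, it
is likewise a VUS.
"""

from __future__ import annotations

import json
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import ConfigurationError

VALID_CODES = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)

CLASSES = ("Pathogenic", "Likely pathogenic", "VUS", "Likely benign", "Benign")

RULES_PATH = resources.files("csburden.data") / "acmg_rules.yaml"

_CLASS_KEYS = {
    "pathogenic": "Pathogenic",
    "likely_pathogenic": "Likely pathogenic",
    "benign": "Benign",
    "likely_benign": "Likely benign",
}


def load_rules(path: str | Path | None = None) -> dict[str, list[dict]]:
    """Load the combining table (packaged default or an override file)."""
    if path is None:
        text = RULES_PATH.read_text()
    else:
        text = Path(path).read_text()
    rules = yaml.safe_load(text)
    missing = set(_CLASS_KEYS) - set(rules)
    if missing:
        raise ConfigurationError(f"combining table missing class(es): {sorted(missing)}")
    return rules


_RULES_CACHE: dict[str, list[dict]] | None = None


def _rules() -> dict[str, list[dict]]:
    global _RULES_CACHE
    if _RULES_CACHE is None:
        _RULES_CACHE = load_rules()
    return _RULES_CACHE


def category_counts(codes: Iterable[str]) -> dict[str, int]:
    """Count evidence codes per strength category."""
    counts = {"PVS": 0, "PS": 0, "PM": 0, "PP": 0, "BA": 0, "BS": 0, "BP": 0}
    for code in codes:
        if code not in VALID_CODES:
            raise ConfigurationError(f"unknown ACMG evidence code {code!r}")
        for prefix in counts:
            if code.startswith(prefix) and code[len(prefix):].isdigit():
                counts[prefix] += 1
                break
    return counts


def _first_match(rule_list: list[dict], counts: Mapping[str, int]) -> str | None:
    for rule in rule_list:
        if all(counts.get(cat, 0) >= need for cat, need in rule.items() if cat != "id"):
            return rule["id"]
    return None


def combine_evidence(
    codes: Iterable[str], rules: dict[str, list[dict]] | None = None
) -> tuple[str, str | None]:
    """Combine assigned evidence codes into a pathogenicity class.

    Returns ``(class, rule_id)`` where ``rule_id`` names the combining
    rule that fired (``None`` for VUS).  Conflicting pathogenic- and
    benign-direction evidence yields VUS with a warning; a BA1
    (stand-alone benign) co-occurring with PVS1 additionally warns that
    the evidence set itself is inconsistent.

    Raises
    ------
    ConfigurationError
        On any code outside the ACMG vocabulary.
    """
    codes = set(codes)
    if rules is None:
        rules = _rules()
    counts = category_counts(codes)
    if "BA1" in codes and "PVS1" in codes:
        warnings.warn(
            "evidence set carries both BA1 and PVS1; classification "
            "falls back to VUS",
            stacklevel=2,
        )
    path_rule = _first_match(rules["pathogenic"], counts)
    lp_rule = _first_match(rules["likely_pathogenic"], counts)
    benign_rule = _first_match(rules["benign"], counts)
    lb_rule = _first_match(rules["likely_benign"], counts)

    pathogenic_fired = path_rule or lp_rule
    benign_fired = benign_rule or lb_rule
    if pathogenic_fired and benign_fired:
        warnings.warn(
            "conflicting pathogenic and benign evidence; class is VUS",
            stacklevel=2,
        )
        return "VUS", None
    if path_rule:
        return "Pathogenic", path_rule
    if lp_rule:
        return "Likely pathogenic", lp_rule
    if benign_rule:
        return "Benign", benign_rule
    if lb_rule:
        return "Likely benign", lb_rule
    return "VUS", None


def classify_json(payload: str | dict) -> dict:
    """JSON-in / JSON-out wrapper: {variant_id, codes[]} -> {class, rule_fired}."""
    if isinstance(payload, str):
        payload = json.loads(payload)
    cls, rule = combine_evidence(payload.get("codes", []))
    return {
        "variant_id": payload.get("variant_id"),
        "class": cls,
        "rule_fired": rule,
    }
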