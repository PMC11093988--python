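"""Assign substrate labels to PULs from their CAZyme inventory.

The rules mirror the classification used for North Sea flavobacterial
genomes: a GH13 (the canonical α-amylase family) marks a locus as
α-glucan-targeting, while a combination of families from
{GH3, GH16, GH17, GH30, GH5} — at least two distinct families, including an
endo-β-1,3-glucanase core family (GH16 or GH17) — marks it as
β-glucan-(laminarin-)targeting.  Subfamily tokens such as ``GH13_31``
inherit their parent family's rule by prefix.  A locus matching both rule
sets is labelled ``ambiguous``; conflicts are resolved only through the
explicit manual-curation channel, never by silent priority.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import CurationError, ParameterError
from .pul_caller import PULCall

ALPHA_GLUCAN = "alpha_glucan"
BETA_GLUCAN = "beta_glucan"
AMBIGUOUS = "ambiguous"
OTHER = "other"


def base_family(token: str) -> str:
    """Parent CAZy family of a (sub)family token: GH13_31 -> GH13."""
    return token.split("_", 1)[0]


@dataclass(frozen=True)
class SubstrateRuleSet:
    alpha_families: frozenset[str] = frozenset({"GH13"})
    beta_families: frozenset[str] = frozenset({"GH3", "GH16", "GH17", "GH30", "GH5"})
    beta_core: frozenset[str] = frozenset({"GH16", "GH17"})
    beta_min_distinct: int = 2

    def __post_init__(self) -> None:
        if not self.beta_core <= self.beta_families:
            raise ParameterError("beta_core must be a subset of beta_families")
        if self.beta_min_distinct < 1:
            raise ParameterError("beta_min_distinct must be >= 1")


DEFAULT_RULES = SubstrateRuleSet()


def classify_substrate(
    pul: PULCall | Iterable[str], rules: SubstrateRuleSet = DEFAULT_RULES
) -> str:
    """Substrate label for one PUL (or a bare inventory of family tokens).

    Deterministic, idempotent, and invariant to multiplicity and order of
    the inventory: only the set of parent families matters.
    """
    inventory = pul.cazyme_inventory if isinstance(pul, PULCall) else pul
    parents = {base_family(tok) for tok in inventory}
    alpha_hit = bool(parents & rules.alpha_families)
    beta_present = parents & rules.beta_families
    beta_hit = len(beta_present) >= rules.beta_min_distinct and bool(
        parents & rules.beta_core
    )
    if alpha_hit and beta_hit:
        return AMBIGUOUS
    if alpha_hit:
        return ALPHA_GLUCAN
    if beta_hit:
        return BETA_GLUCAN
    return OTHER


def classify_all(
    puls: list[PULCall], rules: SubstrateRuleSet = DEFAULT_RULES
) -> list[PULCall]:
    """Return new PULCalls with the substrate field filled in."""
    return [
        dataclasses.replace(p, substrate=classify_substrate(p, rules)) for p in puls
    ]


def apply_curation(
    puls: list[PULCall],
    overrides: Mapping[str, tuple[str, str]],
) -> list[PULCall]:
    """Apply manual substrate overrides keyed by pul_id.

    ``overrides`` maps pul_id -> (substrate label, note).  Overridden calls
    get ``curated=True`` and carry the note; everything else is untouched.
    Unknown pul_ids raise :class:`CurationError` listing all offenders.
    """
    known = {p.pul_id for p in puls}
    unknown = set(overrides) - known
    if unknown:
        raise CurationError(unknown)
    out = []
    for p in puls:
        if p.pul_id in overrides:
            substrate, note = overrides[p.pul_id]
            out.append(
                dataclasses.replace(
                    p, substrate=substrate, curated=True, curation_note=note
                )
            )
        else:
            out.append(p)
    return out
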