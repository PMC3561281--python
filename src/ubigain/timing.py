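"""Dating retained gains on the human-lineage clade ladder.

A gained lysine is dated to the smallest ladder clade that contains every
primate species observed to carry it (the minimal covering clade). When the
species that would discriminate between adjacent ladder branches are missing
from the alignment, the call is flagged ambiguous and every clade consistent
with the observations is listed, but the reported clade is always the
smallest. Lysines observed in non-primate mammals that survived screening
are treated as homoplasy — independent appearances, never merged into the
dated gain — and are logged on the call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .alignments import MISSING, ColumnProfile, SpeciesTree
from .screening import SiteCall

logger = logging.getLogger(__name__)


class DatingContractError(ValueError):
    """infer_origin_clade was invoked outside its contract (no reference K)."""


@dataclass(frozen=True)
class OriginCall:
    """Result of dating one gain."""

    clade: str
    consistent_clades: tuple[str, ...]
    homoplasy_species: tuple[str, ...]

    @property
    def ambiguous(self) -> bool:
        return len(self.consistent_clades) > 1


@dataclass(frozen=True)
class GainSummary:
    """Per-branch gain counts over the ladder (Figure-2-style tabulation)."""

    counts_by_clade: dict[str, int]
    total_sites: int
    total_proteins: int


def lysine_bearing_species(profile: ColumnProfile) -> frozenset[str]:
    """Exactly the species with an observed 'K' at the column; MISSING excluded."""
    return frozenset(
        s for s, r in profile.residue_by_species.items() if r == "K"
    )


def infer_origin_clade(profile: ColumnProfile, tree: SpeciesTree) -> OriginCall:
    """Date a gain to the smallest ladder clade covering all lysine-bearing primates.

    The consistent-clade list starts at the minimal covering clade and
    extends to successively larger ladder clades as long as every species
    they add is MISSING at the column (a gain on those deeper branches would
    be indistinguishable); it stops at the first clade adding a species with
    an observed non-lysine residue.
    """
    ks = lysine_bearing_species(profile)
    primate_ks = ks & tree.primates
    if tree.reference_species not in ks or not primate_ks:
        raise DatingContractError(
            "origin-clade inference requires an observed reference lysine"
        )
    homoplasy = tuple(sorted(ks - tree.primates))
    if homoplasy:
        logger.info(
            "column %d: non-primate lysines ignored as homoplasy: %s",
            profile.column, ", ".join(homoplasy),
        )
    minimal_idx = None
    for i, clade in enumerate(tree.ladder):
        if primate_ks <= clade.members:
            minimal_idx = i
            break
    if minimal_idx is None:  # unreachable: the top ladder clade is all primates
        raise DatingContractError("lysine-bearing primate outside every ladder clade")
    consistent = [tree.ladder[minimal_idx].name]
    prev = tree.ladder[minimal_idx].members
    for clade in tree.ladder[minimal_idx + 1 :]:
        added = clade.members - prev
        if all(profile.residue(s) is MISSING for s in added):
            consistent.append(clade.name)
            prev = clade.members
        else:
            break
    return OriginCall(
        clade=consistent[0],
        consistent_clades=tuple(consistent),
        homoplasy_species=homoplasy,
    )


def tabulate_gains(calls: list[SiteCall], tree: SpeciesTree) -> GainSummary:
    """Count dated gains per ladder branch, smallest clade first.

    All calls must be retained with an origin clade set; the per-branch
    counts sum to the number of calls and the protein total counts distinct
    genes.
    """
    counts = {clade.name: 0 for clade in tree.ladder}
    genes = set()
    for call in calls:
        if not call.retained or call.origin_clade is None:
            raise DatingContractError(
                f"tabulate_gains requires retained, dated calls; got {call.site.protein_id}"
                f":{call.site.position} status={call.status}"
            )
        if call.origin_clade not in counts:
            raise DatingContractError(f"unknown origin clade {call.origin_clade!r}")
        counts[call.origin_clade] += 1
        genes.add(call.gene_id)
    return GainSummary(
        counts_by_clade=counts,
        total_sites=len(calls),
        total_proteins=len(genes),
    )
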