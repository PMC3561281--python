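"""Site mapping and the lineage-gain screening filters.

Each ubiquitylated lysine is mapped into its gene's orthologous alignment
(position first, unique peptide search as fallback) and then passed through
four filters, applied in a fixed order with ALL failing reasons collected:

MULTI_COPY          the human protein sequence occurs in more than one gene
                    set — orthology is uncertain, the whole set is dropped.
EUARCHONTOGLIRES_K  a non-primate Euarchontoglires species (treeshrew, mouse,
                    rat, kangaroo rat, guinea pig, squirrel, rabbit, pika)
                    carries a lysine aligned with the human site — the
                    lysine predates the primate lineage.
MANY_NONPRIMATE_K   too large a fraction of non-primate mammals carry an
                    aligned lysine — likely ancestral presence with losses,
                    not a primate gain.
LOW_CONSERVATION    the surrounding region is poorly conserved — the column
                    itself cannot be trusted.

The last two reify what was a manual-inspection judgment into explicit,
configurable thresholds; reproducing any particular hand-curated set is not
promised. MISSING residues never count for or against any filter: a fully
missing outgroup passes with a low-information flag rather than discarding
the site.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .alignments import (
    MISSING,
    ColumnProfile,
    OrthologAlignment,
    SpeciesTree,
    column_of_position,
    position_of_column,
    residue_profile,
)
from .sites_io import ModSite

logger = logging.getLogger(__name__)

# discard reason codes, in the order the filters run
NO_ALIGNMENT = "NO_ALIGNMENT"
PEPTIDE_MISMATCH = "PEPTIDE_MISMATCH"
MULTI_COPY = "MULTI_COPY"
EUARCHONTOGLIRES_K = "EUARCHONTOGLIRES_K"
MANY_NONPRIMATE_K = "MANY_NONPRIMATE_K"
LOW_CONSERVATION = "LOW_CONSERVATION"

RETAINED = "retained"
DISCARDED = "discarded"


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for the automated screening filters.

    conservation_window
        Reference residues on each side of the site over which regional
        conservation is averaged (site column excluded).
    conservation_min_identity
        Minimum mean fraction of non-missing species matching the human
        residue across the window; below it the site fails LOW_CONSERVATION.
    nonprimate_lysine_max_fraction
        Maximum tolerated fraction of non-primate species (with an observed
        residue) carrying an aligned lysine.
    window_radius
        Radius of the new/additional/shifted window analysis downstream.
    allow_missing_reference_peptide_mismatch
        Keep sites whose reported peptide disagrees with the reference
        context instead of discarding them (for permissive exploration).
    """

    conservation_window: int = 10
    conservation_min_identity: float = 0.6
    nonprimate_lysine_max_fraction: float = 0.2
    window_radius: int = 5
    allow_missing_reference_peptide_mismatch: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.conservation_min_identity <= 1.0):
            raise ValueError("conservation_min_identity must be in [0, 1]")
        if not (0.0 <= self.nonprimate_lysine_max_fraction <= 1.0):
            raise ValueError("nonprimate_lysine_max_fraction must be in [0, 1]")
        if self.conservation_window < 1 or self.window_radius < 1:
            raise ValueError("radii must be >= 1")


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    value: float | None = None
    flag: str | None = None


@dataclass(frozen=True)
class MapResult:
    """Outcome of mapping a site into its alignment."""

    column: int | None
    corrected_position: int | None = None
    failure: str | None = None  # NO_ALIGNMENT or PEPTIDE_MISMATCH

    @property
    def ok(self) -> bool:
        return self.column is not None


@dataclass
class SiteCall:
    """The full per-site verdict accumulated along the pipeline."""

    site: ModSite
    gene_id: str | None
    column: int | None = None
    status: str = DISCARDED
    reasons: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    corrected_position: int | None = None
    origin_clade: str | None = None
    consistent_clades: list[str] = field(default_factory=list)
    ambiguous_origin: bool = False
    homoplasy_species: list[str] = field(default_factory=list)
    window_class: str | None = None
    acetylated_too: bool = False

    @property
    def retained(self) -> bool:
        return self.status == RETAINED

    @property
    def effective_position(self) -> int:
        return self.corrected_position or self.site.position


def _context_matches(ref: str, center: int, peptide: str) -> bool:
    """Does the reference context around 1-based *center* equal *peptide*?

    Comparison is aligned at the peptide center; 'X' on either side matches
    anything, and positions truncated at either terminus are ignored (the
    reported peptide may itself be terminus-truncated).
    """
    flank = len(peptide) // 2
    for off in range(-flank, flank + 1):
        p = center + off
        if p < 1 or p > len(ref):
            continue
        a = ref[p - 1]
        b = peptide[off + flank]
        if a != b and a != "X" and b != "X":
            return False
    return True


def _peptide_hits(ref: str, peptide: str) -> list[int]:
    """All 1-based lysine positions whose context matches *peptide* exactly."""
    return [
        p
        for p in range(1, len(ref) + 1)
        if ref[p - 1] == "K" and _context_matches(ref, p, peptide)
    ]


def map_site(site: ModSite, aln: OrthologAlignment | None) -> MapResult:
    """Locate the site's lysine column in the gene alignment.

    If the reference residue at the reported position is a lysine and the
    surrounding context matches the reported peptide, the site maps there.
    If the position does not hold a lysine (coordinate drift between
    accession versions), a unique exact peptide match elsewhere remaps the
    site with a logged position correction; zero or multiple matches fail
    with PEPTIDE_MISMATCH.
    """
    if aln is None:
        return MapResult(column=None, failure=NO_ALIGNMENT)
    ref = aln.ungapped_reference
    p = site.position
    if 1 <= p <= len(ref) and ref[p - 1] == "K":
        if _context_matches(ref, p, site.peptide):
            return MapResult(column=column_of_position(aln, p))
        return MapResult(column=None, failure=PEPTIDE_MISMATCH)
    hits = _peptide_hits(ref, site.peptide)
    if len(hits) == 1:
        logger.info(
            "%s %s: position corrected %d -> %d by unique peptide match",
            aln.gene_id, site.protein_id, p, hits[0],
        )
        return MapResult(
            column=column_of_position(aln, hits[0]), corrected_position=hits[0]
        )
    return MapResult(column=None, failure=PEPTIDE_MISMATCH)


def build_reference_index(
    alignments: Iterable[OrthologAlignment],
) -> Counter[str]:
    """Occurrence count of each ungapped human sequence across all gene sets."""
    return Counter(a.ungapped_reference for a in alignments)


def filter_multicopy(
    aln: OrthologAlignment, reference_index: Counter[str]
) -> FilterResult:
    """Fail when the human sequence occurs in more than one gene set (paralogy).

    Exact full-length identity after gap removal; near-identical paralogs
    cannot be detected without external annotation.
    """
    n = reference_index.get(aln.ungapped_reference, 1)
    return FilterResult(passed=n <= 1, value=float(n))


def filter_euarchontoglires(profile: ColumnProfile, tree: SpeciesTree) -> FilterResult:
    """Fail iff any non-primate Euarchontoglires species carries an aligned K.

    MISSING never triggers a failure; if every outgroup species is missing
    the filter passes with a low-information flag.
    """
    eua = [s for s, tag in tree.major_clade.items() if tag == "eua"]
    observed = [s for s in eua if profile.residue(s) is not MISSING]
    k_bearing = [s for s in observed if profile.residue(s) == "K"]
    if k_bearing:
        return FilterResult(passed=False, value=float(len(k_bearing)))
    flag = "EUA_ALL_MISSING" if not observed else None
    return FilterResult(passed=True, value=0.0, flag=flag)


def filter_nonprimate_lysines(
    profile: ColumnProfile, tree: SpeciesTree, cfg: ScreenConfig
) -> FilterResult:
    """Fail when too many non-primate mammals carry an aligned lysine.

    The fraction is lysine-bearing / residue-bearing among non-primate
    species; MISSING species are excluded from the denominator, and an empty
    denominator passes with a low-information flag.
    """
    nonpri = [s for s, tag in tree.major_clade.items() if tag != "pri"]
    observed = [s for s in nonpri if profile.residue(s) is not MISSING]
    if not observed:
        return FilterResult(passed=True, value=0.0, flag="NONPRIMATE_ALL_MISSING")
    frac = sum(1 for s in observed if profile.residue(s) == "K") / len(observed)
    return FilterResult(passed=frac <= cfg.nonprimate_lysine_max_fraction, value=frac)


def filter_conservation(
    aln: OrthologAlignment,
    column: int,
    tree: SpeciesTree,
    cfg: ScreenConfig,
) -> FilterResult:
    """Fail when regional conservation around the site is below threshold.

    Over the window of ``conservation_window`` reference residues each side
    of the site (clipped at the termini, site column excluded), each column
    contributes the fraction of non-missing non-reference species whose
    residue matches the human residue; the filter value is the mean over
    columns with at least one informative species.
    """
    pos = position_of_column(aln, column)
    ref_len = aln.reference_length
    fractions: list[float] = []
    for off in range(-cfg.conservation_window, cfg.conservation_window + 1):
        if off == 0:
            continue
        p = pos + off
        if p < 1 or p > ref_len:
            continue
        col = column_of_position(aln, p)
        prof = residue_profile(aln, col, tree)
        ref_res = prof.residue(aln.reference_species)
        if ref_res is MISSING:
            continue
        others = [
            r
            for s, r in prof.residue_by_species.items()
            if s != aln.reference_species and r is not MISSING
        ]
        if not others:
            continue
        fractions.append(sum(1 for r in others if r == ref_res) / len(others))
    if not fractions:
        return FilterResult(passed=True, value=None, flag="NO_INFORMATIVE_WINDOW")
    identity = sum(fractions) / len(fractions)
    return FilterResult(passed=identity >= cfg.conservation_min_identity, value=identity)


def screen_site(
    site: ModSite,
    aln: OrthologAlignment | None,
    tree: SpeciesTree,
    cfg: ScreenConfig,
    reference_index: Counter[str] | None = None,
) -> SiteCall:
    """Map one site and apply all screening filters, collecting every failure.

    Filters run in the fixed order MULTI_COPY, EUARCHONTOGLIRES_K,
    MANY_NONPRIMATE_K, LOW_CONSERVATION; they are independent predicates, so
    the order affects only the ordering of the reported reasons, never the
    verdict. The site is retained iff no filter fails.
    """
    call = SiteCall(site=site, gene_id=aln.gene_id if aln else None)
    mapped = map_site(site, aln)
    if not mapped.ok:
        if mapped.failure == PEPTIDE_MISMATCH and cfg.allow_missing_reference_peptide_mismatch:
            call.flags.append("PEPTIDE_MISMATCH_TOLERATED")
        else:
            call.reasons.append(mapped.failure)
            return call
    if mapped.column is None:  # tolerated mismatch still has no column to screen
        return call
    call.column = mapped.column
    call.corrected_position = mapped.corrected_position
    assert aln is not None
    profile = residue_profile(aln, mapped.column, tree)

    checks: Sequence[tuple[str, FilterResult]] = (
        (
            MULTI_COPY,
            filter_multicopy(aln, reference_index)
            if reference_index is not None
            else FilterResult(passed=True),
        ),
        (EUARCHONTOGLIRES_K, filter_euarchontoglires(profile, tree)),
        (MANY_NONPRIMATE_K, filter_nonprimate_lysines(profile, tree, cfg)),
        (LOW_CONSERVATION, filter_conservation(aln, mapped.column, tree, cfg)),
    )
    for code, result in checks:
        if not result.passed:
            call.reasons.append(code)
        if result.flag:
            call.flags.append(result.flag)
    if not call.reasons:
        call.status = RETAINED
    return call
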