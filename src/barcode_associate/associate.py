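"""Rule-based association of unknown larvae/females with named species.

An unknown specimen is associated with a species when, against a reference
set of confirmed, identified adult males (optionally also identified
females), one of three rules fires, checked in order:

R1 (identical): its sequence is identical to a reference of the species
    (pairwise distance exactly zero).
R2 (near-identical nest): every reference within the near-identity
    threshold (default 0.02 substitutions/site, the conventional 2% COI
    species boundary) belongs to one species.
R3 (monophyly on both trees): in both the NJ and the ML tree, the smallest
    clade (bipartition side) containing the unknown and at least one
    reference is single-species, for the same species, and that clade has
    bootstrap support at or above the gate (default 50) in at least one
    tree.

Zero-distance or near-identity conflicts between species, and NJ/ML tree
discordance, block assignment. Unknowns that remain unresolved are grouped
into lettered ambiguity clades (A, B, C, ...) by the unknown-only clades
they share on both trees — the candidate cryptic or unsampled lineages.

The two-tier workflow runs the cascade on the pooled dataset first, then
re-runs distances, trees and rules on per-region datasets filtered to the
species that gained associations, and only confirms an association when both
tiers agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from barcode_associate.distmat import (
    DistanceMatrix,
    DivergenceSummary,
    build_matrix,
    summarize_divergence,
)
from barcode_associate.mltree import (
    SubstitutionModel,
    ml_bootstrap,
    ml_tree,
    model_parameters_fit,
)
from barcode_associate.njtree import bootstrap_support
from barcode_associate.records import UNKNOWN, Dataset, SpecimenRecord
from barcode_associate.tree import PhyloTree

logger = logging.getLogger(__name__)

ZERO_TOL = 1e-12

RULE_R1 = "R1_identical"
RULE_R2 = "R2_near_identical_nest"
RULE_R3 = "R3_monophyly_both_trees"


@dataclass
class AssociationConfig:
    """Thresholds and build settings for the association workflow."""

    near_threshold: float = 0.02
    min_support: float = 50.0
    model: str = "k2p"  # distance model for R1/R2 and the NJ tree
    include_female_refs: bool = False
    nj_replicates: int = 1000
    ml_replicates: int = 0  # 0: ML point tree only, support gate uses NJ
    ml_gamma: bool = True
    fit_ml_model: bool = True
    do_nni: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.near_threshold <= 0:
            raise ValueError("near_threshold must be positive")
        if not 0 <= self.min_support <= 100:
            raise ValueError("min_support must be in [0, 100]")


@dataclass
class AssociationResult:
    """Per-unknown verdict."""

    specimen_id: str
    status: str  # associated | unassociated | ambiguous
    assigned_species: str | None = None
    rule: str | None = None
    tier: str = "pooled"
    evidence: dict = field(default_factory=dict)
    ambiguity_clade: str | None = None


def reference_specimens(
    ds: Dataset, include_females: bool = False
) -> list[SpecimenRecord]:
    """Identified adult references (males; optionally identified females)."""
    stages = {"male"} | ({"female"} if include_females else set())
    return [r for r in ds.records if not r.is_unknown and r.life_stage in stages]


def monophyly(
    tree: PhyloTree, leaf_subset: set[str] | frozenset[str]
) -> tuple[bool, float | None]:
    """Is the subset one side of a bipartition of the unrooted tree?

    Singletons, the full leaf set, and all-but-one subsets are trivially
    monophyletic with support not applicable (None). For internal splits the
    defining edge's bootstrap support is returned when annotated.
    """
    subset = set(leaf_subset)
    if not subset:
        raise ValueError("leaf subset must be non-empty")
    missing = subset - set(tree.taxa)
    if missing:
        raise KeyError(f"leaves not in tree: {sorted(missing)}")
    n = tree.n_leaves
    if len(subset) in (1, n - 1, n):
        return True, None
    if not tree.has_split(subset):
        return False, None
    return True, tree.support_for(subset)


def _ref_distances(
    u_id: str, dm: DistanceMatrix, refs: list[SpecimenRecord]
) -> list[tuple[str, str, float]]:
    """(ref_id, species, distance) for every reference with a defined distance."""
    out = []
    for r in refs:
        d = dm.distance(u_id, r.specimen_id)
        if not np.isnan(d):
            out.append((r.specimen_id, r.species_label, float(d)))
    return out


def rule_R1(
    u_id: str, dm: DistanceMatrix, refs: list[SpecimenRecord]
) -> AssociationResult | None:
    """Assign when the unknown is sequence-identical to references of one species."""
    zero = [(rid, sp, d) for rid, sp, d in _ref_distances(u_id, dm, refs) if d <= ZERO_TOL]
    if not zero:
        return None
    species = sorted({sp for _, sp, _ in zero})
    evidence = {"identical_refs": [rid for rid, _, _ in zero], "species": species}
    if len(species) == 1:
        return AssociationResult(
            u_id, "associated", species[0], RULE_R1, evidence=evidence
        )
    return AssociationResult(
        u_id, "ambiguous", None, None,
        evidence={**evidence, "conflict": "identical to references of multiple species"},
    )


def rule_R2(
    u_id: str,
    dm: DistanceMatrix,
    refs: list[SpecimenRecord],
    near_threshold: float = 0.02,
) -> AssociationResult | None:
    """Assign when all near-identical references belong to one species."""
    if near_threshold <= 0:
        raise ValueError("near_threshold must be positive")
    near = [
        (rid, sp, d)
        for rid, sp, d in _ref_distances(u_id, dm, refs)
        if d <= near_threshold
    ]
    if not near:
        return None
    species = sorted({sp for _, sp, _ in near})
    evidence = {
        "near_refs": [rid for rid, _, _ in near],
        "species": species,
        "min_distance": min(d for _, _, d in near),
        "threshold": near_threshold,
    }
    if len(species) == 1:
        return AssociationResult(
            u_id, "associated", species[0], RULE_R2, evidence=evidence
        )
    return AssociationResult(
        u_id, "ambiguous", None, None,
        evidence={**evidence, "conflict": "near-identical references of multiple species"},
    )


def _enclosing_species_clade(
    tree: PhyloTree, u_id: str, ref_ids: set[str], labels: dict[str, str]
) -> tuple[frozenset[str], set[str]] | None:
    """The unknown's enclosing species group, as a split side.

    First finds the smallest split side containing the unknown and at least
    one reference; its labeled membership defines the candidate species
    (possibly several, when the unknown sits inside a mixed clade). When the
    candidate is a single species, returns the *largest* side around the
    unknown whose labeled members are purely that species — the species-level
    monophyletic group whose bootstrap support is meaningful — rather than an
    arbitrary subclade of it.
    """
    taxa = set(tree.taxa)
    sides = [
        candidate
        for side in tree.splits()
        for candidate in (frozenset(side), frozenset(taxa - side))
        if u_id in candidate and len(candidate) < len(taxa)
    ]
    with_ref = [s for s in sides if s & ref_ids]
    if not with_ref:
        return None
    minimal = min(with_ref, key=len)
    species = {labels[x] for x in minimal if labels.get(x, UNKNOWN) != UNKNOWN}
    if len(species) != 1:
        return minimal, species
    sp = next(iter(species))
    pure = [
        s
        for s in with_ref
        if {labels[x] for x in s if labels.get(x, UNKNOWN) != UNKNOWN} == {sp}
    ]
    return max(pure, key=len), species


def rule_R3(
    u_id: str,
    nj_tree: PhyloTree,
    ml_tree_: PhyloTree,
    labels: dict[str, str],
    refs: list[SpecimenRecord],
    min_support: float = 50.0,
) -> AssociationResult | None:
    """Assign when nested in a single-species clade on both trees.

    The clade must be the same species in both trees and carry bootstrap
    support at or above ``min_support`` in at least one tree. When neither
    tree carries any support annotation the gate is waived (point-estimate
    mode). Tree discordance blocks assignment.
    """
    for t in (nj_tree, ml_tree_):
        if u_id not in t.taxa:
            raise KeyError(f"unknown {u_id} absent from tree")
    ref_ids = {r.specimen_id for r in refs}
    found = []
    for t in (nj_tree, ml_tree_):
        hit = _enclosing_species_clade(t, u_id, ref_ids, labels)
        if hit is None:
            return None
        found.append(hit)
    (side_nj, sp_nj), (side_ml, sp_ml) = found
    if len(sp_nj) != 1 or len(sp_ml) != 1 or sp_nj != sp_ml:
        if sp_nj and sp_ml and (len(sp_nj) > 1 or len(sp_ml) > 1 or sp_nj != sp_ml):
            return AssociationResult(
                u_id, "ambiguous", None, None,
                evidence={
                    "conflict": "trees disagree on the enclosing species clade",
                    "nj_species": sorted(sp_nj),
                    "ml_species": sorted(sp_ml),
                },
            )
        return None
    species = next(iter(sp_nj))
    s_nj = nj_tree.support_for(side_nj) if 2 <= len(side_nj) <= nj_tree.n_leaves - 2 else None
    s_ml = ml_tree_.support_for(side_ml) if 2 <= len(side_ml) <= ml_tree_.n_leaves - 2 else None
    any_support_annotated = bool(nj_tree.support) or bool(ml_tree_.support)
    gate_ok = (
        not any_support_annotated
        or (s_nj is not None and s_nj >= min_support)
        or (s_ml is not None and s_ml >= min_support)
    )
    evidence = {
        "clade_nj": sorted(side_nj),
        "clade_ml": sorted(side_ml),
        "support_nj": s_nj,
        "support_ml": s_ml,
        "min_support": min_support,
    }
    if not gate_ok:
        return AssociationResult(
            u_id, "ambiguous", None, None,
            evidence={**evidence, "conflict": "clade support below gate in both trees"},
        )
    return AssociationResult(u_id, "associated", species, RULE_R3, evidence=evidence)


def _unknown_only_clade(tree: PhyloTree, u_id: str, labels: dict[str, str]) -> set[str]:
    """Largest split side containing the unknown and no labeled specimen."""
    taxa = set(tree.taxa)
    best: set[str] = {u_id}
    for side in tree.splits():
        for candidate in (set(side), taxa - side):
            if u_id not in candidate:
                continue
            if any(labels.get(x, UNKNOWN) != UNKNOWN for x in candidate):
                continue
            if len(candidate) > len(best):
                best = candidate
    return best


def associate_all(
    ds: Dataset,
    dm: DistanceMatrix,
    nj_tree: PhyloTree | None,
    ml_tree_: PhyloTree | None,
    config: AssociationConfig | None = None,
) -> list[AssociationResult]:
    """Apply R1 -> R2 -> R3 to every unknown; letter residual ambiguity clades.

    Trees may be None (distance-only mode, used by small filtered tiers);
    R3 is then skipped. Output order follows input record order and is
    invariant to it in content.
    """
    config = config or AssociationConfig()
    refs = reference_specimens(ds, config.include_female_refs)
    labels = ds.labels()
    results: list[AssociationResult] = []
    for rec in ds.unknowns:
        res = rule_R1(rec.specimen_id, dm, refs)
        if res is None:
            res = rule_R2(rec.specimen_id, dm, refs, config.near_threshold)
        if res is None and nj_tree is not None and ml_tree_ is not None:
            res = rule_R3(
                rec.specimen_id, nj_tree, ml_tree_, labels, refs, config.min_support
            )
        if res is None:
            res = AssociationResult(rec.specimen_id, "unassociated")
        res.tier = ds.tier_tag
        results.append(res)

    # Letter residual lineages: unresolved unknowns grouped by the
    # unknown-only clades they share on both trees (discovery order).
    unresolved = [r for r in results if r.status != "associated"]
    if unresolved and nj_tree is not None and ml_tree_ is not None:
        group_of: dict[str, frozenset[str]] = {}
        for r in unresolved:
            in_nj = _unknown_only_clade(nj_tree, r.specimen_id, labels)
            in_ml = _unknown_only_clade(ml_tree_, r.specimen_id, labels)
            group_of[r.specimen_id] = frozenset(in_nj & in_ml)
        letters: dict[frozenset[str], str] = {}
        for r in sorted(unresolved, key=lambda x: x.specimen_id):
            g = group_of[r.specimen_id]
            if g not in letters:
                letters[g] = chr(ord("A") + len(letters))
            r.ambiguity_clade = letters[g]
            if len(g) > 1 and r.status == "unassociated":
                # co-located unknowns form an equivocal lineage
                r.status = "ambiguous"
                r.evidence.setdefault("clade_members", sorted(g))
    return results


def results_table(results: list[AssociationResult]) -> pd.DataFrame:
    """Association report as a tidy table (TSV-ready)."""
    rows = []
    for r in results:
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "status": r.status,
                "species": r.assigned_species or "",
                "rule": r.rule or "",
                "tier": r.tier,
                "min_distance_to_assigned": r.evidence.get("min_distance", ""),
                "clade_support_nj": r.evidence.get("support_nj", ""),
                "clade_support_ml": r.evidence.get("support_ml", ""),
                "ambiguity_clade": r.ambiguity_clade or "",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class TierAnalysis:
    """Distance matrix, trees, divergence summary and verdicts for one tier."""

    dataset: Dataset
    dm: DistanceMatrix
    nj_tree: PhyloTree | None
    ml_tree: PhyloTree | None
    summary: DivergenceSummary
    results: list[AssociationResult]
    notes: list[str] = field(default_factory=list)


@dataclass
class TwoTierReport:
    """Pooled verdicts, per-region confirmations, and final statuses."""

    pooled: TierAnalysis
    filtered: dict[str, TierAnalysis]
    final: list[AssociationResult]
    notes: list[str] = field(default_factory=list)


def analyze_tier(ds: Dataset, config: AssociationConfig) -> TierAnalysis:
    """Distances, NJ(+bootstrap), ML tree and rule cascade for one dataset."""
    notes: list[str] = []
    dm = build_matrix(ds, config.model)
    n_species = len(ds.species)
    nj_t = ml_t = None
    if len(ds) >= 3 and n_species >= 3 and dm.is_fully_defined:
        nj_t = bootstrap_support(
            ds, config.model, replicates=config.nj_replicates, seed=config.seed
        )
        if config.fit_ml_model:
            model = model_parameters_fit(
                nj_t, ds, "TIM2", gamma=config.ml_gamma, max_sweeps=2
            )
        else:
            from barcode_associate.mltree import empirical_base_freqs

            model = SubstitutionModel.tim2(
                empirical_base_freqs(ds),
                gamma_alpha=DEFAULT_PIPELINE_ALPHA if config.ml_gamma else None,
            )
        if config.ml_replicates > 0:
            ml_t = ml_bootstrap(
                ds,
                model,
                replicates=config.ml_replicates,
                seed=config.seed + 1,
                do_nni=config.do_nni,
            ).tree
        else:
            ml_t = ml_tree(ds, model, do_nni=config.do_nni).tree
    else:
        notes.append(
            f"tier {ds.tier_tag!r}: fewer than 3 species or undefined distances; "
            "tree-based analysis skipped, distance rules only"
        )
    summary = summarize_divergence(dm, ds.labels())
    results = associate_all(ds, dm, nj_t, ml_t, config)
    return TierAnalysis(ds, dm, nj_t, ml_t, summary, results, notes)


DEFAULT_PIPELINE_ALPHA = 0.5


def two_tier_workflow(pooled: Dataset, config: AssociationConfig | None = None) -> TwoTierReport:
    """Pooled analysis, then per-region filtered confirmation runs.

    Filtered datasets contain, per region, every specimen of each species
    that gained at least one pooled association, plus the unknowns associated
    to those species. The final status of an unknown is 'associated' only
    when its pooled and filtered verdicts name the same species; pooled-only
    associations that dissolve in the filtered run are downgraded to
    ambiguous.
    """
    config = config or AssociationConfig()
    if pooled.tier_tag != "pooled":
        raise ValueError("two-tier workflow starts from a pooled dataset")
    pooled_tier = analyze_tier(pooled, config)
    pooled_by_id = {r.specimen_id: r for r in pooled_tier.results}

    assoc_species = sorted(
        {r.assigned_species for r in pooled_tier.results if r.status == "associated"}
    )
    assigned_to = {
        r.specimen_id: r.assigned_species
        for r in pooled_tier.results
        if r.status == "associated"
    }

    filtered: dict[str, TierAnalysis] = {}
    notes: list[str] = []
    for region in ("east", "west"):
        keep = [
            rec.specimen_id
            for rec in pooled.records
            if rec.region == region
            and (
                rec.species_label in assoc_species
                or assigned_to.get(rec.specimen_id) in assoc_species
            )
        ]
        if len(keep) < 2:
            notes.append(f"filtered tier {region!r}: fewer than 2 specimens, skipped")
            continue
        sub = pooled.subset(keep, tier_tag=region)
        filtered[region] = analyze_tier(sub, config)

    final: list[AssociationResult] = []
    confirmed: dict[str, AssociationResult] = {}
    for tier in filtered.values():
        for r in tier.results:
            confirmed[r.specimen_id] = r
    for rec in pooled.unknowns:
        p = pooled_by_id[rec.specimen_id]
        f = confirmed.get(rec.specimen_id)
        if p.status != "associated":
            final.append(p)
            continue
        if f is None:
            out = AssociationResult(
                rec.specimen_id, p.status, p.assigned_species, p.rule,
                tier="pooled", evidence=dict(p.evidence), ambiguity_clade=p.ambiguity_clade,
            )
            out.evidence["note"] = "no filtered-tier run covered this specimen"
            final.append(out)
            continue
        if f.status == "associated" and f.assigned_species == p.assigned_species:
            out = AssociationResult(
                rec.specimen_id, "associated", p.assigned_species, p.rule,
                tier=f.tier, evidence={"pooled": p.evidence, "filtered": f.evidence},
            )
            final.append(out)
        else:
            out = AssociationResult(
                rec.specimen_id, "ambiguous", None, None, tier=f.tier,
                evidence={
                    "conflict": "pooled and filtered verdicts disagree",
                    "pooled_species": p.assigned_species,
                    "filtered_status": f.status,
                    "filtered_species": f.assigned_species,
                },
                ambiguity_clade=f.ambiguity_clade,
            )
            final.append(out)
    return TwoTierReport(pooled_tier, filtered, final, notes)
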