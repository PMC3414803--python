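"""Per-family MGE composition, specificity classification and reporting.

A family is "MGE-type specific" when the bulk of its members originate
from a single MGE class; phages and predicted prophages are merged into
one "(pro)phage" class for this purpose because a prophage is simply an
integrated phage.  Families below a minimum size are set aside as
"small".  Members much shorter than a functional recombinase are
flagged as likely defective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from tbssr.mcl import FamintPartition
from tbssr.msa import MotifCall
from tbssr.records import ProteinRecord


@dataclass
class AnnotationRules:
    min_family_size: int = 4
    purity_threshold: float = 0.9
    merge_phage_prophage: bool = True
    defective_max_len: int = 200

    def __post_init__(self) -> None:
        if not 0.5 < self.purity_threshold <= 1:
            raise ValueError("purity_threshold must be in (0.5, 1]")


@dataclass
class FamilyProfile:
    famint: int
    size: int
    composition: dict[str, int]
    specificity: str
    motif: MotifCall | None = None
    defective_ids: list[str] = field(default_factory=list)
    purity: float = 0.0


def _merged_class(mge_type: str, rules: AnnotationRules) -> str:
    if rules.merge_phage_prophage and mge_type in ("phage", "prophage"):
        return "(pro)phage"
    return mge_type


def family_composition(
    partition: FamintPartition, proteins: list[ProteinRecord]
) -> dict[int, dict[str, int]]:
    """Raw per-family MGE-class counts (phage and prophage kept apart)."""
    by_id = {p.id: p for p in proteins}
    missing = [pid for pid in partition.assignment if pid not in by_id]
    if missing:
        raise ValueError(f"unknown protein ids in partition: {missing[:3]}")
    comp: dict[int, dict[str, int]] = {}
    for pid, fam in partition.assignment.items():
        c = comp.setdefault(fam, {})
        t = by_id[pid].mge_type
        c[t] = c.get(t, 0) + 1
    return comp


def _merged_fractions(
    composition: dict[str, int], rules: AnnotationRules
) -> dict[str, float]:
    total = sum(composition.values())
    merged: dict[str, int] = {}
    for t, n in composition.items():
        k = _merged_class(t, rules)
        merged[k] = merged.get(k, 0) + n
    return {k: n / total for k, n in merged.items()}


def classify_specificity(
    composition: dict[str, int], rules: AnnotationRules | None = None
) -> str:
    """"small", "mixed" or "specific:<merged class>".

    A family is specific when the largest merged-class fraction reaches
    the purity threshold; raising the threshold can only move families
    from specific to mixed, never the reverse.
    """
    if not composition:
        raise ValueError("empty composition")
    rules = rules or AnnotationRules()
    size = sum(composition.values())
    if size < rules.min_family_size:
        return "small"
    fracs = _merged_fractions(composition, rules)
    top = max(sorted(fracs), key=lambda k: fracs[k])
    if fracs[top] >= rules.purity_threshold:
        return f"specific:{top}"
    return "mixed"


def flag_defective(
    members: list[ProteinRecord], rules: AnnotationRules | None = None
) -> list[str]:
    """Ids of members strictly shorter than the defective-length cutoff."""
    rules = rules or AnnotationRules()
    return [p.id for p in members if p.length < rules.defective_max_len]


def build_profiles(
    partition: FamintPartition,
    proteins: list[ProteinRecord],
    motifs: dict[int, MotifCall] | None = None,
    rules: AnnotationRules | None = None,
) -> list[FamilyProfile]:
    rules = rules or AnnotationRules()
    motifs = motifs or {}
    comp = family_composition(partition, proteins)
    by_id = {p.id: p for p in proteins}
    profiles = []
    for fam in sorted(comp):
        c = comp[fam]
        members = [by_id[pid] for pid in partition.members(fam)]
        fracs = _merged_fractions(c, rules)
        profiles.append(
            FamilyProfile(
                famint=fam,
                size=sum(c.values()),
                composition=c,
                specificity=classify_specificity(c, rules),
                motif=motifs.get(fam),
                defective_ids=flag_defective(members, rules),
                purity=max(fracs.values()),
            )
        )
    return profiles


def family_report(
    profiles: list[FamilyProfile],
    partition: FamintPartition,
    rules: AnnotationRules | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Tabular family report plus headline summary statistics.

    The table has one row per family of size >= ``min_family_size``
    with composition, computed purity, specificity and motif label.
    The summary aggregates 3-member / 2-member / singleton families and
    reports two headline fractions: the percentage of proteins in
    MGE-type-specific families of qualifying size, and the percentage
    of proteins in qualifying-size families that are specific among
    those (both definitions are emitted because the headline statistic
    can be read either way).
    """
    rules = rules or AnnotationRules()
    total = len(partition.assignment)
    rows = []
    for p in profiles:
        if p.size < rules.min_family_size:
            continue
        rows.append(
            {
                "famint": p.famint,
                "size": p.size,
                "composition": ";".join(
                    f"{k}:{v}" for k, v in sorted(p.composition.items())
                ),
                "purity": round(p.purity, 4),
                "specificity": p.specificity,
                "motif": p.motif.label if p.motif else "",
                "n_defective": len(p.defective_ids),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "famint", "size", "composition", "purity",
            "specificity", "motif", "n_defective",
        ],
    )
    sizes = [p.size for p in profiles]
    spec_proteins = sum(
        p.size
        for p in profiles
        if p.size >= rules.min_family_size
        and p.specificity.startswith("specific:")
    )
    large_proteins = sum(p.size for p in profiles if p.size >= rules.min_family_size)
    summary = {
        "n_proteins": total,
        "n_families": len(profiles),
        "n_families_3": sum(1 for s in sizes if s == 3),
        "n_families_2": sum(1 for s in sizes if s == 2),
        "n_singletons": sum(1 for s in sizes if s == 1),
        "pct_specific_of_all": 100.0 * spec_proteins / total if total else 0.0,
        "pct_specific_of_large": (
            100.0 * spec_proteins / large_proteins if large_proteins else 0.0
        ),
    }
    return table, summary


def per_protein_table(
    profiles: list[FamilyProfile],
    partition: FamintPartition,
) -> pd.DataFrame:
    """Machine-readable per-protein annotation."""
    by_fam = {p.famint: p for p in profiles}
    rows = []
    for pid in sorted(partition.assignment):
        fam = partition.assignment[pid]
        p = by_fam[fam]
        rows.append(
            {
                "protein_id": pid,
                "famint": fam,
                "family_size": p.size,
                "specificity": p.specificity,
                "motif_label": p.motif.label if p.motif else "",
                "defective": pid in p.defective_ids,
            }
        )
    return pd.DataFrame(rows)
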