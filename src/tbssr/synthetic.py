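"""Synthetic protein sets and annotated replicons with planted truth.

The generator emulates a desk-scale recombinase corpus: a configurable
number of families, each derived from an independent random ancestor by
per-site substitution, plus unrelated singleton sequences.  Family
members carry MGE-type, host and replicon metadata, and motif-carrying
families have the catalytic R-(x~30)-Y residues (with one intervening
anchor residue) exempted from mutation, so the planted motif columns
are perfectly conserved.  Background residues are uniform over the 20
amino acids, which maximises the separation between planted families
and keeps recovery tests sharp.

Annotated replicons are laid out gene by gene: planted RIT trios,
Tn554-like tandems and BIM pairs obey every detector rule, while decoys
violate exactly one rule each, making sensitivity/precision exactly
measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tbssr.elements import ElementCall, GeneFeature
from tbssr.records import AA_ALPHABET, ProteinRecord

_MGE_CYCLE = ("GI", "phage", "prophage", "plasmid", "ICE", "RIT", "BIM")

#: Default host pool per MGE type.  Several genera have two or more
#: species (they collapse to genus nodes) and some have a single
#: representative (kept at species/strain level), so the host-network
#: grouping rule is exercised out of the box.
_DEFAULT_HOSTS: dict[str, list[str]] = {
    "GI": [
        "Cupriavidus metallidurans CH34",
        "Cupriavidus eutrophus H16",
        "Pseudomonas putida KT2440",
    ],
    "phage": [
        "Escherichia coli K-12",
        "Escherichia coli O157:H7",
        "Salmonella enterica LT2",
    ],
    "prophage": [
        "Bacillus subtilis 168",
        "Bacillus cereus ATCC 14579",
        "Staphylococcus aureus N315",
    ],
    "plasmid": [
        "Rhodococcus erythropolis PR4",
        "Rhodococcus jostii RHA1",
        "Novosphingobium aromaticivorans DSM 12444",
    ],
    "ICE": [
        "Burkholderia phytofirmans PsJN",
        "Bordetella petrii DSM 12804",
    ],
    "RIT": [
        "Acidithiobacillus ferrooxidans ATCC 23270",
        "Caulobacter sp. K31",
        "Gramella forsetii KT0803",
    ],
    "BIM": [
        "Dinoroseobacter shibae DFL 12",
        "Mesorhizobium loti MAFF303099",
    ],
}


@dataclass
class SynthParams:
    """Study conditions of the synthetic corpus.

    ``within_family_identity`` is the expected per-site identity of each
    member to its family ancestor; pairwise identity between members is
    correspondingly lower (p**2 + (1-p)**2/19 at the site level).
    ``motif_fraction`` is the fraction of families carrying a planted
    catalytic motif; spacing between the planted R and Y is drawn from
    ``motif_spacing_range``.
    """

    n_families: int = 8
    family_size_range: tuple[int, int] = (12, 40)
    n_singletons: int = 20
    seq_length_range: tuple[int, int] = (280, 450)
    within_family_identity: float = 0.6
    motif_spacing_range: tuple[int, int] = (28, 32)
    motif_fraction: float = 1.0
    mge_type_assignment: dict[int, str] | None = None
    hosts_per_type: dict[str, list[str]] | None = None
    confounder: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family_size_range[0] < 1:
            raise ValueError("family sizes must be >= 1")
        if not 0 < self.within_family_identity <= 1:
            raise ValueError("within_family_identity must be in (0, 1]")
        if self.within_family_identity <= 0.1:
            raise ValueError(
                "within_family_identity must exceed the ~0.05-0.1 background"
            )
        if not 0 <= self.motif_fraction <= 1:
            raise ValueError("motif_fraction must be in [0, 1]")
        min_len = self.seq_length_range[0]
        motif_span = self.motif_spacing_range[1] + 1
        if min_len * self.within_family_identity < motif_span:
            raise ValueError(
                "identity target incompatible with sequence length: "
                "expected conserved sites fall below the motif span"
            )


@dataclass
class TruthEntry:
    true_family: int
    mge_type: str
    host: str
    motif_positions: tuple[int, int] | None = None  # (R_index, Y_index)


@dataclass
class TruthTable:
    """Planted ground truth: one entry per generated protein."""

    entries: dict[str, TruthEntry] = field(default_factory=dict)

    def labels(self, ids: list[str]) -> list[int]:
        return [self.entries[i].true_family for i in ids]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(
        AA_ALPHABET[k] for k in rng.integers(0, len(AA_ALPHABET), size=length)
    )


def mutate_sequence(
    seq: str,
    target_identity: float,
    protected: set[int] | frozenset[int],
    rng: np.random.Generator,
) -> str:
    """Per-site substitution; protected sites are never touched.

    Each unprotected site is substituted with probability
    ``1 - target_identity``, the replacement drawn uniformly from the 19
    alternative residues, so the expected fraction of unchanged sites is
    the target (slightly above it when sites are protected).
    """
    if not seq:
        raise ValueError("empty sequence")
    if not 0 <= target_identity <= 1:
        raise ValueError("target_identity must be in [0, 1]")
    bad = [i for i in protected if not 0 <= i < len(seq)]
    if bad:
        raise ValueError(f"protected indices out of range: {bad[:3]}")
    out = list(seq)
    mutate_mask = rng.random(len(seq)) >= target_identity
    for i, flag in enumerate(mutate_mask):
        if not flag or i in protected:
            continue
        alternatives = AA_ALPHABET.replace(out[i], "")
        out[i] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(out)


def generate_protein_set(
    params: SynthParams | None = None,
) -> tuple[list[ProteinRecord], TruthTable]:
    """Generate the synthetic corpus and its planted truth table.

    Family *f* gets MGE type from ``mge_type_assignment`` (default:
    cycling through the seven MGE classes; the value "mixed" draws a
    type per member).  Hosts are drawn from the per-type pool.
    Singletons are independent random sequences with their own truth
    family numbers.  The seed fully determines the output.
    """
    params = params or SynthParams()
    rng = np.random.default_rng(params.seed)
    hosts = params.hosts_per_type or _DEFAULT_HOSTS
    records: list[ProteinRecord] = []
    truth = TruthTable()
    n_motif_fams = int(round(params.motif_fraction * params.n_families))
    lo_len, hi_len = params.seq_length_range
    lo_sz, hi_sz = params.family_size_range
    prev_ancestor: str | None = None
    for f in range(params.n_families):
        length = int(rng.integers(lo_len, hi_len + 1))
        size = int(rng.integers(lo_sz, hi_sz + 1))
        if params.confounder and f == 1 and prev_ancestor is not None:
            length = len(prev_ancestor)
            ancestor = mutate_sequence(prev_ancestor, 0.3, frozenset(), rng)
        else:
            ancestor = random_sequence(length, rng)
        protected: frozenset[int] = frozenset()
        motif_pos: tuple[int, int] | None = None
        if f < n_motif_fams:
            spacing = int(
                rng.integers(
                    params.motif_spacing_range[0],
                    params.motif_spacing_range[1] + 1,
                )
            )
            y_pos = length - 1 - int(rng.integers(5, 31))
            r_pos = y_pos - spacing
            anc = list(ancestor)
            anc[r_pos] = "R"
            anc[r_pos + 1] = "H"
            anc[y_pos] = "Y"
            ancestor = "".join(anc)
            protected = frozenset({r_pos, r_pos + 1, y_pos})
            motif_pos = (r_pos, y_pos)
        if f == 0:
            prev_ancestor = ancestor
        if params.mge_type_assignment and f in params.mge_type_assignment:
            fam_type = params.mge_type_assignment[f]
        else:
            fam_type = _MGE_CYCLE[f % len(_MGE_CYCLE)]
        for m in range(size):
            if fam_type == "mixed":
                mge = _MGE_CYCLE[int(rng.integers(0, len(_MGE_CYCLE)))]
            else:
                mge = fam_type
            pool = hosts.get(mge) or sum(hosts.values(), [])
            host = pool[int(rng.integers(0, len(pool)))]
            seq = mutate_sequence(
                ancestor, params.within_family_identity, protected, rng
            )
            pid = f"F{f:02d}_{m:03d}"
            records.append(
                ProteinRecord(
                    id=pid,
                    sequence=seq,
                    mge_type=mge,
                    host=host,
                    replicon=f"rep_{mge}_{f}",
                )
            )
            truth.entries[pid] = TruthEntry(
                true_family=f,
                mge_type=mge,
                host=host,
                motif_positions=motif_pos,
            )
    all_hosts = sorted({h for pool in hosts.values() for h in pool})
    for s in range(params.n_singletons):
        length = int(rng.integers(lo_len, hi_len + 1))
        mge = _MGE_CYCLE[int(rng.integers(0, len(_MGE_CYCLE)))]
        host = all_hosts[int(rng.integers(0, len(all_hosts)))]
        pid = f"S{s:03d}"
        records.append(
            ProteinRecord(
                id=pid,
                sequence=random_sequence(length, rng),
                mge_type=mge,
                host=host,
                replicon=f"rep_singleton_{s}",
            )
        )
        truth.entries[pid] = TruthEntry(
            true_family=params.n_families + s,
            mge_type=mge,
            host=host,
        )
    return records, truth


# ---------------------------------------------------------------------------
# Annotated replicons


@dataclass
class ElementPlan:
    """Layout plan for one synthetic replicon.

    ``items`` is an ordered list of element kinds; real elements are
    "rit", "tn554" (with TnpC), "tn554_no_tnpc" and "bim".  Decoy kinds
    violate exactly one detector rule each:

    - ``rit_decoy_strand``   middle gene on the opposite strand
    - ``rit_decoy_overlap``  one overlap of 12 bp (outside 4-8)
    - ``rit_decoy_span``     total span well above 3.7 kb
    - ``tn554_decoy_strand`` short partner on the opposite strand
    - ``tn554_decoy_long``   long member below 611 aa
    - ``bim_decoy_gap``      partner gene far beyond the gap limit
    """

    items: list[str]
    replicon_id: str = "synthrep"
    spacing: int = 800
    partner_famint: int = 45
    with_sequence: bool = False
    seed: int = 0


@dataclass
class SynthReplicon:
    replicon_id: str
    length: int
    features: list[GeneFeature]
    planted_elements: list[ElementCall]
    sequence: str | None = None


def _gene_len(product_aa: int) -> int:
    """CDS nucleotide length for a product of the given size (with stop)."""
    return 3 * (product_aa + 1)


def default_element_suite() -> ElementPlan:
    """Standard detection test-bed: 3 RITs, 2 Tn554-like tandems
    (with and without TnpC), 1 BIM and 6 single-rule-violation decoys."""
    return ElementPlan(
        items=[
            "rit",
            "tn554",
            "rit",
            "bim",
            "rit_decoy_strand",
            "tn554_no_tnpc",
            "rit_decoy_overlap",
            "rit",
            "rit_decoy_span",
            "tn554_decoy_strand",
            "tn554_decoy_long",
            "bim_decoy_gap",
        ]
    )


def generate_annotated_replicon(plan: ElementPlan) -> SynthReplicon:
    """Lay out planted elements and decoys left to right on one replicon."""
    if plan.spacing < 1:
        raise ValueError("element spacing must be positive (layout error)")
    rng = np.random.default_rng(plan.seed)
    features: list[GeneFeature] = []
    planted: list[ElementCall] = []
    cursor = plan.spacing
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"g{counter:03d}"

    def add(start: int, product_aa: int, strand: str, is_tbssr: bool,
            famint: int | None = None) -> GeneFeature:
        f = GeneFeature(
            replicon=plan.replicon_id,
            start=start,
            end=start + _gene_len(product_aa),
            strand=strand,
            id=new_id(),
            product_len=product_aa,
            is_tbssr=is_tbssr,
            famint=famint,
        )
        features.append(f)
        return f

    for kind in plan.items:
        start = cursor
        if kind.startswith("rit"):
            o1 = int(rng.integers(4, 9))
            o2 = int(rng.integers(4, 9))
            if kind == "rit_decoy_overlap":
                o1 = 12
            span_target = int(rng.integers(3350, 3651))
            if kind == "rit_decoy_span":
                # oversized genes keep every product outside the Tn554
                # length windows so this decoy fails exactly one rule
                span_target = 4200
                aa1 = int(rng.integers(440, 470))
                aa2 = int(rng.integers(440, 470))
            else:
                aa1 = int(rng.integers(360, 400))
                aa2 = int(rng.integers(360, 400))
            l1, l2 = _gene_len(aa1), _gene_len(aa2)
            l3 = span_target - l1 - l2 + o1 + o2
            l3 -= l3 % 3
            span = l1 + l2 + l3 - o1 - o2
            strands = ["+", "+", "+"]
            if kind == "rit_decoy_strand":
                strands[1] = "-"
            a = add(start, aa1, strands[0], True, famint=1)
            b = add(a.end - o1, aa2, strands[1], True, famint=5)
            c = add(b.end - o2, l3 // 3 - 1, strands[2], True, famint=2)
            if kind == "rit":
                planted.append(
                    ElementCall(
                        type="RIT",
                        members=[a.id, b.id, c.id],
                        replicon=plan.replicon_id,
                        span=span,
                        strand="+",
                        diagnostics={"overlap_AB": o1, "overlap_BC": o2,
                                     "span": span},
                    )
                )
            cursor = c.end + plan.spacing
        elif kind.startswith("tn554"):
            long_aa = int(rng.integers(611, 829))
            if kind == "tn554_decoy_long":
                long_aa = 500
            short_aa = int(rng.integers(300, 401))
            gap = int(rng.integers(20, 200))
            strands = ["+", "+"]
            if kind == "tn554_decoy_strand":
                strands[1] = "-"
            a = add(start, long_aa, strands[0], True, famint=27)
            b = add(a.end + gap, short_aa, strands[1], True, famint=33)
            members = [a.id, b.id]
            has_tnpc = False
            end = b.end
            if kind == "tn554":
                tnpc = add(b.end + int(rng.integers(20, 200)), 200, "+", False)
                members.append(tnpc.id)
                has_tnpc = True
                end = tnpc.end
            else:
                # keep any following gene out of TnpC range
                end = b.end
            if kind in ("tn554", "tn554_no_tnpc"):
                planted.append(
                    ElementCall(
                        type="Tn554_like",
                        members=members,
                        replicon=plan.replicon_id,
                        span=end - a.start,
                        strand="+",
                        has_tnpC=has_tnpc,
                        diagnostics={"long_aa": long_aa, "short_aa": short_aa,
                                     "gap": gap},
                    )
                )
            cursor = end + plan.spacing
        elif kind.startswith("bim"):
            gap = 1000 if kind == "bim_decoy_gap" else int(rng.integers(20, 250))
            a = add(start, 350, "+", True, famint=19)
            b = add(a.end + gap, 250, "+", False, famint=plan.partner_famint)
            if kind == "bim":
                planted.append(
                    ElementCall(
                        type="BIM",
                        members=[a.id, b.id],
                        replicon=plan.replicon_id,
                        span=b.end - a.start,
                        strand="+",
                        diagnostics={"gap": gap,
                                     "partner_famint": plan.partner_famint},
                    )
                )
            cursor = b.end + plan.spacing
        elif kind == "filler":
            f = add(start, int(rng.integers(150, 400)),
                    "+" if rng.integers(0, 2) else "-", False)
            cursor = f.end + plan.spacing
        else:
            raise ValueError(f"unknown plan item {kind!r}")
    features.sort(key=lambda f: (f.start, f.end))
    length = cursor
    sequence = None
    if plan.with_sequence:
        nts = "ACGT"
        sequence = "".join(
            nts[k] for k in rng.integers(0, 4, size=length)
        )
    return SynthReplicon(
        replicon_id=plan.replicon_id,
        length=length,
        features=features,
        planted_elements=planted,
        sequence=sequence,
    )
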