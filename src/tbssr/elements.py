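"""Rule-based detection of composite recombinase elements.

Three element architectures are recognised from gene geometry alone, so
the detectors work on a plain annotated replicon without prior protein
clustering:

RIT ("recombinases in trio")
    three adjacent, co-oriented recombinase genes whose open reading
    frames overlap by a few base pairs (4-8 bp), the whole element
    spanning about 3.5 kb.
Tn554-like tandem
    an abnormally long recombinase (611-828 aa, TnpA-like) next to a
    typical-size one (around 350 aa, TnpB-like) transcribed in the same
    direction, often followed by a third co-oriented accessory gene
    (TnpC).  The long member's N-terminal extension over a canonical
    recombinase is reported and flagged when it exceeds 400 aa.
BIM ("bipartite module")
    a recombinase gene adjacent to a member of a designated conserved
    partner family of unknown function.

A direct / inverted exact-repeat scanner supports the search for
element-boundary binding sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class GeneFeature:
    """A CDS on a replicon; coordinates 0-based half-open internally."""

    replicon: str
    start: int
    end: int
    strand: str
    id: str
    product_len: int = -1
    is_tbssr: bool = False
    famint: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"feature {self.id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.id}: strand must be + or -")
        if self.product_len < 0:
            self.product_len = (self.end - self.start) // 3 - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ElementRules:
    rit_overlap_range: tuple[int, int] = (4, 8)
    rit_span_range: tuple[int, int] = (3300, 3700)
    rit_require_same_strand: bool = True
    tn554_long_range: tuple[int, int] = (611, 828)
    tn554_short_range: tuple[int, int] = (275, 425)
    tn554_max_gap: int = 500
    tn554_require_same_strand: bool = True
    long_next_extension_min: int = 400
    bim_partner_max_gap: int = 300

    def __post_init__(self) -> None:
        for name in (
            "rit_overlap_range", "rit_span_range",
            "tn554_long_range", "tn554_short_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered")


@dataclass
class ElementCall:
    """One detected element with the diagnostics that justified it."""

    type: str  # RIT | Tn554_like | BIM
    members: list[str]
    replicon: str
    span: int
    strand: str
    diagnostics: dict = field(default_factory=dict)
    has_tnpC: bool = False
    conflict: bool = False


def _overlap(a: GeneFeature, b: GeneFeature) -> int:
    """Nucleotide-interval overlap, 0 when disjoint."""
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _gap(a: GeneFeature, b: GeneFeature) -> int:
    """Intergenic distance between two features in genomic order."""
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    return max(0, hi.start - lo.end)


def _check_sorted(features: list[GeneFeature]) -> None:
    for a, b in zip(features, features[1:]):
        if (a.replicon, a.start) > (b.replicon, b.start):
            raise ValueError("features must be sorted by (replicon, start)")


def _by_replicon(features: list[GeneFeature]) -> dict[str, list[GeneFeature]]:
    out: dict[str, list[GeneFeature]] = {}
    for f in features:
        out.setdefault(f.replicon, []).append(f)
    return out


def find_rit(
    features: list[GeneFeature], rules: ElementRules | None = None
) -> list[ElementCall]:
    """Detect RIT trios among consecutive recombinase genes.

    Every window of three consecutive features that are all
    recombinases, co-oriented (when required), with both pairwise
    overlaps inside ``rit_overlap_range`` and total span inside
    ``rit_span_range`` yields one call.  Members are labelled A/B/C in
    transcription order (genomic order on +, reversed on -).  Windows
    sharing a gene are all reported, flagged as conflicting.
    """
    rules = rules or ElementRules()
    _check_sorted(features)
    calls: list[ElementCall] = []
    for rep, feats in _by_replicon(features).items():
        for k in range(len(feats) - 2):
            a, b, c = feats[k], feats[k + 1], feats[k + 2]
            if not (a.is_tbssr and b.is_tbssr and c.is_tbssr):
                continue
            if rules.rit_require_same_strand and not (
                a.strand == b.strand == c.strand
            ):
                continue
            o1, o2 = _overlap(a, b), _overlap(b, c)
            lo, hi = rules.rit_overlap_range
            if not (lo <= o1 <= hi and lo <= o2 <= hi):
                continue
            span = max(f.end for f in (a, b, c)) - min(f.start for f in (a, b, c))
            slo, shi = rules.rit_span_range
            if not (slo <= span <= shi):
                continue
            ordered = [a, b, c] if a.strand == "+" else [c, b, a]
            calls.append(
                ElementCall(
                    type="RIT",
                    members=[f.id for f in ordered],
                    replicon=rep,
                    span=span,
                    strand=a.strand,
                    diagnostics={
                        "overlap_AB": o1,
                        "overlap_BC": o2,
                        "span": span,
                    },
                )
            )
    seen: dict[str, int] = {}
    for i, call in enumerate(calls):
        for m in call.members:
            if m in seen:
                call.conflict = True
                calls[seen[m]].conflict = True
            seen[m] = i
    return calls


def find_tn554_like(
    features: list[GeneFeature], rules: ElementRules | None = None
) -> list[ElementCall]:
    """Detect Tn554-like long+short recombinase tandems.

    Adjacent co-oriented recombinase pairs with one product in the long
    range and one in the short range and an intergenic gap within
    ``tn554_max_gap`` are called; the next co-oriented non-recombinase
    gene downstream (in transcription direction) within the same gap
    limit is attached as putative TnpC.
    """
    rules = rules or ElementRules()
    _check_sorted(features)
    calls: list[ElementCall] = []
    llo, lhi = rules.tn554_long_range
    slo, shi = rules.tn554_short_range
    for rep, feats in _by_replicon(features).items():
        for k in range(len(feats) - 1):
            a, b = feats[k], feats[k + 1]
            if not (a.is_tbssr and b.is_tbssr):
                continue
            if rules.tn554_require_same_strand and a.strand != b.strand:
                continue
            la, lb = a.product_len, b.product_len
            pair_ok = (llo <= la <= lhi and slo <= lb <= shi) or (
                llo <= lb <= lhi and slo <= la <= shi
            )
            if not pair_ok:
                continue
            if _gap(a, b) > rules.tn554_max_gap:
                continue
            long_f = a if llo <= la <= lhi else b
            members = [a.id, b.id]
            has_tnpc = False
            tnpc_id = None
            # downstream in transcription direction
            if a.strand == "+":
                nxt = feats[k + 2] if k + 2 < len(feats) else None
                edge = b
            else:
                nxt = feats[k - 1] if k - 1 >= 0 else None
                edge = a
            if (
                nxt is not None
                and not nxt.is_tbssr
                and nxt.strand == a.strand
                and _gap(edge, nxt) <= rules.tn554_max_gap
            ):
                has_tnpc = True
                tnpc_id = nxt.id
                members.append(nxt.id)
            span_feats = [a, b] + ([nxt] if has_tnpc else [])
            span = max(f.end for f in span_feats) - min(f.start for f in span_feats)
            ext = long_f.product_len - 350
            calls.append(
                ElementCall(
                    type="Tn554_like",
                    members=members,
                    replicon=rep,
                    span=span,
                    strand=a.strand,
                    has_tnpC=has_tnpc,
                    diagnostics={
                        "long_aa": long_f.product_len,
                        "short_aa": (b if long_f is a else a).product_len,
                        "gap": _gap(a, b),
                        "tnpC_id": tnpc_id,
                        "n_extension_aa": ext,
                        "n_extension_flag": ext >= rules.long_next_extension_min,
                    },
                )
            )
    return calls


def find_bim(
    features: list[GeneFeature],
    partner_famint: int | None,
    rules: ElementRules | None = None,
) -> list[ElementCall]:
    """Detect BIM pairs: a recombinase next to a partner-family gene."""
    rules = rules or ElementRules()
    if partner_famint is None:
        raise ValueError("BIM detection requires a designated partner family")
    _check_sorted(features)
    calls: list[ElementCall] = []
    for rep, feats in _by_replicon(features).items():
        for k in range(len(feats) - 1):
            a, b = feats[k], feats[k + 1]
            pair = None
            if a.is_tbssr and b.famint == partner_famint and not b.is_tbssr:
                pair = (a, b)
            elif b.is_tbssr and a.famint == partner_famint and not a.is_tbssr:
                pair = (b, a)
            if pair is None:
                continue
            if _gap(a, b) > rules.bim_partner_max_gap:
                continue
            span = max(a.end, b.end) - min(a.start, b.start)
            calls.append(
                ElementCall(
                    type="BIM",
                    members=[pair[0].id, pair[1].id],
                    replicon=rep,
                    span=span,
                    strand=pair[0].strand,
                    diagnostics={"gap": _gap(a, b), "partner_famint": partner_famint},
                )
            )
    return calls


def validate_call(call: ElementCall, rules: ElementRules | None = None) -> bool:
    """Re-check a call's diagnostics against the rules (self-consistency)."""
    rules = rules or ElementRules()
    d = call.diagnostics
    if call.type == "RIT":
        lo, hi = rules.rit_overlap_range
        slo, shi = rules.rit_span_range
        return (
            lo <= d["overlap_AB"] <= hi
            and lo <= d["overlap_BC"] <= hi
            and slo <= d["span"] <= shi
        )
    if call.type == "Tn554_like":
        llo, lhi = rules.tn554_long_range
        slo, shi = rules.tn554_short_range
        return (
            llo <= d["long_aa"] <= lhi
            and slo <= d["short_aa"] <= shi
            and d["gap"] <= rules.tn554_max_gap
        )
    if call.type == "BIM":
        return d["gap"] <= rules.bim_partner_max_gap
    raise ValueError(f"unknown element type {call.type!r}")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def mirror_features(
    features: list[GeneFeature], replicon_length: int
) -> list[GeneFeature]:
    """Coordinates of all features after reverse-complementing a replicon."""
    out = [
        GeneFeature(
            replicon=f.replicon,
            start=replicon_length - f.end,
            end=replicon_length - f.start,
            strand="-" if f.strand == "+" else "+",
            id=f.id,
            product_len=f.product_len,
            is_tbssr=f.is_tbssr,
            famint=f.famint,
        )
        for f in features
    ]
    return sorted(out, key=lambda f: (f.replicon, f.start))


@dataclass
class RepeatHit:
    type: str  # direct | inverted
    pos1: int
    pos2: int
    length: int
    low_complexity: bool = False


def _is_low_complexity(segment: str) -> bool:
    if not segment:
        return True
    top = max(segment.count(b) for b in set(segment))
    return top / len(segment) >= 0.9


def scan_repeats(
    sequence: str,
    min_len: int = 9,
    max_window: int = 600,
    include_low_complexity: bool = False,
) -> list[RepeatHit]:
    """Exact maximal direct and inverted repeats within a window.

    Both copies must start within ``max_window`` of each other.  Seeds
    of length ``min_len`` are extended maximally in both directions and
    de-duplicated, so only non-extendable repeats are reported.  Near
    homopolymeric hits are flagged as low-complexity and dropped unless
    requested.
    """
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotides {sorted(bad)}")
    n = len(seq)
    k = min_len
    if n < 2 * k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)

    found: set[tuple[str, int, int, int]] = set()

    def add_direct(p: int, q: int) -> None:
        length = k
        while p > 0 and q > p and seq[p - 1] == seq[q - 1]:
            p -= 1
            q -= 1
            length += 1
        while q + length < n and seq[p + length] == seq[q + length]:
            length += 1
        if length >= min_len and q - p <= max_window:
            found.add(("direct", p, q, length))

    def add_inverted(p: int, q: int, length: int) -> None:
        # seq[q:q+length] == revcomp(seq[p:p+length]); extend outward
        comp = _COMPLEMENT
        while p > 0 and q + length < n and seq[p - 1] == seq[q + length].translate(comp):
            p -= 1
            length += 1
        while p + length <= q - 1 and seq[p + length] == seq[q - 1].translate(comp):
            q -= 1
            length += 1
        if length >= min_len and q - p <= max_window:
            found.add(("inverted", p, q, length))

    for kmer, positions in index.items():
        if len(positions) > 1:
            for a_i in range(len(positions) - 1):
                for b_i in range(a_i + 1, len(positions)):
                    p, q = positions[a_i], positions[b_i]
                    if q - p <= max_window:
                        add_direct(p, q)
        rc = reverse_complement(kmer)
        for q in index.get(rc, []):
            for p in positions:
                if p < q and q - p <= max_window:
                    add_inverted(p, q, k)

    hits = [
        RepeatHit(t, p, q, length, _is_low_complexity(seq[p : p + length]))
        for (t, p, q, length) in sorted(found)
    ]
    # drop seeds subsumed by a longer repeat at the same diagonal
    maximal: list[RepeatHit] = []
    for h in hits:
        subsumed = False
        for g in hits:
            if g is h or g.type != h.type or g.length <= h.length:
                continue
            if (
                g.pos1 <= h.pos1
                and h.pos1 + h.length <= g.pos1 + g.length
                and g.pos2 <= h.pos2 + (g.length - h.length)
                and g.pos2 + g.length >= h.pos2 + h.length
            ):
                subsumed = True
                break
        if not subsumed:
            maximal.append(h)
    if include_low_complexity:
        return maximal
    return [h for h in maximal if not h.low_complexity]
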