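"""Core protein record container shared by all stages."""

from __future__ import annotations

from dataclasses import dataclass, field

#: MGE classes of origin tracked per protein. "unknown" is accepted on input
#: for proteins whose genetic context is unresolved.
MGE_TYPES = ("phage", "prophage", "plasmid", "GI", "ICE", "RIT", "BIM", "unknown")

#: 20 standard amino acids plus X for ambiguous residues.
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
AA_ALPHABET_X = AA_ALPHABET + "X"


@dataclass
class ProteinRecord:
    """One TBSSR sequence with its MGE-type, host and replicon metadata.

    Parameters
    ----------
    id : str
        Unique identifier; first whitespace-free token of a FASTA header.
    sequence : str
        Amino-acid sequence over the 20-letter alphabet plus ``X``.
    mge_type : str
        MGE class of origin (one of :data:`MGE_TYPES`).
    host : str
        Free-text host organism, conventionally "Genus species strain".
    replicon : str
        Replicon of origin (plasmid / chromosome / phage genome name).
    """

    id: str
    sequence: str
    mge_type: str = "unknown"
    host: str = ""
    replicon: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(AA_ALPHABET_X)
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residues {sorted(bad)!r}"
            )
        if self.mge_type not in MGE_TYPES:
            raise ValueError(
                f"protein {self.id!r}: unknown MGE type {self.mge_type!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)
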