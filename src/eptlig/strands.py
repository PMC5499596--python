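"""Strand definitions for the nicked-duplex ligation system.

The system comprises three oligonucleotides: a donor strand bearing an
electrophilic phosphorothioester (EPT) end, an acceptor strand bearing a
nucleophilic amino end, and a template to which both hybridize adjacently,
leaving a nick between the donor's reactive end and the acceptor's amine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .errors import AlphabetError, ConfigurationError

DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")

#: Recognised end chemistries. ``PS`` is the unactivated phosphorothioate
#: precursor, ``EPT`` the activated electrophile, ``NH2`` the amine.
END_CHEMISTRIES = (
    "none",
    "PS_5p",
    "PS_3p",
    "EPT_5p",
    "EPT_3p",
    "NH2_5p",
    "NH2_3p",
)

ROLES = ("donor", "acceptor", "template")

_REACTIVE = {"EPT_5p", "EPT_3p", "NH2_5p", "NH2_3p", "PS_5p", "PS_3p"}


@dataclass(frozen=True)
class Strand:
    """A single oligonucleotide with an optional reactive end.

    Parameters
    ----------
    id : str
        Identifier (used as the FASTA record id).
    sequence : str
        5'->3' sequence over ``{A,C,G,T}`` (DNA) or ``{A,C,G,U}`` (RNA).
    role : str
        One of ``donor`` (EPT strand), ``acceptor`` (amino strand) or
        ``template``.
    end_chem : str
        End chemistry tag; templates must carry ``none``.
    label : str or None
        Optional fluorophore tag (e.g. ``FAM_3p``); annotation only.
    two_prime_ome : tuple of int
        0-based residue indices carrying a 2'-O-methyl modification.
    """

    id: str
    sequence: str
    role: str = "template"
    end_chem: str = "none"
    label: str | None = None
    two_prime_ome: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        letters = set(seq)
        if not seq:
            raise AlphabetError(f"strand {self.id!r}: empty sequence")
        if not (letters <= DNA_ALPHABET or letters <= RNA_ALPHABET):
            bad = sorted(letters - (DNA_ALPHABET | RNA_ALPHABET))
            raise AlphabetError(
                f"strand {self.id!r}: characters {bad} outside the DNA/RNA alphabet"
            )
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown role {self.role!r}")
        if self.end_chem not in END_CHEMISTRIES:
            raise ConfigurationError(f"unknown end chemistry {self.end_chem!r}")
        self._check_role_chemistry()

    def _check_role_chemistry(self):
        if self.role == "template" and self.end_chem in _REACTIVE:
            raise ConfigurationError(
                f"template strand {self.id!r} cannot carry reactive end {self.end_chem!r}"
            )
        if self.role == "donor" and not self.end_chem.startswith(("EPT", "PS")):
            raise ConfigurationError(
                f"donor strand {self.id!r} must carry an EPT (or PS precursor) end"
            )
        if self.role == "acceptor" and not self.end_chem.startswith("NH2"):
            raise ConfigurationError(
                f"acceptor strand {self.id!r} must carry an amino end"
            )

    @property
    def is_rna(self) -> bool:
        return "U" in self.sequence

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> str:
        """5'->3' reverse complement of the sequence (same alphabet)."""
        seq = Seq(self.sequence)
        rc = seq.reverse_complement_rna() if self.is_rna else seq.reverse_complement()
        return str(rc)


def reverse_complement(sequence: str, rna: bool = False) -> str:
    """Reverse complement of a bare sequence string (5'->3' in, 5'->3' out)."""
    seq = Seq(sequence.upper())
    return str(seq.reverse_complement_rna() if rna else seq.reverse_complement())
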