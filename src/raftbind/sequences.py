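"""Tau-K18 sequence construction, mutation, charge and hydropathy analysis.

K18 is the 130-residue microtubule-binding fragment of human tau
(2N4R numbering 243-372) spanning the four imperfect repeats R1-R4.
The membrane-binding-deficient variant (MBD-K18) carries the three
hydrophobic-to-glutamate substitutions V287E, I308E and V318E.

Sequences are carried with their absolute (2N4R) numbering so that
mutation specs written in the field's convention (``V287E``) apply
directly.  Formal charges use a fixed side-chain-only model: Lys/Arg
+1, Asp/Glu -1, His and termini neutral - the convention under which
WT-K18 counts (+21, -11) and MBD-K18 (+21, -14).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: side-chain formal charges at neutral pH; His treated as neutral,
#: termini uncharged.
SIDE_CHAIN_CHARGE: Mapping[str, int] = {"K": +1, "R": +1, "D": -1, "E": -1}

K18_OFFSET = 243
K18_LENGTH = 130

#: canonical 2N4R tau repeat boundaries (inclusive absolute ranges)
REPEAT_BOUNDS: Mapping[str, tuple[int, int]] = {
    "R1": (244, 274),
    "R2": (275, 305),
    "R3": (306, 336),
    "R4": (337, 368),
}

MBD_MUTATIONS = ("V287E", "I308E", "V318E")

_MUT_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class MutationError(ValueError):
    """Raised when a mutation spec does not match the sequence."""


@dataclass(frozen=True)
class MutationSpec:
    """A point substitution in absolute (2N4R) numbering, e.g. V287E."""

    wild_residue: str
    absolute_position: int
    mutant_residue: str

    def __post_init__(self) -> None:
        for aa in (self.wild_residue, self.mutant_residue):
            if aa not in AMINO_ACIDS:
                raise MutationError(f"unknown amino-acid code {aa!r}")

    @classmethod
    def parse(cls, token: str) -> "MutationSpec":
        m = _MUT_RE.match(token.strip().upper())
        if not m:
            raise MutationError(f"cannot parse mutation token {token!r}")
        return cls(m.group(1), int(m.group(2)), m.group(3))

    def __str__(self) -> str:  # round-trips through parse()
        return f"{self.wild_residue}{self.absolute_position}{self.mutant_residue}"


@dataclass(frozen=True)
class PeptideSequence:
    """An amino-acid sequence with absolute numbering.

    ``numbering_offset`` is the absolute position of the first residue
    (243 for K18), so residue ``i`` (0-based) sits at absolute position
    ``numbering_offset + i``.
    """

    residues: str
    numbering_offset: int = 1
    chain_id: str = "A"

    def __post_init__(self) -> None:
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-standard residue codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def absolute_range(self) -> tuple[int, int]:
        """Inclusive (first, last) absolute positions."""
        return self.numbering_offset, self.numbering_offset + len(self.residues) - 1

    def at(self, absolute_position: int) -> str:
        """Residue code at an absolute position."""
        i = absolute_position - self.numbering_offset
        if not 0 <= i < len(self.residues):
            raise IndexError(
                f"position {absolute_position} outside "
                f"{self.absolute_range()}"
            )
        return self.residues[i]

    def local_index(self, absolute_position: int) -> int:
        """1-based index within the chain (position 287 of K18 -> 45)."""
        self.at(absolute_position)  # bounds check
        return absolute_position - self.numbering_offset + 1


@dataclass(frozen=True)
class ChargeSummary:
    """Formal charge bookkeeping in elementary charges."""

    positive_count: int
    negative_count: int  # <= 0

    @property
    def net(self) -> int:
        return self.positive_count + self.negative_count


@dataclass(frozen=True)
class HydropathyProfile:
    """Window-averaged Kyte-Doolittle hydropathy, one value per residue.

    Positions whose centered window was truncated at a terminus are
    flagged in ``edge``.
    """

    values: tuple[float, ...]
    window: int
    numbering_offset: int
    edge: tuple[bool, ...] = field(repr=False, default=())

    def value_at(self, absolute_position: int) -> float:
        return self.values[absolute_position - self.numbering_offset]


def load_k18_reference() -> PeptideSequence:
    """Load the packaged wild-type K18 sequence (2N4R 243-372)."""
    with resources.files("raftbind.data").joinpath("k18_wt.fasta").open() as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    return PeptideSequence(str(record.seq), numbering_offset=K18_OFFSET)


def build_k18(variant: str = "wild_type") -> PeptideSequence:
    """Build the WT-K18 or MBD-K18 sequence.

    Parameters
    ----------
    variant:
        ``"wild_type"`` for WT-K18 or ``"mbd"`` for the
        membrane-binding-deficient triple mutant (V287E, I308E, V318E).
    """
    wt = load_k18_reference()
    if variant == "wild_type":
        return wt
    if variant == "mbd":
        return apply_mutations(wt, [MutationSpec.parse(t) for t in MBD_MUTATIONS])
    raise ValueError(f"unknown K18 variant {variant!r} (use 'wild_type' or 'mbd')")


def apply_mutations(
    seq: PeptideSequence, specs: Iterable[MutationSpec]
) -> PeptideSequence:
    """Apply point mutations, validating each wild residue.

    Raises :class:`MutationError` if a spec's wild residue does not
    match the sequence at that absolute position (this also makes
    double application of the same spec fail loudly).
    """
    residues = list(seq.residues)
    for spec in specs:
        seq.at(spec.absolute_position)  # bounds check, raises IndexError
        i = spec.absolute_position - seq.numbering_offset
        if residues[i] != spec.wild_residue:
            raise MutationError(
                f"{spec}: expected {spec.wild_residue} at "
                f"{spec.absolute_position}, found {residues[i]}"
            )
        residues[i] = spec.mutant_residue
    return PeptideSequence("".join(residues), seq.numbering_offset, seq.chain_id)


def formal_charges(seq: PeptideSequence | str) -> ChargeSummary:
    """Count formal side-chain charges (K/R +1, D/E -1, His neutral).

    Termini are uncharged; including them would shift the counts to
    (+1, -1) but leave the net unchanged.  Additive over concatenation.
    """
    residues = seq.residues if isinstance(seq, PeptideSequence) else seq
    pos = sum(1 for aa in residues if SIDE_CHAIN_CHARGE.get(aa, 0) > 0)
    neg = sum(1 for aa in residues if SIDE_CHAIN_CHARGE.get(aa, 0) < 0)
    return ChargeSummary(positive_count=pos, negative_count=-neg)


def hydropathy_profile(seq: PeptideSequence, window: int = 5) -> HydropathyProfile:
    """Kyte-Doolittle hydropathy smoothed by a centered moving average.

    The window must be odd; at the termini the window is truncated to
    the available positions (keeping the profile the same length as
    the sequence) and those positions are flagged as edges.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window > len(seq):
        raise ValueError("window exceeds sequence length")
    raw = [KYTE_DOOLITTLE[aa] for aa in seq.residues]
    half = window // 2
    n = len(raw)
    values = []
    edge = []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        values.append(sum(raw[lo:hi]) / (hi - lo))
        edge.append(hi - lo < window)
    return HydropathyProfile(
        tuple(values), window, seq.numbering_offset, tuple(edge)
    )


def repeat_annotation(seq: PeptideSequence) -> dict[int, str]:
    """Map each absolute position to its tau repeat (R1-R4) or flank.

    Positions before R1 are labelled ``"N-terminal"``; positions after
    R4, ``"C-terminal"``.  Requires the sequence to span the full
    243-372 fragment.
    """
    first, last = seq.absolute_range()
    if first > K18_OFFSET or last < K18_OFFSET + K18_LENGTH - 1:
        raise ValueError(
            f"sequence {first}-{last} does not cover the K18 span "
            f"{K18_OFFSET}-{K18_OFFSET + K18_LENGTH - 1}"
        )
    labels: dict[int, str] = {}
    for pos in range(first, last + 1):
        label = None
        for name, (lo, hi) in REPEAT_BOUNDS.items():
            if lo <= pos <= hi:
                label = name
                break
        if label is None:
            label = "N-terminal" if pos < REPEAT_BOUNDS["R1"][0] else "C-terminal"
        labels[pos] = label
    return labels


def repeat_context(seq: PeptideSequence, absolute_position: int) -> str:
    """Describe where a position falls within its repeat.

    Returns e.g. ``"R2 (middle)"``: the repeat is split into thirds
    (start / middle / end) so mutation sites can be situated the way
    the field describes them (V287E mid-R2; I308E near the start of R3).
    """
    label = repeat_annotation(seq)[absolute_position]
    if label not in REPEAT_BOUNDS:
        return label
    lo, hi = REPEAT_BOUNDS[label]
    frac = (absolute_position - lo) / (hi - lo)
    third = "start" if frac < 1 / 3 else ("middle" if frac < 2 / 3 else "end")
    return f"{label} ({third})"


def accumulated_index(chain_index: int, local_index: int, chain_length: int = K18_LENGTH) -> int:
    """Accumulated residue number across oligomer chains (1-based).

    Chain A local residue 66 -> 66; chain B local 66 -> 196; chain D
    local 76 -> 466, with contiguous 130-residue blocks per chain.
    """
    if not 1 <= local_index <= chain_length:
        raise ValueError(f"local index {local_index} outside 1..{chain_length}")
    if chain_index < 0:
        raise ValueError("chain_index is 0-based and must be >= 0")
    return chain_index * chain_length + local_index
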