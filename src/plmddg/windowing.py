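"""Fixed-length, mutation-centered sequence windows.

Windows are aligned so that the mutated residue occupies the exact
center; positions that fall outside the chain are filled with the
padding symbol "X".  The window length L must therefore be odd.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .dataset import AMINO_ACIDS, PAD_SYMBOL, MutationRecord
from .errors import ConfigurationError, LookupError_, PositionRangeError, UsageError


@dataclass(frozen=True)
class SequenceWindow:
    """A mutation-centered residue string of odd length L.

    ``residues[center_offset]`` is the residue at the mutation site and is
    never the padding symbol; all real residues form one contiguous block
    containing the center.
    """

    residues: str
    source: tuple[str, str, int]  # (complex_id, chain, 1-based position)
    variant: str = "wildtype"  # or "mutant"

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def center_offset(self) -> int:
        return (len(self.residues) - 1) // 2

    @property
    def center_residue(self) -> str:
        return self.residues[self.center_offset]

    @property
    def n_valid(self) -> int:
        """Number of real (non-padding) residues."""
        return sum(c != PAD_SYMBOL for c in self.residues)

    def to_fasta(self) -> str:
        cid, chain, pos = self.source
        return f">{cid}_{chain}_{pos}_{self.variant}\n{self.residues}\n"


def extract_window(sequence: str, position: int, length: int) -> SequenceWindow:
    """Extract the wild-type window of odd ``length`` centered at the
    1-based ``position``, padding with "X" wherever the chain runs out.
    """
    if length < 1 or length % 2 == 0:
        raise ConfigurationError(f"window length must be odd and >= 1, got {length}")
    if not 1 <= position <= len(sequence):
        raise PositionRangeError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    half = (length - 1) // 2
    p = position - 1
    chars = []
    for j in range(p - half, p + half + 1):
        chars.append(sequence[j] if 0 <= j < len(sequence) else PAD_SYMBOL)
    return SequenceWindow("".join(chars), source=("", "", position))


def apply_mutation(window: SequenceWindow, mut_aa: str) -> SequenceWindow:
    """Return the mutant window: identical except at the center residue."""
    if window.variant != "wildtype":
        raise UsageError("apply_mutation expects a wildtype window")
    if mut_aa == PAD_SYMBOL or mut_aa not in AMINO_ACIDS:
        raise ConfigurationError(f"invalid mutant residue {mut_aa!r}")
    if mut_aa == window.center_residue:
        raise UsageError(
            f"mutant residue {mut_aa!r} equals the current center residue"
        )
    return replace(window, residues=_with_center(window.residues, mut_aa),
                   variant="mutant")


def _with_center(residues: str, aa: str) -> str:
    c = (len(residues) - 1) // 2
    return residues[:c] + aa + residues[c + 1:]


def window_batch(
    records: Sequence[MutationRecord],
    sequences: Mapping[str, str],
    length: int,
) -> list[tuple[SequenceWindow, SequenceWindow]]:
    """Build (wildtype, mutant) window pairs for every record.

    The chain sequences are the *original* (pre-mutation) chains, so for a
    reverse record the residue found at the site is the record's mutant:
    its wildtype window is obtained by substituting the record's wt_aa at
    the center — i.e. a reverse record's wildtype window equals its forward
    partner's mutant window.
    """
    out = []
    for rec in records:
        seq = sequences.get(rec.chain_key)
        if seq is None:
            raise LookupError_(
                f"no sequence for {rec.chain_key} (record {rec.mutation_name})"
            )
        raw = extract_window(seq, rec.position, length)
        raw = replace(raw, source=(rec.complex_id, rec.chain, rec.position))
        wt = raw if raw.center_residue == rec.wt_aa else replace(
            raw, residues=_with_center(raw.residues, rec.wt_aa)
        )
        mut = replace(
            wt, residues=_with_center(wt.residues, rec.mut_aa), variant="mutant"
        )
        out.append((wt, mut))
    return out
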