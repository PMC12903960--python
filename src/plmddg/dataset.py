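"""Mutation tables: parsing, validation, augmentation, folds, summaries.

A *mutation record* describes one missense mutation in a protein--DNA
complex together with its experimental binding free-energy change
ddG = dG(mutant) - dG(wildtype) in kcal/mol (positive = destabilizing
binding).  Records carry a binding-class label (DSB = double-stranded,
SSB = single-stranded DNA-binding protein) and a train/independent
partition label; both are inputs, not inferences.

Reverse augmentation exploits the thermodynamic antisymmetry
ddG(wt->mut) = -ddG(mut->wt): every forward record gains a mirror record
with swapped residues and negated label, balancing the label
distribution around zero.
"""

from __future__ import annotations

import csv
import json
import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import (
    ConfigurationError,
    PositionRangeError,
    RecordValueError,
    SequenceMismatchError,
    TableFormatError,
    UsageError,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD_SYMBOL = "X"
ALPHABET = AMINO_ACIDS + PAD_SYMBOL  # 21 symbols

BINDING_CLASSES = ("DSB", "SSB")
PARTITIONS = ("train", "independent")

#: canonical column names of a mutation table
CANONICAL_COLUMNS = (
    "complex_id",
    "chain",
    "wt_aa",
    "position",
    "mut_aa",
    "ddg",
    "binding_class",
    "partition",
)


@dataclass(frozen=True)
class MutationRecord:
    """One missense mutation with its ddG label.

    ``position`` is a 1-based index into the supplied chain sequence;
    mapping from author (PDB) numbering to sequence index is the data
    preparer's responsibility — this module only checks that ``wt_aa``
    matches the sequence at ``position``.
    """

    complex_id: str
    chain: str
    wt_aa: str
    position: int
    mut_aa: str
    ddg: float
    binding_class: str
    partition: str
    is_reverse: bool = False
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if self.wt_aa not in AMINO_ACIDS:
            raise RecordValueError(f"unknown wild-type residue {self.wt_aa!r}")
        if self.mut_aa not in AMINO_ACIDS:
            raise RecordValueError(f"unknown mutant residue {self.mut_aa!r}")
        if self.wt_aa == self.mut_aa:
            raise RecordValueError(
                f"wild-type and mutant residue are both {self.wt_aa!r}"
            )
        if self.position < 1:
            raise RecordValueError(f"position must be >= 1, got {self.position}")
        if self.binding_class not in BINDING_CLASSES:
            raise RecordValueError(
                f"unknown binding class {self.binding_class!r}; "
                f"expected one of {BINDING_CLASSES}"
            )
        if self.partition not in PARTITIONS:
            raise RecordValueError(
                f"unknown partition {self.partition!r}; expected one of {PARTITIONS}"
            )

    @property
    def chain_key(self) -> str:
        return f"{self.complex_id}_{self.chain}"

    @property
    def site_key(self) -> tuple:
        """Key shared by a forward record and its reverse partner."""
        lo, hi = sorted((self.wt_aa, self.mut_aa))
        return (self.complex_id, self.chain, self.position, lo, hi)

    @property
    def mutation_name(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass
class DatasetSummary:
    """Descriptive statistics over the forward records of a dataset."""

    n_records: int
    n_complexes: int
    mean_ddg: float
    per_wt_mean_ddg: dict[str, float]
    mutant_aa_frequency: dict[str, float]
    flank_aa_frequency: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# parsing


def _sniff_delimiter(path: Path) -> str:
    text = path.read_text().splitlines()[0]
    if "\t" in text:
        return "\t"
    return ","


def read_mutation_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> list[MutationRecord]:
    """Read a delimited mutation table into validated records.

    ``dialect`` maps canonical field names to the file's column names
    (identity by default).  Row order is preserved; every record is read
    with ``is_reverse=False``.  Duplicate (complex, chain, position,
    mutation) rows are kept but flagged ``is_duplicate=True``.
    """
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"mutation table not found: {path}")
    delimiter = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    mapping = {name: name for name in CANONICAL_COLUMNS}
    if dialect:
        mapping.update(dialect)
    missing = [c for c, src in mapping.items() if src not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s) "
            f"{[mapping[c] for c in missing]} (have {list(df.columns)})"
        )

    records: list[MutationRecord] = []
    seen: dict[tuple, int] = {}
    for i in range(len(df)):
        raw = {c: df.iloc[i][mapping[c]] for c in CANONICAL_COLUMNS}
        i = i + 2  # human row number: 1-based with header row first
        try:
            ddg = float(raw["ddg"])
        except (TypeError, ValueError):
            raise RecordValueError(
                f"{path} row {i}: non-numeric ddG value {raw['ddg']!r}"
            ) from None
        try:
            position = int(raw["position"])
        except (TypeError, ValueError):
            raise RecordValueError(
                f"{path} row {i}: non-integer position {raw['position']!r}"
            ) from None
        try:
            rec = MutationRecord(
                complex_id=str(raw["complex_id"]).strip(),
                chain=str(raw["chain"]).strip(),
                wt_aa=str(raw["wt_aa"]).strip(),
                position=position,
                mut_aa=str(raw["mut_aa"]).strip(),
                ddg=ddg,
                binding_class=str(raw["binding_class"]).strip(),
                partition=str(raw["partition"]).strip(),
            )
        except RecordValueError as exc:
            raise RecordValueError(f"{path} row {i}: {exc}") from None
        key = (rec.complex_id, rec.chain, rec.position, rec.wt_aa, rec.mut_aa)
        if key in seen:
            rec = replace(rec, is_duplicate=True)
        else:
            seen[key] = i
        records.append(rec)
    return records


def write_mutation_table(records: Sequence[MutationRecord], path: str | Path) -> None:
    """Write records as a TSV with the canonical columns plus flags."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(list(CANONICAL_COLUMNS) + ["is_reverse"])
        for r in records:
            writer.writerow(
                [r.complex_id, r.chain, r.wt_aa, r.position, r.mut_aa,
                 repr(r.ddg), r.binding_class, r.partition, int(r.is_reverse)]
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read chain sequences keyed ``<complex_id>_<chain>``.

    Non-standard residue letters are normalized to the padding symbol "X"
    (the one normalization rule this package applies to input sequences).
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        seqs[rec.id] = "".join(c if c in AMINO_ACIDS else PAD_SYMBOL for c in s)
    return seqs


# ---------------------------------------------------------------------------
# validation


def validate_against_sequence(record: MutationRecord, sequence: str) -> MutationRecord:
    """Check that ``sequence[position]`` (1-based) is the record's wild-type
    residue; returns the record unchanged on success.

    For a reverse record the residue present in the *original* chain is the
    record's ``mut_aa`` (the mutation has been flipped), so that is what is
    checked instead.
    """
    if not sequence:
        raise PositionRangeError("empty sequence")
    if not 1 <= record.position <= len(sequence):
        raise PositionRangeError(
            f"{record.complex_id}_{record.chain} {record.mutation_name}: "
            f"position {record.position} outside sequence of length {len(sequence)}"
        )
    expected = record.mut_aa if record.is_reverse else record.wt_aa
    found = sequence[record.position - 1]
    if found != expected:
        raise SequenceMismatchError(
            f"{record.complex_id}_{record.chain} position {record.position}: "
            f"expected {expected}, found {found}"
        )
    return record


def validate_records(
    records: Sequence[MutationRecord], sequences: Mapping[str, str]
) -> list[MutationRecord]:
    """Validate every record against its chain sequence."""
    out = []
    for rec in records:
        if rec.chain_key not in sequences:
            raise SequenceMismatchError(
                f"no sequence for {rec.chain_key} (record {rec.mutation_name})"
            )
        out.append(validate_against_sequence(rec, sequences[rec.chain_key]))
    return out


# ---------------------------------------------------------------------------
# augmentation


def reverse_augment(records: Sequence[MutationRecord]) -> list[MutationRecord]:
    """Append, for every forward record, its reverse mutation with negated
    ddG (``is_reverse=True``).  Output = forwards in input order followed by
    reverses in the same order; pairwise label sums are exactly zero.
    """
    if any(r.is_reverse for r in records):
        raise UsageError(
            "input already contains reverse records; augmenting twice is forbidden"
        )
    reverses = [
        replace(r, wt_aa=r.mut_aa, mut_aa=r.wt_aa, ddg=-r.ddg, is_reverse=True)
        for r in records
    ]
    return list(records) + reverses


# ---------------------------------------------------------------------------
# cross-validation folds


def split_folds(
    records: Sequence[MutationRecord],
    k: int,
    seed: int,
    pairing: str = "pairwise",
) -> np.ndarray:
    """Assign each record a fold index in [0, k).

    Grouping unit depends on ``pairing``: ``pairwise`` keeps a forward
    record and its reverse in one fold (and co-assigns duplicates of the
    same site), ``by_complex`` keeps whole complexes together, ``none``
    treats every record independently.  Groups are shuffled with ``seed``
    and dealt round-robin, so group counts per fold differ by at most one.
    """
    if k < 2:
        raise ConfigurationError(f"k must be >= 2, got {k}")
    if not records:
        raise ConfigurationError("cannot split an empty record collection")
    if pairing == "pairwise":
        keys = [r.site_key for r in records]
    elif pairing == "by_complex":
        keys = [r.complex_id for r in records]
    elif pairing == "none":
        keys = list(range(len(records)))
    else:
        raise ConfigurationError(f"unknown pairing mode {pairing!r}")

    groups: dict = {}
    for key in keys:
        if key not in groups:
            groups[key] = len(groups)
    n_groups = len(groups)
    if k > n_groups:
        raise ConfigurationError(
            f"k={k} exceeds the {n_groups} grouping unit(s) under {pairing!r}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_groups)
    group_fold = {g: int(order[g] % k) for g in range(n_groups)}
    # order[g] % k deals shuffled groups cyclically: fold sizes differ <= 1
    return np.array([group_fold[groups[key]] for key in keys], dtype=int)


# ---------------------------------------------------------------------------
# summaries


def summarize(
    records: Sequence[MutationRecord],
    sequences: Mapping[str, str] | None = None,
    flank: int = 5,
) -> DatasetSummary:
    """Descriptive statistics over forward records.

    Flank frequencies count residues at offsets -flank..-1, +1..+flank
    around each mutation site, clipped at the sequence ends; they are
    omitted (with a warning) when sequences are unavailable.
    """
    forward = [r for r in records if not r.is_reverse]
    if not forward:
        return DatasetSummary(0, 0, float("nan"), {}, {}, {})

    ddgs = np.array([r.ddg for r in forward])
    by_wt: dict[str, list[float]] = defaultdict(list)
    mut_counts: dict[str, int] = defaultdict(int)
    for r in forward:
        by_wt[r.wt_aa].append(r.ddg)
        mut_counts[r.mut_aa] += 1

    n = len(forward)
    mutant_freq = {aa: c / n for aa, c in sorted(mut_counts.items())}

    flank_freq: dict[str, float] = {}
    if sequences is not None:
        counts: dict[str, int] = defaultdict(int)
        total = 0
        for r in forward:
            seq = sequences.get(r.chain_key)
            if seq is None:
                warnings.warn(
                    f"no sequence for {r.chain_key}; skipped in flank statistics"
                )
                continue
            p = r.position - 1
            for off in range(-flank, flank + 1):
                if off == 0:
                    continue
                j = p + off
                if 0 <= j < len(seq):
                    counts[seq[j]] += 1
                    total += 1
        if total:
            flank_freq = {aa: c / total for aa, c in sorted(counts.items())}
    else:
        warnings.warn("no sequences supplied; flank statistics omitted")

    return DatasetSummary(
        n_records=n,
        n_complexes=len({r.complex_id for r in forward}),
        mean_ddg=float(ddgs.mean()),
        per_wt_mean_ddg={aa: float(np.mean(v)) for aa, v in sorted(by_wt.items())},
        mutant_aa_frequency=mutant_freq,
        flank_aa_frequency=flank_freq,
    )


def filter_records(
    records: Iterable[MutationRecord],
    binding_class: str | None = None,
    partition: str | None = None,
) -> list[MutationRecord]:
    """Select records by binding class and/or partition label."""
    out = list(records)
    if binding_class is not None:
        out = [r for r in out if r.binding_class == binding_class]
    if partition is not None:
        out = [r for r in out if r.partition == partition]
    return out
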