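"""DNA multiple-sequence alignments: the container and FASTA/relaxed-PHYLIP I/O.

Residues live in {A, C, G, T} plus missing/ambiguity symbols (gap ``-``,
``?``, ``N`` and the IUPAC ambiguity codes).  A missing or ambiguous symbol
is treated downstream as a partially observed state: its leaf conditional
vector is 1 for every compatible nucleotide.

Columns carry ``site_ids`` — their indices in the original alignment — so
that cross-validation fold splitting can be audited: splitting never alters
residues, only column membership.  Site ids are 0-based internally and
1-based in human-facing reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from phylocv.substitution import NUCLEOTIDES


class AlignmentError(ValueError):
    """Malformed alignment input (ragged rows, bad residues, duplicate taxa)."""


#: symbol -> tuple of compatible nucleotide indices (A=0, C=1, G=2, T=3)
AMBIGUITY_CODES: dict[str, tuple[int, ...]] = {
    "A": (0,), "C": (1,), "G": (2,), "T": (3,),
    "R": (0, 2), "Y": (1, 3), "S": (1, 2), "W": (0, 3),
    "K": (2, 3), "M": (0, 1),
    "B": (1, 2, 3), "D": (0, 2, 3), "H": (0, 1, 3), "V": (0, 1, 2),
    "N": (0, 1, 2, 3), "-": (0, 1, 2, 3), "?": (0, 1, 2, 3),
}

#: symbol -> 0/1 conditional-likelihood row over (A, C, G, T)
SYMBOL_MASKS: dict[str, np.ndarray] = {
    sym: np.array([1.0 if i in idx else 0.0 for i in range(4)])
    for sym, idx in AMBIGUITY_CODES.items()
}


def _clean_sequence(seq: str, taxon: str) -> str:
    s = seq.upper().replace("U", "T")
    for pos, ch in enumerate(s):
        if ch not in AMBIGUITY_CODES:
            raise AlignmentError(
                f"illegal residue {ch!r} at position {pos + 1} of taxon {taxon!r}"
            )
    return s


@dataclass
class Alignment:
    """An aligned set of DNA sequences over a shared set of columns."""

    taxon_names: list[str]
    sequences: np.ndarray  # (n_taxa, n_sites) array of single characters
    site_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype="U1")
        if self.sequences.ndim != 2:
            raise AlignmentError("sequences must form a 2-D taxon x site matrix")
        if len(self.taxon_names) != self.sequences.shape[0]:
            raise AlignmentError("one sequence row per taxon name required")
        if len(set(self.taxon_names)) != len(self.taxon_names):
            dupes = sorted({t for t in self.taxon_names if self.taxon_names.count(t) > 1})
            raise AlignmentError(f"duplicate taxon names: {dupes}")
        if any(not t for t in self.taxon_names):
            raise AlignmentError("taxon names must be non-empty")
        if self.site_ids is None:
            self.site_ids = np.arange(self.sequences.shape[1])
        self.site_ids = np.asarray(self.site_ids, dtype=int)
        if self.site_ids.shape != (self.sequences.shape[1],):
            raise AlignmentError("site_ids must have one entry per column")
        bad = ~np.isin(self.sequences, list(AMBIGUITY_CODES))
        if bad.any():
            row, col = np.argwhere(bad)[0]
            raise AlignmentError(
                f"illegal residue {self.sequences[row, col]!r} at site {col + 1} "
                f"of taxon {self.taxon_names[row]!r}"
            )

    @classmethod
    def from_sequences(cls, records: list[tuple[str, str]],
                       site_ids: np.ndarray | None = None) -> "Alignment":
        """Build from (name, sequence-string) pairs, validating lengths/residues."""
        if not records:
            raise AlignmentError("alignment needs at least one sequence")
        lengths = {name: len(seq) for name, seq in records}
        if len(set(lengths.values())) > 1:
            shortest = min(lengths, key=lengths.get)  # type: ignore[arg-type]
            raise AlignmentError(
                f"sequences have unequal lengths; taxon {shortest!r} has "
                f"{lengths[shortest]} residues where others have more"
            )
        cleaned = [(name, _clean_sequence(seq, name)) for name, seq in records]
        mat = np.array([list(seq) for _, seq in cleaned], dtype="U1")
        return cls([name for name, _ in cleaned], mat, site_ids)

    @property
    def n_taxa(self) -> int:
        return self.sequences.shape[0]

    @property
    def n_sites(self) -> int:
        return self.sequences.shape[1]

    def column(self, j: int) -> dict[str, str]:
        """Site pattern at column j as a taxon -> residue mapping."""
        return {t: self.sequences[i, j] for i, t in enumerate(self.taxon_names)}

    def take_columns(self, indices: np.ndarray) -> "Alignment":
        """Sub-alignment of the given columns; residues and site_ids preserved."""
        idx = np.asarray(indices, dtype=int)
        return Alignment(list(self.taxon_names), self.sequences[:, idx],
                         self.site_ids[idx])

    def reordered(self, taxon_names: list[str]) -> "Alignment":
        """Same alignment with rows permuted into the given taxon order."""
        pos = {t: i for i, t in enumerate(self.taxon_names)}
        idx = [pos[t] for t in taxon_names]
        return Alignment(list(taxon_names), self.sequences[idx, :], self.site_ids)


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read a DNA alignment from FASTA or relaxed sequential PHYLIP.

    Lowercase input is upcased and RNA ``U`` mapped to ``T``.  Ragged rows,
    duplicate taxa and illegal residues raise :class:`AlignmentError`.
    """
    path = Path(path)
    if format == "fasta":
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise AlignmentError(f"no FASTA records found in {path}")
        return Alignment.from_sequences(records)
    if format == "phylip":
        return _read_relaxed_phylip(path)
    raise ValueError(f"unknown alignment format {format!r}")


def _read_relaxed_phylip(path: Path) -> Alignment:
    # relaxed dialect: header "ntaxa nsites", then whitespace-delimited
    # name/sequence tokens; sequences may wrap across lines
    tokens = path.read_text().split()
    if len(tokens) < 2:
        raise AlignmentError(f"{path}: not a PHYLIP file (missing header)")
    try:
        n_taxa, n_sites = int(tokens[0]), int(tokens[1])
    except ValueError as exc:
        raise AlignmentError(f"{path}: bad PHYLIP header") from exc
    records: list[tuple[str, str]] = []
    pos = 2
    for _ in range(n_taxa):
        if pos >= len(tokens):
            raise AlignmentError(f"{path}: fewer taxa than header declares")
        name = tokens[pos]
        pos += 1
        chunks: list[str] = []
        need = n_sites
        while need > 0:
            if pos >= len(tokens):
                raise AlignmentError(
                    f"sequences have unequal lengths; taxon {name!r} has "
                    f"{n_sites - need} residues where {n_sites} were declared"
                )
            chunk = tokens[pos]
            pos += 1
            chunks.append(chunk)
            need -= len(chunk)
        if need < 0:
            raise AlignmentError(f"taxon {name!r}: sequence longer than declared")
        records.append((name, "".join(chunks)))
    return Alignment.from_sequences(records)


def write_alignment(alignment: Alignment, path, format: str = "fasta") -> None:
    """Write an alignment as FASTA or relaxed sequential PHYLIP."""
    path = Path(path)
    rows = ["".join(alignment.sequences[i]) for i in range(alignment.n_taxa)]
    if format == "fasta":
        with path.open("w") as fh:
            for name, seq in zip(alignment.taxon_names, rows):
                fh.write(f">{name}\n{seq}\n")
    elif format == "phylip":
        with path.open("w") as fh:
            fh.write(f"{alignment.n_taxa} {alignment.n_sites}\n")
            for name, seq in zip(alignment.taxon_names, rows):
                fh.write(f"{name} {seq}\n")
    else:
        raise ValueError(f"unknown alignment format {format!r}")
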