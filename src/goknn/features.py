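"""TFPSSM gapped-dipeptide features computed from PSI-BLAST PSSMs.

A protein of length ``n`` is profiled by an ``n x 20`` position-specific
scoring matrix (PSSM) of log-odds scores.  The gapped dipeptide ``XdY``
denotes residue types ``X`` and ``Y`` separated by exactly ``d`` positions;
with maximum gap ``l`` the feature space has ``20 * (l + 1) * 20``
dimensions (5600 at the default ``l = 13``).

The TFPSSM value of ``XdY`` is a soft occurrence count: each PSSM row is
squashed through the logistic function to per-position residue weights, and
every ordered position pair ``(i, i + d + 1)`` contributes
``w(i, X) * w(i + d + 1, Y)``.  The vector is then normalized to unit sum,
a term-frequency per protein.  This transform (logistic weights,
product-sum, unit-sum normalization) is this package's reconstruction of
the gapped-dipeptide term-frequency representation; see docs/methods.md.

Sequences without a PSSM fall back to a one-hot profile, which makes the
feature vector equal the plain normalized pattern counts of the sequence.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
from Bio import SeqIO
from scipy.special import expit

__all__ = [
    "AMINO_ACIDS",
    "PSIBLAST_PARAMS",
    "Pssm",
    "GappedDipeptide",
    "TfpssmVector",
    "parse_ascii_pssm",
    "write_ascii_pssm",
    "one_hot_pssm",
    "enumerate_patterns",
    "pattern_index",
    "pssm_to_prob",
    "compute_tfpssm",
    "tfpssm_from_sequence",
    "read_fasta",
    "write_feature_table",
    "read_feature_table",
]

#: the 20 standard amino acids in the column order used throughout
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: PSI-BLAST setting documented for generating the profiles this package
#: consumes (PSI-BLAST itself is never executed here)
PSIBLAST_PARAMS = (
    "-matrix BLOSUM80 -evalue 1e-5 -gapopen 9 -gapextend 2 "
    "-threshold 999 -seq yes -soft_masking true -num_iterations 2"
)

DEFAULT_MAX_GAP = 13


@dataclass
class Pssm:
    """A protein sequence with its ``n x 20`` log-odds score matrix.

    Columns follow :data:`AMINO_ACIDS`.  Nonstandard sequence letters
    (B, Z, X, U, O, ...) are allowed; their positions contribute zero
    weight but still occupy a row, preserving gap distances.
    """

    protein_id: str
    sequence: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"{self.protein_id}: scores must be n x 20, got {self.scores.shape}"
            )
        if self.scores.shape[0] != len(self.sequence):
            raise ValueError(
                f"{self.protein_id}: {len(self.sequence)} residues but "
                f"{self.scores.shape[0]} score rows"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GappedDipeptide:
    """Residue pair ``XdY``: types X and Y separated by exactly d positions."""

    x: str
    d: int
    y: str

    def __str__(self) -> str:
        return f"{self.x}{self.d}{self.y}"


@dataclass
class TfpssmVector:
    protein_id: str
    max_gap: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = 20 * (self.max_gap + 1) * 20
        if self.values.shape != (expected,):
            raise ValueError(
                f"{self.protein_id}: expected {expected} dims, got {self.values.shape}"
            )


def parse_ascii_pssm(stream: IO[str] | str, protein_id: str = "") -> Pssm:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    The sequence is reconstructed from the residue-letter column; scores are
    the first 20 numeric columns of each row.  Header and trailing
    statistics lines are ignored.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    sequence: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(stream, 1):
        fields = line.split()
        # residue rows: position index, letter, >= 20 numeric columns
        if len(fields) < 22 or not fields[0].isdigit() or len(fields[1]) != 1:
            continue
        pos = int(fields[0])
        if pos != len(sequence) + 1:
            raise ValueError(
                f"line {lineno}: position {pos} out of order "
                f"(expected {len(sequence) + 1})"
            )
        try:
            rows.append([float(v) for v in fields[2:22]])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric score cell: {exc}") from None
        sequence.append(fields[1])
    if not rows:
        raise ValueError("no PSSM rows found in stream")
    return Pssm(protein_id=protein_id, sequence="".join(sequence), scores=np.array(rows))


def write_ascii_pssm(pssm: Pssm, stream: IO[str]) -> None:
    """Write the ASCII PSSM dialect :func:`parse_ascii_pssm` reads."""
    stream.write("\nLast position-specific scoring matrix computed\n")
    stream.write(" " * 10 + "  ".join(AMINO_ACIDS) + "\n")
    for i, (letter, row) in enumerate(zip(pssm.sequence, pssm.scores), 1):
        cells = " ".join(f"{v:6g}" for v in row)
        stream.write(f"{i:5d} {letter} {cells}\n")
    stream.write("\n")


def one_hot_pssm(protein_id: str, sequence: str, magnitude: float = 1000.0) -> Pssm:
    """A surrogate PSSM whose logistic weights are (numerically) one-hot.

    Used for proteins that have a sequence but no profile: the resulting
    TFPSSM equals the normalized sequence pattern counts.
    """
    scores = np.full((len(sequence), 20), -magnitude)
    for i, letter in enumerate(sequence):
        j = _AA_INDEX.get(letter)
        if j is not None:
            scores[i, j] = magnitude
    return Pssm(protein_id=protein_id, sequence=sequence, scores=scores)


def enumerate_patterns(sequence: str, max_gap: int) -> Iterator[GappedDipeptide]:
    """Yield one ``XdY`` occurrence per position pair ``(i, i + d + 1)``.

    Occurrences with a nonstandard letter at either end are skipped.
    """
    n = len(sequence)
    for i in range(n):
        if sequence[i] not in _AA_INDEX:
            continue
        for d in range(min(max_gap, n - i - 2) + 1):
            j = i + d + 1
            if sequence[j] in _AA_INDEX:
                yield GappedDipeptide(sequence[i], d, sequence[j])


def pattern_index(g: GappedDipeptide, max_gap: int) -> int:
    """Bijective vector index of ``XdY``: ``aa(X)*(l+1)*20 + d*20 + aa(Y)``."""
    if not 0 <= g.d <= max_gap:
        raise ValueError(f"gap {g.d} outside [0, {max_gap}]")
    try:
        xi, yi = _AA_INDEX[g.x], _AA_INDEX[g.y]
    except KeyError as exc:
        raise ValueError(f"nonstandard amino acid {exc} in pattern {g}") from None
    return xi * (max_gap + 1) * 20 + g.d * 20 + yi


def pssm_to_prob(pssm: Pssm) -> np.ndarray:
    """Logistic transform ``1 / (1 + exp(-s))`` of every score.

    Rows at nonstandard sequence positions are zeroed so they contribute
    nothing to pattern weights while keeping their position.
    """
    prob = expit(pssm.scores)
    mask = np.fromiter(
        (c in _AA_INDEX for c in pssm.sequence), dtype=bool, count=len(pssm.sequence)
    )
    prob[~mask] = 0.0
    return prob


def compute_tfpssm(pssm: Pssm, max_gap: int = DEFAULT_MAX_GAP) -> TfpssmVector:
    """TFPSSM vector of a protein: soft gapped-dipeptide counts, unit sum.

    ``raw[X, d, Y] = sum_i prob(i, X) * prob(i + d + 1, Y)`` over all valid
    positions, then normalized so the vector sums to 1.  Proteins shorter
    than 2 residues have no pairs and yield the zero vector (with warning).
    """
    prob = pssm_to_prob(pssm)
    n = len(pssm)
    raw = np.zeros((20, max_gap + 1, 20))
    for d in range(max_gap + 1):
        if n - d - 1 < 1:
            break
        # all position pairs at gap d at once: (20, 20) outer-product sum
        raw[:, d, :] = prob[: n - d - 1].T @ prob[d + 1 :]
    values = raw.reshape(-1)
    total = values.sum()
    if total > 0:
        values = values / total
    else:
        warnings.warn(
            f"{pssm.protein_id}: no residue pairs (n={n}); zero feature vector",
            stacklevel=2,
        )
    return TfpssmVector(protein_id=pssm.protein_id, max_gap=max_gap, values=values)


def tfpssm_from_sequence(
    protein_id: str, sequence: str, max_gap: int = DEFAULT_MAX_GAP
) -> TfpssmVector:
    """TFPSSM of a bare sequence via the one-hot profile (pattern counts)."""
    return compute_tfpssm(one_hot_pssm(protein_id, sequence), max_gap)


def read_fasta(stream: IO[str] | str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{record id: uppercase sequence}``."""
    if isinstance(stream, str) and "\n" in stream:
        stream = io.StringIO(stream)
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(stream, "fasta")}


def write_feature_table(vectors: Iterable[TfpssmVector], path: str | Path) -> None:
    """Persist vectors as TSV (protein_id + dense values) with a JSON sidecar."""
    path = Path(path)
    max_gap = None
    with path.open("w") as fh:
        for v in vectors:
            if max_gap is None:
                max_gap = v.max_gap
            elif v.max_gap != max_gap:
                raise ValueError("mixed max_gap values in one feature table")
            fh.write(v.protein_id + "\t" + "\t".join(f"{x:.12g}" for x in v.values) + "\n")
    sidecar = {"max_gap": max_gap, "normalization": "unit_sum", "transform": "logistic"}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_feature_table(path: str | Path) -> list[TfpssmVector]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    out = []
    with path.open() as fh:
        for line in fh:
            pid, *vals = line.rstrip("\n").split("\t")
            out.append(
                TfpssmVector(pid, meta["max_gap"], np.array([float(v) for v in vals]))
            )
    return out
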