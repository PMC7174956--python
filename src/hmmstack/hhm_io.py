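"""Reading, writing and normalizing HHsuite ``.hhm`` profiles.

A ``.hhm`` file stores a profile hidden Markov model built from a multiple
sequence alignment (e.g. by HHblits).  For each of the ``L`` match states it
records 20 emission scores, one per standard amino acid, in units of
``-1000 * log2(p)`` where ``p`` is the emission probability; a ``*`` marks a
probability too small to represent.  Only this L x 20 match-emission block is
used here — insert/delete states and transition scores are ignored.

Scores are mapped back to probabilities with ``f(x) = 2**(-x/1000)`` and
``f(*) = 0``, yielding an L x 20 matrix of values in [0, 1] that downstream
feature encoders consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np

__all__ = [
    "STAR",
    "STANDARD_AA",
    "HHMParseError",
    "HMMProfile",
    "NormalizedProfile",
    "LabeledDataset",
    "parse_hhm",
    "write_hhm",
    "normalize_profile",
    "load_dataset",
    "read_labels",
    "read_fasta_ids",
]

#: Sentinel for the ``*`` marker (negligible emission probability) in the
#: integer score matrix.  All genuine scores are >= 0.
STAR: int = -1

#: The 20 standard amino acids, in HHsuite column order.
STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"


class HHMParseError(ValueError):
    """Raised when a ``.hhm`` file is malformed; names the offending line."""

    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


@dataclass
class HMMProfile:
    """Raw match-emission block of one protein's profile HMM.

    ``raw_scores`` is an ``L x 20`` integer matrix; entries are non-negative
    HHM scores or :data:`STAR` (-1) for ``*`` markers.  ``alphabet`` is the
    amino-acid column order declared in the file header and is carried
    through all downstream feature computations (never re-sorted).
    """

    protein_id: str
    length: int
    residues: str
    raw_scores: np.ndarray
    alphabet: str = STANDARD_AA

    def __post_init__(self):
        self.raw_scores = np.asarray(self.raw_scores, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        if self.length < 1:
            raise ValueError(f"profile length must be >= 1, got {self.length}")
        if self.raw_scores.shape != (self.length, 20):
            raise ValueError(
                f"raw_scores must be {self.length} x 20, got {self.raw_scores.shape}"
            )
        bad = (self.raw_scores < 0) & (self.raw_scores != STAR)
        if bad.any():
            raise ValueError("raw scores must be non-negative integers or STAR")
        if len(self.residues) != self.length:
            raise ValueError("residues string length must equal profile length")
        if sorted(self.alphabet) != sorted(STANDARD_AA):
            raise ValueError(
                f"alphabet must be a permutation of the 20 standard amino acids, got {self.alphabet!r}"
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, HMMProfile):
            return NotImplemented
        return (
            self.protein_id == other.protein_id
            and self.length == other.length
            and self.residues == other.residues
            and self.alphabet == other.alphabet
            and np.array_equal(self.raw_scores, other.raw_scores)
        )


@dataclass
class NormalizedProfile:
    """An ``L x 20`` matrix of emission probabilities in [0, 1].

    Produced from an :class:`HMMProfile` via score-to-probability
    normalization; STAR positions are exactly 0.
    """

    protein_id: str
    length: int
    matrix: np.ndarray
    alphabet: str = STANDARD_AA

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (self.length, 20):
            raise ValueError(
                f"matrix must be {self.length} x 20, got {self.matrix.shape}"
            )
        if (self.matrix < 0).any() or (self.matrix > 1).any():
            raise ValueError("normalized entries must lie in [0, 1]")


@dataclass
class LabeledDataset:
    """Labeled collection of normalized profiles for a binary task.

    Labels are 1 for the positive class (DNA-binding protein) and 0 for the
    negative class.  Protein ids are unique.
    """

    entries: list[tuple[str, NormalizedProfile, int]] = field(default_factory=list)

    def __post_init__(self):
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate protein ids: {dupes}")
        for _, _, label in self.entries:
            if label not in (0, 1):
                raise ValueError(f"labels must be 0 or 1, got {label!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]

    @property
    def labels(self) -> np.ndarray:
        return np.array([e[2] for e in self.entries], dtype=np.int64)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return len(self) - self.n_positive


def normalize_score(x: int) -> float:
    """Map one HHM score to a probability: STAR -> 0, else ``2**(-x/1000)``."""
    return 0.0 if x == STAR else float(2.0 ** (-x / 1000.0))


def normalize_profile(profile: HMMProfile) -> NormalizedProfile:
    """Convert raw HHM scores to emission probabilities in [0, 1].

    Entry-wise: ``*`` (STAR) maps to exactly 0; an integer score ``x`` maps
    to ``2**(-x/1000)``, so score 0 is probability 1 and score 1000 is 0.5.
    Shape and alphabet are preserved; no rescaling is applied afterwards.
    """
    scores = profile.raw_scores
    with np.errstate(over="ignore"):
        mat = np.power(2.0, -scores.astype(np.float64) / 1000.0)
    mat[scores == STAR] = 0.0
    return NormalizedProfile(
        protein_id=profile.protein_id,
        length=profile.length,
        matrix=mat,
        alphabet=profile.alphabet,
    )


def _open_lines(source: Union[str, Path, IO[str]]) -> tuple[list[str], str]:
    if hasattr(source, "read"):
        text = source.read()
        name = getattr(source, "name", "<stream>")
    else:
        path = Path(source)
        text = path.read_text()
        name = str(path)
    return text.splitlines(), name


def parse_hhm(source: Union[str, Path, IO[str]]) -> HMMProfile:
    """Parse the match-emission block of an HHsuite ``.hhm`` file (v2/v3).

    Scans from the ``HMM`` column-header line to the ``//`` terminator.  The
    transition-name header, the begin-state transition line, the NULL model
    line and every per-state transition/diversity line are skipped; each
    match state contributes only its first line (20 emission scores).
    ``*`` tokens become :data:`STAR`.

    Raises
    ------
    HHMParseError
        On a malformed header, a row with a number of emission fields
        different from 20, a length mismatch with the ``LENG`` header, or a
        missing ``//`` terminator.  The error names the line number.
    """
    lines, name = _open_lines(source)
    protein_id = Path(name).stem if name != "<stream>" else "<stream>"
    declared_len: int | None = None
    header_idx: int | None = None
    alphabet: str | None = None

    for i, line in enumerate(lines):
        if line.startswith("NAME"):
            parts = line.split(maxsplit=1)
            if len(parts) == 2:
                protein_id = parts[1].split()[0]
        elif line.startswith("LENG"):
            try:
                declared_len = int(line.split()[1])
            except (IndexError, ValueError):
                raise HHMParseError("malformed LENG header", i + 1) from None
        elif line.startswith("HMM"):
            tokens = line.split()
            cols = tokens[1:]
            if len(cols) != 20 or any(len(c) != 1 for c in cols):
                raise HHMParseError(
                    f"HMM header must declare 20 single-letter columns, got {len(cols)}",
                    i + 1,
                )
            alphabet = "".join(cols)
            if sorted(alphabet) != sorted(STANDARD_AA):
                raise HHMParseError(
                    f"HMM header columns are not the 20 standard amino acids: {alphabet}",
                    i + 1,
                )
            header_idx = i
            break

    if header_idx is None or alphabet is None:
        raise HHMParseError("no HMM column-header line found", len(lines))

    residues: list[str] = []
    rows: list[list[int]] = []
    terminated = False
    i = header_idx + 1
    if i < len(lines) and "->" in lines[i]:
        i += 1  # transition-name header (M->M M->I ...)
    # begin-state transition line: first token is not a residue letter
    if i < len(lines):
        first = lines[i].split()
        if first and not (first[0].isalpha() and len(first[0]) == 1):
            i += 1

    while i < len(lines):
        line = lines[i]
        stripped = line.strip()
        if stripped == "//":
            terminated = True
            break
        if not stripped:
            i += 1
            continue
        tokens = stripped.split()
        if not (tokens[0].isalpha() and len(tokens[0]) == 1):
            raise HHMParseError(
                f"expected a match-state emission line, got {stripped[:40]!r}", i + 1
            )
        if len(tokens) < 2 or not tokens[1].isdigit():
            raise HHMParseError("emission line lacks a state index", i + 1)
        fields = tokens[2:]
        if len(fields) != 20:
            raise HHMParseError(
                f"expected 20 emission fields, got {len(fields)}", i + 1
            )
        row: list[int] = []
        for tok in fields:
            if tok == "*":
                row.append(STAR)
            else:
                try:
                    val = int(tok)
                except ValueError:
                    raise HHMParseError(
                        f"non-integer emission score {tok!r}", i + 1
                    ) from None
                if val < 0:
                    raise HHMParseError(f"negative emission score {val}", i + 1)
                row.append(val)
        residues.append(tokens[0])
        rows.append(row)
        i += 1  # skip the transition/diversity line of this state
        if i < len(lines) and lines[i].strip() != "//":
            i += 1

    if not terminated:
        raise HHMParseError("missing '//' terminator", len(lines))
    if declared_len is not None and declared_len != len(rows):
        raise HHMParseError(
            f"LENG header says {declared_len} states but body has {len(rows)}",
            len(lines),
        )
    if not rows:
        raise HHMParseError("no match states found", len(lines))

    return HMMProfile(
        protein_id=protein_id,
        length=len(rows),
        residues="".join(residues),
        raw_scores=np.array(rows, dtype=np.int64),
        alphabet=alphabet,
    )


def write_hhm(profile: HMMProfile, sink: Union[str, Path, IO[str]]) -> None:
    """Write a minimal ``.hhm`` file that :func:`parse_hhm` reads back equal."""
    profile.validate()
    out: list[str] = []
    out.append("HHsearch 1.5")
    out.append(f"NAME  {profile.protein_id}")
    out.append(f"LENG  {profile.length}")
    out.append("NULL   " + "\t".join(["*"] * 20))
    out.append("HMM    " + "\t".join(profile.alphabet))
    out.append(
        "       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\tNeff_I\tNeff_D"
    )
    out.append("       " + "\t".join(["0"] + ["*"] * 9))
    for i in range(profile.length):
        fields = [
            "*" if s == STAR else str(int(s)) for s in profile.raw_scores[i]
        ]
        out.append(f"{profile.residues[i]} {i + 1}\t" + "\t".join(fields))
        out.append("       " + "\t".join(["0"] + ["*"] * 9))
    out.append("//")
    text = "\n".join(out) + "\n"
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text)


def read_labels(path: Union[str, Path]) -> dict[str, int]:
    """Read a two-column TSV (protein_id, label in {0,1}) into a dict."""
    labels: dict[str, int] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}: line {line_no}: expected two columns")
        pid, lab = parts[0].strip(), parts[1].strip()
        if lab not in ("0", "1"):
            raise ValueError(f"{path}: line {line_no}: label must be 0 or 1, got {lab!r}")
        if pid in labels:
            raise ValueError(f"{path}: duplicate protein id {pid!r}")
        labels[pid] = int(lab)
    return labels


def read_fasta_ids(path: Union[str, Path]) -> list[str]:
    """Return the record ids of a FASTA file (order preserved)."""
    from Bio import SeqIO

    return [rec.id for rec in SeqIO.parse(str(path), "fasta")]


def load_dataset(
    profile_dir: Union[str, Path],
    labels: Union[str, Path, dict],
    require_both_classes: bool = True,
) -> LabeledDataset:
    """Load normalized profiles for every labeled protein id.

    ``labels`` is a two-column TSV path (id, 0/1) or an id->label mapping;
    ``profile_dir`` must contain one ``<id>.hhm`` per id.  Ids whose profile
    file is missing are reported collectively in the raised error.
    """
    profile_dir = Path(profile_dir)
    label_map = labels if isinstance(labels, dict) else read_labels(labels)
    if not label_map:
        raise ValueError("label table is empty")

    missing = [pid for pid in label_map if not (profile_dir / f"{pid}.hhm").exists()]
    if missing:
        raise FileNotFoundError(
            f"missing .hhm profiles for {len(missing)} id(s): {sorted(missing)}"
        )

    entries: list[tuple[str, NormalizedProfile, int]] = []
    for pid, label in label_map.items():
        prof = parse_hhm(profile_dir / f"{pid}.hhm")
        entries.append((pid, normalize_profile(prof), int(label)))

    ds = LabeledDataset(entries)
    if require_both_classes and (ds.n_positive == 0 or ds.n_negative == 0):
        raise ValueError(
            f"dataset must contain both classes, got {ds.n_positive} positive / "
            f"{ds.n_negative} negative"
        )
    return ds
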