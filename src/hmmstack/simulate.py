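"""Synthetic profile-HMM generator for a two-class protein task.

Emulates the inputs the pipeline normally gets from HHblits: per-protein
``L x 20`` match-emission profiles written as ``.hhm`` files, with class
labels in a TSV.  Each protein draws a protein-level emission profile from
a Dirichlet centred on its class mean; each match-state row is then a
Dirichlet draw centred on a blend of the protein profile and the previous
row, so adjacent rows are correlated and the transition-composition (TPC)
features carry class signal beyond plain composition.  Probabilities are
converted to HHM score units (``round(-1000 * log2 p)``), with values below
``2**-20`` written as ``*`` — mirroring how HHsuite marks negligible
probabilities — plus optional extra ``*`` dropout.

The class signal lives entirely in the emissions: the two class means are
the shared background tilted up/down by ``separation`` along a fixed
log-space direction.  ``separation = 0`` makes the classes exchangeable;
the default 1.0 gives a moderately hard problem and 3.0 a nearly separable
one (see docs/methods.md for the calibration).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np

from .hhm_io import (
    STANDARD_AA,
    STAR,
    HMMProfile,
    LabeledDataset,
    load_dataset,
    write_hhm,
)

__all__ = [
    "SimulationConfig",
    "class_mean_emissions",
    "generate_profile",
    "generate_dataset",
    "worked_example_profile",
]

#: Probabilities below this are written as ``*`` (STAR).
STAR_FLOOR = 2.0 ** -20

# Fixed mean-zero log-space direction separating the two classes (unit
# amplitude 0.1 per unit of `separation`); alternating sign over the
# HHsuite alphabet order.
_CLASS_DIRECTION = 0.1 * np.array([1.0 if i % 2 == 0 else -1.0 for i in range(20)])

# Mildly non-uniform shared background composition (sums to 1).
_BACKGROUND = np.array(
    [1.0 + 0.5 * np.cos(2.0 * np.pi * i / 20.0) for i in range(20)]
)
_BACKGROUND = _BACKGROUND / _BACKGROUND.sum()


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-class profile dataset.

    ``separation`` scales the class difference (0 = identical
    distributions); ``length_range`` respects the benchmark convention of
    excluding proteins shorter than 50 residues; ``star_rate`` is extra
    ``*`` dropout beyond the quantization floor.  ``row_concentration``
    and ``protein_concentration`` set the Dirichlet noise at the two
    levels; ``blend`` couples adjacent rows (first-order signal for TPC).
    """

    n_pos: int = 20
    n_neg: int = 20
    length_range: tuple[int, int] = (50, 300)
    separation: float = 1.0
    star_rate: float = 0.02
    seed: int = 0
    row_concentration: float = 50.0
    protein_concentration: float = 100.0
    blend: float = 0.3

    def __post_init__(self):
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("n_pos and n_neg must be >= 0")
        if self.length_range[0] < 2 or self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must satisfy 2 <= min <= max")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not (0.0 <= self.star_rate < 1.0):
            raise ValueError("star_rate must lie in [0, 1)")
        if not (0.0 <= self.blend < 1.0):
            raise ValueError("blend must lie in [0, 1)")


def class_mean_emissions(class_label: int, separation: float) -> np.ndarray:
    """Mean emission profile of a class: background tilted by the class
    direction, ``+`` for the positive class and ``-`` for the negative."""
    sign = 1.0 if class_label == 1 else -1.0
    m = _BACKGROUND * np.exp(sign * separation * _CLASS_DIRECTION)
    return m / m.sum()


def _probs_to_scores(p: np.ndarray) -> np.ndarray:
    """Inverse of score normalization: ``round(-1000 * log2 p)``, with
    probabilities below the floor emitted as STAR."""
    scores = np.full(p.shape, STAR, dtype=np.int64)
    ok = p >= STAR_FLOOR
    scores[ok] = np.rint(-1000.0 * np.log2(p[ok])).astype(np.int64)
    return scores


def generate_profile(
    length: int,
    class_label: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    protein_id: str = "synthetic",
) -> HMMProfile:
    """Draw one synthetic profile of the given length and class."""
    if length < 2:
        raise ValueError(f"profile length must be >= 2, got {length}")
    if class_label not in (0, 1):
        raise ValueError("class_label must be 0 or 1")
    m_class = class_mean_emissions(class_label, cfg.separation)
    m_protein = rng.dirichlet(cfg.protein_concentration * m_class + 1e-6)

    rows = np.empty((length, 20), dtype=np.float64)
    prev = m_protein
    for i in range(length):
        target = (1.0 - cfg.blend) * m_protein + cfg.blend * prev
        row = rng.dirichlet(cfg.row_concentration * target + 1e-6)
        rows[i] = row
        prev = row

    scores = _probs_to_scores(rows)
    if cfg.star_rate > 0:
        drop = rng.random(scores.shape) < cfg.star_rate
        scores[drop] = STAR

    residues = "".join(
        rng.choice(list(STANDARD_AA), size=length, p=m_protein / m_protein.sum())
    )
    return HMMProfile(
        protein_id=protein_id,
        length=length,
        residues=residues,
        raw_scores=scores,
        alphabet=STANDARD_AA,
    )


def generate_dataset(
    cfg: SimulationConfig, out_dir: Union[str, Path], id_prefix: str = ""
) -> LabeledDataset:
    """Write ``n_pos + n_neg`` synthetic ``.hhm`` files plus ``labels.tsv``
    and return the loaded dataset.  Fully reproducible from ``cfg.seed``;
    ``id_prefix`` keeps ids distinct across independently generated sets."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    label_lines = []
    for label, count, tag in ((1, cfg.n_pos, "pos"), (0, cfg.n_neg, "neg")):
        for i in range(count):
            pid = f"{id_prefix}{tag}_{i + 1:04d}"
            length = int(
                rng.integers(cfg.length_range[0], cfg.length_range[1] + 1)
            )
            prof = generate_profile(length, label, cfg, rng, protein_id=pid)
            write_hhm(prof, out_dir / f"{pid}.hhm")
            label_lines.append(f"{pid}\t{label}")
    (out_dir / "labels.tsv").write_text("\n".join(label_lines) + "\n")
    return load_dataset(out_dir, out_dir / "labels.tsv", require_both_classes=False)


def worked_example_profile() -> HMMProfile:
    """A fixed 3 x 20 profile with small scores whose AAC and TPC are
    hand-computable; used as a worked example and test fixture."""
    scores = np.full((3, 20), STAR, dtype=np.int64)
    # row 1: A (prob 1/2), C (prob 1/4)
    scores[0, 0] = 1000
    scores[0, 1] = 2000
    # row 2: C (prob 1), D (prob 1/2)
    scores[1, 1] = 0
    scores[1, 2] = 1000
    # row 3: A (prob 1/4), Y (prob 1/2)
    scores[2, 0] = 2000
    scores[2, 19] = 1000
    return HMMProfile(
        protein_id="worked_example",
        length=3,
        residues="ACY",
        raw_scores=scores,
        alphabet=STANDARD_AA,
    )
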