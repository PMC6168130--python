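"""Synthetic benchmark generator with planted position-specific residue
preferences.

Proteins are drawn from a background residue distribution (uniform over the
20 amino acids by default); at each planted phosphosite the center is set to
S or T with equal probability and, independently per mapped offset, the
preferred residue is written with probability ``effect_size`` (otherwise the
background residue stands).  All non-planted S/T positions become negatives —
including "hard negatives" within 15 residues of a planted site, which are
deliberately kept.  Planted sites are spaced at least 31 residues apart so
positive windows never overlap and cannot contaminate each other's flanks.

The default preference map mirrors the residue preferences reported around
PrkC sites: lysine at -10, -4, +7, +11; arginine at -9, -1; histidine at
-13, +12; alanine at -5, -3; glycine at -2; phenylalanine at +3.  The
generator is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import (
    AMINO_ACIDS,
    DEFAULT_FLANK,
    LabeledDataset,
    PhosphoSite,
    ProteinRecord,
    build_labeled_dataset,
)

#: offset -> preferred residue (see module docstring)
DEFAULT_PREFERENCES: dict[int, str] = {
    -13: "H",
    -10: "K",
    -9: "R",
    -5: "A",
    -4: "K",
    -3: "A",
    -2: "G",
    -1: "R",
    3: "F",
    7: "K",
    11: "K",
    12: "H",
}


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic benchmark; the seed fixes everything."""

    n_proteins: int = 50
    min_length: int = 350
    max_length: int = 450
    n_sites_per_protein: int = 4
    effect_size: float = 0.8
    preferences: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_PREFERENCES))
    background: dict[str, float] | None = None  # None = uniform over 20
    seed: int = 42

    def __post_init__(self):
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must be in [0, 1]")
        for off in self.preferences:
            if off == 0 or abs(off) > DEFAULT_FLANK:
                raise ValueError(
                    f"preference offset {off} outside the window flank "
                    f"(+-{DEFAULT_FLANK}, 0 reserved for the S/T center)"
                )
        if self.min_length < 2 * DEFAULT_FLANK + 1 or self.max_length < self.min_length:
            raise ValueError("bad protein length range")

    def background_probs(self) -> np.ndarray:
        if self.background is None:
            return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
        p = np.array([self.background.get(a, 0.0) for a in AMINO_ACIDS], dtype=float)
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")
        return p


def _plant_positions(rng, length: int, n_sites: int, min_gap: int = 31) -> list[int]:
    # rejection-sample 1-based positions spaced >= min_gap apart, kept in the
    # window-complete interior so every planted offset lies inside the protein
    lo, hi = DEFAULT_FLANK + 1, length - DEFAULT_FLANK
    for _ in range(200):
        cand = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_sites, replace=False))
        if n_sites == 1 or np.diff(cand).min() >= min_gap:
            return [int(c) for c in cand]
    raise ValueError(
        f"could not place {n_sites} sites with spacing {min_gap} in length {length}"
    )


def generate_benchmark(
    spec: SyntheticSpec,
) -> tuple[list[ProteinRecord], list[PhosphoSite], LabeledDataset]:
    """Generate proteins, the planted positive-site list, and the full labeled
    dataset (all other S/T positions as negatives)."""
    rng = np.random.default_rng(spec.seed)
    bg = spec.background_probs()
    aa = np.array(list(AMINO_ACIDS))
    proteins: list[ProteinRecord] = []
    sites: list[PhosphoSite] = []
    for i in range(spec.n_proteins):
        length = int(rng.integers(spec.min_length, spec.max_length + 1))
        seq = rng.choice(aa, size=length, p=bg)
        positions = _plant_positions(rng, length, spec.n_sites_per_protein)
        for pos in positions:
            seq[pos - 1] = "S" if rng.random() < 0.5 else "T"
            for offset, residue in spec.preferences.items():
                j = pos - 1 + offset
                if 0 <= j < length and rng.random() < spec.effect_size:
                    seq[j] = residue
        acc = f"SYN{i + 1:04d}"
        proteins.append(
            ProteinRecord(accession=acc, sequence="".join(seq), description=f"{acc} synthetic")
        )
        # a planted offset may overwrite a neighbouring planted center; keep
        # only positions still carrying S/T as positives
        sites.extend(
            PhosphoSite(accession=acc, position=p, gene="synthetic", organism="synthetic")
            for p in positions
            if seq[p - 1] in "ST"
        )
    dataset = build_labeled_dataset(proteins, sites)
    return proteins, sites, dataset


def empirical_effect(dataset: LabeledDataset, offset: int, residue: str) -> float:
    """Observed frequency difference (positives minus negatives) of ``residue``
    at window ``offset`` — the oracle for generator correctness."""
    if abs(offset) > DEFAULT_FLANK:
        raise ValueError(f"offset {offset} outside +-{DEFAULT_FLANK}")
    j = offset + DEFAULT_FLANK
    counts = {"positive": [0, 0], "negative": [0, 0]}
    for w in dataset.windows:
        if w.label in counts:
            counts[w.label][0] += w.peptide[j] == residue
            counts[w.label][1] += 1
    (kp, np_), (kn, nn) = counts["positive"], counts["negative"]
    if np_ == 0 or nn == 0:
        raise ValueError("dataset must contain both classes")
    return kp / np_ - kn / nn
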