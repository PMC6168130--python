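"""Shared fixtures and hand-rolled oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from prkc_psp.dataio import ALPHABET, AMINO_ACIDS, LabeledDataset, PeptideWindow

FLANK = 15
WLEN = 31


def make_window(
    peptide: str, label: str = "unknown", accession: str = "W", position: int = 100
) -> PeptideWindow:
    assert len(peptide) == WLEN
    return PeptideWindow(
        accession=accession, position=position, peptide=peptide, label=label
    )


def window_from_pairs(
    pairs: dict[int, str],
    center: str = "S",
    fill: str = "A",
    label: str = "unknown",
    accession: str = "W",
    position: int = 100,
) -> PeptideWindow:
    """Build a 31-mer with residues at 1-based window positions ``pairs``
    (position 16 is the center) and ``fill`` elsewhere."""
    chars = [fill] * WLEN
    chars[FLANK] = center
    for pos1, residue in pairs.items():
        assert pos1 != 16, "use center= for position 16"
        chars[pos1 - 1] = residue
    return make_window("".join(chars), label, accession, position)


def random_window(rng: np.random.Generator, label: str, k: int) -> PeptideWindow:
    chars = list(rng.choice(list(ALPHABET), size=WLEN))
    chars[FLANK] = "S" if rng.random() < 0.5 else "T"
    return make_window("".join(chars), label, accession=f"R{label[:3]}", position=k)


def random_training_set(
    rng: np.random.Generator, n_pos: int, n_neg: int
) -> list[PeptideWindow]:
    return [random_window(rng, "positive", 100 + i) for i in range(n_pos)] + [
        random_window(rng, "negative", 1000 + i) for i in range(n_neg)
    ]


def oracle_encode(window, pos_windows, neg_windows):
    """Brute-force recount of the 62 location features, independent of the
    production encoder."""
    v = []
    for u in range(WLEN):
        c = window.peptide[u]
        v.append(sum(w.peptide[u] == c for w in pos_windows) / len(pos_windows))
    for u in range(WLEN):
        c = window.peptide[u]
        v.append(sum(w.peptide[u] == c for w in neg_windows) / len(neg_windows))
    return np.array(v)


def pairwise_auroc(scores, labels) -> float:
    """Mann-Whitney AROC by explicit pairwise comparison, ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == "positive"]
    neg = [s for s, l in zip(scores, labels) if l == "negative"]
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


@pytest.fixture(scope="session")
def separable_dataset() -> LabeledDataset:
    """Disjoint residue alphabets for the two classes: trivially separable."""
    rng = np.random.default_rng(123)
    pos_alpha, neg_alpha = list("ACDEFGHIKL"), list("MNPQRVWY")
    windows = []
    for i in range(30):
        chars = list(rng.choice(pos_alpha, size=WLEN))
        chars[FLANK] = "S"
        windows.append(make_window("".join(chars), "positive", "POS", 50 + i))
    for i in range(60):
        chars = list(rng.choice(neg_alpha, size=WLEN))
        chars[FLANK] = "T"
        windows.append(make_window("".join(chars), "negative", "NEG", 50 + i))
    return LabeledDataset(windows=windows)


@pytest.fixture(scope="session")
def small_benchmark():
    """A small planted-signal benchmark reused across model/predict tests."""
    from prkc_psp.synthetic import SyntheticSpec, generate_benchmark

    spec = SyntheticSpec(
        n_proteins=12,
        min_length=120,
        max_length=180,
        n_sites_per_protein=3,
        effect_size=0.9,
        seed=11,
    )
    return generate_benchmark(spec)


@pytest.fixture(scope="session")
def small_predictor(small_benchmark):
    from prkc_psp.model import SVMConfig, build_predictor

    _, _, dataset = small_benchmark
    return build_predictor(dataset, SVMConfig(seed=11), n_folds=5, seed=11)
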