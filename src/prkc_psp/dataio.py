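"""Sequence and site I/O: the curated PrkC site table, FASTA/TSV readers,
peptide-window extraction and labeled-dataset assembly.

Every prediction unit is a 31-residue peptide window centered on a serine or
threonine.  Positions are 1-based indices into the protein sequence throughout,
matching the coordinate convention of UniProt feature annotations.  Windows
overhanging a terminus are padded with ``X``, which downstream modules treat as
an ordinary 21st alphabet symbol.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Terminal-padding / unknown-residue symbol.
PAD = "X"
#: Full symbol alphabet used by the feature encoding (20 residues + padding).
ALPHABET = AMINO_ACIDS + PAD
#: Flank half-width: windows span [site - 15, site + 15], 31 residues.
DEFAULT_FLANK = 15
WINDOW_LENGTH = 2 * DEFAULT_FLANK + 1

_AMBIGUOUS = {"B", "Z", "U", "O", "J"}


class FastaParseError(ValueError):
    """Raised for missing, empty or malformed FASTA input."""


class SiteListParseError(ValueError):
    """Raised for malformed site-list TSV rows; carries the line number."""


class ResidueMismatchError(ValueError):
    """The residue at a claimed phosphosite is not S or T.

    This almost always signals a sequence-version conflict between the site
    annotation and the supplied FASTA, so it is raised loudly instead of
    silently skipping the site (silent skips would corrupt class counts).
    """

    def __init__(self, accession: str, position: int, observed: str):
        self.accession = accession
        self.position = position
        self.observed = observed
        super().__init__(
            f"residue at {accession}:{position} is {observed!r}, expected S or T "
            f"(sequence-version mismatch?)"
        )


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence, uppercase, over the 20 amino acids plus X."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.accession:
            raise ValueError("accession must be nonempty")
        if not self.sequence:
            raise FastaParseError(f"record {self.accession!r} has an empty sequence")
        if any(c.isspace() for c in self.sequence):
            raise ValueError(f"sequence of {self.accession} contains whitespace")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PhosphoSite:
    """A curated phosphorylation site: accession, 1-based position, provenance."""

    accession: str
    position: int
    gene: str = ""
    organism: str = ""
    pmids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class PeptideWindow:
    """A 31-mer S/T-centered peptide with its label.

    ``label`` is ``"positive"``, ``"negative"`` or ``"unknown"`` (the last only
    in prediction mode).  ``peptide[15]`` (0-based) is the central S/T.
    """

    accession: str
    position: int
    peptide: str
    label: str = "unknown"

    def __post_init__(self):
        if len(self.peptide) != WINDOW_LENGTH:
            raise ValueError(
                f"window must have length {WINDOW_LENGTH}, got {len(self.peptide)}"
            )
        if self.center not in "ST":
            raise ValueError(f"window center must be S or T, got {self.center!r}")
        if self.label not in ("positive", "negative", "unknown"):
            raise ValueError(f"bad label {self.label!r}")

    @property
    def center(self) -> str:
        return self.peptide[DEFAULT_FLANK]


@dataclass
class LabeledDataset:
    """All labeled windows of a substrate collection, deterministically ordered."""

    windows: list[PeptideWindow] = field(default_factory=list)

    @property
    def n_positive(self) -> int:
        return sum(1 for w in self.windows if w.label == "positive")

    @property
    def n_negative(self) -> int:
        return sum(1 for w in self.windows if w.label == "negative")

    @property
    def counts(self) -> tuple[int, int]:
        return (self.n_positive, self.n_negative)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


def load_curated_sites() -> list[PhosphoSite]:
    """Load the embedded curated table of experimentally identified PrkC sites.

    The table ships inside the package: 36 sites in 14 Bacillus subtilis
    substrates, each with its UniProt accession, 1-based position, gene name
    and supporting PubMed identifiers.  Row order is preserved.
    """
    text = (
        resources.files("prkc_psp").joinpath("data/curated_sites.tsv").read_text()
    )
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    sites = [
        PhosphoSite(
            accession=r["accession"],
            position=int(r["position"]),
            gene=r["gene"],
            organism=r["organism"],
            pmids=tuple(r["pmids"].split(";")),
        )
        for r in rows
    ]
    # packaging integrity: fixed row/substrate counts and unique (acc, pos)
    assert len(sites) == 36, "curated table must contain exactly 36 sites"
    assert len({s.accession for s in sites}) == 14, "curated table spans 14 substrates"
    assert len({(s.accession, s.position) for s in sites}) == 36
    return sites


def _clean_sequence(raw: str, name: str) -> str:
    seq = str(raw).upper().replace("-", "").replace("*", "").replace(".", "")
    if seq != str(raw).upper():
        logger.warning("stripped gap/stop characters from %s", name)
    bad = sorted({c for c in seq if c not in ALPHABET})
    if bad:
        logger.warning("mapping non-standard letters %s in %s to %s", bad, name, PAD)
        for c in bad:
            if c not in _AMBIGUOUS:
                logger.warning("unexpected sequence character %r in %s", c, name)
            seq = seq.replace(c, PAD)
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, order preserved.

    Sequences are uppercased; gaps and stop symbols are stripped and ambiguous
    letters (B, Z, U, O, ...) mapped to X, each with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FastaParseError(f"FASTA file not found: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _clean_sequence(str(rec.seq), rec.id)
        if not seq:
            raise FastaParseError(f"record {rec.id!r} in {path} has an empty sequence")
        records.append(
            ProteinRecord(accession=rec.id, sequence=seq, description=rec.description)
        )
    if not records:
        raise FastaParseError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: str | Path, proteins: Iterable[ProteinRecord]) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for p in proteins:
            header = f">{p.accession}"
            if p.description and p.description != p.accession:
                header = f">{p.description}"
            fh.write(header + "\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


def extract_window(
    protein: ProteinRecord,
    position: int,
    flank: int = DEFAULT_FLANK,
    label: str = "unknown",
) -> PeptideWindow:
    """Extract the ``2*flank + 1``-mer window centered at ``position`` (1-based).

    Offsets falling before the first or after the last residue are filled with
    the padding symbol X, so every extractable window has the full length.
    Raises :class:`ResidueMismatchError` if the central residue is not S/T.
    """
    seq = protein.sequence
    if not 1 <= position <= len(seq):
        raise IndexError(
            f"position {position} out of range for {protein.accession} "
            f"(length {len(seq)})"
        )
    center = seq[position - 1]
    if center not in "ST":
        raise ResidueMismatchError(protein.accession, position, center)
    lo = position - 1 - flank
    hi = position + flank  # exclusive, 0-based
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    peptide = PAD * left_pad + seq[max(lo, 0) : min(hi, len(seq))] + PAD * right_pad
    return PeptideWindow(
        accession=protein.accession, position=position, peptide=peptide, label=label
    )


def build_labeled_dataset(
    proteins: Sequence[ProteinRecord], sites: Sequence[PhosphoSite]
) -> LabeledDataset:
    """Assemble the labeled benchmark from substrate sequences and known sites.

    Windows at the listed sites are positives; windows at every other S or T
    residue of the same proteins are negatives.  Output is ordered by
    (accession, position), so repeated builds are identical.
    """
    by_acc = {p.accession: p for p in proteins}
    if len(by_acc) != len(proteins):
        raise ValueError("duplicate accessions among proteins")
    positive_keys = set()
    for s in sites:
        if s.accession not in by_acc:
            raise KeyError(f"site accession {s.accession!r} not among supplied proteins")
        positive_keys.add((s.accession, s.position))
    windows: list[PeptideWindow] = []
    for acc in sorted(by_acc):
        protein = by_acc[acc]
        for pos0, residue in enumerate(protein.sequence):
            pos = pos0 + 1
            if residue in "ST":
                lab = "positive" if (acc, pos) in positive_keys else "negative"
                windows.append(extract_window(protein, pos, label=lab))
    # every claimed site must actually have been hit (S/T check via extract)
    got = {(w.accession, w.position) for w in windows if w.label == "positive"}
    missing = positive_keys - got
    if missing:
        acc, pos = sorted(missing)[0]
        raise ResidueMismatchError(acc, pos, by_acc[acc].sequence[pos - 1])
    return LabeledDataset(windows=windows)


def read_site_list(path: str | Path) -> list[tuple[str, int]]:
    """Read a TSV with header whose first two columns are accession, position."""
    path = Path(path)
    if not path.exists():
        raise SiteListParseError(f"site list not found: {path}")
    out: list[tuple[str, int]] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise SiteListParseError(f"{path}: empty file (header expected)")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise SiteListParseError(f"{path}:{lineno}: expected >= 2 columns")
            acc = row[0].strip()
            try:
                pos = int(row[1])
            except ValueError as exc:
                raise SiteListParseError(
                    f"{path}:{lineno}: position {row[1]!r} is not an integer"
                ) from exc
            if not acc or pos < 1:
                raise SiteListParseError(
                    f"{path}:{lineno}: bad record ({acc!r}, {pos})"
                )
            out.append((acc, pos))
    return out


def write_site_list(path: str | Path, sites: Iterable[tuple[str, int]]) -> None:
    """Write (accession, position) pairs as a two-column TSV with header."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["accession", "position"])
        for acc, pos in sites:
            w.writerow([acc, pos])


PREDICTION_COLUMNS = [
    "accession",
    "position",
    "residue",
    "peptide",
    "score",
    "passes_high",
    "passes_medium",
    "passes_low",
    "seen_in_training",
]


def write_predictions(path: str | Path, predictions) -> None:
    """Write site predictions as TSV (readable back with :func:`read_site_list`)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(PREDICTION_COLUMNS)
        for p in predictions:
            w.writerow(
                [
                    p.accession,
                    p.position,
                    p.residue,
                    p.peptide,
                    f"{p.score:.6f}",
                    int("high" in p.passed),
                    int("medium" in p.passed),
                    int("low" in p.passed),
                    int(p.seen_in_training),
                ]
            )


UNIPROT_FASTA_URL = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"


def fetch_substrates(path: str | Path, accessions: Sequence[str] | None = None) -> None:
    """Convenience helper: download the curated substrate sequences from UniProt.

    Network-gated; never invoked by the test suite.  The package itself does
    not require any download — this exists so that users can reconstruct the
    full benchmark (36 positives / 512 negatives on the canonical sequences)
    with one command.
    """
    from urllib.request import urlopen

    if accessions is None:
        accessions = sorted({s.accession for s in load_curated_sites()})
    with open(path, "w") as fh:
        for acc in accessions:
            with urlopen(UNIPROT_FASTA_URL.format(acc=acc), timeout=30) as resp:
                fh.write(resp.read().decode())
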