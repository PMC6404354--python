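"""Sequence and site-annotation I/O, window extraction, snapshot comparison.

Proteins are read from FASTA; site annotations from a tab-separated table
with columns ``protein_id, position, glyco_type, label``. Candidate-site
peptide windows are fixed 15-mers (seven residues either side of the site),
padded with ``'X'`` beyond the termini. Positions are 1-based throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: symbols outside the 20-letter alphabet that get mapped to 'X'
NONSTANDARD = set("BZUOJ*")

WINDOW_FLANK = 7
WINDOW_LENGTH = 2 * WINDOW_FLANK + 1  # 15
CENTER_INDEX = WINDOW_FLANK  # 0-based index of the candidate site (p8)

GLYCO_TYPES = ("C", "N", "O-S", "O-T")
#: residue each glycosylation type attaches to
TYPE_RESIDUE = {"C": "W", "N": "N", "O-S": "S", "O-T": "T"}

SITE_COLUMNS = ("protein_id", "position", "glyco_type", "label")


class FastaError(ValueError):
    """Malformed or inconsistent FASTA input."""


class SiteTableError(ValueError):
    """Malformed or inconsistent site-annotation table."""


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: sequence must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """1-based residue lookup."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"{self.id}: position {position} out of range 1..{len(self.sequence)}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class SiteAnnotation:
    protein_id: str
    position: int
    residue: str
    glyco_type: str
    label: str  # "positive" | "unlabelled"

    def __post_init__(self):
        if self.glyco_type not in GLYCO_TYPES:
            raise ValueError(f"unknown glyco_type {self.glyco_type!r}")
        if self.label not in ("positive", "unlabelled"):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def key(self) -> str:
        return f"{self.protein_id}:{self.position}"


@dataclass(frozen=True)
class PeptideWindow:
    """Fixed 15-symbol peptide centred on the candidate site."""

    symbols: str

    def __post_init__(self):
        if len(self.symbols) != WINDOW_LENGTH:
            raise ValueError(
                f"window must have exactly {WINDOW_LENGTH} symbols, got {len(self.symbols)}"
            )
        bad = set(self.symbols) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise ValueError(f"invalid window symbols: {sorted(bad)}")

    @property
    def center(self) -> str:
        return self.symbols[CENTER_INDEX]

    def __len__(self) -> int:
        return WINDOW_LENGTH

    def __str__(self) -> str:
        return self.symbols


@dataclass
class RelabellingSummary:
    """Arithmetic over two annotation snapshots of the same glycosylation type.

    ``pct_mislabelled`` is N1 over the growth in positives between snapshots;
    ``actual_prior`` is (N1 + earlier positives) over the earlier totals.
    Both are plain fractions (multiply by 100 for percentages).
    """

    n_new_positive: int
    n_previously_unlabelled: int  # N1
    pct_mislabelled: float
    actual_prior: float
    degenerate: bool = False  # no growth between snapshots

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _normalize_sequence(raw: str) -> tuple[str, int]:
    seq = raw.upper()
    n_sub = sum(1 for ch in seq if ch in NONSTANDARD)
    if n_sub:
        for ch in NONSTANDARD:
            seq = seq.replace(ch, "X")
    bad = set(seq) - set(AMINO_ACIDS) - {"X"}
    if bad:
        raise FastaError(f"unexpected sequence symbols: {sorted(bad)}")
    return seq, n_sub


def read_fasta(path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into ProteinRecords.

    Sequences are uppercased; non-standard symbols (B, Z, U, O, J, ``*``)
    are mapped to 'X' with a logged substitution count. Duplicate ids are
    an error.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    total_subs = 0
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FastaError(f"malformed FASTA {path}: {exc}") from exc
    for rec in parsed:
        if rec.id in seen:
            raise FastaError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise FastaError(f"record {rec.id!r} has an empty sequence")
        seq, n_sub = _normalize_sequence(str(rec.seq))
        total_subs += n_sub
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    if total_subs:
        logger.info("read_fasta: mapped %d non-standard symbols to 'X'", total_subs)
    return records


def write_fasta(path, proteins: Iterable[ProteinRecord]) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i : i + 60] + "\n")


def read_sites(path, proteins: Sequence[ProteinRecord]) -> tuple[list[SiteAnnotation], list[dict]]:
    """Read the TSV site table, filling residues from the sequences.

    Returns (accepted annotations, rejection report). Rows whose stated
    position carries a residue inconsistent with the glycosylation type are
    rejected and reported rather than raising; unknown protein ids raise.
    """
    by_id = {p.id: p for p in proteins}
    accepted: list[SiteAnnotation] = []
    rejected: list[dict] = []
    unknown: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip() for h in header] != list(SITE_COLUMNS):
            raise SiteTableError(
                f"expected header {SITE_COLUMNS}, got {tuple(header)}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(SITE_COLUMNS):
                raise SiteTableError(f"line {lineno}: expected 4 fields, got {len(parts)}")
            pid, pos_s, gtype, label = parts
            if pid not in by_id:
                unknown.append(pid)
                continue
            protein = by_id[pid]
            position = int(pos_s)
            if not 1 <= position <= len(protein):
                rejected.append(
                    {"line": lineno, "protein_id": pid, "position": position,
                     "reason": "position out of range"}
                )
                continue
            residue = protein.residue(position)
            expected = TYPE_RESIDUE.get(gtype)
            if expected is None:
                raise SiteTableError(f"line {lineno}: unknown glyco_type {gtype!r}")
            if residue != expected:
                rejected.append(
                    {"line": lineno, "protein_id": pid, "position": position,
                     "reason": f"residue {residue!r} inconsistent with type {gtype}"}
                )
                continue
            accepted.append(
                SiteAnnotation(protein_id=pid, position=position, residue=residue,
                               glyco_type=gtype, label=label)
            )
    if unknown:
        raise SiteTableError(f"unknown protein ids: {sorted(set(unknown))}")
    if rejected:
        logger.warning("read_sites: rejected %d inconsistent rows", len(rejected))
    return accepted, rejected


def write_sites(path, sites: Iterable[SiteAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SITE_COLUMNS) + "\n")
        for s in sites:
            fh.write(f"{s.protein_id}\t{s.position}\t{s.glyco_type}\t{s.label}\n")


def extract_window(protein: ProteinRecord, position: int) -> PeptideWindow:
    """15-mer around ``position`` (1-based), 'X'-padded past either terminus."""
    if not 1 <= position <= len(protein):
        raise IndexError(
            f"{protein.id}: position {position} out of range 1..{len(protein)}"
        )
    seq = protein.sequence
    lo = position - 1 - WINDOW_FLANK
    hi = position - 1 + WINDOW_FLANK + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    core = seq[max(lo, 0) : min(hi, len(seq))]
    return PeptideWindow("X" * left_pad + core + "X" * right_pad)


def matches_sequon(protein: ProteinRecord, position: int) -> bool:
    """N[!P][ST][!P] test at ``position`` (which must hold an N).

    Sites too close to the C-terminus to evaluate all four residues are
    treated as non-motif.
    """
    seq = protein.sequence
    i = position - 1
    if i + 3 >= len(seq):
        return False
    return (
        seq[i] == "N"
        and seq[i + 1] != "P"
        and seq[i + 2] in "ST"
        and seq[i + 3] != "P"
    )


def enumerate_candidates(
    protein: ProteinRecord,
    glyco_type: str,
    positive_positions: Iterable[int] = (),
    motif_mode: str | None = None,
) -> list[SiteAnnotation]:
    """All unlabelled candidate sites of ``glyco_type`` in ``protein``.

    Every position carrying the type's residue and not annotated positive is
    a candidate. For N-linked sites, ``motif_mode`` restricts to the sequon
    subset (``"motif"``) or its complement (``"non-motif"``); the two subsets
    partition the full candidate set.
    """
    residue = TYPE_RESIDUE[glyco_type]
    positives = set(positive_positions)
    out = []
    for i, ch in enumerate(protein.sequence, start=1):
        if ch != residue or i in positives:
            continue
        if glyco_type == "N" and motif_mode is not None:
            in_motif = matches_sequon(protein, i)
            if motif_mode == "motif" and not in_motif:
                continue
            if motif_mode == "non-motif" and in_motif:
                continue
        out.append(
            SiteAnnotation(protein_id=protein.id, position=i, residue=residue,
                           glyco_type=glyco_type, label="unlabelled")
        )
    return out


def compare_snapshots(
    earlier_positives: int,
    earlier_unlabelled: int,
    later_positives: int,
    n_previously_unlabelled: int,
) -> RelabellingSummary:
    """Relabelling arithmetic between two annotation snapshots.

    ``n_previously_unlabelled`` (N1) counts sites positive in the later
    snapshot that the earlier snapshot held as unlabelled. With no growth in
    positives the mislabelling percentage is undefined and reported as 0
    with ``degenerate=True``.
    """
    if later_positives < earlier_positives:
        raise ValueError(
            "snapshots out of order: later positive count "
            f"{later_positives} < earlier {earlier_positives}"
        )
    growth = later_positives - earlier_positives
    if growth == 0:
        pct = 0.0
        degenerate = True
    else:
        pct = n_previously_unlabelled / growth
        degenerate = False
    prior = (n_previously_unlabelled + earlier_positives) / (
        earlier_unlabelled + earlier_positives
    )
    return RelabellingSummary(
        n_new_positive=later_positives,
        n_previously_unlabelled=n_previously_unlabelled,
        pct_mislabelled=pct,
        actual_prior=prior,
        degenerate=degenerate,
    )
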