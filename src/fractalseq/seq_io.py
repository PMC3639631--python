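"""Reading, writing and dissecting nucleotide sequences.

Sequences are plain DNA strings over ``{A, C, G, T}``.  RNA input is
accepted and uracil is folded to T at read time: GenBank mRNA records are
written in DNA alphabet anyway, and uracil must never receive its own
numeric encoding because its atom sum collides with cytosine's (see
:mod:`fractalseq.encoding`).

An mRNA/CDS pair carries the coding region of a transcript plus the
*concatenated noncoding remainder* — the 5' and 3' untranslated stretches
joined in sequence order.  That remainder is the "long noncoding" portion
this package profiles against the coding portion.

Manifest coordinates are 1-based inclusive, matching the GenBank feature
convention; they are converted to 0-based half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
#: characters accepted on input; U is normalized to T
INPUT_BASES = frozenset("ACGTU")

ROLES = ("mrna", "cds", "noncoding", "other")


class SequenceAlphabetError(ValueError):
    """A residue outside the 4-letter DNA alphabet (after U->T folding)."""


class AmbiguousPlacementError(ValueError):
    """A CDS that matches its mRNA at more than one position."""


class PairingError(ValueError):
    """A manifest row that cannot be resolved into a valid mRNA/CDS pair."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated DNA sequence with a role label.

    Parameters
    ----------
    id : str
        Record identifier, unique within a loaded collection.
    residues : str
        Uppercase string over ``{A, C, G, T}``.
    role : str
        One of ``mrna``, ``cds``, ``noncoding``, ``other``.
    organism : str, optional
        Free-text species label, used for grouping in cross-species maps.
    """

    id: str
    residues: str
    role: str = "other"
    organism: Optional[str] = None

    def __post_init__(self) -> None:
        # an empty noncoding remainder is legal (CDS spanning the whole mRNA)
        if not self.residues and self.role != "noncoding":
            raise SequenceAlphabetError(f"sequence {self.id!r}: empty residues")
        if self.role not in ROLES:
            raise ValueError(f"sequence {self.id!r}: unknown role {self.role!r}")
        bad = next((i for i, c in enumerate(self.residues) if c not in VALID_BASES), None)
        if bad is not None:
            raise SequenceAlphabetError(
                f"sequence {self.id!r}: invalid residue {self.residues[bad]!r} "
                f"at position {bad + 1}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def _normalize(record_id: str, raw: str) -> str:
    """Uppercase and fold U->T, rejecting anything else non-ACGT."""
    up = raw.upper()
    for i, c in enumerate(up):
        if c not in INPUT_BASES:
            raise SequenceAlphabetError(
                f"sequence {record_id!r}: invalid residue {c!r} at position {i + 1}"
            )
    return up.replace("U", "T")


def read_fasta(
    path: str | Path,
    role: str = "other",
    organism: Optional[str] = None,
    drop_invalid: bool = False,
) -> list[NucleotideSequence]:
    """Read a (possibly multi-record, wrapped) FASTA file.

    Lowercase input and U residues are normalized; any other non-ACGT
    character raises :class:`SequenceAlphabetError` naming the record and
    1-based position, unless ``drop_invalid`` is set, in which case the
    offending record is skipped with a logged warning.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    out: list[NucleotideSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        try:
            residues = _normalize(rec.id, str(rec.seq))
            out.append(NucleotideSequence(rec.id, residues, role=role, organism=organism))
        except SequenceAlphabetError:
            if not drop_invalid:
                raise
            logger.warning("dropping record %r: non-ACGT residues", rec.id)
    if not out:
        raise ValueError(f"{path}: all records dropped as invalid")
    return out


def write_fasta(sequences: Iterable[NucleotideSequence], path: str | Path) -> None:
    """Write sequences as wrapped FASTA; round-trips id and residues."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences]
    SeqIO.write(records, str(Path(path)), "fasta")


@dataclass(frozen=True)
class MrnaCdsPair:
    """An mRNA, its CDS, and the concatenated noncoding remainder.

    ``noncoding`` is the 5' segment before the CDS joined to the 3' segment
    after it (empty when the CDS spans the whole mRNA, ``None`` when the CDS
    cannot be located on the mRNA at all).  ``cds_start``/``cds_end`` are
    1-based inclusive coordinates on the mRNA.
    """

    gene: str
    mrna: NucleotideSequence
    cds: NucleotideSequence
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    noncoding: Optional[NucleotideSequence] = field(default=None)

    def __post_init__(self) -> None:
        if not 0 < len(self.cds) <= len(self.mrna):
            raise PairingError(
                f"pair {self.gene!r}: CDS length {len(self.cds)} out of range "
                f"for mRNA length {len(self.mrna)}"
            )
        if (self.cds_start is None) != (self.cds_end is None):
            raise PairingError(f"pair {self.gene!r}: cds_start/cds_end must come together")
        if self.cds_start is not None:
            s, e = self.cds_start, self.cds_end
            if not (1 <= s <= e <= len(self.mrna)):
                raise PairingError(
                    f"pair {self.gene!r}: coordinates [{s}, {e}] out of range "
                    f"for mRNA length {len(self.mrna)}"
                )
            if self.mrna.residues[s - 1 : e] != self.cds.residues:
                raise PairingError(
                    f"pair {self.gene!r}: CDS does not match mRNA[{s}..{e}]"
                )
        if self.noncoding is not None:
            if len(self.noncoding) != len(self.mrna) - len(self.cds):
                raise PairingError(
                    f"pair {self.gene!r}: noncoding length inconsistent with "
                    "mRNA/CDS lengths"
                )

    @property
    def len_ratio(self) -> float:
        """CDS length over mRNA length, in (0, 1]."""
        return len(self.cds) / len(self.mrna)


def locate_cds(mrna: NucleotideSequence, cds: NucleotideSequence) -> tuple[int, int]:
    """Find the unique placement of a CDS on its mRNA.

    Returns 1-based inclusive ``(start, end)``.  Raises
    :class:`PairingError` when absent, :class:`AmbiguousPlacementError`
    when the CDS occurs more than once (no way to pick UTR boundaries).
    """
    hits = []
    pos = mrna.residues.find(cds.residues)
    while pos != -1:
        hits.append(pos)
        if len(hits) > 1:
            break
        pos = mrna.residues.find(cds.residues, pos + 1)
    if not hits:
        raise PairingError(
            f"CDS {cds.id!r} not found within mRNA {mrna.id!r}"
        )
    if len(hits) > 1:
        raise AmbiguousPlacementError(
            f"CDS {cds.id!r} matches mRNA {mrna.id!r} at multiple positions"
        )
    start = hits[0] + 1
    return start, start + len(cds) - 1


def extract_noncoding(
    mrna: NucleotideSequence,
    cds: NucleotideSequence,
    cds_start: Optional[int] = None,
    cds_end: Optional[int] = None,
) -> NucleotideSequence:
    """Concatenate the 5' and 3' noncoding regions flanking the CDS.

    When coordinates are not supplied the CDS is located by exact,
    unambiguous substring search.  The result preserves mRNA character
    order; a CDS spanning the whole mRNA yields an empty remainder.
    """
    if cds_start is None:
        cds_start, cds_end = locate_cds(mrna, cds)
    assert cds_end is not None
    remainder = mrna.residues[: cds_start - 1] + mrna.residues[cds_end:]
    return NucleotideSequence(
        id=f"{mrna.id}|noncoding", residues=remainder, role="noncoding",
        organism=mrna.organism,
    )


def build_pair(
    gene: str,
    mrna: NucleotideSequence,
    cds: NucleotideSequence,
    cds_start: Optional[int] = None,
    cds_end: Optional[int] = None,
) -> MrnaCdsPair:
    """Assemble a validated pair, deriving the noncoding remainder.

    If the CDS was supplied as a separate record and does not occur as a
    contiguous substring of the mRNA, the pair is still returned but with
    ``noncoding=None`` and no coordinates (noncoding metrics unavailable).
    An ambiguous placement is an error: silently picking one match would
    fabricate UTR boundaries.
    """
    if cds_start is None:
        try:
            cds_start, cds_end = locate_cds(mrna, cds)
        except AmbiguousPlacementError:
            raise
        except PairingError:
            logger.warning(
                "pair %r: CDS %r is not a contiguous substring of mRNA %r; "
                "noncoding region unavailable", gene, cds.id, mrna.id,
            )
            return MrnaCdsPair(gene=gene, mrna=mrna, cds=cds)
    noncoding = extract_noncoding(mrna, cds, cds_start, cds_end)
    return MrnaCdsPair(
        gene=gene, mrna=mrna, cds=cds,
        cds_start=cds_start, cds_end=cds_end, noncoding=noncoding,
    )


MANIFEST_COLUMNS = ("gene", "mrna_id", "cds_id", "cds_start", "cds_end")


def _collect_sequences(sequence_dir: str | Path) -> dict[str, NucleotideSequence]:
    sequence_dir = Path(sequence_dir)
    paths = sorted(
        p for p in sequence_dir.iterdir()
        if p.suffix.lower() in {".fa", ".fasta", ".fna"}
    )
    if not paths:
        raise ValueError(f"{sequence_dir}: no FASTA files (*.fa, *.fasta, *.fna)")
    pool: dict[str, NucleotideSequence] = {}
    for p in paths:
        for seq in read_fasta(p):
            if seq.id in pool:
                raise ValueError(f"duplicate sequence id {seq.id!r} across FASTA files")
            pool[seq.id] = seq
    return pool


def load_pairs(
    manifest: str | Path,
    sequence_dir: str | Path | Mapping[str, NucleotideSequence],
) -> list[MrnaCdsPair]:
    """Resolve a tab-separated pairing manifest against a sequence pool.

    The manifest has a header row with columns ``gene  mrna_id  cds_id
    cds_start  cds_end``; each row supplies either ``cds_id`` (a separate
    FASTA record) or 1-based inclusive coordinates, not both.
    ``sequence_dir`` may be a directory of FASTA files or an id->sequence
    mapping.
    """
    if isinstance(sequence_dir, (str, Path)):
        pool = _collect_sequences(sequence_dir)
    else:
        pool = dict(sequence_dir)

    table = pd.read_csv(manifest, sep="\t", dtype=str).fillna("")
    missing = [c for c in ("gene", "mrna_id") if c not in table.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")

    pairs: list[MrnaCdsPair] = []
    for idx, row in table.iterrows():
        gene = row["gene"]
        mrna_id = row["mrna_id"]
        if mrna_id not in pool:
            raise PairingError(f"manifest row {idx}: unknown mrna_id {mrna_id!r}")
        mrna = NucleotideSequence(
            pool[mrna_id].id, pool[mrna_id].residues, role="mrna",
            organism=pool[mrna_id].organism,
        )
        cds_id = row.get("cds_id", "")
        start_txt = str(row.get("cds_start", "")).strip()
        end_txt = str(row.get("cds_end", "")).strip()
        has_coords = bool(start_txt) or bool(end_txt)
        if bool(cds_id) == has_coords:
            raise PairingError(
                f"manifest row {idx} ({gene}): supply cds_id or coordinates, not both/neither"
            )
        if cds_id:
            if cds_id not in pool:
                raise PairingError(f"manifest row {idx}: unknown cds_id {cds_id!r}")
            cds = NucleotideSequence(
                pool[cds_id].id, pool[cds_id].residues, role="cds",
                organism=pool[cds_id].organism,
            )
            pairs.append(build_pair(gene, mrna, cds))
        else:
            try:
                start, end = int(start_txt), int(end_txt)
            except ValueError as exc:
                raise PairingError(
                    f"manifest row {idx} ({gene}): bad coordinates "
                    f"{start_txt!r}..{end_txt!r}"
                ) from exc
            if not (1 <= start <= end <= len(mrna)):
                raise PairingError(
                    f"manifest row {idx} ({gene}): coordinates [{start}, {end}] "
                    f"out of range for mRNA length {len(mrna)}"
                )
            cds = NucleotideSequence(
                id=f"{mrna.id}|cds", residues=mrna.residues[start - 1 : end], role="cds",
                organism=mrna.organism,
            )
            pairs.append(build_pair(gene, mrna, cds, start, end))
    return pairs
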