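"""Reading and writing the formats the mining pipeline touches.

Transcripts arrive as nucleotide FASTA (a de novo assembly), annotations and
read counts as TSV, and positional results leave as GFF3. The module also
loads the packaged reference tables: hand-transcribed peptide-precursor,
mature-peptide and RPKM tables for a spiny-lobster CNS neuropeptidome, used
as ground truth throughout the test-suite and the worked examples. Fixture
files are checksummed at load time so silent edits fail loudly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Transcript",
    "AnnotationRecord",
    "PeptideTableRow",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "read_annotation_table",
    "read_signal_table",
    "load_paper_fixtures",
    "write_gff3_features",
    "write_peptide_table",
]

_NT_ALPHABET = set("ACGTN")


class FastaFormatError(ValueError):
    """Malformed FASTA input (bad record, empty sequence, duplicate ID)."""


@dataclass(frozen=True)
class Transcript:
    """A nucleotide transcript record."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        if not seq:
            raise FastaFormatError(f"transcript {self.id!r} has an empty sequence")
        bad = set(seq) - _NT_ALPHABET
        if bad:
            raise FastaFormatError(
                f"transcript {self.id!r} contains non-nucleotide symbols {sorted(bad)}"
            )

    @property
    def length_nt(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AnnotationRecord:
    """A best-hit annotation for one transcript (description + e-value)."""

    transcript_id: str
    description: str
    evalue: float = 0.0
    comments: str = ""

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"{self.transcript_id}: e-value must be >= 0")


@dataclass(frozen=True)
class PeptideTableRow:
    """One mature-peptide row of the packaged peptide table."""

    family: str
    peptide: str
    amidated: bool
    best_hit: str = ""
    identity_note: str = ""


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read a nucleotide FASTA file into a list of :class:`Transcript`.

    Order is preserved, sequences are uppercased, and duplicate IDs are
    rejected. Raises :class:`FastaFormatError` naming the offending record.
    """
    path = Path(path)
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for index, record in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not record.id:
            raise FastaFormatError(f"record {index}: missing header ID")
        if record.id in seen:
            raise FastaFormatError(f"record {index}: duplicate ID {record.id!r}")
        try:
            transcripts.append(Transcript(record.id, str(record.seq)))
        except FastaFormatError as exc:
            raise FastaFormatError(f"record {index}: {exc}") from exc
        seen.add(record.id)
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.seq), id=t.id, description="") for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def read_annotation_table(path: str | Path) -> list[AnnotationRecord]:
    """Read a TSV of (transcript_id, description, evalue[, comments])."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AnnotationRecord(
                transcript_id=str(row.transcript_id),
                description=str(row.description),
                evalue=float(row.evalue) if str(getattr(row, "evalue", "")) else 0.0,
                comments=str(getattr(row, "comments", "")),
            )
        )
    return records


def read_signal_table(path: str | Path) -> dict[str, int]:
    """Read external signal-peptide annotations: transcript_id -> length (aa)."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.transcript_id): int(r.signal_length)
        for r in df.itertuples(index=False)
    }


# sha256 of the packaged fixture files; load_paper_fixtures refuses to serve
# a table whose bytes have drifted from the transcription that was validated
# against the printed source.
_FIXTURE_SHA256 = {
    "table1": "f89ac64cde8b6a24df93b865da98f037d392931231175758fc50ee2cce4397e3",
    "table2": "1232689aadcfdb8ca49dbedaddcde31d0d86479bde97dd9796cc9535af23487c",
    "table3": "06347c0892e25acfa1071dfc22c3a3b081c204ab1d05bf31b2735867d784aaf2",
}


def _fixture_bytes(name: str) -> bytes:
    data = resources.files("neuromine.data").joinpath(f"{name}.tsv").read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    expected = _FIXTURE_SHA256[name]
    if expected and digest != expected:
        raise RuntimeError(
            f"packaged fixture {name}.tsv has been modified "
            f"(sha256 {digest}, expected {expected})"
        )
    return data


def load_paper_fixtures(name: str):
    """Load a packaged reference table.

    ``table1`` -> list of :class:`AnnotationRecord` (37 precursor transcripts,
    with the hormone-family label and curator comment attached via a parallel
    DataFrame; returned as a DataFrame for convenience).
    ``table2`` -> list of :class:`PeptideTableRow` (printed mature peptides;
    amidation was marked by a trailing lowercase 'a' in the source and is
    stored as a boolean).
    ``table3`` -> DataFrame of per-sample RPKM values for the four pooled
    libraries (male/female x brain/eyestalk) plus printed tissue means.
    """
    import io

    if name not in _FIXTURE_SHA256:
        raise ValueError(f"unknown fixture {name!r}; expected table1|table2|table3")
    df = pd.read_csv(io.BytesIO(_fixture_bytes(name)), sep="\t", keep_default_na=False)
    if name == "table1":
        return df
    if name == "table2":
        return [
            PeptideTableRow(
                family=row.family,
                peptide=row.peptide,
                amidated=bool(int(row.amidated)),
                best_hit=row.best_hit,
                identity_note=row.identity_note,
            )
            for row in df.itertuples(index=False)
        ]
    return df


def table1_annotation_records(df: pd.DataFrame | None = None) -> list[AnnotationRecord]:
    """View the precursor table as annotation records for keyword mining."""
    if df is None:
        df = load_paper_fixtures("table1")
    return [
        AnnotationRecord(
            transcript_id=row.transcript,
            description=row.best_hit,
            evalue=float(row.evalue),
            comments=row.comments,
        )
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# GFF3 output


class CoordinateError(ValueError):
    """A feature's coordinates fall outside its transcript or ORF."""


def _peptide_nt_span(orf, start_aa: int, end_aa: int) -> tuple[int, int, str]:
    """Map protein positions (1-based, inclusive) onto transcript nt coords."""
    n_codons = (orf.end_nt - orf.start_nt + 1) // 3
    if not 1 <= start_aa <= end_aa:
        raise CoordinateError(f"bad protein span {start_aa}..{end_aa}")
    if end_aa > n_codons:
        raise CoordinateError(
            f"protein span {start_aa}..{end_aa} exceeds ORF of {n_codons} codons"
        )
    if orf.frame > 0:
        nt_start = orf.start_nt + 3 * (start_aa - 1)
        nt_end = orf.start_nt + 3 * end_aa - 1
        strand = "+"
    else:
        nt_end = orf.end_nt - 3 * (start_aa - 1)
        nt_start = orf.end_nt - 3 * end_aa + 1
        strand = "-"
    return nt_start, nt_end, strand


def write_gff3_features(precursors: Sequence, peptides, path: str | Path) -> None:
    """Write ORF / signal peptide / cleavage site / mature peptide features.

    ``precursors`` is a sequence of precursor models (each carrying the ORF,
    signal prediction and transcript length); ``peptides`` maps transcript_id
    to its mature peptides. Coordinates are 1-based inclusive per GFF3.
    """
    lines = ["##gff-version 3"]
    for model in precursors:
        orf = model.orf
        tid = orf.transcript_id
        strand = "+" if orf.frame > 0 else "-"
        if model.transcript_length is not None and orf.end_nt > model.transcript_length:
            raise CoordinateError(
                f"ORF on {tid} ends at {orf.end_nt}, beyond transcript "
                f"length {model.transcript_length}"
            )
        lines.append(
            "\t".join(
                [
                    tid, "neuromine", "ORF",
                    str(orf.start_nt), str(orf.end_nt), ".", strand,
                    "0", f"ID=orf_{tid};completeness={orf.completeness}",
                ]
            )
        )
        if model.signal is not None and model.signal.length_aa > 0:
            s, e, st = _peptide_nt_span(orf, 1, model.signal.length_aa)
            lines.append(
                "\t".join(
                    [tid, "neuromine", "signal_peptide", str(s), str(e), ".",
                     st, ".", f"ID=signal_{tid};source={model.signal.source}"]
                )
            )
        for i, pep in enumerate(peptides.get(tid, []), start=1):
            s, e, st = _peptide_nt_span(orf, pep.start_aa, pep.end_aa)
            attrs = f"ID=pep_{tid}_{i};sequence={pep.sequence}"
            if pep.amidated:
                attrs += ";amidated=true"
            if pep.pyroglutamate:
                attrs += ";pyroglutamate=true"
            lines.append(
                "\t".join(
                    [tid, "neuromine", "mature_peptide", str(s), str(e), ".",
                     st, "0", attrs]
                )
            )
            if pep.site_motif:
                site_start = pep.end_aa + (2 if pep.amidated else 1)
                site_end = site_start + len(pep.site_motif) - 1
                s, e, st = _peptide_nt_span(orf, site_start, site_end)
                lines.append(
                    "\t".join(
                        [tid, "neuromine", "cleavage_site", str(s), str(e), ".",
                         st, ".", f"ID=site_{tid}_{i};motif={pep.site_motif}"]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_peptide_table(rows: Iterable[dict], path: str | Path) -> None:
    """Write the mature-peptide report TSV."""
    cols = [
        "transcript_id", "family", "start_aa", "end_aa",
        "sequence", "amidated", "pyroglutamate", "evidence",
    ]
    df = pd.DataFrame(list(rows))
    for c in cols:
        if c not in df.columns:
            df[c] = ""
    df[cols].to_csv(path, sep="\t", index=False)
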