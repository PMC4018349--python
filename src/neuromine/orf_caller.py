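"""Six-frame ORF discovery and precursor-ORF selection.

De novo assemblies are unoriented, so all six reading frames are scanned with
the standard genetic code. Besides conventional ATG-to-stop ORFs, three
partial classes are reported, because neuropeptide precursors in fragmented
assemblies frequently run off a contig edge:

* ``partial_nterm`` - frame start to the first stop (N-terminus truncated)
* ``partial_cterm`` - an ATG-initiated frame that never reaches a stop
* ``partial_both``  - a frame with no stop at all (both ends open)

Codons containing ``N`` translate to ``X`` and terminate ORF extension.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .sequence_io import Transcript

__all__ = ["OpenReadingFrame", "find_orfs", "select_precursor_orf"]

COMPLETENESS = ("complete", "partial_nterm", "partial_cterm", "partial_both")

_FRAME_ORDER = {f: i for i, f in enumerate((1, 2, 3, -1, -2, -3))}


@dataclass(frozen=True)
class OpenReadingFrame:
    transcript_id: str
    frame: int  # +1..+3 forward, -1..-3 reverse
    start_nt: int  # 1-based inclusive, transcript coordinates
    end_nt: int  # includes the stop codon when one is present
    protein: str
    completeness: str
    has_stop: bool

    def __post_init__(self) -> None:
        if self.completeness not in COMPLETENESS:
            raise ValueError(f"bad completeness {self.completeness!r}")
        span = self.end_nt - self.start_nt + 1
        expected = span // 3 - (1 if self.has_stop else 0)
        if len(self.protein) != expected:
            raise ValueError(
                f"{self.transcript_id} frame {self.frame}: protein length "
                f"{len(self.protein)} inconsistent with span {span}"
            )

    @property
    def length_aa(self) -> int:
        return len(self.protein)


def _translate_frame(seq: str) -> str:
    """Translate a frame, stops as '*', N-containing codons as 'X'."""
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def find_orfs(transcript: Transcript, min_aa: int = 40) -> list[OpenReadingFrame]:
    """Scan all six frames of ``transcript`` for complete and partial ORFs.

    ORFs shorter than ``min_aa`` residues are dropped. For each frame the
    protein sequence is cut into stop-delimited segments; a segment yields a
    complete ORF from its first Met when a stop follows, the leading segment
    additionally yields an edge-truncated (partial_nterm) ORF, and the
    trailing stop-free segment yields a partial_cterm (from its first Met) or
    partial_both (whole open frame) ORF. 'X' residues (ambiguity codons)
    terminate extension like stops but are not reported as boundaries.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = transcript.seq
    if len(seq) < 3:
        return []
    rc = str(Seq(seq).reverse_complement())
    orfs: list[OpenReadingFrame] = []
    for frame in (1, 2, 3, -1, -2, -3):
        offset = abs(frame) - 1
        strand_seq = seq if frame > 0 else rc
        protein = _translate_frame(strand_seq[offset:])
        if not protein:
            continue
        orfs.extend(
            _orfs_in_frame(transcript, frame, offset, protein, len(seq), min_aa)
        )
    return orfs


def _segment_bounds(protein: str):
    """Yield (start, end, has_stop) protein-index segments between stops/Xs."""
    start = 0
    for i, aa in enumerate(protein):
        if aa in "*X":
            yield start, i, aa == "*"
            start = i + 1
    if start < len(protein):
        yield start, len(protein), False


def _orfs_in_frame(transcript, frame, offset, protein, tlen, min_aa):
    out = []
    leading = True
    for seg_start, seg_end, has_stop in _segment_bounds(protein):
        segment = protein[seg_start:seg_end]
        met = segment.find("M")
        if has_stop:
            if leading and met != 0 and seg_end - seg_start >= min_aa:
                out.append(
                    _make_orf(transcript, frame, offset, seg_start, seg_end,
                              protein, tlen, "partial_nterm", True)
                )
            if met >= 0 and seg_end - (seg_start + met) >= min_aa:
                out.append(
                    _make_orf(transcript, frame, offset, seg_start + met,
                              seg_end, protein, tlen, "complete", True)
                )
        else:
            if leading and met != 0 and seg_end - seg_start >= min_aa:
                out.append(
                    _make_orf(transcript, frame, offset, seg_start, seg_end,
                              protein, tlen, "partial_both", False)
                )
            if met >= 0 and seg_end - (seg_start + met) >= min_aa:
                out.append(
                    _make_orf(transcript, frame, offset, seg_start + met,
                              seg_end, protein, tlen, "partial_cterm", False)
                )
        leading = False
    return out


def _make_orf(transcript, frame, offset, aa_start, aa_end, protein, tlen,
              completeness, has_stop):
    """Build an ORF from protein indices [aa_start, aa_end) in this frame."""
    nt_from = offset + 3 * aa_start  # 0-based on the translated strand
    nt_to = offset + 3 * aa_end + (3 if has_stop else 0)  # exclusive
    if frame > 0:
        start_nt, end_nt = nt_from + 1, nt_to
    else:  # map reverse-strand coordinates back onto the forward transcript
        start_nt, end_nt = tlen - nt_to + 1, tlen - nt_from
    return OpenReadingFrame(
        transcript_id=transcript.id,
        frame=frame,
        start_nt=start_nt,
        end_nt=end_nt,
        protein=protein[aa_start:aa_end],
        completeness=completeness,
        has_stop=has_stop,
    )


def select_precursor_orf(orfs: list[OpenReadingFrame]) -> OpenReadingFrame:
    """Pick the precursor ORF: longest protein, then complete-before-partial,
    then frame order (+1,+2,+3,-1,-2,-3), then lowest start coordinate."""
    if not orfs:
        raise ValueError("cannot select a precursor ORF from an empty collection")
    return min(
        orfs,
        key=lambda o: (
            -o.length_aa,
            0 if o.completeness == "complete" else 1,
            _FRAME_ORDER[o.frame],
            o.start_nt,
        ),
    )
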