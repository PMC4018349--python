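"""Precursor maturation: from a prepro-peptide to its mature peptides.

A secreted neuropeptide precursor is organised as

    signal peptide | peptide [G] site | peptide [G] site | ... | peptide

where ``site`` is a prohormone-convertase cleavage motif (dibasic KR/RK/KK/RR
by default; monobasic R is an opt-in used by e.g. myosuppressin precursors)
and an optional glycine immediately before the site donates the C-terminal
amide of the mature peptide. Processing steps modelled here:

1. signal-peptide removal (sequence heuristic, or an external annotation);
2. convertase cleavage immediately C-terminal to each site motif;
3. carboxypeptidase trimming of the exposed basic residues - only residues
   that belong to the matched motif are removed, never peptide-intrinsic
   basics (a mature peptide may itself end in R);
4. amidation when the trimmed peptide exposes a C-terminal glycine;
5. N-terminal pyroglutamate flagged (never edited) for Gln-initial peptides.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

__all__ = [
    "DIBASIC_GRAMMAR",
    "SignalPrediction",
    "CleavageSite",
    "MaturePeptide",
    "PrecursorModel",
    "DegenerateSegmentError",
    "predict_signal_peptide",
    "find_cleavage_sites",
    "segment_propeptide",
    "trim_and_modify",
    "process_precursor",
]

#: Default prohormone-convertase grammar: dibasic motifs only.
DIBASIC_GRAMMAR: tuple[str, ...] = ("KR", "RK", "KK", "RR")

#: Residues accepted at the -3 and -1 positions of a signal-peptidase site.
SMALL_RESIDUES = set("AGSCT")

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")


class DegenerateSegmentError(ValueError):
    """Trimming a segment would leave an empty mature peptide."""


@dataclass(frozen=True)
class SignalPrediction:
    length_aa: int
    source: str = "heuristic"  # or "external"
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.length_aa < 0 or self.length_aa > 45:
            raise ValueError("signal length must be in [0, 45] aa")
        if self.source not in ("heuristic", "external"):
            raise ValueError(f"bad signal source {self.source!r}")


@dataclass(frozen=True)
class CleavageSite:
    motif: str
    pos_aa: int  # 1-based position of the motif's LAST residue in the propeptide
    kind: str  # dibasic | monobasic


@dataclass(frozen=True)
class MaturePeptide:
    raw_segment: str
    sequence: str
    amidated: bool
    pyroglutamate: bool
    start_aa: int  # 1-based within the full precursor protein
    end_aa: int
    site_motif: str = ""  # trailing convertase motif of the raw segment


@dataclass(frozen=True)
class PrecursorModel:
    protein: str
    signal: SignalPrediction | None
    propeptide: str
    sites: tuple[CleavageSite, ...]
    orf: object | None = None
    transcript_length: int | None = None


def _max_core_hydrophobicity(protein: str, upto: int, window: int = 6) -> float:
    """Best mean Kyte-Doolittle score of a ``window``-residue run in
    protein[0:upto]. Returns -inf when the region is shorter than the window."""
    best = float("-inf")
    for i in range(0, upto - window + 1):
        mean = sum(KYTE_DOOLITTLE[aa] for aa in protein[i : i + window]) / window
        best = max(best, mean)
    return best


def predict_signal_peptide(
    protein: str,
    min_len: int = 8,
    max_len: int = 45,
    core_threshold: float = 1.6,
) -> SignalPrediction:
    """Von-Heijne-style signal-peptide heuristic.

    A candidate cleavage point after residue ``L`` qualifies when the
    residues at positions -1 and -3 (i.e. L and L-2) are small (A/G/S/C/T,
    the signal-peptidase pocket rule) and some 6-residue window upstream of
    the -3 position has mean Kyte-Doolittle hydrophobicity above
    ``core_threshold`` (the h-region). Among qualifying points the one with
    the most hydrophobic core wins; ties go to the shortest signal. Returns
    length 0 when nothing qualifies. This is a coarse stand-in intended for
    synthetic and well-behaved sequences - curated annotations can be
    supplied instead and then take precedence downstream.
    """
    if len(protein) < 15:
        return SignalPrediction(0, "heuristic", 0.0)
    best_len, best_score = 0, float("-inf")
    for L in range(min_len, min(max_len, len(protein) - 1) + 1):
        minus1 = protein[L - 1]
        minus3 = protein[L - 3]
        if minus1 not in SMALL_RESIDUES or minus3 not in SMALL_RESIDUES:
            continue
        core = _max_core_hydrophobicity(protein, upto=L - 3)
        if core <= core_threshold:
            continue
        if core > best_score:
            best_len, best_score = L, core
    if best_len == 0:
        return SignalPrediction(0, "heuristic", 0.0)
    return SignalPrediction(best_len, "heuristic", best_score)


def find_cleavage_sites(
    propeptide: str,
    grammar: tuple[str, ...] = DIBASIC_GRAMMAR,
    monobasic_r: bool = False,
) -> list[CleavageSite]:
    """Left-to-right, non-overlapping scan for convertase motifs.

    Overlapping candidates (e.g. ``KRR``) resolve to the leftmost match and
    scanning resumes after the consumed motif. With ``monobasic_r`` a single
    R not part of a dibasic motif is also a site (opt-in; on by default it
    would falsely split peptides with internal arginines).
    """
    if not grammar:
        raise ValueError("cleavage grammar must be non-empty")
    motifs = sorted(grammar, key=len, reverse=True)  # longest match first
    sites: list[CleavageSite] = []
    i = 0
    n = len(propeptide)
    while i < n:
        hit = next(
            (m for m in motifs if propeptide.startswith(m, i)), None
        )
        if hit is not None:
            sites.append(
                CleavageSite(hit, i + len(hit), "dibasic" if len(hit) > 1 else "monobasic")
            )
            i += len(hit)
        elif monobasic_r and propeptide[i] == "R":
            sites.append(CleavageSite("R", i + 1, "monobasic"))
            i += 1
        else:
            i += 1
    return sites


def segment_propeptide(
    propeptide: str, sites: list[CleavageSite]
) -> list[tuple[str, int]]:
    """Cut immediately C-terminal to each site motif.

    Returns (raw_segment, start_aa) pairs where ``start_aa`` is the 1-based
    position of the segment within the propeptide. Segments carry their
    trailing motif; their concatenation reproduces the propeptide exactly;
    empty segments between adjacent sites are dropped.
    """
    segments: list[tuple[str, int]] = []
    prev = 0
    for site in sorted(sites, key=lambda s: s.pos_aa):
        end = site.pos_aa  # inclusive, 1-based == exclusive 0-based
        if propeptide[end - len(site.motif) : end] != site.motif:
            raise ValueError(
                f"site {site.motif}@{site.pos_aa} does not match the propeptide"
            )
        if end > prev:
            segments.append((propeptide[prev:end], prev + 1))
        prev = end
    if prev < len(propeptide):
        segments.append((propeptide[prev:], prev + 1))
    return segments


def trim_and_modify(
    segment: str, trailing_motif: str, start_aa: int = 1
) -> MaturePeptide:
    """Carboxypeptidase-trim a raw segment and flag terminal modifications.

    Exactly the ``trailing_motif`` residues are removed (empty motif for the
    precursor-terminal segment). A then-exposed C-terminal glycine is the
    amide donor: it is stripped and the peptide flagged amidated. A terminal
    segment ending in G is treated the same way. An N-terminal glutamine is
    flagged as a pyroglutamate candidate without editing the sequence.
    """
    if trailing_motif:
        if not segment.endswith(trailing_motif):
            raise ValueError(
                f"segment {segment!r} does not end with motif {trailing_motif!r}"
            )
        core = segment[: len(segment) - len(trailing_motif)]
    else:
        core = segment
    amidated = False
    if core.endswith("G") and len(core) > 1:
        core = core[:-1]
        amidated = True
    if not core:
        raise DegenerateSegmentError(
            f"segment {segment!r} is nothing but cleavage/amidation residues"
        )
    return MaturePeptide(
        raw_segment=segment,
        sequence=core,
        amidated=amidated,
        pyroglutamate=core.startswith("Q"),
        start_aa=start_aa,
        end_aa=start_aa + len(core) - 1,
        site_motif=trailing_motif,
    )


def process_precursor(
    protein: str,
    signal: SignalPrediction | None = None,
    grammar: tuple[str, ...] = DIBASIC_GRAMMAR,
    monobasic_r: bool = False,
) -> tuple[PrecursorModel, list[MaturePeptide]]:
    """Run the full maturation cascade on a precursor protein.

    ``signal`` defaults to the packaged heuristic; pass an external
    prediction to override it. Peptide coordinates are reported on the full
    precursor protein (signal included).
    """
    protein = protein.upper()
    if signal is None:
        signal = predict_signal_peptide(protein)
    if signal.length_aa >= len(protein):
        raise ValueError("signal peptide consumes the whole protein")
    propeptide = protein[signal.length_aa :]
    sites = find_cleavage_sites(propeptide, grammar, monobasic_r)
    peptides: list[MaturePeptide] = []
    segments = segment_propeptide(propeptide, sites)
    for idx, (segment, seg_start) in enumerate(segments):
        trailing = ""
        for motif in sorted(grammar, key=len, reverse=True):
            # the segment's own trailing motif, if it was cut at a site
            if segment.endswith(motif) and _segment_ends_at_site(
                seg_start, segment, sites, motif
            ):
                trailing = motif
                break
        if not trailing and monobasic_r and _segment_ends_at_site(
            seg_start, segment, sites, "R"
        ):
            trailing = "R"
        try:
            pep = trim_and_modify(segment, trailing, start_aa=seg_start)
        except DegenerateSegmentError:
            continue  # pure linker material (e.g. trailing site at the C-end)
        offset = signal.length_aa
        peptides.append(
            MaturePeptide(
                raw_segment=pep.raw_segment,
                sequence=pep.sequence,
                amidated=pep.amidated,
                pyroglutamate=pep.pyroglutamate,
                start_aa=pep.start_aa + offset,
                end_aa=pep.end_aa + offset,
                site_motif=pep.site_motif,
            )
        )
    model = PrecursorModel(
        protein=protein,
        signal=signal,
        propeptide=propeptide,
        sites=tuple(sites),
    )
    return model, peptides


def _segment_ends_at_site(seg_start, segment, sites, motif) -> bool:
    end_pos = seg_start + len(segment) - 1  # 1-based position of last residue
    return any(s.pos_aa == end_pos and s.motif == motif for s in sites)
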