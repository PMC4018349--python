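"""Peptide- and precursor-level hormone family assignment.

Three evidence channels, in decreasing precedence:

* **motif** - anchored sequence patterns on mature peptides (the C-terminal
  YXFGLamide of A-type allatostatins, W-X6-Wamide of B-type, the
  QCxFNxxSCF box shared by C-type allatostatins and prohormone-1, ...);
* **scaffold** - cysteine-count plus domain-length fingerprints for the
  disulfide-rich protein hormones (CHH/MIH-type 6-cysteine domains,
  neuroparsin's 12, CFSH's 10, ...);
* **keyword** - mining of BLAST best-hit description strings, the coarsest
  channel, with a generic "hormone" bucket for otherwise unnamed candidates.

The motif library, scaffold table and keyword map are packaged data files
(YAML), not code; see ``neuromine/data/``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .maturation import MaturePeptide
from .sequence_io import AnnotationRecord

__all__ = [
    "FamilyMotif",
    "CysteineScaffold",
    "FamilyAssignment",
    "UNCLASSIFIED",
    "UNASSIGNED_HORMONE",
    "load_motif_library",
    "load_scaffolds",
    "load_keyword_map",
    "match_peptide_motifs",
    "scan_cysteine_scaffold",
    "keyword_mine",
    "assign_family",
    "classify_annotation_records",
]

UNCLASSIFIED = "unclassified"
UNASSIGNED_HORMONE = "unassigned_hormone"


@dataclass(frozen=True)
class FamilyMotif:
    family: str
    pattern: str
    requires_amidation: bool = False
    min_len: int = 1
    max_len: int = 10_000
    cys_count: int | None = None
    scope: str = "peptide"

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError(f"{self.family}: min_len > max_len")
        re.compile(self.pattern)  # fail fast on a bad pattern

    @property
    def specificity(self) -> int:
        """Number of literal residue characters in the pattern (tie-breaker:
        more literals = more specific)."""
        return sum(1 for c in re.sub(r"\[[^\]]*\]|\{[^}]*\}", "", self.pattern)
                   if c.isalpha())


@dataclass(frozen=True)
class CysteineScaffold:
    family: str
    cys_count: tuple[int, ...]
    min_len: int
    max_len: int

    @property
    def midpoint(self) -> float:
        return (self.min_len + self.max_len) / 2


@dataclass(frozen=True)
class FamilyAssignment:
    subject_id: str
    family: str
    evidence: str  # motif | scaffold | keyword | none
    detail: str = ""
    secondary: tuple[str, ...] = ()


def _data_path(name: str) -> str:
    return resources.files("neuromine.data").joinpath(name).read_text()


def load_motif_library(path: str | Path | None = None) -> list[FamilyMotif]:
    text = Path(path).read_text() if path else _data_path("motifs.yaml")
    entries = yaml.safe_load(text)
    return [FamilyMotif(**e) for e in entries]


def load_scaffolds(path: str | Path | None = None) -> list[CysteineScaffold]:
    text = Path(path).read_text() if path else _data_path("scaffolds.yaml")
    out = []
    for e in yaml.safe_load(text):
        cys = e["cys_count"]
        cys = tuple(cys) if isinstance(cys, list) else (int(cys),)
        out.append(
            CysteineScaffold(e["family"], cys, int(e["min_len"]), int(e["max_len"]))
        )
    return out


def load_keyword_map(path: str | Path | None = None) -> dict:
    text = Path(path).read_text() if path else _data_path("keywords.yaml")
    data = yaml.safe_load(text)
    return {
        "families": {f: [t.lower() for t in terms] for f, terms in data["families"].items()},
        "generic": [t.lower() for t in data.get("generic", [])],
    }


def match_peptide_motifs(
    peptide: MaturePeptide | str,
    library: list[FamilyMotif] | None = None,
    amidated: bool | None = None,
    subject_id: str = "",
) -> list[FamilyAssignment]:
    """All motif-library families matching a mature peptide.

    Length, amidation and cysteine-count constraints are enforced before the
    pattern is searched. Accepts a :class:`MaturePeptide` or a plain sequence
    plus ``amidated`` flag.
    """
    if library is None:
        library = load_motif_library()
    if isinstance(peptide, MaturePeptide):
        seq, amide = peptide.sequence, peptide.amidated
    else:
        seq, amide = str(peptide), bool(amidated)
    hits = []
    for motif in library:
        if motif.scope != "peptide":
            continue
        if motif.requires_amidation and not amide:
            continue
        if not motif.min_len <= len(seq) <= motif.max_len:
            continue
        if motif.cys_count is not None and seq.count("C") != motif.cys_count:
            continue
        if re.search(motif.pattern, seq):
            hits.append(
                FamilyAssignment(subject_id, motif.family, "motif", motif.pattern)
            )
    return hits


def scan_cysteine_scaffold(
    domain: str,
    scaffolds: list[CysteineScaffold] | None = None,
    subject_id: str = "",
    length_slack: int = 0,
) -> list[FamilyAssignment]:
    """Families whose cysteine count and domain-length range both match.

    ``length_slack`` relaxes the length bounds symmetrically (useful at the
    71-73 vs 74 residue boundary between the hyperglycemic-hormone and
    molt-inhibiting-hormone scaffolds, where assemblies are often a residue
    off); ambiguous multi-family results are resolved downstream.
    """
    if len(domain) < 20:
        raise ValueError("domain too short for a scaffold scan (< 20 aa)")
    if scaffolds is None:
        scaffolds = load_scaffolds()
    n_cys = domain.count("C")
    hits = []
    for sc in scaffolds:
        if n_cys in sc.cys_count and (
            sc.min_len - length_slack <= len(domain) <= sc.max_len + length_slack
        ):
            hits.append(
                FamilyAssignment(
                    subject_id, sc.family, "scaffold",
                    f"{n_cys}C/{len(domain)}aa",
                )
            )
    return hits


def keyword_mine(
    records: list[AnnotationRecord],
    keywords: dict | None = None,
    use_comments: bool = False,
) -> list[FamilyAssignment]:
    """Scan annotation descriptions for hormone names and abbreviations.

    Matching is case-insensitive substring search over the whole description
    (optionally falling back to the curator comment field when the
    description itself names no family). Records hit only by a generic term
    ("hormone") are flagged ``unassigned_hormone``.
    """
    if keywords is None:
        keywords = load_keyword_map()
    out: list[FamilyAssignment] = []
    for rec in records:
        texts = [rec.description]
        if use_comments and rec.comments:
            texts.append(rec.comments)
        families: list[tuple[str, str]] = []
        for text in texts:
            low = text.lower()
            for family, terms in keywords["families"].items():
                for term in terms:
                    if term in low:
                        families.append((family, term))
                        break
            if families:
                break  # description suffices; don't dilute with comments
        if families:
            primary, term = families[0]
            secondary = [f for f, _ in families[1:]]
            if any(t in rec.description.lower() for t in keywords["generic"]):
                secondary.append(UNASSIGNED_HORMONE)
            out.append(
                FamilyAssignment(
                    rec.transcript_id, primary, "keyword", term,
                    secondary=tuple(dict.fromkeys(secondary)),
                )
            )
        elif any(t in rec.description.lower() for t in keywords["generic"]):
            out.append(
                FamilyAssignment(rec.transcript_id, UNASSIGNED_HORMONE, "keyword",
                                 "generic")
            )
    return out


def assign_family(
    motif_hits: list[FamilyAssignment] | None = None,
    scaffold_hits: list[FamilyAssignment] | None = None,
    keyword_hits: list[FamilyAssignment] | None = None,
    subject_id: str = "",
    motif_library: list[FamilyMotif] | None = None,
    scaffolds: list[CysteineScaffold] | None = None,
    domain_length: int | None = None,
) -> FamilyAssignment:
    """Combine evidence channels into one primary assignment.

    Precedence: motif > scaffold > keyword. Within the motif level ties go to
    the most specific pattern (most literal residues); within the scaffold
    level to the family whose length-range midpoint is nearest the observed
    domain length. Non-primary candidates are retained in ``secondary``.
    """
    motif_hits = motif_hits or []
    scaffold_hits = scaffold_hits or []
    keyword_hits = [
        h for h in (keyword_hits or []) if h.family != UNASSIGNED_HORMONE
    ] or [h for h in (keyword_hits or [])]

    def finish(primary: FamilyAssignment, pool: list[FamilyAssignment]):
        others = tuple(
            dict.fromkeys(
                [h.family for h in pool if h.family != primary.family]
                + list(primary.secondary)
            )
        )
        return FamilyAssignment(
            subject_id or primary.subject_id, primary.family, primary.evidence,
            primary.detail, secondary=others,
        )

    if motif_hits:
        if motif_library is None:
            motif_library = load_motif_library()
        spec_map = {m.pattern: m.specificity for m in motif_library}
        best = max(motif_hits, key=lambda h: spec_map.get(h.detail, 0))
        return finish(best, motif_hits + scaffold_hits + keyword_hits)
    if scaffold_hits:
        if len(scaffold_hits) > 1 and domain_length is not None:
            if scaffolds is None:
                scaffolds = load_scaffolds()
            mid = {s.family: s.midpoint for s in scaffolds}
            best = min(
                scaffold_hits,
                key=lambda h: abs(mid.get(h.family, 1e9) - domain_length),
            )
        else:
            best = scaffold_hits[0]
        return finish(best, motif_hits + scaffold_hits + keyword_hits)
    if keyword_hits:
        return finish(keyword_hits[0], keyword_hits)
    return FamilyAssignment(subject_id, UNCLASSIFIED, "none")


def classify_annotation_records(
    records: list[AnnotationRecord], keywords: dict | None = None
) -> list[FamilyAssignment]:
    """Keyword-classify a whole annotation table, one assignment per record.

    Descriptions are mined first; records whose best hit is uninformative
    (e.g. a "hypothetical protein") fall back to the curator comment string,
    so every curated record receives its family.
    """
    if keywords is None:
        keywords = load_keyword_map()
    by_id = {r.transcript_id: r for r in records}
    first = {h.subject_id: h for h in keyword_mine(records, keywords)}
    out = []
    for rec in records:
        hit = first.get(rec.transcript_id)
        if hit is None or hit.family == UNASSIGNED_HORMONE:
            retry = keyword_mine([by_id[rec.transcript_id]], keywords, use_comments=True)
            if retry and retry[0].family != UNASSIGNED_HORMONE:
                hit = retry[0]
        out.append(
            assign_family(keyword_hits=[hit] if hit else [],
                          subject_id=rec.transcript_id)
        )
    return out
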