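"""End-to-end orchestration: transcripts in, peptide/family/expression
reports out, with a manifest recording inputs, seeds and checksums so a rerun
with the same config is byte-identical (timestamps excluded by design)."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .conservation import consensus_motif
from .expression import CountMatrix, SampleInfo, quantify, summarize
from .family_classifier import (
    assign_family,
    classify_annotation_records,
    load_motif_library,
    match_peptide_motifs,
)
from .maturation import (
    DIBASIC_GRAMMAR,
    SignalPrediction,
    predict_signal_peptide,
    process_precursor,
)
from .orf_caller import find_orfs, select_precursor_orf
from .sequence_io import (
    read_annotation_table,
    read_fasta,
    read_signal_table,
    write_gff3_features,
    write_peptide_table,
)

log = logging.getLogger("neuromine")

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


@dataclass
class PipelineConfig:
    fasta: str
    out_dir: str
    annotations: str | None = None
    signals: str | None = None
    counts: str | None = None
    motif_library: str | None = None
    grammar: tuple[str, ...] = DIBASIC_GRAMMAR
    monobasic_r: bool = False
    min_orf_aa: int = 40
    alpha: float = 0.05
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "grammar" in raw:
            raw["grammar"] = tuple(str(raw["grammar"]).replace(" ", "").split(","))
        return cls(**raw)

    def validate(self) -> None:
        if not Path(self.fasta).exists():
            raise ConfigError(f"fasta not found: {self.fasta}")
        for label in ("annotations", "signals", "counts", "motif_library"):
            value = getattr(self, label)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"{label} not found: {value}")
        for motif in self.grammar:
            if not motif or not set(motif) <= set("KR"):
                raise ConfigError(f"invalid cleavage motif {motif!r}")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")

    def to_yaml(self) -> str:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        data["grammar"] = ",".join(self.grammar)
        return yaml.safe_dump(data, sort_keys=True)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


#: A complete ORF is preferred over a longer headless open frame as long as it
#: reaches this fraction of the open frame's length: start/stop evidence beats
#: a small length edge, but a genuinely longer partial precursor still wins.
COMPLETE_ORF_MARGIN = 0.8


def select_pipeline_orf(orfs):
    """Precursor ORF choice for pipeline runs.

    The bare longest-ORF rule is degenerate on short transcripts whose
    reverse strand happens to be stop-free: a fully open frame outranks the
    true complete ORF by a residue or two. Prefer the longest complete ORF
    whenever it reaches ``COMPLETE_ORF_MARGIN`` of the longest call.
    """
    best = select_precursor_orf(orfs)
    if best.completeness == "complete":
        return best
    completes = [o for o in orfs if o.completeness == "complete"]
    if completes:
        best_complete = select_precursor_orf(completes)
        if best_complete.length_aa >= COMPLETE_ORF_MARGIN * best.length_aa:
            return best_complete
    return best


def run_pipeline(config: PipelineConfig) -> dict:
    """Run orfs -> signals -> peptides -> classify -> conserve -> quant.

    Optional stages (classification without annotations, quantification
    without counts) are skipped with a logged notice. Returns a report dict
    with the paths written. Stage failures abort with the stage name and the
    offending record in the exception message.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"outputs": {}}
    timings: dict[str, float] = {}

    def stage(name):
        log.info("stage %s", name)
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = time.perf_counter() - timings[name]
        log.info("stage %s done in %.2fs", name, timings[name])

    # --- orfs ---------------------------------------------------------
    stage("orfs")
    transcripts = read_fasta(config.fasta)
    precursors = {}
    orf_rows = []
    for t in transcripts:
        try:
            orfs = find_orfs(t, min_aa=config.min_orf_aa)
            if not orfs:
                continue
            chosen = select_pipeline_orf(orfs)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"stage orfs failed on {t.id}: {exc}") from exc
        precursors[t.id] = (t, chosen)
        orf_rows.append(
            {
                "transcript_id": t.id, "frame": chosen.frame,
                "start_nt": chosen.start_nt, "end_nt": chosen.end_nt,
                "length_aa": chosen.length_aa, "completeness": chosen.completeness,
            }
        )
    orf_path = out / "orfs.tsv"
    pd.DataFrame(orf_rows).to_csv(orf_path, sep="\t", index=False)
    report["outputs"]["orfs"] = str(orf_path)
    done("orfs")

    # --- signals ------------------------------------------------------
    stage("signals")
    external = read_signal_table(config.signals) if config.signals else {}
    signals = {}
    for tid, (t, orf) in precursors.items():
        if tid in external:
            signals[tid] = SignalPrediction(external[tid], "external", 1.0)
        else:
            signals[tid] = predict_signal_peptide(orf.protein)
    done("signals")

    # --- peptides -----------------------------------------------------
    stage("peptides")
    models = []
    peptides_by_tid = {}
    pep_rows = []
    for tid, (t, orf) in precursors.items():
        try:
            model, peps = process_precursor(
                orf.protein, signals[tid], config.grammar, config.monobasic_r
            )
        except Exception as exc:
            raise RuntimeError(f"stage peptides failed on {tid}: {exc}") from exc
        model = type(model)(
            protein=model.protein, signal=model.signal,
            propeptide=model.propeptide, sites=model.sites,
            orf=orf, transcript_length=t.length_nt,
        )
        models.append(model)
        peptides_by_tid[tid] = peps
        for p in peps:
            pep_rows.append(
                {
                    "transcript_id": tid, "family": "", "start_aa": p.start_aa,
                    "end_aa": p.end_aa, "sequence": p.sequence,
                    "amidated": p.amidated, "pyroglutamate": p.pyroglutamate,
                    "evidence": "",
                }
            )
    pep_path = out / "peptides.tsv"
    gff_path = out / "features.gff3"
    write_gff3_features(models, peptides_by_tid, gff_path)
    report["outputs"]["gff3"] = str(gff_path)
    done("peptides")

    # --- classify -----------------------------------------------------
    stage("classify")
    library = load_motif_library(config.motif_library)
    fam_rows = []
    pep_families = {}
    for tid, peps in peptides_by_tid.items():
        for p in peps:
            hits = match_peptide_motifs(p, library, subject_id=tid)
            primary = assign_family(
                motif_hits=hits, subject_id=tid, motif_library=library
            )
            pep_families[(tid, p.start_aa)] = primary.family
    for row in pep_rows:
        row["family"] = pep_families.get((row["transcript_id"], row["start_aa"]), "")
        row["evidence"] = "motif" if row["family"] not in ("", "unclassified") else ""
    write_peptide_table(pep_rows, pep_path)
    report["outputs"]["peptides"] = str(pep_path)
    if config.annotations:
        records = read_annotation_table(config.annotations)
        for hit in classify_annotation_records(records):
            fam_rows.append(
                {
                    "subject_id": hit.subject_id, "family": hit.family,
                    "evidence": hit.evidence, "detail": hit.detail,
                    "secondary": ";".join(hit.secondary),
                }
            )
        fam_path = out / "families.tsv"
        pd.DataFrame(fam_rows).to_csv(fam_path, sep="\t", index=False)
        report["outputs"]["families"] = str(fam_path)
    else:
        log.info("stage classify: no annotation table; transcript-level "
                 "classification skipped")
    done("classify")

    # --- conserve -----------------------------------------------------
    stage("conserve")
    cons_rows = []
    by_family: dict[str, list] = {}
    for (tid, start), fam in pep_families.items():
        if fam in ("", "unclassified"):
            continue
        pep = next(p for p in peptides_by_tid[tid] if p.start_aa == start)
        by_family.setdefault(fam, []).append(pep)
    for fam, peps in sorted(by_family.items()):
        if len(peps) < 2:
            continue
        lengths = [len(p.sequence) for p in peps]
        modal = max(sorted(set(lengths)), key=lengths.count)
        usable = [p for p in peps if abs(len(p.sequence) - modal) <= 5]
        if len(usable) < 2:
            continue
        motif = consensus_motif(
            [p.sequence for p in usable], [p.amidated for p in usable]
        )
        cons_rows.append(
            {
                "family": fam, "members": len(usable), "consensus": motif.motif,
                "invariant_positions": motif.invariant_positions,
                "columns": len(motif.columns),
            }
        )
    cons_path = out / "consensus.tsv"
    pd.DataFrame(cons_rows).to_csv(cons_path, sep="\t", index=False)
    report["outputs"]["consensus"] = str(cons_path)
    done("conserve")

    # --- quant --------------------------------------------------------
    stage("quant")
    if config.counts:
        matrix = _read_counts_tsv(config.counts, precursors)
        records = quantify(matrix, alpha=config.alpha)
        quant_path = out / "expression.tsv"
        summarize(records).to_csv(quant_path, sep="\t", index=False)
        report["outputs"]["expression"] = str(quant_path)
    else:
        log.info("stage quant: no counts supplied; skipped")
    done("quant")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": yaml.safe_load(config.to_yaml()),
        "inputs": {
            label: _sha256(path)
            for label, path in [
                ("fasta", config.fasta), ("annotations", config.annotations),
                ("signals", config.signals), ("counts", config.counts),
            ]
            if path
        },
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    manifest_path = out / "manifest.json"
    stable = dict(manifest)
    stable.pop("timings_s")
    manifest_path.write_text(json.dumps(stable, indent=2, sort_keys=True) + "\n")
    report["outputs"]["manifest"] = str(manifest_path)
    report["timings_s"] = manifest["timings_s"]
    return report


def _read_counts_tsv(path: str, precursors: dict) -> CountMatrix:
    """Counts TSV: a '#lib_size' header line then transcript_id x samples.

    Sample columns are named like M_BR/F_BR/M_ES/F_ES; tissue is inferred
    from the BR/ES suffix and sex from the M/F prefix.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#lib_size"):
        raise ConfigError("counts TSV must start with a '#lib_size' line")
    import io

    header = lines[0].split("\t")[1:]
    lib_size = {}
    for item in header:
        name, _, value = item.partition("=")
        lib_size[name] = int(value)
    df = pd.read_csv(io.StringIO("\n".join(lines[1:])), sep="\t", index_col=0)
    samples = []
    for name in df.columns:
        sex = "M" if name.upper().startswith("M") else "F"
        tissue = "brain" if name.upper().endswith("BR") else "eyestalk"
        samples.append(SampleInfo(name, tissue, sex))
    lengths = {tid: t.length_nt for tid, (t, _) in precursors.items()}
    for tid in df.index:
        lengths.setdefault(tid, 1)
    return CountMatrix(
        samples=samples,
        counts=df.T.astype(int),
        lib_size=lib_size,
        lengths=lengths,
    )
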