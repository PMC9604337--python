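"""Orchestration of the full comparative analysis over N genomes.

``run_compare`` reads annotated mitogenomes (GenBank flat files or
FASTA + feature-table TSV pairs), computes every stage that its inputs
support — composition by region, gene/junction accounting, codon usage,
control-region motif scans, and (when per-gene alignments are supplied)
divergence statistics — and writes one TSV per published-table analogue
plus a JSON sidecar of the parameters used.  Stages whose inputs are
missing are skipped with a logged warning; partial results are still
written.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import (classify_codons, junction_gaps, shared_junctions,
                         spacer_overlap_report, strand_census)
from .codons import count_codons, rscu
from .composition import composition_by_region
from .control_region import scan_control_region
from .divergence import gene_divergence_table, sliding_window_pi
from .io import extract_region, read_alignment, read_feature_table, read_genbank
from .model import MitocompError, MitogenomeRecord

log = logging.getLogger("mitocomp")


@dataclass
class RunConfig:
    genbank_paths: list[Path] = field(default_factory=list)
    fasta_table_pairs: list[tuple[Path, Path]] = field(default_factory=list)
    alignment_dir: Path | None = None       # per-gene aligned FASTA: <gene>.fasta
    out_dir: Path = Path("mitocomp_out")
    include_cr_junctions: bool = False
    use_declared_ign: bool = False
    omega_aggregation: str = "ratio_of_means"
    window: int = 100
    step: int = 25
    cr_min_period: int = 10
    cr_min_copies: float = 1.9
    cr_min_identity: float = 0.85

    def validate(self) -> None:
        for p in [*self.genbank_paths,
                  *(q for pair in self.fasta_table_pairs for q in pair)]:
            if not Path(p).exists():
                raise MitocompError(f"input path does not exist: {p}")
        if self.alignment_dir is not None and not Path(self.alignment_dir).is_dir():
            raise MitocompError(f"alignment directory does not exist: {self.alignment_dir}")


def load_genomes(config: RunConfig) -> list[MitogenomeRecord]:
    records = [read_genbank(p) for p in config.genbank_paths]
    records += [read_feature_table(fa, tsv)
                for fa, tsv in config.fasta_table_pairs]
    if not records:
        raise MitocompError("no genomes supplied")
    return records


def run_compare(config: RunConfig) -> dict[str, Path]:
    """Run every supported stage; returns {output name: written path}."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = load_genomes(config)
    written: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out / f"{name}.tsv"
        frame.to_csv(path, sep="\t", float_format="%.6g")
        written[name] = path

    # gene table with junction gaps (published-gene-table analogue)
    gene_rows = []
    for rec in records:
        gaps = {g.downstream: g.ign
                for g in junction_gaps(rec, config.use_declared_ign)}
        for f in rec.features:
            gene_rows.append({
                "record": rec.id, "gene": f.name, "class": f.gene_class,
                "from": f.start, "to": f.end, "size": f.span(rec.length),
                "ign": gaps.get(f.name, ""), "start_codon": f.start_codon or "",
                "stop_codon": f.stop_codon or "", "direction": f.strand,
            })
    emit("gene_table", pd.DataFrame(gene_rows).set_index(["record", "gene"]))

    so_rows = []
    for rec in records:
        rep = spacer_overlap_report(rec, config.include_cr_junctions,
                                    config.use_declared_ign)
        census = strand_census(rec)
        so_rows.append({
            "record": rec.id,
            "spacer_count": rep.spacer_count, "spacer_total_bp": rep.spacer_total_bp,
            "spacer_max_bp": rep.spacer_max_bp,
            "overlap_count": rep.overlap_count,
            "overlap_total_bp": rep.overlap_total_bp,
            "overlap_max_bp": rep.overlap_max_bp,
            "genes_J": census["J"], "genes_N": census["N"],
        })
    emit("spacer_overlap", pd.DataFrame(so_rows).set_index("record"))

    try:
        shared = shared_junctions(records, config.use_declared_ign)
        with open(out / "shared_junctions.json", "w") as fh:
            json.dump({kind: [{"upstream": g.upstream, "downstream": g.downstream,
                               "ign": g.ign} for g in gaps]
                       for kind, gaps in shared.items()}, fh, indent=2)
        written["shared_junctions"] = out / "shared_junctions.json"
    except MitocompError as exc:
        log.warning("shared-junction stage skipped: %s", exc)

    with_seq = [r for r in records if r.sequence is not None]
    comp_rows, codon_rows, rscu_rows, cr_rows = [], [], [], []
    for rec in with_seq:
        table = composition_by_region(rec).reset_index()
        table.insert(0, "record", rec.id)
        comp_rows.append(table)
        for c in classify_codons(rec):
            codon_rows.append({"record": rec.id, "gene": c.gene,
                               "start_codon": c.start_codon,
                               "start_typical": c.start_typical,
                               "stop_codon": c.stop_codon,
                               "stop_complete": c.stop_complete})
        pcgs = [extract_region(rec, f) for f in rec.features
                if f.gene_class == "PCG"]
        usage = rscu(count_codons(pcgs)).as_frame()
        usage.insert(0, "record", rec.id)
        rscu_rows.append(usage)
        try:
            hits = scan_control_region(
                rec, min_period=config.cr_min_period,
                min_copies=config.cr_min_copies,
                min_identity=config.cr_min_identity)
        except KeyError as exc:
            log.warning("CR scan skipped for %s: %s", rec.id, exc)
            continue
        for h in hits["microsatellites"] + hits["tandem_repeats"]:
            cr_rows.append({"record": rec.id, "type": "repeat",
                            "motif": h.motif, "period": h.period,
                            "copies": round(h.copies, 2),
                            "identity": round(h.identity, 3),
                            "start": h.start, "end": h.end})
        for h in hits["stem_loops"]:
            cr_rows.append({"record": rec.id, "type": "stem_loop",
                            "motif": h.loop_seq, "period": h.stem_len,
                            "copies": float("nan"),
                            "identity": h.motif_match,
                            "start": h.arm5_start, "end": h.arm3_end})
    if comp_rows:
        emit("composition", pd.concat(comp_rows).set_index(["record", "region"]))
        emit("codon_classification",
             pd.DataFrame(codon_rows).set_index(["record", "gene"]))
        emit("rscu", pd.concat(rscu_rows).set_index(["record", "codon"]))
        if cr_rows:
            emit("cr_hits", pd.DataFrame(cr_rows).set_index(["record", "type"]))
    else:
        log.warning("no sequences supplied; composition/codon/CR stages skipped")

    if config.alignment_dir is not None:
        alignments = {p.stem: read_alignment(p, codon_aware=True)
                      for p in sorted(Path(config.alignment_dir).glob("*.fasta"))}
        if len(alignments) == 0:
            log.warning("alignment directory empty; divergence stage skipped")
        else:
            table = gene_divergence_table(alignments, config.omega_aggregation)
            emit("divergence", table)
            win_rows = []
            for gene, aln in alignments.items():
                for start, mid, pi in sliding_window_pi(
                        aln, config.window, config.step).per_window:
                    win_rows.append({"gene": gene, "start": start,
                                     "midpoint": mid, "pi": pi})
            emit("windows", pd.DataFrame(win_rows).set_index(["gene", "start"]))
    else:
        log.warning("no alignments supplied; divergence stage skipped")

    params = {k: str(v) if isinstance(v, Path) else v
              for k, v in vars(config).items()
              if not isinstance(v, list)}
    params["version"] = __version__
    params["records"] = [r.id for r in records]
    with open(out / "params.json", "w") as fh:
        json.dump(params, fh, indent=2, default=str)
    written["params"] = out / "params.json"
    return written
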