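"""Readers and writers for annotated mitogenomes and alignments.

GenBank flat files and FASTA go through Biopython; the canonical tabular
fixture format is a feature-table TSV with columns
``name  class  start  end  strand  [start_codon  stop_codon  ign]``
so published gene tables can be committed verbatim as test data.
"""
from __future__ import annotations

import csv
import warnings
from pathlib import Path

from Bio import AlignIO, SeqIO

from .model import Alignment, GeneFeature, MitocompError, MitogenomeRecord

# Normalisation of common GenBank gene/product labels to the comparative
# mitogenomics vocabulary (nad2, cox1, trnL1, rrnS, CR, ...).
_PCG_ALIASES = {
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4", "nd4l": "nad4L",
    "nd5": "nad5", "nd6": "nad6", "nad4l": "nad4L",
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "cox1": "cox1", "cox2": "cox2", "cox3": "cox3",
    "atp6": "atp6", "atp8": "atp8", "atpase6": "atp6", "atpase8": "atp8",
    "cytb": "cytb", "cob": "cytb", "cyb": "cytb",
    "nad1": "nad1", "nad2": "nad2", "nad3": "nad3", "nad4": "nad4",
    "nad5": "nad5", "nad6": "nad6",
}
_PRODUCT_PCG = {
    "nadh dehydrogenase subunit 1": "nad1", "nadh dehydrogenase subunit 2": "nad2",
    "nadh dehydrogenase subunit 3": "nad3", "nadh dehydrogenase subunit 4": "nad4",
    "nadh dehydrogenase subunit 4l": "nad4L", "nadh dehydrogenase subunit 5": "nad5",
    "nadh dehydrogenase subunit 6": "nad6",
    "cytochrome c oxidase subunit 1": "cox1", "cytochrome c oxidase subunit i": "cox1",
    "cytochrome c oxidase subunit 2": "cox2", "cytochrome c oxidase subunit ii": "cox2",
    "cytochrome c oxidase subunit 3": "cox3", "cytochrome c oxidase subunit iii": "cox3",
    "atp synthase f0 subunit 6": "atp6", "atp synthase f0 subunit 8": "atp8",
    "cytochrome b": "cytb",
}
_AA3 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "gln": "Q",
    "glu": "E", "gly": "G", "his": "H", "ile": "I", "leu": "L", "lys": "K",
    "met": "M", "phe": "F", "pro": "P", "ser": "S", "thr": "T", "trp": "W",
    "tyr": "Y", "val": "V",
}


def normalize_gene_name(raw: str, gene_class: str | None = None) -> str | None:
    """Map a GenBank label to the standard symbol; None when unrecognised."""
    label = raw.strip()
    low = label.lower().replace("-", "").replace("_", "").replace(" ", "")
    if low in _PCG_ALIASES:
        return _PCG_ALIASES[low]
    if label.lower() in _PRODUCT_PCG:
        return _PRODUCT_PCG[label.lower()]
    if low in {"rrnl", "lrrna", "16s", "16srrna", "16sribosomalrna", "largesubunitribosomalrna"}:
        return "rrnL"
    if low in {"rrns", "srrna", "12s", "12srrna", "12sribosomalrna", "smallsubunitribosomalrna"}:
        return "rrnS"
    if low in {"cr", "dloop", "controlregion", "atrichregion", "at-richregion"}:
        return "CR"
    stripped = label.strip()
    # "tRNA-Leu(UUR)" style labels before the bare "trnL" style: a genuine
    # trnA/trnN symbol has an amino-acid letter right after "trn", while the
    # long form has a separator after "trna"
    if (stripped.lower().startswith("trna")
            and len(stripped) > 4 and not stripped[4].isalnum()):
        return _trna_symbol(stripped[4:].lstrip("-_ "))
    if low.startswith("trn"):
        return _trna_symbol(stripped[3:].lstrip("-_ "))
    return None


def _trna_symbol(rest: str) -> str | None:
    """'Leu(UUR)' / 'L1' / 'S' / 'Ile' -> trnL2 / trnL1 / trnS / trnI."""
    rest = rest.strip()
    if not rest:
        return None
    anticodon = None
    if "(" in rest:
        rest, _, tail = rest.partition("(")
        anticodon = tail.rstrip(")").upper().replace("T", "U")
        rest = rest.strip()
    low = rest.lower()
    digit = ""
    if low and low[-1] in "12":
        digit = low[-1]
        low = low[:-1]
    if low in _AA3:
        aa = _AA3[low]
    elif len(low) == 1 and low.upper() in _AA3.values():
        aa = low.upper()
    else:
        return None
    if aa == "L" and not digit and anticodon:
        digit = "1" if anticodon in {"UAG", "CUN", "NAG"} else "2"
    if aa == "S" and not digit and anticodon:
        digit = "1" if anticodon in {"UCU", "GCU", "AGN", "NCU"} else "2"
    return f"trn{aa}{digit}"


_CLASS_BY_FEATURE_TYPE = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                          "D-loop": "CR", "misc_feature": None}


def read_genbank(path: str | Path) -> MitogenomeRecord:
    """Read an annotated mitogenome from a GenBank flat file.

    Features carry 1-based inclusive coordinates; the annotated forward
    strand becomes J and the complement N.  Unrecognised gene labels are
    kept raw with a warning.
    """
    path = Path(path)
    try:
        seqrec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise MitocompError(f"{path}: malformed GenBank file: {exc}") from exc
    features = []
    for feat in seqrec.features:
        if feat.type not in _CLASS_BY_FEATURE_TYPE:
            continue
        quals = feat.qualifiers
        raw = (quals.get("gene") or quals.get("product") or quals.get("note") or [""])[0]
        gene_class = _CLASS_BY_FEATURE_TYPE[feat.type]
        name = normalize_gene_name(raw)
        if name == "CR":
            gene_class = "CR"
        if gene_class is None:
            if name is None:
                continue  # unannotated misc_feature
            gene_class = "CR" if name == "CR" else None
        if name is None:
            warnings.warn(f"{path.name}: unrecognised gene label {raw!r}; kept as-is",
                          stacklevel=2)
            name = raw
        if gene_class is None:
            continue
        start = int(feat.location.start) + 1
        end = int(feat.location.end)
        strand = "N" if feat.location.strand == -1 else "J"
        features.append(GeneFeature(name=name, gene_class=gene_class,
                                    start=start, end=end, strand=strand))
    features.sort(key=lambda f: f.start)
    circular = "circular" in (seqrec.annotations.get("topology", ""),)
    return MitogenomeRecord(id=seqrec.id, length=len(seqrec.seq),
                            sequence=str(seqrec.seq), circular=circular or True,
                            features=features)


_TABLE_COLUMNS = ("name", "class", "start", "end", "strand",
                  "start_codon", "stop_codon", "ign")


def read_feature_table(seq_path: str | Path, table_path: str | Path) -> MitogenomeRecord:
    """Assemble a record from a FASTA sequence plus a feature-table TSV."""
    seqrec = SeqIO.read(str(seq_path), "fasta")
    features = load_feature_table(table_path)
    return MitogenomeRecord(id=seqrec.id, length=len(seqrec.seq),
                            sequence=str(seqrec.seq), circular=True,
                            features=features)


def load_feature_table(table_path: str | Path) -> list[GeneFeature]:
    """Parse a feature-table TSV into GeneFeatures (no sequence required)."""
    features = []
    with open(table_path) as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t")
        if reader.fieldnames is None or "name" not in reader.fieldnames:
            raise MitocompError(f"{table_path}: missing header with 'name' column")
        for i, row in enumerate(reader, start=2):
            try:
                start = int(row["start"])
                end = int(row["end"])
            except (KeyError, ValueError) as exc:
                raise MitocompError(f"{table_path}:{i}: bad coordinates: {exc}") from exc
            if start < 1 or end < 1:
                raise MitocompError(
                    f"{table_path}:{i}: coordinates are 1-based inclusive, got "
                    f"{start}..{end}")
            ign = row.get("ign") or None
            features.append(GeneFeature(
                name=row["name"].strip(),
                gene_class=row["class"].strip(),
                start=start, end=end,
                strand=(row.get("strand") or "J").strip(),
                start_codon=(row.get("start_codon") or "").strip() or None,
                stop_codon=(row.get("stop_codon") or "").strip() or None,
                declared_ign=int(ign) if ign is not None else None,
            ))
    return features


def table_record(table_path: str | Path, record_id: str,
                 length: int | None = None) -> MitogenomeRecord:
    """Sequence-less record from a feature table; length defaults to the
    largest end coordinate (the control region closes the circle in the
    published tables)."""
    features = load_feature_table(table_path)
    if length is None:
        length = max(f.end for f in features)
    return MitogenomeRecord(id=record_id, length=length, sequence=None,
                            circular=True, features=features)


def write_feature_table(record: MitogenomeRecord, table_path: str | Path) -> None:
    with open(table_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TABLE_COLUMNS)
        for f in record.features:
            writer.writerow([
                f.name, f.gene_class, f.start, f.end, f.strand,
                f.start_codon or "", f.stop_codon or "",
                "" if f.declared_ign is None else f.declared_ign,
            ])


def write_fasta(record: MitogenomeRecord, path: str | Path) -> None:
    if record.sequence is None:
        raise MitocompError(f"{record.id}: no sequence to write")
    with open(path, "w") as fh:
        fh.write(f">{record.id}\n")
        for i in range(0, record.length, 70):
            fh.write(record.sequence[i:i + 70] + "\n")


def read_alignment(path: str | Path, codon_aware: bool = False) -> Alignment:
    """Read an aligned FASTA file."""
    msa = AlignIO.read(str(path), "fasta")
    return Alignment(ids=[r.id for r in msa], rows=[str(r.seq) for r in msa],
                     codon_aware=codon_aware)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, row in zip(aln.ids, aln.rows):
            fh.write(f">{name}\n{row}\n")


def extract_region(record: MitogenomeRecord, feature: GeneFeature) -> str:
    """The feature's sequence read 5'->3' on its coding strand.

    N-strand features are reverse-complemented; origin-spanning features wrap
    across position ``length`` -> 1 on circular records.
    """
    from .model import reverse_complement
    if record.sequence is None:
        raise MitocompError(f"{record.id}: record carries no sequence")
    if feature.spans_origin:
        if not record.circular:
            raise MitocompError(
                f"{feature.name}: end < start on a non-circular record")
        seq = record.sequence[feature.start - 1:] + record.sequence[:feature.end]
    else:
        seq = record.sequence[feature.start - 1:feature.end]
    return reverse_complement(seq) if feature.strand == "N" else seq
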