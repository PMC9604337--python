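"""Bundled gryllotalpid gene tables.

The package ships the published mitogenome organisation of the six mole
crickets (Gryllotalpidae) as feature-table TSVs, so every coordinate-level
statistic — junction gaps, spacer/overlap accounting, strand census, region
sizes — runs without any download.  Sequence-level statistics need the
deposited nucleotide sequences, which are not redistributed here.
"""
from __future__ import annotations

from importlib import resources

from .io import table_record
from .model import MitogenomeRecord

#: species key -> (display name, accession, genome length bp)
SPECIES = {
    "gryllotalpa_henana": ("Gryllotalpa henana", "ON243749", 15504),
    "g_orientalis_chn": ("G. orientalis (China)", "ON210982", 15497),
    "g_orientalis_kr": ("G. orientalis (Korea)", "AY660929", 15521),
    "g_pluvialis": ("G. pluvialis", "EU938371", 15525),
    "gryllotalpa_sp": ("Gryllotalpa sp.", "MK903562", 15506),
    "g_unispina": ("G. unispina", "KC894752", 15513),
}


def species_keys() -> list[str]:
    return list(SPECIES)


def load_reference(key: str) -> MitogenomeRecord:
    """Sequence-less record for one of the six bundled gene tables."""
    if key not in SPECIES:
        raise KeyError(f"unknown species key {key!r}; choose from {list(SPECIES)}")
    _, accession, length = SPECIES[key]
    ref = resources.files("mitocomp.data.table3").joinpath(f"{key}.tsv")
    with resources.as_file(ref) as path:
        return table_record(path, record_id=accession, length=length)


def load_all_references() -> dict[str, MitogenomeRecord]:
    return {key: load_reference(key) for key in SPECIES}
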