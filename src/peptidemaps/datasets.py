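"""Packaged reference tables and fixtures.

The receptor annotation mirrors the published 38-gene neuropeptide receptor
overview (gene, family, QC metrics, compartment means); the gene lists give
the 13 ionotropic and 23 metabotropic neurotransmitter receptor genes used
for the evolutionary contrasts; the PET table lists the 16 neurotransmitter
maps with their signaling class; the 455-region atlas is a synthetic
geometry (400 cortical + 54 subcortical parcels + 1 hypothalamus) matching
the whole-brain parcellation's structure counts and strata.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .atlas import RegionAtlas, ReceptorAnnotation


def _data_path(name: str):
    return resources.files("peptidemaps.data").joinpath(name)


def load_receptor_annotation() -> ReceptorAnnotation:
    """The packaged 38-gene receptor annotation table."""
    with resources.as_file(_data_path("receptor_annotation.tsv")) as p:
        return ReceptorAnnotation(pd.read_csv(p, sep="\t"))


def load_neurotransmitter_genes() -> pd.DataFrame:
    """Ionotropic / metabotropic neurotransmitter receptor gene lists."""
    with resources.as_file(_data_path("neurotransmitter_genes.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_pet_receptors() -> pd.DataFrame:
    """The 16 PET neurotransmitter maps with signaling-class labels."""
    with resources.as_file(_data_path("pet_receptors.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_atlas455() -> RegionAtlas:
    """Synthetic 455-region whole-brain atlas fixture (400 + 54 + 1)."""
    with resources.as_file(_data_path("atlas455.tsv")) as p:
        return RegionAtlas(pd.read_csv(p, sep="\t"))
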