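"""Packaged habu-snake (Protobothrops) venom datasets.

The relative-abundance table, pairwise protein-similarity matrix, published
per-family phylogenetic-signal values, and intraperitoneal LD50 values for
ten Protobothrops venom samples (eight adult taxa, one subadult, and a
second geographic sample of P. mucrosquamatus).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .composition import AbundanceTable

__all__ = [
    "habu_abundance",
    "habu_psc_matrix",
    "habu_signal_table",
    "habu_ld50",
    "PROTEIN_FAMILIES",
    "ABUNDANT_FAMILIES",
    "TRACE_FAMILIES",
    "CURRENT_STUDY_ADULTS",
    "ADULT_TAXA",
    "SIGNAL_TAXA",
]

#: the 14 protein families scored across all venoms
PROTEIN_FAMILIES = [
    "SVMP", "SVSP", "PLA2", "CRISP", "Disintegrin", "BPP/CNP", "CTL",
    "LAAO", "VEGF", "NGF", "PDE", "5NT", "PLB", "QC",
]

#: the three dominant enzyme families
ABUNDANT_FAMILIES = ["SVMP", "SVSP", "PLA2"]

#: trace families (average abundance < 0.3%)
TRACE_FAMILIES = ["NGF", "PLB", "5NT", "QC"]

#: the five adult venoms quantified in the originating study
CURRENT_STUDY_ADULTS = [
    "P. cornutus",
    "P. jerdonii",
    "P. mucrosquamatus",
    "P. sieversorum",
    "P. xiangchengensis",
]

#: the eight adult taxa used for the cross-taxon CV analysis
#: (mainland P. mucrosquamatus sample; Taiwan sample and the subadult
#: P. mangshanensis excluded)
ADULT_TAXA = CURRENT_STUDY_ADULTS + ["P. elegans", "P. flavoviridis", "P. kelomohy"]

#: the nine taxa screened by the >1%-in->=5-taxa trait filter
SIGNAL_TAXA = ADULT_TAXA + ["P. mangshanensis (subadult)"]


def _path(name: str):
    return resources.files(__package__) / "data" / name


def habu_abundance() -> AbundanceTable:
    """Taxa x family percent-abundance table (missing = not detected)."""
    with resources.as_file(_path("habu_abundance.csv")) as p:
        return AbundanceTable.read_csv(p)


def habu_psc_matrix() -> pd.DataFrame:
    """Pairwise protein similarity coefficients (%) of the five adult venoms."""
    with resources.as_file(_path("habu_psc.csv")) as p:
        return pd.read_csv(p, index_col=0)


def habu_signal_table() -> pd.DataFrame:
    """Published Blomberg's K and permutation p per venom trait."""
    with resources.as_file(_path("habu_signal.csv")) as p:
        return pd.read_csv(p, index_col=0)


def habu_ld50() -> pd.DataFrame:
    """Intraperitoneal mouse LD50 (ug/g) with 95% confidence limits."""
    with resources.as_file(_path("habu_ld50.csv")) as p:
        return pd.read_csv(p, index_col=0)
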