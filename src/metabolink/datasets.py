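"""Bundled example data.

The shipped inventory is a SYNTHETIC stand-in: a constructed list of 90
metabolite names of the kind quantified by 1H-NMR in neural cell extracts,
with compound-class annotations (8 classes over the 88 classified entries;
2 entries are unassigned). It exists so inventory-level operations are
demonstrable and testable without the original study data; it is not a
measured dataset.
"""
from __future__ import annotations

from pathlib import Path

from .io import AnnotationTable, read_annotation_table

_DATA_DIR = Path(__file__).parent / "data"


def inventory_path() -> Path:
    return _DATA_DIR / "neural_metabolite_inventory_synthetic.csv"


def load_inventory() -> AnnotationTable:
    """Load the synthetic 90-metabolite inventory annotation table."""
    return read_annotation_table(inventory_path())
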